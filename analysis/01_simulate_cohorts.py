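"""Generate the synthetic cohorts used throughout the analysis.

Writes a study-sized longitudinal cohort (67 subjects, 5 OGTT cells blanked
at random, as in the emulated study) and a large calibration cohort
(1000 subjects) whose marginal means anchor every downstream check.
"""

import argparse
from pathlib import Path

import numpy as np

from glucopcs.io import write_cohort
from glucopcs.simulate import GeneratorConfig, generate_cohort, inject_missingness


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    study = generate_cohort(GeneratorConfig(n_subjects=67, seed=args.seed))
    study = inject_missingness(study, 5, seed=args.seed + 1)
    write_cohort(study, args.out_dir / "cohort_study.csv")

    large = generate_cohort(GeneratorConfig(n_subjects=1000, seed=args.seed + 10))
    write_cohort(large, args.out_dir / "cohort_large.csv")

    v1 = large[large.visit == "V1"]
    t = GeneratorConfig().targets["V1"]
    print(f"seed {args.seed}: study cohort {len(study)} rows "
          f"({int(study[[c for c in study.columns if c[0] in 'gic' and c != 'gdm']].isna().sum().sum())} missing cells), large cohort {len(large)} rows")
    print(f"large-cohort V1 calibration: fasting glucose {v1.g0.mean():.1f} mg/dl "
          f"(target {t.g_mean[0]}), log fasting insulin {np.log(v1.i0).mean():.2f} "
          f"(target {t.ln_i_mean[0]}), GDM prevalence {(v1.gdm == 'GDM').mean():.1%}")


if __name__ == "__main__":
    main()
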