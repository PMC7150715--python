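"""Derive the loading matrix and project the rescaled scores PCS1-3.

Loadings are derived once from the large calibration cohort (the stand-in
for the original derivation population) and then applied, together with
that cohort's standardization statistics, to the study-sized cohort —
mirroring the transfer of previously derived eigenvectors to a new sample.
"""

import argparse
from pathlib import Path

import pandas as pd

from glucopcs.io import read_cohort
from glucopcs.pcs import (
    build_feature_matrix,
    derive_loadings,
    project_scores,
    read_loadings,
    score_orthogonality_check,
    write_loadings,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    large = read_cohort(args.out_dir / "cohort_large.csv")
    features = build_feature_matrix(large)
    loadings = derive_loadings(features)
    write_loadings(loadings, args.out_dir / "loadings.csv")
    features.stats.to_frame().to_csv(
        args.out_dir / "standardization_stats.csv", index=False, float_format="%.12g"
    )
    scores_large = project_scores(features, loadings)
    pd.concat([large[["subject_id", "visit", "gdm"]], scores_large.pcs], axis=1).to_csv(
        args.out_dir / "scores_large.csv", index=False, float_format="%.12g"
    )

    fracs = loadings.variance_fractions
    print(f"derivation cohort: top-3 components explain {100 * fracs.sum():.1f}% "
          f"of the variance ({', '.join(f'{100*f:.1f}%' for f in fracs)}); "
          f"max |score correlation| {score_orthogonality_check(scores_large):.1e}")

    study_path = args.out_dir / "cohort_study_completed.csv"
    study = read_cohort(study_path if study_path.exists()
                        else args.out_dir / "cohort_study.csv")
    ext = read_loadings(args.out_dir / "loadings.csv")
    feats_study = build_feature_matrix(study, stats=features.stats)
    scores_study = project_scores(feats_study, ext)
    pd.concat([study[["subject_id", "visit", "gdm"]], scores_study.pcs], axis=1).to_csv(
        args.out_dir / "scores_study.csv", index=False, float_format="%.12g"
    )
    for visit in ("V1", "V2", "V3"):
        m = scores_study.pcs[(study.visit == visit).to_numpy()].mean()
        print(f"study cohort {visit}: PCS1 {m['PCS1']:.2f}, PCS2 {m['PCS2']:.2f}, "
              f"PCS3 {m['PCS3']:.2f}")


if __name__ == "__main__":
    main()
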