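"""Associations of the scores with glucometabolic indices and visit dynamics.

Builds the Spearman correlation map (per visit and pooled), the ISSI-2
regression on the three scores, and the random-intercept visit model of
PCS1, reporting the directions the score system is expected to show.
"""

import argparse
from pathlib import Path

import pandas as pd

from glucopcs.analysis import fit_issi2_model, lmm_random_intercept, spearman_map
from glucopcs.io import read_cohort


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_cohort(args.out_dir / "cohort_large.csv")
    panels = pd.read_csv(args.out_dir / "indices_large.csv")
    scores = pd.read_csv(args.out_dir / "scores_large.csv")
    pcs = scores[["PCS1", "PCS2", "PCS3"]]
    numeric = panels.drop(columns=["subject_id", "visit", "flags"])

    cmap = spearman_map(pcs, numeric, visit=cohort["visit"])
    cmap.to_csv(args.out_dir / "correlation_map.csv", index=False, float_format="%.4g")
    byv1 = cmap[cmap.visit == "V1"].set_index(["score", "index"])
    print("V1 Spearman correlations: "
          f"PCS1-Matsuda {byv1.loc[('PCS1', 'matsuda'), 'rho']:+.2f}, "
          f"PCS1-Sec-total {byv1.loc[('PCS1', 'sec_total'), 'rho']:+.2f}, "
          f"PCS2-mean glucose {byv1.loc[('PCS2', 'g_mean'), 'rho']:+.2f}, "
          f"PCS3-HOMA-IR {byv1.loc[('PCS3', 'homa_ir'), 'rho']:+.2f}")

    v1 = (cohort.visit == "V1").to_numpy()
    model = fit_issi2_model(numeric.loc[v1, "issi2"], pcs.loc[v1])
    print("ISSI-2 on PCS1-3 at V1: "
          + ", ".join(f"b({k}) {v:+.2f}" for k, v in model.coef.items())
          + f"; R^2 {model.r_squared:.1%}")

    lmm = lmm_random_intercept(pcs["PCS1"], cohort["visit"], cohort["subject_id"])
    print(f"PCS1 visit model (random intercept): global p {lmm.p_global:.2e}, "
          f"fixed effects {dict((k, round(v, 3)) for k, v in lmm.fe_params.items())}")


if __name__ == "__main__":
    main()
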