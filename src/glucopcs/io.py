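"""Cohort CSV interchange and the end-to-end pipeline.

A cohort is one RFC-4180 CSV with one row per subject-visit and the
canonical header (see :data:`~glucopcs.simulate.COHORT_COLUMNS`); missing
values round-trip as empty fields. :func:`run_pipeline` drives the full
sequence simulate/load → impute → index panels → feature matrix → scores →
statistical report, writing every stage's output and a log of seeds and row
counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis as an
from . import pcs as pcsmod
from .indices import panel_table
from .simulate import (
    COHORT_COLUMNS,
    MEASUREMENT_COLUMNS,
    GeneratorConfig,
    generate_cohort,
    inject_missingness,
)
from .units import UnitPolicy

log = logging.getLogger("glucopcs")

_BOOL_COLUMNS = ("primiparous", "family_history", "history_gdm")


class CohortFormatError(ValueError):
    """Raised for malformed cohort CSV input."""


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV; values keep 12 significant digits, missing cells
    are empty fields."""
    cohort[list(COHORT_COLUMNS)].to_csv(path, index=False, float_format="%.12g")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Errors name the offending columns/rows: unknown columns, missing
    mandatory columns, an empty file, and non-positive concentrations are
    all explicit failures rather than silent coercions.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CohortFormatError(f"{path}: empty cohort file") from exc
    unknown = set(df.columns) - set(COHORT_COLUMNS)
    if unknown:
        raise CohortFormatError(f"{path}: unknown columns {sorted(unknown)}")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortFormatError(f"{path}: missing mandatory columns {sorted(missing)}")
    if len(df) == 0:
        raise CohortFormatError(f"{path}: cohort has no rows")
    for col in MEASUREMENT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[(df[col].notna()) & ((vals <= 0) | vals.isna())]
        if len(bad):
            raise CohortFormatError(
                f"{path}: non-positive or non-numeric {col} at rows {list(bad[:5])}"
            )
        df[col] = vals
    for col in _BOOL_COLUMNS:
        df[col] = df[col].map(
            lambda v: v if pd.isna(v) else bool(v) if isinstance(v, (bool, np.bool_)) else str(v).lower() == "true"
        )
    return df[list(COHORT_COLUMNS)]


@dataclass
class PipelineConfig:
    """Paths, seed and toggles of one full pipeline run."""

    out_dir: str
    cohort_path: str | None = None  # None -> simulate
    loadings_path: str | None = None  # None -> derive from the cohort
    stats_path: str | None = None  # None -> self-standardize
    seed: int = 0
    generator: GeneratorConfig | None = None
    unit_policy: UnitPolicy = field(default_factory=UnitPolicy)
    m_imputations: int = 50
    ntree: int = 10_000
    run_rf: bool = True
    run_lmm: bool = True


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    analytic = asdict(config)
    analytic.pop("out_dir", None)  # where results land does not change them
    payload = json.dumps(analytic, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write a report bundle.

    Stages: obtain cohort (simulate or read) → impute missing OGTT cells →
    compute index panels → build feature matrix → obtain loadings (read or
    derive) → project scores → statistical report (visit contrasts,
    correlation map, GDM logistic models, importance, ISSI-2 model).
    Returns a manifest dict of the written files; deterministic under
    ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    manifest = {"config_hash": chash, "seed": config.seed, "files": {}}

    def save(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, index=False, float_format="%.12g")
        manifest["files"][name] = str(p)

    # stage 1: cohort
    if config.cohort_path:
        cohort = read_cohort(config.cohort_path)
        log.info("loaded cohort %s: %d rows", config.cohort_path, len(cohort))
    else:
        gen = config.generator or GeneratorConfig(seed=config.seed)
        cohort = generate_cohort(gen)
        if gen.missing_cells:
            cohort = inject_missingness(cohort, gen.missing_cells, seed=gen.seed + 1)
        log.info("simulated cohort: %d rows (seed %d)", len(cohort), gen.seed)
    n_rows = len(cohort)
    save(cohort, "cohort.csv")

    # stage 2: imputation
    n_missing = int(cohort[list(MEASUREMENT_COLUMNS)].isna().sum().sum())
    if n_missing:
        cohort = an.impute_chained(
            cohort, an.ImputationConfig(m=config.m_imputations, seed=config.seed + 2)
        )
        log.info("imputed %d missing cells (m=%d)", n_missing, config.m_imputations)
    assert len(cohort) == n_rows, "stage must not drop rows"

    # stage 3: index panels
    panels = panel_table(cohort, policy=config.unit_policy)
    save(pd.concat([cohort[["subject_id", "visit"]], panels], axis=1), "indices.csv")

    # stage 4: features, loadings, scores
    stats = None
    if config.stats_path:
        stats = pcsmod.StandardizationStats.from_frame(pd.read_csv(config.stats_path))
    features = pcsmod.build_feature_matrix(cohort, stats=stats)
    if config.loadings_path:
        loadings = pcsmod.read_loadings(config.loadings_path)
    else:
        loadings = pcsmod.derive_loadings(features)
        pcsmod.write_loadings(loadings, out / "loadings.csv")
        manifest["files"]["loadings.csv"] = str(out / "loadings.csv")
    save(features.stats.to_frame(), "standardization_stats.csv")
    scores = pcsmod.project_scores(features, loadings)
    score_out = pd.concat([cohort[["subject_id", "visit", "gdm"]], scores.pcs], axis=1)
    save(score_out, "scores.csv")

    # stage 5: statistics
    report = {"seed": config.seed, "config_hash": chash, "n_rows": n_rows,
              "n_missing_imputed": n_missing,
              "loadings_provenance": loadings.provenance}
    numeric_panels = panels.drop(columns=["flags"])
    cmap = an.spearman_map(scores.pcs, numeric_panels, visit=cohort["visit"])
    save(cmap, "correlation_map.csv")

    v1 = cohort["visit"] == "V1"
    y = (cohort.loc[v1, "gdm"] == "GDM").to_numpy(dtype=float)
    if 0 < y.sum() < len(y):
        gdm_models = {}
        for col in scores.pcs.columns:
            fit = an.fit_logistic_univariable(y, scores.pcs.loc[v1, col].to_numpy(), scale=0.01)
            gdm_models[col] = {
                "odds_ratio_per_0.01": fit.odds_ratio, "ci": [fit.ci_low, fit.ci_high],
                "p": fit.p, "events": fit.events, "separation": fit.separation,
            }
        report["gdm_logistic"] = gdm_models
        if config.run_rf:
            X = pd.concat(
                [scores.pcs.loc[v1].reset_index(drop=True),
                 cohort.loc[v1, ["age", "bmi", "g0"]].reset_index(drop=True),
                 numeric_panels.loc[v1, ["g_mean", "ogis", "tis"]].reset_index(drop=True)],
                axis=1,
            )
            imp = an.rf_importance(X, y, ntree=config.ntree, seed=config.seed + 3)
            imp.table.to_csv(out / "importance.csv", index=False, float_format="%.6g")
            manifest["files"]["importance.csv"] = str(out / "importance.csv")
            report["rf_ntree"] = imp.ntree
    mask = np.isfinite(numeric_panels["issi2"].to_numpy()) & v1.to_numpy()
    model = an.fit_issi2_model(
        numeric_panels.loc[mask, "issi2"], scores.pcs.loc[mask]
    )
    report["issi2_model"] = {
        "coef": model.coef.to_dict(), "r_squared": model.r_squared,
        "p": model.pvalues.to_dict(),
    }
    if config.run_lmm:
        lmm = an.lmm_random_intercept(
            scores.pcs["PCS1"], cohort["visit"], cohort["subject_id"]
        )
        report["pcs1_visit_model"] = {
            "fixed_effects": lmm.fe_params.to_dict(), "p_global": lmm.p_global,
            "intercept_variance": lmm.intercept_var, "method": lmm.method,
        }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    manifest["files"]["report.json"] = str(out / "report.json")
    log.info("pipeline done: %d files in %s", len(manifest["files"]), out)
    return manifest
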