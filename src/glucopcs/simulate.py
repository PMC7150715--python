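"""Synthetic longitudinal OGTT cohort generator.

Emulates a pregnancy cohort examined at two prepartum visits (V1, V2) and
one postpartum visit (V3): each subject carries two lognormal latents —
insulin sensitivity ``si`` and β-cell function ``beta`` — and insulin
sensitivity is shifted multiplicatively by visit (V2 < V1 < V3, the
physiological fall of insulin action in late gestation and its recovery
after delivery).

Curve mechanism, per subject-visit:

* glucose(t) = fasting + amplitude·shape(t), with a fixed unimodal shape
  peaking at 30-60 min and amplitude decreasing in ``si·beta`` (low
  disposition ⇒ larger excursions ⇒ IADPSG-positive tails);
* insulin(t) is a lognormal secretion response increasing in ``beta`` and
  in the glucose excursion, decreasing in ``si`` (compensatory
  hyperinsulinaemia);
* C-peptide(t) follows a slowly decaying exponential smoothing of the
  insulin secretion deviations (slower peripheral kinetics).

Per-visit marginal means are anchored exactly (up to sampling noise) to the
configured target table, which defaults to the marginal summaries of a
67-woman pregnancy cohort: raw-scale means/SDs for glucose and age,
log-scale for insulin and BMI, square-root scale for C-peptide. GDM status
is *emergent*: it is assigned by applying the IADPSG thresholds to the
generated prepartum glucose values, so its ~9% prevalence and its
enrichment in low ``si·beta`` subjects arise from the mechanism, not from a
label draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indices import OGTT_TIMES, classify_gdm_iadpsg

VISITS = ("V1", "V2", "V3")

#: Cohort CSV schema (one row per subject-visit).
COHORT_COLUMNS = (
    "subject_id", "visit", "age", "bmi",
    "g0", "g30", "g60", "g90", "g120",
    "i0", "i30", "i60", "i90", "i120",
    "cp0", "cp30", "cp60", "cp90", "cp120",
    "gdm", "primiparous", "family_history", "history_gdm",
)

#: OGTT measurement columns eligible for injected missingness (post-load only).
POSTLOAD_COLUMNS = tuple(
    f"{p}{t}" for p in ("g", "i", "cp") for t in OGTT_TIMES if t > 0
)

MEASUREMENT_COLUMNS = tuple(f"{p}{t}" for p in ("g", "i", "cp") for t in OGTT_TIMES)


@dataclass(frozen=True)
class VisitTargets:
    """Marginal calibration targets for one visit.

    Glucose and age on the raw scale, insulin and BMI as natural-log
    mean/SD, C-peptide as square-root mean/SD — the scales on which each
    variable is approximately normal.
    """

    g_mean: tuple
    g_sd: tuple
    ln_i_mean: tuple
    ln_i_sd: tuple
    sqrt_cp_mean: tuple
    sqrt_cp_sd: tuple
    ln_bmi_mean: float
    ln_bmi_sd: float
    age_mean: float
    age_sd: float


#: Default study conditions: per-visit marginal targets of the emulated cohort.
DEFAULT_TARGETS = {
    "V1": VisitTargets(
        g_mean=(76.8, 125.1, 118.5, 102.8, 97.1),
        g_sd=(7.5, 25.5, 33.4, 29.6, 24.5),
        ln_i_mean=(1.84, 3.62, 3.63, 3.29, 3.28),
        ln_i_sd=(0.83, 1.34, 1.24, 1.38, 1.35),
        sqrt_cp_mean=(1.30, 2.48, 2.80, 2.71, 2.61),
        sqrt_cp_sd=(0.25, 0.43, 0.53, 0.59, 0.61),
        ln_bmi_mean=3.24, ln_bmi_sd=0.18,
        age_mean=29.8, age_sd=5.1,
    ),
    "V2": VisitTargets(
        g_mean=(77.8, 129.7, 131.9, 114.5, 102.7),
        g_sd=(9.3, 25.4, 31.8, 29.8, 25.6),
        ln_i_mean=(1.86, 3.46, 3.63, 3.60, 3.50),
        ln_i_sd=(1.04, 1.57, 1.32, 1.28, 1.14),
        sqrt_cp_mean=(1.43, 2.60, 3.10, 3.06, 2.94),
        sqrt_cp_sd=(0.27, 0.50, 0.55, 0.63, 0.62),
        ln_bmi_mean=3.31, ln_bmi_sd=0.16,
        age_mean=30.1, age_sd=4.8,
    ),
    "V3": VisitTargets(
        g_mean=(83.0, 126.4, 110.4, 91.9, 94.0),
        g_sd=(9.3, 21.8, 29.6, 20.8, 18.0),
        ln_i_mean=(1.00, 3.00, 3.14, 3.04, 2.52),
        ln_i_sd=(1.41, 1.30, 1.09, 1.06, 1.04),
        sqrt_cp_mean=(1.30, 2.34, 2.62, 2.59, 2.47),
        sqrt_cp_sd=(0.27, 0.34, 0.34, 0.38, 0.44),
        ln_bmi_mean=3.22, ln_bmi_sd=0.14,
        age_mean=31.9, age_sd=5.4,
    ),
}


@dataclass(frozen=True)
class LatentModel:
    """Structural constants of the latent mechanism (dimensionless).

    ``sigma_si``/``sigma_beta`` are the log-scale SDs of the two latents;
    ``rho`` their log-scale correlation (negative: β-cell compensation for
    insulin resistance); ``c_age`` ties insulin sensitivity negatively to
    age. ``kappa_g``/``kappa_a`` scale fasting glucose and excursion
    amplitude inversely to disposition ``si·beta``; ``s_i``/``b_i``/
    ``gamma_i`` shape the insulin response (sensitivity, β-cell, excursion
    links); ``b_c``/``kernel_tau`` the C-peptide smoothing; the ``s_*``
    terms are shared (per subject-visit) and per-time noise SDs.
    """

    sigma_si: float = 0.50
    sigma_beta: float = 0.40
    rho: float = -0.30
    c_age: float = 0.30
    visit_shift: tuple = (1.0, 0.72, 1.25)  # multiplicative on si at V1, V2, V3
    kappa_g: float = 0.12
    kappa_a: float = 0.55
    s_amp_shared: float = 0.30
    s_amp_time: float = 0.18
    s_i: float = 0.55
    b_i: float = 0.50
    b_i_dyn: float = 0.50  # extra post-load (stimulated) β-cell response
    gamma_i: float = 0.35
    s_i_shared: float = 0.32
    s_i_time: float = 0.24
    b_c: float = 0.26
    kernel_tau: float = 75.0
    s_c_shared: float = 0.08
    s_c_time: float = 0.05
    # fasting (hepatic) insulin-resistance factor: joint loading on the
    # fasting glucose/insulin/C-peptide cells only
    f_g0_frac: float = 0.80  # fraction of the fasting-glucose noise SD
    f_i0: float = 0.45  # log-insulin units
    f_cp0: float = 0.08  # sqrt-C-peptide units (on top of the smoothed term)
    bmi_shared: float = 0.94
    bmi_si: float = -0.35
    g0_noise_floor: float = 0.03


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one synthetic cohort draw.

    ``visit_counts`` is the dropout schedule (subjects retained per visit,
    scaled to ``n_subjects``); ``gdm_fraction`` is the *target* prevalence
    the default calibration was designed around — the realized fraction is
    emergent and reported, never forced. ``noise_scale`` and
    ``latent_scale`` multiply every noise SD and every latent SD (0 gives
    degenerate, identical subjects); they exist for testing, the study
    conditions are the defaults.
    """

    n_subjects: int = 67
    visit_counts: tuple = (67, 57, 23)
    targets: dict = field(default_factory=lambda: dict(DEFAULT_TARGETS))
    model: LatentModel = field(default_factory=LatentModel)
    gdm_fraction: float = 0.09
    missing_cells: int = 5
    seed: int = 0
    noise_scale: float = 1.0
    latent_scale: float = 1.0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if not 0 <= self.gdm_fraction < 1:
            raise ValueError("gdm_fraction must lie in [0, 1)")
        if self.missing_cells < 0:
            raise ValueError("missing_cells must be non-negative")
        for visit, t in self.targets.items():
            for name in ("g_sd", "ln_i_sd", "sqrt_cp_sd"):
                if np.any(np.asarray(getattr(t, name)) <= 0):
                    raise ValueError(f"{visit}: target {name} must be positive")
            if t.ln_bmi_sd <= 0 or t.age_sd <= 0:
                raise ValueError(f"{visit}: target SDs must be positive")


def _smoothing_weights(tau: float) -> np.ndarray:
    """Lower-triangular causal kernel over the OGTT grid, rows normalized."""
    t = np.asarray(OGTT_TIMES, dtype=float)
    lag = t[:, None] - t[None, :]
    w = np.where(lag >= 0, np.exp(-lag / tau), 0.0)
    return w / w.sum(axis=1, keepdims=True)


def _visit_curves(
    d_si: np.ndarray,
    d_beta: np.ndarray,
    visit: str,
    config: GeneratorConfig,
    draws: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Curves for subjects with latent deviations ``d_si``, ``d_beta``.

    ``d_si``/``d_beta`` are log-scale deviations from the visit mean
    (``d_si = ln(si / visit_shift)``). ``draws`` supplies the standard-normal
    noise draws; ``None`` means noise-free (the deterministic mechanism).
    Returns arrays ``g``, ``i``, ``cp`` of shape (n, 5).
    """
    m = config.model
    t = config.targets[visit]
    n = len(d_si)
    ns = config.noise_scale if draws is not None else 0.0
    if draws is None:
        z = np.zeros
        draws = {
            "u_amp": z(n), "u_i": z(n), "u_c": z(n), "u_fast": z(n),
            "e_g0": z(n), "e_amp": z((n, 4)), "e_i": z((n, 5)), "e_c": z((n, 5)),
        }

    d_x = d_si + d_beta  # disposition deviation
    var_x = _latent_var(config)

    # fasting glucose: lognormal, mean anchored to the target
    cv2 = (t.g_sd[0] / t.g_mean[0]) ** 2
    s_g0 = math.sqrt(max(cv2 - m.kappa_g**2 * var_x, m.g0_noise_floor**2)) * ns
    f = m.f_g0_frac
    g0_noise = s_g0 * (f * draws["u_fast"] + math.sqrt(1 - f**2) * draws["e_g0"])
    ln_g0 = (
        math.log(t.g_mean[0])
        - 0.5 * (m.kappa_g**2 * var_x + s_g0**2)
        - m.kappa_g * d_x
        + g0_noise
    )
    g0 = np.exp(ln_g0)

    # excursion amplitude: lognormal with mean 1
    amp_shared_ln = -m.kappa_a * d_x + m.s_amp_shared * ns * draws["u_amp"]
    var_amp = (
        m.kappa_a**2 * var_x
        + (m.s_amp_shared * ns) ** 2
        + (m.s_amp_time * ns) ** 2
    )
    amp = np.exp(
        amp_shared_ln[:, None] + m.s_amp_time * ns * draws["e_amp"] - 0.5 * var_amp
    )
    delta = np.asarray(t.g_mean) - t.g_mean[0]
    g = np.empty((n, 5))
    g[:, 0] = g0
    g[:, 1:] = g0[:, None] + delta[1:] * amp

    # insulin: log-scale response around the per-time targets
    ln_i = np.tile(np.asarray(t.ln_i_mean), (n, 1)).astype(float)
    dev = (
        -m.s_i * d_si[:, None]
        + m.b_i * d_beta[:, None]
        + (m.s_i_shared * ns) * draws["u_i"][:, None]
        + (m.s_i_time * ns) * draws["e_i"]
    )
    dev[:, 1:] += m.gamma_i * amp_shared_ln[:, None]  # excursion drives post-load insulin
    dev[:, 1:] += m.b_i_dyn * d_beta[:, None]  # β-cell amplifies the stimulated response
    dev[:, 0] += m.f_i0 * ns * draws["u_fast"]  # hepatic factor raises fasting insulin
    ln_i += dev
    i = np.exp(ln_i)

    # C-peptide: slow exponential smoothing of the secretion deviations
    w = _smoothing_weights(m.kernel_tau)
    smoothed = dev @ w.T
    sqrt_cp = (
        np.asarray(t.sqrt_cp_mean)[None, :]
        + m.b_c * smoothed
        + (m.s_c_shared * ns) * draws["u_c"][:, None]
        + (m.s_c_time * ns) * draws["e_c"]
    )
    sqrt_cp[:, 0] += m.f_cp0 * ns * draws["u_fast"]
    cp = np.maximum(sqrt_cp, 0.05) ** 2
    return {"g": g, "i": i, "cp": cp}


def _latent_var(config: GeneratorConfig) -> float:
    """Variance of the disposition deviation d_si + d_beta."""
    m = config.model
    ls = config.latent_scale
    s1, s2 = m.sigma_si * ls, m.sigma_beta * ls
    return s1**2 + s2**2 + 2 * m.rho * s1 * s2


def synthesize_curves(
    si: float | np.ndarray, beta: float | np.ndarray, visit: str, config: GeneratorConfig
) -> dict[str, np.ndarray]:
    """Noise-free curves for given latent values at one visit.

    Exposes the deterministic core of the mechanism (used e.g. to verify
    that the Matsuda index of the generated curves increases in ``si``).
    """
    si = np.atleast_1d(np.asarray(si, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if np.any(si <= 0) or np.any(beta <= 0):
        raise ValueError("latents si and beta must be positive")
    shift = config.model.visit_shift[VISITS.index(visit)]
    return _visit_curves(np.log(si / shift), np.log(beta), visit, config, draws=None)


def generate_cohort(
    config: GeneratorConfig, return_latents: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a longitudinal cohort; deterministic given ``config.seed``.

    Returns one row per subject-visit following the canonical cohort schema
    (plus, when ``return_latents``, a per-subject-visit table of the true
    latents for validation studies). GDM status is assigned by the IADPSG
    thresholds on the generated prepartum (V1/V2) glucose values and
    attached to every row of the subject.
    """
    rng = np.random.default_rng(config.seed)
    m = config.model
    n = config.n_subjects
    ns, ls = config.noise_scale, config.latent_scale

    # demographics and subject latents
    t1 = config.targets["V1"]
    age = np.clip(t1.age_mean + t1.age_sd * ns * rng.standard_normal(n), 18.0, 45.0)
    z_age = (age - t1.age_mean) / t1.age_sd if ns > 0 else np.zeros(n)
    cov = np.array([[1.0, m.rho], [m.rho, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
    c = m.c_age
    ln_si0 = m.sigma_si * ls * (math.sqrt(1 - c**2) * z[:, 0] - c * z_age)
    ln_beta = m.sigma_beta * ls * z[:, 1]
    z_bmi = rng.standard_normal(n) * ns

    primiparous = rng.random(n) < 0.672
    fh_missing = rng.random(n) < 1.0 / 67.0
    family_history = rng.random(n) < 0.348
    var_x = max(_latent_var(config), 1e-12)
    risk = -(ln_si0 + ln_beta) / math.sqrt(var_x)
    p_hist = 1.0 / (1.0 + np.exp(-(-1.75 + 1.4 * risk)))
    history_gdm = (~primiparous) & (rng.random(n) < p_hist)

    # dropout schedule, nested subsets
    counts = np.round(np.asarray(config.visit_counts) * n / config.visit_counts[0]).astype(int)
    present = {VISITS[0]: np.arange(n)}
    for v_idx in (1, 2):
        prev = present[VISITS[v_idx - 1]]
        keep = min(counts[v_idx], len(prev))
        present[VISITS[v_idx]] = np.sort(rng.choice(prev, size=keep, replace=False))

    age_offset = {"V1": 0.0, "V2": 0.2, "V3": 1.0}
    rows = []
    latents = []
    curves_by_visit = {}
    for v_idx, visit in enumerate(VISITS):
        idx = present[visit]
        k = len(idx)
        draws = {
            "u_amp": rng.standard_normal(k),
            "u_i": rng.standard_normal(k),
            "u_c": rng.standard_normal(k),
            "u_fast": rng.standard_normal(k),
            "e_g0": rng.standard_normal(k),
            "e_amp": rng.standard_normal((k, 4)),
            "e_i": rng.standard_normal((k, 5)),
            "e_c": rng.standard_normal((k, 5)),
        }
        curves = _visit_curves(ln_si0[idx], ln_beta[idx], visit, config, draws)
        curves_by_visit[visit] = (idx, curves)
        t = config.targets[visit]
        d_si_std = ln_si0[idx] / (m.sigma_si * ls) if ls > 0 else np.zeros(k)
        ln_bmi = t.ln_bmi_mean + t.ln_bmi_sd * (
            m.bmi_shared * z_bmi[idx] + m.bmi_si * d_si_std
        )
        shift = m.visit_shift[v_idx]
        for j, s in enumerate(idx):
            row = {
                "subject_id": f"S{s + 1:04d}",
                "visit": visit,
                "age": round(age[s] + age_offset[visit], 1),
                "bmi": float(np.exp(ln_bmi[j])),
            }
            for p, arr in (("g", curves["g"]), ("i", curves["i"]), ("cp", curves["cp"])):
                for ti, tt in enumerate(OGTT_TIMES):
                    row[f"{p}{tt}"] = float(arr[j, ti])
            row["primiparous"] = bool(primiparous[s])
            row["family_history"] = None if fh_missing[s] else bool(family_history[s])
            row["history_gdm"] = bool(history_gdm[s])
            rows.append(row)
            latents.append(
                {
                    "subject_id": f"S{s + 1:04d}",
                    "visit": visit,
                    "si": float(np.exp(ln_si0[s]) * shift),
                    "beta": float(np.exp(ln_beta[s])),
                }
            )

    df = pd.DataFrame(rows)
    # GDM from the generated prepartum glucose (IADPSG), subject-level
    status = {}
    for visit in ("V1", "V2"):
        sub = df[df["visit"] == visit]
        for _, r in sub.iterrows():
            verdict = classify_gdm_iadpsg(r["g0"], r["g60"], r["g120"])
            if verdict == "GDM":
                status[r["subject_id"]] = "GDM"
    df["gdm"] = df["subject_id"].map(lambda s: status.get(s, "NGT"))
    df = df[list(COHORT_COLUMNS)].sort_values(["subject_id", "visit"]).reset_index(drop=True)
    lat = pd.DataFrame(latents).sort_values(["subject_id", "visit"]).reset_index(drop=True)
    return (df, lat) if return_latents else df


def inject_missingness(cohort: pd.DataFrame, n_cells: int, seed: int) -> pd.DataFrame:
    """Set ``n_cells`` post-load OGTT measurements missing, completely at random.

    Only dynamic (post-load) cells are eligible; fasting values and
    covariates are never blanked. Returns a copy; reproducible under
    ``seed``.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    out = cohort.copy()
    eligible = [
        (ri, col)
        for col in POSTLOAD_COLUMNS
        for ri in out.index[out[col].notna()]
    ]
    if n_cells > len(eligible):
        raise ValueError(
            f"n_cells={n_cells} exceeds the {len(eligible)} eligible post-load cells"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_cells, replace=False)
    for k in chosen:
        ri, col = eligible[k]
        out.loc[ri, col] = np.nan
    return out
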