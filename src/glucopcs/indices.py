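"""Fasting and dynamic indices of insulin action, secretion and β-cell function.

All formulas take the canonical units (glucose mg/dl, insulin μU/ml,
C-peptide ng/ml); :func:`compute_panel` applies a :class:`~glucopcs.units.UnitPolicy`
once and evaluates the full panel for one OGTT occasion sampled at
0/30/60/90/120 min after a 75 g oral glucose load.

Published formula constants live in :mod:`glucopcs.constants`. The β-cell
dose-response quantities ``g_sens`` and ``rate_sens`` are regression
surrogates (slope of the insulin secretion rate on concurrent glucose, and
early incremental secretion on the early rate of glucose change), not a fit
of a mechanistic dose-response model; they are labelled as surrogates in all
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from .constants import CPEPTIDE_KINETICS, OGIS_CONSTANTS, STUMVOLL_CONSTANTS
from .units import (
    CANONICAL_POLICY,
    GLUCOSE_MGDL_PER_MMOLL,
    UnitPolicy,
    cpeptide_to_nmoll,
    glucose_to_mmoll,
    insulin_to_pmoll,
)

#: Sampling grid of the 2-h OGTT, minutes after the glucose load.
OGTT_TIMES = (0, 30, 60, 90, 120)

#: IADPSG diagnostic thresholds, mmol/l (fasting, 1-h, 2-h), inclusive.
IADPSG_THRESHOLDS_MMOLL = (5.1, 10.0, 8.5)

DEFAULT_BSA_M2 = 1.73
DEFAULT_DOSE_G = 75.0


def _require_positive(**named):
    for name, value in named.items():
        arr = np.asarray(value, dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


def auc_trapezoid(values, times=OGTT_TIMES, t_start=0, t_end=120) -> float:
    """Trapezoid-rule area under ``values`` over ``[t_start, t_end]``.

    ``t_start`` and ``t_end`` must lie on the sampling grid; the result is
    the exact trapezoid integral (value·min), total area (not incremental).
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise ValueError("times and values must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if t_start not in t or t_end not in t:
        raise ValueError(f"window [{t_start}, {t_end}] not on the time grid {t}")
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    lo = int(np.searchsorted(t, t_start))
    hi = int(np.searchsorted(t, t_end))
    return float(np.trapezoid(v[lo : hi + 1], t[lo : hi + 1]))


def homa_ir(g0: float, i0: float) -> float:
    """Homeostasis model assessment of insulin resistance.

    ``(G0[mmol/l] × I0[μU/ml]) / 22.5`` with G0 given in mg/dl.
    """
    _require_positive(g0=g0, i0=i0)
    return float(glucose_to_mmoll(g0) * i0 / 22.5)


def quicki(g0: float, i0: float) -> float:
    """Quantitative insulin sensitivity check index, ``1/(ln G0 + ln I0)``.

    Natural logarithms on mg/dl and μU/ml: this variant reproduces the
    0.15-0.20 range typical of pregnancy cohorts (the base-10 variant sits
    near 0.33-0.40 instead).
    """
    _require_positive(g0=g0, i0=i0)
    denom = math.log(g0) + math.log(i0)
    if denom == 0:
        raise ValueError("ln(g0) + ln(i0) is zero; QUICKI undefined")
    return 1.0 / denom


def matsuda(glucose, insulin) -> float:
    """Matsuda-DeFronzo whole-body insulin sensitivity index.

    ``10000 / sqrt(G0·I0·Ḡ·Ī)`` with means taken over all five OGTT points
    (mg/dl, μU/ml).
    """
    g = np.asarray(glucose, dtype=float)
    i = np.asarray(insulin, dtype=float)
    _require_positive(glucose=g, insulin=i)
    if g.shape != (5,) or i.shape != (5,):
        raise ValueError("matsuda expects five glucose and five insulin points")
    return float(10000.0 / math.sqrt(g[0] * i[0] * g.mean() * i.mean()))


def ogis_2h(
    g0: float,
    g90: float,
    g120: float,
    i0: float,
    i90: float,
    dose: float = DEFAULT_DOSE_G,
    bsa: float = DEFAULT_BSA_M2,
) -> float:
    """Oral glucose insulin sensitivity index, 2-hour variant (ml·min⁻¹·m⁻²).

    Model-based glucose clearance from G(0), G(90), G(120), I(0), I(90);
    constants transcribed from the primary reference in
    :data:`~glucopcs.constants.OGIS_CONSTANTS`.
    """
    _require_positive(g0=g0, g90=g90, g120=g120, i0=i0, i90=i90, dose=dose, bsa=bsa)
    c = OGIS_CONSTANTS
    dose_per_bsa = dose / bsa  # g/m2
    flux = (c.p1 * dose_per_bsa - c.v_distribution * (g120 - g90) / 30.0) / g90
    x1 = c.p4 * (flux + c.p3 / g0) / (i90 - i0 + c.p2)
    x2 = (c.p5 * (g90 - c.g_clamp) + 1.0) * x1
    return float(
        0.5 * (x2 + math.sqrt(x2**2 + 4.0 * c.p5 * c.p6 * (g90 - c.g_clamp) * x1))
    )


def stumvoll_indices(
    g30: float, g90: float, i0: float, i30: float, i120: float, bmi: float
) -> tuple[float, float, float, float]:
    """Stumvoll demographic regression indices ``(mcr, isi, ph1, ph2)``.

    Inputs in canonical units (mg/dl, μU/ml); conversion to the mmol/l and
    pmol/l units of the published coefficients happens here, once.
    """
    _require_positive(g30=g30, g90=g90, i0=i0, i30=i30, i120=i120, bmi=bmi)
    g30_mm = float(glucose_to_mmoll(g30))
    g90_mm = float(glucose_to_mmoll(g90))
    i0_pm = float(insulin_to_pmoll(i0))
    i30_pm = float(insulin_to_pmoll(i30))
    i120_pm = float(insulin_to_pmoll(i120))
    c = STUMVOLL_CONSTANTS
    mcr = c.mcr[0] + c.mcr[1] * bmi + c.mcr[2] * i120_pm + c.mcr[3] * g90_mm
    isi = c.isi[0] + c.isi[1] * bmi + c.isi[2] * i120_pm + c.isi[3] * g90_mm
    ph1 = c.ph1[0] + c.ph1[1] * i30_pm + c.ph1[2] * g30_mm + c.ph1[3] * i0_pm
    ph2 = c.ph2[0] + c.ph2[1] * i30_pm + c.ph2[2] * g30_mm + c.ph2[3] * i0_pm
    return float(mcr), float(isi), float(ph1), float(ph2)


def insulinogenic(glucose, insulin) -> tuple[float, float, float]:
    """Insulinogenic indices ``(sec_early, sec_late, sec_total)``.

    sec_early = ΔI(30-0)/ΔG(30-0); sec_late and sec_total are the
    AUC_insulin/AUC_glucose ratios over 60-120 and 0-120 min. A flat early
    glucose increment (G30 == G0) makes sec_early undefined: NaN is
    returned so callers can flag it rather than silently drop the row.
    """
    g = np.asarray(glucose, dtype=float)
    i = np.asarray(insulin, dtype=float)
    _require_positive(glucose=g, insulin=i)
    dg = g[1] - g[0]
    sec_early = float((i[1] - i[0]) / dg) if dg != 0 else float("nan")
    sec_late = auc_trapezoid(i, OGTT_TIMES, 60, 120) / auc_trapezoid(g, OGTT_TIMES, 60, 120)
    sec_total = auc_trapezoid(i, OGTT_TIMES, 0, 120) / auc_trapezoid(g, OGTT_TIMES, 0, 120)
    return sec_early, float(sec_late), float(sec_total)


def issi2(matsuda_value: float, sec_total: float) -> float:
    """Oral disposition index: the exact product Matsuda × Sec-total."""
    if not (np.isfinite(matsuda_value) and np.isfinite(sec_total)):
        raise ValueError("issi2 requires finite inputs")
    return float(matsuda_value * sec_total)


def isr_deconvolution(
    cpeptide,
    age: float,
    bsa: float = DEFAULT_BSA_M2,
    per_bsa: bool = True,
    dt: float = 0.25,
) -> tuple[np.ndarray, float]:
    """Insulin secretion rate from C-peptide by two-compartment deconvolution.

    C-peptide (ng/ml at the five OGTT times) is interpolated linearly on a
    fine grid; with population kinetic constants (k1, k2, k3 from
    :data:`~glucopcs.constants.CPEPTIDE_KINETICS`, age-adjusted) the
    peripheral compartment starts at its fasting steady state and the
    secretion rate is recovered as ``ISR = V·(dC1/dt + (k1+k3)·C1 − k2·C2)``.

    Returns the ISR sampled at the five OGTT times (nmol·min⁻¹·m⁻² when
    ``per_bsa``, else nmol·min⁻¹) and the total insulin secretion
    TIS = ∫₀¹²⁰ ISR dt (nmol·m⁻² or nmol).
    """
    cp = np.asarray(cpeptide, dtype=float)
    _require_positive(bsa=bsa)
    if np.any(~np.isfinite(cp)) or np.any(cp < 0):
        raise ValueError(f"C-peptide must be non-negative and finite, got {cp!r}")
    if age < 0:
        raise ValueError("age must be non-negative")
    if cp.shape != (5,):
        raise ValueError("isr_deconvolution expects five C-peptide points")

    k1, k2, k3 = CPEPTIDE_KINETICS.rate_constants(age)
    vd = CPEPTIDE_KINETICS.vd_litre_per_m2 * bsa  # litres
    times = np.asarray(OGTT_TIMES, dtype=float)
    grid = np.arange(0.0, 120.0 + dt / 2, dt)
    c1 = np.interp(grid, times, cpeptide_to_nmoll(cp))
    dc1 = np.gradient(c1, dt)

    c2 = np.empty_like(c1)
    c2[0] = k1 * c1[0] / k2  # fasting steady state
    for j in range(1, len(grid)):
        # exponential (exact for constant input) update of the slow pool
        decay = math.exp(-k2 * dt)
        c2[j] = c2[j - 1] * decay + (k1 * 0.5 * (c1[j - 1] + c1[j]) / k2) * (1 - decay)

    isr_grid = vd * (dc1 + (k1 + k3) * c1 - k2 * c2)  # nmol/min
    scale = 1.0 / bsa if per_bsa else 1.0
    tis = float(np.trapezoid(isr_grid, grid) * scale)
    idx = np.searchsorted(grid, times)
    return isr_grid[idx] * scale, tis


def gsens_ratesens(glucose, isr_series) -> tuple[float, float]:
    """β-cell regression surrogates ``(g_sens, rate_sens)``.

    g_sens: least-squares slope of the insulin secretion rate on concurrent
    glucose across the five OGTT points ((nmol·min⁻¹·m⁻²)/(mg/dl)).
    rate_sens: early (0-30 min) incremental ISR per unit rate of glucose
    change over the same window. Degenerate glucose (constant curve, or flat
    0-30 segment for rate_sens) yields NaN so callers can flag it.
    """
    g = np.asarray(glucose, dtype=float)
    isr = np.asarray(isr_series, dtype=float)
    if g.shape != isr.shape or g.size < 3:
        raise ValueError("need matching glucose and ISR series of length >= 3")
    if np.ptp(g) == 0:
        g_sens = float("nan")
    else:
        g_sens = float(np.polyfit(g, isr, 1)[0])
    dgdt = (g[1] - g[0]) / 30.0
    rate_sens = float((isr[1] - isr[0]) / dgdt) if dgdt != 0 else float("nan")
    return g_sens, rate_sens


def classify_gdm_iadpsg(g0, g60, g120) -> str:
    """IADPSG classification from fasting, 1-h and 2-h glucose (mg/dl).

    GDM iff fasting ≥ 5.1, 1-h ≥ 10.0 or 2-h ≥ 8.5 mmol/l (inclusive,
    evaluated on the mg/dl equivalents). A missing value that cannot be
    compensated by a positive criterion elsewhere yields ``"unknown"``.
    """
    values = (g0, g60, g120)
    thresholds = tuple(t * GLUCOSE_MGDL_PER_MMOLL for t in IADPSG_THRESHOLDS_MMOLL)
    present = [v is not None and np.isfinite(v) for v in values]
    for v, th, ok in zip(values, thresholds, present):
        if ok and v >= th:
            return "GDM"
    return "NGT" if all(present) else "unknown"


@dataclass
class IndexPanel:
    """All indices for one subject-visit; NaN fields carry a flag entry."""

    homa_ir: float = float("nan")
    quicki: float = float("nan")
    matsuda: float = float("nan")
    ogis: float = float("nan")
    mcr: float = float("nan")
    isi_stumvoll: float = float("nan")
    ph1: float = float("nan")
    ph2: float = float("nan")
    sec_early: float = float("nan")
    sec_late: float = float("nan")
    sec_total: float = float("nan")
    issi2: float = float("nan")
    tis: float = float("nan")
    g_sens: float = float("nan")
    rate_sens: float = float("nan")
    g_mean: float = float("nan")
    flags: dict = field(default_factory=dict)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls) if f.name != "flags"]


def compute_panel(
    row,
    policy: UnitPolicy = CANONICAL_POLICY,
    bsa: float = DEFAULT_BSA_M2,
    dose: float = DEFAULT_DOSE_G,
) -> IndexPanel:
    """Evaluate the full index panel for one OGTT row.

    ``row`` is any mapping with keys ``g0..g120, i0..i120, cp0..cp120, age``
    (``bmi`` is needed for the Stumvoll indices). Unit conversion happens
    here, once. Indices whose inputs are missing or degenerate come back as
    NaN with an entry in ``panel.flags`` naming the reason; fully complete
    rows yield a fully finite panel.
    """
    def grab(prefix, converter):
        vals = np.array([row.get(f"{prefix}{t}", np.nan) for t in OGTT_TIMES], dtype=float)
        return converter(vals)

    g = grab("g", policy.glucose_mgdl)
    i = grab("i", policy.insulin_uuml)
    cp = grab("cp", policy.cpeptide_ngml)
    age = float(row.get("age", np.nan))
    bmi = float(row.get("bmi", np.nan))

    panel = IndexPanel()

    def attempt(name, fn, *args):
        try:
            if any(np.any(~np.isfinite(np.asarray(a, dtype=float))) for a in args):
                raise ValueError("missing input")
            return fn(*args)
        except (ValueError, ZeroDivisionError) as exc:
            panel.flags[name] = str(exc)
            return None

    if (v := attempt("homa_ir", homa_ir, g[0], i[0])) is not None:
        panel.homa_ir = v
    if (v := attempt("quicki", quicki, g[0], i[0])) is not None:
        panel.quicki = v
    if (v := attempt("matsuda", matsuda, g, i)) is not None:
        panel.matsuda = v
    if (v := attempt("ogis", ogis_2h, g[0], g[3], g[4], i[0], i[3], dose, bsa)) is not None:
        panel.ogis = v
    if (v := attempt("stumvoll", stumvoll_indices, g[1], g[3], i[0], i[1], i[4], bmi)) is not None:
        panel.mcr, panel.isi_stumvoll, panel.ph1, panel.ph2 = v
    if (v := attempt("insulinogenic", insulinogenic, g, i)) is not None:
        panel.sec_early, panel.sec_late, panel.sec_total = v
        if math.isnan(panel.sec_early):
            panel.flags["sec_early"] = "G30 equals G0; early insulinogenic index undefined"
    if np.isfinite(panel.matsuda) and np.isfinite(panel.sec_total):
        panel.issi2 = issi2(panel.matsuda, panel.sec_total)
    else:
        panel.flags.setdefault("issi2", "matsuda or sec_total unavailable")
    isr = attempt("tis", isr_deconvolution, cp, age, bsa)
    if isr is not None:
        isr_series, panel.tis = isr
        if np.all(np.isfinite(g)):
            panel.g_sens, panel.rate_sens = gsens_ratesens(g, isr_series)
            if math.isnan(panel.g_sens):
                panel.flags["g_sens"] = "constant glucose; slope undefined"
            if math.isnan(panel.rate_sens):
                panel.flags["rate_sens"] = "flat 0-30 glucose segment"
        else:
            panel.flags["g_sens"] = panel.flags["rate_sens"] = "glucose incomplete"
    if np.all(np.isfinite(g)):
        panel.g_mean = float(g.mean())
    else:
        panel.flags["g_mean"] = "glucose incomplete"
    return panel


def panel_table(
    cohort,
    policy: UnitPolicy = CANONICAL_POLICY,
    bsa: float = DEFAULT_BSA_M2,
    dose: float = DEFAULT_DOSE_G,
):
    """Index panels for every row of a cohort frame.

    Returns a DataFrame (same index as ``cohort``) with one column per
    panel field plus a ``flags`` column carrying semicolon-joined flag
    notes for rows with undefined indices.
    """
    import pandas as pd

    records = []
    for _, row in cohort.iterrows():
        panel = compute_panel(row, policy=policy, bsa=bsa, dose=dose)
        rec = {name: getattr(panel, name) for name in IndexPanel.field_names()}
        rec["flags"] = "; ".join(f"{k}: {v}" for k, v in sorted(panel.flags.items()))
        records.append(rec)
    return pd.DataFrame(records, index=cohort.index)
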