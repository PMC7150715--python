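"""Statistical stage: imputation, group tests, GDM models, variable importance.

Covers the cohort-level analyses around the scores: chained-equation
imputation of sporadically missing OGTT cells, Spearman correlation mapping
of scores against index panels, Welch and contingency tests for group
contrasts, univariable logistic GDM models with profile-likelihood
confidence intervals, bagged-tree permutation variable importance, the
disposition-index (ISSI-2) regression on the three scores, and
random-intercept mixed models for visit effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

import statsmodels.api as sm
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.tree import DecisionTreeClassifier

from .simulate import MEASUREMENT_COLUMNS

_LN_COLS = tuple(c for c in MEASUREMENT_COLUMNS if c.startswith("i"))
_SQRT_COLS = tuple(c for c in MEASUREMENT_COLUMNS if c.startswith("cp"))


# ---------------------------------------------------------------------------
# imputation


@dataclass(frozen=True)
class ImputationConfig:
    """Chained-equation imputation settings: ``m`` completed datasets are
    drawn (posterior-sampling linear conditionals on transformed scales) and
    averaged cellwise."""

    m: int = 50
    max_iter: int = 10
    seed: int = 0
    method: str = "chained-normal"

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be at least 1")


def impute_chained(cohort: pd.DataFrame, config: ImputationConfig) -> pd.DataFrame:
    """Fill missing OGTT cells by the average of ``m`` chained-equation draws.

    Conditional models are normal-linear on the normalizing scales (log
    insulin, square-root C-peptide, raw glucose), with age and BMI as extra
    predictors. Observed cells are returned bit-identical; only missing
    OGTT measurement cells change. Deterministic under ``config.seed``.
    """
    cols = list(MEASUREMENT_COLUMNS)
    work = cohort[cols].astype(float).copy()
    if work.notna().sum().min() == 0:
        empty = [c for c in cols if cohort[c].notna().sum() == 0]
        raise ValueError(f"cannot impute: columns entirely missing: {empty}")
    mask = work.isna()
    if not mask.to_numpy().any():
        return cohort.copy()

    trans = work.copy()
    for c in _LN_COLS:
        trans[c] = np.log(trans[c])
    for c in _SQRT_COLS:
        trans[c] = np.sqrt(trans[c])
    X = trans.to_numpy()
    extra = cohort[["age", "bmi"]].astype(float).to_numpy()
    full = np.hstack([X, extra])

    acc = np.zeros_like(X)
    for j in range(config.m):
        imp = IterativeImputer(
            sample_posterior=True,
            max_iter=config.max_iter,
            random_state=(config.seed + j) % (2**31 - 1),
            keep_empty_features=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filled = imp.fit_transform(full)[:, : X.shape[1]]
        acc += filled
    acc /= config.m

    est = pd.DataFrame(acc, columns=cols, index=work.index)
    for c in _LN_COLS:
        est[c] = np.exp(est[c])
    for c in _SQRT_COLS:
        est[c] = est[c] ** 2
    out = cohort.copy()
    for c in cols:
        out[c] = np.where(mask[c], est[c], cohort[c].astype(float)) if mask[c].any() else cohort[c]
    return out


# ---------------------------------------------------------------------------
# simple tests


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t(mean1, sd1, n1, mean2, sd2, n2) -> WelchResult:
    """Welch's two-sample t-test from summary statistics.

    Satterthwaite degrees of freedom, two-sided p. Use
    :func:`welch_t_samples` for raw samples.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def welch_t_samples(x, y) -> WelchResult:
    """Welch's t-test from raw samples (unequal variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    res = stats.ttest_ind(x, y, equal_var=False)
    v1, v2 = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    df = (v1 + v2) ** 2 / (v1**2 / (len(x) - 1) + v2**2 / (len(y) - 1))
    return WelchResult(float(res.statistic), float(df), float(res.pvalue))


def pearson_chi2(table) -> tuple[float, float]:
    """Pearson chi-squared test on a 2×2 table, without continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has an empty margin")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p (sum of tables as or less probable)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table must be 2x2 with non-negative integer counts")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# logistic regression with profile-likelihood intervals


@dataclass
class LogisticFit:
    """Univariable logistic fit; the OR is reported per ``scale`` predictor
    units (e.g. 0.01 score units)."""

    beta: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    events: int
    scale: float = 1.0
    separation: bool = False


def _profile_loglik(y, x, beta: float) -> float:
    """Log-likelihood maximized over the intercept at fixed slope.

    ``x`` is centred first (slope and profile shape are unaffected) so the
    optimal intercept stays within a modest bounded search range.
    """
    eta_x = beta * (x - x.mean())

    def nll(a):
        eta = a + eta_x
        return -np.sum(y * eta - np.logaddexp(0.0, eta))

    res = optimize.minimize_scalar(nll, bounds=(-60.0, 60.0), method="bounded",
                                   options={"xatol": 1e-10})
    return -float(res.fun)


def fit_logistic_univariable(y, x, scale: float = 1.0, ci: bool = True) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome on one
    predictor, with profile-likelihood 95% CI and likelihood-ratio p.

    Complete separation is detected and flagged (the corresponding CI side
    is unbounded and reported as ``inf``/``0``) rather than raised.
    ``ci=False`` skips the (comparatively costly) profile interval and
    returns NaN bounds — useful in large simulation loops.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    events = int(y.sum())
    if events == 0 or events == len(y):
        raise ValueError("need at least one event and one non-event")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")

    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0, maxiter=200)
            beta = float(fit.params[1])
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:
            beta, converged = np.sign(np.corrcoef(x, y)[0, 1]) * 50.0 / max(x.std(), 1e-12), False
    if not converged or abs(beta) * x.std() > 25.0:
        separation = True

    ll_hat = _profile_loglik(y, x, beta)
    p_event = events / len(y)
    ll_null = len(y) * (p_event * np.log(p_event) + (1 - p_event) * np.log(1 - p_event))
    lr = max(0.0, 2.0 * (ll_hat - ll_null))
    p = float(stats.chi2.sf(lr, 1))

    if ci:
        crit = stats.chi2.ppf(0.95, 1) / 2.0  # 1.9207
        span = 40.0 / max(x.std(), 1e-12)

        def deficit(b):
            return (ll_hat - _profile_loglik(y, x, b)) - crit

        def bound(direction):
            b_far = beta + direction * span
            if deficit(b_far) <= 0:
                return direction * np.inf  # profile flat: separation side
            return float(optimize.brentq(deficit, beta, b_far, xtol=1e-8))

        lo, hi = bound(-1.0), bound(+1.0)
        if not np.isfinite(lo) or not np.isfinite(hi):
            separation = True
    else:
        lo = hi = float("nan")
    def _edge(b, unbounded):
        if np.isnan(b):
            return float("nan")
        return float(np.exp(b * scale)) if np.isfinite(b) else unbounded

    return LogisticFit(
        beta=beta,
        odds_ratio=float(np.exp(beta * scale)),
        ci_low=_edge(lo, 0.0),
        ci_high=_edge(hi, float("inf")),
        p=p,
        n=len(y),
        events=events,
        scale=scale,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# bagged-tree permutation importance


@dataclass
class ImportanceTable:
    """Permutation variable importance (mean out-of-bag accuracy drop over
    all trees), sorted descending."""

    table: pd.DataFrame
    ntree: int
    seed: int


def rf_importance(X: pd.DataFrame, y, ntree: int = 10_000, seed: int = 0) -> ImportanceTable:
    """Bagged-tree permutation importance of each predictor for a binary outcome.

    For each bootstrap tree the out-of-bag accuracy is computed before and
    after permuting one predictor; the importance is the mean accuracy
    difference over all trees (the permutation-importance principle of
    conditional-inference forests, here on CART trees).
    """
    if ntree < 100:
        raise ValueError("ntree must be at least 100")
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("outcome has a single class")
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    rng = np.random.default_rng(seed)
    totals = np.zeros(p)
    counts = np.zeros(p)
    max_feat = max(1, int(np.sqrt(p)))
    for _ in range(ntree):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) == 0:
            continue
        tree = DecisionTreeClassifier(
            max_features=max_feat, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(Xv[boot], y[boot])
        acc0 = np.mean(tree.predict(Xv[oob]) == y[oob])
        perm = rng.permutation(len(oob))
        for j in range(p):
            Xp = Xv[oob].copy()
            Xp[:, j] = Xp[perm, j]
            totals[j] += acc0 - np.mean(tree.predict(Xp) == y[oob])
            counts[j] += 1
    imp = totals / np.maximum(counts, 1)
    table = (
        pd.DataFrame({"predictor": X.columns, "importance": imp})
        .sort_values("importance", ascending=False)
        .reset_index(drop=True)
    )
    return ImportanceTable(table=table, ntree=ntree, seed=seed)


# ---------------------------------------------------------------------------
# disposition-index regression and mixed model


@dataclass
class Issi2Model:
    coef: pd.Series  # b1..b3 (score coefficients)
    conf_int: pd.DataFrame
    r_squared: float
    pvalues: pd.Series


def fit_issi2_model(issi2_values, scores: pd.DataFrame, log_response: bool = False) -> Issi2Model:
    """OLS of the oral disposition index on the three scores.

    Reports coefficient signs, 95% Wald CIs and R². ``log_response`` fits
    log(ISSI-2) instead of the raw index.
    """
    yv = np.asarray(issi2_values, dtype=float)
    if len(yv) < 10:
        raise ValueError("need at least 10 rows")
    if np.any(~np.isfinite(yv)) or scores.isna().to_numpy().any():
        raise ValueError("missing values in response or scores")
    if log_response:
        yv = np.log(yv)
    Xd = sm.add_constant(scores.astype(float))
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        raise ValueError("scores are collinear; coefficients not identifiable")
    fit = sm.OLS(yv, Xd).fit()
    keep = list(scores.columns)
    ci = fit.conf_int()
    ci.columns = ["low", "high"]
    return Issi2Model(
        coef=fit.params[keep],
        conf_int=ci.loc[keep],
        r_squared=float(fit.rsquared),
        pvalues=fit.pvalues[keep],
    )


@dataclass
class MixedVisitModel:
    fe_params: pd.Series
    fe_se: pd.Series
    p_global: float
    intercept_var: float
    n_subjects: int
    method: str = "mixed"


def lmm_random_intercept(response, visit, subject) -> MixedVisitModel:
    """Random-intercept-per-subject model of a response on visit.

    Fixed effect: visit category; the global visit test is a likelihood
    ratio against the intercept-only model (both by maximum likelihood).
    When no subject has repeated visits the model degenerates and an OLS
    ANOVA is used instead, with a warning.
    """
    df = pd.DataFrame(
        {"y": np.asarray(response, dtype=float), "visit": np.asarray(visit), "subject": np.asarray(subject)}
    ).dropna()
    n_visits = df["visit"].nunique()
    repeated = (df.groupby("subject").size() > 1).any()
    if not repeated:
        warnings.warn("no repeated measurements; falling back to one-way OLS ANOVA")
        fit = sm.OLS.from_formula("y ~ C(visit)", df).fit()
        null = sm.OLS.from_formula("y ~ 1", df).fit()
        lr = 2.0 * (fit.llf - null.llf)
        p = float(stats.chi2.sf(lr, n_visits - 1))
        return MixedVisitModel(
            fe_params=fit.params, fe_se=fit.bse, p_global=p,
            intercept_var=0.0, n_subjects=df["subject"].nunique(), method="ols",
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.MixedLM.from_formula("y ~ C(visit)", groups="subject", data=df).fit(reml=False)
        null = sm.MixedLM.from_formula("y ~ 1", groups="subject", data=df).fit(reml=False)
    lr = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(stats.chi2.sf(lr, n_visits - 1))
    return MixedVisitModel(
        fe_params=full.fe_params,
        fe_se=full.bse[full.fe_params.index],
        p_global=p,
        intercept_var=float(full.cov_re.iloc[0, 0]),
        n_subjects=df["subject"].nunique(),
    )


# ---------------------------------------------------------------------------
# correlation map


def spearman_map(
    scores: pd.DataFrame, panels: pd.DataFrame, visit: pd.Series | None = None
) -> pd.DataFrame:
    """Spearman rho/p for every (score, index) pair, per visit and pooled.

    Rank correlation with average ranks for ties; pairs with fewer than 5
    joint observations or a constant member are flagged and given NaN rho.
    """
    frames = {"pooled": np.ones(len(scores), dtype=bool)}
    if visit is not None:
        v = np.asarray(visit)
        for lab in pd.unique(v):
            frames[str(lab)] = v == lab
    rows = []
    for lab, mask in frames.items():
        for s in scores.columns:
            for ix in panels.columns:
                a = scores.loc[mask, s].to_numpy(dtype=float)
                b = panels.loc[mask, ix].to_numpy(dtype=float)
                ok = np.isfinite(a) & np.isfinite(b)
                a, b = a[ok], b[ok]
                flag = ""
                if len(a) < 5:
                    rho = pv = float("nan")
                    flag = "insufficient pairs"
                elif np.ptp(a) == 0 or np.ptp(b) == 0:
                    rho = pv = float("nan")
                    flag = "constant column"
                else:
                    rho, pv = stats.spearmanr(a, b)
                rows.append(
                    {"visit": lab, "score": s, "index": ix, "rho": rho, "p": pv,
                     "n": len(a), "flag": flag}
                )
    return pd.DataFrame(rows)
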