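"""Principal-component scores of glucose homeostasis (PCS1-3).

The scoring procedure: the 17 per-visit variables (glucose, insulin and
C-peptide at 0/30/60/90/120 min, age, BMI) are transformed (insulin and BMI
by natural log, C-peptide by square root), centred and standardized against
a designated *training* source to form the feature matrix ``A``; scores are
the matrix product ``S = A × V`` with a 17×3 loading (eigenvector) matrix
``V``, rescaled elementwise to ``PCS = (S + 100)/17``.

``V`` either comes from an external CSV (matched by variable name, never by
position) or is derived from a training cohort as the top eigenvectors of
the feature correlation matrix.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical feature column order: 5 glucose + 5 insulin + 5 C-peptide + age + BMI.
FEATURE_COLUMNS = (
    "g0", "g30", "g60", "g90", "g120",
    "i0", "i30", "i60", "i90", "i120",
    "cp0", "cp30", "cp60", "cp90", "cp120",
    "age", "bmi",
)

SCORE_COLUMNS = ("PC1", "PC2", "PC3")

#: Rescale applied to raw scores: PCS = (S + RESCALE_SHIFT) / RESCALE_DIVISOR.
RESCALE_SHIFT = 100.0
RESCALE_DIVISOR = 17.0


def _identity(x):
    return np.asarray(x, dtype=float)


def _log(x):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("log transform requires positive values")
    return np.log(x)


def _sqrt(x):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("sqrt transform requires non-negative values")
    return np.sqrt(x)


@dataclass(frozen=True)
class TransformSpec:
    """Per-variable normalizing transforms and the fixed 17-column order.

    Glucose and age stay on their original scale; insulin and BMI are
    log-transformed; C-peptide is square-root-transformed.
    """

    columns: tuple = FEATURE_COLUMNS

    _TRANSFORMS = {
        "g": _identity,
        "i": _log,
        "cp": _sqrt,
        "age": _identity,
        "bmi": _log,
    }

    def transform_for(self, column: str):
        if column in ("age", "bmi"):
            return self._TRANSFORMS[column]
        for prefix in ("cp", "g", "i"):
            if column.startswith(prefix):
                return self._TRANSFORMS[prefix]
        raise KeyError(f"unknown feature column {column!r}")

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        """Transform each feature column of ``df``; returns a new frame."""
        missing = [c for c in self.columns if c not in df.columns]
        if missing:
            raise ValueError(f"cohort lacks feature columns: {missing}")
        out = {}
        for c in self.columns:
            vals = df[c].to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)):
                raise ValueError(
                    f"column {c!r} contains missing values; impute before scoring"
                )
            out[c] = self.transform_for(c)(vals)
        return pd.DataFrame(out, index=df.index)


DEFAULT_TRANSFORMS = TransformSpec()


@dataclass(frozen=True)
class StandardizationStats:
    """Per-column mean and SD of transformed training data (defines A)."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self):
        if list(self.mean.index) != list(FEATURE_COLUMNS) or list(
            self.sd.index
        ) != list(FEATURE_COLUMNS):
            raise ValueError("stats must cover exactly the 17 canonical columns")
        if np.any(self.sd.to_numpy() <= 0):
            raise ValueError("standardization SDs must be positive")

    @classmethod
    def from_transformed(cls, transformed: pd.DataFrame) -> "StandardizationStats":
        t = transformed[list(FEATURE_COLUMNS)]
        return cls(mean=t.mean(), sd=t.std(ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"variable": FEATURE_COLUMNS,
                             "mean": self.mean.to_numpy(),
                             "sd": self.sd.to_numpy()})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StandardizationStats":
        if not {"variable", "mean", "sd"} <= set(df.columns):
            raise ValueError("stats table needs columns variable, mean, sd")
        df = df.set_index("variable")
        try:
            df = df.loc[list(FEATURE_COLUMNS)]
        except KeyError as exc:
            raise ValueError(f"stats table missing variables: {exc}") from exc
        return cls(mean=df["mean"], sd=df["sd"])


@dataclass
class FeatureMatrix:
    """Standardized n×17 feature matrix ``A`` with row identifiers."""

    values: pd.DataFrame  # columns = FEATURE_COLUMNS
    stats: StandardizationStats

    @property
    def a(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class LoadingMatrix:
    """17×3 eigenvector matrix with eigenvalues and provenance."""

    v: pd.DataFrame  # index = FEATURE_COLUMNS, columns = SCORE_COLUMNS
    eigenvalues: np.ndarray | None = None
    variance_fractions: np.ndarray | None = None
    provenance: str = "external-file"

    def __post_init__(self):
        if list(self.v.index) != list(FEATURE_COLUMNS):
            raise ValueError("loading matrix rows must be the 17 canonical variables")
        expected = [f"PC{j + 1}" for j in range(self.v.shape[1])]
        if list(self.v.columns) != expected:
            raise ValueError(f"loading matrix columns must be {expected}")
        if self.eigenvalues is not None:
            ev = np.asarray(self.eigenvalues, dtype=float)
            if np.any(np.diff(ev) > 1e-12) or np.any(ev <= 0):
                raise ValueError("eigenvalues must be positive and non-increasing")


@dataclass
class ScoreMatrix:
    """Raw scores ``S`` and rescaled scores ``PCS = (S+100)/17``."""

    s: pd.DataFrame
    pcs: pd.DataFrame
    loadings_provenance: str = "external-file"


def build_feature_matrix(
    cohort: pd.DataFrame,
    spec: TransformSpec = DEFAULT_TRANSFORMS,
    stats: StandardizationStats | None = None,
) -> FeatureMatrix:
    """Transform, centre and standardize cohort rows into the matrix ``A``.

    ``stats`` designates the training source of the centring constants; when
    omitted the cohort is standardized against itself (self-standardization,
    appropriate only when loadings are also derived from this cohort).
    """
    transformed = spec.apply(cohort)
    if stats is None:
        stats = StandardizationStats.from_transformed(transformed)
    a = (transformed[list(FEATURE_COLUMNS)] - stats.mean) / stats.sd
    return FeatureMatrix(values=a, stats=stats)


def derive_loadings(training: FeatureMatrix, k: int = 3) -> LoadingMatrix:
    """Top-``k`` eigenvectors of the training feature correlation matrix.

    Because ``A`` is standardized, ``AᵀA/(n−1)`` is the correlation matrix;
    its leading unit eigenvectors are the loadings. Sign convention: the
    first component is oriented so its loading on fasting insulin (``i0``)
    is negative (higher score = higher insulin sensitivity); later
    components are oriented so their largest-magnitude loading is positive.
    """
    a = training.a
    n = a.shape[0]
    if n <= len(FEATURE_COLUMNS):
        raise ValueError(f"need more rows than features to derive loadings (n={n})")
    corr = a.T @ a / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if eigvals[k - 1] <= 1e-12:
        raise ValueError("training matrix is rank deficient below k components")
    v = eigvecs[:, :k].copy()
    i0_idx = FEATURE_COLUMNS.index("i0")
    if v[i0_idx, 0] > 0:
        v[:, 0] *= -1.0
    for j in range(1, k):
        if v[np.argmax(np.abs(v[:, j])), j] < 0:
            v[:, j] *= -1.0
    frame = pd.DataFrame(
        v, index=list(FEATURE_COLUMNS), columns=[f"PC{j + 1}" for j in range(k)]
    )
    return LoadingMatrix(
        v=frame,
        eigenvalues=eigvals[:k],
        variance_fractions=eigvals[:k] / eigvals.sum(),
        provenance="derived-from-cohort",
    )


def correlation_eigenvalues(training: FeatureMatrix) -> np.ndarray:
    """All 17 eigenvalues of the training correlation matrix, descending."""
    a = training.a
    corr = a.T @ a / (a.shape[0] - 1)
    return np.sort(np.linalg.eigvalsh(corr))[::-1]


def project_scores(features: FeatureMatrix, loadings: LoadingMatrix) -> ScoreMatrix:
    """Project ``S = A × V`` and rescale to ``PCS = (S + 100)/17``.

    Feature columns are aligned to the loading-matrix rows by name; a
    mismatch is a hard error, never a silent positional match.
    """
    if list(features.values.columns) != list(loadings.v.index):
        raise ValueError(
            "feature columns do not match loading-matrix rows: "
            f"{list(features.values.columns)} vs {list(loadings.v.index)}"
        )
    s = features.values.to_numpy(dtype=float) @ loadings.v.to_numpy(dtype=float)
    s_df = pd.DataFrame(s, index=features.values.index, columns=loadings.v.columns)
    pcs = (s_df + RESCALE_SHIFT) / RESCALE_DIVISOR
    pcs.columns = [c.replace("PC", "PCS") for c in s_df.columns]
    return ScoreMatrix(s=s_df, pcs=pcs, loadings_provenance=loadings.provenance)


def score_orthogonality_check(scores: ScoreMatrix) -> float:
    """Max |pairwise Pearson correlation| among score columns.

    Valid only for scores projected with loadings derived from the same
    standardized cohort (PCA scores are uncorrelated on their training
    data); external-loading projections raise, since the property does not
    apply there.
    """
    if scores.loadings_provenance != "derived-from-cohort":
        raise ValueError(
            "orthogonality holds only on the derivation cohort; "
            "scores were projected with external loadings"
        )
    s = scores.s.to_numpy(dtype=float)
    if s.shape[1] < 2:
        return 0.0
    corr = np.corrcoef(s, rowvar=False)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    return float(np.max(np.abs(off)))


def write_loadings(loadings: LoadingMatrix, path) -> None:
    """Write a loading matrix as CSV with an optional eigenvalue header."""
    with open(path, "w", newline="") as fh:
        if loadings.eigenvalues is not None:
            ev = ",".join(f"{e:.12g}" for e in loadings.eigenvalues)
            fh.write(f"#eigenvalue,{ev}\n")
        loadings.v.rename_axis("variable").to_csv(fh, float_format="%.12g")


def read_loadings(path) -> LoadingMatrix:
    """Read a loading matrix CSV; rows are matched to the canonical
    variable order by name (any row order is accepted)."""
    eigenvalues = None
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    body = []
    for line in lines:
        if line.startswith("#eigenvalue"):
            parts = [p for p in line.split(",")[1:] if p.strip()]
            eigenvalues = np.array([float(p) for p in parts])
        elif line.strip():
            body.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body)))
    if "variable" not in df.columns:
        raise ValueError("loading CSV needs a 'variable' column")
    df = df.set_index("variable")
    unknown = set(df.index) - set(FEATURE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown variable names in loading CSV: {sorted(unknown)}")
    if set(df.index) != set(FEATURE_COLUMNS):
        raise ValueError(
            f"loading CSV must contain exactly the 17 canonical variables, got {len(df)}"
        )
    if list(df.columns) != list(SCORE_COLUMNS):
        raise ValueError(f"loading CSV columns must be {SCORE_COLUMNS}, got {list(df.columns)}")
    if df.isna().to_numpy().any():
        raise ValueError("loading CSV contains non-numeric or empty cells")
    df = df.loc[list(FEATURE_COLUMNS)].astype(float)
    return LoadingMatrix(v=df, eigenvalues=eigenvalues, provenance="external-file")
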