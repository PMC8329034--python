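"""Morphometric statistics engine.

Implements the feature-extraction path used to distil the 28 femoral
parameters into a small set of principal components: column
standardization, sampling-adequacy tests (KMO, Bartlett sphericity),
eigendecomposition of the correlation matrix with a two-part retention
rule (cumulative contribution rate >= 90 %, eigenvalue floor 0.5), varimax
rotation for interpretation, per-subject component and composite scores,
tertile classification, and ANOVA validation of the classes.

Component scores are plain linear forms in the standardized parameters,
``p_i = sum_j a_ij X_j`` for the proximal block and ``q_i = sum_j b_ij Y_j``
for the distal block, where the ``a_ij`` / ``b_ij`` rows are unit
eigenvectors of the block correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import CohortMatrix, ParameterSchema, FEMUR_SCHEMA

__all__ = [
    "SummaryStats",
    "CorrelationMatrix",
    "EigenSystem",
    "LoadingMatrix",
    "AnovaResult",
    "standardize",
    "inverse_standardize",
    "summary_stats",
    "correlation_matrix",
    "kmo",
    "bartlett_sphericity",
    "eigendecompose",
    "retain_components",
    "component_scores",
    "varimax_rotate",
    "dominant_parameters",
    "composite_score",
    "classify_cohort",
    "anova_by_class",
    "reconstruct_parameters",
    "analyze_block",
]


# ---------------------------------------------------------------------------
# standardization and summaries

def standardize(cohort: CohortMatrix) -> CohortMatrix:
    """Center and scale every column to mean 0, sample SD 1 (n-1 denominator).

    The column means and SDs are stored on the returned cohort so the
    transform is invertible via :func:`inverse_standardize`.
    """
    means = cohort.values.mean(axis=0)
    sds = cohort.values.std(axis=0, ddof=1)
    for j, s in enumerate(sds):
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"parameter {cohort.columns[j]} has zero variance; cannot standardize")
    z = (cohort.values - means) / sds
    return CohortMatrix(z, cohort.columns, cohort.schema, cohort.subject_ids,
                        standardized=True, means=means, sds=sds)


def inverse_standardize(cohort: CohortMatrix) -> CohortMatrix:
    if not cohort.standardized or cohort.means is None:
        raise ValueError("cohort is not a standardized cohort with stored means/SDs")
    x = cohort.values * cohort.sds + cohort.means
    return CohortMatrix(x, cohort.columns, cohort.schema, cohort.subject_ids)


@dataclass(frozen=True)
class SummaryStats:
    """Per-parameter sample mean, SD (n-1) and adjusted Fisher-Pearson skewness."""

    table: pd.DataFrame  # index = parameter names; columns mean, sd, skewness
    n: int

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.loc[name]


def summary_stats(cohort: CohortMatrix) -> SummaryStats:
    if cohort.n < 3:
        raise ValueError("skewness requires at least 3 subjects")
    table = pd.DataFrame(
        {
            "mean": cohort.values.mean(axis=0),
            "sd": cohort.values.std(axis=0, ddof=1),
            "skewness": stats.skew(cohort.values, axis=0, bias=False),
        },
        index=cohort.columns,
    )
    return SummaryStats(table, cohort.n)


# ---------------------------------------------------------------------------
# correlation structure and adequacy tests

@dataclass(frozen=True)
class CorrelationMatrix:
    values: np.ndarray
    columns: tuple[str, ...]
    n: int                      # sample size used to estimate it
    rank_deficient: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(v) > 1 + 1e-8):
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def p(self) -> int:
        return self.values.shape[0]


def correlation_matrix(standardized: CohortMatrix) -> CorrelationMatrix:
    """Pearson correlation of a standardized cohort (z'z / (n-1))."""
    if not standardized.standardized:
        raise ValueError("correlation_matrix expects a standardized cohort")
    n = standardized.n
    r = standardized.values.T @ standardized.values / (n - 1)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    deficient = n <= standardized.p
    if deficient:
        warnings.warn("n <= p: correlation matrix is rank deficient", stacklevel=2)
    return CorrelationMatrix(r, tuple(standardized.columns), n, deficient)


def _partial_correlations(r: np.ndarray) -> np.ndarray:
    """Partial correlations from the (pseudo-)inverse correlation matrix."""
    try:
        inv = np.linalg.inv(r)
    except np.linalg.LinAlgError:
        warnings.warn("correlation matrix singular; using pseudo-inverse", stacklevel=3)
        inv = np.linalg.pinv(r)
    d = np.sqrt(np.abs(np.diag(inv)))
    q = -inv / np.outer(d, d)
    np.fill_diagonal(q, 1.0)
    return q


def kmo(corr: CorrelationMatrix) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    ``KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2)`` over off-diagonal
    elements, where ``q_ij`` are partial correlations.  Values near 1 mean
    the block is suitable for component extraction.
    """
    r = corr.values
    off = ~np.eye(corr.p, dtype=bool)
    r2 = np.sum(r[off] ** 2)
    if r2 < 1e-300:
        raise ValueError("no correlations to assess (identity correlation matrix)")
    q = _partial_correlations(r)
    q2 = np.sum(q[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett_sphericity(corr: CorrelationMatrix, n: int) -> tuple[float, int, float]:
    """Bartlett's test of sphericity (H0: correlation matrix is identity).

    Returns ``(chi2, df, p_value)`` with
    ``chi2 = -(n - 1 - (2p + 5)/6) * ln det(R)`` on ``p(p-1)/2`` degrees of
    freedom.
    """
    p = corr.p
    if n <= p:
        raise ValueError("Bartlett test requires n > p")
    sign, logdet = np.linalg.slogdet(corr.values)
    if sign <= 0:
        raise ValueError("correlation matrix is singular; Bartlett statistic undefined")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


# ---------------------------------------------------------------------------
# eigenstructure, retention, loadings

@dataclass(frozen=True)
class EigenSystem:
    """Descending eigenvalues/eigenvectors of a correlation matrix.

    Contribution rates are ``lambda_k / p`` (fraction of the total variance
    of p standardized variables explained by component k).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray        # unit columns, one per eigenvalue
    p: int

    @property
    def contribution_rates(self) -> np.ndarray:
        return self.eigenvalues / self.p

    @property
    def cumulative_rates(self) -> np.ndarray:
        return np.cumsum(self.contribution_rates)

    @classmethod
    def from_rates(cls, rates: np.ndarray, p: int) -> "EigenSystem":
        """Build a vector-free eigensystem from printed contribution rates."""
        lam = np.asarray(rates, dtype=float) * p
        return cls(lam, np.zeros((p, len(lam))), p)


def eigendecompose(corr: CorrelationMatrix) -> EigenSystem:
    lam, vec = np.linalg.eigh(corr.values)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vec = vec[:, order]
    # sign convention: largest-magnitude entry of each eigenvector positive
    for k in range(vec.shape[1]):
        j = np.argmax(np.abs(vec[:, k]))
        if vec[j, k] < 0:
            vec[:, k] = -vec[:, k]
    return EigenSystem(lam, vec, corr.p)


def retain_components(eig: EigenSystem, var_threshold: float = 0.90,
                      eig_floor: float = 0.5) -> int:
    """Number of components to keep.

    The smallest k whose cumulative contribution rate reaches
    ``var_threshold`` (inclusive), truncated so that every retained
    eigenvalue is strictly greater than ``eig_floor``.  When the two
    criteria conflict the eigenvalue floor wins and a warning is emitted.
    """
    lam = eig.eigenvalues
    if lam.size == 0:
        raise ValueError("empty eigensystem")
    cum = eig.cumulative_rates
    k = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    k = min(k, lam.size)
    k_var = k
    while k > 0 and lam[k - 1] <= eig_floor:
        k -= 1
    if k == 0:
        raise ValueError("no eigenvalue exceeds the floor; nothing to retain")
    if k < k_var:
        warnings.warn(
            f"variance threshold wants k={k_var} but eigenvalue floor {eig_floor} "
            f"truncates to k={k}", stacklevel=2)
    return k


@dataclass(frozen=True)
class LoadingMatrix:
    """k x p loading matrix; rows are components, columns variables.

    Raw loadings are unit eigenvector rows; rotated loadings (varimax) keep
    per-variable communalities but lose row unit norms.
    """

    matrix: np.ndarray
    variables: tuple[str, ...]
    rotated: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.variables):
            raise ValueError("loading matrix width must match variable count")

    @property
    def k(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def communalities(self) -> np.ndarray:
        return np.sum(self.matrix ** 2, axis=0)

    @classmethod
    def from_columns(cls, table: np.ndarray, variables: list[str],
                     rotated: bool = False) -> "LoadingMatrix":
        """Build from the printed orientation (variables as rows, components
        as columns)."""
        return cls(np.asarray(table, dtype=float).T, tuple(variables), rotated)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.T, index=self.variables,
                            columns=[f"PC{i+1}" for i in range(self.k)])


def component_scores(standardized_subject: np.ndarray, loadings: LoadingMatrix) -> np.ndarray:
    """Score vector ``s_i = sum_j loading_ij x_j`` for one standardized subject
    (or a whole n x p standardized matrix, giving n x k scores)."""
    x = np.asarray(standardized_subject, dtype=float)
    if x.shape[-1] != loadings.p:
        raise ValueError(f"subject vector has {x.shape[-1]} entries, loadings expect {loadings.p}")
    return x @ loadings.matrix.T


def varimax_rotate(loadings: LoadingMatrix, kaiser_normalize: bool = True,
                   tol: float = 1e-10, max_sweeps: int = 1000) -> LoadingMatrix:
    """Varimax rotation by pairwise Jacobi sweeps.

    Maximizes the variance of squared loadings within each component under
    an orthogonal rotation; communalities are invariant.  With Kaiser
    normalization each variable is scaled to unit communality during the
    rotation and rescaled afterwards.
    """
    if loadings.rotated:
        raise ValueError("loadings are already rotated")
    if loadings.k == 1:
        return LoadingMatrix(loadings.matrix.copy(), loadings.variables,
                             rotated=False, note="k=1: rotation is a no-op")
    A = loadings.matrix.T.copy()          # p x k, variables as rows
    p, k = A.shape
    h = np.sqrt(np.sum(A ** 2, axis=1))
    if kaiser_normalize:
        scale = np.where(h > 0, h, 1.0)
        A = A / scale[:, None]

    def criterion(M):
        sq = M ** 2
        return np.sum(sq ** 2) - np.sum(np.sum(sq, axis=0) ** 2) / p

    last = criterion(A)
    for _ in range(max_sweeps):
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = A[:, i], A[:, j]
                u = x ** 2 - y ** 2
                v = 2.0 * x * y
                num = 2.0 * (np.sum(u * v) - np.sum(u) * np.sum(v) / p)
                den = np.sum(u ** 2 - v ** 2) - (np.sum(u) ** 2 - np.sum(v) ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                A[:, i], A[:, j] = c * x + s * y, -s * x + c * y
        cur = criterion(A)
        if cur - last < tol:
            break
        last = cur
    if kaiser_normalize:
        A = A * scale[:, None]
    return LoadingMatrix(A.T, loadings.variables, rotated=True)


def dominant_parameters(rotated: LoadingMatrix,
                        schema: ParameterSchema | None = None) -> dict[int, list[str]]:
    """Assign each variable to the component with its largest absolute
    loading; returns ``{component index (1-based): [parameter names]}`` in
    schema (variable) order.  Ties within 1e-9 go to the lower component
    index with a warning."""
    out: dict[int, list[str]] = {i + 1: [] for i in range(rotated.k)}
    absm = np.abs(rotated.matrix)
    for j, name in enumerate(rotated.variables):
        col = absm[:, j]
        best = int(np.argmax(col))
        near = np.nonzero(col >= col[best] - 1e-9)[0]
        if len(near) > 1:
            warnings.warn(f"loading tie for {name}; assigned to component {near[0] + 1}",
                          stacklevel=2)
            best = int(near[0])
        out[best + 1].append(name)
    return out


# ---------------------------------------------------------------------------
# composite scoring, classification, validation

def composite_score(scores: np.ndarray, rates: np.ndarray,
                    normalized: bool = False) -> np.ndarray | float:
    """Variance-contribution-weighted sum of component scores,
    ``F = sum_k rate_k s_k``.  ``normalized=True`` divides by ``sum(rates)``."""
    scores = np.asarray(scores, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if scores.shape[-1] != rates.shape[0]:
        raise ValueError("score / rate dimension mismatch")
    f = scores @ rates
    if normalized:
        f = f / rates.sum()
    return f


def classify_cohort(composites: np.ndarray) -> np.ndarray:
    """Tertile split of composite scores into classes 1 (low) / 2 / 3 (high).

    Ties are broken by subject order (stable sort); class sizes differ by at
    most one, with earlier tertiles taking the extra subject.
    """
    f = np.asarray(composites, dtype=float)
    n = f.size
    if n < 3:
        raise ValueError("classification requires n >= 3")
    if np.ptp(f) == 0:
        raise ValueError("degenerate scores: all composite scores identical")
    order = np.argsort(f, kind="stable")
    labels = np.empty(n, dtype=int)
    sizes = [len(c) for c in np.array_split(np.arange(n), 3)]
    bounds = np.cumsum(sizes)
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    labels = np.searchsorted(bounds, ranks, side="right") + 1
    return labels


@dataclass(frozen=True)
class AnovaResult:
    table: pd.DataFrame           # index parameter; columns F, p
    significant_fraction: float   # share of parameters with p < 0.05


def anova_by_class(cohort: CohortMatrix, labels: np.ndarray,
                   alpha: float = 0.05) -> AnovaResult:
    """Classical one-way ANOVA of every parameter across the class labels."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    counts = {int(c): int(np.sum(labels == c)) for c in classes}
    if any(v < 2 for v in counts.values()):
        raise ValueError(f"every class needs >= 2 subjects, got {counts}")
    rows = {}
    for j, name in enumerate(cohort.columns):
        groups = [cohort.values[labels == c, j] for c in classes]
        F, p = stats.f_oneway(*groups)
        rows[name] = (float(F), float(p))
    table = pd.DataFrame(rows, index=["F", "p"]).T
    frac = float(np.mean(table["p"] < alpha))
    return AnovaResult(table, frac)


def reconstruct_parameters(scores: np.ndarray, loadings: LoadingMatrix) -> np.ndarray:
    """Least-squares reconstruction of the standardized parameter vector,
    ``x_hat = A^T s`` — the orthogonal projection onto the span of the
    retained components.  Only valid for raw (unit eigenvector row)
    loadings."""
    if loadings.rotated:
        raise ValueError("reconstruction requires raw loadings (rotated rows are not orthonormal)")
    s = np.asarray(scores, dtype=float)
    if s.shape[-1] != loadings.k:
        raise ValueError("score dimension does not match loading rows")
    return s @ loadings.matrix


# ---------------------------------------------------------------------------
# full block pipeline

@dataclass
class BlockAnalysis:
    """PCA of one parameter block, end to end."""

    columns: list[str]
    kmo: float
    bartlett: tuple[float, int, float]
    eigen: EigenSystem
    k: int
    loadings: LoadingMatrix
    rotated: LoadingMatrix
    dominant: dict[int, list[str]]
    scores: np.ndarray            # n x k
    composite: np.ndarray         # n

    def to_report(self) -> dict:
        chi2, df, pval = self.bartlett
        return {
            "columns": self.columns,
            "kmo": self.kmo,
            "bartlett": {"chi2": chi2, "df": df, "p": pval},
            "eigenvalues": self.eigen.eigenvalues.tolist(),
            "contribution_rates": self.eigen.contribution_rates.tolist(),
            "cumulative_rates": self.eigen.cumulative_rates.tolist(),
            "k": self.k,
            "loadings": self.loadings.to_frame().to_dict(orient="list"),
            "rotated_loadings": self.rotated.to_frame().to_dict(orient="list"),
            "dominant_parameters": {str(c): names for c, names in self.dominant.items()},
        }


def analyze_block(cohort: CohortMatrix, columns: list[str] | None = None,
                  var_threshold: float = 0.90, eig_floor: float = 0.5) -> BlockAnalysis:
    """Run the full extraction path on a parameter block: standardize,
    adequacy tests, eigendecomposition, retention, rotation, scoring."""
    block = cohort if columns is None else cohort.select(columns)
    z = standardize(block)
    corr = correlation_matrix(z)
    adequacy = kmo(corr)
    bart = bartlett_sphericity(corr, z.n)
    eig = eigendecompose(corr)
    k = retain_components(eig, var_threshold, eig_floor)
    raw = LoadingMatrix(eig.eigenvectors[:, :k].T, tuple(block.columns))
    rot = varimax_rotate(raw) if k >= 2 else LoadingMatrix(
        raw.matrix.copy(), raw.variables, rotated=False, note="k=1")
    dom = dominant_parameters(rot if k >= 2 else raw)
    scores = component_scores(z.values, raw)
    comp = composite_score(scores, eig.contribution_rates[:k])
    return BlockAnalysis(list(block.columns), adequacy, bart, eig, k, raw, rot,
                         dom, scores, comp)
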