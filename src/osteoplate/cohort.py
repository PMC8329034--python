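"""Synthetic cohort generation.

No subject-level femoral data is deposited with the reference statistics,
so downstream testing needs a cohort emulator: multivariate-normal
parameter vectors whose per-parameter means/SDs match the reference cohort
and whose correlation structure is reconstructed from the published
loading matrices and variance contribution rates.

Reconstruction: with unit eigenvector rows ``v_k`` and contribution rates
``r_k``, the rank-k correlation backbone is ``R0 = sum_k (r_k p) v_k v_k^T``;
the residual variance ``1 - communality`` is placed on the diagonal as
uncorrelated noise (diagonal reset to 1), and the result is repaired to
positive semidefiniteness by eigenvalue clipping.  Cross-block
correlations (proximal-distal, shaft, overall length) are not published
and are set to zero, so the full matrix is block-diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import reference
from .morphometry import (
    CorrelationMatrix, LoadingMatrix, bartlett_sphericity, correlation_matrix,
    kmo, standardize, summary_stats,
)
from .schema import CohortMatrix, FEMUR_SCHEMA, ParameterSchema

__all__ = [
    "CohortSpec",
    "ReconstructedCorrelation",
    "reconstruct_correlation",
    "default_correlation",
    "proximal_reconstructed_correlation",
    "generate_cohort",
    "validate_cohort",
]


@dataclass(frozen=True)
class ReconstructedCorrelation:
    values: np.ndarray
    provenance: str
    repair_delta: float     # Frobenius norm of the PSD repair adjustment

    @property
    def p(self) -> int:
        return self.values.shape[0]


def reconstruct_correlation(loadings: LoadingMatrix, rates: np.ndarray,
                            provenance: str = "reconstructed") -> ReconstructedCorrelation:
    """Correlation matrix consistent with published loadings and rates."""
    A = np.asarray(loadings.matrix, dtype=float)
    rates = np.asarray(rates, dtype=float)
    k, p = A.shape
    if rates.shape != (k,):
        raise ValueError("one contribution rate per loading row required")
    if np.any((rates <= 0) | (rates >= 1)):
        raise ValueError("rates must lie in (0, 1)")
    norms = np.linalg.norm(A, axis=1)
    if np.any(np.abs(norms - 1) > 0.05):
        raise ValueError(f"loading rows must be unit eigenvectors; norms {norms}")
    lam = rates * p
    if lam.sum() > p * 1.05:
        raise ValueError("rates * p exceed total variance: inconsistent inputs")
    r0 = (A.T * lam) @ A
    np.fill_diagonal(r0, 1.0)
    before = r0.copy()
    # PSD repair: eigenvalue clipping, then restore symmetry and unit diagonal
    w, v = np.linalg.eigh((r0 + r0.T) / 2.0)
    w = np.clip(w, 1e-8, None)
    r = (v * w) @ v.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    delta = float(np.linalg.norm(r - before, "fro"))
    return ReconstructedCorrelation(r, provenance, delta)


def proximal_reconstructed_correlation() -> ReconstructedCorrelation:
    """9 x 9 proximal-block correlation from the reference loading table."""
    lm = LoadingMatrix.from_columns(reference.PROXIMAL_LOADINGS,
                                    FEMUR_SCHEMA.region_names("proximal"))
    return reconstruct_correlation(lm, reference.PROXIMAL_RATES,
                                   "proximal loadings (4 comps) + rates")


def _distal_reconstructed_correlation() -> ReconstructedCorrelation:
    # only the six genuine distal columns are usable (the printed seventh is
    # a communality column); rows renormalized to unit length
    cols = reference.distal_loadings_usable()     # 16 x 6
    A = cols.T
    A = A / np.linalg.norm(A, axis=1, keepdims=True)
    lm = LoadingMatrix(A, tuple(FEMUR_SCHEMA.region_names("distal")))
    return reconstruct_correlation(lm, reference.DISTAL_RATES[:6],
                                   "distal loadings (6 usable comps) + rates")


def default_correlation(schema: ParameterSchema = FEMUR_SCHEMA) -> tuple[np.ndarray, dict]:
    """Block-diagonal correlation over all 29 columns (28 parameters + H_f).

    Proximal and distal blocks are reconstructed from the reference tables;
    the shaft block and H_f carry no published correlation information and
    are independent.
    """
    names = schema.names
    p = len(names)
    r = np.eye(p)
    prox = proximal_reconstructed_correlation()
    dist = _distal_reconstructed_correlation()
    ip = [names.index(n) for n in schema.region_names("proximal")]
    idx = [names.index(n) for n in schema.region_names("distal")]
    r[np.ix_(ip, ip)] = prox.values
    r[np.ix_(idx, idx)] = dist.values
    info = {"proximal_repair_delta": prox.repair_delta,
            "distal_repair_delta": dist.repair_delta}
    return r, info


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort.

    Defaults reproduce the reference cohort's printed means/SDs; the
    correlation source is one of ``"reconstructed"`` (default),
    ``"identity"``, or a user-supplied matrix over the schema columns.
    """

    n: int
    seed: int
    correlation: str | np.ndarray = "reconstructed"
    schema: ParameterSchema = field(default_factory=lambda: FEMUR_SCHEMA)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")


def generate_cohort(spec: CohortSpec) -> CohortMatrix:
    """Draw a multivariate-normal cohort under the spec.

    Deterministic under a fixed seed.  Values are de-standardized with the
    schema means/SDs, so e.g. the femoral length column reproduces
    mean 420.072 mm / SD 22.968 mm at large n.
    """
    schema = spec.schema
    names = schema.names
    p = len(names)
    if isinstance(spec.correlation, str):
        if spec.correlation == "reconstructed":
            r, _ = default_correlation(schema)
        elif spec.correlation == "identity":
            r = np.eye(p)
        else:
            raise ValueError(f"unknown correlation source {spec.correlation!r}")
    else:
        r = np.asarray(spec.correlation, dtype=float)
        if r.shape != (p, p):
            raise ValueError("user correlation has wrong shape")
    try:
        chol = np.linalg.cholesky(r + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "correlation matrix is not positive semidefinite; repair it with "
            "reconstruct_correlation first") from exc
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n, p)) @ chol.T
    values = z * schema.sds() + schema.means()
    return CohortMatrix(values, names, schema)


def validate_cohort(cohort: CohortMatrix) -> dict:
    """Distributional sanity report: per-parameter skewness (flagging
    |skew| > 0.5), KMO of the proximal+distal block, Bartlett p-value."""
    if cohort.n < 30:
        raise ValueError("validation requires n >= 30")
    ss = summary_stats(cohort)
    skew = ss.table["skewness"]
    flagged = [n for n in cohort.columns if abs(skew[n]) > 0.5]
    block_names = [n for n in cohort.columns
                   if cohort.schema[n].region in ("proximal", "distal")]
    report = {
        "n": cohort.n,
        "skewness": {n: float(skew[n]) for n in cohort.columns},
        "skew_flagged": flagged,
    }
    if len(block_names) >= 2:
        z = standardize(cohort.select(block_names))
        corr = correlation_matrix(z)
        try:
            report["kmo"] = kmo(corr)
        except ValueError as exc:
            report["kmo"] = None
            report["kmo_error"] = str(exc)
        try:
            _, _, pval = bartlett_sphericity(corr, cohort.n)
            report["bartlett_p"] = pval
        except ValueError as exc:
            report["bartlett_p"] = None
            report["bartlett_error"] = str(exc)
    return report
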