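"""Statistical engine: standardization, adequacy tests, PCA retention,
rotation, scoring, classification and reconstruction."""

import numpy as np
import pytest

from osteoplate.morphometry import (
    CorrelationMatrix, EigenSystem, LoadingMatrix, anova_by_class,
    bartlett_sphericity, classify_cohort, component_scores, composite_score,
    correlation_matrix, dominant_parameters, eigendecompose,
    inverse_standardize, kmo, reconstruct_parameters, retain_components,
    standardize, summary_stats, varimax_rotate,
)
from osteoplate.reference import (DISTAL_RATES, PROXIMAL_LOADINGS, PROXIMAL_RATES)
from osteoplate.schema import CohortMatrix, FEMUR_SCHEMA

PROX = FEMUR_SCHEMA.region_names("proximal")


def _cohort(values, columns):
    return CohortMatrix(np.asarray(values, dtype=float), columns,
                        standardized=True)


# ---------------------------------------------------------------------------
# standardization / summaries

def test_standardize_round_trip_and_moments(rng):
    vals = rng.normal(50, 5, size=(40, 3)).clip(min=1)
    c = CohortMatrix(vals, ["H_fh", "L_fn", "D_fh"])
    z = standardize(c)
    assert np.allclose(z.values.mean(axis=0), 0, atol=1e-10)
    assert np.allclose(z.values.std(axis=0, ddof=1), 1, atol=1e-10)
    back = inverse_standardize(z)
    assert np.allclose(back.values, vals, atol=1e-9)


def test_standardize_rejects_constant_column():
    c = _cohort(np.column_stack([np.ones(10), np.arange(10.0)]), ["H_fh", "L_fn"])
    with pytest.raises(ValueError, match="H_fh"):
        standardize(c)


def test_summary_stats_symmetric_and_small():
    c = _cohort(np.column_stack([[-1.0, 0.0, 1.0], [1.0, 2.0, 3.0]]),
                ["H_fh", "L_fn"])
    ss = summary_stats(c)
    assert ss["H_fh"]["skewness"] == pytest.approx(0.0, abs=1e-12)
    assert ss["L_fn"]["mean"] == pytest.approx(2.0)
    assert ss["L_fn"]["sd"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        summary_stats(_cohort([[1.0], [2.0]], ["H_fh"]))


# ---------------------------------------------------------------------------
# correlation and adequacy

def test_correlation_identical_columns_and_oracle():
    x = np.array([1.0, -0.5, 2.0])
    c = _cohort(np.column_stack([x, x]), ["H_fh", "L_fn"])
    r = correlation_matrix(standardize(CohortMatrix(
        np.column_stack([x + 3, x + 3]), ["H_fh", "L_fn"], standardized=True)))
    assert r.values[0, 1] == pytest.approx(1.0)

    # 3 x 2 hand matrix against the direct sum z_i z_j / (n-1) formula
    vals = np.array([[1.0, 2.0], [2.0, 1.0], [4.0, 5.0]])
    z = standardize(CohortMatrix(vals, ["H_fh", "L_fn"], standardized=True))
    r = correlation_matrix(z)
    brute = z.values[:, 0] @ z.values[:, 1] / 2.0
    assert r.values[0, 1] == pytest.approx(brute, abs=1e-12)


def test_correlation_independent_columns_vanish(rng):
    n = 4000
    vals = rng.normal(size=(n, 3))
    z = standardize(CohortMatrix(vals, ["H_fh", "L_fn", "D_fh"], standardized=True))
    r = correlation_matrix(z).values
    off = r[~np.eye(3, dtype=bool)]
    assert np.all(np.abs(off) < 3 / np.sqrt(n))


def _kmo_oracle(r):
    inv = np.linalg.inv(r)
    p = r.shape[0]
    q = np.zeros_like(r)
    for i in range(p):
        for j in range(p):
            q[i, j] = -inv[i, j] / np.sqrt(inv[i, i] * inv[j, j])
    num = den_q = 0.0
    for i in range(p):
        for j in range(p):
            if i != j:
                num += r[i, j] ** 2
                den_q += q[i, j] ** 2
    return num / (num + den_q)


def _random_correlation(rng, p):
    a = rng.normal(size=(p + 3, p))
    r = np.corrcoef(a, rowvar=False)
    return r


def test_kmo_two_variables_is_half(rng):
    # for p=2 the partial correlation equals the correlation, so the ratio
    # is r^2 / (r^2 + r^2) = 1/2 for any r != 0
    for rho in (-0.8, 0.3, 0.95):
        r = CorrelationMatrix(np.array([[1.0, rho], [rho, 1.0]]), ("a", "b"), 10)
        assert kmo(r) == pytest.approx(0.5, abs=1e-12)


def test_kmo_identity_errors():
    r = CorrelationMatrix(np.eye(4), tuple("abcd"), 10)
    with pytest.raises(ValueError, match="no correlations"):
        kmo(r)


def test_kmo_matches_partial_correlation_oracle(rng):
    for p in (4, 5, 6):
        for _ in range(5):
            m = _random_correlation(rng, p)
            r = CorrelationMatrix(m, tuple(f"v{i}" for i in range(p)), 20)
            assert kmo(r) == pytest.approx(_kmo_oracle(m), abs=1e-10)


def test_bartlett_identity_and_formula():
    r = CorrelationMatrix(np.eye(3), ("a", "b", "c"), 50)
    chi2, df, p = bartlett_sphericity(r, 50)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert df == 3
    assert p == pytest.approx(1.0)

    m = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
    chi2, df, p = bartlett_sphericity(CorrelationMatrix(m, ("a", "b", "c"), 50), 50)
    expected = -(50 - 1 - (2 * 3 + 5) / 6) * np.log(np.linalg.det(m))
    assert chi2 == pytest.approx(expected, rel=1e-12)
    assert df == 3

    near = np.array([[1.0, 0.9999, 0.0], [0.9999, 1.0, 0.0], [0.0, 0.0, 1.0]])
    chi2, _, p = bartlett_sphericity(CorrelationMatrix(near, ("a", "b", "c"), 50), 50)
    assert chi2 > 100 and p < 1e-10


# ---------------------------------------------------------------------------
# eigenstructure and retention

def test_eigendecompose_identity_and_rank_one(rng):
    eig = eigendecompose(CorrelationMatrix(np.eye(5), tuple("abcde"), 10))
    assert np.allclose(eig.eigenvalues, 1.0)
    assert eig.contribution_rates.sum() == pytest.approx(1.0)

    v = rng.normal(size=4)
    v /= np.linalg.norm(v)
    lam = 2.5
    m = lam * np.outer(v, v)
    w, vec = np.linalg.eigh(m)
    es = EigenSystem(np.sort(w)[::-1], vec, 4)
    assert es.eigenvalues[0] == pytest.approx(lam)
    assert np.allclose(es.eigenvalues[1:], 0, atol=1e-12)


def test_eigendecompose_sign_convention_and_trace(rng):
    m = _random_correlation(rng, 6)
    eig = eigendecompose(CorrelationMatrix(m, tuple(f"v{i}" for i in range(6)), 20))
    assert eig.eigenvalues.sum() == pytest.approx(6.0, abs=1e-6)
    for k in range(6):
        col = eig.eigenvectors[:, k]
        assert col[np.argmax(np.abs(col))] > 0
    assert np.allclose(eig.eigenvectors.T @ eig.eigenvectors, np.eye(6), atol=1e-8)


def test_reconstruction_backbone_eigenvalues_match_rates():
    # the rank-4 backbone sum_k (rate_k * 9) v_k v_k^T has eigenvalues
    # rate_k * 9 (construction oracle)
    A = PROXIMAL_LOADINGS.T
    lam = PROXIMAL_RATES * 9
    r0 = (A.T * lam) @ A
    w = np.sort(np.linalg.eigvalsh((r0 + r0.T) / 2))[::-1]
    assert np.allclose(w[:4], [3.875, 2.290, 1.276, 0.702], atol=0.05)


def test_retention_reproduces_reference_counts():
    prox = EigenSystem.from_rates(PROXIMAL_RATES_FULL := np.concatenate(
        [PROXIMAL_RATES, [0.03, 0.02, 0.015, 0.01, 0.005]]), 9)
    assert retain_components(prox) == 4
    dist = EigenSystem.from_rates(np.concatenate(
        [DISTAL_RATES, np.full(9, (1 - DISTAL_RATES.sum()) / 9)]), 16)
    assert retain_components(dist) == 7


def test_retention_equal_eigenvalues_inclusive_boundary():
    eig = EigenSystem.from_rates(np.full(10, 0.1), 10)
    assert retain_components(eig) == 9   # cumulative 9/10 meets >= 0.90


def test_retention_floor_wins_with_warning():
    # variance rule wants 3 components but the third eigenvalue is under 0.5
    eig = EigenSystem(np.array([4.0, 3.0, 0.4, 0.3]), np.zeros((8, 4)), 8)
    with pytest.warns(UserWarning, match="floor"):
        assert retain_components(eig) == 2


def test_retention_monotone_in_threshold(rng):
    lam = np.sort(rng.uniform(0.6, 3.0, size=7))[::-1]
    lam *= 7 / lam.sum()
    eig = EigenSystem(lam, np.zeros((7, 7)), 7)
    ks = [retain_components(eig, var_threshold=t) for t in np.linspace(0.3, 0.999, 15)]
    assert all(a <= b for a, b in zip(ks, ks[1:]))


# ---------------------------------------------------------------------------
# scores and loadings

def test_component_scores_linear_forms():
    lm = LoadingMatrix.from_columns(PROXIMAL_LOADINGS, PROX)
    assert np.allclose(component_scores(np.zeros(9), lm), 0.0)
    e1 = np.eye(9)[0]
    assert np.allclose(component_scores(e1, lm), [0.348, 0.291, 0.384, 0.289])
    v1 = PROXIMAL_LOADINGS[:, 0]
    s = component_scores(v1, lm)
    assert s[0] == pytest.approx(1.001, abs=0.05)
    assert np.all(np.abs(s[1:]) < 0.05)
    with pytest.raises(ValueError):
        component_scores(np.zeros(5), lm)


def test_reference_loading_rows_are_unit_eigenvectors():
    lm = LoadingMatrix.from_columns(PROXIMAL_LOADINGS, PROX)
    norms = np.linalg.norm(lm.matrix, axis=1)
    assert np.allclose(norms, 1.0, atol=0.01)


def _varimax_criterion(A):
    sq = A ** 2
    return np.sum(sq ** 2) - np.sum(np.sum(sq, axis=0) ** 2) / A.shape[0]


def test_varimax_preserves_communalities_and_norm(rng):
    A = rng.normal(size=(3, 8))
    lm = LoadingMatrix(A, tuple(f"v{i}" for i in range(8)))
    rot = varimax_rotate(lm)
    assert rot.rotated
    assert np.allclose(rot.communalities(), lm.communalities(), atol=1e-8)
    assert np.linalg.norm(rot.matrix) == pytest.approx(np.linalg.norm(A), abs=1e-8)


def test_varimax_simple_structure_fixed_point():
    A = np.zeros((2, 6))
    A[0, :3] = 0.9
    A[1, 3:] = 0.8
    rot = varimax_rotate(LoadingMatrix(A, tuple("abcdef")))
    # already perfectly simple: unchanged up to column sign/order
    got = np.sort(np.abs(rot.matrix).ravel())
    assert np.allclose(got, np.sort(np.abs(A).ravel()), atol=1e-8)


def test_varimax_beats_random_rotations(rng):
    A = rng.normal(size=(3, 6))       # 3 components x 6 variables
    rot = varimax_rotate(LoadingMatrix(A, tuple(f"v{i}" for i in range(6))),
                         kaiser_normalize=False)
    best = _varimax_criterion(rot.matrix.T)
    for _ in range(1000):
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert _varimax_criterion((q @ A).T) <= best + 1e-9


def test_dominant_parameters_identity_and_oracle(rng):
    lm = LoadingMatrix(np.eye(4), ("a", "b", "c", "d"), rotated=True)
    dom = dominant_parameters(lm)
    assert dom == {1: ["a"], 2: ["b"], 3: ["c"], 4: ["d"]}

    A = rng.normal(size=(3, 7))
    dom = dominant_parameters(LoadingMatrix(A, tuple(f"v{i}" for i in range(7)),
                                            rotated=True))
    for j in range(7):
        comp = int(np.argmax(np.abs(A[:, j]))) + 1
        assert f"v{j}" in dom[comp]


def test_dominant_parameters_reference_pattern():
    # fixture shaped like the published rotated solution: D_fh, D_fn, L_t,
    # H_t1 load on component 1
    A = np.full((4, 9), 0.05)
    heavy = [PROX.index(n) for n in ("D_fh", "D_fn", "L_t", "H_t1")]
    A[0, heavy] = 0.9
    A[1, [PROX.index("L_fhs"), PROX.index("L_fn")]] = 0.9
    A[2, [PROX.index("H_fh"), PROX.index("A_fn")]] = 0.9
    A[3, PROX.index("H_t2")] = 0.9
    dom = dominant_parameters(LoadingMatrix(A, tuple(PROX), rotated=True))
    assert dom[1] == ["D_fh", "D_fn", "L_t", "H_t1"]


# ---------------------------------------------------------------------------
# composite score, classes, ANOVA

def test_composite_score_arithmetic():
    assert composite_score(np.zeros(4), PROXIMAL_RATES) == pytest.approx(0.0)
    assert composite_score(np.array([2.5]), np.array([1.0])) == pytest.approx(2.5)
    f = composite_score(np.ones(4), PROXIMAL_RATES)
    assert f == pytest.approx(0.90474, abs=1e-12)


def test_classify_tertiles():
    labels = classify_cohort(np.arange(1.0, 10.0))
    assert labels.tolist() == [1, 1, 1, 2, 2, 2, 3, 3, 3]
    assert sorted(classify_cohort(np.array([5.0, 1.0, 9.0])).tolist()) == [1, 2, 3]
    with pytest.raises(ValueError, match="degenerate"):
        classify_cohort(np.ones(6))


def test_classify_sizes_near_equal(rng):
    labels = classify_cohort(rng.uniform(size=100))
    sizes = np.bincount(labels)[1:]
    assert set(sizes.tolist()) <= {33, 34}


def test_anova_hand_fixture_and_large_effect(rng):
    vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])[:, None] + 10
    c = CohortMatrix(vals, ["H_fh"])
    labels = np.array([1, 1, 1, 2, 2, 2])
    res = anova_by_class(c, labels)
    # by-hand one-way ANOVA: groups {11,12,13} vs {14,15,16}
    # SSB = 2*3*(1.5)^2 = 13.5, SSW = 4, F = 13.5 / (4/4) = 13.5
    assert res.table.loc["H_fh", "F"] == pytest.approx(13.5, rel=1e-12)

    shifted = rng.normal(size=(30, 1))
    shifted[15:] += 5.0
    c2 = CohortMatrix(shifted + 50, ["H_fh"])
    res2 = anova_by_class(c2, np.repeat([1, 2], 15))
    assert res2.table.loc["H_fh", "p"] < 0.05
    with pytest.raises(ValueError):
        anova_by_class(c2, np.array([1] * 29 + [2]))


def test_anova_type_one_error_rate(rng):
    # identical class means: rejection rate should sit at the nominal level
    hits = 0
    n_sim = 500
    for _ in range(n_sim):
        vals = rng.normal(size=(30, 1)) + 100
        labels = classify_cohort(rng.uniform(size=30))
        res = anova_by_class(CohortMatrix(vals, ["H_fh"]), labels)
        hits += res.table.loc["H_fh", "p"] < 0.05
    assert hits / n_sim == pytest.approx(0.05, abs=0.02)


# ---------------------------------------------------------------------------
# reconstruction

def test_reconstruction_projection_identity(rng):
    lm = LoadingMatrix.from_columns(PROXIMAL_LOADINGS, PROX)
    assert np.allclose(reconstruct_parameters(np.zeros(4), lm), 0.0)

    s = rng.normal(size=4)
    x = s @ lm.matrix                       # vector in the retained span
    assert np.allclose(reconstruct_parameters(component_scores(x, lm), lm), x,
                       atol=1e-2)           # rows are unit only to table precision

    x = rng.normal(size=9)
    xh = reconstruct_parameters(component_scores(x, lm), lm)
    assert np.linalg.norm(xh) <= np.linalg.norm(x) * (1 + 0.02)
    # residual orthogonal to every retained eigenvector (up to table rounding)
    resid = x - xh
    gram = np.abs(lm.matrix @ lm.matrix.T - np.eye(4)).max()
    assert np.all(np.abs(lm.matrix @ resid) < 10 * gram * np.linalg.norm(x) + 1e-8)


def test_reconstruction_exact_for_orthonormal_rows(rng):
    q, _ = np.linalg.qr(rng.normal(size=(9, 4)))
    lm = LoadingMatrix(q.T, tuple(PROX))
    s = rng.normal(size=4)
    x = s @ lm.matrix
    assert np.allclose(reconstruct_parameters(component_scores(x, lm), lm), x,
                       atol=1e-8)
    x = rng.normal(size=9)
    xh = reconstruct_parameters(component_scores(x, lm), lm)
    assert np.all(np.abs(lm.matrix @ (x - xh)) < 1e-8)


def test_reconstruction_rejects_rotated(rng):
    lm = LoadingMatrix(rng.normal(size=(3, 6)), tuple(f"v{i}" for i in range(6)),
                       rotated=True)
    with pytest.raises(ValueError, match="raw"):
        reconstruct_parameters(np.zeros(3), lm)
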