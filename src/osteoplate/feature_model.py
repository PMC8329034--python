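"""Plate feature model.

The undersurface of the eagle-shaped plate is carried by twelve feature
curves: one closed boundary curve (C0) and eleven internal auxiliary
curves — the tail ridge C1 and head ridge C2 running longitudinally, and
nine transverse costal curves C3..C11.  The structural (shape) constraint
is the matrix of pairwise topological relations between these curves:

* boundary-internal (BI) relations are classified by intersection count:
  ``BI_0`` (disjoint), ``BI_11`` (one contact), ``BI_21`` (two contacts);
* internal-internal (II) relations are classified by intersection
  position: ``II_0`` (disjoint), ``II_11`` (endpoint-endpoint),
  ``II_12`` (endpoint-interior), ``II_13`` (interior-interior).

The dimension side of the model is the semantic parameter set (total
length L, width W, tail/head lengths l1/l2, local widths w0..w8, bump
heights h0..h8, thicknesses, hole parameters) with its inheritance
hierarchy, derived from bone morphology either directly (primary mapping)
or through principal-component scores (component mapping).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import InitVar, dataclass, field, asdict

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize

from . import reference
from .morphometry import LoadingMatrix, SummaryStats, reconstruct_parameters
from .schema import FEMUR_SCHEMA, FemurParameterSet, ParameterSchema

__all__ = [
    "FeatureCurve",
    "TopologyMatrix",
    "intersection_profile",
    "classify_relation",
    "topology_matrix",
    "validate_topology",
    "SemanticParameterSet",
    "DimensionConstraint",
    "DerivationCoefficients",
    "derive_semantic_parameters",
    "dimension_constraints",
    "check_dimension_constraints",
    "ComponentMapping",
    "default_component_mapping",
    "apply_component_mapping",
    "complete_plate_fixture",
    "eagle_template_matrix",
]

BI_LABELS = ("BI_0", "BI_11", "BI_21")
II_LABELS = ("II_0", "II_11", "II_12", "II_13")


# ---------------------------------------------------------------------------
# feature curves

@dataclass
class FeatureCurve:
    """Cubic-spline curve through an ordered 3-D point sequence (mm)."""

    id: str
    kind: str                 # "boundary" | "internal"
    points: np.ndarray        # m x 3
    closed: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be m x 3")
        if len(self.points) < 4:
            raise ValueError("a feature curve needs at least 4 points")
        if np.any(np.linalg.norm(np.diff(self.points, axis=0), axis=1) == 0):
            raise ValueError("consecutive duplicate points")
        if self.kind not in ("boundary", "internal"):
            raise ValueError("kind must be boundary or internal")
        if self.kind == "boundary" and not self.closed:
            raise ValueError("boundary curves must be closed")
        if self.kind == "internal" and self.closed:
            raise ValueError("internal curves must be open")
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        t = np.concatenate([[0.0], np.cumsum(d)])
        self._t = t
        bc = "periodic" if self.closed else "not-a-knot"
        self._spline = CubicSpline(t, pts, bc_type=bc)

    @property
    def length(self) -> float:
        return float(self._t[-1])

    def evaluate(self, t) -> np.ndarray:
        return self._spline(np.asarray(t, dtype=float))

    def sample(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(0.0, self.length, n)
        return t, self.evaluate(t)

    def termini(self) -> np.ndarray:
        if self.closed:
            return np.empty((0, 3))
        return np.vstack([self.points[0], self.points[-1]])

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "FeatureCurve":
        pts = self.points
        if rotation is not None:
            pts = pts @ np.asarray(rotation).T
        if translation is not None:
            pts = pts + np.asarray(translation)
        return FeatureCurve(self.id, self.kind, pts, self.closed)


# ---------------------------------------------------------------------------
# intersection machinery

def _segment_pair_distances(P, Q):
    """Min distance between every segment of polyline P and of polyline Q.

    Returns (dist, s, t) arrays of shape (len(P)-1, len(Q)-1) where s, t are
    the local parameters of the closest points on each segment.
    """
    A, B = P[:-1], P[1:]
    C, D = Q[:-1], Q[1:]
    d1 = (B - A)[:, None, :]
    d2 = (D - C)[None, :, :]
    r = A[:, None, :] - C[None, :, :]
    a = np.sum(d1 * d1, axis=2)
    e = np.sum(d2 * d2, axis=2)
    f = np.sum(d2 * r, axis=2)
    c = np.sum(d1 * r, axis=2)
    b = np.sum(d1 * d2, axis=2)
    denom = a * e - b * b
    s = np.where(denom > 1e-30, np.clip((b * f - c * e) / np.where(denom > 1e-30, denom, 1.0), 0, 1), 0.0)
    t = (b * s + f) / np.where(e > 1e-30, e, 1.0)
    t_cl = np.clip(t, 0, 1)
    # re-project s for clamped t
    s = np.clip((b * t_cl - c) / np.where(a > 1e-30, a, 1.0), 0, 1)
    p1 = A[:, None, :] + s[..., None] * d1
    p2 = C[None, :, :] + t_cl[..., None] * d2
    dist = np.linalg.norm(p1 - p2, axis=2)
    return dist, s, t_cl


def _chord_deviation(curve: FeatureCurve, t: np.ndarray, pts: np.ndarray) -> float:
    mid = curve.evaluate((t[:-1] + t[1:]) / 2.0)
    chord_mid = (pts[:-1] + pts[1:]) / 2.0
    return float(np.max(np.linalg.norm(mid - chord_mid, axis=1)))


def _refine_hit(c1, c2, t1, t2, tol):
    """Polish a candidate intersection by minimizing the gap ||c1(t)-c2(s)||."""

    def gap(x):
        d = c1.evaluate(x[0]) - c2.evaluate(x[1])
        return float(d @ d)

    res = minimize(gap, x0=[t1, t2], method="L-BFGS-B",
                   bounds=[(0.0, c1.length), (0.0, c2.length)],
                   options={"ftol": 1e-18, "gtol": 1e-14, "maxiter": 200})
    d = np.sqrt(max(res.fun, 0.0))
    return res.x[0], res.x[1], d


def _point_curve_distance(curve: FeatureCurve, point: np.ndarray,
                          n: int = 1024) -> float:
    """Distance from a fixed point to a curve (polyline + local refinement)."""
    t, p = curve.sample(n)
    a, b = p[:-1], p[1:]
    ab = b - a
    denom = np.sum(ab * ab, axis=1)
    s = np.clip(np.sum((point - a) * ab, axis=1) / np.where(denom > 0, denom, 1.0), 0, 1)
    proj = a + s[:, None] * ab
    d = np.linalg.norm(proj - point, axis=1)
    i = int(np.argmin(d))
    lo = t[max(i - 1, 0)]
    hi = t[min(i + 2, n - 1)]
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(lambda x: float(np.sum((curve.evaluate(x) - point) ** 2)),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    return float(np.sqrt(min(res.fun, d[i] ** 2)))


def _endpoint_class(curve: FeatureCurve, point: np.ndarray, tol: float) -> bool:
    term = curve.termini()
    return bool(len(term) and np.min(np.linalg.norm(term - point, axis=1)) <= tol)


def intersection_profile(c1: FeatureCurve, c2: FeatureCurve,
                         tol: float = 1e-6, n_coarse: int = 384) -> list[tuple[np.ndarray, str]]:
    """All intersection points of two feature curves with position classes.

    Each hit is classified as ``endpoint-endpoint``, ``endpoint-interior``
    or ``interior-interior``, where "endpoint" means within ``tol`` of a
    curve terminus.  Tangential touches count once.  Overlapping colinear
    stretches of positive length raise an error.
    """
    t1, p1 = c1.sample(n_coarse)
    t2, p2 = c2.sample(n_coarse)
    cd = _chord_deviation(c1, t1, p1) + _chord_deviation(c2, t2, p2)
    dist, s, t = _segment_pair_distances(p1, p2)
    cand = np.argwhere(dist <= tol + cd + 1e-9)
    if cand.size == 0:
        return []

    # group candidate segment pairs into connected neighborhoods
    cand = cand[np.lexsort((cand[:, 1], cand[:, 0]))]
    groups: list[list[np.ndarray]] = []
    for ij in cand:
        placed = False
        for g in groups:
            if any(abs(ij[0] - kl[0]) <= 2 and abs(ij[1] - kl[1]) <= 2 for kl in g[-8:]):
                g.append(ij)
                placed = True
                break
        if not placed:
            groups.append([ij])

    hits: list[tuple[float, float, np.ndarray]] = []
    seg1 = t1[1] - t1[0]
    seg2 = t2[1] - t2[0]
    for g in groups:
        g = np.asarray(g)
        # seed at the best candidate of the group
        d_g = dist[g[:, 0], g[:, 1]]
        i, j = g[np.argmin(d_g)]
        u0 = t1[i] + s[i, j] * seg1
        v0 = t2[j] + t[i, j] * seg2
        u, v, d = _refine_hit(c1, c2, u0, v0, tol)
        if d > tol:
            continue
        # degenerate-overlap probe: walk along c1 away from the contact and
        # measure the distance of the walked (fixed) point to c2
        span = 0.0
        for du in (50 * tol, 500 * tol, 0.05 * c1.length):
            for sgn in (+1.0, -1.0):
                uu = min(max(u + sgn * du, 0.0), c1.length)
                if uu == u:
                    continue
                if _point_curve_distance(c2, c1.evaluate(uu)) <= tol:
                    span = max(span, abs(uu - u))
        if span > max(1000 * tol, 1e-3):
            raise ValueError("degenerate overlap: curves coincide over a positive length")
        hits.append((u, v, c1.evaluate(u)))

    # merge duplicates (tangential touches, group fragmentation)
    merged: list[tuple[float, float, np.ndarray]] = []
    merge_eps = max(100 * tol, 1e-4)
    for u, v, pt in hits:
        if any(np.linalg.norm(pt - m[2]) <= merge_eps for m in merged):
            continue
        merged.append((u, v, pt))

    out = []
    for u, v, pt in merged:
        e1 = _endpoint_class(c1, pt, max(tol, 1e-9))
        e2 = _endpoint_class(c2, pt, max(tol, 1e-9))
        cls = ("endpoint-endpoint" if e1 and e2
               else "endpoint-interior" if e1 or e2
               else "interior-interior")
        out.append((pt, cls))
    return out


def classify_relation(c1: FeatureCurve, c2: FeatureCurve, tol: float = 1e-6,
                      n_coarse: int = 384) -> str:
    """Topological relation label between two feature curves."""
    if c1.kind == "boundary" and c2.kind == "boundary":
        raise ValueError("the model has a single boundary curve; got two")
    hits = intersection_profile(c1, c2, tol, n_coarse)
    if c1.kind == "boundary" or c2.kind == "boundary":
        n = min(len(hits), 2)
        return BI_LABELS[n]
    if not hits:
        return "II_0"
    rank = {"endpoint-endpoint": 1, "endpoint-interior": 2, "interior-interior": 3}
    return f"II_1{max(rank[c] for _, c in hits)}"


@dataclass
class TopologyMatrix:
    """Symmetric matrix of relation labels over a curve set."""

    labels: list[list[str]]
    curve_ids: list[str]

    @property
    def n(self) -> int:
        return len(self.curve_ids)

    def __getitem__(self, key) -> str:
        i, j = key
        return self.labels[i][j]

    def to_json(self, path=None) -> str:
        payload = json.dumps({"curve_ids": self.curve_ids, "labels": self.labels}, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "TopologyMatrix":
        try:
            data = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                data = json.load(fh)
        return cls(data["labels"], data["curve_ids"])


def eagle_template_matrix() -> TopologyMatrix:
    """The published 12 x 12 eagle-plate adjacency matrix."""
    ids = [f"C{i}" for i in range(12)]
    return TopologyMatrix([row[:] for row in reference.EAGLE_ADJACENCY], ids)


def topology_matrix(curves: list[FeatureCurve], tol: float = 1e-6,
                    n_coarse: int = 384) -> TopologyMatrix:
    """Pairwise relation classification of a curve set (one boundary curve)."""
    n_boundary = sum(c.kind == "boundary" for c in curves)
    if n_boundary != 1:
        raise ValueError(f"exactly one boundary curve required, got {n_boundary}")
    n = len(curves)
    labels = [["" for _ in range(n)] for _ in range(n)]
    for i, c in enumerate(curves):
        labels[i][i] = "B" if c.kind == "boundary" else "I"
    for i in range(n):
        for j in range(i + 1, n):
            lab = classify_relation(curves[i], curves[j], tol, n_coarse)
            labels[i][j] = lab
            labels[j][i] = lab
    return TopologyMatrix(labels, [c.id for c in curves])


def validate_topology(m: TopologyMatrix, template: TopologyMatrix) -> list[tuple[int, int, str, str]]:
    """Cell-by-cell diff against a template; empty list means structurally
    valid."""
    if m.n != template.n:
        raise ValueError(f"dimension mismatch: {m.n} vs {template.n}")
    diffs = []
    for i in range(m.n):
        for j in range(i, m.n):
            if m.labels[i][j] != template.labels[i][j]:
                diffs.append((i, j, m.labels[i][j], template.labels[i][j]))
    return diffs


# ---------------------------------------------------------------------------
# semantic parameters

@dataclass(frozen=True)
class SemanticParameterSet:
    """Plate-level parameters (all mm) with the inheritance hierarchy
    L -> {l1, l2} and W -> {w0..w8}; h0..h8 are local bump heights, t1/t2
    tail/head thickness, d1..d3 hole diameters, s1 tail hole clear spacing.

    The hierarchy identities are enforced at construction unless
    ``validate=False`` (used to represent candidate sets whose violations
    are to be *reported* by :func:`check_dimension_constraints`).
    """

    L: float
    W: float
    l1: float
    l2: float
    w: tuple[float, ...]      # w0..w8
    h: tuple[float, ...]      # h0..h8
    t1: float
    t2: float
    d1: float
    d2: float
    d3: float
    s1: float
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool = True) -> None:
        if len(self.w) != 9 or len(self.h) != 9:
            raise ValueError("w and h must each have 9 entries (indices 0..8)")
        if not validate:
            return
        for name in ("L", "W", "l1", "l2", "t1", "t2", "d1", "d2", "d3", "s1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(wi <= 0 for wi in self.w):
            raise ValueError("local widths must be positive")
        if any(hi < 0 for hi in self.h):
            raise ValueError("bump heights must be non-negative")
        if abs(self.L - (self.l1 + self.l2)) > 1e-9:
            raise ValueError("hierarchy violation: L != l1 + l2")
        if max(self.w) > self.W + 1e-9:
            raise ValueError("hierarchy violation: max(w_i) > W")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["w"] = list(self.w)
        d["h"] = list(self.h)
        d["units"] = "mm"
        return d

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_dict(cls, d: dict) -> "SemanticParameterSet":
        d = {k: v for k, v in d.items() if k != "units"}
        d["w"] = tuple(d["w"])
        d["h"] = tuple(d["h"])
        return cls(**d)


_FIXTURE_DEFAULT_H_TAIL = (0.0, 0.0)


def complete_plate_fixture(printed: dict) -> SemanticParameterSet:
    """Expand a published plate parameter list (which prints only a subset
    of the w_i/h_i) into a full SemanticParameterSet.

    Unprinted widths are filled by linear interpolation between printed
    neighbors (w3, w4 between w2 and w5; w6 between w5 and w7; w8 = w0),
    tail bump heights default to 0, and W is the largest local width.
    """
    p = dict(printed)
    w2, w5, w7 = p["w2"], p["w5"], p["w7"]
    w = (p["w0"], p["w1"], w2,
         p.get("w3", w2 + (w5 - w2) / 3.0),
         p.get("w4", w2 + 2.0 * (w5 - w2) / 3.0),
         w5,
         p.get("w6", (w5 + w7) / 2.0),
         w7,
         p.get("w8", p["w0"]))
    h = (p.get("h0", 0.0), p.get("h1", 0.0), p["h2"], p["h3"], p["h4"],
         p["h5"], p["h6"], p["h7"], p["h8"])
    l1, l2 = p["l1"], p["l2"]
    return SemanticParameterSet(
        L=l1 + l2, W=max(w), l1=l1, l2=l2, w=w, h=h,
        t1=p["t1"], t2=p["t2"], d1=p["d1"], d2=p["d2"], d3=p["d3"], s1=p["s1"])


@dataclass(frozen=True)
class DimensionConstraint:
    parameter: str
    relation: str             # expression over bone parameters
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("constraint range must have lo < hi")


@dataclass(frozen=True)
class DerivationCoefficients:
    """Coefficient table of the primary mapping from bone morphology to
    plate semantic parameters.

    Calibrated once so the reference mean femur produces a plate of the
    published Plate-A magnitude; every coefficient is user-overridable.
    """

    alpha_L: float = 255.0 / 420.072      # L = alpha_L * H_f
    alpha_W: float = 29.0 / 25.94         # W = alpha_W * D_fs
    beta: float = 39.0 / 65.86            # l2 = beta * L_t (head spans the trochanter)
    gamma: tuple[float, ...] = field(default_factory=lambda: tuple(
        np.array([12.0, 14.0, 16.0, 16 + 13 / 3, 16 + 26 / 3, 29.0, 21.0, 13.0, 12.0]) / 29.0))
    eta: tuple[float, ...] = field(default_factory=lambda: tuple(
        np.array([0.0, 0.0, 1.6, 2.4, 7.9, 8.3, 5.2, 0.8, 0.7]) / 10.73))
    t1: float = 3.0
    t2: float = 3.0
    d1: float = 7.0
    d2: float = 5.0
    d3: float = 5.0
    s1: float = 6.0


DEFAULT_COEFFS = DerivationCoefficients()


def _derived_values(bone, coeffs: DerivationCoefficients) -> dict:
    L = coeffs.alpha_L * bone["H_f"]
    W = coeffs.alpha_W * bone["D_fs"]
    l2 = coeffs.beta * bone["L_t"]
    out = {"L": L, "W": W, "l2": l2, "l1": L - l2}
    for i, g in enumerate(coeffs.gamma):
        out[f"w{i}"] = g * W
    for i, e in enumerate(coeffs.eta):
        out[f"h{i}"] = e * bone["H_t1"]
    return out


def dimension_constraints(coeffs: DerivationCoefficients = DEFAULT_COEFFS,
                          stats: SummaryStats | None = None,
                          schema: ParameterSchema = FEMUR_SCHEMA,
                          n_sd: float = 3.0) -> list[DimensionConstraint]:
    """Default admissible ranges: value at the mean shape +/- n_sd times the
    linearly propagated SD of the driving bone parameters."""

    def msd(name):
        if stats is not None and name in stats.table.index:
            row = stats.table.loc[name]
            return float(row["mean"]), float(row["sd"])
        e = schema[name]
        return e.mean, e.sd

    mHf, sHf = msd("H_f")
    mDfs, sDfs = msd("D_fs")
    mLt, sLt = msd("L_t")
    mHt1, sHt1 = msd("H_t1")
    cons = [
        DimensionConstraint("L", "alpha_L * H_f",
                            coeffs.alpha_L * (mHf - n_sd * sHf),
                            coeffs.alpha_L * (mHf + n_sd * sHf)),
        DimensionConstraint("W", "alpha_W * D_fs",
                            coeffs.alpha_W * (mDfs - n_sd * sDfs),
                            coeffs.alpha_W * (mDfs + n_sd * sDfs)),
        DimensionConstraint("l2", "beta * L_t",
                            coeffs.beta * (mLt - n_sd * sLt),
                            coeffs.beta * (mLt + n_sd * sLt)),
    ]
    s_l1 = np.hypot(coeffs.alpha_L * sHf, coeffs.beta * sLt)
    m_l1 = coeffs.alpha_L * mHf - coeffs.beta * mLt
    cons.append(DimensionConstraint("l1", "L - l2",
                                    m_l1 - n_sd * s_l1, m_l1 + n_sd * s_l1))
    for i, g in enumerate(coeffs.gamma):
        c = g * coeffs.alpha_W
        cons.append(DimensionConstraint(
            f"w{i}", f"gamma_{i} * alpha_W * D_fs",
            c * (mDfs - n_sd * sDfs), c * (mDfs + n_sd * sDfs)))
    for i, e in enumerate(coeffs.eta):
        if e > 0:
            cons.append(DimensionConstraint(
                f"h{i}", f"eta_{i} * H_t1",
                e * (mHt1 - n_sd * sHt1), e * (mHt1 + n_sd * sHt1)))
    return cons


def derive_semantic_parameters(bone: FemurParameterSet,
                               coeffs: DerivationCoefficients = DEFAULT_COEFFS,
                               constraints: list[DimensionConstraint] | None = None,
                               ) -> SemanticParameterSet:
    """Primary mapping: plate semantic parameters from one femur.

    ``L = alpha_L * H_f``; ``W = alpha_W * D_fs``; ``l2 = beta * L_t`` (the
    head spans the trochanter) with ``l1 = L - l2``; local widths/heights
    scale W and the trochanter bump height.  Raises if any derived value
    leaves its admissible dimension-constraint range.
    """
    vals = _derived_values(bone, coeffs)
    if constraints is None:
        constraints = dimension_constraints(coeffs)
    violations = [
        f"{c.parameter}={vals[c.parameter]:.3f} outside [{c.lo:.3f}, {c.hi:.3f}] ({c.relation})"
        for c in constraints
        if c.parameter in vals and not (c.lo <= vals[c.parameter] <= c.hi)
    ]
    if violations:
        raise ValueError("dimension constraint violations: " + "; ".join(violations))
    return SemanticParameterSet(
        L=vals["L"], W=vals["W"], l1=vals["l1"], l2=vals["l2"],
        w=tuple(vals[f"w{i}"] for i in range(9)),
        h=tuple(vals[f"h{i}"] for i in range(9)),
        t1=coeffs.t1, t2=coeffs.t2, d1=coeffs.d1, d2=coeffs.d2,
        d3=coeffs.d3, s1=coeffs.s1)


def check_dimension_constraints(params: SemanticParameterSet,
                                stats: SummaryStats | None = None,
                                coeffs: DerivationCoefficients = DEFAULT_COEFFS,
                                ) -> list[str]:
    """Constraint audit: hierarchy identities checked exactly, ranges from
    the propagated-SD defaults.  Violations are returned as data, never
    raised."""
    violations: list[str] = []
    if abs(params.L - (params.l1 + params.l2)) > 1e-9:
        violations.append(f"L: l1 + l2 = {params.l1 + params.l2:.6f} != L = {params.L:.6f}")
    for i, wi in enumerate(params.w):
        if wi > params.W + 1e-9:
            violations.append(f"w{i}: local width {wi:.3f} exceeds W = {params.W:.3f}")
    for i, hi in enumerate(params.h):
        if hi < 0:
            violations.append(f"h{i}: bump height negative")
    vals = {"L": params.L, "W": params.W, "l1": params.l1, "l2": params.l2}
    vals.update({f"w{i}": v for i, v in enumerate(params.w)})
    vals.update({f"h{i}": v for i, v in enumerate(params.h)})
    for c in dimension_constraints(coeffs, stats):
        if c.parameter in vals and not (c.lo <= vals[c.parameter] <= c.hi):
            violations.append(
                f"{c.parameter}: {vals[c.parameter]:.3f} outside [{c.lo:.3f}, {c.hi:.3f}]")
    return violations


# ---------------------------------------------------------------------------
# component mapping

def _completed_distal_loadings() -> LoadingMatrix:
    """7 x 16 raw distal loadings: the six genuine published columns plus a
    synthetic seventh row completing the orthonormal set.

    The completion seeds on the femoral-surface-ratio axis (C_f, the
    variable the seventh rotated component explains), projects out the six
    published rows and normalizes; it is deterministic and flagged in the
    provenance note.
    """
    names = FEMUR_SCHEMA.region_names("distal")
    A = reference.distal_loadings_usable().T            # 6 x 16
    A = A / np.linalg.norm(A, axis=1, keepdims=True)
    seed = np.zeros(16)
    seed[names.index("C_f")] = 1.0
    v = seed - A.T @ (A @ seed)
    v = v / np.linalg.norm(v)
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return LoadingMatrix(np.vstack([A, v]), tuple(names),
                         note="row 7 is a synthetic orthonormal completion")


@dataclass
class ComponentMapping:
    """Component mapping: plate parameters driven by the principal-component
    score set P4 = {p1..p4, q1..q7}.

    Scores are turned back into standardized bone parameters by projection
    (``x_hat = A^T s``), de-standardized with the cohort means/SDs, and fed
    through the primary parametric derivation.  Bone parameters outside the
    two PCA blocks are linked to their strongest reconstructed correlates:
    standardized H_f follows the dominant proximal size component
    (p1 / sqrt(lambda1)) and standardized D_fs follows reconstructed D_fn.
    Zero scores reproduce the base (mean-shape) plate exactly.
    """

    proximal_loadings: LoadingMatrix
    distal_loadings: LoadingMatrix
    coeffs: DerivationCoefficients
    schema: ParameterSchema
    lambda1: float                      # top proximal eigenvalue (for the H_f link)

    def __post_init__(self) -> None:
        if self.proximal_loadings.rotated or self.distal_loadings.rotated:
            raise ValueError("component mapping requires raw (unrotated) loadings")

    @property
    def base_parameters(self) -> SemanticParameterSet:
        return derive_semantic_parameters(
            FemurParameterSet.mean_shape(self.schema), self.coeffs)

    def bone_from_scores(self, scores: np.ndarray) -> FemurParameterSet:
        scores = np.asarray(scores, dtype=float)
        kp = self.proximal_loadings.k
        kd = self.distal_loadings.k
        if scores.shape != (kp + kd,):
            raise ValueError(f"P4 must have {kp}+{kd} scores, got {scores.shape}")
        sp, sd_scores = scores[:kp], scores[kp:]
        z_prox = reconstruct_parameters(sp, self.proximal_loadings)
        z_dist = reconstruct_parameters(sd_scores, self.distal_loadings)
        values = {e.name: e.mean for e in self.schema}
        for name, z in zip(self.schema.region_names("proximal"), z_prox):
            e = self.schema[name]
            values[name] = e.mean + e.sd * z
        for name, z in zip(self.schema.region_names("distal"), z_dist):
            e = self.schema[name]
            values[name] = e.mean + e.sd * z
        # out-of-block links
        z_hf = sp[0] / np.sqrt(self.lambda1)
        e = self.schema["H_f"]
        values["H_f"] = e.mean + e.sd * z_hf
        dfn_idx = self.schema.region_names("proximal").index("D_fn")
        e = self.schema["D_fs"]
        values["D_fs"] = e.mean + e.sd * z_prox[dfn_idx]
        return FemurParameterSet(values, self.schema)


def default_component_mapping(coeffs: DerivationCoefficients = DEFAULT_COEFFS,
                              schema: ParameterSchema = FEMUR_SCHEMA) -> ComponentMapping:
    prox = LoadingMatrix.from_columns(reference.PROXIMAL_LOADINGS,
                                      schema.region_names("proximal"))
    dist = _completed_distal_loadings()
    lam1 = reference.PROXIMAL_RATES[0] * 9
    return ComponentMapping(prox, dist, coeffs, schema, lam1)


def apply_component_mapping(scores: np.ndarray,
                            mapping: ComponentMapping) -> SemanticParameterSet:
    """Evaluate the component mapping at a P4 score vector (4 proximal + 7
    distal scores)."""
    return derive_semantic_parameters(mapping.bone_from_scores(scores),
                                      mapping.coeffs)
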