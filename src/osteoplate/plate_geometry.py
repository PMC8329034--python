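"""Plate undersurface and solid generation.

Pipeline: semantic parameters (+ a bone contact surface) -> transverse
feature-point profiles at 11 axial stations -> skeleton curves (boundary
C0, ridges C1/C2, costals C3..C11) -> tensor-product cubic loft of the
undersurface -> thickness-extruded watertight shell with hole placements
-> point-to-surface fit report.

Stations: two in the tail (plus the tail tip), one just below the neck,
the neck itself, six across the head and the head tip — the near-neck
station is tied to the head span so the axial node layout resolves the
trochanter bump for any femur size.  All coordinates mm; the plate axis
runs along the bone axis (+z), laterally outward +x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.interpolate import RectBivariateSpline
from scipy.spatial import cKDTree

from .bone import BoneSurfaceMesh, PlanarSurface
from .feature_model import (FeatureCurve, SemanticParameterSet, TopologyMatrix,
                            eagle_template_matrix, topology_matrix)

__all__ = [
    "station_layout",
    "FeaturePointGrid",
    "SkeletonCurves",
    "UndersurfacePatch",
    "PlateSolidSpec",
    "FitReport",
    "build_feature_points",
    "build_skeleton",
    "loft_undersurface",
    "extrude_solid",
    "place_holes",
    "fit_deviation",
    "sample_contact_points",
    "export_mesh",
    "hole_count",
]

# fraction of l2 below the neck at which the last tail station sits; chosen
# so the station spacing tracks the trochanter bump width
NECK_STATION_OFFSET = 0.4081
TAIL_STATION_FRACTION = 0.55
# station index -> semantic width/height index (w0..w8 / h0..h8); the two
# tail-most stations share w0 and the two head-most share w8
WIDTH_INDEX = (0, 0, 1, 2, 3, 4, 5, 6, 7, 8, 8)
# costal curve id per station (tips carry no costal)
COSTAL_AT_STATION = {1: "C10", 2: "C11", 3: "C9", 4: "C3", 5: "C4",
                     6: "C5", 7: "C6", 8: "C7", 9: "C8"}
HEAD_HOLE_STATIONS = (5, 7)   # stations carrying the d2 / d3 head holes


def station_layout(l1: float, l2: float) -> np.ndarray:
    """Axial positions (plate coordinates, mm) of the 11 stations."""
    z = np.concatenate([
        [0.0, TAIL_STATION_FRACTION * l1, l1 - NECK_STATION_OFFSET * l2, l1],
        l1 + np.arange(1, 7) / 7.0 * l2,
        [l1 + l2],
    ])
    if not np.all(np.diff(z) > 0):
        raise ValueError("stations are not strictly increasing; l1/l2 out of range")
    return z


@dataclass
class FeaturePointGrid:
    """Feature points for the loft and the skeleton.

    The loft grid is rectangular — 11 stations x m constant-arc-offset
    samples spanning the full plate width W — so the axial spline lines are
    decoupled from the varying local widths; the eagle outline acts as a
    trim curve on this domain.  The per-station costal profiles (spanning
    the local width w_i) are carried alongside for skeleton construction.
    """

    stations: np.ndarray          # 11 axial positions, plate coords
    s_values: np.ndarray          # m arc offsets spanning [-W/2, W/2]
    widths: np.ndarray            # per-station local profile width (mm)
    heights: np.ndarray           # per-station apex lift attribution (mm)
    points: np.ndarray            # 11 x m x 3 rectangular loft grid
    profiles: list                # 11 arrays (m_i x 3), station profiles
    params: SemanticParameterSet
    z_offset: float = 0.0         # bone z of plate z=0
    from_surface: bool = True

    @property
    def n_stations(self) -> int:
        return len(self.stations)

    @property
    def m(self) -> int:
        return self.points.shape[1]

    def apexes(self) -> np.ndarray:
        return self.points[:, self.m // 2, :]

    def transformed(self, rotation=None, translation=None) -> "FeaturePointGrid":
        def tf(pts):
            if rotation is not None:
                pts = pts @ np.asarray(rotation).T
            if translation is not None:
                pts = pts + np.asarray(translation)
            return pts

        return FeaturePointGrid(self.stations.copy(), self.s_values.copy(),
                                self.widths.copy(), self.heights.copy(),
                                tf(self.points), [tf(p) for p in self.profiles],
                                self.params, self.z_offset, self.from_surface)


def _apex_lift(profile: np.ndarray) -> float:
    """Perpendicular distance of the profile apex from the end-to-end chord."""
    a, b = profile[0], profile[-1]
    apex = profile[len(profile) // 2]
    d = b - a
    d = d / np.linalg.norm(d)
    v = apex - a
    return float(np.linalg.norm(v - (v @ d) * d))


def _profile_offsets(s_values: np.ndarray, w: float) -> np.ndarray:
    """Arc offsets of one costal profile: the loft-grid offsets interior to
    the local width plus the exact +/- w/2 endpoints."""
    inner = s_values[np.abs(s_values) < w / 2.0 - 1e-12]
    return np.unique(np.concatenate([[-w / 2.0], inner, [w / 2.0]]))


def build_feature_points(params: SemanticParameterSet,
                         bone: BoneSurfaceMesh | PlanarSurface | None,
                         n_profile: int = 49) -> FeaturePointGrid:
    """Sample the feature points of the 11 stations.

    With a bone surface every point — loft grid and profile alike — is a
    sample of the contact surface (arc offsets centered on the lateral
    line), and the recorded bump height of a station is the measured apex
    lift of its profile.  Without a bone, profiles are analytic parabolic
    arcs of apex height h_i over width w_i — the free-space template mode.
    """
    if n_profile < 5 or n_profile % 2 == 0:
        raise ValueError("n_profile must be odd and >= 5")
    zs = station_layout(params.l1, params.l2)
    widths = np.array([params.w[i] for i in WIDTH_INDEX])
    L = params.L
    s_values = np.linspace(-params.W / 2.0, params.W / 2.0, n_profile)

    if bone is None:
        def template_point(z, s, w, h):
            x = h * (1.0 - (2.0 * np.asarray(s) / w) ** 2)
            return np.stack(np.broadcast_arrays(x, s, np.full_like(np.asarray(s, dtype=float), z)), axis=-1)

        h_at = np.array([params.h[i] for i in WIDTH_INDEX])
        pts = np.stack([template_point(z, s_values, w, h)
                        for z, w, h in zip(zs, widths, h_at)])
        profiles = [template_point(z, _profile_offsets(s_values, w), w, h)
                    for z, w, h in zip(zs, widths, h_at)]
        return FeaturePointGrid(zs, s_values, widths, h_at.copy(), pts,
                                profiles, params, 0.0, from_surface=False)

    extent = bone.z_max - bone.z_min
    if L > extent + 1e-9:
        raise ValueError(f"plate footprint exceeds contact region axially by {L - extent:.3f} mm")
    half_max = max(widths.max(), params.W) / 2.0
    if half_max > bone.contact_halfwidth() + 1e-9:
        raise ValueError(
            f"plate footprint exceeds contact region laterally by "
            f"{half_max - bone.contact_halfwidth():.3f} mm")
    z0 = bone.z_max - L
    pts = np.stack([bone.surface_point(z0 + z, s_values) for z in zs])
    profiles = [bone.surface_point(z0 + z, _profile_offsets(s_values, w))
                for z, w in zip(zs, widths)]
    heights = np.array([_apex_lift(p) for p in profiles])
    return FeaturePointGrid(zs, s_values, widths, heights, pts, profiles, params, z0)


@dataclass
class SkeletonCurves:
    """The 12 skeleton curves of the eagle plate, in id order C0..C11."""

    curves: list[FeatureCurve]
    grid: FeaturePointGrid | None = None

    def __getitem__(self, cid: str) -> FeatureCurve:
        for c in self.curves:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def topology(self, tol: float = 1e-6, n_coarse: int = 384) -> TopologyMatrix:
        return topology_matrix(self.curves, tol, n_coarse)

    def transformed(self, rotation=None, translation=None) -> "SkeletonCurves":
        grid = None if self.grid is None else self.grid.transformed(rotation, translation)
        return SkeletonCurves([c.transformed(rotation, translation) for c in self.curves], grid)


def build_skeleton(grid: FeaturePointGrid) -> SkeletonCurves:
    """Skeleton curves through the feature-point grid.

    Costals interpolate their station profiles; the tail ridge C1 runs
    through the apexes of the tail stations up to the neck junction, the
    head ridge C2 from the junction to the head tip (they share exactly the
    junction point); the boundary C0 closes through the profile ends and
    the two tip apexes, so each ridge touches it exactly once and each
    costal twice.
    """
    if grid.n_stations < 11:
        raise ValueError("skeleton requires the full 11-station grid")
    apex = grid.apexes()
    curves: list[FeatureCurve] = []

    left = np.stack([p[0] for p in grid.profiles])
    right = np.stack([p[-1] for p in grid.profiles])
    boundary_nodes = np.vstack([left, apex[-1][None, :], right[::-1], apex[0][None, :]])
    curves.append(FeatureCurve("C0", "boundary", boundary_nodes, closed=True))
    curves.append(FeatureCurve("C1", "internal", apex[0:4]))       # tail ridge
    curves.append(FeatureCurve("C2", "internal", apex[3:11]))      # head ridge
    by_id = {cid: FeatureCurve(cid, "internal", grid.profiles[i])
             for i, cid in COSTAL_AT_STATION.items()}
    for k in range(3, 12):
        curves.append(by_id[f"C{k}"])
    return SkeletonCurves(curves, grid)


# ---------------------------------------------------------------------------
# lofted undersurface

class UndersurfacePatch:
    """Tensor-product cubic spline surface through the rectangular loft grid.

    Parameterized by (u, v): u is the axial station coordinate (mm along
    the plate axis), v the lateral arc offset (mm, 0 on the apex line).
    Interpolates every grid point; the eagle outline trims this domain.
    """

    def __init__(self, grid: FeaturePointGrid):
        pts = grid.points
        u = grid.stations.astype(float)
        v = grid.s_values.astype(float)
        self.u_domain = (float(u[0]), float(u[-1]))
        self.v_domain = (float(v[0]), float(v[-1]))
        self.grid = grid
        self._fx = RectBivariateSpline(u, v, pts[:, :, 0], kx=3, ky=3, s=0)
        self._fy = RectBivariateSpline(u, v, pts[:, :, 1], kx=3, ky=3, s=0)
        self._fz = RectBivariateSpline(u, v, pts[:, :, 2], kx=3, ky=3, s=0)
        self._check_regularity()

    def evaluate(self, u, v) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        return np.stack([self._fx.ev(u, v), self._fy.ev(u, v), self._fz.ev(u, v)], axis=-1)

    def derivatives(self, u, v):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        su = np.stack([f.ev(u, v, dx=1) for f in (self._fx, self._fy, self._fz)], axis=-1)
        sv = np.stack([f.ev(u, v, dy=1) for f in (self._fx, self._fy, self._fz)], axis=-1)
        return su, sv

    def normal(self, u, v) -> np.ndarray:
        su, sv = self.derivatives(u, v)
        n = np.cross(su, sv)
        norm = np.linalg.norm(n, axis=-1, keepdims=True)
        return n / np.where(norm > 0, norm, 1.0)

    def _check_regularity(self, nu: int = 60, nv: int = 15) -> None:
        uu = np.linspace(*self.u_domain, nu)
        vv = np.linspace(*self.v_domain, nv)
        U, V = np.meshgrid(uu, vv, indexing="ij")
        su, sv = self.derivatives(U.ravel(), V.ravel())
        n = np.cross(su, sv).reshape(nu, nv, 3)
        mag = np.linalg.norm(n, axis=-1)
        if np.any(mag < 1e-12):
            raise ValueError("degenerate loft: vanishing surface Jacobian")
        n = n / mag[..., None]
        # orientation must vary continuously: neighboring normals never flip
        if (np.any(np.sum(n[1:] * n[:-1], axis=-1) < 0)
                or np.any(np.sum(n[:, 1:] * n[:, :-1], axis=-1) < 0)):
            raise ValueError("self-intersecting loft: surface orientation flips")

    def dense_samples(self, nu: int = 240, nv: int = 33):
        uu = np.linspace(*self.u_domain, nu)
        vv = np.linspace(*self.v_domain, nv)
        U, V = np.meshgrid(uu, vv, indexing="ij")
        P = self.evaluate(U.ravel(), V.ravel())
        return U.ravel(), V.ravel(), P


def loft_undersurface(skel: SkeletonCurves) -> UndersurfacePatch:
    """Loft the undersurface through the costal sample points of a skeleton."""
    if skel.grid is None:
        raise ValueError("skeleton carries no feature-point grid to loft")
    return UndersurfacePatch(skel.grid)


# ---------------------------------------------------------------------------
# solid, holes

@dataclass
class Hole:
    center: np.ndarray
    axis: np.ndarray
    diameter: float
    label: str

    def to_dict(self) -> dict:
        return {"center": self.center.tolist(), "axis": self.axis.tolist(),
                "diameter": self.diameter, "label": self.label}


@dataclass
class PlateSolidSpec:
    """Solid plate description: undersurface, thickness field, holes, shell."""

    patch: UndersurfacePatch
    params: SemanticParameterSet
    mesh: trimesh.Trimesh
    holes: list[Hole] = field(default_factory=list)
    normal_sign: float = 1.0

    def to_json(self, path=None) -> str:
        d = {
            "parameters": self.params.to_dict(),
            "thickness": {"t1": self.params.t1, "t2": self.params.t2,
                          "blend": "smoothstep over 10% of L at the neck"},
            "holes": [h.to_dict() for h in self.holes],
            "units": "mm",
        }
        payload = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def extrude_solid(patch: UndersurfacePatch, params: SemanticParameterSet,
                  nu: int = 120, nv: int = 25) -> PlateSolidSpec:
    """Offset the undersurface by the blended thickness field and stitch a
    watertight shell.

    Thickness is t1 over the tail and t2 over the head, blended by a
    smoothstep across a neck band 10% of L wide.  The offset direction is
    the surface normal oriented away from the bone.
    """
    if params.t1 <= 0 or params.t2 <= 0:
        raise ValueError("thickness must be positive")
    from scipy.interpolate import PchipInterpolator
    grid = patch.grid
    # eagle outline as a trim on the rectangular loft domain; monotone
    # interpolation keeps the outline inside the station widths
    w_of_u = PchipInterpolator(grid.stations, grid.widths)
    uu = np.linspace(*patch.u_domain, nu)
    vfrac = np.linspace(-0.5, 0.5, nv)
    U = np.repeat(uu, nv).reshape(nu, nv)
    V = vfrac[None, :] * w_of_u(uu)[:, None]
    P = patch.evaluate(U.ravel(), V.ravel()).reshape(nu, nv, 3)
    N = patch.normal(U.ravel(), V.ravel()).reshape(nu, nv, 3)
    sign = 1.0 if N[..., 0].mean() >= 0 else -1.0
    N = N * sign
    band = 0.10 * params.L
    t = params.t1 + (params.t2 - params.t1) * _smoothstep((uu - (params.l1 - band / 2)) / band)
    outer = P + N * t[:, None, None]

    # reject offsets that fold the outer surface
    d_in = np.diff(P, axis=0)
    d_out = np.diff(outer, axis=0)
    if np.any(np.sum(d_in * d_out, axis=-1) < 0):
        raise ValueError("thickness exceeds local curvature radius: offset self-intersects")

    def vid(layer, i, j):
        return layer * nu * nv + i * nv + j

    verts = np.vstack([P.reshape(-1, 3), outer.reshape(-1, 3)])
    faces = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            a, b = vid(0, i, j), vid(0, i, j + 1)
            c, d = vid(0, i + 1, j), vid(0, i + 1, j + 1)
            faces += [[a, d, b], [a, c, d]]                  # bottom, outward = -N
            a, b = vid(1, i, j), vid(1, i, j + 1)
            c, d = vid(1, i + 1, j), vid(1, i + 1, j + 1)
            faces += [[a, b, d], [a, d, c]]                  # top, outward = +N
    for i in range(nu - 1):                                  # long side walls
        a, b = vid(0, i, 0), vid(0, i + 1, 0)
        c, d = vid(1, i, 0), vid(1, i + 1, 0)
        faces += [[a, b, d], [a, d, c]]
        a, b = vid(0, i, nv - 1), vid(0, i + 1, nv - 1)
        c, d = vid(1, i, nv - 1), vid(1, i + 1, nv - 1)
        faces += [[a, d, b], [a, c, d]]
    for j in range(nv - 1):                                  # end walls
        a, b = vid(0, 0, j), vid(0, 0, j + 1)
        c, d = vid(1, 0, j), vid(1, 0, j + 1)
        faces += [[a, d, b], [a, c, d]]
        a, b = vid(0, nu - 1, j), vid(0, nu - 1, j + 1)
        c, d = vid(1, nu - 1, j), vid(1, nu - 1, j + 1)
        faces += [[a, b, d], [a, d, c]]
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    return PlateSolidSpec(patch, params, mesh, [], sign)


def hole_count(l1: float, d1: float, s1: float) -> int:
    """Number of tail holes that fit: floor((l1 - d1)/(s1 + d1)) + 1."""
    return int(np.floor((l1 - d1) / (s1 + d1))) + 1


def place_holes(spec: PlateSolidSpec, skel: SkeletonCurves) -> PlateSolidSpec:
    """Place screw holes.

    Tail holes of diameter d1 are centered on the tail ridge C1 with clear
    rim spacing s1 (center-to-center arc distance s1 + d1), as many as fit
    in l1; head holes d2/d3 sit at the apexes of the two named head
    stations.  Hole axes follow the outward surface normal.
    """
    p = spec.params
    if p.s1 <= 0:
        raise ValueError("hole spacing s1 must be positive")
    tail_w = min(p.w[0], p.w[1])
    if p.d1 >= tail_w:
        raise ValueError(f"tail hole diameter {p.d1} exceeds tail width {tail_w}")
    c1 = skel["C1"]
    n = hole_count(p.l1, p.d1, p.s1)
    holes: list[Hole] = []
    pitch = p.s1 + p.d1
    grid = spec.patch.grid
    for i in range(n):
        a = p.d1 / 2.0 + i * pitch
        if a > c1.length:
            break
        center = c1.evaluate(a)
        u = grid.stations[0] + a * (grid.stations[3] - grid.stations[0]) / c1.length
        axis = spec.normal_sign * spec.patch.normal(np.clip(u, *spec.patch.u_domain), 0.0)
        holes.append(Hole(center, axis, p.d1, f"tail_{i}"))
    for st, d in zip(HEAD_HOLE_STATIONS, (p.d2, p.d3)):
        u = grid.stations[st]
        center = spec.patch.evaluate(u, 0.0)
        axis = spec.normal_sign * spec.patch.normal(u, 0.0)
        holes.append(Hole(center, axis, d, f"head_s{st}"))
    spec.holes = holes
    return spec


# ---------------------------------------------------------------------------
# fit evaluation

@dataclass(frozen=True)
class FitReport:
    """Point-to-undersurface distances (mm)."""

    distances: np.ndarray
    max: float
    mean: float
    rms: float
    n: int
    n_fallback: int = 0

    def to_dict(self) -> dict:
        return {"max_mm": self.max, "mean_mm": self.mean, "rms_mm": self.rms,
                "n": self.n, "n_fallback": self.n_fallback}


def fit_deviation(patch: UndersurfacePatch, contact_points: np.ndarray,
                  iters: int = 60) -> FitReport:
    """Minimum Euclidean distance of each contact point to the patch.

    Newton (Gauss-Newton) projection in the (u, v) parameter plane, seeded
    from the nearest of a dense surface sampling; points whose projection
    does not converge fall back to the dense-sample distance and are
    counted in ``n_fallback``.
    """
    pts = np.asarray(contact_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("contact point set must be non-empty n x 3")
    su_, sv_, samples = patch.dense_samples()
    tree = cKDTree(samples)
    d0, idx = tree.query(pts)
    u = su_[idx].copy()
    v = sv_[idx].copy()
    lo_u, hi_u = patch.u_domain
    lo_v, hi_v = patch.v_domain
    best_d = d0.copy()
    best_u, best_v = u.copy(), v.copy()
    for _ in range(iters):
        S = patch.evaluate(u, v)
        r = S - pts
        d = np.linalg.norm(r, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_u[better], best_v[better] = u[better], v[better]
        Su, Sv = patch.derivatives(u, v)
        g1 = np.sum(Su * r, axis=1)
        g2 = np.sum(Sv * r, axis=1)
        a11 = np.sum(Su * Su, axis=1)
        a12 = np.sum(Su * Sv, axis=1)
        a22 = np.sum(Sv * Sv, axis=1)
        det = a11 * a22 - a12 * a12
        det = np.where(np.abs(det) < 1e-18, 1e-18, det)
        du = -(a22 * g1 - a12 * g2) / det
        dv = -(-a12 * g1 + a11 * g2) / det
        step = np.sqrt(du * du + dv * dv)
        cap = 0.05 * (hi_u - lo_u)
        scale = np.divide(cap, step, out=np.ones_like(step), where=step > cap)
        u = np.clip(u + du * scale, lo_u, hi_u)
        v = np.clip(v + dv * scale, lo_v, hi_v)
        if np.max(step) < 1e-12:
            break
    # converged where the projected gradient is ~0 or the minimizer sits on
    # the domain edge; everything else keeps the dense-sample fallback
    S = patch.evaluate(best_u, best_v)
    r = S - pts
    Su, Sv = patch.derivatives(best_u, best_v)
    g = np.hypot(np.sum(Su * r, axis=1), np.sum(Sv * r, axis=1))
    interior = ((best_u > lo_u) & (best_u < hi_u) & (best_v > lo_v) & (best_v < hi_v))
    stalled = interior & (g > 1e-6 * np.maximum(1.0, best_d))
    n_fb = int(np.sum(stalled))
    dist = best_d
    return FitReport(dist, float(dist.max()), float(dist.mean()),
                     float(np.sqrt(np.mean(dist ** 2))), len(pts), n_fb)


def sample_contact_points(bone, params: SemanticParameterSet, n: int = 500,
                          seed: int = 0) -> np.ndarray:
    """Draw n contact-region samples across the plate footprint (uniform in
    axial position and local width), on the bone surface."""
    rng = np.random.default_rng(seed)
    zs = station_layout(params.l1, params.l2)
    widths = np.array([params.w[i] for i in WIDTH_INDEX])
    z0 = bone.z_max - params.L
    z = rng.uniform(0.0, params.L, n)
    w_here = np.interp(z, zs, widths)
    s = rng.uniform(-0.5, 0.5, n) * w_here
    return bone.surface_point(z0 + z, s)


def export_mesh(mesh: trimesh.Trimesh, path, fmt: str | None = None):
    """Write a mesh as binary STL or ASCII OBJ/PLY; round-trips through
    float32 for STL."""
    if mesh is None or len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise ValueError("empty mesh")
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1]
    fmt = fmt.lower()
    if fmt not in ("stl", "obj", "ply"):
        raise ValueError(f"unknown mesh format {fmt!r}")
    if fmt == "ply":
        from trimesh.exchange.ply import export_ply
        with open(path, "wb") as fh:
            fh.write(export_ply(mesh, encoding="ascii"))
    else:
        mesh.export(path, file_type=fmt)
    return path
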