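"""Synthetic femur contact surface.

A smooth parametric proxy for the lateral surface of a proximal femur +
shaft, sufficient for exercising the plate-fitting pipeline: a generalized
cylinder of length ``H_fs`` and radius ``D_fs/2`` whose axis bows laterally
as a constant-curvature arc with total direction change ``180 deg - A_fs``
(apex at mid-shaft), carrying a greater-trochanter bump of peak height
``H_t1`` near the proximal end.  The trochanter's interior offset ``H_t2``
is modeled as a medial-side indentation whose circumferential weight
vanishes on the lateral contact strip, so it shapes the medial silhouette
without perturbing the plate-contact surface.

Coordinates: mm, right handed; bone axis +z (z = 0 distal, z = H_fs
proximal top), lateral +x.  The labeled contact region is the lateral
strip |theta| <= 1.45 rad.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import trimesh

from .schema import FemurParameterSet

__all__ = ["BoneSurfaceMesh", "PlanarSurface", "generate_bone_surface"]

CONTACT_HALF_ANGLE = 1.45         # rad, lateral contact strip half-width
BUMP_SIGMA_FRACTION = 1.0 / 6.0   # axial bump sigma as fraction of L_t
BUMP_CENTER_FRACTION = 0.26647    # bump center depth below the top, x L_t
BUMP_ARC_SIGMA_FRACTION = 1.0 / 3.0  # circumferential sigma (arc mm) x L_t


@dataclass
class BoneSurfaceMesh:
    """Triangulated synthetic femur with its generating analytic surface."""

    params: dict
    mesh: trimesh.Trimesh
    contact_vertex_mask: np.ndarray
    resolution: int

    # analytic pieces, set by generate_bone_surface
    _radius: float = 0.0
    _extent: float = 0.0
    _arc_R: float = np.inf
    _bump: tuple[float, float, float, float] = (0.0, 1.0, 1.0, 0.0)  # H_t1, zc, sz, s_arc

    @property
    def z_min(self) -> float:
        return 0.0

    @property
    def z_max(self) -> float:
        return self._extent

    @property
    def radius(self) -> float:
        return self._radius

    def contact_halfwidth(self) -> float:
        """Arc half-width (mm) of the labeled lateral contact strip."""
        return CONTACT_HALF_ANGLE * self._radius

    def _axis_x(self, z):
        if not np.isfinite(self._arc_R):
            return np.zeros_like(np.asarray(z, dtype=float))
        zm = self._extent / 2.0
        R = self._arc_R
        return np.sqrt(R * R - (np.asarray(z, dtype=float) - zm) ** 2) - np.sqrt(R * R - zm * zm)

    def _bump_height(self, z, theta):
        h, zc, sz, sa = self._bump
        if h == 0.0:
            return np.zeros(np.broadcast(z, theta).shape)
        st = sa / self._radius   # circumferential sigma in radians
        return h * np.exp(-((np.asarray(z) - zc) ** 2) / (2 * sz * sz)) \
                 * np.exp(-(np.asarray(theta) ** 2) / (2 * st * st))

    def surface_point(self, z, s):
        """Point on the contact surface at height ``z`` (mm) and lateral arc
        offset ``s`` (mm, measured on the nominal cylinder from the lateral
        line; positive toward +y)."""
        z = np.asarray(z, dtype=float)
        s = np.asarray(s, dtype=float)
        theta = s / self._radius
        r_eff = self._radius + self._bump_height(z, theta)
        x = self._axis_x(z) + r_eff * np.cos(theta)
        y = r_eff * np.sin(theta)
        return np.stack(np.broadcast_arrays(x, y, z), axis=-1)


class PlanarSurface:
    """Flat 'bone' stand-in (synthetic test fixture): the plane x = 0."""

    def __init__(self, extent: float = 300.0, halfwidth: float = 50.0):
        self._extent = extent
        self._halfwidth = halfwidth

    @property
    def z_min(self) -> float:
        return 0.0

    @property
    def z_max(self) -> float:
        return self._extent

    def contact_halfwidth(self) -> float:
        return self._halfwidth

    def surface_point(self, z, s):
        z = np.asarray(z, dtype=float)
        s = np.asarray(s, dtype=float)
        zero = np.zeros(np.broadcast(z, s).shape)
        return np.stack(np.broadcast_arrays(zero, s, z), axis=-1)


def generate_bone_surface(params: FemurParameterSet | Mapping[str, float],
                          resolution: int = 64,
                          n_angular: int = 96) -> BoneSurfaceMesh:
    """Build the synthetic femur surface for one parameter set.

    ``resolution`` is the number of axial rings (>= 8).  The construction is
    pure: identical inputs give identical vertex buffers.
    """
    p = dict(params)
    D_fs, H_fs, A_fs = p["D_fs"], p["H_fs"], p["A_fs"]
    L_t, H_t1 = p["L_t"], p["H_t1"]
    if resolution < 8:
        raise ValueError("resolution must be at least 8 rings")
    if not (150.0 < A_fs <= 180.0):
        raise ValueError("A_fs must lie in (150, 180] degrees")
    for key in ("D_fs", "H_fs", "L_t"):
        if p[key] <= 0:
            raise ValueError(f"{key} must be positive")
    if H_t1 < 0 or p.get("H_t2", 0.0) < 0:
        raise ValueError("bump parameters must be non-negative")

    radius = D_fs / 2.0
    bend = np.deg2rad(180.0 - A_fs)
    arc_R = H_fs / (2.0 * np.sin(bend / 2.0)) if bend > 1e-12 else np.inf
    zc = H_fs - BUMP_CENTER_FRACTION * L_t
    sz = BUMP_SIGMA_FRACTION * L_t
    sa = BUMP_ARC_SIGMA_FRACTION * L_t

    bone = BoneSurfaceMesh(params=p, mesh=None, contact_vertex_mask=None,
                           resolution=resolution, _radius=radius, _extent=H_fs,
                           _arc_R=arc_R, _bump=(H_t1, zc, sz, sa))

    # triangulated shell: rings x angular samples, medial indentation applied
    H_t2 = p.get("H_t2", 0.0)
    zs = np.linspace(0.0, H_fs, resolution)
    thetas = np.linspace(-np.pi, np.pi, n_angular, endpoint=False)
    Z, T = np.meshgrid(zs, thetas, indexing="ij")
    r_eff = radius + bone._bump_height(Z, T)
    if H_t2 > 0:
        # interior-side offset: medial Gaussian (about theta = pi), narrow
        # enough to vanish on the lateral contact strip
        dth = np.minimum(np.abs(T - np.pi), np.abs(T + np.pi))
        med = np.exp(-(dth ** 2) / (2 * 0.30 ** 2))
        ax = np.exp(-((Z - zc) ** 2) / (2 * sz * sz))
        r_eff = r_eff - H_t2 * med * ax
    X = bone._axis_x(Z) + r_eff * np.cos(T)
    Y = r_eff * np.sin(T)
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    faces = []
    for i in range(resolution - 1):
        for j in range(n_angular):
            a = i * n_angular + j
            b = i * n_angular + (j + 1) % n_angular
            c = a + n_angular
            d = b + n_angular
            faces.append([a, b, d])
            faces.append([a, d, c])
    # end caps (fans about ring centroids)
    base_c = len(verts)
    verts = np.vstack([verts, verts[:n_angular].mean(axis=0),
                       verts[-n_angular:].mean(axis=0)])
    top0 = (resolution - 1) * n_angular
    for j in range(n_angular):
        faces.append([base_c, (j + 1) % n_angular, j])
        faces.append([base_c + 1, top0 + j, top0 + (j + 1) % n_angular])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)

    mask = np.zeros(len(verts), dtype=bool)
    theta_grid = np.tile(thetas, resolution)
    mask[:resolution * n_angular] = np.abs(theta_grid) <= CONTACT_HALF_ANGLE
    bone.mesh = mesh
    bone.contact_vertex_mask = mask
    return bone
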