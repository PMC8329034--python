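"""End-to-end plate design runs.

Convenience drivers tying the stages together: femur parameters ->
synthetic bone surface -> semantic parameters -> feature grid -> skeleton
-> lofted undersurface -> solid with holes -> fit report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bone import BoneSurfaceMesh, generate_bone_surface
from .feature_model import (DEFAULT_COEFFS, DerivationCoefficients,
                            SemanticParameterSet, derive_semantic_parameters,
                            eagle_template_matrix, validate_topology)
from .plate_geometry import (FeaturePointGrid, FitReport, PlateSolidSpec,
                             SkeletonCurves, UndersurfacePatch,
                             build_feature_points, build_skeleton, extrude_solid,
                             fit_deviation, loft_undersurface, place_holes,
                             sample_contact_points)
from .schema import FEMUR_SCHEMA, FemurParameterSet

__all__ = ["PlateBuild", "design_plate", "size_mode_femurs"]


@dataclass
class PlateBuild:
    femur: FemurParameterSet
    bone: BoneSurfaceMesh
    params: SemanticParameterSet
    grid: FeaturePointGrid
    skeleton: SkeletonCurves
    patch: UndersurfacePatch
    solid: PlateSolidSpec
    fit: FitReport


def design_plate(femur: FemurParameterSet,
                 coeffs: DerivationCoefficients = DEFAULT_COEFFS,
                 params: SemanticParameterSet | None = None,
                 bone: BoneSurfaceMesh | None = None,
                 n_contact: int = 500,
                 contact_seed: int = 0,
                 check_topology: bool = True,
                 with_solid: bool = True) -> PlateBuild:
    """Run the whole design pipeline for one femur.

    The fit report measures the 500 (by default) dense contact-region
    samples against the lofted undersurface.
    """
    if bone is None:
        bone = generate_bone_surface(femur)
    if params is None:
        params = derive_semantic_parameters(femur, coeffs)
    grid = build_feature_points(params, bone)
    skel = build_skeleton(grid)
    if check_topology:
        diffs = validate_topology(skel.topology(), eagle_template_matrix())
        if diffs:
            raise ValueError(f"skeleton topology deviates from the eagle template: {diffs}")
    patch = loft_undersurface(skel)
    solid = None
    if with_solid:
        solid = extrude_solid(patch, params)
        solid = place_holes(solid, skel)
    contact = sample_contact_points(bone, params, n=n_contact, seed=contact_seed)
    fit = fit_deviation(patch, contact)
    return PlateBuild(femur, bone, params, grid, skel, patch, solid, fit)


def size_mode_femurs(n: int = 20, span_sd: float = 2.0, seed: int = 0) -> list[FemurParameterSet]:
    """Femur parameter sets sweeping +/- span_sd SDs along the joint size
    mode (all length parameters co-vary; the shaft bend angle alternates
    sign), the anatomically admissible way to span the cohort range."""
    rng = np.random.default_rng(seed)
    ts = np.linspace(-span_sd, span_sd, n)
    out = []
    for i, t in enumerate(ts):
        vals = {}
        for e in FEMUR_SCHEMA:
            if e.unit == "degree":
                vals[e.name] = e.mean
            else:
                vals[e.name] = e.mean + t * e.sd
        s = (-1) ** i * abs(t)
        a = FEMUR_SCHEMA["A_fs"]
        vals["A_fs"] = min(a.mean + s * a.sd, 180.0)
        # small seeded jitter on the remaining angles
        for name in ("A_fn", "A_m", "A_l"):
            e = FEMUR_SCHEMA[name]
            vals[name] = e.mean + rng.normal(0, 0.2) * e.sd
        out.append(FemurParameterSet(vals))
    return out
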