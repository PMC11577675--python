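"""Virtual biplanar medial open-wedge high tibial osteotomy.

Plans the main cut (medial entry at half the plateau width below the
plateau, sagittal hinge axis 15 mm below the plateau at the lateral cortex,
plane inclination following the medial tibial slope), adds the coronal
biplanar plane 10 mm posterior to the tuberosity apex, splits the tibia into
two watertight fragments and opens the wedge by a rigid rotation of the
distal fragment about the hinge axis.

Fragment membership of a point p:

* ascending:  proximal iff p is above the main plane AND posterior to the
  biplanar plane; everything else (shaft plus the anterior tuberosity
  column) is distal — the tuberosity travels with the wedge.
* descending: distal iff p is below the main plane AND posterior to the
  biplanar plane; the anterior tuberosity column stays proximal.

The wedge height h maps to the opening angle via the chord relation
theta = 2*arcsin(h / (2 W)), W being the perpendicular distance from the
medial entry point to the hinge axis, so the gap between the two images of
the entry point equals h exactly. A small-angle arctangent mapping is
available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .anatomy import LimbModel
from .geometry import Axis, Plane, RigidTransform, unit
from .mesh import TriMesh
from .patella import reposition_patella_on_limb

HINGE_DEPTH_MM = 15.0  # hinge axis depth below the plateau at the lateral cortex
BIPLANAR_OFFSET_MM = 10.0  # biplanar plane offset posterior to the tuberosity
DEFAULT_HEIGHTS_MM = (6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0)
VARIANTS = ("ascending", "descending")


@dataclass(frozen=True)
class OsteotomyPlan:
    variant: str
    main_cut_plane: Plane  # normal points proximal
    biplanar_plane: Plane  # normal points anterior
    medial_entry_point: np.ndarray
    hinge_axis: Axis
    entry_to_hinge_distance: float  # W, mm

    def as_dict(self) -> dict:
        return {
            "variant": self.variant,
            "main_cut_plane": {
                "point": list(self.main_cut_plane.point),
                "normal": list(self.main_cut_plane.normal),
            },
            "biplanar_plane": {
                "point": list(self.biplanar_plane.point),
                "normal": list(self.biplanar_plane.normal),
            },
            "medial_entry_point": list(self.medial_entry_point),
            "hinge_axis": {
                "point": list(self.hinge_axis.point),
                "direction": list(self.hinge_axis.direction),
            },
            "entry_to_hinge_distance": self.entry_to_hinge_distance,
        }


@dataclass
class OsteotomizedLimb:
    limb_id: str
    variant: str
    wedge_height_mm: float
    wedge_angle_deg: float
    plan: OsteotomyPlan
    landmarks: "Landmarks"  # transformed copy
    wedge_transform: RigidTransform
    proximal_fragment_mesh: TriMesh | None
    distal_fragment_mesh: TriMesh | None
    landmark_assignment: dict  # point name -> 'proximal' | 'distal'
    parent: LimbModel = field(repr=False, default=None)


def plan_osteotomy(limb: LimbModel, variant: str) -> OsteotomyPlan:
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    lm = limb.landmarks
    shape = limb.shape
    from .metrics import build_frames

    frames = build_frames(lm)
    ap_t = frames.tibial.ap
    if float((lm.tibial_tuberosity_apex - lm.knee_center_tibia) @ ap_t) <= 0:
        raise ValueError("degenerate anatomy: tuberosity posterior to plateau center")

    width = 2.0 * shape.plateau_halfwidth
    entry_depth = width / 2.0
    entry = np.array([shape.medial_cortex_x(-entry_depth), 0.0, -entry_depth])
    hinge_pt = np.array([shape.lateral_cortex_x(-HINGE_DEPTH_MM), 0.0, -HINGE_DEPTH_MM])

    slope = math.radians(limb.anthropometry["medial_tibial_slope_deg"])
    # sagittal direction within the cut plane: anterior end proximal by `slope`
    d_slope = np.array([0.0, math.cos(slope), math.sin(slope)])
    d_span = unit(hinge_pt - entry)
    normal = unit(np.cross(d_span, d_slope))
    if normal[2] < 0:
        normal = -normal
    main_plane = Plane(entry, normal)

    hinge_axis = Axis(hinge_pt, d_slope)
    r = entry - hinge_pt
    w = float(np.linalg.norm(r - (r @ hinge_axis.direction) * hinge_axis.direction))

    bp_point = lm.tibial_tuberosity_apex - BIPLANAR_OFFSET_MM * ap_t
    biplanar = Plane(bp_point, ap_t)
    return OsteotomyPlan(
        variant=variant,
        main_cut_plane=main_plane,
        biplanar_plane=biplanar,
        medial_entry_point=entry,
        hinge_axis=hinge_axis,
        entry_to_hinge_distance=w,
    )


def wedge_angle_from_height(
    h: float, plan: OsteotomyPlan, method: str = "chord"
) -> float:
    """Opening angle (degrees) producing a medial gap of `h` mm."""
    w = plan.entry_to_hinge_distance
    if h < 0:
        raise ValueError("wedge height must be >= 0")
    if method == "chord":
        if h >= 2.0 * w:
            raise ValueError(f"wedge height {h} >= 2W = {2 * w:.1f}: impossible opening")
        return math.degrees(2.0 * math.asin(h / (2.0 * w)))
    if method == "arctan":
        return math.degrees(math.atan2(h, w))
    raise ValueError("method must be 'chord' or 'arctan'")


def _is_distal(p: np.ndarray, plan: OsteotomyPlan) -> bool:
    above = plan.main_cut_plane.signed_distance(p) > 0
    posterior = plan.biplanar_plane.signed_distance(p) < 0
    if plan.variant == "ascending":
        return not (above and posterior)
    return (not above) and posterior


def split_fragments(limb: LimbModel, plan: OsteotomyPlan):
    """Cut the tibia with the main + biplanar planes.

    Returns (proximal_mesh, distal_mesh, landmark_assignment). Each fragment
    is a closed mesh; the complement fragment may consist of two adjacent
    closed sub-solids sharing the unreached part of a cut plane.
    """
    tibia = limb.tibia_mesh
    if tibia is None:
        raise ValueError("limb has no tibia mesh")
    if not tibia.is_watertight():
        raise ValueError("tibia mesh is not watertight")
    main = plan.main_cut_plane
    bp = plan.biplanar_plane

    above = tibia.clip_halfspace(main.flipped())  # proximal side of main cut
    below = tibia.clip_halfspace(main)
    if plan.variant == "ascending":
        proximal = above.clip_halfspace(bp)  # posterior part of plateau block
        anterior_col = above.clip_halfspace(bp.flipped())
        distal = TriMesh.concatenate([below, anterior_col])
    else:
        distal = below.clip_halfspace(bp)
        anterior_col = below.clip_halfspace(bp.flipped())
        proximal = TriMesh.concatenate([above, anterior_col])

    for name, m in (("proximal", proximal), ("distal", distal)):
        if m.is_empty() or not m.is_watertight():
            raise ValueError(f"{plan.variant} cut produced invalid {name} fragment")

    assignment = {
        name: ("distal" if _is_distal(p, plan) else "proximal")
        for name, p in limb.landmarks.tibial_points().items()
    }
    if plan.variant == "ascending":
        if assignment["tibial_tuberosity_apex"] != "distal":
            raise ValueError("ascending cut must keep the tuberosity distal")
    else:
        if assignment["tibial_tuberosity_apex"] != "proximal":
            raise ValueError("descending cut must keep the tuberosity proximal")
    if assignment["ankle_center"] != "distal":
        raise ValueError("ankle center must be distal")
    for nm in ("medial_plateau_edge", "lateral_plateau_edge", "knee_center_tibia"):
        if assignment[nm] != "proximal":
            raise ValueError(f"{nm} must be proximal")
    return proximal, distal, assignment


def _wedge_transform(plan: OsteotomyPlan, theta_deg: float) -> RigidTransform:
    """Rotation of the distal fragment opening the medial gap and valgizing."""
    theta = math.radians(theta_deg)
    for sign in (-1.0, 1.0):
        t = RigidTransform.rotation_about_axis(plan.hinge_axis, sign * theta)
        moved = t.apply(plan.medial_entry_point)
        if plan.main_cut_plane.signed_distance(moved) <= 0:
            return t
    return RigidTransform.rotation_about_axis(plan.hinge_axis, 0.0)


def apply_wedge(
    limb: LimbModel,
    plan: OsteotomyPlan,
    h: float,
    with_meshes: bool = True,
    reposition: bool = True,
    angle_method: str = "chord",
) -> OsteotomizedLimb:
    """Open the planned osteotomy to a medial gap of `h` mm."""
    theta = wedge_angle_from_height(h, plan, method=angle_method)
    transform = _wedge_transform(plan, theta)

    if with_meshes:
        proximal, distal, assignment = split_fragments(limb, plan)
        distal = TriMesh(transform.apply(distal.vertices), distal.faces)
    else:
        proximal = distal = None
        assignment = {
            name: ("distal" if _is_distal(p, plan) else "proximal")
            for name, p in limb.landmarks.tibial_points().items()
        }

    lm = limb.landmarks.copy()
    for name, side in assignment.items():
        if side == "distal":
            pts = lm.tibial_points()
            lm.set_tibial_point(name, transform.apply(pts[name]))

    ost = OsteotomizedLimb(
        limb_id=limb.limb_id,
        variant=plan.variant,
        wedge_height_mm=h,
        wedge_angle_deg=theta,
        plan=plan,
        landmarks=lm,
        wedge_transform=transform,
        proximal_fragment_mesh=proximal,
        distal_fragment_mesh=distal,
        landmark_assignment=assignment,
        parent=limb,
    )
    if reposition and plan.variant == "ascending":
        reposition_patella_on_limb(ost, limb)
    return ost


def medial_gap(ost: OsteotomizedLimb) -> float:
    """Distance between the two images of the medial entry point (the chord)."""
    entry = ost.plan.medial_entry_point
    return float(np.linalg.norm(ost.wedge_transform.apply(entry) - entry))


def run_osteotomy_grid(
    cohort: list[LimbModel],
    heights=DEFAULT_HEIGHTS_MM,
    variants=VARIANTS,
    with_meshes: bool = True,
    reposition: bool = True,
) -> list[OsteotomizedLimb]:
    """Full (limb x variant x height) experiment grid."""
    if not cohort:
        raise ValueError("cohort is empty")
    out = []
    for limb in cohort:
        for variant in variants:
            plan = plan_osteotomy(limb, variant)
            # the fragment split is height-independent; reuse it per variant
            if with_meshes:
                proximal, distal, assignment = split_fragments(limb, plan)
            for h in heights:
                try:
                    ost = apply_wedge(
                        limb,
                        plan,
                        h,
                        with_meshes=False,
                        reposition=reposition,
                    )
                except Exception as exc:  # noqa: BLE001 - annotate grid cell
                    raise RuntimeError(
                        f"osteotomy failed at limb={limb.limb_id} "
                        f"variant={variant} h={h}: {exc}"
                    ) from exc
                if with_meshes:
                    ost.proximal_fragment_mesh = proximal
                    ost.distal_fragment_mesh = TriMesh(
                        ost.wedge_transform.apply(distal.vertices), distal.faces
                    )
                out.append(ost)
    return out


def grid_manifest(osteotomies: list[OsteotomizedLimb]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "limb_id": o.limb_id,
                "variant": o.variant,
                "wedge_height_mm": o.wedge_height_mm,
                "wedge_angle_deg": o.wedge_angle_deg,
            }
            for o in osteotomies
        ]
    )
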