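import math

import numpy as np
import pytest

from osteokin import metrics
from osteokin.anatomy import CohortSpec, generate_cohort, generate_limb
from osteokin.geometry import Axis, RigidTransform
from osteokin.osteotomy import (
    HINGE_DEPTH_MM,
    OsteotomyPlan,
    apply_wedge,
    medial_gap,
    plan_osteotomy,
    run_osteotomy_grid,
    split_fragments,
    wedge_angle_from_height,
)


@pytest.fixture(scope="module")
def limb():
    return generate_limb(CohortSpec(n_limbs=1, seed=7), 0)


@pytest.fixture(scope="module")
def plans(limb):
    return {v: plan_osteotomy(limb, v) for v in ("ascending", "descending")}


# ------------------------------------------------------------------ planning


def test_entry_depth_is_half_plateau_width(limb, plans):
    width = limb.anthropometry["plateau_width_mm"]
    entry = plans["ascending"].medial_entry_point
    assert entry[2] == pytest.approx(-width / 2, abs=1e-9)
    # entry lies on the analytic medial cortex
    assert entry[0] == pytest.approx(limb.shape.medial_cortex_x(entry[2]), abs=1e-9)


def test_hinge_depth_and_in_plane(limb, plans):
    plan = plans["ascending"]
    assert plan.hinge_axis.point[2] == pytest.approx(-HINGE_DEPTH_MM, abs=1e-9)
    # hinge axis lies in the main cut plane
    for lam in (-20.0, 0.0, 20.0):
        p = plan.hinge_axis.point + lam * plan.hinge_axis.direction
        assert abs(plan.main_cut_plane.signed_distance(p)) < 1e-9


def test_biplanar_offset(limb, plans):
    plan = plans["ascending"]
    d = plan.biplanar_plane.signed_distance(limb.landmarks.tibial_tuberosity_apex)
    assert d == pytest.approx(10.0, abs=1e-9)


def test_main_plane_parallel_to_slope(limb, plans):
    slope = math.radians(limb.anthropometry["medial_tibial_slope_deg"])
    d_slope = np.array([0.0, math.cos(slope), math.sin(slope)])
    # plane contains the sagittal slope direction: normal orthogonal to it
    assert abs(plans["ascending"].main_cut_plane.normal @ d_slope) < 1e-6


def test_degenerate_anatomy_error(limb):
    import copy

    bad = copy.deepcopy(limb)
    bad.landmarks.tibial_tuberosity_apex = np.array([0.0, -40.0, -30.0])
    with pytest.raises(ValueError, match="tuberosity posterior"):
        plan_osteotomy(bad, "ascending")


# ---------------------------------------------------------------- angle map


def test_wedge_angle_examples(plans):
    plan = OsteotomyPlan(
        variant="ascending",
        main_cut_plane=plans["ascending"].main_cut_plane,
        biplanar_plane=plans["ascending"].biplanar_plane,
        medial_entry_point=plans["ascending"].medial_entry_point,
        hinge_axis=plans["ascending"].hinge_axis,
        entry_to_hinge_distance=66.0,
    )
    assert wedge_angle_from_height(0.0, plan) == pytest.approx(0.0, abs=1e-12)
    assert wedge_angle_from_height(6.0, plan) == pytest.approx(5.211, abs=1e-3)
    # 2*arcsin(12/132) = 10.4318 deg (independent evaluation)
    assert wedge_angle_from_height(12.0, plan) == pytest.approx(10.4318, abs=1e-3)
    with pytest.raises(ValueError):
        wedge_angle_from_height(2 * 66.0, plan)
    with pytest.raises(ValueError):
        wedge_angle_from_height(-1.0, plan)
    # alternative small-angle mapping
    assert wedge_angle_from_height(6.0, plan, method="arctan") == pytest.approx(
        math.degrees(math.atan(6.0 / 66.0))
    )


def test_wedge_angle_strictly_increasing(plans):
    hs = np.linspace(0, 12, 25)
    th = [wedge_angle_from_height(h, plans["ascending"]) for h in hs]
    assert np.all(np.diff(th) > 0)


def test_chord_oracle_random():
    # independent oracle: rotate a point at distance W about an axis by
    # theta(h); the chord it travels must equal h (law of cosines)
    rng = np.random.default_rng(123)
    plan_proto = None
    for _ in range(100):
        w = rng.uniform(30.0, 90.0)
        h = rng.uniform(0.0, min(12.0, 1.9 * w))
        theta = 2.0 * math.asin(h / (2.0 * w))
        chord = math.sqrt(2.0 * w * w * (1.0 - math.cos(theta)))
        assert chord == pytest.approx(h, abs=1e-9)


# ------------------------------------------------------------------ cutting


@pytest.mark.parametrize("variant", ["ascending", "descending"])
def test_split_fragments(limb, plans, variant):
    prox, dist, assignment = split_fragments(limb, plans[variant])
    assert prox.is_watertight()
    assert dist.is_watertight()
    total = prox.volume() + dist.volume()
    assert total == pytest.approx(limb.tibia_mesh.volume(), rel=1e-3)
    if variant == "ascending":
        assert assignment["tibial_tuberosity_apex"] == "distal"
        assert assignment["patellar_tendon_insertion"] == "distal"
    else:
        assert assignment["tibial_tuberosity_apex"] == "proximal"
        assert assignment["patellar_tendon_insertion"] == "proximal"
    assert assignment["ankle_center"] == "distal"
    assert assignment["medial_plateau_edge"] == "proximal"
    assert assignment["lateral_plateau_edge"] == "proximal"


# ------------------------------------------------------------------- wedges


def test_apply_wedge_zero_is_identity(limb, plans):
    ost = apply_wedge(limb, plans["ascending"], 0.0, with_meshes=False)
    for name in limb.landmarks._POINT_FIELDS:
        assert np.array_equal(
            getattr(ost.landmarks, name), getattr(limb.landmarks, name)
        ), name


@pytest.mark.parametrize("h", [3.0, 6.0, 12.0])
def test_wedge_rigidity_and_gap(limb, plans, h):
    for variant in ("ascending", "descending"):
        ost = apply_wedge(limb, plans[variant], h, with_meshes=False)
        t = ost.wedge_transform
        assert t.is_proper(tol=1e-9)
        # hinge axis points are fixed
        for lam in (-10.0, 0.0, 30.0):
            p = ost.plan.hinge_axis.point + lam * ost.plan.hinge_axis.direction
            np.testing.assert_allclose(t.apply(p), p, atol=1e-9)
        assert medial_gap(ost) == pytest.approx(h, abs=1e-6)
        # rigidity: pairwise distances among transformed points preserved
        pts = np.array(
            [limb.landmarks.ankle_center, limb.landmarks.tibial_tuberosity_apex]
        )
        moved = t.apply(pts)
        assert np.linalg.norm(moved[0] - moved[1]) == pytest.approx(
            np.linalg.norm(pts[0] - pts[1]), abs=1e-9
        )


def test_hka_delta_matches_wedge_angle_and_variant_independent(limb, plans):
    pre = metrics.hka_angle(limb.landmarks)
    for h in (6.0, 12.0):
        deltas = []
        for variant in ("ascending", "descending"):
            ost = apply_wedge(limb, plans[variant], h, with_meshes=False)
            deltas.append(metrics.hka_angle(ost.landmarks) - pre)
        assert deltas[0] == pytest.approx(deltas[1], abs=1e-9)
        assert deltas[0] > 0  # valgizing correction


def test_deltas_strictly_increasing_in_height(limb, plans):
    pre_hka = metrics.hka_angle(limb.landmarks)
    pre_ttg = metrics.tt_tg_axial(limb.landmarks)
    hka_d, ttg_d = [], []
    for h in range(6, 13):
        ost = apply_wedge(limb, plans["ascending"], float(h), with_meshes=False)
        hka_d.append(metrics.hka_angle(ost.landmarks) - pre_hka)
        ttg_d.append(metrics.tt_tg_axial(ost.landmarks) - pre_ttg)
    assert np.all(np.diff(hka_d) > 0)
    assert np.all(np.diff(ttg_d) > 0)
    assert all(d > 0 for d in ttg_d)  # lateralization


def test_fragment_meshes_transform_rigidly(limb, plans):
    ost = apply_wedge(limb, plans["ascending"], 8.0, with_meshes=True)
    assert ost.proximal_fragment_mesh.is_watertight()
    assert ost.distal_fragment_mesh.is_watertight()
    # volume is preserved by the rigid wedge transform
    prox, dist, _ = split_fragments(limb, plans["ascending"])
    assert ost.distal_fragment_mesh.volume() == pytest.approx(
        dist.volume(), rel=1e-9
    )


# --------------------------------------------------------------------- grid


def test_grid_counts():
    cohort = generate_cohort(CohortSpec(n_limbs=1, seed=2), with_meshes=False)
    grid = run_osteotomy_grid(cohort, with_meshes=False)
    assert len(grid) == 14  # 2 variants x 7 heights
    assert sum(1 for g in grid if g.variant == "ascending") == 7


def test_grid_empty_cohort_error():
    with pytest.raises(ValueError):
        run_osteotomy_grid([], with_meshes=False)


def test_grid_failure_names_cell():
    cohort = generate_cohort(CohortSpec(n_limbs=1, seed=2), with_meshes=False)
    with pytest.raises(RuntimeError, match="limb000"):
        run_osteotomy_grid(cohort, heights=(1e6,), with_meshes=False)
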