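import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteokin import metrics
from osteokin.anatomy import CohortSpec, generate_cohort, generate_limb
from osteokin.geometry import Axis, RigidTransform
from osteokin.metrics import (
    build_frames,
    build_index_table,
    coronal_angle_deg,
    hka_angle,
    insall_salvati,
    tt_tg_axial,
)
from osteokin.osteotomy import apply_wedge, plan_osteotomy, run_osteotomy_grid


@pytest.fixture(scope="module")
def limb():
    return generate_limb(CohortSpec(n_limbs=1, seed=11), 0, with_meshes=False)


def test_frames_orthonormal_right_handed(limb):
    frames = build_frames(limb.landmarks)
    for fr in (frames.femoral, frames.tibial, frames.patellar):
        B = fr.basis()
        np.testing.assert_allclose(B.T @ B, np.eye(3), atol=1e-9)
        assert np.linalg.det(B) == pytest.approx(1.0, abs=1e-9)


def test_coronal_angle_collinear():
    assert coronal_angle_deg([0, 0, 800], [0, 0, 400], [0, 0, 0]) == pytest.approx(
        180.0, abs=1e-9
    )


def test_coronal_angle_derived_offset():
    # tan(2 deg) * 400 mm = 13.96 mm coronal offset at the ankle
    a = coronal_angle_deg([0, 0, 800], [0, 0, 400], [13.96, 0, 0])
    assert a == pytest.approx(178.0, abs=0.01)


def test_hka_sign_convention(limb):
    lm = limb.landmarks.copy()
    # push the ankle medially (varus for right convention): HKA < 180
    lm.ankle_center = np.array([-20.0, 0.0, -380.0])
    assert hka_angle(lm) < 180
    lm.ankle_center = np.array([20.0, 0.0, -380.0])
    assert hka_angle(lm) > 180


def test_hka_coincident_points_error(limb):
    lm = limb.landmarks.copy()
    lm.ankle_center = lm.knee_center_tibia.copy()
    with pytest.raises(ValueError):
        hka_angle(lm)


def test_tt_tg_axis_aligned(limb):
    lm = limb.landmarks.copy()
    lm.trochlear_groove_point = np.array([0.0, 20.0, 12.0])
    lm.tibial_tuberosity_apex = np.array([4.0, 25.0, -30.0])
    assert tt_tg_axial(lm) == pytest.approx(4.0, abs=1e-12)


def test_insall_salvati_direct_ratio(limb):
    lm = limb.landmarks.copy()
    lm.patella_distal_pole = np.array([0.0, 35.0, 0.0])
    lm.patella_proximal_pole = np.array([0.0, 35.0, 50.0])
    lm.patellar_tendon_insertion = np.array([0.0, 35.0, -40.0])
    assert insall_salvati(lm) == pytest.approx(0.8, abs=1e-12)


def test_insall_salvati_zero_length_error(limb):
    lm = limb.landmarks.copy()
    lm.patella_proximal_pole = lm.patella_distal_pole.copy()
    with pytest.raises(ValueError):
        insall_salvati(lm)


@settings(max_examples=25, deadline=None)
@given(
    st.floats(-3, 3),
    st.lists(st.floats(-0.8, 0.8), min_size=3, max_size=3).filter(
        lambda v: sum(x * x for x in v) > 1e-3
    ),
    st.lists(st.floats(-50, 50), min_size=3, max_size=3),
)
def test_rigid_motion_equivariance(angle, direction, translation):
    limb = generate_limb(CohortSpec(n_limbs=1, seed=11), 0, with_meshes=False)
    t = RigidTransform.rotation_about_axis(Axis([5.0, -3.0, 40.0], direction), angle)
    t = RigidTransform(t.R, t.t + np.asarray(translation))
    lm2 = limb.landmarks.transformed_all(t)
    assert hka_angle(lm2) == pytest.approx(hka_angle(limb.landmarks), abs=1e-9)
    assert tt_tg_axial(lm2) == pytest.approx(tt_tg_axial(limb.landmarks), abs=1e-9)
    assert insall_salvati(lm2) == pytest.approx(
        insall_salvati(limb.landmarks), abs=1e-9
    )


def test_ttg_delta_under_known_lateral_shift(limb):
    # displace the tuberosity 2.1 mm along the femoral ML axis: delta = 2.1
    lm = limb.landmarks.copy()
    frames = build_frames(lm)
    before = tt_tg_axial(lm, frames)
    lm.tibial_tuberosity_apex = lm.tibial_tuberosity_apex + 2.1 * frames.femoral.ml
    assert tt_tg_axial(lm, frames) - before == pytest.approx(2.1, abs=1e-9)


def test_descending_index_identity(limb):
    plan = plan_osteotomy(limb, "descending")
    ost = apply_wedge(limb, plan, 9.0, with_meshes=False)
    assert tt_tg_axial(ost.landmarks) - tt_tg_axial(limb.landmarks) == 0.0
    assert insall_salvati(ost.landmarks) - insall_salvati(limb.landmarks) == 0.0


def test_index_table_identity_deltas(limb):
    # pre == post (h=0 wedges) -> all deltas zero
    plan_a = plan_osteotomy(limb, "ascending")
    plan_d = plan_osteotomy(limb, "descending")
    posts = [
        apply_wedge(limb, plan_a, 0.0, with_meshes=False),
        apply_wedge(limb, plan_d, 0.0, with_meshes=False),
    ]
    table = build_index_table([limb], posts)
    post = table[table["variant"] != "preop"]
    assert (post[["d_hka", "d_ttg", "d_is"]].abs() < 1e-12).all().all()


def test_index_table_full_grid_row_count():
    cohort = generate_cohort(CohortSpec(n_limbs=2, seed=9), with_meshes=False)
    grid = run_osteotomy_grid(cohort, with_meshes=False)
    table = build_index_table(cohort, grid)
    assert len(table) == 2 + 2 * 2 * 7
    assert (table["variant"] == "preop").sum() == 2


def test_index_table_missing_cell_error():
    cohort = generate_cohort(CohortSpec(n_limbs=2, seed=9), with_meshes=False)
    grid = run_osteotomy_grid(cohort, with_meshes=False)
    with pytest.raises(ValueError, match="missing grid cell"):
        build_index_table(cohort, grid[:-1])


def test_index_table_summary_hand_check():
    # 2-limb toy grid, one variant x one height: mean/SD by hand
    cohort = generate_cohort(CohortSpec(n_limbs=2, seed=9), with_meshes=False)
    grid = run_osteotomy_grid(
        cohort, heights=(6.0,), variants=("ascending",), with_meshes=False
    )
    table = build_index_table(cohort, grid)
    post = table[table["variant"] == "ascending"]
    d = post["d_hka"].to_numpy()
    summary = metrics.summarize_index_table(table)
    assert summary[("d_hka", "mean")].iloc[0] == pytest.approx(d.mean())
    assert summary[("d_hka", "std")].iloc[0] == pytest.approx(d.std(ddof=1))
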