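import numpy as np
import pytest

from osteokin.anatomy import CohortSpec, generate_cohort, generate_limb, mirror_limb
from osteokin.osteotomy import apply_wedge, plan_osteotomy, run_osteotomy_grid
from osteokin.squat import (
    SimParams,
    build_knee_model,
    estimate_body_weight,
    ligament_energy_at,
    run_experiment,
    run_squat,
    solve_equilibrium_at_flexion,
)


@pytest.fixture(scope="module")
def limb():
    return generate_limb(CohortSpec(n_limbs=1, seed=7), 0, with_meshes=False)


@pytest.fixture(scope="module")
def model(limb):
    return build_knee_model(limb)


TOY = dict(
    quad_force_bw0=0.0,
    quad_force_bw_slope=0.0,
    tendon_stiffness=0.0,
    lig_stiffness={"ACL": 0.0, "PCL": 0.0, "MCL": 0.0, "LCL": 0.0},
    hamstring_force_bw=0.0,
    channel_stiffness=0.0,
    channel_quartic=0.0,
    tilt_stiffness=0.0,
    # toy energies are tiny; tighten the relative-gradient contract so the
    # closed-form comparison is meaningful at 1e-8 in the solution
    residual_tol=1e-10,
)


# ------------------------------------------------------------- body weight


def test_body_weight_identity_coefficients():
    assert estimate_body_weight(70.0, (1.0, 0.0)) == pytest.approx(70.0)


def test_body_weight_default_is_linear_form():
    a, b = SimParams().bw_coefficients
    assert estimate_body_weight(45.0) == pytest.approx(a * 45.0 + b)


def test_body_weight_linearity():
    assert estimate_body_weight(80.0, (2.0, 0.0)) == pytest.approx(
        2 * estimate_body_weight(40.0, (2.0, 0.0))
    )


def test_body_weight_errors():
    with pytest.raises(ValueError):
        estimate_body_weight(-1.0)
    with pytest.raises(ValueError):
        estimate_body_weight(1.0, (1.0, -100.0))


# ------------------------------------------------------------- model build


def test_slack_zero_pretension_at_start(model):
    assert ligament_energy_at(model, model.params.flexion_start, 0.0) == pytest.approx(
        0.0, abs=1e-12
    )


def test_osteotomized_inherits_preop_parameters(limb, model):
    plan = plan_osteotomy(limb, "ascending")
    ost = apply_wedge(limb, plan, 12.0, with_meshes=False)
    m = build_knee_model(ost, preop=model)
    np.testing.assert_array_equal(m.lig_slack, model.lig_slack)
    assert m.tendon_length == model.tendon_length
    assert m.groove_radius == model.groove_radius
    with pytest.raises(ValueError):
        build_knee_model(ost)  # preop model is required


def test_missing_ligament_error(limb):
    import copy

    bad = copy.deepcopy(limb)
    del bad.landmarks.ligaments["ACL"]
    with pytest.raises(ValueError, match="ACL"):
        build_knee_model(bad)


# ------------------------------------------------------------- equilibrium


def test_toy_single_spring_closed_form(limb):
    p = SimParams(**TOY, extra_ml_springs=((5.0, 3.7),))
    m = build_knee_model(limb, p)
    pose = solve_equilibrium_at_flexion(m, 30.0)
    assert pose.patellar_shift_mm == pytest.approx(3.7, abs=1e-8)


def test_toy_two_springs_closed_form(limb):
    k1, r1, k2, r2 = 5.0, 3.0, 15.0, -2.0
    p = SimParams(**TOY, extra_ml_springs=((k1, r1), (k2, r2)))
    m = build_knee_model(limb, p)
    pose = solve_equilibrium_at_flexion(m, 30.0)
    assert pose.patellar_shift_mm == pytest.approx(
        (k1 * r1 + k2 * r2) / (k1 + k2), abs=1e-8
    )


def test_flexion_out_of_range(model):
    with pytest.raises(ValueError):
        solve_equilibrium_at_flexion(model, 2.0)


def test_mirror_antisymmetry(limb, model):
    mm = build_knee_model(mirror_limb(limb))
    for f in (5.0, 55.0, 100.0):
        a = solve_equilibrium_at_flexion(model, f)
        b = solve_equilibrium_at_flexion(mm, f)
        assert b.patellar_shift_mm == pytest.approx(-a.patellar_shift_mm, abs=1e-6)
        assert b.patellar_tilt_deg == pytest.approx(-a.patellar_tilt_deg, abs=1e-6)
        assert b.patellar_rotation_deg == pytest.approx(
            -a.patellar_rotation_deg, abs=1e-6
        )
        assert b.tibiofemoral_rotation_deg == pytest.approx(
            -a.tibiofemoral_rotation_deg, abs=1e-6
        )


def test_warm_start_energy_not_increased(model):
    a = solve_equilibrium_at_flexion(model, 40.0)
    b = solve_equilibrium_at_flexion(model, 41.0, warm_start=a)
    assert b.energy <= model.energy(a.q, 41.0) + 1e-9 * (1 + abs(b.energy))
    assert b.residual < model.params.residual_tol


# -------------------------------------------------------------- full sweep


def test_run_squat_series_and_determinism(model):
    c1 = run_squat(model)
    c2 = run_squat(model)
    assert len(c1.flexion_deg) == 96
    for param, v in c1.series.items():
        assert len(v) == 96
        assert np.all(np.isfinite(v))
        assert np.array_equal(v, c2.series[param])  # bitwise determinism
    assert c1.max_jump <= model.params.continuity_bound


def test_zero_wedge_curves_identical_to_preop(limb, model):
    plan = plan_osteotomy(limb, "descending")
    ost = apply_wedge(limb, plan, 0.0, with_meshes=False)
    m0 = build_knee_model(ost, preop=model)
    pre = run_squat(model)
    post = run_squat(m0)
    for param in pre.series:
        assert np.array_equal(pre.series[param], post.series[param])


def test_experiment_counts_single_limb():
    cohort = generate_cohort(CohortSpec(n_limbs=1, seed=5), with_meshes=False)
    grid = run_osteotomy_grid(cohort, with_meshes=False)
    result = run_experiment(cohort, grid)
    assert result.n_models == 15  # 1 preop + 14 osteotomy states
    assert result.samples_per_parameter() == 15 * 96 == 1440
    df = result.to_frame()
    assert np.isfinite(df["value"]).all()
    assert len(df) == 4 * 1440
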