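import dataclasses

import numpy as np
import pytest

from osteokin import metrics
from osteokin.anatomy import (
    CohortSpec,
    Landmarks,
    build_tibia_mesh,
    generate_cohort,
    generate_limb,
    mirror_limb,
)


def test_determinism_bitwise():
    spec = CohortSpec(n_limbs=2, seed=7)
    a = generate_limb(spec, 0)
    b = generate_limb(spec, 0)
    for name in Landmarks._POINT_FIELDS:
        assert np.array_equal(
            getattr(a.landmarks, name), getattr(b.landmarks, name)
        ), name
    assert np.array_equal(a.tibia_mesh.vertices, b.tibia_mesh.vertices)
    assert a.side == b.side


def test_degenerate_distribution_hka_exact():
    spec = CohortSpec(
        n_limbs=4,
        seed=1,
        hka_deg=(180.0, 0.0),
        ttg_mm=(13.6, 0.0),
        insall_salvati=(0.8, 0.0),
        plateau_width_mm=(75.0, 0.0),
        tibia_length_mm=(380.0, 0.0),
        femur_length_mm=(430.0, 0.0),
        femoral_head_diameter_mm=(46.0, 0.0),
        medial_tibial_slope_deg=(7.0, 0.0),
    )
    for limb in generate_cohort(spec, with_meshes=False):
        assert metrics.hka_angle(limb.landmarks) == pytest.approx(180.0, abs=1e-6)
        assert metrics.tt_tg_axial(limb.landmarks) == pytest.approx(13.6, abs=1e-6)
        assert metrics.insall_salvati(limb.landmarks) == pytest.approx(0.8, abs=1e-6)


def test_measured_indices_match_draws_exactly():
    spec = CohortSpec(n_limbs=5, seed=42)
    for limb in generate_cohort(spec, with_meshes=False):
        d = limb.anthropometry
        assert metrics.hka_angle(limb.landmarks) == pytest.approx(
            d["hka_deg"], abs=1e-9
        )
        assert metrics.tt_tg_axial(limb.landmarks) == pytest.approx(
            d["ttg_mm"], abs=1e-9
        )
        assert metrics.insall_salvati(limb.landmarks) == pytest.approx(
            d["insall_salvati"], abs=1e-9
        )


def test_cohort_size_and_unique_ids():
    cohort = generate_cohort(CohortSpec(n_limbs=13, seed=5), with_meshes=False)
    assert len(cohort) == 13
    assert len({l.limb_id for l in cohort}) == 13
    assert len(generate_cohort(CohortSpec(n_limbs=1, seed=5), with_meshes=False)) == 1


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        CohortSpec(n_limbs=0)
    with pytest.raises(ValueError):
        CohortSpec(hka_deg=(178.0, -1.0))
    with pytest.raises(ValueError):
        generate_limb(CohortSpec(n_limbs=1), 1)


def test_infeasible_draws_error():
    from osteokin.anatomy import InfeasibleDrawError

    spec = CohortSpec(n_limbs=1, seed=0, plateau_width_mm=(-500.0, 0.1))
    with pytest.raises(InfeasibleDrawError):
        generate_limb(spec, 0)


def test_tibia_mesh_topology(small_cohort):
    for limb in small_cohort:
        m = limb.tibia_mesh
        assert m.is_watertight()
        assert m.euler_characteristic() == 2
        assert limb.femur_mesh.is_watertight()
        assert limb.patella_mesh.is_watertight()


def test_tuberosity_apex_is_mesh_vertex(small_cohort):
    for limb in small_cohort:
        apex = limb.landmarks.tibial_tuberosity_apex
        d = np.linalg.norm(limb.tibia_mesh.vertices - apex, axis=1).min()
        assert d < 1e-9


def test_plateau_width_measured_on_mesh(small_cohort):
    for limb in small_cohort:
        want = limb.anthropometry["plateau_width_mm"]
        ring = limb.tibia_mesh.vertices[np.abs(limb.tibia_mesh.vertices[:, 2]) < 1e-9]
        got = ring[:, 0].max() - ring[:, 0].min()
        assert got == pytest.approx(want, abs=0.5)


def test_mirrored_mesh_is_reflection(small_cohort):
    limb = small_cohort[0]
    mm = build_tibia_mesh(limb.shape, mirrored=True)
    ref = limb.tibia_mesh.mirrored(0)
    assert np.array_equal(mm.vertices, ref.vertices)
    assert mm.is_watertight()
    assert mm.volume() == pytest.approx(limb.tibia_mesh.volume())


def test_mirror_limb_flips_side_and_coordinates(small_cohort):
    limb = small_cohort[0]
    m = mirror_limb(limb)
    assert m.side != limb.side
    np.testing.assert_allclose(
        m.landmarks.ankle_center,
        limb.landmarks.ankle_center * [-1, 1, 1],
    )


def test_plateau_edges_ordered_for_right_convention(small_cohort):
    for limb in small_cohort:
        lm = limb.landmarks
        assert lm.lateral_plateau_edge[0] > lm.medial_plateau_edge[0]


def test_landmark_json_roundtrip(tmp_path, small_cohort):
    lm = small_cohort[0].landmarks
    lm.save_json(tmp_path / "lm.json")
    lm2 = Landmarks.load_json(tmp_path / "lm.json")
    for name in Landmarks._POINT_FIELDS:
        assert np.array_equal(getattr(lm, name), getattr(lm2, name))
    assert lm2.femoral_head_diameter == lm.femoral_head_diameter
    assert set(lm2.ligaments) == set(lm.ligaments)


def test_calibration_sample_means():
    # cheap version of the acceptance calibration (n=300, 3 standard errors)
    spec = CohortSpec(n_limbs=300, seed=42)
    hka, ttg, isr = [], [], []
    for i in range(spec.n_limbs):
        limb = generate_limb(spec, i, with_meshes=False)
        hka.append(limb.anthropometry["hka_deg"])
        ttg.append(limb.anthropometry["ttg_mm"])
        isr.append(limb.anthropometry["insall_salvati"])
    for vals, (mean, sd) in ((hka, spec.hka_deg), (ttg, spec.ttg_mm), (isr, spec.insall_salvati)):
        se = sd / np.sqrt(len(vals))
        assert abs(np.mean(vals) - mean) < 3 * se
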