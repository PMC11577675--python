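"""Anatomical coordinate frames and index measurements.

Implements the three indices the pipeline tracks pre- and post-osteotomy:

* HKA — hip–knee–ankle angle in the coronal plane (180 deg = neutral,
  varus < 180, valgization increases the value),
* axial TT–TG — signed mediolateral distance between the tibial tuberosity
  apex and the trochlear groove along the femoral epicondylar axis
  (lateral positive),
* Insall–Salvati — 3D patellar tendon length over 3D patellar length.

All measurements are built from dot products of landmark differences, so
they are invariant under a common rigid motion of the whole landmark set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anatomy import Landmarks
from .geometry import angle_between_deg, orthonormalize, unit


@dataclass(frozen=True)
class Frame:
    origin: np.ndarray
    ml: np.ndarray  # mediolateral, lateral positive (right convention)
    ap: np.ndarray  # anteroposterior, anterior positive
    pd: np.ndarray  # proximodistal, proximal positive

    def basis(self) -> np.ndarray:
        return np.column_stack([self.ml, self.ap, self.pd])

    def to_local(self, p: np.ndarray) -> np.ndarray:
        return (np.asarray(p, float) - self.origin) @ self.basis()


@dataclass(frozen=True)
class AnatomicalFrames:
    femoral: Frame
    tibial: Frame
    patellar: Frame


def build_frames(lm: Landmarks) -> AnatomicalFrames:
    # femoral: ML from epicondyles, PD toward the hip, AP completes RH set
    ml_f = unit(lm.lateral_epicondyle - lm.medial_epicondyle)
    pd_f = orthonormalize(ml_f, lm.hip_center - lm.knee_center_femur)
    ap_f = np.cross(pd_f, ml_f)
    femoral = Frame(lm.knee_center_femur.copy(), ml_f, ap_f, pd_f)

    # tibial: long axis toward the ankle, ML from plateau edges
    pd_t = unit(lm.knee_center_tibia - lm.ankle_center)
    ml_t = orthonormalize(pd_t, lm.lateral_plateau_edge - lm.medial_plateau_edge)
    ap_t = np.cross(pd_t, ml_t)
    tibial = Frame(lm.knee_center_tibia.copy(), ml_t, ap_t, pd_t)

    # patellar: long axis from poles, ML borrowed from femur
    pd_p = unit(lm.patella_proximal_pole - lm.patella_distal_pole)
    ml_p = orthonormalize(pd_p, ml_f)
    ap_p = np.cross(pd_p, ml_p)
    patellar = Frame(lm.patella_center.copy(), ml_p, ap_p, pd_p)
    return AnatomicalFrames(femoral, tibial, patellar)


def coronal_angle_deg(hip, knee, ankle, ap_normal=(0.0, 1.0, 0.0)) -> float:
    """Unsigned angle at the knee between knee->hip and knee->ankle projected
    onto the plane orthogonal to `ap_normal`."""
    n = unit(np.asarray(ap_normal, float))
    u = np.asarray(hip, float) - np.asarray(knee, float)
    v = np.asarray(ankle, float) - np.asarray(knee, float)
    up = u - (u @ n) * n
    vp = v - (v @ n) * n
    return angle_between_deg(up, vp)


def hka_angle(lm: Landmarks) -> float:
    """Signed coronal HKA: 180 = collinear, varus < 180, valgus > 180."""
    frames = build_frames(lm)
    ap = frames.femoral.ap
    ml = frames.femoral.ml
    delta = 180.0 - coronal_angle_deg(
        lm.hip_center, lm.knee_center_tibia, lm.ankle_center, ap_normal=ap
    )
    v = lm.ankle_center - lm.knee_center_tibia
    vp = v - (v @ ap) * ap
    sign = 1.0 if vp @ ml >= 0 else -1.0  # ankle lateral of axis -> valgus
    return 180.0 + sign * delta


def tt_tg_axial(lm: Landmarks, frames: AnatomicalFrames | None = None) -> float:
    """Signed ML tuberosity-to-groove offset in the femoral axial plane."""
    if frames is None:
        frames = build_frames(lm)
    ml = frames.femoral.ml
    if np.linalg.norm(ml) < 1e-9:
        raise ValueError("degenerate femoral ML axis")
    return float((lm.tibial_tuberosity_apex - lm.trochlear_groove_point) @ ml)


def insall_salvati(lm: Landmarks) -> float:
    patellar_len = float(
        np.linalg.norm(lm.patella_proximal_pole - lm.patella_distal_pole)
    )
    if patellar_len < 1e-9:
        raise ValueError("zero patellar length")
    tendon_len = float(
        np.linalg.norm(lm.patella_distal_pole - lm.patellar_tendon_insertion)
    )
    return tendon_len / patellar_len


def measure_indices(lm: Landmarks) -> dict:
    return {
        "hka_deg": hka_angle(lm),
        "ttg_mm": tt_tg_axial(lm),
        "is_ratio": insall_salvati(lm),
    }


def build_index_table(cohort_pre, cohort_post) -> pd.DataFrame:
    """Per limb x state index table with deltas vs the preoperative limb.

    `cohort_pre` is a list of LimbModel; `cohort_post` a list of
    OsteotomizedLimb. Raises if any (limb, variant, height) cell is missing
    relative to the full grid implied by the post models.
    """
    pre_rows = {}
    rows = []
    for limb in cohort_pre:
        idx = measure_indices(limb.landmarks)
        pre_rows[limb.limb_id] = idx
        rows.append(
            {
                "limb_id": limb.limb_id,
                "variant": "preop",
                "wedge_height_mm": 0.0,
                "hka_deg": idx["hka_deg"],
                "ttg_mm": idx["ttg_mm"],
                "is_ratio": idx["is_ratio"],
                "d_hka": 0.0,
                "d_ttg": 0.0,
                "d_is": 0.0,
            }
        )
    seen = set()
    variants = set()
    heights = set()
    for ost in cohort_post:
        if ost.limb_id not in pre_rows:
            raise ValueError(f"post model {ost.limb_id} has no preoperative match")
        pre = pre_rows[ost.limb_id]
        idx = measure_indices(ost.landmarks)
        variants.add(ost.variant)
        heights.add(ost.wedge_height_mm)
        seen.add((ost.limb_id, ost.variant, ost.wedge_height_mm))
        rows.append(
            {
                "limb_id": ost.limb_id,
                "variant": ost.variant,
                "wedge_height_mm": ost.wedge_height_mm,
                "hka_deg": idx["hka_deg"],
                "ttg_mm": idx["ttg_mm"],
                "is_ratio": idx["is_ratio"],
                "d_hka": idx["hka_deg"] - pre["hka_deg"],
                "d_ttg": idx["ttg_mm"] - pre["ttg_mm"],
                "d_is": idx["is_ratio"] - pre["is_ratio"],
            }
        )
    for limb_id in pre_rows:
        for v in variants:
            for h in heights:
                if (limb_id, v, h) not in seen:
                    raise ValueError(
                        f"missing grid cell: limb={limb_id} variant={v} h={h}"
                    )
    return pd.DataFrame(rows)


def summarize_index_table(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of deltas per (variant, wedge height) — report companion."""
    post = table[table["variant"] != "preop"]
    return (
        post.groupby(["variant", "wedge_height_mm"])[["d_hka", "d_ttg", "d_is"]]
        .agg(["mean", "std"])
        .reset_index()
    )
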