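"""Patellar landmark repositioning after tuberosity-moving osteotomies.

For ascending-variant models the tuberosity (and with it the patellar
tendon insertion) travels with the distal fragment; the patella is then
translated purely along the femoral proximodistal axis so that the 3D
patellar tendon length returns to its preoperative value, while the
patella's anteroposterior and mediolateral coordinates in the femoral frame
stay fixed. Descending models are returned unchanged.

The proximodistal coordinate of the distal pole solves

    |distal_pole(z) - insertion|^2 = L0^2

with the proximal (larger-z) root chosen; the distal root would drop the
patella below the joint line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class TendonInfeasibleError(RuntimeError):
    """Tendon cannot reach the new insertion at the preserved length."""


@dataclass
class PatellaState:
    center: np.ndarray
    proximal_pole: np.ndarray
    distal_pole: np.ndarray
    tendon_length: float  # L0, preoperative distal pole -> insertion distance

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        self.proximal_pole = np.asarray(self.proximal_pole, float)
        self.distal_pole = np.asarray(self.distal_pole, float)
        if np.linalg.norm(self.proximal_pole - self.distal_pole) <= 0:
            raise ValueError("patellar pole distance must be > 0")
        if not self.tendon_length > 0:
            raise ValueError("tendon length must be > 0")

    def copy(self) -> "PatellaState":
        return PatellaState(
            self.center.copy(),
            self.proximal_pole.copy(),
            self.distal_pole.copy(),
            self.tendon_length,
        )


def reposition_patella(
    pre: PatellaState,
    post_insertion: np.ndarray,
    frames,
    variant: str,
    context: str = "",
) -> PatellaState:
    """Return the post-osteotomy patella state (see module docstring)."""
    if variant == "descending":
        return pre.copy()
    if variant != "ascending":
        raise ValueError("variant must be 'ascending' or 'descending'")

    pd_axis = frames.femoral.pd
    ins = np.asarray(post_insertion, float)
    rel = pre.distal_pole - ins
    z_old = float(rel @ pd_axis)
    perp = rel - z_old * pd_axis
    perp_sq = float(perp @ perp)
    disc = pre.tendon_length**2 - perp_sq
    if disc < 0:
        raise TendonInfeasibleError(
            f"tendon length {pre.tendon_length:.3f} mm cannot span the "
            f"AP/ML offset {math.sqrt(perp_sq):.3f} mm to the new insertion"
            + (f" ({context})" if context else "")
        )
    z_new = math.sqrt(disc)  # proximal root (insertion-relative PD coordinate)
    dz = z_new - z_old
    shift = dz * pd_axis
    out = pre.copy()
    out.center = pre.center + shift
    out.proximal_pole = pre.proximal_pole + shift
    out.distal_pole = pre.distal_pole + shift
    return out


def reposition_patella_on_limb(ost, pre_limb) -> None:
    """Apply the repositioning in place to an OsteotomizedLimb's landmarks."""
    from .metrics import build_frames

    pre_lm = pre_limb.landmarks
    l0 = float(
        np.linalg.norm(pre_lm.patella_distal_pole - pre_lm.patellar_tendon_insertion)
    )
    pre_state = PatellaState(
        pre_lm.patella_center,
        pre_lm.patella_proximal_pole,
        pre_lm.patella_distal_pole,
        l0,
    )
    if np.array_equal(
        ost.landmarks.patellar_tendon_insertion, pre_lm.patellar_tendon_insertion
    ):
        return  # zero-height wedge: exact identity, avoid sqrt round-off
    frames = build_frames(pre_lm)
    post = reposition_patella(
        pre_state,
        ost.landmarks.patellar_tendon_insertion,
        frames,
        ost.variant,
        context=f"limb={ost.limb_id} h={ost.wedge_height_mm}",
    )
    ost.landmarks.patella_center = post.center
    ost.landmarks.patella_proximal_pole = post.proximal_pole
    ost.landmarks.patella_distal_pole = post.distal_pole
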