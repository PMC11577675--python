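"""Quasi-static squat simulator (5–100 deg knee flexion).

A deliberately self-contained, fully documented stand-in for a commercial
multibody engine: at each prescribed flexion angle the free coordinates

    q = (psi, s, u, rho, tau)
      psi  tibial internal(+)/external(-) rotation about the tibial long axis
      s    patellar mediolateral channel coordinate (mm, +X positive)
      u    patellar slide along the trochlear arc (rad)
      rho  patellar coronal rotation (rad, distal pole toward +X positive)
      tau  patellar tilt (rad)

minimize a total potential energy composed of

* a body-weight-scaled quadriceps force potential (force x muscle length),
* a stiff patellar-tendon spring pinning the distal pole at the
  preoperative tendon length L0 from the (possibly osteotomized) insertion,
* four tension-only ligament springs (ACL/PCL/MCL/LCL) with slack lengths
  calibrated to zero pre-tension at the preoperative 5 deg pose,
* constant-force hamstring lines (biceps femoris, semimembranosus),
* groove-channel terms: the patella centre rides a circular sagittal arc
  with a quadratic mediolateral channel cross-section (plus a stiffening
  quartic wall), tilt is drawn toward a shift-proportional groove-contact
  angle, and an arc-guidance spring on the slide coordinate models
  patellofemoral congruence (it also removes a tendon-root bistability
  that otherwise snaps the equilibrium path near 100 deg flexion),
* quadratic (and, for tibial rotation, quartic) soft-tissue envelope
  regularizers.

Everything is explicit configuration (`SimParams`); there is no randomness.
The femur is the fixed body; tibial flexion is prescribed about the
epicondylar axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .anatomy import LimbModel
from .geometry import rotation_matrix, unit
from .osteotomy import OsteotomizedLimb

GRAVITY = 9.81
PARAMETERS = (
    "patellar_shift",
    "patellar_tilt",
    "patellar_rotation",
    "tibiofemoral_rotation",
)


@dataclass(frozen=True)
class SimParams:
    """All simulator constants, with units."""

    quad_force_bw0: float = 0.35  # quadriceps force at 5 deg, x body weight
    quad_force_bw_slope: float = 1.5  # additional x BW at 100 deg
    tendon_stiffness: float = 300.0  # N/mm, stiff tendon-link spring
    lig_stiffness: dict = field(
        default_factory=lambda: {"ACL": 120.0, "PCL": 120.0, "MCL": 90.0, "LCL": 90.0}
    )  # N/mm
    hamstring_force_bw: float = 0.05  # per muscle, x body weight
    channel_curvature: float = 0.02  # 1/mm, trochlear cross-section y = c*s^2
    channel_stiffness: float = 15.0  # N/mm, lateral groove-wall restraint
    channel_quartic: float = 0.5  # N/mm^3, stiffening groove walls
    psi_quartic: float = 2.0e5  # N*mm/rad^4, stiffening soft-tissue envelope
    tilt_coupling_rad_per_mm: float = -0.014  # groove-contact tilt per mm shift
    tilt_stiffness: float = 3000.0  # N*mm/rad^2
    rho_stiffness: float = 100000.0  # N*mm/rad^2
    psi_stiffness: float = 12000.0  # N*mm/rad^2, soft-tissue envelope
    u_stiffness: float = 1.0e4  # N*mm/rad^2, patellofemoral arc-guidance spring
    patellar_lag: float = 0.62  # arc angle advance per knee flexion radian
    groove_center_offset: tuple = (0.0, 2.0, 8.0)  # arc centre vs femoral knee centre
    bw_coefficients: tuple = (2.741, -54.9)  # kg per mm femoral head, offset
    flexion_start: float = 5.0
    flexion_end: float = 100.0
    continuity_bound: float = 2.0  # max allowed per-degree jump (mm or deg)
    gtol: float = 1e-8
    residual_tol: float = 1e-8  # relative gradient-norm tolerance
    extra_ml_springs: tuple = ()  # ((stiffness N/mm, rest mm), ...) test hook


def estimate_body_weight(femoral_head_diameter: float, coefficients=None) -> float:
    """Linear body-weight regression on femoral head diameter (kg)."""
    if not femoral_head_diameter > 0:
        raise ValueError("femoral head diameter must be > 0")
    a, b = coefficients if coefficients is not None else SimParams().bw_coefficients
    bw = a * femoral_head_diameter + b
    if bw <= 0:
        raise ValueError(f"nonpositive body weight estimate: {bw:.2f} kg")
    return float(bw)


@dataclass
class KneeModel:
    model_id: str
    variant: str  # 'preop' | 'ascending' | 'descending'
    wedge_height_mm: float
    params: SimParams
    body_weight_kg: float
    # fixed femoral-side points
    quad_origin: np.ndarray
    lig_origins: np.ndarray  # (4, 3) ACL, PCL, MCL, LCL
    ham_origins: np.ndarray  # (2, 3)
    # tibial-side points in the neutral (extended) pose
    lig_insertions: np.ndarray  # (4, 3)
    ham_insertions: np.ndarray  # (2, 3)
    tendon_insertion: np.ndarray
    # joint geometry
    epi_mid: np.ndarray
    flex_dir: np.ndarray  # unit, lateral epicondyle direction
    flex_sign: float  # +1 right-convention, -1 mirrored
    spin_point: np.ndarray  # knee centre tibia
    spin_dir: np.ndarray  # unit tibial long axis, proximal
    # patellar mechanism
    tendon_length: float  # L0
    patella_half_length: float
    groove_center: np.ndarray
    groove_radius: float
    groove_lambda0: float
    groove_x: float
    s_init: float
    lig_slack: np.ndarray | None = None  # (4,), set at preop 5 deg pose

    # ------------------------------------------------------------ kinematics

    def _flex_R(self, flexion_deg: float) -> np.ndarray:
        cache = self.__dict__.setdefault("_flex_cache", {})
        R = cache.get(flexion_deg)
        if R is None:
            ang = -math.radians(flexion_deg) * self.flex_sign
            R = rotation_matrix(self.flex_dir, ang)
            cache[flexion_deg] = R
        return R

    def tibial_points_world(self, flexion_deg: float, psi: float, pts: np.ndarray):
        """Map neutral-pose tibial points through spin then flexion."""
        Rs = rotation_matrix(self.spin_dir, psi)
        p = (pts - self.spin_point) @ Rs.T + self.spin_point
        Rf = self._flex_R(flexion_deg)
        return (p - self.epi_mid) @ Rf.T + self.epi_mid

    def _attachment_points(self) -> np.ndarray:
        """Stacked tibial attachment points: 4 ligaments, 2 hamstrings, tendon."""
        pts = self.__dict__.get("_att_pts")
        if pts is None:
            pts = np.vstack(
                [self.lig_insertions, self.ham_insertions, self.tendon_insertion[None, :]]
            )
            self.__dict__["_att_pts"] = pts
        return pts

    def patella_points(self, flexion_deg: float, s, u, rho):
        """Patella centre and poles from the channel parametrization."""
        lam = (
            self.groove_lambda0
            + self.params.patellar_lag
            * math.radians(flexion_deg - self.params.flexion_start)
            + u
        )
        cl, sl = math.cos(lam), math.sin(lam)
        e_r = np.array([0.0, cl, -sl])
        p_long = np.array([0.0, sl, cl])  # -d(e_r)/d(lam): proximal at lam=0
        radius = self.groove_radius + self.params.channel_curvature * s * s
        center = self.groove_center + radius * e_r
        center = center + np.array([self.groove_x + s - self.groove_center[0], 0.0, 0.0])
        axis = math.cos(rho) * p_long - math.sin(rho) * np.array([1.0, 0.0, 0.0])
        prox = center + self.patella_half_length * axis
        dist = center - self.patella_half_length * axis
        return center, prox, dist

    # ---------------------------------------------------------------- energy

    def quad_force(self, flexion_deg: float) -> float:
        frac = (flexion_deg - self.params.flexion_start) / (
            self.params.flexion_end - self.params.flexion_start
        )
        return (
            self.body_weight_kg
            * GRAVITY
            * (self.params.quad_force_bw0 + self.params.quad_force_bw_slope * frac)
        )

    def energy(self, q: np.ndarray, flexion_deg: float) -> float:
        psi, s, u, rho, tau = q
        p = self.params
        world = self.tibial_points_world(flexion_deg, psi, self._attachment_points())
        _, prox, dist = self.patella_points(flexion_deg, s, u, rho)

        e = 0.0
        # ligaments: tension-only
        dl = world[:4] - self.lig_origins
        lens = np.sqrt(np.einsum("ij,ij->i", dl, dl))
        stretch = lens - self.lig_slack
        stretch[stretch < 0.0] = 0.0
        e += 0.5 * float(self._lig_k @ (stretch * stretch))
        # hamstrings: constant force x length
        dh = world[4:6] - self.ham_origins
        hl = np.sqrt(np.einsum("ij,ij->i", dh, dh))
        e += p.hamstring_force_bw * self.body_weight_kg * GRAVITY * float(hl.sum())
        # quadriceps
        dq = self.quad_origin - prox
        e += self.quad_force(flexion_deg) * math.sqrt(float(dq @ dq))
        # tendon link
        dt = dist - world[6]
        tl = math.sqrt(float(dt @ dt))
        e += 0.5 * p.tendon_stiffness * (tl - self.tendon_length) ** 2
        # groove-contact tilt preference and regularizers
        tau_ref = p.tilt_coupling_rad_per_mm * s
        e += 0.5 * p.channel_stiffness * s * s + p.channel_quartic * s**4
        e += 0.5 * p.tilt_stiffness * (tau - tau_ref) ** 2
        e += 0.5 * p.rho_stiffness * rho * rho
        e += 0.5 * p.psi_stiffness * psi * psi + p.psi_quartic * psi**4
        e += 0.5 * p.u_stiffness * u * u
        for k, rest in p.extra_ml_springs:
            e += 0.5 * k * (s - rest) ** 2
        return e

    @property
    def _lig_k(self) -> np.ndarray:
        return np.array(
            [self.params.lig_stiffness[n] for n in ("ACL", "PCL", "MCL", "LCL")]
        )


@dataclass
class KneePose:
    flexion_deg: float
    tibiofemoral_rotation_deg: float  # external positive (right convention)
    patellar_shift_mm: float  # lateral positive (right convention)
    patellar_tilt_deg: float
    patellar_rotation_deg: float  # distal pole lateral positive
    residual: float
    energy: float
    q: np.ndarray

    def values(self) -> dict:
        return {
            "patellar_shift": self.patellar_shift_mm,
            "patellar_tilt": self.patellar_tilt_deg,
            "patellar_rotation": self.patellar_rotation_deg,
            "tibiofemoral_rotation": self.tibiofemoral_rotation_deg,
        }


@dataclass
class KinematicCurves:
    limb_id: str
    variant: str
    wedge_height_mm: float
    flexion_deg: np.ndarray
    series: dict  # parameter -> np.ndarray
    residual_max: float
    max_jump: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for param, vals in self.series.items():
            for f, v in zip(self.flexion_deg, vals):
                rows.append(
                    {
                        "limb_id": self.limb_id,
                        "variant": self.variant,
                        "wedge_height_mm": self.wedge_height_mm,
                        "flexion_deg": float(f),
                        "parameter": param,
                        "value": float(v),
                    }
                )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------


def build_knee_model(
    limb_or_ost, params: SimParams | None = None, preop: KneeModel | None = None
) -> KneeModel:
    """Assemble a KneeModel from a preoperative or osteotomized limb.

    Osteotomized inputs must pass the preoperative model via `preop`: slack
    lengths, tendon length and groove geometry are inherited so that only
    bone geometry differs between the states.
    """
    params = params or SimParams()
    if isinstance(limb_or_ost, OsteotomizedLimb):
        lm = limb_or_ost.landmarks
        model_id = limb_or_ost.limb_id
        variant = limb_or_ost.variant
        h = limb_or_ost.wedge_height_mm
        if preop is None:
            raise ValueError("osteotomized input requires the preoperative KneeModel")
    elif isinstance(limb_or_ost, LimbModel):
        lm = limb_or_ost.landmarks
        model_id = limb_or_ost.limb_id
        variant = "preop"
        h = 0.0
    else:
        raise TypeError("expected LimbModel or OsteotomizedLimb")

    for name in ("ACL", "PCL", "MCL", "LCL"):
        if name not in lm.ligaments:
            raise ValueError(f"missing ligament attachment: {name}")

    lig_origins = np.array([lm.ligaments[n][0] for n in ("ACL", "PCL", "MCL", "LCL")])
    lig_insertions = np.array(
        [lm.ligaments[n][1] for n in ("ACL", "PCL", "MCL", "LCL")]
    )
    ham_origins = np.array(
        [lm.hamstrings[n][0] for n in ("biceps_femoris", "semimembranosus")]
    )
    ham_insertions = np.array(
        [lm.hamstrings[n][1] for n in ("biceps_femoris", "semimembranosus")]
    )

    epi_mid = 0.5 * (lm.medial_epicondyle + lm.lateral_epicondyle)
    flex_dir = unit(lm.lateral_epicondyle - lm.medial_epicondyle)
    spin_dir = unit(lm.knee_center_tibia - lm.ankle_center)
    # handedness: +1 when (long axis x ML) points anterior (right convention)
    anterior_ref = lm.tibial_tuberosity_apex - lm.knee_center_tibia
    flex_sign = 1.0 if float(np.cross(spin_dir, flex_dir) @ anterior_ref) >= 0 else -1.0

    half_len = 0.5 * float(np.linalg.norm(lm.patella_proximal_pole - lm.patella_distal_pole))
    l0 = float(np.linalg.norm(lm.patella_distal_pole - lm.patellar_tendon_insertion))

    if preop is not None:
        groove_center = preop.groove_center
        groove_radius = preop.groove_radius
        lambda0 = preop.groove_lambda0
        groove_x = preop.groove_x
        s_init = preop.s_init
        slack = preop.lig_slack.copy()
        bw = preop.body_weight_kg
        l0 = preop.tendon_length  # inherit the preoperative tendon link length
        half_len = preop.patella_half_length
    else:
        off = np.asarray(params.groove_center_offset, float)
        groove_x = float(lm.trochlear_groove_point[0])
        groove_center = lm.knee_center_femur + np.array([0.0, off[1], off[2]])
        rel = lm.patella_center - groove_center
        groove_radius = float(math.hypot(rel[1], rel[2]))
        lambda0 = math.atan2(-rel[2], rel[1])
        s_init = float(lm.patella_center[0] - groove_x)
        slack = None
        bw = estimate_body_weight(lm.femoral_head_diameter, params.bw_coefficients)

    model = KneeModel(
        model_id=model_id,
        variant=variant,
        wedge_height_mm=h,
        params=params,
        body_weight_kg=bw,
        quad_origin=lm.quadriceps_origin.copy(),
        lig_origins=lig_origins,
        ham_origins=ham_origins,
        lig_insertions=lig_insertions,
        ham_insertions=ham_insertions,
        tendon_insertion=lm.patellar_tendon_insertion.copy(),
        epi_mid=epi_mid,
        flex_dir=flex_dir,
        flex_sign=flex_sign,
        spin_point=lm.knee_center_tibia.copy(),
        spin_dir=spin_dir,
        tendon_length=l0,
        patella_half_length=half_len,
        groove_center=groove_center,
        groove_radius=groove_radius,
        groove_lambda0=lambda0,
        groove_x=groove_x,
        s_init=s_init,
        lig_slack=slack,
    )
    if model.lig_slack is None:
        # zero pre-tension at the preoperative 5 deg pose with neutral spin
        lig_w = model.tibial_points_world(params.flexion_start, 0.0, lig_insertions)
        model.lig_slack = np.linalg.norm(lig_w - lig_origins, axis=1)
    return model


def ligament_energy_at(model: KneeModel, flexion_deg: float, psi: float = 0.0) -> float:
    lig_w = model.tibial_points_world(flexion_deg, psi, model.lig_insertions)
    lens = np.linalg.norm(lig_w - model.lig_origins, axis=1)
    stretch = np.maximum(lens - model.lig_slack, 0.0)
    return 0.5 * float(model._lig_k @ stretch**2)


def _grad(fun, x, eps=1e-5):
    g = np.empty_like(x)
    for i in range(len(x)):
        xp = x.copy()
        xm = x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (fun(xp) - fun(xm)) / (2 * eps)
    return g


def _fd_hessian(fun, x, eps=1e-4):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        xp = x.copy()
        xm = x.copy()
        xp[i] += eps
        xm[i] -= eps
        H[i] = (_grad(fun, xp, eps) - _grad(fun, xm, eps)) / (2 * eps)
    return 0.5 * (H + H.T)


class EquilibriumError(RuntimeError):
    pass


def _dof_scale(model: KneeModel) -> np.ndarray:
    """Per-DOF scale (~1/sqrt of diagonal stiffness) used as preconditioner.

    The stiffness spread across DOFs spans several orders of magnitude;
    optimizing in scaled coordinates keeps BFGS well-conditioned.
    """
    cached = model.__dict__.get("_dof_scale_v")
    if cached is not None:
        return cached
    x0 = np.array([0.0, model.s_init, 0.0, 0.0, 0.0])
    f = model.params.flexion_start
    e0 = model.energy(x0, f)
    h = 1e-4
    diag = np.empty(5)
    for i in range(5):
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        diag[i] = (model.energy(xp, f) - 2 * e0 + model.energy(xm, f)) / (h * h)
    diag = np.clip(np.abs(diag), 1e-2, None)
    scale = 1.0 / np.sqrt(diag)
    model.__dict__["_dof_scale_v"] = scale
    return scale


def solve_equilibrium_at_flexion(
    model: KneeModel, flexion_deg: float, warm_start: KneePose | None = None
) -> KneePose:
    p = model.params
    if not (p.flexion_start <= flexion_deg <= p.flexion_end):
        raise ValueError(
            f"flexion {flexion_deg} outside [{p.flexion_start}, {p.flexion_end}]"
        )
    if warm_start is not None:
        x0 = np.asarray(
            warm_start.q if isinstance(warm_start, KneePose) else warm_start,
            dtype=float,
        ).copy()
    else:
        x0 = np.array([0.0, model.s_init, 0.0, 0.0, 0.0])

    scale = _dof_scale(model)
    fun = lambda z: model.energy(z * scale, flexion_deg)  # noqa: E731
    jac = lambda z: _grad(fun, z)  # noqa: E731
    z0 = x0 / scale
    e0 = fun(z0)
    # the convergence contract is on the RELATIVE gradient norm; give BFGS a
    # matching absolute target and leave the last digits to the Newton polish
    gtol = max(p.gtol, 0.2 * p.residual_tol * (1.0 + abs(e0)))
    res = minimize(
        fun, z0, jac=jac, method="BFGS", options={"gtol": gtol, "maxiter": 200}
    )
    z, e = res.x, float(res.fun)
    # damped-Newton polish: BFGS with finite-difference gradients stalls at
    # the round-off noise floor before the relative tolerance is met
    g = res.jac if res.jac is not None else jac(z)
    residual = float(np.linalg.norm(g)) / (1.0 + abs(e))
    for _ in range(12):
        if residual <= 0.25 * p.residual_tol:
            break
        H = _fd_hessian(fun, z)
        try:
            step = np.linalg.solve(H + 1e-9 * np.eye(len(z)), -g)
        except np.linalg.LinAlgError:
            break
        for damp in (1.0, 0.5, 0.25, 0.1):
            z_new = z + damp * step
            e_new = fun(z_new)
            if e_new <= e + 1e-12 * (1.0 + abs(e)):
                z, e = z_new, e_new
                break
        else:
            break
        g = jac(z)
        residual = float(np.linalg.norm(g)) / (1.0 + abs(e))
    if e > e0 + 1e-9 * (1.0 + abs(e0)):
        raise EquilibriumError(
            f"energy increased at flexion {flexion_deg}: {e0} -> {e}"
        )
    if residual > p.residual_tol:
        raise EquilibriumError(
            f"no convergence at flexion {flexion_deg}: relative gradient "
            f"{residual:.2e} > {p.residual_tol:.0e}"
        )
    x = z * scale
    psi, s, u, rho, tau = x
    return KneePose(
        flexion_deg=float(flexion_deg),
        tibiofemoral_rotation_deg=-math.degrees(psi),
        patellar_shift_mm=float(s),
        patellar_tilt_deg=math.degrees(tau),
        patellar_rotation_deg=math.degrees(rho),
        residual=residual,
        energy=e,
        q=x,
    )


def run_squat(model: KneeModel) -> KinematicCurves:
    """Sweep flexion at integer degrees, warm-starting each solve."""
    p = model.params
    flexion = np.arange(p.flexion_start, p.flexion_end + 0.5, 1.0)
    poses: list[KneePose] = []
    for f in flexion:
        # plain previous-pose warm start: extrapolating across degrees can
        # hop energy basins at deep flexion and break curve continuity
        start = poses[-1].q if poses else None
        try:
            pose = solve_equilibrium_at_flexion(model, float(f), warm_start=start)
        except EquilibriumError as exc:
            raise EquilibriumError(f"model {model.model_id}: {exc}") from exc
        poses.append(pose)
    series = {
        param: np.array([pose.values()[param] for pose in poses])
        for param in PARAMETERS
    }
    max_jump = max(
        float(np.abs(np.diff(v)).max()) if len(v) > 1 else 0.0
        for v in series.values()
    )
    if max_jump > p.continuity_bound:
        warnings.warn(
            f"model {model.model_id}: per-degree jump {max_jump:.2f} exceeds "
            f"bound {p.continuity_bound}",
            stacklevel=2,
        )
    return KinematicCurves(
        limb_id=model.model_id,
        variant=model.variant,
        wedge_height_mm=model.wedge_height_mm,
        flexion_deg=flexion,
        series=series,
        residual_max=max(pose.residual for pose in poses),
        max_jump=max_jump,
    )


@dataclass
class CohortResult:
    preop_curves: dict  # limb_id -> KinematicCurves
    post_curves: list  # KinematicCurves

    @property
    def n_models(self) -> int:
        return len(self.preop_curves) + len(self.post_curves)

    def samples_per_parameter(self) -> int:
        n = sum(len(c.flexion_deg) for c in self.preop_curves.values())
        n += sum(len(c.flexion_deg) for c in self.post_curves)
        return n

    def to_frame(self) -> pd.DataFrame:
        frames = [c.to_frame() for c in self.preop_curves.values()]
        frames += [c.to_frame() for c in self.post_curves]
        return pd.concat(frames, ignore_index=True)


def run_experiment(
    cohort: list[LimbModel],
    osteotomies: list[OsteotomizedLimb],
    params: SimParams | None = None,
    progress: bool = False,
) -> CohortResult:
    """Simulate every preoperative limb and every osteotomized model."""
    params = params or SimParams()
    preop_models = {}
    preop_curves = {}
    for limb in cohort:
        m = build_knee_model(limb, params)
        preop_models[limb.limb_id] = m
        preop_curves[limb.limb_id] = run_squat(m)
        if progress:
            print(f"simulated preop {limb.limb_id}")
    post_curves = []
    for ost in osteotomies:
        m = build_knee_model(ost, params, preop=preop_models[ost.limb_id])
        post_curves.append(run_squat(m))
        if progress:
            print(
                f"simulated {ost.limb_id} {ost.variant} h={ost.wedge_height_mm:g}"
            )
    return CohortResult(preop_curves=preop_curves, post_curves=post_curves)
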