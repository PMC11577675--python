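"""Synthetic lower-limb generator.

Produces parametric limb models (landmark sets + simplified watertight bone
meshes) whose measurable anatomical indices — hip–knee–ankle angle (HKA),
axial tibial-tuberosity-to-trochlear-groove distance (TT–TG) and the
Insall–Salvati ratio — equal the values drawn from a configurable cohort
distribution. The construction is exact by design: every index is placed
into the landmark geometry in closed form, so the metrics module recovers
the drawn value to floating-point precision.

Coordinate convention (fixed across the package): right-handed, millimetres,
+X lateral for a right limb, +Y anterior, +Z proximal, tibial plateau centre
at the origin. Left limbs are generated directly in this mirrored-to-right
convention with ``mirrored=True`` recorded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .mesh import TriMesh

LANDMARK_SCHEMA_VERSION = "1.0"

#: landmark point names that belong to the tibia and take part in the
#: osteotomy fragment assignment
TIBIAL_POINT_NAMES = (
    "knee_center_tibia",
    "ankle_center",
    "medial_plateau_edge",
    "lateral_plateau_edge",
    "tibial_tuberosity_apex",
    "patellar_tendon_insertion",
)

LIGAMENT_NAMES = ("ACL", "PCL", "MCL", "LCL")
HAMSTRING_NAMES = ("biceps_femoris", "semimembranosus")


class InfeasibleDrawError(RuntimeError):
    """Raised when rejection resampling exceeds its cap."""


# --------------------------------------------------------------------------
# landmark container


@dataclass
class Landmarks:
    """Named anatomical points (mm) plus the femoral head diameter."""

    hip_center: np.ndarray
    knee_center_femur: np.ndarray
    knee_center_tibia: np.ndarray
    ankle_center: np.ndarray
    medial_plateau_edge: np.ndarray
    lateral_plateau_edge: np.ndarray
    tibial_tuberosity_apex: np.ndarray
    patellar_tendon_insertion: np.ndarray
    trochlear_groove_point: np.ndarray
    medial_epicondyle: np.ndarray
    lateral_epicondyle: np.ndarray
    patella_center: np.ndarray
    patella_proximal_pole: np.ndarray
    patella_distal_pole: np.ndarray
    quadriceps_origin: np.ndarray
    femoral_head_diameter: float
    # name -> (femoral origin, tibial insertion)
    ligaments: dict = field(default_factory=dict)
    # name -> (proximal origin, tibial/fibular insertion)
    hamstrings: dict = field(default_factory=dict)

    _POINT_FIELDS = (
        "hip_center",
        "knee_center_femur",
        "knee_center_tibia",
        "ankle_center",
        "medial_plateau_edge",
        "lateral_plateau_edge",
        "tibial_tuberosity_apex",
        "patellar_tendon_insertion",
        "trochlear_groove_point",
        "medial_epicondyle",
        "lateral_epicondyle",
        "patella_center",
        "patella_proximal_pole",
        "patella_distal_pole",
        "quadriceps_origin",
    )

    def __post_init__(self):
        for name in self._POINT_FIELDS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.ligaments = {
            k: (np.asarray(a, float), np.asarray(b, float))
            for k, (a, b) in self.ligaments.items()
        }
        self.hamstrings = {
            k: (np.asarray(a, float), np.asarray(b, float))
            for k, (a, b) in self.hamstrings.items()
        }
        self.validate()

    def validate(self) -> None:
        for name in self._POINT_FIELDS:
            p = getattr(self, name)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name} must be a finite 3-vector")
        if not (self.femoral_head_diameter > 0):
            raise ValueError("femoral_head_diameter must be positive")

    def copy(self) -> "Landmarks":
        return Landmarks(
            **{n: getattr(self, n).copy() for n in self._POINT_FIELDS},
            femoral_head_diameter=self.femoral_head_diameter,
            ligaments={k: (a.copy(), b.copy()) for k, (a, b) in self.ligaments.items()},
            hamstrings={k: (a.copy(), b.copy()) for k, (a, b) in self.hamstrings.items()},
        )

    def tibial_points(self) -> dict:
        """Points participating in osteotomy fragment assignment."""
        pts = {n: getattr(self, n) for n in TIBIAL_POINT_NAMES}
        for k, (_, ins) in self.ligaments.items():
            pts[f"ligament:{k}"] = ins
        for k, (_, ins) in self.hamstrings.items():
            pts[f"hamstring:{k}"] = ins
        return pts

    def set_tibial_point(self, name: str, value: np.ndarray) -> None:
        value = np.asarray(value, dtype=float)
        if name.startswith("ligament:"):
            key = name.split(":", 1)[1]
            self.ligaments[key] = (self.ligaments[key][0], value)
        elif name.startswith("hamstring:"):
            key = name.split(":", 1)[1]
            self.hamstrings[key] = (self.hamstrings[key][0], value)
        else:
            setattr(self, name, value)

    def transformed_all(self, transform) -> "Landmarks":
        """Apply one rigid transform to every point (for equivariance checks)."""
        out = self.copy()
        for n in self._POINT_FIELDS:
            setattr(out, n, transform.apply(getattr(out, n)))
        out.ligaments = {
            k: (transform.apply(a), transform.apply(b))
            for k, (a, b) in out.ligaments.items()
        }
        out.hamstrings = {
            k: (transform.apply(a), transform.apply(b))
            for k, (a, b) in out.hamstrings.items()
        }
        return out

    # -------------------------------------------------------------- JSON IO

    def as_dict(self) -> dict:
        return {
            "schema_version": LANDMARK_SCHEMA_VERSION,
            "points": {n: list(getattr(self, n)) for n in self._POINT_FIELDS},
            "femoral_head_diameter": self.femoral_head_diameter,
            "ligaments": {
                k: {"origin": list(a), "insertion": list(b)}
                for k, (a, b) in self.ligaments.items()
            },
            "hamstrings": {
                k: {"origin": list(a), "insertion": list(b)}
                for k, (a, b) in self.hamstrings.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Landmarks":
        if d.get("schema_version") != LANDMARK_SCHEMA_VERSION:
            raise ValueError("unsupported landmark schema version")
        return cls(
            **{n: d["points"][n] for n in cls._POINT_FIELDS},
            femoral_head_diameter=d["femoral_head_diameter"],
            ligaments={
                k: (v["origin"], v["insertion"]) for k, v in d["ligaments"].items()
            },
            hamstrings={
                k: (v["origin"], v["insertion"]) for k, v in d["hamstrings"].items()
            },
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "Landmarks":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# --------------------------------------------------------------------------
# cohort specification


@dataclass(frozen=True)
class CohortSpec:
    """Distribution parameters for a synthetic cohort, (mean, sd) pairs."""

    n_limbs: int = 13
    seed: int = 0
    hka_deg: tuple = (178.1, 2.7)
    ttg_mm: tuple = (13.6, 2.4)
    insall_salvati: tuple = (0.8, 0.1)
    plateau_width_mm: tuple = (75.0, 5.0)
    tibia_length_mm: tuple = (380.0, 20.0)
    femur_length_mm: tuple = (430.0, 25.0)
    femoral_head_diameter_mm: tuple = (46.0, 3.0)
    medial_tibial_slope_deg: tuple = (7.0, 2.0)

    _DRAW_FIELDS = (
        "hka_deg",
        "ttg_mm",
        "insall_salvati",
        "plateau_width_mm",
        "tibia_length_mm",
        "femur_length_mm",
        "femoral_head_diameter_mm",
        "medial_tibial_slope_deg",
    )

    def __post_init__(self):
        if self.n_limbs < 1:
            raise ValueError("n_limbs must be >= 1")
        for name in self._DRAW_FIELDS:
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name}: sd must be >= 0")

    def means(self) -> np.ndarray:
        return np.array([getattr(self, n)[0] for n in self._DRAW_FIELDS])

    def sds(self) -> np.ndarray:
        return np.array([getattr(self, n)[1] for n in self._DRAW_FIELDS])


_FEASIBLE_RANGES = {
    "hka_deg": (170.001, 189.999),
    "ttg_mm": (-30.0, 30.0),
    "insall_salvati": (0.2, 2.0),
    "plateau_width_mm": (45.0, 110.0),
    "tibia_length_mm": (200.0, 560.0),
    "femur_length_mm": (220.0, 640.0),
    "femoral_head_diameter_mm": (25.0, 75.0),
    "medial_tibial_slope_deg": (-5.0, 20.0),
}


# --------------------------------------------------------------------------
# tibia shape (analytic contour; mesh and cortex queries derive from it)


@dataclass(frozen=True)
class TibiaShape:
    """Elliptic-contour extrusion with a tuberosity prominence.

    The same analytic contour backs both mesh generation and cortex-point
    queries, so planned osteotomy entry/hinge points lie on the mesh surface
    by construction.
    """

    plateau_halfwidth: float  # ML semi-axis at plateau level
    plateau_ap_semi: float = 15.5
    shaft_ml_semi: float = 14.0
    shaft_ap_semi: float = 13.0
    taper_depth: float = 70.0  # metaphyseal taper length below plateau
    tilt_tan: float = 0.0  # coronal shaft tilt, x = tilt_tan * z
    length: float = 360.0  # axial extent (plateau to distal cut-off)
    tuberosity_theta: float = math.radians(80.0)  # slightly lateral of anterior
    tuberosity_z: float = -30.0
    tuberosity_amp: float = 14.0
    tuberosity_sigma_theta: float = 0.35
    tuberosity_sigma_z: float = 9.0

    def center(self, z):
        z = np.asarray(z, dtype=float)
        return np.stack([self.tilt_tan * z, np.zeros_like(z), z], axis=-1)

    def _taper(self, z):
        s = np.clip(np.asarray(z, dtype=float) / -self.taper_depth, 0.0, 1.0)
        return 3 * s**2 - 2 * s**3

    def semi_axes(self, z):
        f = self._taper(z)
        a = self.plateau_halfwidth + (self.shaft_ml_semi - self.plateau_halfwidth) * f
        b = self.plateau_ap_semi + (self.shaft_ap_semi - self.plateau_ap_semi) * f
        return a, b

    def bump(self, theta, z):
        dth = np.angle(np.exp(1j * (np.asarray(theta) - self.tuberosity_theta)))
        dz = np.asarray(z, dtype=float) - self.tuberosity_z
        return self.tuberosity_amp * np.exp(
            -(dth**2) / (2 * self.tuberosity_sigma_theta**2)
            - dz**2 / (2 * self.tuberosity_sigma_z**2)
        )

    def surface_point(self, theta, z):
        a, b = self.semi_axes(z)
        d = self.bump(theta, z)
        c = self.center(z)
        return c + np.stack(
            [(a + d) * np.cos(theta), (b + d) * np.sin(theta), np.zeros_like(a)],
            axis=-1,
        )

    def medial_cortex_x(self, z: float) -> float:
        return float(self.surface_point(math.pi, z)[0])

    def lateral_cortex_x(self, z: float) -> float:
        return float(self.surface_point(0.0, z)[0])

    def tuberosity_apex(self) -> np.ndarray:
        return np.asarray(
            self.surface_point(self.tuberosity_theta, self.tuberosity_z), dtype=float
        )


def build_tibia_mesh(
    shape: TibiaShape, n_theta: int = 72, mirrored: bool = False
) -> TriMesh:
    """Watertight extruded-contour tibia solid.

    The angular grid is anchored so that theta = 0, pi and the tuberosity
    angle are exact grid nodes: the plateau ML extent and the tuberosity apex
    are then exact mesh vertices.
    """
    if n_theta % 72 != 0:
        raise ValueError("n_theta must be a multiple of 72 to keep anchor angles")
    theta = np.arange(n_theta) * (2 * math.pi / n_theta)
    z_end = -shape.length
    z1 = np.linspace(0.0, shape.tuberosity_z, 16)
    z2 = np.linspace(shape.tuberosity_z, -shape.taper_depth, 14)[1:]
    z3 = np.linspace(-shape.taper_depth, z_end, 12)[1:]
    zs = np.concatenate([z1, z2, z3])

    tt, zz = np.meshgrid(theta, zs, indexing="xy")
    pts = shape.surface_point(tt, zz).reshape(-1, 3)
    nz = len(zs)
    top_center = shape.center(0.0)
    bot_center = shape.center(z_end)
    verts = np.vstack([pts, top_center[None, :], bot_center[None, :]])
    i_top, i_bot = nz * n_theta, nz * n_theta + 1

    faces = []
    for k in range(nz - 1):
        r0, r1 = k * n_theta, (k + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            a, b = r0 + j, r0 + jn
            c, d = r1 + jn, r1 + j
            faces.append((a, c, b))
            faces.append((a, d, c))
    for j in range(n_theta):
        jn = (j + 1) % n_theta
        faces.append((i_top, j, jn))  # top cap, +z outward
        r = (nz - 1) * n_theta
        faces.append((i_bot, r + jn, r + j))  # bottom cap, -z outward
    m = TriMesh(verts, np.array(faces, dtype=np.int64))
    if m.volume() < 0:
        m = TriMesh(m.vertices, m.faces[:, ::-1])
    if mirrored:
        m = m.mirrored(axis=0)
    return m


def _build_extrusion(centers, ml_semi, ap_semi, n_theta=36) -> TriMesh:
    """Generic capped elliptic tube along a polyline of section centers."""
    theta = np.arange(n_theta) * (2 * math.pi / n_theta)
    rings = []
    for c, a, b in zip(centers, ml_semi, ap_semi):
        rings.append(
            np.column_stack(
                [
                    c[0] + a * np.cos(theta),
                    c[1] + b * np.sin(theta),
                    np.full(n_theta, c[2]),
                ]
            )
        )
    nz = len(rings)
    verts = np.vstack(rings + [centers[0][None, :], centers[-1][None, :]])
    i_first, i_last = nz * n_theta, nz * n_theta + 1
    faces = []
    for k in range(nz - 1):
        r0, r1 = k * n_theta, (k + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append((r0 + j, r1 + jn, r0 + jn))
            faces.append((r0 + j, r1 + j, r1 + jn))
    for j in range(n_theta):
        jn = (j + 1) % n_theta
        faces.append((i_first, j, jn))
        r = (nz - 1) * n_theta
        faces.append((i_last, r + jn, r + j))
    m = TriMesh(verts, np.array(faces, dtype=np.int64))
    if m.volume() < 0:
        m = TriMesh(m.vertices, m.faces[:, ::-1])
    return m


def build_femur_mesh(knee_center_femur, hip_center, epi_halfwidth) -> TriMesh:
    """Coarse femur solid: condylar flare tapering into a cylindrical shaft."""
    k = np.asarray(knee_center_femur, float)
    h = np.asarray(hip_center, float)
    fracs = np.linspace(0.0, 1.0, 10)
    centers = np.array([k + f * (h - k) for f in fracs])
    ml = np.interp(fracs, [0, 0.12, 1.0], [epi_halfwidth, 16.0, 14.0])
    ap = np.interp(fracs, [0, 0.12, 1.0], [min(30.0, epi_halfwidth), 15.0, 14.0])
    return _build_extrusion(centers, ml, ap, n_theta=36)


def build_patella_mesh(center, half_length) -> TriMesh:
    """Ellipsoidal patella solid (UV sphere scaled to ML/AP/PD semi-axes)."""
    c = np.asarray(center, float)
    n_u, n_v = 24, 11
    us = np.arange(n_u) * (2 * math.pi / n_u)
    vs = np.linspace(-math.pi / 2, math.pi / 2, n_v + 2)[1:-1]
    semi = np.array([12.0, 6.5, half_length])
    rings = []
    for v in vs:
        rings.append(
            np.column_stack(
                [
                    c[0] + semi[0] * np.cos(v) * np.cos(us),
                    c[1] + semi[1] * np.cos(v) * np.sin(us),
                    np.full(n_u, c[2] + semi[2] * np.sin(v)),
                ]
            )
        )
    verts = np.vstack(rings + [(c - [0, 0, semi[2]])[None, :], (c + [0, 0, semi[2]])[None, :]])
    i_bot, i_top = n_v * n_u, n_v * n_u + 1
    faces = []
    for k2 in range(n_v - 1):
        r0, r1 = k2 * n_u, (k2 + 1) * n_u
        for j in range(n_u):
            jn = (j + 1) % n_u
            faces.append((r0 + j, r0 + jn, r1 + jn))
            faces.append((r0 + j, r1 + jn, r1 + j))
    for j in range(n_u):
        jn = (j + 1) % n_u
        faces.append((i_bot, jn, j))
        r = (n_v - 1) * n_u
        faces.append((i_top, r + j, r + jn))
    m = TriMesh(verts, np.array(faces, dtype=np.int64))
    if m.volume() < 0:
        m = TriMesh(m.vertices, m.faces[:, ::-1])
    return m


# --------------------------------------------------------------------------
# limb model


@dataclass
class LimbModel:
    limb_id: str
    side: str  # 'left' | 'right'
    mirrored: bool  # True when a left limb is stored in right convention
    landmarks: Landmarks
    shape: TibiaShape
    anthropometry: dict
    tibia_mesh: TriMesh
    femur_mesh: TriMesh
    patella_mesh: TriMesh


PATELLA_LENGTH_MM = 42.0  # fixed patellar pole distance for all synthetic limbs
_TENDON_ELEVATION_RAD = math.radians(14.0)


def generate_limb(spec: CohortSpec, index: int, with_meshes: bool = True) -> LimbModel:
    """Deterministically construct limb `index` of the cohort.

    The random stream is keyed on (seed, index) so each limb is reproducible
    in isolation. Infeasible draws are rejection-resampled up to 100 times.
    """
    if index >= spec.n_limbs:
        raise ValueError("index must be < spec.n_limbs")
    rng = np.random.default_rng([spec.seed, index])
    means, sds = spec.means(), spec.sds()
    draws = None
    rejections = 0
    for _ in range(101):
        cand = rng.normal(means, sds)
        d = dict(zip(spec._DRAW_FIELDS, cand))
        ok = all(
            _FEASIBLE_RANGES[k][0] <= d[k] <= _FEASIBLE_RANGES[k][1]
            for k in spec._DRAW_FIELDS
        )
        if ok:
            draws = d
            break
        rejections += 1
    if draws is None:
        raise InfeasibleDrawError(
            f"limb {index}: >100 infeasible draws (last: {d})"
        )
    side = "left" if rng.random() < 0.5 else "right"
    lm, shape = _construct_landmarks(draws)
    meshes = (None, None, None)
    if with_meshes:
        tibia = build_tibia_mesh(shape)
        femur = build_femur_mesh(
            lm.knee_center_femur,
            lm.hip_center,
            float(lm.lateral_epicondyle[0]),
        )
        patella = build_patella_mesh(lm.patella_center, PATELLA_LENGTH_MM / 2)
        meshes = (tibia, femur, patella)
    return LimbModel(
        limb_id=f"limb{index:03d}",
        side=side,
        mirrored=(side == "left"),
        landmarks=lm,
        shape=shape,
        anthropometry={**draws, "rejections": rejections},
        tibia_mesh=meshes[0],
        femur_mesh=meshes[1],
        patella_mesh=meshes[2],
    )


def generate_cohort(spec: CohortSpec, with_meshes: bool = True) -> list[LimbModel]:
    return [generate_limb(spec, i, with_meshes=with_meshes) for i in range(spec.n_limbs)]


def mirror_limb(limb: LimbModel) -> LimbModel:
    """Reflect a limb through the sagittal plane (x -> -x).

    Used for reflection-symmetry checks; the generator itself always stores
    limbs in the right-limb convention.
    """
    flip = np.array([-1.0, 1.0, 1.0])
    lm = limb.landmarks.copy()
    for n in lm._POINT_FIELDS:
        setattr(lm, n, getattr(lm, n) * flip)
    lm.ligaments = {k: (a * flip, b * flip) for k, (a, b) in lm.ligaments.items()}
    lm.hamstrings = {k: (a * flip, b * flip) for k, (a, b) in lm.hamstrings.items()}
    return LimbModel(
        limb_id=limb.limb_id + "_mirror",
        side="left" if limb.side == "right" else "right",
        mirrored=not limb.mirrored,
        landmarks=lm,
        shape=limb.shape,
        anthropometry=dict(limb.anthropometry),
        tibia_mesh=limb.tibia_mesh.mirrored(0) if limb.tibia_mesh else None,
        femur_mesh=limb.femur_mesh.mirrored(0) if limb.femur_mesh else None,
        patella_mesh=limb.patella_mesh.mirrored(0) if limb.patella_mesh else None,
    )


def _construct_landmarks(d: dict) -> tuple[Landmarks, TibiaShape]:
    width = d["plateau_width_mm"]
    lt = d["tibia_length_mm"]
    lf = d["femur_length_mm"]
    varus = math.radians(180.0 - d["hka_deg"])  # > 0 for varus limbs

    shape = TibiaShape(
        plateau_halfwidth=width / 2,
        shaft_ml_semi=min(14.0, 0.42 * width / 2 + 2.0),
        tilt_tan=math.tan(varus),
        length=lt * math.cos(varus),
    )

    knee_t = np.zeros(3)
    knee_f = np.array([0.0, 0.0, 2.0])
    hip = knee_f + np.array([0.0, 0.0, lf])
    ankle = np.array([-lt * math.sin(varus), 0.0, -lt * math.cos(varus)])
    med_edge = np.array([-width / 2, 0.0, 0.0])
    lat_edge = np.array([width / 2, 0.0, 0.0])

    apex = shape.tuberosity_apex()
    insertion = apex + np.array([0.0, -1.0, 4.0])
    groove = np.array([apex[0] - d["ttg_mm"], 20.0, 12.0])

    l0 = d["insall_salvati"] * PATELLA_LENGTH_MM
    # tendon runs proximally with a mediolateral component that parks the
    # patella near the trochlear channel (mild residual lateralization)
    dx = (groove[0] + 0.35 * d["ttg_mm"]) - insertion[0]
    u = np.array(
        [
            dx / max(l0, 1e-9),
            math.sin(_TENDON_ELEVATION_RAD),
            math.cos(_TENDON_ELEVATION_RAD),
        ]
    )
    u = u / np.linalg.norm(u)
    distal_pole = insertion + l0 * u
    proximal_pole = distal_pole + np.array([0.0, 0.0, PATELLA_LENGTH_MM])
    patella_center = 0.5 * (distal_pole + proximal_pole)

    epi_halfwidth = width / 2 + 6.0
    med_epi = np.array([-epi_halfwidth, 0.0, 25.0])
    lat_epi = np.array([epi_halfwidth, 0.0, 25.0])
    quad_origin = np.array([groove[0] + 5.0, 30.0, 0.5 * lf])

    def cortex(theta, z, inset=0.0):
        p = np.asarray(shape.surface_point(theta, z), dtype=float)
        return p + inset * (shape.center(z) - p) / max(np.linalg.norm(shape.center(z) - p), 1e-9)

    fib_head = cortex(0.0, -18.0) + np.array([3.0, -8.0, 0.0])
    ligaments = {
        "ACL": (np.array([6.0, -4.0, 16.0]), np.array([1.0, 8.0, -3.0])),
        "PCL": (np.array([-6.0, -6.0, 14.0]), np.array([0.0, -14.0, -9.0])),
        "MCL": (med_epi.copy(), cortex(math.pi, -60.0, inset=0.5) + np.array([0.0, 4.0, 0.0])),
        "LCL": (lat_epi.copy(), fib_head.copy()),
    }
    hamstrings = {
        "biceps_femoris": (
            np.array([12.0, -28.0, 0.75 * lf]),
            fib_head + np.array([1.0, -2.0, -4.0]),
        ),
        "semimembranosus": (
            np.array([-10.0, -28.0, 0.75 * lf]),
            cortex(math.pi, -8.0, inset=1.5) + np.array([0.0, -10.0, 0.0]),
        ),
    }

    lm = Landmarks(
        hip_center=hip,
        knee_center_femur=knee_f,
        knee_center_tibia=knee_t,
        ankle_center=ankle,
        medial_plateau_edge=med_edge,
        lateral_plateau_edge=lat_edge,
        tibial_tuberosity_apex=apex,
        patellar_tendon_insertion=insertion,
        trochlear_groove_point=groove,
        medial_epicondyle=med_epi,
        lateral_epicondyle=lat_epi,
        patella_center=patella_center,
        patella_proximal_pole=proximal_pole,
        patella_distal_pole=distal_pole,
        quadriceps_origin=quad_origin,
        femoral_head_diameter=d["femoral_head_diameter_mm"],
        ligaments=ligaments,
        hamstrings=hamstrings,
    )
    return lm, shape
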