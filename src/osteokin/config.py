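"""Experiment configuration: YAML round-trip, defaults, hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .anatomy import CohortSpec
from .squat import SimParams


@dataclass
class ExperimentConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    wedge_heights_mm: tuple = (6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0)
    variants: tuple = ("ascending", "descending")
    sim: SimParams = field(default_factory=SimParams)
    mixed_model_angles: tuple = (20.0, 40.0, 60.0, 100.0)
    ttest_flexion_deg: float = 100.0
    ttest_wedge_height_mm: float = 12.0
    holm: bool = False
    output_dir: str = "osteokin_out"
    write_meshes: bool = True

    def __post_init__(self):
        hs = tuple(float(h) for h in self.wedge_heights_mm)
        if any(h <= 0 for h in hs):
            raise ValueError("wedge heights must be positive")
        if list(hs) != sorted(hs):
            raise ValueError("wedge heights must be sorted ascending")
        self.wedge_heights_mm = hs
        self.variants = tuple(self.variants)
        for v in self.variants:
            if v not in ("ascending", "descending"):
                raise ValueError(f"unknown variant {v!r}")
        if not (
            self.sim.flexion_start >= 5.0 - 1e-9 and self.sim.flexion_end <= 100.0 + 1e-9
        ):
            raise ValueError("flexion range must lie within [5, 100]")

    # ----------------------------------------------------------- serialization

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        d["sim"] = dataclasses.asdict(self.sim)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            for k, v in list(c.items()):
                if isinstance(v, list):
                    c[k] = tuple(v)
            d["cohort"] = CohortSpec(**c)
        if "sim" in d:
            s = dict(d["sim"])
            for k, v in list(s.items()):
                if isinstance(v, list):
                    s[k] = tuple(
                        tuple(x) if isinstance(x, list) else x for x in v
                    )
            d["sim"] = SimParams(**s)
        for k in ("wedge_heights_mm", "variants", "mixed_model_angles"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(_plain(self.as_dict()), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def config_hash(self) -> str:
        blob = json.dumps(_plain(self.as_dict()), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(x) for x in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
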