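"""Invariant checks over a produced artifact tree (`osteokin validate`)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class CheckResult:
    name: str
    passed: bool
    detail: str = ""


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def validate_artifacts(model_dir) -> list[CheckResult]:
    out = Path(model_dir)
    checks: list[CheckResult] = []
    required = [
        out / "tables" / "index_table.csv",
        out / "tables" / "manifest.csv",
        out / "curves" / "curves.csv",
        out / "logs" / "run.json",
    ]
    missing = [str(p) for p in required if not p.exists()]
    if missing:
        return [CheckResult("artifacts-present", False, f"missing: {missing}")]
    checks.append(CheckResult("artifacts-present", True))

    table = _read_table(out / "tables" / "index_table.csv")
    manifest = _read_table(out / "tables" / "manifest.csv")
    with open(out / "logs" / "run.json") as fh:
        run = json.load(fh)

    # grid completeness
    post = table[table["variant"] != "preop"]
    n_limbs = table["limb_id"].nunique()
    n_var = post["variant"].nunique()
    n_h = post["wedge_height_mm"].nunique()
    complete = len(post) == n_limbs * n_var * n_h and len(manifest) == len(post)
    checks.append(
        CheckResult(
            "grid-complete",
            complete,
            f"{len(post)} post rows for {n_limbs} limbs x {n_var} variants x {n_h} heights",
        )
    )

    # descending identities: TT-TG and Insall-Salvati deltas exactly zero
    desc = post[post["variant"] == "descending"]
    if len(desc):
        ok = bool(
            (desc["d_ttg"].abs() < 1e-9).all() and (desc["d_is"].abs() < 1e-9).all()
        )
        checks.append(
            CheckResult(
                "descending-identity",
                ok,
                f"max |d_ttg|={desc['d_ttg'].abs().max():.2e}, "
                f"max |d_is|={desc['d_is'].abs().max():.2e}",
            )
        )

    # HKA delta equal across variants per (limb, height)
    if n_var == 2:
        piv = post.pivot_table(
            index=["limb_id", "wedge_height_mm"], columns="variant", values="d_hka"
        )
        diff = (piv["ascending"] - piv["descending"]).abs().max()
        checks.append(
            CheckResult("hka-variant-independent", bool(diff < 1e-9), f"max diff {diff:.2e}")
        )

    # HKA delta strictly increasing in wedge height per limb/variant
    mono = True
    for (_, _), grp in post.groupby(["limb_id", "variant"]):
        g = grp.sort_values("wedge_height_mm")
        if not np.all(np.diff(g["d_hka"].to_numpy()) > 0):
            mono = False
    checks.append(CheckResult("hka-monotone", mono))

    # ascending TT-TG delta strictly increasing
    asc = post[post["variant"] == "ascending"]
    mono_ttg = True
    for _, grp in asc.groupby("limb_id"):
        g = grp.sort_values("wedge_height_mm")
        if not np.all(np.diff(g["d_ttg"].to_numpy()) > 0):
            mono_ttg = False
    if len(asc):
        checks.append(CheckResult("ascending-ttg-monotone", mono_ttg))

    # curves: completeness and continuity
    curves = _read_table(out / "curves" / "curves.csv")
    per_model = curves.groupby(["limb_id", "variant", "wedge_height_mm", "parameter"])[
        "value"
    ].count()
    checks.append(
        CheckResult(
            "curves-complete",
            bool(per_model.nunique() == 1),
            f"series lengths: {sorted(per_model.unique())}",
        )
    )
    checks.append(
        CheckResult(
            "config-hash-recorded",
            "config_hash" in run and bool(run["config_hash"]),
            run.get("config_hash", ""),
        )
    )
    return checks
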