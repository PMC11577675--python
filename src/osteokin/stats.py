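"""Statistical pipeline for the flexion-sweep experiment.

Per-curve RMSE against the preoperative model, median/range summaries per
(parameter, variant, wedge height), paired change t-tests at a chosen
flexion angle, and random-intercept linear mixed models of the kinematic
value on wedge height and cut variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .squat import PARAMETERS, CohortResult

DEFAULT_MIXED_MODEL_ANGLES = (20.0, 40.0, 60.0, 100.0)


# --------------------------------------------------------------------------
# RMSE


def rmse_curve(post: np.ndarray, pre: np.ndarray) -> float:
    post = np.asarray(post, float)
    pre = np.asarray(pre, float)
    if post.shape != pre.shape:
        raise ValueError(f"series length mismatch: {post.shape} vs {pre.shape}")
    d = post - pre
    return float(math.sqrt(np.mean(d * d)))


@dataclass(frozen=True)
class RmseRecord:
    limb_id: str
    variant: str
    wedge_height_mm: float
    parameter: str
    rmse: float


def rmse_records(result: CohortResult) -> list[RmseRecord]:
    out = []
    for curves in result.post_curves:
        pre = result.preop_curves[curves.limb_id]
        for param in PARAMETERS:
            out.append(
                RmseRecord(
                    limb_id=curves.limb_id,
                    variant=curves.variant,
                    wedge_height_mm=curves.wedge_height_mm,
                    parameter=param,
                    rmse=rmse_curve(curves.series[param], pre.series[param]),
                )
            )
    return out


def summarize_rmse(records: list[RmseRecord]) -> pd.DataFrame:
    """Median/min/max RMSE per (parameter, variant, wedge height)."""
    if not records:
        raise ValueError("no RMSE records")
    df = pd.DataFrame([r.__dict__ for r in records])
    g = (
        df.groupby(["parameter", "variant", "wedge_height_mm"])["rmse"]
        .agg(median="median", min="min", max="max", n="count")
        .reset_index()
    )
    if (g["n"] == 0).any():
        raise ValueError("empty summary cell")
    return g


# --------------------------------------------------------------------------
# change t-test (one-sample, paired differences vs the preoperative curve)


def paired_ttest(differences: np.ndarray) -> dict:
    d = np.asarray(differences, float)
    if len(d) < 2:
        raise ValueError("need at least 2 paired differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return {"mean": mean, "sd": 0.0, "t": None, "p": None, "degenerate": True}
    t = mean / (sd / math.sqrt(len(d)))
    p = 2.0 * sps.t.sf(abs(t), df=len(d) - 1)
    return {"mean": mean, "sd": sd, "t": float(t), "p": float(p), "degenerate": False}


def change_ttest_at_flexion(
    result: CohortResult, flexion: float, wedge_height: float = 12.0
) -> pd.DataFrame:
    """Per (parameter, variant): mean change vs preop at one flexion angle."""
    rows = []
    for param in PARAMETERS:
        for variant in ("ascending", "descending"):
            diffs = []
            for curves in result.post_curves:
                if curves.variant != variant or curves.wedge_height_mm != wedge_height:
                    continue
                pre = result.preop_curves[curves.limb_id]
                idx = np.where(curves.flexion_deg == flexion)[0]
                if len(idx) == 0:
                    raise ValueError(f"flexion {flexion} not on the grid")
                i = int(idx[0])
                diffs.append(curves.series[param][i] - pre.series[param][i])
            if not diffs:
                continue
            r = paired_ttest(np.asarray(diffs))
            rows.append(
                {
                    "parameter": param,
                    "variant": variant,
                    "wedge_height_mm": wedge_height,
                    "flexion_deg": flexion,
                    "n": len(diffs),
                    **r,
                }
            )
    return pd.DataFrame(rows)


def holm_correction(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default in reports)."""
    p = np.asarray(pvalues, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


# --------------------------------------------------------------------------
# linear mixed models


@dataclass
class MixedModelResult:
    flexion_deg: float
    parameter: str
    coef_height: float
    coef_variant: float
    p_height: float
    p_variant: float
    coef_height_std: float
    coef_variant_std: float
    random_intercept_var: float
    converged: bool
    singular: bool
    n_obs: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def mixed_model_frame(result: CohortResult, flexion: float, parameter: str) -> pd.DataFrame:
    rows = []
    for curves in result.post_curves:
        idx = np.where(curves.flexion_deg == flexion)[0]
        if len(idx) == 0:
            raise ValueError(f"flexion {flexion} not on the grid")
        rows.append(
            {
                "limb_id": curves.limb_id,
                "variant_code": 1.0 if curves.variant == "ascending" else 0.0,
                "wedge_height_mm": curves.wedge_height_mm,
                "value": float(curves.series[parameter][int(idx[0])]),
            }
        )
    return pd.DataFrame(rows)


def fit_mixed_model_frame(df: pd.DataFrame) -> dict:
    """REML random-intercept fit of value ~ height(centred) + variant."""
    df = df.copy()
    df["height_c"] = df["wedge_height_mm"] - df["wedge_height_mm"].mean()
    model = smf.mixedlm("value ~ height_c + variant_code", df, groups=df["limb_id"])
    import warnings as _w

    fit = None
    err = None
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        for method in ("lbfgs", "cg", "powell"):
            try:
                fit = model.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError) as exc:
                err = exc
    if fit is None:
        # singular fit: reported with diagnostics rather than silently dropped
        nan = float("nan")
        return {
            "coef_height": nan,
            "coef_variant": nan,
            "p_height": nan,
            "p_variant": nan,
            "coef_height_std": nan,
            "coef_variant_std": nan,
            "ci_height": (nan, nan),
            "ci_variant": (nan, nan),
            "random_intercept_var": nan,
            "converged": False,
            "singular": True,
            "n_obs": int(len(df)),
            "error": str(err),
        }
    sd_y = float(df["value"].std(ddof=1))
    sd_h = float(df["height_c"].std(ddof=1))
    sd_v = float(df["variant_code"].std(ddof=1))
    coef_h = float(fit.params["height_c"])
    coef_v = float(fit.params["variant_code"])
    ci = fit.conf_int()
    return {
        "coef_height": coef_h,
        "coef_variant": coef_v,
        "p_height": float(fit.pvalues["height_c"]),
        "p_variant": float(fit.pvalues["variant_code"]),
        "coef_height_std": coef_h * sd_h / sd_y if sd_y > 0 else float("nan"),
        "coef_variant_std": coef_v * sd_v / sd_y if sd_y > 0 else float("nan"),
        "ci_height": (float(ci.loc["height_c", 0]), float(ci.loc["height_c", 1])),
        "ci_variant": (
            float(ci.loc["variant_code", 0]),
            float(ci.loc["variant_code", 1]),
        ),
        "random_intercept_var": float(fit.cov_re.iloc[0, 0]),
        "converged": bool(fit.converged),
        "singular": bool(fit.cov_re.iloc[0, 0] < 1e-10),
        "n_obs": int(len(df)),
    }


def fit_mixed_model(result: CohortResult, flexion: float, parameter: str) -> MixedModelResult:
    df = mixed_model_frame(result, flexion, parameter)
    r = fit_mixed_model_frame(df)
    return MixedModelResult(
        flexion_deg=flexion,
        parameter=parameter,
        coef_height=r["coef_height"],
        coef_variant=r["coef_variant"],
        p_height=r["p_height"],
        p_variant=r["p_variant"],
        coef_height_std=r["coef_height_std"],
        coef_variant_std=r["coef_variant_std"],
        random_intercept_var=r["random_intercept_var"],
        converged=r["converged"],
        singular=r["singular"],
        n_obs=r["n_obs"],
    )


def qq_export(result: CohortResult, flexion: float = 100.0) -> pd.DataFrame:
    """Sorted sample vs normal quantiles per parameter (plot-data export)."""
    rows = []
    for param in PARAMETERS:
        vals = []
        for curves in result.post_curves:
            i = int(np.where(curves.flexion_deg == flexion)[0][0])
            vals.append(curves.series[param][i])
        vals = np.sort(np.asarray(vals))
        n = len(vals)
        theo = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        for t, v in zip(theo, vals):
            rows.append(
                {
                    "parameter": param,
                    "flexion_deg": flexion,
                    "theoretical_quantile": float(t),
                    "sample_value": float(v),
                }
            )
    return pd.DataFrame(rows)


def qualitative_concordance(records: list[RmseRecord]) -> pd.DataFrame:
    """Soft cross-variant checks (logged, not hard-asserted).

    For each parameter and wedge height: is the ascending median RMSE larger
    than the descending one (expected for the patellofemoral parameters, and
    reversed for tibiofemoral rotation at large wedges)?
    """
    summary = summarize_rmse(records)
    piv = summary.pivot_table(
        index=["parameter", "wedge_height_mm"], columns="variant", values="median"
    ).reset_index()
    piv["ascending_gt_descending"] = piv.get("ascending", np.nan) > piv.get(
        "descending", np.nan
    )
    return piv
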