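"""End-to-end orchestration: generate -> osteotomize -> simulate -> analyze.

Produces a deterministic artifact tree:

    out/
      meshes/      fragment and bone meshes (STL)
      landmarks/   per-model landmark JSON
      curves/      tidy kinematic curves CSV
      tables/      index table, manifest, RMSE summary, t-tests,
                   mixed models (CSV) + report.json bundle
      logs/        run.json with config hash and seed
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd

from . import metrics, osteotomy, stats
from .anatomy import generate_cohort
from .config import ExperimentConfig
from .squat import run_experiment


def run_pipeline(
    config: ExperimentConfig,
    out_dir=None,
    write_meshes: bool | None = None,
    progress: bool = False,
) -> dict:
    """Run the whole experiment; returns a dict of in-memory results."""
    t0 = time.time()
    cohort = generate_cohort(config.cohort)
    osteotomies = osteotomy.run_osteotomy_grid(
        cohort,
        heights=config.wedge_heights_mm,
        variants=config.variants,
        with_meshes=True,
    )
    index_table = metrics.build_index_table(cohort, osteotomies)
    manifest = osteotomy.grid_manifest(osteotomies)
    result = run_experiment(cohort, osteotomies, params=config.sim, progress=progress)

    records = stats.rmse_records(result)
    rmse_summary = stats.summarize_rmse(records)
    ttests = stats.change_ttest_at_flexion(
        result, config.ttest_flexion_deg, config.ttest_wedge_height_mm
    )
    if config.holm and ttests["p"].notna().any():
        mask = ttests["p"].notna()
        ttests.loc[mask, "p_holm"] = stats.holm_correction(
            ttests.loc[mask, "p"].to_numpy()
        )
    mixed = []
    for angle in config.mixed_model_angles:
        for param in stats.PARAMETERS:
            mixed.append(stats.fit_mixed_model(result, angle, param).as_dict())
    mixed_df = pd.DataFrame(mixed)
    concordance = stats.qualitative_concordance(records)
    qq = stats.qq_export(result, config.ttest_flexion_deg)

    results = {
        "cohort": cohort,
        "osteotomies": osteotomies,
        "index_table": index_table,
        "manifest": manifest,
        "result": result,
        "rmse_records": records,
        "rmse_summary": rmse_summary,
        "ttests": ttests,
        "mixed_models": mixed_df,
        "concordance": concordance,
        "qq": qq,
        "runtime_s": time.time() - t0,
    }
    if out_dir is not None:
        write_artifacts(
            results,
            config,
            out_dir,
            write_meshes=config.write_meshes if write_meshes is None else write_meshes,
        )
    return results


def write_artifacts(results, config: ExperimentConfig, out_dir, write_meshes=True):
    out = Path(out_dir)
    for sub in ("meshes", "landmarks", "curves", "tables", "logs"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    header = f"# osteokin config_hash={config.config_hash()} seed={config.cohort.seed}\n"

    def to_csv(df: pd.DataFrame, path: Path):
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    for limb in results["cohort"]:
        limb.landmarks.save_json(out / "landmarks" / f"{limb.limb_id}_preop.json")
        if write_meshes and limb.tibia_mesh is not None:
            limb.tibia_mesh.save_stl(out / "meshes" / f"{limb.limb_id}_tibia.stl")
    for ost in results["osteotomies"]:
        tag = f"{ost.limb_id}_{ost.variant}_h{ost.wedge_height_mm:g}"
        ost.landmarks.save_json(out / "landmarks" / f"{tag}.json")
        with open(out / "landmarks" / f"{tag}_plan.json", "w") as fh:
            json.dump(ost.plan.as_dict(), fh, indent=1)
        if write_meshes and ost.proximal_fragment_mesh is not None:
            ost.proximal_fragment_mesh.save_stl(out / "meshes" / f"{tag}_proximal.stl")
            ost.distal_fragment_mesh.save_stl(out / "meshes" / f"{tag}_distal.stl")

    to_csv(results["result"].to_frame(), out / "curves" / "curves.csv")
    to_csv(results["index_table"], out / "tables" / "index_table.csv")
    to_csv(results["manifest"], out / "tables" / "manifest.csv")
    to_csv(results["rmse_summary"], out / "tables" / "rmse_summary.csv")
    to_csv(results["ttests"], out / "tables" / "ttests.csv")
    to_csv(results["mixed_models"], out / "tables" / "mixed_models.csv")
    to_csv(results["concordance"], out / "tables" / "concordance.csv")
    to_csv(results["qq"], out / "tables" / "qq_data.csv")

    report = {
        "config_hash": config.config_hash(),
        "seed": config.cohort.seed,
        "n_preop": len(results["cohort"]),
        "n_osteotomy": len(results["osteotomies"]),
        "samples_per_parameter": results["result"].samples_per_parameter(),
        "runtime_s": results["runtime_s"],
        "rmse_summary": results["rmse_summary"].to_dict(orient="records"),
        "ttests": json.loads(results["ttests"].to_json(orient="records")),
        "mixed_models": json.loads(results["mixed_models"].to_json(orient="records")),
    }
    with open(out / "tables" / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    with open(out / "logs" / "run.json", "w") as fh:
        json.dump(
            {
                "config_hash": config.config_hash(),
                "seed": config.cohort.seed,
                "config": config.as_dict(),
            },
            fh,
            indent=1,
            default=str,
        )
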