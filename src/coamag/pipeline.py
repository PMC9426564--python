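"""End-to-end orchestration: distance -> cluster -> plan.

The pipeline runs the bespoke computation (metagenomic distances, the
silhouette-optimal Ward clustering and the strategy plans); assembly and
read mapping are external and consumed later through SAM/BAM by the depth
and coverage operations.  Completed stages whose outputs are newer than
their inputs are skipped on re-runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .coassembly_clustering import (find_optimal_clustering,
                                    find_suboptimal_clustering,
                                    plan_from_labels)
from .config import RunConfig, dump_config
from .io_formats import (read_coassembly_manifest, read_distance_matrix,
                         read_sample_manifest, write_coassembly_manifest,
                         write_distance_matrix, _open_text)
from .kmer_distance import pairwise_distances
from .strategy_planner import emit_plan, plan_strategy

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _fresh(output: Path, inputs: list[Path]) -> bool:
    if not output.exists():
        return False
    out_mtime = output.stat().st_mtime
    return all(p.exists() and p.stat().st_mtime <= out_mtime for p in inputs)


def write_silhouette_curve(result, path) -> None:
    """Two-column TSV (k, mean_silhouette): the sweep's plot data."""
    with _open_text(path, "wt") as out:
        out.write("k\tmean_silhouette\n")
        for k in sorted(result.silhouette_by_k):
            out.write(f"{k}\t{result.silhouette_by_k[k]:.10g}\n")


def run_pipeline(config: RunConfig, manifest: str | Path, out_dir: str | Path) -> dict:
    """Run distance -> cluster -> plan; returns the machine-readable summary.

    Outputs under ``out_dir``: dist.tsv, silhouette.tsv, groups.tsv,
    plans/<strategy>.{units,jobs}.tsv, config.yaml and run_summary.json.
    Stages are idempotent: a stage is skipped when its outputs are newer
    than its inputs.
    """
    manifest = Path(manifest)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = read_sample_manifest(manifest)
    summary: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "n_samples": len(samples),
        "stages": {},
    }
    dump_config(config, out_dir / "config.yaml")

    dist_path = out_dir / "dist.tsv"
    stage_inputs = [manifest] + [Path(p) for s in samples for p in s.read_paths]
    if _fresh(dist_path, stage_inputs):
        summary["stages"]["distance"] = "skipped"
        matrix = read_distance_matrix(dist_path, metric_name=config.metric)
    else:
        try:
            matrix = pairwise_distances(samples, k=config.k, metric=config.metric,
                                        min_abundance=config.min_abundance)
        except Exception as exc:
            raise StageError("distance", exc) from exc
        write_distance_matrix(matrix, dist_path)
        summary["stages"]["distance"] = "done"

    groups_path = out_dir / "groups.tsv"
    sil_path = out_dir / "silhouette.tsv"
    if _fresh(groups_path, [dist_path]) and _fresh(sil_path, [dist_path]):
        summary["stages"]["cluster"] = "skipped"
        plan = read_coassembly_manifest(groups_path)
    else:
        try:
            k_max = config.k_max if config.k_max is not None else matrix.n - 1
            result = find_optimal_clustering(matrix, k_min=config.k_min, k_max=k_max)
            chosen_k = result.optimal_k
            if config.suboptimal_target is not None:
                chosen_k = find_suboptimal_clustering(result, config.suboptimal_target)
            plan = plan_from_labels(matrix.sample_ids, result.labels_by_k[chosen_k])
        except Exception as exc:
            raise StageError("cluster", exc) from exc
        write_silhouette_curve(result, sil_path)
        write_coassembly_manifest(plan, groups_path)
        summary["stages"]["cluster"] = "done"
        summary["optimal_k"] = result.optimal_k
        if result.suboptimal_k is not None:
            summary["suboptimal_k"] = result.suboptimal_k

    plans_dir = out_dir / "plans"
    plans_dir.mkdir(exist_ok=True)
    plan_outputs = [plans_dir / f"{s}.units.tsv" for s in config.strategies]
    if all(_fresh(p, [groups_path, manifest]) for p in plan_outputs):
        summary["stages"]["plan"] = "skipped"
    else:
        try:
            for strategy in config.strategies:
                splan = plan_strategy(samples, plan, strategy)
                emit_plan(splan, plans_dir / strategy)
        except Exception as exc:
            raise StageError("plan", exc) from exc
        summary["stages"]["plan"] = "done"

    with open(out_dir / "run_summary.json", "w") as out:
        json.dump(summary, out, indent=2, sort_keys=True)
        out.write("\n")
    return summary
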