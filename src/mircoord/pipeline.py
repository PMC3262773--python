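"""End-to-end orchestration: clusters -> network -> modules -> TO -> tests.

The pipeline consumes a small config (YAML file or keyword arguments), runs
every stage in the order of the analysis, writes per-stage TSV/JSON outputs
plus one summary JSON, and stamps every output with the config hash and the
seed. A single global seed is expanded into independent per-stage substreams
so changing the replicate count of one stage does not shift another stage's
draws.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clustering, modules as modules_mod, network as network_mod
from .errors import MircoordError
from .modules import MCODEParams
from .overlap import category_pairs, compute_pair_overlaps, to_distribution, to_vs_steps_curve
from .permutation import (
    clustered_mirna_enrichment,
    entropy_null_test,
    generate_random_clusters,
    module_membership_permutation,
    to_contrast_test,
)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineStageError(MircoordError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    annotation: str
    sif: str
    tf_list: str | None = None
    family_table: str | None = None
    id_map: str | None = None
    out_dir: str = "mircoord_out"
    cutoff_bp: int = 10_000
    max_span_bp: int | None = None
    same_strand_only: bool = False
    scan_cutoffs_bp: tuple[int, ...] = (5_000, 10_000, 15_000)
    mcode: dict = field(default_factory=dict)
    steps: tuple = (1, "closure")
    max_steps: int = 8
    target_universe: str = "all"
    n_random_sets_for_pairs: int = 20
    B: int = 1000
    seed: int = 0
    allow_module_reuse: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("scan_cutoffs_bp", "steps"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def stage_seeds(self) -> dict[str, int]:
        """Independent substream seeds, one per randomized stage."""
        state = np.random.SeedSequence(self.seed).generate_state(3)
        names = ("random_clusters", "module_permutation", "to_contrast")
        return {name: int(s % (2**31)) for name, s in zip(names, state)}


def _stamp(config: PipelineConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed}


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def _write_json(obj: dict, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        json.dump({**_stamp(config), **obj}, fh, indent=1, default=str)
        fh.write("\n")


def _test_report(test) -> dict:
    null = np.array(test.null_values, dtype=float)
    null = null[~np.isnan(null)]
    qs = np.quantile(null, [0.0, 0.25, 0.5, 0.75, 1.0]) if len(null) else []
    return {
        "observed": test.observed,
        "p_value": test.p_value,
        "direction": test.direction,
        "B": test.B,
        "null_quantiles": [float(q) for q in qs],
    }


# ---------------------------------------------------------------------------
# stages (each runnable standalone; the pipeline composes them)


def stage_clusters(config: PipelineConfig, out_dir: Path) -> clustering.ClusterCallResult:
    genes = clustering.read_mirna_annotations(
        config.annotation, family_table=config.family_table
    )
    result = clustering.detect_clusters(
        genes,
        cutoff_bp=config.cutoff_bp,
        max_span_bp=config.max_span_bp,
        same_strand_only=config.same_strand_only,
    )
    _write_tsv(clustering.cluster_table(result), out_dir / "clusters.tsv", config)
    iso = pd.DataFrame(
        [{"mirna_id": g.id, "chrom": g.chrom, "start": g.start, "end": g.end}
         for g in result.isolated]
    )
    _write_tsv(iso, out_dir / "isolated.tsv", config)
    scan = clustering.cutoff_scan(genes, list(config.scan_cutoffs_bp))
    _write_tsv(scan, out_dir / "cutoff_scan.tsv", config)
    return result


def stage_network(config: PipelineConfig, out_dir: Path):
    net = network_mod.read_sif(config.sif, tf_list=config.tf_list)
    report = network_mod.validate_network(net)
    _write_json(
        {
            "n_nodes_by_type": report.n_nodes_by_type,
            "n_edges": report.n_edges,
            "n_violations": report.n_violations,
            "genes_with_outgoing": list(report.genes_with_outgoing),
            "n_weak_components": report.n_weak_components,
            "largest_component_size": report.largest_component_size,
        },
        out_dir / "network_validation.json",
        config,
    )
    return net


def stage_modules(config: PipelineConfig, net, clusters, id_map, out_dir: Path):
    params = MCODEParams(**config.mcode)
    graph = modules_mod.undirected_projection(net)
    found = modules_mod.predict_modules(graph, params)
    module_df = pd.DataFrame(
        [
            {"module_id": m.module_id, "score": m.score, "size": len(m),
             "seed": m.seed, "members": ";".join(sorted(m.members))}
            for m in found
        ],
        columns=["module_id", "score", "size", "seed", "members"],
    )
    _write_tsv(module_df, out_dir / "modules.tsv", config)
    report = modules_mod.modules_report(found, clusters, net, id_map=id_map)
    _write_tsv(report, out_dir / "modules_report.tsv", config)
    return found


def stage_overlap(config: PipelineConfig, clusters, net, id_map, random_sets, out_dir: Path):
    pairs = category_pairs(clusters, net, id_map=id_map, random_cluster_sets=random_sets)
    tables = []
    dist_summary: dict[str, dict] = {}
    for steps in config.steps:
        for cat, plist in pairs.items():
            if not plist:
                continue
            overlaps = compute_pair_overlaps(
                net, plist, steps, target_universe=config.target_universe
            )
            hist, edges, mean = to_distribution(overlaps)
            dist_summary.setdefault(str(steps), {})[cat] = {
                "mean_to": mean,
                "n_pairs": len(overlaps),
                "hist": [float(h) for h in hist],
            }
            df = pd.DataFrame(
                [
                    {"mirna_i": o.mirna_i, "mirna_j": o.mirna_j, "category": cat,
                     "steps": o.steps, "l_i": o.l_i, "l_j": o.l_j,
                     "shared": o.shared, "to": o.to}
                    for o in overlaps
                ]
            )
            tables.append(df)
    if tables:
        _write_tsv(pd.concat(tables, ignore_index=True), out_dir / "pair_overlaps.tsv", config)
    curves, crossing = to_vs_steps_curve(
        pairs, net, max_steps=config.max_steps, target_universe=config.target_universe
    )
    curve_df = pd.DataFrame(
        [
            {"category": c.category, "steps": k, "mean_to": m, "n_pairs": c.n_pairs}
            for c in curves
            for k, m in zip(c.steps_axis, c.mean_to)
        ]
    )
    _write_tsv(curve_df, out_dir / "to_vs_steps.tsv", config)
    return pairs, dist_summary, curves, crossing


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; return (and write) the summary dictionary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    id_map = network_mod.read_id_map(config.id_map) if config.id_map else None
    summary: dict = {
        **_stamp(config),
        "stage_seeds": seeds,
        "config": asdict(config),
    }

    def run_stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # noqa: BLE001 - wrapped with stage context
            raise PipelineStageError(name, exc) from exc

    clusters = run_stage("clusters", stage_clusters, config, out_dir)
    summary["clusters"] = {
        "n_clusters": len(clusters.clusters),
        "n_isolated": len(clusters.isolated),
        "n_homo": sum(1 for c in clusters.clusters if c.cluster_type == "homo"),
        "n_hetero": sum(1 for c in clusters.clusters if c.cluster_type == "hetero"),
    }

    net = run_stage("network", stage_network, config, out_dir)

    all_mirna_ids = [g.id for c in clusters.clusters for g in c.members] + [
        g.id for g in clusters.isolated
    ]
    random_sets = run_stage(
        "random_clusters",
        lambda: generate_random_clusters(
            all_mirna_ids, clusters,
            B=config.n_random_sets_for_pairs, seed=seeds["random_clusters"],
        ),
    )

    found = run_stage("modules", stage_modules, config, net, clusters, id_map, out_dir)
    summary["modules"] = {
        "n_modules": len(found),
        "n_with_same_cluster_pair": int(
            modules_mod.modules_report(found, clusters, net, id_map=id_map)[
                "has_same_cluster_pair"
            ].sum()
        ),
    }

    pairs, dist_summary, curves, crossing = run_stage(
        "overlap", stage_overlap, config, clusters, net, id_map, random_sets, out_dir
    )
    summary["target_overlap"] = {
        "distributions": dist_summary,
        "curves": {
            c.category: {"steps": list(c.steps_axis), "mean_to": list(c.mean_to)}
            for c in curves
        },
        "crossing_step_vs_random": crossing,
        "target_universe": config.target_universe,
    }

    def permtests():
        perms = module_membership_permutation(
            found, net.mirnas, B=config.B,
            seed=seeds["module_permutation"], allow_reuse=config.allow_module_reuse,
        )
        enrich = clustered_mirna_enrichment(
            found, clusters, perms, net, id_map=id_map, seed=seeds["module_permutation"]
        )
        null_sets = generate_random_clusters(
            all_mirna_ids, clusters, B=config.B, seed=seeds["random_clusters"]
        )
        entropy = entropy_null_test(
            found, clusters, null_sets, net, id_map=id_map, seed=seeds["random_clusters"]
        )
        contrasts = {}
        for steps in config.steps:
            ov = {
                cat: compute_pair_overlaps(
                    net, plist, steps, target_universe=config.target_universe
                )
                for cat, plist in pairs.items()
                if plist
            }
            for cat in ("homo", "hetero"):
                if cat in ov and "random" in ov:
                    contrasts[f"{cat}_vs_random_steps_{steps}"] = to_contrast_test(
                        ov[cat], ov["random"], B=config.B, seed=seeds["to_contrast"]
                    )
        return enrich, entropy, contrasts

    enrich, entropy, contrasts = run_stage("permutation_tests", permtests)
    tests = {
        "enrichment_homo": _test_report(enrich["homo"]),
        "enrichment_hetero": _test_report(enrich["hetero"]),
        "module_entropy": _test_report(entropy),
        **{name: _test_report(t) for name, t in contrasts.items()},
    }
    summary["tests"] = tests
    _write_json({"tests": tests}, out_dir / "permutation_tests.json", config)
    _write_json(summary, out_dir / "summary.json", config)
    return summary
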