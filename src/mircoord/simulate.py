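"""Synthetic annotation + family + network scenarios with planted ground truth.

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* miRNA genes laid out on chromosomes so that planted clusters chain at the
  10 kb cutoff and everything else stays isolated (intra-cluster gaps well
  below the cutoff, inter-locus gaps well above);
* **homo-clusters** whose members draw most of their direct targets from a
  shared pool (one family, one seed sequence), giving high direct target
  overlap;
* **hetero-clusters** whose members have disjoint direct targets but private
  TF chains converging on a shared terminal gene set after a configurable
  number of regulation steps (default 3), giving zero overlap below the
  convergence step and positive overlap at and beyond it;
* **planted modules**: dense near-cliques of module TFs plus the miRNAs of
  designated clusters (module TFs regulate the attached miRNA cluster and the
  module genes), which MCODE-style detection should recover;
* background regulation: free TFs wired to random targets, isolated miRNAs
  with a few random direct targets. Background edges never touch the private
  hetero chain TFs, so convergence cannot be short-circuited.

``null_mode`` rewires nothing structurally: it relabels the miRNA nodes of
the finished network by a uniform random permutation, preserving every degree
while destroying the association between genomic clustering and network
position — the exchangeable null for all three permutation tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .clustering import MirnaGene
from .network import RegulatoryNetwork, write_sif

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "Scenario",
    "default_config",
    "minimal_config",
    "convergence_motif_config",
    "null_calibration_config",
    "build_scenario",
    "generate_scenario",
    "fixture_suite",
]

GENE_LEN_BP = 80


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic dataset.

    Defaults are a desk-scale rendering of a genome-wide analysis: 100
    miRNAs of which 40% sit in 14 clusters of 2-4 genes (6 homo, 8 hetero)
    and 60 are isolated — roughly the observed preponderance of isolated
    miRNAs — with ten planted modules each hosting one cluster.
    """

    seed: int = 0
    n_chromosomes: int = 3
    n_tf: int = 30                      # free background TFs
    n_gene: int = 200                   # free background genes
    n_isolated_mirna: int = 60
    homo_clusters: tuple[tuple[int, str], ...] = (
        (3, "mir-syn-a"), (2, "mir-syn-b"), (4, "mir-syn-c"),
        (3, "mir-syn-d"), (2, "mir-syn-e"), (3, "mir-syn-f"),
    )
    hetero_clusters: tuple[tuple[int, tuple[str, ...]], ...] = tuple(
        (size, tuple(f"mir-syn-h{i}{j}" for j in range(size)))
        for i, size in enumerate((2, 3, 4, 3, 2, 3, 4, 2))
    )
    intra_cluster_gap_bp: int = 2_000
    inter_locus_gap_bp: int = 50_000
    cluster_cutoff_bp: int = 10_000
    homo_shared_target_fraction: float = 0.9
    homo_target_pool: int = 10
    homo_private_targets: int = 1
    hetero_private_targets: int = 3
    hetero_convergence_step: int = 3
    hetero_shared_terminal_targets: int = 5
    isolated_targets: int = 3
    extra_random_targets: int = 0     # background noise targets per miRNA
    background_edge_prob: float = 0.002
    planted_module_specs: tuple[tuple[int, int, tuple[str, ...]], ...] = tuple(
        (5, 0, (key,))
        for key in [f"homo_{i}" for i in range(5)] + [f"het_{i}" for i in range(5)]
    )
    null_mode: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.homo_shared_target_fraction <= 1.0:
            raise ValueError("homo_shared_target_fraction must lie in [0, 1]")
        if not 0.0 <= self.background_edge_prob <= 1.0:
            raise ValueError("background_edge_prob must lie in [0, 1]")
        if not (
            self.intra_cluster_gap_bp
            < self.cluster_cutoff_bp
            < self.inter_locus_gap_bp
        ):
            raise ValueError(
                "need intra_cluster_gap_bp < cluster_cutoff_bp < inter_locus_gap_bp"
            )
        if self.hetero_convergence_step < 1:
            raise ValueError("hetero_convergence_step must be >= 1")
        n_pick = round(self.homo_shared_target_fraction * self.homo_target_pool)
        if self.homo_clusters and n_pick == 0 and self.homo_private_targets == 0:
            raise ValueError(
                "homo members would have zero targets "
                "(shared fraction x pool rounds to 0 and no private targets)"
            )
        for size, families in self.hetero_clusters:
            if len(families) != size:
                raise ValueError(
                    f"hetero cluster of size {size} needs {size} family labels"
                )
            if len(set(families)) < 2:
                raise ValueError("a hetero cluster needs >= 2 distinct families")
        known = {f"homo_{i}" for i in range(len(self.homo_clusters))} | {
            f"het_{i}" for i in range(len(self.hetero_clusters))
        }
        seen_keys: set[str] = set()
        for _nt, _ng, keys in self.planted_module_specs:
            for k in keys:
                if k not in known:
                    raise ValueError(f"planted module references unknown cluster {k!r}")
                if k in seen_keys:
                    raise ValueError(f"cluster {k!r} attached to more than one module")
                seen_keys.add(k)

    @property
    def expected_homo_direct_to(self) -> float:
        """Analytic mean direct TO of a planted homo pair.

        Each member picks m = round(fraction x pool) targets from the pool;
        the expected shared count between two members is m^2/pool
        (hypergeometric), and both have l = m + private targets.
        """
        m = round(self.homo_shared_target_fraction * self.homo_target_pool)
        if self.homo_target_pool == 0:
            return 0.0
        l = m + self.homo_private_targets
        return (m * m / self.homo_target_pool) / (l + 1)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    true_clusters: tuple[dict, ...]
    true_module_members: tuple[frozenset[str], ...]
    hetero_convergence_step: int
    expected_direct_overlap: float | None

    def to_json(self) -> dict:
        return {
            "true_clusters": list(self.true_clusters),
            "true_module_members": [sorted(m) for m in self.true_module_members],
            "hetero_convergence_step": self.hetero_convergence_step,
            "expected_direct_overlap": self.expected_direct_overlap,
        }


@dataclass
class Scenario:
    config: ScenarioConfig
    genes: list[MirnaGene]
    families: dict[str, str]
    network: RegulatoryNetwork
    tf_ids: list[str]
    ground_truth: GroundTruth
    paths: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# preset configs


def default_config(seed: int = 0, null_mode: bool = False) -> ScenarioConfig:
    return ScenarioConfig(seed=seed, null_mode=null_mode)


def minimal_config(seed: int = 0) -> ScenarioConfig:
    """Hand-checkable scenario with <= 30 network nodes."""
    return ScenarioConfig(
        seed=seed,
        n_chromosomes=2,
        n_tf=2,
        n_gene=6,
        n_isolated_mirna=2,
        homo_clusters=((2, "mir-syn-a"),),
        hetero_clusters=((2, ("mir-syn-x", "mir-syn-y")),),
        homo_shared_target_fraction=1.0,
        homo_target_pool=4,
        homo_private_targets=0,
        hetero_private_targets=1,
        hetero_shared_terminal_targets=1,
        isolated_targets=1,
        background_edge_prob=0.0,
        planted_module_specs=((3, 0, ("homo_0",)),),
    )


def convergence_motif_config(seed: int = 0) -> ScenarioConfig:
    """The bare 3-step convergence motif: one miRNA pair, two private 2-TF
    chains converging on one shared terminal gene."""
    return ScenarioConfig(
        seed=seed,
        n_chromosomes=1,
        n_tf=0,
        n_gene=0,
        n_isolated_mirna=0,
        homo_clusters=(),
        hetero_clusters=((2, ("mir-syn-x", "mir-syn-y")),),
        homo_target_pool=0,
        homo_private_targets=0,
        hetero_private_targets=0,
        hetero_convergence_step=3,
        hetero_shared_terminal_targets=1,
        isolated_targets=0,
        background_edge_prob=0.0,
        planted_module_specs=(),
    )


def null_calibration_config(seed: int = 0) -> ScenarioConfig:
    """Large exchangeable-null scenario for p-value uniformity checks.

    A Kolmogorov-Smirnov comparison against the continuous uniform is valid
    only when the permutation statistics take many values. Two granularity
    requirements size this preset: (a) the enrichment count statistic needs a
    wide null spread, so 40 planted modules of 12 miRNA slots are drawn from
    1200 miRNAs (null sd of the category count > 7); (b) the module-entropy
    statistic must not sit on an atom at "all clusters distinct", so clusters
    have 6 members and 62% of miRNAs are clustered, making same-cluster
    collisions in modules near-certain under relabeling.
    """
    homo = tuple((6, f"mir-syn-fam{i}") for i in range(50))
    hetero = tuple(
        (6, tuple(f"mir-syn-hf{i}{j}" for j in range(6))) for i in range(75)
    )
    keys = [f"homo_{i}" for i in range(50)] + [f"het_{i}" for i in range(30)]
    modules = tuple((3, 0, tuple(keys[2 * i : 2 * i + 2])) for i in range(40))
    return ScenarioConfig(
        seed=seed,
        n_chromosomes=10,
        n_tf=80,
        n_gene=500,
        n_isolated_mirna=450,
        homo_clusters=homo,
        hetero_clusters=hetero,
        extra_random_targets=4,
        background_edge_prob=0.03,
        planted_module_specs=modules,
        null_mode=True,
    )


# ---------------------------------------------------------------------------
# construction


def _mirna_ids(config: ScenarioConfig) -> tuple[list[list[str]], list[list[str]], list[str]]:
    homo = [
        [f"hsa-mir-syn-h{ci:02d}-{j}" for j in range(size)]
        for ci, (size, _fam) in enumerate(config.homo_clusters)
    ]
    het = [
        [f"hsa-mir-syn-e{ci:02d}-{j}" for j in range(size)]
        for ci, (size, _fams) in enumerate(config.hetero_clusters)
    ]
    iso = [f"hsa-mir-syn-i{k:04d}" for k in range(config.n_isolated_mirna)]
    return homo, het, iso


def _layout_genome(
    config: ScenarioConfig, loci: list[list[str]]
) -> list[MirnaGene]:
    """Place loci (each a list of gene ids forming one cluster-or-singleton)
    round-robin across chromosomes, gaps chosen so exactly the intended
    clusters chain at the cutoff."""
    cursor = {f"chr{c + 1}": 1_000 for c in range(config.n_chromosomes)}
    chrom_names = sorted(cursor, key=lambda c: int(c[3:]))
    genes: list[MirnaGene] = []
    for li, member_ids in enumerate(loci):
        chrom = chrom_names[li % len(chrom_names)]
        pos = cursor[chrom]
        for mid in member_ids:
            genes.append(
                MirnaGene(id=mid, chrom=chrom, start=pos, end=pos + GENE_LEN_BP, strand="+")
            )
            pos += GENE_LEN_BP + config.intra_cluster_gap_bp
        # last gene's end plus the inter-locus gap
        cursor[chrom] = (pos - config.intra_cluster_gap_bp) + config.inter_locus_gap_bp
    return genes


def build_scenario(config: ScenarioConfig) -> Scenario:
    """Construct the scenario in memory (no files written)."""
    rng = np.random.default_rng(config.seed)
    homo_ids, het_ids, iso_ids = _mirna_ids(config)

    # genomic layout + families -------------------------------------------
    loci = homo_ids + het_ids + [[m] for m in iso_ids]
    genes = _layout_genome(config, loci)
    families: dict[str, str] = {}
    for (size, fam), members in zip(config.homo_clusters, homo_ids):
        for m in members:
            families[m] = fam
    for (size, fams), members in zip(config.hetero_clusters, het_ids):
        for m, f in zip(members, fams):
            families[m] = f
    for k, m in enumerate(iso_ids):
        families[m] = f"mir-syn-iso{k}"

    # node inventory -------------------------------------------------------
    net = RegulatoryNetwork()
    all_mirnas = [m for locus in loci for m in locus]
    for m in all_mirnas:
        net.add_node(m, "miRNA")

    chain_len = config.hetero_convergence_step - 1
    chain_tfs: dict[str, list[str]] = {}  # hetero member -> its private TF chain
    for ci, members in enumerate(het_ids):
        for j, m in enumerate(members):
            chain_tfs[m] = [f"TF-ch-e{ci:02d}{j}-{s}" for s in range(1, chain_len + 1)]
    module_tfs = [
        [f"TF-m{mi:02d}-{k}" for k in range(nt)]
        for mi, (nt, _ng, _keys) in enumerate(config.planted_module_specs)
    ]
    free_tfs = [f"TF-f{k:03d}" for k in range(config.n_tf)]
    tf_ids = sorted(
        {t for chain in chain_tfs.values() for t in chain}
        | {t for mod in module_tfs for t in mod}
        | set(free_tfs)
    )
    for t in tf_ids:
        net.add_node(t, "TF")

    pool_genes = [
        [f"G-pool-h{ci:02d}-{k}" for k in range(config.homo_target_pool)]
        for ci in range(len(homo_ids))
    ]
    homo_priv = {
        m: [f"G-priv-{m}-{k}" for k in range(config.homo_private_targets)]
        for members in homo_ids
        for m in members
    }
    het_priv = {
        m: [f"G-hpriv-{m}-{k}" for k in range(config.hetero_private_targets)]
        for members in het_ids
        for m in members
    }
    term_genes = [
        [f"G-term-e{ci:02d}-{k}" for k in range(config.hetero_shared_terminal_targets)]
        for ci in range(len(het_ids))
    ]
    module_genes = [
        [f"G-m{mi:02d}-{k}" for k in range(ng)]
        for mi, (_nt, ng, _keys) in enumerate(config.planted_module_specs)
    ]
    free_genes = [f"G-f{k:04d}" for k in range(config.n_gene)]
    for g in sorted(
        {g for pool in pool_genes for g in pool}
        | {g for lst in homo_priv.values() for g in lst}
        | {g for lst in het_priv.values() for g in lst}
        | {g for lst in term_genes for g in lst}
        | {g for lst in module_genes for g in lst}
        | set(free_genes)
    ):
        net.add_node(g, "gene")

    # homo wiring: shared pool picks + private targets ---------------------
    n_pick = round(config.homo_shared_target_fraction * config.homo_target_pool)
    for ci, members in enumerate(homo_ids):
        pool = pool_genes[ci]
        for m in members:
            picks = (
                [pool[i] for i in rng.choice(len(pool), size=n_pick, replace=False)]
                if n_pick
                else []
            )
            for g in sorted(picks) + homo_priv[m]:
                net.add_edge(m, g, "represses")

    # hetero wiring: private chains converging on shared terminals ---------
    for ci, members in enumerate(het_ids):
        for m in members:
            chain = chain_tfs[m]
            hops = [m, *chain]
            for a, b in zip(hops, hops[1:]):
                net.add_edge(a, b, "represses" if a == m else "regulates")
            last = hops[-1]
            for g in term_genes[ci]:
                net.add_edge(last, g, "represses" if last == m else "regulates")
            for g in het_priv[m]:
                net.add_edge(m, g, "represses")

    # isolated miRNAs: a few random direct targets -------------------------
    iso_candidates = sorted(free_genes) + sorted(free_tfs)
    for m in iso_ids:
        k = min(config.isolated_targets, len(iso_candidates))
        if k:
            idx = rng.choice(len(iso_candidates), size=k, replace=False)
            for i in sorted(idx):
                net.add_edge(m, iso_candidates[i], "represses")

    # optional per-miRNA background noise targets --------------------------
    if config.extra_random_targets and iso_candidates:
        k = min(config.extra_random_targets, len(iso_candidates))
        for m in sorted(all_mirnas):
            idx = rng.choice(len(iso_candidates), size=k, replace=False)
            for i in sorted(idx):
                if iso_candidates[i] != m:
                    net.add_edge(m, iso_candidates[i], "represses")

    # planted modules: TF near-clique regulating the attached cluster ------
    key_members = {f"homo_{ci}": ms for ci, ms in enumerate(homo_ids)}
    key_members.update({f"het_{ci}": ms for ci, ms in enumerate(het_ids)})
    true_modules: list[frozenset[str]] = []
    for mi, (nt, ng, keys) in enumerate(config.planted_module_specs):
        tfs = module_tfs[mi]
        genes_m = module_genes[mi]
        mirnas_m = [m for k in keys for m in key_members[k]]
        for i, a in enumerate(tfs):
            for b in tfs[i + 1 :]:
                net.add_edge(a, b, "regulates")
        for t in tfs:
            for m in mirnas_m:
                net.add_edge(t, m, "regulates")  # TF drives the miRNA cluster
            for g in genes_m:
                net.add_edge(t, g, "regulates")
        true_modules.append(frozenset(tfs) | frozenset(genes_m) | frozenset(mirnas_m))

    # background regulation by free TFs ------------------------------------
    if config.background_edge_prob > 0 and free_tfs:
        protected = {t for chain in chain_tfs.values() for t in chain}
        candidates = sorted(set(net.graph.nodes()) - protected)
        for t in sorted(free_tfs):
            mask = rng.random(len(candidates)) < config.background_edge_prob
            for i in np.flatnonzero(mask):
                if candidates[i] != t:
                    net.add_edge(t, candidates[i], "regulates")

    # ground truth ----------------------------------------------------------
    true_clusters = []
    for ci, members in enumerate(homo_ids):
        true_clusters.append(
            {"cluster_key": f"homo_{ci}", "members": list(members), "cluster_type": "homo"}
        )
    for ci, members in enumerate(het_ids):
        true_clusters.append(
            {"cluster_key": f"het_{ci}", "members": list(members), "cluster_type": "hetero"}
        )

    # null mode: relabel miRNA nodes by a uniform permutation ---------------
    if config.null_mode:
        order = sorted(all_mirnas)
        perm = rng.permutation(len(order))
        mapping = {order[i]: order[perm[i]] for i in range(len(order))}
        net = RegulatoryNetwork(nx.relabel_nodes(net.graph, mapping, copy=True))
        true_modules = [
            frozenset(mapping.get(n, n) for n in mod) for mod in true_modules
        ]
        expected_to = None
    else:
        expected_to = config.expected_homo_direct_to

    gt = GroundTruth(
        true_clusters=tuple(true_clusters),
        true_module_members=tuple(true_modules),
        hetero_convergence_step=config.hetero_convergence_step,
        expected_direct_overlap=expected_to,
    )
    return Scenario(
        config=config,
        genes=genes,
        families=families,
        network=net,
        tf_ids=tf_ids,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# file emission


def _write_gff3(genes: Sequence[MirnaGene], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tmircoord-synth\tmiRNA_primary_transcript\t"
                f"{g.start + 1}\t{g.end}\t.\t{g.strand if g.strand != 'unknown' else '.'}"
                f"\t.\tID={g.id};Name={g.id}\n"
            )


def _write_family_table(families: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tfamily\n")
        for mid in sorted(families):
            fh.write(f"{mid}\t{families[mid]}\n")


def generate_scenario(config: ScenarioConfig, out_dir: str | Path) -> Scenario:
    """Build a scenario and write its files to ``out_dir``.

    Emits annotation GFF3, family table TSV, network SIF, TF list and a
    ground-truth JSON manifest. Byte-identical for identical configs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenario = build_scenario(config)
    paths = {
        "annotation": out_dir / "mirna_annotation.gff3",
        "families": out_dir / "mirna_families.tsv",
        "network": out_dir / "regulatory_network.sif",
        "tf_list": out_dir / "tf_list.txt",
        "ground_truth": out_dir / "ground_truth.json",
    }
    _write_gff3(scenario.genes, paths["annotation"])
    _write_family_table(scenario.families, paths["families"])
    write_sif(scenario.network, paths["network"])
    paths["tf_list"].write_text("".join(t + "\n" for t in scenario.tf_ids))
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {"seed": config.seed, "config": asdict(config),
             **scenario.ground_truth.to_json()},
            fh, indent=1, default=list,
        )
        fh.write("\n")
    scenario.paths = paths
    return scenario


def fixture_suite(out_dir: str | Path, seed: int = 0) -> dict:
    """Emit the canned scenarios (minimal, convergence motif, null) plus a
    manifest of seeds and expected summary values."""
    out_dir = Path(out_dir)
    presets = {
        "minimal": minimal_config(seed),
        "convergence_motif": convergence_motif_config(seed),
        "null": default_config(seed, null_mode=True),
    }
    manifest: dict = {}
    for name, config in presets.items():
        scenario = generate_scenario(config, out_dir / name)
        n_clusters = len(config.homo_clusters) + len(config.hetero_clusters)
        manifest[name] = {
            "seed": config.seed,
            "files": {k: str(v) for k, v in scenario.paths.items()},
            "expected": {
                "n_clusters": n_clusters,
                "n_isolated": config.n_isolated_mirna,
                "hetero_convergence_step": config.hetero_convergence_step,
                "expected_direct_overlap": scenario.ground_truth.expected_direct_overlap,
            },
        }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return manifest
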