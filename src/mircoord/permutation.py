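"""Permutation null models and empirical significance tests.

Three null models mirror the analysis questions:

* **Random miRNA clusters** — miRNA ids are re-assigned uniformly at random
  into the observed cluster-size multiset, with every isolated miRNA kept as
  a size-1 pseudo-cluster. This asks whether genomic co-clustering predicts
  anything beyond group sizes.
* **Random module membership** — each detected module's miRNA slots are
  refilled by drawing uniformly without replacement from all network miRNAs
  (disjointly across modules within a replicate by default). This asks
  whether clustered miRNAs are enriched in dense modules.
* **Label permutation** — for contrasting mean TO between two pair
  categories, pooled pair TO values are randomly re-labelled.

Empirical p-values use the positively biased, never-zero estimator
``p = (1 + #{null >= observed}) / (1 + B)`` (or ``<=`` for direction
"less"). No multiple-testing correction is applied; raw empirical p-values
are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .clustering import ClusterCallResult
from .entropy import composition_probs, normalized_entropy
from .errors import ValidationError
from .modules import NetworkModule
from .network import RegulatoryNetwork
from .overlap import PairOverlap

__all__ = [
    "RandomClusterSet",
    "ModuleEntropyResult",
    "EmpiricalTest",
    "empirical_p",
    "generate_random_clusters",
    "module_membership_permutation",
    "categorize_mirnas",
    "clustered_mirna_enrichment",
    "module_cluster_entropy",
    "entropy_null_test",
    "to_contrast_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RandomClusterSet:
    """One replicate of size-preserving random clusters.

    ``clusters`` lists (cluster_id, member ids); the size multiset equals the
    observed one, isolated miRNAs included as size-1 pseudo-clusters.
    """

    clusters: tuple[tuple[str, tuple[str, ...]], ...]
    replicate_index: int
    seed: int

    def assignment(self, min_size: int = 2) -> dict[str, str]:
        """miRNA id -> cluster id, restricted to clusters of >= min_size."""
        return {
            m: cid
            for cid, members in self.clusters
            if len(members) >= min_size
            for m in members
        }


@dataclass(frozen=True)
class ModuleEntropyResult:
    module_id: int
    e_c: float
    n_c: int
    cluster_probs: dict[str, float]


@dataclass(frozen=True)
class EmpiricalTest:
    observed: float
    null_values: tuple[float, ...]
    p_value: float
    direction: str
    B: int
    seed: int


def empirical_p(
    observed: float, null_values: Sequence[float], direction: str
) -> float:
    """(1 + exceedances) / (1 + B); never zero, in (0, 1]."""
    null = np.asarray(null_values, dtype=float)
    null = null[~np.isnan(null)]
    b = len(null)
    if b == 0:
        raise ValueError("empty null distribution")
    if direction == "greater":
        hits = int(np.sum(null >= observed))
    elif direction == "less":
        hits = int(np.sum(null <= observed))
    else:
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    return (1 + hits) / (1 + b)


# ---------------------------------------------------------------------------
# null model 1: random miRNA clusters


def generate_random_clusters(
    mirnas: Sequence[str],
    observed: ClusterCallResult,
    B: int = 1000,
    seed: int = 0,
) -> list[RandomClusterSet]:
    """Size-preserving random re-assignment of miRNAs into clusters.

    Each replicate permutes the miRNA ids uniformly and partitions them into
    the observed size multiset (real clusters plus one size-1 pseudo-cluster
    per isolated miRNA). Reproducible from ``seed``.
    """
    sizes = [len(c) for c in observed.clusters] + [1] * len(observed.isolated)
    if len(mirnas) != sum(sizes):
        raise ValidationError(
            f"{len(mirnas)} miRNAs supplied but observed clustering covers "
            f"{sum(sizes)}"
        )
    rng = np.random.default_rng(seed)
    mirnas = list(mirnas)
    out = []
    for rep in range(B):
        perm = [mirnas[i] for i in rng.permutation(len(mirnas))]
        clusters = []
        pos = 0
        for ci, size in enumerate(sizes):
            clusters.append((f"rc{ci:04d}", tuple(perm[pos : pos + size])))
            pos += size
        out.append(RandomClusterSet(tuple(clusters), replicate_index=rep, seed=seed))
    return out


# ---------------------------------------------------------------------------
# null model 2: random module membership


def module_membership_permutation(
    modules: Sequence[NetworkModule],
    network_mirnas: Sequence[str],
    B: int = 1000,
    seed: int = 0,
    allow_reuse: bool = False,
) -> list[dict[int, frozenset[str]]]:
    """Random re-assignment of miRNAs into modules, per-module counts kept.

    Default draws are disjoint across modules within one replicate (a global
    permutation sliced into per-module slots); ``allow_reuse`` instead draws
    each module independently, letting a miRNA sit in several modules.
    """
    network_mirnas = sorted(set(network_mirnas))
    counts = {
        m.module_id: len(set(m.members) & set(network_mirnas)) for m in modules
    }
    total = sum(counts.values())
    if not allow_reuse and total > len(network_mirnas):
        raise ValidationError(
            f"module miRNA slots ({total}) exceed network miRNA count "
            f"({len(network_mirnas)})"
        )
    rng = np.random.default_rng(seed)
    out = []
    for _rep in range(B):
        replicate: dict[int, frozenset[str]] = {}
        if allow_reuse:
            for mid, c in counts.items():
                idx = rng.choice(len(network_mirnas), size=c, replace=False)
                replicate[mid] = frozenset(network_mirnas[i] for i in idx)
        else:
            perm = rng.permutation(len(network_mirnas))
            pos = 0
            for mid, c in counts.items():
                replicate[mid] = frozenset(
                    network_mirnas[i] for i in perm[pos : pos + c]
                )
                pos += c
        out.append(replicate)
    return out


# ---------------------------------------------------------------------------
# enrichment of clustered miRNAs in modules


def categorize_mirnas(
    clusters: ClusterCallResult, id_map: Mapping[str, str] | None = None
) -> dict[str, str]:
    """miRNA id (network namespace) -> 'homo' | 'hetero' | 'isolated'."""
    id_map = dict(id_map or {})
    cats = {}
    for c in clusters.clusters:
        for g in c.members:
            cats[id_map.get(g.id, g.id)] = c.cluster_type or "unlabeled"
    for g in clusters.isolated:
        cats[id_map.get(g.id, g.id)] = "isolated"
    return cats


def _mean_category_count(
    module_mirnas: Iterable[Iterable[str]], category_of: Mapping[str, str], category: str
) -> float:
    per_module = [
        sum(1 for m in members if category_of.get(m) == category)
        for members in module_mirnas
    ]
    return float(np.mean(per_module)) if per_module else math.nan


def clustered_mirna_enrichment(
    modules: Sequence[NetworkModule],
    clusters: ClusterCallResult,
    permutations: Sequence[Mapping[int, frozenset[str]]],
    network: RegulatoryNetwork,
    id_map: Mapping[str, str] | None = None,
    seed: int = 0,
) -> dict[str, EmpiricalTest]:
    """Enrichment of homo-/hetero-clustered miRNAs in modules.

    Observed statistic per category: average per-module count of miRNAs of
    that category. Null from the module-membership permutations; one-sided
    p (greater).
    """
    category_of = categorize_mirnas(clusters, id_map)
    mirna_set = set(network.mirnas)
    observed_members = [
        sorted(set(m.members) & mirna_set) for m in modules
    ]
    results = {}
    for category in ("homo", "hetero"):
        obs = _mean_category_count(observed_members, category_of, category)
        null = [
            _mean_category_count(rep.values(), category_of, category)
            for rep in permutations
        ]
        results[category] = EmpiricalTest(
            observed=obs,
            null_values=tuple(null),
            p_value=empirical_p(obs, null, "greater"),
            direction="greater",
            B=len(null),
            seed=seed,
        )
    return results


# ---------------------------------------------------------------------------
# module cluster entropy (E_c)


def module_cluster_entropy(
    module_mirnas: Iterable[str],
    cluster_assignment: Mapping[str, object],
    module_id: int = -1,
) -> ModuleEntropyResult:
    """Cluster entropy E_c of a module.

    ``cluster_assignment`` maps a miRNA id to its genomic cluster id; only
    the module's miRNAs that belong to some cluster enter the composition.
    E_c = -(1/ln N_c) sum_i p_i ln p_i with E_c = 0 when all clustered
    members come from one cluster.
    """
    labels = [
        str(cluster_assignment[m]) for m in module_mirnas if m in cluster_assignment
    ]
    if not labels:
        raise ValidationError(
            f"module {module_id}: no member belongs to any miRNA cluster"
        )
    probs = composition_probs(labels)
    return ModuleEntropyResult(
        module_id=module_id,
        e_c=normalized_entropy(probs),
        n_c=len(probs),
        cluster_probs={str(k): v for k, v in probs.items()},
    )


def _avg_module_entropy(
    modules_mirnas: Sequence[tuple[int, list[str]]],
    cluster_assignment: Mapping[str, object],
    min_clustered: int = 2,
) -> float:
    """Average E_c over modules with >= min_clustered clustered miRNAs."""
    values = []
    for mid, members in modules_mirnas:
        clustered = [m for m in members if m in cluster_assignment]
        if len(clustered) < min_clustered:
            continue
        values.append(module_cluster_entropy(clustered, cluster_assignment, mid).e_c)
    return float(np.mean(values)) if values else math.nan


def entropy_null_test(
    modules: Sequence[NetworkModule],
    clusters: ClusterCallResult,
    random_cluster_sets: Sequence[RandomClusterSet],
    network: RegulatoryNetwork,
    id_map: Mapping[str, str] | None = None,
    seed: int = 0,
) -> EmpiricalTest:
    """Is the average module cluster entropy lower than under random clusters?

    Observed: average E_c over modules holding >= 2 clustered miRNAs, with
    cluster ids from the observed genomic clustering. Null: the same statistic
    with each random cluster set's assignment substituted. One-sided p (less):
    low entropy means same-cluster miRNAs concentrate in the same module.
    """
    id_map = dict(id_map or {})
    mirna_set = set(network.mirnas)
    modules_mirnas = [
        (m.module_id, sorted(set(m.members) & mirna_set)) for m in modules
    ]
    observed_assignment = {
        id_map.get(g.id, g.id): f"c{ci:04d}"
        for ci, c in enumerate(clusters.clusters)
        for g in c.members
    }
    obs = _avg_module_entropy(modules_mirnas, observed_assignment)
    if math.isnan(obs):
        raise ValidationError("no module holds >= 2 clustered miRNAs")
    null = [
        _avg_module_entropy(modules_mirnas, rep.assignment(min_size=2))
        for rep in random_cluster_sets
    ]
    n_nan = sum(math.isnan(v) for v in null)
    if n_nan:
        logger.info("entropy_null_test: %d null replicate(s) had no eligible module", n_nan)
    return EmpiricalTest(
        observed=obs,
        null_values=tuple(null),
        p_value=empirical_p(obs, null, "less"),
        direction="less",
        B=len(null),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# TO contrast between pair categories


def to_contrast_test(
    overlaps_a: Sequence[PairOverlap],
    overlaps_b: Sequence[PairOverlap],
    B: int = 1000,
    seed: int = 0,
    direction: str = "greater",
) -> EmpiricalTest:
    """Permutation contrast of mean TO between two pair categories.

    Observed statistic: mean(TO_a) - mean(TO_b). Null: B random re-labellings
    of the pooled TO values into groups of the original sizes. One-sided
    p in ``direction`` (default: a exceeds b).
    """
    if not overlaps_a or not overlaps_b:
        raise ValueError("both pair categories must be non-empty")
    pairs_a = {(o.mirna_i, o.mirna_j) for o in overlaps_a}
    pairs_b = {(o.mirna_i, o.mirna_j) for o in overlaps_b}
    if pairs_a == pairs_b:
        raise ValidationError("the two categories contain identical pair lists")
    a = np.array([o.to for o in overlaps_a], dtype=float)
    b = np.array([o.to for o in overlaps_b], dtype=float)
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(B):
        perm = rng.permutation(len(pooled))
        na = pooled[perm[: len(a)]]
        nb = pooled[perm[len(a):]]
        null.append(float(na.mean() - nb.mean()))
    return EmpiricalTest(
        observed=observed,
        null_values=tuple(null),
        p_value=empirical_p(observed, null, direction),
        direction=direction,
        B=B,
        seed=seed,
    )
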