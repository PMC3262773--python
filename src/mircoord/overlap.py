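"""Target-overlap (TO) statistics for miRNA pairs.

For miRNAs *i* and *j* with target sets of sizes ``l_i`` and ``l_j`` sharing
``shared`` targets,

    TO_ij = shared / (min(l_i, l_j) + 1)

The +1 in the denominator keeps the ratio defined when a miRNA has no
targets and bounds TO strictly below 1; two identical target sets of size
``l`` give TO = l/(l+1). Target sets are taken at a regulation-step bound
(steps=1: direct targets only) or at full reachability ("closure": direct
plus all indirect targets).

The module compares TO between pair categories — pairs within homo-clusters,
within hetero-clusters, and within size-matched random clusters — as
distributions at fixed steps and as mean-TO curves over steps 1..k.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterCallResult
from .network import RegulatoryNetwork, Steps, TargetProfile, k_step_targets

__all__ = [
    "PairOverlap",
    "CategoryCurve",
    "pair_target_overlap",
    "target_profiles",
    "compute_pair_overlaps",
    "category_pairs",
    "to_distribution",
    "to_vs_steps_curve",
    "pair_table",
]

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass(frozen=True)
class PairOverlap:
    mirna_i: str
    mirna_j: str
    steps: Steps
    shared: int
    l_i: int
    l_j: int

    @property
    def to(self) -> float:
        return self.shared / (min(self.l_i, self.l_j) + 1)


@dataclass(frozen=True)
class CategoryCurve:
    """Mean TO per regulation-step bound for one pair category."""

    category: str
    steps_axis: tuple[int, ...]
    mean_to: tuple[float, ...]
    n_pairs: int


def pair_target_overlap(profile_i: TargetProfile, profile_j: TargetProfile) -> PairOverlap:
    """TO of one miRNA pair from two target profiles at the same step bound."""
    if profile_i.steps != profile_j.steps:
        raise ValueError(
            f"profiles computed at different steps: "
            f"{profile_i.steps!r} vs {profile_j.steps!r}"
        )
    shared = len(profile_i.targets & profile_j.targets)
    return PairOverlap(
        mirna_i=profile_i.mirna_id,
        mirna_j=profile_j.mirna_id,
        steps=profile_i.steps,
        shared=shared,
        l_i=profile_i.l,
        l_j=profile_j.l,
    )


def target_profiles(
    network: RegulatoryNetwork,
    mirna_ids: Iterable[str],
    steps: Steps,
    target_universe: str = "all",
) -> dict[str, TargetProfile]:
    """Target profile per miRNA at one step bound (computed once per miRNA)."""
    return {
        m: k_step_targets(network, m, steps, target_universe=target_universe)
        for m in mirna_ids
    }


def compute_pair_overlaps(
    network: RegulatoryNetwork,
    pairs: Sequence[Pair],
    steps: Steps,
    target_universe: str = "all",
) -> list[PairOverlap]:
    ids = sorted({m for p in pairs for m in p})
    profiles = target_profiles(network, ids, steps, target_universe)
    return [pair_target_overlap(profiles[i], profiles[j]) for i, j in pairs]


def _intra_cluster_pairs(member_lists: Iterable[Sequence[str]]) -> list[Pair]:
    pairs: list[Pair] = []
    for members in member_lists:
        for a, b in itertools.combinations(sorted(members), 2):
            pairs.append((a, b))
    return pairs


def category_pairs(
    clusters: ClusterCallResult,
    network: RegulatoryNetwork,
    id_map: Mapping[str, str] | None = None,
    random_cluster_sets: Sequence | None = None,
) -> dict[str, list[Pair]]:
    """Unordered intra-cluster miRNA pairs per category.

    Homo and hetero pairs come from the observed genomic clusters; random
    pairs from the size-preserving random cluster sets (pooled across
    replicates). Members absent from the network are excluded with a logged
    count.
    """
    id_map = dict(id_map or {})
    known = set(network.mirnas)
    n_dropped = 0

    def mapped(members: Iterable[str]) -> list[str]:
        nonlocal n_dropped
        out = []
        for m in members:
            nid = id_map.get(m, m)
            if nid in known:
                out.append(nid)
            else:
                n_dropped += 1
        return out

    homo_lists, hetero_lists = [], []
    for c in clusters.clusters:
        mapped_members = mapped(c.member_ids)
        if len(mapped_members) < 2:
            continue
        (homo_lists if c.cluster_type == "homo" else hetero_lists).append(mapped_members)

    out = {
        "homo": _intra_cluster_pairs(homo_lists),
        "hetero": _intra_cluster_pairs(hetero_lists),
    }
    if random_cluster_sets is not None:
        random_lists = [
            mapped(members)
            for rep in random_cluster_sets
            for _cid, members in rep.clusters
            if len(members) >= 2
        ]
        out["random"] = _intra_cluster_pairs(
            [m for m in random_lists if len(m) >= 2]
        )
    if n_dropped:
        logger.info("category_pairs: %d cluster member(s) absent from network", n_dropped)
    return out


def to_distribution(
    overlaps: Sequence[PairOverlap], bins: int = 10
) -> tuple[np.ndarray, np.ndarray, float]:
    """Relative-frequency histogram of TO over [0, 1] plus the mean.

    Bins are right-closed — (0.0, 0.1], ..., (0.9, 1.0] with TO = 0 counted
    in the first bin — so a tail statement like "TO > 0.8" is exactly the sum
    of the last two default bins.

    Returns (relative frequencies, bin edges, mean TO).
    """
    if not overlaps:
        raise ValueError("cannot build a TO distribution from zero pairs")
    tos = np.array([o.to for o in overlaps], dtype=float)
    idx = np.clip(np.ceil(tos * bins).astype(int) - 1, 0, bins - 1)
    counts = np.bincount(idx, minlength=bins).astype(float)
    edges = np.linspace(0.0, 1.0, bins + 1)
    return counts / counts.sum(), edges, float(tos.mean())


def to_vs_steps_curve(
    pairs_by_category: Mapping[str, Sequence[Pair]],
    network: RegulatoryNetwork,
    max_steps: int = 8,
    margin: float = 0.0,
    target_universe: str = "all",
) -> tuple[list[CategoryCurve], dict[str, int | None]]:
    """Mean TO per category for step bounds 1..max_steps.

    Also reports, for each non-random category, the smallest step bound at
    which its mean TO exceeds the random category's mean by ``margin``
    (None when it never does, or when there is no random category).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    steps_axis = tuple(range(1, max_steps + 1))
    curves = []
    for category in sorted(pairs_by_category):
        pairs = list(pairs_by_category[category])
        means = []
        for k in steps_axis:
            overlaps = compute_pair_overlaps(network, pairs, k, target_universe)
            means.append(
                float(np.mean([o.to for o in overlaps])) if overlaps else float("nan")
            )
        curves.append(
            CategoryCurve(
                category=category,
                steps_axis=steps_axis,
                mean_to=tuple(means),
                n_pairs=len(pairs),
            )
        )

    crossing: dict[str, int | None] = {}
    by_name = {c.category: c for c in curves}
    random_curve = by_name.get("random")
    for c in curves:
        if c.category == "random" or random_curve is None:
            continue
        crossing[c.category] = next(
            (
                k
                for k, m, r in zip(c.steps_axis, c.mean_to, random_curve.mean_to)
                if not np.isnan(m) and m > r + margin
            ),
            None,
        )
    return curves, crossing


def pair_table(
    overlaps: Sequence[PairOverlap], category: str | None = None
) -> pd.DataFrame:
    rows = [
        {
            "mirna_i": o.mirna_i,
            "mirna_j": o.mirna_j,
            "category": category,
            "steps": o.steps,
            "l_i": o.l_i,
            "l_j": o.l_j,
            "shared": o.shared,
            "to": o.to,
        }
        for o in overlaps
    ]
    return pd.DataFrame(
        rows,
        columns=["mirna_i", "mirna_j", "category", "steps", "l_i", "l_j", "shared", "to"],
    )
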