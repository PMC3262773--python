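"""Genomic miRNA cluster calling and family-composition classification.

A miRNA cluster is a run of precursor miRNA genes on one chromosome in which
consecutive genes lie within a distance cutoff of each other (10 kb by
default, the valley of the bimodal inter-miRNA distance distribution).
Clusters are classified by family composition:

* **homo-cluster** — all members from one miRNA family (family entropy 0);
* **hetero-cluster** — members from several families (family entropy > 0).

Family entropy is the Shannon entropy of the family composition normalized by
``ln(N_fam)``, ranging 0-1.

Coordinates are held internally as 0-based half-open intervals; GFF3 input
(1-based closed) is converted on read, BED passes through.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .entropy import composition_probs, normalized_entropy
from .errors import ParseError, ValidationError

__all__ = [
    "MirnaGene",
    "MirnaCluster",
    "ClusterCallResult",
    "read_mirna_annotations",
    "read_family_table",
    "detect_clusters",
    "family_entropy",
    "classify_cluster",
    "cutoff_scan",
    "write_cluster_table",
    "write_isolated_table",
]

DEFAULT_CUTOFF_BP = 10_000


@dataclass(frozen=True)
class MirnaGene:
    """A precursor miRNA gene: 0-based half-open genomic interval plus family."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"gene {self.id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValidationError(f"gene {self.id!r}: bad strand {self.strand!r}")

    def with_family(self, family: str | None) -> "MirnaGene":
        return MirnaGene(self.id, self.chrom, self.start, self.end, self.strand, family)


@dataclass(frozen=True)
class MirnaCluster:
    """An ordered run of >=2 miRNA genes on one chromosome.

    ``family_entropy``/``n_families``/``family_probs``/``cluster_type`` are
    populated only when every member carries a family label; otherwise they
    are None and the classification operations raise.
    """

    members: tuple[MirnaGene, ...]
    chrom: str = field(init=False)
    span_bp: int = field(init=False)
    family_entropy: float | None = field(init=False)
    n_families: int | None = field(init=False)
    family_probs: dict[str, float] | None = field(init=False)
    cluster_type: str | None = field(init=False)

    def __post_init__(self) -> None:
        members = tuple(sorted(self.members, key=lambda g: (g.start, g.end, g.id)))
        if len(members) < 2:
            raise ValidationError("a cluster needs at least 2 members")
        chroms = {g.chrom for g in members}
        if len(chroms) != 1:
            raise ValidationError(f"cluster members span chromosomes {sorted(chroms)}")
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "chrom", members[0].chrom)
        object.__setattr__(
            self, "span_bp", max(g.end for g in members) - members[0].start
        )
        if all(g.family is not None for g in members):
            probs = composition_probs(g.family for g in members)
            e = normalized_entropy(probs)
            object.__setattr__(self, "family_probs", probs)
            object.__setattr__(self, "n_families", len(probs))
            object.__setattr__(self, "family_entropy", e)
            object.__setattr__(
                self, "cluster_type", "homo" if len(probs) == 1 else "hetero"
            )
        else:
            for name in ("family_probs", "n_families", "family_entropy", "cluster_type"):
                object.__setattr__(self, name, None)

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return max(g.end for g in self.members)

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(g.id for g in self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClusterCallResult:
    """Partition of an annotation set into clusters and isolated miRNAs."""

    clusters: tuple[MirnaCluster, ...]
    isolated: tuple[MirnaGene, ...]
    cutoff_bp: int
    max_span_bp: int | None = None

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.clusters) + len(self.isolated)

    def cluster_of(self) -> dict[str, int]:
        """Map miRNA id -> index of the cluster containing it."""
        return {
            g.id: i for i, c in enumerate(self.clusters) for g in c.members
        }


# ---------------------------------------------------------------------------
# IO


def read_family_table(path: str | Path) -> dict[str, str]:
    """Read a TSV with header ``mirna_id<TAB>family`` into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mirna_id", "family"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: family table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    dup = df["mirna_id"][df["mirna_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate mirna_id {dup.iloc[0]!r}")
    return dict(zip(df["mirna_id"], df["family"]))


def _parse_gff3(path: Path) -> list[MirnaGene]:
    from gffutils.feature import feature_from_line

    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 GFF3 fields, got {len(line.split(chr(9)))}"
                )
            try:
                feat = feature_from_line(line)
                start1, end1 = int(feat.start), int(feat.end)
            except (ValueError, TypeError):
                raise ParseError(f"{path}:{lineno}: malformed GFF3 record") from None
            name = feat.attributes.get("Name") or feat.attributes.get("ID")
            if not name:
                raise ParseError(f"{path}:{lineno}: record has neither Name nor ID attribute")
            genes.append(
                MirnaGene(
                    id=name[0],
                    chrom=feat.seqid,
                    start=start1 - 1,  # GFF3 is 1-based closed
                    end=end1,
                    strand=feat.strand if feat.strand in ("+", "-") else "unknown",
                )
            )
    return genes


def _parse_bed(path: Path) -> list[MirnaGene]:
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}:{lineno}: BED needs >=4 columns (chrom,start,end,name)"
                )
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "unknown"
            genes.append(MirnaGene(id=name, chrom=chrom, start=start, end=end, strand=strand))
    return genes


def read_mirna_annotations(
    path: str | Path,
    family_table: str | Path | None = None,
    fmt: str | None = None,
) -> list[MirnaGene]:
    """Read precursor miRNA genes from GFF3 or BED, optionally attaching families.

    Format is taken from ``fmt`` ("gff3" or "bed") or guessed from the file
    extension. GFF3 coordinates (1-based closed) are converted to the internal
    0-based half-open convention; BED is already in it. Genes missing from the
    family table keep ``family=None``.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "bed" if suffix == ".bed" else "gff3"
    if fmt == "gff3":
        genes = _parse_gff3(path)
    elif fmt == "bed":
        genes = _parse_bed(path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")

    seen: set[str] = set()
    for g in genes:
        if g.id in seen:
            raise ValidationError(f"{path}: duplicate miRNA id {g.id!r}")
        seen.add(g.id)

    if family_table is not None:
        families = read_family_table(family_table)
        genes = [g.with_family(families.get(g.id)) for g in genes]
    return genes


# ---------------------------------------------------------------------------
# cluster calling


def _gap(prev: MirnaGene, nxt: MirnaGene) -> int:
    """Gap between consecutive sorted intervals, clamped at 0 for overlaps."""
    return max(0, nxt.start - prev.end)


def _split_by_span(chain: list[MirnaGene], max_span_bp: int) -> list[list[MirnaGene]]:
    """Greedy left-to-right split so no segment's genomic span exceeds the limit."""
    segments: list[list[MirnaGene]] = []
    current: list[MirnaGene] = []
    seg_start = 0
    for g in chain:
        if not current:
            current, seg_start = [g], g.start
        elif max(g.end, max(x.end for x in current)) - seg_start <= max_span_bp:
            current.append(g)
        else:
            segments.append(current)
            current, seg_start = [g], g.start
    if current:
        segments.append(current)
    return segments


def detect_clusters(
    genes: Iterable[MirnaGene],
    cutoff_bp: int = DEFAULT_CUTOFF_BP,
    max_span_bp: int | None = None,
    same_strand_only: bool = False,
) -> ClusterCallResult:
    """Chain miRNA genes into genomic clusters.

    On each chromosome, genes sorted by start are chained transitively:
    consecutive genes whose gap (next start minus previous end, clamped at 0)
    is at most ``cutoff_bp`` fall in one chain. Chains of one gene are
    isolated miRNAs. With ``max_span_bp`` set, chains are greedily split
    left-to-right so no cluster exceeds that genomic span (the short-transcript
    constraint on intergenic clusters).

    The output partitions the input: every gene lands in exactly one cluster
    or in the isolated list. Results do not depend on the input order.
    """
    if cutoff_bp <= 0:
        raise ValueError("cutoff_bp must be positive")
    genes = list(genes)
    seen: set[str] = set()
    for g in genes:
        if g.id in seen:
            raise ValidationError(f"duplicate miRNA id {g.id!r}")
        seen.add(g.id)

    def group_key(g: MirnaGene):
        return (g.chrom, g.strand) if same_strand_only else (g.chrom,)

    clusters: list[MirnaCluster] = []
    isolated: list[MirnaGene] = []
    for _key, group in itertools.groupby(
        sorted(genes, key=lambda g: (group_key(g), g.start, g.end, g.id)), key=group_key
    ):
        chrom_genes = list(group)
        chain: list[MirnaGene] = []
        chains: list[list[MirnaGene]] = []
        for g in chrom_genes:
            if chain and _gap(chain[-1], g) <= cutoff_bp:
                chain.append(g)
            else:
                if chain:
                    chains.append(chain)
                chain = [g]
        if chain:
            chains.append(chain)
        for ch in chains:
            segments = (
                _split_by_span(ch, max_span_bp) if max_span_bp is not None else [ch]
            )
            for seg in segments:
                if len(seg) >= 2:
                    clusters.append(MirnaCluster(tuple(seg)))
                else:
                    isolated.extend(seg)

    clusters.sort(key=lambda c: (c.chrom, c.start, c.member_ids))
    isolated.sort(key=lambda g: (g.chrom, g.start, g.id))
    return ClusterCallResult(
        clusters=tuple(clusters),
        isolated=tuple(isolated),
        cutoff_bp=cutoff_bp,
        max_span_bp=max_span_bp,
    )


def family_entropy(cluster: MirnaCluster) -> float:
    """Normalized family entropy E_fam of a cluster, in [0, 1].

    E_fam = -(1/ln N_fam) * sum_i p_i ln p_i over the family composition,
    with E_fam = 0 for a single family (the limit; 1/ln 1 is never evaluated).
    """
    for g in cluster.members:
        if g.family is None:
            raise ValidationError(f"member {g.id!r} has no family label")
    assert cluster.family_entropy is not None
    return cluster.family_entropy


def classify_cluster(cluster: MirnaCluster) -> str:
    """'homo' if every member shares one family, else 'hetero'."""
    for g in cluster.members:
        if g.family is None:
            raise ValidationError(f"member {g.id!r} has no family label")
    assert cluster.cluster_type is not None
    return cluster.cluster_type


def cutoff_scan(
    genes: Sequence[MirnaGene], cutoffs_bp: Sequence[int]
) -> pd.DataFrame:
    """Cluster/isolated counts for each distance cutoff (sensitivity scan)."""
    rows = []
    for cutoff in cutoffs_bp:
        res = detect_clusters(genes, cutoff_bp=cutoff)
        rows.append(
            {
                "cutoff_bp": cutoff,
                "n_clusters": len(res.clusters),
                "n_isolated": len(res.isolated),
            }
        )
    return pd.DataFrame(rows, columns=["cutoff_bp", "n_clusters", "n_isolated"])


# ---------------------------------------------------------------------------
# tabular output


def cluster_table(result: ClusterCallResult) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(result.clusters):
        rows.append(
            {
                "cluster_id": f"cluster_{i:03d}",
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "n_members": len(c),
                "member_ids": ";".join(c.member_ids),
                "n_families": c.n_families,
                "family_entropy": c.family_entropy,
                "cluster_type": c.cluster_type,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "chrom", "start", "end", "n_members",
            "member_ids", "n_families", "family_entropy", "cluster_type",
        ],
    )


def write_cluster_table(result: ClusterCallResult, path: str | Path) -> Path:
    path = Path(path)
    cluster_table(result).to_csv(path, sep="\t", index=False)
    return path


def write_isolated_table(result: ClusterCallResult, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {"mirna_id": g.id, "chrom": g.chrom, "start": g.start,
             "end": g.end, "strand": g.strand, "family": g.family}
            for g in result.isolated
        ],
        columns=["mirna_id", "chrom", "start", "end", "strand", "family"],
    )
    df.to_csv(path, sep="\t", index=False)
    return path
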