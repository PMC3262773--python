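"""Genomic cluster calling, family entropy and homo/hetero classification."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from mircoord.clustering import (
    MirnaCluster,
    MirnaGene,
    classify_cluster,
    cutoff_scan,
    detect_clusters,
    family_entropy,
    read_mirna_annotations,
)
from mircoord.entropy import normalized_entropy
from mircoord.errors import ParseError, ValidationError


def gene(i, start, chrom="chr1", length=80, family=None, strand="+"):
    return MirnaGene(
        id=f"mir-{i}", chrom=chrom, start=start, end=start + length,
        strand=strand, family=family,
    )


# ---------------------------------------------------------------------------
# annotation IO


def test_gff3_coordinates_converted_to_zero_based(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tmiRNA_primary_transcript\t100\t180\t.\t+\t.\tID=MI01;Name=hsa-mir-1\n"
    )
    (g,) = read_mirna_annotations(p)
    assert (g.id, g.chrom, g.start, g.end, g.strand) == ("hsa-mir-1", "chr1", 99, 180, "+")


def test_bed_coordinates_pass_through(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t99\t180\thsa-mir-1\t0\t-\n")
    (g,) = read_mirna_annotations(p)
    assert (g.start, g.end, g.strand) == (99, 180, "-")


def test_duplicate_id_rejected(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t0\t80\tm1\nchr1\t500\t580\tm1\n")
    with pytest.raises(ValidationError, match="m1"):
        read_mirna_annotations(p)


def test_malformed_line_reports_line_number(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text("chr1\tsrc\tmiRNA\t1\t80\t.\t+\t.\tID=a\nchr1\tbroken\n")
    with pytest.raises(ParseError, match=":2"):
        read_mirna_annotations(p)


def test_family_table_attached_and_missing_left_none(tmp_path):
    ann = tmp_path / "a.bed"
    ann.write_text("chr1\t0\t80\tm1\nchr1\t500\t580\tm2\n")
    fam = tmp_path / "fam.tsv"
    fam.write_text("mirna_id\tfamily\nm1\tfamA\n")
    g1, g2 = read_mirna_annotations(ann, family_table=fam)
    assert g1.family == "famA" and g2.family is None


# ---------------------------------------------------------------------------
# cluster calling


def test_ten_kb_rule_chains_near_genes_and_isolates_far_ones():
    res = detect_clusters([gene(1, 0), gene(2, 5000), gene(3, 30000)])
    assert len(res.clusters) == 1
    assert res.clusters[0].member_ids == ("mir-1", "mir-2")
    assert [g.id for g in res.isolated] == ["mir-3"]


def test_transitive_chaining_joins_consecutive_gaps():
    res = detect_clusters([gene(1, 0), gene(2, 8000), gene(3, 16000)])
    assert len(res.clusters) == 1 and len(res.clusters[0]) == 3


def test_clusters_never_span_chromosomes():
    res = detect_clusters([gene(1, 0, "chr1"), gene(2, 100, "chr2")])
    assert not res.clusters and len(res.isolated) == 2


def test_overlapping_genes_always_cluster():
    res = detect_clusters([gene(1, 0, length=500), gene(2, 100)])
    assert len(res.clusters) == 1


def test_empty_input_gives_empty_result():
    res = detect_clusters([])
    assert res.clusters == () and res.isolated == ()


def test_same_strand_option_splits_antisense_neighbors():
    genes = [gene(1, 0, strand="+"), gene(2, 1000, strand="-")]
    assert len(detect_clusters(genes).clusters) == 1
    assert len(detect_clusters(genes, same_strand_only=True).clusters) == 0


def test_max_span_constraint_splits_long_chains():
    # three genes chained at 3 kb gaps; span limit forces a left-to-right split
    genes = [gene(1, 0), gene(2, 3080), gene(3, 6160)]
    res = detect_clusters(genes, max_span_bp=4000)
    assert [c.member_ids for c in res.clusters] == [("mir-1", "mir-2")]
    assert [g.id for g in res.isolated] == ["mir-3"]
    for c in res.clusters:
        assert c.span_bp <= 4000


@st.composite
def gene_sets(draw):
    n = draw(st.integers(1, 25))
    starts = draw(
        st.lists(st.integers(0, 200_000), min_size=n, max_size=n, unique=True)
    )
    chroms = draw(st.lists(st.sampled_from(["chr1", "chr2"]), min_size=n, max_size=n))
    return [gene(i, s, c) for i, (s, c) in enumerate(zip(starts, chroms))]


@settings(max_examples=60, derandomize=True)
@given(gene_sets(), st.integers(1, 3))
def test_partition_order_invariance_and_cutoff_monotonicity(genes, scale):
    cutoff = 5000 * scale
    res = detect_clusters(genes, cutoff_bp=cutoff)
    ids_in = {g.id for g in genes}
    ids_out = {g.id for c in res.clusters for g in c.members} | {
        g.id for g in res.isolated
    }
    assert ids_in == ids_out
    assert res.n_genes == len(genes)

    shuffled = list(reversed(genes))
    res2 = detect_clusters(shuffled, cutoff_bp=cutoff)
    assert [c.member_ids for c in res2.clusters] == [c.member_ids for c in res.clusters]

    coarse = detect_clusters(genes, cutoff_bp=cutoff * 2)
    coarse_sets = [set(c.member_ids) for c in coarse.clusters] + [
        {g.id} for g in coarse.isolated
    ]
    for c in res.clusters:
        assert sum(set(c.member_ids) <= s for s in coarse_sets) == 1


# ---------------------------------------------------------------------------
# family entropy / classification


def cluster_with_families(families):
    genes = [
        gene(i, i * 1000, family=f) for i, f in enumerate(families)
    ]
    return MirnaCluster(tuple(genes))


@pytest.mark.parametrize(
    "families,expected",
    [
        (("A", "A", "A"), 0.0),
        (("A", "B"), 1.0),
        (("A", "A", "B"), 0.9182958340544896),
        (("A", "B", "C", "D"), 1.0),
    ],
)
def test_family_entropy_matches_hand_values(families, expected):
    assert family_entropy(cluster_with_families(families)) == pytest.approx(
        expected, abs=1e-12
    )


def test_missing_family_label_raises_with_member_name():
    c = MirnaCluster((gene(0, 0, family="A"), gene(1, 1000, family=None)))
    with pytest.raises(ValidationError, match="mir-1"):
        family_entropy(c)
    with pytest.raises(ValidationError, match="mir-1"):
        classify_cluster(c)


@pytest.mark.parametrize(
    "families,expected",
    [(("A", "A", "A"), "homo"), (("A", "B"), "hetero"), (("A", "A", "B"), "hetero")],
)
def test_classification_follows_family_uniformity(families, expected):
    c = cluster_with_families(families)
    assert classify_cluster(c) == expected
    assert (classify_cluster(c) == "homo") == (family_entropy(c) == 0.0)


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.sampled_from("ABCDEF"), min_size=2, max_size=12))
def test_entropy_agrees_with_brute_force_formula(families):
    """-(1/ln N) sum p ln p recomputed independently, to 1e-12."""
    value = family_entropy(cluster_with_families(families))
    counts = {f: families.count(f) for f in set(families)}
    n_fam = len(counts)
    if n_fam == 1:
        brute = 0.0
    else:
        brute = -sum(
            (c / len(families)) * math.log(c / len(families)) for c in counts.values()
        ) / math.log(n_fam)
    assert value == pytest.approx(brute, abs=1e-12)
    assert 0.0 <= value <= 1.0
    assert (value == 0.0) == (n_fam == 1)
    if n_fam == len(families):
        assert value == pytest.approx(1.0, abs=1e-12)


def test_entropy_helper_rejects_empty_composition():
    with pytest.raises(ValueError):
        normalized_entropy([])


# ---------------------------------------------------------------------------
# cutoff scan


def test_cutoff_scan_reruns_detection_per_cutoff():
    genes = [gene(1, 0), gene(2, 5000), gene(3, 30000)]
    df = cutoff_scan(genes, [4000, 6000])
    assert list(df["n_clusters"]) == [0, 1]
    assert list(df["n_isolated"]) == [3, 1]


def test_cutoff_scan_single_gene_and_repeat_cutoffs():
    df = cutoff_scan([gene(1, 0)], [10_000, 10_000])
    assert list(df["n_clusters"]) == [0, 0]
    assert list(df["n_isolated"]) == [1, 1]
    assert df.iloc[0].equals(df.iloc[1])
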