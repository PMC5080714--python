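"""Repeat parsing, distance clustering and orientation classification."""

import math
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from aluome import repeat_catalog as rc
from aluome import synthetic_data as syn
from conftest import brute_force_clusters, make_repeat


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

RMSK_HEADER = "\t".join(rc.RMSK_COLUMNS)


def _write(tmp_path, text, name="rmsk.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_read_repeats_filters_family_and_sorts(tmp_path):
    rows = [
        "chr1\t5000\t5300\t+\tAluSp\tSINE\tAlu",
        "chr1\t100\t400\t-\tMIRb\tSINE\tMIR",
        "chr1\t1000\t1300\t-\tAluY\tSINE\tAlu",
    ]
    path = _write(tmp_path, RMSK_HEADER + "\n" + "\n".join(rows) + "\n")
    feats = rc.read_repeats(path)
    assert [f.name for f in feats] == ["AluY", "AluSp"]  # sorted by coordinate
    assert all(f.family == "Alu" for f in feats)


def test_read_repeats_empty_file(tmp_path):
    path = _write(tmp_path, RMSK_HEADER + "\n")
    assert rc.read_repeats(path) == []


def test_read_repeats_malformed_row_names_line(tmp_path):
    path = _write(
        tmp_path,
        RMSK_HEADER + "\nchr1\t100\t400\t+\tAluSp\tSINE\tAlu\n"
        "chr1\t900\t500\t+\tAluY\tSINE\tAlu\n",
    )
    with pytest.raises(rc.ParseError, match=":3:"):
        rc.read_repeats(path)


def test_read_repeats_unknown_dialect(tmp_path):
    path = _write(tmp_path, RMSK_HEADER + "\n")
    with pytest.raises(ValueError, match="dialect"):
        rc.read_repeats(path, dialect="gff")


def test_read_repeats_bed6_roundtrip(tmp_path):
    feats = [make_repeat("chr1", 100, 400, "+"), make_repeat("chr2", 0, 300, "-")]
    path = tmp_path / "alus.bed"
    rc.write_repeats_bed(feats, path)
    back = rc.read_repeats(path, dialect="bed6")
    assert back == feats


# ---------------------------------------------------------------------------
# pair orientation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "strands, expected",
    [
        (("+", "+"), rc.DSINE),
        (("-", "-"), rc.DSINE),
        (("+", "-"), rc.TISINE),  # 3' ends face each other (tail-to-tail)
        (("-", "+"), rc.HISINE),  # 5' ends face each other (head-to-head)
    ],
)
def test_classify_pair(strands, expected):
    left = make_repeat("chr1", 100, 400, strands[0])
    right = make_repeat("chr1", 500, 800, strands[1])
    assert rc.classify_pair(left, right) == expected
    assert rc.AluPair(left, right).orientation == expected


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_single_alu_is_one_singleton_cluster():
    clusters = rc.cluster_alus([make_repeat("chr1", 100, 400, "+")])
    assert [c.size for c in clusters] == [1]
    assert clusters[0].configuration() == rc.SSINE


def test_cluster_threshold_splits_at_gap():
    feats = [
        make_repeat("chr1", 0, 300, "+"),
        make_repeat("chr1", 400, 700, "+"),     # gap 100 -> joined
        make_repeat("chr1", 1100, 1400, "+"),   # gap 400 -> split
    ]
    clusters = rc.cluster_alus(feats, rc.ClusterParams(max_gap=300))
    assert sorted(c.size for c in clusters) == [1, 2]


def test_gap_exactly_at_threshold_joins():
    feats = [make_repeat("chr1", 0, 300, "+"), make_repeat("chr1", 600, 900, "-")]
    clusters = rc.cluster_alus(feats, rc.ClusterParams(max_gap=300))
    assert [c.size for c in clusters] == [2]


def test_overlapping_repeats_are_joined():
    feats = [make_repeat("chr1", 0, 300, "+"), make_repeat("chr1", 200, 500, "-")]
    clusters = rc.cluster_alus(feats)
    assert [c.size for c in clusters] == [2]


def test_chromosomes_never_share_a_cluster():
    feats = [make_repeat("chr1", 0, 300, "+"), make_repeat("chr2", 0, 300, "+")]
    assert [c.size for c in rc.cluster_alus(feats)] == [1, 1]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["chr1", "chr2"]),
            st.integers(min_value=0, max_value=5000),
            st.integers(min_value=10, max_value=400),
            st.sampled_from(["+", "-"]),
        ),
        max_size=50,
    )
)
def test_clustering_matches_transitive_closure_oracle(raw):
    feats = sorted(
        (make_repeat(c, s, s + ln, strand) for c, s, ln, strand in raw),
        key=lambda f: (f.chrom, f.start, f.end),
    )
    clusters = rc.cluster_alus(feats, rc.ClusterParams(max_gap=300))
    got = [list(c.members) for c in clusters]
    expected = brute_force_clusters(feats, 300)
    assert got == expected
    # partition-of-elements invariant
    assert sum(c.size for c in clusters) == len(feats)


def test_fraction_clustered_monotone_in_max_gap():
    params = syn.SimParams(seed=5)
    rmsk, _ = syn.simulate_repeat_annotation(params)
    feats = syn.repeats_from_frame(rmsk)
    fractions = [
        rc.summarize_catalog(rc.cluster_alus(feats, rc.ClusterParams(g))).fraction_clustered
        for g in (0, 50, 150, 300, 600, 1200)
    ]
    assert fractions == sorted(fractions)


# ---------------------------------------------------------------------------
# catalog summary
# ---------------------------------------------------------------------------

def test_isolated_alus_summary():
    feats = [make_repeat("chr1", i * 10_000, i * 10_000 + 300, "+") for i in range(10)]
    s = rc.summarize_catalog(rc.cluster_alus(feats))
    assert s.fraction_single == 1.0
    assert s.fraction_in_pairs == 0.0


def test_planted_fraction_arithmetic():
    params = syn.SimParams(
        seed=11,
        n_chromosomes=3,
        planted_counts={rc.SSINE: 60, rc.DSINE: 13, rc.TISINE: 4, rc.HISINE: 3},
    )
    rmsk, _ = syn.simulate_repeat_annotation(params)
    s = rc.summarize_catalog(rc.cluster_alus(syn.repeats_from_frame(rmsk)))
    assert s.n_alus == 100
    assert s.fraction_dSINE == 26 / 100
    assert s.fraction_iSINE == 14 / 100
    assert s.fraction_in_pairs == 40 / 100
    # internal consistency invariants
    assert s.fraction_single + s.fraction_clustered == pytest.approx(1.0)
    assert s.fraction_hiSINE + s.fraction_tiSINE == pytest.approx(s.fraction_iSINE)


def test_median_gap_and_fraction_within():
    feats = [
        make_repeat("chr1", 0, 300, "+"),
        make_repeat("chr1", 310, 610, "+"),     # gap 10
        make_repeat("chr1", 1610, 1910, "+"),   # gap 1000
    ]
    s = rc.summarize_catalog(rc.cluster_alus(feats, rc.ClusterParams(max_gap=0)))
    assert s.median_neighbor_gap == 505
    assert s.fraction_within_median == pytest.approx(2 / 3)


def test_within_median_gap_counting_mode():
    feats = [
        make_repeat("chr1", 0, 300, "+"),
        make_repeat("chr1", 310, 610, "+"),
        make_repeat("chr1", 1610, 1910, "+"),
    ]
    s = rc.summarize_catalog(
        rc.cluster_alus(feats, rc.ClusterParams(max_gap=0)), within_stat="gaps"
    )
    assert s.fraction_within_median == pytest.approx(1 / 2)


def test_empty_catalog_is_undefined_not_crash():
    s = rc.summarize_catalog([])
    assert s.n_alus == 0
    assert math.isnan(s.fraction_single)
    assert math.isnan(s.median_neighbor_gap)


def test_strand_flip_swaps_head_tail_and_mirror_flip_is_identity():
    """Flipping every strand swaps hiSINE<->tiSINE; flipping strands AND
    mirroring coordinates is the reverse-complement view of the genome and
    preserves every orientation class."""
    params = syn.SimParams(
        seed=23, planted_counts={rc.SSINE: 10, rc.DSINE: 6, rc.HISINE: 5,
                                 rc.TISINE: 2},
    )
    rmsk, _ = syn.simulate_repeat_annotation(params)
    feats = syn.repeats_from_frame(rmsk)
    L = params.chrom_length

    def flip(f):
        return make_repeat(f.chrom, f.start, f.end,
                           "-" if f.strand == "+" else "+", f.name, f.family)

    def mirror(f):
        return make_repeat(f.chrom, L - f.end, L - f.start, f.strand,
                           f.name, f.family)

    s0 = rc.summarize_catalog(rc.cluster_alus(feats))
    assert (s0.fraction_hiSINE, s0.fraction_tiSINE) == (10 / 36, 4 / 36)

    flipped = sorted(map(flip, feats), key=lambda f: (f.chrom, f.start, f.end))
    s1 = rc.summarize_catalog(rc.cluster_alus(flipped))
    assert (s1.fraction_hiSINE, s1.fraction_tiSINE) == \
        (s0.fraction_tiSINE, s0.fraction_hiSINE)
    assert s1.fraction_dSINE == s0.fraction_dSINE
    assert s1.fraction_single == s0.fraction_single
    assert s1.median_neighbor_gap == s0.median_neighbor_gap

    revcomp = sorted((mirror(flip(f)) for f in feats),
                     key=lambda f: (f.chrom, f.start, f.end))
    s2 = rc.summarize_catalog(rc.cluster_alus(revcomp))
    assert s2.to_dict() == s0.to_dict()


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def test_stratify_by_region_midpoint_assignment():
    from aluome import genome_partition as gp

    params = syn.SimParams(seed=31, n_genes=6)
    genes, sizes = syn.simulate_gene_annotation(params)
    pm = gp.project_partitions(genes, sizes)
    rmsk, truth = syn.simulate_repeat_annotation(
        params,
        partition=pm,
        placement_fractions={"genic": 0.5, "intergenic": 0.5},
    )
    clusters = rc.cluster_alus(syn.repeats_from_frame(rmsk))
    strata = rc.stratify_by_region(clusters, pm)
    # every cluster lands in exactly one stratum
    assert strata["genic"].n_alus + strata["intergenic"].n_alus == len(rmsk)
    # per-unit truth: compare against label at each planted unit's midpoint
    expected = Counter()
    for uid, unit in truth.groupby("unit_id"):
        mid = (unit["start"].min() + unit["end"].max()) // 2
        expected[pm.label_at(unit["chrom"].iloc[0], mid, level=1)] += len(unit)
    assert strata["genic"].n_alus == expected["genic"]
    assert strata["intergenic"].n_alus == expected["intergenic"]


def test_stratify_all_genic_leaves_intergenic_empty():
    from aluome import genome_partition as gp

    params = syn.SimParams(seed=37, n_genes=4)
    genes, sizes = syn.simulate_gene_annotation(params)
    pm = gp.project_partitions(genes, sizes)
    g = genes[1]
    s = g.span[0] + 10
    clusters = rc.cluster_alus([make_repeat(g.chrom, s, s + 300, "+")])
    strata = rc.stratify_by_region(clusters, pm)
    assert strata["genic"].n_alus == 1
    assert strata["intergenic"].n_alus == 0
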