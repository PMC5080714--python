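"""GTF reading, hierarchical partition projection and Aluome coverage."""

import numpy as np
import pytest

from aluome import genome_partition as gp
from aluome import synthetic_data as syn
from aluome.repeat_catalog import ParseError
from conftest import make_repeat, per_base_labels

GTF_LINE = (
    "{chrom}\tsrc\t{feat}\t{start}\t{end}\t.\t{strand}\t.\t"
    'gene_id "{gid}"; transcript_id "{tid}"; gene_type "{gtype}";'
)


def write_gtf(tmp_path, lines, name="test.gtf"):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


def simple_gene_lines(gid="G1", gtype="protein_coding", chrom="chr1", strand="+"):
    """Two-exon gene, 1-based inclusive: exons [101,200],[301,400]; CDS [151,350]."""
    tid = gid + ".1"
    mk = lambda feat, s, e: GTF_LINE.format(
        chrom=chrom, feat=feat, start=s, end=e, strand=strand,
        gid=gid, tid=tid, gtype=gtype,
    )
    return [
        mk("gene", 101, 400),
        mk("transcript", 101, 400),
        mk("exon", 101, 200),
        mk("exon", 301, 400),
        mk("CDS", 151, 200),
        mk("CDS", 301, 350),
    ]


# ---------------------------------------------------------------------------
# read_gtf
# ---------------------------------------------------------------------------

def test_gene_type_allow_list(tmp_path):
    lines = simple_gene_lines("G1", "miRNA") + simple_gene_lines("G2", "lincRNA")
    genes = gp.read_gtf(write_gtf(tmp_path, lines))
    assert [g.gene_id for g in genes] == ["G2"]  # lincRNA is Pol II, miRNA is not


def test_coordinates_converted_and_utrs_derived(tmp_path):
    genes = gp.read_gtf(write_gtf(tmp_path, simple_gene_lines()))
    tx = genes[0].transcripts[0]
    assert tx.exons == [(100, 200), (300, 400)]  # 0-based half-open
    assert tx.cds == [(150, 200), (300, 350)]
    assert tx.utr5 == [(100, 150)]   # plus strand: upstream of CDS
    assert tx.utr3 == [(350, 400)]


def test_utrs_derived_on_minus_strand(tmp_path):
    genes = gp.read_gtf(write_gtf(tmp_path, simple_gene_lines(strand="-")))
    tx = genes[0].transcripts[0]
    assert tx.utr5 == [(350, 400)]   # minus strand: 5' UTR is genomically right
    assert tx.utr3 == [(100, 150)]


def test_missing_attribute_raises_with_line_number(tmp_path):
    bad = 'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "G1";'
    path = write_gtf(tmp_path, simple_gene_lines() + [bad])
    with pytest.raises(ParseError, match=":7:"):
        gp.read_gtf(path)


def test_exon_outside_transcript_span_rejected(tmp_path):
    lines = simple_gene_lines()
    lines.append(
        GTF_LINE.format(chrom="chr1", feat="exon", start=901, end=1000, strand="+",
                        gid="G1", tid="G1.1", gtype="protein_coding")
    )
    with pytest.raises(ParseError, match="outside declared transcript span"):
        gp.read_gtf(write_gtf(tmp_path, lines))


def test_gtf_roundtrip_with_simulator(tmp_path):
    params = syn.SimParams(seed=3, n_genes=8)
    genes, _ = syn.simulate_gene_annotation(params)
    path = tmp_path / "sim.gtf"
    syn.write_gtf(genes, path)
    back = gp.read_gtf(path)
    assert len(back) == len(genes)
    for orig, parsed in zip(genes, back):
        for tx_o, tx_p in zip(orig.transcripts, parsed.transcripts):
            assert tx_p.exons == tx_o.exons
            assert tx_p.cds == gp.merge_intervals(tx_o.cds)
            assert tx_p.utr5 == tx_o.utr5
            assert tx_p.utr3 == tx_o.utr3


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def test_single_gene_genic_intergenic_split(tmp_path):
    lines = [
        GTF_LINE.format(chrom="chr1", feat=feat, start=101, end=200, strand="+",
                        gid="G1", tid="G1.1", gtype="protein_coding")
        for feat in ("gene", "transcript", "exon")
    ]
    genes = gp.read_gtf(write_gtf(tmp_path, lines))
    pm = gp.project_partitions(genes, {"chr1": 1000})
    assert pm.level1["genic"] == {"chr1": [(100, 200)]}
    assert pm.level1["intergenic"] == {"chr1": [(0, 100), (200, 1000)]}


def test_exon_of_one_isoform_beats_intron_of_another(tmp_path):
    params = syn.SimParams(seed=3, n_genes=4)
    genes, sizes = syn.simulate_gene_annotation(params)
    g = genes[0]  # carries the exon-skipping second isoform
    assert len(g.transcripts) == 2
    full, skipping = g.transcripts
    skipped = [iv for iv in full.exons if iv not in skipping.exons]
    assert skipped
    pm = gp.project_partitions(genes, sizes)
    mid = sum(skipped[0]) // 2
    assert pm.label_at(g.chrom, mid, level=2) == "exonic"


def test_coding_beats_utr_claims():
    """A base coding in one isoform and UTR in another is labeled coding."""
    tx_a = gp.TranscriptModel("T1", "chr1", "+", exons=[(0, 300)],
                              cds=[(0, 300)], utr5=[], utr3=[])
    tx_b = gp.TranscriptModel("T2", "chr1", "+", exons=[(0, 300)],
                              cds=[(0, 100)], utr5=[], utr3=[(100, 300)])
    gene = gp.GeneModel("G1", "protein_coding", "chr1", "+", [tx_a, tx_b])
    pm = gp.project_partitions([gene], {"chr1": 400})
    assert pm.label_at("chr1", 200, level=3) == "coding"
    # with reversed precedence the UTR claim wins instead
    pm2 = gp.project_partitions(
        [gene], {"chr1": 400},
        exon_precedence=("utr3", "utr5", "coding", "noncoding"),
    )
    assert pm2.label_at("chr1", 200, level=3) == "utr3"


def test_gene_past_chromosome_end_is_clipped():
    tx = gp.TranscriptModel("T1", "chr1", "+", exons=[(500, 1500)], cds=[],
                            utr5=[], utr3=[])
    gene = gp.GeneModel("G1", "protein_coding", "chr1", "+", [tx])
    pm = gp.project_partitions([gene], {"chr1": 1000})
    assert pm.level1["genic"] == {"chr1": [(500, 1000)]}


def test_partition_conservation_and_nesting():
    params = syn.SimParams(seed=17, n_genes=10)
    genes, sizes = syn.simulate_gene_annotation(params)
    pm = gp.project_partitions(genes, sizes)

    def level_nt(level):
        return {lab: gp._dict_length(ivd) for lab, ivd in pm.labels(level).items()}

    l1, l2, l3 = level_nt(1), level_nt(2), level_nt(3)
    assert sum(l1.values()) == sum(sizes.values())
    assert l2["exonic"] + l2["intronic"] == l1["genic"]
    assert sum(l3.values()) == l2["exonic"]


def test_partition_matches_per_base_oracle():
    """Interval projection equals per-nucleotide labeling on 10-kb chromosomes."""
    params = syn.SimParams(seed=29, n_chromosomes=2, chrom_length=10_000,
                           n_genes=2, exons_per_gene=(2, 3),
                           utr3_length=(400, 600))
    genes, sizes = syn.simulate_gene_annotation(params)
    pm = gp.project_partitions(genes, sizes)
    oracle = per_base_labels(genes, sizes)
    for chrom, (l1, l2, l3) in oracle.items():
        for level, arr in ((1, l1), (2, l2), (3, l3)):
            for label, ivd in pm.labels(level).items():
                mask = np.zeros(sizes[chrom], dtype=bool)
                for s, e in ivd.get(chrom, []):
                    mask[s:e] = True
                assert (arr == label).sum() == mask.sum()
                assert np.array_equal(np.nonzero(arr == label)[0], np.nonzero(mask)[0])


# ---------------------------------------------------------------------------
# Aluome coverage
# ---------------------------------------------------------------------------

def test_fully_intergenic_alu():
    pm = gp.project_partitions([], {"chr1": 10_000})
    cov = gp.aluome_coverage([make_repeat("chr1", 1000, 1300, "+")], pm)
    row = cov[(cov.level == 1) & (cov.label == "intergenic")].iloc[0]
    assert row.aluome_fraction == 1.0
    assert row.aluome_nt == 300


def test_proportional_coverage_gives_unit_enrichment():
    """Alu nucleotides spread proportionally to label sizes -> enrichment 1."""
    tx = gp.TranscriptModel("T1", "chr1", "+", exons=[(0, 4000)],
                            cds=[(0, 4000)], utr5=[], utr3=[])
    gene = gp.GeneModel("G1", "protein_coding", "chr1", "+", [tx])
    pm = gp.project_partitions([gene], {"chr1": 10_000})
    # one Alu covering 10% of genic and one covering 10% of intergenic territory
    alus = [make_repeat("chr1", 0, 400, "+"), make_repeat("chr1", 4000, 4600, "+")]
    cov = gp.aluome_coverage(alus, pm)
    l1 = cov[cov.level == 1].set_index("label")
    assert l1.loc["genic", "enrichment"] == pytest.approx(1.0)
    assert l1.loc["intergenic", "enrichment"] == pytest.approx(1.0)


def test_planted_intronic_share_recovered_exactly():
    """70% of genic Alu nucleotides planted in introns -> intronic fraction 0.70."""
    params = syn.SimParams(seed=41, n_genes=12)
    genes, sizes = syn.simulate_gene_annotation(params)
    pm = gp.project_partitions(genes, sizes)
    alus = []
    n_intron, n_exon = 7, 3
    placed_i = placed_e = 0
    for g in genes:
        tx = g.transcripts[0]
        introns = gp.subtract_intervals([tx.span], tx.exons)
        if placed_i < n_intron and introns and introns[0][1] - introns[0][0] >= 340:
            s = introns[0][0] + 20
            alus.append(make_repeat(g.chrom, s, s + 300, "+"))
            placed_i += 1
        elif placed_e < n_exon:
            us, ue = tx.utr3[0]
            alus.append(make_repeat(g.chrom, us + 20, us + 320, "+"))
            placed_e += 1
    assert placed_i == n_intron and placed_e == n_exon
    cov = gp.aluome_coverage(alus, pm).set_index(["level", "label"])
    assert cov.loc[(2, "intronic"), "aluome_fraction"] == pytest.approx(0.70)
    assert cov.loc[(2, "exonic"), "aluome_fraction"] == pytest.approx(0.30)


def test_coverage_fraction_conservation():
    params = syn.SimParams(seed=43)
    genes, sizes = syn.simulate_gene_annotation(params)
    pm = gp.project_partitions(genes, sizes)
    rmsk, _ = syn.simulate_repeat_annotation(
        params, partition=pm,
        placement_fractions={"intronic": 0.4, "utr3": 0.2, "intergenic": 0.4},
    )
    cov = gp.aluome_coverage(syn.repeats_from_frame(rmsk), pm)
    for level in (1, 2, 3):
        sub = cov[cov.level == level]
        assert sub.genome_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert sub.aluome_fraction.sum() == pytest.approx(1.0, abs=1e-9)


def test_alu_on_unknown_chromosome_skipped():
    pm = gp.project_partitions([], {"chr1": 1000})
    cov = gp.aluome_coverage([make_repeat("chrUn", 0, 300, "+")], pm)
    assert cov[cov.level == 1].aluome_nt.sum() == 0
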