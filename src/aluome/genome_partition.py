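"""Hierarchical genome partition and proportional "Aluome" coverage.

The genome is tiled on three nested levels, following the ENCODE-style
projection of a GENCODE annotation:

1. genomic:  genic / intergenic (a base is genic iff covered by >= 1 gene);
2. genic:    exonic / intronic  (exonic iff covered by >= 1 exon of any isoform);
3. exonic:   coding / utr5 / utr3 / noncoding, resolved across isoforms by a
             configurable precedence (default coding > utr5 > utr3 > noncoding).

The "Aluome" is the set of genomic nucleotides annotated as Alu.  For every
partition label we report the fraction of the genome and the fraction of the
Aluome it holds (within a level, each normalized to the level's parent
territory) and their ratio — the enrichment of Alu nucleotides in that label.
Strand is ignored throughout: partitions describe genomic territory.

Coordinates are 0-based half-open internally; GTF input is 1-based inclusive
and converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

from .repeat_catalog import ParseError, RepeatFeature

log = logging.getLogger(__name__)

Interval = tuple[int, int]
IntervalDict = dict[str, list[Interval]]  # chrom -> sorted disjoint intervals

#: Pol II gene types retained by default (GENCODE v19 spellings).
POL2_GENE_TYPES = (
    "protein_coding",
    "IG_C_gene", "IG_C_pseudogene", "IG_D_gene", "IG_J_gene",
    "IG_J_pseudogene", "IG_V_gene", "IG_V_pseudogene",
    "TR_C_gene", "TR_D_gene", "TR_J_gene", "TR_J_pseudogene",
    "TR_V_gene", "TR_V_pseudogene",
    "polymorphic_pseudogene", "pseudogene", "processed_transcript",
    "lincRNA", "sense_intronic", "sense_overlapping",
    "3prime_overlapping_ncrna", "antisense",
)

DEFAULT_EXON_PRECEDENCE = ("coding", "utr5", "utr3", "noncoding")


# ---------------------------------------------------------------------------
# interval set algebra (sorted, disjoint, 0-based half-open)
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals; touching intervals ([a,b),[b,c)) are coalesced."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Set difference a \\ b; both inputs merged first."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Set intersection of two interval collections."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def _merge_dict(d: IntervalDict) -> IntervalDict:
    return {c: merge_intervals(ivs) for c, ivs in d.items()}


def _dict_length(d: IntervalDict) -> int:
    return sum(total_length(ivs) for ivs in d.values())


def _dict_op(op, a: IntervalDict, b: IntervalDict) -> IntervalDict:
    chroms = set(a) | set(b)
    out = {}
    for c in chroms:
        ivs = op(a.get(c, []), b.get(c, []))
        if ivs:
            out[c] = ivs
    return out


# ---------------------------------------------------------------------------
# gene models from GTF
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """Exon/CDS/UTR structure of one isoform, 0-based half-open, exons sorted."""

    transcript_id: str
    chrom: str
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], max(e for _, e in self.exons))

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneModel:
    """A gene with >= 1 isoform, all on one chromosome and strand."""

    gene_id: str
    gene_type: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )


def read_gtf(
    path,
    allowed_gene_types: Sequence[str] | None = POL2_GENE_TYPES,
) -> list[GeneModel]:
    """Read a GENCODE-style GTF into gene models, restricted by gene type.

    Requires ``gene_id``/``transcript_id`` attributes (``gene_type`` on
    transcript-bearing features; missing ones raise :class:`ParseError` with
    the line number).  GTF 1-based inclusive coordinates are converted to
    0-based half-open.  Explicit UTR features are split into 5'/3' by their
    position relative to the CDS and the strand; transcripts lacking UTR
    features get them derived as (exons minus CDS) on each side of the CDS
    span.  ``stop_codon`` features are folded into the CDS.
    ``allowed_gene_types=None`` keeps every gene.
    """
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, TranscriptModel] = {}
    tx_gene: dict[str, str] = {}
    tx_span: dict[str, Interval] = {}
    explicit_utr: dict[str, list[Interval]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            ftype = feat.featuretype
            if ftype not in ("gene", "transcript", "exon", "CDS", "UTR", "stop_codon"):
                continue
            attrs = feat.attributes

            def need(key: str) -> str:
                if key not in attrs:
                    raise ParseError(f"{path}:{lineno}: missing attribute {key!r}")
                return attrs[key][0]

            start, end = feat.start - 1, feat.end  # to 0-based half-open
            gid = need("gene_id")
            if ftype == "gene":
                gtype = need("gene_type")
                genes.setdefault(
                    gid, GeneModel(gid, gtype, feat.seqid, feat.strand)
                )
                continue
            tid = need("transcript_id")
            if gid not in genes:
                genes[gid] = GeneModel(gid, need("gene_type"), feat.seqid, feat.strand)
            if tid not in transcripts:
                transcripts[tid] = TranscriptModel(tid, feat.seqid, feat.strand)
                tx_gene[tid] = gid
            tx = transcripts[tid]
            if ftype == "transcript":
                tx_span[tid] = (start, end)
            elif ftype == "exon":
                tx.exons.append((start, end))
            elif ftype in ("CDS", "stop_codon"):
                tx.cds.append((start, end))
            elif ftype == "UTR":
                explicit_utr.setdefault(tid, []).append((start, end))

    for tid, tx in transcripts.items():
        if not tx.exons:
            raise ParseError(f"{path}: transcript {tid} has no exons")
        tx.exons = merge_intervals(tx.exons)
        tx.cds = merge_intervals(tx.cds)
        if tid in tx_span:
            span = tx_span[tid]
            bad = [iv for iv in tx.exons if iv[0] < span[0] or iv[1] > span[1]]
            if bad:
                raise ParseError(
                    f"{path}: transcript {tid}: exon {bad[0]} outside declared "
                    f"transcript span {span}"
                )
        utr = explicit_utr.get(tid)
        if utr is None:
            utr = subtract_intervals(tx.exons, tx.cds)
        if tx.cds:
            cds_lo = tx.cds[0][0]
            cds_hi = tx.cds[-1][1]
            left = [iv for iv in utr if iv[1] <= cds_lo]
            right = [iv for iv in utr if iv[0] >= cds_hi]
            # UTR pieces overlapping the CDS span would be annotation errors;
            # they are dropped from both sides.
            if tx.strand == "+":
                tx.utr5, tx.utr3 = left, right
            else:
                tx.utr5, tx.utr3 = right, left
        genes[tx_gene[tid]].transcripts.append(tx)

    out = [g for g in genes.values() if g.transcripts]
    if allowed_gene_types is not None:
        allowed = set(allowed_gene_types)
        out = [g for g in out if g.gene_type in allowed]
    out.sort(key=lambda g: (g.chrom, g.span))
    return out


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV (chrom, length) -> dict."""
    table = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(table["chrom"], table["size"].astype(int)))


# ---------------------------------------------------------------------------
# partition projection
# ---------------------------------------------------------------------------

@dataclass
class PartitionMap:
    """Disjoint hierarchical labeling of the genome on three levels.

    ``level1`` tiles every chromosome with genic/intergenic; ``level2`` tiles
    the genic territory with exonic/intronic; ``level3`` tiles the exonic
    territory with coding/utr5/utr3/noncoding.
    """

    chrom_sizes: dict[str, int]
    level1: dict[str, IntervalDict]
    level2: dict[str, IntervalDict]
    level3: dict[str, IntervalDict]

    LEVEL_PARENTS = {1: None, 2: "genic", 3: "exonic"}

    def labels(self, level: int) -> dict[str, IntervalDict]:
        return {1: self.level1, 2: self.level2, 3: self.level3}[level]

    def label_at(self, chrom: str, pos: int, level: int = 1) -> str | None:
        """Label covering position ``pos`` at the given level (None if uncovered)."""
        for label, ivd in self.labels(level).items():
            for s, e in ivd.get(chrom, []):
                if s <= pos < e:
                    return label
        return None

    def to_bed(self, level: int, path) -> None:
        with open(path, "w") as fh:
            rows = []
            for label, ivd in self.labels(level).items():
                for chrom, ivs in ivd.items():
                    rows.extend((chrom, s, e, label) for s, e in ivs)
            for chrom, s, e, label in sorted(rows):
                fh.write(f"{chrom}\t{s}\t{e}\t{label}\n")


def project_partitions(
    genes: Sequence[GeneModel],
    chrom_sizes: dict[str, int],
    exon_precedence: Sequence[str] = DEFAULT_EXON_PRECEDENCE,
) -> PartitionMap:
    """Project gene models onto the genome hierarchically.

    A base is genic iff covered by any gene span, exonic iff covered by any
    exon of any isoform; within the exonic territory, overlapping isoform
    claims are resolved by ``exon_precedence`` (earlier labels win).  Features
    extending past the chromosome end are clipped with a warning.
    """
    if set(exon_precedence) != set(DEFAULT_EXON_PRECEDENCE):
        raise ValueError(f"exon_precedence must permute {DEFAULT_EXON_PRECEDENCE}")

    def clipped(chrom: str, ivs: Iterable[Interval]) -> list[Interval]:
        size = chrom_sizes[chrom]
        out = []
        for s, e in ivs:
            if e > size or s < 0:
                log.warning("interval %s:%d-%d clipped to chromosome bounds", chrom, s, e)
            s, e = max(0, s), min(e, size)
            if s < e:
                out.append((s, e))
        return out

    genic: IntervalDict = {}
    exonic: IntervalDict = {}
    claims: dict[str, IntervalDict] = {"coding": {}, "utr5": {}, "utr3": {}}
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise KeyError(f"chromosome {g.chrom} missing from chrom_sizes")
        genic.setdefault(g.chrom, []).extend(clipped(g.chrom, [g.span]))
        for tx in g.transcripts:
            exonic.setdefault(g.chrom, []).extend(clipped(g.chrom, tx.exons))
            claims["coding"].setdefault(g.chrom, []).extend(clipped(g.chrom, tx.cds))
            claims["utr5"].setdefault(g.chrom, []).extend(clipped(g.chrom, tx.utr5))
            claims["utr3"].setdefault(g.chrom, []).extend(clipped(g.chrom, tx.utr3))

    genic = _merge_dict(genic)
    exonic = _dict_op(intersect_intervals, _merge_dict(exonic), genic)
    whole: IntervalDict = {c: [(0, n)] for c, n in chrom_sizes.items()}
    intergenic = _dict_op(subtract_intervals, whole, genic)
    intronic = _dict_op(subtract_intervals, genic, exonic)

    level3: dict[str, IntervalDict] = {}
    remaining = exonic
    for label in exon_precedence:
        if label == "noncoding":
            continue
        got = _dict_op(intersect_intervals, remaining, _merge_dict(claims[label]))
        level3[label] = got
        remaining = _dict_op(subtract_intervals, remaining, got)
    level3["noncoding"] = remaining

    return PartitionMap(
        chrom_sizes=dict(chrom_sizes),
        level1={"genic": genic, "intergenic": intergenic},
        level2={"exonic": exonic, "intronic": intronic},
        level3={k: level3[k] for k in ("coding", "utr5", "utr3", "noncoding")},
    )


# ---------------------------------------------------------------------------
# Aluome coverage
# ---------------------------------------------------------------------------

LEVEL_OF_LABEL = {
    "genic": 1, "intergenic": 1,
    "exonic": 2, "intronic": 2,
    "coding": 3, "utr5": 3, "utr3": 3, "noncoding": 3,
}


def aluome_coverage(
    alus: Sequence[RepeatFeature],
    partition: PartitionMap,
) -> pd.DataFrame:
    """Proportional genome/Aluome coverage and enrichment per partition label.

    The Aluome is the merged union of Alu intervals; its nucleotides are
    apportioned to labels by exact base-wise intersection (an element
    straddling a boundary contributes to both sides pro rata).  Within each
    level, ``genome_fraction`` and ``aluome_fraction`` are normalized to the
    level's parent territory (level 1: whole genome; level 2: genic; level 3:
    exonic), so each column sums to 1 per level.  ``enrichment`` is their
    ratio.  Alus on chromosomes absent from the partition are skipped with a
    warning.
    """
    aluome: IntervalDict = {}
    for f in alus:
        if f.chrom not in partition.chrom_sizes:
            log.warning("Alu on unknown chromosome %s skipped", f.chrom)
            continue
        aluome.setdefault(f.chrom, []).append((f.start, f.end))
    aluome = _merge_dict(aluome)

    rows = []
    for level in (1, 2, 3):
        labels = partition.labels(level)
        parent_genome = sum(_dict_length(ivd) for ivd in labels.values())
        parent_aluome = sum(
            _dict_length(_dict_op(intersect_intervals, aluome, ivd))
            for ivd in labels.values()
        )
        for label, ivd in labels.items():
            g_nt = _dict_length(ivd)
            a_nt = _dict_length(_dict_op(intersect_intervals, aluome, ivd))
            g_frac = g_nt / parent_genome if parent_genome else float("nan")
            a_frac = a_nt / parent_aluome if parent_aluome else float("nan")
            rows.append(
                {
                    "level": level,
                    "label": label,
                    "genome_nt": g_nt,
                    "genome_fraction": g_frac,
                    "aluome_nt": a_nt,
                    "aluome_fraction": a_frac,
                    "enrichment": a_frac / g_frac if g_frac else float("nan"),
                }
            )
    return pd.DataFrame(rows)
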