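"""Synthetic genomes, repeat annotations, gene models and FPKM tables.

Every downstream stage of the package can be exercised against data with
known planted structure: repeat configurations (singles, tandem pairs,
head-to-head / tail-to-tail inverted pairs, larger clusters) planted far
enough apart that distance clustering must recover them exactly; multi-exon
gene models with UTR/CDS structure on both strands, including an
overlapping-isoform case; Alus planted inside 3' UTR exons with a chosen
per-transcript configuration; and log-normal FPKM tables in which
inverted-configuration transcripts carry a planted multiplicative
down-shift.  Only coordinates and strands are simulated — no nucleotide
sequence — which is all the genomic and transcript pipelines consume.

All generators are deterministic given their seed, at byte level once
written by the ``write_*`` helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import repeat_catalog as rc
from . import transcript_alu as ta
from .genome_partition import (
    GeneModel,
    LEVEL_OF_LABEL,
    PartitionMap,
    TranscriptModel,
    subtract_intervals,
)
from .repeat_catalog import RMSK_COLUMNS, RepeatFeature

#: The 15 ENCODE cell lines whose RNA-seq the expression stage emulates.
ENCODE_CELL_LINES = (
    "HepG2", "HSMM", "IMR90", "MCF-7", "NHEK", "NHLF", "K562", "GM12878",
    "Huvec", "Sknsh", "A549", "AG04450", "BJ", "H1-hESC", "HeLa-S3",
)

ALU_NAMES = ("AluSp", "AluSx", "AluSg", "AluY", "AluJb")

PLANT_CLASSES = (rc.SSINE, rc.DSINE, rc.HISINE, rc.TISINE, rc.CLUSTER3PLUS)


class CapacityError(ValueError):
    """Planted features cannot fit inside the simulated chromosomes."""


@dataclass(frozen=True)
class SimParams:
    """Geometry of the simulated genome and the planted repeat configurations.

    ``gap_range_within_cluster`` bounds the gaps inside a planted cluster and
    must stay at or below ``cluster_max_gap`` (the clustering threshold,
    default 300 nt — the Alu length scale); ``gap_min_between_clusters`` must
    exceed it, so planted truth labels are unambiguous by construction.
    """

    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes: int = 12
    exons_per_gene: tuple[int, int] = (3, 6)
    utr3_length: tuple[int, int] = (1500, 2500)
    planted_counts: dict[str, int] = field(
        default_factory=lambda: {rc.SSINE: 20, rc.DSINE: 5, rc.HISINE: 3,
                                 rc.TISINE: 3, rc.CLUSTER3PLUS: 2}
    )
    gap_range_within_cluster: tuple[int, int] = (20, 300)
    gap_min_between_clusters: int = 1000
    alu_length: int = 300
    cluster_max_gap: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.gap_range_within_cluster
        if not (0 <= lo <= hi):
            raise ValueError("gap_range_within_cluster must be 0 <= lo <= hi")
        if hi > self.cluster_max_gap:
            raise ValueError(
                "gap_range_within_cluster max must be <= cluster_max_gap"
            )
        if self.gap_min_between_clusters <= self.cluster_max_gap:
            raise ValueError(
                "gap_min_between_clusters must exceed cluster_max_gap"
            )
        unknown = set(self.planted_counts) - set(PLANT_CLASSES)
        if unknown:
            raise ValueError(f"unknown planted classes {sorted(unknown)}")
        if any(v < 0 for v in self.planted_counts.values()):
            raise ValueError("planted counts must be >= 0")
        if self.n_chromosomes < 1 or self.chrom_length < 1 or self.alu_length < 1:
            raise ValueError("n_chromosomes, chrom_length, alu_length must be >= 1")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}


@dataclass(frozen=True)
class ExpressionSimParams:
    """Log-normal FPKM model with a planted shift for inverted transcripts.

    FPKM ~ exp(Normal(baseline_log_mean, baseline_log_sd)) per transcript per
    cell line; iAlu-category transcripts have their expectation (and median)
    multiplied by ``repression_factor``.  Defaults put the bulk of values
    well above the standard FPKM>=3 cutoff so filtering is not the story.
    """

    n_cell_lines: int = 15
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 0.8
    repression_factor: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.repression_factor <= 1):
            raise ValueError("repression_factor must be in (0, 1]")
        if self.n_cell_lines < 1:
            raise ValueError("n_cell_lines must be >= 1")
        if self.baseline_log_sd < 0:
            raise ValueError("baseline_log_sd must be >= 0")

    def cell_line_names(self) -> list[str]:
        if self.n_cell_lines <= len(ENCODE_CELL_LINES):
            return list(ENCODE_CELL_LINES[: self.n_cell_lines])
        return list(ENCODE_CELL_LINES) + [
            f"CL{i + 1}" for i in range(len(ENCODE_CELL_LINES), self.n_cell_lines)
        ]


# ---------------------------------------------------------------------------
# repeat annotation with planted configurations
# ---------------------------------------------------------------------------

def _unit_strands(kind: str, rng: np.random.Generator) -> list[str]:
    if kind == rc.SSINE:
        return [rng.choice(["+", "-"])]
    if kind == rc.DSINE:
        s = rng.choice(["+", "-"])
        return [s, s]
    if kind == rc.HISINE:
        return ["-", "+"]
    if kind == rc.TISINE:
        return ["+", "-"]
    if kind == rc.CLUSTER3PLUS:
        return list(rng.choice(["+", "-"], size=3))
    raise ValueError(f"unknown planted class {kind!r}")


def _unit_geometry(
    strands: Sequence[str], params: SimParams, rng: np.random.Generator
) -> list[tuple[int, int, str]]:
    """(offset_start, offset_end, strand) per element, offsets from unit start."""
    lo, hi = params.gap_range_within_cluster
    out = []
    pos = 0
    for k, strand in enumerate(strands):
        if k > 0:
            pos += int(rng.integers(lo, hi + 1))
        out.append((pos, pos + params.alu_length, strand))
        pos += params.alu_length
    return out


def simulate_repeat_annotation(
    params: SimParams,
    partition: PartitionMap | None = None,
    placement_fractions: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant the configured repeat units; returns (rmsk table, truth table).

    Without a partition, units are laid out left to right across the
    chromosomes with inter-unit gaps of at least
    ``gap_min_between_clusters``.  With a partition and
    ``placement_fractions`` (label -> probability; labels from any partition
    level, e.g. ``{"utr3": 0.3, "intronic": 0.3, "intergenic": 0.4}``), each
    unit is dropped uniformly into a random interval of a drawn label, kept
    clear of previously placed units by the same minimum separation.

    The rmsk table is in the package's rmsk dialect; the truth table has one
    row per element with its unit id and configuration class.  Identical
    parameters (including seed) give identical tables.
    """
    rng = np.random.default_rng(params.seed)
    units: list[str] = []
    for kind in PLANT_CLASSES:  # fixed order, then shuffled: deterministic
        units.extend([kind] * params.planted_counts.get(kind, 0))
    units = [units[i] for i in rng.permutation(len(units))]

    placements: list[tuple[str, int, str, list[tuple[int, int, str]]]] = []
    sep = params.gap_min_between_clusters

    if partition is None:
        chroms = params.chrom_names()
        ci = 0
        cursor = int(rng.integers(0, sep))
        for uid, kind in enumerate(units):
            geom = _unit_geometry(_unit_strands(kind, rng), params, rng)
            span = geom[-1][1]
            while cursor + span > params.chrom_length:
                ci += 1
                if ci >= len(chroms):
                    raise CapacityError(
                        f"planted units exceed {len(chroms)} chromosome(s) "
                        f"of {params.chrom_length} nt"
                    )
                cursor = int(rng.integers(0, sep))
            placements.append((chroms[ci], cursor, kind, geom))
            cursor += span + sep + int(rng.integers(0, sep))
    else:
        if not placement_fractions:
            raise ValueError("placement_fractions required with a partition")
        labels = list(placement_fractions)
        probs = np.array([placement_fractions[k] for k in labels], dtype=float)
        if (probs < 0).any() or probs.sum() <= 0:
            raise ValueError("placement fractions must be non-negative, sum > 0")
        probs = probs / probs.sum()
        slots = {
            lab: [
                (chrom, s, e)
                for chrom, ivs in partition.labels(LEVEL_OF_LABEL[lab])[lab].items()
                for s, e in ivs
            ]
            for lab in labels
        }
        occupied: dict[str, list[tuple[int, int]]] = {}
        margin = 10
        for uid, kind in enumerate(units):
            geom = _unit_geometry(_unit_strands(kind, rng), params, rng)
            span = geom[-1][1]
            placed = False
            for _ in range(200):
                lab = labels[rng.choice(len(labels), p=probs)]
                fitting = [iv for iv in slots[lab] if iv[2] - iv[1] >= span + 2 * margin]
                if not fitting:
                    continue
                chrom, s, e = fitting[rng.integers(len(fitting))]
                start = int(rng.integers(s + margin, e - margin - span + 1))
                box = (start - sep, start + span + sep)
                if any(b0 < box[1] and box[0] < b1 for b0, b1 in occupied.get(chrom, [])):
                    continue
                occupied.setdefault(chrom, []).append(box)
                placements.append((chrom, start, kind, geom))
                placed = True
                break
            if not placed:
                raise CapacityError(
                    f"could not place unit {uid} ({kind}) inside labels {labels}"
                )

    rmsk_rows, truth_rows = [], []
    for uid, (chrom, base, kind, geom) in enumerate(placements):
        for k, (off_s, off_e, strand) in enumerate(geom):
            name = ALU_NAMES[int(rng.integers(len(ALU_NAMES)))]
            rmsk_rows.append(
                {
                    "genoName": chrom,
                    "genoStart": base + off_s,
                    "genoEnd": base + off_e,
                    "strand": strand,
                    "repName": name,
                    "repClass": "SINE",
                    "repFamily": "Alu",
                }
            )
            truth_rows.append(
                {
                    "chrom": chrom,
                    "start": base + off_s,
                    "end": base + off_e,
                    "strand": strand,
                    "unit_id": uid,
                    "config": kind,
                    "member_index": k,
                }
            )
    rmsk = pd.DataFrame(rmsk_rows, columns=RMSK_COLUMNS)
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "start", "end", "strand", "unit_id", "config", "member_index"],
    )
    order = rmsk.sort_values(["genoName", "genoStart"]).index
    return rmsk.loc[order].reset_index(drop=True), truth.loc[order].reset_index(drop=True)


def repeats_from_frame(rmsk: pd.DataFrame) -> list[RepeatFeature]:
    """rmsk-dialect DataFrame -> sorted RepeatFeature list."""
    feats = [
        RepeatFeature(
            chrom=r.genoName,
            start=int(r.genoStart),
            end=int(r.genoEnd),
            strand=r.strand,
            name=r.repName,
            family=r.repFamily,
        )
        for r in rmsk.itertuples()
    ]
    feats.sort(key=lambda f: (f.chrom, f.start, f.end))
    return feats


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def simulate_gene_annotation(
    params: SimParams,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Multi-exon genes with 5'UTR/CDS/3'UTR on alternating strands.

    Genes are laid out left to right with wide inter-gene gaps.  The first
    gene (when it has >= 3 exons) carries a second isoform that skips one
    internal exon, so one isoform's exon lies inside the other's intron —
    the case hierarchical projection must resolve.  The 3' UTR is a single
    terminal exon long enough to host planted Alu configurations.
    """
    rng = np.random.default_rng(params.seed + 1)
    chroms = params.chrom_names()
    margin = min(5_000, max(100, params.chrom_length // 20))
    gap_lo = min(3_000, max(200, params.chrom_length // 10))
    genes: list[GeneModel] = []
    ci = 0
    cursor = margin
    for gi in range(params.n_genes):
        n_exons = int(rng.integers(params.exons_per_gene[0], params.exons_per_gene[1] + 1))
        utr3_len = int(rng.integers(params.utr3_length[0], params.utr3_length[1] + 1))
        strand = "+" if gi % 2 == 0 else "-"

        # transcript-order widths: 5' exon, internal CDS exons, 3' exon
        widths = [220] + [150] * (n_exons - 2) + [100 + utr3_len]
        introns = [int(rng.integers(400, 901)) for _ in range(n_exons - 1)]
        if strand == "-":
            widths = widths[::-1]
            introns = introns[::-1]
        span = sum(widths) + sum(introns)
        if cursor + span > params.chrom_length - margin:
            ci += 1
            cursor = margin
            if ci >= len(chroms):
                raise CapacityError(
                    f"{params.n_genes} genes exceed the simulated genome"
                )
        chrom = chroms[ci]

        exons = []
        pos = cursor
        for k, w in enumerate(widths):
            exons.append((pos, pos + w))
            pos += w + (introns[k] if k < len(introns) else 0)

        # genomic-order exon composition
        if strand == "+":
            five_exon, three_exon = exons[0], exons[-1]
        else:
            five_exon, three_exon = exons[-1], exons[0]
        utr5 = [(five_exon[0], five_exon[0] + 120)] if strand == "+" else \
               [(five_exon[1] - 120, five_exon[1])]
        utr3 = [(three_exon[1] - utr3_len, three_exon[1])] if strand == "+" else \
               [(three_exon[0], three_exon[0] + utr3_len)]
        cds = subtract_intervals(exons, utr5 + utr3)

        gid = f"SIMG{gi:04d}"
        tx_a = TranscriptModel(
            transcript_id=f"{gid}.1", chrom=chrom, strand=strand,
            exons=list(exons), cds=cds, utr5=utr5, utr3=utr3,
        )
        gene = GeneModel(gid, "protein_coding", chrom, strand, [tx_a])
        if gi == 0 and n_exons >= 3:
            skip = 1 if strand == "+" else n_exons - 2  # an internal CDS exon
            exons_b = [iv for k, iv in enumerate(exons) if k != skip]
            cds_b = subtract_intervals(exons_b, utr5 + utr3)
            gene.transcripts.append(
                TranscriptModel(
                    transcript_id=f"{gid}.2", chrom=chrom, strand=strand,
                    exons=exons_b, cds=cds_b, utr5=list(utr5), utr3=list(utr3),
                )
            )
        genes.append(gene)
        cursor = pos + int(rng.integers(gap_lo, 2 * gap_lo + 1))
    return genes, params.chrom_sizes()


def genes_to_gtf(genes: Sequence[GeneModel]) -> str:
    """Render gene models as GENCODE-attribute-style GTF (1-based inclusive)."""
    lines = ["##description: synthetic annotation (aluome.synthetic_data)"]

    def attr(gid: str, tid: str | None, gtype: str) -> str:
        parts = [f'gene_id "{gid}";']
        if tid:
            parts.append(f'transcript_id "{tid}";')
        parts.append(f'gene_type "{gtype}";')
        return " ".join(parts)

    def row(chrom, feat, s, e, strand, attrs):
        return f"{chrom}\taluome_sim\t{feat}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"

    for g in genes:
        gs, ge = g.span
        lines.append(row(g.chrom, "gene", gs, ge, g.strand, attr(g.gene_id, None, g.gene_type)))
        for tx in g.transcripts:
            a = attr(g.gene_id, tx.transcript_id, g.gene_type)
            ts, te = tx.span
            lines.append(row(g.chrom, "transcript", ts, te, g.strand, a))
            for s, e in tx.exons:
                lines.append(row(g.chrom, "exon", s, e, g.strand, a))
            for s, e in tx.cds:
                lines.append(row(g.chrom, "CDS", s, e, g.strand, a))
            for s, e in tx.utr5 + tx.utr3:
                lines.append(row(g.chrom, "UTR", s, e, g.strand, a))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Alus planted inside 3' UTR exons, by transcript configuration
# ---------------------------------------------------------------------------

#: Transcript-order relative orientations planted for each requested category
#: (S = sense, A = antisense).  "iAlu" is the mixed inverted case.
CATEGORY_PATTERNS = {
    ta.NOSINE: "",
    ta.SINGLE: "S",
    ta.TANDEM: "SS",
    ta.TAIL_TAIL: "SA",
    ta.HEAD_HEAD: "AS",
    ta.IALU: "SAS",
}


def plant_transcript_alus(
    genes: Sequence[GeneModel],
    category_counts: dict[str, int],
    params: SimParams,
    seed: int | None = None,
) -> tuple[list[RepeatFeature], pd.DataFrame]:
    """Plant Alus in 3' UTR exons so transcripts get the requested categories.

    One gene per requested transcript (all of a gene's isoforms share the
    terminal 3' UTR exon, so they inherit the same configuration; the truth
    table lists every isoform).  Returns the planted features plus a truth
    table (transcript_id, category, subcategory).  Raises
    :class:`CapacityError` when there are not enough genes or a UTR exon is
    too short for its pattern.
    """
    unknown = set(category_counts) - set(CATEGORY_PATTERNS)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    rng = np.random.default_rng(params.seed + 2 if seed is None else seed)
    wanted: list[str] = []
    for cat in CATEGORY_PATTERNS:  # fixed order for determinism
        wanted.extend([cat] * category_counts.get(cat, 0))
    if len(wanted) > len(genes):
        raise CapacityError(
            f"{len(wanted)} planted transcripts requested but only "
            f"{len(genes)} genes available"
        )
    wanted = [wanted[i] for i in rng.permutation(len(wanted))]

    features: list[RepeatFeature] = []
    truth_rows = []
    margin = 20
    for gene, cat in zip(genes, wanted):
        pattern = CATEGORY_PATTERNS[cat]
        tx = gene.transcripts[0]
        if pattern:
            (us, ue) = tx.utr3[0]
            n = len(pattern)
            gaps = [int(rng.integers(50, 151)) for _ in range(n - 1)]
            need = n * params.alu_length + sum(gaps) + 2 * margin
            if ue - us < need:
                raise CapacityError(
                    f"3' UTR of {tx.transcript_id} ({ue - us} nt) cannot host "
                    f"pattern {pattern!r} ({need} nt)"
                )
            # transcript order -> genomic order
            genomic_pattern = pattern if gene.strand == "+" else pattern[::-1]
            pos = us + margin
            for k, rel in enumerate(genomic_pattern):
                if k > 0:
                    pos += gaps[k - 1]
                strand = gene.strand if rel == "S" else ("-" if gene.strand == "+" else "+")
                features.append(
                    RepeatFeature(
                        chrom=gene.chrom,
                        start=pos,
                        end=pos + params.alu_length,
                        strand=strand,
                        name=ALU_NAMES[int(rng.integers(len(ALU_NAMES)))],
                        family="Alu",
                    )
                )
                pos += params.alu_length
        primary = cat if cat in (ta.NOSINE, ta.SINGLE, ta.TANDEM, ta.IALU) else ta.IALU
        sub = cat if cat in (ta.HEAD_HEAD, ta.TAIL_TAIL) else ""
        for tx in gene.transcripts:
            truth_rows.append(
                {
                    "transcript_id": tx.transcript_id,
                    "category": primary,
                    "subcategory": sub,
                }
            )
    features.sort(key=lambda f: (f.chrom, f.start, f.end))
    truth = pd.DataFrame(truth_rows, columns=["transcript_id", "category", "subcategory"])
    return features, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    profiles: Sequence[ta.TranscriptAluProfile],
    params: ExpressionSimParams = ExpressionSimParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-normal FPKM per transcript per cell line; iAlu transcripts shifted.

    Returns (FPKM table indexed by transcript_id, truth table recording the
    multiplicative factor each transcript received).  With
    ``repression_factor=1`` every category is drawn from the identical
    distribution.  Deterministic per seed.
    """
    rng = np.random.default_rng(params.seed)
    cols = params.cell_line_names()
    rows, truth_rows = [], []
    for p in profiles:
        factor = params.repression_factor if p.category == ta.IALU else 1.0
        draws = np.exp(
            rng.normal(
                params.baseline_log_mean + np.log(factor),
                params.baseline_log_sd,
                size=len(cols),
            )
        )
        rows.append(draws)
        truth_rows.append(
            {"transcript_id": p.transcript_id, "category": p.category,
             "factor": factor}
        )
    fpkm = pd.DataFrame(
        rows, index=[p.transcript_id for p in profiles], columns=cols
    )
    fpkm.index.name = "transcript_id"
    return fpkm, pd.DataFrame(truth_rows, columns=["transcript_id", "category", "factor"])


# ---------------------------------------------------------------------------
# writers (plain-text, byte-deterministic)
# ---------------------------------------------------------------------------

def write_rmsk(rmsk: pd.DataFrame, path) -> None:
    rmsk.to_csv(path, sep="\t", index=False)


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def write_gtf(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write(genes_to_gtf(genes))


def write_fpkm(fpkm: pd.DataFrame, path) -> None:
    fpkm.to_csv(path, sep="\t")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
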