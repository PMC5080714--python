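"""Alu configurations of mature transcripts.

Only Alu elements fully contained in a single exon survive splicing as intact
elements of the mature mRNA, so those are the ones considered here.  They are
projected through the spliced exon chain into mature-transcript coordinates
(5'->3' along the transcript; for minus-strand genes genomic order reverses),
given a relative orientation (sense iff repeat strand equals gene strand),
and each transcript is assigned one configuration category:

* ``noSINE``  — no exon-contained Alu;
* ``single``  — exactly one;
* ``tandem``  — >= 2, every adjacent pair in the same relative orientation;
* ``iAlu``    — >= 2 with at least one adjacent pair inverted; sub-labels
  ``head_head`` (every adjacent pair antisense,sense) and ``tail_tail``
  (every adjacent pair sense,antisense).

An adjacent sense,antisense pair reads tail-to-tail along the transcript (the
3' ends of the two elements face each other and can base-pair on fold-back);
antisense,sense reads head-to-head.  Unlike genomic clustering there is no
distance bound between transcript-level neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .genome_partition import GeneModel, TranscriptModel
from .repeat_catalog import RepeatFeature

NOSINE = "noSINE"
SINGLE = "single"
TANDEM = "tandem"
IALU = "iAlu"
HEAD_HEAD = "head_head"
TAIL_TAIL = "tail_tail"

SENSE = "sense"
ANTISENSE = "antisense"


@dataclass(frozen=True)
class TranscriptAlu:
    """One exon-contained Alu in mature-transcript coordinates."""

    name: str
    family: str
    tx_start: int
    tx_end: int
    relative_orientation: str  # sense / antisense


@dataclass(frozen=True)
class TranscriptAluProfile:
    """Ordered exonic Alus of one transcript plus its configuration category.

    ``adjacent_pairs`` holds, for each consecutive Alu pair along the mature
    transcript, its orientation (tandem/head_head/tail_tail) and whether both
    members come from the same Alu subfamily (recorded as annotation only).
    ``subcategory`` is head_head or tail_tail when every adjacent pair agrees,
    else None; it is only ever set for iAlu transcripts.
    """

    transcript_id: str
    alus: tuple[TranscriptAlu, ...]
    adjacent_pairs: tuple[tuple[str, bool], ...]
    category: str
    subcategory: str | None = None

    @property
    def n_alus(self) -> int:
        return len(self.alus)


def assign_exonic_alus(
    transcript: TranscriptModel,
    alus: Sequence[RepeatFeature],
) -> list[RepeatFeature]:
    """Alus whose genomic interval lies entirely within a single exon.

    Elements straddling an exon boundary, spanning an intron, or contained in
    introns are excluded: they do not survive splicing intact.
    """
    kept = []
    for a in alus:
        if a.chrom != transcript.chrom:
            continue
        if any(s <= a.start and a.end <= e for s, e in transcript.exons):
            kept.append(a)
    return kept


def to_transcript_coords(
    transcript: TranscriptModel,
    contained: Sequence[RepeatFeature],
) -> list[TranscriptAlu]:
    """Map exon-contained Alus into mature-transcript coordinates, sorted 5'->3'.

    Genomic positions are threaded through the spliced exon chain; on
    minus-strand transcripts the chain is read right-to-left so genomic order
    reverses.  Orientation is sense iff the repeat strand equals the
    transcript strand.
    """
    offsets = []
    off = 0
    for s, e in transcript.exons:  # sorted genomic order
        offsets.append(off)
        off += e - s
    length = off

    def tx_pos(g: int) -> int:
        for (s, e), o in zip(transcript.exons, offsets):
            if s <= g < e:
                fwd = o + (g - s)
                return fwd if transcript.strand == "+" else length - 1 - fwd
        raise ValueError(f"genomic position {g} not exonic in {transcript.transcript_id}")

    out = []
    for a in contained:
        p1 = tx_pos(a.start)
        p2 = tx_pos(a.end - 1)
        lo, hi = min(p1, p2), max(p1, p2)
        out.append(
            TranscriptAlu(
                name=a.name,
                family=a.family,
                tx_start=lo,
                tx_end=hi + 1,
                relative_orientation=SENSE
                if a.strand == transcript.strand
                else ANTISENSE,
            )
        )
    out.sort(key=lambda t: (t.tx_start, t.tx_end))
    return out


def pair_orientation(first: str, second: str) -> str:
    """Orientation of an adjacent Alu pair in transcript order.

    Equal orientations -> tandem; (sense, antisense) -> tail_tail;
    (antisense, sense) -> head_head.
    """
    if first == second:
        return TANDEM
    return TAIL_TAIL if first == SENSE else HEAD_HEAD


def classify_transcript(
    transcript_id: str,
    alus: Sequence[TranscriptAlu],
) -> TranscriptAluProfile:
    """Assign the configuration category from the ordered exonic Alus."""
    alus = tuple(sorted(alus, key=lambda t: (t.tx_start, t.tx_end)))
    pairs = tuple(
        (
            pair_orientation(a.relative_orientation, b.relative_orientation),
            a.family == b.family,
        )
        for a, b in zip(alus, alus[1:])
    )
    if not alus:
        category, sub = NOSINE, None
    elif len(alus) == 1:
        category, sub = SINGLE, None
    else:
        kinds = [p[0] for p in pairs]
        if all(k == TANDEM for k in kinds):
            category, sub = TANDEM, None
        else:
            category = IALU
            if all(k == HEAD_HEAD for k in kinds):
                sub = HEAD_HEAD
            elif all(k == TAIL_TAIL for k in kinds):
                sub = TAIL_TAIL
            else:
                sub = None
    return TranscriptAluProfile(
        transcript_id=transcript_id,
        alus=alus,
        adjacent_pairs=pairs,
        category=category,
        subcategory=sub,
    )


def build_profiles(
    genes: Sequence[GeneModel],
    alus: Sequence[RepeatFeature],
) -> list[TranscriptAluProfile]:
    """Profile every transcript of every gene (categories are per transcript)."""
    by_chrom: dict[str, list[RepeatFeature]] = {}
    for a in alus:
        by_chrom.setdefault(a.chrom, []).append(a)
    profiles = []
    for g in genes:
        for tx in g.transcripts:
            contained = assign_exonic_alus(tx, by_chrom.get(tx.chrom, []))
            ordered = to_transcript_coords(tx, contained)
            profiles.append(classify_transcript(tx.transcript_id, ordered))
    return profiles


def profiles_to_frame(profiles: Sequence[TranscriptAluProfile]) -> pd.DataFrame:
    """Per-transcript summary table (one row per transcript)."""
    return pd.DataFrame(
        {
            "transcript_id": p.transcript_id,
            "n_alus": p.n_alus,
            "category": p.category,
            "subcategory": p.subcategory or "",
            "pair_orientations": ",".join(k for k, _ in p.adjacent_pairs),
        }
        for p in profiles
    )
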