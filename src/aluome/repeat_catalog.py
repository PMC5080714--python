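"""Catalog of Alu repeats: parsing, distance clustering, orientation classes.

Alu elements are ~300-nt primate SINEs annotated by RepeatMasker under repeat
family "Alu".  This module restricts a repeat annotation to that family,
chains neighboring elements into clusters by genomic distance, and classifies
clusters of exactly two elements by relative strand orientation:

* ``dSINE`` — direct (tandem) pair, both elements on the same strand;
* ``iSINE`` — inverted pair, elements on opposite strands, split into
  ``hiSINE`` (head-to-head, 5' ends facing: ``-`` then ``+``) and
  ``tiSINE`` (tail-to-tail, 3' ends facing: ``+`` then ``-``).

Inverted pairs can base-pair intramolecularly once transcribed, which is why
their genomic frequency relative to tandem pairs is of interest.

All coordinates are 0-based half-open; the gap between two repeats is
``next.start - prev.end``, so adjacent elements have gap 0 and the clustering
threshold ("at most ``max_gap`` nucleotides apart") is inclusive.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .genome_partition import PartitionMap

log = logging.getLogger(__name__)

# orientation labels
SSINE = "sSINE"
DSINE = "dSINE"
ISINE = "iSINE"
HISINE = "hiSINE"
TISINE = "tiSINE"
CLUSTER3PLUS = "cluster3plus"

#: Column set of the rmsk dialect read and written by this package (a
#: projection of the UCSC RepeatMasker table; 0-based half-open coordinates).
RMSK_COLUMNS = [
    "genoName",
    "genoStart",
    "genoEnd",
    "strand",
    "repName",
    "repClass",
    "repFamily",
]

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class ParseError(ValueError):
    """Malformed annotation row; message names the offending line."""


@dataclass(frozen=True)
class RepeatFeature:
    """One genomic repeat interval (0-based half-open) with strand and family."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str = ""
    family: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class ClusterParams:
    """Clustering threshold: elements at most ``max_gap`` nt apart chain together."""

    max_gap: int = 300

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass(frozen=True)
class AluCluster:
    """A maximal run of repeats with consecutive gaps <= max_gap, sorted by start."""

    members: tuple[RepeatFeature, ...]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return max(m.end for m in self.members)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def configuration(self) -> str:
        """Truth-comparable configuration label (sSINE/dSINE/hiSINE/tiSINE/cluster3plus)."""
        if self.size == 1:
            return SSINE
        if self.size == 2:
            return classify_pair(self.members[0], self.members[1])
        return CLUSTER3PLUS


@dataclass(frozen=True)
class AluPair:
    """A cluster of exactly two repeats with its orientation class."""

    left: RepeatFeature
    right: RepeatFeature
    orientation: str = field(init=False)

    def __post_init__(self) -> None:
        if self.left.chrom != self.right.chrom:
            raise ValueError("pair members must share a chromosome")
        if self.left.start > self.right.start:
            raise ValueError("pair members must be in genomic order")
        object.__setattr__(self, "orientation", classify_pair(self.left, self.right))

    @property
    def gap(self) -> int:
        return max(0, self.right.start - self.left.end)


@dataclass(frozen=True)
class CatalogSummary:
    """Genome-wide configuration fractions over all cataloged Alu elements.

    All ``fraction_*`` fields are proportions of the total element count
    (``n_alus``), so ``fraction_dSINE + fraction_iSINE = fraction_in_pairs``
    and ``fraction_hiSINE + fraction_tiSINE = fraction_iSINE``.  On an empty
    catalog the fractions are NaN ("undefined"), never a division error.
    """

    n_alus: int
    fraction_single: float
    fraction_clustered: float
    fraction_in_pairs: float
    fraction_dSINE: float
    fraction_iSINE: float
    fraction_hiSINE: float
    fraction_tiSINE: float
    median_neighbor_gap: float
    fraction_within_median: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def read_repeats(
    path,
    dialect: str = "rmsk",
    family_filter: str | None = "Alu",
) -> list[RepeatFeature]:
    """Read a repeat annotation and restrict it to one repeat family.

    ``dialect="rmsk"`` expects a tab-separated file whose header contains at
    least the :data:`RMSK_COLUMNS`; extra columns (as in full UCSC dumps) are
    ignored.  ``dialect="bed6"`` expects headerless BED6; the name field is
    ``repName|repFamily`` (a bare name is taken as its own family).  Records
    are returned sorted by (chrom, start, end); ``family_filter=None``
    disables the family restriction.
    """
    if dialect == "rmsk":
        table = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in RMSK_COLUMNS if c not in table.columns]
        if missing:
            raise ParseError(f"{path}: rmsk header lacks columns {missing}")
        rows = table[RMSK_COLUMNS].itertuples(index=True)
        features = []
        for row in rows:
            lineno = row.Index + 2  # header is line 1
            try:
                features.append(
                    RepeatFeature(
                        chrom=row.genoName,
                        start=int(row.genoStart),
                        end=int(row.genoEnd),
                        strand=row.strand,
                        name=row.repName,
                        family=row.repFamily,
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    elif dialect == "bed6":
        table = pd.read_csv(
            path, sep="\t", header=None, names=BED6_COLUMNS, comment="#", dtype=str
        )
        features = []
        for row in table.itertuples(index=True):
            lineno = row.Index + 1
            name, _, fam = str(row.name).partition("|")
            try:
                features.append(
                    RepeatFeature(
                        chrom=row.chrom,
                        start=int(row.start),
                        end=int(row.end),
                        strand=row.strand,
                        name=name,
                        family=fam or name,
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'rmsk' or 'bed6'")

    if family_filter is not None:
        features = [f for f in features if f.family == family_filter]
    features.sort(key=lambda f: (f.chrom, f.start, f.end))
    return features


def write_repeats_bed(features: Iterable[RepeatFeature], path) -> None:
    """Write features as BED6 with ``repName|family`` in the name field."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}|{f.family}\t0\t{f.strand}\n"
            )


# ---------------------------------------------------------------------------
# clustering & classification
# ---------------------------------------------------------------------------

def cluster_alus(
    features: Sequence[RepeatFeature],
    params: ClusterParams = ClusterParams(),
) -> list[AluCluster]:
    """Single-linkage chaining of repeats within ``max_gap`` nucleotides.

    Consecutive same-chromosome features join one cluster iff
    ``next.start - prev.end <= max_gap`` (inclusive).  Overlapping records
    (negative gap) are treated as gap 0, i.e. always joined, and logged.
    Every feature ends up in exactly one maximal cluster.
    """
    feats = sorted(features, key=lambda f: (f.chrom, f.start, f.end))
    clusters: list[AluCluster] = []
    current: list[RepeatFeature] = []
    for f in feats:
        if not current:
            current = [f]
            continue
        prev = current[-1]
        if f.chrom == prev.chrom:
            gap = f.start - prev.end
            if gap < 0:
                log.info(
                    "overlapping repeats %s:%d-%d and %s:%d-%d joined (gap<0 -> 0)",
                    prev.chrom, prev.start, prev.end, f.chrom, f.start, f.end,
                )
                gap = 0
            if gap <= params.max_gap:
                current.append(f)
                continue
        clusters.append(AluCluster(tuple(current)))
        current = [f]
    if current:
        clusters.append(AluCluster(tuple(current)))
    return clusters


def classify_pair(left: RepeatFeature, right: RepeatFeature) -> str:
    """Orientation class of two repeats in genomic order.

    Same strand -> dSINE (tandem).  ``(+, -)`` -> tiSINE (the 3' ends face
    each other), ``(-, +)`` -> hiSINE (5' ends face each other).
    """
    if left.strand == right.strand:
        return DSINE
    return TISINE if left.strand == "+" else HISINE


def summarize_catalog(
    clusters: Sequence[AluCluster],
    within_stat: str = "alus",
) -> CatalogSummary:
    """Configuration fractions and neighbor-gap statistics of a clustered catalog.

    Pair-orientation fractions count only clusters of size exactly 2 (both
    members), as proportions of all elements; clusters of size >= 3 count
    toward ``fraction_clustered`` only.  ``median_neighbor_gap`` is the median
    of consecutive same-chromosome gaps (overlaps clamped to 0).
    ``fraction_within_median`` is, with ``within_stat="alus"`` (default), the
    fraction of all elements whose nearest same-chromosome neighbor is at most
    the median away; with ``within_stat="gaps"`` it is the fraction of gaps at
    most the median (~0.5 by construction, kept for comparison).
    """
    if within_stat not in ("alus", "gaps"):
        raise ValueError("within_stat must be 'alus' or 'gaps'")
    n = sum(c.size for c in clusters)
    if n == 0:
        nan = float("nan")
        return CatalogSummary(0, nan, nan, nan, nan, nan, nan, nan, nan, nan)

    n_single = sum(1 for c in clusters if c.size == 1)
    pair_counts = {DSINE: 0, HISINE: 0, TISINE: 0}
    for c in clusters:
        if c.size == 2:
            pair_counts[classify_pair(c.members[0], c.members[1])] += 1

    features = sorted(
        (m for c in clusters for m in c.members),
        key=lambda f: (f.chrom, f.start, f.end),
    )
    gaps: list[int] = []          # consecutive same-chromosome gaps
    nearest: list[float] = []     # per element, gap to closest neighbor
    i = 0
    while i < len(features):
        j = i
        while j + 1 < len(features) and features[j + 1].chrom == features[i].chrom:
            j += 1
        chrom_feats = features[i : j + 1]
        chrom_gaps = [
            max(0, b.start - a.end) for a, b in zip(chrom_feats, chrom_feats[1:])
        ]
        gaps.extend(chrom_gaps)
        for k in range(len(chrom_feats)):
            cands = []
            if k > 0:
                cands.append(chrom_gaps[k - 1])
            if k < len(chrom_gaps):
                cands.append(chrom_gaps[k])
            nearest.append(min(cands) if cands else math.inf)
        i = j + 1

    if gaps:
        med = float(pd.Series(gaps).median())
        if within_stat == "alus":
            frac_within = sum(1 for g in nearest if g <= med) / n
        else:
            frac_within = sum(1 for g in gaps if g <= med) / len(gaps)
    else:
        med = float("nan")
        frac_within = float("nan")

    n_d = 2 * pair_counts[DSINE]
    n_hi = 2 * pair_counts[HISINE]
    n_ti = 2 * pair_counts[TISINE]
    return CatalogSummary(
        n_alus=n,
        fraction_single=n_single / n,
        fraction_clustered=(n - n_single) / n,
        fraction_in_pairs=(n_d + n_hi + n_ti) / n,
        fraction_dSINE=n_d / n,
        fraction_iSINE=(n_hi + n_ti) / n,
        fraction_hiSINE=n_hi / n,
        fraction_tiSINE=n_ti / n,
        median_neighbor_gap=med,
        fraction_within_median=frac_within,
    )


def stratify_by_region(
    clusters: Sequence[AluCluster],
    partition: "PartitionMap",
    within_stat: str = "alus",
) -> dict[str, CatalogSummary]:
    """Split the catalog into genic/intergenic strata and summarize each.

    Each cluster is assigned by the level-1 partition label at its span
    midpoint; a cluster straddling a boundary is counted once (and logged).
    """
    strata: dict[str, list[AluCluster]] = {"genic": [], "intergenic": []}
    for c in clusters:
        label = partition.label_at(c.chrom, c.midpoint, level=1)
        if label is None:
            log.warning(
                "cluster %s:%d-%d outside partitioned territory; skipped",
                c.chrom, c.start, c.end,
            )
            continue
        start_label = partition.label_at(c.chrom, c.start, level=1)
        end_label = partition.label_at(c.chrom, max(c.start, c.end - 1), level=1)
        if start_label != label or end_label != label:
            log.info(
                "cluster %s:%d-%d spans a genic/intergenic boundary; assigned %s by midpoint",
                c.chrom, c.start, c.end, label,
            )
        strata[label].append(c)
    return {
        label: summarize_catalog(cs, within_stat=within_stat)
        for label, cs in strata.items()
    }
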