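"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately avoid the package's own algorithms:
clustering by transitive closure over the pairwise gap relation, partition
labeling per nucleotide, transcript projection per base, rank-sum p-values
by enumerating all group assignments, and folding thermodynamics by
exhaustively generating every secondary structure.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict

import numpy as np
import pytest

from aluome import seqdesign as sd
from aluome.repeat_catalog import RepeatFeature


# ---------------------------------------------------------------------------
# clustering oracle: transitive closure over "gap <= max_gap"
# ---------------------------------------------------------------------------

def brute_force_clusters(features, max_gap):
    """Partition features by transitive closure of the pairwise gap relation."""
    feats = list(features)
    n = len(feats)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i, j in itertools.combinations(range(n), 2):
        a, b = feats[i], feats[j]
        if a.chrom != b.chrom:
            continue
        gap = max(b.start - a.end, a.start - b.end, 0)
        if a.start < b.end and b.start < a.end:
            gap = 0
        if gap <= max_gap:
            union(i, j)
    groups = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(feats[i])
    return sorted(
        (sorted(g, key=lambda f: (f.start, f.end)) for g in groups.values()),
        key=lambda g: (g[0].chrom, g[0].start),
    )


# ---------------------------------------------------------------------------
# per-nucleotide partition labeling oracle
# ---------------------------------------------------------------------------

def per_base_labels(genes, chrom_sizes):
    """Label every nucleotide of every chromosome at the three levels.

    Returns {chrom: (level1, level2, level3)} arrays of label strings;
    level2/level3 entries are "" outside their parent territory.
    """
    out = {}
    for chrom, size in chrom_sizes.items():
        l1 = np.array(["intergenic"] * size, dtype=object)
        l2 = np.array([""] * size, dtype=object)
        l3 = np.array([""] * size, dtype=object)
        covering = [g for g in genes if g.chrom == chrom]
        for g in covering:
            s, e = g.span
            l1[max(0, s) : min(size, e)] = "genic"
        exonic = np.zeros(size, dtype=bool)
        claims = {"coding": np.zeros(size, dtype=bool),
                  "utr5": np.zeros(size, dtype=bool),
                  "utr3": np.zeros(size, dtype=bool)}
        for g in covering:
            for tx in g.transcripts:
                for s, e in tx.exons:
                    exonic[max(0, s) : min(size, e)] = True
                for label, ivs in (("coding", tx.cds), ("utr5", tx.utr5),
                                   ("utr3", tx.utr3)):
                    for s, e in ivs:
                        claims[label][max(0, s) : min(size, e)] = True
        genic = l1 == "genic"
        l2[genic & exonic] = "exonic"
        l2[genic & ~exonic] = "intronic"
        ex = genic & exonic
        for i in np.nonzero(ex)[0]:
            if claims["coding"][i]:
                l3[i] = "coding"
            elif claims["utr5"][i]:
                l3[i] = "utr5"
            elif claims["utr3"][i]:
                l3[i] = "utr3"
            else:
                l3[i] = "noncoding"
        out[chrom] = (l1, l2, l3)
    return out


# ---------------------------------------------------------------------------
# per-base transcript projection oracle
# ---------------------------------------------------------------------------

def per_base_tx_map(exons, strand):
    """genomic position -> mature-transcript position, built base by base."""
    genomic = [g for s, e in sorted(exons) for g in range(s, e)]
    if strand == "-":
        genomic = genomic[::-1]
    return {g: t for t, g in enumerate(genomic)}


# ---------------------------------------------------------------------------
# rank-sum enumeration oracle
# ---------------------------------------------------------------------------

def exact_ranksum_pvalues(x, y):
    """(p_less, p_two) for tie-free samples by enumerating group assignments."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n = len(x)
    ws = [sum(c) for c in itertools.combinations(range(1, len(pooled) + 1), n)]
    total = len(ws)
    p_less = sum(1 for w in ws if w <= w_obs) / total
    p_ge = sum(1 for w in ws if w >= w_obs) / total
    p_two = min(1.0, 2 * min(p_less, p_ge))
    return p_less, p_two


# ---------------------------------------------------------------------------
# exhaustive folding oracle (toy energy model: -1/pair, kT=1, min loop 3)
# ---------------------------------------------------------------------------

def enumerate_structures(seq):
    """All pair sets of nested structures with hairpin loops >= 3."""
    n = len(seq)

    def helper(lo, hi):  # structures over positions [lo, hi)
        if hi - lo <= sd.MIN_LOOP:
            return [frozenset()]
        # position lo unpaired, or paired with some j
        out = [s for s in helper(lo + 1, hi)]
        for j in range(lo + sd.MIN_LOOP + 1, hi):
            if sd.can_pair(seq[lo], seq[j]):
                for inner in helper(lo + 1, j):
                    for outer in helper(j + 1, hi):
                        out.append(inner | outer | {(lo, j)})
        return out

    return helper(0, n)


def oracle_fold(seq):
    """(max_pairs, Z, efe, bpp) by exhaustive enumeration."""
    structures = enumerate_structures(seq)
    n = len(seq)
    weights = [math.exp(len(s)) for s in structures]
    z = sum(weights)
    bpp = np.zeros((n, n))
    for s, w in zip(structures, weights):
        for i, j in s:
            bpp[i, j] += w
            bpp[j, i] += w
    bpp /= z
    max_pairs = max(len(s) for s in structures)
    return max_pairs, z, -math.log(z), bpp


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def nussinov():
    return sd.NussinovEngine()


@pytest.fixture(scope="session")
def toy_template():
    """16-nt hairpin: two 6-nt designable stem arms around a fixed AAAA loop."""
    return sd.DesignTemplate(
        full_sequence="GGGGGGAAAACCCCCC",
        segments=(("designable", 0, 6), ("spacer", 6, 10), ("designable", 10, 16)),
    )


def make_repeat(chrom, start, end, strand, name="AluSp", family="Alu"):
    return RepeatFeature(chrom=chrom, start=start, end=end, strand=strand,
                        name=name, family=family)
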