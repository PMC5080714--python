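"""Expression stratification of Alu-configuration categories.

Transcript FPKM tables (rows = transcripts, columns = cell lines) are
filtered to robustly expressed transcripts (default: FPKM >= 3 in every cell
line, boundary inclusive), pooled per configuration category with one
observation per transcript per cell line, and compared pairwise with the
Wilcoxon rank-sum (Mann-Whitney U) test.  The pooling convention means a
category's n counts transcript x cell-line occurrences, matching how the
source cohorts report category sizes across 15 cell lines.

The test uses exact enumeration when both pools have n <= 25 and there are
no ties, otherwise the normal approximation with midrank tie correction and
continuity correction.  The default one-sided alternative is "group a is
lower" (the directional claim of interest: inverted-configuration transcripts
are repressed relative to tandem ones).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .transcript_alu import (
    HEAD_HEAD,
    IALU,
    NOSINE,
    SINGLE,
    TAIL_TAIL,
    TANDEM,
    TranscriptAluProfile,
)

log = logging.getLogger(__name__)

#: The seven pooled categories: head_head/tail_tail are the iAlu transcripts
#: whose adjacent pairs are uniformly so, hence subsets of iAlu; "all" is the
#: union of every surviving transcript.
POOL_CATEGORIES = ("all", SINGLE, IALU, HEAD_HEAD, TAIL_TAIL, TANDEM, NOSINE)


@dataclass(frozen=True)
class ExpressionFilter:
    """Expression cutoff: keep transcripts with FPKM >= min_fpkm (inclusive)."""

    min_fpkm: float = 3.0
    require_all_cell_lines: bool = True

    def __post_init__(self) -> None:
        if self.min_fpkm < 0:
            raise ValueError("min_fpkm must be >= 0")


@dataclass(frozen=True)
class CategoryExpression:
    """Pooled FPKM observations of one category (transcript x cell line)."""

    category: str
    values: tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values else float("nan")


@dataclass(frozen=True)
class TestResult:
    """Wilcoxon rank-sum comparison of two category pools.

    ``statistic`` is the rank sum W of group a (midranks); ``direction``
    names the group with the lower mean rank; ``p_one_sided`` tests the
    alternative "group a is stochastically lower".
    """

    group_a: str
    group_b: str
    statistic: float
    p_two_sided: float
    p_one_sided: float
    direction: str
    method: str


def filter_expressed(
    fpkm: pd.DataFrame,
    flt: ExpressionFilter = ExpressionFilter(),
) -> list[str]:
    """Transcript ids passing the FPKM cutoff (>= min_fpkm, inclusive).

    With ``require_all_cell_lines`` the cutoff must hold in every column,
    otherwise in at least one.  Transcripts with any missing value are
    dropped and logged.
    """
    if fpkm.shape[1] < 1:
        raise ValueError("FPKM table needs at least one cell-line column")
    has_na = fpkm.isna().any(axis=1)
    if has_na.any():
        log.warning("%d transcripts with missing FPKM dropped", int(has_na.sum()))
    ok = fpkm.loc[~has_na]
    passing = (ok >= flt.min_fpkm).all(axis=1) if flt.require_all_cell_lines \
        else (ok >= flt.min_fpkm).any(axis=1)
    return list(ok.index[passing])


def pool_by_category(
    surviving: Sequence[str],
    profiles: Sequence[TranscriptAluProfile],
    fpkm: pd.DataFrame,
) -> list[CategoryExpression]:
    """Pool per-cell-line FPKM observations into the seven categories.

    Each surviving transcript contributes one observation per cell line to
    its primary category pool (noSINE/single/tandem/iAlu) and, for iAlu
    transcripts with a uniform pair orientation, additionally to head_head or
    tail_tail; every surviving transcript enters "all".  Transcripts without
    a profile are excluded with a warning.
    """
    by_id = {p.transcript_id: p for p in profiles}
    members: dict[str, list[str]] = {c: [] for c in POOL_CATEGORIES}
    for tid in surviving:
        p = by_id.get(tid)
        if p is None:
            log.warning("transcript %s has no Alu profile; excluded", tid)
            continue
        members["all"].append(tid)
        members[p.category].append(tid)
        if p.subcategory is not None:
            members[p.subcategory].append(tid)
    out = []
    for cat in POOL_CATEGORIES:
        tids = members[cat]
        values = tuple(fpkm.loc[tids].to_numpy().ravel()) if tids else ()
        out.append(CategoryExpression(category=cat, values=values))
    return out


def compare_categories(
    a: CategoryExpression,
    b: CategoryExpression,
) -> TestResult:
    """Wilcoxon rank-sum test between two pools.

    Exact null enumeration when both n <= 25 and the pooled values are
    tie-free, otherwise normal approximation with tie and continuity
    correction.  Reports the rank sum of ``a``, two-sided p, and the
    one-sided p for "a lower than b".
    """
    if a.n == 0 or b.n == 0:
        raise ValueError("both pools must be non-empty")
    x = np.asarray(a.values, dtype=float)
    y = np.asarray(b.values, dtype=float)
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    exact = tie_free and a.n <= 25 and b.n <= 25
    method = "exact" if exact else "asymptotic"

    u_less = stats.mannwhitneyu(
        x, y, alternative="less", method=method, use_continuity=not exact
    )
    u_two = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=not exact
    )
    # rank sum of group a from U: W_a = U_a + n_a (n_a + 1) / 2
    w_a = float(u_less.statistic) + a.n * (a.n + 1) / 2.0
    mean_rank_a = w_a / a.n
    mean_rank_b = ((a.n + b.n) * (a.n + b.n + 1) / 2.0 - w_a) / b.n
    if mean_rank_a < mean_rank_b:
        direction = a.category
    elif mean_rank_b < mean_rank_a:
        direction = b.category
    else:
        direction = "tie"
    return TestResult(
        group_a=a.category,
        group_b=b.category,
        statistic=w_a,
        p_two_sided=float(u_two.pvalue),
        p_one_sided=float(u_less.pvalue),
        direction=direction,
        method=method,
    )


def pairwise_tests(
    pools: Sequence[CategoryExpression],
    bonferroni: bool = False,
) -> pd.DataFrame:
    """All pairwise rank-sum tests over non-empty pools (long format).

    Raw p-values by default; ``bonferroni=True`` adds columns with the
    family-wise corrected values (correction over the reported grid).
    """
    pools = [p for p in pools if p.n > 0]
    rows = []
    for i, pa in enumerate(pools):
        for pb in pools[i + 1 :]:
            r = compare_categories(pa, pb)
            rows.append(
                {
                    "group_a": r.group_a,
                    "group_b": r.group_b,
                    "n_a": pa.n,
                    "n_b": pb.n,
                    "statistic": r.statistic,
                    "p_two_sided": r.p_two_sided,
                    "p_one_sided": r.p_one_sided,
                    "direction": r.direction,
                    "method": r.method,
                }
            )
    table = pd.DataFrame(rows)
    if bonferroni and len(table):
        m = len(table)
        table["p_two_sided_bonferroni"] = (table["p_two_sided"] * m).clip(upper=1.0)
        table["p_one_sided_bonferroni"] = (table["p_one_sided"] * m).clip(upper=1.0)
    return table


def category_summary(pools: Sequence[CategoryExpression]) -> pd.DataFrame:
    """Per-category n (pooled observations) and mean FPKM."""
    return pd.DataFrame(
        {"category": p.category, "n": p.n, "mean_fpkm": p.mean} for p in pools
    )
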