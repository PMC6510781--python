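"""Shared statistics: one-tailed Fisher enrichment, stringency scans,
Bonferroni correction and Mann-Whitney group comparisons.

Fold enrichment is the prevalence of an annotation inside a gene category
divided by its prevalence in the FULL gene universe (the "background"
convention used when plotting category bars against an all-genes line).
The Fisher exact p is computed on the category-vs-complement 2x2 table in
a direction chosen a priori per analysis, never inferred from the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

Direction = Literal["enrichment", "depletion"]


@dataclass
class EnrichmentResult:
    """One 2x2 Fisher test with a universe-relative fold.

    Table layout: ``a`` = category & annotated, ``b`` = category not
    annotated, ``c`` = complement & annotated, ``d`` = complement not
    annotated.
    """

    a: int
    b: int
    c: int
    d: int
    prevalence_category: float
    prevalence_background: float
    fold: float
    direction: Direction
    p: float
    p_adjusted: float | None = None
    flagged: str | None = None

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_enrichment(
    category: set,
    annotated: set,
    universe: set,
    direction: Direction = "enrichment",
) -> EnrichmentResult:
    """One-tailed Fisher exact test of an annotation within a gene category.

    ``p`` is the hypergeometric tail on the category-vs-complement table
    in the requested direction; ``fold`` compares the category prevalence
    with the prevalence over the whole universe.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    if not category <= universe:
        raise ValueError("category must be a subset of the universe")
    if not annotated <= universe:
        raise ValueError("annotated must be a subset of the universe")
    a = len(category & annotated)
    b = len(category - annotated)
    c = len(annotated - category)
    d = len(universe) - a - b - c
    prev_bg = len(annotated) / len(universe)
    if not category:
        return EnrichmentResult(
            a, b, c, d, float("nan"), prev_bg, float("nan"), direction, 1.0,
            flagged="empty category",
        )
    prev_cat = a / len(category)
    fold = prev_cat / prev_bg if prev_bg > 0 else float("inf") if a else float("nan")
    alternative = "greater" if direction == "enrichment" else "less"
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return EnrichmentResult(a, b, c, d, prev_cat, prev_bg, fold, direction, float(p))


def bonferroni(pvals: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment ``p -> min(1, m * p)``; ``m`` defaults to the
    number of tests in the list."""
    if m is None:
        m = len(pvals)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if any(p < 0 or p > 1 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, m * p) for p in pvals]


# Exhaustive enumeration stays exact with midranks and ties; cap on the
# number of group assignments before switching to the normal approximation.
_EXACT_COMB_CAP = 20_000


def _rank_sum_exact_p(ranks: np.ndarray, n1: int, observed: float) -> float:
    """Two-sided exact p for a rank-sum statistic by full enumeration over
    group assignments, conditional on the observed (possibly tied) ranks."""
    n = len(ranks)
    total = math.comb(n, n1)
    mean_sum = n1 * ranks.sum() / n
    obs_dev = abs(observed - mean_sum)
    hits = 0
    for idx in combinations(range(n), n1):
        s = ranks[list(idx)].sum()
        if abs(s - mean_sum) >= obs_dev - 1e-12:
            hits += 1
    return hits / total


def mann_whitney(
    group_a: Sequence[float], reference: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U with midrank tie handling; two-sided p.

    Exact (full enumeration over group assignments, valid under ties)
    when the number of assignments is small; otherwise the normal
    approximation with tie correction.

    Returns
    -------
    (U, p) where U is the statistic for ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n1 = a.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2
    if math.comb(n1 + b.size, n1) <= _EXACT_COMB_CAP:
        p = _rank_sum_exact_p(ranks, n1, r1)
    else:
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(u), float(p)


def exact_rank_sum_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided exact Wilcoxon rank-sum p with explicit tie handling.

    The null distribution is the exact conditional distribution of the
    rank sum over all assignments of the observed midranks, so ties are
    handled without continuity fudges.  Falls back to the tie-corrected
    normal approximation when enumeration is infeasible.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = ranks[: a.size].sum()
    if math.comb(a.size + b.size, a.size) <= _EXACT_COMB_CAP:
        p = _rank_sum_exact_p(ranks, a.size, w)
    else:
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(w), float(p)


def prevalence_scan(
    calls,
    groups: dict[str, set],
    universe: set,
    *,
    annotation_filter: set | None = None,
    directions: dict[str, Direction] | None = None,
    x_values: Iterable[int] = range(2, 11),
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Enrichment of tissue-specific genes within gene groups across the
    stringency grid x = 2..10.

    For each (x, group) cell the "annotated" set is the genes specific at
    ``x`` (optionally intersected with ``annotation_filter``, e.g. genes
    carrying genetic evidence), tested within ``group`` against the full
    universe background.  Emits a long-format table mirroring a
    fold-and-p enrichment grid.

    Parameters
    ----------
    calls
        List of :class:`~tispec.expression.TissueSpecificityCall`.
    directions
        Per-group one-tailed direction, chosen a priori; defaults to
        "enrichment" for every group.
    bonferroni_m
        Family size for the adjustment; defaults to the number of cells
        emitted by this scan.
    """
    from tispec.expression import specific_genes

    rows = []
    results: list[EnrichmentResult | None] = []
    for x in x_values:
        ts = specific_genes(calls, x) & universe
        if annotation_filter is not None:
            ts = ts & annotation_filter
        bg_prev = len(ts) / len(universe)
        for name, members in groups.items():
            direction = (directions or {}).get(name, "enrichment")
            if len(members) == 0:
                rows.append(
                    dict(x=x, group=name, a=np.nan, b=np.nan, c=np.nan, d=np.nan,
                         prevalence=np.nan, background=bg_prev, fold=np.nan,
                         p=np.nan)
                )
                results.append(None)
                continue
            res = fisher_enrichment(members & universe, ts, universe, direction)
            rows.append(
                dict(x=x, group=name, a=res.a, b=res.b, c=res.c, d=res.d,
                     prevalence=res.prevalence_category,
                     background=res.prevalence_background,
                     fold=res.fold, p=res.p)
            )
            results.append(res)
    df = pd.DataFrame(rows)
    valid = df["p"].notna()
    m = bonferroni_m if bonferroni_m is not None else int(valid.sum())
    df["p_adj"] = np.nan
    if valid.any():
        df.loc[valid, "p_adj"] = bonferroni(df.loc[valid, "p"].tolist(), m=m)
    return df
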