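"""Regional frequency-distribution statistics.

Per gene, the percentage of its total replicate-averaged TPM
contributed by each region; per-list mean +/- SEM summaries; top
contributing genes per region; peak-region calls; and pairwise region
comparisons (one-way ANOVA with pooled-variance t contrasts) adjusted
by the Benjamini-Krieger-Yekutieli two-stage step-up FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exprio import GeneList, RegionProfile

__all__ = [
    "FrequencyTable",
    "ListFrequencySummary",
    "PairwiseRegionTest",
    "frequency_table",
    "list_summary",
    "top_contributors",
    "peak_region",
    "pairwise_region_tests",
    "bky_adjust",
]


@dataclass
class FrequencyTable:
    """Gene x region percentages; every row sums to 100."""

    values: pd.DataFrame  # genes x regions, percentages
    dropped_zero_total: tuple[str, ...] = ()

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ListFrequencySummary:
    """Per-region mean/SEM of a gene list's frequency percentages."""

    list_name: str
    table: pd.DataFrame  # index region, columns mean/sem/n
    n_genes: int
    sem_convention_applied: bool = False  # True when n=1 forced SEM to 0


@dataclass(frozen=True)
class PairwiseRegionTest:
    region_a: str
    region_b: str
    t_stat: float
    p_value: float
    significant: bool
    q_level: float
    degenerate: bool = False


def frequency_table(
    profile: RegionProfile, include: Sequence[str] | None = None
) -> FrequencyTable:
    """Percentage of each gene's total TPM contributed by each region.

    ``include`` restricts the denominator (and columns); default is all
    profile regions (brain regions and stem-cell columns alike).  Genes
    whose total TPM over the included regions is zero have no defined
    frequency and are dropped (reported on the result).
    """
    if include is None:
        include = profile.regions
    include = list(include)
    if not include:
        raise ValueError("include set must be non-empty")
    missing = [r for r in include if r not in profile.regions]
    if missing:
        raise ValueError(f"regions not in profile: {missing}")
    df = profile.to_frame()[include]
    totals = df.sum(axis=1)
    zero = totals == 0
    dropped = tuple(df.index[zero])
    kept = df.loc[~zero]
    values = 100.0 * kept.div(totals[~zero], axis=0)
    return FrequencyTable(values=values, dropped_zero_total=dropped)


def list_summary(freq: FrequencyTable, gene_list: GeneList) -> ListFrequencySummary:
    """Mean and SEM of the frequency percentages over a list's genes.

    SEM uses the sample SD (ddof=1) over sqrt(n); with a single gene it
    is reported as 0 and flagged.
    """
    genes = [g for g in gene_list.genes if g in freq.values.index]
    if not genes:
        raise ValueError(
            f"no genes of list {gene_list.name!r} present in the frequency table"
        )
    sub = freq.values.loc[genes]
    n = len(genes)
    mean = sub.mean(axis=0)
    if n == 1:
        sem = pd.Series(0.0, index=sub.columns)
        flagged = True
    else:
        sem = sub.std(axis=0, ddof=1) / np.sqrt(n)
        flagged = False
    table = pd.DataFrame({"mean": mean, "sem": sem, "n": n})
    return ListFrequencySummary(
        list_name=gene_list.name,
        table=table,
        n_genes=n,
        sem_convention_applied=flagged,
    )


def top_contributors(
    freq: FrequencyTable, gene_list: GeneList, region: str, k: int
) -> list[tuple[str, float]]:
    """Top-k list genes by frequency percentage in one region.

    Sorted descending with lexicographic tie-break; the remaining list
    genes are aggregated into a final ``("other", pct)`` record (0 when
    k covers the whole list).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if region not in freq.values.columns:
        raise ValueError(f"region {region!r} absent from frequency table")
    genes = [g for g in gene_list.genes if g in freq.values.index]
    if not genes:
        raise ValueError(f"no genes of list {gene_list.name!r} in frequency table")
    pct = freq.values.loc[genes, region]
    ranked = sorted(pct.items(), key=lambda kv: (-kv[1], kv[0]))
    top = ranked[:k]
    other = float(sum(v for _, v in ranked[k:]))
    return [(g, float(v)) for g, v in top] + [("other", other)]


def peak_region(profile: RegionProfile, gene: str) -> str:
    """Region of maximum replicate-averaged TPM; ties break to the
    lexicographically first region id."""
    if gene not in profile.gene_ids:
        raise ValueError(f"gene {gene!r} not in profile")
    row = profile.to_frame().loc[gene]
    if row.sum() == 0:
        raise ValueError(f"gene {gene!r} has zero TPM in all regions")
    best = row.max()
    candidates = sorted(r for r, v in row.items() if v == best)
    return candidates[0]


def bky_adjust(pvalues: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Krieger-Yekutieli two-stage adaptive step-up.

    Stage 1 runs Benjamini-Hochberg at ``q' = q/(1+q)``; its rejection
    count r1 gives the null estimate ``m0 = m - r1`` (r1 = 0 rejects
    nothing, r1 = m rejects everything).  Stage 2 reruns BH at level
    ``q' * m / m0``, i.e. rejects p_(i) <= i * q' / m0.

    Returns ``(reject, adjusted)`` in input order.  The adjusted values
    are calibrated so that ``adjusted <= q`` reproduces the flags at
    this ``q`` (the two-stage procedure has no q-free adjusted p).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    m = p.size
    q1 = q / (1.0 + q)
    r1 = _bh_reject_count(p, q1)
    if r1 == 0:
        return np.zeros(m, dtype=bool), np.ones(m)
    if r1 == m:
        return np.ones(m, dtype=bool), np.zeros(m)
    m0 = m - r1
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    ranks = np.arange(1, m + 1)
    reject_sorted = np.zeros(m, dtype=bool)
    below = sorted_p <= ranks * q1 / m0
    if below.any():
        reject_sorted[: np.max(np.nonzero(below)[0]) + 1] = True
    # adjusted: monotone-min of p_(i)*m0/(i*q1) * q, so adjusted<=q <=> reject
    raw_adj = sorted_p * m0 / (ranks * q1) * q
    adj_sorted = np.minimum.accumulate(raw_adj[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    reject = np.zeros(m, dtype=bool)
    adjusted = np.zeros(m)
    reject[order] = reject_sorted
    adjusted[order] = adj_sorted
    return reject, adjusted


def _bh_reject_count(p: np.ndarray, level: float) -> int:
    m = p.size
    sorted_p = np.sort(p)
    below = sorted_p <= (np.arange(1, m + 1) * level / m)
    if not below.any():
        return 0
    return int(np.max(np.nonzero(below)[0]) + 1)


def pairwise_region_tests(
    freq: FrequencyTable, gene_list: GeneList, q: float = 0.05
) -> tuple[float, float, list[PairwiseRegionTest]]:
    """One-way ANOVA across regions on per-gene percentages, plus all
    pairwise region contrasts with BKY-adjusted significance flags.

    The unit of observation is the gene (independent-groups reading).
    Contrasts are t statistics on the pooled within-region mean square
    (Fisher-LSD form); the full set of R*(R-1)/2 p values is adjusted
    jointly by :func:`bky_adjust` at level ``q``.

    Returns ``(F, anova_p, tests)``.  A fully degenerate layout (zero
    within-region variance everywhere) yields NaN p values flagged
    ``degenerate``.
    """
    genes = [g for g in gene_list.genes if g in freq.values.index]
    if len(genes) < 2:
        raise ValueError("need at least 2 list genes for region tests")
    regions = list(freq.values.columns)
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    data = [freq.values.loc[genes, r].to_numpy() for r in regions]
    n = len(genes)
    k = len(regions)
    grand = np.mean([x.mean() for x in data])
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in data)
    ss_between = sum(n * (x.mean() - grand) ** 2 for x in data)
    df_within = k * (n - 1)
    df_between = k - 1
    msw = ss_within / df_within if df_within > 0 else np.nan
    degenerate = not np.isfinite(msw) or msw <= 0
    if degenerate:
        f_stat = 0.0 if ss_between == 0 else np.inf
        anova_p = np.nan if ss_between > 0 else 1.0
    else:
        f_stat = (ss_between / df_between) / msw
        anova_p = float(stats.f.sf(f_stat, df_between, df_within))

    pairs = [(regions[i], regions[j]) for i in range(k) for j in range(i + 1, k)]
    raw_p = []
    t_stats = []
    for ra, rb in pairs:
        xa = freq.values.loc[genes, ra].to_numpy()
        xb = freq.values.loc[genes, rb].to_numpy()
        diff = xa.mean() - xb.mean()
        if degenerate:
            t = np.nan if diff != 0 else 0.0
            p = np.nan if diff != 0 else 1.0
        else:
            se = np.sqrt(msw * (1.0 / n + 1.0 / n))
            t = diff / se
            p = 2.0 * float(stats.t.sf(abs(t), df_within))
        t_stats.append(t)
        raw_p.append(p)

    finite = np.isfinite(raw_p)
    flags = np.zeros(len(pairs), dtype=bool)
    if finite.any():
        rej, _ = bky_adjust(np.asarray(raw_p)[finite], q)
        flags[np.nonzero(finite)[0]] = rej
    tests = [
        PairwiseRegionTest(
            region_a=ra,
            region_b=rb,
            t_stat=float(t_stats[i]),
            p_value=float(raw_p[i]),
            significant=bool(flags[i]),
            q_level=q,
            degenerate=bool(not np.isfinite(raw_p[i])),
        )
        for i, (ra, rb) in enumerate(pairs)
    ]
    return float(f_stat), float(anova_p) if np.isfinite(anova_p) else np.nan, tests
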