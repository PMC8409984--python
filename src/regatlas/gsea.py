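"""Gene-set enrichment from scratch.

Target-vs-rest gene ranking (signal-to-noise), weighted running-sum
enrichment score, gene-set permutation null, normalized score, and a
per-list BH FDR with the positive-score significance flag.

Gene-set (not phenotype) permutation is used throughout: regions can
have a single replicate, which makes phenotype permutation degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exprio import ExpressionMatrix, GeneList

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "rank_genes",
    "enrichment_score",
    "permutation_null",
    "normalize_and_test",
    "gsea_all",
]

SN_SD_FLOOR_FRACTION = 0.2  # SD floored at 0.2*|mean| (canonical GSEA)
SN_SD_FLOOR_ABS = 1e-8


@dataclass
class RankedList:
    """Genes ordered by a descending ranking statistic for one target."""

    target: str
    genes: tuple[str, ...]
    statistic: np.ndarray

    def __post_init__(self) -> None:
        self.statistic = np.asarray(self.statistic, dtype=float)
        if len(self.genes) != self.statistic.size:
            raise ValueError("genes/statistic length mismatch")
        if not np.all(np.isfinite(self.statistic)):
            raise ValueError("ranking statistic must be finite")
        if np.any(np.diff(self.statistic) > 0):
            raise ValueError("ranking statistic must be non-increasing")

    def positions(self, gene_set: Iterable[str]) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.genes)}
        return np.array(sorted(index[g] for g in gene_set if g in index), dtype=int)


@dataclass
class EnrichmentResult:
    target: str
    list_name: str
    es: float
    nes: float
    p_perm: float
    fdr: float
    n_permutations: int
    seed: int
    n_genes_in_set: int
    significant: bool = False
    nes_defined: bool = True


def _floored_sd(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1) if x.shape[1] > 1 else np.zeros(x.shape[0])
    floor = np.maximum(SN_SD_FLOOR_FRACTION * np.abs(mean), SN_SD_FLOOR_ABS)
    return np.maximum(sd, floor)


def rank_genes(
    matrix: ExpressionMatrix,
    target_samples: Sequence[str],
    other_samples: Sequence[str],
    metric: str = "s2n",
) -> RankedList:
    """Rank genes by target-vs-rest signal-to-noise, descending.

    s2n = (mean_t - mean_o) / (sd_t + sd_o) with each group SD floored
    at max(0.2*|group mean|, 1e-8); ties break lexicographically by
    gene id.
    """
    if metric != "s2n":
        raise ValueError(f"unknown ranking metric {metric!r}")
    if len(target_samples) < 1 or len(other_samples) < 2:
        raise ValueError("need >=1 target and >=2 other samples")
    df = matrix.to_frame()
    xt = df[list(target_samples)].to_numpy()
    xo = df[list(other_samples)].to_numpy()
    stat = (xt.mean(axis=1) - xo.mean(axis=1)) / (_floored_sd(xt) + _floored_sd(xo))
    order = sorted(range(len(stat)), key=lambda i: (-stat[i], matrix.gene_ids[i]))
    return RankedList(
        target="+".join(target_samples),
        genes=tuple(matrix.gene_ids[i] for i in order),
        statistic=stat[np.array(order)],
    )


def enrichment_score(
    ranked: RankedList, gene_set: Iterable[str], exponent: float = 1.0
) -> tuple[float, np.ndarray, int]:
    """Weighted Kolmogorov-Smirnov-like running-sum enrichment score.

    Hits increment by ``|statistic|^exponent`` normalized over the
    set's hits; misses decrement by ``1/(N - N_hits)``.  Returns the
    signed maximum deviation, the full running sum, and its peak index.
    """
    positions = ranked.positions(gene_set)
    if positions.size == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    return _es_from_positions(ranked.statistic, positions, exponent)


def _es_from_positions(
    statistic: np.ndarray, positions: np.ndarray, exponent: float
) -> tuple[float, np.ndarray, int]:
    n = statistic.size
    n_hits = positions.size
    if n_hits >= n:
        raise ValueError("gene set covers the whole ranked list")
    weights = np.abs(statistic[positions]) ** exponent
    total = weights.sum()
    if total == 0:
        # all hit statistics are exactly zero: fall back to equal weights
        weights = np.ones(n_hits)
        total = float(n_hits)
    steps = np.full(n, -1.0 / (n - n_hits))
    steps[positions] = weights / total
    running = np.cumsum(steps)
    # earliest position within rounding tolerance of the max deviation,
    # so exact +/- ties resolve deterministically, not by float noise
    deviations = np.abs(running)
    peak = int(np.nonzero(deviations >= deviations.max() - 1e-12)[0][0])
    return float(running[peak]), running, peak


def permutation_null(
    ranked: RankedList,
    set_size: int,
    exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """ES of ``n_perm`` uniformly random same-size gene sets."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(ranked.genes)
    if not 1 <= set_size < n:
        raise ValueError("set_size must be in [1, n_genes)")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pos = rng.choice(n, size=set_size, replace=False)
        null[i], _, _ = _es_from_positions(ranked.statistic, np.sort(pos), exponent)
    return null


def normalize_and_test(es: float, null: np.ndarray) -> tuple[float, float, bool]:
    """NES and permutation p against a same-sign null.

    NES = ES / mean(|null values of matching sign|);
    p = (1 + #{same-sign null as or more extreme}) / (n_perm + 1).
    Returns ``(nes, p, nes_defined)``; with no same-sign null values
    the NES is undefined (returned as NaN, flagged).
    """
    null = np.asarray(null, dtype=float)
    n_perm = null.size
    if es == 0:
        return 0.0, 1.0, True
    same_sign = null[null > 0] if es > 0 else null[null < 0]
    if same_sign.size == 0:
        p = 1.0 / (n_perm + 1)
        return float("nan"), p, False
    nes = es / np.abs(same_sign).mean()
    extreme = int((same_sign >= es).sum()) if es > 0 else int((same_sign <= es).sum())
    p = (1 + extreme) / (n_perm + 1)
    return float(nes), float(p), True


def gsea_all(
    matrix: ExpressionMatrix,
    lists: Sequence[GeneList],
    level: str = "group",
    n_perm: int = 1000,
    seed: int = 0,
    q: float = 0.05,
    exponent: float = 1.0,
) -> pd.DataFrame:
    """Run enrichment for every (target, list) pair.

    ``level`` is "group" (samples aggregated by system group, the
    figure-level design) or "region" (each region's replicates vs all
    others).  Significance flag = positive ES and per-list BH FDR < q.
    Lists with no genes in the matrix are skipped (column
    ``skipped_lists`` is recorded in ``DataFrame.attrs``).
    """
    if level == "group":
        targets = _ordered_unique(s.group for s in matrix.samples)
        members = {t: matrix.samples_for(group=t) for t in targets}
    elif level == "region":
        targets = matrix.regions
        members = {t: matrix.samples_for(region=t) for t in targets}
    else:
        raise ValueError("level must be 'group' or 'region'")
    all_ids = matrix.sample_ids
    gene_universe = set(matrix.gene_ids)

    rows: list[EnrichmentResult] = []
    skipped: list[str] = []
    null_cache: dict[tuple[str, int], np.ndarray] = {}
    for ti, target in enumerate(targets):
        target_samples = members[target]
        other_samples = [s for s in all_ids if s not in set(target_samples)]
        ranked = rank_genes(matrix, target_samples, other_samples)
        ranked.target = target
        for li, gl in enumerate(lists):
            present = [g for g in gl.genes if g in gene_universe]
            if not present:
                if gl.name not in skipped:
                    skipped.append(gl.name)
                continue
            es, _, _ = enrichment_score(ranked, present, exponent)
            key = (target, len(present))
            if key not in null_cache:
                # per-(target,size) sub-seed keeps permutations independent
                null_cache[key] = permutation_null(
                    ranked,
                    len(present),
                    exponent,
                    n_perm,
                    seed=seed + 1000 * ti + len(present),
                )
            nes, p, defined = normalize_and_test(es, null_cache[key])
            rows.append(
                EnrichmentResult(
                    target=target,
                    list_name=gl.name,
                    es=es,
                    nes=nes,
                    p_perm=p,
                    fdr=1.0,
                    n_permutations=n_perm,
                    seed=seed,
                    n_genes_in_set=len(present),
                    nes_defined=defined,
                )
            )
    df = pd.DataFrame(
        {
            "target": [r.target for r in rows],
            "list_name": [r.list_name for r in rows],
            "es": [r.es for r in rows],
            "nes": [r.nes for r in rows],
            "p_perm": [r.p_perm for r in rows],
            "n_genes_in_set": [r.n_genes_in_set for r in rows],
            "n_permutations": [r.n_permutations for r in rows],
            "nes_defined": [r.nes_defined for r in rows],
        }
    )
    if not df.empty:
        fdr = np.empty(len(df))
        for name, sub in df.groupby("list_name"):
            _, qvals, _, _ = multipletests(sub["p_perm"], method="fdr_bh")
            fdr[sub.index] = qvals
        df["fdr"] = fdr
        df["significant"] = (df["es"] > 0) & (df["fdr"] < q)
    else:
        df["fdr"] = []
        df["significant"] = []
    df.attrs["skipped_lists"] = skipped
    df.attrs["seed"] = seed
    return df


def _ordered_unique(items: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for x in items:
        seen.setdefault(x, None)
    return list(seen)
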