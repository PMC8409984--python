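"""Synthetic regional expression atlases with planted ground truth.

The generator plants three kinds of structure on top of a log-normal
TPM baseline:

* region-specific marker genes (a multiplicative bump in one region),
* blocks of co-expressed genes sharing a latent region-group profile,
* a developmental-stage program that separates embryonic/stem-cell
  samples from adult brain samples.

All deterministic structure (baselines, marker placement, module
profiles, stage-program gene choice) is a pure function of the config
so that, with ``noise_sd = 0``, the matrix is identical across seeds;
the seed drives only replicate noise and downstream sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .exprio import (
    ExpressionMatrix,
    GeneList,
    SampleMetadata,
    write_expression_matrix,
    write_gene_lists,
    write_sample_metadata,
)

__all__ = [
    "DEFAULT_REGION_GROUPS",
    "AtlasConfig",
    "SyntheticTruth",
    "ListSpec",
    "generate_atlas",
    "generate_gene_lists",
    "write_atlas",
]

# Mirrors a 22-region (adult + embryonic) + 2 stem-cell-line design;
# fully overridable through AtlasConfig.region_groups.
DEFAULT_REGION_GROUPS: dict[str, str] = {
    # homeostatic (hypothalamus + brainstem)
    "ARH": "homeostatic",
    "PVH": "homeostatic",
    "DMH": "homeostatic",
    "VMH": "homeostatic",
    "LHA": "homeostatic",
    "PB": "homeostatic",
    "NTS": "homeostatic",
    "DVC": "homeostatic",
    # executive (cortical)
    "ACA": "executive",
    "FRP": "executive",
    "ENT": "executive",
    # reward
    "ACB": "reward",
    "VTA": "reward",
    # cerebellum
    "CENT2": "cerebellum",
    "CUL45": "cerebellum",
    "UVU": "cerebellum",
    "CBN": "cerebellum",
    "FL": "cerebellum",
    # embryonic brain
    "eFB": "embryonic",
    "eHy": "embryonic",
    "eMB": "embryonic",
    "eHB": "embryonic",
    # stem-cell lines
    "B6-1": "stemcell",
    "B6-2": "stemcell",
}

TPM_TOTAL = 1_000_000.0
# fixed stream for deterministic structure that should not vary with the
# config seed (keeps the noise_sd=0 matrix seed-invariant)
_STRUCTURE_SEED = 987_654_321


@dataclass
class AtlasConfig:
    """Parameters of a synthetic atlas.

    ``replicates_per_region`` may be a single count applied everywhere
    or a per-region mapping (counts 1-4 mimic the real design).
    """

    region_groups: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REGION_GROUPS)
    )
    replicates_per_region: int | Mapping[str, int] = 2
    n_genes: int = 400
    n_modules_planted: int = 5
    module_size: int = 30
    marker_genes_per_region: int = 3
    marker_fold_change: float = 30.0
    module_fold_change: float = 8.0
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 0.8
    noise_sd: float = 0.2
    seed: int = 0
    # developmental-stage program (drives the adult/embryonic sample split)
    developmental_groups: tuple[str, ...] = ("embryonic", "stemcell")
    stage_shift: float = 0.8
    stage_gene_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not self.region_groups:
            raise ValueError("region_groups must be non-empty")
        for r, g in self.region_groups.items():
            if not g:
                raise ValueError(f"region {r!r} has an empty group label")
        counts = {
            "n_genes": self.n_genes,
            "n_modules_planted": self.n_modules_planted,
            "module_size": self.module_size,
            "marker_genes_per_region": self.marker_genes_per_region,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        for r in self.regions:
            if self.replicates_for(r) < 1:
                raise ValueError(f"replicates for region {r!r} must be >= 1")
        if self.marker_fold_change <= 1:
            raise ValueError(
                f"marker_fold_change must be > 1, got {self.marker_fold_change}"
            )
        if self.module_fold_change <= 1:
            raise ValueError(
                f"module_fold_change must be > 1, got {self.module_fold_change}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.stage_gene_fraction <= 1:
            raise ValueError("stage_gene_fraction must be in [0, 1]")
        needed = (
            self.n_modules_planted * self.module_size
            + len(self.regions) * self.marker_genes_per_region
        )
        if self.n_genes < needed:
            raise ValueError(
                f"n_genes={self.n_genes} is too small: need at least "
                f"{needed} = n_modules_planted*module_size "
                f"({self.n_modules_planted}*{self.module_size}) + "
                f"n_regions*marker_genes_per_region "
                f"({len(self.regions)}*{self.marker_genes_per_region})"
            )

    @property
    def regions(self) -> list[str]:
        return list(self.region_groups)

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.region_groups.values():
            seen.setdefault(g, None)
        return list(seen)

    def replicates_for(self, region: str) -> int:
        if isinstance(self.replicates_per_region, Mapping):
            return int(self.replicates_per_region.get(region, 1))
        return int(self.replicates_per_region)


@dataclass
class SyntheticTruth:
    """Planted structure of a generated atlas."""

    marker_of: dict[str, str]
    module_of: dict[str, int]
    module_group: dict[int, str]
    region_groups: dict[str, str]
    gene_ids: list[str]
    list_target_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mods = sorted(set(self.module_of.values()))
        if mods and mods != list(range(1, len(mods) + 1)):
            raise ValueError(f"module ids must be contiguous from 1, got {mods}")
        overlap = set(self.marker_of) & set(self.module_of)
        if overlap:
            raise ValueError(f"markers overlap planted modules: {sorted(overlap)}")

    def planted_peak_group(self, gene: str) -> str | None:
        """Region group where the gene's expression is planted to peak."""
        if gene in self.marker_of:
            return self.region_groups[self.marker_of[gene]]
        if gene in self.module_of:
            return self.module_group[self.module_of[gene]]
        return None

    def genes_peaking_in(self, group: str) -> list[str]:
        return [g for g in self.gene_ids if self.planted_peak_group(g) == group]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "marker_of": self.marker_of,
            "module_of": self.module_of,
            "module_group": {str(k): v for k, v in self.module_group.items()},
            "region_groups": self.region_groups,
            "gene_ids": self.gene_ids,
            "list_target_group": self.list_target_group,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            marker_of=d["marker_of"],
            module_of={k: int(v) for k, v in d["module_of"].items()},
            module_group={int(k): v for k, v in d["module_group"].items()},
            region_groups=d["region_groups"],
            gene_ids=d["gene_ids"],
            list_target_group=d.get("list_target_group", {}),
        )


def _baseline_log_means(config: AtlasConfig) -> np.ndarray:
    """Deterministic log10 baselines: shuffled normal quantiles."""
    n = config.n_genes
    q = stats.norm.ppf((np.arange(n) + 0.5) / n)
    mu = config.baseline_log_mean + config.baseline_log_sd * q
    perm = np.random.default_rng(_STRUCTURE_SEED).permutation(n)
    return mu[perm]


def _plan_structure(config: AtlasConfig) -> tuple[list[str], SyntheticTruth, np.ndarray]:
    """Gene ids, truth, and the deterministic log10 effect matrix."""
    regions = config.regions
    groups = config.groups
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]

    marker_of: dict[str, int] = {}
    module_of: dict[str, int] = {}
    idx = 0
    marker_map: dict[str, str] = {}
    for r in regions:
        for _ in range(config.marker_genes_per_region):
            marker_map[gene_ids[idx]] = r
            idx += 1
    module_group: dict[int, str] = {}
    for m in range(1, config.n_modules_planted + 1):
        module_group[m] = groups[(m - 1) % len(groups)]
        for _ in range(config.module_size):
            module_of[gene_ids[idx]] = m
            idx += 1
    background = gene_ids[idx:]

    effect = np.zeros((n, len(regions)))
    region_index = {r: j for j, r in enumerate(regions)}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for g, r in marker_map.items():
        effect[gene_index[g], region_index[r]] = np.log10(config.marker_fold_change)

    log_mod = np.log10(config.module_fold_change)
    for g, m in module_of.items():
        i = gene_index[g]
        primary = module_group[m]
        for r in regions:
            if config.region_groups[r] == primary:
                effect[i, region_index[r]] += log_mod
        # secondary half-amplitude signature keeps modules sharing a
        # primary group distinguishable (deterministic)
        if config.n_modules_planted > len(groups):
            secondary = groups[m % len(groups)]
            if secondary != primary:
                for r in regions:
                    if config.region_groups[r] == secondary:
                        effect[i, region_index[r]] += 0.5 * log_mod

    # developmental-stage program over a deterministic slice of the
    # background genes: shifts embryonic+stemcell, and a second slice
    # shifts stemcell only (separates mESC within the embryonic clade)
    dev = set(config.developmental_groups) & set(groups)
    if dev and config.stage_gene_fraction > 0 and background:
        stride = max(1, round(1.0 / config.stage_gene_fraction))
        dev_cols = [region_index[r] for r in regions if config.region_groups[r] in dev]
        stem_cols = [
            region_index[r] for r in regions if config.region_groups[r] == "stemcell"
        ]
        for j, g in enumerate(background):
            i = gene_index[g]
            if j % stride == 0:
                effect[i, dev_cols] += config.stage_shift
            elif j % stride == 1 and stem_cols:
                effect[i, stem_cols] += config.stage_shift

    truth = SyntheticTruth(
        marker_of=marker_map,
        module_of=module_of,
        module_group=module_group,
        region_groups=dict(config.region_groups),
        gene_ids=gene_ids,
    )
    return gene_ids, truth, effect


def generate_atlas(config: AtlasConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a TPM atlas plus its planted truth.

    Each sample column is renormalized to a total of 1e6 TPM.  Markers
    have a ``marker_fold_change``-times-higher pre-noise mean in their
    region; genes of a planted module share one latent region profile
    plus i.i.d. replicate noise of scale ``noise_sd`` (log10).
    """
    gene_ids, truth, effect = _plan_structure(config)
    rng = np.random.default_rng(config.seed)
    mu = _baseline_log_means(config)

    samples: list[SampleMetadata] = []
    cols: list[np.ndarray] = []
    for j, r in enumerate(config.regions):
        for rep in range(1, config.replicates_for(r) + 1):
            samples.append(
                SampleMetadata(
                    sample_id=f"{r}_{rep}",
                    region=r,
                    group=config.region_groups[r],
                    replicate=rep,
                )
            )
            log_tpm = mu + effect[:, j]
            if config.noise_sd > 0:
                log_tpm = log_tpm + config.noise_sd * rng.standard_normal(len(gene_ids))
            cols.append(10.0 ** log_tpm)
    values = np.column_stack(cols)
    values *= TPM_TOTAL / values.sum(axis=0, keepdims=True)
    return ExpressionMatrix(values, gene_ids, samples), truth


@dataclass(frozen=True)
class ListSpec:
    """Recipe for one synthetic gene list.

    ``strength`` is the fraction of genes drawn from genes planted to
    peak in ``target_group``; the rest are drawn uniformly from the
    whole gene universe.  ``shared_with``/``n_shared`` force an exact
    overlap with a previously generated list.
    """

    name: str
    size: int
    target_group: str
    strength: float = 1.0
    category: str | None = None
    shared_with: str | None = None
    n_shared: int = 0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"list {self.name!r}: size must be >= 1")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError(f"list {self.name!r}: strength must be in [0, 1]")
        if self.n_shared < 0 or self.n_shared > self.size:
            raise ValueError(f"list {self.name!r}: invalid n_shared")


def generate_gene_lists(
    truth: SyntheticTruth, specs: Sequence[ListSpec], seed: int = 0
) -> list[GeneList]:
    """Draw gene lists preferentially from genes peaking in a target group."""
    rng = np.random.default_rng(seed)
    known_groups = set(truth.region_groups.values())
    out: dict[str, GeneList] = {}
    for spec in specs:
        if spec.target_group not in known_groups:
            raise ValueError(
                f"list {spec.name!r}: target group {spec.target_group!r} not in "
                f"truth groups {sorted(known_groups)}"
            )
        chosen: list[str] = []
        if spec.shared_with is not None:
            if spec.shared_with not in out:
                raise ValueError(
                    f"list {spec.name!r}: shared_with list {spec.shared_with!r} "
                    "not generated yet"
                )
            donor = list(out[spec.shared_with].genes)
            if spec.n_shared > len(donor):
                raise ValueError(
                    f"list {spec.name!r}: n_shared={spec.n_shared} exceeds donor size"
                )
            chosen.extend(rng.choice(donor, size=spec.n_shared, replace=False))
        pool_target = [g for g in truth.genes_peaking_in(spec.target_group) if g not in chosen]
        n_remaining = spec.size - len(chosen)
        n_target = int(round(spec.strength * n_remaining))
        if n_target > len(pool_target):
            raise ValueError(
                f"list {spec.name!r}: requested {n_target} genes peaking in "
                f"{spec.target_group!r} but only {len(pool_target)} are available"
            )
        chosen.extend(rng.choice(pool_target, size=n_target, replace=False))
        pool_rest = [g for g in truth.gene_ids if g not in chosen]
        n_rest = spec.size - len(chosen)
        if spec.shared_with is not None:
            # keep the forced overlap exact: do not re-draw donor genes
            pool_rest = [g for g in pool_rest if g not in set(out[spec.shared_with].genes)]
        if n_rest > len(pool_rest):
            raise ValueError(f"list {spec.name!r}: size exceeds available genes")
        chosen.extend(rng.choice(pool_rest, size=n_rest, replace=False))
        truth.list_target_group[spec.name] = spec.target_group
        out[spec.name] = GeneList(
            name=spec.name,
            category=spec.category or spec.name,
            genes=tuple(chosen),
        )
    return list(out.values())


def write_atlas(
    matrix: ExpressionMatrix,
    truth: SyntheticTruth,
    out_dir: str | Path,
    lists: Sequence[GeneList] | None = None,
) -> dict[str, Path]:
    """Dump matrix / metadata / truth (and optional lists) as TSV+JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.json",
    }
    write_expression_matrix(matrix, paths["matrix"])
    write_sample_metadata(matrix.samples, paths["metadata"])
    truth.to_json(paths["truth"])
    if lists is not None:
        paths["lists"] = out / "lists.tsv"
        write_gene_lists(lists, paths["lists"])
    return paths
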