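"""Expression matrix / metadata / gene-list I/O and elementary transforms.

File conventions: tab-separated, UTF-8, ``.`` decimal, mandatory header
row.  The expression matrix is genes-as-rows with a leading ``gene_id``
column; metadata columns are fixed as
``(sample_id, region, group, replicate, batch)``; gene-list files are
two-column ``(gene, list_name)`` with an optional third ``category``
column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMetadata",
    "ExpressionMatrix",
    "RegionProfile",
    "GeneList",
    "SymbolMappingReport",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_gene_lists",
    "write_gene_lists",
    "aggregate_transcripts_to_genes",
    "average_replicates",
    "scale_per_gene",
    "map_symbols",
]

METADATA_COLUMNS = ("sample_id", "region", "group", "replicate", "batch")


@dataclass(frozen=True)
class SampleMetadata:
    """One sequenced sample: a replicate of one anatomical region."""

    sample_id: str
    region: str
    group: str
    replicate: int
    batch: str | None = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(
                f"replicate must be >= 1, got {self.replicate} for sample "
                f"{self.sample_id!r}"
            )


class ExpressionMatrix:
    """Gene x sample TPM matrix with per-sample metadata.

    Parameters
    ----------
    values
        ``(n_genes, n_samples)`` array of non-negative TPM values.
    gene_ids
        Unique gene identifiers, one per row.
    samples
        One :class:`SampleMetadata` per column, in column order.
    """

    def __init__(
        self,
        values: np.ndarray | pd.DataFrame,
        gene_ids: Sequence[str],
        samples: Sequence[SampleMetadata],
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if values.shape != (len(gene_ids), len(samples)):
            raise ValueError(
                f"shape mismatch: values {values.shape} vs "
                f"{len(gene_ids)} genes x {len(samples)} samples"
            )
        dup = _duplicates(gene_ids)
        if dup:
            raise ValueError(f"duplicate gene ids: {sorted(dup)}")
        sample_ids = [s.sample_id for s in samples]
        dup = _duplicates(sample_ids)
        if dup:
            raise ValueError(f"duplicate sample ids: {sorted(dup)}")
        pairs = [(s.region, s.replicate) for s in samples]
        dup = _duplicates(pairs)
        if dup:
            raise ValueError(f"duplicate (region, replicate) pairs: {sorted(dup)}")
        neg = np.argwhere(values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative expression value at gene {gene_ids[i]!r}, "
                f"sample {sample_ids[j]!r}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite expression values")
        self.values = values
        self.gene_ids = list(gene_ids)
        self.samples = list(samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def regions(self) -> list[str]:
        """Region ids in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.region, None)
        return list(seen)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def samples_for(self, *, region: str | None = None, group: str | None = None) -> list[str]:
        """Sample ids matching a region and/or group filter."""
        out = []
        for s in self.samples:
            if region is not None and s.region != region:
                continue
            if group is not None and s.group != group:
                continue
            out.append(s.sample_id)
        return out


@dataclass
class RegionProfile:
    """Gene x region matrix of replicate-averaged TPM."""

    values: np.ndarray
    gene_ids: list[str]
    regions: list[str]
    region_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.regions)):
            raise ValueError("RegionProfile dimension mismatch")
        if (self.values < 0).any():
            raise ValueError("negative values in RegionProfile")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.regions)


@dataclass(frozen=True)
class GeneList:
    """A named, ordered set of gene symbols with a category label."""

    name: str
    category: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene list {self.name!r} is empty")
        dup = _duplicates(self.genes)
        if dup:
            raise ValueError(f"duplicate genes in list {self.name!r}: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass(frozen=True)
class SymbolMappingReport:
    """Which symbols of a list survived mapping onto a matrix."""

    list_name: str
    n_input: int
    n_mapped: int
    dropped: tuple[str, ...]


def _duplicates(items: Iterable) -> set:
    seen: set = set()
    dup: set = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file {path} missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        batch = getattr(row, "batch", None)
        if batch is not None and (pd.isna(batch) or batch == ""):
            batch = None
        records.append(
            SampleMetadata(
                sample_id=str(row.sample_id),
                region=str(row.region),
                group=str(row.group),
                replicate=int(row.replicate),
                batch=batch,
            )
        )
    return records


def write_sample_metadata(samples: Sequence[SampleMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (s.sample_id, s.region, s.group, s.replicate, s.batch if s.batch else "")
            for s in samples
        ],
        columns=list(METADATA_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def read_expression_matrix(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TPM TSV plus its metadata TSV.

    The matrix header must consist of sample ids that all appear in the
    metadata; metadata entries without a matrix column are an error too,
    so the pair of files always describes the same set of samples.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    dup = _duplicates(df.index)
    if dup:
        raise ValueError(f"duplicate gene ids in {path}: {sorted(dup)}")
    meta = read_sample_metadata(metadata_path)
    by_id = {s.sample_id: s for s in meta}
    unknown = [c for c in df.columns if c not in by_id]
    if unknown:
        raise ValueError(f"samples in matrix header absent from metadata: {unknown}")
    absent = [sid for sid in by_id if sid not in set(df.columns)]
    if absent:
        raise ValueError(f"metadata samples absent from matrix header: {absent}")
    if not all(np.issubdtype(d, np.number) for d in df.dtypes):
        bad = [c for c, d in df.dtypes.items() if not np.issubdtype(d, np.number)]
        raise ValueError(f"non-numeric values in columns {bad} of {path}")
    values = df.to_numpy(dtype=float)
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative value in {path} at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    samples = [by_id[c] for c in df.columns]
    return ExpressionMatrix(values, [str(g) for g in df.index], samples)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "gene_id"
    # repr round-trips float64 exactly through pandas' parser
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_gene_lists(path: str | Path) -> list[GeneList]:
    """Read (gene, list_name[, category]) TSV into GeneList objects.

    Lists come back in order of first appearance; genes keep file order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene" not in df.columns or "list_name" not in df.columns:
        raise ValueError(f"gene-list file {path} must have 'gene' and 'list_name' columns")
    has_cat = "category" in df.columns
    order: dict[str, list[str]] = {}
    cats: dict[str, str] = {}
    for row in df.itertuples(index=False):
        name = str(row.list_name)
        order.setdefault(name, [])
        gene = str(row.gene)
        if gene in order[name]:
            raise ValueError(f"duplicate gene {gene!r} in list {name!r} in {path}")
        order[name].append(gene)
        if has_cat and name not in cats:
            cats[name] = str(row.category)
    return [
        GeneList(name=name, category=cats.get(name, name), genes=tuple(genes))
        for name, genes in order.items()
    ]


def write_gene_lists(lists: Sequence[GeneList], path: str | Path) -> None:
    rows = [
        (g, gl.name, gl.category)
        for gl in lists
        for g in gl.genes
    ]
    pd.DataFrame(rows, columns=["gene", "list_name", "category"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def aggregate_transcripts_to_genes(
    matrix: ExpressionMatrix, transcript_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Sum transcript-level TPM rows to gene level.

    Every transcript (row id) must be mapped to exactly one gene; the
    per-sample TPM total is conserved exactly.  Genes are emitted in
    order of first appearance among the transcripts.
    """
    unmapped = [t for t in matrix.gene_ids if t not in transcript_to_gene]
    if unmapped:
        raise ValueError(f"unmapped transcripts: {unmapped}")
    gene_order: dict[str, list[int]] = {}
    for i, t in enumerate(matrix.gene_ids):
        gene_order.setdefault(transcript_to_gene[t], []).append(i)
    out = np.empty((len(gene_order), matrix.values.shape[1]))
    for k, rows in enumerate(gene_order.values()):
        out[k] = matrix.values[rows].sum(axis=0)
    return ExpressionMatrix(out, list(gene_order), matrix.samples)


def average_replicates(
    matrix: ExpressionMatrix, regions: Sequence[str] | None = None
) -> RegionProfile:
    """Arithmetic mean of TPM across the replicates of each region.

    Regions with a single replicate pass through unchanged.  ``regions``
    restricts/orders the output; default is the matrix's region order.
    """
    if regions is None:
        regions = matrix.regions
    cols = []
    groups: dict[str, str] = {}
    idx_by_region: dict[str, list[int]] = {}
    for j, s in enumerate(matrix.samples):
        idx_by_region.setdefault(s.region, []).append(j)
        groups.setdefault(s.region, s.group)
    for r in regions:
        if r not in idx_by_region:
            raise ValueError(f"region {r!r} has no samples in the matrix")
        cols.append(matrix.values[:, idx_by_region[r]].mean(axis=1))
    return RegionProfile(
        values=np.column_stack(cols),
        gene_ids=list(matrix.gene_ids),
        regions=list(regions),
        region_groups={r: groups[r] for r in regions},
    )


def scale_per_gene(profile: RegionProfile | pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score (population SD); constant rows map to zeros."""
    df = profile.to_frame() if isinstance(profile, RegionProfile) else profile
    values = df.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    centered = values - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, centered / np.where(sd == 0, 1.0, sd), 0.0)
    return pd.DataFrame(scaled, index=df.index, columns=df.columns)


def _case_normalize(symbol: str) -> str:
    # all-caps human style (LEPR) -> title-case mouse style (Lepr)
    if symbol.isupper():
        return symbol.capitalize()
    return symbol


def map_symbols(
    gene_list: GeneList,
    gene_ids: Sequence[str],
    mode: str = "exact",
) -> tuple[GeneList, SymbolMappingReport]:
    """Restrict a gene list to symbols present in a matrix.

    ``mode="case-normalize"`` converts all-uppercase symbols to
    title case before matching (human list onto mouse matrix).  Symbols
    that still fail to match are dropped and reported; an empty result
    is an error.
    """
    if mode not in ("exact", "case-normalize"):
        raise ValueError(f"unknown mapping mode {mode!r}")
    universe = set(gene_ids)
    kept: list[str] = []
    dropped: list[str] = []
    for g in gene_list.genes:
        cand = g if mode == "exact" else (_case_normalize(g) if g not in universe else g)
        if cand in universe:
            if cand not in kept:
                kept.append(cand)
        else:
            dropped.append(g)
    report = SymbolMappingReport(
        list_name=gene_list.name,
        n_input=len(gene_list.genes),
        n_mapped=len(kept),
        dropped=tuple(dropped),
    )
    if not kept:
        raise ValueError(
            f"gene list {gene_list.name!r} is empty after mapping onto the matrix"
        )
    return GeneList(gene_list.name, gene_list.category, tuple(kept)), report
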