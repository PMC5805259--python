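"""Taxon-by-sample count tables: construction, normalisation, rarefaction.

Tables are built from per-read assignments by rolling each read up to its
ancestor at a target rank (family or species). Reads resolved shallower than
the target rank — and reads with no consistent placement at all — accrue to a
single UNDETERMINED row, so column sums always conserve the number of
assigned reads per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .constants import (
    POOL_ALL,
    POOL_VIRUS_AND_BACTERIA,
    POOL_VIRUS_ONLY,
    UNDETERMINED,
)
from .errors import ValidationError
from .taxonomy import TaxonomyTree

if TYPE_CHECKING:  # pragma: no cover
    from .assignment import ReadAssignment


@dataclass
class TaxonTable:
    """A taxa × samples matrix of non-negative integer read counts.

    ``counts`` rows are lineage labels (plus optionally the UNDETERMINED
    row); columns are sample ids. ``metadata``, when present, is indexed by
    sample id and carries at least a ``sex`` column.
    """

    rank: str
    counts: pd.DataFrame
    metadata: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.rank not in ("family", "species"):
            raise ValidationError(f"unsupported table rank {self.rank!r}")
        if not self.counts.index.is_unique or not self.counts.columns.is_unique:
            raise ValidationError("taxon table labels must be unique")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValidationError("taxon table counts must be non-negative")
        self.counts = self.counts.astype(np.int64)
        if self.metadata is not None:
            missing = [s for s in self.counts.columns if s not in self.metadata.index]
            if missing:
                raise ValidationError(f"samples missing from metadata: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def drop_samples(self, sample_ids: Iterable[str]) -> "TaxonTable":
        keep = [s for s in self.counts.columns if s not in set(sample_ids)]
        return TaxonTable(self.rank, self.counts[keep], self.metadata)

    def with_counts(self, counts: pd.DataFrame) -> "TaxonTable":
        return TaxonTable(self.rank, counts, self.metadata)


def _pool_selector(pool: str):
    if pool == POOL_ALL:
        return lambda a: True
    if pool == POOL_VIRUS_ONLY:
        return lambda a: not a.bacterial_hit
    if pool == POOL_VIRUS_AND_BACTERIA:
        return lambda a: a.bacterial_hit
    raise ValidationError(f"unknown homology pool {pool!r}")


def build_taxon_table(
    per_sample_assignments: Mapping[str, Iterable["ReadAssignment"]],
    tree: TaxonomyTree,
    rank: str,
    pool: str = POOL_ALL,
    metadata: Optional[pd.DataFrame] = None,
) -> TaxonTable:
    """Roll per-read assignments up to ``rank`` and tabulate counts per sample.

    Each assignment contributes one count to its ancestor at ``rank``; an
    assignment resolved shallower than ``rank`` (e.g. a genus-level LCA when
    tabulating species) or assigned UNDETERMINED increments the UNDETERMINED
    row. ``pool`` restricts which homology classes are counted.
    """
    if rank not in ("family", "species"):
        raise ValidationError(f"unknown table rank {rank!r}")
    include = _pool_selector(pool)
    label_cache: dict[str, str] = {}
    columns: dict[str, dict[str, int]] = {}
    for sample_id, assignments in per_sample_assignments.items():
        col: dict[str, int] = {}
        for assignment in assignments:
            if not include(assignment):
                continue
            label = _roll_up_label(assignment.taxon_id, tree, rank, label_cache)
            col[label] = col.get(label, 0) + 1
        columns[sample_id] = col
    taxa = sorted({t for col in columns.values() for t in col if t != UNDETERMINED})
    if any(UNDETERMINED in col for col in columns.values()):
        taxa.append(UNDETERMINED)
    counts = pd.DataFrame(
        {s: [columns[s].get(t, 0) for t in taxa] for s in columns},
        index=pd.Index(taxa, name="taxon"),
        dtype=np.int64,
    )
    return TaxonTable(rank, counts, metadata)


def _roll_up_label(
    taxon_id: str, tree: TaxonomyTree, rank: str, cache: dict[str, str]
) -> str:
    if taxon_id == UNDETERMINED:
        return UNDETERMINED
    key = taxon_id
    if key not in cache:
        ancestor = tree.ancestor_at_rank(taxon_id, rank)
        cache[key] = UNDETERMINED if ancestor is None else tree.lineage_label(ancestor)
    return cache[key]


@dataclass
class RelativeAbundance:
    """Column-normalised proportions; all-zero samples are left as zeros and
    listed in ``zero_samples``."""

    proportions: pd.DataFrame
    zero_samples: list[str] = field(default_factory=list)


def relative_abundance(table: TaxonTable) -> RelativeAbundance:
    sums = table.sample_sums()
    zero_samples = [s for s in table.samples if sums[s] == 0]
    safe = sums.replace(0, 1)
    proportions = table.counts.astype(float).div(safe, axis=1)
    return RelativeAbundance(proportions, zero_samples)


def presence_absence(table: TaxonTable, min_count: int = 1) -> pd.DataFrame:
    """Binary detection matrix: 1 iff count ≥ ``min_count``.

    The UNDETERMINED row is dropped — unplaced reads are real reads for
    sequencing-depth purposes but not a taxon whose prevalence is meaningful.
    """
    if min_count < 1:
        raise ValidationError("min_count must be ≥ 1")
    binary = (table.counts >= min_count).astype(np.int64)
    return binary.drop(index=UNDETERMINED, errors="ignore")


@dataclass
class RarefactionResult:
    table: TaxonTable
    dropped_samples: list[str]
    depth: int
    seed: int


def subsample_table(table: TaxonTable, depth: int, seed: int) -> RarefactionResult:
    """Rarefy every sample to exactly ``depth`` reads without replacement.

    Samples whose total count is below ``depth`` are dropped and listed.
    Subsampling is a multivariate hypergeometric draw per retained column,
    reproducible for a fixed ``seed``.
    """
    if depth < 1:
        raise ValidationError("rarefaction depth must be ≥ 1")
    sums = table.sample_sums()
    dropped = [s for s in table.samples if sums[s] < depth]
    kept = [s for s in table.samples if sums[s] >= depth]
    if not kept:
        warnings.warn(
            f"rarefaction depth {depth} exceeds every sample's read count; "
            "result is an empty table",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    data = {}
    for sample in kept:
        col = table.counts[sample].to_numpy()
        data[sample] = rng.multivariate_hypergeometric(col, depth)
    rarefied = pd.DataFrame(data, index=table.counts.index, dtype=np.int64)
    return RarefactionResult(table.with_counts(rarefied), dropped, depth, seed)
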