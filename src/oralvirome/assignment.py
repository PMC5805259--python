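"""Hit filtering and best-hit / lowest-common-ancestor read assignment.

A read's candidate hits are first filtered (e-value strictly below 1e-3,
identity ≥ 80%, alignment covering ≥ 75% of the read length by default).
Surviving hits are ranked by identity, then alignment length, then bit
score; the co-optimal set is every hit tied with the best one (optionally
within a configurable margin). A read whose co-optimal hits all point to one
taxon is assigned at that closest-to-tip level; otherwise it is assigned to
the lowest common ancestor of the co-optimal taxa, or flagged UNDETERMINED
when they share no ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .constants import UNDETERMINED
from .errors import ConfigurationError, ValidationError
from .io import AlignmentHit
from .taxonomy import TaxonomyTree


@dataclass(frozen=True, slots=True)
class FilterThresholds:
    """Hit-retention thresholds.

    ``max_evalue`` is an exclusive bound (a hit at exactly the threshold is
    discarded); identity and coverage bounds are inclusive.
    """

    max_evalue: float = 1e-3
    min_identity: float = 80.0
    min_coverage: float = 0.75

    def __post_init__(self) -> None:
        if not self.max_evalue > 0:
            raise ValidationError("max_evalue must be > 0")
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValidationError("min_identity must lie in [0, 100]")
        if not 0.0 < self.min_coverage <= 1.0:
            raise ValidationError("min_coverage must lie in (0, 1]")


@dataclass(frozen=True, slots=True)
class ReadAssignment:
    """The taxonomic placement of one read.

    ``subject_ids`` records the co-optimal subjects in rank order (best
    first); partitioning uses them to vote on the read's reference class.
    """

    query_id: str
    taxon_id: str
    resolution_rank: Optional[str]
    co_optimal_count: int
    viral_hit: bool = False
    bacterial_hit: bool = False
    subject_ids: tuple[str, ...] = ()

    @property
    def undetermined(self) -> bool:
        return self.taxon_id == UNDETERMINED


def filter_hits(
    hits: Iterable[AlignmentHit], thresholds: FilterThresholds
) -> list[AlignmentHit]:
    """Retain hits passing every threshold; order preserved; idempotent."""
    retained = []
    for hit in hits:
        if hit.query_length is None:
            raise ConfigurationError(
                f"hit for query {hit.query_id!r} lacks query_length"
            )
        if (
            hit.e_value < thresholds.max_evalue
            and hit.percent_identity >= thresholds.min_identity
            and hit.coverage >= thresholds.min_coverage
        ):
            retained.append(hit)
    return retained


def _ranking_key(hit: AlignmentHit):
    # Descending identity, then alignment length, then bit score; subject id
    # as a last deterministic tie-break so ordering is reproducible.
    return (-hit.percent_identity, -hit.alignment_length, -hit.bit_score, hit.subject_id)


def rank_hits(hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    """Deduplicate to the best hit per subject, then sort by the ranking key."""
    best_per_subject: dict[str, AlignmentHit] = {}
    for hit in hits:
        incumbent = best_per_subject.get(hit.subject_id)
        if incumbent is None or _ranking_key(hit) < _ranking_key(incumbent):
            best_per_subject[hit.subject_id] = hit
    return sorted(best_per_subject.values(), key=_ranking_key)


def co_optimal_set(
    ranked: Sequence[AlignmentHit], tie_margin: float = 0.0
) -> list[AlignmentHit]:
    """Hits tied with the top hit on identity and alignment length.

    With the default ``tie_margin`` of 0, only exact ties qualify. A positive
    margin (in identity percentage points) admits hits whose identity is
    within ``tie_margin`` of the top hit and whose alignment length is within
    the corresponding relative margin (``tie_margin`` percent shorter).
    """
    if tie_margin < 0:
        raise ValidationError("tie_margin must be ≥ 0")
    top = ranked[0]
    min_identity = top.percent_identity - tie_margin
    min_length = top.alignment_length * (1.0 - tie_margin / 100.0)
    return [
        h
        for h in ranked
        if h.percent_identity >= min_identity and h.alignment_length >= min_length
    ]


def assign_read(
    hits: Sequence[AlignmentHit],
    tree: TaxonomyTree,
    tie_margin: float = 0.0,
) -> ReadAssignment:
    """Assign one read from its (already filtered) hits.

    Raises ``UnknownSubjectError`` if any co-optimal subject is missing from
    the taxonomy's subject map.
    """
    if not hits:
        raise ValidationError("assign_read requires at least one hit")
    query_ids = {h.query_id for h in hits}
    if len(query_ids) != 1:
        raise ValidationError(f"hits span multiple queries: {sorted(query_ids)}")
    ranked = rank_hits(hits)
    co_optimal = co_optimal_set(ranked, tie_margin)
    taxa = [tree.taxon_for_subject(h.subject_id) for h in co_optimal]
    distinct = set(taxa)
    if len(distinct) == 1:
        taxon_id = taxa[0]
    else:
        lca = tree.lca(distinct)
        taxon_id = UNDETERMINED if lca is None else lca
    return ReadAssignment(
        query_id=next(iter(query_ids)),
        taxon_id=taxon_id,
        resolution_rank=None if taxon_id == UNDETERMINED else tree.rank_of(taxon_id),
        co_optimal_count=len(co_optimal),
        subject_ids=tuple(h.subject_id for h in co_optimal),
    )


@dataclass
class SampleAssignments:
    """Per-sample assignment result: one record per read with ≥1 filtered
    viral hit, plus the ids of reads matching only the bacterial database."""

    assignments: list[ReadAssignment]
    bacterial_only_queries: frozenset[str]

    @property
    def n_viral(self) -> int:
        return len(self.assignments)

    @property
    def n_bacterial_only(self) -> int:
        return len(self.bacterial_only_queries)

    @property
    def n_virus_and_bacteria(self) -> int:
        return sum(1 for a in self.assignments if a.bacterial_hit)

    @property
    def n_virus_only(self) -> int:
        return self.n_viral - self.n_virus_and_bacteria


def assign_all(
    viral_hits: Iterable[AlignmentHit],
    bacterial_hits: Iterable[AlignmentHit],
    tree: TaxonomyTree,
    thresholds: FilterThresholds = FilterThresholds(),
    tie_margin: float = 0.0,
) -> SampleAssignments:
    """Filter both hit tables and assign every read with viral evidence.

    A read is a *viral read* when at least one of its viral-database hits
    survives filtering; it additionally carries ``bacterial_hit=True`` when
    at least one bacterial-database hit for the same query also survives.
    Reads with only bacterial evidence are tallied separately (they are the
    bacterial fraction of the library, not part of the virome).
    """
    viral_by_query: dict[str, list[AlignmentHit]] = {}
    for hit in filter_hits(viral_hits, thresholds):
        viral_by_query.setdefault(hit.query_id, []).append(hit)
    bacterial_queries = {h.query_id for h in filter_hits(bacterial_hits, thresholds)}
    assignments = []
    for query_id, hits in viral_by_query.items():
        assignment = assign_read(hits, tree, tie_margin)
        assignments.append(
            replace(
                assignment,
                viral_hit=True,
                bacterial_hit=query_id in bacterial_queries,
            )
        )
    return SampleAssignments(
        assignments=assignments,
        bacterial_only_queries=frozenset(bacterial_queries - viral_by_query.keys()),
    )
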