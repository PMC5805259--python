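"""Partition viral reads by reference class and dual-database homology.

Every assigned viral read falls in exactly one homology pool — ``virus_only``
(no filtered hit in the bacterial database) or ``virus_and_bacteria`` — and
one reference class: prophage, bacteriophage, or eukaryotic virus. The
summary reports counts and within-pool percentages for the two pools and
their union, mirroring the dataset-level splits a virome survey prints
(e.g. a read pool dominated by prophages overall but balanced once reads
with bacterial homology are excluded).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .assignment import ReadAssignment
from .constants import (
    HOMOLOGY_POOLS,
    POOL_ALL,
    POOL_VIRUS_AND_BACTERIA,
    POOL_VIRUS_ONLY,
    VIRAL_CLASSES,
)
from .errors import AnnotationError, UnknownSubjectError, ValidationError
from .taxonomy import TaxonomyTree


def viral_class_of(assignment: ReadAssignment, tree: TaxonomyTree) -> str:
    """Reference class of one read: the majority class of its co-optimal
    hits, ties broken in favour of the top-ranked hit's class."""
    if not assignment.subject_ids:
        raise AnnotationError(
            f"read {assignment.query_id!r} carries no subject ids to classify"
        )
    classes = []
    for subject_id in assignment.subject_ids:
        try:
            cls = tree.class_of_subject(subject_id)
        except UnknownSubjectError as exc:
            raise AnnotationError(str(exc)) from exc
        if cls not in VIRAL_CLASSES:
            raise AnnotationError(
                f"subject {subject_id!r} has non-viral class {cls!r}"
            )
        classes.append(cls)
    tally = Counter(classes)
    top_count = max(tally.values())
    for cls in classes:  # first hit in rank order whose class is maximal
        if tally[cls] == top_count:
            return cls
    raise AssertionError("unreachable")


@dataclass
class PartitionSummary:
    """Counts and within-pool percentages per (homology pool, viral class).

    ``proportions`` entries are percentages in [0, 100]; pools with zero
    reads have no proportion entries.
    """

    counts: dict[tuple[str, str], int]
    proportions: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def from_pool_counts(
        cls,
        virus_only: Mapping[str, int],
        virus_and_bacteria: Mapping[str, int],
    ) -> "PartitionSummary":
        """Build the summary from per-class counts of the two disjoint pools;
        the ``all`` pool is their cell-wise sum."""
        counts: dict[tuple[str, str], int] = {}
        for viral_class in VIRAL_CLASSES:
            vo = int(virus_only.get(viral_class, 0))
            vb = int(virus_and_bacteria.get(viral_class, 0))
            if vo < 0 or vb < 0:
                raise ValidationError("pool counts must be non-negative")
            counts[(POOL_VIRUS_ONLY, viral_class)] = vo
            counts[(POOL_VIRUS_AND_BACTERIA, viral_class)] = vb
            counts[(POOL_ALL, viral_class)] = vo + vb
        summary = cls(counts=counts)
        summary._compute_proportions()
        return summary

    def _compute_proportions(self) -> None:
        self.proportions = {}
        for pool in HOMOLOGY_POOLS:
            total = self.total(pool)
            if total == 0:
                continue
            for viral_class in VIRAL_CLASSES:
                self.proportions[(pool, viral_class)] = (
                    100.0 * self.counts[(pool, viral_class)] / total
                )

    def total(self, pool: str = POOL_ALL) -> int:
        return sum(self.counts[(pool, c)] for c in VIRAL_CLASSES)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: pool, viral_class, count, percent."""
        rows = []
        for pool in HOMOLOGY_POOLS:
            for viral_class in VIRAL_CLASSES:
                rows.append(
                    {
                        "pool": pool,
                        "viral_class": viral_class,
                        "count": self.counts[(pool, viral_class)],
                        "percent": self.proportions.get((pool, viral_class)),
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        """JSON-friendly nested mapping (full precision percentages)."""
        out: dict = {}
        for pool in HOMOLOGY_POOLS:
            out[pool] = {
                "total": self.total(pool),
                "counts": {
                    c: self.counts[(pool, c)] for c in VIRAL_CLASSES
                },
                "percent": {
                    c: self.proportions.get((pool, c)) for c in VIRAL_CLASSES
                },
            }
        return out


def partition_summary(
    assignments: Iterable[ReadAssignment],
    tree: TaxonomyTree,
    classes: Optional[Iterable[str]] = None,
) -> PartitionSummary:
    """Tally reads into (homology pool × viral class) cells.

    ``classes`` may supply precomputed per-read classes (same order as
    ``assignments``); otherwise each read is classified by majority vote of
    its co-optimal hits via :func:`viral_class_of`.
    """
    assignments = list(assignments)
    if classes is None:
        classes = [viral_class_of(a, tree) for a in assignments]
    else:
        classes = list(classes)
        if len(classes) != len(assignments):
            raise ValidationError("classes must align one-to-one with assignments")
    virus_only: Counter = Counter()
    virus_and_bacteria: Counter = Counter()
    for assignment, cls in zip(assignments, classes):
        if cls not in VIRAL_CLASSES:
            raise ValidationError(f"unknown viral class {cls!r}")
        if assignment.bacterial_hit:
            virus_and_bacteria[cls] += 1
        else:
            virus_only[cls] += 1
    return PartitionSummary.from_pool_counts(virus_only, virus_and_bacteria)


def write_partition_summary(summary: PartitionSummary, tsv_path, json_path=None) -> None:
    frame = summary.to_frame()
    frame["percent"] = frame["percent"].map(
        lambda v: "" if pd.isna(v) else f"{v:.1f}"
    )
    frame.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        import json

        with open(json_path, "w", encoding="utf-8") as handle:
            json.dump(summary.to_dict(), handle, indent=2)
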