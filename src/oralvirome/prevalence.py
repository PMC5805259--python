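"""Core-virome prevalence analysis.

Each detected taxon is placed in one of four occupancy tiers by the fraction
of samples in which it is present: the core virome (> 75% of samples),
frequently shared (50–75%), moderately shared (25–50%), and
individual-specific (< 25%). Taxa detected in exactly one sample are
singletons. Because the prose ranges share their endpoints, the boundaries
are resolved half-open on the lower side of each upper tier: a taxon in
exactly half the samples is *frequently shared*, one in exactly a quarter is
*moderately shared*, and the core tier is strictly above 75%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import pandas as pd

from .errors import ValidationError

CATEGORIES = ("high", "medium_high", "medium_low", "low")

_CATEGORY_DESCRIPTION = {
    "high": "core (> 75% of samples)",
    "medium_high": "frequently shared (50–75%)",
    "medium_low": "moderately shared (25–50%)",
    "low": "individual-specific (< 25%)",
}


@dataclass(frozen=True, slots=True)
class PrevalenceRecord:
    """Occupancy of one taxon across the cohort."""

    taxon: str
    occurrences: int
    n_samples: int
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 <= self.occurrences <= self.n_samples:
            raise ValidationError(
                f"occurrences {self.occurrences} outside [0, {self.n_samples}]"
            )

    @property
    def fraction(self) -> float:
        return self.occurrences / self.n_samples

    @property
    def singleton(self) -> bool:
        return self.occurrences == 1


def occurrence_counts(presence: pd.DataFrame) -> list[PrevalenceRecord]:
    """Per-taxon occupancy from a binary presence matrix (taxa × samples).

    Categories are left unset; use :func:`categorize_records`.
    """
    if presence.shape[1] < 1:
        raise ValidationError("presence matrix needs at least one sample")
    n_samples = presence.shape[1]
    row_sums = presence.sum(axis=1)
    return [
        PrevalenceRecord(taxon=str(taxon), occurrences=int(occ), n_samples=n_samples)
        for taxon, occ in row_sums.items()
    ]


def categorize_prevalence(occurrences: int, n_samples: int) -> Optional[str]:
    """Occupancy tier for a taxon seen in ``occurrences`` of ``n_samples``.

    Returns ``None`` for an absent taxon (zero occurrences).
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be ≥ 1")
    if not 0 <= occurrences <= n_samples:
        raise ValidationError(
            f"occurrences {occurrences} outside [0, {n_samples}]"
        )
    if occurrences == 0:
        return None
    fraction = occurrences / n_samples
    if fraction > 0.75:
        return "high"
    if fraction >= 0.50:
        return "medium_high"
    if fraction >= 0.25:
        return "medium_low"
    return "low"


def categorize_records(
    records: Iterable[PrevalenceRecord],
) -> list[PrevalenceRecord]:
    """Fill the category of every record (absent taxa keep ``None``)."""
    return [
        replace(r, category=categorize_prevalence(r.occurrences, r.n_samples))
        for r in records
    ]


@dataclass
class CategoryDistribution:
    """Fractions of detected taxa per occupancy tier, plus the singleton
    fraction (singletons are a subset of the ``low`` tier)."""

    fractions: dict[str, float]
    singleton_fraction: float
    n_taxa: int

    def to_dict(self) -> dict:
        return {
            "fractions": dict(self.fractions),
            "singleton_fraction": self.singleton_fraction,
            "n_taxa": self.n_taxa,
        }


def category_distribution(
    records: Iterable[PrevalenceRecord],
) -> CategoryDistribution:
    """Distribution of detected taxa over the four tiers.

    Absent taxa (zero occurrences) are excluded; fractions sum to 1 over the
    remaining taxa.
    """
    detected = [r for r in records if r.occurrences >= 1]
    detected = categorize_records(detected)
    if not detected:
        raise ValidationError("no detected taxa to categorize")
    n = len(detected)
    fractions = {
        category: sum(1 for r in detected if r.category == category) / n
        for category in CATEGORIES
    }
    singleton_fraction = sum(1 for r in detected if r.singleton) / n
    return CategoryDistribution(fractions, singleton_fraction, n)


def prevalence_frame(records: Iterable[PrevalenceRecord]) -> pd.DataFrame:
    """Tabular view: taxon, occurrences, n_samples, fraction, category,
    singleton — the per-(pool, rank) prevalence report."""
    records = categorize_records(records)
    return pd.DataFrame(
        {
            "taxon": [r.taxon for r in records],
            "occurrences": [r.occurrences for r in records],
            "n_samples": [r.n_samples for r in records],
            "fraction": [r.fraction for r in records],
            "category": [r.category for r in records],
            "singleton": [r.singleton for r in records],
        }
    )


def occupancy_histogram(records: Iterable[PrevalenceRecord]) -> pd.DataFrame:
    """Number of taxa per occurrence count (occupancy spectrum)."""
    detected = [r for r in records if r.occurrences >= 1]
    counts = pd.Series([r.occurrences for r in detected]).value_counts().sort_index()
    return pd.DataFrame({"occurrences": counts.index, "n_taxa": counts.values})
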