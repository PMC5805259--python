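"""Alpha and beta diversity with Monte Carlo permutation group tests.

Alpha diversity is the Shannon index in bits (log base 2, the convention of
QIIME-era pipelines); groups are compared with a two-tailed two-sample t
statistic whose null distribution is obtained by permuting group labels,
with Benjamini–Hochberg FDR adjustment across comparisons. Beta diversity
uses the Bray-Curtis dissimilarity; within- and between-group distance sets
are compared with label-permutation t-tests under Bonferroni correction.

Permutation p-values use the add-one estimator
``p = (1 + #{|t*| ≥ |t|}) / (1 + B)``, which can never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .tables import TaxonTable


def shannon(counts: Sequence[float]) -> float:
    """Shannon diversity H = −Σ pᵢ log2 pᵢ over taxon proportions, in bits."""
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0 or (arr < 0).any():
        raise ValidationError("counts must be a non-empty non-negative vector")
    total = arr.sum()
    if total <= 0:
        raise ValidationError("Shannon diversity is undefined for all-zero counts")
    p = arr[arr > 0] / total
    return float(-(p * np.log2(p)).sum())


# -- Bray-Curtis -----------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric Bray-Curtis dissimilarity matrix with a zero diagonal.

    A pair of samples that both have zero total counts has no defined
    dissimilarity; such entries are stored as 0 and listed in
    ``undefined_pairs``.
    """

    ids: tuple[str, ...]
    data: np.ndarray
    undefined_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValidationError("distance matrix shape must match ids")
        if not np.allclose(self.data, self.data.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if ((self.data < -1e-12) | (self.data > 1 + 1e-12)).any():
            raise ValidationError("Bray-Curtis distances must lie in [0, 1]")

    def to_skbio(self):
        """The scikit-bio DistanceMatrix view (for ordination etc.)."""
        from skbio.stats.distance import DistanceMatrix as SkbioDM

        return SkbioDM(self.data, ids=self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.ids), columns=list(self.ids))


def bray_curtis_matrix(table: Union[TaxonTable, pd.DataFrame]) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between sample columns.

    BC(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ); 0 for identical columns, 1 for disjoint
    supports.
    """
    counts = table.counts if isinstance(table, TaxonTable) else table
    if counts.shape[1] < 2:
        raise ValidationError("Bray-Curtis needs at least two samples")
    ids = tuple(str(c) for c in counts.columns)
    X = counts.to_numpy(dtype=float)
    n = X.shape[1]
    data = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            denom = (X[:, i] + X[:, j]).sum()
            if denom == 0:
                undefined.append((ids[i], ids[j]))
                continue
            d = np.abs(X[:, i] - X[:, j]).sum() / denom
            data[i, j] = data[j, i] = d
    return DistanceMatrix(ids, data, tuple(undefined))


# -- permutation t-tests ---------------------------------------------------


def _t_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-variance two-sample t; 0 for two degenerate equal groups and
    ±inf for zero pooled variance with unequal means."""
    nx, ny = len(x), len(y)
    mx, my = x.mean(), y.mean()
    pooled = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled == 0:
        if mx == my:
            return 0.0
        return float(np.inf if mx > my else -np.inf)
    return float((mx - my) / np.sqrt(pooled * (1 / nx + 1 / ny)))


def permutation_t_test(
    x: Sequence[float],
    y: Sequence[float],
    n_permutations: int = 999,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Two-tailed label-permutation t-test; returns (observed t, raw p)."""
    if n_permutations < 99:
        raise ValidationError("use at least 99 permutations")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least two observations")
    rng = rng if rng is not None else np.random.default_rng()
    observed = _t_statistic(x, y)
    pooled = np.concatenate([x, y])
    nx = len(x)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if abs(_t_statistic(perm[:nx], perm[nx:])) >= abs(observed):
            exceed += 1
    p_raw = (1 + exceed) / (1 + n_permutations)
    return observed, p_raw


def fdr_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment (order preserved)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


@dataclass(frozen=True, slots=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    observed_t: float
    p_raw: float
    p_adjusted: float
    n_permutations: int
    seed: Optional[int]


def compare_alpha(
    alpha: Mapping[str, float],
    groups: Mapping[str, str],
    n_permutations: int = 999,
    seed: Optional[int] = None,
) -> list[GroupComparison]:
    """Compare per-sample Shannon values between every pair of groups.

    ``alpha`` maps sample id → Shannon value; ``groups`` maps sample id →
    group label (e.g. F/M). Raw permutation p-values are adjusted with
    Benjamini–Hochberg across all reported comparisons.
    """
    by_group: dict[str, list[float]] = {}
    for sample_id, value in alpha.items():
        label = groups.get(sample_id)
        if label is None:
            raise ValidationError(f"sample {sample_id!r} has no group label")
        by_group.setdefault(label, []).append(float(value))
    labels = sorted(by_group)
    if len(labels) < 2:
        raise ValidationError("need at least two groups to compare")
    rng = np.random.default_rng(seed)
    results = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            t, p_raw = permutation_t_test(
                by_group[a], by_group[b], n_permutations, rng
            )
            results.append(
                GroupComparison(
                    a, b, len(by_group[a]), len(by_group[b]),
                    t, p_raw, np.nan, n_permutations, seed,
                )
            )
    adjusted = fdr_bh([r.p_raw for r in results])
    return [
        GroupComparison(
            r.group_a, r.group_b, r.n_a, r.n_b, r.observed_t,
            r.p_raw, adj, r.n_permutations, r.seed,
        )
        for r, adj in zip(results, adjusted)
    ]


# -- beta diversity group comparisons --------------------------------------


def boxplot_stats(values: Sequence[float]) -> dict[str, float]:
    """Five-number summary (min, Q1, median, Q3, max)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("no values to summarise")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {
        "min": float(arr.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(arr.max()),
    }


@dataclass
class BetaComparisonResult:
    """Within/between distance sets, their five-number summaries, and the
    permutation tests between sets (Bonferroni-adjusted)."""

    distance_sets: dict[str, np.ndarray]
    stats: dict[str, dict[str, float]]
    comparisons: list[GroupComparison]
    skipped: list[str] = field(default_factory=list)


def _distance_sets(
    dm: DistanceMatrix, labels: np.ndarray, group_names: Sequence[str]
) -> dict[str, np.ndarray]:
    undefined = set(dm.undefined_pairs) | {(b, a) for a, b in dm.undefined_pairs}
    n = len(dm.ids)
    sets: dict[str, list[float]] = {f"within_{g}": [] for g in group_names}
    sets["between_" + "".join(group_names)] = []
    for i in range(n):
        for j in range(i + 1, n):
            if (dm.ids[i], dm.ids[j]) in undefined:
                continue
            if labels[i] == labels[j]:
                sets[f"within_{labels[i]}"].append(dm.data[i, j])
            else:
                sets["between_" + "".join(group_names)].append(dm.data[i, j])
    return {k: np.asarray(v) for k, v in sets.items()}


def compare_beta(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_permutations: int = 999,
    seed: Optional[int] = None,
) -> BetaComparisonResult:
    """Compare within-group and between-group Bray-Curtis distance sets.

    The three sets (within each group, between groups) are compared pairwise
    with a t statistic whose null distribution comes from permuting the
    sample labels and rebuilding the distance sets; raw p-values are
    Bonferroni-multiplied by the number of comparisons (capped at 1). A set
    left empty by a size-one group skips its comparisons with a notice.
    """
    labels = np.array([groups.get(s) for s in dm.ids], dtype=object)
    if any(l is None for l in labels):
        missing = [s for s, l in zip(dm.ids, labels) if l is None]
        raise ValidationError(f"samples missing group labels: {missing}")
    group_names = sorted(set(labels))
    if len(group_names) != 2:
        raise ValidationError("beta comparison expects exactly two groups")
    rng = np.random.default_rng(seed)
    observed_sets = _distance_sets(dm, labels, group_names)
    stats = {
        name: boxplot_stats(values)
        for name, values in observed_sets.items()
        if values.size
    }
    set_names = list(observed_sets)
    pairs = [
        (a, b)
        for i, a in enumerate(set_names)
        for b in set_names[i + 1 :]
    ]
    comparisons = []
    skipped = []
    testable = []
    for a, b in pairs:
        if observed_sets[a].size < 2 or observed_sets[b].size < 2:
            skipped.append(
                f"{a} vs {b}: a distance set has fewer than two members"
            )
            continue
        testable.append((a, b))
    n_tests = len(testable)
    for a, b in testable:
        observed_t = _t_statistic(observed_sets[a], observed_sets[b])
        exceed = 0
        for _ in range(n_permutations):
            perm_labels = rng.permutation(labels)
            perm_sets = _distance_sets(dm, perm_labels, group_names)
            if perm_sets[a].size < 2 or perm_sets[b].size < 2:
                continue
            if abs(_t_statistic(perm_sets[a], perm_sets[b])) >= abs(observed_t):
                exceed += 1
        p_raw = (1 + exceed) / (1 + n_permutations)
        comparisons.append(
            GroupComparison(
                a, b, observed_sets[a].size, observed_sets[b].size,
                observed_t, p_raw, min(1.0, p_raw * n_tests),
                n_permutations, seed,
            )
        )
    return BetaComparisonResult(observed_sets, stats, comparisons, skipped)


def comparisons_frame(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    comparisons = list(comparisons)
    return pd.DataFrame(
        {
            "group_a": [c.group_a for c in comparisons],
            "group_b": [c.group_b for c in comparisons],
            "n_a": [c.n_a for c in comparisons],
            "n_b": [c.n_b for c in comparisons],
            "t": [c.observed_t for c in comparisons],
            "p_raw": [c.p_raw for c in comparisons],
            "p_adjusted": [c.p_adjusted for c in comparisons],
            "n_permutations": [c.n_permutations for c in comparisons],
            "seed": [c.seed for c in comparisons],
        }
    )
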