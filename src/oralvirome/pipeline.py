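"""End-to-end orchestration: assign → partition → tabulate → prevalence →
diversity, driven by a YAML config, with a machine-readable summary.

The run directory receives fixed filenames per stage; the summary JSON is
stamped with a hash of the effective configuration and the seeds used, and
records the read-accounting totals (bacterial-only reads, viral reads, and
the virus-only / virus-and-bacteria split), per-(pool, rank) category
distributions, and the group-comparison p-values.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as iomod
from .assignment import FilterThresholds, SampleAssignments, assign_all
from .constants import POOL_ALL, POOL_VIRUS_ONLY, UNDETERMINED
from .diversity import (
    bray_curtis_matrix,
    compare_alpha,
    compare_beta,
    comparisons_frame,
    shannon,
)
from .errors import ConfigurationError
from .partitioning import partition_summary, write_partition_summary
from .prevalence import (
    category_distribution,
    occurrence_counts,
    prevalence_frame,
)
from .tables import build_taxon_table, presence_absence, subsample_table
from .taxonomy import TaxonomyTree

logger = logging.getLogger("oralvirome")

#: Default rarefaction depths per homology pool: the lenient/strict regime
#: (all hits subsampled deeper than virus-only hits, whose per-sample totals
#: are far smaller).
DEFAULT_DEPTHS = {POOL_ALL: [157, 700], POOL_VIRUS_ONLY: [22, 80]}


@dataclass
class PipelineConfig:
    taxonomy_nodes: Path
    taxonomy_subjects: Path
    metadata: Path
    hits_dir: Path
    out_dir: Path
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    tie_margin: float = 0.0
    ranks: tuple[str, ...] = ("family", "species")
    pools: tuple[str, ...] = (POOL_ALL, POOL_VIRUS_ONLY)
    depths: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_DEPTHS.items()})
    n_permutations: int = 999
    seed: int = 1

    def __post_init__(self) -> None:
        for attr in ("taxonomy_nodes", "taxonomy_subjects", "metadata", "hits_dir", "out_dir"):
            setattr(self, attr, Path(getattr(self, attr)))
        for pool, depths in self.depths.items():
            if any(d < 1 for d in depths) or sorted(depths) != list(depths):
                raise ConfigurationError(
                    f"depths for pool {pool!r} must be positive and sorted"
                )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        thresholds = FilterThresholds(**raw.pop("thresholds", {}))
        base = Path(path).parent
        for key in ("taxonomy_nodes", "taxonomy_subjects", "metadata", "hits_dir", "out_dir"):
            if key in raw and not Path(raw[key]).is_absolute():
                raw[key] = base / raw[key]
        if "ranks" in raw:
            raw["ranks"] = tuple(raw["ranks"])
        if "pools" in raw:
            raw["pools"] = tuple(raw["pools"])
        return cls(thresholds=thresholds, **raw)

    @classmethod
    def for_fixture(cls, fixture_dir, out_dir, **overrides) -> "PipelineConfig":
        """Config pointing at a fixture directory laid out by
        :func:`oralvirome.simulate.write_fixture`."""
        fixture_dir = Path(fixture_dir)
        return cls(
            taxonomy_nodes=fixture_dir / "taxonomy_nodes.tsv",
            taxonomy_subjects=fixture_dir / "taxonomy_subjects.tsv",
            metadata=fixture_dir / "metadata.tsv",
            hits_dir=fixture_dir / "hits",
            out_dir=Path(out_dir),
            **overrides,
        )

    def to_dict(self) -> dict:
        return {
            "taxonomy_nodes": str(self.taxonomy_nodes),
            "taxonomy_subjects": str(self.taxonomy_subjects),
            "metadata": str(self.metadata),
            "hits_dir": str(self.hits_dir),
            "out_dir": str(self.out_dir),
            "thresholds": {
                "max_evalue": self.thresholds.max_evalue,
                "min_identity": self.thresholds.min_identity,
                "min_coverage": self.thresholds.min_coverage,
            },
            "tie_margin": self.tie_margin,
            "ranks": list(self.ranks),
            "pools": list(self.pools),
            "depths": {k: list(v) for k, v in self.depths.items()},
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def discover_samples(hits_dir: Path) -> list[str]:
    return sorted(p.name[: -len(".viral.tsv")] for p in hits_dir.glob("*.viral.tsv"))


def load_inputs(config: PipelineConfig):
    tree = iomod.read_taxonomy(config.taxonomy_nodes, config.taxonomy_subjects)
    metadata = iomod.read_sample_metadata(config.metadata)
    samples = discover_samples(config.hits_dir)
    if not samples:
        raise ConfigurationError(f"no *.viral.tsv hit tables in {config.hits_dir}")
    return tree, metadata, samples


def stage_assign(
    config: PipelineConfig, tree: TaxonomyTree, samples: list[str]
) -> dict[str, SampleAssignments]:
    """Parse, filter, and assign every sample's hit tables."""
    results = {}
    for sample_id in samples:
        viral = iomod.read_hit_table(
            config.hits_dir / f"{sample_id}.viral.tsv", "viral"
        )
        bacterial_path = config.hits_dir / f"{sample_id}.bacterial.tsv"
        bacterial = (
            iomod.read_hit_table(bacterial_path, "bacterial")
            if bacterial_path.exists()
            else []
        )
        results[sample_id] = assign_all(
            viral, bacterial, tree, config.thresholds, config.tie_margin
        )
    return results


def write_assignments(
    assignments: dict[str, SampleAssignments], tree: TaxonomyTree, out_dir: Path
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for sample_id, result in assignments.items():
        with open(out_dir / f"{sample_id}.assignments.tsv", "w", encoding="utf-8") as handle:
            handle.write("query_id\tlineage\trank\tviral_hit\tbacterial_hit\n")
            for a in result.assignments:
                lineage = (
                    UNDETERMINED
                    if a.undetermined
                    else tree.lineage_label(a.taxon_id)
                )
                handle.write(
                    f"{a.query_id}\t{lineage}\t{a.resolution_rank or ''}\t"
                    f"{int(a.viral_hit)}\t{int(a.bacterial_hit)}\n"
                )


def read_accounting(assignments: dict[str, SampleAssignments]) -> dict:
    totals = {
        "bacterial_reads": sum(r.n_bacterial_only for r in assignments.values()),
        "viral_reads": sum(r.n_viral for r in assignments.values()),
        "virus_only": sum(r.n_virus_only for r in assignments.values()),
        "virus_and_bacteria": sum(
            r.n_virus_and_bacteria for r in assignments.values()
        ),
    }
    assert totals["viral_reads"] == totals["virus_only"] + totals["virus_and_bacteria"]
    return totals


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage for each (pool, rank, depth) combination."""
    t_start = time.perf_counter()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    tree, metadata, samples = load_inputs(config)
    summary: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_samples": len(samples),
    }

    logger.info("assigning %d samples", len(samples))
    assignments = stage_assign(config, tree, samples)
    write_assignments(assignments, tree, out / "assignments")
    summary["read_accounting"] = read_accounting(assignments)

    all_assignments = [a for r in assignments.values() for a in r.assignments]
    partition = partition_summary(all_assignments, tree)
    write_partition_summary(
        partition, out / "partition_summary.tsv", out / "partition_summary.json"
    )
    summary["partition"] = partition.to_dict()

    per_sample = {s: assignments[s].assignments for s in samples}
    summary["prevalence"] = {}
    summary["diversity"] = {}
    tables = {}
    for pool in config.pools:
        for rank in config.ranks:
            table = build_taxon_table(per_sample, tree, rank, pool, metadata)
            tables[(pool, rank)] = table
            stem = f"{pool}.{rank}"
            iomod.write_taxon_table(table, out / f"table.{stem}.tsv", "tsv")
            if not table.counts.empty:
                iomod.write_taxon_table(
                    table, out / f"table.{stem}.biom.json", "biom_json"
                )
            presence = presence_absence(table)
            records = occurrence_counts(presence)
            prevalence_frame(records).to_csv(
                out / f"prevalence.{stem}.tsv", sep="\t", index=False
            )
            if any(r.occurrences >= 1 for r in records):
                summary["prevalence"][stem] = category_distribution(records).to_dict()
            else:
                summary["prevalence"][stem] = None

    drop_log_rows = []
    for pool in config.pools:
        species_table = tables.get((pool, "species"))
        if species_table is None:
            continue
        for depth in config.depths.get(pool, []):
            rarefied = subsample_table(species_table, depth, config.seed)
            for sample_id in rarefied.dropped_samples:
                drop_log_rows.append(
                    {"pool": pool, "depth": depth, "sample_id": sample_id}
                )
            key = f"{pool}.depth{depth}"
            if len(rarefied.table.samples) < 4:
                summary["diversity"][key] = {
                    "retained_samples": len(rarefied.table.samples),
                    "note": "too few samples retained for group comparison",
                }
                continue
            alpha = {
                s: shannon(rarefied.table.counts[s]) for s in rarefied.table.samples
            }
            groups = {s: metadata.loc[s, "sex"] for s in rarefied.table.samples}
            alpha_cmp = compare_alpha(
                alpha, groups, config.n_permutations, config.seed
            )
            comparisons_frame(alpha_cmp).to_csv(
                out / f"alpha_comparison.{key}.tsv", sep="\t", index=False
            )
            dm = bray_curtis_matrix(rarefied.table)
            beta = compare_beta(dm, groups, config.n_permutations, config.seed)
            comparisons_frame(beta.comparisons).to_csv(
                out / f"beta_comparison.{key}.tsv", sep="\t", index=False
            )
            pd.DataFrame(beta.stats).T.to_csv(
                out / f"beta_boxplot_stats.{key}.tsv", sep="\t"
            )
            summary["diversity"][key] = {
                "retained_samples": len(rarefied.table.samples),
                "dropped_samples": rarefied.dropped_samples,
                "alpha": [
                    {
                        "groups": [c.group_a, c.group_b],
                        "t": c.observed_t,
                        "p_raw": c.p_raw,
                        "p_adjusted": c.p_adjusted,
                    }
                    for c in alpha_cmp
                ],
                "beta": [
                    {
                        "sets": [c.group_a, c.group_b],
                        "t": c.observed_t,
                        "p_raw": c.p_raw,
                        "p_bonferroni": c.p_adjusted,
                    }
                    for c in beta.comparisons
                ],
            }
    pd.DataFrame(drop_log_rows, columns=["pool", "depth", "sample_id"]).to_csv(
        out / "rarefaction_drop_log.tsv", sep="\t", index=False
    )

    summary["runtime_seconds"] = round(time.perf_counter() - t_start, 2)
    with open(out / "summary.json", "w", encoding="utf-8") as handle:
        json.dump(summary, handle, indent=2)
    logger.info("pipeline finished in %.1fs", summary["runtime_seconds"])
    return summary
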