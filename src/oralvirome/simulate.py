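"""Synthetic virome fixtures with ground truth.

The generator emulates the structure of an oral DNA virome cohort: a
72-sample community in which a small block of "core" taxa is present in
nearly every sample while a long tail of sporadic taxa yields a
singleton-dominated occupancy spectrum; per-sample read pools are dominated
by prophage-class reference sequences; and reads hitting prophages usually
also match the bacterial database, whereas eukaryotic-virus reads rarely do.

It produces (i) a rank-complete taxonomy with one reference subject per
species, (ii) a ground-truth taxon-by-sample count matrix, and (iii) noisy
dual-database alignment-hit tables whose identity / coverage / e-value
distributions straddle the filtering thresholds, with optional off-target
co-optimal hits that force genus-level LCA assignments. Everything is
deterministic under an explicit seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as iomod
from .constants import SEX_LEVELS, VIRAL_CLASSES
from .errors import ValidationError
from .io import AlignmentHit
from .taxonomy import TaxonNode, TaxonomyTree

DEFAULT_CLASS_MIX = {
    "prophage": 0.5,
    "bacteriophage": 0.3,
    "eukaryotic_virus": 0.2,
}

#: Probability that a read of each reference class also matches the
#: bacterial database: prophage reads nearly always do, eukaryotic-virus
#: reads almost never.
DEFAULT_P_BACTERIAL = {
    "prophage": 0.95,
    "bacteriophage": 0.5,
    "eukaryotic_virus": 0.02,
}


@dataclass(frozen=True, slots=True)
class TaxonModel:
    """Community parameters of one species-level taxon."""

    taxon_id: str
    viral_class: str
    prevalence_prob: float
    log_mean: float = 0.0
    log_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence_prob <= 1.0:
            raise ValidationError("prevalence_prob must lie in [0, 1]")
        if self.viral_class not in VIRAL_CLASSES:
            raise ValidationError(f"unknown viral class {self.viral_class!r}")


@dataclass(frozen=True, slots=True)
class NoiseModel:
    """Alignment-noise parameters.

    Identities of passing hits are normal around 95% (sd 4, truncated to
    [0, 100]); read coverage is Beta(18, 2) (mean 0.9); e-values are
    log-uniform over [1e-30, 1e-4]. A ``fail_rate`` fraction of reads draw a
    value that violates one threshold (low identity, short alignment, or
    weak e-value) and is removed by the hit filter; ``off_target_rate`` is
    the chance a passing read gains a co-optimal hit to a sibling species,
    creating a genus-level LCA case.
    """

    identity_mean: float = 95.0
    identity_sd: float = 4.0
    coverage_alpha: float = 18.0
    coverage_beta: float = 2.0
    log10_evalue_min: float = -30.0
    log10_evalue_max: float = -4.0
    fail_rate: float = 0.02
    off_target_rate: float = 0.05
    read_length: int = 250

    def __post_init__(self) -> None:
        if not 0.0 <= self.fail_rate <= 1.0:
            raise ValidationError("fail_rate must lie in [0, 1]")
        if not 0.0 <= self.off_target_rate <= 1.0:
            raise ValidationError("off_target_rate must lie in [0, 1]")
        if self.read_length < 1:
            raise ValidationError("read_length must be ≥ 1")


@dataclass
class CommunityModel:
    """Full generative model for a multi-sample virome fixture."""

    taxa: list[TaxonModel]
    n_samples: int = 72
    sex_split: tuple[float, float] = (0.5, 0.5)
    reads_per_sample: int = 2800
    prophage_read_share: float = 0.92
    p_bacterial_homology: dict = field(
        default_factory=lambda: dict(DEFAULT_P_BACTERIAL)
    )
    bacterial_only_reads_per_sample: int = 150
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be ≥ 1")
        if self.reads_per_sample < 1:
            raise ValidationError("reads_per_sample must be ≥ 1")
        if not np.isclose(sum(self.sex_split), 1.0):
            raise ValidationError("sex_split proportions must sum to 1")
        if not 0.0 <= self.prophage_read_share <= 1.0:
            raise ValidationError("prophage_read_share must lie in [0, 1]")
        for cls, p in self.p_bacterial_homology.items():
            if cls not in VIRAL_CLASSES or not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"invalid bacterial-homology probability {cls!r}={p}"
                )
        if not self.taxa:
            raise ValidationError("community model needs at least one taxon")


def simulate_taxonomy(
    n_families: int = 12,
    species_per_family: int = 4,
    class_mix: Optional[dict] = None,
    seed: int = 0,
    families_per_order: int = 3,
    genera_per_family: int = 2,
) -> TaxonomyTree:
    """Build a rank-complete synthetic taxonomy with one subject per species.

    Families are assigned a reference class (whole-family, as real phage
    families are) by drawing from ``class_mix``; each family holds
    ``genera_per_family`` genera with the species split between them, so
    sibling species exist for LCA test cases.
    """
    if n_families < 1 or species_per_family < 1:
        raise ValidationError("need at least one family and one species each")
    mix = dict(class_mix or DEFAULT_CLASS_MIX)
    if set(mix) - set(VIRAL_CLASSES) or not np.isclose(sum(mix.values()), 1.0):
        raise ValidationError(f"class_mix must be a distribution over {VIRAL_CLASSES}")
    rng = np.random.default_rng(seed)
    classes = sorted(mix)
    probs = np.array([mix[c] for c in classes])
    nodes: list[TaxonNode] = []
    subject_map: dict[str, tuple[str, str]] = {}
    n_orders = (n_families + families_per_order - 1) // families_per_order
    for o in range(n_orders):
        nodes.append(TaxonNode(f"o{o:02d}", f"Simulavirales_{o}", "order", None))
    for f in range(n_families):
        order_id = f"o{f // families_per_order:02d}"
        family_id = f"f{f:03d}"
        family_class = str(rng.choice(classes, p=probs))
        nodes.append(TaxonNode(family_id, f"Simviridae_{f}", "family", order_id))
        n_genera = min(genera_per_family, species_per_family)
        for g in range(n_genera):
            nodes.append(
                TaxonNode(
                    f"{family_id}g{g}", f"Simvirus_{f}_{g}", "genus", family_id
                )
            )
        for s in range(species_per_family):
            genus_id = f"{family_id}g{s % n_genera}"
            species_id = f"{family_id}s{s:02d}"
            nodes.append(
                TaxonNode(
                    species_id, f"Simulated virus {f}-{s}", "species", genus_id
                )
            )
            subject_map[f"ref|{species_id}"] = (species_id, family_class)
    return TaxonomyTree(nodes, subject_map)


def default_taxa(
    tree: TaxonomyTree,
    n_samples: int,
    seed: int = 0,
    core_fraction: float = 0.15,
    core_prob_range: tuple[float, float] = (0.9, 1.0),
    tail_prob_max: float = 0.2,
) -> list[TaxonModel]:
    """Prevalence spectrum: a small core block present in ≥90% of samples and
    a long tail of sporadic taxa (probabilities from 1/n_samples up to
    ``tail_prob_max``), which yields singleton-dominated occupancy. Core
    taxa get a higher lognormal abundance mean so they dominate read pools.
    """
    rng = np.random.default_rng(seed)
    species = sorted(tree.species_ids())
    n_core = max(1, round(core_fraction * len(species)))
    core_ids = set(
        rng.choice(np.array(species, dtype=object), size=n_core, replace=False)
    )
    taxa = []
    for species_id in species:
        viral_class = tree.class_of_subject(f"ref|{species_id}")
        if species_id in core_ids:
            prob = float(rng.uniform(*core_prob_range))
            log_mean = 1.0
        else:
            # tail from one-expected-sample up to tail_prob_max (degenerate
            # for very small cohorts, where 1/n_samples may exceed the cap)
            lo = 1.0 / n_samples
            prob = float(rng.uniform(lo, max(tail_prob_max, lo)))
            log_mean = 0.0
        taxa.append(
            TaxonModel(
                taxon_id=species_id,
                viral_class=viral_class,
                prevalence_prob=prob,
                log_mean=log_mean,
                log_sd=1.0,
            )
        )
    return taxa


def default_model(
    n_samples: int = 72,
    reads_per_sample: int = 2800,
    seed: int = 0,
    n_families: int = 12,
    species_per_family: int = 4,
    **overrides,
) -> tuple[CommunityModel, TaxonomyTree]:
    """The study-scale default: 72 samples (36 F / 36 M), ~2800 viral reads
    per sample, prophage-dominated pool. Returns (model, taxonomy)."""
    tree = simulate_taxonomy(n_families, species_per_family, seed=seed)
    taxa = default_taxa(tree, n_samples, seed=seed)
    model = CommunityModel(
        taxa=taxa,
        n_samples=n_samples,
        reads_per_sample=reads_per_sample,
        **overrides,
    )
    return model, tree


def small_fixture_model(seed: int = 0) -> tuple[CommunityModel, TaxonomyTree]:
    """A desk-scale fixture: 12 samples × ~420 viral reads ≈ 5k reads."""
    return default_model(n_samples=12, reads_per_sample=420, seed=seed)


@dataclass
class CommunityTruth:
    """Ground truth of one simulated cohort."""

    counts: pd.DataFrame  # species lineage label × sample, integer reads
    presence: pd.DataFrame  # Bernoulli presence truth (before read draws)
    metadata: pd.DataFrame  # sample_id-indexed, 'sex' column
    taxon_ids: list[str]  # species taxon ids aligned with counts rows
    classes: list[str]  # viral class per row

    @property
    def detected(self) -> pd.DataFrame:
        """Presence realised in reads (a taxon can be present but draw 0)."""
        return (self.counts > 0).astype(int)


def simulate_community(
    model: CommunityModel, tree: TaxonomyTree, seed: int
) -> CommunityTruth:
    """Draw presence, abundances, and read counts for every sample.

    Presence is independent Bernoulli per (taxon, sample); conditional on
    presence, abundance weights are lognormal; weights are rescaled so that
    prophage-class taxa receive ``prophage_read_share`` of each sample's
    expected reads, then reads are drawn multinomially.
    """
    rng = np.random.default_rng(seed)
    taxa = model.taxa
    n_taxa, n_samples = len(taxa), model.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    n_female = round(model.sex_split[0] * n_samples)
    sexes = [SEX_LEVELS[0]] * n_female + [SEX_LEVELS[1]] * (n_samples - n_female)
    metadata = pd.DataFrame({"sex": sexes}, index=pd.Index(sample_ids, name="sample_id"))

    probs = np.array([t.prevalence_prob for t in taxa])
    presence = rng.random((n_taxa, n_samples)) < probs[:, None]
    log_means = np.array([t.log_mean for t in taxa])
    log_sds = np.array([t.log_sd for t in taxa])
    weights = rng.lognormal(
        mean=log_means[:, None], sigma=log_sds[:, None], size=(n_taxa, n_samples)
    )
    weights = weights * presence

    is_prophage = np.array([t.viral_class == "prophage" for t in taxa])
    share = model.prophage_read_share
    for j in range(n_samples):
        w_pro = weights[is_prophage, j].sum()
        w_other = weights[~is_prophage, j].sum()
        if 0 < share < 1 and w_pro > 0 and w_other > 0:
            weights[is_prophage, j] *= (share / (1 - share)) * (w_other / w_pro)

    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    for j in range(n_samples):
        total = weights[:, j].sum()
        if total > 0:
            counts[:, j] = rng.multinomial(
                model.reads_per_sample, weights[:, j] / total
            )

    labels = [tree.lineage_label(t.taxon_id) for t in taxa]
    index = pd.Index(labels, name="taxon")
    return CommunityTruth(
        counts=pd.DataFrame(counts, index=index, columns=sample_ids),
        presence=pd.DataFrame(presence.astype(int), index=index, columns=sample_ids),
        metadata=metadata,
        taxon_ids=[t.taxon_id for t in taxa],
        classes=[t.viral_class for t in taxa],
    )


@dataclass
class HitTableSet:
    """Per-sample alignment-hit tables plus per-read ground truth."""

    viral: dict[str, list[AlignmentHit]]
    bacterial: dict[str, list[AlignmentHit]]
    read_truth: pd.DataFrame  # query_id, sample_id, species, class, flags


def simulate_hit_tables(
    truth: CommunityTruth,
    model: CommunityModel,
    tree: TaxonomyTree,
    seed: int,
) -> HitTableSet:
    """Turn true read counts into noisy dual-database hit tables.

    Every read gets one primary viral hit against its species' reference
    subject; a ``fail_rate`` fraction draw a threshold-violating value (and
    are recorded as not passing); passing reads may gain an exact-tie
    co-optimal hit to a sibling species (``off_target_rate``) and a
    bacterial-database hit with the class-specific homology probability.
    ``bacterial_only_reads_per_sample`` extra reads match only bacteria.
    """
    rng = np.random.default_rng(seed)
    noise = model.noise
    L = noise.read_length
    siblings = _sibling_map(tree)
    class_of = {t.taxon_id: t.viral_class for t in model.taxa}
    p_bact = model.p_bacterial_homology

    viral: dict[str, list[AlignmentHit]] = {}
    bacterial: dict[str, list[AlignmentHit]] = {}
    truth_rows: list[dict] = []
    counts = truth.counts.to_numpy()
    for j, sample_id in enumerate(truth.counts.columns):
        v_hits: list[AlignmentHit] = []
        b_hits: list[AlignmentHit] = []
        read_no = 0
        for i, species_id in enumerate(truth.taxon_ids):
            c = int(counts[i, j])
            if c == 0:
                continue
            cls = class_of[species_id]
            subject = f"ref|{species_id}"
            family_id = tree.ancestor_at_rank(species_id, "family")
            fails = rng.random(c) < noise.fail_rate
            identities = np.clip(
                rng.normal(noise.identity_mean, noise.identity_sd, c), 0.0, 100.0
            )
            coverages = rng.beta(noise.coverage_alpha, noise.coverage_beta, c)
            evalues = 10.0 ** rng.uniform(
                noise.log10_evalue_min, noise.log10_evalue_max, c
            )
            fail_modes = rng.integers(0, 3, c)
            off_targets = rng.random(c) < noise.off_target_rate
            bact_flags = rng.random(c) < p_bact.get(cls, 0.0)
            bact_identities = rng.uniform(85.0, 99.0, c)
            bact_coverages = rng.beta(noise.coverage_alpha, noise.coverage_beta, c)
            for k in range(c):
                query_id = f"{sample_id}:r{read_no:06d}"
                read_no += 1
                identity, cov, evalue = identities[k], coverages[k], evalues[k]
                if fails[k]:
                    if fail_modes[k] == 0:
                        identity = rng.uniform(50.0, 75.0)
                    elif fail_modes[k] == 1:
                        cov = rng.uniform(0.2, 0.6)
                    else:
                        evalue = 10.0 ** rng.uniform(-2.5, -1.0)
                alen = max(1, round(cov * L))
                bits = round(2.0 * alen * identity / 100.0, 1)
                v_hits.append(
                    AlignmentHit(
                        query_id, subject, round(identity, 2), alen,
                        evalue, bits, L, "viral",
                    )
                )
                passes = (
                    identity >= 80.0 and alen / L >= 0.75 and evalue < 1e-3
                )
                ambiguous = False
                if passes and off_targets[k] and siblings.get(species_id):
                    sib = siblings[species_id][
                        int(rng.integers(len(siblings[species_id])))
                    ]
                    # exact tie on identity and length → co-optimal pair
                    v_hits.append(
                        AlignmentHit(
                            query_id, f"ref|{sib}", round(identity, 2), alen,
                            evalue, max(0.0, bits - 0.5), L, "viral",
                        )
                    )
                    ambiguous = True
                has_bacterial = False
                if bact_flags[k]:
                    b_alen = max(1, round(bact_coverages[k] * L))
                    b_id = bact_identities[k]
                    b_hits.append(
                        AlignmentHit(
                            query_id, f"bact|{family_id}", round(b_id, 2),
                            b_alen, 1e-20, round(2.0 * b_alen * b_id / 100.0, 1),
                            L, "bacterial",
                        )
                    )
                    has_bacterial = b_alen / L >= 0.75
                truth_rows.append(
                    {
                        "query_id": query_id,
                        "sample_id": sample_id,
                        "species_id": species_id,
                        "viral_class": cls,
                        "passes_filter": passes,
                        "ambiguous": ambiguous,
                        "bacterial_hit": passes and has_bacterial,
                    }
                )
        b_only_ids = rng.uniform(85.0, 99.0, model.bacterial_only_reads_per_sample)
        b_only_cov = rng.beta(
            noise.coverage_alpha, noise.coverage_beta,
            model.bacterial_only_reads_per_sample,
        )
        for k in range(model.bacterial_only_reads_per_sample):
            alen = max(1, round(b_only_cov[k] * L))
            b_hits.append(
                AlignmentHit(
                    f"{sample_id}:b{k:05d}", "bact|background",
                    round(b_only_ids[k], 2), alen, 1e-20,
                    round(2.0 * alen * b_only_ids[k] / 100.0, 1), L, "bacterial",
                )
            )
        viral[sample_id] = v_hits
        bacterial[sample_id] = b_hits
    return HitTableSet(viral, bacterial, pd.DataFrame(truth_rows))


def _sibling_map(tree: TaxonomyTree) -> dict[str, list[str]]:
    by_genus: dict[str, list[str]] = {}
    for species_id in sorted(tree.species_ids()):
        genus = tree.nodes[species_id].parent_id
        by_genus.setdefault(genus, []).append(species_id)
    return {
        s: [x for x in members if x != s]
        for members in by_genus.values()
        for s in members
    }


def write_fixture(
    out_dir,
    tree: TaxonomyTree,
    model: CommunityModel,
    truth: CommunityTruth,
    hits: HitTableSet,
    seed: int,
) -> Path:
    """Write a complete fixture directory (hit tables, taxonomy, metadata,
    truth tables, generating config). Deterministic: same seed and model
    give byte-identical files."""
    out = Path(out_dir)
    (out / "hits").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    iomod.write_taxonomy(
        tree, out / "taxonomy_nodes.tsv", out / "taxonomy_subjects.tsv"
    )
    iomod.write_sample_metadata(truth.metadata, out / "metadata.tsv")
    for sample_id in truth.counts.columns:
        iomod.write_hit_table(
            hits.viral[sample_id], out / "hits" / f"{sample_id}.viral.tsv"
        )
        iomod.write_hit_table(
            hits.bacterial[sample_id], out / "hits" / f"{sample_id}.bacterial.tsv"
        )
    truth.counts.to_csv(out / "truth" / "species_counts.tsv", sep="\t")
    truth.presence.to_csv(out / "truth" / "presence.tsv", sep="\t")
    hits.read_truth.to_csv(out / "truth" / "read_truth.tsv", sep="\t", index=False)
    config = {
        "seed": seed,
        "n_samples": model.n_samples,
        "reads_per_sample": model.reads_per_sample,
        "prophage_read_share": model.prophage_read_share,
        "bacterial_only_reads_per_sample": model.bacterial_only_reads_per_sample,
        "p_bacterial_homology": dict(model.p_bacterial_homology),
        "noise": asdict(model.noise),
        "n_taxa": len(model.taxa),
    }
    with open(out / "config.yaml", "w", encoding="utf-8") as handle:
        yaml.safe_dump(config, handle, sort_keys=True)
    return out


def default_fixture_path() -> Path:
    """Directory of the tiny fixture shipped with the package (12 samples,
    40 viral reads per sample, seed 0) — parseable by every reader and used
    in examples; regenerate larger instances with :func:`default_model`."""
    return Path(__file__).parent / "data" / "default_fixture"


def simulate_fixture(
    model: CommunityModel, tree: TaxonomyTree, seed: int
) -> tuple[CommunityTruth, HitTableSet]:
    """Community draw + hit tables with sub-seeds derived from ``seed``."""
    seq = np.random.SeedSequence(seed).spawn(2)
    truth = simulate_community(model, tree, seed=seq[0].generate_state(1)[0] % 2**31)
    hits = simulate_hit_tables(
        truth, model, tree, seed=seq[1].generate_state(1)[0] % 2**31
    )
    return truth, hits
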