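# Methods

## Problem and scope

The package analyses an oral DNA virome cohort downstream of read
pre-processing: its inputs are per-sample tabular alignment hits (BLAST
outfmt 6, 12 columns, optionally a 13th `qlen` column) of
quality-filtered, host-depleted reads against a viral reference database
(complete viral genomes plus prophage entries) and a bacterial database,
together with a rank-labelled taxonomy (order → family → genus → species)
and sample metadata (sex F/M). Read QC, host filtering, and reference
database construction are upstream concerns and out of scope; no aligner is
run.

## Hit filtering

A hit is retained when

- e-value **strictly below** 10⁻³ (a hit at exactly the threshold is
  discarded),
- percent identity ≥ 80 (inclusive),
- alignment length / read length ≥ 0.75 (inclusive).

The coverage denominator is the full read length, which is why standard
12-column tables must be accompanied by read lengths (13th column or a
two-column sidecar TSV). Alignment length may exceed read length in gapped
alignments; the ratio is used as-is. Filtering is order-preserving and
idempotent.

## Best-hit / LCA assignment

Per read, hits are first reduced to the best hit per subject, then ranked
by (identity desc, alignment length desc, bit score desc, subject id) — bit
score is a deterministic tie-break of last resort, and the subject id makes
the ordering fully reproducible. The *co-optimal set* is every hit tied
with the top hit on identity and alignment length. With the default
`tie_margin = 0` only exact ties qualify — the most conservative reading of
"best hit"; a positive margin (identity percentage points, with a matching
relative margin on alignment length) is available for robustness studies.
Shrinking the margin can only move an assignment deeper, never shallower
(the co-optimal set shrinks monotonically), and this is property-tested.

If all co-optimal hits map to one taxon the read is assigned there
(closest-to-tip, normally species); otherwise to the lowest common ancestor
of the co-optimal taxa; if the taxa share no root, the read is
UNDETERMINED. A read is *viral* if ≥ 1 viral-database hit survives
filtering; it is additionally flagged `bacterial_hit` if ≥ 1
bacterial-database hit for the same query also survives. Reads with only
bacterial evidence are tallied as the bacterial fraction and never enter
the virome tables. Each viral read therefore lands in exactly one homology
pool (`virus_only` / `virus_and_bacteria`), and pool totals are additive by
construction.

## Partitioning by reference class

Each viral-database subject carries a class annotation: `prophage`
(prophage regions predicted from bacterial genomes), `bacteriophage` (free
phage genome records), or `eukaryotic_virus`. A read's class is the
majority class of its co-optimal hits, ties resolved in favour of the
top-ranked hit. Summaries report counts and within-pool percentages for
`virus_only`, `virus_and_bacteria`, and their union; reports round to one
decimal, machine-readable outputs keep full precision.

## Taxon tables and rarefaction

Tables are built at family or species rank by rolling each read up to its
ancestor at the target rank; reads resolved shallower than the target rank
(e.g. a genus-level LCA in a species table) and UNDETERMINED reads accrue
to a single UNDETERMINED row, so column sums conserve per-sample read
counts at every rank. UNDETERMINED reads are real sequencing effort: they
participate in column sums and rarefaction, and remain a row in diversity
tables, but are excluded from presence/absence and prevalence
categorisation, where only named taxa are meaningful.

Rarefaction draws exactly `depth` reads per sample **without replacement**
(multivariate hypergeometric), dropping and logging samples below depth.
The default depth pairs mirror a lenient/strict regime — 157/700 for
all-hit tables and 22/80 for virus-only tables, whose per-sample totals are
roughly an order of magnitude smaller. The rarefied proportion of a taxon
is an unbiased estimate of its original proportion (tested over 1000
seeds).

## Prevalence tiers

With occupancy fraction f = occurrences / n_samples:

- **high (core)**: f > 0.75 — strictly above, "more than 75%";
- **medium_high (frequently shared)**: 0.50 ≤ f ≤ 0.75;
- **medium_low (moderately shared)**: 0.25 ≤ f < 0.50;
- **low (individual-specific)**: f < 0.25.

The prose ranges for the middle tiers share their endpoints; the boundaries
are resolved half-open on the lower side of each upper tier, so exactly 50%
is `medium_high` and exactly 25% is `medium_low`. A taxon seen once is a
singleton (a subset of `low`); absent taxa receive no category. Category
distributions are computed per (pool, rank) over detected taxa and sum
to 1. Family-level aggregation can only widen occupancy: a family occurs
wherever any of its species does (asserted as an invariant).

## Diversity

- **Shannon**: H = −Σ pᵢ log₂ pᵢ in bits (base 2, the QIIME-era default;
  stated here because the index name alone does not fix the base).
- **Bray-Curtis**: BC(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) over count columns; a
  pair of all-zero samples has no defined dissimilarity and is stored as 0
  with the pair flagged.
- **Group tests**: pooled-variance two-sample t statistic; the null
  distribution comes from label permutations; the p-value uses the add-one
  estimator (1 + #{|t*| ≥ |t|}) / (1 + B) with B = 999 by default, so it is
  never zero. Degenerate inputs (both groups constant and equal) give t = 0
  and p = 1. Alpha comparisons are Benjamini–Hochberg-adjusted across all
  reported pairs (via statsmodels); beta comparisons between the three
  distance sets (within-F, within-M, between) are Bonferroni-multiplied by
  the number of tests, capped at 1. Beta comparisons operate on tables
  rarefied at the same depths as alpha. Under a true null the rejection
  rate at α = 0.05 is calibrated to [0.02, 0.08] over 500 simulations
  (tested).

## Synthetic-data generator

The generator emulates the cohort structure the pipeline targets, not
sequencing chemistry:

- **Cohort**: 72 samples by default, deterministic 36 F / 36 M split, with
  ~2,800 viral reads per sample (the cohort-scale average); the desk-scale
  fixture used throughout the tests is 12 samples × 420 reads ≈ 5k reads.
- **Prevalence spectrum**: ~15% of species form a core block with presence
  probability 0.9–1.0 and elevated abundance (lognormal log-mean 1 vs 0,
  log-sd 1); the rest draw presence probabilities between 1/n_samples and
  0.2, yielding the singleton-dominated occupancy spectrum characteristic
  of real viromes.
- **Read pools**: presence is Bernoulli per (taxon, sample); conditional
  abundances are lognormal, rescaled so prophage-class taxa receive 92% of
  each sample's expected reads, then counts are multinomial.
- **Hit noise**: passing identities ~ Normal(95, 4) truncated to [0, 100];
  coverage ~ Beta(18, 2) (mean 0.9); e-values log-uniform on [10⁻³⁰,
  10⁻⁴]; 2% of reads draw one threshold-violating value. 5% of passing
  reads gain an exact-tie hit to a sibling species, forcing a genus-level
  LCA. Bacterial homology per class: prophage 0.95, bacteriophage 0.5,
  eukaryotic virus 0.02. These distributions are stated defaults, chosen to
  straddle the filter thresholds realistically, and are fully configurable.
- **Ground truth**: the true count matrix, Bernoulli presence, and a
  per-read table (species, class, pass/ambiguous/bacterial flags) are kept,
  enabling exact recovery checks in the noiseless limit and 3-standard-
  error recovery checks under default noise.

What the generator does **not** model: nucleotide sequences and alignment
itself, within-genome position of prophages, sample-depth variation
(reads_per_sample is constant unless overridden), taxon-taxon correlations,
and any sex effect (by default) — so passing recovery tests demonstrate
correctness of the bookkeeping and statistics on communities of this
structure, not robustness to every property of real sequencing data.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; fixtures are byte-reproducible.
- BIOM output follows the 1.0 JSON schema (sparse, taxa × samples); the
  writer/reader is local because the format is plain JSON, and round trips
  are tested.
- Lineage labels are semicolon-joined with `o__/f__/g__/s__` prefixes;
  undetermined and unnamed taxa render as `..__u` / `..__n`.
- The UNDETERMINED sentinel is a reserved row label; taxonomies are
  validated as rank-ordered forests (no cycles, parent exactly one rank
  shallower).
- Percentages in reports are rounded to one decimal; machine outputs keep
  full precision.

## Known limitations

- The LCA tie policy at `tie_margin > 0` (relative margin on alignment
  length) is one of several defensible conventions; results at the default
  margin 0 do not depend on it.
- Beta-diversity permutation tests permute sample labels and rebuild
  distance sets, which is standard but approximate in small cohorts where
  few distinct label partitions exist.
- Real reference databases contain multi-subject species and shared
  prophage regions across host families; the generator's one-subject-per-
  species simplification makes species-level recovery easier than in
  production use.
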