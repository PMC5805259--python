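"""Shared vocabulary for ranks, reference classes, and sentinels."""

#: Taxonomic ranks handled by the pipeline, shallowest first.
RANKS = ("order", "family", "genus", "species")

#: Rank index lookup (order=0 ... species=3).
RANK_INDEX = {rank: i for i, rank in enumerate(RANKS)}

#: Lineage-label prefixes, QIIME-style double underscore.
RANK_PREFIX = {"order": "o__", "family": "f__", "genus": "g__", "species": "s__"}

#: Name markers: a taxon whose name could not be determined at a rank, and a
#: taxon that exists but has no name in the reference taxonomy.
UNDETERMINED_NAME = "_u"
UNNAMED_NAME = "_n"

#: Row label / assignment sentinel for reads that cannot be placed.
UNDETERMINED = "UNDETERMINED"

#: Reference classes a viral-database subject can carry. ``bacterial`` is
#: allowed in subject maps (for bacterial-database subjects) but never counts
#: as a viral class.
VIRAL_CLASSES = ("prophage", "bacteriophage", "eukaryotic_virus")
SUBJECT_CLASSES = VIRAL_CLASSES + ("bacterial",)

#: Homology pools: reads matching only the viral database, reads matching
#: both databases, and their union.
POOL_VIRUS_ONLY = "virus_only"
POOL_VIRUS_AND_BACTERIA = "virus_and_bacteria"
POOL_ALL = "all"
HOMOLOGY_POOLS = (POOL_VIRUS_ONLY, POOL_VIRUS_AND_BACTERIA, POOL_ALL)

#: Database labels for alignment-hit tables.
DB_LABELS = ("viral", "bacterial")

#: Sex levels recorded in the study metadata.
SEX_LEVELS = ("F", "M")
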