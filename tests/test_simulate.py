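import numpy as np
import pandas as pd
import pytest

from oralvirome import io as iomod
from oralvirome.assignment import assign_all
from oralvirome.errors import ValidationError
from oralvirome.simulate import (
    CommunityModel,
    NoiseModel,
    TaxonModel,
    default_fixture_path,
    default_model,
    simulate_community,
    simulate_fixture,
    simulate_hit_tables,
    simulate_taxonomy,
    write_fixture,
)


class TestSimulateTaxonomy:
    def test_node_and_subject_counts(self):
        tree = simulate_taxonomy(n_families=3, species_per_family=2, seed=0)
        ranks = pd.Series([n.rank for n in tree.nodes.values()]).value_counts()
        assert ranks["family"] == 3
        assert ranks["species"] == 6
        assert len(tree.subject_map) == 6

    def test_pure_prophage_mix(self):
        tree = simulate_taxonomy(
            3, 2, class_mix={"prophage": 1.0}, seed=1
        )
        assert all(cls == "prophage" for _, cls in tree.subject_map.values())

    def test_same_seed_identical_trees(self):
        a = simulate_taxonomy(5, 3, seed=7)
        b = simulate_taxonomy(5, 3, seed=7)
        assert a.nodes == b.nodes and a.subject_map == b.subject_map

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValidationError):
            simulate_taxonomy(3, 2, class_mix={"prophage": 0.5})


class TestSimulateCommunity:
    @staticmethod
    def _model(tree, probs, n_samples=20, reads=100):
        taxa = [
            TaxonModel(t, tree.class_of_subject(f"ref|{t}"), p)
            for t, p in zip(sorted(tree.species_ids()), probs)
        ]
        return CommunityModel(taxa=taxa, n_samples=n_samples, reads_per_sample=reads)

    def test_certain_and_impossible_presence(self):
        tree = simulate_taxonomy(2, 2, seed=0)
        model = self._model(tree, [1.0, 1.0, 0.0, 0.0])
        truth = simulate_community(model, tree, seed=3)
        assert (truth.presence.iloc[0] == 1).all()
        assert (truth.presence.iloc[2] == 0).all()
        assert (truth.counts.iloc[2] == 0).all()

    def test_mean_occurrences_match_binomial_expectation(self):
        """prevalence 0.9 over 72 samples → mean occupancy 64.8, matched
        within 3 standard errors over 1000 replicates."""
        tree = simulate_taxonomy(1, 2, seed=0)
        model = self._model(tree, [0.9, 0.5], n_samples=72, reads=10)
        occurrences = [
            simulate_community(model, tree, seed=s).presence.iloc[0].sum()
            for s in range(1000)
        ]
        se_mean = np.sqrt(72 * 0.9 * 0.1 / 1000)
        assert abs(np.mean(occurrences) - 64.8) <= 3 * se_mean

    def test_column_sums_equal_reads_per_sample(self):
        tree = simulate_taxonomy(3, 2, seed=0)
        model = self._model(tree, [0.8] * 6, reads=500)
        truth = simulate_community(model, tree, seed=1)
        assert (truth.counts.sum(axis=0) == 500).all()

    def test_sex_split_deterministic(self):
        tree = simulate_taxonomy(2, 2, seed=0)
        model = self._model(tree, [1.0] * 4, n_samples=72)
        truth = simulate_community(model, tree, seed=5)
        assert (truth.metadata["sex"] == "F").sum() == 36


class TestSimulateHitTables:
    def test_noiseless_limit_recovers_truth_exactly(self):
        tree = simulate_taxonomy(4, 3, seed=2)
        taxa = [
            TaxonModel(t, tree.class_of_subject(f"ref|{t}"), 0.7)
            for t in sorted(tree.species_ids())
        ]
        model = CommunityModel(
            taxa=taxa,
            n_samples=6,
            reads_per_sample=200,
            noise=NoiseModel(
                fail_rate=0.0,
                off_target_rate=0.0,
                identity_sd=0.0,
                coverage_alpha=900.0,  # coverage tightly at 0.9: no
                coverage_beta=100.0,  # accidental threshold failures
            ),
            bacterial_only_reads_per_sample=0,
        )
        truth = simulate_community(model, tree, seed=4)
        hits = simulate_hit_tables(truth, model, tree, seed=5)
        from oralvirome.tables import build_taxon_table

        per_sample = {
            s: assign_all(hits.viral[s], hits.bacterial[s], tree).assignments
            for s in truth.counts.columns
        }
        table = build_taxon_table(per_sample, tree, "species")
        recovered = table.counts.reindex(
            index=truth.counts.index, fill_value=0
        )[truth.counts.columns]
        pd.testing.assert_frame_equal(
            recovered, truth.counts, check_names=False
        )
        assert hits.read_truth.passes_filter.all()
        assert not hits.read_truth.ambiguous.any()

    def test_truth_rows_match_distinct_queries_without_off_target(self):
        tree = simulate_taxonomy(3, 2, seed=1)
        taxa = [
            TaxonModel(t, tree.class_of_subject(f"ref|{t}"), 0.6)
            for t in sorted(tree.species_ids())
        ]
        model = CommunityModel(
            taxa=taxa, n_samples=4, reads_per_sample=150,
            noise=NoiseModel(off_target_rate=0.0),
            bacterial_only_reads_per_sample=0,
        )
        truth = simulate_community(model, tree, seed=2)
        hits = simulate_hit_tables(truth, model, tree, seed=3)
        n_queries = sum(
            len({h.query_id for h in table}) for table in hits.viral.values()
        )
        assert n_queries == len(hits.read_truth)
        assert n_queries == truth.counts.values.sum()

    def test_off_target_ties_fall_to_genus_for_flagged_reads(self):
        tree = simulate_taxonomy(2, 4, seed=3)
        taxa = [
            TaxonModel(t, tree.class_of_subject(f"ref|{t}"), 0.9)
            for t in sorted(tree.species_ids())
        ]
        model = CommunityModel(
            taxa=taxa, n_samples=3, reads_per_sample=300,
            noise=NoiseModel(fail_rate=0.0, off_target_rate=0.3),
            bacterial_only_reads_per_sample=0,
        )
        truth = simulate_community(model, tree, seed=6)
        hits = simulate_hit_tables(truth, model, tree, seed=7)
        flagged = hits.read_truth.set_index("query_id")["ambiguous"]
        for sample, table in hits.viral.items():
            by_query: dict[str, list] = {}
            for h in table:
                by_query.setdefault(h.query_id, []).append(h)
            from oralvirome.assignment import assign_read

            for query, query_hits in by_query.items():
                a = assign_read(query_hits, tree)
                expected_rank = "genus" if flagged[query] else "species"
                assert a.resolution_rank == expected_rank

    def test_bacterial_homology_skews_dual_pool_toward_prophage(self):
        """With near-certain prophage bacterial homology and near-zero
        eukaryotic homology, the dual-homology pool is prophage-enriched
        relative to the virus-only pool (the generator's binomial
        expectation)."""
        from oralvirome.partitioning import partition_summary

        model, tree = default_model(
            n_samples=10, reads_per_sample=400, seed=9,
            bacterial_only_reads_per_sample=0,
        )
        truth = simulate_community(model, tree, seed=10)
        hits = simulate_hit_tables(truth, model, tree, seed=11)
        assignments = [
            a
            for s in truth.counts.columns
            for a in assign_all(hits.viral[s], hits.bacterial[s], tree).assignments
        ]
        summary = partition_summary(assignments, tree)
        dual = summary.proportions.get(("virus_and_bacteria", "prophage"), 0)
        only = summary.proportions.get(("virus_only", "prophage"), 0)
        assert dual > only


class TestFixtureFiles:
    def test_written_fixture_parses_back(self, tmp_path, small_sim):
        out = write_fixture(
            tmp_path / "fx", small_sim.tree, small_sim.model,
            small_sim.truth, small_sim.hits, 0,
        )
        tree = iomod.read_taxonomy(
            out / "taxonomy_nodes.tsv", out / "taxonomy_subjects.tsv"
        )
        assert tree.nodes == small_sim.tree.nodes
        meta = iomod.read_sample_metadata(out / "metadata.tsv")
        assert list(meta.index) == list(small_sim.truth.counts.columns)
        sample = small_sim.truth.counts.columns[0]
        hits = iomod.read_hit_table(out / "hits" / f"{sample}.viral.tsv", "viral")
        assert len(hits) == len(small_sim.hits.viral[sample])

    def test_same_seed_byte_identical(self, tmp_path):
        for name in ("a", "b"):
            model, tree = default_model(n_samples=3, reads_per_sample=50, seed=5)
            truth, hits = simulate_fixture(model, tree, 5)
            write_fixture(tmp_path / name, tree, model, truth, hits, 5)
        files_a = sorted((tmp_path / "a").rglob("*.tsv"))
        assert files_a
        for file_a in files_a:
            file_b = tmp_path / "b" / file_a.relative_to(tmp_path / "a")
            assert file_a.read_bytes() == file_b.read_bytes()

    def test_shipped_default_fixture_is_valid(self):
        path = default_fixture_path()
        tree = iomod.read_taxonomy(
            path / "taxonomy_nodes.tsv", path / "taxonomy_subjects.tsv"
        )
        meta = iomod.read_sample_metadata(path / "metadata.tsv")
        assert len(meta) == 12
        hits = iomod.read_hit_table(path / "hits" / "S001.viral.tsv", "viral")
        assert hits and all(h.query_length is not None for h in hits)
        assert all(h.subject_id in tree.subject_map for h in hits)
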