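"""Community-matrix construction: pooling, harmonization, binarization,
exclusions and trait splits."""

import numpy as np
import pandas as pd
import pytest

from bankbeta import community as com


def trap_table(rows):
    base = {"catchment": "B", "site_code": "B1", "position": 1, "bank": "left", "visit": 1}
    return pd.DataFrame([base | r for r in rows])


class TestPoolTraps:
    def test_counts_sum_across_traps(self):
        rows = [{"trap": t, "taxon": "A", "rank": "species", "count": 1} for t in range(1, 7)]
        pooled = com.pool_traps(trap_table(rows))
        assert len(pooled) == 1
        assert pooled.iloc[0]["count"] == 6
        assert pooled.iloc[0]["sample_id"] == "B1-L-V1"

    def test_empty_traps_give_empty_sample(self):
        pooled = com.pool_traps(trap_table([]).reindex(
            columns=["catchment", "site_code", "position", "bank", "visit",
                     "trap", "taxon", "rank", "count"]))
        assert pooled.empty

    def test_partial_overlap_hand_sum(self):
        rows = [
            {"trap": 1, "taxon": "A", "rank": "species", "count": 2},
            {"trap": 2, "taxon": "A", "rank": "species", "count": 1},
            {"trap": 2, "taxon": "B", "rank": "species", "count": 3},
        ]
        pooled = com.pool_traps(trap_table(rows)).set_index("taxon")["count"]
        assert pooled.to_dict() == {"A": 3, "B": 3}

    def test_mixed_banks_rejected_with_trap_id(self):
        rows = trap_table([{"trap": 1, "taxon": "A", "rank": "species", "count": 1},
                           {"trap": 9, "taxon": "B", "rank": "species", "count": 1}])
        rows.loc[1, "bank"] = "right"
        with pytest.raises(com.CommunityDataError, match="9"):
            com.pool_traps(rows)

    def test_pooling_preserves_any_trap_presence(self, rng):
        # presence in >= 1 trap implies presence in the pooled sample
        rows = [
            {"trap": t, "taxon": f"sp{s}", "rank": "species",
             "count": int(rng.integers(0, 3))}
            for t in range(1, 7) for s in range(8)
        ]
        table = trap_table(rows)
        pooled = com.pool_traps(table)
        seen = set(table.loc[table["count"] > 0, "taxon"])
        assert set(pooled["taxon"]) == seen


class TestHarmonize:
    def test_genus_merged_into_species(self):
        table = pd.DataFrame(
            [
                ("s1", "Pterostichus", "genus", 2),
                ("s1", "Pterostichus madidus", "species", 3),
            ],
            columns=com.OCC_COLUMNS,
        )
        out = com.harmonize_taxa(table, {"Pterostichus": "Pterostichus madidus"})
        assert len(out) == 1
        assert out.iloc[0]["taxon"] == "Pterostichus madidus"
        assert out.iloc[0]["count"] == 5

    def test_no_genus_records_identity(self):
        table = pd.DataFrame([("s1", "A", "species", 2)], columns=com.OCC_COLUMNS)
        out = com.harmonize_taxa(table, {})
        pd.testing.assert_frame_equal(out, table)

    def test_relabel_when_target_species_absent(self):
        table = pd.DataFrame([("s1", "Agonum", "genus", 4)], columns=com.OCC_COLUMNS)
        out = com.harmonize_taxa(table, {"Agonum": "Agonum emarginatum"})
        assert out.iloc[0]["taxon"] == "Agonum emarginatum"
        assert out.iloc[0]["count"] == 4

    def test_unmapped_genus_is_error_not_silent_drop(self):
        table = pd.DataFrame([("s1", "Bembidion", "genus", 1)], columns=com.OCC_COLUMNS)
        with pytest.raises(com.CommunityDataError, match="Bembidion"):
            com.harmonize_taxa(table, {})

    def test_family_records_dropped_with_warning(self, caplog):
        table = pd.DataFrame(
            [("s1", "Carabidae", "family", 1), ("s1", "A", "species", 2)],
            columns=com.OCC_COLUMNS,
        )
        with caplog.at_level("WARNING", logger="bankbeta.community"):
            out = com.harmonize_taxa(table, {})
        assert list(out["taxon"]) == ["A"]
        assert any("family" in r.message for r in caplog.records)

    def test_total_count_conserved(self, rng):
        taxa = ["A", "B", "Pterostichus", "Agonum"]
        ranks = {"A": "species", "B": "species", "Pterostichus": "genus", "Agonum": "genus"}
        rows = [
            (f"s{rng.integers(3)}", t, ranks[t], int(rng.integers(0, 5)))
            for t in taxa for _ in range(6)
        ]
        table = pd.DataFrame(rows, columns=com.OCC_COLUMNS)
        out = com.harmonize_taxa(table, {"Pterostichus": "A", "Agonum": "B"})
        assert out["count"].sum() == table["count"].sum()
        # (sample, taxon) unique after aggregation
        assert not out.duplicated(["sample_id", "taxon"]).any()


class TestBinarize:
    @staticmethod
    def meta():
        from conftest import make_metadata

        return make_metadata(n_sites=1, n_visits=1)

    def test_abundance_invariance(self):
        meta = self.meta()
        table = pd.DataFrame(
            [("B1-L-V1", "A", "species", 5), ("B1-L-V1", "B", "species", 1),
             ("B1-R-V1", "A", "species", 1), ("B1-R-V1", "B", "species", 99)],
            columns=com.OCC_COLUMNS,
        )
        m = com.binarize(table, meta)
        assert (m.occurrence.loc["B1-L-V1"] == m.occurrence.loc["B1-R-V1"]).all()

    def test_zero_count_species_column_absent(self):
        meta = self.meta()
        table = pd.DataFrame(
            [("B1-L-V1", "A", "species", 5), ("B1-L-V1", "B", "species", 0)],
            columns=com.OCC_COLUMNS,
        )
        m = com.binarize(table, meta)
        assert list(m.occurrence.columns) == ["A"]

    def test_unknown_sample_is_error(self):
        table = pd.DataFrame([("ghost", "A", "species", 1)], columns=com.OCC_COLUMNS)
        with pytest.raises(com.CommunityDataError, match="ghost"):
            com.binarize(table, self.meta())

    def test_full_design_has_96_rows(self, full_matrix):
        assert full_matrix.shape[0] == 96

    def test_columns_lexicographic(self, full_matrix):
        assert list(full_matrix.occurrence.columns) == sorted(full_matrix.occurrence.columns)


class TestExclusions:
    def test_study_exclusions_arithmetic(self, full_matrix):
        m94 = com.apply_exclusions(full_matrix, [("B6", 4, "livestock")])
        assert m94.shape[0] == 94
        m92 = com.apply_exclusions(m94, [("B3", 4, "singleton-inflation")])
        assert m92.shape[0] == 92
        assert len(m92.exclusion_log) == 2

    def test_rows_removed_in_pairs(self, full_matrix):
        m = com.apply_exclusions(full_matrix, [("C2", 1, ""), ("B1", 3, "")])
        assert (full_matrix.shape[0] - m.shape[0]) % 2 == 0

    def test_empty_exclusion_list_is_identity(self, full_matrix):
        m = com.apply_exclusions(full_matrix, [])
        pd.testing.assert_frame_equal(m.occurrence, full_matrix.occurrence)

    def test_unknown_site_visit_is_error(self, full_matrix):
        with pytest.raises(com.CommunityDataError, match="Z9"):
            com.apply_exclusions(full_matrix, [("Z9", 1, "")])


class TestSplitByFlight:
    def test_definition_example(self):
        from conftest import make_metadata, matrix_from_sets

        meta = make_metadata(n_sites=1, n_visits=1)
        m = matrix_from_sets({"B1-L-V1": {"A", "B", "C"}, "B1-R-V1": {"A"}}, meta)
        traits = {"A": "macropterous", "B": "brachypterous", "C": "polymorphic"}
        splits = com.split_by_flight(m, traits)
        assert splits["flight_capable"].species == ["A"]
        assert splits["limited_flight"].species == ["B", "C"]

    def test_columns_partition(self, analyzed_matrix, default_sim):
        splits = com.split_by_flight(analyzed_matrix, default_sim.traits)
        fc = set(splits["flight_capable"].species)
        lf = set(splits["limited_flight"].species)
        assert fc & lf == set()
        assert fc | lf == set(splits["all_species"].species)

    def test_all_zero_rows_retained(self, analyzed_matrix, default_sim):
        splits = com.split_by_flight(analyzed_matrix, default_sim.traits)
        assert splits["limited_flight"].shape[0] == analyzed_matrix.shape[0]

    def test_missing_trait_is_error(self, analyzed_matrix, default_sim):
        traits = default_sim.traits.drop(analyzed_matrix.species[0])
        with pytest.raises(com.CommunityDataError, match=analyzed_matrix.species[0]):
            com.split_by_flight(analyzed_matrix, traits)

    def test_all_macropterous_pool_degenerate_subset(self):
        from conftest import make_metadata, matrix_from_sets

        meta = make_metadata(n_sites=1, n_visits=1)
        m = matrix_from_sets({"B1-L-V1": {"A"}, "B1-R-V1": {"A"}}, meta)
        splits = com.split_by_flight(m, {"A": "macropterous"})
        assert splits["limited_flight"].shape == (2, 0)
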