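"""Sorensen pairwise dissimilarity, Baselga partition, cross-channel
extraction and summaries — checked against brute-force set algebra and
scipy's Dice dissimilarity (identical to Sorensen on binary data)."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import dice

from bankbeta import beta as bt
from bankbeta import community as com
from conftest import make_metadata, matrix_from_sets

SPECIES = [f"sp{i}" for i in range(12)]


class TestSorensenPair:
    def test_identical_sets_zero(self):
        assert bt.sorensen_pair({"A", "B", "C"}, {"A", "B", "C"}).beta_sor == 0.0

    def test_disjoint_sets_one(self):
        assert bt.sorensen_pair({"A"}, {"B"}).beta_sor == 1.0

    def test_hand_computed_triple(self):
        a, b, c, sor = bt.sorensen_pair({"A", "B", "C"}, {"A", "B", "D"})
        assert (a, b, c) == (2, 1, 1)
        assert sor == pytest.approx(2 / 6)

    def test_both_empty_undefined(self):
        assert math.isnan(bt.sorensen_pair(set(), set()).beta_sor)

    def test_one_empty_is_complete_dissimilarity(self):
        assert bt.sorensen_pair({"A", "B"}, set()).beta_sor == 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        x=st.sets(st.sampled_from(SPECIES)),
        y=st.sets(st.sampled_from(SPECIES)),
    )
    def test_symmetry_and_range(self, x, y):
        rx = bt.sorensen_pair(x, y)
        ry = bt.sorensen_pair(y, x)
        assert (rx.a, rx.b, rx.c) == (ry.a, ry.c, ry.b)
        if x or y:
            assert rx.beta_sor == ry.beta_sor
            assert 0.0 <= rx.beta_sor <= 1.0

    def test_agreement_with_set_oracle_and_scipy(self, rng):
        # brute-force oracle: element-wise membership counting
        for _ in range(100):
            x = set(rng.choice(SPECIES, rng.integers(0, 10), replace=False))
            y = set(rng.choice(SPECIES, rng.integers(0, 10), replace=False))
            a = sum(1 for s in SPECIES if s in x and s in y)
            b = sum(1 for s in SPECIES if s in x and s not in y)
            c = sum(1 for s in SPECIES if s in y and s not in x)
            got = bt.sorensen_pair(x, y)
            assert (got.a, got.b, got.c) == (a, b, c)
            if x or y:
                expect = (b + c) / (2 * a + b + c)
                assert got.beta_sor == pytest.approx(expect, abs=1e-15)
                if x and y:
                    vx = np.array([s in x for s in SPECIES])
                    vy = np.array([s in y for s in SPECIES])
                    assert got.beta_sor == pytest.approx(dice(vx, vy), abs=1e-12)


class TestBaselgaPartition:
    def test_equal_unique_counts_pure_turnover(self):
        sim, sne = bt.baselga_partition(3, 2, 2)
        assert sne == pytest.approx(0.0, abs=1e-15)

    def test_perfect_nestedness_pure_richness_difference(self):
        sim, sne = bt.baselga_partition(2, 3, 0)
        assert sim == 0.0
        assert sne == pytest.approx(3 / 7)

    def test_hand_computed_partition(self):
        sim, sne = bt.baselga_partition(1, 2, 1)
        assert sim == pytest.approx(0.5)
        assert sne == pytest.approx(0.1)

    def test_all_zero_undefined(self):
        sim, sne = bt.baselga_partition(0, 0, 0)
        assert math.isnan(sim) and math.isnan(sne)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            bt.baselga_partition(-1, 0, 1)

    def test_partition_identity_random_triples(self, rng):
        # beta_sim + beta_sne == beta_sor to 1e-12 over 1000 random triples
        for _ in range(1000):
            a, b, c = (int(v) for v in rng.integers(0, 40, 3))
            if a + b + c == 0:
                continue
            sor = (b + c) / (2 * a + b + c)
            sim, sne = bt.baselga_partition(a, b, c)
            assert abs(sim + sne - sor) < 1e-12
            assert sne >= -1e-15
            assert sim <= sor + 1e-15

    def test_vectorized_matches_scalar(self, rng):
        abc = rng.integers(0, 20, size=(200, 3))
        sor, sim, sne = bt.beta_components(abc[:, 0], abc[:, 1], abc[:, 2])
        for i, (a, b, c) in enumerate(abc):
            s_sim, s_sne = bt.baselga_partition(int(a), int(b), int(c))
            if a + b + c == 0:
                assert math.isnan(sor[i])
            else:
                assert sim[i] == pytest.approx(s_sim, abs=1e-14)
                assert sne[i] == pytest.approx(s_sne, abs=1e-14)


class TestCrossChannelExtract:
    def test_full_design_yields_48_pairs(self, full_matrix):
        assert len(bt.cross_channel_extract(full_matrix)) == 48

    def test_after_exclusions_46_pairs(self, analyzed_matrix):
        pairs = bt.cross_channel_extract(analyzed_matrix)
        assert len(pairs) == 46
        assert not pairs["undefined"].any()

    def test_orphan_bank_flagged_not_dropped(self, full_matrix):
        drop = full_matrix.metadata.index[0]
        m = com.CommunityMatrix(
            full_matrix.occurrence.drop(index=drop),
            full_matrix.metadata.drop(index=drop),
        )
        pairs = bt.cross_channel_extract(m)
        assert len(pairs) == 47
        assert len(pairs.attrs["missing"]) == 1

    def test_duplicate_bank_sample_is_error(self, full_matrix):
        meta = full_matrix.metadata.copy()
        meta.loc[meta.index[1], ["catchment", "site_code", "position", "bank", "visit"]] = (
            meta.loc[meta.index[0], ["catchment", "site_code", "position", "bank", "visit"]]
        )
        m = com.CommunityMatrix(full_matrix.occurrence, meta)
        with pytest.raises(ValueError, match="duplicate"):
            bt.cross_channel_extract(m)

    def test_degenerate_and_undefined_flags(self):
        meta = make_metadata(n_sites=2, n_visits=1)
        m = matrix_from_sets(
            {"B1-L-V1": {"A"}, "B1-R-V1": set(), "B2-L-V1": set(), "B2-R-V1": set()},
            meta,
        )
        pairs = bt.cross_channel_extract(m).set_index("site_code")
        assert pairs.loc["B1", "degenerate"]
        assert pairs.loc["B1", "beta_sor"] == 1.0
        assert pairs.loc["B2", "undefined"]
        assert math.isnan(pairs.loc["B2", "beta_sor"])

    def test_abundance_rescaling_invariance(self, default_sim):
        scaled = default_sim.traps.assign(count=default_sim.traps["count"] * 7)
        base = com.binarize(com.pool_all_traps(default_sim.traps), default_sim.metadata)
        resc = com.binarize(com.pool_all_traps(scaled), default_sim.metadata)
        pd.testing.assert_frame_equal(
            bt.cross_channel_extract(base), bt.cross_channel_extract(resc)
        )


class TestSummarize:
    def make_pairs(self, values):
        return pd.DataFrame({"dataset": "all_species", "beta_sor": values})

    def test_singleton(self):
        out = bt.summarize_beta(self.make_pairs([0.5])).iloc[0]
        assert out["min"] == out["mean"] == out["max"] == 0.5
        assert math.isnan(out["sd"])

    def test_hand_computed(self):
        out = bt.summarize_beta(self.make_pairs([0.0, 1.0])).iloc[0]
        assert out["mean"] == 0.5
        assert out["min"] == 0.0 and out["max"] == 1.0
        assert out["sd"] == pytest.approx(np.std([0, 1], ddof=1))

    def test_undefined_pairs_excluded_and_empty_is_error(self):
        out = bt.summarize_beta(self.make_pairs([0.25, float("nan")])).iloc[0]
        assert out["n"] == 1
        with pytest.raises(ValueError):
            bt.summarize_beta(self.make_pairs([float("nan")]))
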