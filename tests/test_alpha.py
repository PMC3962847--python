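"""Richness and diversity estimators: exact values, oracles, invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amplicore import (OtuTable, SubsampleSpec, ace, alpha_summary, chao1,
                       faith_pd, rarefaction_curve, shannon, shannon_evenness)
from amplicore.alpha import FrequencyCounts, shannon_ci
from amplicore.io import read_tree


class TestShannon:
    def test_uniform_is_log_k(self):
        assert shannon([10, 10, 10, 10, 10]) == pytest.approx(math.log(5))

    def test_single_category_is_zero(self):
        assert shannon([23, 0, 0, 0, 0]) == 0.0

    def test_hand_evaluated_mixture(self):
        # -sum p ln p for (13,26,24,36,41); /ln 5 gives the 0.960 evenness
        assert shannon([13, 26, 24, 36, 41]) == pytest.approx(1.5447, abs=1e-3)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_ci_contains_point(self):
        est = shannon_ci([13, 26, 24, 36, 41])
        assert est.lo <= est.value <= est.hi


class TestShannonEvenness:
    @pytest.mark.parametrize("counts, expected", [
        ((4, 3, 4, 6, 6), 0.979),
        ((11, 3, 12, 4, 9), 0.925),
    ])
    def test_published_core_rows(self, counts, expected):
        assert shannon_evenness(counts, 5) == pytest.approx(expected, abs=5e-4)

    def test_equal_counts_give_one(self):
        assert shannon_evenness([7, 7, 7], 3) == pytest.approx(1.0)

    def test_fewer_than_two_categories_rejected(self):
        with pytest.raises(ValueError):
            shannon_evenness([5], 1)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(1, 500), min_size=2, max_size=8),
           st.randoms(use_true_random=False))
    def test_permutation_and_scale_invariance(self, counts, rnd):
        k = len(counts)
        e = shannon_evenness(counts, k)
        assert 0.0 <= e <= 1.0
        shuffled = list(counts)
        rnd.shuffle(shuffled)
        assert shannon_evenness(shuffled, k) == pytest.approx(e)
        assert shannon_evenness([10 * c for c in counts], k) == pytest.approx(e)


class TestChao1:
    def test_five_singletons(self):
        assert chao1(FrequencyCounts.from_counts([1] * 5)).value == 15.0

    def test_no_singletons_equals_sobs(self):
        fc = FrequencyCounts.from_counts([2, 3, 4])
        assert chao1(fc).value == 3.0

    def test_direct_formula(self):
        fc = FrequencyCounts.from_counts([1, 1, 2, 2, 3])
        est = chao1(fc)
        assert est.value == pytest.approx(5 + 2 * 1 / 6)
        assert est.lo <= est.value <= est.hi

    def test_matches_skbio(self):
        from skbio.diversity.alpha import chao1 as sk_chao1
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(0, 8, size=30)
            counts[0] = max(counts[0], 1)
            ours = chao1(FrequencyCounts.from_counts(counts)).value
            assert ours == pytest.approx(sk_chao1(counts, bias_corrected=True))


class TestAce:
    def test_empty_rare_class_gives_sobs(self):
        fc = FrequencyCounts.from_counts([11, 12, 20])
        assert ace(fc).value == 3.0

    def test_all_singletons_fall_back_to_chao1(self):
        fc = FrequencyCounts.from_counts([1, 1, 1])
        est = ace(fc)
        assert est.flag == "chao1_fallback"
        assert est.value == chao1(fc).value

    def test_formula_oracle(self):
        # independent spreadsheet-style evaluation for counts {1,1,2,3,12}:
        # S_abund=1, S_rare=4, N_rare=7, C=5/7, gamma^2=0.0667 -> 6.7867
        fc = FrequencyCounts.from_counts([1, 1, 2, 3, 12])
        est = ace(fc)
        assert est.value == pytest.approx(6.7867, abs=1e-3)
        assert est.lo <= est.value <= est.hi

    def test_matches_skbio(self):
        from skbio.diversity.alpha import ace as sk_ace
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(0, 30, size=40)
            counts[:5] = rng.integers(2, 6, size=5)  # nonzero rare class, F1 varies
            fc = FrequencyCounts.from_counts(counts)
            est = ace(fc)
            if est.flag is None:
                assert est.value == pytest.approx(sk_ace(counts), rel=1e-9)

    def test_estimators_at_least_sobs(self, random_table_factory):
        t = random_table_factory(seed=8, max_count=6)
        for row in t.counts.to_numpy():
            fc = FrequencyCounts.from_counts(row)
            assert chao1(fc).value >= fc.s_obs
            assert ace(fc).value >= fc.s_obs


class TestFaithPD:
    @pytest.fixture
    def small_tree(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,C:2);\n")
        return read_tree(p)

    def test_all_leaves_give_total_length(self, small_tree):
        assert faith_pd(small_tree, {"A", "B", "C"}) == pytest.approx(5.0)

    def test_single_leaf_path_to_root(self, small_tree):
        assert faith_pd(small_tree, {"A"}) == pytest.approx(2.0)

    def test_star_tree_counts_present_edges(self, tmp_path):
        p = tmp_path / "star.nwk"
        p.write_text("(A:1,B:1,C:1,D:1);\n")
        tree = read_tree(p)
        assert faith_pd(tree, {"A", "C", "D"}) == pytest.approx(3.0)

    def test_unknown_leaf_listed(self, small_tree):
        with pytest.raises(KeyError, match="Z"):
            faith_pd(small_tree, {"A", "Z"})

    def test_matches_skbio(self, tmp_path):
        from skbio.diversity.alpha import faith_pd as sk_faith
        rng = np.random.default_rng(2)
        from amplicore.simulate import _random_ultrametric_tree
        names = [f"L{i}" for i in range(12)]
        tree = _random_ultrametric_tree(names, rng)
        counts = rng.integers(0, 3, size=12)
        counts[0] = 1
        ours = faith_pd(tree, {n for n, c in zip(names, counts) if c > 0})
        assert ours == pytest.approx(
            float(sk_faith(counts, taxa=names, tree=tree)))


class TestRarefaction:
    def test_endpoints(self):
        counts = [5, 3, 2]
        n = sum(counts)
        curve = rarefaction_curve(counts, [0, 1, n])
        assert curve[0] == 0.0
        assert curve[1] == pytest.approx(1.0)
        assert curve[2] == pytest.approx(3.0)

    def test_exhaustive_enumeration_oracle(self):
        # (2,2) at n=2: 2 - 2*C(2,2)/C(4,2) = 5/3
        assert rarefaction_curve([2, 2], [2])[0] == pytest.approx(5 / 3)

    def test_nondecreasing_and_bounded(self, random_table_factory):
        t = random_table_factory(seed=9)
        counts = t.counts.iloc[0].to_numpy()
        depths = np.arange(0, counts.sum() + 1, 25)
        curve = rarefaction_curve(counts, depths)
        assert np.all(np.diff(curve) >= -1e-9)
        assert curve[-1] <= (counts > 0).sum() + 1e-9

    def test_monte_carlo_oracle(self):
        """Analytic curve matches the mean of many hypergeometric draws."""
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 6, size=12)
        counts[0] = max(counts[0], 1)
        depth = int(counts.sum() // 2)
        expected = rarefaction_curve(counts, [depth])[0]
        n_mc = 10_000
        draws = rng.multivariate_hypergeometric(counts, depth, size=n_mc)
        sobs = (draws > 0).sum(axis=1)
        se = sobs.std(ddof=1) / np.sqrt(n_mc)
        assert abs(sobs.mean() - expected) < 3 * se


class TestAlphaSummary:
    def test_full_depth_single_replicate_matches_direct(self, random_table_factory):
        t = random_table_factory(seed=10)
        depth = int(t.sample_totals().min())
        spec = SubsampleSpec(depth=depth, replicates=1, seed=0)
        summary = alpha_summary(t, spec)
        # the sample at min depth is passed through unchanged
        s_min = t.sample_totals().idxmin()
        row = t.counts.loc[s_min].to_numpy()
        fc = FrequencyCounts.from_counts(row)
        assert summary.data.loc[s_min, "sobs"] == fc.s_obs
        assert summary.data.loc[s_min, "shannon"] == pytest.approx(shannon(row))

    def test_degenerate_one_otu_samples(self):
        t = OtuTable(pd.DataFrame([[9], [7]], index=["A", "B"],
                                  columns=["o"]))
        summary = alpha_summary(t, SubsampleSpec(depth=7, replicates=3, seed=0))
        assert (summary.data["sobs"] == 1).all()
        assert (summary.data["shannon"] == 0).all()
        assert (summary.data["chao1"] == 1).all()

    def test_cis_contain_estimates_and_estimators_exceed_sobs(
            self, random_table_factory):
        t = random_table_factory(seed=11, n_otus=80, max_count=8)
        spec = SubsampleSpec(depth=int(t.sample_totals().min()),
                             replicates=3, seed=1)
        d = alpha_summary(t, spec).data
        assert (d["chao1"] >= d["sobs"] - 1e-9).all()
        assert (d["ace"] >= d["sobs"] - 1e-9).all()
        assert (d["chao1_lo"] <= d["chao1"]).all()
        assert (d["chao1"] <= d["chao1_hi"]).all()
        assert (d["shannon_lo"] <= d["shannon"]).all()

    def test_chao1_underestimates_simulated_truth_but_exceeds_sobs(self):
        """At shallow depth Chao1 stays between observed and true richness."""
        from amplicore import SimulationConfig, simulate
        hits = 0
        for seed in range(6):
            ds = simulate(SimulationConfig(seed=seed))
            spec = SubsampleSpec(depth=1500, replicates=3, seed=seed)
            d = alpha_summary(ds.table, spec).data
            true = ds.true_richness
            ok = ((d["chao1"] > d["sobs"]) &
                  (d["chao1"].to_numpy() < true.to_numpy())).all()
            hits += bool(ok)
        assert hits >= 5
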