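"""Spearman/ReBoot associations, power, group comparisons, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import _oracles
from nutrinet.association import (
    AssociationResult,
    DegenerateNullError,
    RebootParams,
    bh_fdr,
    category_composition,
    classify_pc_nc,
    correlation_power,
    group_compare,
    reboot_significance,
    spearman_rho,
)
from nutrinet.profiles import FeatureTable


class TestSpearmanRho:
    def test_perfect_anticorrelation(self):
        assert spearman_rho([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (1,1,0) gives 0.5
        assert spearman_rho([1, 2, 3], [2, 1, 3]) == pytest.approx(0.5)

    def test_rank_invariance(self):
        x = np.array([0.3, 1.2, 2.9, 3.1, 7.0])
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)

    def test_constant_input_warns_nan(self):
        with pytest.warns(UserWarning):
            out = spearman_rho([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(out)

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 8, n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            assert spearman_rho(x, y) == pytest.approx(
                _oracles.spearman(x, y), abs=1e-12
            )


class TestCorrelationPower:
    def test_null_rho_gives_alpha(self):
        assert correlation_power(0.0, 20) == pytest.approx(0.05)
        assert correlation_power(0.0, 50, alpha=0.10) == pytest.approx(0.10)

    def test_strong_correlation_near_one(self):
        # |rho| = 0.8 at n = 20 is detectable almost surely
        assert correlation_power(0.8, 20) == pytest.approx(0.995, abs=5e-4)

    def test_perfect_correlation_is_one(self):
        assert correlation_power(1.0, 10) == 1.0
        assert correlation_power(-1.0, 10) == 1.0

    def test_monotone_in_n(self):
        powers = [correlation_power(0.5, n) for n in (5, 10, 20, 40, 80)]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_sign_irrelevant(self):
        assert correlation_power(0.6, 15) == correlation_power(-0.6, 15)


def _composition(rows: dict) -> FeatureTable:
    data = pd.DataFrame(rows).T
    data.columns = [f"s{i+1}" for i in range(data.shape[1])]
    return FeatureTable(data, "taxon-genus", "normalized")


class TestRebootSignificance:
    @pytest.fixture()
    def comp(self, rng):
        raw = np.abs(rng.normal(1.0, 0.3, (6, 20)))
        rows = {f"f{i}": raw[i] for i in range(6)}
        rows["copy"] = rows["f0"] * 1.5  # monotone copy of f0
        data = pd.DataFrame(rows).T
        data /= data.sum(axis=0)
        data.columns = [f"s{i+1}" for i in range(20)]
        return FeatureTable(data, "taxon-genus", "normalized")

    def test_exact_copy_is_maximal_signal(self, comp):
        z, p = reboot_significance("f0", "copy", comp, RebootParams(300, 300, seed=1))
        assert z > 3.0
        assert p < 1e-3

    def test_z_197_pairs_with_p_0049(self):
        # the |z| > 1.97 edge rule corresponds to two-sided p < 0.05
        p = 2 * norm.sf(1.97)
        assert p == pytest.approx(0.0488, abs=5e-4)
        assert p < 0.05

    def test_deterministic_for_fixed_seed(self, comp):
        params = RebootParams(200, 200, seed=11)
        assert reboot_significance("f0", "f1", comp, params) == reboot_significance(
            "f0", "f1", comp, params
        )

    def test_index_target(self, comp, rng):
        index = np.arange(20.0)
        z, p = reboot_significance("f1", index, comp, RebootParams(200, 200, seed=2))
        assert np.isfinite(z) and 0 <= p <= 1

    def test_degenerate_null_raises(self):
        comp = _composition({"a": [0.5] * 8, "b": [0.5] * 8})
        with pytest.raises(DegenerateNullError):
            reboot_significance("a", "b", comp, RebootParams(100, 100, seed=3))

    def test_unknown_feature_rejected(self, comp):
        with pytest.raises(KeyError):
            reboot_significance("nope", "f1", comp, RebootParams(100, 100, seed=4))


class TestBhFdr:
    def test_step_up_hand_example(self):
        # all four share min(p_i * m / i) = 0.04
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            assert np.allclose(bh_fdr(p), _oracles.bh_adjust(list(p)), atol=1e-12)

    def test_nan_passthrough(self):
        out = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and np.isfinite(out[0])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_q_at_least_p_for_largest(self, ps):
        q = bh_fdr(ps)
        i = int(np.argmax(ps))
        assert q[i] >= ps[i] - 1e-12


def _ranked(rows, samples):
    data = pd.DataFrame(rows).T
    data.columns = samples
    return FeatureTable(data, "taxon-genus", "ranked")


class TestGroupCompare:
    def test_hand_computed_eta_and_kw(self):
        table = _ranked({"f": [1, 2, 3, 4]}, ["a1", "a2", "b1", "b2"])
        classes = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        res = group_compare(table, classes)[0]
        assert res.eta_squared == pytest.approx(0.8)  # SSB=4, SST=5
        assert res.kw_H == pytest.approx(2.4)

    def test_identical_groups_flat(self):
        table = _ranked({"f": [2, 2, 2, 2, 2, 2]}, [f"s{i}" for i in range(6)])
        classes = pd.Series(
            {"s0": "A", "s1": "A", "s2": "B", "s3": "B", "s4": "C", "s5": "C"}
        )
        res = group_compare(table, classes)[0]
        assert res.anova_F == 0.0
        assert res.eta_squared == 0.0

    def test_matches_oracles_on_random_tables(self, rng):
        samples = [f"s{i}" for i in range(12)]
        classes = pd.Series(dict(zip(samples, ["A"] * 4 + ["B"] * 4 + ["C"] * 4)))
        rows = {f"f{i}": rng.integers(0, 6, 12).astype(float) for i in range(20)}
        rows = {k: v for k, v in rows.items() if np.ptp(v) > 0}
        table = _ranked(rows, samples)
        results = group_compare(table, classes)
        for r in results:
            row = table.row(r.feature_id)
            groups = [row[:4], row[4:8], row[8:]]
            assert r.eta_squared == pytest.approx(
                _oracles.eta_squared([list(g) for g in groups]), abs=1e-10
            )
            assert r.kw_H == pytest.approx(
                _oracles.kruskal_wallis_h([list(g) for g in groups]), abs=1e-10
            )

    def test_separated_groups_significant_with_tukey(self):
        table = _ranked(
            {"f": [1, 2, 3, 10, 11, 12, 20, 21, 22]}, [f"s{i}" for i in range(9)]
        )
        classes = pd.Series(
            dict(zip([f"s{i}" for i in range(9)], ["A"] * 3 + ["B"] * 3 + ["C"] * 3))
        )
        res = group_compare(table, classes)[0]
        assert res.anova_p < 0.001
        assert all(t.significant for t in res.tukey_pairs)
        ac = [t for t in res.tukey_pairs if {t.group_a, t.group_b} == {"A", "C"}][0]
        ab = [t for t in res.tukey_pairs if {t.group_a, t.group_b} == {"A", "B"}][0]
        assert ac.q_statistic > ab.q_statistic

    def test_tukey_matches_statsmodels(self, rng):
        # cross-check the unequal-n q statistic via statsmodels' adjusted p
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate([rng.normal(10, 1, 5), rng.normal(11, 1, 7),
                                 rng.normal(13, 1, 4)])
        labels = ["A"] * 5 + ["B"] * 7 + ["C"] * 4
        samples = [f"s{i}" for i in range(16)]
        table = _ranked({"f": values}, samples)
        res = group_compare(table, pd.Series(dict(zip(samples, labels))))[0]
        import itertools

        sm = pairwise_tukeyhsd(values, labels)
        ours = {frozenset((t.group_a, t.group_b)): t.p_value for t in res.tukey_pairs}
        pairs = list(itertools.combinations(sm.groupsunique, 2))
        for (a, b), p_adj in zip(pairs, sm.pvalues):
            assert ours[frozenset((a, b))] == pytest.approx(float(p_adj), abs=1e-4)

    def test_small_class_skipped_with_warning(self):
        table = _ranked({"f": [1, 2, 3, 4, 5]}, [f"s{i}" for i in range(5)])
        classes = pd.Series(
            {"s0": "A", "s1": "A", "s2": "B", "s3": "B", "s4": "C"}
        )
        with pytest.warns(UserWarning, match="<2 samples"):
            assert group_compare(table, classes) == []


class TestPcNcClassification:
    def test_threshold_split(self):
        results = [
            AssociationResult("up", 0.7, 2.5, 0.01, 0.9, "positive"),
            AssociationResult("down", -0.7, -2.5, 0.01, 0.9, "negative"),
            AssociationResult("flat", 0.1, 1.0, 0.3, 0.1, "none"),
        ]
        pc, nc = classify_pc_nc(results)
        assert pc == ["up"] and nc == ["down"]
        assert not set(pc) & set(nc)

    def test_boundary_is_exclusive(self):
        results = [AssociationResult("edge", 0.5, 1.97, 0.05, 0.5, "none")]
        pc, nc = classify_pc_nc(results)
        assert pc == [] and nc == []


class TestCategoryComposition:
    def test_even_split(self):
        comp = category_composition(["a", "b", "c", "d"],
                                    {"a": "X", "b": "X", "c": "Y", "d": "Y"})
        assert comp == {"X": 50.0, "Y": 50.0}

    def test_planted_three_to_one(self):
        comp = category_composition(
            ["a", "b", "c", "d"], {"a": "A", "b": "A", "c": "A", "d": "B"}
        )
        assert comp == {"A": 75.0, "B": 25.0}

    def test_unmapped_goes_to_unknown(self):
        comp = category_composition(["a", "b"], {"a": "X"})
        assert comp == {"X": 50.0, "unknown": 50.0}

    def test_empty_warns(self):
        with pytest.warns(UserWarning):
            assert category_composition([], {}) == {}

    def test_percentages_sum_to_100(self, rng):
        feats = [f"f{i}" for i in range(37)]
        cmap = {f: f"cat{rng.integers(5)}" for f in feats}
        assert sum(category_composition(feats, cmap).values()) == pytest.approx(100.0)
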