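"""Feature-table filtering, normalization, ranking, core detection, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutrinet.profiles import (
    FeatureTable,
    HitThresholds,
    cluster_abundance_patterns,
    core_features,
    filter_hits,
    group_cumulative_abundance,
    normalize_abundance,
    rank_normalize,
)


def make_table(rows: dict, kind="taxon-genus", state="counts"):
    data = pd.DataFrame(rows).T
    data.columns = [f"s{i+1}" for i in range(data.shape[1])]
    return FeatureTable(data, kind=kind, state=state)


class TestFeatureTable:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            make_table({"a": [1, -2, 3]})

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_table({"a": [1, 2, 3]}, kind="species")

    def test_tsv_round_trip(self, tmp_path, normalized_genus):
        path = tmp_path / "t.tsv"
        normalized_genus.to_tsv(path)
        back = FeatureTable.from_tsv(path, "taxon-genus", "normalized")
        assert back.feature_ids == normalized_genus.feature_ids
        assert np.allclose(back.values, normalized_genus.values)


class TestFilterHits:
    @staticmethod
    def hits(rows):
        return pd.DataFrame(
            rows,
            columns=["read_id", "sample_id", "feature_id", "identity_pct",
                     "coverage_pct", "alignment_length"],
        )

    def test_taxa_thresholds_strictly_exceeded(self):
        h = self.hits([("r1", "s1", "f1", 70, 80, 100)])
        counts = filter_hits(h, HitThresholds.taxa())
        assert counts.loc["f1", "s1"] == 1

    def test_boundary_values_fail(self):
        # equal to a threshold is not "greater than"
        h = self.hits(
            [
                ("r1", "s1", "f1", 65, 80, 100),  # identity at bound
                ("r2", "s1", "f1", 70, 70, 100),  # coverage at bound
                ("r3", "s1", "f1", 70, 80, 75),   # length at bound
            ]
        )
        counts = filter_hits(h, HitThresholds.taxa())
        assert counts.empty or counts.to_numpy().sum() == 0

    def test_eggnog_filter_fails_on_coverage(self):
        h = self.hits([("r1", "s1", "f1", 70, 85, 200)])
        counts = filter_hits(h, HitThresholds.eggnog())
        assert counts.to_numpy().sum() == 0

    def test_eggnog_filter_ignores_length(self):
        h = self.hits([("r1", "s1", "f1", 70, 95, 10)])
        counts = filter_hits(h, HitThresholds.eggnog())
        assert counts.loc["f1", "s1"] == 1

    def test_missing_column_rejected(self):
        h = self.hits([("r1", "s1", "f1", 70, 80, 100)]).drop(columns=["coverage_pct"])
        with pytest.raises(ValueError, match="missing"):
            filter_hits(h, HitThresholds.taxa())

    def test_percentages_validated(self):
        with pytest.raises(ValueError):
            HitThresholds(0, 70)


class TestNormalizeAbundance:
    def test_divides_by_whole_metagenome_total(self):
        t = make_table({"a": [500, 100]})
        totals = pd.Series({"s1": 10_000, "s2": 10_000})
        out = normalize_abundance(t, totals)
        assert out.data.loc["a", "s1"] == pytest.approx(0.05)
        assert out.state == "normalized"

    def test_all_zero_feature_stays_zero(self):
        t = make_table({"a": [0, 0], "b": [5, 5]})
        out = normalize_abundance(t, pd.Series({"s1": 10, "s2": 10}))
        assert (out.data.loc["a"] == 0).all()

    def test_scale_invariance(self):
        t1 = make_table({"a": [3, 4], "b": [5, 6]})
        t2 = make_table({"a": [6, 8], "b": [10, 12]})
        n1 = normalize_abundance(t1, pd.Series({"s1": 100, "s2": 50}))
        n2 = normalize_abundance(t2, pd.Series({"s1": 200, "s2": 100}))
        assert np.allclose(n1.values, n2.values)

    def test_zero_total_rejected(self):
        t = make_table({"a": [1, 2]})
        with pytest.raises(ValueError):
            normalize_abundance(t, pd.Series({"s1": 0, "s2": 10}))

    def test_column_sums_below_one(self, normalized_genus):
        assert (normalized_genus.values.sum(axis=0) <= 1.0 + 1e-12).all()


class TestRankNormalize:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([10, 20, 30], [1, 2, 3]),
            ([5, 5, 10], [1.5, 1.5, 3]),
            ([7, 7, 7, 7], [2.5, 2.5, 2.5, 2.5]),
        ],
    )
    def test_rank_conventions(self, row, expected):
        t = make_table({"a": row}, state="counts")
        norm = FeatureTable(t.data, t.kind, "normalized")
        assert rank_normalize(norm).data.loc["a"].tolist() == expected

    def test_requires_normalized_state(self):
        with pytest.raises(ValueError):
            rank_normalize(make_table({"a": [1, 2]}, state="counts"))

    @given(st.permutations(list(range(6))))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, perm):
        vals = np.array(perm, dtype=float)
        t1 = FeatureTable(
            pd.DataFrame([vals], index=["a"], columns=[f"s{i}" for i in range(6)]),
            "taxon-genus", "normalized",
        )
        t2 = FeatureTable(
            pd.DataFrame([np.exp(vals)], index=["a"], columns=[f"s{i}" for i in range(6)]),
            "taxon-genus", "normalized",
        )
        assert rank_normalize(t1).data.equals(rank_normalize(t2).data)


class TestCoreFeatures:
    def test_prevalence_rule(self):
        t = make_table(
            {"core": [0.02, 0.02, 0.0], "rare": [0.005, 0.005, 0.005]},
            state="counts",
        )
        norm = FeatureTable(t.data, t.kind, "normalized")
        assert core_features(norm) == ["core"]

    def test_exact_threshold_excluded(self):
        # "greater than 0.01" is strict
        t = FeatureTable(
            pd.DataFrame([[0.01, 0.01, 0.01]], index=["f"], columns=["s1", "s2", "s3"]),
            "taxon-genus", "normalized",
        )
        assert core_features(t) == []

    def test_prevalence_count_is_ceiling(self):
        # 3 samples at 50% prevalence needs ceil(1.5) = 2 samples
        t = FeatureTable(
            pd.DataFrame([[0.02, 0.0, 0.0]], index=["f"], columns=["s1", "s2", "s3"]),
            "taxon-genus", "normalized",
        )
        assert core_features(t) == []


class TestClusterPatterns:
    def test_identical_rows_share_label(self):
        t = FeatureTable(
            pd.DataFrame(
                [[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]],
                index=["a", "b", "c"],
                columns=["s1", "s2", "s3", "s4"],
            ),
            "taxon-genus", "ranked",
        )
        groups = cluster_abundance_patterns(t, 2)
        assert groups.labels["a"] == groups.labels["b"] != groups.labels["c"]

    def test_singletons_when_k_equals_n(self):
        t = FeatureTable(
            pd.DataFrame(
                [[1, 2, 3], [3, 2, 1], [2, 3, 1]],
                index=["a", "b", "c"], columns=["s1", "s2", "s3"],
            ),
            "taxon-genus", "ranked",
        )
        groups = cluster_abundance_patterns(t, 3)
        assert len(set(groups.labels.values())) == 3

    def test_k_larger_than_features_rejected(self, ranked_genus):
        with pytest.raises(ValueError):
            cluster_abundance_patterns(ranked_genus, len(ranked_genus.feature_ids) + 1)

    def test_row_scaling_invariance(self, ranked_genus):
        scaled = FeatureTable(ranked_genus.data * 7.0, ranked_genus.kind, "ranked")
        g1 = cluster_abundance_patterns(ranked_genus, 4)
        g2 = cluster_abundance_patterns(scaled, 4)
        assert g1.labels == g2.labels

    def test_planted_four_group_recovery(self, rng):
        # four archetype patterns, members are monotone copies: within-group
        # Spearman 1, between-group well below; recovery must be exact
        from sklearn.metrics import adjusted_rand_score

        n = 24
        archetypes = [rng.normal(size=n) for _ in range(2)]
        archetypes.append(-archetypes[0])
        archetypes.append(rng.permutation(archetypes[1]))
        rows, names, truth = [], [], []
        for g, arch in enumerate(archetypes):
            for m in range(5):
                rows.append(np.exp(0.5 * arch) * (m + 1))
                names.append(f"g{g}_m{m}")
                truth.append(g)
        t = FeatureTable(
            pd.DataFrame(rows, index=names, columns=[f"s{i}" for i in range(n)]),
            "taxon-genus", "ranked",
        )
        groups = cluster_abundance_patterns(t, 4)
        predicted = [groups.labels[f] for f in names]
        assert adjusted_rand_score(truth, predicted) == 1.0


class TestGroupCumulativeAbundance:
    @pytest.fixture()
    def table_and_groups(self):
        t = FeatureTable(
            pd.DataFrame(
                [[1, 2, 3], [3, 2, 1], [2, 2, 2]],
                index=["a", "b", "c"], columns=["s1", "s2", "s3"],
            ),
            "taxon-genus", "ranked",
        )
        groups = cluster_abundance_patterns(t, 3)
        return t, groups

    def test_single_member_group_equals_row(self, table_and_groups):
        t, groups = table_and_groups
        label = groups.labels["a"]
        out = group_cumulative_abundance(t, groups, label)
        assert np.allclose(out.to_numpy(), t.data.loc["a"].to_numpy())

    def test_union_of_all_groups_is_column_sum(self, table_and_groups):
        t, groups = table_and_groups
        out = group_cumulative_abundance(t, groups, groups.group_names())
        assert np.allclose(out.to_numpy(), t.values.sum(axis=0))

    def test_unknown_label_rejected(self, table_and_groups):
        t, groups = table_and_groups
        with pytest.raises(KeyError):
            group_cumulative_abundance(t, groups, "G99")
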