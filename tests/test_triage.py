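"""Triage stage: quantile binning, aggregation, categorization, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from memscreen.triage import (
    CategoryThresholds,
    aggregate_quantiles,
    apply_exclusions,
    categorize,
    select_candidates,
    to_quantile_bins,
    Q_LEVELS,
)


def _matrix(values, genes=None, models=None):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    models = models or [f"m{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=models)


class TestQuantileBins:
    def test_zero_scores_are_negative_predictions(self):
        q = to_quantile_bins(_matrix([[0.0], [0.0], [0.0]]))
        assert (q.to_numpy() == 0.0).all()

    def test_four_distinct_positive_scores_fill_the_four_bins(self):
        q = to_quantile_bins(_matrix([[0.1], [0.2], [0.3], [0.4]]))
        assert list(q.iloc[:, 0]) == [0.25, 0.5, 0.75, 1.0]

    def test_eight_distinct_scores_two_per_bin_vs_sort_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0.01, 1.0, size=8)
        q = to_quantile_bins(_matrix(scores.reshape(-1, 1)))
        # oracle: sort and slice into four equal groups
        order = np.argsort(scores)
        expected = np.empty(8)
        for rank, idx in enumerate(order):
            expected[idx] = (rank // 2 + 1) * 0.25
        np.testing.assert_array_equal(q.iloc[:, 0].to_numpy(), expected)

    def test_ties_share_the_average_rank_bin(self):
        # two tied scores straddling the 2nd/3rd quartile boundary of 4 points
        q = to_quantile_bins(_matrix([[0.1], [0.5], [0.5], [0.9]]))
        col = list(q.iloc[:, 0])
        assert col[0] == 0.25 and col[3] == 1.0
        assert col[1] == col[2]  # tied scores get the same bin

    def test_coverage_mask_preserved(self):
        raw = _matrix([[0.5, np.nan], [np.nan, 0.3], [0.2, 0.8]])
        q = to_quantile_bins(raw)
        assert q.isna().equals(raw.isna())

    def test_models_are_quantized_independently(self):
        raw = _matrix([[0.9, 0.1], [0.1, 0.9]])
        q = to_quantile_bins(raw)
        assert q.iloc[0, 0] > q.iloc[1, 0]
        assert q.iloc[0, 1] < q.iloc[1, 1]

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            to_quantile_bins(_matrix([[1.2]]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        scores=st.lists(st.floats(0.001, 1.0), min_size=1, max_size=30),
        scale=st.floats(0.1, 5.0),
    )
    def test_scale_free_under_strictly_increasing_transform(self, scores, scale):
        """Only the rank order of positive scores matters: x -> 1-exp(-scale*x)
        (strictly increasing into (0,1)) leaves Q unchanged."""
        raw = _matrix(np.asarray(scores).reshape(-1, 1))
        transformed = 1.0 - np.exp(-scale * raw)
        pd.testing.assert_frame_equal(to_quantile_bins(raw), to_quantile_bins(transformed))

    def test_emitted_levels_are_the_five_q_values(self, planted_200):
        from memscreen.simulate import simulate_scores

        q = to_quantile_bins(simulate_scores(200, 10, planted_200, 0.8, seed=0))
        vals = q.to_numpy()
        vals = vals[np.isfinite(vals)]
        assert set(np.unique(vals)) <= set(Q_LEVELS)


class TestAggregate:
    def test_constant_row(self):
        aggs = aggregate_quantiles(_matrix([[1.0, 1.0, 1.0]]))
        row = aggs.iloc[0]
        assert row["mean_Q"] == 1.0 and row["sd_Q"] == 0.0 and row["coverage"] == 3

    def test_sample_sd_with_divisor_n_minus_1(self):
        aggs = aggregate_quantiles(_matrix([[0.0, 0.25]]))
        row = aggs.iloc[0]
        assert row["mean_Q"] == pytest.approx(0.125)
        assert row["sd_Q"] == pytest.approx(0.1767767, abs=1e-6)
        assert row["coverage"] == 2

    def test_population_sd_option(self):
        aggs = aggregate_quantiles(_matrix([[0.0, 0.25]]), population_sd=True)
        assert aggs.iloc[0]["sd_Q"] == pytest.approx(0.125)

    def test_zero_coverage_rows_omitted(self):
        aggs = aggregate_quantiles(_matrix([[np.nan, np.nan], [0.5, 0.75]]))
        assert list(aggs.index) == ["g1"]

    def test_singleton_coverage_sd_zero(self):
        aggs = aggregate_quantiles(_matrix([[0.5, np.nan]]))
        assert aggs.iloc[0]["sd_Q"] == 0.0 and aggs.iloc[0]["coverage"] == 1


def _oracle_categorize(aggs: pd.DataFrame, th: CategoryThresholds) -> pd.Series:
    """Independent brute-force reimplementation of the three class rules."""
    eligible = aggs[aggs["coverage"] >= th.min_coverage]
    sds = sorted(eligible["sd_Q"])
    # linear-interpolation quantile, computed by hand
    h = (len(sds) - 1) * th.sd_quantile_level
    lo = int(np.floor(h))
    cutoff = sds[lo] + (h - lo) * (sds[min(lo + 1, len(sds) - 1)] - sds[lo])
    labels = {}
    for gene, row in aggs.iterrows():
        label = "uncategorized"
        if row["coverage"] >= th.min_coverage:
            if row["mean_Q"] >= th.positive_min_mean:
                label = "positive"
            elif row["mean_Q"] == th.negative_mean:
                label = "negative"
            elif (
                th.variable_mean_low <= row["mean_Q"] <= th.variable_mean_high
                and row["sd_Q"] > cutoff
            ):
                label = "variable"
        labels[gene] = label
    return pd.Series(labels)


def _random_aggs(rng, n):
    mean_q = rng.choice([0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.5, 0.7, 1.0], size=n)
    return pd.DataFrame(
        {
            "mean_Q": mean_q,
            "sd_Q": np.round(rng.uniform(0, 0.5, size=n), 3),
            "coverage": rng.integers(1, 11, size=n),
        },
        index=[f"g{i}" for i in range(n)],
    )


class TestCategorize:
    def test_positive_rule(self):
        aggs = pd.DataFrame(
            {"mean_Q": [0.6, 0.6], "sd_Q": [0.1, 0.1], "coverage": [8, 6]},
            index=["hit", "undercovered"],
        )
        labels = categorize(aggs).labels
        assert labels["hit"] == "positive"
        assert labels["undercovered"] == "uncategorized"

    def test_negative_rule_requires_unanimous_zero_and_coverage(self):
        aggs = pd.DataFrame(
            {"mean_Q": [0.0, 0.0], "sd_Q": [0.0, 0.0], "coverage": [7, 6]},
            index=["neg", "undercovered"],
        )
        labels = categorize(aggs).labels
        assert labels["neg"] == "negative"
        assert labels["undercovered"] == "uncategorized"

    def test_variable_labels_match_enumeration_oracle_on_handset_cohort(self):
        rng = np.random.default_rng(42)
        aggs = pd.DataFrame(
            {
                "mean_Q": np.full(20, 0.2),
                "sd_Q": np.round(rng.uniform(0, 0.5, 20), 3),
                "coverage": np.full(20, 10),
            },
            index=[f"g{i}" for i in range(20)],
        )
        th = CategoryThresholds()
        result = categorize(aggs, th)
        expected = _oracle_categorize(aggs, th)
        pd.testing.assert_series_equal(result.labels, expected, check_names=False)
        # top 10% by sd (strictly above the interpolated 90% quantile)
        assert (result.labels == "variable").sum() == 2

    def test_every_gene_gets_exactly_one_label(self):
        rng = np.random.default_rng(7)
        aggs = _random_aggs(rng, 100)
        labels = categorize(aggs).labels
        assert len(labels) == 100
        assert set(labels) <= {"positive", "negative", "variable", "uncategorized"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            categorize(pd.DataFrame(columns=["mean_Q", "sd_Q", "coverage"]))

    def test_no_gene_meets_coverage_rejected(self):
        aggs = pd.DataFrame({"mean_Q": [0.5], "sd_Q": [0.1], "coverage": [3]}, index=["g"])
        with pytest.raises(ValueError, match="min_coverage"):
            categorize(aggs)

    def test_negative_class_soundness_on_simulated_scores(self, planted_200):
        """A gene labeled negative has Q = 0 in every covering model."""
        from memscreen.simulate import simulate_scores

        qm = to_quantile_bins(simulate_scores(200, 10, planted_200, 0.9, seed=3))
        aggs = aggregate_quantiles(qm)
        labels = categorize(aggs).labels
        negatives = labels.index[labels == "negative"]
        assert len(negatives) > 0
        block = qm.loc[negatives].to_numpy()
        assert np.nanmax(block) == 0.0

    def test_invalid_threshold_ordering_rejected(self):
        with pytest.raises(ValueError):
            CategoryThresholds(variable_mean_low=0.3, variable_mean_high=0.2)


class TestExclusions:
    @pytest.fixture
    def assignment(self):
        aggs = pd.DataFrame(
            {"mean_Q": [0.8, 0.0, 0.6], "sd_Q": [0.1, 0.0, 0.2], "coverage": [9, 9, 9]},
            index=["a", "b", "c"],
        )
        return categorize(aggs)

    def test_empty_sets_identity(self, assignment):
        out = apply_exclusions(assignment)
        pd.testing.assert_series_equal(out.labels, assignment.labels)

    def test_essential_positive_becomes_uncategorized(self, assignment):
        out = apply_exclusions(assignment, essential={"a"})
        assert out.labels["a"] == "uncategorized"
        assert out.labels["b"] == "negative"
        assert "a" in out.excluded

    def test_gene_in_both_sets_excluded_once_total_labeling(self, assignment):
        out = apply_exclusions(assignment, essential={"c"}, already_annotated={"c"})
        assert len(out.labels) == 3
        assert out.labels["c"] == "uncategorized"
        # idempotent
        again = apply_exclusions(out, essential={"c"})
        pd.testing.assert_series_equal(again.labels, out.labels)


class TestSelection:
    @pytest.fixture
    def assignment(self):
        aggs = pd.DataFrame(
            {
                "mean_Q": [0.8] * 5 + [0.0] * 9 + [0.2] * 15 + [0.3] * 10,
                "sd_Q": [0.05] * 5 + [0.0] * 9 + [0.49] * 15 + [0.1] * 10,
                "coverage": [10] * 39,
            },
            index=[f"g{i:02d}" for i in range(39)],
        )
        return categorize(aggs, CategoryThresholds(sd_quantile_level=0.6))

    def test_exhaustive_request_returns_whole_pool(self, assignment):
        sizes = {k: v for k, v in assignment.counts().items() if k != "uncategorized"}
        out = select_candidates(assignment, sizes, seed=0)
        assert len(out) == sum(sizes.values())
        assert set(out["gene"]) == set(
            assignment.labels.index[assignment.labels != "uncategorized"]
        )

    def test_class_sizes_5_9_15_give_29_candidates(self, assignment):
        out = select_candidates(
            assignment, {"positive": 5, "negative": 9, "variable": 15}, seed=1
        )
        assert len(out) == 29
        assert out["label"].value_counts().to_dict() == {
            "variable": 15, "negative": 9, "positive": 5,
        }

    def test_same_seed_identical_selection(self, assignment):
        a = select_candidates(assignment, {"positive": 3, "variable": 5}, seed=9)
        b = select_candidates(assignment, {"positive": 3, "variable": 5}, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_oversized_request_rejected(self, assignment):
        with pytest.raises(ValueError, match="eligible"):
            select_candidates(assignment, {"positive": 6}, seed=0)

    def test_overlap_matches_hypergeometric_expectation(self):
        """Two independent draws of 10 from a 100-gene class overlap
        Hypergeometric(100, 10, 10): mean 1 over many trials."""
        aggs = pd.DataFrame(
            {"mean_Q": [0.9] * 100, "sd_Q": [0.0] * 100, "coverage": [10] * 100},
            index=[f"g{i:03d}" for i in range(100)],
        )
        assignment = categorize(aggs)
        base = set(select_candidates(assignment, {"positive": 10}, seed=123456)["gene"])
        overlaps = [
            len(base & set(select_candidates(assignment, {"positive": 10}, seed=s)["gene"]))
            for s in range(1000)
        ]
        expected_mean = 10 * 10 / 100  # n*K/N
        assert np.mean(overlaps) == pytest.approx(expected_mean, abs=0.15)
        # and the full distribution is close to the closed form
        obs = np.bincount(overlaps, minlength=11) / 1000
        expect = sps.hypergeom.pmf(np.arange(11), 100, 10, 10)
        assert np.abs(obs - expect).max() < 0.05


class TestPlantedRecovery:
    def test_positive_and_negative_classes_recovered(self, planted_200):
        """Full coverage, 10 models: planted positives and negatives are
        recovered with >= 90% precision and recall (pooled over seeds; a
        single 20-gene class has ~5% counting noise per draw)."""
        from memscreen.simulate import simulate_scores

        truth = pd.Series(planted_200)
        tp = {"positive": 0, "negative": 0}
        called = {"positive": 0, "negative": 0}
        n_seeds = 10
        for seed in range(n_seeds):
            m = simulate_scores(200, 10, planted_200, coverage_prob=1.0, seed=seed)
            labels = categorize(aggregate_quantiles(to_quantile_bins(m))).labels
            for cls in tp:
                tp[cls] += int(((labels == cls) & (truth == cls)).sum())
                called[cls] += int((labels == cls).sum())
        for cls in tp:
            assert tp[cls] / called[cls] >= 0.9
            assert tp[cls] / (20 * n_seeds) >= 0.9
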