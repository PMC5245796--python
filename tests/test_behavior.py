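"""Frequency tables, friend-average vectors, CC curves, ordinal fits."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brushnet import (
    BehaviorVector,
    FitFailure,
    FriendshipMatrix,
    StatsError,
    UndefinedResult,
    correlation_curve,
    correlation_length,
    cross_correlation,
    frequency_table,
    friend_average_vector,
    ordinal_association,
)
from brushnet.synth import CohortSpec, generate_cohort

from conftest import random_digraph


class TestFrequencyTable:
    @pytest.mark.parametrize(
        "counts, expected_mean",
        [((79, 97, 21, 4), 1.75), ((98, 88, 11, 4), 1.61)],
        ids=["round1", "round2"],
    )
    def test_published_marginals(self, counts, expected_mean):
        scores = np.repeat([1, 2, 3, 4], counts)
        ft = frequency_table(BehaviorVector(scores))
        assert round(ft.mean, 2) == expected_mean
        assert ft.table["count"].sum() == 201
        assert np.isclose(ft.table["percent"].sum(), 100.0)

    def test_degenerate_all_best(self):
        ft = frequency_table(BehaviorVector(np.ones(10, dtype=int)))
        assert ft.mean == 1.0 and ft.table.loc[1, "percent"] == 100.0

    def test_invalid_scores_rejected(self):
        with pytest.raises(StatsError):
            BehaviorVector([0, 1, 2])
        with pytest.raises(StatsError):
            BehaviorVector([])


class TestFriendAverage:
    def test_simple_mean(self):
        net = FriendshipMatrix.from_edges([(0, 1), (0, 2), (0, 3)], 4)
        v0 = BehaviorVector([4, 1, 2, 3])
        v1 = friend_average_vector(net, v0, 1)
        assert v1[0] == 2.0

    def test_isolated_student_undefined_at_every_level(self, chain):
        v0 = BehaviorVector([1, 2, 3, 4])
        for lvl in (1, 2, 3):
            assert np.isnan(friend_average_vector(chain, v0, lvl)[3])

    @pytest.mark.parametrize("level", [1, 2, 3])
    def test_matches_bfs_enumeration_oracle(self, rng, level):
        net = random_digraph(rng, 30)
        scores = rng.integers(1, 5, size=30)
        v0 = BehaviorVector(scores)
        vi = friend_average_vector(net, v0, level)
        g = nx.from_numpy_array(net.adj, create_using=nx.DiGraph)
        dist = dict(nx.all_pairs_shortest_path_length(g))
        for j in range(30):
            exact = [k for k, d in dist[j].items() if d == level]
            if exact:
                assert np.isclose(vi[j], np.mean(scores[exact]))
            else:
                assert np.isnan(vi[j])


class TestCrossCorrelation:
    def test_self_correlation_is_one(self, rng):
        x = rng.integers(1, 5, 50).astype(float)
        assert np.isclose(cross_correlation(x, x), 1.0)

    def test_raw_mode_is_inner_product(self, rng):
        x = rng.integers(1, 5, 40).astype(float)
        y = rng.integers(1, 5, 40).astype(float)
        assert np.isclose(cross_correlation(x, y, mode="raw"), float(x @ y))

    def test_raw_zero_vector(self):
        z = np.zeros(5)
        assert cross_correlation(z, np.arange(5.0), mode="raw") == 0.0

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        manual = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert np.isclose(cross_correlation(x, y), manual)

    def test_undefined_when_constant(self):
        with pytest.raises(UndefinedResult):
            cross_correlation(np.ones(10), np.arange(10.0))

    def test_undefined_below_three_pairs(self):
        x = np.array([1.0, 2.0, np.nan, np.nan])
        with pytest.raises(UndefinedResult):
            cross_correlation(x, x)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.floats(-5, 5), st.floats(-5, 5)), min_size=5, max_size=30
        ),
        a=st.floats(0.1, 4.0),
        b=st.floats(-3.0, 3.0),
    )
    def test_affine_invariance_and_symmetry(self, data, a, b):
        x = np.array([p[0] for p in data])
        y = np.array([p[1] for p in data])
        if np.ptp(x) < 1e-6 or np.ptp(y) < 1e-6:
            return
        r = cross_correlation(x, y)
        assert np.isclose(cross_correlation(a * x + b, y), r, atol=1e-8)
        assert np.isclose(cross_correlation(y, x), r, atol=1e-12)


class TestCorrelationCurveAndLength:
    def test_within_classroom_homogeneity_gives_high_cc1(self):
        # two disconnected cliques-of-naming with behaviour equal to component
        edges = [(i, j) for i in range(4) for j in range(4) if i != j]
        edges += [(i + 4, j + 4) for i in range(4) for j in range(4) if i != j]
        net = FriendshipMatrix.from_edges(edges, 8)
        v0 = BehaviorVector([1] * 4 + [4] * 4)
        curve = correlation_curve(net, v0, max_level=2)
        assert curve.values[0] > 0.99
        assert curve.n_defined[0] == 8 and curve.n_defined[1] == 0

    def test_null_behavior_within_permutation_band(self, default_cohort):
        state, _ = default_cohort
        rng = np.random.default_rng(0)
        hits = 0
        for s in range(20):
            scores = rng.permutation(state.behavior.scores)
            length = correlation_length(
                state.network, BehaviorVector(scores), n_perm=199, rng=s
            )
            hits += length == 0
        assert hits >= 16  # ~alpha = 0.05 per level, 20 null draws

    def test_assortative_cohort_has_positive_cc1_and_length_one(self):
        lengths = []
        for s in range(10):
            state, _ = generate_cohort(CohortSpec(seed=600 + s))
            curve = correlation_curve(state.network, state.behavior)
            assert curve.values[0] > 0
            lengths.append(
                correlation_length(state.network, state.behavior, n_perm=299, rng=s)
            )
        assert np.mean([l >= 1 for l in lengths]) >= 0.7
        assert np.median(lengths) == 1

    def test_length_monotone_in_alpha(self, default_cohort):
        state, _ = default_cohort
        kwargs = dict(n_perm=299, max_level=4)
        l_strict = correlation_length(
            state.network, state.behavior, alpha=0.01, rng=7, **kwargs
        )
        l_loose = correlation_length(
            state.network, state.behavior, alpha=0.2, rng=7, **kwargs
        )
        assert l_loose >= l_strict

    def test_strong_static_diffusion_lengthens_correlation(self):
        # behaviour spreading on a fixed network pushes association deeper
        from brushnet.synth import emulate_study_pair

        before, after = [], []
        for s in range(6):
            r1, r2 = emulate_study_pair(
                CohortSpec(seed=800 + s), u=0.2, p=0.0, weeks=22
            )
            before.append(
                correlation_length(r1.network, r1.behavior, n_perm=299, rng=s)
            )
            after.append(
                correlation_length(r2.network, r2.behavior, n_perm=299, rng=s)
            )
        assert np.mean(after) > np.mean(before)


class TestOrdinalAssociation:
    def test_noisy_copy_is_significantly_positive(self, rng):
        scores = rng.integers(1, 5, size=120)
        predictor = scores + rng.normal(0, 1.0, size=120)
        fit = ordinal_association(BehaviorVector(scores), {"x": predictor})
        assert fit.coef.loc["x", "estimate"] > 0
        assert fit.coef.loc["x", "pvalue"] < 0.05
        assert fit.thresholds.size == 3
        assert np.all(np.diff(fit.thresholds) > 0)

    def test_exact_copy_separates(self, rng):
        # a perfect predictor completely separates the levels: the MLE
        # diverges and the fit must be refused rather than reported
        scores = rng.integers(1, 5, size=120)
        with pytest.raises(FitFailure, match="separation"):
            ordinal_association(BehaviorVector(scores), {"x": scores.astype(float)})

    def test_zero_variance_predictor_rejected(self, rng):
        scores = rng.integers(1, 5, size=50)
        with pytest.raises(FitFailure):
            ordinal_association(BehaviorVector(scores), {"x": np.ones(50)})

    def test_too_few_cases_rejected(self, rng):
        scores = rng.integers(1, 5, size=10)
        with pytest.raises(FitFailure):
            ordinal_association(BehaviorVector(scores), {"x": rng.normal(size=10)})

    def test_popularity_coupling_gives_negative_slope(self):
        state, _ = generate_cohort(CohortSpec(seed=321))
        fit = ordinal_association(
            state.behavior, {"in_degree": state.network.in_degree().astype(float)}
        )
        assert fit.coef.loc["in_degree", "estimate"] < 0
        assert fit.coef.loc["in_degree", "pvalue"] < 0.05
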