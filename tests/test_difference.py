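"""Baseline averaging, the weight matrix, and the pd statistic."""

from datetime import date as Date, timedelta

import numpy as np
import pytest

from sensorgraphs.difference import (
    BaselineMatrix,
    compute_baseline,
    daily_series,
    graph_difference,
    make_weight_matrix,
    percent_difference,
)
from sensorgraphs.errors import (
    ContentError,
    DegenerateBaselineError,
    InsufficientDataError,
    ParameterError,
)
from sensorgraphs.graphs import AdjacencyMatrix


def random_matrix(rng, labels=("a", "b", "c")):
    n = len(labels)
    return AdjacencyMatrix(labels, rng.integers(0, 50, size=(n, n)).astype(float))


class TestWeightMatrix:
    def test_default_2x2(self):
        W = make_weight_matrix(2)
        assert np.array_equal(W.values, [[1.0, 1.5], [1.5, 1.0]])

    def test_n1(self):
        assert np.array_equal(make_weight_matrix(1).values, [[1.0]])

    def test_unweighted_mode(self):
        assert np.array_equal(make_weight_matrix(3, 1, 1).values, np.ones((3, 3)))

    @pytest.mark.parametrize("diag,offdiag", [(0, 1.5), (1, 0), (-1, 1.5)])
    def test_nonpositive_weights_rejected(self, diag, offdiag):
        with pytest.raises(ParameterError):
            make_weight_matrix(2, diag, offdiag)


class TestBaseline:
    def test_mean_of_identical_matrices(self):
        M = AdjacencyMatrix(("x", "y"), [[1.0, 2.0], [3.0, 4.0]])
        base = compute_baseline([M] * 7, 7)
        assert np.array_equal(base.values, M.values)
        assert base.window == 7

    def test_seventh_fractions(self):
        """7-day averages of integer counts land on multiples of 1/7."""
        rng = np.random.default_rng(3)
        dailies = [random_matrix(rng) for _ in range(7)]
        base = compute_baseline(dailies, 7)
        assert np.allclose(base.values * 7, np.round(base.values * 7))

    def test_matches_per_cell_mean_oracle(self):
        rng = np.random.default_rng(11)
        dailies = [random_matrix(rng) for _ in range(7)]
        base = compute_baseline(dailies, 7)
        for i in range(3):
            for j in range(3):
                cells = [d.values[i, j] for d in dailies]
                assert base.values[i, j] == pytest.approx(sum(cells) / 7, abs=1e-12)

    def test_bathroom_occupancy_pattern(self):
        """Seven days of bathroom counts totalling 800 average to 114.29."""
        labels = ("Bathroom",)
        counts = [120, 110, 115, 100, 130, 105, 120]  # sums to 800
        dailies = [AdjacencyMatrix(labels, [[float(c)]]) for c in counts]
        base = compute_baseline(dailies, 7)
        assert round(base.values[0, 0], 2) == 114.29

    def test_insufficient_days(self):
        M = AdjacencyMatrix.zeros(("x",))
        with pytest.raises(InsufficientDataError):
            compute_baseline([M, M], 7)

    def test_provenance_recorded(self):
        M = AdjacencyMatrix.zeros(("x",))
        dates = [Date(2015, 1, 1) + timedelta(days=i) for i in range(9)]
        base = compute_baseline([M] * 9, 7, dates=dates)
        assert base.dates == tuple(dates[:7])


class TestDifference:
    def test_diff_with_itself_is_zero(self):
        rng = np.random.default_rng(0)
        B = random_matrix(rng)
        assert graph_difference(B, B) == 0

    def test_half_baseline(self):
        rng = np.random.default_rng(1)
        B = random_matrix(rng)
        W = make_weight_matrix(3)
        half = AdjacencyMatrix(B.labels, B.values / 2)
        expected = 0.5 * float((W.values * B.values).sum())
        assert graph_difference(B, half, W) == pytest.approx(expected, abs=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        B, D1, D2 = (random_matrix(rng) for _ in range(3))
        W = make_weight_matrix(3)
        zero = AdjacencyMatrix.zeros(B.labels)
        for alpha, beta in [(0.3, 0.4), (1.0, 0.0), (0.5, 0.5)]:
            mix = AdjacencyMatrix(B.labels, alpha * D1.values + beta * D2.values)
            lhs = graph_difference(B, mix, W)
            rhs = (
                alpha * graph_difference(B, D1, W)
                + beta * graph_difference(B, D2, W)
                + (1 - alpha - beta) * graph_difference(B, zero, W)
            )
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        B = AdjacencyMatrix.zeros(("x", "y"))
        D = AdjacencyMatrix.zeros(("x",))
        with pytest.raises(ContentError):
            graph_difference(B, D, make_weight_matrix(2))


class TestPercentDifference:
    def test_identical_day_is_zero(self):
        rng = np.random.default_rng(4)
        B = random_matrix(rng)
        assert percent_difference(B, B).pd == 0

    def test_empty_day_is_one(self):
        rng = np.random.default_rng(5)
        B = random_matrix(rng)
        zero = AdjacencyMatrix.zeros(B.labels)
        assert percent_difference(B, zero).pd == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("c", [0.0, 0.25, 0.5, 1.0])
    @pytest.mark.parametrize("weights", [(1.0, 1.5), (1.0, 1.0), (2.0, 0.5)])
    def test_uniform_scaling_closed_form(self, c, weights):
        """D = (1-c) B gives pd = c exactly, whatever the weights."""
        rng = np.random.default_rng(6)
        B = random_matrix(rng)
        W = make_weight_matrix(3, *weights)
        D = AdjacencyMatrix(B.labels, (1 - c) * B.values)
        assert percent_difference(B, D, W).pd == pytest.approx(c, abs=1e-12)

    def test_more_activity_means_negative_pd(self):
        rng = np.random.default_rng(7)
        B = random_matrix(rng)
        base_pd = percent_difference(B, B).pd
        for i in range(3):
            for j in range(3):
                bumped = B.copy()
                bumped.values[i, j] += 1
                assert percent_difference(B, bumped).pd < base_pd

    def test_weight_sensitivity_to_transition_mass(self):
        """Equal weights ignore where mass sits; 1.5 off-diagonal does not."""
        B = AdjacencyMatrix(("x", "y"), [[10.0, 10.0], [10.0, 10.0]])
        on_diag = AdjacencyMatrix(("x", "y"), [[20.0, 0.0], [10.0, 10.0]])
        off_diag = AdjacencyMatrix(("x", "y"), [[0.0, 20.0], [10.0, 10.0]])
        flat = make_weight_matrix(2, 1, 1)
        assert percent_difference(B, on_diag, flat).pd == pytest.approx(
            percent_difference(B, off_diag, flat).pd, abs=1e-12
        )
        weighted = make_weight_matrix(2)
        assert percent_difference(B, on_diag, weighted).pd > percent_difference(
            B, off_diag, weighted
        ).pd

    def test_degenerate_baseline_rejected(self):
        zero = AdjacencyMatrix.zeros(("x", "y"))
        with pytest.raises(DegenerateBaselineError):
            percent_difference(zero, zero)


class TestDailySeries:
    def _dates(self, n):
        return [Date(2015, 2, 1) + timedelta(days=i) for i in range(n)]

    def test_identical_days_are_all_zero(self):
        rng = np.random.default_rng(8)
        B = random_matrix(rng)
        base = BaselineMatrix(B)
        series = daily_series(base, list(zip(self._dates(10), [B] * 10)))
        assert np.allclose(series.pd_values, 0)
        assert len(series) == 10

    def test_linear_decline_recovered_exactly(self):
        rng = np.random.default_rng(9)
        B = random_matrix(rng)
        base = BaselineMatrix(B)
        c = 0.002
        dailies = [
            (d, AdjacencyMatrix(B.labels, (1 - c * t) * B.values))
            for t, d in enumerate(self._dates(50))
        ]
        series = daily_series(base, dailies)
        expected = c * np.arange(50)
        assert np.allclose(series.pd_values, expected, atol=1e-12)

    def test_matches_per_day_recomputation(self):
        rng = np.random.default_rng(10)
        B = random_matrix(rng)
        base = BaselineMatrix(B)
        dailies = [(d, random_matrix(rng)) for d in self._dates(40)]
        series = daily_series(base, dailies)
        for date, M in dailies:
            expected = percent_difference(base, M).pd
            assert series.pd_values[series.dates.index(date)] == expected

    def test_duplicate_dates_rejected(self):
        rng = np.random.default_rng(12)
        B = random_matrix(rng)
        with pytest.raises(ContentError, match="duplicate"):
            daily_series(
                BaselineMatrix(B), [(Date(2015, 2, 1), B), (Date(2015, 2, 1), B)]
            )
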