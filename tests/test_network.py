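"""Sliding windows, graph construction, nodal efficiency, dnE matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnecpm import (GraphConfig, InputError, WindowSpec, dne_matrix,
                    efficiency_curves, fc_to_graph, make_windows,
                    nodal_efficiency, subject_dne, window_fc)
from dnecpm.network import EfficiencyCurves
from tests.conftest import make_ts


def floyd_warshall_oracle(lengths):
    """Independent all-pairs shortest-path oracle (pure-python triple loop)."""
    n = lengths.shape[0]
    d = [[float(lengths[i][j]) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return np.array(d)


def efficiency_oracle(lengths):
    d = floyd_warshall_oracle(lengths)
    n = d.shape[0]
    e = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                e[i] += 1.0 / d[i, j]
    return e / (n - 1)


def random_length_matrix(rng, n, binary, density=0.6):
    mat = np.full((n, n), np.inf)
    np.fill_diagonal(mat, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                mat[i, j] = mat[j, i] = 1.0 if binary else rng.uniform(0.2, 5.0)
    return mat


class TestMakeWindows:
    @pytest.mark.parametrize("t,length,step,expected", [
        (240, 50, 1, 191),
        (50, 50, 1, 1),
        (236, 50, 1, 187),
        (100, 30, 5, 15),
    ])
    def test_window_count(self, t, length, step, expected):
        wins = make_windows(t, WindowSpec(length, step))
        assert len(wins) == expected
        assert wins[0] == (0, length)
        assert all(b - a == length for a, b in wins)

    def test_short_series_rejected(self):
        with pytest.raises(InputError):
            make_windows(40, WindowSpec(50, 1))

    @given(t=st.integers(3, 500), length=st.integers(3, 500),
           step=st.integers(1, 20))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_count_formula_exact(self, t, length, step):
        if t < length:
            return
        wins = make_windows(t, WindowSpec(length, step))
        assert len(wins) == (t - length) // step + 1
        assert wins[-1][1] <= t


class TestWindowFc:
    def test_identical_series_correlate_perfectly(self, rng):
        row = rng.standard_normal(60)
        ts = make_ts(np.vstack([row, row, rng.standard_normal(60)]))
        fc = window_fc(ts, (0, 50))
        assert fc[0, 1] == pytest.approx(1.0)

    def test_negated_series_anticorrelate(self, rng):
        row = rng.standard_normal(60)
        ts = make_ts(np.vstack([row, -row]))
        fc = window_fc(ts, (0, 50))
        assert fc[0, 1] == pytest.approx(-1.0)

    def test_independent_series_weakly_correlated(self, rng):
        ts = make_ts(rng.standard_normal((10, 50)))
        fc = window_fc(ts, (0, 50))
        off = fc[np.triu_indices(10, 1)]
        assert np.max(np.abs(off)) < 0.5  # null |r| at n=50 w.p. > 0.999

    def test_out_of_bounds_rejected(self, random_ts):
        with pytest.raises(InputError):
            window_fc(random_ts, (100, 160))


class TestFcToGraph:
    def test_uniform_positive_binary_graph_is_complete(self):
        fc = np.full((5, 5), 0.5)
        np.fill_diagonal(fc, 1.0)
        g = fc_to_graph(fc, GraphConfig(mode="binary"))
        assert len(g.edges) == 10
        assert np.all(g.lengths == 1.0)

    def test_proportional_threshold_edge_count(self, rng):
        n = 246
        a = rng.uniform(0.01, 0.99, (n, n))
        fc = (a + a.T) / 2
        np.fill_diagonal(fc, 1.0)
        g = fc_to_graph(fc, GraphConfig(sparsity=0.1))
        assert len(g.edges) == 3014  # ceil(0.1 * 246 * 245 / 2)

    def test_all_negative_discard_gives_edgeless_graph(self):
        fc = np.full((4, 4), -0.3)
        np.fill_diagonal(fc, 1.0)
        g = fc_to_graph(fc, GraphConfig(negative_policy="discard"))
        assert len(g.edges) == 0

    def test_absolute_policy_rectifies(self):
        fc = np.full((3, 3), -0.4)
        np.fill_diagonal(fc, 1.0)
        g = fc_to_graph(fc, GraphConfig(negative_policy="absolute"))
        assert np.allclose(g.weights, 0.4)
        assert np.allclose(g.lengths, 2.5)

    def test_weighted_lengths_are_reciprocal_weights(self, rng):
        a = rng.uniform(0.1, 0.9, (6, 6))
        fc = (a + a.T) / 2
        np.fill_diagonal(fc, 1.0)
        g = fc_to_graph(fc)
        assert np.allclose(g.lengths, 1.0 / g.weights)


class TestNodalEfficiency:
    def test_binary_triangle(self):
        mat = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        assert np.allclose(nodal_efficiency(mat), 1.0)

    def test_binary_path(self):
        mat = np.full((3, 3), np.inf)
        np.fill_diagonal(mat, 0.0)
        mat[0, 1] = mat[1, 0] = 1.0
        mat[1, 2] = mat[2, 1] = 1.0
        e = nodal_efficiency(mat)
        assert e[0] == pytest.approx(0.75)   # (1 + 1/2) / 2
        assert e[1] == pytest.approx(1.0)
        assert e[2] == pytest.approx(0.75)

    @pytest.mark.parametrize("binary", [True, False])
    def test_matches_brute_force_oracle(self, rng, binary):
        for _ in range(30):
            n = int(rng.integers(3, 13))
            mat = random_length_matrix(rng, n, binary)
            assert np.allclose(nodal_efficiency(mat.copy()),
                               efficiency_oracle(mat), atol=1e-10)

    def test_negative_lengths_rejected(self):
        mat = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(InputError):
            nodal_efficiency(mat)


class TestEfficiencyCurvesAndDne:
    def test_curve_shape_at_acquisition_scale(self, rng):
        ts = make_ts(rng.standard_normal((5, 240)))
        curves = efficiency_curves(ts, WindowSpec(50, 1))
        assert curves.data.shape == (5, 191)
        assert curves.window_starts[0] == 0
        assert curves.window_starts[-1] == 190

    def test_duplicate_curves_give_unit_entry(self, rng):
        base = rng.standard_normal(40)
        data = np.vstack([base, base, rng.standard_normal(40)])
        m = dne_matrix(EfficiencyCurves(data=data, window_starts=np.arange(40)))
        assert m.data[0, 1] == pytest.approx(1.0)

    def test_negated_curve_gives_minus_one(self, rng):
        base = rng.standard_normal(40)
        data = np.vstack([base, -base])
        m = dne_matrix(EfficiencyCurves(data=data, window_starts=np.arange(40)))
        assert m.data[0, 1] == pytest.approx(-1.0)

    def test_degenerate_curve_flagged_and_zeroed(self, rng):
        data = np.vstack([np.ones(30), rng.standard_normal((2, 30))])
        m = dne_matrix(EfficiencyCurves(data=data, window_starts=np.arange(30)))
        assert m.degenerate_nodes == {0}
        assert np.all(m.data[0, 1:] == 0) and np.all(m.data[1:, 0] == 0)
        assert m.data[0, 0] == 1.0

    def test_too_few_windows_rejected(self, rng):
        curves = EfficiencyCurves(data=rng.standard_normal((3, 2)),
                                  window_starts=np.arange(2))
        with pytest.raises(InputError):
            dne_matrix(curves)

    def test_dne_invariant_to_affine_signal_rescaling(self, rng):
        ts = make_ts(rng.standard_normal((5, 80)))
        scaled = make_ts(3.2 * ts.data + 1.7)
        spec = WindowSpec(30, 2)
        m0 = subject_dne(ts, spec)
        m1 = subject_dne(scaled, spec)
        assert np.allclose(m0.data, m1.data, atol=1e-10)

    def test_dne_entries_bounded(self, rng):
        ts = make_ts(rng.standard_normal((8, 100)))
        m = subject_dne(ts, WindowSpec(30, 2))
        assert np.allclose(m.data, m.data.T)
        assert np.all(np.diag(m.data) == 1.0)
        assert np.all(np.abs(m.data) <= 1.0)
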