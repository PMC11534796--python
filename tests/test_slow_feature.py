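import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftcast.slow_feature import (
    SlowNodeSet,
    extract_slow_feature,
    fluctuation_scores,
    moving_average,
    select_slow_nodes,
    sign_align,
    smooth,
)


def brute_force_moving_average(x, w):
    out = np.empty_like(x, dtype=float)
    for n in range(len(x)):
        lo = max(0, n - w + 1)
        out[n] = np.mean(x[lo:n + 1])
    return out


class TestMovingAverage:
    def test_constant_series(self):
        assert np.allclose(moving_average(np.full(20, 3.5), 5), 3.5)

    def test_window_one_is_identity(self):
        x = np.random.default_rng(0).standard_normal(30)
        assert np.array_equal(moving_average(x, 1), x)

    @pytest.mark.parametrize("w", [1, 2, 3, 7, 10, 25])
    def test_matches_brute_force(self, w):
        x = np.arange(10, dtype=float)
        assert np.allclose(moving_average(x, w), brute_force_moving_average(x, w),
                           atol=1e-12)
        r = np.random.default_rng(w).standard_normal(40)
        assert np.allclose(moving_average(r, w), brute_force_moving_average(r, w),
                           atol=1e-12)

    def test_2d_acts_along_time_axis(self):
        x = np.random.default_rng(1).standard_normal((50, 4))
        got = moving_average(x, 6)
        for j in range(4):
            assert np.allclose(got[:, j], brute_force_moving_average(x[:, j], 6))

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            moving_average(np.zeros(5), 0)


class TestFluctuationScores:
    def test_constant_node_scores_zero(self):
        trace = np.column_stack([np.full(200, 2.0),
                                 np.sin(np.arange(200))])
        s = fluctuation_scores(trace, 10, (0, 200))
        assert s.scores[0] == 0.0
        assert s.scores[1] > 0.1

    def test_alternating_node_scores_its_amplitude(self):
        c = 0.37
        alt = c * (-1.0) ** np.arange(400)
        trace = alt[:, None]
        s = fluctuation_scores(trace, 2, (10, 400))
        assert s.scores[0] == pytest.approx(c, rel=1e-12)

    def test_slow_drift_scores_near_zero(self):
        drift = np.sin(np.linspace(0, 0.3, 1000))  # far slower than the window
        s = fluctuation_scores(drift[:, None], 20, (50, 1000))
        assert s.scores[0] < 2e-4

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(3)
        trace = rng.standard_normal((300, 2))
        w, (a, b) = 15, (40, 290)
        s = fluctuation_scores(trace, w, (a, b))
        for j in range(2):
            ma = brute_force_moving_average(trace[:, j], w)
            resid = (trace[:, j] - ma)[a:b]
            assert s.scores[j] == pytest.approx(resid.std(ddof=0), rel=1e-12)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            fluctuation_scores(np.zeros((50, 2)), 10, (30, 30))
        with pytest.raises(ValueError):
            fluctuation_scores(np.zeros((50, 2)), 10, (30, 35))


class TestSelection:
    def test_ten_percent_of_500_is_50(self):
        scores = np.random.default_rng(0).uniform(size=500)
        sel = select_slow_nodes(scores, 0.10)
        assert len(sel.indices) == 50

    def test_ties_break_by_ascending_index(self):
        sel = select_slow_nodes(np.zeros(500), 0.10)
        assert np.array_equal(sel.indices, np.arange(50))

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(9)
        scores = rng.uniform(size=137)
        sel = select_slow_nodes(scores, 0.25)
        k = round(0.25 * 137)
        oracle = np.sort(sorted(range(137), key=lambda i: (scores[i], i))[:k])
        assert np.array_equal(sel.indices, oracle)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            select_slow_nodes(np.ones(10), 0.0)


class TestExtraction:
    def test_absolute_values(self):
        trace = np.array([[-0.2], [0.3]])
        out = extract_slow_feature(trace, SlowNodeSet(np.array([0]), 1.0))
        assert np.allclose(out, [0.2, 0.3])

    def test_opposite_signs_do_not_cancel(self):
        c = 0.8
        trace = np.column_stack([np.full(10, c), np.full(10, -c)])
        out = extract_slow_feature(trace, SlowNodeSet(np.array([0, 1]), 1.0))
        assert np.allclose(out, c)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        trace = rng.standard_normal((1000, 50))
        idx = np.sort(rng.choice(50, 20, replace=False))
        out = extract_slow_feature(trace, SlowNodeSet(idx, 0.4))
        oracle = np.array([np.mean([abs(trace[n, i]) for i in idx])
                           for n in range(1000)])
        assert np.allclose(out, oracle, atol=1e-12)

    def test_empty_node_set_rejected(self):
        with pytest.raises(ValueError):
            extract_slow_feature(np.zeros((5, 3)), SlowNodeSet(np.array([], int), 0.0))


class TestSmoothing:
    def test_constant_input_is_fixed_point(self):
        h = smooth(np.full(100, 0.7), tau_f=200.0, h0=0.7)
        assert np.allclose(h, 0.7)

    def test_unit_step_closed_form(self):
        tau = 50.0
        n = 200
        h = smooth(np.ones(n), tau_f=tau, h0=0.0)
        expected = 1.0 - (1.0 - 1.0 / tau) ** np.arange(n)
        assert np.allclose(h, expected, atol=1e-12)

    def test_tau_one_is_pure_delay(self):
        u = np.random.default_rng(0).standard_normal(20)
        h = smooth(u, tau_f=1.0, h0=0.0)
        assert np.allclose(h[1:], u[:-1])

    def test_impulse_response_matches_recursion(self):
        tau = 200.0
        n = 500
        u = np.zeros(n)
        u[0] = 1.0
        h = smooth(u, tau_f=tau, h0=0.0)
        k = np.arange(1, n)
        expected = (1.0 / tau) * (1.0 - 1.0 / tau) ** (k - 1)
        assert np.allclose(h[1:], expected, atol=1e-12)
        # DC gain exactly 1: geometric sum of the impulse response
        assert (1.0 / tau) / (1.0 - (1.0 - 1.0 / tau)) == pytest.approx(1.0)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            smooth(np.zeros(5), tau_f=0.5)


class TestSignAlign:
    def test_identical_and_inverted(self):
        x = np.random.default_rng(0).standard_normal(100)
        assert sign_align(x, x) == 1
        assert sign_align(-x, x) == -1

    def test_correlation_magnitude_invariant(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(200), rng.standard_normal(200)
        s = sign_align(a, b)
        r_aligned = np.corrcoef(s * a, b)[0, 1]
        assert r_aligned == pytest.approx(abs(np.corrcoef(a, b)[0, 1]))
        assert r_aligned >= 0


def test_selection_stable_across_disjoint_scoring_halves(exp1_lorenz_data):
    """Node selection is a property of the reservoir, not of the particular
    scoring window: selections from two disjoint halves of the training
    window overlap by at least 60%."""
    from driftcast.reservoir import SlowReservoirConfig, drive, init_slow_reservoir

    cfg, y, _ = exp1_lorenz_data
    w = init_slow_reservoir(SlowReservoirConfig(seed=0))
    trace = drive(w, (y.y,))
    mid = (cfg.n_transient + len(trace)) // 2
    first = select_slow_nodes(
        fluctuation_scores(trace, cfg.n_window, (cfg.n_transient, mid)), 0.10)
    second = select_slow_nodes(
        fluctuation_scores(trace, cfg.n_window, (mid, len(trace))), 0.10)
    overlap = len(set(first.indices) & set(second.indices))
    assert overlap >= 0.6 * len(first.indices)


@settings(deadline=None, max_examples=40)
@given(data=st.lists(st.floats(min_value=-1, max_value=1), min_size=3, max_size=60),
       tau=st.floats(min_value=1.0, max_value=300.0))
def test_pipeline_nonnegativity_and_smoothing_bounds(data, tau):
    """The extracted feature is a mean of absolute values, hence nonnegative,
    and the low-pass output stays inside the input's range when started there."""
    trace = np.asarray(data)[:, None]
    u = extract_slow_feature(trace, SlowNodeSet(np.array([0]), 1.0))
    assert np.all(u >= 0.0)
    h = smooth(u, tau_f=tau)
    assert np.all(h >= u.min() - 1e-12)
    assert np.all(h <= u.max() + 1e-12)
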