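"""RLS canceller: recursion correctness, oracle equivalence, tracking."""

import numpy as np
import pytest

from nirsrls import (
    RLSConfig,
    SampledSeries,
    lowpass_filter,
    pvef_correct,
    rls_filter,
    rls_init,
    rls_step,
)


def series(values, fs=10.0):
    return SampledSeries(np.asarray(values, dtype=float), fs)


def regressors(x, order):
    """Causal lagged-reference design matrix, zero-padded at the start."""
    xp = np.concatenate([np.zeros(order - 1), x])
    return np.stack([xp[i : i + order][::-1] for i in range(len(x))])


class TestInitAndStep:
    def test_default_init_state(self):
        state = rls_init(RLSConfig())
        assert state.weights.shape == (16,)
        assert not state.weights.any()
        np.testing.assert_array_equal(state.p_matrix, 100.0 * np.eye(16))
        assert state.n_seen == 0

    def test_order_one_is_scalar_state(self):
        state = rls_init(RLSConfig(order_n=1))
        assert state.weights.shape == (1,) and state.p_matrix.shape == (1, 1)

    @pytest.mark.parametrize("kwargs", [dict(forgetting=0.0), dict(forgetting=1.5),
                                        dict(order_n=0), dict(p0_scale=0.0)])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RLSConfig(**kwargs)

    def test_zero_regressor_passes_target_through(self):
        state = rls_init(RLSConfig(order_n=3))
        w_before = state.weights.copy()
        state, e = rls_step(state, np.zeros(3), 2.5)
        assert e == 2.5
        np.testing.assert_array_equal(state.weights, w_before)
        assert state.n_seen == 1

    def test_nonfinite_input_rejected(self):
        state = rls_init(RLSConfig(order_n=2))
        with pytest.raises(ValueError):
            rls_step(state, np.array([1.0, np.nan]), 0.0)

    def test_p_matrix_stays_symmetric(self):
        rng = np.random.default_rng(0)
        state = rls_init(RLSConfig(order_n=8, forgetting=0.99))
        for _ in range(500):
            state, _ = rls_step(state, rng.standard_normal(8), rng.standard_normal(),
                                forgetting=0.99)
        assert np.max(np.abs(state.p_matrix - state.p_matrix.T)) < 1e-8


class TestBatchLeastSquaresOracle:
    """With lambda=1 and large P0, RLS solves the same normal equations as
    batch least squares — checked against numpy's independent solver."""

    @pytest.mark.parametrize("seed", range(10))
    def test_final_weights_match_lstsq(self, seed):
        rng = np.random.default_rng(seed)
        order, n = 4, 200
        x = rng.standard_normal(n)
        w_true = rng.standard_normal(order)
        X = regressors(x, order)
        d = X @ w_true + 0.1 * rng.standard_normal(n)

        state = rls_init(RLSConfig(order_n=order, forgetting=1.0, p0_scale=1e6))
        for i in range(n):
            state, _ = rls_step(state, X[i], d[i], forgetting=1.0)
        w_batch = np.linalg.lstsq(X, d, rcond=None)[0]
        np.testing.assert_allclose(state.weights, w_batch, atol=1e-6)


class TestRLSFilter:
    def test_exact_fir_relationship_recovered(self):
        # d(n) = 2 x(n-1): weights converge to (0, 2) and the error vanishes
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        d = 2.0 * np.concatenate([[0.0], x[:-1]])
        out, state = rls_filter(
            series(x), series(d),
            RLSConfig(order_n=2, forgetting=1.0, p0_scale=1e8), return_state=True
        )
        np.testing.assert_allclose(state.weights, [0.0, 2.0], atol=1e-6)
        assert np.abs(out.values[50:]).max() < 1e-6

    def test_identical_channels_cancel(self):
        t = np.arange(2000) / 10.0
        x = np.sin(2 * np.pi * 1.2 * t)
        out = rls_filter(series(x), series(x))
        rms = lambda v: np.sqrt(np.mean(v**2))
        assert rms(out.values[1000:]) < 0.01 * rms(x)

    def test_zero_reference_passes_target_through(self):
        rng = np.random.default_rng(2)
        d = rng.standard_normal(300)
        out = rls_filter(series(np.zeros(300)), series(d))
        np.testing.assert_array_equal(out.values, d)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rls_filter(series(np.zeros(10)), series(np.zeros(11)))

    def test_recovers_slow_evoked_from_interference_mixture(self):
        rng = np.random.default_rng(3)
        t = np.arange(4000) / 10.0
        interference = np.sin(2 * np.pi * 1.2 * t) + 0.5 * np.sin(2 * np.pi * 0.25 * t)
        evoked = 0.5 * np.sin(2 * np.pi * 0.025 * t)
        target = interference + evoked + 0.05 * rng.standard_normal(4000)
        out = rls_filter(series(interference), series(target))
        r = np.corrcoef(out.values[500:], evoked[500:])[0, 1]
        assert r > 0.8

    def test_tracks_step_change_in_mapping(self):
        # forgetting < 1: after the FIR mapping jumps, the error re-converges
        # within a few memory horizons 1/(1-lambda)
        lam = 0.99
        horizon = int(1 / (1 - lam))
        rng = np.random.default_rng(4)
        x = rng.standard_normal(2000)
        X = regressors(x, 2)
        w1, w2 = np.array([1.0, 0.5]), np.array([-0.5, 2.0])
        change = 1000
        d = np.concatenate([X[:change] @ w1, X[change:] @ w2])
        out = rls_filter(series(x), series(d), RLSConfig(order_n=2, forgetting=lam))
        rms = lambda v: np.sqrt(np.mean(v**2))
        settled = out.values[change + 3 * horizon : change + 5 * horizon]
        assert rms(settled) < 0.05 * rms(d[change:])


class TestLowpassAndPVEF:
    def test_dc_passes_unchanged(self):
        out = lowpass_filter(series(np.full(500, 2.0)))
        np.testing.assert_allclose(out.values, 2.0, rtol=1e-9)

    def test_cardiac_frequency_strongly_attenuated(self):
        t = np.arange(4000) / 10.0
        out = lowpass_filter(series(np.sin(2 * np.pi * 1.2 * t)), cutoff_hz=0.125)
        assert np.sqrt(np.mean(out.values**2)) < 0.01

    def test_stimulation_frequency_preserved(self):
        t = np.arange(8000) / 10.0
        out = lowpass_filter(series(np.sin(2 * np.pi * 0.025 * t)), cutoff_hz=0.125)
        mid = out.values[2000:6000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(series(np.zeros(100)), cutoff_hz=5.0)

    @pytest.mark.parametrize(
        "values,pvef,expected",
        [(np.zeros(5), 9.15, np.zeros(5)),
         (np.ones(1), 9.15, np.array([9.15])),
         (np.array([1.0, -2.0]), 1.0, np.array([1.0, -2.0]))],
    )
    def test_partial_volume_scaling(self, values, pvef, expected):
        out = pvef_correct(series(values), pvef)
        np.testing.assert_allclose(out.values, expected)
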