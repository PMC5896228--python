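"""Short-separation interference cancellation by recursive least squares.

The long-separation (target) channel is modelled as an FIR-filtered copy of
the short-separation (reference) channel plus the evoked signal; because
the reference samples superficial tissue only, whatever the FIR mapping can
explain is physiological interference, and the prediction error is the
cleaned signal. The FIR weights are estimated online by exponentially
weighted recursive least squares, updated point by point:

    k = P x / (lambda + x' P x)
    e = d - w' x              (a-priori error = output sample)
    w <- w + k e
    P <- (P - k x' P) / lambda

with x the current + past reference samples (causal regressor, order N=16
by default), forgetting factor lambda = 0.999, zero initial weights and
P0 = p0_scale * I. The a-priori error is the standard canceller output; a
forgetting factor below one lets the weights track slow non-stationarity
with an effective memory of ~1/(1-lambda) samples.

Also here: the zero-phase Butterworth low-pass used as the conventional
comparison method, and the partial-volume scale correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .series import SampledSeries

__all__ = [
    "RLSConfig",
    "RLSState",
    "rls_init",
    "rls_step",
    "rls_filter",
    "lowpass_filter",
    "pvef_correct",
    "DEFAULT_PVEF",
]

#: Partial volume effect factor: ratio of sampling-volume to activated-volume
#: optical pathlength, used to rescale underestimated concentration changes.
DEFAULT_PVEF = 9.15


@dataclass(frozen=True)
class RLSConfig:
    """RLS canceller settings: FIR order, forgetting factor, P0 scale."""

    order_n: int = 16
    forgetting: float = 0.999
    p0_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.order_n < 1:
            raise ValueError(f"order_n must be >= 1, got {self.order_n}")
        if not (0 < self.forgetting <= 1):
            raise ValueError(f"forgetting factor must be in (0, 1], got {self.forgetting}")
        if self.p0_scale <= 0:
            raise ValueError("p0_scale must be > 0")

    def init_weights(self) -> np.ndarray:
        """Zero initial coefficient vector of length order_n."""
        return np.zeros(self.order_n)


@dataclass
class RLSState:
    """Mutable filter state: weight vector, inverse-correlation matrix, count."""

    weights: np.ndarray
    p_matrix: np.ndarray
    n_seen: int = 0


def rls_init(config: RLSConfig) -> RLSState:
    """Fresh state: zero weights, P = p0_scale * identity."""
    return RLSState(
        weights=config.init_weights(),
        p_matrix=config.p0_scale * np.eye(config.order_n),
        n_seen=0,
    )


def rls_step(
    state: RLSState, x_vec: np.ndarray, d: float, forgetting: float = 0.999
) -> tuple[RLSState, float]:
    """One exponentially weighted RLS update; returns the a-priori error.

    The state is updated in place (and also returned). P is re-symmetrized
    after the rank-one update to stop round-off from accumulating asymmetry.
    """
    x = np.asarray(x_vec, dtype=float)
    if x.shape != state.weights.shape:
        raise ValueError(f"regressor length {x.size} != filter order {state.weights.size}")
    if not (np.all(np.isfinite(x)) and np.isfinite(d)):
        raise ValueError("non-finite input to rls_step")

    p = state.p_matrix
    px = p @ x
    k = px / (forgetting + x @ px)
    e = d - state.weights @ x
    state.weights = state.weights + k * e
    p = (p - np.outer(k, px)) / forgetting
    state.p_matrix = 0.5 * (p + p.T)
    state.n_seen += 1
    return state, float(e)


def rls_filter(
    reference: SampledSeries,
    target: SampledSeries,
    config: RLSConfig = RLSConfig(),
    return_state: bool = False,
) -> SampledSeries | tuple[SampledSeries, RLSState]:
    """Run the RLS canceller over a record; the error sequence is the output.

    The regressor at sample n is [ref(n), ref(n-1), ..., ref(n-N+1)],
    zero-padded before the record start (causal — no lookahead, so the
    canceller is usable in real time). With ``return_state`` the final
    :class:`RLSState` is returned alongside the output, for run logging.
    """
    if not reference.same_clock(target):
        raise ValueError("reference and target must share length and sampling rate")
    n = len(target)
    order = config.order_n
    lam = config.forgetting

    ref = np.concatenate([np.zeros(order - 1), reference.values])
    d = target.values
    w = config.init_weights()
    p = config.p0_scale * np.eye(order)
    out = np.empty(n)
    for i in range(n):
        x = ref[i : i + order][::-1]  # [ref(n), ref(n-1), ...]
        px = p @ x
        k = px / (lam + x @ px)
        e = d[i] - w @ x
        out[i] = e
        w = w + k * e
        p = (p - np.outer(k, px)) / lam
        p = 0.5 * (p + p.T)
    cleaned = target.with_values(out)
    if return_state:
        return cleaned, RLSState(weights=w, p_matrix=p, n_seen=n)
    return cleaned


def lowpass_filter(series: SampledSeries, cutoff_hz: float = 0.125) -> SampledSeries:
    """Zero-phase 4th-order Butterworth low-pass (forward-backward)."""
    if not (0 < cutoff_hz < series.fs / 2):
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={series.fs / 2} Hz)"
        )
    sos = sps.butter(4, cutoff_hz, btype="low", fs=series.fs, output="sos")
    return series.with_values(sps.sosfiltfilt(sos, series.values))


def pvef_correct(series: SampledSeries, pvef: float = DEFAULT_PVEF) -> SampledSeries:
    """Rescale by the partial volume effect factor.

    Concentration changes are underestimated because the activation occupies
    only part of the optically sampled volume; compensation multiplies.
    """
    if pvef <= 0:
        raise ValueError(f"pvef must be > 0, got {pvef}")
    return series.with_values(series.values * pvef)
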