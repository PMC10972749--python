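"""Rectified integration and normalization of multiunit nerve/EMG signals.

The signal is rectified about its median (robust to spike asymmetry and
amplifier offset) and passed through a first-order leaky integrator
with time constant τ = 0.02 s, the only integration constant stated for
this preparation.  Stimulus responses are expressed as percentage change
of the integrated signal from a pre-stimulus baseline and, for
between-animal comparability, normalized to the response to systemic
serotonin over the 100 s after administration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .core import SampledTrace, StimulusEpoch

__all__ = [
    "IntegratorConfig",
    "NormalizedResponse",
    "integrate_signal",
    "percent_change",
    "normalize_to_serotonin",
    "stimulus_response",
]


@dataclass(frozen=True)
class IntegratorConfig:
    """Leaky-integrator time constant in seconds (default 0.02 s)."""

    tau_s: float = 0.02

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")


def integrate_signal(
    trace: SampledTrace, cfg: IntegratorConfig | None = None
) -> SampledTrace:
    """Median-rectify and exponentially integrate a nerve/EMG trace.

    The output is the first-order exponential moving average of
    ``|x - median(x)|`` with time constant ``tau_s``, discretized
    exactly (``alpha = 1 - exp(-dt/tau)``), so a unit step in rectified
    amplitude reaches ``1 - 1/e`` of its asymptote at ``t = tau``.
    Same length and sampling rate as the input.
    """
    cfg = cfg or IntegratorConfig()
    if trace.kind not in ("nerve", "emg"):
        raise ValueError(f"integration expects a nerve or emg trace, got {trace.kind!r}")
    dt = 1.0 / trace.sampling_rate_hz
    if cfg.tau_s < 2.0 * dt:
        raise ValueError(
            f"tau_s = {cfg.tau_s} s is below the resolvable limit "
            f"2/sampling_rate = {2.0 * dt} s"
        )
    rect = np.abs(trace.values - np.median(trace.values))
    alpha = 1.0 - np.exp(-dt / cfg.tau_s)
    # y[n] = (1 - alpha) y[n-1] + alpha r[n], zero initial state
    y = lfilter([alpha], [1.0, -(1.0 - alpha)], rect)
    return SampledTrace(
        values=y,
        sampling_rate_hz=trace.sampling_rate_hz,
        t0_s=trace.t0_s,
        kind=trace.kind,
    )


def percent_change(
    integrated: SampledTrace,
    stim_window: tuple[float, float],
    baseline_window: tuple[float, float],
) -> float:
    """Percent change of the integrated signal from baseline.

    ``100 * (mean(stim) - mean(baseline)) / mean(baseline)`` over
    half-open time windows.
    """
    for name, (a, b) in (("stim", stim_window), ("baseline", baseline_window)):
        if not a < b:
            raise ValueError(f"{name} window start must precede its end")
        if a < integrated.t0_s - 1e-9 or b > integrated.t0_s + integrated.duration_s + 1e-9:
            raise ValueError(f"{name} window [{a}, {b}) s lies outside the trace")
    stim = integrated.slice_window(*stim_window)
    base = integrated.slice_window(*baseline_window)
    if stim.size == 0 or base.size == 0:
        raise ValueError("empty analysis window")
    base_mean = float(base.mean())
    if base_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return 100.0 * (float(stim.mean()) - base_mean) / base_mean


@dataclass(frozen=True)
class NormalizedResponse:
    """Stimulus response as a fraction of the serotonin reference response."""

    pct_change_baseline: float
    serotonin_pct_change: float
    normalized: float
    stim_window: tuple[float, float]
    baseline_window: tuple[float, float]
    serotonin_window: tuple[float, float]


def normalize_to_serotonin(
    response_pct: float,
    serotonin_trace: SampledTrace,
    serotonin_onset_s: float,
    window_s: float = 100.0,
    baseline_s: float = 60.0,
    cfg: IntegratorConfig | None = None,
    stim_window: Optional[tuple[float, float]] = None,
    baseline_window: Optional[tuple[float, float]] = None,
) -> NormalizedResponse:
    """Normalize a stimulus response to the serotonin reference response.

    The serotonin percent change is computed on the integrated trace
    over ``[onset, onset + window_s)`` against the ``baseline_s``
    immediately before administration.  A nonpositive serotonin response
    marks an unusable reference trial and raises.
    """
    integrated = integrate_signal(serotonin_trace, cfg)
    ser_window = (serotonin_onset_s, serotonin_onset_s + window_s)
    base_window = (serotonin_onset_s - baseline_s, serotonin_onset_s)
    ser_pct = percent_change(integrated, ser_window, base_window)
    if ser_pct <= 0:
        raise ValueError(
            f"serotonin response is nonpositive ({ser_pct:.2f}%); "
            "reference trial unusable"
        )
    return NormalizedResponse(
        pct_change_baseline=response_pct,
        serotonin_pct_change=ser_pct,
        normalized=response_pct / ser_pct,
        stim_window=stim_window or (float("nan"), float("nan")),
        baseline_window=baseline_window or (float("nan"), float("nan")),
        serotonin_window=ser_window,
    )


def stimulus_response(
    trace: SampledTrace,
    epoch: StimulusEpoch,
    baseline_s: float = 60.0,
    cfg: IntegratorConfig | None = None,
) -> float:
    """Integrated percent change for one stimulus epoch.

    Baseline is the ``baseline_s`` window immediately before stimulus
    onset (60 s by default, a package convention; the stimulus window is
    the epoch itself).
    """
    integrated = integrate_signal(trace, cfg)
    return percent_change(
        integrated,
        (epoch.start_s, epoch.end_s),
        (epoch.start_s - baseline_s, epoch.start_s),
    )
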