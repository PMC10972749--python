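"""Synthetic physiological recordings with known ground truth.

Every downstream stage of the toolkit (breath segmentation, gasp/sigh
calling, calcium response classification, nerve integration) is tested
against data produced here, because the study conditions it emulates —
anaesthetized-mouse tracheal pressure with embedded augmented breaths,
two-channel vagal-ganglion ROI fluorescence with photobleaching, and
multiunit nerve activity with stimulus-locked gain changes — have no
public raw-signal counterpart.

Design notes
------------
* Breaths are built as a half-sine inspiration followed by an
  alpha-function (rise-and-decay exponential) expiration, concatenated
  cycle by cycle.  This reproduces the asymmetric pressure morphology of
  a tracheostomized mouse well enough to exercise segmentation without a
  lung-mechanics model.
* Gasps and sighs are injected by scaling one whole breath cycle by
  ``gasp_gain`` (> 1.5 so the injected event exceeds the >50% detection
  rule by construction); the two are distinguished only by stimulus
  context, exactly as downstream classification does.
* Photobleaching multiplies both fluorescence channels by the same
  exponential envelope, so the ratiometric pipeline cancels it.
* Nerve activity is a stationary spiky process multiplied by a
  per-epoch gain envelope, so the rectified-integrated mean scales
  exactly with the stated gain.
* All randomness flows from one integer seed through named substreams,
  so regeneration is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .core import SampledTrace, StimulusEpoch

__all__ = [
    "BreathSimParams",
    "CalciumSimParams",
    "NerveSimParams",
    "GroundTruth",
    "gen_breath_trace",
    "gen_calcium_session",
    "gen_nerve_trace",
    "gen_stimulus_protocol",
    "PROTOCOLS",
]

# Substream ids keep the three generators statistically independent even
# when driven by the same global seed.
_STREAMS = {"breath": 101, "calcium": 202, "nerve": 303}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


@dataclass
class GroundTruth:
    """Generating truth serialized alongside every synthetic dataset."""

    breath_onsets_s: list[float] = field(default_factory=list)
    events: list[dict[str, Any]] = field(default_factory=list)
    tidal_volumes_ml: list[float] = field(default_factory=list)
    breath_amplitudes: list[float] = field(default_factory=list)
    responders: dict[str, list[int]] = field(default_factory=dict)
    selectivity: dict[int, str] = field(default_factory=dict)
    unhealthy_rois: list[int] = field(default_factory=list)
    nerve_gains: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "breath_onsets_s": self.breath_onsets_s,
            "events": self.events,
            "tidal_volumes_ml": self.tidal_volumes_ml,
            "breath_amplitudes": self.breath_amplitudes,
            "responders": self.responders,
            "selectivity": {str(k): v for k, v in self.selectivity.items()},
            "unhealthy_rois": self.unhealthy_rois,
            "nerve_gains": self.nerve_gains,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            breath_onsets_s=list(d.get("breath_onsets_s", [])),
            events=list(d.get("events", [])),
            tidal_volumes_ml=list(d.get("tidal_volumes_ml", [])),
            breath_amplitudes=list(d.get("breath_amplitudes", [])),
            responders={k: list(v) for k, v in d.get("responders", {}).items()},
            selectivity={int(k): v for k, v in d.get("selectivity", {}).items()},
            unhealthy_rois=list(d.get("unhealthy_rois", [])),
            nerve_gains={k: float(v) for k, v in d.get("nerve_gains", {}).items()},
        )


# ---------------------------------------------------------------------------
# Respiratory traces
# ---------------------------------------------------------------------------


@dataclass
class BreathSimParams:
    """Parameters for a synthetic respiratory trace.

    Defaults emulate urethane-anaesthetized mouse breathing at 150
    breaths/min sampled at 1 kHz (acquisition-rate convention; EMG/ECG
    hardware in this preparation samples at 1-2 kHz).  ``gasp_gain``
    must exceed 1.5 so that an injected event satisfies the >50%
    amplitude rule against its neighbours by construction.
    ``compression_attenuation`` is the fractional reduction of cyclic
    amplitude during a compression epoch (the cuff is titrated to a
    40-60% reduction in peak tracheal pressure).
    """

    duration_s: float = 60.0
    sampling_rate_hz: float = 1000.0
    base_rate_bpm: float = 150.0
    base_amplitude: float = 1.0
    gasp_times_s: Sequence[float] = ()
    gasp_gain: float = 2.0
    sigh_times_s: Sequence[float] = ()
    noise_sd: float = 0.0
    epochs: Sequence[StimulusEpoch] = ()
    compression_attenuation: float = 0.5
    insp_fraction: float = 0.35
    kind: str = "pressure"
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.base_rate_bpm <= 0:
            raise ValueError("base_rate_bpm must be positive")
        if self.gasp_gain <= 1.5:
            raise ValueError(
                "gasp_gain must exceed 1.5 so injected events satisfy the "
                ">50% amplitude rule by construction"
            )
        if not 0.4 <= self.compression_attenuation <= 0.6:
            raise ValueError("compression_attenuation must lie in [0.4, 0.6]")
        if not 0 < self.insp_fraction < 1:
            raise ValueError("insp_fraction must lie in (0, 1)")
        if self.kind not in ("pressure", "flow"):
            raise ValueError("kind must be 'pressure' or 'flow'")
        for t in list(self.gasp_times_s) + list(self.sigh_times_s):
            if not 0 <= t < self.duration_s:
                raise ValueError(f"event time {t} s outside [0, {self.duration_s}) s")
        period = 60.0 / self.base_rate_bpm
        times = sorted(list(self.gasp_times_s) + list(self.sigh_times_s))
        for a, b in zip(times, times[1:]):
            if b - a < period:
                raise ValueError(
                    f"injected events at {a} s and {b} s collide: separation "
                    f"{b - a:.3f} s is below one breath period ({period:.3f} s)"
                )

    @property
    def breath_period_s(self) -> float:
        return 60.0 / self.base_rate_bpm


def _cycle_waveform(phase: np.ndarray, period: float, insp_fraction: float) -> np.ndarray:
    """Unit-amplitude breath cycle: half-sine inspiration, alpha expiration."""
    t_insp = insp_fraction * period
    t_exp = period - t_insp
    t_pk = t_exp / 6.0  # expiration decays to ~4% of peak by cycle end
    out = np.empty_like(phase)
    insp = phase < t_insp
    out[insp] = np.sin(np.pi * phase[insp] / t_insp)
    s = phase[~insp] - t_insp
    out[~insp] = -(s / t_pk) * np.exp(1.0 - s / t_pk)
    return out


def gen_breath_trace(params: BreathSimParams) -> tuple[SampledTrace, GroundTruth]:
    """Generate a respiratory trace with injected gasps/sighs.

    Returns the trace and a :class:`GroundTruth` listing breath onsets,
    per-breath peak amplitudes, injected events (type, breath index and
    onset time) and — for flow traces — per-breath tidal volumes in ml.
    """
    params.validate()
    rng = _rng(params.seed, "breath")
    fs = params.sampling_rate_hz
    period = params.breath_period_s
    n_samples = round(params.duration_s * fs)
    t = np.arange(n_samples) / fs

    onsets = np.arange(0.0, params.duration_s - 1e-12, period)
    n_breaths = onsets.size

    # Per-breath amplitude: base x event gain x compression attenuation.
    amps = np.full(n_breaths, params.base_amplitude)
    events: list[dict[str, Any]] = []
    for etype, times in (("gasp", params.gasp_times_s), ("sigh", params.sigh_times_s)):
        for t_ev in times:
            k = int(np.clip(round(t_ev / period), 0, n_breaths - 1))
            amps[k] *= params.gasp_gain
            events.append(
                {"type": etype, "time_s": float(onsets[k]), "breath_index": k}
            )
    for epoch in params.epochs:
        if epoch.label == "compression":
            in_epoch = (onsets >= epoch.start_s) & (onsets < epoch.end_s)
            amps[in_epoch] *= 1.0 - params.compression_attenuation
    events.sort(key=lambda e: e["time_s"])

    breath_idx = np.minimum((t / period).astype(int), n_breaths - 1)
    phase = t - onsets[breath_idx]
    values = amps[breath_idx] * _cycle_waveform(phase, period, params.insp_fraction)
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=n_samples)

    truth = GroundTruth(
        breath_onsets_s=[float(o) for o in onsets],
        events=events,
        breath_amplitudes=[float(a) for a in amps],
    )
    if params.kind == "flow":
        # inspiratory half-sine of peak A and width w integrates to 2Aw/pi
        t_insp = params.insp_fraction * period
        truth.tidal_volumes_ml = [float(2.0 * a * t_insp / np.pi) for a in amps]

    trace = SampledTrace(values=values, sampling_rate_hz=fs, t0_s=0.0, kind=params.kind)
    return trace, truth


# ---------------------------------------------------------------------------
# Calcium imaging sessions
# ---------------------------------------------------------------------------


@dataclass
class CalciumSimParams:
    """Parameters for a two-channel ROI fluorescence session.

    Defaults emulate volumetric vagal-ganglion imaging at 2 Hz (typical
    volume rates are 1.5-3 Hz) with a compression epoch and an inflation
    epoch separated by rest.  Responder ROIs carry a stimulus-locked
    transient of peak amplitude ``response_amplitude_dff`` on the GCaMP
    channel only; both channels share one exponential photobleaching
    envelope so ratiometric normalization to tdTomato cancels it.
    Unhealthy ROIs get distinctively strong, unvarying GCaMP signal.
    """

    n_rois: int = 100
    duration_s: float = 240.0
    sampling_rate_hz: float = 2.0
    epochs: Sequence[StimulusEpoch] = field(
        default_factory=lambda: (
            StimulusEpoch("compression", 60.0, 70.0, 100.0),
            StimulusEpoch("inflation", 160.0, 170.0, 200.0),
        )
    )
    responder_map: Mapping[int, Sequence[str]] = field(default_factory=dict)
    response_amplitude_dff: float = 1.0
    bleach_tau_s: float = 600.0
    noise_sd: float = 0.05
    baseline_gcamp: float = 1.0
    baseline_tdtomato: float = 1.0
    unhealthy_level: float = 5.0
    unhealthy_rois: Sequence[int] = ()
    rise_tau_s: float = 1.0
    decay_tau_s: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        labels = {e.label for e in self.epochs}
        for roi, resp in self.responder_map.items():
            if not 0 <= int(roi) < self.n_rois:
                raise ValueError(f"responder_map references unknown ROI {roi}")
            for lab in resp:
                if lab not in labels:
                    raise ValueError(
                        f"responder_map for ROI {roi} references epoch label "
                        f"{lab!r} not present in the session (have {sorted(labels)})"
                    )
        for roi in self.unhealthy_rois:
            if not 0 <= int(roi) < self.n_rois:
                raise ValueError(f"unhealthy_rois references unknown ROI {roi}")
        for e in self.epochs:
            if e.end_s > self.duration_s:
                raise ValueError(f"epoch {e.label!r} extends beyond the session")


def _transient_kernel(
    t: np.ndarray, epoch: StimulusEpoch, rise_tau: float, decay_tau: float
) -> np.ndarray:
    """Unit-peak calcium transient: saturating rise in-epoch, exponential decay after."""
    k = np.zeros_like(t)
    rising = (t >= epoch.start_s) & (t < epoch.end_s)
    k[rising] = 1.0 - np.exp(-(t[rising] - epoch.start_s) / rise_tau)
    k_end = 1.0 - np.exp(-epoch.duration_s / rise_tau)
    after = t >= epoch.end_s
    k[after] = k_end * np.exp(-(t[after] - epoch.end_s) / decay_tau)
    peak = k.max()
    if peak > 0:
        k /= peak
    return k


def _truth_selectivity(
    responds: set[str],
) -> str:
    """Expected selectivity class for equal-amplitude transients."""
    has_c = "compression" in responds
    has_i = "inflation" in responds
    if has_c and has_i:
        return "polymodal"
    if has_c:
        return "compression_selective"
    if has_i:
        return "inflation_selective"
    return "nonresponsive"


def gen_calcium_session(params: CalciumSimParams):
    """Generate paired GCaMP/tdTomato ROI matrices with known responders.

    Returns ``(RoiTraceSet, GroundTruth)``.  The import of the trace-set
    container is deferred so that this module stays independent of the
    analysis code it feeds.
    """
    from .calcium import RoiTraceSet

    params.validate()
    rng = _rng(params.seed, "calcium")
    n_t = round(params.duration_s * params.sampling_rate_hz)
    t = np.arange(n_t) / params.sampling_rate_hz

    kernels = {
        e.label: _transient_kernel(t, e, params.rise_tau_s, params.decay_tau_s)
        for e in params.epochs
    }
    bleach = np.exp(-t / params.bleach_tau_s) if params.bleach_tau_s > 0 else np.ones_like(t)

    unhealthy = {int(r) for r in params.unhealthy_rois}
    gcamp = np.empty((params.n_rois, n_t))
    tdtom = np.empty((params.n_rois, n_t))
    responders: dict[str, list[int]] = {e.label: [] for e in params.epochs}
    selectivity: dict[int, str] = {}

    for i in range(params.n_rois):
        if i in unhealthy:
            g = params.unhealthy_level * params.baseline_gcamp * np.ones(n_t)
            r = params.baseline_tdtomato * np.ones(n_t)
            selectivity[i] = "nonresponsive"
        else:
            signal = np.zeros(n_t)
            labels = {str(l) for l in params.responder_map.get(i, ())}
            for lab in labels:
                signal += params.response_amplitude_dff * kernels[lab]
                responders[lab].append(i)
            g = params.baseline_gcamp * (1.0 + signal)
            r = params.baseline_tdtomato * np.ones(n_t)
            if params.noise_sd > 0:
                g = g + rng.normal(0.0, params.noise_sd, n_t)
                r = r + rng.normal(0.0, params.noise_sd, n_t)
            selectivity[i] = _truth_selectivity(labels)
        gcamp[i] = g * bleach
        tdtom[i] = r * bleach

    traces = RoiTraceSet(
        gcamp=gcamp,
        tdtomato=tdtom,
        sampling_rate_hz=params.sampling_rate_hz,
        roi_ids=list(range(params.n_rois)),
    )
    truth = GroundTruth(
        responders={k: sorted(v) for k, v in responders.items()},
        selectivity=selectivity,
        unhealthy_rois=sorted(unhealthy),
    )
    return traces, truth


# ---------------------------------------------------------------------------
# Nerve / EMG traces
# ---------------------------------------------------------------------------


@dataclass
class NerveSimParams:
    """Rate-modulated multiunit nerve activity.

    A stationary spiky process (Poisson spike train with random-sign
    exponential spikes riding on Gaussian background) is multiplied by a
    per-epoch gain envelope.  Because rectification and integration are
    positively homogeneous, the integrated mean scales exactly with the
    gain, so a suction gain of 1.5 yields a +50% change from baseline.
    """

    duration_s: float = 300.0
    sampling_rate_hz: float = 2000.0
    baseline_rate_hz: float = 200.0
    spike_amplitude: float = 1.0
    spike_tau_s: float = 0.002
    background_sd: float = 0.05
    epochs: Sequence[StimulusEpoch] = ()
    epoch_gains: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_rate_hz <= 0:
            raise ValueError("baseline_rate_hz must be positive")
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        for e in self.epochs:
            if e.start_s < 0 or e.end_s > self.duration_s:
                raise ValueError(
                    f"epoch {e.label!r} [{e.start_s}, {e.end_s}) s lies outside "
                    f"the {self.duration_s} s trace"
                )
        for lab in self.epoch_gains:
            if lab not in {e.label for e in self.epochs}:
                raise ValueError(f"epoch_gains references unknown epoch label {lab!r}")


def gen_nerve_trace(params: NerveSimParams) -> tuple[SampledTrace, GroundTruth]:
    """Generate a zero-median spiky nerve trace with per-epoch gain."""
    params.validate()
    rng = _rng(params.seed, "nerve")
    fs = params.sampling_rate_hz
    n = round(params.duration_s * fs)
    t = np.arange(n) / fs

    # Stationary unit-gain spiking process.
    x = rng.normal(0.0, params.background_sd, n)
    n_spikes = rng.poisson(params.baseline_rate_hz * params.duration_s)
    spike_idx = rng.integers(0, n, size=n_spikes)
    signs = rng.choice([-1.0, 1.0], size=n_spikes)
    impulses = np.zeros(n)
    np.add.at(impulses, spike_idx, signs * params.spike_amplitude)
    kernel_len = max(int(round(5 * params.spike_tau_s * fs)), 1)
    kernel = np.exp(-np.arange(kernel_len) / (params.spike_tau_s * fs))
    x = x + np.convolve(impulses, kernel)[:n]

    gain = np.ones(n)
    gains: dict[str, float] = {}
    for epoch in params.epochs:
        g = float(params.epoch_gains.get(epoch.label, 1.0))
        gains[epoch.label] = g
        gain[(t >= epoch.start_s) & (t < epoch.end_s)] = g
    x = x * gain

    trace = SampledTrace(values=x, sampling_rate_hz=fs, t0_s=0.0, kind="nerve")
    return trace, GroundTruth(nerve_gains=gains)


# ---------------------------------------------------------------------------
# Stimulus protocols
# ---------------------------------------------------------------------------

#: Protocol name -> builder.  Durations follow the study conventions:
#: thoracic-cuff compression 10 s; tracheal suction 5 s at -5 (low) or
#: -10 (high) cmH2O; nebulized stimuli 5 s with reflexes monitored for
#: the subsequent 5 min; optogenetic illumination 10 s; CNO injection
#: followed by a 7-min delay and a 30-min recording; ventilator-driven
#: lung inflation 10 s (Hering-Breuer testing).  For compression,
#: suction and inflation the observation window is the epoch plus 30 s
#: (a package convention; gasping after these challenges is acute).
PROTOCOLS = (
    "compression",
    "suction_low",
    "suction_high",
    "methacholine",
    "optogenetic",
    "cno",
    "inflation",
)


def gen_stimulus_protocol(name: str, start_s: float = 60.0) -> list[StimulusEpoch]:
    """Build the epoch list for a named stimulus protocol.

    ``start_s`` leaves a pre-stimulus baseline (default 60 s, ample for
    the 10-s breathing baseline and the 20-s fluorescence F0 window).
    """
    if name == "compression":
        return [StimulusEpoch("compression", start_s, start_s + 10.0, start_s + 40.0)]
    if name == "suction_low":
        return [
            StimulusEpoch(
                "suction_low",
                start_s,
                start_s + 5.0,
                start_s + 35.0,
                meta={"target_pressure_cmh2o": -5.0},
            )
        ]
    if name == "suction_high":
        return [
            StimulusEpoch(
                "suction_high",
                start_s,
                start_s + 5.0,
                start_s + 35.0,
                meta={"target_pressure_cmh2o": -10.0},
            )
        ]
    if name == "methacholine":
        return [
            StimulusEpoch(
                "methacholine",
                start_s,
                start_s + 5.0,
                start_s + 5.0 + 300.0,
                meta={"nebulizer_duty": 0.5},
            )
        ]
    if name == "optogenetic":
        return [StimulusEpoch("illumination", start_s, start_s + 10.0, start_s + 10.0)]
    if name == "cno":
        return [
            StimulusEpoch(
                "cno",
                start_s,
                start_s + 1.0,
                start_s + 1800.0,
                meta={"analysis_delay_s": 420.0},
            )
        ]
    if name == "inflation":
        return [StimulusEpoch("inflation", start_s, start_s + 10.0, start_s + 40.0)]
    raise ValueError(f"unknown protocol {name!r}; valid protocols: {PROTOCOLS}")
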