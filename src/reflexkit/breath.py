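"""Breath segmentation and per-breath respiratory features.

The acquisition software used for whole-body plethysmography and
anaesthetized pressure recordings is proprietary, so segmentation here
is a deliberately parameter-sparse reimplementation: smooth with a short
moving average, find inspiratory peaks by prominence against a robust
noise estimate, then place breath boundaries at baseline crossings
between peaks.  Amplitudes are magnitudes relative to the local baseline
(zero flow, or the inter-breath pressure plateau), which is what the
ratio-based gasp rule downstream consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import SampledTrace

logger = logging.getLogger(__name__)

__all__ = [
    "Breath",
    "BreathTable",
    "EupneaFilterConfig",
    "EupneaSummary",
    "segment_breaths",
    "compute_tidal_volumes",
    "filter_eupneic",
    "summarize_eupnea",
]


@dataclass(frozen=True)
class Breath:
    """One respiratory cycle.

    Amplitudes are nonnegative magnitudes relative to the local
    baseline; ``tidal_volume_ml`` and ``peak_insp_flow`` are populated
    for flow traces only (integral and maximum of inspiratory flow).
    """

    index: int
    insp_onset_s: float
    insp_peak_s: float
    exp_onset_s: float
    exp_end_s: float
    insp_amplitude: float
    exp_amplitude: float
    duration_s: float
    inst_rate_bpm: float
    tidal_volume_ml: Optional[float] = None
    peak_insp_flow: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.insp_onset_s < self.insp_peak_s < self.exp_onset_s <= self.exp_end_s):
            raise ValueError(
                f"breath {self.index}: timestamps must satisfy "
                "insp_onset < insp_peak < exp_onset <= exp_end"
            )


_COLUMNS = [
    "index",
    "insp_onset_s",
    "insp_peak_s",
    "exp_onset_s",
    "exp_end_s",
    "insp_amplitude",
    "exp_amplitude",
    "duration_s",
    "inst_rate_bpm",
    "tidal_volume_ml",
    "peak_insp_flow",
]


@dataclass
class BreathTable:
    """Ordered, non-overlapping breaths segmented from one trace."""

    breaths: list[Breath] = field(default_factory=list)
    source: str = ""
    kind: str = "pressure"

    def __post_init__(self) -> None:
        for i, b in enumerate(self.breaths):
            if b.index != i:
                raise ValueError("breath indices must be contiguous from 0")
        for a, b in zip(self.breaths, self.breaths[1:]):
            if b.insp_onset_s < a.exp_end_s - 1e-9:
                raise ValueError("breaths must be non-overlapping and ordered")

    def __len__(self) -> int:
        return len(self.breaths)

    def __iter__(self):
        return iter(self.breaths)

    def __getitem__(self, i: int) -> Breath:
        return self.breaths[i]

    def onsets_s(self) -> np.ndarray:
        return np.array([b.insp_onset_s for b in self.breaths])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {c: getattr(b, "index" if c == "index" else c) for c in _COLUMNS}
            for b in self.breaths
        ]
        return pd.DataFrame(rows, columns=_COLUMNS)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, source: str = "", kind: str = "pressure"
    ) -> "BreathTable":
        breaths = []
        for i, row in enumerate(df.itertuples(index=False)):
            d = row._asdict()
            tv = d.get("tidal_volume_ml")
            pif = d.get("peak_insp_flow")
            breaths.append(
                Breath(
                    index=i,
                    insp_onset_s=float(d["insp_onset_s"]),
                    insp_peak_s=float(d["insp_peak_s"]),
                    exp_onset_s=float(d["exp_onset_s"]),
                    exp_end_s=float(d["exp_end_s"]),
                    insp_amplitude=float(d["insp_amplitude"]),
                    exp_amplitude=float(d["exp_amplitude"]),
                    duration_s=float(d["duration_s"]),
                    inst_rate_bpm=float(d["inst_rate_bpm"]),
                    tidal_volume_ml=None if pd.isna(tv) else float(tv),
                    peak_insp_flow=None if pd.isna(pif) else float(pif),
                )
            )
        return cls(breaths=breaths, source=source, kind=kind)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + x.size]
    return out


def _robust_noise_sd(x: np.ndarray) -> float:
    """Noise s.d. from the median absolute first difference.

    For iid Gaussian noise, |diff| has median 0.6745 * sd * sqrt(2); a
    smooth oscillation contributes almost nothing to first differences,
    so this estimates the noise floor rather than signal amplitude.
    """
    d = np.abs(np.diff(x))
    if d.size == 0:
        return 0.0
    return float(np.median(d) / (0.6745 * np.sqrt(2.0)))


def segment_breaths(
    trace: SampledTrace,
    smoothing_window_s: float = 0.02,
    prominence_factor: float = 3.0,
    min_relative_prominence: float = 0.05,
) -> BreathTable:
    """Segment a pressure or flow trace into breaths.

    The trace is smoothed with a ``smoothing_window_s`` moving average;
    inspiratory peaks are detected with prominence at least
    ``max(prominence_factor * noise_sd, min_relative_prominence * robust
    range)``; inspiratory onset is the last baseline crossing before the
    peak, expiratory onset the first after, and expiratory end the next
    breath's onset (trace end for the last breath).  The baseline is the
    midpoint between the median peak height and the median inter-peak
    trough — robust to the asymmetric duty cycle of pressure waveforms,
    where the plain median sits well below the inter-breath plateau.  A
    too-short or constant trace returns an empty table with a warning
    rather than raising.
    """
    if trace.kind not in ("pressure", "flow"):
        raise ValueError(f"cannot segment trace of kind {trace.kind!r}")
    x = np.asarray(trace.values, dtype=float)
    fs = trace.sampling_rate_hz
    empty = BreathTable(breaths=[], kind=trace.kind)
    if x.size < 4:
        logger.warning("trace too short to segment (%d samples)", x.size)
        return empty

    window = max(int(round(smoothing_window_s * fs)), 1)
    xs = _moving_average(x, window)
    lo, hi = np.percentile(xs, [2.5, 97.5])
    robust_range = float(hi - lo)
    if robust_range <= 0:
        logger.warning("trace is constant; no breaths segmented")
        return empty

    noise_sd = _robust_noise_sd(xs)
    prominence = max(
        prominence_factor * noise_sd, min_relative_prominence * robust_range
    )
    peaks, _ = find_peaks(xs, prominence=prominence)
    if peaks.size == 0:
        logger.warning("no inspiratory peaks found; no breaths segmented")
        return empty

    # Baseline: midpoint of typical peak and inter-peak trough levels.
    troughs = [
        float(xs[a : b + 1].min()) for a, b in zip(peaks, peaks[1:]) if b > a
    ]
    if not troughs:
        troughs = [float(xs.min())]
    baseline = 0.5 * (float(np.median(xs[peaks])) + float(np.median(troughs)))
    peaks = peaks[xs[peaks] > baseline]
    if peaks.size == 0:
        logger.warning("no inspiratory peaks above baseline; no breaths segmented")
        return empty

    below = xs <= baseline
    breaths: list[Breath] = []
    bounds = np.concatenate(([0], peaks, [x.size - 1]))
    raw_records = []
    for j, p in enumerate(peaks):
        left_lim = bounds[j]  # previous peak (or trace start)
        right_lim = bounds[j + 2]  # next peak (or trace end)
        seg_before = np.flatnonzero(below[left_lim:p])
        onset_idx = left_lim + seg_before[-1] if seg_before.size else left_lim
        seg_after = np.flatnonzero(below[p : right_lim + 1])
        exp_onset_idx = p + seg_after[0] if seg_after.size else right_lim
        raw_records.append((onset_idx, p, exp_onset_idx))

    for j, (onset_idx, p, exp_onset_idx) in enumerate(raw_records):
        if j + 1 < len(raw_records):
            exp_end_idx = raw_records[j + 1][0]
        else:
            exp_end_idx = x.size - 1
        exp_end_idx = max(exp_end_idx, exp_onset_idx)
        if not onset_idx < p < exp_onset_idx:
            continue  # degenerate cycle (peak at a boundary)
        insp_amp = float(xs[p] - baseline)
        exp_seg = xs[exp_onset_idx : exp_end_idx + 1]
        exp_amp = float(max(baseline - exp_seg.min(), 0.0)) if exp_seg.size else 0.0
        t0 = trace.t0_s
        onset_s = t0 + onset_idx / fs
        exp_end_s = t0 + exp_end_idx / fs
        duration = exp_end_s - onset_s
        if duration <= 0:
            continue
        breaths.append(
            Breath(
                index=len(breaths),
                insp_onset_s=onset_s,
                insp_peak_s=t0 + p / fs,
                exp_onset_s=t0 + exp_onset_idx / fs,
                exp_end_s=exp_end_s,
                insp_amplitude=insp_amp,
                exp_amplitude=exp_amp,
                duration_s=duration,
                inst_rate_bpm=60.0 / duration,
            )
        )
    return BreathTable(breaths=breaths, kind=trace.kind)


def compute_tidal_volumes(trace: SampledTrace, breaths: BreathTable) -> BreathTable:
    """Fill tidal volume and peak inspiratory flow from a flow trace.

    Tidal volume is the time-integral (trapezoidal) of the positive part
    of the flow over the inspiratory phase ``[insp_onset, exp_onset)``;
    peak inspiratory flow is its maximum.  Flow in ml/s integrates to
    ml.
    """
    if trace.kind != "flow":
        raise ValueError(f"tidal volumes require a flow trace, got {trace.kind!r}")
    if breaths.kind != "flow":
        raise ValueError("breath table was not derived from a flow trace")
    fs = trace.sampling_rate_hz
    dt = 1.0 / fs
    out = []
    for b in breaths:
        i0 = trace.index_at(b.insp_onset_s)
        i1 = trace.index_at(b.exp_onset_s)
        seg = np.clip(trace.values[i0 : i1 + 1], 0.0, None)
        if seg.size < 2:
            tv, pif = 0.0, float(seg.max()) if seg.size else 0.0
        else:
            tv = float(np.trapezoid(seg, dx=dt))
            pif = float(seg.max())
        out.append(replace(b, tidal_volume_ml=tv, peak_insp_flow=pif))
    return BreathTable(breaths=out, source=breaths.source, kind=breaths.kind)


@dataclass
class EupneaFilterConfig:
    """Bounds excluding respiratory events outside typical adult mouse
    breathing: tidal volume above 2 ml or below 0.05 ml, or an
    instantaneous rate above 400 breaths/min.  Bounds are inclusive for
    retention (a breath at exactly 2 ml is kept; the exclusion rule is
    strictly 'greater than')."""

    tv_max_ml: float = 2.0
    tv_min_ml: float = 0.05
    bpm_max: float = 400.0

    def __post_init__(self) -> None:
        if not self.tv_min_ml < self.tv_max_ml:
            raise ValueError("tv_min_ml must be below tv_max_ml")
        if self.bpm_max <= 0:
            raise ValueError("bpm_max must be positive")


def filter_eupneic(
    breaths: BreathTable, cfg: EupneaFilterConfig | None = None
) -> tuple[BreathTable, dict[str, int]]:
    """Drop non-eupneic breaths; report removal counts per rule.

    Tidal-volume bounds apply only to breaths that carry a tidal volume
    (flow traces); the rate bound applies always.  A breath violating
    several rules is counted under each.  Retained breaths are
    re-indexed from 0.
    """
    cfg = cfg or EupneaFilterConfig()
    report = {"tv_max": 0, "tv_min": 0, "bpm_max": 0, "removed": 0, "retained": 0}
    kept: list[Breath] = []
    for b in breaths:
        bad = False
        if b.tidal_volume_ml is not None:
            if b.tidal_volume_ml > cfg.tv_max_ml:
                report["tv_max"] += 1
                bad = True
            if b.tidal_volume_ml < cfg.tv_min_ml:
                report["tv_min"] += 1
                bad = True
        if b.inst_rate_bpm > cfg.bpm_max:
            report["bpm_max"] += 1
            bad = True
        if bad:
            report["removed"] += 1
        else:
            kept.append(replace(b, index=len(kept)))
    report["retained"] = len(kept)
    return BreathTable(breaths=kept, source=breaths.source, kind=breaths.kind), report


@dataclass
class EupneaSummary:
    """Averaged eupneic breathing parameters, optionally weight-normalized."""

    mean_tidal_volume_ml: Optional[float]
    mean_rate_bpm: float
    minute_volume_ml_per_min: Optional[float]
    n_breaths: int
    body_weight_g: Optional[float] = None
    tv_per_gram: Optional[float] = None
    minute_volume_per_gram: Optional[float] = None


def summarize_eupnea(
    breaths: BreathTable,
    window: tuple[float, float],
    body_weight_g: float | None = None,
) -> EupneaSummary:
    """Average breathing parameters over a half-open time window.

    A breath belongs to ``[start, end)`` by its inspiratory onset.
    Minute volume is mean tidal volume times mean rate.  When a body
    weight is supplied, volume-dependent measures are divided by it
    (ml/g and ml/min/g).
    """
    start, end = window
    if not start < end:
        raise ValueError("window start must precede window end")
    if len(breaths) == 0:
        raise ValueError("breath table is empty; nothing to summarize")
    onsets = breaths.onsets_s()
    sel = [b for b in breaths if start <= b.insp_onset_s < end]
    if not sel:
        span = (float(onsets.min()), float(onsets.max()))
        if end <= span[0] or start > span[1]:
            raise ValueError(
                f"window [{start}, {end}) lies outside the recorded span "
                f"[{span[0]:.3f}, {span[1]:.3f}] s"
            )
        raise ValueError(f"no breaths with onset in window [{start}, {end}) s")
    rates = [b.inst_rate_bpm for b in sel]
    mean_rate = float(np.mean(rates))
    tvs = [b.tidal_volume_ml for b in sel if b.tidal_volume_ml is not None]
    mean_tv = float(np.mean(tvs)) if len(tvs) == len(sel) else None
    mv = mean_tv * mean_rate if mean_tv is not None else None
    tv_g = mean_tv / body_weight_g if (mean_tv is not None and body_weight_g) else None
    mv_g = mv / body_weight_g if (mv is not None and body_weight_g) else None
    return EupneaSummary(
        mean_tidal_volume_ml=mean_tv,
        mean_rate_bpm=mean_rate,
        minute_volume_ml_per_min=mv,
        n_breaths=len(sel),
        body_weight_g=body_weight_g,
        tv_per_gram=tv_g,
        minute_volume_per_gram=mv_g,
    )
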