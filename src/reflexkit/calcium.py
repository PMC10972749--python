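"""Ratiometric calcium-imaging response classification in vagal ganglia.

Two-channel (GCaMP / tdTomato) ROI traces are converted to a
ratiometric ΔF/F₀ — the ratio R(t) = GCaMP/tdTomato cancels shared
photobleaching, motion and expression-level differences — with F₀ taken
from the 20 s preceding each stimulus.  A cell is responsive to a
stimulus when its evoked ΔF/F₀ peak is at least 3 s.d. above its mean
across the whole imaging session, and responsive cells are classified
by the ratio of compression to inflation responses (Rc/Ri):
compression-selective above 2, inflation-selective below 0.5, polymodal
in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import StimulusEpoch, pct

__all__ = [
    "RoiMask",
    "RoiTraceSet",
    "ResponseProfile",
    "TallySummary",
    "extract_roi_traces",
    "exclude_unhealthy",
    "ratiometric_dff",
    "score_responsiveness",
    "classify_selectivity",
    "tally_responses",
    "analyze_session",
]

RC_RI_UPPER = 2.0
RC_RI_LOWER = 0.5


@dataclass(frozen=True)
class RoiMask:
    """Pixel set of one ROI (0-based row/column pairs)."""

    roi_id: int
    pixels: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.pixels) == 0:
            raise ValueError(f"ROI {self.roi_id} has an empty mask")


@dataclass
class RoiTraceSet:
    """Paired GCaMP/tdTomato ROI x time matrices."""

    gcamp: np.ndarray
    tdtomato: np.ndarray
    sampling_rate_hz: float
    roi_ids: list[int] = field(default_factory=list)
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.gcamp = np.asarray(self.gcamp, dtype=float)
        self.tdtomato = np.asarray(self.tdtomato, dtype=float)
        if self.gcamp.shape != self.tdtomato.shape:
            raise ValueError("GCaMP and tdTomato matrices must have the same shape")
        if self.gcamp.ndim != 2:
            raise ValueError("ROI matrices must be 2-D (ROI x time)")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not self.roi_ids:
            self.roi_ids = list(range(self.gcamp.shape[0]))
        if len(self.roi_ids) != self.gcamp.shape[0]:
            raise ValueError("roi_ids length must match the number of rows")

    @property
    def n_rois(self) -> int:
        return self.gcamp.shape[0]

    @property
    def n_frames(self) -> int:
        return self.gcamp.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_frames) / self.sampling_rate_hz

    def index_at(self, t_s: float) -> int:
        idx = int(np.ceil((t_s - self.t0_s) * self.sampling_rate_hz - 1e-9))
        return int(np.clip(idx, 0, self.n_frames))


def extract_roi_traces(
    stack: Mapping[str, np.ndarray],
    masks: Sequence[RoiMask] | np.ndarray,
    sampling_rate_hz: float,
) -> RoiTraceSet:
    """Average mask pixels per frame and channel into ROI traces.

    ``stack`` maps channel name (``gcamp``, ``tdtomato``) to a
    (frames, rows, cols) array.  ``masks`` is either a list of
    :class:`RoiMask` (which may not overlap) or an integer label image
    where 0 is background and each positive label is one ROI.
    """
    try:
        g = np.asarray(stack["gcamp"], dtype=float)
        r = np.asarray(stack["tdtomato"], dtype=float)
    except KeyError as exc:
        raise ValueError("stack must provide 'gcamp' and 'tdtomato' channels") from exc
    if g.shape != r.shape or g.ndim != 3:
        raise ValueError("channel stacks must be (frames, rows, cols) of equal shape")
    n_frames, n_rows, n_cols = g.shape

    if isinstance(masks, np.ndarray):
        labels = np.unique(masks)
        labels = labels[labels > 0]
        mask_list = [
            RoiMask(int(lab), tuple(map(tuple, np.argwhere(masks == lab))))
            for lab in labels
        ]
    else:
        mask_list = list(masks)
        seen: set[tuple[int, int]] = set()
        for m in mask_list:
            overlap = seen.intersection(m.pixels)
            if overlap:
                raise ValueError(f"ROI {m.roi_id} overlaps another ROI at {sorted(overlap)[0]}")
            seen.update(m.pixels)

    gm = np.empty((len(mask_list), n_frames))
    rm = np.empty((len(mask_list), n_frames))
    for i, m in enumerate(mask_list):
        rows = np.array([p[0] for p in m.pixels])
        cols = np.array([p[1] for p in m.pixels])
        if rows.min() < 0 or cols.min() < 0 or rows.max() >= n_rows or cols.max() >= n_cols:
            raise ValueError(f"ROI {m.roi_id} has pixels outside the {n_rows}x{n_cols} frame")
        gm[i] = g[:, rows, cols].mean(axis=1)
        rm[i] = r[:, rows, cols].mean(axis=1)
    return RoiTraceSet(
        gcamp=gm,
        tdtomato=rm,
        sampling_rate_hz=sampling_rate_hz,
        roi_ids=[m.roi_id for m in mask_list],
    )


def exclude_unhealthy(
    traces: RoiTraceSet,
    cv_threshold: float = 0.01,
    level_percentile: float = 90.0,
) -> dict[int, bool]:
    """Flag unhealthy cells: distinctively strong, unvarying GCaMP signal.

    The test runs on the bleaching-corrected signal (the GCaMP/tdTomato
    ratio) so that a shared photobleaching envelope does not masquerade
    as variability: an ROI is flagged when the coefficient of variation
    of its ratio trace is below ``cv_threshold`` and its mean ratio
    exceeds the ``level_percentile`` of ROI mean ratios.
    """
    if np.any(traces.tdtomato <= 0):
        raise ValueError("tdTomato traces must be strictly positive")
    ratio = traces.gcamp / traces.tdtomato
    means = ratio.mean(axis=1)
    sds = ratio.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means != 0, sds / np.abs(means), np.inf)
    level_cut = np.percentile(means, level_percentile)
    flags = (cv < cv_threshold) & (means > level_cut)
    return {roi: bool(f) for roi, f in zip(traces.roi_ids, flags)}


@dataclass
class ResponseProfile:
    """Per-ROI ΔF/F₀ trace, response magnitudes and classifications."""

    roi_id: int
    dff: np.ndarray
    times_s: np.ndarray
    f0: dict[str, float] = field(default_factory=dict)
    session_mean: float = 0.0
    session_sd: float = 0.0
    response_magnitude: dict[str, float] = field(default_factory=dict)
    responsive: dict[str, bool] = field(default_factory=dict)
    rc_ri: Optional[float] = None
    selectivity: str = "nonresponsive"
    excluded_unhealthy: bool = False


def ratiometric_dff(
    traces: RoiTraceSet,
    epochs: Sequence[StimulusEpoch],
    f0_window_s: float = 20.0,
) -> list[ResponseProfile]:
    """Compute the ratiometric ΔF/F₀ trace and per-epoch baselines.

    R(t) = GCaMP(t)/tdTomato(t).  Each epoch's F₀ is the mean of R over
    the ``f0_window_s`` immediately preceding that epoch, tolerating
    slow drift between stimuli; the session-wide ΔF/F₀ trace used for
    the responsiveness threshold is referenced to the first epoch's F₀.
    """
    if not epochs:
        raise ValueError("at least one stimulus epoch is required")
    if np.any(traces.tdtomato <= 0):
        raise ValueError("tdTomato traces must be strictly positive")
    epochs = sorted(epochs, key=lambda e: e.start_s)
    first = epochs[0]
    if first.start_s - f0_window_s < traces.t0_s - 1e-9:
        raise ValueError(
            f"insufficient baseline: need {f0_window_s} s before the first "
            f"stimulus at {first.start_s} s (trace starts at {traces.t0_s} s)"
        )
    ratio = traces.gcamp / traces.tdtomato
    times = traces.times_s
    profiles = []
    for row, roi in enumerate(traces.roi_ids):
        r = ratio[row]
        f0s: dict[str, float] = {}
        for e in epochs:
            i0 = traces.index_at(e.start_s - f0_window_s)
            i1 = traces.index_at(e.start_s)
            if i1 <= i0:
                raise ValueError(f"empty F0 window before epoch {e.label!r}")
            f0s[e.label] = float(r[i0:i1].mean())
        f0_session = f0s[first.label]
        if f0_session <= 0:
            raise ValueError(f"nonpositive F0 for ROI {roi}")
        dff = (r - f0_session) / f0_session
        profiles.append(
            ResponseProfile(roi_id=roi, dff=dff, times_s=times, f0=f0s)
        )
    return profiles


def score_responsiveness(
    profiles: Iterable[ResponseProfile],
    traces: RoiTraceSet,
    epochs: Sequence[StimulusEpoch],
    response_lag_s: float = 5.0,
) -> list[ResponseProfile]:
    """Call per-epoch responsiveness against the 3-s.d. session threshold.

    The response magnitude for epoch *e* is the peak ΔF/F₀ (relative to
    that epoch's own F₀) over ``[start, end + response_lag_s)``; the
    window extends past stimulus offset to capture offset-peaking
    transients.  A cell is responsive when the magnitude is positive and
    at least ``session_mean + 3 * session_sd`` of its full-session
    ΔF/F₀ trace.
    """
    ratio = traces.gcamp / traces.tdtomato
    out = []
    for row, p in enumerate(profiles):
        p.session_mean = float(p.dff.mean())
        p.session_sd = float(p.dff.std())
        threshold = p.session_mean + 3.0 * p.session_sd
        r = ratio[row]
        for e in epochs:
            i0 = traces.index_at(e.start_s)
            i1 = traces.index_at(e.end_s + response_lag_s)
            if i1 <= i0 or e.start_s < traces.t0_s or i0 >= traces.n_frames:
                raise ValueError(f"epoch {e.label!r} lies outside the session")
            f0 = p.f0[e.label]
            mag = float((r[i0:i1] - f0).max() / f0)
            p.response_magnitude[e.label] = mag
            p.responsive[e.label] = bool(mag > 0 and mag >= threshold)
        out.append(p)
    return out


def classify_selectivity(profile: ResponseProfile) -> str:
    """Assign a selectivity class from the Rc/Ri response ratio.

    Requires responsiveness to at least one of compression or inflation;
    otherwise the cell is ``nonresponsive``.  Rc/Ri > 2 is
    compression-selective, < 0.5 inflation-selective, interior values
    polymodal.  Exact boundary values (2 or 0.5) fall to polymodal,
    the interval whose open bounds they sit on.
    """
    for lab in ("compression", "inflation"):
        if lab not in profile.response_magnitude:
            raise ValueError(f"profile for ROI {profile.roi_id} lacks a {lab!r} magnitude")
    if not (
        profile.responsive.get("compression") or profile.responsive.get("inflation")
    ):
        profile.selectivity = "nonresponsive"
        profile.rc_ri = None
        return profile.selectivity
    rc = profile.response_magnitude["compression"]
    ri = profile.response_magnitude["inflation"]
    if ri <= 0 and rc > 0:
        ratio = float("inf")
    elif ri <= 0:
        ratio = float("nan")
    else:
        ratio = rc / ri
    profile.rc_ri = ratio
    if np.isnan(ratio):
        profile.selectivity = "polymodal"
    elif ratio > RC_RI_UPPER:
        profile.selectivity = "compression_selective"
    elif ratio < RC_RI_LOWER:
        profile.selectivity = "inflation_selective"
    else:
        profile.selectivity = "polymodal"
    return profile.selectivity


@dataclass
class TallySummary:
    """Population accounting of compression/inflation responsiveness.

    Counts partition the cohort into compression-only, inflation-only,
    both and neither; derived percentages are rounded half-up to one
    decimal.  ``any_compression`` and ``any_inflation`` pool the dual
    responders; conditional percentages are taken among compression
    responders (stretch-insensitive vs also inflation-responsive).
    """

    compression_only: int
    inflation_only: int
    both: int
    neither: int

    def __post_init__(self) -> None:
        for name in ("compression_only", "inflation_only", "both", "neither"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be nonnegative")

    @property
    def total(self) -> int:
        return self.compression_only + self.inflation_only + self.both + self.neither

    @property
    def any_compression(self) -> int:
        return self.compression_only + self.both

    @property
    def any_inflation(self) -> int:
        return self.inflation_only + self.both

    def percentages(self, decimals: int = 1) -> dict[str, float]:
        total = self.total
        if total == 0:
            raise ValueError("empty cohort")
        out = {
            "compression_only": pct(self.compression_only, total, decimals),
            "inflation_only": pct(self.inflation_only, total, decimals),
            "both": pct(self.both, total, decimals),
            "neither": pct(self.neither, total, decimals),
            "any_compression": pct(self.any_compression, total, decimals),
            "any_inflation": pct(self.any_inflation, total, decimals),
        }
        if self.any_compression > 0:
            out["compression_stretch_insensitive"] = pct(
                self.compression_only, self.any_compression, decimals
            )
            out["compression_also_inflation"] = pct(
                self.both, self.any_compression, decimals
            )
        return out

    def to_dict(self) -> dict:
        return {
            "counts": {
                "compression_only": self.compression_only,
                "inflation_only": self.inflation_only,
                "both": self.both,
                "neither": self.neither,
                "total": self.total,
                "any_compression": self.any_compression,
                "any_inflation": self.any_inflation,
            },
            "percentages": self.percentages(),
        }


def tally_responses(
    flags: Iterable[tuple[bool, bool]] | None = None,
    *,
    counts: Mapping[str, int] | None = None,
) -> TallySummary:
    """Tally a cohort by (compression, inflation) responsiveness.

    Either pass per-ROI boolean pairs ``(responsive_compression,
    responsive_inflation)`` — each ROI then falls in exactly one of the
    four categories — or pre-computed ``counts`` with keys
    ``compression_only``, ``inflation_only``, ``both``, ``neither``.
    """
    if (flags is None) == (counts is None):
        raise ValueError("provide exactly one of flags or counts")
    if counts is not None:
        extra = set(counts) - {"compression_only", "inflation_only", "both", "neither"}
        if extra:
            raise ValueError(f"unexpected count categories: {sorted(extra)}")
        return TallySummary(
            compression_only=int(counts.get("compression_only", 0)),
            inflation_only=int(counts.get("inflation_only", 0)),
            both=int(counts.get("both", 0)),
            neither=int(counts.get("neither", 0)),
        )
    c = {"compression_only": 0, "inflation_only": 0, "both": 0, "neither": 0}
    for comp, infl in flags:
        if comp and infl:
            c["both"] += 1
        elif comp:
            c["compression_only"] += 1
        elif infl:
            c["inflation_only"] += 1
        else:
            c["neither"] += 1
    return TallySummary(**c)


def analyze_session(
    traces: RoiTraceSet,
    epochs: Sequence[StimulusEpoch],
    f0_window_s: float = 20.0,
    response_lag_s: float = 5.0,
    cv_threshold: float = 0.01,
    level_percentile: float = 90.0,
) -> list[ResponseProfile]:
    """Full per-session pipeline: health screen, ΔF/F₀, responsiveness,
    selectivity.  Unhealthy ROIs keep their traces but are flagged and
    left nonresponsive/unclassified."""
    unhealthy = exclude_unhealthy(traces, cv_threshold, level_percentile)
    profiles = ratiometric_dff(traces, epochs, f0_window_s)
    profiles = score_responsiveness(profiles, traces, epochs, response_lag_s)
    labels = {e.label for e in epochs}
    for p in profiles:
        p.excluded_unhealthy = unhealthy.get(p.roi_id, False)
        if p.excluded_unhealthy:
            p.responsive = {lab: False for lab in p.responsive}
            p.selectivity = "nonresponsive"
            p.rc_ri = None
        elif {"compression", "inflation"} <= labels:
            classify_selectivity(p)
    return profiles
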