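"""Gasp/sigh classification and stimulus-aligned reflex metrics.

A gasp (augmented breath) is operationalized by amplitude ratios
against the immediate neighbours: under the anaesthetized rule a breath
is called when its expiratory amplitude exceeds both neighbours by more
than 50%; the plethysmography rule additionally requires the same of
the inspiratory amplitude.  The threshold is strict (a ratio of exactly
1.5 is not a call).  The same amplitude rule detects spontaneous sighs;
an event is typed *gasp* when it falls inside a stimulus observation
window and *sigh* otherwise — context is the only separator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .breath import BreathTable
from .core import StimulusEpoch, sem

logger = logging.getLogger(__name__)

__all__ = [
    "EventCall",
    "ReflexSummary",
    "HeringBreuerResult",
    "classify_events",
    "gasp_frequency",
    "normalize_to_baseline",
    "hering_breuer",
    "latency_to_first_gasp",
    "aggregate_trials",
    "reflex_summary",
]

#: Fractional amplitude increase a gasp must exceed over both neighbours.
EVENT_THRESHOLD = 0.5


@dataclass(frozen=True)
class EventCall:
    """One augmented-breath call with its neighbour amplitude ratios."""

    breath_index: int
    time_s: float
    event_type: str  # gasp | sigh
    exp_ratio_prev: float
    exp_ratio_next: float
    insp_ratio_prev: float
    insp_ratio_next: float
    in_epoch: str = "none"


def _ratio(a: float, b: float) -> float:
    """Amplitude ratio a/b; an event against a silent neighbour is infinite."""
    if b <= 0:
        return float("inf") if a > 0 else 0.0
    return a / b


def classify_events(
    breaths: BreathTable,
    rule: str = "anaesthetized",
    epochs: Sequence[StimulusEpoch] = (),
    threshold: float = EVENT_THRESHOLD,
) -> list[EventCall]:
    """Call gasps/sighs on interior breaths of a table.

    ``rule='anaesthetized'`` uses expiratory amplitude only (pressure or
    EMG-inferred recordings); ``rule='plethysmography'`` requires both
    inspiratory and expiratory amplitudes to exceed the neighbours.  The
    first and last breaths are never callable.  An event whose
    inspiratory onset falls within an epoch's half-open observation
    window ``[start, observation_end)`` is typed ``gasp`` and annotated
    with that epoch's label; events outside all windows are ``sigh``.
    """
    if rule not in ("anaesthetized", "plethysmography"):
        raise ValueError("rule must be 'anaesthetized' or 'plethysmography'")
    if len(breaths) < 3:
        logger.warning("fewer than 3 breaths; no events callable")
        return []
    lim = 1.0 + threshold
    calls: list[EventCall] = []
    for i in range(1, len(breaths) - 1):
        prev_b, b, next_b = breaths[i - 1], breaths[i], breaths[i + 1]
        erp = _ratio(b.exp_amplitude, prev_b.exp_amplitude)
        ern = _ratio(b.exp_amplitude, next_b.exp_amplitude)
        irp = _ratio(b.insp_amplitude, prev_b.insp_amplitude)
        irn = _ratio(b.insp_amplitude, next_b.insp_amplitude)
        hit = erp > lim and ern > lim
        if rule == "plethysmography":
            hit = hit and irp > lim and irn > lim
        if not hit:
            continue
        label = "none"
        for e in epochs:
            if e.contains(b.insp_onset_s, through_observation=True):
                label = e.label
                break
        calls.append(
            EventCall(
                breath_index=b.index,
                time_s=b.insp_onset_s,
                event_type="gasp" if label != "none" else "sigh",
                exp_ratio_prev=erp,
                exp_ratio_next=ern,
                insp_ratio_prev=irp,
                insp_ratio_next=irn,
                in_epoch=label,
            )
        )
    return calls


def gasp_frequency(
    events: Iterable[EventCall],
    epoch: StimulusEpoch,
    denominator: str = "observation_window",
) -> float:
    """Gasps per minute over the chosen half-open window.

    ``observation_window`` counts over ``[start, observation_end)``
    (e.g. the 5-min monitoring after a nebulized stimulus);
    ``stimulus_window`` counts over the stimulus itself, as used for
    gasps per minute of optogenetic illumination.
    """
    if denominator == "observation_window":
        end = epoch.observation_end_s
    elif denominator == "stimulus_window":
        end = epoch.end_s
    else:
        raise ValueError("denominator must be 'observation_window' or 'stimulus_window'")
    length_min = (end - epoch.start_s) / 60.0
    if length_min <= 0:
        raise ValueError("window has zero length")
    n = sum(
        1
        for ev in events
        if ev.event_type == "gasp" and epoch.start_s <= ev.time_s < end
    )
    return n / length_min


def normalize_to_baseline(
    times_s: Sequence[float],
    values: Sequence[float],
    epoch: StimulusEpoch,
    baseline_window_s: float = 10.0,
) -> np.ndarray:
    """Divide a per-breath feature series by its pre-stimulus baseline.

    The baseline is the mean of values whose times fall in the half-open
    window ``[start - baseline_window_s, start)`` immediately before
    stimulus introduction.
    """
    t = np.asarray(times_s, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise ValueError("times and values must have the same length")
    mask = (t >= epoch.start_s - baseline_window_s) & (t < epoch.start_s)
    if not mask.any():
        raise ValueError(
            f"no samples in the {baseline_window_s} s baseline before "
            f"stimulus at {epoch.start_s} s"
        )
    baseline = float(v[mask].mean())
    if baseline == 0:
        raise ValueError("baseline mean is zero; cannot normalize")
    return v / baseline


@dataclass(frozen=True)
class HeringBreuerResult:
    """Inflation-evoked breathing-rate suppression (Hering-Breuer reflex)."""

    baseline_rate_bpm: float
    inflation_rate_bpm: float
    normalized_rate: float
    inflation_flow_setting: Optional[float] = None  # ml/min/g body weight


def _count_rate_bpm(breaths: BreathTable, start: float, end: float) -> float:
    """Breathing rate from breath count over a half-open window."""
    n = sum(1 for b in breaths if start <= b.insp_onset_s < end)
    return 60.0 * n / (end - start)


def hering_breuer(
    breaths: BreathTable,
    inflation_epoch: StimulusEpoch,
    baseline_window: tuple[float, float] | None = None,
) -> HeringBreuerResult:
    """Rate during lung inflation relative to the pre-inflation baseline.

    The baseline defaults to the 10 s immediately before inflation (the
    same convention as stimulus-evoked breathing normalization).  Rates
    are breath counts divided by window length, so complete apnoea
    during inflation gives a normalized rate of exactly 0.
    """
    if baseline_window is None:
        baseline_window = (inflation_epoch.start_s - 10.0, inflation_epoch.start_s)
    b0, b1 = baseline_window
    if not b0 < b1 <= inflation_epoch.start_s:
        raise ValueError("baseline window must precede the inflation epoch")
    baseline_rate = _count_rate_bpm(breaths, b0, b1)
    if baseline_rate == 0:
        raise ValueError("no breaths in the baseline window")
    infl_rate = _count_rate_bpm(breaths, inflation_epoch.start_s, inflation_epoch.end_s)
    return HeringBreuerResult(
        baseline_rate_bpm=baseline_rate,
        inflation_rate_bpm=infl_rate,
        normalized_rate=infl_rate / baseline_rate,
        inflation_flow_setting=inflation_epoch.meta.get("flow_ml_min_g"),
    )


def latency_to_first_gasp(
    events: Iterable[EventCall], epoch: StimulusEpoch
) -> Optional[float]:
    """Seconds from stimulus onset to the first gasp in the observation
    window, or ``None`` if no gasp occurred."""
    times = [
        ev.time_s
        for ev in events
        if ev.event_type == "gasp"
        and epoch.start_s <= ev.time_s < epoch.observation_end_s
    ]
    if not times:
        return None
    return min(times) - epoch.start_s


@dataclass(frozen=True)
class ReflexSummary:
    """Per-trial reflex metrics for one stimulus epoch."""

    gasps_per_min: float
    latency_to_first_gasp_s: Optional[float]
    window: tuple[float, float]


def reflex_summary(
    events: Iterable[EventCall],
    epoch: StimulusEpoch,
    denominator: str = "observation_window",
) -> ReflexSummary:
    events = list(events)
    end = (
        epoch.observation_end_s if denominator == "observation_window" else epoch.end_s
    )
    return ReflexSummary(
        gasps_per_min=gasp_frequency(events, epoch, denominator),
        latency_to_first_gasp_s=latency_to_first_gasp(events, epoch),
        window=(epoch.start_s, end),
    )


def aggregate_trials(
    per_animal_trials: Mapping[str, Sequence[float]],
) -> dict:
    """Per-animal trial means, then group mean +/- s.e.m. over animals.

    Figure-style aggregation: each animal contributes the average of its
    trials (typically three); the group statistic is the mean of animal
    means with s.e.m. = sample s.d. / sqrt(n_animals).
    """
    if not per_animal_trials:
        raise ValueError("no animals to aggregate")
    animal_means = {}
    for animal, trials in per_animal_trials.items():
        trials = list(trials)
        if not trials:
            raise ValueError(f"animal {animal!r} has no trials")
        animal_means[animal] = float(np.mean(trials))
    means = list(animal_means.values())
    return {
        "animal_means": animal_means,
        "group_mean": float(np.mean(means)),
        "group_sem": sem(means),
        "n_animals": len(means),
    }
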