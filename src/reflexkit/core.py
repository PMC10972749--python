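"""Core data containers shared across the toolkit.

A :class:`SampledTrace` is a uniformly sampled 1-D physiological signal
(tracheal/oesophageal pressure, pneumotachograph flow, multiunit nerve
activity, EMG, or fluorescence). A :class:`StimulusEpoch` is a labelled
time interval describing an applied airway challenge together with the
observation window over which reflexes are scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Any, Iterable, Sequence

import numpy as np

TRACE_KINDS = ("pressure", "flow", "nerve", "emg", "fluorescence")

EPOCH_LABELS = (
    "compression",
    "suction_low",
    "suction_high",
    "inflation",
    "methacholine",
    "citric_acid",
    "gas",
    "illumination",
    "cno",
    "serotonin",
    "none",
)


@dataclass(frozen=True)
class SampledTrace:
    """Uniformly sampled 1-D signal.

    Parameters
    ----------
    values
        Signal samples. cmH2O for pressure, ml/s for flow, arbitrary
        units for nerve/EMG/fluorescence.
    sampling_rate_hz
        Sampling rate in Hz; must be positive.
    t0_s
        Time of the first sample in seconds.
    kind
        One of ``pressure``, ``flow``, ``nerve``, ``emg``,
        ``fluorescence``.
    """

    values: np.ndarray
    sampling_rate_hz: float
    t0_s: float = 0.0
    kind: str = "pressure"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if not np.all(np.isfinite(values)):
            raise ValueError("trace values must be finite")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.kind not in TRACE_KINDS:
            raise ValueError(
                f"unknown trace kind {self.kind!r}; expected one of {TRACE_KINDS}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        """Sample times in seconds (first sample at ``t0_s``)."""
        return self.t0_s + np.arange(self.n_samples) / self.sampling_rate_hz

    def index_at(self, t_s: float) -> int:
        """Index of the first sample at or after time ``t_s`` (clipped)."""
        idx = int(np.ceil((t_s - self.t0_s) * self.sampling_rate_hz - 1e-9))
        return int(np.clip(idx, 0, self.n_samples))

    def slice_window(self, start_s: float, end_s: float) -> np.ndarray:
        """Samples in the half-open time window ``[start_s, end_s)``."""
        return self.values[self.index_at(start_s) : self.index_at(end_s)]


@dataclass(frozen=True)
class StimulusEpoch:
    """Labelled stimulus interval with an observation window.

    ``[start_s, end_s)`` is the stimulus delivery itself;
    ``[start_s, observation_end_s)`` is the span over which evoked
    reflexes are scored (for nebulized stimuli the paper-style protocol
    keeps monitoring for 5 min after delivery).
    """

    label: str
    start_s: float
    end_s: float
    observation_end_s: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in EPOCH_LABELS:
            raise ValueError(
                f"unknown epoch label {self.label!r}; expected one of {EPOCH_LABELS}"
            )
        obs = self.observation_end_s
        if obs is None:
            object.__setattr__(self, "observation_end_s", float(self.end_s))
            obs = float(self.end_s)
        if not (self.start_s < self.end_s <= obs):
            raise ValueError(
                "epoch must satisfy start_s < end_s <= observation_end_s "
                f"(got {self.start_s}, {self.end_s}, {obs})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def observation_duration_s(self) -> float:
        return self.observation_end_s - self.start_s

    def contains(self, t_s: float, through_observation: bool = True) -> bool:
        """Whether ``t_s`` falls in the (half-open) epoch window."""
        end = self.observation_end_s if through_observation else self.end_s
        return self.start_s <= t_s < end

    def to_dict(self) -> dict[str, Any]:
        return {
            "label": self.label,
            "start_s": self.start_s,
            "end_s": self.end_s,
            "observation_end_s": self.observation_end_s,
            "meta": dict(self.meta),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StimulusEpoch":
        return cls(
            label=d["label"],
            start_s=float(d["start_s"]),
            end_s=float(d["end_s"]),
            observation_end_s=(
                float(d["observation_end_s"])
                if d.get("observation_end_s") is not None
                else None
            ),
            meta=dict(d.get("meta", {})),
        )


def epochs_to_json(epochs: Iterable[StimulusEpoch]) -> str:
    return json.dumps([e.to_dict() for e in epochs], indent=2)


def epochs_from_json(text: str) -> list[StimulusEpoch]:
    return [StimulusEpoch.from_dict(d) for d in json.loads(text)]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero at the given decimal place.

    Cohort percentages are conventionally printed with half-up rounding
    (e.g. 25/495 -> 5.1%), which differs from banker's rounding at exact
    ties.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: float, total: float, decimals: int = 1) -> float:
    """Percentage ``100 * count / total`` rounded half-up.

    ``decimals=0`` returns a whole-number percentage as a float.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, decimals)


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean: sample s.d. (ddof=1) / sqrt(n)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("sem of empty sequence")
    if arr.size == 1:
        return 0.0
    return float(np.std(arr, ddof=1) / np.sqrt(arr.size))
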