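"""File formats, run configuration and summary reporting.

Conventions used throughout the package:

* all time windows are half-open ``[start, end)``;
* sample indexing is 0-based;
* traces travel as two-column CSV with header ``time_s,value``;
* breath tables and ROI matrices travel as CSV, epochs/ground
  truth/configs/reports as JSON;
* cohort percentages are rounded half-up (1 decimal by default).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .breath import BreathTable
from .core import SampledTrace, StimulusEpoch

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "parse_trace_csv",
    "write_trace_csv",
    "read_breath_table_csv",
    "write_breath_table_csv",
    "read_epochs_json",
    "write_epochs_json",
    "read_roi_matrix_csv",
    "write_roi_matrix_csv",
    "read_stack_tiff",
    "write_stack_tiff",
    "write_summary",
]


@dataclass
class RunConfig:
    """Every analysis threshold and window, with study defaults.

    The defaults reproduce the stated quantification constants: the
    >50% augmented-breath amplitude rule, the 3-s.d. responsiveness
    criterion, Rc/Ri selectivity bounds of 2 and 0.5, a 20-s F0 window,
    a 10-s pre-stimulus breathing baseline, eupneic bounds (0.05-2 ml
    tidal volume, 400 BPM), the 0.02-s integrator time constant and the
    100-s serotonin reference window.
    """

    event_threshold: float = 0.5  # fractional amplitude increase for a call
    responsiveness_sd: float = 3.0
    rc_ri_upper: float = 2.0
    rc_ri_lower: float = 0.5
    f0_window_s: float = 20.0
    baseline_window_s: float = 10.0
    tv_max_ml: float = 2.0
    tv_min_ml: float = 0.05
    bpm_max: float = 400.0
    integrator_tau_s: float = 0.02
    serotonin_window_s: float = 100.0
    nerve_baseline_s: float = 60.0
    response_lag_s: float = 5.0
    smoothing_window_s: float = 0.02
    unhealthy_cv_threshold: float = 0.01
    unhealthy_level_percentile: float = 90.0
    percent_decimals: int = 1
    rounding: str = "half_up"
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**dict(d))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))

    def updated(self, **overrides: Any) -> "RunConfig":
        """New config with the given fields replaced (CLI > file > defaults)."""
        return dataclasses.replace(self, **overrides)


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------


def parse_trace_csv(
    path: str | Path, kind: str = "pressure", uniformity_tol: float = 0.01
) -> SampledTrace:
    """Read a two-column ``time_s,value`` CSV into a trace.

    The sampling rate is inferred from the median time step; any step
    deviating from it by more than ``uniformity_tol`` (1%) is a
    non-uniform-sampling error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if list(df.columns[:2]) != ["time_s", "value"]:
        raise ValueError(
            f"{path}: expected header 'time_s,value', got {list(df.columns[:2])}"
        )
    for col in ("time_s", "value"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: non-numeric rows in column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    dt = float(np.median(steps))
    if np.max(np.abs(steps - dt)) > uniformity_tol * dt:
        raise ValueError(
            f"{path}: non-uniform sampling (max step deviation exceeds "
            f"{100 * uniformity_tol:.0f}% of the median step {dt:g} s)"
        )
    return SampledTrace(
        values=df["value"].to_numpy(dtype=float),
        sampling_rate_hz=1.0 / dt,
        t0_s=float(t[0]),
        kind=kind,
    )


def write_trace_csv(trace: SampledTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": trace.times_s, "value": trace.values})
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Breath tables, epochs, ROI matrices
# ---------------------------------------------------------------------------


def write_breath_table_csv(table: BreathTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_breath_table_csv(
    path: str | Path, kind: str = "pressure"
) -> BreathTable:
    return BreathTable.from_dataframe(pd.read_csv(path), source=str(path), kind=kind)


def write_epochs_json(epochs: list[StimulusEpoch], path: str | Path) -> None:
    Path(path).write_text(json.dumps([e.to_dict() for e in epochs], indent=2))


def read_epochs_json(path: str | Path) -> list[StimulusEpoch]:
    return [StimulusEpoch.from_dict(d) for d in json.loads(Path(path).read_text())]


def write_roi_matrix_csv(matrix: np.ndarray, roi_ids: list[int], path: str | Path) -> None:
    """ROI x time matrix as CSV: one row per ROI, first column ``roi_id``."""
    df = pd.DataFrame(np.asarray(matrix))
    df.insert(0, "roi_id", roi_ids)
    df.to_csv(path, index=False)


def read_roi_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[int]]:
    df = pd.read_csv(path)
    if "roi_id" not in df.columns:
        raise ValueError(f"{path}: expected a 'roi_id' first column")
    roi_ids = df["roi_id"].astype(int).tolist()
    return df.drop(columns=["roi_id"]).to_numpy(dtype=float), roi_ids


def write_stack_tiff(
    stack: Mapping[str, np.ndarray], path: str | Path, sampling_rate_hz: float
) -> None:
    """Two-channel stack as multi-frame TIFF plus a JSON sidecar giving
    channel order and frame rate."""
    import tifffile

    path = Path(path)
    channels = sorted(stack)
    arr = np.stack([np.asarray(stack[c], dtype=np.float32) for c in channels], axis=1)
    tifffile.imwrite(path, arr)  # (frames, channels, rows, cols)
    sidecar = {"channels": channels, "sampling_rate_hz": sampling_rate_hz}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_stack_tiff(path: str | Path) -> tuple[dict[str, np.ndarray], float]:
    import tifffile

    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise ValueError(f"missing channel sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    arr = tifffile.imread(path)
    channels = sidecar["channels"]
    stack = {c: np.asarray(arr[:, i], dtype=float) for i, c in enumerate(channels)}
    return stack, float(sidecar["sampling_rate_hz"])


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    return obj


def write_summary(
    results: Mapping[str, Any] | pd.DataFrame,
    path: str | Path,
    fmt: str = "json",
    config: RunConfig | None = None,
) -> Path:
    """Write analysis results deterministically as CSV or JSON.

    JSON output embeds the full :class:`RunConfig` for provenance; keys
    are sorted so identical inputs produce byte-identical files.  CSV
    output writes one table with a fixed column order (an empty result
    set yields a header-only file).
    """
    path = Path(path)
    if fmt == "json":
        payload = {
            "config": (config or RunConfig()).to_dict(),
            "results": _jsonable(dict(results)),
        }
        path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
    elif fmt == "csv":
        if isinstance(results, pd.DataFrame):
            df = results
        else:
            flat = _jsonable(dict(results))
            df = pd.DataFrame([flat]) if flat else pd.DataFrame()
        df.to_csv(path, index=False)
    else:
        raise ValueError("fmt must be 'json' or 'csv'")
    return path
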