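"""Line-scan recordings and their reduction to fluorescence traces.

A recording is a 2-D intensity array (lines x pixels).  The analysis path is
the one used for the confocal data: average each line over the spatial axis
to obtain mean intensity versus time, smooth with a 6th-order local
polynomial over 10 neighbours on each side (Savitzky-Golay, window 21), and
normalize to the resting baseline F0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
from scipy.signal import savgol_filter

__all__ = [
    "LineScanRecording",
    "FluorescenceTrace",
    "read_linescan",
    "write_linescan",
    "extract_trace",
    "smooth_trace",
    "normalize_f0",
    "write_trace_csv",
    "read_trace_csv",
]


@dataclass
class LineScanRecording:
    """2-D line-scan fluorescence intensity with acquisition metadata.

    ``intensity`` has shape (n_lines, n_pixels); row t was scanned at time
    ``t / line_rate_hz``.
    """

    intensity: np.ndarray
    line_rate_hz: float
    pixel_size_um: float = float("nan")
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError(
                f"line-scan intensity must be 2-D (lines x pixels), "
                f"got {self.intensity.ndim}-D"
            )
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if not self.line_rate_hz or self.line_rate_hz <= 0:
            raise ValueError("line_rate_hz must be positive (time axis undefined)")

    @property
    def n_lines(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.intensity.shape[1]


@dataclass
class FluorescenceTrace:
    """Uniformly sampled fluorescence versus time.

    ``value`` is in arbitrary F units, or F/F0 when ``normalized`` is set
    (``f0`` then records the baseline used).
    """

    time_s: np.ndarray
    value: np.ndarray
    normalized: bool = False
    f0: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_s.shape != self.value.shape or self.time_s.ndim != 1:
            raise ValueError("time_s and value must be equal-length 1-D arrays")
        if self.time_s.size >= 2:
            steps = np.diff(self.time_s)
            if np.any(steps <= 0):
                raise ValueError("time_s must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("time grid must be uniform")
        if self.normalized and (self.f0 is None or self.f0 <= 0):
            raise ValueError("normalized trace requires the positive f0 used")

    @property
    def dt(self) -> float:
        if self.time_s.size < 2:
            raise ValueError("trace too short to define dt")
        return float(self.time_s[1] - self.time_s[0])

    def __len__(self) -> int:
        return self.value.size


# ---------------------------------------------------------------------------
# I/O: single-page grayscale TIFF or CSV, with a JSON metadata sidecar

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_linescan(rec: LineScanRecording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording as TIFF (rows = lines) or CSV plus a JSON sidecar."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "tiff")
    if fmt == "tiff":
        tifffile.imwrite(path, rec.intensity.astype(np.float64), photometric="minisblack")
    elif fmt == "csv":
        np.savetxt(path, rec.intensity, delimiter=",")
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    sidecar = {
        "line_rate_hz": rec.line_rate_hz,
        "pixel_size_um": rec.pixel_size_um,
        "metadata": rec.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, default=float))
    return path


def read_linescan(
    path: str | Path,
    format: str | None = None,
    line_rate_hz: float | None = None,
    pixel_size_um: float | None = None,
) -> LineScanRecording:
    """Read a recording written by :func:`write_linescan`.

    Acquisition metadata comes from the JSON sidecar; ``line_rate_hz`` /
    ``pixel_size_um`` arguments override it (and are required if there is no
    sidecar).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "tiff")
    if fmt == "tiff":
        arr = np.asarray(tifffile.imread(path), dtype=float)
    elif fmt == "csv":
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    if arr.ndim != 2:
        raise ValueError(
            f"expected a single-page 2-D line-scan image, got shape {arr.shape}"
        )
    meta: dict[str, Any] = {}
    rate = line_rate_hz
    px = pixel_size_um
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        rate = rate if rate is not None else info.get("line_rate_hz")
        px = px if px is not None else info.get("pixel_size_um")
        meta = info.get("metadata", {})
    if rate is None:
        raise ValueError("line_rate_hz missing: supply it or provide a sidecar")
    return LineScanRecording(
        intensity=arr,
        line_rate_hz=float(rate),
        pixel_size_um=float(px) if px is not None else float("nan"),
        metadata=meta,
    )


def write_trace_csv(trace: FluorescenceTrace, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([trace.time_s, trace.value]),
        delimiter=",",
        header="time_s,value",
        comments="",
    )
    return path


def read_trace_csv(path: str | Path, normalized: bool = False, f0: float | None = None) -> FluorescenceTrace:
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return FluorescenceTrace(arr[:, 0], arr[:, 1], normalized=normalized, f0=f0)


# ---------------------------------------------------------------------------
# Trace operations

def extract_trace(rec: LineScanRecording) -> FluorescenceTrace:
    """Mean signal intensity as a function of time (mean over the pixel axis)."""
    value = rec.intensity.mean(axis=1)
    time_s = np.arange(rec.n_lines) / rec.line_rate_hz
    return FluorescenceTrace(time_s=time_s, value=value)


def smooth_trace(trace: FluorescenceTrace, order: int = 6, neighbors: int = 10) -> FluorescenceTrace:
    """Local least-squares polynomial smoothing (Savitzky-Golay).

    A polynomial of degree ``order`` is fitted over a centred window of
    ``2*neighbors + 1`` samples.  Edges are handled by evaluating the
    polynomial fitted to the nearest full window (``mode='interp'``), so the
    trace length and time grid are unchanged.
    """
    window = 2 * neighbors + 1
    if order >= window:
        raise ValueError(
            f"polynomial order {order} must be below the window size {window}"
        )
    if len(trace) < window:
        raise ValueError(f"trace length {len(trace)} shorter than window {window}")
    smoothed = savgol_filter(trace.value, window_length=window, polyorder=order, mode="interp")
    return replace(trace, value=smoothed)


def normalize_f0(trace: FluorescenceTrace, f0: float) -> FluorescenceTrace:
    """Divide by the resting baseline F0, yielding an F/F0 trace."""
    if trace.normalized:
        raise ValueError("trace is already normalized")
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    return FluorescenceTrace(
        time_s=trace.time_s,
        value=trace.value / f0,
        normalized=True,
        f0=float(f0),
    )
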