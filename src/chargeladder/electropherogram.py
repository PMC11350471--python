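"""Electropherogram traces: I/O, peak detection, rung assignment.

A trace is a uniformly sampled detector signal versus migration time from a
single capillary-electrophoresis run. Peak detection works on a smoothed,
baseline-corrected copy of the signal; peak positions are then refined on
the raw baseline-corrected signal so that noiseless Gaussian peaks are
located to machine precision. Ladder rungs Ac(0), Ac(1), ... are assigned
relative to the neutral EOF (electroosmotic flow) marker, by default the
earliest-eluting peak (anionic proteins migrate after the marker).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks, peak_widths

__all__ = [
    "Trace",
    "Peak",
    "RungAssignment",
    "read_trace",
    "write_trace",
    "detect_peaks",
    "assign_rungs",
]


class TraceParseError(ValueError):
    """Raised when a trace file is malformed; carries the offending line."""


@dataclass
class Trace:
    """Time series of detector signal with run metadata."""

    time_min: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_min.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if self.time_min.size < 10:
            raise ValueError("trace must have at least 10 samples")
        if not (np.all(np.isfinite(self.time_min)) and np.all(np.isfinite(self.signal))):
            raise ValueError("trace contains non-finite values")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time_min)))


@dataclass(frozen=True)
class Peak:
    """One detected peak (heights/areas are baseline-corrected)."""

    centroid_min: float
    apex_min: float
    height: float
    area: float
    width_min: float

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("peak height must be positive")
        if self.width_min <= 0:
            raise ValueError("peak width must be positive")


@dataclass(frozen=True)
class RungAssignment:
    """EOF marker plus ladder rungs keyed by acetylation number N."""

    eof_peak: Peak
    rungs: tuple[tuple[int, Peak], ...]
    dropped: tuple[Peak, ...] = ()

    def __post_init__(self) -> None:
        ns = [n for n, _ in self.rungs]
        if ns != list(range(len(ns))):
            raise ValueError("rung numbers must be consecutive from 0")
        sides = {p.centroid_min > self.eof_peak.centroid_min for _, p in self.rungs}
        if len(sides) > 1:
            raise ValueError("rungs straddle the EOF marker")


# -- I/O ------------------------------------------------------------------


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as CSV with '#'-prefixed key=value metadata header."""
    with open(path, "w") as fh:
        for key, value in trace.metadata.items():
            fh.write(f"# {key}={value}\n")
        fh.write("time_min,signal\n")
        for t, s in zip(trace.time_min, trace.signal):
            fh.write(f"{float(t)!r},{float(s)!r}\n")


def read_trace(path: str | Path) -> Trace:
    """Read a trace CSV written by :func:`write_trace` (metadata optional)."""
    metadata: dict = {}
    times: list[float] = []
    signals: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, value = body.split("=", 1)
                    metadata[key.strip()] = _coerce(value.strip())
                continue
            if line.lower().replace(" ", "").startswith("time_min,"):
                continue
            parts = line.split(",")
            try:
                t, s = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as exc:
                raise TraceParseError(f"{path}: non-numeric row at line {lineno}: {line!r}") from exc
            times.append(t)
            signals.append(s)
    t_arr = np.array(times)
    if t_arr.size >= 2 and np.any(np.diff(t_arr) <= 0):
        bad = int(np.argmax(np.diff(t_arr) <= 0)) + 2
        raise TraceParseError(f"{path}: time not strictly increasing at data row {bad}")
    return Trace(t_arr, np.array(signals), metadata)


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


# -- peak detection -------------------------------------------------------


def _gaussian_centroid(t: np.ndarray, y: np.ndarray) -> float | None:
    """Peak centre by weighted log-quadratic (Caruana/Guo) interpolation.

    Fits log(y) = a t^2 + b t + c with weights y^2 over the above-half-height
    region; exact for a sampled Gaussian, robust in moderate noise. Returns
    None when the region is too small or the curvature is non-negative.
    """
    if t.size < 4 or np.any(y <= 0):
        return None
    logy = np.log(y)
    w = y * y
    # weighted quadratic least squares, centred for conditioning
    t0 = t.mean()
    x = t - t0
    A = np.stack([x * x, x, np.ones_like(x)], axis=1)
    Aw = A * w[:, None]
    try:
        coef, *_ = np.linalg.lstsq(Aw, logy * w, rcond=None)
    except np.linalg.LinAlgError:
        return None
    a, b, _ = coef
    if a >= 0:
        return None
    return float(t0 - b / (2.0 * a))


def detect_peaks(
    trace: Trace,
    min_height: float = 0.05,
    min_separation_min: float | None = None,
    smooth_window_points: int = 5,
    baseline_window_min: float | None = None,
) -> list[Peak]:
    """Detect peaks in a trace.

    Pipeline: moving-average smoothing (``smooth_window_points``) →
    baseline estimate by rolling minimum over ``baseline_window_min``
    (default: at least five median peak widths, estimated in a first pass) →
    local maxima above ``min_height`` (fraction of the corrected maximum),
    separated by at least ``min_separation_min`` (default: twice the median
    peak width) → per-peak centroid by Gaussian interpolation over the
    above-half-height region of the raw corrected signal, falling back to
    the intensity-weighted mean. Peaks are returned in time order.
    """
    if min_height <= 0 or smooth_window_points <= 0:
        raise ValueError("detection parameters must be positive")
    n = trace.signal.size
    if n < smooth_window_points:
        raise ValueError("trace shorter than smoothing window")
    dt = trace.dt
    smoothed = uniform_filter1d(trace.signal, size=smooth_window_points, mode="nearest")

    # first pass with generous defaults to size the baseline/separation windows
    width_pts = _median_peak_width_pts(smoothed)
    if baseline_window_min is None:
        baseline_pts = max(int(round(5 * width_pts)), 25)
    else:
        baseline_pts = max(int(round(baseline_window_min / dt)), 3)
    baseline = minimum_filter1d(smoothed, size=min(baseline_pts, n), mode="nearest")
    corrected = smoothed - baseline
    top = corrected.max()
    if top <= 0:
        return []
    if min_separation_min is None:
        # two median Gaussian sigmas (FWHM/2.355): wide enough to reject
        # within-peak noise maxima, narrow enough to keep adjacent rungs
        distance = max(int(round(2 * width_pts / 2.355)), 1)
    else:
        distance = max(int(round(min_separation_min / dt)), 1)
    idx, _ = find_peaks(corrected, height=min_height * top, distance=distance)
    if idx.size == 0:
        return []

    raw_corrected = trace.signal - baseline
    peaks = []
    for i in idx:
        peaks.append(_measure_peak(trace.time_min, raw_corrected, int(i), dt))
    return sorted(peaks, key=lambda p: p.centroid_min)


def _median_peak_width_pts(smoothed: np.ndarray) -> float:
    """Median FWHM (in samples) of prominent maxima; coarse, first-pass.

    Works on a coarsely baseline-corrected copy and only considers peaks
    with at least 25 % of the corrected maximum, so that detector noise and
    baseline drift cannot drag the width estimate down.
    """
    n = smoothed.size
    coarse = smoothed - minimum_filter1d(smoothed, size=max(n // 10, 3), mode="nearest")
    top = coarse.max()
    if top <= 0:
        return 5.0
    idx, _ = find_peaks(coarse, height=0.25 * top)
    if idx.size == 0:
        return 5.0
    widths = peak_widths(coarse, idx, rel_height=0.5)[0]
    return float(np.median(widths)) if widths.size else 5.0


def _measure_peak(time: np.ndarray, corrected: np.ndarray, apex_idx: int, dt: float) -> Peak:
    """Measure one peak from the raw baseline-corrected signal."""
    height = float(corrected[apex_idx])
    half = height / 2.0
    lo = apex_idx
    while lo > 0 and corrected[lo - 1] > half:
        lo -= 1
    hi = apex_idx
    while hi < corrected.size - 1 and corrected[hi + 1] > half:
        hi += 1
    region = slice(lo, hi + 1)
    t_reg = time[region]
    y_reg = corrected[region]
    centroid = _gaussian_centroid(t_reg, y_reg)
    if centroid is None:
        centroid = float(np.sum(t_reg * y_reg) / np.sum(y_reg))
    fwhm = (hi - lo + 1) * dt
    # integrate over a wider window (out to ~2 FWHM each side, bounded by zeros)
    wlo = max(0, lo - 2 * (hi - lo + 1))
    whi = min(corrected.size - 1, hi + 2 * (hi - lo + 1))
    area = float(np.trapezoid(np.clip(corrected[wlo : whi + 1], 0, None), time[wlo : whi + 1]))
    return Peak(
        centroid_min=float(centroid),
        apex_min=float(time[apex_idx]),
        height=height,
        area=area,
        width_min=float(fwhm),
    )


# -- rung assignment ------------------------------------------------------

MarkerRule = Callable[[Sequence[Peak]], Peak]

_MARKER_RULES: dict[str, MarkerRule] = {
    "earliest": lambda peaks: min(peaks, key=lambda p: p.centroid_min),
    "tallest": lambda peaks: max(peaks, key=lambda p: p.height),
}


def assign_rungs(
    peaks: Sequence[Peak],
    expected_n_rungs: int,
    marker_rule: str | MarkerRule = "earliest",
) -> RungAssignment:
    """Assign the EOF marker and ladder rungs N = 0..expected_n_rungs-1.

    Under the anionic convention the neutral marker elutes first and the
    ladder follows in elution order (more acetylations → more negative →
    later). Extra peaks beyond ``expected_n_rungs`` are dropped and returned
    in ``dropped``.
    """
    if expected_n_rungs < 1:
        raise ValueError("expected_n_rungs must be positive")
    if len(peaks) < expected_n_rungs + 1:
        raise ValueError(
            f"need at least {expected_n_rungs + 1} peaks (marker + {expected_n_rungs} rungs), "
            f"got {len(peaks)}: short by {expected_n_rungs + 1 - len(peaks)}"
        )
    rule = _MARKER_RULES[marker_rule] if isinstance(marker_rule, str) else marker_rule
    marker = rule(peaks)
    rest = sorted((p for p in peaks if p is not marker), key=lambda p: p.centroid_min)
    after = [p for p in rest if p.centroid_min > marker.centroid_min]
    if len(after) < expected_n_rungs:
        raise ValueError(
            f"only {len(after)} peaks elute after the EOF marker; "
            f"expected {expected_n_rungs} rungs"
        )
    kept = after[:expected_n_rungs]
    dropped = tuple(after[expected_n_rungs:])
    return RungAssignment(
        eof_peak=marker,
        rungs=tuple((n, p) for n, p in enumerate(kept)),
        dropped=dropped,
    )
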