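"""FRAP (fluorescence recovery after photobleaching) quantification.

A trace is normalised to the mean of one or two pre-bleach baseline
frames, split into per-bleach segments, and each segment is summarised by
its bleach floor, maximum recovered fraction, mobile fraction, and the
half-time of maximum recovery: the first time the trace reaches 50% of the
maximum fluorescence recovered above the bleach floor, linearly
interpolated between frames.  The per-segment reference is the baseline
for the first bleach and the last pre-bleach sample for later bleaches, so
that a fully mobile remainder recovers to a fraction of 1 after a second
bleach.  An optional single-exponential fit cross-checks the
nonparametric half-time (t_half ~ ln 2 / k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class FRAPTrace:
    """ROI intensity vs time, with optional declared bleach frames."""

    times_s: np.ndarray
    intensities: np.ndarray
    bleach_frames: tuple[int, ...] | None = None
    n_baseline_frames: int = 2
    baseline_mean: float | None = None  # set by normalize_trace

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_s.shape != self.intensities.shape:
            raise ValueError("times and intensities must have the same length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n_baseline_frames not in (1, 2):
            raise ValueError("n_baseline_frames must be 1 or 2")


@dataclass
class Segment:
    """One post-bleach stretch: [bleach frame, next bleach or end)."""

    start: int
    stop: int  # exclusive
    pre_bleach_reference: float
    times_s: np.ndarray
    values: np.ndarray


@dataclass
class ExponentialFit:
    k_per_s: float
    amplitude: float
    floor: float
    rss: float
    converged: bool

    @property
    def t_half_s(self) -> float:
        return math.log(2.0) / self.k_per_s if self.k_per_s > 0 else math.nan

    @property
    def plateau(self) -> float:
        return self.floor + self.amplitude


@dataclass
class FRAPResult:
    """Per-segment recovery metrics."""

    segment_index: int
    pre_bleach_reference: float
    bleach_floor: float
    max_recovered: float
    max_recovered_fraction: float
    final_fraction: float
    recovered_amplitude: float
    mobile_fraction: float
    t_half_s: float | None
    t_half_frame_s: float | None
    flags: list[str] = field(default_factory=list)
    exponential_fit: ExponentialFit | None = None


def normalize_trace(trace: FRAPTrace) -> FRAPTrace:
    """Divide by the mean of the declared pre-bleach baseline frames."""
    nb = trace.n_baseline_frames
    if trace.bleach_frames is not None and trace.bleach_frames[0] < nb:
        raise ValueError("baseline frames must precede the first bleach")
    baseline = float(np.mean(trace.intensities[:nb]))
    if baseline <= 0:
        raise ValueError(f"baseline mean must be positive, got {baseline}")
    return replace(
        trace,
        intensities=trace.intensities / baseline,
        baseline_mean=baseline,
    )


def detect_bleach_frames(trace: FRAPTrace, max_bleaches: int = 2, sd_factor: float = 3.0) -> tuple[int, ...]:
    """Auto-detect bleach frames as the largest single-frame drops.

    A drop qualifies when it exceeds ``sd_factor`` times a robust estimate
    (1.4826 * MAD) of the frame-to-frame variation; up to ``max_bleaches``
    of the largest qualifying drops are returned in time order.
    """
    x = trace.intensities
    diffs = np.diff(x)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    local_sd = 1.4826 * mad
    drops = -diffs
    threshold = max(sd_factor * local_sd, 1e-12)
    candidates = np.flatnonzero(drops > threshold)
    if candidates.size == 0:
        raise ValueError(
            "no bleach step detected: no single-frame drop exceeds "
            f"{sd_factor}x the local sd ({local_sd:.3g})"
        )
    largest = candidates[np.argsort(drops[candidates])[::-1][:max_bleaches]]
    return tuple(sorted(int(i) + 1 for i in largest))  # frame *after* the drop


def segment_bleaches(trace: FRAPTrace, bleach_frames: tuple[int, ...] | None = None) -> list[Segment]:
    """Split a normalised trace into per-bleach segments.

    Each segment starts at its bleach-floor frame (first post-bleach
    sample) and runs to the next bleach (exclusive) or trace end.  The
    pre-bleach reference is the mean of the baseline frames for the first
    segment and the last pre-bleach sample for subsequent segments.
    """
    if bleach_frames is None:
        bleach_frames = trace.bleach_frames
    if bleach_frames is None:
        bleach_frames = detect_bleach_frames(trace)
    bleach_frames = tuple(int(b) for b in bleach_frames)
    if any(b2 <= b1 for b1, b2 in zip(bleach_frames, bleach_frames[1:])):
        raise ValueError("bleach frames must be strictly increasing")
    if bleach_frames[0] < trace.n_baseline_frames:
        raise ValueError("first bleach precedes the baseline frames")

    segments = []
    bounds = list(bleach_frames) + [len(trace.intensities)]
    for s, (start, stop) in enumerate(zip(bounds[:-1], bounds[1:])):
        if s == 0:
            ref = float(np.mean(trace.intensities[: trace.n_baseline_frames]))
        else:
            ref = float(trace.intensities[start - 1])
        segments.append(
            Segment(
                start=start,
                stop=stop,
                pre_bleach_reference=ref,
                times_s=trace.times_s[start:stop] - trace.times_s[start],
                values=trace.intensities[start:stop],
            )
        )
    return segments


def _interpolated_crossing(times: np.ndarray, values: np.ndarray, level: float) -> float | None:
    """First time ``values`` reaches ``level``, linear between samples."""
    above = values >= level
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0))


def recovery_metrics(
    segment: Segment,
    segment_index: int = 0,
    smooth: bool = False,
) -> FRAPResult:
    """Bleach floor, recovered fraction, mobile fraction, and t_half.

    ``smooth`` applies an optional 3-frame moving average before taking
    the maximum (off by default).
    """
    values = segment.values
    if smooth and values.size >= 3:
        kernel = np.ones(3) / 3.0
        values = np.convolve(values, kernel, mode="same")
        values[0] = np.mean(segment.values[:2])
        values[-1] = np.mean(segment.values[-2:])
    floor = float(segment.values[0])
    max_rec = float(np.max(values))
    amplitude = max_rec - floor
    ref = segment.pre_bleach_reference
    flags: list[str] = []
    mobile = amplitude / (ref - floor) if ref > floor else math.nan
    if not (ref > floor):
        flags.append("pre-bleach reference not above bleach floor")
    frac = max_rec / ref if ref > 0 else math.nan
    final_frac = float(segment.values[-1]) / ref if ref > 0 else math.nan
    if frac > 1:
        flags.append("recovery exceeds pre-bleach reference")

    if amplitude <= 0:
        flags.append("non-positive recovery amplitude; t_half undefined")
        t_half = t_half_frame = None
    else:
        level = floor + 0.5 * amplitude
        t_half = _interpolated_crossing(segment.times_s, values, level)
        idx = np.flatnonzero(values >= level)
        t_half_frame = float(segment.times_s[idx[0]]) if idx.size else None

    return FRAPResult(
        segment_index=segment_index,
        pre_bleach_reference=ref,
        bleach_floor=floor,
        max_recovered=max_rec,
        max_recovered_fraction=frac,
        final_fraction=final_frac,
        recovered_amplitude=amplitude,
        mobile_fraction=mobile,
        t_half_s=t_half,
        t_half_frame_s=t_half_frame,
        flags=flags,
    )


def fit_recovery_exponential(segment: Segment) -> ExponentialFit:
    """Least-squares fit of floor + A * (1 - exp(-k t)) to a segment."""
    t = segment.times_s
    y = segment.values
    if y.size < 5:
        raise ValueError("need at least 5 post-bleach points for an exponential fit")

    def model(t, floor, amp, k):
        return floor + amp * (1.0 - np.exp(-k * t))

    span = max(t[-1] - t[0], 1e-9)
    p0 = (float(y[0]), float(max(y.max() - y[0], 1e-6)), 1.0 / span * 3.0)
    try:
        popt, _ = curve_fit(
            model, t, y, p0=p0, bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf]), maxfev=10000
        )
        rss = float(np.sum((model(t, *popt) - y) ** 2))
        return ExponentialFit(k_per_s=float(popt[2]), amplitude=float(popt[1]), floor=float(popt[0]), rss=rss, converged=True)
    except RuntimeError:
        return ExponentialFit(k_per_s=math.nan, amplitude=math.nan, floor=math.nan, rss=math.inf, converged=False)


def analyze_frap_trace(
    trace: FRAPTrace,
    bleach_frames: tuple[int, ...] | None = None,
    smooth: bool = False,
    fit_exponential: bool = False,
) -> list[FRAPResult]:
    """Normalise, segment, and summarise a FRAP trace (one result per bleach)."""
    norm = normalize_trace(trace)
    segments = segment_bleaches(norm, bleach_frames)
    results = []
    for i, seg in enumerate(segments):
        res = recovery_metrics(seg, segment_index=i, smooth=smooth)
        if fit_exponential and seg.values.size >= 5:
            res.exponential_fit = fit_recovery_exponential(seg)
        results.append(res)
    return results
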