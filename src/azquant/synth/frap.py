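"""Synthetic FRAP traces with single-exponential recovery ground truth.

The expected trace is piecewise: a flat baseline, then for each bleach a
drop to a floor (a fraction of the immediately preceding level) followed by
recovery F(t) = floor + amplitude * (1 - exp(-k (t - t_bleach))).  After
the first bleach only the mobile fraction of the lost signal recovers;
after a second bleach the remaining pool is fully mobile and recovers
toward the pre-second-bleach level.  Gaussian noise (sd ``noise_sd``) is
added last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from azquant.frap import FRAPTrace
from azquant.synth.scene import GroundTruth


@dataclass(frozen=True)
class FRAPTraceSpec:
    baseline_level: float = 100.0
    n_baseline_frames: int = 2
    bleach_frames: tuple[int, ...] = (5,)
    bleach_floor_fraction: float = 0.05
    mobile_fraction: float = 0.4
    recovery_rate_per_s: float = math.log(2.0) / 16.1
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mobile_fraction <= 1.0):
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if not (0.0 <= self.bleach_floor_fraction < 1.0):
            raise ValueError("bleach_floor_fraction must lie in [0, 1)")
        if self.n_baseline_frames not in (1, 2):
            raise ValueError("n_baseline_frames must be 1 or 2")
        bf = self.bleach_frames
        if len(bf) == 0 or any(b2 <= b1 for b1, b2 in zip(bf, bf[1:])):
            raise ValueError("bleach_frames must be non-empty and strictly increasing")
        if bf[0] <= self.n_baseline_frames - 1:
            raise ValueError("all bleach frames must come after the baseline frames")
        if not (self.recovery_rate_per_s > 0):
            raise ValueError("recovery_rate_per_s must be > 0")


def render_frap_trace(
    spec: FRAPTraceSpec,
    n_frames: int,
    frame_interval_s: float = 1.0,
    seed: int = 0,
) -> tuple[FRAPTrace, GroundTruth]:
    """Render a noiseless-expectation trace plus optional Gaussian noise.

    Ground-truth params record, per bleach segment, the floor, the
    asymptotic plateau, the expected mobile fraction and the true
    half-time ln(2)/k.
    """
    if n_frames <= spec.bleach_frames[-1]:
        raise ValueError("n_frames must exceed the last bleach frame")
    times = np.arange(n_frames) * frame_interval_s
    expected = np.full(n_frames, spec.baseline_level, dtype=float)

    k = spec.recovery_rate_per_s
    segments_truth = []
    for s, bframe in enumerate(spec.bleach_frames):
        pre_level = expected[bframe - 1]
        floor = spec.bleach_floor_fraction * pre_level
        if s == 0:
            amplitude = spec.mobile_fraction * (pre_level - floor)
        else:
            # the remaining mobile pool is fully mobile
            amplitude = pre_level - floor
        stop = spec.bleach_frames[s + 1] if s + 1 < len(spec.bleach_frames) else n_frames
        t_rel = times[bframe:stop] - times[bframe]
        expected[bframe:stop] = floor + amplitude * (1.0 - np.exp(-k * t_rel))
        segments_truth.append(
            {
                "segment": s,
                "bleach_frame": bframe,
                "pre_bleach_level": float(pre_level),
                "floor": float(floor),
                "amplitude": float(amplitude),
                "plateau": float(floor + amplitude),
                "mobile_fraction": spec.mobile_fraction if s == 0 else 1.0,
                "t_half_s": math.log(2.0) / k,
            }
        )

    rng = np.random.default_rng(seed)
    values = expected.copy()
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=n_frames)

    trace = FRAPTrace(
        times_s=times,
        intensities=values,
        bleach_frames=spec.bleach_frames,
        n_baseline_frames=spec.n_baseline_frames,
    )
    truth = GroundTruth(
        params={
            "recovery_rate_per_s": k,
            "t_half_s": math.log(2.0) / k,
            "mobile_fraction": spec.mobile_fraction,
            "baseline_level": spec.baseline_level,
            "segments": segments_truth,
            "frame_interval_s": frame_interval_s,
            "noise_sd": spec.noise_sd,
            "seed": seed,
        },
        events=[{"kind": "bleach", "frame": b} for b in spec.bleach_frames],
    )
    return trace, truth
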