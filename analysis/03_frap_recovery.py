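#!/usr/bin/env python
"""FRAP quantification on simulated double-bleach traces.

Simulates 30 condensate FRAP traces (two consecutive bleach steps, 40%
mobile pool, recovery half-time 16.1 s, 1 Hz sampling, measurement noise),
then measures per-segment recovery: the first bleach recovers to the
mobile fraction, the second recovers nearly completely — the mobile pool
stays fully mobile.  Output: results/frap/frap_results.csv
"""

import math
from pathlib import Path

import numpy as np
import pandas as pd

from azquant import frap
from azquant.synth import FRAPTraceSpec, render_frap_trace

OUT = Path("results/frap")
SEED = 7
N_TRACES = 30
K = math.log(2) / 16.1  # /s


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    rows = []
    for i in range(N_TRACES):
        spec = FRAPTraceSpec(
            baseline_level=100.0,
            bleach_frames=(5, 205),
            mobile_fraction=float(rng.uniform(0.35, 0.45)),
            recovery_rate_per_s=K * float(rng.uniform(0.9, 1.1)),
            bleach_floor_fraction=0.05,
            noise_sd=0.8,
        )
        trace, truth = render_frap_trace(spec, n_frames=420, frame_interval_s=1.0, seed=int(rng.integers(0, 2**31)))
        for res in frap.analyze_frap_trace(trace, fit_exponential=True):
            rows.append(
                {
                    "trace": i,
                    "segment": res.segment_index,
                    "true_t_half_s": truth.params["t_half_s"],
                    "t_half_s": res.t_half_s,
                    "max_recovered_fraction": res.max_recovered_fraction,
                    "mobile_fraction": res.mobile_fraction,
                    "exp_fit_t_half_s": res.exponential_fit.t_half_s if res.exponential_fit else None,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "frap_results.csv", index=False)
    for seg, label in [(0, "first bleach"), (1, "second bleach")]:
        sub = df[df.segment == seg]
        sem = sub.t_half_s.std(ddof=1) / math.sqrt(len(sub))
        print(
            f"{label}: t_1/2 max recovery = {sub.t_half_s.mean():.1f} +/- {sem:.1f} s, "
            f"recovered fraction = {sub.max_recovered_fraction.mean():.2f} "
            f"(n = {len(sub)} traces)"
        )


if __name__ == "__main__":
    main()
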