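#!/usr/bin/env python
"""Assumption-gated statistics on the confocal cohort measurements.

Reads results/confocal/measurements.csv (running the cohort simulation
first if missing), applies the Shapiro/Levene-gated test selection, and
reports the omnibus test, post hoc table, and mean +/- SEM summaries.
Output: results/confocal/stats_report.json
"""

import importlib.util
import json
from pathlib import Path

import pandas as pd

from azquant import stats as azstats

OUT = Path("results/confocal")


def main() -> None:
    csv = OUT / "measurements.csv"
    if not csv.exists():
        spec = importlib.util.spec_from_file_location(
            "confocal_cohort", Path(__file__).parent / "05_confocal_cohort.py"
        )
        mod = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(mod)
        mod.main()
    table = pd.read_csv(csv)
    groups = {g: table.loc[table.group == g, "normalized"].to_numpy() for g in table.group.unique()}
    report = azstats.run_comparison(groups, reference_group="control")

    print(f"Assumption gating: Shapiro p = {report.selection.shapiro_p}, Levene p = {report.selection.levene_p:.3f}")
    print(f"Selected test: {report.test_name}; omnibus p = {report.p_value:.3g}")
    print(report.summary.to_string(index=False))

    payload = {
        "test": report.test_name,
        "statistic": report.statistic,
        "p_value": report.p_value,
        "assumptions": {"shapiro_p": report.selection.shapiro_p, "levene_p": report.selection.levene_p},
        "posthoc": report.posthoc.to_dict(orient="records"),
        "summary": report.summary.to_dict(orient="records"),
    }
    (OUT / "stats_report.json").write_text(json.dumps(payload, indent=2))
    print(f"Wrote {OUT / 'stats_report.json'}")


if __name__ == "__main__":
    main()
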