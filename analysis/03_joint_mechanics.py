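#!/usr/bin/env python
"""Joint-level mechanics of every cohort trial.

Runs each simulated trial through the full chain (filtering, contact
detection, inverse dynamics, exoskeleton/MTU decomposition, average
positive power) and writes per-trial outcomes plus time-normalised cycle
curves.

Writes: results/cohort_outcomes.csv, results/cycle_curves_p00.csv.
"""

import importlib.util
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from hopexo.io import load_trial
from hopexo.pipeline import analyze_trial, cohort_outcomes

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def _ensure_cohort():
    if not any(COHORT_DIR.glob("*/manifest.yaml")):
        spec = importlib.util.spec_from_file_location(
            "simulate_cohort", Path(__file__).parent / "02_simulate_cohort.py"
        )
        mod = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(mod)
        mod.main()


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    _ensure_cohort()
    results, pids = [], []
    audit_failures = 0
    for d in sorted(COHORT_DIR.glob("*/manifest.yaml")):
        trial = load_trial(d.parent)
        res = analyze_trial(trial)
        if res.exo_report is not None and not res.exo_report.passed:
            audit_failures += 1
        results.append(res)
        pids.append(trial.meta["participant_id"])
        if d.parent.name == "p00_DG":
            res.normalized_curves().to_csv(
                RESULTS / "cycle_curves_p00.csv", index=False, float_format="%.5g"
            )
    table = cohort_outcomes(results, pids)
    table.to_csv(RESULTS / "cohort_outcomes.csv", index=False)

    summary = table.groupby("condition")[
        ["hop_frequency_hz", "peak_vgrf_n", "total_avg_pos_power_w_per_kg",
         "mtu_avg_pos_power_ankle_w_per_kg", "percent_exo_ankle"]
    ].mean().round(3)
    print(f"analysed {len(results)} trials; "
          f"spring-delivery audit failures: {audit_failures}")
    print(summary.to_string())


if __name__ == "__main__":
    main()
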