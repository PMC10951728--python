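#!/usr/bin/env python
"""Condition-level inference on the cohort outcomes.

One-way repeated-measures ANOVA (participant as the random effect) per
outcome, followed by Sidak-corrected paired t-tests where the main effect
is significant.

Reads results/cohort_outcomes.csv; writes results/stats_anova.csv and
results/stats_posthoc.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from hopexo.stats import posthoc_sidak, rm_anova

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

# Marker-derived outcomes only: the generator's GRF is deterministic given
# participant mass, so GRF-only outcomes (peak vGRF, contact time) have no
# within-participant variance and their F statistics degenerate.
OUTCOMES = [
    "rom_knee_deg",
    "rom_ankle_deg",
    "mtu_avg_moment_ankle_nm_per_kg",
    "mtu_avg_moment_knee_nm_per_kg",
    "mtu_avg_pos_power_ankle_w_per_kg",
    "mtu_avg_pos_power_knee_w_per_kg",
    "percent_overall_ankle",
    "percent_overall_hip",
    "total_avg_pos_power_w_per_kg",
]


def main() -> None:
    table = pd.read_csv(RESULTS / "cohort_outcomes.csv")
    anova_rows, posthoc_frames = [], []
    for outcome in OUTCOMES:
        sub = table[["participant", "condition", outcome]].rename(
            columns={outcome: "value"}
        )
        res = rm_anova(sub)
        anova_rows.append(
            {"outcome": outcome, "F": res.F, "df1": res.df1, "df2": res.df2,
             "p": res.p, "significant": res.significant}
        )
        ph = posthoc_sidak(sub)
        if not ph.empty:
            ph.insert(0, "outcome", outcome)
            posthoc_frames.append(ph)
    anova = pd.DataFrame(anova_rows)
    anova.to_csv(RESULTS / "stats_anova.csv", index=False)
    posthoc = (
        pd.concat(posthoc_frames, ignore_index=True)
        if posthoc_frames else pd.DataFrame()
    )
    posthoc.to_csv(RESULTS / "stats_posthoc.csv", index=False)

    print(anova.to_string(index=False,
                          formatters={"F": "{:.2f}".format, "p": "{:.4g}".format}))
    if not posthoc.empty:
        sig = posthoc[posthoc.p_sidak < 0.05]
        print(f"\n{len(sig)} Sidak-significant pairwise differences "
              f"across {posthoc.outcome.nunique()} gated outcomes")


if __name__ == "__main__":
    main()
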