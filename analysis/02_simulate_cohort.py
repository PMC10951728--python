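#!/usr/bin/env python
"""Simulate the synthetic hopping cohort.

Six synthetic participants (mass ~ N(66, 5.7) kg) hop under all four
conditions (no exoskeleton, degressive, linear, progressive springs) at
2.4 Hz, eight analysed hops per trial, with 1 mm marker noise.  Per-leg
spring stiffness follows the body-mass prescription.  Trial bundles
(TRC markers, per-leg force CSVs, ground truth, manifest) go to
scratch/cohort/ for the downstream scripts.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from hopexo.hopper import HopperParams, emit_cohort
from hopexo.io import write_trial

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"

N_PARTICIPANTS = 6
CONDITIONS = ["NH", "DG", "LN", "PG"]
SEED = 42


def build_cohort():
    template = HopperParams(n_hops=8, marker_noise_sd=0.001)
    return emit_cohort(N_PARTICIPANTS, CONDITIONS, template, seed=SEED)


def main() -> None:
    trials = build_cohort()
    for trial, gt in trials:
        pid = trial.meta["participant_id"]
        write_trial(trial, COHORT_DIR / f"p{pid:02d}_{trial.condition}",
                    ground_truth=gt)
    masses = sorted({t.participant["mass"] for t, _ in trials})
    print(f"wrote {len(trials)} trials ({N_PARTICIPANTS} participants x "
          f"{len(CONDITIONS)} conditions) to {COHORT_DIR}")
    print("participant masses (kg):", [f"{m:.1f}" for m in masses])


if __name__ == "__main__":
    main()
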