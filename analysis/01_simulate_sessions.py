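#!/usr/bin/env python
"""Simulate one recording session per task paradigm, plus a behavioral cohort.

Generates raw two-wavelength intensity recordings for the finger-tapping,
1-back, 2-back and alternate-uses block designs (default physiological
noise, one spike and one step artifact each), writes them with their event
markers and ground truth under results/sessions/, and a 26-participant
behavioral accuracy/reaction-time table under results/behavioral.csv.
"""

import dataclasses
from pathlib import Path

from fnirspipe.io_events import write_markers, write_recording
from fnirspipe.synth import (ArtifactSpec, SimulationConfig, generate_block_design,
                             simulate_behavioral, simulate_recording, write_ground_truth)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2026


def main() -> None:
    outdir = RESULTS / "sessions"
    outdir.mkdir(parents=True, exist_ok=True)
    for i, paradigm in enumerate(["finger_tapping", "nback1", "nback2", "aut"]):
        cfg = SimulationConfig.for_paradigm(paradigm, seed=SEED + i)
        dur = cfg.session_duration_s
        cfg = dataclasses.replace(cfg, artifacts=[
            ArtifactSpec(0.25 * dur, "spike", 0.5, 0.4),
            ArtifactSpec(0.60 * dur, "step", 0.5, 0.4),
        ])
        rec, truth = simulate_recording(cfg)
        write_recording(rec, outdir / f"{paradigm}_recording.csv")
        write_markers(generate_block_design(cfg), outdir / f"{paradigm}_markers.csv")
        write_ground_truth(truth, outdir / f"{paradigm}_ground_truth.csv")
        print(f"{paradigm}: {rec.n_samples} samples over {dur:.0f} s, "
              f"{cfg.n_blocks} task blocks, 2 injected artifacts")

    behav = simulate_behavioral(26, accuracy_drop=0.2, rt_increase_s=0.33,
                                seed=SEED, mean_accuracy_a=0.86, accuracy_sd=0.10)
    behav.to_csv(RESULTS / "behavioral.csv", index=False)
    print(f"behavioral cohort: n={len(behav)}, "
          f"mean accuracy drop {behav['accuracy_a'].mean() - behav['accuracy_b'].mean():.3f}, "
          f"mean RT increase {behav['rt_b_s'].mean() - behav['rt_a_s'].mean():.3f} s")


if __name__ == "__main__":
    main()
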