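#!/usr/bin/env python
"""Synthesize the reference gait motions used by every later stage.

Generates one canonical cycle per study speed (0.63, 1.05, 1.33 m/s
walking; 3.91 m/s running) for the 63 kg / 1.73 m model, verifies the
kinematic-consistency invariants, writes the diagnostic table under
results/ and the full motion CSVs (~0.5 MB each) under scratch/motions/.
"""

import os

import pandas as pd

from treadgait import build_model, generate_reference, kinematic_consistency_check, save_motion

ROOT = os.path.join(os.path.dirname(__file__), "..")
OUT = os.path.join(ROOT, "results")
MOTION_DIR = os.path.join(ROOT, "scratch", "motions")
SPEEDS = (0.63, 1.05, 1.33, 3.91)


def main():
    os.makedirs(OUT, exist_ok=True)
    os.makedirs(MOTION_DIR, exist_ok=True)
    model = build_model(63.0, 1.73)
    rows = []
    for speed in SPEEDS:
        motion = generate_reference(speed, model, seed=1)
        save_motion(motion, os.path.join(MOTION_DIR, f"reference_{speed:.2f}mps.csv"))
        rep = kinematic_consistency_check(motion, model)
        rows.append({
            "speed_mps": speed,
            "cycle_duration_s": motion.cycle_duration,
            "max_velocity_mismatch_rad_s": rep.max_velocity_mismatch,
            "speed_error_pct": rep.speed_error_pct,
            "periodicity_gap_rad": rep.periodicity_gap,
            "passed": rep.passed,
        })
        print(f"{speed:.2f} m/s: T={motion.cycle_duration:.3f} s, "
              f"consistency {'OK' if rep.passed else 'FAILED'}")
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(OUT, "reference_consistency.csv"), index=False)
    print(f"wrote reference_consistency.csv to results/ and "
          f"{len(SPEEDS)} motion CSVs to scratch/motions/")


if __name__ == "__main__":
    main()
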