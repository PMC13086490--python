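#!/usr/bin/env python
"""ECG reduction: R-peak detection, heart rate and quality-index filtering.

Generates bursts at the holding-tank baseline (48 bpm) and swim-tunnel
(82 bpm) rates across noise levels, showing HR recovery on clean signals and
the quality index degrading monotonically with noise.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from swimtag import synth
from swimtag.cardio import burst_to_record, filter_hr

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--out", type=Path, default=Path("results/heart_rate"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

rng = np.random.default_rng(args.seed)
rows = []
for hr_true in (48.0, 82.0):
    for noise in (0.0, 0.05, 0.2, 0.6):
        records = []
        for _ in range(50):
            burst, _ = synth.gen_ecg(hr_true, noise_sd=noise, rng=rng)
            records.append(burst_to_record(burst))
        kept, flagged, dropped = filter_hr(records)
        hr_est = [r.hr_bpm for r in kept if r.hr_bpm is not None]
        rows.append({
            "hr_true": hr_true,
            "noise_sd": noise,
            "mean_hr": np.mean(hr_est) if hr_est else np.nan,
            "mean_qi": np.mean([r.qi for r in records]),
            "n_kept": len(kept),
            "n_review": len(flagged),
            "n_dropped": len(dropped),
        })

table = pd.DataFrame(rows)
table.to_csv(args.out / "hr_by_noise.csv", index=False)
print("HR recovery and QI filtering by noise level (50 bursts each):")
print(table.round(3).to_string(index=False))

clean = table[table["noise_sd"] == 0.0]
print("\nclean-signal HR error (bpm):",
      np.abs(clean["mean_hr"] - clean["hr_true"]).round(4).tolist())
print(f"wrote {args.out}/hr_by_noise.csv")
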