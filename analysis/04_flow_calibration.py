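#!/usr/bin/env python
"""Flow calibration: generate unsteady profiles and recover their parameters.

Generates the tank profile (0.50 +/- 0.05 m s-1, 100 s period) and the
swim-tunnel profile (+/- 0.1 m s-1, 12 s period) with measurement noise,
then fits a sinusoid to each as one would to flow-meter readings.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from swimtag.flow import fit_sinusoid, generate_flow

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--out", type=Path, default=Path("results/flow"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

protocols = {
    "tank": dict(mean=0.50, amplitude=0.05, period_s=100.0, dt_s=1.0, duration_s=3600.0),
    "tunnel": dict(mean=0.60, amplitude=0.10, period_s=12.0, dt_s=0.25, duration_s=600.0),
}
rows = []
for name, p in protocols.items():
    profile = generate_flow(p["mean"], p["amplitude"], p["period_s"], p["duration_s"],
                            p["dt_s"], noise_sd=0.01,
                            rng=np.random.default_rng(args.seed))
    pd.DataFrame({"time_s": profile.time_s, "speed_mps": profile.speed_mps}).to_csv(
        args.out / f"{name}_profile.csv", index=False)
    fit = fit_sinusoid(profile.speed_mps, p["dt_s"])
    rows.append({"protocol": name, "true_period_s": p["period_s"],
                 "fit_period_s": fit.period_s, "fit_mean": fit.mean_speed,
                 "fit_amplitude": fit.amplitude,
                 "identifiable": fit.period_identifiable})
table = pd.DataFrame(rows)
table.to_csv(args.out / "sinusoid_fits.csv", index=False)
print("Sinusoid fits to noisy flow profiles (noise sd 0.01 m s-1):")
print(table.round(4).to_string(index=False))
print(f"wrote profiles and fits to {args.out}")
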