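#!/usr/bin/env python
"""Regression transfer: predict free-swimming energetics at the tank speed.

Evaluates the stored swim-tunnel calibration lines at 0.50 m s-1 under both
flow conditions, chains them through the MO2 models, and compares against
the tank observations supplied as inputs.
"""

import argparse
from pathlib import Path

from swimtag.io import write_report
from swimtag.models import build_report, chain_predict_mo2, published_models

parser = argparse.ArgumentParser()
parser.add_argument("--speed", type=float, default=0.50)
parser.add_argument("--out", type=Path, default=Path("results/field_predictions"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

# tank observations at 0.50 m s-1 (day means from the sentinel study)
observed = {
    "steady": {"ext_accel_mg": 12.90, "odba_ms2": 1.12},
    "unsteady": {"ext_accel_mg": 14.60, "odba_ms2": 1.09},
}

reg = published_models()
for cond in ("steady", "unsteady"):
    rep = build_report(args.speed, cond, observed=observed[cond])
    write_report(rep, args.out / f"report_{cond}.json",
                 config={"speed": args.speed, "condition": cond})
    print(f"{cond} flow at {args.speed} m s-1:")
    print(f"  predicted acceleration {rep.predicted_ext_accel_mg:6.2f} m*g*   "
          f"(observed {observed[cond]['ext_accel_mg']})")
    print(f"  predicted ODBA         {rep.predicted_odba_ms2:6.2f} m s-2  "
          f"(observed {observed[cond]['odba_ms2']})")
    print(f"  MO2 via acceleration   {rep.predicted_mo2_from_accel:6.1f} mg kg-1 h-1")
    print(f"  MO2 via ODBA           {rep.predicted_mo2_from_odba:6.1f} mg kg-1 h-1")

# MO2 implied by the observed (not predicted) steady activity levels
mo2_obs_accel = reg["mo2_vs_accel"]["steady"].slope * 12.90 + reg["mo2_vs_accel"]["steady"].intercept
mo2_obs_odba = reg["mo2_vs_odba"]["steady"].slope * 1.13 + reg["mo2_vs_odba"]["steady"].intercept
print(f"\nsteady MO2 from observed activity: {mo2_obs_accel:.1f} (acceleration), "
      f"{mo2_obs_odba:.1f} (ODBA) mg kg-1 h-1")
print(f"wrote reports to {args.out}")
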