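"""Kidney blood-flow response per injection group, via the LSCI chain.

Simulates speckle movies (baseline, 15 min, 24 h) for each dose group
with its known flow scenario, runs the full contrast -> flow -> ROI ->
baseline-normalisation chain, and classifies each group against the 20 %
physiological-variation threshold.  The 3.1 um / 30e6 group's outcome is
not on record and is not simulated.  Writes results/flow_safety.csv.
"""

from pathlib import Path

import pandas as pd

from renoperf import lsci
from renoperf import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results"

# group -> (diameter um, dose, true relative flows at 15 min / 24 h)
GROUPS = {
    "control (no injection)": (None, None, {"15 min": 0.95, "24 h": 1.0}),
    "sham (saline)": (None, None, {"15 min": 0.9, "24 h": 0.97}),
    "3.1 um, 20e6": (3.1, 20e6, {"15 min": 0.85, "24 h": 0.95}),
    "4.0 um, 10e6": (4.0, 10e6, {"15 min": 0.9, "24 h": 0.95}),
    "4.0 um, 20e6": (4.0, 20e6, {"15 min": 0.53, "24 h": 0.47}),
}

rows = []
for i, (group, (diam, dose, flows)) in enumerate(GROUPS.items()):
    cfg = syn.SpeckleSimConfig(
        frame_height=128, frame_width=128, n_frames=25,
        tau_c_ms=0.5, n_subframes=80, seed=100 + i,
    )
    experiment = syn.simulate_flow_experiment(
        0.5, {"baseline": 1.0, **flows}, cfg
    )
    roi = lsci.ROISpec(14, 14, 100, 100)
    series = lsci.flow_timeseries_from_experiment(experiment, roi)
    label = lsci.classify_flow_response(series, "24 h", threshold_percent=20.0)
    rows.append(
        {
            "group": group,
            "diameter_um": diam,
            "dose": dose,
            "percent_15min": round(series.percent_of_baseline["15 min"]),
            "percent_24h": round(series.percent_of_baseline["24 h"]),
            "true_15min": round(100 * flows["15 min"]),
            "true_24h": round(100 * flows["24 h"]),
            "safety_label": label.label,
        }
    )

OUT.mkdir(exist_ok=True)
df = pd.DataFrame(rows)
df.to_csv(OUT / "flow_safety.csv", index=False)
print(df.to_string(index=False))
print(
    "\nOnly the 4.0 um capsules at 20e6 fail to recover by 24 h "
    "(final flow below 80 % of baseline -> irreversible drop); the same "
    "dose of 3.1 um capsules and the halved dose of 4.0 um capsules stay "
    "within the physiological range."
)
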