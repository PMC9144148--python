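"""Optoacoustic band alteration over the imaging schedule, plus depth.

Simulates broadband acoustic traces at the six imaging timepoints with
known per-timepoint power scalings (the unsafe-dose trajectory: both
vessel classes lose signal and do not recover), splits them into the
11-33 and 33-99 MHz bands, and computes the alteration A = I_t/I_0 * 100.
Also builds a synthetic two-channel depth stack in which the large-vessel
band is confined to the first 0.75 mm and recovers that extinction depth.
Writes results/pa_alteration.csv and results/pa_depth_profile.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from renoperf import pa
from renoperf import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results"

# intensity scaling per timepoint (fraction of pre-injection band power)
SCHEDULE = {
    "before": 1.0,
    "5 min": 0.45,
    "15 min": 0.5,
    "1 h": 0.55,
    "24 h": 0.5,
    "5 days": 0.55,
}

frames = []
for i, (label, scale) in enumerate(SCHEDULE.items()):
    sig = syn.simulate_pa_signal(
        2.0 * np.sqrt(scale), 1.0 * np.sqrt(scale),
        seed=300 + i, timepoint_label=label,
    )
    frames.append(pa.band_split_intensity(sig))
series = pd.concat(frames, ignore_index=True)
alteration = pa.alteration_timecourse(series, "before")

OUT.mkdir(exist_ok=True)
table = series.merge(alteration, on=["timepoint", "band"])
table.to_csv(OUT / "pa_alteration.csv", index=False)
print(table.to_string(index=False))

# depth-resolved band profile: large vessels visible only near the surface
nz, dz = 24, 0.125
depths = np.arange(nz) * dz
low = np.where(depths < 0.75, 1.0, 1e-4)[:, None, None] * np.ones((nz, 16, 16))
high = np.ones((nz, 16, 16))  # capillary band present at every depth
profile = pa.depth_band_profile(pa.ReconVolume(low, high, (dz, 0.016, 0.016)))
profile.to_csv(OUT / "pa_depth_profile.csv", index=False)
depth = pa.extinction_depth(profile, band="low", fraction=0.1)
print(
    f"\nAlteration at the reference is 100 % in both bands by construction; "
    f"the injected ~50 % power drop is recovered at every later timepoint. "
    f"Large-vessel (low-band) signal extends to {depth + dz:.2f} mm depth; "
    f"the capillary band persists through the stack."
)
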