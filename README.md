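# renoperf

Quantitative analysis toolkit for renal-artery drug-carrier dosimetry:
given microcapsules injected into a kidney's arterial supply, how hard
can you dose before perfusion is irreversibly compromised, and where
does the injected payload end up?

`renoperf` implements the three measurement chains such a study rests
on, each exercisable end-to-end on synthetic data with known ground
truth:

1. **Laser speckle contrast imaging (LSCI) flow analysis.** Spatial
   speckle contrast `K = σ/μ` in a 5×5 sliding window, 25-frame
   averaging, conversion to the conventional flow index `1/K²`,
   Gaussian smoothing (σ = 7 px), ROI statistics (200×200 px default),
   normalisation to each animal's baseline, and a three-way safety
   classification (*physiological* / *reversible drop* / *irreversible
   drop*) against the 20 % physiological-variation threshold.
2. **Optoacoustic band alteration.** Splitting broadband mesoscopy
   signals into a large-vessel band (11–33 MHz) and a capillary band
   (33–99 MHz), per-band mean power, and the alteration
   `A = I_t / I_0 · 100 %` relative to the pre-injection reference,
   plus depth-resolved band profiles of reconstructed volumes.
3. **Biodistribution (%ID).** Ex vivo organ fluorescence with area-scaled
   autofluorescence correction,
   `TRE_organ = TRE_exp − (TRE_ctrl / Area_ctrl) · Area_exp`, organ %ID
   as the share of the corrected total; and the digest route, mapping
   785 nm plate-reader emission to dye mass through a linear calibration
   line and `%ID = mass_sample / mass_injected · 100 %`.

The synthetic module (`renoperf.synthetic`) generates every input with
controlled ground truth: fully developed dynamic speckle with a chosen
field decorrelation time τ_c (flow ∝ 1/τ_c), organ tables with per-area
autofluorescence and log-normal noise, band-limited acoustic noise, and
linear-response fluorimetry plates.

## Worked example

Simulate an unsafe-dose experiment — flow dropping to 53 % of baseline
at 15 min and 47 % at 24 h — and run the full LSCI chain on the movies:

```python
from renoperf import lsci, synthetic as syn

cfg = syn.SpeckleSimConfig(frame_height=128, frame_width=128, n_frames=25,
                           tau_c_ms=0.5, n_subframes=80, seed=7)
exp = syn.simulate_flow_experiment(
    0.5, {"baseline": 1.0, "15 min": 0.53, "24 h": 0.47}, cfg)
roi = lsci.ROISpec(14, 14, 100, 100)
series = lsci.flow_timeseries_from_experiment(exp, roi)
print({k: round(v) for k, v in series.percent_of_baseline.items()})
print(lsci.classify_flow_response(series, "24 h", threshold_percent=20.0).label)
```

```
{'baseline': 100, '15 min': 56, '24 h': 50}
irreversible-drop
```

The chain recovers the injected flow levels to within a few percentage
points (the `1/K²` index carries a small positive model bias at finite
exposure-to-τ_c ratios) and flags the non-recovering final value as an
irreversible drop. The headline dose–size arithmetic is one call each:

```python
>>> round(lsci.relative_change(3.1, 4.0, reference="old"))   # diameter
29
>>> round(lsci.relative_change(20e6, 10e6, reference="old")) # safe dose
-50
```

i.e. a 29 % increase in capsule diameter forces at least a 50 %
reduction in dose to keep kidney perfusion in the safe range.

The numbered scripts under `analysis/` run the complete study on
synthetic data (size distributions, per-group flow safety, band
alteration timecourse, %ID kinetics, dose–size summary) and write their
tables to `results/`. The `renoperf` CLI exposes the same chains on
files (`renoperf run --config cfg.yaml`, `renoperf simulate ...`,
`renoperf lsci|pa|biodist|quantify ...`).

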