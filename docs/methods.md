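# Methods

## Dynamic speckle model

The simulator draws a complex circular-Gaussian speckle field on a
Fourier-limited grid: an i.i.d. complex-Gaussian spectrum restricted to
a circular pupil of radius `N / (2 · grain_px)` frequency pixels, so the
speckle grain is `grain_px` pixels wide (default 2 px — the pattern
stays Nyquist-sampled, as an LSCI instrument's F-stop is tuned to
ensure). The per-pixel instantaneous intensity of such a field is
negative-exponential, so a single static frame has contrast
`K = σ/μ = 1` exactly in expectation.

Temporal evolution is a first-order autoregression on the field,
`E ← ρE + √(1−ρ²) E_new` with `ρ = exp(−Δt/τ_c)`, which gives the
exponential field correlation `g1(t) = exp(−t/τ_c)`. A camera frame is
the mean of `n_subframes` instantaneous intensities spread over the
exposure `T`, the discrete analogue of finite-exposure integration. For
exponential `g1` the expected squared contrast is the classical
finite-exposure integral

    K² = β · (e^(−2x) − 1 + 2x) / (2x²),    x = T/τ_c,

equivalently `K² = β · (2/T)∫₀ᵀ (1−t/T)|g1(t)|² dt`; the test suite
evaluates that integral by independent numerical quadrature and checks
the measured contrast of simulated movies against it. Simulations agree
within ~1 % when `n_subframes ≳ 8x` (the discrete sub-frame sum
overestimates the continuous integral by roughly `x/n_subframes`);
configurations used in the tests follow that rule.

The coherence factor `β ∈ (0,1]` is realised as a constant incoherent
pedestal `(1/√β − 1)·⟨I⟩` added to each frame, which rescales `K²` by
exactly `β` at every exposure without altering the dynamics. Detector
noise is off by default (keeping the analytic oracles tight); an
additive Gaussian read-noise term is available via `read_noise_sd`.

**Flow mapping.** Relative flow is defined as `baseline_τ_c / τ_c`
(single-scattering assumption: scatterer speed ∝ 1/τ_c). The pipeline's
flow index is the conventional `1/K²`. Because `1/K²(x) ≈ x + 0.5` at
moderate `x` rather than `x` itself, baseline-normalised percent flow
carries a small positive bias at finite `x` (≈ +1–3 percentage points
at baseline `x = 20` for drops to 47–53 %); the end-to-end recovery
tests budget 5 percentage points for it. Working at larger `x` shrinks
the bias but demands proportionally more sub-frames.

**Windowed vs. global contrast.** The 5×5 sliding-window estimator is
the production map (it is what the instrument software computes), but
on speckle whose grain is comparable to the window it underestimates K
by ~10 % (few independent speckles per window and correlated samples
shrink the sample variance). This multiplicative bias is independent of
τ_c, so it cancels in baseline-normalised flow ratios — which is all
the pipeline reports. Physics validation against the `K²(x)` model
therefore uses the global σ/μ over a large ROI (`lsci.frame_contrast`),
which is bias-free on frames much larger than the grain.

## LSCI processing chain

Order of operations: per-frame 5×5 contrast → average 25 consecutive
contrast maps → invert to `1/K²` → Gaussian smooth (σ = 7 px, reflective
boundaries) → ROI mean ± sample SD → percent of the individual baseline
→ safety classification. Numerical choices:

* windowed statistics are computed two-pass over a sliding-window view
  (mean, then squared deviations) — numerically faithful to the
  per-window definition, free of one-pass cancellation;
* sample (n−1) standard deviation everywhere (window statistic and ROI);
* reflective ("symmetric") edge padding, output the same size as input;
* window means below `1e-12 × max(frame)` are masked, not divided;
  zero-contrast pixels are masked and counted on conversion to flow;
* masked pixels are filled with the valid-pixel mean before smoothing so
  they do not depress their neighbourhood; the mask is preserved;
* percent-of-baseline is stored at full precision (the baseline itself
  is pinned to exactly 100); rendered reports round to integers.

Safety classification is three-way with an inclusive boundary: every
timepoint at or above `100 − threshold` percent (default threshold
20 %) is *physiological*; a dip below that floor with a recovered final
timepoint is a *reversible drop*; a final value below the floor is an
*irreversible drop*. Flow changes of up to 20 % occur in kidneys
without any intervention, which motivates the default.

## Optoacoustic bands

Band splitting is an ideal brick-wall mask on the FFT of the trace;
band intensity is the mean power (mean squared amplitude) of the
band-limited component, computed via one-sided Parseval weights.
Brick-wall masking makes energy bookkeeping exact — low + high band
power equals total power for an in-band signal — at the cost of not
modelling any real filter's roll-off; "intensity" as *power* (rather
than amplitude) is this package's convention and is stated, not claimed
universal. Frequency bins are claimed by bands in declaration order, so
the shared 33 MHz edge belongs to the low band and interior energy is
never double-counted. Alteration is `A = I_t/I_0 · 100 %` per band and
timepoint; the reference maps to exactly 100 by construction, and a
band absent at a timepoint yields an absent row, never a zero.
Tomographic reconstruction is out of scope: depth profiles operate on
already-reconstructed co-registered two-channel volumes (Z from the
organ surface inward), reporting per-layer band means and, optionally,
the deepest layer at which a band exceeds a stated fraction (default
10 %) of its surface value.

## Biodistribution

The autofluorescence correction is
`TRE_organ = TRE_exp − (TRE_ctrl/Area_ctrl) · Area_exp`: the control
organ's radiant efficiency per unit area, scaled to the experimental
organ's area, is that organ's autofluorescence estimate. Negative
corrected values are clamped to zero and flagged rather than
propagated; %ID is each organ's share of the corrected total (rows sum
to 100 by construction; an all-zero corrected table raises, since the
share is undefined). Units are carried as opaque consistent radiant
efficiency units — no absolute radiometric calibration is attempted,
and no depth/photon-transport correction is applied.

The digest route fits an ordinary least-squares line to
(mass, emission at 785 nm) standard pairs (≥ 3 standards, ≥ 2 distinct
masses; r² reported) and inverts it for samples, averaging the five
replicate wells' intensities *before* inversion (the linear map makes
the order immaterial for the mean, but averaging first propagates noise
more predictably). Negative masses clamp to zero with a flag.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the estimators
assume: fully developed speckle with exponential field correlation;
organ tables whose control TRE is exactly per-area autofluorescence and
whose experimental TRE adds a signal proportional to true %ID, both
under multiplicative log-normal noise (CV 5 % default — fluorescence
readouts are positive and right-skewed); acoustic traces as independent
band-limited Gaussian noise; plates with Gaussian-shaped spectra
peaking at 785 nm and linear mass response. Defaults follow the
acquisition settings of the target instruments: 10 ms exposure at
30 fps for the camera; 250 MHz sampling for acoustic traces (well above
Nyquist for 99 MHz content); a 770–840 nm, 1 nm-step emission grid; a
nine-organ dissection panel with plausible relative areas; dye signal
about four times the total autofluorescence.

They deliberately do **not** emulate: motion artefacts, speckle from
layered or multiply-scattering tissue, detector shot noise or spatial
nonuniformity, acoustic attenuation/dispersion or transducer response,
organ-depth photon losses, or spectral overlap between dye and
autofluorescence. Passing tests therefore demonstrate the correctness
of the estimators under their stated assumptions, not robustness to
everything real acquisitions add.

## Problem sizes and determinism

Physics checks run on 20 frames of 256² px (static contrast and the
`K²(x)` grid at `x ∈ {0.1, 1, 10}`); end-to-end flow recovery on 25
frames of 128² px with a centred 100×100 ROI at baseline `x = 20`
(τ_c = 0.5 ms, 80 sub-frames); biodistribution recovery on 1000
replicate tables; calibration on 200 noisy plates. These sizes hold the
Monte-Carlo error comfortably below the assertion tolerances. All
randomness flows through `numpy.random.default_rng` seeds carried in the
configs (per-timepoint seeds are spawned from the experiment seed), so
identical configs give bit-identical outputs; pipeline runs embed a
config hash in their reports and reruns are byte-identical.

## Open design choices

* The contrast→flow transform is fixed to `1/K²` (the field's
  conventional qualitative index); `1/K` or raw `K` normalisation are
  not offered.
* ROI placement is always explicit in config — the instrument workflow
  places it manually on the kidney image, so there is no principled
  automatic default beyond centring.
* The 16-bit TIFF interchange format quantises intensities (scale kept
  in the JSON sidecar); in-memory processing is float64 throughout.
* Group statistics across animals (n = 3 in the motivating protocol)
  are descriptive only; no hypothesis testing is included.
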