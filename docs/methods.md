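# Methods

`gabapipe` re-implements, as a tested library, an analysis pipeline for
J-difference-edited (MEGA-sLASER) GABA magnetic-resonance spectroscopy:
multi-coil transient combination, eddy-current compensation, spectral
registration, difference-artifact suppression, simplified Voigt
linear-combination quantification, and reproducibility-driven tuning of the
quantification parameters. Because raw 7 T human acquisitions of this kind
are not publicly available, the package ships a synthetic cohort generator
with exact ground truth; every quantitative claim the test suite makes is
about the behavior of the algorithms on that generator.

## Signal model and coordinate conventions

A free induction decay (FID) is a complex series sampled at `dwell_time`
seconds (sample 0 is t = 0). The carrier sits on water; a resonance at
chemical shift δ (ppm) appears at frequency offset
`(4.7 − δ) · f0` Hz with `f0 = 297.2` MHz, the 7 T proton frequency. The
conventional printed pairs (23.1 Hz ↔ 0.078 ppm) reproduce under this
choice. Default axes use 4 kHz spectral width with 1024–4096 points.

Each resonance is a Voigt-damped complex exponential

    s(t) = a · exp(2πi Δf t − α t − β t²),

with Lorentzian damping α (s⁻¹; FWHM = α/π Hz) and Gaussian damping β
(s⁻²; FWHM = 2√(β ln 2)/π Hz). The Gaussian term models intra-voxel B0
inhomogeneity and is shared by all resonances of a region; α is
per-resonance.

## Synthetic cohorts

`synthetic.default_resonance_tables` provides two regions:

* **hippocampus** — β = 1470 s⁻², α = 15 s⁻¹ (NAA FWHM ≃ 23 Hz), unit
  amplitude scale;
* **pcc** — β = 126 s⁻² (NAA FWHM ≃ 9 Hz), amplitudes × 2.2 (larger voxel,
  closer receive coils).

Editing is phenomenological (the study this emulates used pre-simulated
basis sets, so no density-matrix simulation is attempted): `off_only`
resonances appear identically in both editing conditions and cancel in the
difference (tCr 3.03, Cr 3.91, Cho, mI, Glx, residual water); `inverted`
resonances flip sign between conditions so the difference carries twice
their amplitude (the GABA pseudo-doublet, two singlets at 2.95/3.05 ppm
tied to one concentration); `co_edited` resonances appear in edit-on only
(macromolecule at 3.0 ppm — together with GABA this is "GABA+" — Glx at
3.75 ppm, and co-edited signal at 2.5/2.7 ppm). NAA additionally carries
`edit_on_scale = −0.15`: the 1.9 ppm editing pulse nearly inverts the
2.01 ppm singlet in the edit-on condition, which gives the difference
spectrum its characteristic large inverted NAA. With the default
`noise_sd = 0.6` per coil sample this reproduces the realistic relation
between off- and difference-spectrum NAA SNR (≈ 44/35 hippocampus,
≈ 208/169 PCC on the default 32+32-transient, 8-coil protocol).

Ground-truth GABA+/tCr is defined on the scale the difference fit reports:
(2·GABA + MM)/tCr = 0.22 at nominal concentrations. Between-subject
variation multiplies each concentration group by an independent
`max(0.1, 1 + cv·z)` factor drawn once per subject (default cv = 5%).

Instrumental artifacts per measurement:

* **drift** — independent random walks in phase and frequency across the
  interleaved on/off transient stream (defaults 0.05 rad and 0.5 Hz per
  TR; the study reports no magnitudes, so these are configuration values,
  not measurements). `ArtifactSpec.drift_corrupted()` (0.4 rad, 1.5 Hz, no
  eddy term) is the severe-instability condition used by the
  pipeline-comparison experiments — it is the regime in which straight
  averaging visibly breaks down, the qualitative situation the comparison
  is about.
* **residual eddy current** — a multiplicative phase `A·exp(−t/τ)`
  (default 1 rad, τ = 12 ms) applied to *all* transients including the
  water reference; the identity of this phase on water and metabolite
  transients is precisely the assumption eddy-current compensation
  exploits.
* optional **spurious echo** — a delayed, scaled copy of the signal.

The water reference is 1000× the metabolite scale; suppressed transients
keep a 0.2% water residual (≈ 2× metabolite scale, i.e. good VAPOR
suppression). The residual matters: this fitter has no dedicated
water-removal step (real pipelines run HLSVD before export), and a 10×
residual makes the difference fit collapse when DAS/DO rotate the edit-on
average — the rotated water leaks into the difference 90° out of phase,
which no non-negative real amplitude with a single global phase can model.

One integer seed fixes the whole cohort bit-exactly; per-subject
concentration draws come from a (seed, subject) stream so a subject's
repeated measurements share ground truth.

What the generator does **not** emulate: genuine J-evolution and multiplet
structure, lipid/scalp contamination, B0 field maps and spatially varying
lineshapes, motion-induced voxel displacement, frequency-dependent coil
sensitivities. Passing tests therefore demonstrate algorithmic
correctness under the stated statistical structure, not performance on
arbitrary in vivo data.

## Preprocessing

* **Coil combination** — `w = N⁻¹ s`: `s` is the complex water amplitude
  per coil (mean of the first 4 water-reference samples), `N` the
  across-coil covariance of the final quarter of every water-suppressed
  FID (signal-free tails). The conjugate-weighted sum maximizes SNR under
  correlated noise and zero-phases the combined water at t = 0. A singular
  or ill-conditioned `N` falls back to its diagonal with a warning.
* **Eddy-current compensation (ECC)** — the unwrapped phase of the
  coil-combined water FID is subtracted sample-by-sample from every
  transient. Where the water magnitude falls below 5× its tail noise sd
  the phase is held at the last reliable value; the tail noise is
  estimated from first differences so residual slow signal does not
  inflate it.
* **Spectral registration (SR)** — per transient, (φ, f) minimize the
  stacked real/imaginary L2 misfit to the mean edit-off signal over the
  first 100 ms of the FID, by bounded trust-region least squares with an
  analytic Jacobian (f bounded to ±20 Hz by default, tolerance 1e-9). The
  100 ms window covers the decayed hippocampal signal (T2* ≈ 25 ms); with
  an equal-weight 400 ms window the estimate is tail-noise dominated and
  drift recovery degrades by an order of magnitude. Aligning the edit-on
  transients to the edit-off mean (the default, following the procedure
  being re-implemented) picks up a constant systematic rotation from the
  genuine on/off spectral difference; it is invisible to CoV statistics
  but biases absolute ratios, so a `per_condition` reference mode is
  provided and used where accuracy rather than reproducibility is under
  test.
* **Difference-artifact suppression (DAS)** — the same 2-parameter
  least-squares, applied to the *averaged* edit-on vs edit-off signals
  band-limited to 2.8–3.5 ppm. The band limit is evaluated inside the
  iteration (equivalently: the misfit is taken over the masked spectra).
  Masking once and then modulating the fixed band-limited time signal is
  subtly wrong: the hard spectral edges do not commute with frequency
  modulation, and the resulting edge leakage buries a genuine 1 Hz offset.
* **Difference optimization (DO)** — minimizes the L1 norm of the
  magnitude of the difference spectrum over the same span (Powell search);
  a reconstruction from the method's description, flagged approximate.
  Both DAS and DO are pulled slightly off zero by the genuine edited
  signal inside the span; the pull is constant across repeated
  measurements.

`run_pipeline` composes these in the fixed order ECC → SR → average →
DAS/DO → subtract, for seven named variants (`plain`, `SR`, `ECC+SR`,
`SR+DAS`, `ECC+SR+DAS`, `SR+DO`, `ECC+SR+DO`).

## Quantification

The fitter models the FID from the 1-based start sample n_s onward as

    M(t) = exp(iφ0 + 2πi Δf t − β t²) · Σ_m a_m e^(−α_m t) B_m(t)

with non-negative amplitudes solved by NNLS inside each evaluation of a
bounded trust-region optimization over (φ0, Δf, β, α_m), using the
variable-projection Jacobian in the Kaufman approximation (amplitudes held
at their current NNLS solution). β is initialized at the shaping parameter
β_s (the quantity tuned on the grid); α_m start at 2 s⁻¹. n_s = 1 uses
the whole FID; the fitted window is capped at 1024 samples (256 ms), past
which the signal is noise. There is no spline baseline and no soft
constraints — baseline handling is n_s truncation only, deliberately, so
the two tuned knobs are exactly the two that matter.

The basis is rendered from the same resonance tables with a nominal 1 s⁻¹
damping (the fitted α_m, β supply the lineshape). The edit-off basis
carries NAA, tCr (3.03 ppm group — the "total creatine" denominator
convention), Cr 3.91, Cho, mI, Glx, the GABA pseudo-doublet as it appears
in edit-off (inverted outer lines, one tied amplitude) and a water entry.
The difference basis carries GABA (tied doublet), MM 3.0, co-edited
2.5/2.7 ppm entries, Glx 3.75, an inverted NAA entry and water.

Derived quantities:

* **CRLB%** — Fisher information `Re(JᴴJ)/σ²` over all parameters
  (amplitudes, φ0, Δf, β, α_m) with analytic partials; σ estimated from
  the final 10% of fitted-residual samples; reported as
  100·√((F⁻¹)_aa)/a. `crlb_group` bounds a summed amplitude (GABA+MM),
  which is tighter than either component because the overlapping 3.0 ppm
  entries anticorrelate.
* **FWHM(NAA)** — width at half maximum of the real part of the rendered
  fitted NAA component (baseline-free by construction), linear
  interpolation between bins; inverted components are sign-flipped first.
* **SNR(NAA)** — peak |real| of the phased fitted model in 1.7–2.3 ppm
  over twice the RMS of the linearly detrended real data spectrum in
  8.5–10.5 ppm. Detrending removes the constant baseline offset
  (`fid[0]/2` per resonance) inherent to one-sided DFTs, which is not
  noise and would otherwise decouple SNR from the noise level.
* **GABA+/tCr** — (GABA + MM amplitudes of the difference fit)/(tCr of
  the off fit); no editing-efficiency or relaxation calibration, since
  constant factors cancel in coefficients of variation.

## Reproducibility statistics and parameter tuning

CoV^intra is sd/mean (ddof = 1) over one subject's repeated measurements;
mCoV^intra its mean over subjects. CoV^inter is computed per measurement
index across subjects; its mean over the (three) indices is mCoV^inter and
their sd is the quoted error — the per-index convention is a choice (it is
the one that yields an error bar at all). Subjects with failed fits at a
grid point are excluded pairwise with a warning. All CoV statistics are
scale- and subject-permutation-invariant.

The tuning grid defaults to β_s ∈ {200, 300, 450, 600, 900, 1200, 1500,
2000, 3000, 5000} and n_s ∈ {1, 2, 3, 4, 5, 6, 8, 10, 15, 20, 30, 40,
50}, applied independently to the difference and off fits (13² = 169
pairs); only the ranges and counts are prescribed by the procedure being
re-implemented, so the grids include its endpoints and reported optima.
Step 1 picks β_s minimizing the mean over the two reference routines (SR
and ECC+SR+DAS) of the median mCoV^intra over all pairs (ties → smaller
β_s). Step 2, at that β_s, picks the (n_s_diff, n_s_off) pair minimizing
the median mCoV^intra over the six variants (ties → lexicographically
smaller pair). "First decile" summaries are 10th percentiles with linear
interpolation — the boundary of the best tenth of grid points under
lower-is-better mCoV.

## Numerical choices and degenerate inputs

* All 2-parameter phase/frequency fits start at (0, 0) and never return a
  point worse than the start.
* For heavily damped signals φ and f are nearly collinear over the signal
  support; corrections along this valley are equivalent in-band but not
  out-of-band, which is why DAS/DO corrections can disagree in f by a few
  tenths of a Hz while agreeing closely in effect.
* NNLS guarantees a_m ≥ 0; entries genuinely absent get exactly 0 and an
  infinite CRLB%.
* The ppm→bin mask for band limiting includes both endpoints; an empty
  mask raises.
* Failed convergence flags the result and returns the best iterate.

## Desk-scale problem sizes

The default simulated protocol (10 subjects × 3 measurements × (32+32)
transients × 8 coils) matches the emulated study; tests and the
acceptance script run reduced designs — typically 3–4 subjects, 16+16
transients, 2–4 coils, 1024–2048 points and 3–6 seeds, with a 3 × 4²
tuning grid — chosen so the full suite runs on a laptop CPU in minutes
while leaving every qualitative contrast (plain vs SR, ECC vs not, n_s
dependence) clearly resolved.

## Known limitations

* The linear-combination fitter is a simplified stand-in: no spline
  baseline, no soft constraints, singlet-only basis. Claims about β_s and
  n_s concern this fitter; the β_s grid matches the original tool's units
  only nominally (the s⁻² Gaussian-decay convention here is a choice).
* Absolute quantification (water-scaled, institutional units) and
  partial-volume correction are out of scope.
* DAS/DO share the genuine-edited-signal pull discussed above; on cohorts
  where spectral registration already removed all misalignment they add a
  small constant artifact rather than helping.
* The inter-subject CoV of real cohorts includes biological and
  methodological variance inseparable at this scale; synthetic mCoV^inter
  converges to the configured between-subject CV plus measurement noise.
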