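# Methods

This note documents the models, numerical choices and limitations of
`vfadose`, in the spirit of a methods appendix. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. VFA-SPGR relaxometry

The spoiled gradient-echo steady-state signal at flip angle α is
S = M₀(1−E₁)sin α / (1−E₁cos α) with E₁ = exp(−TR/T₁). With two or more
flip angles the model linearizes: plotting y = S/sin α against
x = S/tan α gives a line with slope E₁ and intercept M₀(1−E₁). The fit
is ordinary least squares along the angle axis, which for the default
two-angle protocol (7°/36°, TR 15 ms, TE 3.38 ms) reduces to the exact
two-point line. T₁ = −TR/ln E₁; maps are reported as R1 = 1000/T₁ in
s⁻¹.

Numerical/contract choices:

- **Masking, not clamping.** Fits with E₁ ∉ (0,1) or a non-positive
  intercept have no physical T₁ (pure-noise voxels, or noise pushing the
  two-point slope out of range). They are flagged invalid and set NaN;
  clamping would bias every downstream profile statistic. Background is
  additionally pre-masked where the per-voxel maximum signal falls below
  5 % of a robust global maximum (99th percentile of the max-signal
  volume) — the threshold is a repository decision; scanner software
  masking rules are generally undocumented.
- **Units.** Angles are degrees at every interface and converted to
  radians exactly once; TR/T₁ are ms; R1 is s⁻¹ (r1·t1_ms = 1000 at
  every valid voxel, asserted by tests).
- **B1 ideality.** Nominal flip angles are taken as true flip angles; no
  transmit-field correction is applied. At 3 T over a 35 mm vial this is
  a few-percent systematic at most, and it is a known limitation of
  two-point VFA generally.
- Accuracy: noiseless round-trips recover (T₁, M₀) to < 1e−8 relative
  over T₁ ∈ [200, 4000] ms; under magnitude noise calibrated to a 3.7 %
  R1 CV the median fitted R1 is within 2 % of truth (both asserted).

## 2. Calibration and the radiation chemical yield

ROI statistics use voxel-center inclusion in a circle (default φ10 mm)
on the slice nearest the requested plane — no partial-volume weighting;
at 1 mm resolution this is the simplest reproducible rule. Calibration
curves are unweighted OLS of ROI-mean R1 on level (mM or Gy), matching
simple linear fits; an inverse-variance weighted variant is available
but not default. R² is 1 − SS_res/SS_tot, identical to the squared
Pearson correlation for simple OLS.

**Slope standard error.** Two estimates are offered. The textbook
residual-based SE has heavy t-tails with few levels: with 5 calibration
levels the slope statistic is t(3), for which |t| ≤ 3·SE covers only
~94 % — so coverage-style checks against ±3 SE are run with
`se_method="propagated"`, which propagates the per-point standard errors
of the ROI means (Var(slope) = Σcᵢ²·SEMᵢ², cᵢ = (xᵢ−x̄)/Sxx) and restores
near-nominal normal coverage (measured 99.5 % over 1000 replicates).

**G-value.** G(Fe³⁺) = sensitivity / relaxivity / density, with unit
bookkeeping (s⁻¹kGy⁻¹)/(s⁻¹mM⁻¹) = µmol·L⁻¹·Gy⁻¹ and division by kg/L
yielding µmol/J. Uncertainty is propagated from independent relative
errors in quadrature. The default density is 1.007 kg/L with an
uncertainty of ±0.004 supplied by the caller (the published figure
prints "± 4", an evident typo for ±0.004). With the published inputs
(1.08 s⁻¹kGy⁻¹, 5.7 s⁻¹mM⁻¹) the yield is 0.188 µmol/J.

## 3. Depth-dose analysis

- **Depth convention.** Depth 0 is the first valid gel voxel along the
  beam axis (axis 0 by default); voxel centers sit at (i+0.5)·spacing.
  Profiles carry `origin_mm` so absolute positions remain recoverable —
  edge ringing can make the first "valid" voxel sit one voxel outside
  the nominal gel boundary.
- **Averaging modes.** "Averaging n adjacent slices" is ambiguous
  between in-plane neighborhoods and the slice-select direction; both
  are implemented (`mode="box"`: n×n in-plane boxcar, the default;
  `mode="slices"`: n positions along the slice axis only) and neither is
  asserted as the canonical reading. For i.i.d. voxel noise the n×n
  profile fluctuation shrinks ~1/n (asserted at n=7 vs n=1 against the
  generator truth).
- **Bragg peak.** Global maximum, ties broken toward the shallower
  depth; optional 3-point parabolic refinement, off by default. A flat
  profile is degenerate and raises.
- **PDD.** Normalized so the mean over the entrance window (default
  15 ± 5 mm, a plateau stretch) is 100 % — the literal first voxel is
  contaminated by edge ringing and meniscus effects. PDD is invariant
  under positive rescaling of the input.
- **IC comparison.** Both curves are linearly interpolated (no
  extrapolation) onto the intersection of their depth ranges at the gel
  sampling pitch.
- **Entrance-dose recovery.** The estimator divides the mean δR1 over
  depths 8–24 mm of a **5×5** boxcar profile by the entrance
  sensitivity. The 5×5 window stays on the flat top of the 10 mm square
  field; a 7×7 window spans the penumbra and biases the plateau reading
  by ~−2 % beyond the physical ~−1.5 % plateau decline, while a single
  line is too noisy at the lowest dose (δR1 ≈ 0.16 s⁻¹ against a
  per-voxel noise SD ≈ 0.05 s⁻¹ at CV 3.7 %). Residual expected bias is
  the plateau decline itself (~−1.5 %), well inside the 5 % recovery
  band asserted end-to-end.
- **SNR/CV.** CV % = 100·σ/mean and SNR = mean/σ over the same valid ROI
  voxels; SNR is the companion definition to the CV formula since no
  separate noise-only region is guaranteed to exist in a cropped gel
  volume. σ = 0 reports CV 0 and an infinite SNR sentinel.
- Negative δR1 values are preserved so noise statistics stay unbiased.

## 4. Synthetic phantom

The generator's defaults are the study conditions, not tuning knobs:
φ35 × 78 mm vial at 1 mm isotropic voxels in a 96×64×64 grid (beam axis
= slowest axis; gel entrance at z = 2 mm), Bragg peak 48 mm deep,
entrance/peak sensitivities 1.08/3.84 s⁻¹kGy⁻¹, ESD series 0–600 Gy,
noise CV 3.7 %, flip angles 7°/36° at TR 15 ms.

**Depth-dose curve.** A deliberately simple parametric stand-in (no
particle transport): a linearly declining plateau (0.1 %/mm — the
plateau of a pristine carbon beam is not strictly flat), an
**asymmetric-Gaussian** peak (proximal σ 2.5 mm, distal σ 0.6 mm)
reaching `peak_to_entrance_ratio` (default 3.5) times the entrance dose,
and a sigmoid-gated fragmentation tail of 10 % of the local plateau dose
decaying within a few falloff-widths. The curve equals the entrance dose
exactly at z = 0. The asymmetry is deliberate and physical: a Bragg
curve rises gradually and drops over ~1 mm (range straggling through a
~100 mm water-equivalent degrader), and it is precisely this sharp
distal edge — resolved peak, sub-voxel falloff — that produces the
truncation-artifact signature (overshoot at the peak, undershoot beyond
it) at 1 mm sampling. A single symmetric Gaussian cannot produce both a
resolved peak and a ringing edge.

**Lateral model.** Dose is separable: depth curve × square-field
indicator convolved (analytically, via error functions) with a Gaussian
penumbra whose σ narrows from 1.2 mm at the entrance to 0.8 mm at 38 mm
and grows 0.08 mm/mm beyond — monotone non-decreasing past that depth,
mimicking the observed re-widening near the peak; the exact lateral law
is configurable and not asserted as physics. The analytic convolution
conserves lateral flux exactly (asserted to 0.5 % after voxelization).

**Dose → R1.** R1 = background (0.8 s⁻¹) + s(z)·dose/1000, with s(z)
ramping linearly from the entrance to the peak sensitivity over the last
3 proximal peak-widths and constant beyond — an empirical encoding of
the LET-dependent gel response, with no LET model. Note the peak
sensitivity multiplies the *local* dose here, whereas the measured
3.84 s⁻¹kGy⁻¹ is a per-entrance-dose slope; the synthetic peak response
is therefore steeper than the measured one, which is irrelevant to the
linearity and recovery properties the phantom exists to test.

**Acquisition.** Per flip angle: ideal SPGR signal on an 8×-oversampled
in-plane grid (depth + one lateral axis; the slice axis is neither
oversampled nor truncated) → forward DFT, central k-space crop to the
96×64 acquisition matrix, inverse DFT, magnitude → Rician noise. Two
numerical points matter:

- **Cell-centered registration.** Cropping a DFT and inverse-transforming
  samples the band-limited interpolant at source index j·r (r = the
  oversampling ratio), which mis-registers all content by (r−1)/2 source
  pixels — half a millimeter here, and enough to displace the
  reconstructed Bragg peak by voxels once edge lobes fold in. The
  implementation applies the (r−1)/2 half-sample linear phase so output
  samples sit exactly on acquisition voxel centers. A constant image
  reconstructs exactly; reconstructed energy never exceeds source energy
  (Parseval), with equality iff nothing is cropped.
- **Measuring ringing.** On the coarse grid the sample positions can
  alias the ringing lobes (a grid-aligned step shows only ~1 % sampled
  overshoot). `keep_grid=True` returns the zero-filled reconstruction on
  the source grid, where the canonical ~9 % first overshoot of a step is
  measured (asserted in the 8–10 % band).

**Noise.** Rician (magnitude MR), σ calibrated by a documented pre-run:
a Monte-Carlo of the full signal → noise → VFA-fit chain at a plateau
reference R1, iterated twice to hit the target R1-map CV of 3.7 % (the
CV, not σ, is the quantity that is meaningful to match). The calibration
uses a fixed internal random stream, so σ is a deterministic function of
the phantom spec; realization seeds affect only the noise draws, and all
outputs are bit-reproducible per seed. The expensive deterministic stage
(`precompute_acquisition`) is separated from noise realization
(`realize(seed)`) so replicate studies reuse the truncated signals.

**Calibration vials.** Uniform cylinders (R1 = background +
relaxivity·c, default 5.7 s⁻¹mM⁻¹ over 0–0.5 mM) pushed through the same
truncation + Rician chain, with per-vial σ calibration; a vectorized
replicate helper regenerates only the noise across replicates.

## 5. What the phantom does and does not establish

Passing tests show the *pipeline* is correct and well-conditioned under
the stated conditions: linear dose response is recovered (R² ≥ 0.994 at
the peak across the ESD series), entrance doses invert to within 5 %,
the peak localizes to within a voxel, the Gibbs signature has the
documented sign structure, and the calibration slope is recovered with
honest uncertainty. They do not validate gel chemistry, LET dependence,
B0/B1 hardware effects, imperfect spoiling, slice-profile effects, or
positioning errors — none of which are modeled. Measured-data quantities
(the sensitivity values themselves, SNR 18.4/14.2, CV 2.0/3.7 %, the
48 mm peak) enter only as generator parameters or documentation, not as
things a simulation could re-derive.

## 6. Problem sizes

Default analyses run at the native 96×64×64 grid with 8× in-plane
oversampling in the generator. The test suite uses a reduced vial
(32×24×24, 4× oversampling) for chain tests and the full grid for the
acceptance-level checks; the acceptance script averages the dose-series
R² over 10 noise seeds. The whole suite and the acceptance script each
complete in well under a minute on a single CPU.
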