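# vfadose

Whole-3D Fricke-gel dosimetry by variable-flip-angle SPGR R1 mapping.

Nanocomposite Fricke gel (NC-FG) dosimeters convert absorbed radiation
dose into Fe³⁺, which raises the longitudinal relaxation rate
R1 = 1/T1 linearly with dose. Imaging a whole irradiated gel vial with a
fast 3D spoiled-gradient-echo (SPGR) sequence at two flip angles turns an
MRI scanner into a 3D dosimeter — here used to read out the depth–dose
distribution of a 290 MeV/u carbon pencil beam, Bragg peak included.
`vfadose` implements the complete analysis chain plus a synthetic phantom
generator, so the entire pipeline runs and validates without scanner
data.

## What it computes

**R1 mapping (VFA-SPGR).** The SPGR steady-state signal at flip angle αᵢ
is

    Sᵢ = M₀ (1 − E₁) sin αᵢ / (1 − E₁ cos αᵢ),   E₁ = exp(−TR/T₁).

Regressing Sᵢ/sin αᵢ on Sᵢ/tan αᵢ across flip angles (7° and 36° at
TR = 15 ms by default) gives E₁ as the slope, hence T₁ = −TR/ln E₁ and a
voxel-wise R1 map. Unfittable voxels (E₁ ∉ (0,1), background) are masked,
never clamped.

**Dose analysis.** δR1 = R1(irradiated) − R1(control) is the
dose-proportional signal. The package extracts depth profiles along the
beam axis (single line or n×n boxcar averaging), locates the Bragg peak,
normalizes to percentage depth dose (PDD, entrance = 100 %), compares
against an ionization-chamber reference curve, and reports ROI image
quality (SNR, CV %).

**Calibration.** Reference gels with 0–0.5 mM Fe³⁺ give the relaxivity
slope (s⁻¹ mM⁻¹); irradiated vials give the dose sensitivity
(s⁻¹ kGy⁻¹). Their ratio over the gel density ρ is the radiation
chemical yield

    G(Fe³⁺) [µmol/J] = sensitivity [s⁻¹ kGy⁻¹] ÷ relaxivity [s⁻¹ mM⁻¹] ÷ ρ [kg/L].

**Synthetic phantom.** A parametric carbon-beam dose model (declining
plateau, asymmetric-Gaussian Bragg peak at 48 mm, ~10 % fragmentation
tail, depth-dependent lateral penumbra) fills a virtual φ35 × 78 mm vial
at 1 mm isotropic resolution; dose maps to R1 with depth-dependent
sensitivity (entrance 1.08, peak 3.84 s⁻¹ kGy⁻¹); the acquisition is
simulated per flip angle with finite-k-space (truncation/Gibbs)
reconstruction and Rician magnitude noise calibrated to a 3.7 % R1-map
CV. Every stage gets a ground truth.

## Worked example

```python
import numpy as np
from vfadose import (PhantomSpec, generate_phantom_pair, fit_r1_volume,
                     delta_r1, extract_depth_profile, find_bragg_peak,
                     pdd_normalize, g_value)
from vfadose.dose_analysis import entrance_dose_from_profile

study = generate_phantom_pair(PhantomSpec(), seed=1)     # 600 Gy carbon beam
irr  = fit_r1_volume(study.irradiated, study.protocol)
ctrl = fit_r1_volume(study.control, study.protocol)
dmap = delta_r1(irr, ctrl)

center = study.spec.lateral_center_mm
prof = extract_depth_profile(dmap, beam_axis=0, line_center_mm=center,
                             n_slices_avg=7)
peak_depth, peak_value = find_bragg_peak(prof)
pdd = pdd_normalize(prof)

p5 = extract_depth_profile(dmap, 0, center, 5)
esd = entrance_dose_from_profile(p5, study.spec.entrance_sensitivity)
G = g_value(1.08, 5.7, 1.007, dose_sensitivity_se=0.02, conc_slope_se=0.1,
            density_se=0.004)

print(f"Bragg peak: {peak_depth:.1f} mm in-gel, deltaR1 = {peak_value:.2f} s^-1")
print(f"recovered entrance dose: {esd:.0f} Gy (truth 600)")
print(f"G(Fe3+) = {G.g_value:.3f} +/- {G.g_value_se:.3f} umol/J")
```

prints

```
Bragg peak: 48.0 mm in-gel, deltaR1 = 7.17 s^-1
recovered entrance dose: 583 Gy (truth 600)
G(Fe3+) = 0.188 +/- 0.005 umol/J
```

The peak sits at the generator's 48 mm depth; the entrance dose is
recovered within 3 % of the simulated 600 Gy (the plateau itself declines
~1.5 % over the averaging window); the yield reproduces the published
NC-FG value of 0.188 µmol/J.

A command-line interface mirrors the library:
`vfadose simulate | fit-r1 | calibrate | analyze | report`
(NIfTI volumes, YAML protocols/configs, CSV profiles and calibration
tables).

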