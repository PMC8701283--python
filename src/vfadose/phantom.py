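"""Synthetic carbon-beam gel phantom and SPGR acquisition simulator.

Provides ground truth for every pipeline stage: a parametric depth-dose
curve with a Bragg peak, a separable 3D dose distribution inside a
cylindrical gel vial, a linear dose-to-R1 response with depth-dependent
sensitivity, and an MR acquisition model with finite-k-space (truncation)
reconstruction and Rician magnitude noise.

The depth-dose functional form (linearly declining plateau + Gaussian
Bragg peak + sigmoid-gated fragmentation tail of ~10% of the local
plateau dose) is a deliberately simple parametric stand-in for a
290 MeV/u carbon pencil beam; no particle transport is modeled.  The
depth-dependent sensitivity s(z), ramping linearly from the entrance
value (default 1.08 s^-1 kGy^-1) to the peak value (default
3.84 s^-1 kGy^-1) just before the Bragg peak, encodes the empirical
LET-driven response difference of nanocomposite Fricke gel without any
LET model.

Array convention: axis 0 is the beam/depth axis z, axis 1 the in-plane
lateral axis y, axis 2 the slice axis x.  K-space truncation acts on the
(z, y) plane per x-slice, which is where Gibbs ringing crosses the Bragg
peak; the slice axis is never truncated or oversampled.  Physical
coordinates are voxel centers at (i + 0.5) * spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy.special import erf, expit

from .relaxometry import (
    FlipAngleVolumeSet,
    ScanProtocol,
    _fit_e1_intercept,
    spgr_signal,
)

__all__ = [
    "BeamModel",
    "PhantomSpec",
    "PhantomAcquisition",
    "PhantomStudy",
    "depth_dose",
    "dose_volume",
    "dose_to_r1",
    "sensitivity_at_depth",
    "central_axis_delta_r1",
    "apply_kspace_truncation",
    "calibrate_noise_sigma",
    "simulate_acquisition",
    "precompute_acquisition",
    "generate_phantom_pair",
    "build_protocol",
    "generate_calibration_vials",
    "calibration_slope_replicates",
]

# Internal seed for the noise pre-calibration Monte Carlo.  Fixed so that
# the calibrated sigma is a deterministic function of the phantom spec,
# independent of the realization seed.
_CALIBRATION_SEED = 715_517


@dataclass(frozen=True)
class BeamModel:
    """Parametric carbon pencil-beam model.

    The Bragg peak is an asymmetric Gaussian: ``peak_width_mm`` is the
    proximal sigma (slow rise toward the peak), ``distal_falloff_mm`` the
    distal sigma.  The default distal 0.6 mm corresponds to an 80-20%
    dose falloff of about 1 mm, the scale set by range straggling of a
    290 MeV/u carbon beam degraded by a ~100 mm water-equivalent
    absorber; the falloff is much sharper than the rise, which is what
    makes the peak a truncation-artifact-prone edge at 1 mm sampling.
    ``tail_fraction`` is the
    fragmentation-tail dose just beyond the peak as a fraction of the
    local plateau dose (~10% extra dose past the range, from spallation).
    The lateral penumbra sigma narrows linearly from its entrance value
    to a minimum at ``penumbra_min_depth_mm`` and grows linearly beyond
    it (monotone non-decreasing past that depth), mimicking the observed
    re-widening of the field near the peak.
    """

    entrance_dose_gy: float = 600.0
    peak_depth_mm: float = 48.0
    peak_to_entrance_ratio: float = 3.5
    peak_width_mm: float = 2.5
    distal_falloff_mm: float = 0.6
    plateau_slope_per_mm: float = 0.001
    tail_fraction: float = 0.10
    field_side_mm: float = 10.0
    penumbra_entrance_mm: float = 1.2
    penumbra_min_mm: float = 0.8
    penumbra_min_depth_mm: float = 38.0
    penumbra_growth_per_mm: float = 0.08

    def __post_init__(self):
        for name in (
            "peak_depth_mm",
            "peak_width_mm",
            "distal_falloff_mm",
            "field_side_mm",
            "penumbra_entrance_mm",
            "penumbra_min_mm",
            "penumbra_min_depth_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.entrance_dose_gy < 0:
            raise ValueError("entrance_dose_gy must be >= 0")
        if not (0.0 <= self.tail_fraction < 1.0):
            raise ValueError("tail_fraction must lie in [0, 1)")
        if self.peak_to_entrance_ratio <= 1.0:
            raise ValueError("peak_to_entrance_ratio must exceed 1")

    def penumbra_sigma_mm(self, z_mm):
        """Depth-dependent lateral Gaussian blur sigma (mm)."""
        z = np.asarray(z_mm, dtype=float)
        narrowing = self.penumbra_entrance_mm + (
            self.penumbra_min_mm - self.penumbra_entrance_mm
        ) * np.clip(z / self.penumbra_min_depth_mm, 0.0, 1.0)
        growth = self.penumbra_growth_per_mm * np.clip(
            z - self.penumbra_min_depth_mm, 0.0, None
        )
        out = narrowing + growth
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of the synthetic vial, beam, response and scan.

    Geometry defaults emulate a 50 mL glass vial (phi 35 x 78 mm) imaged
    at 1 mm isotropic resolution, beam entering at ``gel_start_mm`` along
    axis 0.  ``kspace_matrix`` is the (z, y) reconstruction matrix;
    ``n_slices`` the x extent.  ``noise_cv`` is the target coefficient of
    variation of the fitted R1 map in a plateau region (the quantity the
    noise sigma is calibrated against), defaulting to 3.7%.
    """

    vial_diameter_mm: float = 35.0
    vial_length_mm: float = 78.0
    voxel_mm: float = 1.0
    gel_start_mm: float = 2.0
    background_r1_per_s: float = 0.8
    entrance_sensitivity: float = 1.08
    peak_sensitivity: float = 3.84
    beam: BeamModel = field(default_factory=BeamModel)
    noise_cv: float = 0.037
    kspace_matrix: tuple[int, int] = (96, 64)
    n_slices: int = 64
    oversample_factor: int = 8
    m0_arb: float = 1000.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.entrance_sensitivity <= 0 or self.peak_sensitivity <= 0:
            raise ValueError("sensitivities must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.oversample_factor < 2:
            raise ValueError("oversample_factor must be >= 2")
        if self.background_r1_per_s <= 0:
            raise ValueError("background_r1_per_s must be positive")
        z_extent = self.kspace_matrix[0] * self.voxel_mm
        if self.gel_start_mm + self.vial_length_mm > z_extent + 1e-9:
            raise ValueError("vial does not fit in the z field of view")
        if self.vial_diameter_mm > min(
            self.kspace_matrix[1], self.n_slices
        ) * self.voxel_mm:
            raise ValueError("vial does not fit in the lateral field of view")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return (self.kspace_matrix[0], self.kspace_matrix[1], self.n_slices)

    @property
    def lateral_center_mm(self) -> tuple[float, float]:
        return (
            self.kspace_matrix[1] * self.voxel_mm / 2.0,
            self.n_slices * self.voxel_mm / 2.0,
        )


def build_protocol(spec: PhantomSpec) -> ScanProtocol:
    """Scan protocol matched to the phantom grid (TR 15, FA 7/36)."""
    return ScanProtocol(
        tr_ms=15.0,
        te_ms=3.38,
        flip_angles_deg=(7.0, 36.0),
        fov_mm=(
            spec.kspace_matrix[0] * spec.voxel_mm,
            spec.kspace_matrix[1] * spec.voxel_mm,
        ),
        matrix=spec.kspace_matrix,
        slice_thickness_mm=spec.voxel_mm,
        n_slices=spec.n_slices,
        nex=1,
        bandwidth_hz_px=130.0,
    )


# ---------------------------------------------------------------------------
# dose model


def _raw_depth_dose(z, beam: BeamModel):
    d0 = beam.entrance_dose_gy
    zp = beam.peak_depth_mm
    wd = beam.distal_falloff_mm
    plateau = d0 * np.clip(1.0 - beam.plateau_slope_per_mm * z, 0.0, None)
    # plateau terminates smoothly just past the peak (particles stop);
    # widths tied to the distal falloff scale
    gate = expit(-(z - (zp + 2.0 * wd)) / (wd / 3.0))
    rise = expit((z - zp) / (wd / 2.0))
    decay = np.where(
        z > zp, np.exp(-0.5 * ((z - zp) / (1.5 * wd)) ** 2), 1.0
    )
    tail = beam.tail_fraction * plateau * rise * decay
    return plateau * gate + tail


def _peak_term(z, beam: BeamModel):
    """Asymmetric unit Gaussian: proximal sigma peak_width_mm, distal
    sigma distal_falloff_mm (continuous with zero slope at the apex)."""
    zp = beam.peak_depth_mm
    sigma = np.where(z <= zp, beam.peak_width_mm, beam.distal_falloff_mm)
    return np.exp(-0.5 * ((z - zp) / sigma) ** 2)


def depth_dose(z_mm, beam: BeamModel):
    """Central-axis depth-dose curve in Gy (z in mm from the gel surface).

    Piecewise-smooth: linearly declining plateau, asymmetric-Gaussian
    Bragg peak of height ``peak_to_entrance_ratio`` x entrance dose at
    ``peak_depth_mm`` (gradual proximal rise, sharp distal falloff), and
    a sigmoid-gated fragmentation tail that decays to ~0 within a few
    falloff widths beyond the peak.  Exactly equals ``entrance_dose_gy``
    at z = 0.
    """
    z = np.asarray(z_mm, dtype=float)
    d0 = beam.entrance_dose_gy
    zp = beam.peak_depth_mm
    base_zp = float(_raw_depth_dose(np.asarray(zp, dtype=float), beam))
    amp = beam.peak_to_entrance_ratio * d0 - base_zp
    if d0 > 0 and amp <= 0:
        raise ValueError(
            "peak_to_entrance_ratio too small for the plateau+tail baseline"
        )
    out = _raw_depth_dose(z, beam) + amp * _peak_term(z, beam)
    if d0 > 0:
        f0 = float(_raw_depth_dose(np.asarray(0.0), beam)) + amp * float(
            _peak_term(np.asarray(0.0), beam)
        )
        out = out * (d0 / f0)
    return float(out) if out.ndim == 0 else out


def _lateral_factor(u, half_side, sigma):
    """Unit square-field edge profile convolved with a Gaussian.

    ``u`` is the lateral offset from the field axis; broadcasting over a
    depth-dependent ``sigma`` is supported.  Integrates to the field side
    exactly; the sigma -> 0 limit is the sharp indicator.
    """
    u = np.asarray(u, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    sharp = (np.abs(u) <= half_side).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(sigma > 0, sigma, 1.0)
        smooth = 0.5 * (
            erf((half_side - u) / (np.sqrt(2.0) * s))
            + erf((half_side + u) / (np.sqrt(2.0) * s))
        )
    return np.where(sigma > 0, smooth, sharp)


def _grid_coords(spec: PhantomSpec, oversample: bool = False):
    """Voxel-center coordinates (z, y, x) in mm; (z, y) optionally oversampled."""
    ov = spec.oversample_factor if oversample else 1
    nz, ny, nx = spec.grid_shape
    dz = spec.voxel_mm / ov
    z = (np.arange(nz * ov) + 0.5) * dz
    y = (np.arange(ny * ov) + 0.5) * dz
    x = (np.arange(nx) + 0.5) * spec.voxel_mm
    return z, y, x


def _vial_mask_2d(spec: PhantomSpec, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    yc, xc = spec.lateral_center_mm
    r2 = (y[:, None] - yc) ** 2 + (x[None, :] - xc) ** 2
    return r2 <= (spec.vial_diameter_mm / 2.0) ** 2


def _gel_z_mask(spec: PhantomSpec, z: np.ndarray) -> np.ndarray:
    return (z >= spec.gel_start_mm) & (z <= spec.gel_start_mm + spec.vial_length_mm)


def dose_volume(spec: PhantomSpec, oversample: bool = False):
    """3D dose array (Gy) and vial mask on the phantom grid.

    The dose is separable, D(z, y, x) = depth_dose(z) * Ly(y; z) *
    Lx(x; z), with L the square-field indicator convolved with the
    depth-dependent Gaussian penumbra.  Voxels outside the cylindrical
    gel volume are zero and masked out.
    """
    beam = spec.beam
    if beam.field_side_mm >= spec.vial_diameter_mm:
        raise ValueError(
            f"field side {beam.field_side_mm} mm does not fit in the "
            f"{spec.vial_diameter_mm} mm vial"
        )
    z, y, x = _grid_coords(spec, oversample)
    zd = z - spec.gel_start_mm
    d_curve = np.where(zd >= 0, depth_dose(np.clip(zd, 0.0, None), beam), 0.0)
    sigma = beam.penumbra_sigma_mm(np.clip(zd, 0.0, None))
    half = beam.field_side_mm / 2.0
    yc, xc = spec.lateral_center_mm
    ly = _lateral_factor(y[None, :] - yc, half, sigma[:, None])  # (nz, ny)
    lx = _lateral_factor(x[None, :] - xc, half, sigma[:, None])  # (nz, nx)

    mask = (
        _vial_mask_2d(spec, y, x)[None, :, :]
        & _gel_z_mask(spec, z)[:, None, None]
    )
    dose = d_curve[:, None, None] * ly[:, :, None] * lx[:, None, :]
    dose = np.where(mask, dose, 0.0)
    return dose, mask


def sensitivity_at_depth(z_mm, spec: PhantomSpec):
    """Dose sensitivity s(z) in s^-1 kGy^-1.

    Linear ramp from the entrance value (for z below peak - 3 peak
    widths) to the peak value at the Bragg-peak depth, constant beyond.
    """
    zp = spec.beam.peak_depth_mm
    w = spec.beam.peak_width_mm
    out = np.interp(
        np.asarray(z_mm, dtype=float),
        [zp - 3.0 * w, zp],
        [spec.entrance_sensitivity, spec.peak_sensitivity],
    )
    return float(out) if out.ndim == 0 else out


def dose_to_r1(dose: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Ideal (noiseless) R1 volume from a dose volume.

    R1 = background + s(z) * dose / 1000 (dose in Gy, sensitivity per
    kGy).  The background applies everywhere; callers mask non-gel
    voxels.  The depth coordinate is inferred from axis 0 of ``dose``
    relative to the phantom z field of view.
    """
    dose = np.asarray(dose, dtype=float)
    n0 = dose.shape[0]
    dz = spec.kspace_matrix[0] * spec.voxel_mm / n0
    z = (np.arange(n0) + 0.5) * dz - spec.gel_start_mm
    s = sensitivity_at_depth(np.clip(z, 0.0, None), spec)
    shape = (-1,) + (1,) * (dose.ndim - 1)
    return spec.background_r1_per_s + s.reshape(shape) * dose / 1000.0


def central_axis_delta_r1(spec: PhantomSpec, depth_mm) -> np.ndarray:
    """Ground-truth deltaR1 on the beam axis at the given depths (mm)."""
    zd = np.asarray(depth_mm, dtype=float)
    beam = spec.beam
    sigma = beam.penumbra_sigma_mm(zd)
    l00 = _lateral_factor(0.0, beam.field_side_mm / 2.0, sigma) ** 2
    return sensitivity_at_depth(zd, spec) * depth_dose(zd, beam) * l00 / 1000.0


# ---------------------------------------------------------------------------
# acquisition model


def _truncate_nd(
    img: np.ndarray,
    target: tuple[int, ...],
    axes: tuple[int, ...],
    keep_grid: bool = False,
):
    spectrum = sp_fft.fftshift(sp_fft.fftn(img, axes=axes), axes=axes)
    sl = [slice(None)] * img.ndim
    scale = 1.0
    for ax, t in zip(axes, target):
        n = img.shape[ax]
        start = (n - t) // 2
        sl[ax] = slice(start, start + t)
        scale *= t / n
    cropped = spectrum[tuple(sl)]
    if keep_grid:
        # zero-filled reconstruction: band-limited interpolant evaluated
        # on the source grid (resolution lost, sampling kept)
        padded = np.zeros_like(spectrum)
        padded[tuple(sl)] = cropped
        out = sp_fft.ifftn(sp_fft.ifftshift(padded, axes=axes), axes=axes)
        return np.abs(out)
    # Both grids are cell-centered: downsampling by r = n/t must evaluate
    # the band-limited interpolant at fractional source index j*r + (r-1)/2,
    # not j*r.  The (r-1)/2 half-sample registration is a per-axis linear
    # phase on the cropped spectrum.
    for ax, t in zip(axes, target):
        n = img.shape[ax]
        if t == n:
            continue
        k = np.arange(t) - t // 2
        delta = (n / t - 1.0) / 2.0
        phase = np.exp(2j * np.pi * k * delta / n)
        shape = [1] * img.ndim
        shape[ax] = t
        cropped = cropped * phase.reshape(shape)
    out = sp_fft.ifftn(sp_fft.ifftshift(cropped, axes=axes), axes=axes)
    return np.abs(out) * scale


def apply_kspace_truncation(image, target_matrix, axes=None, keep_grid=False):
    """Finite-k-space reconstruction of an ideal image.

    Forward DFT along ``axes``, central crop of the spectrum to
    ``target_matrix``, inverse DFT, magnitude resampled onto the
    cell-centered acquisition grid.  Amplitudes are preserved (a constant
    image reconstructs exactly); energy outside the retained window is
    discarded, so Gibbs ringing appears at sharp edges.  For a 3D image
    the default truncates the (0, 1) plane slice-by-slice along axis 2;
    1D/2D inputs truncate all their axes.

    ``keep_grid=True`` returns the zero-filled reconstruction on the
    *source* grid instead (band-limited interpolant at full sampling),
    which is how the ringing amplitude itself — e.g. the ~9% Gibbs
    overshoot of a step — is measured without aliasing it onto the
    coarse sample positions.
    """
    img = np.asarray(image, dtype=float)
    if np.isscalar(target_matrix) or np.ndim(target_matrix) == 0:
        target_matrix = (int(target_matrix),)
    target = tuple(int(t) for t in target_matrix)
    if axes is None:
        axes = (0,) if img.ndim == 1 else (0, 1)
    axes = tuple(int(a) for a in axes)
    if len(target) != len(axes):
        raise ValueError("target_matrix and axes must have equal length")
    for ax, t in zip(axes, target):
        if t > img.shape[ax]:
            raise ValueError(
                f"target {t} exceeds source size {img.shape[ax]} on axis {ax}"
            )
        if t < 1:
            raise ValueError("target matrix entries must be >= 1")
    if img.ndim == 3 and set(axes) == {0, 1} and not keep_grid:
        nx = img.shape[2]
        out = np.empty((target[0], target[1], nx), dtype=float)
        for ix in range(nx):  # slice-wise to bound memory
            out[:, :, ix] = _truncate_nd(img[:, :, ix], target, (0, 1))
        return out
    return _truncate_nd(img, target, axes, keep_grid=keep_grid)


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator):
    if sigma <= 0:
        return np.array(signal, dtype=float, copy=True)
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def calibrate_noise_sigma(
    protocol: ScanProtocol,
    r1_ref_per_s: float,
    m0: float,
    noise_cv: float,
    n_samples: int = 30_000,
    n_iter: int = 2,
) -> float:
    """Complex-noise sigma giving the target R1-map CV at a reference R1.

    Monte-Carlo pre-run: simulate ``n_samples`` voxels of the reference
    tissue through the full signal -> Rician noise -> VFA fit chain and
    scale sigma multiplicatively until the CV of the fitted R1 matches
    ``noise_cv`` (the mapping is close to linear, so two iterations
    suffice).  Uses a fixed internal random stream, so the result is a
    deterministic function of the inputs.
    """
    if noise_cv <= 0:
        return 0.0
    t1_ref = 1000.0 / r1_ref_per_s
    angles = protocol.flip_angles_rad
    signals = np.array(
        [spgr_signal(m0, t1_ref, protocol, a) for a in protocol.flip_angles_deg]
    )
    rng = np.random.default_rng(_CALIBRATION_SEED)
    noisy_base = rng.normal(size=(2, len(angles), n_samples))
    sigma = noise_cv * float(signals.min())
    for _ in range(n_iter):
        meas = np.hypot(
            signals[:, None] + sigma * noisy_base[0],
            sigma * noisy_base[1],
        )
        e1, b = _fit_e1_intercept(meas, angles)
        ok = np.isfinite(e1) & (e1 > 0) & (e1 < 1) & (b > 0)
        r1 = -1000.0 * np.log(e1[ok]) / protocol.tr_ms
        cv = float(r1.std(ddof=1) / r1.mean())
        sigma *= noise_cv / cv
    return float(sigma)


def simulate_acquisition(
    r1_ideal: np.ndarray,
    m0_map: np.ndarray,
    protocol: ScanProtocol,
    spec: PhantomSpec,
    sigma: float | None = None,
    seed: int | None = None,
) -> FlipAngleVolumeSet:
    """Simulate the multi-flip-angle acquisition of one ideal R1 volume.

    Per flip angle: ideal SPGR signal image -> k-space truncation of the
    (z, y) plane to ``spec.kspace_matrix`` -> Rician magnitude noise.
    ``r1_ideal`` may be in-plane oversampled (any multiple of the
    k-space matrix); passing it at the acquisition matrix makes the
    truncation step the identity.  If ``sigma`` is None it is calibrated
    against ``spec.noise_cv`` at the median positive R1 of the volume.
    """
    r1_ideal = np.asarray(r1_ideal, dtype=float)
    m0_map = np.asarray(m0_map, dtype=float)
    if r1_ideal.shape != m0_map.shape:
        raise ValueError("r1_ideal and m0_map must share one shape")
    if sigma is None:
        if spec.noise_cv > 0:
            ref = float(np.median(r1_ideal[(r1_ideal > 0) & (m0_map > 0)]))
            sigma = calibrate_noise_sigma(protocol, ref, spec.m0_arb, spec.noise_cv)
        else:
            sigma = 0.0
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    gel = (r1_ideal > 0) & (m0_map > 0)
    t1 = np.where(gel, 1000.0 / np.where(gel, r1_ideal, 1.0), 1.0)
    volumes = []
    for a in protocol.flip_angles_deg:
        s = np.where(gel, spgr_signal(m0_map, t1, protocol, a), 0.0)
        s = apply_kspace_truncation(s, spec.kspace_matrix, axes=(0, 1))
        volumes.append(_rician(s, sigma, rng))
    return FlipAngleVolumeSet(
        volumes=volumes,
        voxel_spacing_mm=(spec.voxel_mm,) * 3,
        flip_angles_deg=protocol.flip_angles_deg,
    )


@dataclass
class PhantomStudy:
    """One noisy realization of the paired irradiated/control experiment."""

    spec: PhantomSpec
    protocol: ScanProtocol
    irradiated: FlipAngleVolumeSet
    control: FlipAngleVolumeSet
    dose_true: np.ndarray
    r1_true: np.ndarray
    delta_r1_true: np.ndarray
    vial_mask: np.ndarray
    noise_sigma_irradiated: float
    noise_sigma_control: float
    seed: int


@dataclass
class PhantomAcquisition:
    """Noiseless truncated signal volumes, reusable across noise seeds.

    The deterministic (and expensive) part of the simulation — building
    the oversampled dose and R1 volumes and pushing them through the
    SPGR + truncation chain — is done once; :meth:`realize` then draws a
    Rician noise realization per seed.
    """

    spec: PhantomSpec
    protocol: ScanProtocol
    irradiated_signals: list[np.ndarray]
    control_signals: list[np.ndarray] | None
    dose_true: np.ndarray
    r1_true: np.ndarray
    delta_r1_true: np.ndarray
    vial_mask: np.ndarray
    noise_sigma_irradiated: float
    noise_sigma_control: float

    def realize(self, seed: int | None = None) -> PhantomStudy:
        if self.control_signals is None:
            raise ValueError("acquisition was precomputed without a control arm")
        seed = self.spec.rng_seed if seed is None else int(seed)
        rng = np.random.default_rng(seed)
        spacing = (self.spec.voxel_mm,) * 3
        irr = FlipAngleVolumeSet(
            volumes=[
                _rician(s, self.noise_sigma_irradiated, rng)
                for s in self.irradiated_signals
            ],
            voxel_spacing_mm=spacing,
            flip_angles_deg=self.protocol.flip_angles_deg,
        )
        ctrl = FlipAngleVolumeSet(
            volumes=[
                _rician(s, self.noise_sigma_control, rng)
                for s in self.control_signals
            ],
            voxel_spacing_mm=spacing,
            flip_angles_deg=self.protocol.flip_angles_deg,
        )
        return PhantomStudy(
            spec=self.spec,
            protocol=self.protocol,
            irradiated=irr,
            control=ctrl,
            dose_true=self.dose_true,
            r1_true=self.r1_true,
            delta_r1_true=self.delta_r1_true,
            vial_mask=self.vial_mask,
            noise_sigma_irradiated=self.noise_sigma_irradiated,
            noise_sigma_control=self.noise_sigma_control,
            seed=seed,
        )


def _plateau_reference_r1(spec: PhantomSpec, depth_mm: float = 15.0) -> float:
    """R1 in the entrance plateau used as the noise-calibration reference."""
    return spec.background_r1_per_s + float(central_axis_delta_r1(spec, depth_mm))


def precompute_acquisition(
    spec: PhantomSpec,
    protocol: ScanProtocol | None = None,
    include_control: bool = True,
) -> PhantomAcquisition:
    """Run the deterministic half of the phantom simulation.

    Builds the in-plane oversampled dose and ideal R1 volumes slice by
    slice along x, computes the SPGR signals, truncates each (z, y)
    plane to the acquisition matrix, and calibrates the Rician noise
    sigma for the irradiated (plateau reference) and control
    (background) volumes.  Ground-truth arrays are evaluated
    analytically at the acquisition-grid voxel centers.
    """
    protocol = build_protocol(spec) if protocol is None else protocol
    beam = spec.beam
    if beam.field_side_mm >= spec.vial_diameter_mm:
        raise ValueError("field does not fit in the vial")

    z, y, x = _grid_coords(spec, oversample=True)
    zd = np.clip(z - spec.gel_start_mm, 0.0, None)
    gel_z = _gel_z_mask(spec, z)
    d_curve = np.where(gel_z, depth_dose(zd, beam), 0.0)
    sigma_p = beam.penumbra_sigma_mm(zd)
    half = beam.field_side_mm / 2.0
    yc, xc = spec.lateral_center_mm
    ly = _lateral_factor(y[None, :] - yc, half, sigma_p[:, None])
    lx = _lateral_factor(x[None, :] - xc, half, sigma_p[:, None])
    s_z = sensitivity_at_depth(zd, spec)
    r_vial = spec.vial_diameter_mm / 2.0

    nz, ny, nx = spec.grid_shape
    n_angles = len(protocol.flip_angles_deg)
    irr_signals = [np.empty((nz, ny, nx)) for _ in range(n_angles)]
    ctrl_signals = [np.empty((nz, ny, nx)) for _ in range(n_angles)] if include_control else None

    y_off2 = (y - yc) ** 2
    for ix in range(nx):
        in_vial = (y_off2 + (x[ix] - xc) ** 2) <= r_vial**2  # (ny_ov,)
        mask_sl = gel_z[:, None] & in_vial[None, :]
        dose_sl = d_curve[:, None] * ly * lx[:, ix][:, None]
        r1_sl = np.where(
            mask_sl, spec.background_r1_per_s + s_z[:, None] * dose_sl / 1000.0, 0.0
        )
        for ia, a in enumerate(protocol.flip_angles_deg):
            t1_sl = np.where(mask_sl, 1000.0 / np.where(mask_sl, r1_sl, 1.0), 1.0)
            s_sl = np.where(mask_sl, spgr_signal(spec.m0_arb, t1_sl, protocol, a), 0.0)
            irr_signals[ia][:, :, ix] = _truncate_nd(s_sl, spec.kspace_matrix, (0, 1))
            if include_control:
                tc = 1000.0 / spec.background_r1_per_s
                sc = np.where(
                    mask_sl, spgr_signal(spec.m0_arb, tc, protocol, a), 0.0
                )
                ctrl_signals[ia][:, :, ix] = _truncate_nd(
                    sc, spec.kspace_matrix, (0, 1)
                )

    dose_true, vial_mask = dose_volume(spec)
    r1_true = np.where(vial_mask, dose_to_r1(dose_true, spec), 0.0)
    delta_true = np.where(vial_mask, r1_true - spec.background_r1_per_s, 0.0)

    sigma_irr = calibrate_noise_sigma(
        protocol, _plateau_reference_r1(spec), spec.m0_arb, spec.noise_cv
    )
    sigma_ctrl = calibrate_noise_sigma(
        protocol, spec.background_r1_per_s, spec.m0_arb, spec.noise_cv
    )
    return PhantomAcquisition(
        spec=spec,
        protocol=protocol,
        irradiated_signals=irr_signals,
        control_signals=ctrl_signals,
        dose_true=dose_true,
        r1_true=r1_true,
        delta_r1_true=delta_true,
        vial_mask=vial_mask,
        noise_sigma_irradiated=sigma_irr,
        noise_sigma_control=sigma_ctrl,
    )


def generate_phantom_pair(
    spec: PhantomSpec,
    protocol: ScanProtocol | None = None,
    seed: int | None = None,
) -> PhantomStudy:
    """Convenience wrapper: precompute + one noise realization."""
    return precompute_acquisition(spec, protocol).realize(seed)


# ---------------------------------------------------------------------------
# calibration-vial fixtures


def _calibration_vial_noiseless(
    r1_value: float,
    protocol: ScanProtocol,
    m0: float,
    vial_diameter_mm: float,
    grid_shape: tuple[int, int, int],
    voxel_mm: float,
    oversample_factor: int,
) -> list[np.ndarray]:
    """Noiseless truncated signal volumes of one uniform cylindrical vial."""
    nz, ny, nx = grid_shape
    ov = oversample_factor
    y = (np.arange(ny * ov) + 0.5) * voxel_mm / ov
    x = (np.arange(nx) + 0.5) * voxel_mm
    yc = ny * voxel_mm / 2.0
    xc = nx * voxel_mm / 2.0
    t1 = 1000.0 / r1_value
    out = []
    for a in protocol.flip_angles_deg:
        s_gel = float(spgr_signal(m0, t1, protocol, a))
        vol = np.empty((nz, ny, nx))
        for ix in range(nx):
            in_vial = ((y - yc) ** 2 + (x[ix] - xc) ** 2) <= (vial_diameter_mm / 2.0) ** 2
            sl = np.broadcast_to(
                s_gel * in_vial[None, :].astype(float), (nz * ov, ny * ov)
            )
            vol[:, :, ix] = _truncate_nd(np.ascontiguousarray(sl), (nz, ny), (0, 1))
        out.append(vol)
    return out


def generate_calibration_vials(
    fe_concentrations_mm: list[float],
    relaxivity: float = 5.7,
    background_r1: float = 0.8,
    protocol: ScanProtocol | None = None,
    noise_cv: float = 0.037,
    seed: int = 0,
    vial_diameter_mm: float = 20.0,
    grid_shape: tuple[int, int, int] = (16, 24, 24),
    voxel_mm: float = 1.0,
    oversample_factor: int = 8,
    m0: float = 1000.0,
):
    """Synthetic Fe3+ reference-vial series with ground truth.

    One uniform cylindrical vial per concentration with
    R1 = background + relaxivity * c, acquired through the same
    truncation + Rician chain as the beam phantom (noise sigma calibrated
    per vial to ``noise_cv``).  Returns ``(volume_sets, truth)`` where
    ``truth`` is a DataFrame with columns ``fe_mM, r1_true_per_s,
    noise_sigma``.
    """
    if any(c < 0 for c in fe_concentrations_mm):
        raise ValueError("concentrations must be >= 0")
    if protocol is None:
        protocol = ScanProtocol(
            matrix=grid_shape[:2],
            fov_mm=(grid_shape[0] * voxel_mm, grid_shape[1] * voxel_mm),
            n_slices=grid_shape[2],
            nex=1,
        )
    rng = np.random.default_rng(seed)
    sets, rows = [], []
    for c in fe_concentrations_mm:
        r1_true = background_r1 + relaxivity * c
        signals = _calibration_vial_noiseless(
            r1_true, protocol, m0, vial_diameter_mm, grid_shape, voxel_mm,
            oversample_factor,
        )
        sigma = calibrate_noise_sigma(protocol, r1_true, m0, noise_cv)
        sets.append(
            FlipAngleVolumeSet(
                volumes=[_rician(s, sigma, rng) for s in signals],
                voxel_spacing_mm=(voxel_mm,) * 3,
                flip_angles_deg=protocol.flip_angles_deg,
            )
        )
        rows.append({"fe_mM": c, "r1_true_per_s": r1_true, "noise_sigma": sigma})
    return sets, pd.DataFrame(rows)


def calibration_slope_replicates(
    fe_concentrations_mm: list[float],
    n_replicates: int,
    relaxivity: float = 5.7,
    background_r1: float = 0.8,
    noise_cv: float = 0.037,
    seed: int = 0,
    roi_diameter_mm: float = 10.0,
    vial_diameter_mm: float = 20.0,
    grid_shape: tuple[int, int, int] = (16, 24, 24),
    voxel_mm: float = 1.0,
    oversample_factor: int = 8,
    m0: float = 1000.0,
) -> pd.DataFrame:
    """Seeded replicate study of the Fe3+ calibration-slope recovery.

    Runs ``n_replicates`` independent noise realizations of the
    calibration-vial series, restricted to the phi-``roi_diameter_mm``
    ROI voxels of the central slice (the only voxels the downstream
    statistic uses), fits each replicate's R1-vs-concentration line, and
    returns per-replicate ``slope`` and propagated ``slope_se`` (from
    the ROI SD / sqrt(n) of each level).  The noiseless signals are
    computed once and shared across replicates; noise is drawn from a
    single seeded stream.
    """
    protocol = ScanProtocol(
        matrix=grid_shape[:2],
        fov_mm=(grid_shape[0] * voxel_mm, grid_shape[1] * voxel_mm),
        n_slices=grid_shape[2],
        nex=1,
    )
    nz, ny, nx = grid_shape
    # ROI: central z slice, circle in the (y, x) plane
    iy, ix_ = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    yc, xc = ny * voxel_mm / 2.0, nx * voxel_mm / 2.0
    d2 = ((iy + 0.5) * voxel_mm - yc) ** 2 + ((ix_ + 0.5) * voxel_mm - xc) ** 2
    roi = d2 <= (roi_diameter_mm / 2.0) ** 2
    iz = nz // 2

    rng = np.random.default_rng(seed)
    angles = protocol.flip_angles_rad
    concs = np.asarray(fe_concentrations_mm, dtype=float)
    means = np.empty((n_replicates, concs.size))
    sems = np.empty_like(means)
    for ic, c in enumerate(concs):
        r1_true = background_r1 + relaxivity * c
        signals = _calibration_vial_noiseless(
            r1_true, protocol, m0, vial_diameter_mm, grid_shape, voxel_mm,
            oversample_factor,
        )
        s_roi = np.stack([s[iz][roi] for s in signals])  # (n_angles, n_roi)
        sigma = calibrate_noise_sigma(protocol, r1_true, m0, noise_cv)
        noise = rng.normal(
            size=(2, n_replicates, s_roi.shape[0], s_roi.shape[1])
        )
        meas = np.hypot(s_roi[None] + sigma * noise[0], sigma * noise[1])
        e1, b = _fit_e1_intercept(np.moveaxis(meas, 1, 0), angles)
        ok = np.isfinite(e1) & (e1 > 0) & (e1 < 1) & (b > 0)
        r1 = np.where(ok, -1000.0 * np.log(np.where(ok, e1, 0.5)) / protocol.tr_ms, np.nan)
        means[:, ic] = np.nanmean(r1, axis=1)
        n_ok = ok.sum(axis=1)
        sems[:, ic] = np.nanstd(r1, axis=1, ddof=1) / np.sqrt(np.maximum(n_ok, 1))

    xb = concs.mean()
    sxx = np.sum((concs - xb) ** 2)
    cweights = (concs - xb) / sxx
    slopes = means @ cweights
    slope_ses = np.sqrt((sems**2) @ (cweights**2))
    return pd.DataFrame(
        {
            "slope": slopes,
            "slope_se": slope_ses,
            "true_slope": relaxivity,
        }
    )
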