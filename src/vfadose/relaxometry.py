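"""Variable-flip-angle (VFA) SPGR relaxometry.

The spoiled gradient-recalled echo (SPGR) steady-state signal at flip angle
``alpha`` is

    S = M0 * (1 - E1) * sin(alpha) / (1 - E1 * cos(alpha)),
    E1 = exp(-TR / T1).

Acquiring S at two or more flip angles and regressing ``S/sin(alpha)`` on
``S/tan(alpha)`` yields E1 as the slope and ``M0*(1-E1)`` as the intercept,
hence ``T1 = -TR / ln(E1)`` and the longitudinal relaxation rate
``R1 = 1/T1``.  This module implements the signal model, the linearized
two-(or multi-)point fit, and its voxel-wise application to 3D volumes.

Conventions: flip angles are degrees at every public interface and are
converted to radians exactly once internally; TR and T1 are milliseconds;
R1 maps are s^-1 (``r1 = 1000 / t1_ms``).  Nominal flip angles are assumed
to be the true flip angles (no B1 transmit correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "ScanProtocol",
    "FlipAngleVolumeSet",
    "R1Volume",
    "VfaFit",
    "e1_from_t1",
    "t1_from_e1",
    "spgr_signal",
    "vfa_fit_voxel",
    "fit_r1_volume",
]


def _maybe_float(x):
    """Return a Python float for 0-d results, pass arrays through."""
    x = np.asarray(x)
    return float(x) if x.ndim == 0 else x


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition parameters of a 3D VFA-SPGR protocol.

    Defaults reproduce the gel-sample protocol used throughout this
    package: TR 15 ms, TE 3.38 ms, flip angles 7 and 36 degrees,
    256x256 in-plane matrix at 1 mm, 40 slices.
    """

    tr_ms: float = 15.0
    te_ms: float = 3.38
    flip_angles_deg: tuple[float, ...] = (7.0, 36.0)
    fov_mm: tuple[float, float] = (256.0, 256.0)
    matrix: tuple[int, int] = (256, 256)
    slice_thickness_mm: float = 1.0
    n_slices: int = 40
    nex: int = 4
    bandwidth_hz_px: float = 130.0

    def __post_init__(self):
        if self.tr_ms <= 0:
            raise ValueError(f"tr_ms must be positive, got {self.tr_ms}")
        angles = tuple(float(a) for a in self.flip_angles_deg)
        if len(angles) < 2:
            raise ValueError("at least two flip angles are required")
        if len(set(angles)) != len(angles):
            raise ValueError(f"flip angles must be pairwise distinct: {angles}")
        if any(not (0.0 < a < 90.0) for a in angles):
            raise ValueError(f"flip angles must lie strictly in (0, 90) deg: {angles}")
        object.__setattr__(self, "flip_angles_deg", angles)
        if any(int(m) < 8 for m in self.matrix):
            raise ValueError(f"matrix entries must be >= 8, got {self.matrix}")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")

    @property
    def flip_angles_rad(self) -> np.ndarray:
        return np.deg2rad(np.asarray(self.flip_angles_deg, dtype=float))


@dataclass
class FlipAngleVolumeSet:
    """Co-registered 3D magnitude volumes, one per flip angle."""

    volumes: list[np.ndarray]
    voxel_spacing_mm: tuple[float, float, float]
    flip_angles_deg: tuple[float, ...]

    def __post_init__(self):
        if len(self.volumes) != len(self.flip_angles_deg):
            raise ValueError(
                f"{len(self.volumes)} volumes for {len(self.flip_angles_deg)} flip angles"
            )
        shapes = {v.shape for v in self.volumes}
        if len(shapes) != 1:
            raise ValueError(f"volumes differ in shape: {sorted(shapes)}")
        for v, a in zip(self.volumes, self.flip_angles_deg):
            if np.any(v < 0):
                raise ValueError(f"negative intensities in the {a} deg volume")
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        self.flip_angles_deg = tuple(float(a) for a in self.flip_angles_deg)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volumes[0].shape

    def stacked(self) -> np.ndarray:
        """(n_angles, nz, ny, nx) float64 view of the data."""
        return np.stack([np.asarray(v, dtype=float) for v in self.volumes])


@dataclass
class R1Volume:
    """Voxel-wise longitudinal relaxation-rate map.

    ``r1_per_s`` is NaN outside ``valid_mask``.  Positivity of R1 inside
    the mask is guaranteed by the fitting routine, not by this container:
    difference maps (deltaR1) legitimately hold negative values.
    """

    r1_per_s: np.ndarray
    m0: np.ndarray
    valid_mask: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        if not (self.r1_per_s.shape == self.m0.shape == self.valid_mask.shape):
            raise ValueError("r1_per_s, m0 and valid_mask must share one shape")
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.r1_per_s.shape


class VfaFit(NamedTuple):
    t1_ms: float
    m0: float
    valid: bool


def e1_from_t1(t1_ms, tr_ms: float):
    """Longitudinal recovery factor E1 = exp(-TR/T1), strictly in (0, 1)."""
    t1 = np.asarray(t1_ms, dtype=float)
    if tr_ms <= 0:
        raise ValueError(f"tr_ms must be positive, got {tr_ms}")
    if np.any(t1 <= 0):
        raise ValueError("t1_ms must be positive")
    return _maybe_float(np.exp(-tr_ms / t1))


def t1_from_e1(e1, tr_ms: float):
    """Invert E1 = exp(-TR/T1): T1 = -TR / ln(E1).

    E1 outside the open interval (0, 1) has no physical T1; this raises
    so that callers fitting voxel-wise can catch-and-mask instead.
    """
    e1a = np.asarray(e1, dtype=float)
    if tr_ms <= 0:
        raise ValueError(f"tr_ms must be positive, got {tr_ms}")
    if np.any((e1a <= 0) | (e1a >= 1)):
        raise ValueError("E1 must lie strictly in (0, 1): unfittable voxel")
    return _maybe_float(-tr_ms / np.log(e1a))


def spgr_signal(m0, t1_ms, protocol: ScanProtocol, angle_deg: float):
    """Steady-state SPGR magnitude signal at one flip angle.

    Broadcasts over array-valued ``m0`` and ``t1_ms``.  The result lies in
    ``[0, m0]`` for angles in [0, 90).
    """
    if not (0.0 <= angle_deg < 90.0):
        raise ValueError(f"angle_deg must lie in [0, 90), got {angle_deg}")
    e1 = np.asarray(e1_from_t1(t1_ms, protocol.tr_ms), dtype=float)
    a = np.deg2rad(angle_deg)
    m0a = np.asarray(m0, dtype=float)
    return _maybe_float(m0a * (1.0 - e1) * np.sin(a) / (1.0 - e1 * np.cos(a)))


def _linearize(signals: np.ndarray, angles_rad: np.ndarray):
    """Map signals to the VFA regression coordinates (x, y) = (S/tan, S/sin)."""
    tan = np.tan(angles_rad)
    sin = np.sin(angles_rad)
    shape = (-1,) + (1,) * (signals.ndim - 1)
    x = signals / tan.reshape(shape)
    y = signals / sin.reshape(shape)
    return x, y


def _fit_e1_intercept(signals: np.ndarray, angles_rad: np.ndarray):
    """Vectorized least-squares line through the linearized VFA points.

    ``signals`` has the flip-angle axis first; the fit runs along it for
    every trailing index.  Returns (e1_slope, intercept); degenerate
    geometry (zero spread in x) yields NaN rather than raising.
    """
    x, y = _linearize(signals, angles_rad)
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    dx = x - xm
    sxx = np.sum(dx * dx, axis=0)
    sxy = np.sum(dx * (y - ym), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
    b = ym - e1 * xm
    return e1, b


def vfa_fit_voxel(signals: Sequence[float], protocol: ScanProtocol) -> VfaFit:
    """Fit (T1, M0) for a single voxel from per-angle signals.

    With exactly two angles this reduces to the exact two-point line.
    Never raises on degenerate data: all-zero signals, a slope outside
    (0, 1), or a non-positive intercept return ``valid=False`` and NaN
    estimates.  Downstream code must honor the flag.
    """
    s = np.asarray(signals, dtype=float)
    angles = protocol.flip_angles_rad
    if s.shape != angles.shape:
        raise ValueError(
            f"expected {len(angles)} signals for protocol angles, got {s.shape}"
        )
    if not np.all(np.isfinite(s)) or np.any(s < 0):
        return VfaFit(np.nan, np.nan, False)
    if np.all(s <= 0):
        return VfaFit(np.nan, np.nan, False)
    e1, b = _fit_e1_intercept(s[:, None], angles)
    e1, b = float(e1[0]), float(b[0])
    if not (np.isfinite(e1) and 0.0 < e1 < 1.0 and b > 0.0):
        return VfaFit(np.nan, np.nan, False)
    t1 = float(t1_from_e1(e1, protocol.tr_ms))
    return VfaFit(t1, b / (1.0 - e1), True)


def fit_r1_volume(
    data: FlipAngleVolumeSet,
    protocol: ScanProtocol,
    background_threshold: float = 0.05,
) -> R1Volume:
    """Voxel-wise VFA fit of a multi-flip-angle volume set.

    Voxels whose maximum per-angle signal falls below
    ``background_threshold`` times a robust global maximum (the 99th
    percentile of the max-signal volume) are pre-masked as background.
    Fits with E1 outside (0, 1) or a non-positive intercept are flagged
    invalid and excluded (NaN in the map), never clamped.
    """
    angles = np.asarray(protocol.flip_angles_deg, dtype=float)
    if len(data.flip_angles_deg) != len(angles) or not np.allclose(
        data.flip_angles_deg, angles
    ):
        raise ValueError(
            f"volume-set angles {data.flip_angles_deg} do not match "
            f"protocol angles {tuple(angles)}"
        )
    stacked = data.stacked()
    smax = stacked.max(axis=0)
    robust_max = float(np.percentile(smax, 99.0))
    premask = smax > background_threshold * robust_max if robust_max > 0 else np.zeros(
        smax.shape, dtype=bool
    )

    e1, b = _fit_e1_intercept(stacked, protocol.flip_angles_rad)
    with np.errstate(divide="ignore", invalid="ignore"):
        valid = (
            premask
            & np.isfinite(e1)
            & np.isfinite(b)
            & (e1 > 0.0)
            & (e1 < 1.0)
            & (b > 0.0)
        )
        t1_ms = np.where(valid, -protocol.tr_ms / np.log(np.where(valid, e1, 0.5)), np.nan)
        m0 = np.where(valid, b / (1.0 - np.where(valid, e1, 0.5)), np.nan)
        r1 = np.where(valid, 1000.0 / t1_ms, np.nan)
    return R1Volume(
        r1_per_s=r1,
        m0=m0,
        valid_mask=valid,
        voxel_spacing_mm=data.voxel_spacing_mm,
    )
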