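"""Depth-dose analysis of R1 / deltaR1 maps.

The dose-proportional signal of a Fricke-gel dosimeter is
deltaR1 = R1(irradiated) - R1(control).  This module builds deltaR1 maps,
extracts depth profiles along the beam axis (optionally averaging an
n x n in-plane neighborhood, or n adjacent slices), localizes the Bragg
peak, normalizes profiles to percentage depth dose (PDD, entrance = 100%),
compares gel PDDs against an ionization-chamber reference, and computes
ROI image-quality metrics (SNR, CV%).

Depth convention: depth 0 mm is the first valid gel voxel along the beam
axis; physical coordinates are voxel centers at (i + 0.5) * spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import roi_mean_r1
from .relaxometry import R1Volume

__all__ = [
    "DepthProfile",
    "ComparisonReport",
    "delta_r1",
    "extract_depth_profile",
    "find_bragg_peak",
    "pdd_normalize",
    "compare_profiles",
    "entrance_dose_from_profile",
    "image_quality",
]


@dataclass
class DepthProfile:
    """Profile of R1, deltaR1 or relative dose along the beam axis."""

    depth_mm: np.ndarray
    value: np.ndarray
    value_sd: np.ndarray | None = None
    n_averaged: int = 1
    origin_mm: float = 0.0  # physical beam-axis coordinate of depth 0

    def __post_init__(self):
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.depth_mm.shape != self.value.shape:
            raise ValueError("depth_mm and value must have equal length")
        if np.any(np.diff(self.depth_mm) <= 0):
            raise ValueError("depth_mm must be strictly increasing")
        if self.value_sd is not None:
            self.value_sd = np.asarray(self.value_sd, dtype=float)
            if self.value_sd.shape != self.value.shape:
                raise ValueError("value_sd must match value in length")

    def __len__(self) -> int:
        return self.depth_mm.size


@dataclass
class ComparisonReport:
    """Gel PDD vs reference (ionization chamber) PDD on a common grid."""

    common_depth_mm: np.ndarray
    gel_pdd: np.ndarray
    reference_pdd: np.ndarray
    pointwise_diff: np.ndarray
    peak_depth_gel_mm: float
    peak_depth_ref_mm: float
    peak_depth_diff_mm: float


def delta_r1(irradiated: R1Volume, control: R1Volume) -> R1Volume:
    """Voxel-wise R1 difference (irradiated - control).

    Valid only where both inputs are valid.  Negative differences (noise)
    are preserved, not clipped, so downstream statistics stay unbiased.
    The m0 array is carried over from the irradiated map.
    """
    if irradiated.shape != control.shape:
        raise ValueError(
            f"shape mismatch: {irradiated.shape} vs {control.shape}"
        )
    if not np.allclose(irradiated.voxel_spacing_mm, control.voxel_spacing_mm):
        raise ValueError("voxel spacings differ between irradiated and control")
    mask = irradiated.valid_mask & control.valid_mask
    diff = np.where(mask, irradiated.r1_per_s - control.r1_per_s, np.nan)
    return R1Volume(
        r1_per_s=diff,
        m0=np.where(mask, irradiated.m0, np.nan),
        valid_mask=mask,
        voxel_spacing_mm=irradiated.voxel_spacing_mm,
    )


def extract_depth_profile(
    r1map: R1Volume,
    beam_axis: int = 0,
    line_center_mm=None,
    n_slices_avg: int = 1,
    mode: str = "box",
) -> DepthProfile:
    """Depth profile along the beam axis through one in-plane point.

    ``n_slices_avg`` must be odd.  For n = 1 the single-voxel line is
    returned; for n > 1 the profile averages, per depth, either the
    n x n in-plane neighborhood around the line (``mode="box"``) or n
    adjacent positions along the last in-plane axis only
    (``mode="slices"``), with the per-depth SD (ddof=1) over the window.
    Depth 0 is the first valid voxel of the center line; the profile runs
    to its last valid voxel.
    """
    if n_slices_avg < 1 or n_slices_avg % 2 == 0:
        raise ValueError(f"n_slices_avg must be an odd integer >= 1, got {n_slices_avg}")
    if mode not in ("box", "slices"):
        raise ValueError(f"mode must be 'box' or 'slices', got {mode!r}")

    arr = np.moveaxis(r1map.r1_per_s, beam_axis, 0)
    mask = np.moveaxis(r1map.valid_mask, beam_axis, 0)
    spacing = list(r1map.voxel_spacing_mm)
    axis_spacing = spacing.pop(beam_axis)

    if line_center_mm is None:
        line_center_mm = (
            arr.shape[1] * spacing[0] / 2.0,
            arr.shape[2] * spacing[1] / 2.0,
        )
    j = int(np.clip(round(line_center_mm[0] / spacing[0] - 0.5), 0, arr.shape[1] - 1))
    k = int(np.clip(round(line_center_mm[1] / spacing[1] - 0.5), 0, arr.shape[2] - 1))

    line_mask = mask[:, j, k]
    if not line_mask.any():
        raise ValueError(
            f"line at in-plane {tuple(line_center_mm)} mm lies outside the valid mask"
        )
    i0 = int(np.argmax(line_mask))
    i1 = len(line_mask) - int(np.argmax(line_mask[::-1]))

    half = n_slices_avg // 2
    if mode == "box":
        j_lo, j_hi = j - half, j + half + 1
        k_lo, k_hi = k - half, k + half + 1
    else:
        j_lo, j_hi = j, j + 1
        k_lo, k_hi = k - half, k + half + 1
    if j_lo < 0 or k_lo < 0 or j_hi > arr.shape[1] or k_hi > arr.shape[2]:
        raise ValueError("averaging window exceeds the volume bounds")

    window = arr[i0:i1, j_lo:j_hi, k_lo:k_hi].reshape(i1 - i0, -1)
    wmask = mask[i0:i1, j_lo:j_hi, k_lo:k_hi].reshape(i1 - i0, -1)
    vals = np.where(wmask, window, np.nan)
    counts = wmask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        total = np.where(wmask, window, 0.0).sum(axis=1)
        mean = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
        sd = np.zeros_like(mean)
        multi = counts > 1
        if multi.any():
            sd[multi] = np.nanstd(vals[multi], axis=1, ddof=1)
    depth = (np.arange(i0, i1) - i0) * axis_spacing
    return DepthProfile(
        depth_mm=depth,
        value=mean,
        value_sd=sd,
        n_averaged=n_slices_avg,
        origin_mm=(i0 + 0.5) * axis_spacing,
    )


def find_bragg_peak(profile: DepthProfile, refine: bool = False):
    """Depth and value of the global profile maximum.

    Ties break toward the shallower depth.  A flat profile has no unique
    peak and raises.  ``refine=True`` applies 3-point parabolic
    interpolation around an interior maximum (off by default).
    """
    v = profile.value
    finite = np.isfinite(v)
    if finite.sum() < 3:
        raise ValueError("need at least 3 finite samples to locate a peak")
    if np.nanmax(v) == np.nanmin(v):
        raise ValueError("flat profile: no unique peak (degenerate)")
    idx = int(np.nanargmax(v))
    depth = float(profile.depth_mm[idx])
    value = float(v[idx])
    if refine and 0 < idx < len(v) - 1 and np.isfinite(v[idx - 1]) and np.isfinite(v[idx + 1]):
        y0, y1, y2 = v[idx - 1], v[idx], v[idx + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            shift = 0.5 * (y0 - y2) / denom
            step = profile.depth_mm[idx + 1] - profile.depth_mm[idx]
            depth += float(shift) * float(step)
            value = float(y1 - 0.25 * (y0 - y2) * shift)
    return depth, value


def pdd_normalize(
    profile: DepthProfile,
    entrance_depth_mm: float = 15.0,
    entrance_window_mm: float = 10.0,
) -> DepthProfile:
    """Normalize a profile to percentage depth dose (entrance = 100%).

    The normalizer is the mean over the entrance window
    ``entrance_depth_mm +/- entrance_window_mm / 2``, a plateau stretch
    rather than the literal first voxel (which is contaminated by edge
    ringing and meniscus effects).
    """
    lo = entrance_depth_mm - entrance_window_mm / 2.0
    hi = entrance_depth_mm + entrance_window_mm / 2.0
    sel = (profile.depth_mm >= lo) & (profile.depth_mm <= hi)
    if not sel.any():
        raise ValueError(
            f"entrance window [{lo}, {hi}] mm contains no profile sample"
        )
    ref = float(np.nanmean(profile.value[sel]))
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError(f"entrance-window mean must be positive, got {ref}")
    scale = 100.0 / ref
    return DepthProfile(
        depth_mm=profile.depth_mm.copy(),
        value=profile.value * scale,
        value_sd=None if profile.value_sd is None else profile.value_sd * scale,
        n_averaged=profile.n_averaged,
        origin_mm=profile.origin_mm,
    )


def compare_profiles(gel: DepthProfile, reference: DepthProfile) -> ComparisonReport:
    """Compare a gel profile with a reference depth-dose curve.

    Both profiles are linearly interpolated (no extrapolation) onto the
    intersection of their depth ranges, sampled at the gel pitch; peak
    depths come from :func:`find_bragg_peak` on the restricted profiles.
    """
    lo = max(gel.depth_mm[0], reference.depth_mm[0])
    hi = min(gel.depth_mm[-1], reference.depth_mm[-1])
    if hi <= lo:
        raise ValueError(
            f"depth ranges are disjoint: gel [{gel.depth_mm[0]}, {gel.depth_mm[-1]}]"
            f" vs reference [{reference.depth_mm[0]}, {reference.depth_mm[-1]}]"
        )
    sel = (gel.depth_mm >= lo) & (gel.depth_mm <= hi)
    grid = gel.depth_mm[sel]
    gel_v = gel.value[sel]
    ref_v = np.interp(grid, reference.depth_mm, reference.value)

    gel_peak, _ = find_bragg_peak(DepthProfile(grid, gel_v))
    ref_peak, _ = find_bragg_peak(DepthProfile(grid, ref_v))
    return ComparisonReport(
        common_depth_mm=grid,
        gel_pdd=gel_v,
        reference_pdd=ref_v,
        pointwise_diff=gel_v - ref_v,
        peak_depth_gel_mm=gel_peak,
        peak_depth_ref_mm=ref_peak,
        peak_depth_diff_mm=gel_peak - ref_peak,
    )


def entrance_dose_from_profile(
    profile: DepthProfile,
    entrance_sensitivity: float,
    window_mm: tuple[float, float] = (8.0, 24.0),
) -> float:
    """Entrance-surface dose (Gy) from a deltaR1 depth profile.

    Divides the mean deltaR1 over the plateau window by the entrance
    dose sensitivity (s^-1 kGy^-1).  The window default spans the flat
    plateau well clear of both the entrance edge (ringing, meniscus) and
    the Bragg peak.  For an unbiased estimate the profile should average
    only the flat top of the field (e.g. a 5x5 in-plane box for a 10 mm
    square field), not the penumbra.
    """
    if entrance_sensitivity <= 0:
        raise ValueError("entrance_sensitivity must be positive")
    lo, hi = window_mm
    sel = (profile.depth_mm >= lo) & (profile.depth_mm <= hi)
    if not sel.any():
        raise ValueError(f"window [{lo}, {hi}] mm contains no profile sample")
    mean_delta = float(np.nanmean(profile.value[sel]))
    return mean_delta / entrance_sensitivity * 1000.0


def image_quality(
    r1map: R1Volume,
    roi_center_mm,
    roi_diameter_mm: float,
    plane="z",
    slab_mm: float | None = None,
):
    """SNR and CV% over a circular ROI of the R1 map.

    CV% = 100 * sigma / mean and SNR = mean / sigma over the same valid
    ROI voxels.  A perfectly uniform ROI reports CV 0 and infinite SNR.
    """
    mean, sd, _ = roi_mean_r1(r1map, roi_center_mm, roi_diameter_mm, plane, slab_mm)
    if sd <= 1e-12 * abs(mean):  # uniform up to summation rounding
        return float("inf"), 0.0
    return mean / sd, 100.0 * sd / mean
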