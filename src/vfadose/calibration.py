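"""Chemical and dose calibration of R1 maps.

Links the relaxometric readout to dosimetric quantities: ROI statistics on
R1 maps, linear calibration fits (R1 vs Fe3+ concentration in mM, or R1 vs
entrance-surface dose in Gy), and the radiation chemical yield

    G(Fe3+) [umol/J] = (dose sensitivity, s^-1 kGy^-1)
                       / (relaxivity, s^-1 mM^-1) / (density, kg/L).

Unit bookkeeping for G: (s^-1 kGy^-1)/(s^-1 mM^-1) = mM/kGy =
umol L^-1 Gy^-1; dividing by kg L^-1 gives umol kg^-1 Gy^-1 = umol/J.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .relaxometry import R1Volume

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "GValueResult",
    "roi_mean_r1",
    "fit_linear_calibration",
    "g_value",
]

_AXIS_LABELS = {"z": 0, "y": 1, "x": 2, 0: 0, 1: 1, 2: 2}


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration level: Fe3+ concentration (mM) or dose (Gy) vs ROI R1."""

    level: float
    r1_mean: float
    r1_sd: float = 0.0
    n_voxels: int | None = None

    def __post_init__(self):
        if self.level < 0:
            raise ValueError(f"level must be >= 0, got {self.level}")
        if self.r1_mean <= 0:
            raise ValueError(f"r1_mean must be positive, got {self.r1_mean}")
        if self.r1_sd < 0:
            raise ValueError(f"r1_sd must be >= 0, got {self.r1_sd}")

    @property
    def sem(self) -> float:
        """Standard error of the ROI mean (r1_sd if n_voxels is unknown)."""
        n = self.n_voxels if self.n_voxels else 1
        return self.r1_sd / np.sqrt(n)


@dataclass
class CalibrationCurve:
    """Linear fit r1_mean = slope * level + intercept."""

    slope: float
    slope_se: float
    intercept: float
    r_squared: float
    points: list[CalibrationPoint] = field(default_factory=list)

    def __post_init__(self):
        levels = {p.level for p in self.points}
        if self.points and len(levels) < 2:
            raise ValueError("a calibration curve needs >= 2 distinct levels")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")

    def predict(self, level):
        return self.slope * np.asarray(level, dtype=float) + self.intercept


@dataclass(frozen=True)
class GValueResult:
    """Radiation chemical yield with propagated uncertainty and its inputs."""

    g_value: float
    g_value_se: float
    inputs: dict

    def __post_init__(self):
        if self.g_value <= 0:
            raise ValueError(f"g_value must be positive, got {self.g_value}")


def roi_mean_r1(
    r1map: R1Volume,
    center_mm,
    diameter_mm: float,
    plane="z",
    slab_mm: float | None = None,
):
    """Mean/SD of R1 over a circular ROI.

    The ROI is a circle of ``diameter_mm`` drawn in the plane normal to
    ``plane`` (axis label 'z'/'y'/'x' or index), centered at the physical
    point ``center_mm`` (3 coordinates, mm, voxel centers at
    ``(i + 0.5) * spacing``).  Membership is by voxel-center inclusion, no
    partial-volume weighting.  Along the normal axis the ROI spans the
    single nearest slice unless ``slab_mm`` requests a thicker slab.
    Only valid voxels contribute.

    Returns ``(mean, sd, n_voxels)``; SD uses ddof=1 (0.0 for a single
    voxel).  An ROI containing no valid voxel raises with the geometry in
    the message.
    """
    axis = _AXIS_LABELS.get(plane)
    if axis is None:
        raise ValueError(f"unknown plane label {plane!r}")
    if diameter_mm <= 0:
        raise ValueError("diameter_mm must be positive")
    center = np.asarray(center_mm, dtype=float)
    if center.shape != (3,):
        raise ValueError("center_mm must have 3 coordinates")
    spacing = np.asarray(r1map.voxel_spacing_mm)
    shape = r1map.shape

    coords = [
        (np.arange(shape[ax]) + 0.5) * spacing[ax] for ax in range(3)
    ]
    inplane_axes = [ax for ax in range(3) if ax != axis]

    # slab selection along the normal axis
    half_slab = (slab_mm if slab_mm is not None else spacing[axis]) / 2.0
    sel_normal = np.abs(coords[axis] - center[axis]) <= half_slab + 1e-9
    if slab_mm is None and not sel_normal.any():
        sel_normal[np.argmin(np.abs(coords[axis] - center[axis]))] = True

    grids = np.meshgrid(*coords, indexing="ij")
    d2 = sum((grids[ax] - center[ax]) ** 2 for ax in inplane_axes)
    sel = d2 <= (diameter_mm / 2.0) ** 2
    sel &= sel_normal.reshape([-1 if ax == axis else 1 for ax in range(3)])
    sel &= r1map.valid_mask

    values = r1map.r1_per_s[sel]
    n = int(values.size)
    if n == 0:
        raise ValueError(
            f"ROI (center {tuple(center)} mm, diameter {diameter_mm} mm, "
            f"plane {plane!r}) contains no valid voxel"
        )
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return mean, sd, n


def fit_linear_calibration(
    points: list[CalibrationPoint],
    weighted: bool = False,
    se_method: str = "residual",
) -> CalibrationCurve:
    """Ordinary least squares of ROI-mean R1 on calibration level.

    ``weighted=True`` switches to inverse-variance weights from each
    point's SEM (requires positive r1_sd everywhere); the default matches
    simple unweighted linear fits.

    ``se_method`` selects the slope standard error: ``"residual"`` (from
    the fit residuals, the textbook OLS estimate) or ``"propagated"``
    (from the per-point SEMs, Var(slope) = sum(c_i^2 sem_i^2) with
    c_i = (x_i - xbar)/Sxx).  With few levels the residual estimate has
    heavy t-tails; the propagated one is preferable whenever honest
    per-point errors exist.
    """
    if len(points) < 2:
        raise ValueError("need at least two calibration points")
    x = np.array([p.level for p in points], dtype=float)
    y = np.array([p.r1_mean for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all calibration levels are identical; cannot fit a line")

    if weighted:
        sem = np.array([p.sem for p in points])
        if np.any(sem <= 0):
            raise ValueError("weighted fit requires positive r1_sd at every point")
        w = 1.0 / sem**2
        sw = w.sum()
        xb, yb = (w * x).sum() / sw, (w * y).sum() / sw
        sxx = (w * (x - xb) ** 2).sum()
        slope = (w * (x - xb) * (y - yb)).sum() / sxx
        intercept = yb - slope * xb
        slope_se = float(np.sqrt(1.0 / sxx))
    else:
        res = stats.linregress(x, y)
        slope, intercept, slope_se = float(res.slope), float(res.intercept), float(
            res.stderr
        )

    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)

    if se_method == "propagated":
        sem = np.array([p.sem for p in points])
        xb = x.mean()
        sxx = np.sum((x - xb) ** 2)
        c = (x - xb) / sxx
        slope_se = float(np.sqrt(np.sum(c**2 * sem**2)))
    elif se_method != "residual":
        raise ValueError(f"unknown se_method {se_method!r}")

    return CalibrationCurve(
        slope=slope,
        slope_se=slope_se,
        intercept=float(intercept),
        r_squared=min(float(r2), 1.0),
        points=list(points),
    )


def g_value(
    dose_sensitivity: float,
    conc_slope: float,
    density: float = 1.007,
    dose_sensitivity_se: float | None = None,
    conc_slope_se: float | None = None,
    density_se: float | None = None,
) -> GValueResult:
    """Radiation chemical yield G(Fe3+) in umol/J.

    ``dose_sensitivity`` is the entrance-surface dose response of R1
    (s^-1 kGy^-1), ``conc_slope`` the Fe3+ relaxivity (s^-1 mM^-1), and
    ``density`` the gel density (kg/L, default 1.007).  Uncertainty, when
    any standard error is given, is propagated from independent relative
    errors in quadrature.
    """
    for name, v in (
        ("dose_sensitivity", dose_sensitivity),
        ("conc_slope", conc_slope),
        ("density", density),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    g = dose_sensitivity / conc_slope / density
    rel2 = 0.0
    for v, se in (
        (dose_sensitivity, dose_sensitivity_se),
        (conc_slope, conc_slope_se),
        (density, density_se),
    ):
        if se is not None:
            rel2 += (se / v) ** 2
    return GValueResult(
        g_value=g,
        g_value_se=g * float(np.sqrt(rel2)),
        inputs={
            "dose_sensitivity_per_s_per_kgy": dose_sensitivity,
            "conc_slope_per_s_per_mm": conc_slope,
            "density_kg_per_l": density,
        },
    )
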