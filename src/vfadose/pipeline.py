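"""End-to-end analysis pipeline: volumes in, dosimetry report out.

Stages: VFA R1 fit of irradiated and control volume sets -> deltaR1 map
-> depth profiles (single line and n x n averaged) -> PDD normalization
-> optional ionization-chamber comparison -> ROI image-quality metrics
-> optional Fe3+ calibration fit and G-value.  Every artifact is
regenerable from the config and seed alone; a JSON log records all
parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as vio
from .calibration import fit_linear_calibration, g_value
from .dose_analysis import (
    compare_profiles,
    delta_r1,
    extract_depth_profile,
    find_bragg_peak,
    image_quality,
    pdd_normalize,
)
from .relaxometry import FlipAngleVolumeSet, ScanProtocol, fit_r1_volume

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is attached to the message."""


@dataclass
class PipelineConfig:
    protocol: ScanProtocol
    irradiated_volumes: list[str]
    control_volumes: list[str]
    output_dir: str
    calibration_csv: str | None = None
    ic_reference_csv: str | None = None
    beam_axis: int = 0
    line_center_mm: tuple[float, float] | None = None
    n_slices_avg: int = 7
    profile_mode: str = "box"
    entrance_depth_mm: float = 15.0
    entrance_window_mm: float = 10.0
    background_threshold: float = 0.05
    roi_center_mm: tuple[float, float, float] | None = None
    roi_diameter_mm: float = 10.0
    roi_plane: str = "z"
    dose_sensitivity: float | None = None
    gel_density_kg_per_l: float = 1.007
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        protocol = vio.protocol_from_dict(raw["protocol"])
        kwargs = {k: v for k, v in raw.items() if k != "protocol"}
        for key in ("line_center_mm", "roi_center_mm"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(protocol=protocol, **kwargs)

    def validate_inputs(self):
        if not self.control_volumes:
            raise PipelineError("config: no control volumes given")
        if len(self.irradiated_volumes) != len(self.protocol.flip_angles_deg):
            raise PipelineError(
                "config: number of irradiated volumes must match the protocol "
                f"flip angles ({len(self.protocol.flip_angles_deg)})"
            )
        if len(self.control_volumes) != len(self.protocol.flip_angles_deg):
            raise PipelineError(
                "config: number of control volumes must match the protocol "
                f"flip angles ({len(self.protocol.flip_angles_deg)})"
            )
        for p in (
            list(self.irradiated_volumes)
            + list(self.control_volumes)
            + [self.calibration_csv, self.ic_reference_csv]
        ):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: input file not found: {p}")


def _load_set(paths, protocol: ScanProtocol, stage: str) -> FlipAngleVolumeSet:
    volumes, spacings = [], []
    for p in paths:
        try:
            vol, sp = vio.read_volume(p)
        except Exception as exc:  # re-raise with stage context
            raise PipelineError(f"{stage}: {exc}") from exc
        volumes.append(vol)
        spacings.append(sp)
    if len({s for s in spacings}) != 1:
        raise PipelineError(f"{stage}: volumes have inconsistent voxel spacing")
    return FlipAngleVolumeSet(
        volumes=volumes,
        voxel_spacing_mm=spacings[0],
        flip_angles_deg=protocol.flip_angles_deg,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis chain; returns a report dict of results
    and artifact paths."""
    config.validate_inputs()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"artifacts": {}, "results": {}}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"{name}: {exc}") from exc
        return wrap

    irr_set = _load_set(config.irradiated_volumes, config.protocol, "read-volumes")
    ctrl_set = _load_set(config.control_volumes, config.protocol, "read-volumes")

    irr_map = stage("fit-r1")(
        fit_r1_volume, irr_set, config.protocol, config.background_threshold
    )
    ctrl_map = stage("fit-r1")(
        fit_r1_volume, ctrl_set, config.protocol, config.background_threshold
    )
    delta = stage("delta-r1")(delta_r1, irr_map, ctrl_map)

    spacing = irr_map.voxel_spacing_mm
    vio.write_volume(irr_map.r1_per_s, spacing, out / "r1_irradiated.nii.gz")
    vio.write_volume(ctrl_map.r1_per_s, spacing, out / "r1_control.nii.gz")
    vio.write_volume(delta.r1_per_s, spacing, out / "delta_r1.nii.gz")
    report["artifacts"]["r1_irradiated"] = str(out / "r1_irradiated.nii.gz")
    report["artifacts"]["r1_control"] = str(out / "r1_control.nii.gz")
    report["artifacts"]["delta_r1"] = str(out / "delta_r1.nii.gz")

    profiles = {}
    for n in sorted({1, config.n_slices_avg}):
        prof = stage("profile")(
            extract_depth_profile,
            delta,
            config.beam_axis,
            config.line_center_mm,
            n,
            config.profile_mode,
        )
        profiles[n] = prof
        path = out / f"delta_r1_profile_n{n}.csv"
        vio.write_profile_csv(prof, path)
        report["artifacts"][f"profile_n{n}"] = str(path)

    main_prof = profiles[config.n_slices_avg]
    peak_depth, peak_value = stage("bragg-peak")(find_bragg_peak, main_prof)
    report["results"]["peak_depth_mm"] = peak_depth
    report["results"]["peak_delta_r1_per_s"] = peak_value

    pdd = stage("pdd")(
        pdd_normalize, main_prof, config.entrance_depth_mm, config.entrance_window_mm
    )
    vio.write_profile_csv(pdd, out / "pdd.csv")
    report["artifacts"]["pdd"] = str(out / "pdd.csv")

    if config.ic_reference_csv:
        ref = stage("ic-compare")(vio.read_reference_pdd_csv, config.ic_reference_csv)
        ref_pdd = stage("ic-compare")(
            pdd_normalize, ref, config.entrance_depth_mm, config.entrance_window_mm
        )
        cmp = stage("ic-compare")(compare_profiles, pdd, ref_pdd)
        vio.write_json_report(
            {
                "common_depth_mm": cmp.common_depth_mm,
                "gel_pdd": cmp.gel_pdd,
                "reference_pdd": cmp.reference_pdd,
                "pointwise_diff": cmp.pointwise_diff,
                "peak_depth_gel_mm": cmp.peak_depth_gel_mm,
                "peak_depth_ref_mm": cmp.peak_depth_ref_mm,
                "peak_depth_diff_mm": cmp.peak_depth_diff_mm,
            },
            out / "ic_comparison.json",
        )
        report["artifacts"]["ic_comparison"] = str(out / "ic_comparison.json")
        report["results"]["peak_depth_diff_mm"] = cmp.peak_depth_diff_mm
        report["results"]["mean_abs_pdd_diff"] = float(
            np.mean(np.abs(cmp.pointwise_diff))
        )

    if config.roi_center_mm is not None:
        snr, cv = stage("image-quality")(
            image_quality,
            ctrl_map,
            config.roi_center_mm,
            config.roi_diameter_mm,
            config.roi_plane,
        )
        report["results"]["snr"] = snr
        report["results"]["cv_percent"] = cv

    if config.calibration_csv:
        points = stage("calibration")(vio.read_calibration_csv, config.calibration_csv)
        curve = stage("calibration")(fit_linear_calibration, points)
        report["results"]["calibration"] = {
            "slope": curve.slope,
            "slope_se": curve.slope_se,
            "intercept": curve.intercept,
            "r_squared": curve.r_squared,
        }
        if config.dose_sensitivity is not None:
            gres = stage("g-value")(
                g_value,
                config.dose_sensitivity,
                curve.slope,
                config.gel_density_kg_per_l,
                conc_slope_se=curve.slope_se,
            )
            report["results"]["g_value_umol_per_j"] = gres.g_value
            report["results"]["g_value_se"] = gres.g_value_se

    log = {
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "protocol"
            },
            "protocol": vio.protocol_to_dict(config.protocol),
        },
        "results": report["results"],
    }
    vio.write_json_report(log, out / "pipeline_log.json")
    report["artifacts"]["log"] = str(out / "pipeline_log.json")
    return report
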