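"""End-to-end pipeline: preprocess → iso-point → depth map → calibration.

:func:`run_pipeline` chains the package's stages on either a simulated
canonical scene or on-disk ENVI inputs, writes every artifact (ENVI
cubes, iso-point report, depth-parameter map as TIFF + CSV, profile and
calibration CSVs, a JSON report) and returns the report as a dict.  A
scene whose iso-point is absent or only at the boundary skips the
depth-parameter stages with an explanatory message, since the band
ratio is then not depth-calibratable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from . import envi
from .calibrate import DepthCalibration, extract_profile
from .errors import AmbiguousIsoPointError
from .isopoint import IsoPointModel, depth_parameter_map
from .phantom import GroundTruth, canonical_scene, simulate_cube
from .preprocess import band_average, median_filter, normalize

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("hsdepth")

#: Lateral clearance (in inclusion diameters) defining the background
#: region used for the depth-parameter baseline.
_BACKGROUND_CLEARANCE_DIAMETERS = 3.0
_INCLUSION_DIAMETER_MM = 2.0


@dataclass
class RunConfig:
    """All pipeline inputs and parameters for one run.

    Either ``scene`` (simulate a canonical phantom) or ``cube_path`` +
    ``reference_path`` (load ENVI data) must be set; ``truth_path``
    supplies ground truth for loaded data.  Every field maps 1:1 to a
    key in the flat key-value config file and to a CLI flag (CLI wins
    on conflict).
    """

    scene: Optional[str] = None
    cube_path: Optional[str] = None
    reference_path: Optional[str] = None
    truth_path: Optional[str] = None
    out_dir: str = "hsdepth_out"
    seed: int = 0
    noise_sigma: float = 0.01
    n_x: int = 95
    n_y: int = 500
    filter_size: int = 5
    band_window: int = 20
    lambda_abs_offset_nm: float = 25.0
    lambda_iso_nm: Optional[float] = None
    lambda_abs_nm: Optional[float] = None
    inner_fraction: float = 0.6
    tolerance: float = 2.0
    write_intermediate: bool = False
    log_level: str = "INFO"

    @staticmethod
    def from_file(path, **overrides) -> "RunConfig":
        """Parse a flat ``key = value`` config file; overrides win."""
        values: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            values[key] = val
        values.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig._coerce(values)

    @staticmethod
    def _coerce(values: dict) -> "RunConfig":
        import dataclasses

        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(RunConfig)}
        for key, val in values.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if val is None or (isinstance(val, str) and val.lower() in ("", "none")):
                kwargs[key] = None
                continue
            typ = fields[key].type
            if isinstance(val, str):
                if "int" in typ:
                    val = int(val)
                elif "float" in typ:
                    val = float(val)
                elif "bool" in typ:
                    val = val.lower() in ("1", "true", "yes")
            kwargs[key] = val
        return RunConfig(**kwargs)


def _background_region(truth: GroundTruth, pitch_x_mm: float, pitch_y_mm: float) -> np.ndarray:
    """Pixels farther than the clearance distance from the inclusion."""
    if not truth.inclusion_mask.any():
        return np.ones_like(truth.inclusion_mask)
    dist = ndimage.distance_transform_edt(
        ~truth.inclusion_mask, sampling=(pitch_x_mm, pitch_y_mm)
    )
    clearance = _BACKGROUND_CLEARANCE_DIAMETERS * _INCLUSION_DIAMETER_MM
    region = dist > clearance
    if not region.any():  # tiny scenes: fall back to the farthest third
        region = dist >= np.quantile(dist[dist > 0], 2.0 / 3.0)
    return region


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns and writes the run report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}

    def stage(name: str):
        log.info("stage: %s", name)
        report["stages"].append(name)

    try:
        stage("acquire")
        if config.scene is not None:
            substrate, inclusion, acq = canonical_scene(
                config.scene,
                n_x=config.n_x,
                n_y=config.n_y,
                noise_sigma=config.noise_sigma,
                seed=config.seed,
            )
            raw, ref, truth = simulate_cube(substrate, inclusion, acq)
            envi.write_envi(raw, out / "cube.raw")
            envi.write_envi(ref, out / "reference.raw")
            truth.to_csv(out / "truth.csv")
            analytic_iso = truth.iso_wavelength_analytic
        else:
            if config.cube_path is None or config.reference_path is None:
                raise ValueError("need either scene= or cube_path= + reference_path=")
            raw = envi.read_envi(config.cube_path)
            ref = envi.read_envi(config.reference_path)
            truth = (
                GroundTruth.from_csv(config.truth_path)
                if config.truth_path is not None
                else None
            )
            analytic_iso = None

        stage("preprocess")
        cube_f = median_filter(raw, config.filter_size)
        ref_f = median_filter(ref, config.filter_size)
        normalized, band_mask = normalize(cube_f, ref_f)
        smoothed = band_average(normalized, config.band_window)
        if config.write_intermediate:
            envi.write_envi(smoothed, out / "normalized.raw")

        stage("isopoint")
        iso_info: dict = {"analytic_iso_nm": analytic_iso}
        lambda_iso = config.lambda_iso_nm
        if truth is not None and truth.inclusion_mask.any():
            model = IsoPointModel.from_cube(smoothed, truth)
            try:
                iso_res = model.fit(tolerance=config.tolerance)
                iso_info.update(iso_res.to_keyvalue())
                (out / "isopoint.txt").write_text(
                    "".join(f"{k} = {v}\n" for k, v in iso_res.to_keyvalue().items())
                )
                if iso_res.status == "found" and lambda_iso is None:
                    lambda_iso = iso_res.iso_wavelength
            except AmbiguousIsoPointError as exc:
                iso_info.update(status="ambiguous", candidates=exc.candidates)
        elif lambda_iso is None:
            raise ValueError("no ground truth available: set lambda_iso_nm explicitly")
        report["isopoint"] = iso_info

        if lambda_iso is None:
            msg = (
                f"iso-point {iso_info.get('status', 'unknown')}: the band ratio is not "
                "depth-calibratable for this scene; skipping depth mapping"
            )
            log.info(msg)
            report["depth_map"] = {"skipped": msg}
            report["calibration"] = {"skipped": msg}
        else:
            stage("depthmap")
            lambda_abs = (
                config.lambda_abs_nm
                if config.lambda_abs_nm is not None
                else lambda_iso - config.lambda_abs_offset_nm
            )
            background = (
                _background_region(
                    truth, smoothed.pitch_x_um / 1000.0, smoothed.pitch_y_um / 1000.0
                )
                if truth is not None
                else None
            )
            dmap = depth_parameter_map(
                smoothed, lambda_abs, lambda_iso, background, band_mask
            )
            dmap.to_tiff(out / "depth_map.tif")
            dmap.to_csv(out / "depth_map.csv")
            report["depth_map"] = {
                "lambda_abs_nm": dmap.lambda_abs_nm,
                "lambda_iso_nm": dmap.lambda_iso_nm,
                "baseline": dmap.baseline,
                "n_valid": int(dmap.valid.sum()),
            }

            if truth is not None and truth.inclusion_mask.any():
                stage("calibrate")
                profile = extract_profile(dmap, truth, axis="along")
                profile.to_csv(out / "profile_along.csv")
                fit = DepthCalibration(profile.labelled()).fit(inner=config.inner_fraction)
                (out / "calibration.txt").write_text(fit.summary() + "\n")
                kv = fit.result.to_keyvalue()
                (out / "calibration.csv").write_text(
                    "key,value\n" + "".join(f"{k},{v}\n" for k, v in kv.items())
                )
                report["calibration"] = kv
            else:
                report["calibration"] = {"skipped": "no ground truth"}
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed in stage '{report['stages'][-1]}': {exc}"
        ) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
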