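"""On-disk formats: scan bundles, manifests, calibration JSON, map CSV and
packaged fixtures.

The canonical scan-bundle form is a directory holding ``meta.json`` (grid,
pitch, dose, instrument, seed) plus one tabular text file per pixel,
``px_<i>_<j>.tsv`` — column 1 the wavenumber axis (cm^-1), columns 2..k the
replicate counts.  All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .atomic import atomic_write_text
from .calibrate import CalibrationFit
from .instrument import GridSpec, MicroscopeConfig, ReplicateStack, RoiScan
from .response import ResponseCurve, default_response, identity_response

__all__ = [
    "FormatError",
    "write_scan_bundle",
    "read_scan_bundle",
    "read_manifest",
    "write_calibration",
    "read_calibration",
    "write_map_csv",
    "read_map_csv",
    "load_table1",
    "make_demo_scans",
]


class FormatError(ValueError):
    """Malformed or incomplete on-disk bundle."""


def _config_to_dict(cfg: MicroscopeConfig) -> dict:
    return {
        "name": cfg.name,
        "axis": {"start": float(cfg.axis[0]), "stop": float(cfg.axis[-1]),
                 "n": int(cfg.axis.size)},
        "spot_diameter_um": cfg.spot_diameter,
        "depth_of_focus_um": cfg.depth_of_focus,
        "polarization": cfg.polarization,
        "pol_angle_rad": cfg.pol_angle,
        "depol_contrast": cfg.depol_contrast,
        "replicate_count": cfg.replicate_count,
        "photon_scale": cfg.photon_scale,
        "shot_noise": cfg.shot_noise,
        "baseline_amplitude": cfg.baseline_amplitude,
        "baseline_decay": cfg.baseline_decay,
        "cosmic_ray_rate": cfg.cosmic_ray_rate,
        "overlap_scale": cfg.overlap_scale,
        "lineshape": cfg.lineshape,
        "response_coefficients": list(cfg.response.coefficients),
    }


def _config_from_dict(doc: dict) -> MicroscopeConfig:
    axis = np.linspace(doc["axis"]["start"], doc["axis"]["stop"],
                       doc["axis"]["n"])
    return MicroscopeConfig(
        axis=axis,
        spot_diameter=doc["spot_diameter_um"],
        depth_of_focus=doc["depth_of_focus_um"],
        polarization=doc["polarization"],
        pol_angle=doc["pol_angle_rad"],
        depol_contrast=doc["depol_contrast"],
        replicate_count=doc["replicate_count"],
        photon_scale=doc["photon_scale"],
        shot_noise=doc["shot_noise"],
        baseline_amplitude=doc["baseline_amplitude"],
        baseline_decay=doc["baseline_decay"],
        cosmic_ray_rate=doc["cosmic_ray_rate"],
        overlap_scale=doc["overlap_scale"],
        lineshape=doc.get("lineshape", "gaussian"),
        response=ResponseCurve(tuple(doc["response_coefficients"])),
        name=doc.get("name", "custom"),
    )


def write_scan_bundle(scan: RoiScan, path) -> None:
    """Write a scan as a directory bundle (meta.json + per-pixel TSVs),
    losslessly (full float precision)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "nx": scan.grid.nx, "ny": scan.grid.ny,
        "pitch_um": scan.grid.pitch, "origin_um": list(scan.grid.origin),
        "dose_gy": scan.dose, "seed": scan.seed,
        "orientation": scan.orientation,
        "instrument": _config_to_dict(scan.instrument),
    }
    atomic_write_text(path / "meta.json", json.dumps(meta, indent=2) + "\n")
    for px in scan.pixels:
        cols = [px.axis] + [px.counts[r] for r in range(px.replicate_count)]
        body = "\n".join(
            "\t".join(repr(float(v)) for v in row)
            for row in np.column_stack(cols)
        )
        atomic_write_text(path / f"px_{px.i}_{px.j}.tsv", body + "\n")


def read_scan_bundle(path) -> RoiScan:
    """Read a directory bundle back into a :class:`RoiScan`.

    Raises :class:`FormatError` naming the offending file when a pixel file
    is missing, an axis mismatches the instrument metadata, or the JSON is
    malformed.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"missing {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed JSON in {meta_path}: {exc}") from exc
    cfg = _config_from_dict(meta["instrument"])
    grid = GridSpec(nx=meta["nx"], ny=meta["ny"], pitch=meta["pitch_um"],
                    origin=tuple(meta["origin_um"]))
    pixels = []
    for j in range(grid.ny):
        for i in range(grid.nx):
            fp = path / f"px_{i}_{j}.tsv"
            if not fp.exists():
                raise FormatError(f"missing pixel file px_{i}_{j}")
            data = np.loadtxt(fp)
            axis, counts = data[:, 0], data[:, 1:].T
            if axis.shape != cfg.axis.shape or not np.allclose(
                    axis, cfg.axis, rtol=0, atol=1e-9):
                raise FormatError(f"axis mismatch in px_{i}_{j}")
            x = grid.origin[0] + i * grid.pitch
            y = grid.origin[1] + j * grid.pitch
            pixels.append(ReplicateStack(i=i, j=j, x=x, y=y, axis=axis,
                                         counts=counts,
                                         dose=meta["dose_gy"]))
    return RoiScan(grid=grid, dose=meta["dose_gy"], pixels=tuple(pixels),
                   instrument=cfg, seed=meta.get("seed"),
                   orientation=meta.get("orientation", "landscape"))


def read_manifest(path) -> pd.DataFrame:
    """Manifest CSV: rows of (scan_dir, dose_gy[, instrument, orientation,
    replicate_set])."""
    df = pd.read_csv(path)
    if "scan_dir" not in df.columns or "dose_gy" not in df.columns:
        raise FormatError("manifest needs scan_dir and dose_gy columns")
    if (df["dose_gy"] < 0).any():
        raise FormatError("manifest doses must be >= 0")
    return df


def write_calibration(fit: CalibrationFit, path, peak: float = 1445.0,
                      instrument: str = "custom-60x") -> None:
    doc = {
        "slope": fit.slope, "intercept": fit.intercept,
        "r_squared": fit.r_squared, "slope_se": fit.slope_se,
        "intercept_se": fit.intercept_se, "residual_sd": fit.residual_sd,
        "n": fit.n, "covariance": [list(r) for r in fit.covariance],
        "peak_cm1": peak, "instrument": instrument,
    }
    atomic_write_text(path, json.dumps(doc, indent=2) + "\n")


def read_calibration(path) -> CalibrationFit:
    with open(path) as fh:
        doc = json.load(fh)
    return CalibrationFit(
        slope=doc["slope"], intercept=doc["intercept"],
        r_squared=doc["r_squared"], slope_se=doc["slope_se"],
        intercept_se=doc["intercept_se"], residual_sd=doc["residual_sd"],
        n=doc["n"],
        covariance=tuple(tuple(r) for r in doc["covariance"]),
    )


def write_map_csv(matrix: np.ndarray, path) -> None:
    atomic_write_text(path, pd.DataFrame(matrix).to_csv(
        index=False, header=False))


def read_map_csv(path) -> np.ndarray:
    return pd.read_csv(path, header=None).to_numpy(float)


def load_table1() -> pd.DataFrame:
    """The packaged printed dose / normalized-intensity / SD / RSD table
    for the three instrument set-ups (17 rows; duplicate samples at 0 and
    1.0 Gy)."""
    with resources.files("ramandose.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def make_demo_scans(outdir, seed: int = 0,
                    doses=(0.0, 0.5, 1.0, 1.5, 2.0)) -> list[Path]:
    """Seeded demo fixture: one small (4x4) scan bundle per dose, generated
    quickly from the default phantom and 60x instrument.  Regeneration with
    the same seed is byte-identical."""
    from .instrument import GridSpec, scan_roi
    from .presets import default_phantom, instrument_preset

    outdir = Path(outdir)
    film = default_phantom(seed=seed)
    cfg = instrument_preset("custom-60x")
    grid = GridSpec(nx=4, ny=4, pitch=11.0, origin=(30.0, 30.0))
    paths = []
    for k, dose in enumerate(doses):
        scan = scan_roi(film, cfg, grid, dose, seed=seed * 1000 + k)
        p = outdir / f"scan_{dose:g}gy"
        write_scan_bundle(scan, p)
        paths.append(p)
    return paths
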