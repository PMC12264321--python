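"""Peak quantification, internal-standard normalization and dose-response
calibration.

The dose read-out is the height of a dose-sensitive polymer band (1445 or
2060 cm^-1) divided by the height of the dose-insensitive 2260 cm^-1
monomer band measured in the same spectrum.  This internal-standard ratio
cancels acquisition nuisances (focus drift, layer-thickness variation,
global intensity scale) and yields a linear response over the 0-2 Gy range,
fitted by ordinary least squares and invertible for dose prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .instrument import MONOMER_BAND, POLYMER_BAND, RoiScan
from .phantom import DomainError, ParameterError
from .preprocess import DegenerateInputError, PreprocessConfig, \
    ProcessedSpectrum, preprocess_pipeline

__all__ = [
    "PeakIntensity",
    "CalibrationFit",
    "RoiResponse",
    "ScanQualityError",
    "peak_intensity",
    "internal_standard_ratio",
    "roi_response",
    "fit_dose_response",
    "predict_dose",
]

log = logging.getLogger(__name__)


class ScanQualityError(ValueError):
    """Too many pixels of a scan were unusable."""


@dataclass(frozen=True)
class PeakIntensity:
    center: float
    value: float
    method: str = "height_at_local_max"


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line ``response = intercept + slope * dose`` with r^2 (squared
    Pearson correlation of fitted vs observed), standard errors and the
    parameter covariance needed for inverse prediction."""

    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    intercept_se: float
    residual_sd: float
    n: int
    covariance: tuple[tuple[float, float], tuple[float, float]]


@dataclass(frozen=True)
class RoiResponse:
    """Per-pixel internal-standard ratios over a scan grid (NaN where a
    pixel was excluded as degenerate) and their summary statistics."""

    ratios: np.ndarray  # (ny, nx), NaN = excluded
    mean: float
    sd: float
    rsd: float
    n_excluded: int
    dose: float


def peak_intensity(
    spectrum: ProcessedSpectrum,
    peak_center: float,
    half_window: float = 10.0,
) -> PeakIntensity:
    """Baseline-corrected peak height: the maximum intensity within
    ``peak_center +- half_window`` (cm^-1), clipped at zero."""
    axis = spectrum.axis
    lo, hi = peak_center - half_window, peak_center + half_window
    if lo < axis[0] or hi > axis[-1]:
        raise DomainError(
            f"window [{lo}, {hi}] cm^-1 outside axis "
            f"[{axis[0]}, {axis[-1]}] cm^-1")
    sel = (axis >= lo) & (axis <= hi)
    value = float(max(np.max(spectrum.intensities[sel]), 0.0))
    return PeakIntensity(center=peak_center, value=value)


def internal_standard_ratio(
    spectrum: ProcessedSpectrum,
    peak_center: float = POLYMER_BAND,
    standard_center: float = MONOMER_BAND,
    half_window: float = 10.0,
) -> float:
    """I(peak) / I(2260): the dose read-out normalized to the monomer
    internal standard.  Invariant under any global rescaling of the raw
    counts."""
    denom = peak_intensity(spectrum, standard_center, half_window).value
    if denom == 0.0:
        raise DegenerateInputError(
            "internal-standard intensity is zero; pixel unusable")
    return peak_intensity(spectrum, peak_center, half_window).value / denom


def roi_response(
    scan: RoiScan,
    peak_center: float = POLYMER_BAND,
    config: PreprocessConfig = PreprocessConfig(),
    standard_center: float = MONOMER_BAND,
    standard_floor_fraction: float = 0.02,
    max_excluded_fraction: float = 0.2,
) -> RoiResponse:
    """Preprocess every pixel and form the grid of internal-standard ratios.

    A pixel is excluded (and logged) when its internal-standard intensity is
    zero or falls below ``standard_floor_fraction`` of the ROI median — such
    pixels sample no crystal material, so their "peak" heights are shot-noise
    residuals and their ratio is meaningless.  The default floor (2% of the
    median) sits well above the noise floor of a crystal-free pixel yet below
    any pixel with genuine crystal overlap.  More than ``max_excluded_fraction`` exclusions raises
    :class:`ScanQualityError`.  The SD uses the n-1 denominator;
    RSD = 100 * sd / mean.
    """
    nx, ny = scan.grid.nx, scan.grid.ny
    peak_vals = np.full((ny, nx), np.nan)
    std_vals = np.full((ny, nx), np.nan)
    for px in scan.pixels:
        spec = preprocess_pipeline(px, config)
        peak_vals[px.j, px.i] = peak_intensity(spec, peak_center).value
        std_vals[px.j, px.i] = peak_intensity(spec, standard_center).value

    positive = std_vals[std_vals > 0]
    floor = standard_floor_fraction * (np.median(positive)
                                       if positive.size else 0.0)
    usable = std_vals > max(floor, 0.0)
    ratios = np.full((ny, nx), np.nan)
    ratios[usable] = peak_vals[usable] / std_vals[usable]

    n_excluded = int((~usable).sum())
    if n_excluded:
        for j, i in zip(*np.nonzero(~usable)):
            log.info("excluding degenerate pixel (%d, %d): internal standard "
                     "%.3g below floor %.3g", i, j, std_vals[j, i], floor)
    if n_excluded > max_excluded_fraction * nx * ny:
        raise ScanQualityError(
            f"{n_excluded}/{nx * ny} pixels excluded "
            f"(> {max_excluded_fraction:.0%})")
    vals = ratios[usable]
    if vals.size < 2:
        raise ScanQualityError("fewer than 2 usable pixels")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return RoiResponse(ratios=ratios, mean=mean, sd=sd,
                       rsd=100.0 * sd / mean, n_excluded=n_excluded,
                       dose=scan.dose)


def fit_dose_response(doses, responses, weights=None) -> CalibrationFit:
    """Ordinary least squares of response on dose.

    Duplicate-dose samples enter as separate points.  ``weights`` (optional)
    are 1/sd^2-style WLS weights; the default is unweighted.
    """
    d = np.asarray(doses, float)
    y = np.asarray(responses, float)
    if d.size != y.size or d.size < 3:
        raise ParameterError("need >= 3 matched (dose, response) points")
    if np.ptp(d) == 0:
        raise ParameterError("doses must not all be equal")
    x = sm.add_constant(d)
    model = sm.WLS(y, x, weights=weights) if weights is not None else sm.OLS(y, x)
    res = model.fit()
    fitted = res.fittedvalues
    r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    cov = res.cov_params()
    return CalibrationFit(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        r_squared=r2, slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        residual_sd=float(np.sqrt(res.scale)), n=int(d.size),
        covariance=((float(cov[0, 0]), float(cov[0, 1])),
                    (float(cov[1, 0]), float(cov[1, 1]))),
    )


def predict_dose(fit: CalibrationFit, response: float) -> tuple[float, float]:
    """Invert the calibration: ``dose = (response - intercept) / slope``.

    The standard error comes from first-order propagation of the
    slope/intercept covariance.  Negative predicted doses are returned as-is
    (the caller sees the sign).
    """
    if abs(fit.slope) < 1e-12:
        raise ParameterError("calibration slope is ~0; unusable fit")
    dose = (response - fit.intercept) / fit.slope
    # gradient of dose wrt (intercept, slope)
    g = np.array([-1.0 / fit.slope, -dose / fit.slope])
    cov = np.asarray(fit.covariance)
    se = float(np.sqrt(g @ cov @ g))
    return float(dose), se
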