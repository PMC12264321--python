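"""Spectrometer spectral-response model.

CCD spectrometers lose sensitivity at higher Raman shifts (longer
wavelengths); measurements of a fluorescence standard yield a smooth
relative-sensitivity curve whose reciprocal corrects acquired spectra.  The
certificate polynomial of the real standard is proprietary to each
calibration, so the package ships a synthetic curve: a polynomial in
wavenumber, flat below ~1500 cm^-1 and declining above, shared by the
virtual instrument (which applies the sensitivity) and the corrector (which
divides it out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ResponseCurve", "identity_response", "default_response"]


@dataclass(frozen=True)
class ResponseCurve:
    """Relative spectral sensitivity as a polynomial in wavenumber (cm^-1).

    ``coefficients`` are in increasing-degree order (numpy Polynomial
    convention).  The curve must be strictly positive over any axis it is
    evaluated on; the correction factor is its reciprocal.
    """

    coefficients: tuple[float, ...]

    def sensitivity(self, axis: np.ndarray) -> np.ndarray:
        s = np.polynomial.polynomial.polyval(np.asarray(axis, float),
                                             np.asarray(self.coefficients))
        if np.any(s <= 0):
            raise ValueError("response curve must be positive on the axis")
        return s

    def correction(self, axis: np.ndarray) -> np.ndarray:
        return 1.0 / self.sensitivity(axis)


def identity_response() -> ResponseCurve:
    return ResponseCurve(coefficients=(1.0,))


# degree-5 fit (frozen; see scripts/derive_response_curve.py) to a smooth
# sigmoid-like sensitivity: ~1.0 below 1500 cm^-1 rolling off to ~0.6 at
# 2313 cm^-1, emulating the declining detector response at high Raman shift
_DEFAULT_COEFFS = (
    0.8146462882775851,
    0.0011653511337746177,
    -2.666954082221889e-06,
    2.799099955778064e-09,
    -1.3467043478159007e-12,
    2.3087317624568553e-16,
)


def default_response() -> ResponseCurve:
    return ResponseCurve(coefficients=_DEFAULT_COEFFS)
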