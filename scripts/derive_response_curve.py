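"""Derive the frozen default spectral-response polynomial.

Fits a degree-5 polynomial in wavenumber to a smooth logistic roll-off:
sensitivity ~1.0 below 1500 cm^-1 declining to ~0.6 near 2313 cm^-1,
emulating the reduced CCD sensitivity at high Raman shift.  The printed
coefficients are frozen into ramandose.response.
"""

import numpy as np

nu = np.linspace(600.0, 2330.0, 800)
target = 1.0 - 0.42 / (1.0 + np.exp(-(nu - 1850.0) / 180.0))
coeffs = np.polynomial.polynomial.polyfit(nu, target, 5)

fit = np.polynomial.polynomial.polyval(nu, coeffs)
print("max |fit - target| =", np.max(np.abs(fit - target)))
print("min fit on [600, 2330] =", fit.min())
print("coefficients (increasing degree):")
for c in coeffs:
    print(f"    {c!r},")
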