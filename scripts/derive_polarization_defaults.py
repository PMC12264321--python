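"""Derive the frozen polarization-anisotropy defaults.

Under linear polarization an oriented crystal scatters with factor
f = (1 - alpha) + alpha * cos^2(theta_pol - phi).  With the doubled axis
angle 2*phi ~ von Mises(0, kappa), E[cos 2phi] = A(kappa) = I1(kappa) /
I0(kappa), so the landscape (theta_pol = 0) and portrait (theta_pol = pi/2)
mean factors are (1 - alpha) + alpha * (1 +- A) / 2 and the relative
landscape-portrait contrast is

    100 * alpha * A(kappa) / ((1 - alpha) + alpha * (1 - A(kappa)) / 2).

alpha = 0.6 is chosen (a strongly anisotropic conjugated backbone that
still scatters when crossed); kappa is then solved so the contrast equals
the observed 45.6%.  The printed values are frozen in ramandose.presets.
"""

from scipy import optimize, special

TARGET_CONTRAST = 45.6
ALPHA = 0.6


def contrast(kappa: float, alpha: float = ALPHA) -> float:
    a_k = special.i1(kappa) / special.i0(kappa)
    return 100.0 * alpha * a_k / ((1 - alpha) + alpha * (1 - a_k) / 2)


kappa = optimize.brentq(lambda k: contrast(k) - TARGET_CONTRAST, 1e-3, 20.0,
                        xtol=1e-12)
print(f"ALPHA_DEFAULT = {ALPHA}")
print(f"KAPPA_DEFAULT = {kappa!r}")
print(f"check: contrast(kappa) = {contrast(kappa):.6f} %")
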