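"""The compound-Poisson specific-energy surrogate.

Specific energy z is the stochastic energy per unit mass in a micrometer
target: events arrive as Poisson(D / z1F) with i.i.d. sizes, so the
relative spread is 100 * sqrt(z1D / D) — huge at low dose, falling as
1/sqrt(D).  The film's ~11% heterogeneity is compared against it.
"""

import numpy as np

from ramandose import (MicrodoseModel, sample_specific_energy,
                       specific_energy_rsd)

model = MicrodoseModel()  # z1D back-solved from a 91% spread at 0.2 Gy
print(f"z1F = {model.z1F:.4f} Gy, cv1 = {model.cv1}, "
      f"z1D = {model.z1D:.4f} Gy\n")

print("dose (Gy)   closed-form RSD   sampled RSD (n=2e5)")
for dose in (0.2, 0.5, 1.0, 2.0):
    closed = specific_energy_rsd(model, dose)
    z = sample_specific_energy(model, dose, 200_000, seed=17)
    sampled = 100.0 * z.std(ddof=1) / z.mean()
    print(f"  {dose:4.1f}       {closed:6.1f}%          {sampled:6.1f}%")

print("\nfilm heterogeneity is ~11% at every dose; energy-deposition "
      "spread at 0.2 Gy is ~91%,")
print("so the film cannot resolve the microdosimetric variation without "
      "statistical decoupling")
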