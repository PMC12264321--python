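# Methods

## Film model

The active layer is modelled in two dimensions. Crystal centers form a
homogeneous Poisson process: the count is Poisson with mean
`coverage_fraction · area / (mean_w · mean_l)`, so the expected total
crystal footprint equals the requested coverage of the film area. Widths
and lengths are zero-truncated normals whose location parameters are
*moment-matched* so the sampled means sit on the nominal values
(1.62 ± 0.35 µm and 9.4 ± 5.6 µm); a plain truncated normal with the
nominal location would overshoot the length mean by ~0.6 µm because the
truncation at zero is only 1.7 SD below the mean. Lengths are additionally
truncated below the crystal's own width (moment-matched at the mean width),
so width ≤ length holds by construction rather than by a post-hoc swap that
would bias the width marginal.

Axis angles are axial: the doubled angle follows a von Mises law about the
coating direction, folded to [0, π). `orientation_kappa = 0` gives
isotropy; the packaged default κ = 0.9633 encodes the partial alignment
needed for the observed orientation contrast (below).

Dose response is linear per crystal: `p_i(D) = min((p0 + c·D)·g_i, 1)` with
defaults p0 = 1×10⁻⁵ and c = 4.2×10⁻⁵ Gy⁻¹. These two values are fixed by
two observations: the normalized polymer signal rises ~9.4× between 0 and
2 Gy (so c/p0 = 4.2 Gy⁻¹), and the monomer channel must stay flat to within
0.46% up to 30 Gy (c·30/(1−p0) ≈ 0.13%). The per-crystal multiplier `g_i`
is log-normal with unit median; its log-SD (`conversion_sigma = 0.156`) is
the one generative knob behind the film's spatial heterogeneity and was
calibrated once, by a seed-averaged sweep (`scripts/calibrate_heterogeneity.py`),
so the default simulated ROI RSD is ~11%. The absolute intensity scale is
arbitrary (spectra are in counts; all analysis quantities are ratios).

### Depth collapse and coverage

All read-outs in the emulated protocol are single-focal-plane maps, so the
28 µm layer is collapsed to 2D and the confocal volume is folded into the
lateral sampling footprint: compositions are sampled over a disk of
diameter `spot_diameter · overlap_scale` with `overlap_scale = 3` (the 6 µm
depth of focus spans several crystal thicknesses, so the probe effectively
averages more crystal cross-section than its 1 µm lateral waist). Together
with the default areal coverage of 0.9, this leaves only ~4% of probe
positions with no crystal at all; such pixels carry no active-layer signal
and are excluded from ROI statistics by the internal-standard floor (below).
A 2D coverage of 0.5 with a bare 1 µm spot would instead leave ~40% of
pixels empty — unphysical for a layer many crystals deep.

The circle/rectangle overlap integral is evaluated by pixelating the probe
disk on a Cartesian grid of 0.05 µm resolution; per-crystal intersection
areas are summed (overlapping crystals both count, since both contribute
scatterers). A Monte Carlo random-point oracle agrees within 2%.

## Virtual instrument

Bands are fixed-width profiles, Gaussian by default, with per-band
half-widths (8 cm⁻¹; 10 cm⁻¹ for the alkyl and laminate bands) and
amplitudes linear in local polymer/monomer weight (laminate bands are
constant). The Gaussian default is deliberate: a pure Lorentzian has
1/Δ² wings, and at a 30 Gy linear extrapolation the 2060 cm⁻¹ polymer band
reaches ~210× the monomer band, whose wings would leak tens of percent into
the 2260 cm⁻¹ window — incompatible with the observed dose stability of the
monomer channel. Physically, resolution-dominated solid-state bands have
near-Gaussian cores and negligible far wings; a `lineshape="lorentzian"`
option is retained for sensitivity studies.

The polymer-band gain scale (1.66×10⁵ relative to the monomer band) was
frozen from one calibration run (`scripts/calibrate_gains.py`) so the
processed, normalized 1445 cm⁻¹ response of an unirradiated default film is
1.65 — the observed 0 Gy level. The large number simply reflects that the
polymer backbone is a vastly stronger Raman scatterer per unit weight than
the residual monomer pool it came from.

Orientation anisotropy: a crystal at axis angle φ scatters with factor
`(1−α) + α·cos²(θ_pol − φ)` under linear polarization and with the
orientation average `(1−α) + α/2` under circular polarization. With the
doubled angle von Mises distributed, the mean landscape/portrait contrast is
`100·α·A(κ) / ((1−α) + α(1−A(κ))/2)` with `A = I₁/I₀`. The defaults
α = 0.6, κ = 0.96327 were fixed by this deterministic integral
(`scripts/derive_polarization_defaults.py`) to give a 45.6% contrast at the
packaged anisotropy; α = 0.6 itself is a model choice (a strongly
anisotropic conjugated backbone that still scatters when crossed), and only
the pair (α, κ) is constrained by the contrast.

Noise: replicates are independent Poisson realizations of the expected
counts (`photon_scale = 500` counts per unit composition weight puts the
monomer peak near 10³ counts, a realistic 1 s CCD exposure); cosmic rays
are additive single-channel spikes, 10–100× the local signal, at a
configurable Poisson rate. The detector response is a degree-5 polynomial
sensitivity, flat below ~1500 cm⁻¹ and rolling off to ~0.62 at the top of
the axis (`scripts/derive_response_curve.py`); the simulator applies it and
the corrector divides it out.

## Preprocessing

Order: despike → average replicates → SNIP → response correction →
(optionally) vector normalization, with provenance recorded per spectrum.

*Despiking* exploits the five-replicate protocol: a value above
`median + z·max(1.4826·MAD, √median)` (z = 8) is replaced by the replicate
median. The √median floor is the Poisson counting noise, so channels where
replicates agree to within shot noise are never touched; the operation is
idempotent and bit-preserves spike-free channels. A single-replicate
fallback uses modified z-scores of first differences (threshold 6) with
neighbor interpolation.

*SNIP* iterates window half-widths m = M…1 (M = 60 channels ≈ 120 cm⁻¹),
clipping each channel to the mean of the window edges. Windows that reach
past the spectrum ends use a robust Theil–Sen linear continuation of the
outer 2M channels as fixed pad values: repeating the end value (index
clamping) drags the estimate down by up to ~25% across hundreds of channels
on a sloped baseline, and a least-squares pad inherits the slope of any
band inside the fit window — the median-based line tracks the local
baseline trend while ignoring a minority peak. The final baseline is capped
at the input, so the estimate cannot exceed the spectrum anywhere. The
optional log-log-square-root compression is off by default. Within the
edge-pad zone (M channels at each end) the monotone-in-M clipping ordering
does not apply; all analysis bands sit well inside the axis.

*Vector normalization* (unit Euclidean norm) is applied only when spectra
from different acquisitions are compared on a common scale; internal-
standard peak ratios are invariant to it, so its position in the chain is
immaterial for the dose read-out.

## Quantification and calibration

Peak intensity is the baseline-corrected height at the window maximum
(±10 cm⁻¹, clipped at zero) — matching the "intensity of the X cm⁻¹ peak"
convention; area integration is not used. The dose read-out is
`I(1445)/I(2260)`, invariant under any global rescaling of the raw counts.

ROI statistics use per-pixel ratios with the n−1 SD denominator;
`RSD = 100·SD/mean`. Pixels whose internal-standard intensity is zero or
below 2% of the ROI median are excluded listwise (they sample no crystal;
their "peaks" are noise residuals and their ratios meaningless —
imputation would bias the RSD); more than 20% exclusions is a scan-quality
error. The 2% floor sits ~5× above the shot-noise residual of a truly
empty pixel and well below any pixel with genuine overlap.

Dose response is ordinary least squares of response on dose (duplicate-dose
samples enter as separate points; r² is the squared Pearson correlation of
fitted vs observed; a 1/sd² weighted option exists). Inverse prediction is
`(response − intercept)/slope` with first-order propagation of the
slope/intercept covariance; negative predictions are returned as-is.

## Microdosimetric surrogate

Specific energy in a micrometer voxel is compound Poisson: event count
~ Poisson(D/z1F), i.i.d. event sizes with mean z1F and CV cv1, giving
`RSD(z) = 100·√(z1D/D)` with `z1D = z1F·(1+cv1²)` — an exact D^(−1/2) law.
Only z1D is identifiable from a printed spread: the default
z1D = 0.91²·0.2 = 0.1656 Gy is back-solved from a 91% spread at 0.2 Gy in
a 1 µm³ voxel, with cv1 = 1 (affecting the gamma-sum sampler only, not the
closed form). The closed form then gives 28.8% at 2 Gy, close to but not
equal to the 27% a full Monte Carlo produces at that dose; the surrogate
makes no claim to reproduce transport-level numbers and is used only as a
comparison scale for the film RSD. The sampler uses the gamma-sum identity
(a sum of N i.i.d. gammas of shape k is a gamma of shape N·k).

## What the synthetic data do and do not show

The generator reproduces: grid geometry and replicate counts, dose-linear
normalized response with the observed 0 Gy level and 0→2 Gy rise, the
monomer channel's dose insensitivity through the full preprocessing chain,
~11% dose-independent ROI heterogeneity with spatial correlation on the
crystal length scale, the linear/circular polarization contrast, shot
noise, cosmic rays and a declining detector response.

It does not model: 3D crystal packing or growth kinetics, confocal depth
sectioning or any PSF beyond a hard-edged disk, detector read noise or dark
current, laser-induced polymerization (power is assumed in the linear
regime), wavenumber-axis miscalibration, saturating dose response above the
linear regime, or radiation transport (the microdose model is a surrogate,
not a simulation). Passing tests therefore validate the analysis chain and
its statistical behavior under the stated generative assumptions, not
detector physics: on real instruments the preprocessing constants (despike
threshold, SNIP half-width, response polynomial) would be re-tuned against
measured standards.

## Numerical choices

- Overlap pixelation: 0.05 µm grid, cached per (diameter, resolution).
- Grid indexing: 0-based, row-major, origin at the lower-left pixel
  center; positions are pixel centers in µm.
- SNIP: decreasing schedule, M = 60 channels, Theil–Sen edge pads, LLS off.
- Peak windows: ±10 cm⁻¹; constructed test peaks are centered on sampled
  channels so discretization does not alias into estimator checks.
- All randomness flows through `numpy.random.default_rng`; scans spawn
  per-pixel child seeds from a `SeedSequence`, so any scan is reproducible
  from (parameters, seed) alone.
- Degenerate inputs: all-zero spectra, zero internal standard, flat
  calibration designs and out-of-film probes raise typed errors rather
  than propagating NaNs.

## Known limitations

- The exclusion floor is relative to the ROI median, so a scan in which
  *most* pixels are crystal-free would pass the floor yet be meaningless;
  the 20% exclusion cap is the guard.
- The Theil–Sen edge pad assumes the outer 2M channels are
  baseline-dominated apart from minority bands; a band occupying most of
  that window would still bias the pad.
- `fit_dose_response` is unweighted by default; with strongly
  dose-dependent pixel variance the weighted option should be preferred.
- The microdose surrogate's cv1 is conventional, not fitted; sampled
  distributions (not just RSDs) should not be over-interpreted.
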