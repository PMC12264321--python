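"""Virtual Raman microscope: synthesize replicate spectra and grid scans
from a film phantom.

The model: each Raman band is a fixed-width line profile (Gaussian by
default, Lorentzian optionally) whose amplitude is linear in the local
polymer or monomer content sampled by the probe spot (laser power is
assumed in the regime where no laser-induced polymerization occurs).
Oriented crystals scatter anisotropically under linear polarization
(cos^2 law with depolarization contrast alpha); circular polarization is
orientation-independent.  A smooth exponentially decaying fluorescence
baseline is added, the whole signal is shaped by the detector response
curve, and replicates are independent Poisson (shot-noise) realizations
with sporadic additive cosmic-ray spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .phantom import Composition, DomainError, FilmPhantom, ParameterError, \
    local_composition
from .response import ResponseCurve, identity_response

__all__ = [
    "Peak",
    "PeakTable",
    "default_peak_table",
    "Spectrum",
    "ReplicateStack",
    "GridSpec",
    "RoiScan",
    "MicroscopeConfig",
    "make_axis",
    "polarization_factor",
    "synthesize_spectrum",
    "scan_roi",
    "oriented_config",
]

POLYMER_BAND = 1445.0
MONOMER_BAND = 2260.0
SECONDARY_POLYMER_BAND = 2060.0


def make_axis(start: float, stop: float, step: float = 2.0) -> np.ndarray:
    """Strictly increasing wavenumber axis (cm^-1)."""
    axis = np.arange(start, stop + 0.5 * step, step, dtype=float)
    if axis.size < 2:
        raise ParameterError("axis must contain at least two channels")
    return axis


def _validate_axis(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, float)
    if axis.ndim != 1 or axis.size < 2 or np.any(np.diff(axis) <= 0):
        raise ParameterError("wavenumber axis must be 1-D strictly increasing")
    return axis


@dataclass(frozen=True)
class Peak:
    """One Raman band: center (cm^-1), role, relative gain and half-width
    at half maximum (cm^-1)."""

    center: float
    role: Literal["polymer", "laminate", "monomer"]
    gain: float
    half_width: float = 8.0


@dataclass(frozen=True)
class PeakTable:
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        centers = [p.center for p in self.peaks]
        if len(set(centers)) != len(centers):
            raise ParameterError("peak centers must be unique")

    def __iter__(self):
        return iter(self.peaks)

    def by_center(self, center: float) -> Peak:
        for p in self.peaks:
            if p.center == center:
                return p
        raise KeyError(center)


#: overall scale of polymer-band gain relative to the monomer band, frozen
#: from one calibration run (scripts/calibrate_gains.py) so that the
#: processed 2260-normalized 1445 cm^-1 response of the default phantom at
#: 0 Gy matches the observed ~1.65
POLYMER_GAIN_SCALE = 1.66377e5


def default_peak_table(polymer_gain_scale: float = POLYMER_GAIN_SCALE) -> PeakTable:
    """Bands of partially polymerized EBT3: polyPCDA backbone and alkyl
    modes (dose-sensitive), polyester laminate modes (constant), and the
    monomer C#C stretch at 2260 cm^-1 (dose-insensitive)."""
    g = polymer_gain_scale
    return PeakTable(peaks=(
        Peak(696.0, "polymer", 0.40 * g),         # delta(CCC) backbone
        Peak(1086.0, "polymer", 0.55 * g),        # nu(C-C) backbone
        Peak(1186.0, "polymer", 0.25 * g, 10.0),  # CH2 wag, alkyl
        Peak(1216.0, "polymer", 0.25 * g, 10.0),
        Peak(1240.0, "polymer", 0.30 * g, 10.0),
        Peak(1333.0, "polymer", 0.35 * g, 10.0),  # CH2 twist, alkyl
        Peak(1445.0, "polymer", 1.00 * g),        # nu(C=C), primary band
        Peak(1614.0, "laminate", 2.0, 10.0),      # polyester C=C
        Peak(1725.0, "laminate", 1.5, 10.0),      # polyester C=O
        Peak(2060.0, "polymer", 1.00 * g),        # nu(C#C) polymer
        Peak(2260.0, "monomer", 1.0),             # nu(C#C) monomer
    ))


@dataclass(frozen=True)
class Spectrum:
    axis: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis", _validate_axis(self.axis))
        inten = np.asarray(self.intensities, float)
        if inten.shape != self.axis.shape:
            raise ParameterError("intensities must match axis length")
        object.__setattr__(self, "intensities", inten)


@dataclass(frozen=True)
class ReplicateStack:
    """Replicate spectra acquired at one grid pixel."""

    i: int
    j: int
    x: float
    y: float
    axis: np.ndarray
    counts: np.ndarray  # (replicates, channels)
    dose: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis", _validate_axis(self.axis))
        counts = np.asarray(self.counts, float)
        if counts.ndim != 2 or counts.shape[1] != self.axis.size:
            raise ParameterError("counts must be (replicates, channels)")
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise ParameterError("counts must be finite and >= 0")
        object.__setattr__(self, "counts", counts)

    @property
    def replicate_count(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class GridSpec:
    """Scan grid: 0-based row-major indexing, origin at the lower-left
    pixel center, positions are pixel centers in um."""

    nx: int
    ny: int
    pitch: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ParameterError("grid dimensions must be >= 1")
        if self.pitch <= 0:
            raise ParameterError("pitch must be positive")

    def positions(self):
        for j in range(self.ny):
            for i in range(self.nx):
                yield i, j, (self.origin[0] + i * self.pitch,
                             self.origin[1] + j * self.pitch)


@dataclass(frozen=True)
class RoiScan:
    grid: GridSpec
    dose: float
    pixels: tuple[ReplicateStack, ...]
    instrument: "MicroscopeConfig"
    seed: int | None = None
    orientation: str = "landscape"

    def __post_init__(self) -> None:
        if len(self.pixels) != self.grid.nx * self.grid.ny:
            raise ParameterError("scan must contain nx*ny pixels")

    @property
    def total_spectra(self) -> int:
        return int(sum(p.replicate_count for p in self.pixels))

    def pixel(self, i: int, j: int) -> ReplicateStack:
        return self.pixels[j * self.grid.nx + i]


@dataclass(frozen=True)
class MicroscopeConfig:
    """Virtual instrument settings.

    ``overlap_scale`` folds the focal depth into the lateral sampling
    footprint: the probe samples crystal overlap over a disk of diameter
    ``spot_diameter * overlap_scale`` (the 2D collapse of the confocal
    volume).  ``photon_scale`` converts composition weight units to expected
    detector counts; ``shot_noise=False`` returns the noise-free expectation.
    """

    axis: np.ndarray
    spot_diameter: float = 1.0
    depth_of_focus: float = 6.0
    polarization: Literal["circular", "linear"] = "circular"
    pol_angle: float = 0.0
    depol_contrast: float = 0.6
    replicate_count: int = 5
    photon_scale: float = 500.0
    shot_noise: bool = True
    baseline_amplitude: float = 200.0
    baseline_decay: float = 900.0
    response: ResponseCurve = field(default_factory=identity_response)
    cosmic_ray_rate: float = 0.0
    peaks: PeakTable = field(default_factory=default_peak_table)
    overlap_scale: float = 3.0
    lineshape: Literal["gaussian", "lorentzian"] = "gaussian"
    name: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis", _validate_axis(self.axis))
        if self.replicate_count < 1:
            raise ParameterError("replicate_count must be >= 1")
        if not 0.0 <= self.depol_contrast <= 1.0:
            raise ParameterError("depol_contrast must lie in [0, 1]")
        if self.spot_diameter <= 0 or self.overlap_scale <= 0:
            raise ParameterError("spot sizes must be positive")
        if self.polarization not in ("circular", "linear"):
            raise ParameterError("polarization must be circular or linear")

    @property
    def probe_diameter(self) -> float:
        return self.spot_diameter * self.overlap_scale


def polarization_factor(
    polarization: str,
    axis_angle: float,
    alpha: float,
    pol_angle: float = 0.0,
):
    """Raman response factor of an oriented crystal.

    Linear polarization: ``(1 - alpha) + alpha * cos^2(pol_angle -
    axis_angle)``; circular: the orientation average ``(1 - alpha) +
    alpha / 2``.  The factor lies in [1 - alpha, 1].  ``axis_angle`` may be
    an array.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError("alpha must lie in [0, 1]")
    if polarization == "circular":
        return (1.0 - alpha) + alpha / 2.0 + 0.0 * np.asarray(axis_angle)
    if polarization == "linear":
        return (1.0 - alpha) + alpha * np.cos(pol_angle - np.asarray(axis_angle)) ** 2
    raise ParameterError(f"unknown polarization {polarization!r}")


def _lorentzian(axis: np.ndarray, center: float, half_width: float) -> np.ndarray:
    return half_width**2 / ((axis - center) ** 2 + half_width**2)


def _gaussian(axis: np.ndarray, center: float, half_width: float) -> np.ndarray:
    return np.exp(-np.log(2.0) * ((axis - center) / half_width) ** 2)


def line_profile(axis: np.ndarray, center: float, half_width: float,
                 lineshape: str) -> np.ndarray:
    """Unit-height band profile with the given half-width at half maximum.

    The Gaussian default reflects resolution-dominated solid-state bands
    whose far wings are negligible; the Lorentzian option adds the heavy
    1/Delta^2 wings of a pure damped oscillator.  With Lorentzian wings the
    strong polymer bands leak measurably into the 2260 cm^-1 monomer window
    at high dose, which the observed stability of that channel rules out.
    """
    if lineshape == "gaussian":
        return _gaussian(axis, center, half_width)
    if lineshape == "lorentzian":
        return _lorentzian(axis, center, half_width)
    raise ParameterError(f"unknown lineshape {lineshape!r}")


def noise_free_signal(
    composition: Composition,
    config: MicroscopeConfig,
) -> np.ndarray:
    """Expected detector counts for a given local composition (no noise,
    no cosmic rays).  Channel weights: polymer bands scale with the polymer
    weight, the monomer band with the monomer weight — both times the
    overlap-weighted mean polarization factor — and laminate bands are
    constant."""
    if composition.polymer_weight < 0 or composition.monomer_weight < 0:
        raise ParameterError("composition weights must be >= 0")
    axis = config.axis
    total = composition.total_overlap
    if total > 0:
        angles = np.array([a for a, _ in composition.orientation_samples])
        weights = np.array([w for _, w in composition.orientation_samples])
        f = polarization_factor(config.polarization, angles,
                                config.depol_contrast, config.pol_angle)
        mean_f = float(np.sum(f * weights) / total)
    else:
        mean_f = 0.0

    signal = np.zeros_like(axis)
    for peak in config.peaks:
        if peak.role == "polymer":
            amp = peak.gain * composition.polymer_weight * mean_f
        elif peak.role == "monomer":
            amp = peak.gain * composition.monomer_weight * mean_f
        else:  # laminate: constant, orientation-independent
            amp = peak.gain
        if amp != 0.0:
            signal += amp * line_profile(axis, peak.center, peak.half_width,
                                         config.lineshape)

    counts = config.photon_scale * signal
    if config.baseline_amplitude > 0:
        counts = counts + config.baseline_amplitude * np.exp(
            -(axis - axis[0]) / config.baseline_decay)
    return counts * config.response.sensitivity(axis)


def synthesize_spectrum(
    composition: Composition,
    dose: float,
    config: MicroscopeConfig,
    seed,
    i: int = 0,
    j: int = 0,
    x: float = 0.0,
    y: float = 0.0,
) -> ReplicateStack:
    """Render a replicate stack for one pixel.

    Replicates are independent Poisson realizations of the noise-free
    expected counts; each replicate independently receives
    ``k ~ Poisson(cosmic_ray_rate)`` single-channel spikes at uniform random
    channels with amplitude 10-100x the local signal.  Deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    expected = noise_free_signal(composition, config)
    n_rep = config.replicate_count
    if config.shot_noise:
        counts = rng.poisson(np.broadcast_to(
            expected, (n_rep, expected.size))).astype(float)
    else:
        counts = np.tile(expected, (n_rep, 1))

    if config.cosmic_ray_rate > 0:
        floor = max(float(np.mean(expected)), 1.0)
        for r in range(n_rep):
            k = rng.poisson(config.cosmic_ray_rate)
            if k == 0:
                continue
            channels = rng.integers(0, expected.size, k)
            local = np.maximum(expected[channels], floor)
            counts[r, channels] += rng.uniform(10.0, 100.0, k) * local

    return ReplicateStack(i=i, j=j, x=x, y=y, axis=config.axis,
                          counts=counts, dose=float(dose))


def oriented_config(config: MicroscopeConfig,
                    orientation: Literal["landscape", "portrait"]) -> MicroscopeConfig:
    """Film mounting relative to the (fixed) laser polarization axis.

    Portrait mounting is equivalent to landscape with the polarization angle
    shifted by pi/2 (mod pi); circular polarization is unaffected.  Applying
    the shift twice restores the original configuration.
    """
    if orientation == "landscape":
        return config
    if orientation != "portrait":
        raise ParameterError("orientation must be landscape or portrait")
    shifted = np.mod(config.pol_angle + np.pi / 2.0, np.pi)
    return replace(config, pol_angle=float(shifted))


def scan_roi(
    film: FilmPhantom,
    config: MicroscopeConfig,
    grid: GridSpec,
    dose: float,
    seed,
    orientation: Literal["landscape", "portrait"] = "landscape",
) -> RoiScan:
    """Point-scan a grid over the film: one replicate stack per node, so the
    scan holds exactly ``nx * ny * replicate_count`` spectra."""
    lx, ly = film.area
    x_max = grid.origin[0] + (grid.nx - 1) * grid.pitch
    y_max = grid.origin[1] + (grid.ny - 1) * grid.pitch
    if grid.origin[0] < 0 or grid.origin[1] < 0 or x_max > lx or y_max > ly:
        raise DomainError("scan grid exceeds film area")

    cfg = oriented_config(config, orientation)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(grid.nx * grid.ny)
    pixels = []
    for (i, j, (x, y)), child in zip(grid.positions(), child_seeds):
        comp = local_composition(film, x, y, cfg.probe_diameter, dose)
        pixels.append(synthesize_spectrum(comp, dose, cfg, child,
                                          i=i, j=j, x=x, y=y))
    return RoiScan(grid=grid, dose=float(dose), pixels=tuple(pixels),
                   instrument=cfg,
                   seed=seed if isinstance(seed, int) else None,
                   orientation=orientation)
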