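"""Virtual EBT3 active layers: heterogeneous LiPCDA crystal fields with
dose-dependent polymer conversion.

The active layer of EBT3 radiochromic film is a ~28 um coating containing
rod-shaped crystals of the lithium salt of pentacosa-10,12-diynoic acid
(LiPCDA).  Ionizing radiation polymerizes a small fraction of the monomer in
each crystal; the polymer backbone carries the dose-sensitive Raman modes
while the residual monomer provides a dose-insensitive internal standard.

The phantom collapses the layer to 2D: crystal centers form a homogeneous
Poisson process over the film area, each crystal is a rectangle (length along
its axis) and the focal depth of the probe is folded into an enlarged
effective sampling footprint chosen at the instrument level.  Per-crystal
conversion multipliers (log-normal, unit median) model the residual
polymer/monomer density decoupling that survives internal-standard
normalization and sets the spatial heterogeneity of the read-out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import optimize, stats
from scipy.spatial import cKDTree

__all__ = [
    "Crystal",
    "Composition",
    "FilmPhantom",
    "generate_film",
    "polymer_fraction",
    "local_composition",
    "save_phantom_params",
    "load_phantom_params",
    "crystals_to_csv",
]

#: default crystal dimensions (mean_w, sd_w, mean_l, sd_l) in um, from
#: published measurements of LiPCDA rod crystals
DEFAULT_CRYSTAL_DIMS = (1.62, 0.35, 9.4, 5.6)

#: grid resolution (um) of the pixelated circle/rectangle overlap integral
OVERLAP_RESOLUTION = 0.05


class ParameterError(ValueError):
    """Invalid generator or model parameter."""


class DomainError(ValueError):
    """Query point outside the film area."""


@dataclass(frozen=True)
class Crystal:
    """A single rod-shaped LiPCDA crystal, modelled as a rectangle.

    ``axis_angle`` is the orientation of the long axis in radians within
    [0, pi); ``conversion_multiplier`` is the per-crystal factor g applied to
    the dose->polymer conversion (unit median across the film).
    """

    center: tuple[float, float]
    axis_angle: float
    width: float
    length: float
    conversion_multiplier: float

    def __post_init__(self) -> None:
        vals = (*self.center, self.axis_angle, self.width, self.length,
                self.conversion_multiplier)
        if not all(np.isfinite(v) for v in vals):
            raise ParameterError("crystal fields must be finite")
        if self.width <= 0 or self.length <= 0:
            raise ParameterError("crystal dimensions must be positive")
        if self.width > self.length:
            raise ParameterError("crystal width must not exceed length")


@dataclass(frozen=True)
class Composition:
    """Local polymer/monomer content sampled by a probe spot.

    ``orientation_samples`` lists (axis_angle, overlap_weight) for every
    crystal intersecting the spot; overlap weights are intersection areas in
    um^2.  Weights are zero iff no crystal intersects the spot.
    """

    polymer_weight: float
    monomer_weight: float
    orientation_samples: tuple[tuple[float, float], ...] = ()

    @property
    def total_overlap(self) -> float:
        return float(sum(w for _, w in self.orientation_samples))


@dataclass(frozen=True)
class FilmPhantom:
    """A generated virtual active layer.

    Parameters
    ----------
    area
        (Lx, Ly) film extent in um.
    active_thickness
        Nominal layer thickness in um (metadata; the model is 2D).
    crystals
        The generated crystal field.
    p0, c
        Baseline polymer fraction at 0 Gy and conversion per Gy.  The
        polymer fraction of crystal i at dose D is
        ``min((p0 + c * D) * g_i, 1)``.
    orientation_kappa
        von Mises concentration of the doubled axis angle about the coating
        direction (angle 0); 0 means isotropic.
    conversion_sigma
        Log-scale SD of the per-crystal conversion multiplier.
    seed
        Seed the field was generated from (regeneration is bit-identical).
    """

    area: tuple[float, float]
    crystals: tuple[Crystal, ...]
    p0: float
    c: float
    orientation_kappa: float
    conversion_sigma: float
    seed: int
    active_thickness: float = 28.0
    coverage_fraction: float | None = None
    crystal_dim_params: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.p0 < 0:
            raise ParameterError("p0 must be >= 0")
        if self.orientation_kappa < 0:
            raise ParameterError("orientation_kappa must be >= 0")
        if self.p0 + self.c * 30.0 >= 1:
            raise ParameterError("p0 + c*D must stay below 1 for D <= 30 Gy")

    # -- cached array views used by the overlap sampler ------------------

    @cached_property
    def _arrays(self) -> dict[str, np.ndarray]:
        n = len(self.crystals)
        out = {
            "cx": np.empty(n), "cy": np.empty(n), "angle": np.empty(n),
            "width": np.empty(n), "length": np.empty(n), "g": np.empty(n),
        }
        for k, cr in enumerate(self.crystals):
            out["cx"][k] = cr.center[0]
            out["cy"][k] = cr.center[1]
            out["angle"][k] = cr.axis_angle
            out["width"][k] = cr.width
            out["length"][k] = cr.length
            out["g"][k] = cr.conversion_multiplier
        return out

    @cached_property
    def _tree(self) -> cKDTree | None:
        if not self.crystals:
            return None
        a = self._arrays
        return cKDTree(np.column_stack([a["cx"], a["cy"]]))

    @cached_property
    def _half_diag_max(self) -> float:
        a = self._arrays
        if a["cx"].size == 0:
            return 0.0
        return float(np.max(np.hypot(a["width"], a["length"])) / 2.0)


def _truncnorm_location(target_mean: float, sd: float, lower: float) -> float:
    """Location mu such that a normal(mu, sd) truncated below at ``lower``
    has mean ``target_mean``.  Moment matching keeps the sampled means on the
    nominal crystal dimensions despite the truncation."""

    def mean_of(mu: float) -> float:
        a = (lower - mu) / sd
        return stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd)

    lo = target_mean - 6.0 * sd
    hi = target_mean + sd
    return float(optimize.brentq(lambda m: mean_of(m) - target_mean, lo, hi,
                                 xtol=1e-10))


def generate_film(
    area: tuple[float, float],
    coverage_fraction: float,
    crystal_dim_params: tuple[float, float, float, float] = DEFAULT_CRYSTAL_DIMS,
    orientation_kappa: float = 0.0,
    conversion_params: tuple[float, float, float] = (1e-5, 4.2e-5, 0.0),
    seed: int = 0,
    active_thickness: float = 28.0,
) -> FilmPhantom:
    """Generate a virtual active layer.

    Crystal centers form a homogeneous Poisson process: the count is drawn
    from a Poisson law whose mean makes the expected total crystal footprint
    equal to ``coverage_fraction`` times the film area.  Widths and lengths
    come from zero-truncated normals moment-matched to the stated means and
    SDs; lengths are additionally truncated below the crystal's own width so
    that width <= length holds by construction.  Axis angles follow a von
    Mises law on the doubled angle (axial statistics) about the coating
    direction; ``orientation_kappa = 0`` gives isotropy.  Conversion
    multipliers are log-normal with unit median and log-SD
    ``conversion_sigma``.

    ``conversion_params`` is (p0, c, conversion_sigma).
    """
    lx, ly = float(area[0]), float(area[1])
    if lx <= 0 or ly <= 0:
        raise ParameterError("film area components must be positive")
    if not 0 < coverage_fraction < 1:
        raise ParameterError("coverage_fraction must lie in (0, 1)")
    mean_w, sd_w, mean_l, sd_l = (float(v) for v in crystal_dim_params)
    if mean_w <= 0 or mean_l <= 0:
        raise ParameterError("crystal mean dimensions must be positive")
    if sd_w < 0 or sd_l < 0:
        raise ParameterError("crystal dimension SDs must be >= 0")
    p0, c, conversion_sigma = (float(v) for v in conversion_params)

    rng = np.random.default_rng(seed)
    expected_n = coverage_fraction * lx * ly / (mean_w * mean_l)
    n = int(rng.poisson(expected_n))

    cx = rng.uniform(0.0, lx, n)
    cy = rng.uniform(0.0, ly, n)

    if sd_w > 0:
        mu_w = _truncnorm_location(mean_w, sd_w, 0.0)
        a_w = (0.0 - mu_w) / sd_w
        widths = stats.truncnorm.rvs(a_w, np.inf, loc=mu_w, scale=sd_w,
                                     size=n, random_state=rng)
    else:
        widths = np.full(n, mean_w)
    if sd_l > 0:
        # lengths truncated below each crystal's width; moment-match at the
        # mean width so the sampled length mean stays on target
        mu_l = _truncnorm_location(mean_l, sd_l, mean_w)
        a_l = (widths - mu_l) / sd_l
        lengths = stats.truncnorm.rvs(a_l, np.inf, loc=mu_l, scale=sd_l,
                                      size=n, random_state=rng)
    else:
        lengths = np.maximum(np.full(n, mean_l), widths)

    if orientation_kappa > 0:
        doubled = rng.vonmises(0.0, orientation_kappa, n)
    else:
        doubled = rng.uniform(-np.pi, np.pi, n)
    angles = np.mod(doubled, 2.0 * np.pi) / 2.0  # axial angle in [0, pi)

    g = np.exp(conversion_sigma * rng.standard_normal(n))

    crystals = tuple(
        Crystal(center=(float(cx[k]), float(cy[k])),
                axis_angle=float(angles[k]),
                width=float(widths[k]), length=float(lengths[k]),
                conversion_multiplier=float(g[k]))
        for k in range(n)
    )
    return FilmPhantom(
        area=(lx, ly), crystals=crystals, p0=p0, c=c,
        orientation_kappa=orientation_kappa, conversion_sigma=conversion_sigma,
        seed=int(seed), active_thickness=active_thickness,
        coverage_fraction=coverage_fraction,
        crystal_dim_params=(mean_w, sd_w, mean_l, sd_l),
    )


def polymer_fraction(film: FilmPhantom, dose: float, crystal: Crystal) -> float:
    """Polymer fraction of one crystal at the given dose (Gy).

    Linear conversion ``(p0 + c * dose) * g`` capped at 1.  The monomer
    fraction ``1 - p`` changes by well under 0.5% (relative) between 0 and
    30 Gy with the default parameters, which is what makes the 2260 cm^-1
    monomer channel usable as an internal standard.
    """
    if dose < 0:
        raise ParameterError("dose must be >= 0")
    p = (film.p0 + film.c * dose) * crystal.conversion_multiplier
    return float(min(p, 1.0))


def _disk_points(spot_diameter: float, resolution: float) -> tuple[np.ndarray, float]:
    """Cartesian sample points covering a centered disk, plus the area each
    point represents."""
    r = spot_diameter / 2.0
    m = max(int(np.ceil(spot_diameter / resolution)), 2)
    coords = (np.arange(m) + 0.5) * (spot_diameter / m) - r
    xx, yy = np.meshgrid(coords, coords)
    inside = xx**2 + yy**2 <= r**2
    cell = (spot_diameter / m) ** 2
    return np.column_stack([xx[inside], yy[inside]]), cell


_DISK_CACHE: dict[tuple[float, float], tuple[np.ndarray, float]] = {}


def local_composition(
    film: FilmPhantom,
    x: float,
    y: float,
    spot_diameter: float,
    dose: float,
    resolution: float = OVERLAP_RESOLUTION,
) -> Composition:
    """Polymer/monomer content sampled by a circular probe spot at (x, y).

    For every crystal rectangle intersecting the spot the overlap weight is
    the intersection area, evaluated by pixelating the spot on a Cartesian
    grid of the stated ``resolution`` (um).  The polymer weight is the
    overlap-weighted sum of per-crystal polymer fractions at ``dose``; the
    monomer weight is the complement, so their sum equals the total
    crystal/spot overlap area.
    """
    lx, ly = film.area
    if not (0.0 <= x <= lx and 0.0 <= y <= ly):
        raise DomainError(f"probe position ({x}, {y}) outside film area")
    if spot_diameter <= 0:
        raise ParameterError("spot_diameter must be positive")
    if dose < 0:
        raise ParameterError("dose must be >= 0")
    if film._tree is None:
        return Composition(0.0, 0.0, ())

    key = (round(spot_diameter, 9), round(resolution, 9))
    if key not in _DISK_CACHE:
        _DISK_CACHE[key] = _disk_points(spot_diameter, resolution)
    pts, cell = _DISK_CACHE[key]

    radius = spot_diameter / 2.0 + film._half_diag_max
    idx = film._tree.query_ball_point([x, y], radius)
    if not idx:
        return Composition(0.0, 0.0, ())

    a = film._arrays
    samples: list[tuple[float, float]] = []
    polymer = 0.0
    monomer = 0.0
    px = pts[:, 0] + x
    py = pts[:, 1] + y
    p_base = film.p0 + film.c * dose
    for k in idx:
        ca, sa = np.cos(a["angle"][k]), np.sin(a["angle"][k])
        dx = px - a["cx"][k]
        dy = py - a["cy"][k]
        u = dx * ca + dy * sa          # along the long axis
        v = -dx * sa + dy * ca         # across
        inside = (np.abs(u) <= a["length"][k] / 2.0) & \
                 (np.abs(v) <= a["width"][k] / 2.0)
        overlap = float(np.count_nonzero(inside)) * cell
        if overlap <= 0.0:
            continue
        p = min(p_base * a["g"][k], 1.0)
        polymer += overlap * p
        monomer += overlap * (1.0 - p)
        samples.append((float(a["angle"][k]), overlap))
    return Composition(polymer, monomer, tuple(samples))


# -- serialization -------------------------------------------------------


def save_phantom_params(film: FilmPhantom, path) -> None:
    """Write the generating parameters + seed as JSON (not the crystal list;
    regeneration from these is bit-identical)."""
    doc = {
        "area": list(film.area),
        "active_thickness": film.active_thickness,
        "coverage_fraction": film.coverage_fraction,
        "crystal_dim_params": list(film.crystal_dim_params)
        if film.crystal_dim_params else None,
        "orientation_kappa": film.orientation_kappa,
        "conversion_params": [film.p0, film.c, film.conversion_sigma],
        "seed": film.seed,
    }
    from .atomic import atomic_write_text
    atomic_write_text(path, json.dumps(doc, indent=2) + "\n")


def load_phantom_params(path) -> FilmPhantom:
    """Regenerate a phantom from a JSON parameter document."""
    with open(path) as fh:
        doc = json.load(fh)
    return generate_film(
        area=tuple(doc["area"]),
        coverage_fraction=doc["coverage_fraction"],
        crystal_dim_params=tuple(doc["crystal_dim_params"]),
        orientation_kappa=doc["orientation_kappa"],
        conversion_params=tuple(doc["conversion_params"]),
        seed=doc["seed"],
        active_thickness=doc.get("active_thickness", 28.0),
    )


def crystals_to_csv(film: FilmPhantom, path) -> None:
    """Write the full crystal table as CSV (x, y, angle, width, length, g)."""
    import pandas as pd

    a = film._arrays
    df = pd.DataFrame({
        "x_um": a["cx"], "y_um": a["cy"], "axis_angle_rad": a["angle"],
        "width_um": a["width"], "length_um": a["length"],
        "conversion_multiplier": a["g"],
    })
    from .atomic import atomic_write_text
    atomic_write_text(path, df.to_csv(index=False))
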