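"""Synthetic landscapes, species niches and occurrence records.

A virtual-ecologist generator: it produces data with the statistical
structure the downstream analysis assumes — spatially smooth, low-variability
"climate-like" continuous fields; a patchy, high-variability categorical
land-use/land-cover (LULC) mosaic with derived distance-to-urban and
population-density surfaces; and species occurrence records sampled from
multiplicative Gaussian niche responses — so that every pipeline stage is
testable without any external download.

Coordinates are planar and km-based (equal-area by construction), with the
landscape origin at (0, 0).  Continuous fields are Gaussian random fields
realized by smoothing white noise with a Gaussian kernel whose sigma is the
field's correlation length in pixels; the LULC mosaic assigns each pixel the
class of its nearest seed point (a Voronoi tessellation) with seed density
set by ``patch_scale``, the characteristic patch diameter in pixels.  Larger
patches make coarse-grain percent-cover layers *more* variable between cells
(each cell is dominated by one class instead of averaging many patches), so
``patch_scale`` is the experiment's control knob for LULC variability.

Every generator is deterministic given its configuration and seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .environment import EnvironmentalLayer

logger = logging.getLogger(__name__)

#: Default LULC legend: code → class name.  Class frequencies are uneven, as
#: in real mosaics (forest and agriculture dominate, wetlands are rare).
LULC_CLASSES: dict[int, str] = {
    0: "urban",
    1: "agriculture",
    2: "forest",
    3: "grassland",
    4: "water",
    5: "wetland",
}
_LULC_PROBS = np.array([0.10, 0.25, 0.30, 0.20, 0.08, 0.07])

#: Continuous field definitions: (mean, sd, default correlation length px,
#: clip at zero?).  Units: temperature °C, precipitation mm/yr, elevation m,
#: NDVI unitless, seasonality in the respective variable's units.
_CONTINUOUS_FIELDS: dict[str, tuple[float, float, float, bool]] = {
    "temperature": (15.0, 4.0, 32.0, False),
    "temperature_seasonality": (8.0, 2.0, 32.0, True),
    "precipitation": (900.0, 300.0, 32.0, True),
    "precipitation_seasonality": (30.0, 8.0, 32.0, True),
    "elevation": (400.0, 250.0, 6.0, True),
    "ndvi": (0.55, 0.15, 8.0, True),
}

#: Niche variables species can respond to, per variable group.  Species
#: respond to the fine-scale fields (the categorical LULC class itself, not
#: the derived coarse percent covers).
GROUP_NICHE_VARIABLES: dict[str, tuple[str, ...]] = {
    "climate": (
        "temperature",
        "temperature_seasonality",
        "precipitation",
        "precipitation_seasonality",
    ),
    "topography": ("elevation",),
    "lulc": ("lulc", "distance_to_urban", "population_density"),
    "ndvi": ("ndvi",),
}


@dataclass(frozen=True)
class LandscapeConfig:
    """Configuration of one synthetic landscape.

    ``pixel_area`` is the area of one fine pixel in km²; ``patch_scale`` the
    characteristic LULC patch diameter in pixels; ``smoothness_per_layer``
    overrides the per-field correlation lengths (pixels).
    """

    width_px: int = 256
    height_px: int = 256
    pixel_area: float = 1.0
    smoothness_per_layer: dict[str, float] = field(default_factory=dict)
    n_lulc_classes: int = 6
    patch_scale: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise ValueError("landscape must be at least 64×64 pixels")
        if self.n_lulc_classes < 2:
            raise ValueError("need at least 2 LULC classes")
        if self.n_lulc_classes > len(LULC_CLASSES):
            raise ValueError(f"at most {len(LULC_CLASSES)} LULC classes supported")
        if self.patch_scale >= min(self.width_px, self.height_px):
            raise ValueError("patch_scale must be smaller than the landscape side")
        if self.patch_scale <= 0 or self.pixel_area <= 0:
            raise ValueError("patch_scale and pixel_area must be positive")

    @property
    def class_names(self) -> dict[int, str]:
        return {k: v for k, v in LULC_CLASSES.items() if k < self.n_lulc_classes}

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        side = math.sqrt(self.pixel_area)
        return (0.0, 0.0, self.width_px * side, self.height_px * side)


@dataclass(frozen=True)
class SpeciesNiche:
    """Gaussian niche of one species over named environmental variables.

    Per-pixel occurrence intensity is

        baseline_rate × Π_v exp(−w_v (x_v − opt_v)² / (2 tol_v²))

    over the variables with weight w_v > 0.  For the categorical ``lulc``
    variable the distance x − opt is 0 for the preferred class and 1
    otherwise, so the same expression applies with a unitless tolerance.
    """

    species_id: str
    response_weights: dict[str, float]
    optima: dict[str, float]
    tolerances: dict[str, float]
    baseline_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        for v, t in self.tolerances.items():
            if t <= 0:
                raise ValueError(f"tolerance for {v!r} must be positive")
        for v, w in self.response_weights.items():
            if w < 0:
                raise ValueError(f"weight for {v!r} must be nonnegative")


def _smooth_unit_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean, unit-sd Gaussian random field with correlation length sigma px."""
    z = rng.standard_normal(shape)
    if sigma > 0:
        z = ndimage.gaussian_filter(z, sigma=sigma, mode="reflect")
    sd = z.std()
    if sd == 0:  # pathological; keep the constant field
        return z
    return (z - z.mean()) / sd


def generate_landscape(config: LandscapeConfig) -> dict[str, EnvironmentalLayer]:
    """Generate all fine-resolution layers of one landscape.

    Returns continuous climate/topography/NDVI/population fields, the
    categorical ``lulc`` mosaic, and ``distance_to_urban`` (km to the nearest
    urban pixel).  All layers share geometry and the configured seed makes
    the output bitwise reproducible.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.height_px, config.width_px)
    px_side = math.sqrt(config.pixel_area)
    layers: dict[str, EnvironmentalLayer] = {}

    for name, (mean, sd, sigma0, clip0) in _CONTINUOUS_FIELDS.items():
        sigma = config.smoothness_per_layer.get(name, sigma0)
        if math.isinf(sigma):
            grid = np.full(shape, mean)
        else:
            grid = mean + sd * _smooth_unit_field(rng, shape, sigma)
            if clip0:
                grid = np.clip(grid, 0.0, None)
        layers[name] = EnvironmentalLayer(
            name=name, kind="continuous", grid=grid, cell_area=config.pixel_area
        )

    # LULC mosaic: nearest-seed (Voronoi) class assignment; seed count set so
    # the mean patch area is ~patch_scale² pixels.
    n_px = config.width_px * config.height_px
    n_seeds = max(config.n_lulc_classes, int(round(n_px / config.patch_scale**2)))
    seeds_xy = rng.uniform(
        low=(0, 0), high=(config.width_px, config.height_px), size=(n_seeds, 2)
    )
    probs = _LULC_PROBS[: config.n_lulc_classes]
    probs = probs / probs.sum()
    seed_classes = rng.choice(config.n_lulc_classes, size=n_seeds, p=probs)
    if not (seed_classes == 0).any():
        seed_classes[rng.integers(n_seeds)] = 0  # guarantee an urban patch
    yy, xx = np.mgrid[0 : config.height_px, 0 : config.width_px]
    centers = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
    _, nearest = cKDTree(seeds_xy).query(centers, k=1)
    lulc = seed_classes[nearest].reshape(shape).astype(np.int64)
    layers["lulc"] = EnvironmentalLayer(
        name="lulc", kind="categorical", grid=lulc, cell_area=config.pixel_area
    )

    # distance (km) from each pixel to the nearest urban pixel
    dist = ndimage.distance_transform_edt(lulc != 0, sampling=px_side)
    layers["distance_to_urban"] = EnvironmentalLayer(
        name="distance_to_urban", kind="continuous", grid=dist,
        cell_area=config.pixel_area,
    )

    # population density: exponential decay from urban cores plus smooth noise
    pop_sigma = config.smoothness_per_layer.get("population_density", 10.0)
    noise = _smooth_unit_field(rng, shape, pop_sigma) if not math.isinf(pop_sigma) else np.zeros(shape)
    pop = 500.0 * np.exp(-dist / 5.0) + 20.0 * np.clip(noise + 1.0, 0.0, None)
    layers["population_density"] = EnvironmentalLayer(
        name="population_density", kind="continuous", grid=pop,
        cell_area=config.pixel_area,
    )
    return layers


def generate_species_pool(
    n_species: int,
    group_affinity: dict[str, float],
    layers: dict[str, EnvironmentalLayer],
    seed: int,
    tolerance_fraction: float = 0.15,
    baseline_rate: float = 1.0,
) -> list[SpeciesNiche]:
    """Draw a species pool with group-structured niches.

    ``group_affinity`` maps variable-group names (climate, topography, lulc,
    ndvi) to nonnegative weights; a group with weight 0 contributes no
    variables to any niche, so it cannot structure the community.  Optima are
    drawn uniformly over each variable's realized range in ``layers`` and
    tolerances set to ``tolerance_fraction`` of that range (a fairly
    specialized niche breadth: six to seven breadths span the gradient, so
    species turn over visibly along it).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    bad = [g for g, w in group_affinity.items() if w < 0]
    if bad:
        raise ValueError(f"negative group affinities: {bad}")
    if not any(w > 0 for w in group_affinity.values()):
        raise ValueError("at least one group affinity must be positive")
    unknown = [g for g in group_affinity if g not in GROUP_NICHE_VARIABLES]
    if unknown:
        raise ValueError(f"unknown variable groups: {unknown}")

    rng = np.random.default_rng(seed)
    niches = []
    for i in range(n_species):
        weights: dict[str, float] = {}
        optima: dict[str, float] = {}
        tols: dict[str, float] = {}
        for group, w in sorted(group_affinity.items()):
            if w == 0:
                continue
            for var in GROUP_NICHE_VARIABLES[group]:
                layer = layers[var]
                weights[var] = float(w)
                if layer.kind == "categorical":
                    classes = np.unique(layer.grid)
                    optima[var] = float(rng.choice(classes))
                    tols[var] = 0.5  # mismatch distance is 0/1
                else:
                    vals = layer.grid[np.isfinite(layer.grid)]
                    lo, hi = float(vals.min()), float(vals.max())
                    optima[var] = float(rng.uniform(lo, hi))
                    tols[var] = max(tolerance_fraction * (hi - lo), 1e-9)
        niches.append(
            SpeciesNiche(
                species_id=f"sp{i:03d}",
                response_weights=weights,
                optima=optima,
                tolerances=tols,
                baseline_rate=baseline_rate,
            )
        )
    return niches


def niche_intensity(
    niche: SpeciesNiche, layers: dict[str, EnvironmentalLayer]
) -> np.ndarray:
    """Per-pixel occurrence intensity surface of one species."""
    ref = next(iter(layers.values()))
    log_int = np.full(ref.shape, math.log(niche.baseline_rate))
    for var, w in niche.response_weights.items():
        if w == 0:
            continue
        layer = layers[var]
        if layer.kind == "categorical":
            # mismatch distance is 0 (preferred class) or 1, scaled by tolerance
            d2 = (layer.grid != niche.optima[var]).astype(float) / niche.tolerances[var] ** 2
        else:
            d2 = ((layer.grid - niche.optima[var]) / niche.tolerances[var]) ** 2
        log_int -= 0.5 * w * d2
    return np.exp(log_int)


def sample_occurrences(
    layers: dict[str, EnvironmentalLayer],
    niches: list[SpeciesNiche],
    n_target: int,
    seed: int,
    bias: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw occurrence records from the species' niche-intensity surfaces.

    ``n_target`` records are allocated by a multinomial draw over the joint
    (species × pixel) intensity surface; each record lands uniformly inside
    its pixel and its coordinates are written with four decimal digits (so
    the recorded-precision filter passes by construction), the parsed floats
    matching the text exactly.  ``bias`` optionally multiplies every species'
    intensity by a per-pixel sampling-effort surface (default: none).
    """
    if not niches:
        logger.warning("empty niche collection: no occurrences sampled")
        return pd.DataFrame(columns=["species_id", "lon", "lat", "lon_text", "lat_text"])
    missing = {
        v for n in niches for v, w in n.response_weights.items() if w > 0
    } - set(layers)
    if missing:
        raise ValueError(f"niches reference variables absent from layers: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    ref = next(iter(layers.values()))
    ny, nx = ref.shape
    px_side = ref.cell_side

    intensity = np.stack([niche_intensity(n, layers) for n in niches])  # (S, ny, nx)
    if bias is not None:
        intensity = intensity * np.asarray(bias, dtype=float)[None, :, :]
    flat = intensity.reshape(len(niches), -1)
    total = flat.sum()
    if total == 0:
        logger.warning("all niche intensities are zero: no occurrences sampled")
        return pd.DataFrame(columns=["species_id", "lon", "lat", "lon_text", "lat_text"])
    counts = rng.multinomial(n_target, (flat / total).ravel()).reshape(flat.shape)

    sp_ix, pix_ix = np.nonzero(counts)
    reps = counts[sp_ix, pix_ix]
    sp_all = np.repeat(sp_ix, reps)
    pix_all = np.repeat(pix_ix, reps)
    iy, ix = np.divmod(pix_all, nx)
    x = (ix + rng.random(len(ix))) * px_side + ref.origin[0]
    y = (iy + rng.random(len(iy))) * px_side + ref.origin[1]

    lon_text = np.array([f"{v:.4f}" for v in x])
    lat_text = np.array([f"{v:.4f}" for v in y])
    out = pd.DataFrame(
        {
            "species_id": np.array([niches[s].species_id for s in sp_all]),
            "lon": lon_text.astype(float),
            "lat": lat_text.astype(float),
            "lon_text": lon_text,
            "lat_text": lat_text,
        }
    )
    # stable shuffle so the record order carries no species structure
    order = rng.permutation(len(out))
    return out.iloc[order].reset_index(drop=True)
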