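"""Synthetic Sentinel-2-style inputs for the maize mapping pipeline.

Real maize mapping consumes five years of Level-1C imagery plus field
campaigns; this module stands in for both so that every downstream stage
(preprocessing, the two classifier families, post-processing, validation)
can be exercised end-to-end and deterministically.

The generative model
--------------------
Each class follows a double-logistic green-fraction curve — the standard
land-surface-phenology form — over the April–October window (DOY 90–300):

    g(t) = A * [ sigmoid(k_g (t - t_peak + W)) - sigmoid(k_s (t - t_peak - W)) ]

with amplitude ``A``, growth/senescence slopes ``k_g``/``k_s`` and a fixed
half-season width ``W`` = 45 days.  Per-band reflectance mixes a green
vegetation endmember with a spectrally flat background at ``base_level``:

    rho_b(t) = base + g(t) * (veg_b - base)

so an amplitude of zero yields a flat series at ``base_level`` in every band.
The aerosols band is generated nearly collinear with blue (coupling noise
0.002) so the r > 0.98 band-selection rule drops it, leaving the eight
channels the classifiers use.  Cloud-contaminated acquisitions replace the
spectrum with bright draws (visible bands U[0.4, 0.9], NIR/SWIR U[0.3, 0.8])
and carry a truth flag so cloud detection can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .constants import (
    BAND_NAMES,
    CLASSES,
    CLASS_CODES,
    SEASON_END_DOY,
    SEASON_START_DOY,
)
from .types import CoarseMask, LabelRaster, PixelTimeSeries, SampleRecord

#: Green-vegetation endmember reflectance, one value per band in BAND_NAMES
#: order (aerosols is derived from blue, see _series_batch).
VEG_ENDMEMBER = np.array(
    [0.050, 0.050, 0.080, 0.040, 0.160, 0.320, 0.450, 0.200, 0.100]
)

#: Half-width of the green season in days (peak-to-inflection distance).
SEASON_HALF_WIDTH = 45.0

_VISIBLE = [BAND_NAMES.index(b) for b in ("aerosols", "blue", "green", "red")]
_NONVISIBLE = [
    BAND_NAMES.index(b)
    for b in ("red_edge1", "red_edge2", "nir", "swir1", "swir2")
]
_BLUE = BAND_NAMES.index("blue")
_AEROSOLS = BAND_NAMES.index("aerosols")

#: Aerosols ~= AEROSOL_SLOPE * blue + AEROSOL_OFFSET + N(0, AEROSOL_JITTER).
AEROSOL_SLOPE = 0.95
AEROSOL_OFFSET = 0.005
AEROSOL_JITTER = 0.002


@dataclass(frozen=True)
class PhenologyParams:
    """Seasonal reflectance model for one class.

    ``amplitude`` is the peak green fraction (NDVI-scale, in [0, 1]);
    ``base_level`` the off-season reflectance; slopes are per-day logistic
    rates; ``noise_sd`` additive reflectance noise; ``cloud_prob`` the
    per-acquisition contamination probability.
    """

    class_label: str
    peak_doy: float
    amplitude: float
    base_level: float
    growth_rate: float = 0.10
    senescence_rate: float = 0.10
    noise_sd: float = 0.02
    cloud_prob: float = 0.15

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must lie in [0, 1]")
        if not 0.0 <= self.base_level <= 1.0:
            raise ValueError("base_level must lie in [0, 1]")
        if self.amplitude + self.base_level > 1.0 + 1e-12:
            raise ValueError("amplitude + base_level must not exceed 1")
        if not 0.0 <= self.cloud_prob <= 1.0:
            raise ValueError("cloud_prob must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.growth_rate <= 0 or self.senescence_rate <= 0:
            raise ValueError("logistic rates must be positive")


#: Study-condition phenologies: summer maize peaking around DOY 200, an
#: earlier-season non-maize crop (winter-wheat-like), and sparsely vegetated
#: non-cropland with a brighter background.
DEFAULT_PHENOLOGY: dict[str, PhenologyParams] = {
    "maize": PhenologyParams("maize", 200.0, 0.65, 0.12),
    "non_maize_crop": PhenologyParams(
        "non_maize_crop", 150.0, 0.55, 0.12, growth_rate=0.09, senescence_rate=0.09
    ),
    "non_cropland": PhenologyParams(
        "non_cropland", 190.0, 0.08, 0.16, growth_rate=0.05, senescence_rate=0.05
    ),
}

#: Default acquisition grid: one scene every 10 days across the season.
DEFAULT_DOY_GRID: tuple[int, ...] = tuple(
    range(SEASON_START_DOY, SEASON_END_DOY + 1, 10)
)

#: Rough lon/lat boxes per zone, only used to place synthetic sample points.
ZONE_BBOX: dict[str, tuple[float, float, float, float]] = {
    "a": (120.0, 40.0, 135.0, 50.0),
    "b": (110.0, 32.0, 120.0, 40.0),
    "c": (100.0, 22.0, 110.0, 32.0),
    "d": (93.0, 32.0, 108.0, 40.0),
    "e": (75.0, 36.0, 93.0, 46.0),
    "south": (105.0, 18.0, 117.0, 26.0),
}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def green_fraction(params: PhenologyParams, doy) -> np.ndarray:
    """Noise-free double-logistic green fraction g(t) in [0, 1]."""
    t = np.asarray(doy, dtype=float)
    rise = _sigmoid(params.growth_rate * (t - (params.peak_doy - SEASON_HALF_WIDTH)))
    fall = _sigmoid(
        params.senescence_rate * (t - (params.peak_doy + SEASON_HALF_WIDTH))
    )
    return params.amplitude * (rise - fall)


def noise_free_bands(params: PhenologyParams, doy) -> np.ndarray:
    """Noise- and cloud-free reflectance, shape (n_doy, 9)."""
    g = green_fraction(params, doy)[:, None]
    base = params.base_level
    bands = base + g * (VEG_ENDMEMBER[None, :] - base)
    bands[:, _AEROSOLS] = AEROSOL_SLOPE * bands[:, _BLUE] + AEROSOL_OFFSET
    return bands


def noise_free_ndvi(params: PhenologyParams, doy) -> np.ndarray:
    """Closed-form NDVI of the noise-free curve (separability oracle)."""
    bands = noise_free_bands(params, doy)
    nir = bands[:, BAND_NAMES.index("nir")]
    red = bands[:, BAND_NAMES.index("red")]
    return (nir - red) / (nir + red)


def ndvi_trajectory_distance(
    p1: PhenologyParams, p2: PhenologyParams, doy_grid=DEFAULT_DOY_GRID
) -> float:
    """L2 distance between two noise-free NDVI trajectories.

    This is the separability measure the generator's difficulty knobs act on:
    widening the peak-day or amplitude gap between classes never decreases it.
    """
    d = noise_free_ndvi(p1, doy_grid) - noise_free_ndvi(p2, doy_grid)
    return float(np.sqrt(np.sum(d * d)))


def _validate_doy_grid(doy_grid) -> np.ndarray:
    grid = np.asarray(doy_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("doy_grid must be a non-empty 1-D sequence")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("doy_grid must be strictly increasing")
    if grid[0] < SEASON_START_DOY or grid[-1] > SEASON_END_DOY:
        raise ValueError(
            f"doy_grid must lie within the season window "
            f"[{SEASON_START_DOY}, {SEASON_END_DOY}]"
        )
    return grid


def _series_batch(
    params: PhenologyParams, doy_grid: np.ndarray, rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Generate n pixel series at once: bands (n, T, 9) and cloud flags (n, T)."""
    t = doy_grid.shape[0]
    bands = np.broadcast_to(noise_free_bands(params, doy_grid), (n, t, 9)).copy()
    if params.noise_sd > 0:
        bands += rng.normal(0.0, params.noise_sd, size=(n, t, 9))
    # re-derive aerosols from the noisy blue so the pair stays near-collinear
    bands[:, :, _AEROSOLS] = (
        AEROSOL_SLOPE * bands[:, :, _BLUE]
        + AEROSOL_OFFSET
        + rng.normal(0.0, AEROSOL_JITTER, size=(n, t))
    )
    cloud = rng.random((n, t)) < params.cloud_prob
    if np.any(cloud):
        idx = np.nonzero(cloud)
        bands[idx[0], idx[1], :] = 0.0
        vis = rng.uniform(0.4, 0.9, size=(len(idx[0]), len(_VISIBLE)))
        nonvis = rng.uniform(0.3, 0.8, size=(len(idx[0]), len(_NONVISIBLE)))
        for j, b in enumerate(_VISIBLE):
            bands[idx[0], idx[1], b] = vis[:, j]
        for j, b in enumerate(_NONVISIBLE):
            bands[idx[0], idx[1], b] = nonvis[:, j]
    np.clip(bands, 0.0, 1.0, out=bands)
    return bands, cloud


def generate_pixel_series(
    params: PhenologyParams, doy_grid=DEFAULT_DOY_GRID, seed: int | None = 0
) -> PixelTimeSeries:
    """One synthetic pixel's acquisition series over the season window.

    The cloud flag on the result is the *truth* contamination flag; cloud
    masking (preprocessing) re-derives its own flags from the spectra.
    """
    grid = _validate_doy_grid(doy_grid)
    rng = np.random.default_rng(seed)
    bands, cloud = _series_batch(params, grid, rng, 1)
    return PixelTimeSeries(grid.astype(int), bands[0], cloud[0])


@dataclass(frozen=True)
class Scenario:
    """One zone-year generation setup; ``seed`` fully determines the output."""

    zone_id: str
    year: int
    n_per_class: dict[str, int]
    params_per_class: dict[str, PhenologyParams] = field(
        default_factory=lambda: dict(DEFAULT_PHENOLOGY)
    )
    seed: int = 0
    doy_grid: tuple[int, ...] = DEFAULT_DOY_GRID

    def __post_init__(self) -> None:
        if self.zone_id not in ZONE_BBOX:
            raise ValueError(f"unknown zone {self.zone_id!r}")
        for cls in self.n_per_class:
            if cls not in CLASSES:
                raise ValueError(f"unknown class {cls!r}")
            if self.n_per_class[cls] < 0:
                raise ValueError("sample counts must be non-negative")


def make_scenario(
    zone_id: str,
    year: int,
    n_per_class: int | dict[str, int] = 300,
    seed: int = 0,
    separability: float = 1.0,
    noise_sd: float | None = None,
    cloud_prob: float | None = None,
) -> Scenario:
    """Build a scenario from the default phenologies.

    ``separability`` in (0, 1] scales the between-class peak-day and
    amplitude gaps: 1.0 is the well-separated reference condition, smaller
    values pull the non-maize classes toward the maize trajectory.
    """
    if not 0.0 < separability <= 1.0:
        raise ValueError("separability must lie in (0, 1]")
    if isinstance(n_per_class, int):
        n_per_class = {c: n_per_class for c in CLASSES}
    maize = DEFAULT_PHENOLOGY["maize"]
    params: dict[str, PhenologyParams] = {}
    for cls, p in DEFAULT_PHENOLOGY.items():
        peak = maize.peak_doy + separability * (p.peak_doy - maize.peak_doy)
        amp = maize.amplitude + separability * (p.amplitude - maize.amplitude)
        q = replace(p, peak_doy=peak, amplitude=amp)
        if noise_sd is not None:
            q = replace(q, noise_sd=noise_sd)
        if cloud_prob is not None:
            q = replace(q, cloud_prob=cloud_prob)
        params[cls] = q
    return Scenario(zone_id, year, n_per_class, params, seed)


def _collection_method(zone: str, year: int, class_label: str) -> str:
    # Mirrors the campaign's scheme: field surveys for crops, yearbook
    # inference for some non-maize sets, provincial products in Xinjiang
    # 2020, visual interpretation for non-cropland.
    if class_label == "non_cropland":
        return "IV"
    if class_label == "maize":
        return "III" if (zone == "e" and year == 2020) else "I"
    return "II" if zone == "d" else "I"


def generate_sample_set(
    scenario: Scenario,
) -> list[tuple[SampleRecord, PixelTimeSeries]]:
    """Labeled point samples with co-generated pixel series.

    Exactly ``n_per_class[c]`` records per class; reproducible bit-for-bit
    from the scenario seed.
    """
    requested = {c: n for c, n in scenario.n_per_class.items() if n > 0}
    if len(requested) < 1:
        raise ValueError("at least one class must have n_per_class >= 1")
    grid = _validate_doy_grid(scenario.doy_grid)
    ss = np.random.SeedSequence(scenario.seed)
    streams = ss.spawn(len(CLASSES))
    lon0, lat0, lon1, lat1 = ZONE_BBOX[scenario.zone_id]
    out: list[tuple[SampleRecord, PixelTimeSeries]] = []
    for ci, cls in enumerate(CLASSES):
        n = requested.get(cls, 0)
        if n == 0:
            continue
        rng = np.random.default_rng(streams[ci])
        lons = rng.uniform(lon0, lon1, n)
        lats = rng.uniform(lat0, lat1, n)
        bands, cloud = _series_batch(scenario.params_per_class[cls], grid, rng, n)
        method = _collection_method(scenario.zone_id, scenario.year, cls)
        for i in range(n):
            rec = SampleRecord(
                id=f"{scenario.zone_id}{scenario.year}-{cls}-{i:05d}",
                lon=float(lons[i]),
                lat=float(lats[i]),
                zone=scenario.zone_id,
                year=scenario.year,
                class_label=cls,
                method=method,
            )
            series = PixelTimeSeries(grid.astype(int), bands[i], cloud[i])
            out.append((rec, series))
    return out


@dataclass
class RasterScene:
    """A synthetic labeled scene: class raster plus per-pixel reflectance.

    ``labels`` includes injected speckles; ``clean_labels`` is the raster
    before injection; ``speckles`` marks the injected cells.  ``bands`` is
    (H, W, T, 9) and ``cloud`` the (H, W, T) truth contamination flags.
    """

    labels: LabelRaster
    clean_labels: LabelRaster
    speckles: np.ndarray
    doy: np.ndarray
    bands: np.ndarray
    cloud: np.ndarray

    def pixel_series(self, row: int, col: int) -> PixelTimeSeries:
        return PixelTimeSeries(
            self.doy, self.bands[row, col], self.cloud[row, col]
        )


def _remove_single_pixel_components(labels: np.ndarray) -> np.ndarray:
    """Merge 4-connected single-cell components into a neighbouring class."""
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    out = labels.copy()
    for _ in range(8):  # converges quickly; bounded for safety
        changed = False
        for code in np.unique(out):
            comp, n = ndimage.label(out == code, structure=structure)
            if n == 0:
                continue
            sizes = np.bincount(comp.ravel())
            for lab in np.nonzero(sizes == 1)[0]:
                if lab == 0:
                    continue
                r, c = np.argwhere(comp == lab)[0]
                neigh = []
                h, w = out.shape
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        neigh.append(out[rr, cc])
                if neigh:
                    vals, counts = np.unique(neigh, return_counts=True)
                    out[r, c] = vals[np.argmax(counts)]
                    changed = True
        if not changed:
            break
    return out


def generate_label_raster(
    width: int,
    height: int,
    patch_size_px: int = 64,
    class_fractions: dict[str, float] | None = None,
    seed: int = 0,
    speckle_rate: float = 0.0,
    params_per_class: dict[str, PhenologyParams] | None = None,
    doy_grid=DEFAULT_DOY_GRID,
    cell_size: float = 10.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> RasterScene:
    """A patchy class raster with a co-registered reflectance stack.

    Patches are nearest-seed (Voronoi) regions of roughly ``patch_size_px``
    cells; seed classes are allocated to ``class_fractions`` by largest
    remainder.  ``speckle_rate`` injects isolated single-pixel flips at
    interior cells whose 3x3 neighbourhood is uniform, at least 3 cells
    apart, so each injected speckle is a genuine 1-cell component.
    """
    if width < 1 or height < 1:
        raise ValueError("width and height must be >= 1")
    if class_fractions is None:
        class_fractions = {"maize": 0.4, "non_maize_crop": 0.35, "non_cropland": 0.25}
    fracs = {c: float(f) for c, f in class_fractions.items() if f > 0}
    if abs(sum(fracs.values()) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    for c in fracs:
        if c not in CLASSES:
            raise ValueError(f"unknown class {c!r}")
    if not 0.0 <= speckle_rate < 1.0:
        raise ValueError("speckle_rate must lie in [0, 1)")
    params_per_class = dict(params_per_class or DEFAULT_PHENOLOGY)
    grid = _validate_doy_grid(doy_grid)

    ss = np.random.SeedSequence(seed)
    rng_patch, rng_speckle, *rng_px = [
        np.random.default_rng(s) for s in ss.spawn(2 + len(CLASSES))
    ]

    n_seeds = max(len(fracs), int(round(width * height / patch_size_px)))
    sr = rng_patch.uniform(0, height, n_seeds)
    sc = rng_patch.uniform(0, width, n_seeds)
    # largest-remainder allocation of seed classes to the fractions
    names = sorted(fracs)
    quotas = np.array([fracs[c] * n_seeds for c in names])
    counts = np.floor(quotas).astype(int)
    rem = n_seeds - counts.sum()
    order = np.argsort(-(quotas - counts))
    for k in range(rem):
        counts[order[k % len(names)]] += 1
    seed_codes = np.repeat(
        [CLASS_CODES[c] for c in names], counts
    )
    rng_patch.shuffle(seed_codes)

    rr, cc = np.meshgrid(
        np.arange(height) + 0.5, np.arange(width) + 0.5, indexing="ij"
    )
    d2 = (rr[:, :, None] - sr[None, None, :]) ** 2 + (
        cc[:, :, None] - sc[None, None, :]
    ) ** 2
    labels = seed_codes[np.argmin(d2, axis=2)].astype(np.uint8)
    if len(fracs) > 1:
        labels = _remove_single_pixel_components(labels)

    clean = labels.copy()
    speckles = np.zeros_like(labels, dtype=bool)
    n_speckle = int(round(speckle_rate * width * height))
    if n_speckle > 0:
        uniform = np.zeros_like(labels, dtype=bool)
        uniform[1:-1, 1:-1] = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                uniform[1:-1, 1:-1] &= (
                    labels[1 + dr : height - 1 + dr, 1 + dc : width - 1 + dc]
                    == labels[1:-1, 1:-1]
                )
        cand = np.argwhere(uniform)
        rng_speckle.shuffle(cand)
        chosen: list[tuple[int, int]] = []
        for r, c in cand:
            if all(max(abs(r - r2), abs(c - c2)) >= 3 for r2, c2 in chosen):
                chosen.append((int(r), int(c)))
                if len(chosen) == n_speckle:
                    break
        all_codes = sorted(set(CLASS_CODES.values()))
        for r, c in chosen:
            others = [k for k in all_codes if k != labels[r, c]]
            labels[r, c] = others[int(rng_speckle.integers(len(others)))]
            speckles[r, c] = True

    t = grid.shape[0]
    bands = np.zeros((height, width, t, 9), dtype=float)
    cloud = np.zeros((height, width, t), dtype=bool)
    for ci, cls in enumerate(CLASSES):
        mask = labels == CLASS_CODES[cls]
        n = int(mask.sum())
        if n == 0:
            continue
        if cls not in params_per_class:
            raise ValueError(f"no phenology parameters for class {cls!r}")
        b, cl = _series_batch(params_per_class[cls], grid, rng_px[ci], n)
        bands[mask] = b
        cloud[mask] = cl

    raster = LabelRaster(labels, cell_size=cell_size, origin=origin)
    clean_raster = LabelRaster(clean, cell_size=cell_size, origin=origin)
    return RasterScene(raster, clean_raster, speckles, grid.astype(int), bands, cloud)


def generate_coarse_mask(
    labels: LabelRaster, coarse_cell_size: float = 1000.0, min_fraction: float = 0.01
) -> CoarseMask:
    """Aggregate a fine label raster into a coarse maize-presence mask.

    A coarse cell is positive when at least ``min_fraction`` of its fine
    cells are maize — emulating a 1-km crop-distribution product derived
    from the same landscape.
    """
    factor = coarse_cell_size / labels.cell_size
    if factor < 1 or abs(factor - round(factor)) > 1e-9:
        raise ValueError("coarse cell size must be an integer multiple of fine")
    f = int(round(factor))
    h, w = labels.data.shape
    ch, cw = -(-h // f), -(-w // f)
    maize = (labels.data == CLASS_CODES["maize"]).astype(float)
    padded = np.zeros((ch * f, cw * f))
    padded[:h, :w] = maize
    frac = padded.reshape(ch, f, cw, f).mean(axis=(1, 3))
    return CoarseMask(
        frac >= min_fraction,
        cell_size=coarse_cell_size,
        origin=labels.origin,
        crs=labels.crs,
    )
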