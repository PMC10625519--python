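"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import BAND_NAMES, CHANNELS, N_MONTHS, NODATA


@dataclass(frozen=True)
class SpectralSample:
    """One acquisition's top-of-atmosphere reflectance, unitless.

    Values outside [0, 1] are tolerated (TOA reflectance can exceed 1 over
    bright targets) but reported by :meth:`out_of_range`.
    """

    rho_aerosols: float
    rho_blue: float
    rho_green: float
    rho_red: float
    rho_red_edge1: float
    rho_red_edge2: float
    rho_nir: float
    rho_swir1: float
    rho_swir2: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [getattr(self, f"rho_{b}") for b in BAND_NAMES], dtype=float
        )

    @classmethod
    def from_array(cls, values: np.ndarray) -> "SpectralSample":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(BAND_NAMES),):
            raise ValueError(
                f"expected {len(BAND_NAMES)} band values, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("reflectances must be finite")
        return cls(*values.tolist())

    def out_of_range(self) -> list[str]:
        """Band names whose reflectance falls outside [0, 1]."""
        arr = self.as_array()
        return [b for b, v in zip(BAND_NAMES, arr) if not 0.0 <= v <= 1.0]


@dataclass
class PixelTimeSeries:
    """Raw per-pixel acquisition series before compositing.

    ``bands`` is (n_acquisitions, 9) in :data:`~maizemap.constants.BAND_NAMES`
    order; ``cloud_flag`` marks acquisitions excluded from compositing (ground
    truth when produced by the generator, detections after cloud masking).
    """

    doy: np.ndarray
    bands: np.ndarray
    cloud_flag: np.ndarray

    def __post_init__(self) -> None:
        self.doy = np.asarray(self.doy, dtype=int)
        self.bands = np.asarray(self.bands, dtype=float)
        self.cloud_flag = np.asarray(self.cloud_flag, dtype=bool)
        n = self.doy.shape[0]
        if self.bands.shape != (n, len(BAND_NAMES)):
            raise ValueError(
                f"bands must be (n, {len(BAND_NAMES)}); got {self.bands.shape}"
            )
        if self.cloud_flag.shape != (n,):
            raise ValueError("cloud_flag must match the number of acquisitions")
        if np.any(self.doy < 1) or np.any(self.doy > 366):
            raise ValueError("day-of-year values must lie in [1, 366]")
        if n > 1 and np.any(np.diff(self.doy) <= 0):
            raise ValueError("day-of-year values must be strictly increasing")

    def __len__(self) -> int:
        return int(self.doy.shape[0])

    def band(self, name: str) -> np.ndarray:
        return self.bands[:, BAND_NAMES.index(name)]

    def spectra(self, i: int) -> SpectralSample:
        return SpectralSample.from_array(self.bands[i])

    def copy(self) -> "PixelTimeSeries":
        return PixelTimeSeries(
            self.doy.copy(), self.bands.copy(), self.cloud_flag.copy()
        )


@dataclass
class FeatureSequence:
    """Monthly composited classifier input: 7 time steps x ordered channels.

    ``gap_mask`` marks cells with no clear acquisition in the month;
    ``fill_mask`` marks cells whose value came from interpolation.
    """

    values: np.ndarray
    channels: tuple[str, ...] = CHANNELS
    gap_mask: np.ndarray | None = None
    fill_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != N_MONTHS:
            raise ValueError(
                f"values must be ({N_MONTHS}, n_channels); got {self.values.shape}"
            )
        if self.values.shape[1] != len(self.channels):
            raise ValueError("values width must match the channel list")
        if self.gap_mask is None:
            self.gap_mask = ~np.isfinite(self.values)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.fill_mask is None:
            self.fill_mask = np.zeros_like(self.gap_mask)
        else:
            self.fill_mask = np.asarray(self.fill_mask, dtype=bool)
        for name, m in (("gap_mask", self.gap_mask), ("fill_mask", self.fill_mask)):
            if m.shape != self.values.shape:
                raise ValueError(f"{name} must have shape {self.values.shape}")

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channels.index(name)]

    def copy(self) -> "FeatureSequence":
        return FeatureSequence(
            self.values.copy(), self.channels, self.gap_mask.copy(),
            self.fill_mask.copy(),
        )


@dataclass(frozen=True)
class SampleRecord:
    """A labeled point sample: where, when, what, and how it was collected."""

    id: str
    lon: float
    lat: float
    zone: str
    year: int
    class_label: str
    method: str


@dataclass
class LabelRaster:
    """Georeferenced class grid (codes 0/1/2, nodata 255) on a square grid.

    ``origin`` is the (x, y) of the top-left corner; rows run southwards, so
    the affine transform is (cell, 0, x0, 0, -cell, y0).  ``equal_area`` flags
    that cell areas are trustworthy for area estimation.
    """

    data: np.ndarray
    cell_size: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str = "EPSG:6933"
    equal_area: bool = True
    nodata: int = NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell centre, each shaped like data."""
        h, w = self.data.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(w) + 0.5) * self.cell_size
        ys = y0 - (np.arange(h) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def copy(self) -> "LabelRaster":
        return replace(self, data=self.data.copy())


@dataclass
class CoarseMask:
    """Binary coarse-resolution maize presence grid (e.g. a 1-km product)."""

    data: np.ndarray
    cell_size: float = 1000.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str = "EPSG:6933"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("mask data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
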