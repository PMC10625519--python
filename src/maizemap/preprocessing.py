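"""From raw acquisition series to the fixed 7 x 10 classifier input.

The chain is: cloud scoring and masking, 30-day median compositing over the
DOY 90–300 season window, linear gap interpolation, then stacking NDVI and
EVI onto the eight selected reflectance channels.  Band selection (the
r > 0.98 Pearson redundancy rule over maize samples) is provided as its own
reportable step.

Indices are computed *after* compositing, on the monthly medians: this keeps
the classifier input at exactly ten channels per month and makes the index
channels consistent with the reflectance channels they accompany.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .constants import (
    BAND_NAMES,
    CHANNELS,
    COMPOSITE_DAYS,
    N_MONTHS,
    REFLECTANCE_CHANNELS,
    SEASON_END_DOY,
    SEASON_START_DOY,
)
from .types import FeatureSequence, PixelTimeSeries, SpectralSample

__all__ = [
    "compute_ndvi",
    "compute_evi",
    "compute_ndsi",
    "compute_ndmi",
    "cloud_score",
    "mask_clouds",
    "composite_monthly",
    "fill_gaps",
    "select_bands",
    "build_feature_sequence",
    "BandSelectionReport",
    "SequenceFeaturizer",
    "DEFAULT_CLOUD_THRESHOLD",
]

#: Default cloud-score masking threshold.
DEFAULT_CLOUD_THRESHOLD = 0.2

#: Cloud-score weights: brightness term, moisture term, snow term.  The
#: brightness weight is 1 so a fully saturated pixel scores 1 before
#: clamping; the index terms nudge the score for bright-but-balanced
#: spectra.  See docs/methods.md for the breakpoints.
CLOUD_WEIGHTS = (1.0, 0.25, 0.25)


def _ratio(num, den):
    """Elementwise num/den with zero denominators mapped to NaN."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = den != 0
    np.divide(num, den, out=out, where=ok)
    return out if out.shape else float(out)


def _bands_of(spectra) -> np.ndarray:
    if isinstance(spectra, SpectralSample):
        return spectra.as_array()
    arr = np.asarray(spectra, dtype=float)
    if arr.shape[-1] != len(BAND_NAMES):
        raise ValueError(f"expected {len(BAND_NAMES)} bands, got {arr.shape}")
    return arr


def _b(bands: np.ndarray, name: str) -> np.ndarray:
    return bands[..., BAND_NAMES.index(name)]


def compute_ndvi(spectra) -> float | np.ndarray:
    """NDVI = (nir - red) / (nir + red); NaN where the denominator is zero."""
    bands = _bands_of(spectra)
    return _ratio(_b(bands, "nir") - _b(bands, "red"),
                  _b(bands, "nir") + _b(bands, "red"))


def compute_evi(spectra) -> float | np.ndarray:
    """EVI = 2.5 (nir - red) / (nir + 6 red - 7.5 blue + 1); NaN on zero den."""
    bands = _bands_of(spectra)
    nir, red, blue = _b(bands, "nir"), _b(bands, "red"), _b(bands, "blue")
    return _ratio(2.5 * (nir - red), nir + 6.0 * red - 7.5 * blue + 1.0)


def compute_ndsi(spectra) -> float | np.ndarray:
    """Snow index (green - swir1) / (green + swir1); NaN on zero denominator."""
    bands = _bands_of(spectra)
    return _ratio(_b(bands, "green") - _b(bands, "swir1"),
                  _b(bands, "green") + _b(bands, "swir1"))


def compute_ndmi(spectra) -> float | np.ndarray:
    """Moisture index (red - swir1) / (red + swir1); NaN on zero denominator."""
    bands = _bands_of(spectra)
    return _ratio(_b(bands, "red") - _b(bands, "swir1"),
                  _b(bands, "red") + _b(bands, "swir1"))


def _rescale(x, lo: float, hi: float):
    return np.clip((np.asarray(x, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def cloud_score(spectra, weights: tuple[float, float, float] = CLOUD_WEIGHTS):
    """Cloud likelihood in [0, 1]: weighted brightness + moisture + snow terms.

    The brightness term averages rescaled blue/aerosols (breakpoints
    0.1–0.5) and red/green (0.15–0.7); the moisture and snow terms rescale
    NDMI and NDSI over 0–0.5, contributing only when the index is positive
    (bright *and* spectrally balanced, as clouds are — dark soils and
    vegetation sit at or below zero).  Undefined indices (zero denominator)
    contribute nothing.  Monotone non-decreasing in each brightness band.
    """
    bands = _bands_of(spectra)
    for name in ("aerosols", "blue", "green", "red", "nir", "swir1"):
        if not np.all(np.isfinite(_b(bands, name))):
            raise ValueError(f"cloud score requires a finite {name} band")
    bright = (
        _rescale(_b(bands, "blue"), 0.1, 0.5)
        + _rescale(_b(bands, "aerosols"), 0.1, 0.5)
        + _rescale(_b(bands, "red"), 0.15, 0.7)
        + _rescale(_b(bands, "green"), 0.15, 0.7)
    ) / 4.0
    moist = np.nan_to_num(_rescale(compute_ndmi(bands), 0.0, 0.5))
    snow = np.nan_to_num(_rescale(compute_ndsi(bands), 0.0, 0.5))
    wb, wm, ws = weights
    score = np.clip(wb * bright + wm * moist + ws * snow, 0.0, 1.0)
    return float(score) if score.shape == () else score


def mask_clouds(
    series: PixelTimeSeries, score_threshold: float = DEFAULT_CLOUD_THRESHOLD
) -> PixelTimeSeries:
    """Flag acquisitions whose cloud score exceeds the threshold.

    Returns a new series whose ``cloud_flag`` holds the detections (the
    input's flags, e.g. generator truth, are not consulted).
    """
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError("score_threshold must lie in [0, 1]")
    scores = cloud_score(series.bands)
    return PixelTimeSeries(series.doy, series.bands.copy(), scores > score_threshold)


def month_window(doy) -> np.ndarray:
    """30-day window index (0..6) per DOY; -1 outside the season window."""
    doy = np.asarray(doy)
    idx = (doy - SEASON_START_DOY) // COMPOSITE_DAYS
    idx = np.where(doy == SEASON_END_DOY, N_MONTHS - 1, idx)  # 300 closes window 7
    idx = np.where((doy < SEASON_START_DOY) | (doy > SEASON_END_DOY), -1, idx)
    return idx.astype(int)


def composite_monthly(series: PixelTimeSeries) -> FeatureSequence:
    """Median-composite the unmasked acquisitions into 7 monthly steps.

    Output channels are the eight selected reflectance bands; months with
    no clear acquisition are gaps (NaN, flagged in ``gap_mask``).
    """
    idx = month_window(series.doy)
    cols = [BAND_NAMES.index(c) for c in REFLECTANCE_CHANNELS]
    values = np.full((N_MONTHS, len(cols)), np.nan)
    for m in range(N_MONTHS):
        sel = (idx == m) & ~series.cloud_flag
        if np.any(sel):
            values[m] = np.median(series.bands[np.ix_(sel, cols)], axis=0)
    return FeatureSequence(values, tuple(REFLECTANCE_CHANNELS))


def fill_gaps(seq: FeatureSequence) -> FeatureSequence:
    """Fill gap months channel-wise: linear interpolation between the nearest
    clear months, nearest-value extension at the sequence ends."""
    values = seq.values.copy()
    fill = seq.fill_mask.copy()
    months = np.arange(seq.values.shape[0], dtype=float)
    for j, name in enumerate(seq.channels):
        gaps = seq.gap_mask[:, j]
        if not gaps.any():
            continue
        if gaps.all():
            raise ValueError(f"channel {name!r} has no clear month to fill from")
        values[gaps, j] = np.interp(months[gaps], months[~gaps], values[~gaps, j])
        fill[gaps, j] = True
    return FeatureSequence(
        values, seq.channels, np.zeros_like(seq.gap_mask), fill
    )


@dataclass
class BandSelectionReport:
    """Outcome of the Pearson-redundancy band screen over maize samples."""

    correlation_matrix: np.ndarray
    band_names: tuple[str, ...]
    threshold: float
    retained: list[str]
    removed: list[tuple[str, str, float]]  # (band, retained partner, r)


def select_bands(
    samples: list[PixelTimeSeries], threshold: float = 0.98
) -> BandSelectionReport:
    """Drop bands correlated above ``threshold`` with an earlier-kept band.

    A single greedy pass in wavelength order over the pooled clear
    acquisitions of the (maize) sample series: a band is removed when its
    |Pearson r| with some already-retained band exceeds the threshold.
    Zero-variance bands have undefined correlation and are retained with a
    warning.
    """
    if len(samples) < 3:
        raise ValueError("band selection needs at least 3 sample series")
    rows = [s.bands[~s.cloud_flag] for s in samples]
    data = np.vstack([r for r in rows if r.size])
    if data.shape[0] < 3:
        raise ValueError("too few clear acquisitions for band selection")
    sd = data.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    retained: list[str] = []
    removed: list[tuple[str, str, float]] = []
    for i, band in enumerate(BAND_NAMES):
        if sd[i] == 0:
            warnings.warn(
                f"band {band!r} is constant; correlation undefined, retained",
                stacklevel=2,
            )
            retained.append(band)
            continue
        partner = None
        for kept in retained:
            k = BAND_NAMES.index(kept)
            r = corr[i, k]
            if np.isfinite(r) and abs(r) > threshold:
                partner = (kept, float(r))
                break
        if partner is None:
            retained.append(band)
        else:
            removed.append((band, partner[0], partner[1]))
    return BandSelectionReport(corr, BAND_NAMES, threshold, retained, removed)


def build_feature_sequence(
    series: PixelTimeSeries,
    cloud_threshold: float = DEFAULT_CLOUD_THRESHOLD,
    mask: bool = True,
) -> FeatureSequence:
    """Full preprocessing of one pixel: mask, composite, fill, add indices.

    Always returns a 7 x 10 sequence in the fixed channel order
    (8 reflectance channels, then NDVI, then EVI, computed from the
    composited reflectances).
    """
    masked = mask_clouds(series, cloud_threshold) if mask else series
    comp = fill_gaps(composite_monthly(masked))
    refl = comp.values
    nir = comp.channel("nir")
    red = comp.channel("red")
    blue = comp.channel("blue")
    ndvi = _ratio(nir - red, nir + red)
    evi = _ratio(2.5 * (nir - red), nir + 6.0 * red - 7.5 * blue + 1.0)
    values = np.column_stack([refl, ndvi, evi])
    src = [comp.channels.index(c) for c in ("nir", "red")]
    ndvi_fill = comp.fill_mask[:, src].any(axis=1)
    evi_fill = comp.fill_mask[
        :, [comp.channels.index(c) for c in ("nir", "red", "blue")]
    ].any(axis=1)
    fill = np.column_stack([comp.fill_mask, ndvi_fill, evi_fill])
    return FeatureSequence(values, CHANNELS, np.zeros_like(fill), fill)


def sequences_to_array(
    seqs: list[FeatureSequence], flatten: bool = False
) -> np.ndarray:
    """Stack feature sequences to (n, 7, 10), or (n, 70) month-major."""
    arr = np.stack([np.asarray(s.values, dtype=float) for s in seqs])
    return arr.reshape(len(seqs), -1) if flatten else arr


class SequenceFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless transformer from raw pixel series to classifier features.

    ``transform`` accepts a list of :class:`PixelTimeSeries` and returns the
    stacked month-major array — (n, 70) when ``flatten`` (the random-forest
    layout), else (n, 7, 10).  Composes with sklearn pipelines.
    """

    def __init__(
        self,
        cloud_threshold: float = DEFAULT_CLOUD_THRESHOLD,
        flatten: bool = True,
    ):
        self.cloud_threshold = cloud_threshold
        self.flatten = flatten

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        seqs = [
            x if isinstance(x, FeatureSequence)
            else build_feature_sequence(x, self.cloud_threshold)
            for x in X
        ]
        return sequences_to_array(seqs, flatten=self.flatten)
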