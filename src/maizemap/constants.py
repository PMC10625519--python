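"""Shared vocabulary: band order, classifier channels, class codes, season window.

The pipeline works on Sentinel-2-style top-of-atmosphere reflectance.  Nine
bands are carried through generation and cloud scoring; the classifier input
is the fixed 7 x 10 sequence of monthly composites over the eight selected
reflectance channels plus NDVI and EVI.
"""

from __future__ import annotations

# Wavelength order of the generated/ingested reflectance bands.
BAND_NAMES: tuple[str, ...] = (
    "aerosols",
    "blue",
    "green",
    "red",
    "red_edge1",
    "red_edge2",
    "nir",
    "swir1",
    "swir2",
)

#: Channels of the classifier input, in the fixed order the models expect.
CHANNELS: tuple[str, ...] = (
    "blue",
    "green",
    "red",
    "red_edge1",
    "red_edge2",
    "nir",
    "swir1",
    "swir2",
    "ndvi",
    "evi",
)

#: Reflectance channels of the classifier input (CHANNELS minus the indices).
REFLECTANCE_CHANNELS: tuple[str, ...] = CHANNELS[:8]

#: Class labels in confusion-matrix / probability-column order.
CLASSES: tuple[str, ...] = ("maize", "non_maize_crop", "non_cropland")

#: Raster class codes (unsigned 8-bit GeoTIFF products).
CLASS_CODES: dict[str, int] = {"non_cropland": 0, "maize": 1, "non_maize_crop": 2}
CODE_CLASSES: dict[int, str] = {v: k for k, v in CLASS_CODES.items()}
NODATA: int = 255

MAIZE: int = CLASS_CODES["maize"]
NON_MAIZE_CROP: int = CLASS_CODES["non_maize_crop"]
NON_CROPLAND: int = CLASS_CODES["non_cropland"]

#: Growing-season window (day of year, April-October) and compositing step.
SEASON_START_DOY: int = 90
SEASON_END_DOY: int = 300
COMPOSITE_DAYS: int = 30
N_MONTHS: int = 7
N_CHANNELS: int = len(CHANNELS)

#: Maize-cultivation zones: (a) North China, (b) Huang-Huai-Hai,
#: (c) Southwest, (d) Gansu, (e) Xinjiang, plus the sample-poor South,
#: classified with models borrowed from adjacent zones.
ZONES: tuple[str, ...] = ("a", "b", "c", "d", "e")
SOUTH_ZONE: str = "south"

#: Sample collection method tags: I field survey, II yearbook-inferred,
#: III existing provincial products, IV visual interpretation.
METHODS: tuple[str, ...] = ("I", "II", "III", "IV")
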