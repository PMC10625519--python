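"""Reference tables from the 2017–2021 China maize mapping campaign.

Three small tables ship with the package as plain CSV:

* the ground-truth sample inventory, keyed by zone (a–e), year, class and
  collection method (I field survey, II yearbook-inferred, III existing
  provincial product, IV visual interpretation);
* the cross-year transfer accuracies in the sample-rich North China zone
  (overall accuracy when training on one year and predicting another);
* the province-level maize area comparison: mapped area versus the
  statistical-yearbook record, per province and year.

They anchor the synthetic scenarios' counting structure and give the
evaluation module fixed inputs for its summary statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "sample_inventory",
    "inventory_lookup",
    "cross_year_accuracy",
    "province_areas",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open("rb") as fh:
        return pd.read_csv(fh)


def sample_inventory() -> pd.DataFrame:
    """Per zone/year/class/method ground-truth sample counts.

    Cells the campaign reported as zero are simply absent;
    :func:`inventory_lookup` returns 0 for them.
    """
    return _read("sample_inventory.csv")


def inventory_lookup(
    zone: str,
    year: int,
    class_label: str,
    method: str | None = None,
    inventory: pd.DataFrame | None = None,
) -> int:
    """Sample count for a (zone, year, class[, method]) cell; 0 if absent."""
    df = sample_inventory() if inventory is None else inventory
    sel = (
        (df["zone"] == zone)
        & (df["year"] == year)
        & (df["class"] == class_label)
    )
    if method is not None:
        sel &= df["method"] == method
    return int(df.loc[sel, "count"].sum())


def cross_year_accuracy() -> pd.DataFrame:
    """Overall accuracies for all ordered 2017–2019 train/test year pairs."""
    return _read("cross_year_oa.csv")


def province_areas() -> pd.DataFrame:
    """Mapped vs yearbook maize area (km²) per province and year, long form."""
    return _read("province_areas.csv")
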