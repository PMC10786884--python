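"""Loaders for the packaged reference tables.

The package bundles three small tables from a published national raised-bog
land-use assessment, used as worked examples and arithmetic fixtures:

* a 7x7 validation confusion matrix (1460 stratified points; rows = map
  class, columns = reference class, in the published class order),
* the per-class land-use areas in hectares,
* the tiered emission-factor table (see :mod:`bogmap.emissions`).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .lucip import class_code
from .validation import ConfusionMatrix


def _read(name: str) -> pd.DataFrame:
    with resources.files("bogmap.data").joinpath(name).open() as f:
        return pd.read_csv(f)


def load_reference_confusion_matrix(
    with_areas: bool = False,
) -> ConfusionMatrix:
    """The bundled 7x7 validation cross-tabulation.

    With ``with_areas=True`` the published per-class areas are attached as
    the mapped stratum areas (the published source does not print the raw
    pixel-counting areas, so the published estimates stand in; adequate for
    demonstrations, not for re-deriving the published area estimates).
    """
    df = _read("reference_confusion_matrix.csv")
    names = list(df["class"])
    counts = df[names].to_numpy()
    codes = [class_code(n) for n in names]
    areas = None
    if with_areas:
        area_map = load_reference_class_areas()
        areas = [area_map[n] for n in names]
    return ConfusionMatrix(counts, codes, areas)


def load_reference_class_areas() -> dict[str, float]:
    """Published per-class land-use areas in hectares."""
    df = _read("reference_class_areas.csv")
    return dict(zip(df["class"], df["area_ha"].astype(float)))
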