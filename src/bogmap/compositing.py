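"""Cloud filtering, QA masking, median compositing and spectral indices.

The pre-processing chain that turns a cloud-contaminated scene series into a
single 12-band feature stack: scenes above a cloud-fraction threshold are
discarded, remaining cloudy pixels are masked via the QA bitmask, the
per-pixel per-band median over clear observations forms the composite, and
NDVI / NDWI are computed from the composited bands (indices after the median,
not per scene).

Nodata is carried as NaN in the arrays with an explicit boolean mask exposed
on the containers; no sentinel reflectance values are used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .lucip import BAND_NAMES, FEATURE_NAMES, N_BANDS
from .synthetic import DEFAULT_PIXEL_SIZE_HA, Scene

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot produce usable output."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class BandSet:
    """Named 10-band reflectance stack, shape (10, H, W), NaN = nodata."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.shape[0] != N_BANDS:
            raise ValueError(f"BandSet data must be ({N_BANDS}, H, W)")

    def band(self, name: str) -> np.ndarray:
        return self.data[BAND_NAMES.index(name)]

    @property
    def mask(self) -> np.ndarray:
        """True where any band is nodata."""
        return np.isnan(self.data).any(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class CompositeImage:
    """12-band per-pixel feature stack: 10 reflectance bands + NDVI + NDWI.

    ``provenance`` counts the clear observations contributing to each pixel;
    pixels with zero clear observations are nodata (NaN) in all 12 layers.
    """

    bands: BandSet
    ndvi: np.ndarray
    ndwi: np.ndarray
    provenance: np.ndarray
    pixel_size_ha: float = DEFAULT_PIXEL_SIZE_HA

    feature_names = FEATURE_NAMES

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape

    @property
    def features(self) -> np.ndarray:
        """(12, H, W) stack in the fixed order B2..B12, NDVI, NDWI."""
        return np.concatenate(
            [self.bands.data, self.ndvi[None], self.ndwi[None]], axis=0
        )

    @property
    def mask(self) -> np.ndarray:
        """True where the pixel is nodata in the feature stack."""
        return np.isnan(self.features).any(axis=0)


def resample_nearest(grid: np.ndarray, factor: int = 2) -> np.ndarray:
    """Nearest-neighbour upsampling (e.g. 20 m -> 10 m band ingest).

    Duplicates pixels, preserving reflectance values exactly.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return np.repeat(np.repeat(grid, factor, axis=-2), factor, axis=-1)


def filter_by_cloud_fraction(series: list[Scene], max_fraction: float = 0.10) -> list[Scene]:
    """Keep scenes with cloud fraction strictly below ``max_fraction``.

    The comparison is strict ``<``: a scene at exactly the threshold is
    discarded.  Order is preserved.  An empty result is returned with a
    warning logged (the composite stage then errors).
    """
    if not 0.0 <= max_fraction <= 1.0:
        raise ValueError("max_fraction must lie in [0, 1]")
    kept = [s for s in series if s.cloud_fraction < max_fraction]
    if not kept:
        logger.warning(
            "cloud filter (< %.3f) removed all %d scenes", max_fraction, len(series)
        )
    return kept


def mask_clouds(scene: Scene) -> Scene:
    """Set every QA-flagged (cloud or cirrus) pixel to nodata in all bands."""
    cloudy = scene.cloudy_mask()
    bands = scene.bands.copy()
    bands[:, cloudy] = np.nan
    return Scene(bands, scene.qa.copy(), scene.date, scene.cloud_fraction)


def median_composite(series: list[Scene]) -> BandSet:
    """Per-pixel, per-band median over clear (non-nodata) observations.

    A pixel-band with an even number of clear observations takes the mean of
    the two central values; a pixel with no clear observation in a band is
    nodata there.
    """
    if not series:
        raise ValueError("median_composite requires at least one scene")
    shapes = {s.bands.shape for s in series}
    if len(shapes) != 1:
        raise ValueError("all scenes must share the same grid")
    stack = np.stack([s.bands for s in series])  # (n, 10, H, W)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN slices
        med = np.nanmedian(stack, axis=0)
    return BandSet(med.astype(np.float32))


def _normalised_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(a - b) / (a + b), with NaN where the denominator is 0 or inputs are nodata."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a - b) / denom
    out[denom == 0] = np.nan
    return out.astype(np.float32)


def ndvi(bands: BandSet) -> np.ndarray:
    """Normalised Difference Vegetation Index, (NIR - Red) / (NIR + Red)."""
    return _normalised_difference(bands.band("B8"), bands.band("B4"))


def ndwi(bands: BandSet) -> np.ndarray:
    """Normalised Difference Water Index, (NNIR - SWIR1) / (NNIR + SWIR1)."""
    return _normalised_difference(bands.band("B8a"), bands.band("B11"))


def build_feature_stack(
    series: list[Scene],
    max_cloud_fraction: float = 0.10,
    pixel_size_ha: float = DEFAULT_PIXEL_SIZE_HA,
) -> CompositeImage:
    """Run the full pre-processing chain: filter, mask, median, indices.

    Raises :class:`PipelineError` naming the failing stage when no scene
    survives the cloud filter or the composite has no valid pixel.
    """
    kept = filter_by_cloud_fraction(series, max_cloud_fraction)
    if not kept:
        raise PipelineError(
            "cloud_filter",
            f"no scene below the {max_cloud_fraction:.0%} cloud-fraction threshold",
        )
    masked = [mask_clouds(s) for s in kept]
    composite = median_composite(masked)
    provenance = np.sum(
        [~np.isnan(s.bands[0]) for s in masked], axis=0
    ).astype(np.int32)
    if int(provenance.max(initial=0)) == 0:
        raise PipelineError("median_composite", "composite contains no valid pixel")
    return CompositeImage(
        bands=composite,
        ndvi=ndvi(composite),
        ndwi=ndwi(composite),
        provenance=provenance,
        pixel_size_ha=pixel_size_ha,
    )
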