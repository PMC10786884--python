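"""Seeded synthetic raised-bog scenes: ground truth, spectra, clouds, polygons.

This module generates everything the downstream pipeline consumes, so that
compositing, classification, validation and emission accounting can be tested
end-to-end without any satellite download:

* a categorical ground-truth land-use map with spatially contiguous patches,
* a catalogue of per-class 10-band mean reflectance signatures,
* a multi-temporal series of noisy scenes with blob-shaped cloud cover
  recorded in a QA bitmask band,
* labelled, disjoint training polygons sitting on pure-class ground.

Everything is driven by explicit integer seeds and is bit-reproducible.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, box

from .lucip import (
    CLASS_NAMES,
    N_BANDS,
    N_CLASSES,
    NODATA,
    SWIR_BANDS,
    VISIBLE_NIR_BANDS,
    class_name,
)

#: QA bitmask layout, bit-compatible with the Sentinel-2 QA60 convention:
#: bit 10 flags opaque cloud, bit 11 flags cirrus.
QA_CLOUD_BIT: int = 1 << 10
QA_CIRRUS_BIT: int = 1 << 11
QA_ANY_CLOUD: int = QA_CLOUD_BIT | QA_CIRRUS_BIT

#: Default pixel footprint: a 10 m pixel is 0.01 ha.
DEFAULT_PIXEL_SIZE_HA: float = 0.01


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ClassMap:
    """Single-band categorical raster of LUCIP class codes.

    ``grid`` holds integer codes (0 = nodata); ``pixel_size_ha`` converts
    pixel counts to hectares.
    """

    grid: np.ndarray
    pixel_size_ha: float = DEFAULT_PIXEL_SIZE_HA
    nodata: int = NODATA

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("ClassMap grid must be 2-D")
        if self.pixel_size_ha <= 0:
            raise ValueError("pixel_size_ha must be positive")
        valid = np.isin(self.grid, [self.nodata, *CLASS_NAMES])
        if not valid.all():
            bad = np.unique(self.grid[~valid])
            raise ValueError(f"invalid class codes in grid: {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def class_counts(self) -> dict[int, int]:
        """Pixel count per class code (nodata excluded)."""
        codes, counts = np.unique(self.grid, return_counts=True)
        return {int(c): int(n) for c, n in zip(codes, counts) if c != self.nodata}

    def class_areas_ha(self) -> dict[int, float]:
        """Mapped (pixel-counting) area in hectares per class code."""
        return {c: n * self.pixel_size_ha for c, n in self.class_counts().items()}

    def proportions(self) -> dict[int, float]:
        counts = self.class_counts()
        total = sum(counts.values())
        return {c: n / total for c, n in counts.items()}


@dataclass
class SpectralSignatureSet:
    """Per-class mean reflectance in the 10 bands, plus per-band noise SD.

    ``means`` has shape (7, 10): row ``code-1`` is the signature of class
    ``code`` in the band order of :data:`bogmap.lucip.BAND_NAMES`.
    """

    means: np.ndarray
    noise_sd: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (N_BANDS,)
        ).copy()
        if self.means.shape != (N_CLASSES, N_BANDS):
            raise ValueError(f"means must be {(N_CLASSES, N_BANDS)}")
        if ((self.means < 0) | (self.means > 1)).any():
            raise ValueError("signature means must lie in [0, 1]")
        if (self.noise_sd < 0).any():
            raise ValueError("noise SDs must be non-negative")

    def separability_margin(self) -> float:
        """Smallest over class pairs of the largest visible/NIR band gap.

        The generator guarantees this exceeds 3x the noise SD, so that a
        nearest-mean classifier on noiseless means is a valid oracle for
        downstream classification tests.
        """
        vis = self.means[:, VISIBLE_NIR_BANDS]
        margin = math.inf
        for i in range(N_CLASSES):
            for j in range(i + 1, N_CLASSES):
                margin = min(margin, float(np.abs(vis[i] - vis[j]).max()))
        return margin

    def closest_pair(self) -> tuple[int, int]:
        """Class-code pair with the smallest Euclidean signature distance."""
        best, pair = math.inf, (0, 0)
        for i in range(N_CLASSES):
            for j in range(i + 1, N_CLASSES):
                d = float(np.linalg.norm(self.means[i] - self.means[j]))
                if d < best:
                    best, pair = d, (i + 1, j + 1)
        return pair


@dataclass
class Scene:
    """One acquisition date: 10 reflectance bands + QA bitmask.

    ``bands`` has shape (10, H, W) with NaN for nodata; ``qa`` is an integer
    bitmask grid (see :data:`QA_CLOUD_BIT` / :data:`QA_CIRRUS_BIT`);
    ``cloud_fraction`` equals the fraction of pixels with either cloud bit
    set, exactly.
    """

    bands: np.ndarray
    qa: np.ndarray
    date: datetime.date
    cloud_fraction: float

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float32)
        self.qa = np.asarray(self.qa)
        if self.bands.ndim != 3 or self.bands.shape[0] != N_BANDS:
            raise ValueError(f"bands must be ({N_BANDS}, H, W)")
        if self.qa.shape != self.bands.shape[1:]:
            raise ValueError("qa grid must be congruent with bands")

    @property
    def shape(self) -> tuple[int, int]:
        return self.qa.shape

    def cloudy_mask(self) -> np.ndarray:
        """Boolean grid, True where either cloud bit is set."""
        return (self.qa & QA_ANY_CLOUD) != 0


@dataclass
class TrainingPolygons:
    """Labelled training polygons: list of (shapely polygon, class code).

    Polygon coordinates live in pixel space (x = column, y = row, origin at
    the top-left corner of pixel (0, 0)); every polygon is wholly inside a
    single-class region of the truth map it was drawn from.
    """

    items: list[tuple[Polygon, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    def counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for _, code in self.items:
            out[code] = out.get(code, 0) + 1
        return out


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``.

    Floors the exact quotas then hands out the remaining units by largest
    fractional remainder; ties go to the lowest index, keeping the result
    deterministic.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must have a positive sum")
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = total - counts.sum()
    # stable sort => ties broken by lowest index
    order = np.argsort(-remainder, kind="stable")
    counts[order[:short]] += 1
    return counts


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def generate_class_map(
    width: int,
    height: int,
    class_proportions,
    patch_scale: int = 20,
    seed: int = 0,
    pixel_size_ha: float = DEFAULT_PIXEL_SIZE_HA,
) -> ClassMap:
    """Generate a contiguous-patch ground-truth class map.

    Seed points are scattered uniformly over the grid (one per
    ``patch_scale**2`` pixels), apportioned to classes by largest remainder
    on ``class_proportions``, and every pixel takes the class of its nearest
    seed.  Nearest-seed labelling is uniform-speed region growing from the
    seeds, so patches are contiguous with mean size ~ ``patch_scale**2``
    pixels, and realised class shares track the request closely (within
    +/-5 percentage points for maps of 200x200 and up).

    Parameters
    ----------
    class_proportions
        Length-7 vector of non-negative shares summing to 1 (tolerance 1e-9),
        in class-code order.
    patch_scale
        Approximate linear size of a patch in pixels (>= 1).
    """
    p = np.asarray(class_proportions, dtype=float)
    if p.shape != (N_CLASSES,):
        raise ValueError(f"class_proportions must have length {N_CLASSES}")
    if (p < 0).any():
        raise ValueError("class proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    if width <= 0 or height <= 0:
        raise ValueError("grid dimensions must be positive")
    if patch_scale < 1:
        raise ValueError("patch_scale must be >= 1")

    rng = np.random.default_rng(seed)
    n_seeds = max(1, round(width * height / patch_scale**2))
    counts = _largest_remainder(p, n_seeds)
    # every requested class keeps at least one seed (steal from the largest)
    for c in range(N_CLASSES):
        if p[c] > 0 and counts[c] == 0:
            counts[int(np.argmax(counts))] -= 1
            counts[c] += 1
    labels = np.repeat(np.arange(1, N_CLASSES + 1), counts)

    pts = rng.uniform([0, 0], [height, width], size=(n_seeds, 2))
    rows, cols = np.mgrid[0:height, 0:width]
    centres = np.column_stack([rows.ravel() + 0.5, cols.ravel() + 0.5])
    _, idx = cKDTree(pts).query(centres, workers=1)
    grid = labels[idx].reshape(height, width).astype(np.int16)
    return ClassMap(grid, pixel_size_ha=pixel_size_ha)


#: Fixed default signature catalogue (unitless BOA reflectance).  The values
#: are synthetic: they are chosen to satisfy the qualitative orderings seen in
#: real raised-bog spectra (built-up brightest in the visible; water darkest
#: in the NIR; grassland and cutaway high in the NIR; cutover and remnant
#: peatland the most similar pair; inter-class contrast compressed in the
#: SWIR), not digitised from any published curve.
_DEFAULT_MEANS = np.array(
    [
        # B2    B3    B4    B5    B6    B7    B8    B8a   B11   B12
        [0.06, 0.08, 0.10, 0.18, 0.30, 0.36, 0.42, 0.43, 0.200, 0.130],  # cutaway
        [0.05, 0.07, 0.08, 0.13, 0.20, 0.25, 0.29, 0.30, 0.190, 0.120],  # cutover
        [0.04, 0.08, 0.06, 0.16, 0.32, 0.40, 0.46, 0.47, 0.210, 0.110],  # grassland
        [0.03, 0.05, 0.04, 0.10, 0.18, 0.22, 0.26, 0.27, 0.150, 0.090],  # forestry
        [0.05, 0.07, 0.09, 0.14, 0.21, 0.26, 0.31, 0.32, 0.195, 0.125],  # remnant
        [0.08, 0.09, 0.07, 0.06, 0.05, 0.04, 0.03, 0.03, 0.090, 0.060],  # water
        [0.22, 0.24, 0.26, 0.27, 0.28, 0.29, 0.30, 0.31, 0.230, 0.150],  # built_up
    ]
)

DEFAULT_NOISE_SD: float = 0.005


def default_signatures(seed: int | None = None) -> SpectralSignatureSet:
    """Return the packaged default spectral signature catalogue.

    The catalogue is a fixed constant table (``seed`` is accepted for
    interface uniformity with the other generators but does not alter it).
    Guaranteed properties, by construction:

    * built-up has the highest reflectance in every visible band;
    * water has the lowest NIR reflectance of all classes;
    * grassland and cutaway have the highest NIR reflectance;
    * cutover and remnant peatland are the closest pair (smallest inter-class
      Euclidean distance), mimicking the hard-to-separate mosaic landscapes;
    * the spread of class means in the two SWIR bands is smaller than in any
      visible/NIR band (separability collapses at long wavelengths);
    * every class pair differs by more than 3x the default noise SD in at
      least one visible/NIR band.
    """
    return SpectralSignatureSet(_DEFAULT_MEANS.copy(), DEFAULT_NOISE_SD)


def _cloud_mask(
    rng: np.random.Generator, shape: tuple[int, int], fraction: float, blob_scale: float
) -> np.ndarray:
    """Spatially correlated cloud mask covering exactly ``fraction`` of pixels.

    White noise is smoothed with a Gaussian kernel and thresholded at the
    quantile that flags exactly ``round(fraction * n_pixels)`` pixels, giving
    contiguous blob-shaped clouds with an exact realised fraction.
    """
    n = shape[0] * shape[1]
    k = int(round(fraction * n))
    mask = np.zeros(shape, dtype=bool)
    if k <= 0:
        return mask
    field_ = gaussian_filter(rng.standard_normal(shape), sigma=blob_scale)
    flat = field_.ravel()
    top = np.argpartition(flat, n - k)[n - k :]
    mask.ravel()[top] = True
    return mask


def generate_scene_series(
    truth: ClassMap,
    sig: SpectralSignatureSet,
    n_scenes: int,
    cloud_fraction_range=(0.0, 0.3),
    seed: int = 0,
    noise_sd: float | np.ndarray | None = None,
    blob_scale: float = 8.0,
    start_date: datetime.date = datetime.date(2018, 1, 1),
    n_days: int = 1095,
) -> list[Scene]:
    """Simulate a multi-temporal acquisition series over ``truth``.

    Each scene's reflectance is the class mean plus independent Gaussian
    noise truncated to [0, 1]; each scene receives an independent blob-shaped
    cloud pattern whose fraction is drawn uniformly from
    ``cloud_fraction_range`` and recorded exactly in the QA band (opaque
    cloud on bit 10, cirrus on bit 11).  When ``n_scenes >= 5`` and the upper
    cloud bound is <= 0.5 the series is repaired so that every pixel is
    cloud-free in at least one scene.

    ``noise_sd`` overrides the catalogue's per-band noise SD when given.
    Acquisition dates are spread evenly over ``n_days`` from ``start_date``.
    """
    lo, hi = float(cloud_fraction_range[0]), float(cloud_fraction_range[1])
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("cloud_fraction_range must satisfy 0 <= lo <= hi <= 1")
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")

    sd = sig.noise_sd if noise_sd is None else np.broadcast_to(
        np.asarray(noise_sd, dtype=float), (N_BANDS,)
    )
    rng = np.random.default_rng(seed)
    h, w = truth.shape
    npix = h * w
    code_grid = truth.grid
    valid = code_grid != truth.nodata
    # (10, H, W) class-mean reflectance; nodata pixels become NaN
    idx = np.where(valid, code_grid - 1, 0)
    base = sig.means[idx].transpose(2, 0, 1).astype(np.float32)
    base[:, ~valid] = np.nan

    scenes: list[Scene] = []
    masks: list[np.ndarray] = []
    for i in range(n_scenes):
        bands = base.copy()
        if (sd > 0).any():
            noise = rng.standard_normal((N_BANDS, h, w)).astype(np.float32)
            bands = bands + noise * sd[:, None, None].astype(np.float32)
            np.clip(bands, 0.0, 1.0, out=bands)
        f = rng.uniform(lo, hi)
        cloudy = _cloud_mask(rng, (h, w), f, blob_scale)
        cirrus = cloudy & (rng.random((h, w)) < 0.2)
        masks.append(cloudy)
        date = start_date + datetime.timedelta(days=round(i * n_days / max(n_scenes, 1)))
        scenes.append(Scene(bands, np.zeros((h, w), dtype=np.uint16), date, 0.0))
        scenes[-1]._cirrus = cirrus  # stashed until QA assembly below

    # guarantee every pixel is clear in >= 1 scene by clearing the QA bits of
    # each always-cloudy pixel in the currently cloudiest scene
    if n_scenes >= 5 and hi <= 0.5:
        always = np.logical_and.reduce(masks)
        if always.any():
            counts = [m.sum() for m in masks]
            for r, c in np.argwhere(always):
                j = int(np.argmax(counts))
                masks[j][r, c] = False
                counts[j] -= 1

    for scene, cloudy in zip(scenes, masks):
        cirrus = scene._cirrus & cloudy
        del scene._cirrus
        qa = np.zeros((h, w), dtype=np.uint16)
        qa[cloudy & ~cirrus] |= QA_CLOUD_BIT
        qa[cirrus] |= QA_CIRRUS_BIT
        scene.qa = qa
        scene.cloud_fraction = float(cloudy.sum() / npix)
    return scenes


def generate_training_polygons(
    truth: ClassMap,
    n_per_class,
    polygon_size: int = 3,
    seed: int = 0,
    max_attempts: int = 10000,
) -> TrainingPolygons:
    """Place disjoint square training polygons on pure-class ground.

    For each class, candidate ``polygon_size x polygon_size`` pixel blocks
    lying entirely within that class are enumerated and drawn at random
    without overlap until the requested count is met.  Polygons are inset by
    a quarter pixel so neighbouring blocks do not touch; all pixel centres of
    the block remain inside.

    Raises
    ------
    ValueError
        If a requested class is absent from the map or the request cannot be
        satisfied without overlap (the class is named in the message).
    """
    n_req = np.asarray(n_per_class, dtype=int)
    if n_req.shape != (N_CLASSES,):
        raise ValueError(f"n_per_class must have length {N_CLASSES}")
    if polygon_size < 1:
        raise ValueError("polygon_size must be >= 1")
    s = int(polygon_size)
    h, w = truth.shape
    if s > h or s > w:
        raise ValueError("polygon_size exceeds grid extent")

    rng = np.random.default_rng(seed)
    occupancy = np.zeros((h, w), dtype=bool)
    items: list[tuple[Polygon, int]] = []
    inset = 0.25

    for code in range(1, N_CLASSES + 1):
        want = int(n_req[code - 1])
        if want <= 0:
            continue
        mask = truth.grid == code
        if not mask.any():
            raise ValueError(
                f"class '{class_name(code)}' is absent from the truth map; "
                f"request unsatisfiable"
            )
        # integral image => top-left corners whose s x s block is pure-class
        ii = np.zeros((h + 1, w + 1), dtype=np.int32)
        ii[1:, 1:] = mask.cumsum(0).cumsum(1)
        block = ii[s:, s:] - ii[:-s, s:] - ii[s:, :-s] + ii[:-s, :-s]
        cand = np.argwhere(block == s * s)
        if len(cand) == 0:
            raise ValueError(
                f"no {s}x{s} pure-class block available for "
                f"'{class_name(code)}'"
            )
        order = rng.permutation(len(cand))
        got = 0
        for k in order[: max_attempts]:
            r, c = cand[k]
            if occupancy[r : r + s, c : c + s].any():
                continue
            occupancy[r : r + s, c : c + s] = True
            poly = box(c + inset, r + inset, c + s - inset, r + s - inset)
            items.append((poly, code))
            got += 1
            if got == want:
                break
        if got < want:
            raise ValueError(
                f"could only place {got}/{want} polygons for "
                f"'{class_name(code)}' without overlap"
            )
    return TrainingPolygons(items)
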