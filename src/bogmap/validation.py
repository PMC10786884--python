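"""Stratified validation, accuracy statistics and unbiased area estimation.

Implements the "good practices" protocol for map accuracy and area
estimation from a stratified random validation sample:

* proportional sample allocation with a per-stratum floor,
* confusion-matrix accuracy statistics (overall, user's and producer's
  accuracy),
* the area-based error matrix  p_ij = W_i * n_ij / n_i.  with stratum
  weights W_i = A_m,i / A_total (mapped-area shares),
* unbiased class-area estimates  A_j = A_total * sum_i p_ij  with the
  stratified standard error

      SE(p_.j) = sqrt( sum_i W_i^2 * q_ij (1 - q_ij) / (n_i. - 1) ),
      q_ij = n_ij / n_i.

  and normal-approximation 95% confidence intervals,
* zonal tabulation of class areas by management-region polygons.

Count-based and area-based overall accuracy are distinct quantities under
stratified sampling with a floor allocation and are reported by separate
functions, never conflated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .lucip import class_name
from .synthetic import ClassMap

Z_95: float = 1.96


@dataclass
class SampleAllocation:
    """Per-class validation point counts for a stratified sample."""

    class_codes: list[int]
    counts: np.ndarray
    min_per_stratum: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[int, int]:
        return {c: int(n) for c, n in zip(self.class_codes, self.counts)}


@dataclass
class ConfusionMatrix:
    """Validation cross-tabulation: rows = map class, columns = reference class.

    ``mapped_areas_ha`` aligns with ``class_codes`` and carries the mapped
    (pixel-counting) area of each map stratum; it is required for the
    area-based estimators but optional for plain accuracy statistics.
    """

    counts: np.ndarray
    class_codes: list[int]
    mapped_areas_ha: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_codes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match class_codes")
        if self.mapped_areas_ha is not None:
            self.mapped_areas_ha = np.asarray(self.mapped_areas_ha, dtype=float)
            if self.mapped_areas_ha.shape != (k,):
                raise ValueError("mapped_areas_ha must align with class_codes")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def class_names(self) -> list[str]:
        return [class_name(c) for c in self.class_codes]

    def to_dataframe(self) -> pd.DataFrame:
        names = self.class_names
        return pd.DataFrame(self.counts, index=names, columns=names)


@dataclass
class AccuracyReport:
    """Count-based accuracy statistics, stored at full precision (percent).

    Undefined entries (zero row or column total) are NaN, never 0.
    ``display()`` applies the integer-truncation convention used in printed
    accuracy tables (e.g. 244/252 = 96.8 displayed as 96).
    """

    class_codes: list[int]
    oa: float
    ua: np.ndarray
    pa: np.ndarray

    def display(self) -> dict[str, object]:
        def trunc(x: float) -> int | None:
            return None if math.isnan(x) else int(math.floor(x))

        names = [class_name(c) for c in self.class_codes]
        return {
            "oa": trunc(self.oa),
            "ua": {n: trunc(v) for n, v in zip(names, self.ua)},
            "pa": {n: trunc(v) for n, v in zip(names, self.pa)},
        }


@dataclass
class AreaEstimate:
    """Unbiased class-area estimates from the area-based error matrix."""

    class_codes: list[int]
    proportions: np.ndarray  # p_.j, sums to 1
    areas_ha: np.ndarray
    se_proportions: np.ndarray
    se_ha: np.ndarray
    ci_low_ha: np.ndarray
    ci_high_ha: np.ndarray
    stratum_weights: np.ndarray  # W_i
    total_area_ha: float
    z: float = Z_95

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": [class_name(c) for c in self.class_codes],
                "proportion": self.proportions,
                "area_ha": self.areas_ha,
                "se_ha": self.se_ha,
                "ci95_low_ha": self.ci_low_ha,
                "ci95_high_ha": self.ci_high_ha,
            }
        )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def allocate_stratified_sample(
    mapped_areas_ha: dict[int, float],
    total_n: int,
    min_per_stratum: int = 50,
    seed: int | None = None,
) -> SampleAllocation:
    """Proportional allocation with a per-stratum floor.

    Classes whose proportional share falls below ``min_per_stratum`` are
    pinned at the floor; the remaining budget is split proportionally to
    mapped area among the rest (pinning cascades until stable), with
    largest-remainder rounding so the counts sum exactly to ``total_n``.
    The rule is deterministic; ``seed`` is accepted for interface symmetry.
    """
    codes = sorted(mapped_areas_ha)
    areas = np.asarray([mapped_areas_ha[c] for c in codes], dtype=float)
    if (areas <= 0).any():
        raise ValueError("every sampled stratum must have positive mapped area")
    k = len(codes)
    if total_n < k * min_per_stratum:
        raise ValueError(
            f"total_n={total_n} cannot satisfy a floor of {min_per_stratum} "
            f"across {k} strata"
        )
    pinned = np.zeros(k, dtype=bool)
    while True:
        budget = total_n - min_per_stratum * pinned.sum()
        share = np.zeros(k)
        free = ~pinned
        share[free] = areas[free] / areas[free].sum() * budget
        newly = free & (share < min_per_stratum)
        if not newly.any():
            break
        pinned |= newly
    counts = np.full(k, min_per_stratum, dtype=int)
    free_idx = np.flatnonzero(~pinned)
    if len(free_idx):
        quota = share[free_idx]
        base = np.floor(quota).astype(int)
        rem = quota - base
        short = budget - base.sum()
        order = np.argsort(-rem, kind="stable")
        base[order[:short]] += 1
        counts[free_idx] = base
    return SampleAllocation(codes, counts, min_per_stratum)


def draw_validation_points(
    class_map: ClassMap, allocation: SampleAllocation, seed: int = 0
) -> list[tuple[tuple[int, int], int]]:
    """Uniform random sampling without replacement within each map stratum.

    Returns ``((row, col), map_class)`` tuples, deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    points: list[tuple[tuple[int, int], int]] = []
    for code, n in zip(allocation.class_codes, allocation.counts):
        locs = np.argwhere(class_map.grid == code)
        if len(locs) < n:
            raise ValueError(
                f"stratum '{class_name(code)}' has {len(locs)} pixels, "
                f"fewer than its allocation of {n}"
            )
        chosen = locs[rng.choice(len(locs), size=int(n), replace=False)]
        points.extend(((int(r), int(c)), int(code)) for r, c in chosen)
    return points


def simulate_reference_labels(
    truth: ClassMap,
    points: list[tuple[tuple[int, int], int]],
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[int]:
    """Reference labels for validation points, read off the truth map.

    Stands in for the manual photo-interpretation of real campaigns; with
    ``error_rate`` > 0 each label is flipped to a uniformly random other
    class with that probability (seeded), emulating interpreter error.
    """
    rng = np.random.default_rng(seed)
    labels = []
    codes = sorted(truth.class_counts())
    for (r, c), _ in points:
        lab = int(truth.grid[r, c])
        if error_rate > 0 and rng.random() < error_rate:
            others = [x for x in codes if x != lab]
            lab = int(rng.choice(others))
        labels.append(lab)
    return labels


# ---------------------------------------------------------------------------
# confusion matrix and accuracy
# ---------------------------------------------------------------------------


def build_confusion_matrix(
    map_labels,
    reference_labels,
    mapped_areas_ha: dict[int, float] | None = None,
    class_codes: list[int] | None = None,
) -> ConfusionMatrix:
    """Cross-tabulate (map class, reference class) label pairs."""
    m = np.asarray(map_labels, dtype=int)
    r = np.asarray(reference_labels, dtype=int)
    if len(m) != len(r):
        raise ValueError("map and reference label lists must have equal length")
    if len(m) == 0:
        raise ValueError("label lists are empty")
    if class_codes is None:
        class_codes = sorted(set(m.tolist()) | set(r.tolist()))
    for c in class_codes:
        class_name(c)  # validates
    index = {c: i for i, c in enumerate(class_codes)}
    unknown = [x for x in np.unique(np.concatenate([m, r])) if int(x) not in index]
    if unknown:
        raise ValueError(f"labels outside the class set: {unknown}")
    k = len(class_codes)
    counts = np.zeros((k, k), dtype=np.int64)
    mi = np.vectorize(index.__getitem__)(m)
    ri = np.vectorize(index.__getitem__)(r)
    np.add.at(counts, (mi, ri), 1)
    areas = None
    if mapped_areas_ha is not None:
        try:
            areas = np.asarray([mapped_areas_ha[c] for c in class_codes], dtype=float)
        except KeyError as e:
            raise ValueError(f"missing mapped area for class code {e.args[0]}") from None
    return ConfusionMatrix(counts, list(class_codes), areas)


def accuracy_report(cm: ConfusionMatrix) -> AccuracyReport:
    """OA, user's and producer's accuracy in percent, full precision."""
    if cm.n == 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(cm.counts).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ua = np.where(cm.row_totals > 0, 100.0 * diag / cm.row_totals, np.nan)
        pa = np.where(cm.col_totals > 0, 100.0 * diag / cm.col_totals, np.nan)
    oa = 100.0 * diag.sum() / cm.n
    return AccuracyReport(list(cm.class_codes), float(oa), ua, pa)


# ---------------------------------------------------------------------------
# area-based estimators
# ---------------------------------------------------------------------------


def _weights(cm: ConfusionMatrix) -> np.ndarray:
    """Stratum weights W_i; zero-area zero-sample rows are permitted.

    A class that exists only in the reference labels (never mapped) has
    W_i = 0 and n_i. = 0 and contributes an all-zero row; a sampled stratum
    without a mapped area, or a mapped stratum without samples, is an error.
    """
    if cm.mapped_areas_ha is None:
        raise ValueError("mapped areas are required for area-based estimators")
    w = cm.mapped_areas_ha / cm.mapped_areas_ha.sum()
    bad_unsampled = (w > 0) & (cm.row_totals == 0)
    if bad_unsampled.any():
        bad = [class_name(c) for c, b in zip(cm.class_codes, bad_unsampled) if b]
        raise ValueError(f"mapped strata with zero samples: {', '.join(bad)}")
    bad_area = (w == 0) & (cm.row_totals > 0)
    if bad_area.any():
        bad = [class_name(c) for c, b in zip(cm.class_codes, bad_area) if b]
        raise ValueError(f"sampled strata with zero mapped area: {', '.join(bad)}")
    return w


def area_error_matrix(cm: ConfusionMatrix) -> np.ndarray:
    """Area-proportion error matrix, p_ij = W_i * n_ij / n_i. (sums to 1)."""
    w = _weights(cm)
    rt = np.maximum(cm.row_totals, 1)  # zero-weight rows are all-zero anyway
    return w[:, None] * cm.counts / rt[:, None]


def area_based_overall_accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent of *area*: 100 * trace of the p_ij matrix.

    The area-weighted counterpart of the count OA; the two differ whenever
    stratum sampling rates are unequal (e.g. floor allocations).
    """
    return 100.0 * float(np.trace(area_error_matrix(cm)))


def unbiased_area_estimates(cm: ConfusionMatrix, z: float = Z_95) -> AreaEstimate:
    """Unbiased class areas with stratified standard errors and CIs.

    Requires every stratum to hold at least 2 samples (the variance
    estimator divides by n_i. - 1).
    """
    w = _weights(cm)
    small = (w > 0) & (cm.row_totals < 2)
    if small.any():
        bad = [class_name(c) for c, s in zip(cm.class_codes, small) if s]
        raise ValueError(
            f"standard error undefined (stratum size < 2) for: {', '.join(bad)}"
        )
    p = area_error_matrix(cm)
    p_dot_j = p.sum(axis=0)
    total_area = float(cm.mapped_areas_ha.sum())
    rt = np.maximum(cm.row_totals, 1)
    q = cm.counts / rt[:, None]
    var = (
        w[:, None] ** 2 * q * (1.0 - q) / np.maximum(rt[:, None] - 1, 1)
    ).sum(axis=0)
    se_p = np.sqrt(var)
    areas = p_dot_j * total_area
    se_ha = se_p * total_area
    return AreaEstimate(
        class_codes=list(cm.class_codes),
        proportions=p_dot_j,
        areas_ha=areas,
        se_proportions=se_p,
        se_ha=se_ha,
        ci_low_ha=areas - z * se_ha,
        ci_high_ha=areas + z * se_ha,
        stratum_weights=w,
        total_area_ha=total_area,
        z=z,
    )


# ---------------------------------------------------------------------------
# zonal tabulation
# ---------------------------------------------------------------------------


def zonal_tabulate(
    class_map: ClassMap, regions: list[tuple[str, Polygon]]
) -> pd.DataFrame:
    """Class area (ha) per named region polygon, by pixel-centre containment.

    Rows are regions, columns the seven class names plus a ``total`` column
    equal to the region's covered pixel area.  An empty region yields a zero
    row with a warning.
    """
    h, w = class_map.shape
    names = [class_name(c) for c in range(1, 8)]
    rows = {}
    for region_name, poly in regions:
        minx, miny, maxx, maxy = poly.bounds
        c0, c1 = max(0, int(math.floor(minx))), min(w, int(math.ceil(maxx)))
        r0, r1 = max(0, int(math.floor(miny))), min(h, int(math.ceil(maxy)))
        areas = np.zeros(7)
        if c1 > c0 and r1 > r0:
            cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
            inside = shapely.contains_xy(poly, cc.ravel() + 0.5, rr.ravel() + 0.5)
            vals = class_map.grid[rr.ravel()[inside], cc.ravel()[inside]]
            for code in range(1, 8):
                areas[code - 1] = (vals == code).sum() * class_map.pixel_size_ha
        if areas.sum() == 0:
            warnings.warn(f"region '{region_name}' covers no classified pixel")
        rows[region_name] = list(areas) + [areas.sum()]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=names + ["total"]
    )
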