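"""Tiered CO2-C emission accounting for peatland land-use classes.

Annual emission per class = area (ha) x emission factor (t CO2-C ha^-1 y^-1),
with an uncertainty range obtained by multiplying the area by the factor's
95% confidence bounds.  Tier 1 factors are the IPCC Wetlands Supplement
defaults; Tier 2 factors come from country-specific flux studies.  Classes
without a factor (remnant peatland, water, built-up) are carried as
explicitly excluded, never as zeros.

Tier totals sum the per-class means and, for the range, the per-class bounds;
summing bounds assumes perfect dependence between classes, so the total range
is labelled a "naive range" wherever it is printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .lucip import CLASS_CODES

TIERS = ("T1", "T2")

#: Note attached to reports that include Tier 2 factors for both extraction
#: classes: in the source compilation the printed class totals for cutover
#: and cutaway are consistent with these two factors transposed; the factors
#: here follow the labels as published.
T2_EXTRACTION_NOTE = (
    "Tier 2 factors for cutover (1.21) and cutaway (1.59) follow their "
    "published labels; published per-class emission totals for these two "
    "classes are consistent with the factors swapped."
)

NAIVE_RANGE_NOTE = (
    "total range is the naive sum of per-class bounds "
    "(assumes perfect dependence between classes)"
)


@dataclass
class EmissionFactor:
    """One (class, tier) emission factor in t CO2-C ha^-1 y^-1 with 95% CI."""

    class_name: str
    tier: str
    ef_mean: float
    ef_low: float
    ef_high: float
    n_sites: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_CODES:
            raise ValueError(f"unknown land-use class: {self.class_name!r}")
        if self.tier not in TIERS:
            raise ValueError(f"tier must be one of {TIERS}, got {self.tier!r}")
        if not (self.ef_low <= self.ef_mean <= self.ef_high):
            raise ValueError(
                f"malformed CI for {self.class_name}/{self.tier}: "
                f"low={self.ef_low}, mean={self.ef_mean}, high={self.ef_high}"
            )


@dataclass
class EmissionReport:
    """Per-(class, tier) emissions with ranges, plus excluded classes.

    ``table`` columns: class, tier, area_ha, ef_mean, ef_low, ef_high,
    emission_t, range_low_t, range_high_t (all full precision; rounding
    happens only in the display helpers).
    """

    table: pd.DataFrame
    excluded: list[str]
    notes: list[str] = field(default_factory=list)

    def tier_table(self, tier: str) -> pd.DataFrame:
        sub = self.table[self.table["tier"] == tier]
        if sub.empty:
            raise ValueError(f"report contains no tier {tier!r} entries")
        return sub

    def to_text(self) -> str:
        """Human-readable emission table (integer tonnes, 2-dp Mt totals)."""
        lines = [
            f"{'class':<18}{'tier':<6}{'area (ha)':>12}{'EF':>8}"
            f"{'emission (t)':>15}{'range (t)':>26}"
        ]
        for _, row in self.table.iterrows():
            rng = f"{row.range_low_t:,.0f} - {row.range_high_t:,.0f}"
            lines.append(
                f"{row['class']:<18}{row.tier:<6}{row.area_ha:>12,.0f}"
                f"{row.ef_mean:>8.2f}{row.emission_t:>15,.0f}{rng:>26}"
            )
        for tier in TIERS:
            if (self.table["tier"] == tier).any():
                tot, lo, hi = total_emissions(self, tier)
                lines.append(
                    f"{tier} total: {tot:.2f} Mt CO2-C/y "
                    f"(naive range {lo:.2f} - {hi:.2f})"
                )
        if self.excluded:
            lines.append("excluded (no emission factor): " + ", ".join(self.excluded))
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


def load_emission_factors(
    source: str | Path | pd.DataFrame | None = None,
) -> list[EmissionFactor]:
    """Load and validate an emission-factor table.

    ``source`` may be a CSV path or a DataFrame with columns ``class, tier,
    ef_mean, ef_low, ef_high, n_sites, source``; ``None`` loads the packaged
    default table (IPCC Tier 1 wetland defaults and Irish literature Tier 2
    values for the four dominant classes).
    """
    if source is None:
        with resources.files("bogmap.data").joinpath("emission_factors.csv").open() as f:
            df = pd.read_csv(f)
    elif isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source)
    required = {"class", "tier", "ef_mean", "ef_low", "ef_high"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"emission-factor table missing columns: {sorted(missing)}")
    factors = []
    for _, row in df.iterrows():
        n_sites = row.get("n_sites")
        factors.append(
            EmissionFactor(
                class_name=str(row["class"]),
                tier=str(row["tier"]),
                ef_mean=float(row["ef_mean"]),
                ef_low=float(row["ef_low"]),
                ef_high=float(row["ef_high"]),
                n_sites=None if pd.isna(n_sites) else int(n_sites),
                source=str(row.get("source", "")),
            )
        )
    return factors


def compute_emissions(
    areas_ha: dict[str | int, float], efs: list[EmissionFactor]
) -> EmissionReport:
    """Emission = area x EF per (class, tier); bounds from the EF's CI.

    Classes with area but no factor in any tier are listed in ``excluded``.
    """
    from .lucip import class_code, class_name as _cname

    named: dict[str, float] = {}
    for key, area in areas_ha.items():
        name = _cname(class_code(key)) if not isinstance(key, str) else key
        if name not in CLASS_CODES:
            raise ValueError(f"unknown land-use class: {name!r}")
        if area < 0:
            raise ValueError(f"negative area for {name}: {area}")
        named[name] = float(area)

    by_class: dict[str, list[EmissionFactor]] = {}
    for ef in efs:
        by_class.setdefault(ef.class_name, []).append(ef)

    rows = []
    for name, area in named.items():
        for ef in by_class.get(name, []):
            rows.append(
                {
                    "class": name,
                    "tier": ef.tier,
                    "area_ha": area,
                    "ef_mean": ef.ef_mean,
                    "ef_low": ef.ef_low,
                    "ef_high": ef.ef_high,
                    "emission_t": area * ef.ef_mean,
                    "range_low_t": area * ef.ef_low,
                    "range_high_t": area * ef.ef_high,
                }
            )
    excluded = sorted(n for n in named if n not in by_class)
    table = pd.DataFrame(
        rows,
        columns=[
            "class", "tier", "area_ha", "ef_mean", "ef_low", "ef_high",
            "emission_t", "range_low_t", "range_high_t",
        ],
    )
    notes = [NAIVE_RANGE_NOTE]
    t2_classes = set(table.loc[table["tier"] == "T2", "class"])
    if {"cutover", "cutaway"} <= t2_classes:
        notes.append(T2_EXTRACTION_NOTE)
    return EmissionReport(table=table, excluded=excluded, notes=notes)


def total_emissions(report: EmissionReport, tier: str) -> tuple[float, float, float]:
    """Tier total and naive range in Mt CO2-C y^-1 (t / 1e6), full precision."""
    sub = report.tier_table(tier)
    return (
        float(sub["emission_t"].sum()) / 1e6,
        float(sub["range_low_t"].sum()) / 1e6,
        float(sub["range_high_t"].sum()) / 1e6,
    )
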