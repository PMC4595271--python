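"""Phenophase-level climate records and season summaries.

Viticultural climate is recorded per phenophase (Flowering, Berry
development, Veraison, Ripening) for each region-year: duration in days,
global radiation (RAD, kJ/m^2), growing degree days (GDD, in the source
table's own degree-day units -- the base temperature is not specified and
the values are treated as opaque accumulations), sunshine hours, rainfall
(mm) and the mean day-night temperature difference (degrees C).

Season summaries add the additive quantities over phenophases and average
the temperature difference.  The published season-level temperature
difference is consistent with an unweighted mean over phenophases for the
recent rows and approximately with a days-weighted mean for one older row;
the unweighted mean is the default and a days-weighted variant is
available via ``weight_by_days=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import pandas as pd

PHENOPHASES = ("Flowering", "Berry development", "Veraison", "Ripening")

#: Additive season quantities (summed over phenophases).
ADDITIVE_FIELDS = ("days", "rad_kj_m2", "gdd", "sunshine_h", "rainfall_mm")

#: All numeric fields carried by a climate record.
NUMERIC_FIELDS = ADDITIVE_FIELDS + ("temp_diff_c",)


@dataclass(frozen=True)
class ClimateRecord:
    """One phenophase of one region-year."""

    region: str
    year: int
    phenophase: str
    days: float
    rad_kj_m2: float
    gdd: float
    sunshine_h: float
    rainfall_mm: float
    temp_diff_c: float

    def __post_init__(self) -> None:
        if self.phenophase not in PHENOPHASES:
            raise ValueError(f"unknown phenophase: {self.phenophase!r}")
        for field in NUMERIC_FIELDS:
            value = getattr(self, field)
            if value is not None and value < 0:
                raise ValueError(f"{field} must be non-negative, got {value}")


def load_climate(path) -> pd.DataFrame:
    """Read a climate CSV with one row per (region, year, phenophase)."""
    df = pd.read_csv(path)
    required = {"region", "year", "phenophase"} | set(NUMERIC_FIELDS)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"climate table missing columns: {sorted(missing)}")
    _check_unique_phenophases(df)
    return df


def reference_climate() -> pd.DataFrame:
    """Published Changli (CL) / Gaotai (GT) phenophase climate rows.

    Season totals are always recomputed from these rows, never copied from
    a printed total line.
    """
    with resources.files("terpomics.data").joinpath(
        "changli_gaotai_climate.csv"
    ).open() as fh:
        return load_climate(fh)


def _check_unique_phenophases(df: pd.DataFrame) -> None:
    dup = df.duplicated(subset=["region", "year", "phenophase"])
    if dup.any():
        rows = df.loc[dup, ["region", "year", "phenophase"]].to_records(index=False)
        raise ValueError(f"duplicate phenophase rows: {list(rows)}")


def season_summary(
    records: pd.DataFrame, *, weight_by_days: bool = False
) -> pd.Series:
    """Season totals for one region-year.

    Additive fields are summed over phenophases; the day-night temperature
    difference is averaged (unweighted by default, optionally weighted by
    phenophase duration) and rounded to 2 decimals for reporting.
    """
    if len(records) == 0:
        raise ValueError("no phenophase records supplied")
    if records["region"].nunique() > 1 or records["year"].nunique() > 1:
        raise ValueError("season_summary expects a single region-year")
    _check_unique_phenophases(records)

    out = {field: records[field].sum() for field in ADDITIVE_FIELDS}
    td = records["temp_diff_c"].dropna()
    if len(td) == 0:
        out["temp_diff_c"] = float("nan")
    elif weight_by_days:
        w = records.loc[td.index, "days"]
        out["temp_diff_c"] = round(float((td * w).sum() / w.sum()), 2)
    else:
        out["temp_diff_c"] = round(float(td.mean()), 2)
    out["region"] = records["region"].iloc[0]
    out["year"] = records["year"].iloc[0]
    return pd.Series(out)


def summarize_all(df: pd.DataFrame, *, weight_by_days: bool = False) -> pd.DataFrame:
    """Season summaries for every region-year in a climate table."""
    rows = [
        season_summary(group, weight_by_days=weight_by_days)
        for _, group in df.groupby(["region", "year"], sort=True)
    ]
    return pd.DataFrame(rows).reset_index(drop=True)


def region_contrast(summary_a: pd.Series, summary_b: pd.Series) -> pd.DataFrame:
    """Per-metric signed difference (B - A) and ratio (B / A).

    Both summaries must refer to the same year.  A zero denominator yields
    a missing ratio rather than an error.
    """
    if summary_a.get("year") != summary_b.get("year"):
        raise ValueError(
            f"mismatched years: {summary_a.get('year')} vs {summary_b.get('year')}"
        )
    metrics = list(ADDITIVE_FIELDS) + ["temp_diff_c"]
    rows = []
    for m in metrics:
        a, b = float(summary_a[m]), float(summary_b[m])
        rows.append(
            {
                "metric": m,
                "a": a,
                "b": b,
                "difference": b - a,
                "ratio": (b / a) if a != 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
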