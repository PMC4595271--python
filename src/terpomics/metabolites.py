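"""GC-MS internal-standard semi-quantification, odor activity and group tests.

Volatile terpenes are semi-quantified relative to a spiked internal
standard (4-methyl-2-pentanol in the motivating assay) with all response
factors fixed at 1: the reported concentration is the analyte/IS peak-area
ratio times the in-sample IS concentration, i.e. IS-equivalent micrograms
per litre.  Free and glycosidically bound fractions are always kept
separate.

Odor activity values (OAV = concentration / sensory threshold) flag
compounds that can contribute to aroma; OAV >= 1 counts as contributing
(the boundary is inclusive so threshold-equal compounds surface for
review).

Group comparison follows the field convention of one-way ANOVA followed by
Duncan's multiple range test, with letter codes: groups sharing a letter
are not significantly different.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class InternalStandard:
    """A spiked internal standard: stock concentration and volumes."""

    name: str
    stock_g_per_l: float
    spiked_volume_ml: float
    sample_volume_ml: float

    def __post_init__(self) -> None:
        for field in ("stock_g_per_l", "spiked_volume_ml", "sample_volume_ml"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")

    @property
    def in_sample_ug_per_l(self) -> float:
        """IS concentration in the prepared sample, in ug/L."""
        return (
            self.stock_g_per_l
            * 1e6
            * self.spiked_volume_ml
            / self.sample_volume_ml
        )


#: The assay's standard spike: 10 uL of 1.0018 g/L 4M2P into 5 mL juice.
FOUR_M2P = InternalStandard(
    name="4-methyl-2-pentanol",
    stock_g_per_l=1.0018,
    spiked_volume_ml=0.010,
    sample_volume_ml=5.0,
)


def quantify_relative(
    analyte_area: float, is_area: float, standard: InternalStandard = FOUR_M2P
) -> float:
    """IS-equivalent concentration (ug/L) from peak areas; linear in analyte area."""
    if is_area <= 0:
        raise ValueError("internal-standard peak area must be positive")
    if analyte_area < 0:
        raise ValueError("analyte peak area must be non-negative")
    return (analyte_area / is_area) * standard.in_sample_ug_per_l


def odor_activity(concentration: float, threshold: float) -> tuple[float, bool]:
    """(OAV, contributing) where OAV = concentration / sensory threshold."""
    if threshold <= 0:
        raise ValueError("sensory threshold must be positive")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    oav = concentration / threshold
    return oav, oav >= 1.0


def oav_table(records: pd.DataFrame, thresholds: pd.DataFrame) -> pd.DataFrame:
    """OAVs for a metabolite table joined against a sensory-threshold table.

    ``records`` needs columns compound, form, region, year, stage,
    replicate, concentration_ug_l; ``thresholds`` needs compound,
    threshold_ug_l.  Compounds with no threshold are omitted (no
    threshold, no OAV).
    """
    merged = records.merge(thresholds[["compound", "threshold_ug_l"]], on="compound")
    merged = merged[merged["threshold_ug_l"] > 0].copy()
    merged["oav"] = merged["concentration_ug_l"] / merged["threshold_ug_l"]
    merged["contributing"] = merged["oav"] >= 1.0
    return merged


def totals_by_form(records: pd.DataFrame) -> pd.DataFrame:
    """Total concentration per (region, year, stage, form), replicate mean +/- SD.

    Each replicate's total is the sum over compounds in that replicate;
    the reported total is the mean of the per-replicate sums and the SD is
    taken over those sums (ddof=1; NaN with a single replicate).  Free and
    bound fractions are never pooled.  Cells with no records are simply
    absent from the output, never reported as zero.
    """
    required = {"compound", "form", "region", "year", "stage", "replicate",
                "concentration_ug_l"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"metabolite table missing columns: {sorted(missing)}")
    per_rep = (
        records.groupby(["region", "year", "stage", "form", "replicate"])[
            "concentration_ug_l"
        ]
        .sum()
        .rename("replicate_total")
        .reset_index()
    )
    out = (
        per_rep.groupby(["region", "year", "stage", "form"])["replicate_total"]
        .agg(total="mean", sd=lambda v: v.std(ddof=1), n_replicates="count")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# One-way ANOVA + Duncan's multiple range test
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4096)
def _q_crit(alpha_p: float, span: int, df_error: int) -> float:
    """Upper studentized-range quantile (cached: the quadrature is slow)."""
    return float(stats.studentized_range.ppf(1.0 - alpha_p, span, df_error))


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Plain one-way ANOVA (F, p) over labelled groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    f_stat, p_val = stats.f_oneway(*(np.asarray(v, float) for v in groups.values()))
    return float(f_stat), float(p_val)


@dataclass(frozen=True)
class AnovaDuncanResult:
    f_statistic: float
    p_value: float
    letters: dict[str, str]
    means: dict[str, float]
    #: pairwise decisions: (label_a, label_b) -> significantly different?
    different: dict[tuple[str, str], bool]


def anova_duncan(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaDuncanResult:
    """One-way ANOVA F/p plus Duncan's multiple range letter codes.

    Duncan's test compares ordered means with studentized-range critical
    values at protection levels alpha_p = 1 - (1 - alpha)**(p - 1) for a
    span of p means, using the harmonic-mean group size for unequal n.  A
    non-significant range protects every sub-range (the standard stepwise
    rule), so non-difference is contiguous in mean order and letters encode
    the pairwise decisions exactly.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(len(v) < 2 for v in data.values()):
        raise ValueError("need at least 2 values per group")

    f_stat, p_val = one_way_anova(data)
    n_total = sum(len(v) for v in data.values())
    k = len(labels)
    df_error = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in data.values()) / df_error
    means = {lab: float(v.mean()) for lab, v in data.items()}

    if not np.isfinite(f_stat):
        # zero within-group variance with differing means: report p ~ 0
        f_stat, p_val = float("inf"), 0.0

    order = sorted(labels, key=lambda lab: (-means[lab], lab))
    m = np.array([means[lab] for lab in order])
    n_h = k / sum(1.0 / len(data[lab]) for lab in order)  # harmonic mean n

    different = np.zeros((k, k), dtype=bool)
    protected = np.zeros((k, k), dtype=bool)
    if mse > 0:
        for span in range(k, 1, -1):
            alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
            r_crit = _q_crit(alpha_p, span, df_error) * np.sqrt(mse / n_h)
            for i in range(0, k - span + 1):
                j = i + span - 1
                if protected[i, j]:
                    continue
                if m[i] - m[j] > r_crit:
                    different[i, j] = different[j, i] = True
                else:
                    protected[i : j + 1, i : j + 1] = True
    else:
        # no residual variance: any two unequal means differ
        for i in range(k):
            for j in range(i + 1, k):
                if m[i] != m[j]:
                    different[i, j] = different[j, i] = True

    letters = _assign_letters(order, different)
    decisions = {
        (a, b): bool(different[order.index(a), order.index(b)])
        for a, b in itertools.combinations(sorted(labels), 2)
    }
    return AnovaDuncanResult(
        f_statistic=float(f_stat),
        p_value=float(p_val),
        letters=letters,
        means=means,
        different=decisions,
    )


def _assign_letters(order: list[str], different: np.ndarray) -> dict[str, str]:
    """Letters for maximal runs of mutually non-different means (sorted order)."""
    k = len(order)
    intervals: list[tuple[int, int]] = []
    i = 0
    while i < k:
        j = i
        while j + 1 < k and not different[i : j + 2, i : j + 2].any():
            j += 1
        if not intervals or intervals[-1][1] < j:
            intervals.append((i, j))
        i += 1
    alphabet = itertools.chain(
        string.ascii_lowercase,
        ("".join(p) for p in itertools.product(string.ascii_lowercase, repeat=2)),
    )
    codes: dict[str, list[str]] = {lab: [] for lab in order}
    for (lo, hi), letter in zip(intervals, alphabet):
        for idx in range(lo, hi + 1):
            codes[order[idx]].append(letter)
    return {lab: "".join(v) for lab, v in codes.items()}


def anova_duncan_table(
    records: pd.DataFrame,
    value_col: str = "concentration_ug_l",
    group_col: str = "region",
    by: Sequence[str] = ("compound", "form", "year", "stage"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run anova_duncan within every stratum of a long metabolite table."""
    rows = []
    for key, sub in records.groupby(list(by), sort=True):
        groups = {
            str(g): v[value_col].to_numpy()
            for g, v in sub.groupby(group_col, sort=True)
        }
        if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
            continue
        res = anova_duncan(groups, alpha=alpha)
        for lab in groups:
            rows.append(
                dict(
                    zip(by, key if isinstance(key, tuple) else (key,)),
                    group=lab,
                    mean=res.means[lab],
                    letters=res.letters[lab],
                    f_statistic=res.f_statistic,
                    p_value=res.p_value,
                )
            )
    return pd.DataFrame(rows)
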