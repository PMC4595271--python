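"""Gene-metabolite correlation and candidate-gene nomination.

Expression and metabolite profiles are aligned on condition cells
(region x year x stage; replicate libraries or extractions averaged into
one value per cell, 16 cells in the full two-region, two-year,
four-stage design) and correlated with Pearson's r; the p-value comes
from the t transform t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of
freedom, two-sided.  No multiple-testing correction is applied to these
screening correlations.

Two correlation modes are supported:

* ``instantaneous`` -- expression at a stage vs. metabolite level at the
  same stage;
* ``cumulative`` -- expression first replaced by its running sum over
  stages within each region-year series, which asks whether accumulated
  transcript output tracks a metabolite pool (appropriate for products
  that accumulate, e.g. glycosidically bound monoterpenes made by a
  glucosyltransferase expressed early).

A gene is nominated as a candidate driver of a regional metabolite
difference when (a) its strongest supporting correlation reaches
``r_min`` with a concordant sign across all supporting metabolites, and
(b) it is significantly differentially expressed between regions at at
least one stage.  Candidates are ranked by max |r| scaled up by the
number of supporting metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MODES = ("instantaneous", "cumulative")


@dataclass(frozen=True)
class CorrelationResult:
    gene: str
    metabolite: str
    mode: str
    n: int
    r: float
    p: float


def cumulative_profile(
    expression: pd.Series, stage_order: Sequence[str]
) -> pd.Series:
    """Running sum of expression over stages within each region-year series.

    ``expression`` is indexed by (region, year, stage) tuples.
    """
    idx = pd.MultiIndex.from_tuples(expression.index, names=["region", "year", "stage"])
    s = pd.Series(expression.to_numpy(dtype=float), index=idx)
    rank = {stage: i for i, stage in enumerate(stage_order)}
    out = s.copy()
    for (region, year), sub in s.groupby(level=["region", "year"]):
        stages = sorted(sub.index, key=lambda t: rank[t[2]])
        running = 0.0
        for cell in stages:
            running += s[cell]
            out[cell] = running
    out.index = expression.index
    return out


def gene_metabolite_corr(
    expression: pd.Series,
    metabolite: pd.Series,
    *,
    mode: str = "instantaneous",
    stage_order: Sequence[str] | None = None,
    gene: str = "",
    metabolite_id: str = "",
) -> CorrelationResult:
    """Pearson correlation of an expression and a metabolite profile.

    Both series must be indexed by the same (region, year, stage) cells.
    Zero-variance profiles yield r = p = NaN (reported as missing rather
    than raising).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if len(expression) != len(metabolite) or not expression.index.equals(
        metabolite.index
    ):
        raise ValueError("profiles are not aligned on the same condition cells")
    if len(expression) < 3:
        raise ValueError("need at least 3 condition cells")
    if mode == "cumulative":
        if stage_order is None:
            raise ValueError("cumulative mode requires stage_order")
        expression = cumulative_profile(expression, stage_order)

    x = expression.to_numpy(dtype=float)
    y = metabolite.to_numpy(dtype=float)
    n = len(x)
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(gene, metabolite_id, mode, n, float("nan"), float("nan"))
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        gene, metabolite_id, mode, n, float(res.statistic), float(res.pvalue)
    )


def correlation_table(
    expression_profiles: pd.DataFrame,
    metabolite_profiles: pd.DataFrame,
    *,
    mode: str = "instantaneous",
    stage_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """All gene x metabolite correlations (rows = profiles, columns = cells)."""
    if not expression_profiles.columns.equals(metabolite_profiles.columns):
        raise ValueError("expression and metabolite cells are not aligned")
    cells = list(expression_profiles.columns)
    rows = []
    for gene in expression_profiles.index:
        expr = pd.Series(
            expression_profiles.loc[gene].to_numpy(dtype=float), index=cells
        )
        for met in metabolite_profiles.index:
            res = gene_metabolite_corr(
                expr,
                pd.Series(
                    metabolite_profiles.loc[met].to_numpy(dtype=float), index=cells
                ),
                mode=mode,
                stage_order=stage_order,
                gene=str(gene),
                metabolite_id=str(met),
            )
            rows.append(
                {
                    "gene": res.gene,
                    "metabolite": res.metabolite,
                    "mode": res.mode,
                    "n": res.n,
                    "r": res.r,
                    "p": res.p,
                }
            )
    return pd.DataFrame(rows)


def nominate_candidates(
    correlations: pd.DataFrame,
    deg_table: pd.DataFrame,
    *,
    r_min: float = 0.8,
    alpha: float = 0.05,
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Rank genes supported by strong correlations AND regional DE evidence.

    ``correlations`` needs columns gene, metabolite, r (p optional);
    ``deg_table`` needs transcript, comparison, significant (the regional
    comparisons).  A gene is nominated iff max |r| >= r_min and the gene
    has a significant regional DEG call at >= 1 stage.  The supporting
    set is sign-concordant by construction: it is the group of
    metabolites sharing the sign of the strongest correlation with
    |r| >= r_min.  Strong opposite-signed correlations do not disqualify
    a candidate (a ripening-induced enzyme inevitably anti-correlates
    with compounds that decline over ripening); they are counted in a
    ``n_discordant`` column for transparency.  Rank score =
    max |r| * (1 + n_supporting / 10); ties broken by gene id.
    """
    if correlations.empty or deg_table.empty:
        raise ValueError("empty correlation or DEG input")
    if "significant" in deg_table.columns:
        sig_mask = deg_table["significant"].astype(bool)
    else:
        sig_mask = deg_table["adjusted_p"] <= alpha
    sig_genes = (
        deg_table[sig_mask]
        .groupby("transcript")["comparison"]
        .agg(lambda c: ";".join(sorted(set(map(str, c)))))
    )
    rows = []
    for gene, sub in correlations.dropna(subset=["r"]).groupby("gene", sort=True):
        strong = sub[sub["r"].abs() >= r_min]
        if strong.empty:
            continue
        if gene not in sig_genes.index:
            continue
        # strongest correlation decides the supporting sign (ties -> positive)
        best = strong.loc[
            strong.assign(key=strong["r"].abs() + 1e-12 * np.sign(strong["r"]))
            ["key"].idxmax()
        ]
        sign = 1 if best["r"] >= 0 else -1
        support = strong[np.sign(strong["r"]) == sign]
        max_abs_r = float(support["r"].abs().max())
        n_support = len(support)
        rows.append(
            {
                "gene": gene,
                "category": (categories or {}).get(gene, ""),
                "n_supporting": n_support,
                "n_discordant": int(len(strong) - n_support),
                "max_abs_r": max_abs_r,
                "sign": sign,
                "supporting_metabolites": ";".join(sorted(support["metabolite"])),
                "deg_evidence": sig_genes[gene],
                "rank_score": max_abs_r * (1 + n_support / 10),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene", "category", "n_supporting", "n_discordant", "max_abs_r",
            "sign", "supporting_metabolites", "deg_evidence", "rank_score",
        ],
    )
    return out.sort_values(
        ["rank_score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
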