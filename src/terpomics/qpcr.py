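"""Relative qPCR expression (2^-dCT) and RNA-seq cross-validation.

Expression is quantified as 2**(-dCT) where dCT is the target threshold
cycle minus the geometric mean of the reference-gene threshold cycles
(here typically GAPDH, actin and ubiquitin).  Technical replicates are
averaged on the CT scale (arithmetic mean) before any transformation.

Validation against RNA-seq compares log2 expression from the two assays
per gene across samples; a gene passes when the correlation is positive
and R^2 exceeds a threshold (default 0.7).  R^2 alone is directionless,
so an anti-correlated gene never validates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def _mean_ct(ct) -> float:
    """Arithmetic mean of technical-replicate CT values (scalar passes through)."""
    arr = np.atleast_1d(np.asarray(ct, dtype=float))
    if arr.size == 0:
        raise ValueError("empty CT value set")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"CT values must be finite and positive, got {arr!r}")
    return float(arr.mean())


def expression_2ddct(ct_target, ct_refs: Iterable) -> float:
    """2^-dCT relative expression with a multi-reference geometric mean.

    Parameters
    ----------
    ct_target
        Target-gene CT, scalar or technical replicates.
    ct_refs
        One CT (scalar or replicate list) per reference gene; must be
        non-empty.  dCT = CT_target - geomean(reference CTs).
    """
    refs = list(ct_refs)
    if len(refs) == 0:
        raise ValueError("at least one reference gene is required")
    target = _mean_ct(ct_target)
    ref_means = np.array([_mean_ct(r) for r in refs])
    ct_ref = float(np.exp(np.mean(np.log(ref_means))))
    return float(2.0 ** -(target - ct_ref))


def expression_table(qpcr: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, gene) 2^-dCT from a long-format qPCR table.

    Expects columns ``sample, gene, ct, role`` where role is ``target`` or
    ``reference``; technical replicates are extra rows.
    """
    required = {"sample", "gene", "ct", "role"}
    if not required.issubset(qpcr.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    rows = []
    for sample, sub in qpcr.groupby("sample", sort=True):
        refs = sub[sub["role"] == "reference"]
        if refs.empty:
            raise ValueError(f"sample {sample!r} has no reference genes")
        ref_cts = [g["ct"].to_numpy() for _, g in refs.groupby("gene", sort=True)]
        for gene, g in sub[sub["role"] == "target"].groupby("gene", sort=True):
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "expression": expression_2ddct(g["ct"].to_numpy(), ref_cts),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ValidationResult:
    gene: str
    n: int
    r_log: float
    r2_log: float
    r_raw: float
    r2_raw: float
    passed: bool


def validate_against_rpkm(
    qpcr_values: Sequence[float],
    rpkm_values: Sequence[float],
    *,
    gene: str = "",
    r2_threshold: float = 0.7,
) -> ValidationResult:
    """Correlate qPCR 2^-dCT with RPKM across paired samples.

    The pass criterion is evaluated on log2-transformed values and
    additionally requires a positive correlation.  Pairs where either
    assay reports a non-positive value are dropped before the log;
    at least 3 pairs must remain.
    """
    q = np.asarray(qpcr_values, dtype=float)
    r = np.asarray(rpkm_values, dtype=float)
    if q.shape != r.shape:
        raise ValueError("paired vectors must have equal length")
    keep = (q > 0) & (r > 0) & np.isfinite(q) & np.isfinite(r)
    q, r = q[keep], r[keep]
    if q.size < 3:
        raise ValueError("need at least 3 positive paired samples")
    r_raw = float(stats.pearsonr(q, r).statistic)
    r_log = float(stats.pearsonr(np.log2(q), np.log2(r)).statistic)
    return ValidationResult(
        gene=gene,
        n=int(q.size),
        r_log=r_log,
        r2_log=r_log**2,
        r_raw=r_raw,
        r2_raw=r_raw**2,
        passed=bool(r_log > 0 and r_log**2 > r2_threshold),
    )
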