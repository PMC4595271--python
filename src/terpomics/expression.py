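"""Read bookkeeping, multi-read rescue, RPKM and replicate-free DE testing.

The quantification contract mirrors early digital gene-expression
practice on a reference transcriptome:

* raw reads are trimmed by 2 nt at each end and kept only if the trimmed
  length is at least 60 nt with at most two ambiguous bases;
* reads mapping to several transcripts are rescued by splitting each
  multi-read group across its candidate transcripts in proportion to the
  candidates' unique-read counts (uniform split when all uniques are
  zero), so assigned counts may be fractional but totals are conserved;
* expression is RPKM = 1e9 * C / (N * L) for assigned count C, transcript
  length L (nt) and N total mapped reads;
* two libraries are compared per gene with the exact conditional binomial
  test (Audic-Claverie equivalent): conditional on the combined count
  k = x + y, x ~ Binomial(k, N1/(N1+N2)) under the null, and the
  two-sided p-value is twice the smaller tail including the observed
  point, capped at 1.  Genes absent from one library default to a count
  of one before testing, which also bounds the log2 ratio.

Multiple testing across genes uses the Bonferroni adjustment, reported in
an ``adjusted_p`` column; a gene is called differentially expressed when
adjusted_p <= alpha and |log2 ratio| >= the fold-change threshold
(defaults 0.05 and 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: nucleotides trimmed from each read end before length filtering
TRIM_PER_END = 2
MIN_TRIMMED_LENGTH = 60
MAX_AMBIGUOUS = 2


def filter_reads(
    raw_reads: Iterable[tuple[float, int]],
    *,
    trim_per_end: int = TRIM_PER_END,
    min_length: int = MIN_TRIMMED_LENGTH,
    max_ambiguous: int = MAX_AMBIGUOUS,
) -> tuple[list[int], list[int]]:
    """Partition reads into (kept, dropped) index lists.

    Each read is a ``(raw_length, ambiguous_base_count)`` pair.  A read is
    kept iff its trimmed length (raw minus ``trim_per_end`` at both ends)
    is at least ``min_length`` and it has at most ``max_ambiguous``
    ambiguous bases.
    """
    kept, dropped = [], []
    for idx, (length, ambiguous) in enumerate(raw_reads):
        if length < 0:
            raise ValueError(f"read {idx}: negative length {length}")
        if ambiguous < 0:
            raise ValueError(f"read {idx}: negative ambiguous count")
        trimmed = length - 2 * trim_per_end
        if trimmed >= min_length and ambiguous <= max_ambiguous:
            kept.append(idx)
        else:
            dropped.append(idx)
    return kept, dropped


def assign_multireads(
    unique_counts: Mapping[str, float],
    groups: Iterable[tuple[Sequence[str], float]],
) -> dict[str, float]:
    """Assigned counts C after proportional rescue of multi-read groups.

    Each group ``(candidates, multiplicity)`` contributes
    ``multiplicity * U_t / sum(U over candidates)`` to every candidate t;
    when every candidate has zero unique reads the group is split
    uniformly.  Totals are conserved: sum(C) = sum(U) + sum(multiplicity).
    """
    assigned = {t: float(u) for t, u in unique_counts.items()}
    for candidates, multiplicity in groups:
        candidates = list(candidates)
        if not candidates:
            raise ValueError("multi-read group with empty candidate set")
        if multiplicity < 0:
            raise ValueError("negative multi-read multiplicity")
        unknown = [c for c in candidates if c not in assigned]
        if unknown:
            raise KeyError(f"candidates not in unique-count table: {unknown}")
        weights = np.array([unique_counts[c] for c in candidates], dtype=float)
        total = weights.sum()
        if total > 0:
            shares = multiplicity * weights / total
        else:
            shares = np.full(len(candidates), multiplicity / len(candidates))
        for c, share in zip(candidates, shares):
            assigned[c] += share
    return assigned


def rpkm(assigned_count: float, length_nt: float, total_mapped: float) -> float:
    """RPKM = 1e9 * C / (N * L) with L in nucleotides."""
    if length_nt <= 0:
        raise ValueError("transcript length must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    if assigned_count < 0:
        raise ValueError("assigned count must be non-negative")
    return 1e9 * assigned_count / (total_mapped * length_nt)


def rpkm_matrix(
    counts: pd.DataFrame,
    lengths: Mapping[str, float] | pd.Series,
    totals: Mapping[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """RPKM for a transcripts x libraries count matrix.

    ``totals`` defaults to the column sums of ``counts`` (every mapped
    read is accounted for in the matrix).
    """
    lengths = pd.Series(lengths, dtype=float).reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])
        raise KeyError(f"transcripts without length annotation: {missing}")
    totals = (
        counts.sum(axis=0) if totals is None else pd.Series(totals, dtype=float)
    )
    return 1e9 * counts.div(lengths, axis=0).div(totals, axis=1)


def deg_test(x: float, n1: float, y: float, n2: float) -> tuple[float, float]:
    """Exact conditional binomial test for one gene in two libraries.

    Returns ``(log2_ratio, raw_p)`` for counts x (library sized n1) vs y
    (library sized n2).  Counts are floored at 1 (the default count for a
    gene undetected in one library) and rounded to the nearest integer
    (ties up) for the exact test; the log2 ratio compares the floored
    per-library rates.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    x = max(1.0, float(x))
    y = max(1.0, float(y))
    log2_ratio = float(np.log2((x / n1) / (y / n2)))

    xi = int(np.floor(x + 0.5))
    yi = int(np.floor(y + 0.5))
    k = xi + yi
    p0 = n1 / (n1 + n2)
    lower = stats.binom.cdf(xi, k, p0)
    upper = stats.binom.sf(xi - 1, k, p0)
    p = min(1.0, 2.0 * min(lower, upper))
    return log2_ratio, float(p)


@dataclass(frozen=True)
class Comparison:
    """A pairwise condition comparison, e.g. GT vs CL at one stage-year."""

    label: str
    condition_a: str
    condition_b: str


def call_degs(
    counts: pd.DataFrame,
    library_conditions: Mapping[str, str] | pd.Series,
    comparisons: Sequence[Comparison],
    *,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    pool_replicates: bool = True,
) -> pd.DataFrame:
    """Pairwise DE calls over a transcripts x libraries count matrix.

    Replicate libraries within a condition are pooled by summation before
    testing (set ``pool_replicates=False`` to test the first library of
    each condition only).  The Bonferroni factor m is the number of
    transcripts tested in the comparison; rows are sorted by adjusted p
    then descending |log2 ratio|.
    """
    cond = pd.Series(library_conditions)
    unknown = [lib for lib in cond.index if lib not in counts.columns]
    if unknown:
        raise KeyError(f"libraries absent from count matrix: {unknown}")

    results = []
    for comp in comparisons:
        libs_a = list(cond.index[cond == comp.condition_a])
        libs_b = list(cond.index[cond == comp.condition_b])
        if not libs_a or not libs_b:
            raise KeyError(
                f"comparison {comp.label!r}: unknown condition "
                f"{comp.condition_a!r} or {comp.condition_b!r}"
            )
        if not pool_replicates:
            libs_a, libs_b = libs_a[:1], libs_b[:1]
        xs = counts[libs_a].sum(axis=1)
        ys = counts[libs_b].sum(axis=1)
        n1 = float(xs.sum())
        n2 = float(ys.sum())
        if n1 == 0 and n2 == 0:
            raise ValueError(f"comparison {comp.label!r}: both totals are zero")
        m = len(counts.index)
        for transcript in counts.index:
            lr, p = deg_test(xs[transcript], n1, ys[transcript], n2)
            adj = min(1.0, m * p)
            results.append(
                {
                    "transcript": transcript,
                    "comparison": comp.label,
                    "log2_ratio": lr,
                    "raw_p": p,
                    "adjusted_p": adj,
                    "significant": bool(
                        adj <= alpha and abs(lr) >= lfc_threshold
                    ),
                }
            )
    out = pd.DataFrame(results)
    if not out.empty:
        out = out.sort_values(
            ["comparison", "adjusted_p", "log2_ratio"],
            key=lambda s: -s.abs() if s.name == "log2_ratio" else s,
            kind="mergesort",
        ).reset_index(drop=True)
    return out
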