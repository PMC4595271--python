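import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from terpomics.expression import (
    Comparison,
    assign_multireads,
    call_degs,
    deg_test,
    filter_reads,
    rpkm,
    rpkm_matrix,
)


class TestFilterReads:
    @pytest.mark.parametrize(
        "length,ambiguous,kept",
        [
            (64, 0, True),   # trims to exactly 60
            (63, 0, False),  # trims to 59
            (100, 3, False),  # too many ambiguous bases
            (100, 2, True),
            (60, 0, False),
        ],
    )
    def test_trim_and_thresholds(self, length, ambiguous, kept):
        kept_idx, dropped_idx = filter_reads([(length, ambiguous)])
        assert (kept_idx == [0]) is kept
        assert (dropped_idx == [0]) is not kept

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError, match="negative length"):
            filter_reads([(-1, 0)])

    def test_partition_is_complete(self, rng):
        reads = [(int(l), int(a)) for l, a in
                 zip(rng.integers(0, 120, 50), rng.integers(0, 5, 50))]
        kept, dropped = filter_reads(reads)
        assert sorted(kept + dropped) == list(range(50))


def brute_force_assignment(unique, groups):
    """Independent per-read loop: each read of a group is assigned its
    fractional weight individually."""
    out = {t: float(u) for t, u in unique.items()}
    for candidates, multiplicity in groups:
        total = sum(unique[c] for c in candidates)
        for _read in range(int(multiplicity)):
            for c in candidates:
                share = unique[c] / total if total > 0 else 1 / len(candidates)
                out[c] += share
    return out


class TestAssignMultireads:
    def test_proportional_split(self):
        out = assign_multireads({"A": 30, "B": 10}, [(["A", "B"], 100)])
        assert out == {"A": 105.0, "B": 35.0}

    def test_uniform_fallback_when_no_uniques(self):
        out = assign_multireads({"A": 0, "B": 0}, [(["A", "B"], 10)])
        assert out == {"A": 5.0, "B": 5.0}

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError, match="empty candidate"):
            assign_multireads({"A": 1}, [([], 5)])

    def test_matches_per_read_brute_force(self, rng):
        transcripts = [f"t{i}" for i in range(4)]
        for _ in range(20):
            unique = {t: int(rng.integers(0, 50)) for t in transcripts}
            groups = []
            remaining = 1000
            for _g in range(3):
                size = int(rng.integers(2, 5))
                cand = list(rng.choice(transcripts, size=size, replace=False))
                mult = int(rng.integers(0, remaining + 1))
                remaining -= mult
                groups.append((cand, mult))
            got = assign_multireads(unique, groups)
            expected = brute_force_assignment(unique, groups)
            for t in transcripts:
                assert got[t] == pytest.approx(expected[t], abs=1e-9)

    @given(
        uniques=st.lists(st.integers(0, 1000), min_size=3, max_size=8),
        mults=st.lists(st.integers(0, 500), min_size=1, max_size=5),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_count_conservation(self, uniques, mults, data):
        unique = {f"t{i}": u for i, u in enumerate(uniques)}
        names = list(unique)
        groups = []
        for m in mults:
            cand = data.draw(
                st.lists(st.sampled_from(names), min_size=1, max_size=len(names),
                         unique=True)
            )
            groups.append((cand, m))
        out = assign_multireads(unique, groups)
        assert sum(out.values()) == pytest.approx(
            sum(uniques) + sum(mults), abs=1e-6
        )


class TestRpkm:
    @pytest.mark.parametrize(
        "c,l,n,expected",
        [(1000, 2000, 1e6, 500.0), (0, 2000, 1e6, 0.0), (1e6, 1000, 1e6, 1e6)],
    )
    def test_formula(self, c, l, n, expected):
        assert rpkm(c, l, n) == pytest.approx(expected)

    @pytest.mark.parametrize("l,n", [(0, 1e6), (-5, 1e6), (1000, 0)])
    def test_invalid_inputs(self, l, n):
        with pytest.raises(ValueError):
            rpkm(100, l, n)

    @given(
        c=st.floats(0, 1e6), l=st.floats(100, 1e5), n=st.floats(1e3, 1e9),
        k=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, c, l, n, k):
        # doubling every count and the library size leaves RPKM unchanged
        assert rpkm(k * c, l, k * n) == pytest.approx(rpkm(c, l, n), rel=1e-9)

    def test_matrix_matches_scalar(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 1000, (5, 3)).astype(float),
            index=[f"t{i}" for i in range(5)],
            columns=["l1", "l2", "l3"],
        )
        lengths = pd.Series(rng.integers(500, 3000, 5), index=counts.index)
        out = rpkm_matrix(counts, lengths)
        totals = counts.sum(axis=0)
        for t in counts.index:
            for lib in counts.columns:
                assert out.loc[t, lib] == pytest.approx(
                    rpkm(counts.loc[t, lib], lengths[t], totals[lib])
                )


class TestDegTest:
    def test_symmetric_null_p_capped_at_one(self):
        lr, p = deg_test(50, 1e6, 50, 1e6)
        assert lr == 0.0
        assert p == 1.0

    def test_pseudocount_floors_undetected_gene(self):
        lr, _ = deg_test(0, 1e6, 64, 1e6)
        assert lr == pytest.approx(-6.0)

    def test_tail_sum_oracle(self):
        # two-sided p = 2 * sum_{i<=1} C(65, i) / 2^65 for x=1, y=64, N1=N2
        expected = 2 * sum(math.comb(65, i) for i in range(2)) / 2**65
        _, p = deg_test(1, 1e6, 64, 1e6)
        assert p == pytest.approx(expected, rel=1e-12)

    @given(
        x=st.integers(0, 500), y=st.integers(0, 500),
        n1=st.floats(1e4, 1e7), n2=st.floats(1e4, 1e7),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, x, y, n1, n2):
        lr1, p1 = deg_test(x, n1, y, n2)
        lr2, p2 = deg_test(y, n2, x, n1)
        assert lr1 == pytest.approx(-lr2, abs=1e-9)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_log_ratio_monotone_in_x(self):
        ratios = [deg_test(x, 1e6, 50, 1e6)[0] for x in range(0, 200, 7)]
        assert all(b >= a for a, b in zip(ratios, ratios[1:]))

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            deg_test(5, 0, 5, 1e6)


class TestCallDegs:
    def _toy(self):
        # equal library sizes ~1e6; only g1 changes (10 vs 1280)
        counts = pd.DataFrame(
            {
                "libA": [10, 100, 100, 999790],
                "libB": [1280, 100, 100, 998520],
            },
            index=["g1", "g2", "g3", "filler"],
        )
        return counts, {"libA": "A", "libB": "B"}, [Comparison("A-vs-B", "A", "B")]

    def test_exactly_one_significant_gene(self):
        counts, cond, comps = self._toy()
        out = call_degs(counts, cond, comps)
        sig = out[out["significant"]]
        assert list(sig["transcript"]) == ["g1"]
        g1 = out.set_index("transcript").loc["g1"]
        # brute-force check of the Bonferroni arithmetic (m = 4 transcripts)
        lr, raw = deg_test(10, counts["libA"].sum(), 1280, counts["libB"].sum())
        assert g1["log2_ratio"] == pytest.approx(lr)
        assert g1["adjusted_p"] == pytest.approx(min(1.0, 4 * raw))

    def test_identical_conditions_yield_no_calls(self):
        counts = pd.DataFrame(
            {"libA": [100, 200, 300], "libB": [100, 200, 300]},
            index=["g1", "g2", "g3"],
        )
        out = call_degs(counts, {"libA": "A", "libB": "B"},
                        [Comparison("cmp", "A", "B")])
        assert not out["significant"].any()

    def test_adjusted_p_is_bonferroni(self):
        counts, cond, comps = self._toy()
        out = call_degs(counts, cond, comps)
        m = counts.shape[0]
        assert np.allclose(
            out["adjusted_p"], np.minimum(1.0, m * out["raw_p"])
        )
        assert (out["adjusted_p"] >= out["raw_p"] - 1e-12).all()

    def test_unknown_condition_rejected(self):
        counts, cond, _ = self._toy()
        with pytest.raises(KeyError):
            call_degs(counts, cond, [Comparison("bad", "A", "nope")])


def test_library_conservation_end_to_end(small_bundle):
    """Sum of assigned counts equals unique + multi-read totals per library."""
    from terpomics.pipeline import assigned_counts

    counts = assigned_counts(small_bundle)
    mult = small_bundle.multiread_groups.groupby("library")["multiplicity"].sum()
    for lib in counts.columns:
        expected = small_bundle.unique_counts[lib].sum() + mult.get(lib, 0)
        assert counts[lib].sum() == pytest.approx(expected, abs=1e-6)
        assert counts[lib].sum() == pytest.approx(
            small_bundle.library_meta.set_index("library").loc[lib, "total_mapped"],
            abs=1e-6,
        )
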