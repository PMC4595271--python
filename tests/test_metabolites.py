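import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from terpomics.metabolites import (
    FOUR_M2P,
    InternalStandard,
    anova_duncan,
    odor_activity,
    oav_table,
    one_way_anova,
    quantify_relative,
    totals_by_form,
)


class TestQuantifyRelative:
    def test_standard_spike_concentration(self):
        # 1.0018 g/L stock, 10 uL into 5 mL -> 2003.6 ug/L in sample
        assert FOUR_M2P.in_sample_ug_per_l == pytest.approx(2003.6)

    def test_area_ratio_two(self):
        # 2e5 / 1e5 with the standard spike -> 4.0072 mg/L
        assert quantify_relative(2e5, 1e5) == pytest.approx(4007.2)

    def test_zero_and_unit_ratio(self):
        assert quantify_relative(0.0, 1e5) == 0.0
        assert quantify_relative(1e5, 1e5) == pytest.approx(
            FOUR_M2P.in_sample_ug_per_l
        )

    def test_nonpositive_is_area_rejected(self):
        with pytest.raises(ValueError):
            quantify_relative(1e5, 0.0)

    @given(area=st.floats(0, 1e8), k=st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_analyte_area(self, area, k):
        assert quantify_relative(k * area, 1e5) == pytest.approx(
            k * quantify_relative(area, 1e5), rel=1e-9
        )

    def test_invalid_standard_rejected(self):
        with pytest.raises(ValueError):
            InternalStandard("x", stock_g_per_l=0, spiked_volume_ml=1,
                             sample_volume_ml=1)


class TestOdorActivity:
    @pytest.mark.parametrize(
        "conc,thr,oav,flag",
        [(50, 25, 2.0, True), (10, 25, 0.4, False), (25, 25, 1.0, True)],
    )
    def test_examples(self, conc, thr, oav, flag):
        got_oav, got_flag = odor_activity(conc, thr)
        assert got_oav == pytest.approx(oav)
        assert got_flag is flag

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            odor_activity(10, 0)

    @given(conc=st.floats(0, 1e5), thr=st.floats(0.01, 1e4),
           k=st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None)
    def test_scale_free(self, conc, thr, k):
        assert odor_activity(k * conc, k * thr)[0] == pytest.approx(
            odor_activity(conc, thr)[0], rel=1e-9
        )


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["compound", "form", "region", "year", "stage", "replicate",
                 "concentration_ug_l"],
    )


class TestTotalsByForm:
    def test_single_replicate_sum(self):
        rec = _records([
            ("c1", "free", "CL", 2011, "E-L38", 1, 10.0),
            ("c2", "free", "CL", 2011, "E-L38", 1, 20.0),
        ])
        out = totals_by_form(rec)
        assert out["total"].iloc[0] == pytest.approx(30.0)
        assert np.isnan(out["sd"].iloc[0])

    def test_mean_of_per_replicate_sums(self):
        rec = _records([
            ("c1", "free", "CL", 2011, "E-L38", 1, 10.0),
            ("c1", "free", "CL", 2011, "E-L38", 2, 20.0),
            ("c2", "free", "CL", 2011, "E-L38", 1, 20.0),
            ("c2", "free", "CL", 2011, "E-L38", 2, 40.0),
        ])
        out = totals_by_form(rec)
        # replicate sums 30 and 60 -> total 45
        assert out["total"].iloc[0] == pytest.approx(45.0)
        assert out["sd"].iloc[0] == pytest.approx(np.std([30, 60], ddof=1))

    def test_forms_never_pooled(self):
        rec = _records([
            ("c1", "free", "CL", 2011, "E-L38", 1, 10.0),
            ("c2", "bound", "CL", 2011, "E-L38", 1, 99.0),
        ])
        out = totals_by_form(rec).set_index("form")
        assert out.loc["free", "total"] == pytest.approx(10.0)
        assert out.loc["bound", "total"] == pytest.approx(99.0)

    def test_empty_cells_absent_not_zero(self):
        rec = _records([("c1", "free", "CL", 2011, "E-L38", 1, 10.0)])
        out = totals_by_form(rec)
        assert len(out) == 1  # no GT/other-stage rows fabricated


_Q_CACHE = {}


def _cached_q(q, span, df):
    key = (q, span, df)
    if key not in _Q_CACHE:
        _Q_CACHE[key] = stats.studentized_range.ppf(q, span, df)
    return _Q_CACHE[key]


def duncan_oracle(groups, alpha=0.05):
    """Independent stepwise Duncan decisions (no letter logic): returns the
    pairwise 'significantly different' map using the protection rule."""
    labels = sorted(groups, key=lambda lab: -np.mean(groups[lab]))
    vals = [np.asarray(groups[lab], float) for lab in labels]
    k = len(labels)
    n_total = sum(len(v) for v in vals)
    df = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in vals) / df
    n_h = k / sum(1.0 / len(v) for v in vals)
    means = [v.mean() for v in vals]
    decisions = {}
    nonsig_spans = []
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            pair = frozenset((labels[i], labels[j]))
            if any(lo <= i and j <= hi for lo, hi in nonsig_spans):
                decisions[pair] = False
                continue
            alpha_p = 1 - (1 - alpha) ** (span - 1)
            crit = _cached_q(round(1 - alpha_p, 12), span, df) * np.sqrt(mse / n_h)
            if means[i] - means[j] > crit:
                decisions[pair] = True
            else:
                decisions[pair] = False
                nonsig_spans.append((i, j))
    return decisions


class TestAnovaDuncan:
    def test_identical_groups_share_one_letter(self):
        res = anova_duncan({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.f_statistic == 0.0
        assert res.letters["a"] == res.letters["b"]

    def test_distant_groups_distinct_letters(self):
        res = anova_duncan({"a": [1, 2, 3], "b": [101, 102, 103]})
        # F = t^2 with t = 100 / sqrt(2/3)
        assert res.f_statistic == pytest.approx((100 / np.sqrt(2 / 3)) ** 2)
        assert set(res.letters["a"]) & set(res.letters["b"]) == set()

    def test_middle_group_shares_letters_with_both_extremes(self):
        groups = {
            "lo": [-0.8, 0.0, 0.8],
            "mid": [0.2, 1.0, 1.8],
            "hi": [1.2, 2.0, 2.8],
        }
        res = anova_duncan(groups)
        assert res.different[("hi", "lo")]
        assert not res.different[("lo", "mid")]
        assert not res.different[("hi", "mid")]
        assert set(res.letters["mid"]) & set(res.letters["lo"])
        assert set(res.letters["mid"]) & set(res.letters["hi"])
        assert not set(res.letters["lo"]) & set(res.letters["hi"])

    def test_letters_encode_oracle_decisions(self, rng):
        """Letters shared <=> not significantly different, against an
        independently coded stepwise oracle, over random instances."""
        for _ in range(25):
            k = int(rng.integers(2, 6))
            groups = {
                f"g{i}": rng.normal(rng.uniform(0, 3), 1.0, size=4)
                for i in range(k)
            }
            res = anova_duncan(groups)
            oracle = duncan_oracle(groups)
            for a, b in itertools.combinations(sorted(groups), 2):
                share = bool(set(res.letters[a]) & set(res.letters[b]))
                assert share is (not oracle[frozenset((a, b))]), (
                    a, b, res.letters, oracle)
                assert res.different[(a, b)] is oracle[frozenset((a, b))]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_duncan({"a": [1, 2, 3]})

    def test_zero_variance_with_different_means(self):
        res = anova_duncan({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert res.p_value == 0.0
        assert res.different[("a", "b")]

    def test_null_rejection_rate_is_calibrated(self):
        """Three equal-mean normal groups: the ANOVA p rejects at ~5%."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            sample = rng.normal(0.0, 1.0, (3, 5))
            _, p = one_way_anova({"a": sample[0], "b": sample[1], "c": sample[2]})
            rejections += p < 0.05
        assert 0.035 <= rejections / reps <= 0.065


def test_oav_table_joins_thresholds(worked_fixture):
    out = oav_table(worked_fixture.metabolites, worked_fixture.thresholds)
    assert (out["contributing"] == (out["oav"] >= 1.0)).all()
    # free linalool at CL harvest: 10*4*2 = 80 ug/L vs threshold 25.2
    row = out[
        (out["compound"] == "free_linalool")
        & (out["region"] == "CL")
        & (out["stage"] == "E-L38")
        & (out["year"] == 2010)
        & (out["replicate"] == 2)
    ]
    assert row["oav"].iloc[0] == pytest.approx(80 * 1.1 / 25.2)
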