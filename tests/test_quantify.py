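"""Ratio normalization: worked examples, invariances, and consistency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinedyn import get_schedule
from spinedyn import quantify as q

BASE10 = get_schedule("baseline10")
DEPRIV = get_schedule("deprivation")


class TestNormalizeSpineValue:
    @pytest.mark.parametrize("args,expected", [
        ((200, 50, 350, 50), 0.5),          # 150 / 300
        ((300, 50, 300, 50), 1.0),          # spine ROI == shaft ROI
        ((125, 25, 450, 50), 0.25),
    ])
    def test_hand_examples(self, args, expected):
        value, flag = q.normalize_spine_value(*args)
        assert value == pytest.approx(expected)
        assert flag == q.FLAG_OK

    def test_zero_numerator_floored_and_flagged(self):
        value, flag = q.normalize_spine_value(100, 100, 300, 50)
        assert flag == q.FLAG_FLOORED
        assert value == pytest.approx(q.EPS_FLOOR / 250)

    def test_nonpositive_denominator_flagged_invalid(self):
        value, flag = q.normalize_spine_value(200, 50, 50, 50)
        assert flag == q.FLAG_BAD_DENOM
        assert np.isnan(value)

    @given(
        spine=st.floats(10, 1e4), bg=st.floats(0, 9),
        shaft=st.floats(10, 1e4), c=st.floats(0.01, 100),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_scale_invariance(self, spine, bg, shaft, c):
        """Multiplying all four raw ROI values by c > 0 leaves the ratio
        unchanged (session gain cancels)."""
        v1, _ = q.normalize_spine_value(spine, bg, shaft, bg)
        v2, _ = q.normalize_spine_value(c * spine, c * bg, c * shaft, c * bg)
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_vectorized_matches_scalar(self):
        vals, flags = q.normalize_spine_value(
            [200, 100, 200], [50, 100, 50], [350, 300, 50], [50, 50, 50])
        assert vals[0] == pytest.approx(0.5)
        assert list(flags) == [q.FLAG_OK, q.FLAG_FLOORED, q.FLAG_BAD_DENOM]


class TestNormalizeTrace:
    def _series(self, values, schedule):
        return pd.Series(values, index=list(schedule.sessions)[:len(values)])

    @pytest.mark.parametrize("mode", ["raw_ratio", "to_day1",
                                      "to_baseline_mean"])
    def test_constant_trace_all_ones(self, mode):
        tr = self._series([2.0] * 7, DEPRIV)
        out = q.normalize_trace(tr, mode, DEPRIV)
        expected = 2.0 if mode == "raw_ratio" else 1.0
        assert np.allclose(out.dropna(), expected)

    def test_to_day1_hand_example(self):
        out = q.normalize_trace(self._series([2.0, 3.0, 4.0], BASE10),
                                "to_day1", BASE10)
        assert list(out.iloc[:3]) == pytest.approx([1.0, 1.5, 2.0])

    def test_to_baseline_mean_hand_example(self):
        tr = self._series([1.0, 1.0, 1.0, 0.8], DEPRIV)
        out = q.normalize_trace(tr, "to_baseline_mean", DEPRIV)
        assert out["VD1"] == pytest.approx(0.8)
        assert out[list(DEPRIV.baseline)].mean() == pytest.approx(1.0)

    def test_missing_reference_excludes_spine(self):
        tr = pd.Series({"BL2": 1.0, "BL3": 1.2, "VD1": 0.9})
        out = q.normalize_trace(tr, "to_baseline_mean", DEPRIV)
        assert out.isna().all()

    def test_ratio_normalizations_commute(self):
        """to_baseline_mean applied after to_day1 equals to_baseline_mean
        of the raw trace."""
        rng = np.random.default_rng(0)
        tr = self._series(rng.lognormal(0, 0.3, 7), DEPRIV)
        direct = q.normalize_trace(tr, "to_baseline_mean", DEPRIV)
        via_day1 = q.normalize_trace(
            q.normalize_trace(tr, "to_day1", DEPRIV), "to_baseline_mean",
            DEPRIV)
        pd.testing.assert_series_equal(direct, via_day1, rtol=1e-12)


class TestRelativeToDendriteMean:
    @pytest.mark.parametrize("values,expected", [
        ([1, 1, 1], [1, 1, 1]),
        ([2, 4], [2 / 3, 4 / 3]),
        ([5], [1.0]),
    ])
    def test_examples(self, values, expected):
        assert q.relative_to_dendrite_mean(values) == pytest.approx(expected)

    def test_output_mean_is_one(self):
        rng = np.random.default_rng(1)
        out = q.relative_to_dendrite_mean(rng.lognormal(0, 0.5, 20))
        assert out.mean() == pytest.approx(1.0)

    def test_no_valid_spines_raises(self):
        with pytest.raises(ValueError):
            q.relative_to_dendrite_mean([np.nan, np.nan])


class TestDailyChange:
    def _series(self, values):
        return pd.Series(values, index=list(BASE10.sessions)[:len(values)])

    def test_hand_example(self):
        out = q.daily_change(self._series([1.0, 2.0, 1.0]), BASE10)
        assert out["D2"] == pytest.approx(2.0)
        assert out["D3"] == pytest.approx(0.5)

    def test_constant_trace_all_ones(self):
        out = q.daily_change(self._series([3.0] * 10), BASE10)
        assert np.allclose(out.dropna(), 1.0)

    def test_gap_emits_no_transition(self):
        out = q.daily_change(self._series([1.0, np.nan, 3.0]), BASE10)
        assert out.dropna().empty

    def test_non_consecutive_days_omitted(self):
        tr = pd.Series(1.0, index=list(DEPRIV.sessions))
        out = q.daily_change(tr, DEPRIV)
        # VD3 -> VD7 spans four days and must not produce a transition
        assert np.isnan(out["VD7"])
        assert out.dropna().shape[0] == 6 - 1  # BL1..VD3 daily transitions


class TestDendriteSummary:
    @pytest.mark.parametrize("values,expected", [
        ([2.0, 0.5], 1.0),
        ([1.0, 4.0], 2.0),
        ([3.0], 3.0),
    ])
    def test_geometric_mean_examples(self, values, expected):
        df = pd.DataFrame({
            "dendrite_id": "d0", "session": "D1", "sglua1": values,
        })
        out = q.dendrite_summary(df)
        assert out["value"].iloc[0] == pytest.approx(expected)

    def test_consistency_with_relative_values(self):
        """gmean of relative-to-dendrite-mean values equals gmean of raw
        values divided by the arithmetic mean."""
        from scipy.stats import gmean
        rng = np.random.default_rng(2)
        vals = rng.lognormal(0, 0.4, 15)
        rel = q.relative_to_dendrite_mean(vals)
        assert gmean(rel) == pytest.approx(gmean(vals) / vals.mean())


class TestExtractRoi:
    def test_uniform_image_returns_value(self):
        stack = np.full((4, 2, 16, 16), 7.0)
        m = np.zeros((4, 16, 16), dtype=bool)
        m[1, 2:5, 2:5] = True
        m2 = np.zeros_like(m)
        m2[2, 8:12, 8:12] = True
        masks = q.RoiMaskSet(shape=(4, 16, 16), masks={"a": m, "b": m2})
        out = q.extract_roi_intensities(stack, masks)
        assert out["a"]["green"] == out["b"]["green"] == 7.0
        assert out["a"]["red"] == 7.0

    def test_empty_mask_raises(self):
        stack = np.zeros((2, 2, 8, 8))
        masks = q.RoiMaskSet(shape=(2, 8, 8),
                             masks={"empty": np.zeros((2, 8, 8), bool)})
        with pytest.raises(ValueError, match="empty"):
            q.extract_roi_intensities(stack, masks)

    def test_shape_mismatch_raises(self):
        stack = np.zeros((2, 2, 8, 8))
        masks = q.RoiMaskSet(shape=(2, 9, 8),
                             masks={"m": np.ones((2, 9, 8), bool)})
        with pytest.raises(ValueError, match="shape"):
            q.extract_roi_intensities(stack, masks)
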