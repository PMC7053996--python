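"""Deprivation analyses: classification, ratios, coordinates, extremes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinedyn import get_schedule
from spinedyn import deprivation as depr
from spinedyn import dynamics as dyn
from spinedyn import quantify as q

DEPRIV = get_schedule("deprivation")


def vd_summaries(ds, derived, compartment=None):
    ratios, fates, pers = derived
    norm = q.normalize_traces(ratios, "to_baseline_mean", ds.schedule)
    norm = norm.loc[norm["spine_id"].isin(pers)]
    summaries = q.dendrite_summary(norm, "sglua1")
    if compartment is not None:
        comp = ds.dendrites.set_index("dendrite_id")["compartment"]
        summaries = summaries.loc[
            summaries["dendrite_id"].map(comp) == compartment]
    return norm, summaries


class TestShamThreshold:
    def test_hand_example(self):
        # changes of -10%, 0%, +10% -> SD 0.1
        assert depr.sham_threshold([0.9, 1.0, 1.1]) == pytest.approx(0.1)

    def test_degenerate_all_equal(self):
        assert depr.sham_threshold([1.0, 1.0, 1.0]) == 0.0

    def test_too_few_units_raises(self):
        with pytest.raises(ValueError):
            depr.sham_threshold([1.0, 1.1])

    def test_printed_constants_available(self):
        assert depr.PAPER_THRESHOLDS == {
            "dendrite": 0.18, "spine": 0.435, "cell": 0.098}


class TestClassifyResponse:
    def test_rule_examples(self):
        vals = pd.Series({"a": 0.80, "b": 0.90, "c": 0.82})
        cls = {c.unit_id: c.label
               for c in depr.classify_response(vals, 0.18)}
        assert cls == {"a": "decrease", "b": "no_decrease", "c": "decrease"}

    def test_missing_vd1_excluded(self):
        vals = pd.Series({"a": 0.5, "b": np.nan})
        cls = depr.classify_response(vals, 0.18)
        assert [c.unit_id for c in cls] == ["a"]

    def test_bad_threshold_raises(self):
        with pytest.raises(ValueError):
            depr.classify_response(pd.Series({"a": 1.0}), 0.0)

    def test_summary_percentage(self):
        vals = pd.Series({f"d{i}": (0.8 if i < 25 else 1.0)
                          for i in range(49)})
        out = depr.classification_summary(depr.classify_response(vals, 0.18))
        assert out["n_decrease"] == 25 and out["n_total"] == 49
        assert out["percent_decrease"] == pytest.approx(51.02, abs=0.01)


class TestDayCorrelation:
    def test_identical_changes(self):
        r, p, n = depr.day1_day7_correlation([0.8, 1.0, 1.2], [0.8, 1.0, 1.2])
        assert r == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(5)
        n = 400
        r, _, _ = depr.day1_day7_correlation(rng.normal(1, 0.1, n),
                                             rng.normal(1, 0.1, n))
        assert abs(r) < 2 / np.sqrt(n)

    def test_shared_subpopulation_induces_positive_r(self, l23_vd_ds,
                                                     l23_vd_derived):
        ds = l23_vd_ds
        _, summaries = vd_summaries(ds, l23_vd_derived, "apical")
        piv = summaries.pivot(index="dendrite_id", columns="session",
                              values="value")
        r, p, n = depr.day1_day7_correlation(piv["VD1"], piv["VD7"])
        assert r > 0


class TestBasalApicalRatio:
    def _frame(self, pairs):
        rows = []
        dend = []
        for i, (ap, ba) in enumerate(pairs):
            for comp, v in (("apical", ap), ("basal", ba)):
                did = f"n{i}_{comp}"
                rows.append(dict(dendrite_id=did, session="VD7", value=v))
                dend.append(dict(dendrite_id=did, neuron_id=f"n{i}",
                                 compartment=comp))
        return pd.DataFrame(rows), pd.DataFrame(dend)

    def test_hand_examples(self):
        s, d = self._frame([(1.0, 1.2), (1.1, 1.1)])
        out = depr.basal_apical_ratio(s, d, "VD7")
        assert out["ratio"].tolist() == pytest.approx([1.2, 1.0])

    def test_small_apical_change_excluded(self):
        s, d = self._frame([(0.01, 1.2), (1.0, 1.5)])
        out = depr.basal_apical_ratio(s, d, "VD7")
        assert out["neuron_id"].tolist() == ["n1"]

    def test_generator_basal_exceeds_apical(self, l23_vd_ds, l23_vd_derived):
        ds = l23_vd_ds
        _, summaries = vd_summaries(ds, l23_vd_derived)
        out = depr.basal_apical_ratio(summaries, ds.dendrites, "VD7")
        assert len(out) >= 10
        assert out["ratio"].mean() > 1.0


class TestRelativeCoordinates:
    def test_depth_examples(self):
        assert depr.relative_depth_on_dendrite([100, 110, 120]) == \
            pytest.approx([0, 0.5, 1])
        assert depr.relative_depth_on_dendrite([100, 120]) == \
            pytest.approx([0, 1])

    def test_distance_examples(self):
        assert depr.relative_distance_on_dendrite([10, 30, 50]) == \
            pytest.approx([0, 0.5, 1])

    def test_equal_coordinates_raise(self):
        with pytest.raises(ValueError):
            depr.relative_depth_on_dendrite([50.0, 50.0])

    @given(a=st.floats(0.1, 10), b=st.floats(-100, 100))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_affine_invariance(self, a, b):
        z = np.array([30.0, 47.0, 55.0, 90.0])
        out1 = depr.relative_depth_on_dendrite(z)
        out2 = depr.relative_depth_on_dendrite(a * z + b)
        assert out2 == pytest.approx(out1, abs=1e-9)


class TestDendriteOrientation:
    def test_toward_pia_is_ascending(self):
        # distal end 10 um shallower over a 50 um segment: ratio 0.2
        assert depr.dendrite_orientation((0, 0, 100), (49, 0, 90)) == "ascending"

    def test_away_from_pia_is_descending(self):
        assert depr.dendrite_orientation((0, 0, 100), (49, 0, 110)) == \
            "descending"

    def test_shallow_slope_excluded(self):
        # 2 um of depth over ~50 um: ratio 0.04 <= 0.1
        assert depr.dendrite_orientation((0, 0, 100), (50, 0, 102)) == "excluded"

    def test_coincident_endpoints_raise(self):
        with pytest.raises(ValueError):
            depr.dendrite_orientation((1, 2, 3), (1, 2, 3))

    def test_z_flip_swaps_orientation(self):
        """Inverting the z axis turns ascending into descending (depth
        convention: z grows downward from the pia)."""
        p, d = (0, 0, 100), (49, 0, 90)
        assert depr.dendrite_orientation(p, d) == "ascending"
        p2, d2 = (0, 0, -100), (49, 0, -90)
        assert depr.dendrite_orientation(p2, d2) == "descending"

    def test_partition_on_generated_dendrites(self, l23_vd_ds):
        """Every dendrite is exactly one of ascending/descending/excluded."""
        counts = {"ascending": 0, "descending": 0, "excluded": 0}
        for _, row in l23_vd_ds.dendrites.iterrows():
            o = depr.dendrite_orientation(
                (row.prox_x_um, row.prox_y_um, row.prox_z_um),
                (row.dist_x_um, row.dist_y_um, row.dist_z_um))
            counts[o] += 1
        assert sum(counts.values()) == len(l23_vd_ds.dendrites)
        assert counts["ascending"] > 0 and counts["descending"] > 0


class TestDendriteDepth:
    def test_relative_depth_among_dendrites(self):
        out = depr.dendrite_depth({
            "a": np.array([90.0, 110.0]),   # mean 100
            "b": np.array([150.0]),
            "c": np.array([200.0]),
        })
        by_id = out.set_index("dendrite_id")
        assert by_id.loc["a", "depth_um"] == pytest.approx(100)
        assert by_id["relative_depth"].tolist() == pytest.approx([0, 0.5, 1])

    def test_single_dendrite_undefined(self):
        out = depr.dendrite_depth({"a": np.array([100.0])})
        assert np.isnan(out["relative_depth"].iloc[0])


class TestCoordinateCorrelation:
    def test_value_equals_coordinate(self):
        r, p, n = depr.coordinate_correlation([0, 0.5, 1], [0, 0.5, 1])
        assert r == pytest.approx(1.0)

    def test_sham_change_vs_depth_null(self, l23_sham_ds):
        """No depth effect is simulated for sham, so change at VD7 is
        uncorrelated with relative depth."""
        ds = l23_sham_ds
        ratios = q.ratio_table(ds.spines)
        fates = dyn.classify_fates(ds.spines, ds.schedule)
        pers = set(fates.loc[fates["fate"] == "persistent", "spine_id"])
        norm = q.normalize_traces(ratios, "to_baseline_mean", ds.schedule)
        norm = norm.loc[norm["spine_id"].isin(pers) &
                        (norm["session"] == "VD7")]
        norm = q.add_relative_to_dendrite_mean(norm, "sglua1")
        vals, coords = [], []
        geo = ds.spines.drop_duplicates("spine_id").set_index("spine_id")
        for _, sub in norm.groupby("dendrite_id"):
            z = geo.loc[sub["spine_id"], "z_um"].to_numpy()
            if len(sub) < 2 or z.max() == z.min():
                continue
            vals.extend(sub["sglua1_rel"])
            coords.extend(depr.relative_depth_on_dendrite(z))
        r, p, n = depr.coordinate_correlation(vals, coords)
        assert abs(r) < 0.1 and p > 0.05


class TestDepthExtremes:
    def test_group_size_rounding(self):
        changes = pd.Series(np.ones(20))
        z = pd.Series(np.arange(20.0))
        # round(0.15 * 20) = 3 spines per group
        deep, sup = depr.depth_extremes_change(changes, z, 0.15)
        assert deep == sup == 1.0

    def test_uniform_change_equal_groups(self):
        changes = pd.Series([1.2] * 10)
        z = pd.Series(np.arange(10.0))
        deep, sup = depr.depth_extremes_change(changes, z)
        assert deep == pytest.approx(sup)

    def test_gradient_detected(self):
        z = pd.Series(np.arange(20.0))
        changes = pd.Series(1.0 + 0.01 * z)
        deep, sup = depr.depth_extremes_change(changes, z, 0.15)
        assert deep > sup

    def test_too_few_spines_raises(self):
        with pytest.raises(ValueError):
            depr.depth_extremes_change(pd.Series([1.0] * 3),
                                       pd.Series([1.0, 2.0, 3.0]), 0.15)


class TestTimecourse:
    def test_sham_flat_and_nonsignificant(self, l23_sham_ds):
        ds = l23_sham_ds
        ratios = q.ratio_table(ds.spines)
        fates = dyn.classify_fates(ds.spines, ds.schedule)
        pers = set(fates.loc[fates["fate"] == "persistent", "spine_id"])
        norm = q.normalize_traces(ratios, "to_baseline_mean", ds.schedule)
        summaries = q.dendrite_summary(
            norm.loc[norm["spine_id"].isin(pers)], "sglua1")
        table, res = depr.timecourse(summaries, ds.schedule)
        assert not res.significant
        assert np.allclose(table["mean"], 1.0, atol=0.1)

    def test_vd_apical_up_at_vd7(self, l23_vd_ds, l23_vd_derived):
        ds = l23_vd_ds
        _, summaries = vd_summaries(ds, l23_vd_derived, "apical")
        table, res = depr.timecourse(summaries, ds.schedule)
        assert table.set_index("session").loc["VD7", "mean"] > 1.0
        assert res.significant

    def test_grip1ko_dips_then_recovers(self):
        """GRIP1-KO timecourse: depressed at VD1, back near baseline by
        VD7, with no late potentiation."""
        from spinedyn import generate_dataset, preset
        ds = generate_dataset(preset("GRIP1KO_VD", seed=16, n_neurons=10,
                                     dendrites_per_neuron=3))
        ratios = q.ratio_table(ds.spines)
        fates = dyn.classify_fates(ds.spines, ds.schedule)
        pers = set(fates.loc[fates["fate"] == "persistent", "spine_id"])
        norm = q.normalize_traces(ratios, "to_baseline_mean", ds.schedule)
        summaries = q.dendrite_summary(
            norm.loc[norm["spine_id"].isin(pers)], "sglua1")
        table, _ = depr.timecourse(summaries, ds.schedule)
        by = table.set_index("session")["mean"]
        assert by["VD1"] < 0.95
        assert by["VD7"] == pytest.approx(1.0, abs=0.07)

    def test_incomplete_dendrite_excluded(self, l23_vd_ds, l23_vd_derived):
        ds = l23_vd_ds
        _, summaries = vd_summaries(ds, l23_vd_derived, "apical")
        drop_one = summaries.iloc[1:]  # remove one dendrite-session row
        table_full, _ = depr.timecourse(summaries, ds.schedule)
        table_drop, _ = depr.timecourse(drop_one, ds.schedule)
        assert table_drop["n"].iloc[0] == table_full["n"].iloc[0] - 1


class TestShamSelfThreshold:
    def test_sham_decrease_rate_near_one_sided_tail(self, l23_sham_ds):
        """With the threshold set to the sham group's own SD, about one
        Gaussian tail (~16%) of sham dendrites classify as decrease."""
        ds = l23_sham_ds
        ratios = q.ratio_table(ds.spines)
        fates = dyn.classify_fates(ds.spines, ds.schedule)
        pers = set(fates.loc[fates["fate"] == "persistent", "spine_id"])
        norm = q.normalize_traces(ratios, "to_baseline_mean", ds.schedule)
        summaries = q.dendrite_summary(
            norm.loc[norm["spine_id"].isin(pers)], "sglua1")
        vd1 = summaries.loc[summaries["session"] == "VD1"].set_index(
            "dendrite_id")["value"]
        thr = depr.sham_threshold(vd1)
        out = depr.classification_summary(depr.classify_response(vd1, thr))
        assert 2 <= out["percent_decrease"] <= 35
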