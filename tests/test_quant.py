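"""Fluorescence quantification, fold changes, dynamics, percentile groups."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from spinedyn.io_core import (
    TIMEPOINTS,
    DendriteCenterline,
    GeometryError,
    RoiPolygon,
    SessionStack,
)
from spinedyn.quant import (
    classify_change,
    classify_dynamics,
    dendrite_reference,
    derive_threshold,
    distribution_shift,
    dynamics_proportions,
    geometric_mean,
    geometric_mean_summary,
    late_mean_folds,
    maintained_increase,
    normalize_and_fold,
    percentile_groups,
    spine_signal,
)
from spinedyn.synthetic import flat_model, sample_fold_changes


def _stack(red, green=None):
    red = np.asarray(red, float)
    green = red.copy() if green is None else np.asarray(green, float)
    return SessionStack(mouse_id="m", hemisphere="CH", genotype="WT",
                        timepoint="T0", red=red, green=green)


def _fold_df(folds_by_track, **meta):
    rows = []
    for key, series in folds_by_track.items():
        for tp, v in series.items():
            rows.append({"track_key": key, "dendrite": meta.get("dendrite", "d1"),
                         "mouse": meta.get("mouse", "m1"),
                         "group": meta.get("group", "WT-CH"),
                         "timepoint": tp, "fold_glua2": v})
    return pd.DataFrame(rows)


class TestSpineSignal:
    def test_top_three_section_sum(self):
        red = np.zeros((5, 8, 8))
        for z, v in enumerate([0, 10, 50, 40, 5]):
            red[z, 2:4, 2:4] = v / 4.0  # 4-pixel blob
        roi = RoiPolygon.from_bbox(2, 2, 4, 4, z_range=(0, 4))
        assert spine_signal(_stack(red), roi, "red") == pytest.approx(100.0)

    def test_all_zero_stack_gives_zero(self):
        roi = RoiPolygon.from_bbox(1, 1, 3, 3, z_range=(0, 2))
        assert spine_signal(_stack(np.zeros((4, 6, 6))), roi, "red") == 0.0

    def test_matches_exhaustive_pixel_loop(self):
        """Randomized ROIs agree exactly with an independent per-pixel,
        per-section summation using a different point-in-polygon test."""
        from matplotlib.path import Path as MplPath

        rng = np.random.default_rng(123)
        arr = rng.integers(0, 1000, size=(10, 24, 24)).astype(float)
        stack = _stack(arr)
        for _ in range(50):
            x0, y0 = rng.integers(0, 18, 2)
            w, h = rng.integers(2, 6, 2)
            roi = RoiPolygon.from_bbox(int(x0), int(y0), int(x0 + w),
                                       int(y0 + h), z_range=(0, 9))
            got = spine_signal(stack, roi, "red")
            path = MplPath([(v[0], v[1]) for v in roi.vertices])
            sums = []
            for z in range(10):
                s = 0.0
                for r in range(24):
                    for c in range(24):
                        if path.contains_point((c + 0.5, r + 0.5)):
                            s += arr[z, r, c]
                sums.append(s)
            expected = sum(sorted(sums)[-3:])
            assert got == expected

    def test_roi_off_volume_is_geometry_error(self):
        roi = RoiPolygon.from_bbox(20, 20, 25, 25, z_range=(0, 2))
        with pytest.raises(GeometryError):
            spine_signal(_stack(np.zeros((4, 8, 8))), roi, "red")

    def test_too_few_sections_rejected(self):
        roi = RoiPolygon.from_bbox(0, 0, 3, 3, z_range=(0, 1))
        with pytest.raises(ValueError):
            spine_signal(_stack(np.zeros((2, 8, 8))), roi, "red")


class TestDendriteReference:
    def _uniform_shaft(self, value=80.0):
        """Straight shaft along x with constant intensity in a thick slab."""
        red = np.zeros((5, 32, 80))
        red[:, 14:18, :] = value
        pts = np.array([[2.0, 2.0, x] for x in np.linspace(0.5, 9.5, 20)])
        cl = DendriteCenterline(pts)   # y = 2 um = row 16
        return _stack(red), cl

    def test_uniform_dendrite_recovers_its_value(self):
        stack, cl = self._uniform_shaft(80.0)
        roi = RoiPolygon.from_bbox(38, 20, 42, 24, z_range=(0, 4))
        ref = dendrite_reference(stack, cl, roi, arc_position=4.5)
        assert ref == pytest.approx(80.0, rel=0.05)

    def test_reference_is_mean_of_two_box_values(self):
        stack, cl = self._uniform_shaft(40.0)
        # make one side brighter: boxes at +-1.5 um from arc 4.5
        stack.red[:, 14:18, :44] = 60.0
        roi = RoiPolygon.from_bbox(38, 20, 42, 24, z_range=(0, 4))
        ref = dendrite_reference(stack, cl, roi, arc_position=4.5)
        assert ref == pytest.approx((60.0 + 40.0) / 2)

    def test_unplaceable_boxes_flag_the_spine(self):
        stack, cl = self._uniform_shaft()
        roi = RoiPolygon.from_bbox(38, 20, 42, 24, z_range=(0, 4))
        excl = np.ones(stack.shape[1:], dtype=bool)  # everything excluded
        assert dendrite_reference(stack, cl, roi, arc_position=4.5,
                                  exclusion_mask=excl) is None


class TestNormalizeAndFold:
    def _records(self, greens, reds=None, refs=None):
        reds = reds or [100.0] * 6
        refs = refs or [50.0] * 6
        return pd.DataFrame([
            {"track_key": "d1/t0", "dendrite": "d1", "mouse": "m1",
             "group": "WT-CH", "timepoint": tp, "raw_green": g,
             "raw_red": r, "dendrite_reference": f}
            for tp, g, r, f in zip(TIMEPOINTS, greens, reds, refs)])

    def test_constant_signals_give_unit_folds(self):
        out = normalize_and_fold(self._records([200.0] * 6))
        assert np.allclose(out["fold_glua2"], 1.0)
        assert np.allclose(out["fold_size"], 1.0)

    def test_doubling_green_doubles_the_fold(self):
        greens = [200.0, 200, 400, 200, 200, 200]
        out = normalize_and_fold(self._records(greens))
        assert out[out.timepoint == "18h"]["fold_glua2"].iloc[0] == 2.0

    def test_reference_changes_cancel(self):
        # gain doubling scales raw sums and reference alike
        greens = [200.0, 400, 200, 200, 200, 200]
        reds = [100.0, 200, 100, 100, 100, 100]
        refs = [50.0, 100, 50, 50, 50, 50]
        out = normalize_and_fold(self._records(greens, reds, refs))
        assert np.allclose(out["fold_glua2"], 1.0)

    def test_zero_baseline_excludes_spine(self):
        recs = self._records([0.0] + [100.0] * 5)
        assert len(normalize_and_fold(recs)) == 0

    def test_floor_applied_to_collapsed_folds(self):
        greens = [200.0, 1e-9, 200, 200, 200, 200]
        out = normalize_and_fold(self._records(greens))
        assert out[out.timepoint == "2h"]["fold_glua2"].iloc[0] == 1e-3

    def test_programmed_trend_recovered_from_noiseless_render(
            self, noiseless_trend_cohort):
        """On a noiseless cohort the measured per-spine fold changes equal
        the programmed receptor trend within rendering tolerance."""
        from spinedyn.pipeline import detect_and_track, quantify_tracks
        from spinedyn.io_core import resolve_config
        cohort, model = noiseless_trend_cohort
        config = resolve_config({"bleedthrough_fraction": 0.0})
        tracked = detect_and_track(cohort, 0.0, config)
        folds = quantify_tracks(cohort, tracked, config)
        g = dict(zip(TIMEPOINTS, model.glua2_trend["WT-CH"]))
        assert folds.track_key.nunique() >= 6
        for row in folds.itertuples(index=False):
            assert row.fold_glua2 == pytest.approx(g[row.timepoint], rel=0.05)


class TestGeometricMean:
    def test_symmetry_on_log_scale(self):
        assert geometric_mean([0.5, 2.0]) == pytest.approx(1.0)
        assert geometric_mean([1.0, 1.0, 1.0]) == 1.0

    def test_lognormal_closed_form(self):
        rng = np.random.default_rng(4)
        x = np.exp(rng.normal(0.1, 0.5, size=1000))
        gm = geometric_mean(x)
        # 99% CI of the mean log
        half = 2.576 * 0.5 / math.sqrt(1000)
        assert math.exp(0.1 - half) <= gm <= math.exp(0.1 + half)

    def test_hierarchical_summary_weights_levels_equally(self):
        df = _fold_df({"a": {"T0": 1.0}, "b": {"T0": 1.0}}, dendrite="d1")
        df2 = _fold_df({"c": {"T0": 4.0}}, dendrite="d2")
        both = pd.concat([df, df2], ignore_index=True)
        out = geometric_mean_summary(both, "fold_glua2")
        # dendrite means 1 and 4 -> mouse gmean 2 (not pooled-spine gmean)
        assert out["mouse"]["value"].iloc[0] == pytest.approx(2.0)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            geometric_mean_summary(_fold_df({}), "fold_glua2")


class TestThreshold:
    def test_two_sd_rule_arithmetic(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 500)
        vals = (vals - vals.mean()) / vals.std(ddof=1) * 15.0
        assert derive_threshold(vals) == pytest.approx(30.0)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            derive_threshold(np.full(100, 7.0))
        with pytest.raises(ValueError):
            derive_threshold([1.0, 2.0])  # too few

    def test_generator_preset_matches_lognormal_closed_form(self):
        """2 SD of simulated trend-free 24-h changes lands within 5% of the
        closed-form value implied by the generator's day noise."""
        model = flat_model()
        folds = sample_fold_changes(model, 5000, np.random.default_rng(6))
        piv = folds.pivot(index="spine_id", columns="timepoint",
                          values="fold_glua2")
        pct = 100.0 * (piv["42h"] / piv["18h"] - 1.0)
        thr = derive_threshold(pct)
        assert thr == pytest.approx(2.0 * model.pct_change_sd(), rel=0.05)


class TestDynamicsClassification:
    @pytest.mark.parametrize("prev,curr,label", [
        (1.0, 1.4, "Up"),       # +40%
        (1.0, 1.0, "Same"),
        (1.0, 1.30, "Same"),    # exactly +30% -> Same (strict rule)
        (1.0, 0.70, "Same"),    # exactly -30% -> Same
        (1.0, 0.69, "Down"),
        (2.0, 1.2, "Down"),     # -40%
    ])
    def test_strict_threshold_rule(self, prev, curr, label):
        pct = 100.0 * (curr - prev) / prev
        assert classify_change(pct) == label

    def test_labels_from_fold_series(self):
        df = _fold_df({"t1": dict(zip(TIMEPOINTS, [1, 1.0, 1.4, 1.4, 0.9, 0.9]))})
        labels = classify_dynamics(df)
        got = labels.set_index("transition")["label"]
        assert got["18h"] == "Up" and got["42h"] == "Same"
        assert got["D6"] == "Down"

    def test_proportions_partition_and_sum_to_one(self):
        folds = {}
        for i, last in enumerate([1.4] * 2 + [1.0] * 5 + [0.6] * 3):
            folds[f"t{i}"] = {"T0": 1.0, "2h": last}
        labels = classify_dynamics(_fold_df(folds))
        props = dynamics_proportions(labels)
        row = props.iloc[0]
        assert (row.frac_up, row.frac_same, row.frac_down) == (0.2, 0.5, 0.3)
        assert row.frac_up + row.frac_same + row.frac_down == pytest.approx(1.0, abs=1e-12)

    def test_tail_fractions_match_analytic_probabilities(self):
        """Trend-free generator: expected Up and Down fractions equal the
        log-normal tail probabilities beyond +/-30%."""
        model = flat_model()
        folds = sample_fold_changes(model, 10_000, np.random.default_rng(9))
        folds["track_key"] = folds.pop("spine_id")
        folds["dendrite"] = "d1"
        labels = classify_dynamics(folds)
        labels = labels[labels.transition == "18h"]
        p_up, p_down = model.up_down_tail_probs(30.0)
        n = len(labels)
        for p_true, lab in ((p_up, "Up"), (p_down, "Down")):
            got = (labels["label"] == lab).mean()
            half = 3.0 * math.sqrt(p_true * (1 - p_true) / n)
            assert abs(got - p_true) <= half


class TestMaintainedIncrease:
    def test_fraction_arithmetic(self):
        folds, n_up = {}, 5
        d10 = [1.5, 1.4, 1.2, 1.0, 0.9]  # 2 of 5 still above 1.3
        for i in range(n_up):
            folds[f"u{i}"] = dict(zip(TIMEPOINTS, [1, 1.0, 1.5, 1.4, 1.3, d10[i]]))
        df = _fold_df(folds)
        labels = classify_dynamics(df)
        out = maintained_increase(labels, df)
        assert out["maintained_fraction"].iloc[0] == pytest.approx(0.4)

    def test_no_up_spines_flagged(self):
        df = _fold_df({"t1": dict(zip(TIMEPOINTS, [1.0] * 6))})
        labels = classify_dynamics(df)
        out = maintained_increase(labels, df)
        assert out["flagged"].iloc[0] and np.isnan(
            out["maintained_fraction"].iloc[0])

    def test_memoryless_generator_matches_conditional_probability(self):
        """Day noise is independent across sessions, so among spines Up at
        18 h the D10 maintenance probability is just P(fold_D10 > 1.3)."""
        model = flat_model()
        folds = sample_fold_changes(model, 20_000, np.random.default_rng(10))
        folds["track_key"] = folds.pop("spine_id")
        folds["dendrite"] = "d1"
        labels = classify_dynamics(folds)
        out = maintained_increase(labels, folds)
        n_up = int(out["n_up"].iloc[0])
        got = out["maintained_fraction"].iloc[0]
        s = model.pct_change_log_sd()
        p_true = float(norm.sf(math.log(1.3) / s))
        half = 3.0 * math.sqrt(p_true * (1 - p_true) / n_up)
        assert abs(got - p_true) <= half


class TestPercentileGroups:
    def _baseline(self, values, dendrite="d1"):
        return pd.DataFrame({"track_key": [f"t{i}" for i in range(len(values))],
                             "dendrite": dendrite, "norm_green": values})

    def test_eight_distinct_values_split_two_per_group(self):
        out = percentile_groups(self._baseline([3, 1, 4, 1.5, 9, 2.6, 5, 7]))
        counts = out["percentile_group"].value_counts()
        assert all(counts[g] == 2 for g in (1, 2, 3, 4))

    def test_all_equal_values_land_in_group_two(self):
        out = percentile_groups(self._baseline([5.0] * 8))
        assert np.all(out["percentile_rank"] == 50.0)
        assert np.all(out["percentile_group"] == 2)

    def test_small_dendrite_excluded(self):
        out = percentile_groups(self._baseline([1.0, 2.0, 3.0]))
        assert len(out) == 0

    def test_matches_sort_and_slice_enumeration(self):
        """Group assignment equals an independent sort-based computation."""
        rng = np.random.default_rng(14)
        values = rng.uniform(0, 10, size=1000)
        out = percentile_groups(self._baseline(values))
        order = np.argsort(values, kind="stable")
        expected = np.empty(len(values), dtype=int)
        for pos, idx in enumerate(order):
            pct = 100.0 * (pos + 1 - 0.5) / len(values)
            expected[idx] = min(4, math.ceil(pct / 25.0))
        got = out.set_index("track_key")["percentile_group"]
        for i in range(len(values)):
            assert got[f"t{i}"] == expected[i]


class TestDistributionShift:
    def test_identical_samples_have_zero_statistic(self):
        x = np.arange(20.0)
        stat, p = distribution_shift(x, x)
        assert stat == 0.0

    def test_disjoint_supports_have_unit_statistic(self):
        stat, _ = distribution_shift(np.arange(10.0), np.arange(100.0, 110))
        assert stat == 1.0

    def test_statistic_equals_max_ecdf_gap(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(0, 1, 200), rng.normal(0.3, 1.2, 200)
        stat, _ = distribution_shift(a, b)
        grid = np.concatenate([a, b])
        gaps = [abs((a <= v).mean() - (b <= v).mean()) for v in grid]
        assert stat == pytest.approx(max(gaps), abs=1e-12)

    def test_small_group_warns_and_uses_exact_p(self):
        with pytest.warns(UserWarning):
            distribution_shift([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])

    def test_late_mean_requires_both_sessions(self):
        df = _fold_df({"a": {"D6": 1.2, "D10": 1.4}, "b": {"D6": 2.0}})
        out = late_mean_folds(df)
        assert list(out["track_key"]) == ["a"]
        assert out["late_mean_fold"].iloc[0] == pytest.approx(1.3)
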