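"""Spine detection, matching, fate rules and turnover statistics."""

import itertools

import numpy as np
import pytest

from spinedyn.io_core import TIMEPOINTS, GeometryError, RoiPolygon
from spinedyn.morphology import (
    SpineDetection,
    SpineTrack,
    assign_arcs,
    classify_fates,
    detect_spines,
    match_spines,
    new_spine_persistence,
    tracks_from_census,
    turnover_rates,
    turnover_table,
)
from spinedyn.synthetic import (
    CohortSpec,
    default_model,
    render_protrusion_calibration,
    simulate_cohort,
)


def _det(tp, arc):
    roi = RoiPolygon.from_bbox(0, 0, 2, 2, z_range=(0, 1))
    return SpineDetection(timepoint=tp, arc_position=float(arc),
                          perpendicular_extent=1.0, roi=roi, peak_section=0)


def _track(presence: str) -> SpineTrack:
    """presence like '110011' over the six timepoints."""
    tr = SpineTrack(track_id=0)
    for tp, flag in zip(TIMEPOINTS, presence):
        tr.present[tp] = flag == "1"
    return tr


class TestDetectionCriterion:
    def test_only_supracriterion_protrusion_detected(self, calibration):
        stack, centerline = calibration
        dets = detect_spines(stack, centerline)
        assert len(dets) == 1
        assert dets[0].perpendicular_extent == pytest.approx(0.625)
        assert dets[0].arc_position == pytest.approx(10.0, abs=0.3)

    def test_decision_is_monotone_in_protrusion_length(self):
        # pixel-multiple lengths: the raster can only realise 0.125 um steps
        lengths = [0.25, 0.375, 0.5, 0.625, 0.75, 1.0, 1.5]
        stack, cl = render_protrusion_calibration(lengths)
        dets = detect_spines(stack, cl)
        accepted_arcs = sorted(d.arc_position for d in dets)
        expected = [5.0 + 5.0 * i for i, L in enumerate(lengths) if L > 0.5]
        assert np.allclose(accepted_arcs, expected, atol=0.3)

    def test_dendrite_only_stack_has_no_detections(self):
        stack, cl = render_protrusion_calibration([])
        assert detect_spines(stack, cl) == []

    def test_centerline_outside_volume_is_geometry_error(self, calibration):
        stack, _ = calibration
        from spinedyn.io_core import DendriteCenterline
        bad = DendriteCenterline(np.array([[0, 0, 0.0], [0, 0, 500.0]]))
        with pytest.raises(GeometryError):
            detect_spines(stack, bad)

    def test_recall_and_precision_on_noisy_render(self, rendered_dendrite):
        cohort = rendered_dendrite
        dend = cohort.dendrites()[0]
        from spinedyn.preprocess import correct_stack
        stack, _ = correct_stack(cohort.stacks[(dend, "T0")], 0.0)
        dets = detect_spines(stack, cohort.centerlines[dend])
        truth = np.sort(
            cohort.spines[cohort.spines.present_T0].arc_um.to_numpy())
        found = np.array(sorted(d.arc_position for d in dets))
        recall = np.mean([np.abs(found - t).min() <= 1.0 for t in truth])
        precision = np.mean([np.abs(truth - f).min() <= 1.0 for f in found])
        assert recall >= 0.9 and precision >= 0.9


class TestMatching:
    def test_identical_sessions_make_every_track_stable(self):
        dets = {tp: [_det(tp, a) for a in (3.0, 7.0, 11.0)]
                for tp in TIMEPOINTS}
        tracks = classify_fates(match_spines(dets))
        assert len(tracks) == 3
        for tr in tracks:
            assert all(tr.fate[tp] == "stable" for tp in TIMEPOINTS)

    def test_extra_detection_opens_a_new_track(self):
        dets = {"T0": [_det("T0", 3.0)], "2h": [_det("2h", 3.1),
                                                _det("2h", 8.0)]}
        tracks = classify_fates(match_spines(dets))
        fates = sorted(tr.fate["2h"] for tr in tracks)
        assert fates == ["new", "stable"]

    def test_duplicate_arc_positions_rejected(self):
        dets = {"T0": [_det("T0", 3.0), _det("T0", 3.0)],
                "2h": [_det("2h", 3.0)]}
        with pytest.raises(ValueError, match="duplicate"):
            match_spines(dets)

    def test_single_session_rejected(self):
        with pytest.raises(ValueError, match="2 sessions"):
            match_spines({"T0": [_det("T0", 1.0)]})

    def test_assignment_matches_exhaustive_enumeration(self):
        """Across random instances the assignment equals the pairing found
        by brute force (max matches, then min total distance)."""
        rng = np.random.default_rng(42)
        cap = 2.0
        for _ in range(100):
            n, m = rng.integers(1, 7), rng.integers(1, 7)
            prev = np.sort(rng.uniform(0, 12, n))
            curr = np.sort(rng.uniform(0, 12, m))
            got = assign_arcs(prev, curr, cap)
            best = None
            k = min(n, m)
            for size in range(k, -1, -1):
                for rows in itertools.combinations(range(n), size):
                    for cols in itertools.permutations(range(m), size):
                        d = [abs(prev[i] - curr[j])
                             for i, j in zip(rows, cols)]
                        if any(x > cap for x in d):
                            continue
                        tot = sum(d)
                        if best is None or tot < best[0] - 1e-12:
                            best = (tot, size)
                if best is not None:
                    break
            got_tot = sum(abs(prev[i] - curr[j]) for i, j in got)
            if best is None:
                assert got == []
            else:
                assert len(got) == best[1]
                assert got_tot == pytest.approx(best[0], abs=1e-9)

    def test_matching_symmetric_for_identical_inputs(self):
        arcs = np.array([1.0, 2.5, 9.0])
        pairs = assign_arcs(arcs, arcs)
        assert pairs == [(0, 0), (1, 1), (2, 2)]


class TestFateRules:
    def test_present_everywhere_is_stable_at_every_transition(self):
        tr = classify_fates([_track("111111")])[0]
        assert all(tr.fate[tp] == "stable" for tp in TIMEPOINTS)

    def test_disappearance_is_eliminated_at_first_absent_session(self):
        tr = classify_fates([_track("111000")])[0]
        assert tr.fate["18h"] == "stable"
        assert tr.fate["42h"] == "eliminated"
        assert tr.fate["D6"] == "absent"

    def test_late_appearance_is_new_then_stable(self):
        tr = classify_fates([_track("001111")])[0]
        assert tr.fate["T0"] == "absent"
        assert tr.fate["18h"] == "new"
        assert tr.fate["42h"] == "stable"
        assert tr.fate["D10"] == "stable"

    def test_census_conservation_identities(self):
        """n_stable + n_new = n_total(t); n_stable + n_eliminated =
        n_total(t-1), on a simulated census."""
        cohort = simulate_cohort(
            CohortSpec(n_mice_per_group=2, dendrites_per_mouse=3,
                       spines_per_dendrite=(12, 12), seed=21),
            default_model(), render=False)
        for tracks in tracks_from_census(cohort.spines).values():
            for k in range(1, len(TIMEPOINTS)):
                tp, prev = TIMEPOINTS[k], TIMEPOINTS[k - 1]
                n_t = sum(t.present[tp] for t in tracks)
                n_p = sum(t.present[prev] for t in tracks)
                stable = sum(t.fate[tp] == "stable" for t in tracks)
                new = sum(t.fate[tp] == "new" for t in tracks)
                elim = sum(t.fate[tp] == "eliminated" for t in tracks)
                assert stable + new == n_t
                assert stable + elim == n_p


class TestTurnover:
    def test_rate_arithmetic(self):
        tracks = [_track("111111") for _ in range(18)]
        tracks += [_track("011111"), _track("001111")]   # 2 appearing
        tracks += [_track("110000"), _track("111000")]   # 2 eliminations
        tracks = classify_fates(tracks)
        row = turnover_rates(tracks, "18h")
        assert row["n_total"] == 21
        assert row["formation_pct"] == pytest.approx(100 / 21)  # 1 new of 21
        assert row["elimination_pct"] == pytest.approx(100 / 21)  # 1 of 21
        row42 = turnover_rates(tracks, "42h")
        assert row42["n_formed"] == 0 and row42["n_eliminated"] == 1

    def test_no_turnover_gives_zero_rates(self):
        tracks = classify_fates([_track("111111") for _ in range(5)])
        for tp in TIMEPOINTS[1:]:
            row = turnover_rates(tracks, tp)
            assert row["formation_pct"] == 0.0
            assert row["elimination_pct"] == 0.0
            assert row["total_spines_pct_change"] == 0.0

    def test_empty_census_is_flagged(self):
        tracks = classify_fates([_track("000000")])
        row = turnover_rates(tracks, "2h")
        assert row["flagged"] and np.isnan(row["formation_pct"])

    def test_density_pulse_recovered_from_large_census(self):
        """The programmed contralateral density pulse at 18 h is recovered
        within 2 percentage points at 20,000 spines."""
        model = default_model()
        spec = CohortSpec(n_mice_per_group=5, groups=("WT-CH",),
                          dendrites_per_mouse=160,
                          spines_per_dendrite=(25, 25), seed=2)
        cohort = simulate_cohort(spec, model, render=False)
        assert cohort.spines.present_T0.sum() >= 19_000
        tbl = turnover_table(tracks_from_census(cohort.spines))
        got = tbl[(tbl.timepoint == "18h")
                  & ~tbl.flagged].total_spines_pct_change.mean()
        programmed = model.expected_density_change_pct("WT-CH", "18h")
        assert got == pytest.approx(programmed, abs=2.0)


class TestNewSpinePersistence:
    def test_fraction_arithmetic(self):
        tracks = [_track("011111"), _track("011000"), _track("001100"),
                  _track("001000")]
        tracks = classify_fates(tracks)
        assert new_spine_persistence(tracks) == pytest.approx(0.25)

    def test_no_new_spines_is_flagged_none(self):
        tracks = classify_fates([_track("111111")])
        assert new_spine_persistence(tracks) is None

    def test_binomial_oracle_at_half_survival(self):
        """With per-interval elimination (1 - 0.5^(1/3)) after 18 h, a new
        18 h spine survives to D10 with probability exactly 1/2."""
        from spinedyn.synthetic import TrajectoryModel
        eps = 1.0 - 0.5 ** (1.0 / 3.0)
        model = TrajectoryModel(
            density_multiplier={"WT-CH": (1.0, 1.0, 1.8, 1.8 * (1 - eps),
                                          1.8 * (1 - eps) ** 2,
                                          1.8 * (1 - eps) ** 3)},
            elimination_hazard={"WT-CH": (0.0, 0.0, eps, eps, eps)},
            sigma_day=0.0, sigma_size=0.0, sigma_gain=0.0,
            mouse_coupling_sd=0.0, shot_noise=False, read_noise_sd=0.0)
        spec = CohortSpec(n_mice_per_group=5, groups=("WT-CH",),
                          dendrites_per_mouse=25,
                          spines_per_dendrite=(20, 20), seed=8)
        cohort = simulate_cohort(spec, model, render=False)
        all_tracks = [t for tracks in
                      tracks_from_census(cohort.spines).values()
                      for t in tracks]
        new_tracks = [t for t in all_tracks
                      if t.fate.get("2h") == "new" or t.fate.get("18h") == "new"]
        n = len(new_tracks)
        assert n >= 1500
        frac = np.mean([t.present["D10"] for t in new_tracks])
        # binomial 99% CI around p = 0.5
        half_width = 2.576 * np.sqrt(0.25 / n)
        assert abs(frac - 0.5) <= half_width + 1e-9
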