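"""End-to-end orchestration: cohort -> corrected stacks -> tracks -> tables.

This is the glue the numbered analysis drivers and the acceptance script
run. Every scientific step lives in the dedicated modules; here we only
sequence them and keep the bookkeeping (track keys, per-dendrite ROI
exclusion masks, table assembly) in one place.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import behavior as beh
from . import morphology as morph
from . import preprocess as pre
from . import quant
from .io_core import TIMEPOINTS, RunConfig, SessionStack, resolve_config
from .synthetic import CohortData, render_control_stack

logger = logging.getLogger("spinedyn")


def estimate_cohort_bleedthrough(cohort: CohortData,
                                 config: RunConfig) -> float:
    """Bleed-through fraction: from config if supplied, otherwise estimated
    once from a rendered red-only control animal (mirrors measuring a
    single control mouse per cohort)."""
    if config.bleedthrough_fraction is not None:
        return config.bleedthrough_fraction
    control = render_control_stack(cohort.model, seed=cohort.spec.seed)
    return pre.estimate_bleedthrough(control)


def detect_and_track(cohort: CohortData, f: float,
                     config: RunConfig) -> dict[str, dict]:
    """Correct every stack, detect spines per session, build tracks.

    Returns per-dendrite dicts with corrected stacks, detections and
    fate-classified tracks.
    """
    out: dict[str, dict] = {}
    for dend in cohort.dendrites():
        if (dend, TIMEPOINTS[0]) not in cohort.stacks:
            continue
        centerline = cohort.centerlines[dend]
        corrected: dict[str, SessionStack] = {}
        detections: dict[str, list] = {}
        for tp in TIMEPOINTS:
            stack = cohort.stacks[(dend, tp)]
            cstack, _ = pre.correct_stack(stack, f)
            corrected[tp] = cstack
            detections[tp] = morph.detect_spines(cstack, centerline)
        tracks = morph.classify_fates(
            morph.match_spines(detections, cap_um=config.match_cap_um))
        out[dend] = {"centerline": centerline, "stacks": corrected,
                     "detections": detections, "tracks": tracks}
    return out


def quantify_tracks(cohort: CohortData, tracked: dict[str, dict],
                    config: RunConfig) -> pd.DataFrame:
    """Per-spine per-session raw sums + dendrite reference -> fold table.

    Only tracks present at every session ("persistent spines") enter the
    fold-change analyses; the turnover analyses use all tracks.
    """
    meta = (cohort.spines[["dendrite", "mouse", "genotype", "hemisphere",
                           "group"]].drop_duplicates("dendrite")
            .set_index("dendrite"))
    records = []
    for dend, parts in tracked.items():
        centerline = parts["centerline"]
        stacks = parts["stacks"]
        dmeta = meta.loc[dend]
        persistent = [tr for tr in parts["tracks"]
                      if all(tr.present.get(tp, False) for tp in TIMEPOINTS)]
        for tp in TIMEPOINTS:
            stack = stacks[tp]
            # exclusion mask: union of all spine ROI footprints this session
            excl = np.zeros(stack.shape[1:], dtype=bool)
            for det in parts["detections"][tp]:
                excl |= det.roi.footprint_mask(stack.shape[1:])
            for tr in persistent:
                det = tr.detections[tp]
                ref = quant.dendrite_reference(
                    stack, centerline, det.roi, det.arc_position,
                    exclusion_mask=excl)
                if ref is None or ref <= 0:
                    continue
                if config.shared_brightest_frames:
                    secs = quant.brightest_sections(stack, det.roi, "red")
                    raw_g = quant.spine_signal(stack, det.roi, "green",
                                               sections=secs)
                    raw_r = quant.spine_signal(stack, det.roi, "red",
                                               sections=secs)
                else:
                    raw_g = quant.spine_signal(stack, det.roi, "green")
                    raw_r = quant.spine_signal(stack, det.roi, "red")
                records.append({
                    "track_key": f"{dend}/t{tr.track_id:04d}",
                    "dendrite": dend,
                    "mouse": dmeta["mouse"], "genotype": dmeta["genotype"],
                    "hemisphere": dmeta["hemisphere"], "group": dmeta["group"],
                    "timepoint": tp, "raw_green": raw_g, "raw_red": raw_r,
                    "dendrite_reference": ref,
                })
    if not records:
        return pd.DataFrame()
    return quant.normalize_and_fold(pd.DataFrame(records),
                                    fold_floor=config.fold_floor)


def turnover_from_tracks(cohort: CohortData,
                         tracked: dict[str, dict]) -> pd.DataFrame:
    tbl = morph.turnover_table(
        {dend: parts["tracks"] for dend, parts in tracked.items()})
    meta = (cohort.spines[["dendrite", "mouse", "group"]]
            .drop_duplicates("dendrite"))
    return tbl.merge(meta, on="dendrite")


def turnover_from_census(cohort: CohortData) -> pd.DataFrame:
    """Turnover table straight from ground-truth presence (no imaging)."""
    tracks_by_dend = morph.tracks_from_census(cohort.spines)
    tbl = morph.turnover_table(tracks_by_dend)
    meta = (cohort.spines[["dendrite", "mouse", "group"]]
            .drop_duplicates("dendrite"))
    return tbl.merge(meta, on="dendrite")


def run_imaging_analysis(cohort: CohortData,
                         config: RunConfig | dict | None = None) -> dict:
    """Full voxel-level analysis of a rendered cohort.

    Returns a dict of result tables: folds, turnover, dynamics labels and
    proportions, percentile groups, late-session KS input, behaviour and
    correlation tables.
    """
    config = config if isinstance(config, RunConfig) else resolve_config(config)
    f = estimate_cohort_bleedthrough(cohort, config)
    tracked = detect_and_track(cohort, f, config)
    folds = quantify_tracks(cohort, tracked, config)
    results: dict = {"bleedthrough_fraction": f, "folds": folds,
                     "turnover": turnover_from_tracks(cohort, tracked)}
    if len(folds):
        labels = quant.classify_dynamics(folds, config.dynamics_threshold_pct)
        results["dynamics_labels"] = labels
        results["dynamics_proportions"] = quant.dynamics_proportions(
            labels, by=("group", "mouse", "dendrite"))
        baseline = folds[folds["timepoint"] == TIMEPOINTS[0]]
        results["percentile_groups"] = quant.percentile_groups(baseline)
        results["late_folds"] = quant.late_mean_folds(folds)
        results["maintained_increase"] = quant.maintained_increase(
            labels, folds, config.dynamics_threshold_pct)
    perf = beh.success_rate(cohort.behavior)
    results["performance"] = perf
    if len(folds):
        mouse_folds = quant.geometric_mean_summary(
            folds, "fold_glua2", levels=("dendrite", "mouse"))["mouse"]
        imaging = (mouse_folds.rename(columns={"value": "value"})
                   [["mouse", "timepoint", "value"]])
        perf_col = ("normalized_rate" if config.spearman_normalized_rate
                    else "success_rate")
        results["paired_regression"] = pd.concat([
            beh.paired_regression(
                imaging[imaging["mouse"].isin(
                    perf[perf["genotype"] == gt]["mouse"])],
                perf, perf_col="normalized_rate").assign(genotype=gt)
            for gt in sorted(perf["genotype"].unique())], ignore_index=True)
        results["spearman"] = pd.concat([
            beh.spearman_matrix(
                imaging[imaging["mouse"].isin(
                    perf[perf["genotype"] == gt]["mouse"])],
                perf, perf_col=perf_col).assign(genotype=gt)
            for gt in sorted(perf["genotype"].unique())], ignore_index=True)
    return results
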