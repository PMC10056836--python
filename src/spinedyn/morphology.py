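"""Spine detection, longitudinal matching, fate rules and turnover rates.

Detection criterion
-------------------
A protrusion counts as a spine only if it extends **more than 0.5 um
(four pixels at 0.125 um/px) perpendicular from the dendritic shaft**; the
boundary case of exactly 0.5 um is rejected (the criterion is strict).
Perpendicular extent is measured from the shaft surface (fixed shaft
radius, default 0.25 um) to the detection's peak-intensity voxel.

Fate rules, per the asymmetric bookkeeping used in longitudinal imaging:

* *stable* at t — present at t and at t-1;
* *eliminated* at t — present at t-1 but not at t (counted against the
  t-1 census);
* *new* at t — present at t, absent at baseline T0, first appearance
  (a detection re-appearing after an elimination starts a new track).

Formation and elimination rates are percentages of the total number of
spines at the imaging period: formation against n(t), elimination against
n(t-1); dendrite-level values are averaged per mouse downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter, label
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu

from .io_core import (
    TIMEPOINTS,
    TP_INDEX,
    DendriteCenterline,
    GeometryError,
    RoiPolygon,
    SessionStack,
)

logger = logging.getLogger("spinedyn")


@dataclass
class SpineDetection:
    """One accepted spine detection in one session."""

    timepoint: str
    arc_position: float           # um along the centerline
    perpendicular_extent: float   # um beyond the shaft surface
    roi: RoiPolygon
    peak_section: int
    peak_intensity: float = 0.0


@dataclass
class SpineTrack:
    """One spine's identity across the six-session schedule."""

    track_id: int
    detections: dict = field(default_factory=dict)   # timepoint -> SpineDetection
    present: dict = field(default_factory=dict)      # timepoint -> bool
    fate: dict = field(default_factory=dict)         # timepoint -> label

    def first_present(self) -> str | None:
        for tp in TIMEPOINTS:
            if self.present.get(tp, False):
                return tp
        return None

    def arc_at(self, tp: str) -> float | None:
        det = self.detections.get(tp)
        return None if det is None else det.arc_position


def _voxel_distance_map(stack: SessionStack, centerline: DendriteCenterline
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(distance um, nearest arc um) of every voxel to the centerline."""
    nz, ny, nx = stack.shape
    lat, ax = stack.lateral_um_per_px, stack.axial_um_per_section
    pts = centerline.points_um
    if (pts[:, 0].min() < 0 or pts[:, 0].max() > (nz - 1) * ax
            or pts[:, 1].min() < 0 or pts[:, 1].max() > (ny - 1) * lat
            or pts[:, 2].min() < 0 or pts[:, 2].max() > (nx - 1) * lat):
        raise GeometryError("centerline extends outside the volume")
    tree, arcs = centerline.kdtree(0.05)
    zz, yy, xx = np.meshgrid(np.arange(nz) * ax, np.arange(ny) * lat,
                             np.arange(nx) * lat, indexing="ij")
    coords = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    d, idx = tree.query(coords, workers=-1)
    return d.reshape(stack.shape), arcs[idx].reshape(stack.shape)


def detect_spines(stack: SessionStack, centerline: DendriteCenterline, *,
                  shaft_radius_um: float = 0.25,
                  shaft_mask_radius_um: float = 0.7,
                  tube_radius_um: float = 3.0,
                  min_extent_um: float = 0.5,
                  smooth_sigma_px: float = 1.0) -> list[SpineDetection]:
    """Detect spines on the corrected morphology channel.

    Pipeline: Otsu threshold restricted to a 3 um tube around the
    centerline; above-threshold voxels beyond the geometric shaft mask
    (``shaft_mask_radius_um``, wide enough to swallow the shaft's intensity
    shoulder) form connected components; components touching the masked
    shaft become candidates, accepted when their peak voxel sits more than
    ``min_extent_um`` beyond the shaft surface (radius
    ``shaft_radius_um``). The ROI is the candidate's bounding rectangle on
    its peak section.
    """
    red = stack.red.astype(float)
    if smooth_sigma_px > 0:
        red = gaussian_filter(red, sigma=(0, smooth_sigma_px, smooth_sigma_px))
    dist, arc_map = _voxel_distance_map(stack, centerline)
    tube = dist <= tube_radius_um
    vals = red[tube]
    if vals.size == 0 or vals.max() == vals.min():
        return []
    thr = threshold_otsu(vals)
    fg = (red > thr) & tube
    shaft_mask = fg & (dist <= shaft_mask_radius_um)
    candidates = fg & (dist > shaft_mask_radius_um)
    labels, n_comp = label(candidates, structure=np.ones((3, 3, 3), bool))
    detections: list[SpineDetection] = []
    for comp_id in range(1, n_comp + 1):
        comp = labels == comp_id
        if not (binary_dilation(comp, iterations=2) & shaft_mask).any():
            continue  # not attached to the shaft
        comp_vals = np.where(comp, red, -np.inf)
        peak = np.unravel_index(np.argmax(comp_vals), comp.shape)
        extent = float(dist[peak] - shaft_radius_um)
        if not extent > min_extent_um:
            continue
        zs = np.flatnonzero(comp.any(axis=(1, 2)))
        foot = comp[peak[0]]
        ys, xs = np.nonzero(foot)
        x0, x1 = int(xs.min()), int(xs.max()) + 1
        y0, y1 = int(ys.min()), int(ys.max()) + 1
        while (x1 - x0) * (y1 - y0) < 4:  # enforce the 4-pixel floor
            x1, y1 = x1 + 1, y1 + 1
        roi = RoiPolygon.from_bbox(x0, y0, x1, y1,
                                   z_range=(int(zs.min()), int(zs.max())))
        detections.append(SpineDetection(
            timepoint=stack.timepoint,
            arc_position=float(arc_map[peak]),
            perpendicular_extent=extent,
            roi=roi,
            peak_section=int(peak[0]),
            peak_intensity=float(red[peak]),
        ))
    detections.sort(key=lambda d: d.arc_position)
    return detections


# ---------------------------------------------------------------------------
# Longitudinal matching


def assign_arcs(prev_arcs: np.ndarray, curr_arcs: np.ndarray,
                cap_um: float = 2.0) -> list[tuple[int, int]]:
    """Optimal one-to-one arc matching with a hard distance cap.

    Maximizes the number of matched pairs with |d| <= cap, then minimizes
    total arc distance, via a padded linear-sum assignment. Returns
    (prev_index, curr_index) pairs.
    """
    n, m = len(prev_arcs), len(curr_arcs)
    if n == 0 or m == 0:
        return []
    big = 1e6
    cost = np.full((n + m, m + n), 0.0)
    d = np.abs(np.subtract.outer(np.asarray(prev_arcs, float),
                                 np.asarray(curr_arcs, float)))
    real = np.where(d <= cap_um, d, 2 * big + 1.0)
    cost[:n, :m] = real
    cost[:n, m:] = big            # prev unmatched
    cost[n:, :m] = big            # curr unmatched
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols)
            if i < n and j < m and d[i, j] <= cap_um]


def match_spines(detections_by_session: dict[str, list[SpineDetection]],
                 cap_um: float = 2.0) -> list[SpineTrack]:
    """Chain consecutive-session assignments into stable spine tracks.

    Tracks carry identity forward while matched; an unmatched track closes
    permanently (a later detection at the same arc opens a new track). New
    track ids are issued in ascending arc order for determinism.
    """
    sessions = [tp for tp in TIMEPOINTS if tp in detections_by_session]
    if len(sessions) < 2:
        raise ValueError("matching needs >= 2 sessions on the centerline")
    for tp in sessions:
        arcs = [d.arc_position for d in detections_by_session[tp]]
        if len(arcs) != len(set(arcs)):
            raise ValueError(f"duplicate arc positions within session {tp}")

    tracks: list[SpineTrack] = []
    next_id = 0
    open_tracks: dict[int, SpineTrack] = {}   # index into current detections

    first = sessions[0]
    for det in sorted(detections_by_session[first], key=lambda d: d.arc_position):
        tr = SpineTrack(track_id=next_id)
        next_id += 1
        tr.detections[first] = det
        tracks.append(tr)
    current = {id(det): tr for tr in tracks
               for det in [tr.detections[first]]}

    prev_dets = sorted(detections_by_session[first], key=lambda d: d.arc_position)
    prev_tracks = [current[id(d)] for d in prev_dets]
    for tp in sessions[1:]:
        curr_dets = sorted(detections_by_session[tp], key=lambda d: d.arc_position)
        pairs = assign_arcs(
            np.array([d.arc_position for d in prev_dets]),
            np.array([d.arc_position for d in curr_dets]), cap_um)
        matched_curr = set()
        curr_tracks: list[SpineTrack] = [None] * len(curr_dets)  # type: ignore
        for i, j in pairs:
            tr = prev_tracks[i]
            tr.detections[tp] = curr_dets[j]
            matched_curr.add(j)
            curr_tracks[j] = tr
        for j, det in enumerate(curr_dets):
            if j not in matched_curr:
                tr = SpineTrack(track_id=next_id)
                next_id += 1
                tr.detections[tp] = det
                tracks.append(tr)
                curr_tracks[j] = tr
        prev_dets = curr_dets
        prev_tracks = curr_tracks

    for tr in tracks:
        for tp in TIMEPOINTS:
            tr.present[tp] = tp in tr.detections
    return tracks


def tracks_from_census(spines: pd.DataFrame) -> dict[str, list[SpineTrack]]:
    """Build per-dendrite tracks directly from a ground-truth census table.

    Bypasses imaging: presence flags come straight from the generator, so
    turnover statistics can be computed at scales where rendering every
    session would be pointless.
    """
    out: dict[str, list[SpineTrack]] = {}
    for dend, grp in spines.groupby("dendrite", sort=True):
        tracks = []
        for tid, row in enumerate(grp.sort_values("arc_um").itertuples(index=False)):
            tr = SpineTrack(track_id=tid)
            for tp in TIMEPOINTS:
                tr.present[tp] = bool(getattr(row, f"present_{tp}"))
            tracks.append(tr)
        out[dend] = classify_fates(tracks)
    return out


# ---------------------------------------------------------------------------
# Fates and turnover


def classify_fates(tracks: list[SpineTrack]) -> list[SpineTrack]:
    """Assign stable/new/eliminated/absent labels per timepoint."""
    for tr in tracks:
        first = tr.first_present()
        for k, tp in enumerate(TIMEPOINTS):
            present = tr.present.get(tp, False)
            if k == 0:
                tr.fate[tp] = "stable" if present else "absent"
                continue
            prev = tr.present.get(TIMEPOINTS[k - 1], False)
            if present:
                if tp == first and not tr.present.get(TIMEPOINTS[0], False):
                    tr.fate[tp] = "new"
                elif prev:
                    tr.fate[tp] = "stable"
                else:
                    # gap in presence: treat re-appearance as new track
                    # upstream; defensively call it new here
                    tr.fate[tp] = "new"
            else:
                tr.fate[tp] = "eliminated" if prev else "absent"
    return tracks


def turnover_rates(tracks: list[SpineTrack], timepoint: str) -> dict:
    """Formation/elimination/density-change percentages at one timepoint."""
    k = TP_INDEX[timepoint]
    n_total = sum(tr.present.get(timepoint, False) for tr in tracks)
    n_t0 = sum(tr.present.get(TIMEPOINTS[0], False) for tr in tracks)
    row = {"timepoint": timepoint, "n_total": n_total,
           "n_formed": 0, "n_eliminated": 0,
           "formation_pct": np.nan, "elimination_pct": np.nan,
           "total_spines_pct_change": np.nan, "flagged": False}
    if k == 0:
        row["total_spines_pct_change"] = 0.0 if n_t0 > 0 else np.nan
        row["flagged"] = n_t0 == 0
        return row
    prev_tp = TIMEPOINTS[k - 1]
    n_prev = sum(tr.present.get(prev_tp, False) for tr in tracks)
    n_new = sum(tr.fate.get(timepoint) == "new" for tr in tracks)
    n_elim = sum(tr.fate.get(timepoint) == "eliminated" for tr in tracks)
    row["n_formed"], row["n_eliminated"] = n_new, n_elim
    if n_total > 0:
        row["formation_pct"] = 100.0 * n_new / n_total
    if n_prev > 0:
        row["elimination_pct"] = 100.0 * n_elim / n_prev
    if n_t0 > 0:
        row["total_spines_pct_change"] = 100.0 * (n_total - n_t0) / n_t0
    row["flagged"] = n_total == 0 or n_prev == 0 or n_t0 == 0
    return row


def turnover_table(tracks_by_dendrite: dict[str, list[SpineTrack]]) -> pd.DataFrame:
    """Per-dendrite per-timepoint turnover summary table."""
    rows = []
    for dend, tracks in tracks_by_dendrite.items():
        for tp in TIMEPOINTS:
            row = turnover_rates(tracks, tp)
            row["dendrite"] = dend
            rows.append(row)
    cols = ["dendrite", "timepoint", "n_total", "n_formed", "n_eliminated",
            "formation_pct", "elimination_pct", "total_spines_pct_change",
            "flagged"]
    return pd.DataFrame(rows)[cols]


def new_spine_persistence(tracks: list[SpineTrack],
                          early_tps: tuple[str, ...] = ("2h", "18h"),
                          final_tp: str = "D10") -> float | None:
    """Fraction of spines newly formed early in training still present at
    the final session; None (flagged) when no new spines exist."""
    new_tracks = [tr for tr in tracks
                  if any(tr.fate.get(tp) == "new" for tp in early_tps)]
    if not new_tracks:
        logger.warning("no new spines at %s; persistence undefined", early_tps)
        return None
    kept = sum(tr.present.get(final_tp, False) for tr in new_tracks)
    return kept / len(new_tracks)
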