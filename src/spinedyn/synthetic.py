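"""Synthetic two-photon cohort generator with full ground truth.

Emulates the statistical structure of a longitudinal spine-imaging study:
multiple mice per genotype x hemisphere condition, several annotated
dendritic segments per mouse, and six imaging sessions (T0, 2h, 18h, 42h,
D6, D10) around a 5-day motor-training block.

The generative model, in layers:

* **Census** — each dendrite starts with a fixed number of spines; between
  sessions spines are eliminated with a per-interval hazard and new spines
  are born so that the expected total follows a programmed per-condition
  density multiplier (e.g. a transient ~15% pulse at 18 h contralateral).
  Eliminated spines never reappear.
* **Trajectories** — each spine carries a baseline surface-receptor level
  (log-normal; stochastically lower in KO) and a size. Per session the
  observable receptor level is ``base * g_m(t) * exp(sigma_day * Z)`` and
  the size is ``size0 * exp(sigma_size * V)``, with iid standard-normal
  draws per spine per session (median-one multiplicative day noise). The
  condition trend ``g(t)`` is modulated per mouse by a latent factor that
  also drives behavioural improvement, coupling imaging to behaviour.
* **Rendering** — a curved dendrite is drawn as a Gaussian-profile tube;
  each present spine adds a neck + head blob perpendicular to the shaft.
  Red intensity encodes size, green encodes size x receptor level; a
  per-stack gain factor, constant background, red->green bleed-through,
  Poisson shot noise and Gaussian read noise complete the image model.
* **Behaviour** — successes out of ~100 daily reach attempts, binomial
  around a logistic-like improvement curve (flat for KO).

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_core import (
    DEFAULT_AXIAL_UM_PER_SECTION,
    DEFAULT_LATERAL_UM_PER_PX,
    GROUPS,
    TIMEPOINTS,
    TP_INDEX,
    DendriteCenterline,
    SessionStack,
    write_stack,
)

N_TP = len(TIMEPOINTS)
TRAINING_DAYS = (1, 2, 3, 4, 5)

#: Geometry constants shared with detection (um).
SHAFT_RADIUS_UM = 0.25
SHAFT_SIGMA_UM = 0.15
HEAD_SIGMA_UM = 0.20
NECK_SIGMA_UM = 0.15


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size and reproducibility contract for one simulation."""

    n_mice_per_group: int = 2
    groups: tuple[str, ...] = GROUPS
    dendrites_per_mouse: int = 4
    spines_per_dendrite: tuple[int, int] = (25, 25)
    seed: int = 0

    def __post_init__(self):
        if self.n_mice_per_group < 1 or self.dendrites_per_mouse < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.spines_per_dendrite
        if lo < 1 or hi < lo:
            raise ValueError("spines_per_dendrite range invalid")
        for g in self.groups:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")


def _flat_trend() -> tuple[float, ...]:
    return (1.0,) * N_TP


@dataclass
class TrajectoryModel:
    """Per-condition dynamics presets for the generator.

    ``glua2_trend`` and ``density_multiplier`` are per-timepoint values
    relative to T0 (first entry must be 1). ``elimination_hazard`` holds the
    five per-interval elimination probabilities; the formation hazard is
    derived so the expected census follows the density multiplier.
    """

    glua2_trend: dict[str, tuple[float, ...]] = field(default_factory=dict)
    density_multiplier: dict[str, tuple[float, ...]] = field(default_factory=dict)
    elimination_hazard: dict[str, tuple[float, ...]] = field(default_factory=dict)
    sigma_day: float = 0.091
    sigma_size: float = 0.05
    sigma_gain: float = 0.05
    baseline_glua2_median: dict[str, float] = field(
        default_factory=lambda: {"WT": 1.0, "KO": 0.75})
    baseline_glua2_logsd: float = 0.6
    #: Per-mouse latent amplitude (log-normal sd) scaling both the sGluA2
    #: trend and behavioural improvement.
    mouse_coupling_sd: float = 0.25
    bleedthrough: float = 0.0003
    background: float = 50.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    #: Behaviour: success probability on day d is
    #: base_rate * (1 + u_m * (curve[d] - 1)), successes ~ Binomial(attempts).
    behavior_base_rate: dict[str, float] = field(
        default_factory=lambda: {"WT": 0.20, "KO": 0.20})
    behavior_curve: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "WT": (1.0, 1.25, 1.5, 1.75, 1.95),
            "KO": (1.0, 1.0, 1.0, 1.0, 1.0),
        })
    attempts_per_day: int = 100

    def __post_init__(self):
        for g in GROUPS:
            self.glua2_trend.setdefault(g, _flat_trend())
            self.density_multiplier.setdefault(g, _flat_trend())
            self.elimination_hazard.setdefault(g, (0.0,) * (N_TP - 1))
        for g, tr in self.glua2_trend.items():
            if len(tr) != N_TP or tr[0] != 1.0 or any(v <= 0 for v in tr):
                raise ValueError(f"glua2_trend[{g}] must be 6 positive values, first 1")
        for g, mult in self.density_multiplier.items():
            if len(mult) != N_TP or mult[0] != 1.0 or any(v <= 0 for v in mult):
                raise ValueError(f"density_multiplier[{g}] invalid")
            for phi in self.formation_hazard(g):
                if phi < -1e-9:
                    raise ValueError(
                        f"density_multiplier[{g}] implies a negative "
                        "formation hazard; raise the elimination hazard")

    def formation_hazard(self, group: str) -> tuple[float, ...]:
        """Per-interval formation hazard implied by the density multiplier."""
        mult = self.density_multiplier[group]
        elim = self.elimination_hazard[group]
        return tuple(
            max(0.0, mult[t] / mult[t - 1] - 1.0 + elim[t - 1])
            for t in range(1, N_TP)
        )

    def expected_density_change_pct(self, group: str, timepoint: str) -> float:
        """Closed-form expected % change in total spines vs T0."""
        return 100.0 * (self.density_multiplier[group][TP_INDEX[timepoint]] - 1.0)

    def pct_change_log_sd(self) -> float:
        """Log-scale sd of a consecutive-session green fold-change ratio."""
        return math.sqrt(2.0 * (self.sigma_day ** 2 + self.sigma_size ** 2))

    def pct_change_sd(self) -> float:
        """Closed-form sd of the percent change 100*(exp(s Z) - 1)."""
        s2 = self.pct_change_log_sd() ** 2
        return 100.0 * math.sqrt(math.exp(s2) * (math.exp(s2) - 1.0))

    def up_down_tail_probs(self, threshold_pct: float = 30.0) -> tuple[float, float]:
        """(P[Up], P[Down]) for a trend-free consecutive transition."""
        from scipy.stats import norm

        s = self.pct_change_log_sd()
        p_up = norm.sf(math.log1p(threshold_pct / 100.0) / s)
        p_down = norm.cdf(math.log1p(-threshold_pct / 100.0) / s)
        return float(p_up), float(p_down)


def default_model() -> TrajectoryModel:
    """Study-condition presets: training-driven contralateral dynamics.

    Contralateral WT: transient spine-density pulse peaking at +15% at 18 h
    and a persistent ~20% receptor accumulation at D6/D10; KO contralateral
    shows a smaller (+8%) pulse and no accumulation; ipsilateral conditions
    stay near flat.
    """
    return TrajectoryModel(
        glua2_trend={
            "WT-CH": (1.0, 1.0, 1.02, 1.08, 1.2, 1.2),
            "WT-IH": (1.0, 1.0, 0.95, 1.0, 1.0, 1.0),
            "KO-CH": (1.0, 1.0, 0.95, 1.0, 1.0, 1.0),
            "KO-IH": (1.0, 1.0, 1.0, 1.0, 0.98, 0.98),
        },
        density_multiplier={
            "WT-CH": (1.0, 1.07, 1.15, 1.10, 1.03, 1.00),
            "WT-IH": (1.0, 1.00, 1.00, 0.99, 0.98, 0.97),
            "KO-CH": (1.0, 1.04, 1.08, 1.05, 1.01, 1.00),
            "KO-IH": (1.0, 1.00, 1.00, 0.99, 0.98, 0.97),
        },
        elimination_hazard={
            "WT-CH": (0.01, 0.015, 0.05, 0.07, 0.04),
            "WT-IH": (0.01, 0.015, 0.03, 0.03, 0.03),
            "KO-CH": (0.01, 0.015, 0.04, 0.05, 0.03),
            "KO-IH": (0.01, 0.015, 0.03, 0.03, 0.03),
        },
    )


def flat_model(**overrides) -> TrajectoryModel:
    """Null preset: no trends, no turnover, default noise."""
    return TrajectoryModel(**overrides)


def small_cohort_spec(seed: int = 0) -> CohortSpec:
    """Fast test-scale cohort: 2 mice x 4 dendrites x 25 spines per group."""
    return CohortSpec(seed=seed)


def paper_scale_spec(seed: int = 0) -> CohortSpec:
    """Full-scale preset: 5 mice, ~36 dendrites/group, ~25 spines each."""
    return CohortSpec(
        n_mice_per_group=5,
        dendrites_per_mouse=7,
        spines_per_dendrite=(20, 30),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Census


def _sample_positions(rng: np.random.Generator, n: int, length: float,
                      existing: np.ndarray | None = None,
                      min_gap: float = 1.0, margin: float = 2.0) -> np.ndarray:
    """Arc positions with pairwise gap >= min_gap; error after 100 attempts."""
    have = np.array([] if existing is None else existing, dtype=float)
    out: list[float] = []
    for _ in range(n):
        for attempt in range(100):
            pos = rng.uniform(margin, length - margin)
            taken = np.concatenate([have, np.array(out)]) if out or have.size else np.array([])
            if taken.size == 0 or np.min(np.abs(taken - pos)) >= min_gap:
                out.append(pos)
                break
        else:
            raise RuntimeError(
                "could not place spine with >= 1 um arc separation after "
                "100 attempts; reduce spine density")
    return np.asarray(out)


def simulate_census(spec: CohortSpec, model: TrajectoryModel,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Per-spine birth/death table for the whole cohort.

    Returns one row per spine that ever exists, with presence flags per
    timepoint (columns ``present_T0`` ... ``present_D10``), arc position,
    protrusion length, baseline receptor level/size, and identifiers.
    """
    rows = []
    spine_counter = 0
    for group in spec.groups:
        genotype, hemisphere = group.split("-")
        phi = model.formation_hazard(group)
        eps = model.elimination_hazard[group]
        for m in range(spec.n_mice_per_group):
            mouse = f"{genotype}{m + 1}"
            u_m = float(np.exp(rng.normal(0.0, model.mouse_coupling_sd)))
            for d in range(spec.dendrites_per_mouse):
                dend = f"{mouse}_{hemisphere}_d{d + 1}"
                lo, hi = spec.spines_per_dendrite
                n0 = int(rng.integers(lo, hi + 1))
                # >= 1 um pairwise gaps block ~2 um per spine (including
                # later births), so leave headroom below the
                # sequential-packing limit
                n_expected = n0 * (1.0 + sum(phi))
                length = max(DendriteCenterline.ANALYSIS_MIN_UM,
                             min(DendriteCenterline.ANALYSIS_MAX_UM,
                                 6.0 + 2.8 * n_expected))
                arcs = _sample_positions(rng, n0, length)
                dend_rows = []
                for arc in arcs:
                    dend_rows.append(_new_spine(
                        rng, model, spine_counter, group, genotype, hemisphere,
                        mouse, dend, u_m, float(arc), born=0, length_um_dend=length))
                    spine_counter += 1
                # evolve census interval by interval
                for t in range(1, N_TP):
                    alive = [r for r in dend_rows if r["present"][t - 1]]
                    # eliminations
                    for r in alive:
                        if rng.random() < eps[t - 1]:
                            for tt in range(t, N_TP):
                                r["present"][tt] = False
                        else:
                            r["present"][t] = r["present"][t - 1]
                    # births (expected phi * current census)
                    n_new = rng.binomial(len(alive), min(1.0, phi[t - 1])) \
                        if alive else 0
                    if n_new:
                        taken = np.array([r["arc_um"] for r in dend_rows
                                          if r["present"][t]])
                        new_arcs = _sample_positions(
                            rng, n_new, length, existing=taken, min_gap=1.0)
                        for arc in new_arcs:
                            r = _new_spine(
                                rng, model, spine_counter, group, genotype,
                                hemisphere, mouse, dend, u_m, float(arc),
                                born=t, length_um_dend=length)
                            spine_counter += 1
                            dend_rows.append(r)
                rows.extend(dend_rows)
    recs = []
    for r in rows:
        rec = {k: v for k, v in r.items() if k != "present"}
        for t, tp in enumerate(TIMEPOINTS):
            rec[f"present_{tp}"] = bool(r["present"][t])
        recs.append(rec)
    return pd.DataFrame(recs)


def _new_spine(rng, model, sid, group, genotype, hemisphere, mouse, dend,
               u_m, arc, born, length_um_dend):
    present = [False] * N_TP
    for t in range(born, N_TP):
        present[t] = True
    return {
        "spine_id": f"s{sid:06d}",
        "group": group,
        "genotype": genotype,
        "hemisphere": hemisphere,
        "mouse": mouse,
        "dendrite": dend,
        "dendrite_length_um": length_um_dend,
        "arc_um": arc,
        "side": int(rng.integers(0, 2)) * 2 - 1,
        "length_um": float(rng.uniform(0.75, 1.5)),
        "size0": float(np.exp(rng.normal(0.0, 0.25))),
        "glua2_base": float(
            model.baseline_glua2_median[genotype]
            * np.exp(rng.normal(0.0, model.baseline_glua2_logsd))),
        "mouse_factor": u_m,
        "born_tp": TIMEPOINTS[born],
        "present": present,
    }


def simulate_trajectories(spines: pd.DataFrame, model: TrajectoryModel,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Per-spine per-session true receptor level and size (present only).

    The true green fold change of a persistent spine between sessions t and
    T0 is ``(glua2(t) * size(t)) / (glua2(T0) * size(T0))``.
    """
    recs = []
    for row in spines.itertuples(index=False):
        g_trend = model.glua2_trend[row.group]
        u = row.mouse_factor
        for t, tp in enumerate(TIMEPOINTS):
            if not getattr(row, f"present_{tp}"):
                continue
            g_m = max(1e-3, 1.0 + u * (g_trend[t] - 1.0))
            glua2 = row.glua2_base * g_m * math.exp(
                rng.normal(0.0, model.sigma_day))
            size = row.size0 * math.exp(rng.normal(0.0, model.sigma_size))
            recs.append({
                "spine_id": row.spine_id,
                "timepoint": tp,
                "true_glua2": glua2,
                "true_size": size,
            })
    return pd.DataFrame(recs)


def sample_fold_changes(model: TrajectoryModel, n_spines: int,
                        rng: np.random.Generator,
                        group: str = "WT-CH") -> pd.DataFrame:
    """Measured-equivalent green fold-change series for n persistent spines.

    Trajectory-level shortcut (no rendering): fold(t) = trend ratio times
    ``exp(s (Z_t - Z_0))`` with the generator's day + size noise. Used for
    large-sample threshold/dynamics studies.
    """
    g = np.array(model.glua2_trend[group])
    s = math.sqrt(model.sigma_day ** 2 + model.sigma_size ** 2)
    z = rng.normal(0.0, s, size=(n_spines, N_TP))
    folds = (g / g[0])[None, :] * np.exp(z - z[:, [0]])
    recs = []
    for i in range(n_spines):
        for t, tp in enumerate(TIMEPOINTS):
            recs.append({"spine_id": f"s{i:06d}", "timepoint": tp,
                         "fold_glua2": folds[i, t]})
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Behaviour


def simulate_behavior(spines_or_mice: pd.DataFrame, model: TrajectoryModel,
                      rng: np.random.Generator,
                      deterministic: bool = False) -> pd.DataFrame:
    """Daily reach attempts and successes per mouse.

    Uses each mouse's latent coupling factor so that mice with stronger
    receptor accumulation also improve more. With ``deterministic`` the
    binomial sampling is replaced by the expected success count.
    """
    mice = (spines_or_mice[["mouse", "genotype", "mouse_factor"]]
            .drop_duplicates("mouse").sort_values("mouse"))
    recs = []
    for row in mice.itertuples(index=False):
        base = model.behavior_base_rate[row.genotype]
        curve = model.behavior_curve[row.genotype]
        for day in TRAINING_DAYS:
            p = base * (1.0 + row.mouse_factor * (curve[day - 1] - 1.0))
            p = float(np.clip(p, 0.01, 0.95))
            attempts = model.attempts_per_day
            if deterministic:
                successes = p * attempts
            else:
                successes = int(rng.binomial(attempts, p))
            recs.append({"mouse": row.mouse, "genotype": row.genotype,
                         "day": day, "attempts": attempts,
                         "successes": successes})
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Rendering


def _dendrite_centerline(length_um: float, rng: np.random.Generator | None,
                         lateral: float = DEFAULT_LATERAL_UM_PER_PX,
                         n_z: int = 12, amp_um: float = 1.5,
                         margin_um: float = 3.0) -> tuple[DendriteCenterline, tuple[int, int, int]]:
    """Curved centerline plus the (Z, Y, X) stack shape that contains it."""
    n_pts = max(2, int(length_um / 0.25))
    x = np.linspace(margin_um, margin_um + length_um, n_pts)
    if rng is None:
        y = np.zeros_like(x)
        amp = 0.0
    else:
        phase = rng.uniform(0, 2 * np.pi)
        amp = amp_um
        y = amp * np.sin(2 * np.pi * x / max(20.0, length_um) + phase)
    y_half_um = amp + 3.5
    y_um = y + y_half_um
    z_um = np.full_like(x, n_z // 2 * DEFAULT_AXIAL_UM_PER_SECTION)
    pts = np.column_stack([z_um, y_um, x])
    nx = int(np.ceil((length_um + 2 * margin_um) / lateral))
    ny = int(np.ceil(2 * y_half_um / lateral))
    return DendriteCenterline(pts), (n_z, ny, nx)


def _voxel_coords_um(shape: tuple[int, int, int], lateral: float,
                     axial: float) -> np.ndarray:
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(
        (np.arange(nz)) * axial,
        (np.arange(ny) + 0.0) * lateral,
        (np.arange(nx) + 0.0) * lateral,
        indexing="ij",
    )
    return np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])


def _render_tube(shape, centerline: DendriteCenterline, lateral, axial,
                 amplitude: float, sigma_um: float = SHAFT_SIGMA_UM,
                 flat_radius_um: float = SHAFT_RADIUS_UM) -> np.ndarray:
    """Gaussian-shoulder tube: flat core out to the shaft radius, then
    Gaussian falloff. Returns a float (Z, Y, X) intensity field."""
    tree, _ = centerline.kdtree(0.05)
    coords = _voxel_coords_um(shape, lateral, axial)
    d, _ = tree.query(coords, workers=-1)
    d = d.reshape(shape)
    excess = np.clip(d - flat_radius_um, 0.0, None)
    out = amplitude * np.exp(-0.5 * (excess / sigma_um) ** 2)
    out[d > flat_radius_um + 5 * sigma_um] = 0.0
    return out


def _spine_axis(centerline: DendriteCenterline, arc: float, side: int) -> tuple[np.ndarray, np.ndarray]:
    """(base point, unit perpendicular in the xy-plane) at an arc position."""
    p = centerline.point_at_arc(arc)
    p2 = centerline.point_at_arc(min(arc + 0.5, centerline.arc_length))
    p1 = centerline.point_at_arc(max(arc - 0.5, 0.0))
    tang = p2 - p1
    tang[0] = 0.0  # keep spines in-plane
    tang /= np.linalg.norm(tang[1:]) + 1e-12
    # side +1 points toward +y for a dendrite running along +x
    perp = np.array([0.0, tang[2], -tang[1]]) * side
    return p, perp


def _add_spine_blob(field: np.ndarray, centerline: DendriteCenterline,
                    arc: float, side: int, length_um: float, amplitude: float,
                    lateral: float, axial: float,
                    snap_to_grid: bool = False) -> None:
    """Add a neck + head blob perpendicular to the shaft, in place."""
    base, perp = _spine_axis(centerline, arc, side)
    head = base + perp * (SHAFT_RADIUS_UM + length_um)
    if snap_to_grid:
        head[1] = round(head[1] / lateral) * lateral
        head[2] = round(head[2] / lateral) * lateral
    nz, ny, nx = field.shape
    # local sub-box around the spine
    pad = length_um + 5 * HEAD_SIGMA_UM + 0.5
    z0 = max(0, int((head[0] - 3.0) / axial)); z1 = min(nz, int(head[0] / axial) + 4)
    y0 = max(0, int((min(base[1], head[1]) - pad) / lateral))
    y1 = min(ny, int((max(base[1], head[1]) + pad) / lateral) + 1)
    x0 = max(0, int((min(base[2], head[2]) - pad) / lateral))
    x1 = min(nx, int((max(base[2], head[2]) + pad) / lateral) + 1)
    if z1 <= z0 or y1 <= y0 or x1 <= x0:
        return
    zz, yy, xx = np.meshgrid(np.arange(z0, z1) * axial,
                             np.arange(y0, y1) * lateral,
                             np.arange(x0, x1) * lateral, indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1)
    # head: isotropic Gaussian
    d_head = np.linalg.norm(coords - head, axis=-1)
    blob = amplitude * np.exp(-0.5 * (d_head / HEAD_SIGMA_UM) ** 2)
    # neck: tube from shaft surface to head
    n_seg = max(2, int(length_um / 0.05))
    seg = base + perp * SHAFT_RADIUS_UM + np.outer(
        np.linspace(0.0, 1.0, n_seg), head - (base + perp * SHAFT_RADIUS_UM))
    tree = cKDTree(seg)
    d_neck, _ = tree.query(coords.reshape(-1, 3))
    neck = 0.7 * amplitude * np.exp(
        -0.5 * (d_neck.reshape(d_head.shape) / NECK_SIGMA_UM) ** 2)
    field[z0:z1, y0:y1, x0:x1] += np.maximum(blob, neck)


def _finalize_channels(red_sig, green_sig, model: TrajectoryModel, gain: float,
                       rng: np.random.Generator | None,
                       quantize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    green_sig = green_sig + model.bleedthrough * red_sig
    red = gain * red_sig + model.background
    green = gain * green_sig + model.background
    if rng is not None:
        if model.shot_noise:
            red = rng.poisson(np.clip(red, 0, None)).astype(float)
            green = rng.poisson(np.clip(green, 0, None)).astype(float)
        if model.read_noise_sd > 0:
            red = red + rng.normal(0, model.read_noise_sd, red.shape)
            green = green + rng.normal(0, model.read_noise_sd, green.shape)
    if quantize:
        red = np.clip(np.round(red), 0, 65535).astype(np.uint16)
        green = np.clip(np.round(green), 0, 65535).astype(np.uint16)
    return red, green


#: Rendering amplitudes (photon-count scale at unit size / receptor level).
DEND_RED_AMP = 400.0
DEND_GREEN_AMP = 60.0
SPINE_RED_AMP = 500.0
SPINE_GREEN_AMP = 250.0


def render_session(meta: Mapping[str, str], centerline: DendriteCenterline,
                   shape: tuple[int, int, int],
                   spine_rows: pd.DataFrame, model: TrajectoryModel,
                   gain: float = 1.0,
                   rng: np.random.Generator | None = None) -> SessionStack:
    """Render one session's two-channel stack from ground-truth spines.

    ``spine_rows`` must carry arc_um, side, length_um and the session's
    true_size / true_glua2 values for the spines present in this session.
    """
    lateral, axial = DEFAULT_LATERAL_UM_PER_PX, DEFAULT_AXIAL_UM_PER_SECTION
    red = _render_tube(shape, centerline, lateral, axial, DEND_RED_AMP)
    green = red * (DEND_GREEN_AMP / DEND_RED_AMP)
    for row in spine_rows.itertuples(index=False):
        _add_spine_blob(red, centerline, row.arc_um, row.side, row.length_um,
                        SPINE_RED_AMP * row.true_size, lateral, axial)
        _add_spine_blob(green, centerline, row.arc_um, row.side, row.length_um,
                        SPINE_GREEN_AMP * row.true_size * row.true_glua2,
                        lateral, axial)
    r, g = _finalize_channels(red, green, model, gain, rng)
    return SessionStack(
        mouse_id=str(meta["mouse_id"]), hemisphere=str(meta["hemisphere"]),
        genotype=str(meta["genotype"]), timepoint=str(meta["timepoint"]),
        red=r, green=g)


def render_control_stack(model: TrajectoryModel, seed: int = 0,
                         noiseless: bool = False) -> SessionStack:
    """Red-only (morphology marker only) control stack for bleed-through
    estimation: the green channel contains only bleed-through + background."""
    rng = np.random.default_rng(seed)
    centerline, shape = _dendrite_centerline(40.0, rng)
    lateral, axial = DEFAULT_LATERAL_UM_PER_PX, DEFAULT_AXIAL_UM_PER_SECTION
    red = _render_tube(shape, centerline, lateral, axial, DEND_RED_AMP)
    for arc in np.arange(4.0, 36.0, 2.0):
        _add_spine_blob(red, centerline, float(arc), 1 if int(arc) % 4 else -1,
                        1.0, SPINE_RED_AMP, lateral, axial)
    green = np.zeros_like(red)
    # the noiseless variant keeps continuous intensities so that sub-count
    # bleed-through is not quantized away
    r, g = _finalize_channels(red, green, model, 1.0,
                              None if noiseless else rng,
                              quantize=not noiseless)
    return SessionStack(mouse_id="control", hemisphere="CH", genotype="WT",
                        timepoint="T0", red=r, green=g)


def render_protrusion_calibration(lengths_um: Sequence[float],
                                  length_um: float = 40.0,
                                  ) -> tuple[SessionStack, DendriteCenterline]:
    """Noiseless straight-dendrite fixture with one spine per length.

    Spine-head centres sit at exactly ``length / 0.125`` pixels
    perpendicular from the shaft surface, at arc positions
    5, 10, 15, ... um. No noise, background or bleed-through.
    """
    for L in lengths_um:
        if not (0.0 < L <= 5.0):
            raise ValueError(f"protrusion length {L} um outside (0, 5]")
    centerline, shape = _dendrite_centerline(length_um, rng=None)
    lateral, axial = DEFAULT_LATERAL_UM_PER_PX, DEFAULT_AXIAL_UM_PER_SECTION
    red = _render_tube(shape, centerline, lateral, axial, DEND_RED_AMP)
    green = red * (DEND_GREEN_AMP / DEND_RED_AMP)
    for i, L in enumerate(lengths_um):
        arc = 5.0 + 5.0 * i
        if arc > length_um - 5.0:
            raise ValueError("too many calibration spines for the segment")
        side = 1 if i % 2 == 0 else -1
        _add_spine_blob(red, centerline, arc, side, float(L), SPINE_RED_AMP,
                        lateral, axial, snap_to_grid=True)
        _add_spine_blob(green, centerline, arc, side, float(L),
                        SPINE_GREEN_AMP, lateral, axial, snap_to_grid=True)
    stack = SessionStack(mouse_id="calib", hemisphere="CH", genotype="WT",
                         timepoint="T0",
                         red=np.clip(np.round(red), 0, 65535).astype(np.uint16),
                         green=np.clip(np.round(green), 0, 65535).astype(np.uint16))
    return stack, centerline


# ---------------------------------------------------------------------------
# Cohort assembly


@dataclass
class CohortData:
    """Everything one simulated cohort produces."""

    spec: CohortSpec
    model: TrajectoryModel
    spines: pd.DataFrame          # ground-truth census
    trajectories: pd.DataFrame    # per spine per session truths
    behavior: pd.DataFrame
    stacks: dict                  # (dendrite, timepoint) -> SessionStack
    centerlines: dict             # dendrite -> DendriteCenterline

    def dendrites(self) -> list[str]:
        return sorted(self.spines["dendrite"].unique())

    def manifest(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "model": {k: v for k, v in asdict(self.model).items()},
            "n_spines": int(len(self.spines)),
            "n_stacks": int(len(self.stacks)),
        }


def simulate_cohort(spec: CohortSpec, model: TrajectoryModel | None = None,
                    render: bool = True,
                    out_dir: str | Path | None = None) -> CohortData:
    """Simulate a full cohort; deterministic for a fixed ``spec.seed``."""
    model = model or default_model()
    ss = np.random.SeedSequence(spec.seed)
    rng_census, rng_traj, rng_beh, rng_render = [
        np.random.default_rng(s) for s in ss.spawn(4)]
    spines = simulate_census(spec, model, rng_census)
    traj = simulate_trajectories(spines, model, rng_traj)
    behavior = simulate_behavior(spines, model, rng_beh)
    stacks: dict = {}
    centerlines: dict = {}
    if render:
        merged = spines.merge(traj, on="spine_id")
        for dend, dgrp in spines.groupby("dendrite", sort=True):
            length = float(dgrp["dendrite_length_um"].iloc[0])
            centerline, shape = _dendrite_centerline(length, rng_render)
            centerlines[dend] = centerline
            meta0 = dgrp.iloc[0]
            for tp in TIMEPOINTS:
                gain = float(np.exp(rng_render.normal(0.0, model.sigma_gain)))
                rows = merged[(merged["dendrite"] == dend)
                              & (merged["timepoint"] == tp)
                              & merged[f"present_{tp}"]]
                stacks[(dend, tp)] = render_session(
                    {"mouse_id": meta0["mouse"],
                     "hemisphere": meta0["hemisphere"],
                     "genotype": meta0["genotype"], "timepoint": tp},
                    centerline, shape, rows, model, gain, rng_render)
    data = CohortData(spec=spec, model=model, spines=spines,
                      trajectories=traj, behavior=behavior,
                      stacks=stacks, centerlines=centerlines)
    if out_dir is not None:
        _write_cohort(data, Path(out_dir))
    return data


def _write_cohort(data: CohortData, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for (dend, tp), stack in data.stacks.items():
        write_stack(stack, out_dir / f"{dend}_{tp}.tif")
    data.spines.to_csv(out_dir / "ground_truth_spines.csv", index=False)
    data.trajectories.to_csv(out_dir / "ground_truth_trajectories.csv",
                             index=False)
    data.behavior.to_csv(out_dir / "behavior.csv", index=False)
    (out_dir / "manifest.json").write_text(
        json.dumps(data.manifest(), indent=1, default=str))
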