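"""Shared data model and file I/O.

Defines the in-memory containers used across the pipeline (two-channel
session stacks, dendrite centerlines, spine ROIs), TIFF/CSV/JSON readers
and writers, and validated run configuration.

Conventions
-----------
* Voxel arrays are ``(Z, Y, X)``, 0-based indices, stored channel-first in
  TIFF as ``(2, Z, Y, X)`` uint16 (channel 0 = red/morphology, 1 = green/
  receptor).
* Lateral calibration defaults to 0.125 um/px (so 4 px = 0.5 um) and axial
  spacing to 1 um/section.
* Imaging timepoints form the fixed ordered vocabulary
  ``T0 < 2h < 18h < 42h < D6 < D10``; anything else is rejected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, Field, ValidationError
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

logger = logging.getLogger("spinedyn")

#: Ordered imaging schedule relative to the first training session.
TIMEPOINTS: tuple[str, ...] = ("T0", "2h", "18h", "42h", "D6", "D10")
TP_INDEX: dict[str, int] = {tp: i for i, tp in enumerate(TIMEPOINTS)}
#: Hours after the first training session (T0 imaged just before).
TP_HOURS: dict[str, float] = {
    "T0": 0.0, "2h": 2.0, "18h": 18.0, "42h": 42.0, "D6": 144.0, "D10": 240.0,
}

HEMISPHERES = ("CH", "IH")
GENOTYPES = ("WT", "KO")
#: genotype x hemisphere condition labels.
GROUPS = ("WT-CH", "WT-IH", "KO-CH", "KO-IH")

DEFAULT_LATERAL_UM_PER_PX = 0.125
DEFAULT_AXIAL_UM_PER_SECTION = 1.0


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


class GeometryError(ValueError):
    """Raised when coordinates fall outside the imaged volume."""


def check_timepoint(tp: str) -> str:
    if tp not in TP_INDEX:
        raise ValueError(
            f"unknown timepoint {tp!r}; expected one of {TIMEPOINTS}"
        )
    return tp


@dataclass
class SessionStack:
    """One imaging session's two-channel volume plus calibration."""

    mouse_id: str
    hemisphere: str
    genotype: str
    timepoint: str
    red: np.ndarray
    green: np.ndarray
    lateral_um_per_px: float = DEFAULT_LATERAL_UM_PER_PX
    axial_um_per_section: float = DEFAULT_AXIAL_UM_PER_SECTION

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red)
        self.green = np.asarray(self.green)
        if self.red.shape != self.green.shape:
            raise ValueError(
                f"channel shapes differ: red {self.red.shape} vs green "
                f"{self.green.shape}"
            )
        if self.red.ndim != 3:
            raise ValueError("channels must be 3-D (Z, Y, X) arrays")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        check_timepoint(self.timepoint)
        if self.lateral_um_per_px <= 0 or self.axial_um_per_section <= 0:
            raise ValueError("calibration must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.red.shape

    @property
    def group(self) -> str:
        return f"{self.genotype}-{self.hemisphere}"

    def with_channels(self, red: np.ndarray, green: np.ndarray) -> "SessionStack":
        """Copy of this stack with replaced channel data."""
        return SessionStack(
            mouse_id=self.mouse_id,
            hemisphere=self.hemisphere,
            genotype=self.genotype,
            timepoint=self.timepoint,
            red=red,
            green=green,
            lateral_um_per_px=self.lateral_um_per_px,
            axial_um_per_section=self.axial_um_per_section,
        )


class DendriteCenterline:
    """Ordered 3-D polyline through the dendritic shaft, in micrometres.

    Points are ``(z, y, x)`` in um. Arc positions are cumulative chord
    lengths from the first point; construction requires strictly
    increasing arc positions (no repeated points).
    """

    ANALYSIS_MIN_UM = 30.0
    ANALYSIS_MAX_UM = 80.0

    def __init__(self, points_um: np.ndarray):
        pts = np.asarray(points_um, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("centerline needs >= 2 points of (z, y, x) um")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("centerline points must be strictly ordered")
        self.points_um = pts
        self.arc_um = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def arc_length(self) -> float:
        return float(self.arc_um[-1])

    def is_analysis_segment(self) -> bool:
        """Whether the segment satisfies the 30-80 um analysis criterion."""
        return self.ANALYSIS_MIN_UM <= self.arc_length <= self.ANALYSIS_MAX_UM

    def resample(self, spacing_um: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        """Dense (points_um, arc_um) sampling at the requested spacing."""
        n = max(2, int(np.ceil(self.arc_length / spacing_um)) + 1)
        arcs = np.linspace(0.0, self.arc_length, n)
        pts = np.column_stack([
            np.interp(arcs, self.arc_um, self.points_um[:, k]) for k in range(3)
        ])
        return pts, arcs

    def point_at_arc(self, arc: float) -> np.ndarray:
        arc = float(np.clip(arc, 0.0, self.arc_length))
        return np.array([
            np.interp(arc, self.arc_um, self.points_um[:, k]) for k in range(3)
        ])

    def kdtree(self, spacing_um: float = 0.05) -> tuple[cKDTree, np.ndarray]:
        pts, arcs = self.resample(spacing_um)
        return cKDTree(pts), arcs


@dataclass
class RoiPolygon:
    """Planar spine ROI: vertex list in pixel coordinates plus z extent.

    Vertices are ``(x, y)`` in 0-based pixel units; the raster footprint is
    the set of pixels whose centres ``(c + 0.5, r + 0.5)`` fall inside the
    polygon (half-open semantics for integer-vertex rectangles).
    ``z_range`` is the inclusive ``(z_min, z_max)`` span of sections the
    spine occupies.
    """

    vertices: tuple[tuple[float, float], ...]
    z_range: tuple[int, int]

    def __post_init__(self) -> None:
        self.vertices = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(self.vertices) < 3:
            raise ValueError("ROI polygon needs >= 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid or not poly.is_simple:
            raise ValueError("ROI polygon must be non-self-intersecting")
        if poly.area < 4.0:
            raise ValueError("ROI footprint must cover >= 4 pixels")
        z0, z1 = self.z_range
        if z1 < z0 or z0 < 0:
            raise ValueError("invalid z_range")
        self._poly = poly

    @property
    def area(self) -> float:
        return self._poly.area

    def bounds_px(self) -> tuple[int, int, int, int]:
        """Integer (x0, y0, x1, y1) bounding box, half-open."""
        minx, miny, maxx, maxy = self._poly.bounds
        return (int(np.floor(minx)), int(np.floor(miny)),
                int(np.ceil(maxx)), int(np.ceil(maxy)))

    def footprint_mask(self, shape_yx: tuple[int, int]) -> np.ndarray:
        """Boolean (Y, X) mask of pixels whose centres lie in the polygon."""
        import shapely

        ny, nx = shape_yx
        x0, y0, x1, y1 = self.bounds_px()
        if x0 < 0 or y0 < 0 or x1 > nx or y1 > ny:
            raise GeometryError("ROI extends outside the volume")
        mask = np.zeros(shape_yx, dtype=bool)
        if x1 <= x0 or y1 <= y0:
            return mask
        ys, xs = np.mgrid[y0:y1, x0:x1]
        inside = shapely.contains_xy(
            self._poly, xs.ravel() + 0.5, ys.ravel() + 0.5
        ).reshape(ys.shape)
        mask[y0:y1, x0:x1] = inside
        return mask

    @staticmethod
    def from_bbox(x0: int, y0: int, x1: int, y1: int,
                  z_range: tuple[int, int]) -> "RoiPolygon":
        """Axis-aligned rectangle covering pixels [x0, x1) x [y0, y1)."""
        return RoiPolygon(
            vertices=((x0, y0), (x1, y0), (x1, y1), (x0, y1)),
            z_range=z_range,
        )


# ---------------------------------------------------------------------------
# Stack I/O


def write_stack(stack: SessionStack, path: str | Path) -> None:
    """Write a SessionStack as channel-first uint16 TIFF + sidecar JSON."""
    path = Path(path)
    data = np.stack([stack.red, stack.green]).astype(np.uint16)
    tifffile.imwrite(path, data)
    meta = {
        "mouse_id": stack.mouse_id,
        "hemisphere": stack.hemisphere,
        "genotype": stack.genotype,
        "timepoint": stack.timepoint,
        "lateral_um_per_px": stack.lateral_um_per_px,
        "axial_um_per_section": stack.axial_um_per_section,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_stack(path: str | Path,
               metadata: Mapping[str, object] | None = None) -> SessionStack:
    """Read a two-channel TIFF stack.

    ``metadata`` overrides/supplies the session descriptor; otherwise the
    sidecar JSON written by :func:`write_stack` is used. Missing calibration
    falls back to the documented defaults with a logged warning.
    """
    path = Path(path)
    data = np.asarray(tifffile.imread(path))
    if data.ndim == 3:
        # 2 pages = 2 channels of a single section
        data = data[:, None, :, :]
    if data.ndim != 4 or data.shape[0] != 2:
        n_ch = data.shape[0] if data.ndim >= 1 else 0
        raise FormatError(
            f"expected 2 channels x Z sections, got array of shape "
            f"{data.shape} ({n_ch} leading planes)"
        )
    meta: dict[str, object] = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    if metadata:
        meta.update(metadata)
    for key, default in (
        ("lateral_um_per_px", DEFAULT_LATERAL_UM_PER_PX),
        ("axial_um_per_section", DEFAULT_AXIAL_UM_PER_SECTION),
    ):
        if key not in meta:
            logger.warning("%s: missing %s; using default %s", path.name, key, default)
            meta[key] = default
    return SessionStack(
        mouse_id=str(meta["mouse_id"]),
        hemisphere=str(meta["hemisphere"]),
        genotype=str(meta["genotype"]),
        timepoint=str(meta["timepoint"]),
        red=data[0],
        green=data[1],
        lateral_um_per_px=float(meta["lateral_um_per_px"]),
        axial_um_per_section=float(meta["axial_um_per_section"]),
    )


def write_results_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write an analysis table as CSV (UTF-8, header, >= 9 sig digits)."""
    if records is None or len(records) == 0:
        raise ValueError("refusing to write an empty results table")
    records.to_csv(path, index=False, float_format="%.10g", encoding="utf-8")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Run configuration


class RunConfig(BaseModel):
    """Validated pipeline configuration with documented defaults."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    #: Up/Same/Down threshold on per-transition percent change.
    dynamics_threshold_pct: float = Field(default=30.0, gt=0)
    #: Master seed for every stochastic step.
    seed: int = Field(default=0, ge=0)
    #: Red->green bleed-through fraction; None means estimate from a
    #: red-only control stack.
    bleedthrough_fraction: float | None = Field(default=None, ge=0.0, lt=1.0)
    #: If True, the three brightest sections are chosen on the morphology
    #: channel and reused for the receptor channel; default selects
    #: independently per channel.
    shared_brightest_frames: bool = False
    #: Correlate imaging against day-1-normalized success rate (True) or
    #: raw success rate (False).
    spearman_normalized_rate: bool = True
    #: Permutations for the mouse-level group-difference test.
    n_permutations: int = Field(default=10_000, ge=1)
    #: Floor applied to fold changes so geometric means stay defined.
    fold_floor: float = Field(default=1e-3, gt=0)
    #: Arc-distance cap (um) for across-session spine matching.
    match_cap_um: float = Field(default=2.0, gt=0)


def resolve_config(mapping: Mapping[str, object] | None = None) -> RunConfig:
    """Resolve a partial key-value mapping into a full RunConfig.

    Unknown keys raise a validation error naming the offending key;
    resolution is idempotent.
    """
    try:
        return RunConfig(**dict(mapping or {}))
    except ValidationError as exc:
        raise ValueError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError("config document must be a JSON object")
    return resolve_config(doc)
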