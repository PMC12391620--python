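"""Real-time image-based gating: thresholds, area/contour features, polygon gates.

The sorter's decision algorithm reduces each fluorescence frame to two
numbers per channel: the thresholded foreground *area* (pixel count) and the
total *contour* (boundary pixel count).  Droplets with n well-separated cells
form distinct clusters in the (area, contour) plane — two small cells of the
same total area as one large cell have a ≈√2 larger contour — so polygon
gates drawn in that plane select droplets by per-channel cell count.  Gates
on different channels are combined with a logical AND, and the result drives
the exclusive two-electrode trigger: HIGH activates electrode E1 (positive
outlet), LOW activates E2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.filters import threshold_otsu

__all__ = [
    "GateFeatures",
    "PolygonGate",
    "GatingStrategy",
    "SortDecision",
    "binarize",
    "gate_features",
    "in_gate",
    "evaluate_strategy",
    "calibrate_gates",
]

log = logging.getLogger(__name__)


class GateConfigError(ValueError):
    """Raised for degenerate polygons or inconsistent strategies."""


@dataclass(frozen=True)
class GateFeatures:
    """Foreground pixel count and boundary pixel count of one channel's mask."""

    area: int
    contour: int

    def __post_init__(self):
        if not (0 <= self.contour <= self.area):
            raise ValueError("features must satisfy 0 <= contour <= area")


@dataclass
class PolygonGate:
    """A polygon in (area, contour) feature space attached to one channel."""

    channel_name: str
    vertices: list[tuple[float, float]]
    boundary_inclusive: bool = True

    def __post_init__(self):
        self.vertices = [(float(a), float(c)) for a, c in self.vertices]
        if len(self.vertices) < 3:
            raise GateConfigError("a polygon gate needs at least 3 vertices")
        if _polygon_area(self.vertices) == 0.0 or self._self_intersects():
            raise GateConfigError("polygon gate must be simple with nonzero area")
        # normalise winding to counter-clockwise on load
        if _polygon_area(self.vertices) < 0:
            self.vertices = self.vertices[::-1]

    def _self_intersects(self) -> bool:
        return not _ShapelyPolygon(self.vertices).is_simple


@dataclass
class GatingStrategy:
    """Per-channel thresholds plus AND-combined polygon gates.

    ``label`` is the human-readable predicate the gates implement, e.g.
    ``"1 effector AND 2-4 targets"``.
    """

    thresholds: dict[str, float]
    gates: list[PolygonGate]
    label: str = ""

    def __post_init__(self):
        if not self.gates:
            raise GateConfigError("a strategy needs at least one gate")
        for g in self.gates:
            if g.channel_name not in self.thresholds:
                raise GateConfigError(
                    f"gate channel {g.channel_name!r} has no threshold configured"
                )

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(g.channel_name for g in self.gates))

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return dict(
            thresholds=self.thresholds,
            label=self.label,
            gates=[
                dict(
                    channel_name=g.channel_name,
                    vertices=[list(v) for v in g.vertices],
                    boundary_inclusive=g.boundary_inclusive,
                )
                for g in self.gates
            ],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "GatingStrategy":
        return cls(
            thresholds={k: float(v) for k, v in d["thresholds"].items()},
            gates=[PolygonGate(**g) for g in d["gates"]],
            label=d.get("label", ""),
        )

    @classmethod
    def load(cls, path: str | Path) -> "GatingStrategy":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class SortDecision:
    """Outcome of the AND-combined gates for one droplet.

    Exclusive electrode mode: positive ⇔ trigger HIGH ⇔ electrode E1 active
    and E2 inactive; negative inverts the pattern.
    """

    droplet_id: int
    positive: bool

    @property
    def trigger(self) -> str:
        return "HIGH" if self.positive else "LOW"

    @property
    def electrode_state(self) -> tuple[bool, bool]:
        """(E1 active, E2 active) — exactly one is ever active."""
        return (True, False) if self.positive else (False, True)


def binarize(image: np.ndarray, threshold: float) -> np.ndarray:
    """Strict intensity threshold: mask = image > threshold."""
    return np.asarray(image) > threshold


def otsu_threshold(image: np.ndarray) -> float:
    """Automatic threshold alternative to the manual midpoint choice."""
    return float(threshold_otsu(np.asarray(image)))


def gate_features(mask: np.ndarray, roi=None) -> GateFeatures:
    """Area and contour of a binary mask, restricted to the ROI disk.

    ``roi`` may be ``None`` (whole mask), a ``(center_row, center_col,
    radius)`` tuple, or an object with ``x``/``y``/``radius`` attributes.
    Area counts foreground pixels; contour counts foreground pixels with at
    least one background 4-neighbour, where pixels beyond the mask edge count
    as background.
    """
    m = np.asarray(mask, dtype=bool)
    if roi is not None:
        if hasattr(roi, "radius"):
            cr, cc, rad = roi.y, roi.x, roi.radius
        else:
            cr, cc, rad = roi
        rr, cc_ = np.ogrid[: m.shape[0], : m.shape[1]]
        m = m & ((rr - cr) ** 2 + (cc_ - cc) ** 2 <= rad**2)
    area = int(m.sum())
    if area == 0:
        return GateFeatures(0, 0)
    padded = np.pad(m, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    contour = int((m & ~interior).sum())
    return GateFeatures(area, contour)


def _polygon_area(vertices) -> float:
    """Signed shoelace area (positive = counter-clockwise)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _on_segment(px, py, ax, ay, bx, by, eps=1e-9) -> bool:
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    scale = max(abs(bx - ax), abs(by - ay), 1.0)
    if abs(cross) > eps * scale:
        return False
    dot = (px - ax) * (bx - ax) + (py - ay) * (by - ay)
    return -eps <= dot <= (bx - ax) ** 2 + (by - ay) ** 2 + eps


def in_gate(features: GateFeatures, gate: PolygonGate) -> bool:
    """Point-in-polygon by ray casting; boundary membership is configurable."""
    return _point_in_gate(float(features.area), float(features.contour), gate)


def _point_in_gate(px: float, py: float, gate: PolygonGate) -> bool:
    verts = gate.vertices
    n = len(verts)
    for i in range(n):
        ax, ay = verts[i]
        bx, by = verts[(i + 1) % n]
        if _on_segment(px, py, ax, ay, bx, by):
            return gate.boundary_inclusive
    inside = False
    for i in range(n):
        ax, ay = verts[i]
        bx, by = verts[(i + 1) % n]
        if (ay > py) != (by > py):
            x_cross = ax + (py - ay) * (bx - ax) / (by - ay)
            if px < x_cross:
                inside = not inside
    return inside


def evaluate_strategy(
    features: dict[str, GateFeatures],
    strategy: GatingStrategy,
    droplet_id: int = -1,
) -> SortDecision:
    """AND all gates; missing channel features raise."""
    for gate in strategy.gates:
        if gate.channel_name not in features:
            raise GateConfigError(
                f"no features supplied for gated channel {gate.channel_name!r}"
            )
    positive = all(in_gate(features[g.channel_name], g) for g in strategy.gates)
    return SortDecision(droplet_id=droplet_id, positive=positive)


def _robust_trim(points: np.ndarray, z_cut: float) -> np.ndarray:
    """Drop points far from the cloud centre in MAD units (per dimension)."""
    if len(points) < 5 or z_cut <= 0:
        return points
    med = np.median(points, axis=0)
    mad = np.median(np.abs(points - med), axis=0)
    mad = np.where(mad > 0, mad, 1.0)
    z = np.abs(points - med) / (1.4826 * mad)
    keep = (z <= z_cut).all(axis=1)
    return points[keep] if keep.sum() >= 3 else points


def _hull_with_margin(points: np.ndarray, margin: float) -> list[tuple[float, float]]:
    """Convex hull of a point cloud, expanded outward by ``margin``.

    Degenerate clouds (identical or collinear points, e.g. the empty-channel
    cluster that collapses onto the origin) fall back to an axis-aligned
    bounding box grown by ``max(margin, 1)``.
    """
    pts = np.asarray(points, dtype=float)
    try:
        hull = ConvexHull(pts)
        poly = _ShapelyPolygon(pts[hull.vertices])
    except (QhullError, ValueError):
        pad = max(margin, 1.0)
        (x0, y0), (x1, y1) = pts.min(axis=0), pts.max(axis=0)
        return [
            (x0 - pad, y0 - pad),
            (x1 + pad, y0 - pad),
            (x1 + pad, y1 + pad),
            (x0 - pad, y1 + pad),
        ]
    if margin > 0:
        poly = poly.buffer(margin, join_style=2)
    coords = list(poly.exterior.coords)[:-1]
    return [(float(x), float(y)) for x, y in coords]


def calibrate_gates(
    features_by_channel: dict[str, np.ndarray],
    counts_by_channel: dict[str, np.ndarray],
    target_counts: dict[str, set[int]],
    thresholds: dict[str, float],
    label: str = "",
    margin: float = 6.0,
    trim_z: float = 3.5,
    min_per_class: int = 20,
    boundary_inclusive: bool = True,
) -> GatingStrategy:
    """Build polygon gates around the feature clusters of requested count classes.

    Parameters
    ----------
    features_by_channel : channel → (n, 2) array of (area, contour) points.
    counts_by_channel : channel → (n,) true per-channel cell counts of the
        labelled calibration droplets.
    target_counts : channel → set of counts the gate should select, e.g.
        ``{"effector_stain": {1}, "target_stain": {2, 3, 4}}``.
    thresholds : per-channel binarisation thresholds to embed in the strategy.
    margin : outward hull expansion in feature units.
    trim_z : robust-MAD cut applied per class before the hull (guards the
        hull against overlapping-cell feature outliers); ``0`` disables.

    Classes with fewer than ``min_per_class`` droplets raise.  A warning is
    logged when the selected clusters overlap the remaining classes.
    """
    gates = []
    for channel, wanted in target_counts.items():
        feats = np.asarray(features_by_channel[channel], dtype=float)
        counts = np.asarray(counts_by_channel[channel])
        cloud_parts = []
        for cls in sorted(wanted):
            pts = feats[counts == cls]
            if len(pts) < min_per_class:
                raise ValueError(
                    f"channel {channel!r}: class {cls} has only {len(pts)} "
                    f"calibration droplets (need >= {min_per_class})"
                )
            cloud_parts.append(_robust_trim(pts, trim_z))
        cloud = np.vstack(cloud_parts)
        gate = PolygonGate(
            channel_name=channel,
            vertices=_hull_with_margin(cloud, margin),
            boundary_inclusive=boundary_inclusive,
        )
        outside = feats[~np.isin(counts, list(wanted))]
        if len(outside):
            leaked = np.mean([_point_in_gate(float(a), float(c), gate)
                              for a, c in outside])
            if leaked > 0.05:
                log.warning(
                    "channel %r: %.0f%% of other-count droplets fall inside the "
                    "calibrated gate (overlapping clusters)",
                    channel,
                    100 * leaked,
                )
        gates.append(gate)
    return GatingStrategy(thresholds=dict(thresholds), gates=gates, label=label)
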