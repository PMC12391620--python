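"""Droplet localisation via the circle Hough transform.

Brightfield droplet rims are high-contrast rings, so the detector builds a
Canny edge map with percentile-derived thresholds and accumulates Hough votes
over a radius range.  Peaks are accepted when they collect at least a set
fraction of the theoretical perimeter votes and survive a greedy
non-maximum suppression that forbids two centres closer than ``r_min``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import canny
from skimage.transform import hough_circle

from .config import RenderConfig
from .render import ImageStack

__all__ = ["DropletROI", "detect_droplets", "extract_crops", "match_rois", "rois_to_frame"]

log = logging.getLogger(__name__)


@dataclass
class DropletROI:
    """A detected droplet: centre (x=col, y=row), radius and crop bookkeeping."""

    droplet_id: int
    x: float
    y: float
    radius: float
    score: float = 0.0
    crop_origin: tuple[int, int] | None = None  # (row, col) of crop corner
    edge_truncated: bool = False


def detect_droplets(
    brightfield: np.ndarray,
    r_min: int,
    r_max: int,
    radius_step: int = 2,
    accept_fraction: float = 0.5,
    canny_sigma: float = 2.0,
) -> list[DropletROI]:
    """Find droplets in a brightfield image.

    Parameters
    ----------
    brightfield : 2-D array
        Brightfield frame (any numeric dtype).
    r_min, r_max : int
        Radius search range in pixels (``r_min < r_max``).
    radius_step : int
        Spacing of the tested radii.
    accept_fraction : float
        Minimum fraction of the theoretical perimeter votes a circle must
        collect (normalised Hough accumulator value).
    canny_sigma : float
        Gaussian width of the Canny edge detector.

    Returns
    -------
    list of DropletROI sorted by accumulator score, descending.  A constant
    image yields an empty list (with a logged warning).
    """
    if r_min >= r_max:
        raise ValueError("r_min must be smaller than r_max")
    img = np.asarray(brightfield, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    lo, hi = np.percentile(img, [1, 99])
    if hi - lo <= 0:
        log.warning("degenerate (constant) brightfield image; no droplets detected")
        return []
    norm = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    edges = canny(norm, sigma=canny_sigma, low_threshold=0.1, high_threshold=0.3)
    radii = np.arange(r_min, r_max + 1, radius_step)
    accum = hough_circle(edges, radii, normalize=True, full_output=False)

    # candidate peaks above the perimeter-vote acceptance threshold
    cand = np.argwhere(accum > accept_fraction)
    if cand.size == 0:
        return []
    scores = accum[cand[:, 0], cand[:, 1], cand[:, 2]]
    order = np.argsort(-scores, kind="stable")  # ties: first-discovered wins
    cand, scores = cand[order], scores[order]

    rois: list[DropletROI] = []
    taken = np.empty((0, 2))
    for (ri, rr, cc), sc in zip(cand, scores):
        if taken.size:
            d2 = np.sum((taken - (rr, cc)) ** 2, axis=1)
            if np.any(d2 < float(r_min) ** 2):
                continue
        rois.append(
            DropletROI(
                droplet_id=len(rois),
                x=float(cc),
                y=float(rr),
                radius=float(radii[ri]),
                score=float(sc),
            )
        )
        taken = np.vstack([taken, (rr, cc)]) if taken.size else np.array([[rr, cc]])
    return rois


def extract_crops(
    stack: ImageStack,
    rois: list[DropletROI],
    crop_size: int,
    background_level: dict[str, float] | None = None,
) -> list[dict[str, np.ndarray]]:
    """Cut fixed-size multi-channel crops centred on each ROI.

    Regions outside the field are padded with the per-channel background
    level (0 if not given); padding marks the ROI ``edge_truncated``.
    ``crop_size`` must be at least twice the largest ROI radius so the whole
    droplet fits.
    """
    H, W = stack.shape
    crops = []
    for roi in rois:
        if crop_size < 2 * roi.radius:
            raise ValueError(
                f"crop_size {crop_size} smaller than droplet diameter {2 * roi.radius:.0f}"
            )
        r0 = int(round(roi.y)) - crop_size // 2
        c0 = int(round(roi.x)) - crop_size // 2
        r1, c1 = r0 + crop_size, c0 + crop_size
        truncated = r0 < 0 or c0 < 0 or r1 > H or c1 > W
        crop = {}
        for ch, img in stack.channels.items():
            bg = 0.0 if background_level is None else background_level.get(ch, 0.0)
            out = np.full((crop_size, crop_size), bg, dtype=img.dtype)
            sr0, sc0 = max(r0, 0), max(c0, 0)
            sr1, sc1 = min(r1, H), min(c1, W)
            out[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = img[sr0:sr1, sc0:sc1]
            crop[ch] = out
        roi.crop_origin = (r0, c0)
        roi.edge_truncated = bool(truncated)
        crops.append(crop)
    return crops


def match_rois(
    rois: list[DropletROI],
    reference: pd.DataFrame,
    max_distance_factor: float = 0.5,
) -> pd.DataFrame:
    """Match detections to reference centres by nearest centre.

    ``reference`` needs columns ``(droplet_id, x, y, radius_px)``.  A
    detection matches the nearest reference centre within
    ``max_distance_factor`` × reference radius; each reference is matched at
    most once (greedy, best detection score first).  This is the static
    nearest-centre assignment also used across timepoints — a documented
    helper, not a motion tracker.

    Returns a frame with columns (roi_id, ref_id, distance); unmatched
    detections carry ``ref_id = -1``.
    """
    ref_xy = reference[["x", "y"]].to_numpy(dtype=float)
    ref_r = reference["radius_px"].to_numpy(dtype=float)
    used = np.zeros(len(reference), dtype=bool)
    rows = []
    for roi in sorted(rois, key=lambda r: -r.score):
        if len(ref_xy) == 0:
            rows.append((roi.droplet_id, -1, np.nan))
            continue
        d = np.hypot(ref_xy[:, 0] - roi.x, ref_xy[:, 1] - roi.y)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= max_distance_factor * ref_r[j]:
            used[j] = True
            rows.append((roi.droplet_id, int(reference["droplet_id"].iloc[j]), float(d[j])))
        else:
            rows.append((roi.droplet_id, -1, float(d[j])))
    return pd.DataFrame(rows, columns=["roi_id", "ref_id", "distance"])


def rois_to_frame(rois: list[DropletROI]) -> pd.DataFrame:
    """ROI list → CSV-ready table (droplet_id, x, y, radius_px, edge_truncated)."""
    return pd.DataFrame(
        [
            dict(
                droplet_id=r.droplet_id,
                x=r.x,
                y=r.y,
                radius_px=r.radius,
                edge_truncated=r.edge_truncated,
            )
            for r in rois
        ],
        columns=["droplet_id", "x", "y", "radius_px", "edge_truncated"],
    )
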