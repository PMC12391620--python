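"""Render ground-truth droplets as multi-channel 16-bit microscopy images.

The rendering model is deliberately simple but faithful to what the analysis
stages consume: a brightfield channel showing the dark droplet rim and dim
cell bodies, one lineage stain per cell type lighting every cell of that type
(alive or dead), and an apoptosis reporter lighting dead cells of either
type, co-located with their lineage stain.  Cells are placed uniformly inside
the droplet with a configurable overlap cap, and three artifact classes can
be injected: a bright air-bubble occlusion, a droplet cut off at the image
border, and a double-layer blur (defocused second emulsion layer).
Gaussian blur and read noise are applied last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import (
    APOPTOSIS_STAIN,
    BRIGHTFIELD,
    EFFECTOR_STAIN,
    TARGET_STAIN,
    RenderConfig,
)
from .killing import DropletGroundTruth

__all__ = ["GenerationError", "ImageStack", "place_cells", "render_droplet", "render_field"]

ANNOTATION_COLUMNS = (
    "droplet_id",
    "x",
    "y",
    "radius_px",
    "n_eff_live",
    "n_eff_dead",
    "n_tgt_live",
    "n_tgt_dead",
    "outlier_class",
    "time_h",
)


class GenerationError(RuntimeError):
    """Raised when a droplet cannot be rendered (e.g. cells do not fit)."""


@dataclass
class ImageStack:
    """One multi-channel acquisition: channel name → 2-D uint16 array."""

    channels: dict[str, np.ndarray] = field(default_factory=dict)
    pixel_size: float = 1.0  # µm per pixel
    acquisition_time: float = 0.0  # hours

    def __post_init__(self):
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def as_array(self) -> np.ndarray:
        """Stack channels into a (C, H, W) array in insertion order."""
        return np.stack([self.channels[ch] for ch in self.channels], axis=0)


def place_cells(
    truth: DropletGroundTruth,
    config: RenderConfig,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> list[tuple[float, float, float]]:
    """Place all cells of a droplet uniformly inside its disk.

    Returns one ``(row_offset, col_offset, radius_px)`` tuple per cell, in
    ``truth.cells`` order, with offsets relative to the droplet centre.  Two
    cells may overlap by at most ``config.max_overlap`` of the smaller radius
    (overlap measured as the deficit of the centre distance below the sum of
    radii).  Raises :class:`GenerationError` when placement fails.
    """
    R = config.droplet_radius_px
    d_lo, d_hi = config.cell_diameter_range
    placed: list[tuple[float, float, float]] = []
    for _ in truth.cells:
        r = rng.uniform(d_lo, d_hi) / (2.0 * config.pixel_size)
        reach = R - r - 1.0
        if reach <= 0:
            raise GenerationError("cell larger than droplet interior")
        for _try in range(max_tries):
            rho = reach * np.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * np.pi)
            rc = (rho * np.sin(theta), rho * np.cos(theta))
            ok = True
            for pr, pc, prad in placed:
                dist = float(np.hypot(rc[0] - pr, rc[1] - pc))
                if (r + prad) - dist > config.max_overlap * min(r, prad):
                    ok = False
                    break
            if ok:
                placed.append((rc[0], rc[1], r))
                break
        else:
            raise GenerationError(
                f"could not place {len(truth.cells)} cells in droplet "
                f"{truth.droplet_id} within the overlap cap"
            )
    return placed


def _paint_disk(img: np.ndarray, center_rc, radius: float, value: float) -> None:
    """Set ``img`` to at least ``value`` inside a disk, clipped to bounds."""
    h, w = img.shape
    r0 = max(int(np.floor(center_rc[0] - radius)) - 1, 0)
    r1 = min(int(np.ceil(center_rc[0] + radius)) + 2, h)
    c0 = max(int(np.floor(center_rc[1] - radius)) - 1, 0)
    c1 = min(int(np.ceil(center_rc[1] + radius)) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.ogrid[r0:r1, c0:c1]
    mask = (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius**2
    region = img[r0:r1, c0:c1]
    region[mask] = np.maximum(region[mask], value)


def _paint_ring(img: np.ndarray, center_rc, r_in: float, r_out: float, value: float) -> None:
    h, w = img.shape
    r0 = max(int(np.floor(center_rc[0] - r_out)) - 1, 0)
    r1 = min(int(np.ceil(center_rc[0] + r_out)) + 2, h)
    c0 = max(int(np.floor(center_rc[1] - r_out)) - 1, 0)
    c1 = min(int(np.ceil(center_rc[1] + r_out)) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.ogrid[r0:r1, c0:c1]
    d2 = (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2
    mask = (d2 >= r_in**2) & (d2 <= r_out**2)
    img[r0:r1, c0:c1][mask] = value


def _fill_disk(img: np.ndarray, center_rc, radius: float, value: float) -> None:
    """Hard-overwrite a disk (used for occluding artifacts)."""
    h, w = img.shape
    r0 = max(int(np.floor(center_rc[0] - radius)) - 1, 0)
    r1 = min(int(np.ceil(center_rc[0] + radius)) + 2, h)
    c0 = max(int(np.floor(center_rc[1] - radius)) - 1, 0)
    c1 = min(int(np.ceil(center_rc[1] + radius)) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.ogrid[r0:r1, c0:c1]
    mask = (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius**2
    img[r0:r1, c0:c1][mask] = value


def _draw_droplet_tile(
    truth: DropletGroundTruth,
    time: float,
    config: RenderConfig,
    rng: np.random.Generator,
    size: tuple[int, int],
    center_rc: tuple[float, float],
) -> dict[str, np.ndarray]:
    """Noise-free, blurred float tile of one droplet on flat background."""
    R = config.droplet_radius_px
    bg = config.background_level
    sig = config.signal_level
    tile = {ch: np.full(size, bg[ch], dtype=np.float64) for ch in config.channel_names}

    # droplet rim in brightfield (dark ring)
    _paint_ring(tile[BRIGHTFIELD], center_rc, R - 2.0, R + 1.0, sig[BRIGHTFIELD])

    offsets = place_cells(truth, config, rng)
    dead_disks: list[tuple[tuple[float, float], float]] = []
    for cell, (dr, dc, r) in zip(truth.cells, offsets):
        crc = (center_rc[0] + dr, center_rc[1] + dc)
        cell_bf = bg[BRIGHTFIELD] * (1.0 - config.cell_brightfield_contrast)
        _fill_disk(tile[BRIGHTFIELD], crc, r, cell_bf)
        lineage = EFFECTOR_STAIN if cell.is_effector else TARGET_STAIN
        _paint_disk(tile[lineage], crc, r, sig[lineage])
        if not cell.alive_at(time):
            _paint_disk(tile[APOPTOSIS_STAIN], crc, r, sig[APOPTOSIS_STAIN])
            dead_disks.append((crc, r))

    blur = config.blur_sigma
    if truth.outlier_class == "double_layer_blur":
        blur = 3.0 * config.blur_sigma
    elif truth.outlier_class == "bubble":
        b_r = rng.uniform(0.4, 0.7) * R
        rho = rng.uniform(0.3, 0.8) * R
        theta = rng.uniform(0.0, 2.0 * np.pi)
        brc = (center_rc[0] + rho * np.sin(theta), center_rc[1] + rho * np.cos(theta))
        bright = min(1.5 * bg[BRIGHTFIELD], float(config.max_intensity))
        _fill_disk(tile[BRIGHTFIELD], brc, b_r, bright)
        _paint_ring(tile[BRIGHTFIELD], brc, b_r, b_r + 2.0, 0.5 * sig[BRIGHTFIELD])
        for ch in config.fluorescence_channels:
            _fill_disk(tile[ch], brc, b_r, bg[ch])  # bubble occludes fluorescence

    if blur > 0:
        for ch in tile:
            tile[ch] = ndimage.gaussian_filter(tile[ch], blur)
    return tile


def _finish(
    tile: dict[str, np.ndarray],
    config: RenderConfig,
    rng: np.random.Generator,
    pixel_size: float,
    time: float,
) -> ImageStack:
    """Add read noise, clip to bit depth, quantise."""
    out = {}
    for ch, img in tile.items():
        noisy = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        out[ch] = np.clip(noisy, 0, config.max_intensity).astype(np.uint16)
    return ImageStack(out, pixel_size=pixel_size, acquisition_time=time)


def _edge_center(size: tuple[int, int], R: float, rng: np.random.Generator):
    """Droplet centre within crop-radius of a random border, so it is cut."""
    h, w = size
    border = int(rng.integers(4))
    d = rng.uniform(0.2, 0.6) * R  # distance of centre to the border
    if border == 0:
        return (d, rng.uniform(R, w - R))
    if border == 1:
        return (h - 1 - d, rng.uniform(R, w - R))
    if border == 2:
        return (rng.uniform(R, h - R), d)
    return (rng.uniform(R, h - R), w - 1 - d)


def render_droplet(
    truth: DropletGroundTruth,
    time: float,
    config: RenderConfig,
    rng: np.random.Generator | int,
) -> ImageStack:
    """Render one droplet into a ``crop_size`` × ``crop_size`` multi-channel crop.

    The droplet is centred unless its ``outlier_class`` is ``edge_cutoff``,
    in which case the centre is moved to within the crop radius of a border.
    """
    if time < 0:
        raise ValueError("time must be non-negative")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    size = (config.crop_size, config.crop_size)
    if truth.outlier_class == "edge_cutoff":
        center = _edge_center(size, config.droplet_radius_px, rng)
    else:
        center = ((size[0] - 1) / 2.0, (size[1] - 1) / 2.0)
    tile = _draw_droplet_tile(truth, time, config, rng, size, center)
    return _finish(tile, config, rng, config.pixel_size, time)


def render_field(
    truths: list[DropletGroundTruth],
    grid_layout: tuple[int, int],
    config: RenderConfig,
    rng: np.random.Generator | int,
    time: float = 0.0,
) -> tuple[ImageStack, pd.DataFrame]:
    """Tile droplets into one large field and emit the true annotation table.

    Droplets occupy a ``rows × cols`` grid of ``crop_size`` tiles with a small
    positional jitter; ``edge_cutoff`` droplets are instead moved to within
    the crop radius of the nearest field border.  Returns the rendered
    :class:`ImageStack` and a CSV-ready table with columns
    ``(droplet_id, x, y, radius_px, n_eff_live, n_eff_dead, n_tgt_live,
    n_tgt_dead, outlier_class, time_h)`` where ``x`` is the column and ``y``
    the row coordinate of the true centre.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    rows, cols = grid_layout
    if rows * cols < len(truths):
        raise GenerationError(
            f"grid {rows}x{cols} cannot hold {len(truths)} droplets"
        )
    tile_px = config.crop_size
    H, W = rows * tile_px, cols * tile_px
    R = config.droplet_radius_px
    bg = config.background_level
    field_imgs = {
        ch: np.full((H, W), bg[ch], dtype=np.float64) for ch in config.channel_names
    }
    jitter = max(min(tile_px / 2.0 - R - 2.0, 4.0), 0.0)

    records = []
    for k, truth in enumerate(truths):
        gr, gc = divmod(k, cols)
        cr = gr * tile_px + (tile_px - 1) / 2.0 + rng.uniform(-jitter, jitter)
        cc = gc * tile_px + (tile_px - 1) / 2.0 + rng.uniform(-jitter, jitter)
        if truth.outlier_class == "edge_cutoff":
            # project the centre to within the crop radius of the nearest border
            d = rng.uniform(0.2, 0.6) * R
            dists = {"top": cr, "bottom": H - 1 - cr, "left": cc, "right": W - 1 - cc}
            side = min(dists, key=dists.get)
            if side == "top":
                cr = d
            elif side == "bottom":
                cr = H - 1 - d
            elif side == "left":
                cc = d
            else:
                cc = W - 1 - d
        # draw on a local window to keep per-droplet blur local
        pad = int(np.ceil(R + 6 * config.blur_sigma * 3 + 4))
        r0, c0 = int(np.floor(cr)) - pad, int(np.floor(cc)) - pad
        r1, c1 = int(np.floor(cr)) + pad + 1, int(np.floor(cc)) + pad + 1
        wr0, wc0 = max(r0, 0), max(c0, 0)
        wr1, wc1 = min(r1, H), min(c1, W)
        size = (r1 - r0, c1 - c0)
        tile = _draw_droplet_tile(
            truth, time, config, rng, size, (cr - r0, cc - c0)
        )
        for ch in field_imgs:
            delta = tile[ch] - bg[ch]
            field_imgs[ch][wr0:wr1, wc0:wc1] += delta[
                wr0 - r0 : wr1 - r0, wc0 - c0 : wc1 - c0
            ]
        el, ed, tl, td = truth.counts_at(time)
        records.append(
            dict(
                droplet_id=truth.droplet_id,
                x=cc,
                y=cr,
                radius_px=R,
                n_eff_live=el,
                n_eff_dead=ed,
                n_tgt_live=tl,
                n_tgt_dead=td,
                outlier_class=truth.outlier_class,
                time_h=time,
            )
        )

    stack = _finish(field_imgs, config, rng, config.pixel_size, time)
    table = pd.DataFrame.from_records(records, columns=list(ANNOTATION_COLUMNS))
    return stack, table
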