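"""Reading and writing the pipeline's on-disk artifacts.

Images travel as multi-page 16-bit TIFF (one page per channel, channel names
and pixel size in the image description); tables as CSV; run manifests as
JSON.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import tifffile

from .render import ImageStack

__all__ = ["save_stack", "load_stack", "write_manifest"]


def save_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as a multi-page TIFF with metadata."""
    meta = dict(
        channel_names=list(stack.channel_names),
        pixel_size_um=stack.pixel_size,
        acquisition_time_h=stack.acquisition_time,
    )
    tifffile.imwrite(
        str(path),
        stack.as_array(),
        photometric="minisblack",
        description=json.dumps(meta),
    )


def load_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF written by :func:`save_stack`.

    TIFFs from other sources are accepted too: pages become channels named
    ``channel_0`` … with a pixel size of 1 µm.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    if data.ndim == 2:
        data = data[None]
    try:
        meta = json.loads(desc)
        names = meta["channel_names"]
        pixel_size = float(meta.get("pixel_size_um", 1.0))
        t = float(meta.get("acquisition_time_h", 0.0))
    except (json.JSONDecodeError, KeyError, TypeError):
        names = [f"channel_{i}" for i in range(len(data))]
        pixel_size, t = 1.0, 0.0
    channels = {name: np.asarray(page) for name, page in zip(names, data)}
    return ImageStack(channels, pixel_size=pixel_size, acquisition_time=t)


def write_manifest(
    path: str | Path,
    stage: str,
    seed: int,
    config_hash: str,
    inputs: dict[str, str],
    outputs: dict[str, str],
    status: str = "ok",
) -> dict:
    """Write the run manifest every CLI stage emits; returns the record."""
    from . import __version__

    record = dict(
        stage=stage,
        status=status,
        seed=int(seed),
        config_hash=config_hash,
        version=__version__,
        inputs=inputs,
        outputs=outputs,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    Path(path).write_text(json.dumps(record, indent=2))
    return record
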