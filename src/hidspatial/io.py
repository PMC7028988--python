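"""TIFF / CSV / YAML round-tripping for pipeline artefacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import DEFAULT_CHANNELS, MultiplexImage, QualityMask


def write_multiplex_tiff(path: str | Path, image: MultiplexImage) -> None:
    """Write one page per channel, channel names + pixel size in the metadata."""
    meta = {"channel_names": list(image.channel_names), "pixel_size_um": image.pixel_size_um}
    pages = np.moveaxis(image.pixels.astype(np.float32), 2, 0)
    tifffile.imwrite(str(path), pages, description=json.dumps(meta))


def read_multiplex_tiff(path: str | Path) -> MultiplexImage:
    with tifffile.TiffFile(str(path)) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    if pages.ndim == 2:
        pages = pages[None]
    names = tuple(meta.get("channel_names", DEFAULT_CHANNELS[: pages.shape[0]]))
    return MultiplexImage(
        pixels=np.moveaxis(pages.astype(float), 0, 2),
        channel_names=names,
        pixel_size_um=float(meta.get("pixel_size_um", 0.495)),
    )


def write_mask_tiff(path: str | Path, mask: QualityMask) -> None:
    tifffile.imwrite(str(path), mask.labels.astype(np.uint8))


def read_mask_tiff(path: str | Path) -> QualityMask:
    return QualityMask(labels=tifffile.imread(str(path)))


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
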