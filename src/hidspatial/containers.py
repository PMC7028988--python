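"""Core in-memory containers shared across the pipeline.

The unit of image analysis is one ROI (region of interest): a multi-channel
field scanned at 20x (1392 x 1040 px, 0.495 um/px in the reference setup),
carried as a :class:`MultiplexImage`.  Pixel-level quality decisions are a
:class:`QualityMask`; segmented cells travel as a plain pandas DataFrame (the
"cell table") with a documented column contract so external segmentation
output can enter the pipeline mid-way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Marker / phenotype vocabulary
# --------------------------------------------------------------------------

#: The four immune markers scored by the pipeline (DAPI is the counterstain,
#: AF the autofluorescence channel; neither is scored).
MARKERS: tuple[str, ...] = ("CD8", "PD-1", "PD-L1", "CD68")

#: Default channel order of a multiplex image.
DEFAULT_CHANNELS: tuple[str, ...] = ("DAPI", "CD8", "PD-1", "PD-L1", "CD68", "AF")

#: Analysis phenotypes -> required positive markers.  A cell may belong to
#: several phenotype sets (e.g. a CD8+PD-1+ cell is also CD8+ and PD-1+).
PHENOTYPES: dict[str, tuple[str, ...]] = {
    "CD8+": ("CD8",),
    "CD8+PD-1+": ("CD8", "PD-1"),
    "CD68+": ("CD68",),
    "CD68+PD-L1+": ("CD68", "PD-L1"),
    "PD-L1+": ("PD-L1",),
    "PD-1+": ("PD-1",),
}

# Quality-mask label codes.
LABEL_BACKGROUND = 0
LABEL_TISSUE = 1
LABEL_ARTIFACT = 2
MASK_LABELS = (LABEL_BACKGROUND, LABEL_TISSUE, LABEL_ARTIFACT)
MASK_LABEL_NAMES = {LABEL_BACKGROUND: "background", LABEL_TISSUE: "tissue", LABEL_ARTIFACT: "artifact"}


def flag_column(marker: str) -> str:
    """Name of the boolean positivity column for ``marker`` in a cell table."""
    return f"{marker}_pos"


def parse_phenotype(label: str) -> tuple[str, ...]:
    """Split a combination label like ``"CD8+PD-1+"`` into its markers."""
    parts = tuple(p for p in label.split("+") if p)
    unknown = [p for p in parts if p not in MARKERS]
    if unknown:
        raise ValueError(f"unknown marker(s) {unknown} in phenotype label {label!r}")
    return parts


def phenotype_mask(cells: pd.DataFrame, phenotype: str) -> pd.Series:
    """Boolean membership of each cell in ``phenotype`` (AND over its markers).

    ``phenotype`` may be any marker combination label, not only the entries of
    :data:`PHENOTYPES`; ``"negative"`` selects cells with no positive marker.
    """
    if phenotype == "negative":
        out = pd.Series(True, index=cells.index)
        for m in MARKERS:
            out &= ~cells[flag_column(m)].astype(bool)
        return out
    markers = PHENOTYPES.get(phenotype) or parse_phenotype(phenotype)
    out = pd.Series(True, index=cells.index)
    for m in markers:
        col = flag_column(m)
        if col not in cells.columns:
            raise ValueError(f"cell table has no positivity column for marker {m!r}")
        out &= cells[col].astype(bool)
    return out


#: Minimal column contract for a cell table.
CELL_TABLE_COLUMNS = ("cell_id", "roi_id", "patient_id", "x", "y")


def validate_cell_table(cells: pd.DataFrame) -> None:
    missing = [c for c in CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table is missing required columns: {missing}")


# --------------------------------------------------------------------------
# Images and masks
# --------------------------------------------------------------------------

@dataclass
class MultiplexImage:
    """An unmixed multi-channel ROI image.

    Parameters
    ----------
    pixels
        ``(H, W, C)`` array of non-negative, finite intensities.
    channel_names
        Ordered channel labels; length must equal ``C``.
    pixel_size_um
        Physical pixel size in micrometres per pixel.
    """

    pixels: np.ndarray
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    pixel_size_um: float = 0.495

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a (H, W, C) array")
        if self.pixels.shape[2] != len(self.channel_names):
            raise ValueError(
                f"{self.pixels.shape[2]} channels but {len(self.channel_names)} channel names"
            )
        if not np.isfinite(self.pixels).all():
            raise ValueError("image intensities must be finite")
        if (self.pixels < 0).any():
            raise ValueError("image intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        """2-D view of one named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}") from None
        return self.pixels[:, :, idx]


@dataclass
class QualityMask:
    """Per-pixel quality labels: background (0), tissue (1) or artifact (2)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask labels must be a 2-D array")
        bad = ~np.isin(self.labels, MASK_LABELS)
        if bad.any():
            raise ValueError(
                f"mask contains {int(bad.sum())} pixels outside the legal label set {MASK_LABELS}"
            )
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape
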