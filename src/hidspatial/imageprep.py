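"""Spectral unmixing, pixel-level quality classification and the ROI gate.

Quality control mirrors a three-class pixel labelling problem — background,
useful tissue, artifact — followed by a hard inclusion rule: an ROI with less
than 30% useful tissue is excluded, and only cells whose centroids fall in
useful tissue are analysed.  The pixel classifier is an interface (image ->
QualityMask): the default is a rule-based classifier on signal level,
autofluorescence saturation and local sharpness, and a learned classifier can
be slotted in without touching the gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import nnls

from .containers import (
    LABEL_ARTIFACT,
    LABEL_BACKGROUND,
    LABEL_TISSUE,
    MultiplexImage,
    QualityMask,
    validate_cell_table,
)

__all__ = [
    "SpectraLibrary",
    "unmix",
    "TissueClassifierParams",
    "RuleBasedTissueClassifier",
    "classify_tissue",
    "evaluate_mask",
    "useful_tissue_fraction",
    "filter_rois",
    "filter_cells_by_mask",
    "DEFAULT_INCLUSION_THRESHOLD",
]

#: ROIs with useful-tissue fraction strictly below this are excluded.
DEFAULT_INCLUSION_THRESHOLD = 0.30


# --------------------------------------------------------------------------
# Linear spectral unmixing
# --------------------------------------------------------------------------

@dataclass
class SpectraLibrary:
    """Reference emission spectra: one column per fluorophore (plus AF).

    ``weights`` has shape ``(n_bands, n_fluorophores)``; columns must be
    non-negative, non-zero and linearly independent.
    """

    weights: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.names = tuple(self.names)
        if self.weights.ndim != 2 or self.weights.shape[1] != len(self.names):
            raise ValueError("weights must be (n_bands, n_fluorophores) matching names")
        if (self.weights < 0).any():
            raise ValueError("spectra must be non-negative")
        norms = np.linalg.norm(self.weights, axis=0)
        zero = [self.names[i] for i in np.flatnonzero(norms == 0)]
        if zero:
            raise ValueError(f"all-zero spectral column(s): {zero}")

    @classmethod
    def from_csv(cls, path) -> "SpectraLibrary":
        """Read a component library: one column per fluorophore, one row per band."""
        frame = pd.read_csv(path)
        return cls(weights=frame.to_numpy(dtype=float), names=tuple(frame.columns))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.weights, columns=list(self.names)).to_csv(path, index=False)


def _collinear_columns(weights: np.ndarray, names: Sequence[str]) -> list[str]:
    # Identify a minimal set of columns whose removal restores full rank.
    cols: list[str] = []
    kept: list[int] = []
    for j in range(weights.shape[1]):
        trial = kept + [j]
        if np.linalg.matrix_rank(weights[:, trial]) < len(trial):
            cols.append(names[j])
        else:
            kept.append(j)
    return cols


def unmix(raw: np.ndarray, library: SpectraLibrary, pixel_size_um: float = 0.495) -> MultiplexImage:
    """Decompose a raw multispectral image into fluorophore abundances.

    Solves, per pixel, the non-negative least-squares problem
    ``raw_pixel ~= weights @ abundances`` (abundances are physical
    concentrations, so negativity is artefactual and is excluded by the
    constraint).  Pixels whose unconstrained solution is already non-negative
    are solved in one vectorised least-squares pass; the remainder fall back
    to per-pixel NNLS.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3:
        raise ValueError("raw must be (H, W, B)")
    H, W, B = raw.shape
    A = library.weights
    if B != A.shape[0]:
        raise ValueError(f"raw has {B} bands but library expects {A.shape[0]}")
    if B < A.shape[1]:
        raise ValueError("need at least as many spectral bands as fluorophores")
    if np.linalg.matrix_rank(A) < A.shape[1]:
        bad = _collinear_columns(A, library.names)
        raise ValueError(f"spectral library is rank deficient; collinear column(s): {bad}")

    flat = raw.reshape(-1, B)
    sol, *_ = np.linalg.lstsq(A, flat.T, rcond=None)
    sol = sol.T  # (H*W, F)
    neg = (sol < -1e-10).any(axis=1)
    if neg.any():
        for idx in np.flatnonzero(neg):
            sol[idx], _ = nnls(A, flat[idx])
    np.clip(sol, 0.0, None, out=sol)
    return MultiplexImage(
        pixels=sol.reshape(H, W, A.shape[1]),
        channel_names=library.names,
        pixel_size_um=pixel_size_um,
    )


# --------------------------------------------------------------------------
# Pixel-level quality classification
# --------------------------------------------------------------------------

@dataclass
class TissueClassifierParams:
    """Thresholds for the rule-based quality classifier.

    Defaults are calibrated on the synthetic renderer (diffuse tissue AF
    ~0.1, artifact AF ~5, sensor noise sigma ~0.02):

    - ``bg_threshold``: background where smoothed total signal falls below it;
    - ``af_threshold``: artifact where the AF channel exceeds it (bright
      bubbles, folds, red blood cells);
    - ``blur_threshold``: artifact where the local high-frequency energy of
      the summed channels (RMS of a high-pass response, locally smoothed)
      drops below this fraction of the image's own median non-background
      energy — out-of-focus patches lose even the sensor noise floor;
    - ``min_region_px``: speckles smaller than this are absorbed into their
      surroundings.
    """

    bg_threshold: float = 0.05
    af_threshold: float = 1.0
    blur_threshold: float = 0.6
    smooth_sigma: float = 4.0
    highpass_sigma: float = 1.0
    energy_sigma: float = 3.0
    min_region_px: int = 256
    af_channel: str = "AF"


class RuleBasedTissueClassifier:
    """Default image -> QualityMask classifier (see TissueClassifierParams)."""

    def __init__(self, params: TissueClassifierParams | None = None) -> None:
        self.params = params or TissueClassifierParams()

    def __call__(self, image: MultiplexImage) -> QualityMask:
        p = self.params
        total = image.pixels.sum(axis=2)
        total_s = ndimage.gaussian_filter(total, sigma=p.smooth_sigma)
        background = total_s < p.bg_threshold

        af = ndimage.gaussian_filter(image.channel(p.af_channel), sigma=p.smooth_sigma / 2)
        bright = af > p.af_threshold

        highpass = total - ndimage.gaussian_filter(total, sigma=p.highpass_sigma)
        energy = np.sqrt(ndimage.gaussian_filter(highpass**2, sigma=p.energy_sigma))
        # Normalise by the image's own in-focus energy so the rule is
        # exposure independent.
        ref = np.median(energy[~background]) if (~background).any() else 1.0
        blurred = (energy < p.blur_threshold * ref) & ~background

        labels = np.full(total.shape, LABEL_TISSUE, dtype=np.uint8)
        labels[background] = LABEL_BACKGROUND
        labels[bright | blurred] = LABEL_ARTIFACT

        labels = self._despeckle(labels, p.min_region_px)
        return QualityMask(labels=labels)

    @staticmethod
    def _despeckle(labels: np.ndarray, min_px: int) -> np.ndarray:
        if min_px <= 1:
            return labels
        out = labels.copy()
        for value in (LABEL_ARTIFACT, LABEL_BACKGROUND, LABEL_TISSUE):
            region = out == value
            comp, n = ndimage.label(region)
            if n == 0:
                continue
            sizes = np.bincount(comp.ravel())
            small = region & (sizes[comp] < min_px)
            if small.any():
                # Replace speckles by their nearest non-speckle label.
                _, (ir, ic) = ndimage.distance_transform_edt(small, return_indices=True)
                out[small] = out[ir[small], ic[small]]
        return out


def classify_tissue(
    image: MultiplexImage,
    params: TissueClassifierParams | None = None,
    classifier: Callable[[MultiplexImage], QualityMask] | None = None,
) -> QualityMask:
    """Label every pixel background / tissue / artifact.

    ``classifier`` may be any callable honouring the image -> QualityMask
    contract (e.g. a trained CNN); the default is the rule-based classifier.
    """
    if classifier is None:
        classifier = RuleBasedTissueClassifier(params)
    mask = classifier(image)
    if mask.shape != image.shape:
        raise ValueError("classifier returned a mask of the wrong shape")
    return mask


def evaluate_mask(predicted: QualityMask, truth: QualityMask) -> float:
    """Pixel-wise accuracy: fraction of pixels with identical labels."""
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {truth.shape}")
    return float(np.mean(predicted.labels == truth.labels))


def useful_tissue_fraction(mask: QualityMask) -> float:
    """Fraction of all pixels labelled tissue."""
    return float(np.mean(mask.labels == LABEL_TISSUE))


def filter_rois(
    masks: Mapping[str, QualityMask],
    threshold: float = DEFAULT_INCLUSION_THRESHOLD,
) -> pd.DataFrame:
    """Apply the inclusion gate: exclude ROIs with tissue fraction < threshold.

    The inequality is strict: an ROI at exactly the threshold is included.
    Returns a log with one row per ROI (roi_id, useful_fraction, included).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"inclusion threshold must be in [0, 1], got {threshold}")
    rows = []
    for roi_id, mask in masks.items():
        frac = useful_tissue_fraction(mask)
        rows.append({"roi_id": roi_id, "useful_fraction": frac, "included": frac >= threshold})
    return pd.DataFrame(rows, columns=["roi_id", "useful_fraction", "included"])


def filter_cells_by_mask(cells: pd.DataFrame, mask: QualityMask) -> pd.DataFrame:
    """Keep exactly the cells whose centroid pixel is labelled tissue.

    The centroid is mapped to its nearest pixel (rounded coordinates).
    Idempotent: filtering an already-filtered table is a no-op.
    """
    validate_cell_table(cells)
    if len(cells) == 0:
        return cells.copy()
    H, W = mask.shape
    xs = cells["x"].to_numpy(dtype=float)
    ys = cells["y"].to_numpy(dtype=float)
    oob = (xs < 0) | (xs >= W) | (ys < 0) | (ys >= H)
    if oob.any():
        bad = cells.loc[cells.index[oob], "cell_id"].tolist()[:5]
        raise ValueError(f"cell centroid(s) out of image bounds, e.g. cell_id {bad}")
    cols = np.clip(np.round(xs).astype(int), 0, W - 1)
    rows_ = np.clip(np.round(ys).astype(int), 0, H - 1)
    keep = mask.labels[rows_, cols] == LABEL_TISSUE
    return cells.loc[cells.index[keep]].copy()
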