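"""Hypothesised Interaction Distribution (HID) proximity statistics.

For a pair of cell phenotypes *i*, *j* the HID counts how often cells of the
two phenotypes occur close to each other in a sample.  With ``C_i`` the set of
phenotype-*i* cells, ``C_j`` the phenotype-*j* cells and ``x`` the cell
centroids,

    H(i, j) = |{ {k, l} : k in C_i, l in C_j, k != l, ||x_k - x_l||_2 < d }|

i.e. the number of unordered pairs of *distinct* cells, one from each
phenotype set, whose centroids lie strictly within distance *d* of each other.
The count is normalised by the total number of cells N in the sample
regardless of phenotype:

    h(i, j) = H(i, j) / N

``d`` is problem specific; 30 um (a neighbourhood of 2-3 cell diameters) is
the conventional radius for hypothesised immune-cell interactions.  Distances
are evaluated in pixel space without rounding ``d``, so the strict-< boundary
is not quantised.

A cell co-expressing both phenotypes belongs to both sets but never pairs
with itself (a zero-distance self pair carries no biological meaning); set
``allow_self_pairs=True`` on :func:`hid_count` to switch this off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .containers import phenotype_mask, validate_cell_table

__all__ = [
    "HIDQuery",
    "HIDResult",
    "microns_to_pixels",
    "hid_count",
    "hid_normalize",
    "patient_hid",
    "hid_sweep",
]


def microns_to_pixels(d_um: float, pixel_size_um: float) -> float:
    """Convert a physical distance to pixels (real-valued, no rounding).

    30 um at 0.495 um/px gives 60.606... px.
    """
    if d_um <= 0:
        raise ValueError(f"d_um must be positive, got {d_um}")
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be positive, got {pixel_size_um}")
    return d_um / pixel_size_um


@dataclass(frozen=True)
class HIDQuery:
    """A proximity query: phenotype pair and radius.

    ``d_um`` defaults to the conventional 30 um interaction neighbourhood.
    """

    phenotype_i: str
    phenotype_j: str
    d_um: float = 30.0
    pixel_size_um: float = 0.495

    def __post_init__(self) -> None:
        if self.d_um <= 0:
            raise ValueError("d_um must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def d_px(self) -> float:
        return microns_to_pixels(self.d_um, self.pixel_size_um)


@dataclass
class HIDResult:
    """Outcome of one HID query on one sample (typically one ROI).

    Attributes
    ----------
    H
        Number of proximal unordered phenotype-i/phenotype-j cell pairs.
    N
        Total number of cells in the sample, regardless of phenotype.
    h
        Normalised frequency ``H / N``.
    pairs
        Optional list of ``(cell_id_k, cell_id_l)`` tuples for the counted
        pairs (for drawing interaction overlays).
    """

    query: HIDQuery
    H: int
    N: int
    h: float
    pairs: list[tuple[object, object]] | None = None


def hid_count(
    cells: pd.DataFrame,
    query: HIDQuery,
    *,
    return_pairs: bool = False,
    allow_self_pairs: bool = False,
) -> HIDResult:
    """Count proximal phenotype pairs among the cells of one sample.

    Uses a k-d tree but is contractually equal to the O(n^2) double loop over
    all cross-phenotype pairs with strict ``< d`` Euclidean distance.

    Parameters
    ----------
    cells
        Cell table for one sample (one ROI); must contain ``cell_id``, ``x``,
        ``y`` and per-marker positivity columns.
    query
        Phenotype pair and radius.
    return_pairs
        Also return the list of counted ``(cell_id, cell_id)`` pairs.
    allow_self_pairs
        If True, a cell belonging to both phenotype sets pairs with itself.
    """
    validate_cell_table(cells)
    n_total = len(cells)
    mask_i = phenotype_mask(cells, query.phenotype_i).to_numpy()
    mask_j = phenotype_mask(cells, query.phenotype_j).to_numpy()
    if n_total == 0:
        raise ValueError("sample contains no cells; h = H/N is undefined for N = 0")

    xy = cells[["x", "y"]].to_numpy(dtype=float)
    ids = cells["cell_id"].to_numpy()
    d_px = query.d_px

    idx_i = np.flatnonzero(mask_i)
    idx_j = np.flatnonzero(mask_j)
    pair_ids = None
    if len(idx_i) == 0 or len(idx_j) == 0:
        H = 0
        pair_ids = [] if return_pairs else None
    elif return_pairs:
        pairs: set[tuple[int, int]] = set()
        tree_j = cKDTree(xy[idx_j])
        # query_ball_point is inclusive at the radius; re-check strictly.
        neighbours = tree_j.query_ball_point(xy[idx_i], r=d_px)
        for a, nb in zip(idx_i, neighbours):
            if not nb:
                continue
            cand = idx_j[nb]
            dist = np.hypot(xy[cand, 0] - xy[a, 0], xy[cand, 1] - xy[a, 1])
            for b, ok in zip(cand, dist < d_px):
                if not ok:
                    continue
                if a == b and not allow_self_pairs:
                    continue
                pairs.add((a, b) if a <= b else (b, a))
        H = len(pairs)
        pair_ids = sorted((ids[a], ids[b]) for a, b in pairs)
    else:
        H = _count_pairs(xy, mask_i, mask_j, d_px, allow_self_pairs)

    h = hid_normalize(H, n_total)
    return HIDResult(query=query, H=H, N=n_total, h=h, pairs=pair_ids)


def _count_pairs(
    xy: np.ndarray,
    mask_i: np.ndarray,
    mask_j: np.ndarray,
    d_px: float,
    allow_self_pairs: bool,
) -> int:
    """Vectorised unordered-pair count via k-d tree dual-tree counting.

    Decomposes the phenotype sets around their intersection A = I & J so every
    unordered cross pair is counted exactly once; ``count_neighbors`` is
    inclusive at the radius, so the largest float strictly below d enforces
    the strict inequality.
    """
    r_strict = np.nextafter(d_px, -np.inf)
    both = mask_i & mask_j
    only_i = mask_i & ~both
    only_j = mask_j & ~both

    def tree(sel: np.ndarray) -> cKDTree | None:
        return cKDTree(xy[sel]) if sel.any() else None

    t_i, t_j, t_a = tree(only_i), tree(only_j), tree(both)
    H = 0
    if t_i and t_j:
        H += t_i.count_neighbors(t_j, r_strict)
    if t_i and t_a:
        H += t_i.count_neighbors(t_a, r_strict)
    if t_a and t_j:
        H += t_a.count_neighbors(t_j, r_strict)
    if t_a:
        n_a = int(both.sum())
        within = t_a.count_neighbors(t_a, r_strict)  # ordered, incl. self pairs
        H += (within - n_a) // 2
        if allow_self_pairs:
            H += n_a
    return int(H)


def hid_normalize(H: int, N: int) -> float:
    """Normalise a raw proximity count by the total cell count: h = H / N."""
    if N <= 0:
        raise ValueError("N must be positive: a sample with no cells cannot contribute")
    if H < 0:
        raise ValueError("H must be non-negative")
    return H / N


_AGGREGATORS = ("median", "mean", "pooled")


def patient_hid(roi_results: Sequence[HIDResult], aggregator: str = "median") -> float:
    """Aggregate per-ROI HID results to a single per-patient scalar.

    ``median`` (default) takes the median of per-ROI ``h`` — consistent with
    the density convention of representing a patient by the median over ROIs.
    ``mean`` averages per-ROI ``h``; ``pooled`` computes ``sum(H) / sum(N)``
    as if the patient's ROIs were one sample.
    """
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"aggregator must be one of {_AGGREGATORS}, got {aggregator!r}")
    results = list(roi_results)
    if not results:
        raise ValueError("patient has no included ROIs; flag as missing upstream")
    hs = np.array([r.h for r in results], dtype=float)
    if aggregator == "median":
        return float(np.median(hs))
    if aggregator == "mean":
        return float(np.mean(hs))
    total_n = sum(r.N for r in results)
    return float(sum(r.H for r in results) / total_n)


def hid_sweep(
    cells: pd.DataFrame,
    phenotype_i: str,
    phenotype_j: str,
    d_um_values: Iterable[float],
    pixel_size_um: float = 0.495,
) -> pd.DataFrame:
    """Evaluate H and h over a grid of radii (H is non-decreasing in d)."""
    rows = []
    for d_um in d_um_values:
        res = hid_count(cells, HIDQuery(phenotype_i, phenotype_j, d_um, pixel_size_um))
        rows.append({"d_um": d_um, "H": res.H, "N": res.N, "h": res.h})
    return pd.DataFrame(rows)
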