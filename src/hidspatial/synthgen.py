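"""Synthetic cohorts, point patterns and rendered ROI images.

Real multiplex-immunofluorescence cohorts of this kind are rarely deposited,
so every downstream stage is exercised against a generator that reproduces
the statistical structure the analysis assumes:

* per patient, 10-20 ROIs of 1392 x 1040 px at 0.495 um/px;
* cells of exclusive marker classes (CD8+, CD8+PD-1+, CD68+, CD68+PD-L1+,
  PD-L1+, PD-1+, negative) placed either uniformly at random (complete
  spatial randomness) or with a parent-offspring clustered process that
  plants an excess of proximal cross-phenotype pairs;
* rendered 6-channel images (DAPI + 4 markers + autofluorescence) with
  bright autofluorescent blobs, locally blurred patches and background
  margins recorded in a ground-truth quality mask;
* survival times from an exponential proportional-hazards model whose
  log-hazard depends on the patient's true HID group and HPV status, with
  independent right censoring.

All randomness flows through numpy Generators seeded from ``SimConfig.seed``;
identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import (
    DEFAULT_CHANNELS,
    LABEL_ARTIFACT,
    LABEL_BACKGROUND,
    LABEL_TISSUE,
    MARKERS,
    MultiplexImage,
    QualityMask,
    flag_column,
    parse_phenotype,
)
from .hid import HIDQuery, HIDResult, hid_count, patient_hid

__all__ = [
    "SimConfig",
    "RoiGroundTruth",
    "CohortTruth",
    "generate_roi_points",
    "render_roi_image",
    "generate_cohort",
]

# Exclusive marker classes and their expected cells per full-size ROI.
# Fractions follow typical OPSCC median percentages (CD8 ~6.6%, CD8+PD-1+
# ~1.5%, CD68 ~3.1%, CD68+PD-L1+ ~1.1%, PD-L1 ~9%, PD-1 ~12.7%) applied to
# ~1200 cells per 0.355 mm^2 field.
DEFAULT_DENSITIES: dict[str, float] = {
    "CD8+": 61.0,
    "CD8+PD-1+": 18.0,
    "CD68+": 24.0,
    "CD68+PD-L1+": 13.0,
    "PD-L1+": 95.0,
    "PD-1+": 134.0,
    "negative": 855.0,
}

#: Offspring classes attracted towards PD-L1-expressing parent cells when
#: colocalization is planted (T-cell classes, mirroring the hypothesised
#: PD-1/PD-L1 and CD8/PD-L1 interactions).
DEFAULT_ATTRACTED = ("CD8+", "CD8+PD-1+", "PD-1+")
DEFAULT_PARENTS = ("PD-L1+", "CD68+PD-L1+")

#: HID features computed for the truth (phenotype set pairs).
DEFAULT_HID_FEATURES = (("CD8+", "PD-L1+"), ("PD-1+", "PD-L1+"))


def _class_flags(label: str) -> dict[str, bool]:
    markers = () if label == "negative" else parse_phenotype(label)
    return {flag_column(m): (m in markers) for m in MARKERS}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the reference OPSCC study design: 72 patients (~57%
    HPV positive), 10-20 randomly placed ROIs per patient at 1392 x 1040 px
    and 0.495 um/px, ~1200 cells per ROI, 40% right censoring and a baseline
    hazard of ln(2)/86.8 per month (median OS 86.8 months in the HPV-negative
    low-risk reference group; HPV positivity multiplies the hazard by 1/3.3).

    ``colocalization_strength`` is a cohort-level scale: each patient draws an
    individual strength s_p and, within a ROI, a fraction s_p / (1 + s_p) of
    each attracted T-cell class is placed within ``cluster_radius_um`` of a
    random PD-L1-expressing parent cell (parent-offspring / Thomas-like
    construction).  With ``strength_distribution='two_point'`` (default) the
    cohort is a mixture of a low-colocalization subpopulation (s_p = 0) and a
    high one (s_p = colocalization_strength) in equal proportion — the
    two-prognostic-group structure the stratified analyses look for;
    ``'uniform'`` draws s_p ~ Uniform(0, colocalization_strength) instead.
    Strength 0 gives complete spatial randomness for every patient.
    """

    n_patients: int = 72
    rois_per_patient: tuple[int, int] = (10, 20)
    image_shape: tuple[int, int] = (1040, 1392)  # (H, W) px
    pixel_size_um: float = 0.495
    phenotype_densities: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES)
    )
    colocalization_strength: float = 0.0
    strength_distribution: str = "two_point"  # 'two_point' | 'uniform'
    cluster_radius_um: float = 20.0
    attracted_classes: tuple[str, ...] = DEFAULT_ATTRACTED
    parent_classes: tuple[str, ...] = DEFAULT_PARENTS
    planted_log_hr: float = 0.0
    effect_stratum: str = "all"  # 'all' | 'hpv_negative' | 'hpv_positive'
    hpv_log_hr: float = -math.log(3.3)
    baseline_hazard: float = math.log(2.0) / 86.8  # events per month
    censoring_model: str = "administrative"  # 'administrative' | 'exponential'
    follow_up_months: tuple[float, float] = (85.2, 204.0)
    censoring_rate: float = 0.40
    hpv_positive_fraction: float = 41.0 / 72.0
    artifact_fraction: float = 0.0
    background_margin_px: int = 0
    planted_feature: tuple[str, str] = ("PD-1+", "PD-L1+")
    hid_features: tuple[tuple[str, str], ...] = DEFAULT_HID_FEATURES
    hid_d_um: float = 30.0
    hid_aggregator: str = "median"
    # Rendering: log-normal intensity parameters for marker-positive and
    # -negative cells (overlapping distributions, ~4.6 sigma apart).
    marker_pos_mu: float = math.log(3.0)
    marker_neg_mu: float = math.log(0.3)
    marker_sigma: float = 0.5
    nucleus_sigma_px: float = 3.0
    cell_radius_px: int = 8
    nucleus_radius_px: int = 4
    noise_sigma: float = 0.02
    tissue_af_level: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.rois_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("rois_per_patient must be an increasing range of positive ints")
        if min(self.image_shape) <= 0:
            raise ValueError("image_shape must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for name, lam in self.phenotype_densities.items():
            if lam < 0:
                raise ValueError(f"density for {name!r} must be >= 0")
        for frac_name in ("censoring_rate", "hpv_positive_fraction", "artifact_fraction"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must be in [0, 1], got {v}")
        if self.colocalization_strength < 0:
            raise ValueError("colocalization_strength must be >= 0")
        if self.effect_stratum not in ("all", "hpv_negative", "hpv_positive"):
            raise ValueError(f"unknown effect_stratum {self.effect_stratum!r}")
        if self.strength_distribution not in ("two_point", "uniform"):
            raise ValueError(f"unknown strength_distribution {self.strength_distribution!r}")
        if self.censoring_model not in ("administrative", "exponential"):
            raise ValueError(f"unknown censoring_model {self.censoring_model!r}")

    def scaled_to_shape(self, image_shape: tuple[int, int]) -> "SimConfig":
        """Copy of the config at a different ROI size, densities scaled by area.

        Keeps the expected cells-per-area constant so spatial statistics are
        comparable across problem sizes.
        """
        ratio = (image_shape[0] * image_shape[1]) / (self.image_shape[0] * self.image_shape[1])
        dens = {k: v * ratio for k, v in self.phenotype_densities.items()}
        return replace(self, image_shape=image_shape, phenotype_densities=dens)

    def design_threshold_raw(self) -> float:
        """Raw-intensity cut midway (geometric) between the planted positive
        and negative marker intensity medians; the threshold the rendered
        images are designed to be scored with (after percentile rescaling)."""
        return math.exp(0.5 * (self.marker_pos_mu + self.marker_neg_mu))


@dataclass
class RoiGroundTruth:
    """Planted truth for one ROI: the true cells and (once rendered) mask."""

    cells: pd.DataFrame
    mask: QualityMask | None = None


@dataclass
class CohortTruth:
    """Planted truth for a cohort: per-patient strengths, HID values, groups."""

    patients: pd.DataFrame  # patient_id, strength, true_hid_*, true_group, ...
    config: SimConfig


def _roi_rng(config: SimConfig, patient_index: int, roi_index: int) -> np.random.Generator:
    # Deterministic per-ROI stream independent of generation order.
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1, patient_index, roi_index))
    )


def generate_roi_points(
    config: SimConfig,
    patient_id: str,
    roi_id: str,
    rng: np.random.Generator,
    colocalization_strength: float | None = None,
) -> tuple[pd.DataFrame, RoiGroundTruth]:
    """Draw one ROI's cell point pattern.

    Cells of each exclusive class are Poisson in number.  With strength 0 all
    cells are uniform over the tissue region; otherwise a fraction
    ``s / (1 + s)`` of each attracted class is placed uniformly within
    ``cluster_radius_um`` of a randomly chosen parent cell.  Expected class
    counts match ``phenotype_densities`` either way.

    Returns the cell table (with true positivity flags and ``true_class``)
    and the ROI ground truth.
    """
    H, W = config.image_shape
    margin = config.background_margin_px
    x_lo, x_hi = float(margin), float(W)
    y_lo, y_hi = 0.0, float(H)
    area_px = (x_hi - x_lo) * (y_hi - y_lo)
    total_density = float(sum(config.phenotype_densities.values()))
    if total_density > 0.2 * area_px:
        raise ValueError(
            f"requested ~{total_density:.0f} cells in {area_px:.0f} tissue pixels; "
            "densities imply a physically impossible packing — reduce densities "
            "or enlarge the image"
        )
    s = config.colocalization_strength if colocalization_strength is None else colocalization_strength
    frac_attracted = s / (1.0 + s)
    radius_px = config.cluster_radius_um / config.pixel_size_um

    # Draw counts for every class first so counts are strength-independent.
    classes = list(config.phenotype_densities)
    counts = {c: int(rng.poisson(config.phenotype_densities[c])) for c in classes}

    def uniform_points(n: int) -> np.ndarray:
        pts = np.empty((n, 2))
        pts[:, 0] = rng.uniform(x_lo, x_hi, size=n)
        pts[:, 1] = rng.uniform(y_lo, y_hi, size=n)
        return pts

    placed: dict[str, np.ndarray] = {}
    # Parents (and every non-attracted class) are uniform.
    for c in classes:
        if c not in config.attracted_classes:
            placed[c] = uniform_points(counts[c])
    parents = [placed[c] for c in config.parent_classes if c in placed and len(placed[c])]
    parent_xy = np.vstack(parents) if parents else np.empty((0, 2))

    for c in classes:
        if c not in config.attracted_classes:
            continue
        n = counts[c]
        n_off = int(rng.binomial(n, frac_attracted)) if (n and len(parent_xy)) else 0
        pts = uniform_points(n)
        if n_off:
            centres = parent_xy[rng.integers(0, len(parent_xy), size=n_off)]
            # Uniform in a disc of radius cluster_radius_um, clipped to bounds.
            theta = rng.uniform(0.0, 2.0 * np.pi, size=n_off)
            r = radius_px * np.sqrt(rng.uniform(0.0, 1.0, size=n_off))
            off = centres + np.c_[r * np.cos(theta), r * np.sin(theta)]
            off[:, 0] = np.clip(off[:, 0], x_lo, np.nextafter(x_hi, -np.inf))
            off[:, 1] = np.clip(off[:, 1], y_lo, np.nextafter(y_hi, -np.inf))
            pts[:n_off] = off
        placed[c] = pts

    n_total = int(sum(counts.values()))
    xy = (
        np.vstack([placed[c] for c in classes if counts[c]])
        if n_total
        else np.empty((0, 2))
    )
    class_col = np.repeat(
        [c for c in classes if counts[c]], [counts[c] for c in classes if counts[c]]
    ) if n_total else np.array([], dtype=object)
    data: dict[str, object] = {
        "cell_id": np.arange(n_total),
        "roi_id": roi_id,
        "patient_id": patient_id,
        "x": xy[:, 0] if n_total else np.array([], dtype=float),
        "y": xy[:, 1] if n_total else np.array([], dtype=float),
        "true_class": class_col,
    }
    present = [c for c in classes if counts[c]]
    reps = [counts[c] for c in present]
    for m in MARKERS:
        col = flag_column(m)
        data[col] = (
            np.repeat([_class_flags(c)[col] for c in present], reps).astype(bool)
            if n_total
            else np.array([], dtype=bool)
        )
    cells = pd.DataFrame(data)
    return cells, RoiGroundTruth(cells=cells)


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _disk_offsets(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    sel = yy**2 + xx**2 <= radius**2
    return np.c_[yy[sel], xx[sel]]


def render_roi_image(
    cells: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[MultiplexImage, QualityMask]:
    """Render a 6-channel image and its ground-truth quality mask.

    DAPI carries a Gaussian nuclear blob per cell.  Each marker channel paints
    a cytoplasmic annulus around every cell, with amplitude drawn from the
    positive log-normal for cells carrying the marker flag and from the dimmer
    negative log-normal otherwise.  The AF channel carries a diffuse tissue
    level plus (optionally) bright artifact blobs; locally blurred patches and
    a background margin complete the artifact taxonomy (bubbles/folds show as
    bright AF, scanning errors as blur).  Everything painted as artifact or
    background is recorded in the truth mask.
    """
    H, W = config.image_shape
    n_chan = len(DEFAULT_CHANNELS)
    img = np.zeros((H, W, n_chan), dtype=float)
    truth = np.full((H, W), LABEL_TISSUE, dtype=np.uint8)

    margin = config.background_margin_px
    tissue = np.ones((H, W), dtype=bool)
    if margin > 0:
        tissue[:, :margin] = False
        truth[:, :margin] = LABEL_BACKGROUND

    n_cells = len(cells)
    if n_cells:
        xs = cells["x"].to_numpy(dtype=float)
        ys = cells["y"].to_numpy(dtype=float)
        if (xs < 0).any() or (xs >= W).any() or (ys < 0).any() or (ys >= H).any():
            raise ValueError("cell centroids must lie inside the image bounds")
        cols = np.clip(np.round(xs).astype(int), 0, W - 1)
        rows_ = np.clip(np.round(ys).astype(int), 0, H - 1)

        # DAPI: delta per nucleus, then one Gaussian pass; rescale so the
        # peak of an isolated nucleus equals its drawn amplitude.
        amp = rng.lognormal(mean=0.0, sigma=0.2, size=n_cells)
        dapi = np.zeros((H, W))
        np.add.at(dapi, (rows_, cols), amp)
        sig = config.nucleus_sigma_px
        dapi = ndimage.gaussian_filter(dapi, sigma=sig) * (2.0 * np.pi * sig**2)
        img[:, :, 0] = dapi

        # Markers: cytoplasmic annulus per cell.
        ann = _disk_offsets(config.cell_radius_px)
        ann = ann[np.hypot(ann[:, 0], ann[:, 1]) > config.nucleus_radius_px - 0.5]
        for ci, marker in enumerate(MARKERS, start=1):
            pos = cells[flag_column(marker)].to_numpy(dtype=bool)
            mu = np.where(pos, config.marker_pos_mu, config.marker_neg_mu)
            amps = rng.lognormal(mean=mu, sigma=config.marker_sigma)
            chan = np.zeros((H, W))
            rr = rows_[:, None] + ann[None, :, 0]
            cc = cols[:, None] + ann[None, :, 1]
            ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            vals = np.broadcast_to(amps[:, None], rr.shape)
            np.maximum.at(chan, (rr[ok], cc[ok]), vals[ok])
            img[:, :, ci] = ndimage.gaussian_filter(chan, sigma=0.8)

    # Diffuse tissue autofluorescence.
    img[:, :, 5][tissue] += config.tissue_af_level
    # Zero any signal painted into the background margin.
    img[~tissue] = 0.0

    # Sensor noise everywhere.
    img += rng.normal(0.0, config.noise_sigma, size=img.shape)

    # Artifacts: half the target area as bright AF blobs, half as blur patches.
    if config.artifact_fraction > 0:
        target = config.artifact_fraction * H * W
        painted = 0.0
        while painted < target / 2.0:  # AF blobs
            r = int(rng.integers(25, 60))
            cy = int(rng.integers(0, H))
            cx = int(rng.integers(margin, W))
            yy, xx = np.ogrid[:H, :W]
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            blob &= tissue
            img[:, :, 5][blob] = 5.0 * rng.lognormal(0.0, 0.1)
            truth[blob] = LABEL_ARTIFACT
            painted += blob.sum()
        painted = 0.0
        while painted < target / 2.0:  # blur patches
            side = int(rng.integers(70, 130))
            r0 = int(rng.integers(0, max(1, H - side)))
            c0 = int(rng.integers(margin, max(margin + 1, W - side)))
            sl = (slice(r0, min(H, r0 + side)), slice(c0, min(W, c0 + side)))
            for ci in range(n_chan):
                img[:, :, ci][sl] = ndimage.gaussian_filter(img[:, :, ci][sl], sigma=4.0)
            patch = np.zeros((H, W), dtype=bool)
            patch[sl] = True
            patch &= tissue
            truth[patch] = LABEL_ARTIFACT
            painted += patch.sum()

    np.clip(img, 0.0, None, out=img)
    return (
        MultiplexImage(pixels=img, channel_names=DEFAULT_CHANNELS, pixel_size_um=config.pixel_size_um),
        QualityMask(labels=truth),
    )


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

def true_roi_hid(cells: pd.DataFrame, config: SimConfig, feature: tuple[str, str]) -> HIDResult:
    """HID of the planted (true) point pattern for one ROI and feature."""
    query = HIDQuery(feature[0], feature[1], d_um=config.hid_d_um, pixel_size_um=config.pixel_size_um)
    return hid_count(cells, query)


def generate_cohort(
    config: SimConfig,
    *,
    keep_cells: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None, CohortTruth]:
    """Generate a full synthetic cohort.

    For every patient: draw HPV status, an individual colocalization strength,
    a number of ROIs and their point patterns; compute the true per-patient
    HID feature (aggregated over ROIs); split patients into high/low at the
    cohort mean of the planted feature; then draw survival from an exponential
    proportional-hazards model,

        lambda_p = baseline * exp(planted_log_hr * 1[high & stratum] +
                                  hpv_log_hr * 1[HPV+]),

    with independent exponential censoring calibrated to ``censoring_rate``.

    Returns ``(patients, cells, truth)``: the clinical/feature table, the
    concatenated per-ROI cell tables (None when ``keep_cells=False``) and the
    planted truth.
    """
    master = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    lo, hi = config.rois_per_patient

    patient_rows = []
    all_cells = []
    feat_names = [f"hid_{i}_{j}" for i, j in config.hid_features]
    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        hpv_pos = bool(master.uniform() < config.hpv_positive_fraction)
        if config.strength_distribution == "two_point":
            strength = config.colocalization_strength if master.uniform() < 0.5 else 0.0
        else:
            strength = float(master.uniform(0.0, config.colocalization_strength))
        n_rois = int(master.integers(lo, hi + 1))
        per_feature: dict[str, list[HIDResult]] = {f: [] for f in feat_names}
        for r in range(n_rois):
            rng = _roi_rng(config, p, r)
            roi_id = f"{pid}_R{r:02d}"
            cells, _ = generate_roi_points(config, pid, roi_id, rng, colocalization_strength=strength)
            if len(cells):
                for name, feature in zip(feat_names, config.hid_features):
                    per_feature[name].append(true_roi_hid(cells, config, feature))
            if keep_cells:
                all_cells.append(cells)
        row = {
            "patient_id": pid,
            "hpv_status": "positive" if hpv_pos else "negative",
            "n_rois": n_rois,
            "strength": strength,
        }
        for name in feat_names:
            row[name] = (
                patient_hid(per_feature[name], config.hid_aggregator) if per_feature[name] else np.nan
            )
        patient_rows.append(row)

    patients = pd.DataFrame(patient_rows)
    planted_name = f"hid_{config.planted_feature[0]}_{config.planted_feature[1]}"
    if planted_name not in patients.columns:
        raise ValueError(f"planted_feature {config.planted_feature} not among hid_features")
    # The high/low cut is the mean of the planted feature over the analysis
    # population the hazard applies to (the whole cohort, or the effect
    # stratum when the effect is planted in one HPV stratum only — matching
    # the subgroup-specific cut convention of the downstream analysis).
    if config.effect_stratum == "hpv_negative":
        cut_pop = patients.loc[patients["hpv_status"] == "negative", planted_name]
    elif config.effect_stratum == "hpv_positive":
        cut_pop = patients.loc[patients["hpv_status"] == "positive", planted_name]
    else:
        cut_pop = patients[planted_name]
    cut = cut_pop.mean()
    patients["true_group"] = np.where(patients[planted_name] > cut, "high", "low")

    # Survival draw (one stream, after all HID truth is fixed).
    surv_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    hpv = (patients["hpv_status"] == "positive").to_numpy()
    high = (patients["true_group"] == "high").to_numpy()
    in_stratum = np.ones(len(patients), dtype=bool)
    if config.effect_stratum == "hpv_negative":
        in_stratum = ~hpv
    elif config.effect_stratum == "hpv_positive":
        in_stratum = hpv
    log_haz = (
        math.log(config.baseline_hazard)
        + config.planted_log_hr * (high & in_stratum)
        + config.hpv_log_hr * hpv
    )
    lam = np.exp(log_haz)
    t_event = surv_rng.exponential(1.0 / lam)
    c = config.censoring_rate
    if c == 0:
        t_cens = np.full(len(patients), np.inf)
    elif config.censoring_model == "administrative":
        # Retrospective-cohort censoring: patients alive at data collection
        # are censored at their own follow-up time, uniform over the accrual
        # window.  Poor-prognosis strata therefore yield more events.
        lo_f, hi_f = config.follow_up_months
        t_cens = surv_rng.uniform(lo_f, hi_f, size=len(patients))
    else:
        # Proportional exponential censoring: every patient is censored with
        # probability censoring_rate exactly.
        lam_c = lam * c / (1.0 - c)
        t_cens = surv_rng.exponential(1.0 / lam_c)
    patients["time_months"] = np.minimum(t_event, t_cens)
    patients["event"] = (t_event <= t_cens).astype(int)

    cells_df = pd.concat(all_cells, ignore_index=True) if (keep_cells and all_cells) else None
    truth = CohortTruth(patients=patients.copy(), config=config)
    return patients, cells_df, truth
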