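"""End-to-end orchestration: simulate -> prep -> segment -> score -> hid -> stats.

Every stage writes its intermediate tables so each number in the final report
is traceable to the CSV that produced it, and a run manifest records the
config snapshot, seed, package versions and per-stage counts (ROIs in/out,
cells detected/retained, patients analysed).  Identical seeds give
byte-identical outputs.

Users whose cells were segmented by other software can enter after the
segmentation stage by supplying a cell table CSV directly (see
``run_pipeline(..., cells_csv=...)``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import MARKERS
from .cells import (
    MarkerThresholds,
    NucleusDetectionParams,
    apply_rescale,
    assign_phenotypes,
    detect_nuclei,
    expand_cells,
    fit_rescale,
    measure_intensities,
    score_positivity,
)
from .cohortstats import RunTablesConfig, run_tables
from .hid import HIDQuery, hid_count, patient_hid
from .imageprep import (
    DEFAULT_INCLUSION_THRESHOLD,
    TissueClassifierParams,
    classify_tissue,
    filter_cells_by_mask,
    filter_rois,
)
from .io import (
    read_multiplex_tiff,
    read_table,
    write_mask_tiff,
    write_multiplex_tiff,
    write_table,
)
from .synthgen import SimConfig, generate_cohort, render_roi_image


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    ``sim`` defines the synthetic cohort when simulating; for real data point
    ``data_dir`` at a directory of per-ROI multiplex TIFFs plus a
    ``clinical.csv``.  ``raw_thresholds`` are marker positivity cut-offs in
    raw intensity units, converted onto the rescaled [0, 1] scale with the
    fitted percentile bounds at scoring time.
    """

    out_dir: str = "results"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    data_dir: str | None = None
    pixel_size_um: float = 0.495
    d_um: tuple[float, ...] = (30.0,)
    rescale_percentiles: tuple[float, float] = (1.0, 99.0)
    inclusion_threshold: float = DEFAULT_INCLUSION_THRESHOLD
    raw_thresholds: dict | None = None
    hid_aggregator: str = "median"
    hid_features: tuple[tuple[str, str], ...] = (("CD8+", "PD-L1+"), ("PD-1+", "PD-L1+"))
    density_phenotypes: tuple[str, ...] = (
        "CD8+", "CD8+PD-1+", "CD68+", "CD68+PD-L1+", "PD-L1+", "PD-1+",
    )
    detection: NucleusDetectionParams = field(default_factory=NucleusDetectionParams)
    classifier: TissueClassifierParams = field(default_factory=TissueClassifierParams)
    tables: RunTablesConfig = field(default_factory=RunTablesConfig)
    overwrite: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.inclusion_threshold <= 1.0:
            raise ValueError(
                f"inclusion_threshold must be in [0, 1], got {self.inclusion_threshold}"
            )
        lo, hi = self.rescale_percentiles
        if not 0 <= lo < hi <= 100:
            raise ValueError("rescale_percentiles must satisfy 0 <= low < high <= 100")
        if any(d <= 0 for d in self.d_um):
            raise ValueError("all d_um values must be positive")
        if self.hid_aggregator not in ("median", "mean", "pooled"):
            raise ValueError(f"unknown hid aggregator {self.hid_aggregator!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_to_jsonable(self), sort_keys=True))


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def make_demo_data(out_dir: str | Path, seed: int = 0) -> SimConfig:
    """Write a small demonstration cohort (images + truth masks + clinical CSV).

    Six patients with four quarter-scale ROIs each — sized to run the full
    pipeline end-to-end in a few minutes on one CPU.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = SimConfig(
        n_patients=6,
        rois_per_patient=(4, 4),
        colocalization_strength=3.0,
        planted_log_hr=np.log(3.0),
        seed=seed,
    ).scaled_to_shape((260, 348))
    patients, cells, truth = generate_cohort(config)
    write_table(out / "clinical.csv", patients)
    write_table(out / "true_cells.csv", cells)
    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        n_rois = int(patients.loc[patients["patient_id"] == pid, "n_rois"].iloc[0])
        for r in range(n_rois):
            roi_id = f"{pid}_R{r:02d}"
            roi_cells = cells[cells["roi_id"] == roi_id]
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3, p, r)))
            image, mask = render_roi_image(roi_cells, config, rng)
            write_multiplex_tiff(out / f"{roi_id}.tiff", image)
            write_mask_tiff(out / f"{roi_id}_truthmask.tiff", mask)
    (out / "README.txt").write_text(
        "Synthetic demonstration cohort: per-ROI multiplex TIFFs (channel per page),\n"
        "ground-truth quality masks (*_truthmask.tiff), clinical.csv and the planted\n"
        "cell table true_cells.csv.\n"
    )
    return config


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    report_text: str


def run_pipeline(
    config: PipelineConfig,
    *,
    cells_csv: str | Path | None = None,
) -> PipelineResult:
    """Execute the full pipeline and write all artefacts under ``out_dir``.

    With ``config.data_dir`` unset, a synthetic cohort is simulated and
    rendered from ``config.sim``.  ``cells_csv`` skips imaging entirely and
    enters at the scored-cell stage (flags must already be present).
    """
    config.validate()
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()):
        if not config.overwrite:
            raise FileExistsError(
                f"results directory {out} is not empty; pass overwrite=True to rerun"
            )
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int | float] = {}
    stage = "setup"
    try:
        if cells_csv is not None:
            stage = "load-cells"
            cells = read_table(cells_csv)
            clinical = read_table(Path(config.data_dir) / "clinical.csv")
            counts["cells_scored"] = len(cells)
        else:
            if config.data_dir is None:
                stage = "simulate"
                data_dir = out / "simulated"
                data_dir.mkdir(exist_ok=True)
                _simulate(config, data_dir)
            else:
                data_dir = Path(config.data_dir)
            clinical = read_table(data_dir / "clinical.csv")
            roi_paths = sorted(
                p for p in data_dir.glob("*.tiff") if not p.stem.endswith("_truthmask")
            )
            counts["rois_scanned"] = len(roi_paths)

            stage = "prep"
            masks = {}
            for path in roi_paths:
                image = read_multiplex_tiff(path)
                mask = classify_tissue(image, params=config.classifier)
                write_mask_tiff(out / f"{path.stem}_mask.tiff", mask)
                masks[path.stem] = mask
            gate = filter_rois(masks, threshold=config.inclusion_threshold)
            write_table(out / "roi_inclusion.csv", gate)
            included = set(gate.loc[gate["included"], "roi_id"])
            counts["rois_included"] = len(included)
            counts["rois_excluded"] = int((~gate["included"]).sum())

            stage = "segment"
            all_cells = []
            marker_pixels: dict[str, list[np.ndarray]] = {m: [] for m in MARKERS}
            for path in roi_paths:
                roi_id = path.stem
                if roi_id not in included:
                    continue
                image = read_multiplex_tiff(path)
                mask = masks[roi_id]
                labels, _ = detect_nuclei(image.channel("DAPI"), config.detection)
                cell_labels = expand_cells(labels, 2.0, image.pixel_size_um)
                patient_id = roi_id.split("_R")[0]
                table = measure_intensities(image, labels, cell_labels, roi_id, patient_id)
                if len(table):
                    table = filter_cells_by_mask(table, mask)
                all_cells.append(table)
                for m in MARKERS:
                    marker_pixels[m].append(image.channel(m).ravel())
            cells = pd.concat([t for t in all_cells if len(t)], ignore_index=True)
            counts["cells_detected"] = int(sum(len(t) for t in all_cells))
            counts["cells_retained"] = len(cells)
            write_table(out / "cells_measured.csv", cells)

            stage = "score"
            lo_p, hi_p = config.rescale_percentiles
            bounds = fit_rescale(
                {m: np.concatenate(marker_pixels[m]) for m in MARKERS}, lo_p, hi_p
            )
            raw_thr = config.raw_thresholds or {
                m: config.sim.design_threshold_raw() for m in MARKERS
            }
            thresholds = MarkerThresholds(
                thresholds={
                    m: float(apply_rescale(raw_thr[m], bounds.bounds[m])) for m in MARKERS
                }
            )
            cells = score_positivity(cells, thresholds, bounds)
            cells = assign_phenotypes(cells)
            write_table(out / "cells_scored.csv", cells)

        stage = "hid"
        hid_rows = []
        for roi_id, grp in cells.groupby("roi_id", sort=True):
            for (pi, pj) in config.hid_features:
                for d_um in config.d_um:
                    q = HIDQuery(pi, pj, d_um=d_um, pixel_size_um=config.pixel_size_um)
                    res = hid_count(grp, q)
                    hid_rows.append(
                        {
                            "roi_id": roi_id,
                            "patient_id": grp["patient_id"].iloc[0],
                            "phenotype_i": pi,
                            "phenotype_j": pj,
                            "d_um": d_um,
                            "H": res.H,
                            "N": res.N,
                            "h": res.h,
                        }
                    )
        roi_hid = pd.DataFrame(hid_rows)
        write_table(out / "hid_per_roi.csv", roi_hid)

        stage = "aggregate"
        features = {}
        from .hid import HIDResult  # local import to keep module top tidy

        for (pi, pj) in config.hid_features:
            for d_um in config.d_um:
                sel = roi_hid[
                    (roi_hid["phenotype_i"] == pi)
                    & (roi_hid["phenotype_j"] == pj)
                    & (roi_hid["d_um"] == d_um)
                ]
                name = f"hid_{pi}_{pj}" + ("" if len(config.d_um) == 1 else f"_d{d_um:g}")
                features[name] = sel.groupby("patient_id").apply(
                    lambda g: patient_hid(
                        [
                            HIDResult(None, int(r.H), int(r.N), float(r.h))
                            for r in g.itertuples()
                        ],
                        config.hid_aggregator,
                    ),
                    include_groups=False,
                )
        from .cohortstats import patient_density, percent_positive

        for phen in config.density_phenotypes:
            per_roi = percent_positive(cells, phen)
            features[f"density_{phen}"] = patient_density(per_roi)
        features_df = pd.DataFrame(features)
        features_df.index.name = "patient_id"
        write_table(out / "patient_features.csv", features_df.reset_index())
        counts["patients_analysed"] = len(features_df)

        stage = "stats"
        report = run_tables(clinical, features_df, config.tables)
        write_table(out / "table_distributions.csv", report.density_table)
        write_table(out / "table_cox.csv", report.cox_table)
        km_dir = out / "km_curves"
        km_dir.mkdir(exist_ok=True)
        for key, frame in report.km_curves.items():
            safe = key.replace("|", "__").replace("/", "-")
            write_table(km_dir / f"{safe}.csv", frame)
        text = report.to_text()
        (out / "report.txt").write_text(text)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    config_snapshot = _to_jsonable(config)
    config_snapshot.pop("out_dir", None)  # run location, not an analysis parameter
    manifest = {
        "package": "hidspatial",
        "version": __version__,
        "seed": config.seed,
        "config": config_snapshot,
        "counts": counts,
        "n_tests": report.n_tests,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(out_dir=out, manifest=manifest, report_text=text)


def _simulate(config: PipelineConfig, data_dir: Path) -> None:
    sim = dataclasses.replace(config.sim, seed=config.seed)
    patients, cells, _ = generate_cohort(sim)
    write_table(data_dir / "clinical.csv", patients)
    write_table(data_dir / "true_cells.csv", cells)
    for p in range(sim.n_patients):
        pid = f"P{p:03d}"
        n_rois = int(patients.loc[patients["patient_id"] == pid, "n_rois"].iloc[0])
        for r in range(n_rois):
            roi_id = f"{pid}_R{r:02d}"
            rng = np.random.default_rng(np.random.SeedSequence(sim.seed, spawn_key=(3, p, r)))
            image, mask = render_roi_image(cells[cells["roi_id"] == roi_id], sim, rng)
            write_multiplex_tiff(data_dir / f"{roi_id}.tiff", image)
            write_mask_tiff(data_dir / f"{roi_id}_truthmask.tiff", mask)
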