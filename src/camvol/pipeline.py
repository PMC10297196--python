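"""End-to-end pipeline: simulate → extract → fit → evaluate → serial.

``run_pipeline`` ties the stages together on disk: it renders a synthetic
cohort (or consumes existing maps plus a truth table), extracts ROI
parameters from every probability map, joins them to ground truth by
nearest centroid, fits the six regression variants, writes the model
comparison and residual diagnostics, and classifies interval change on
the serial pairs with the best-RMSE model.  All randomness flows from
the single config seed; stage sub-seeds are derived from it so reruns
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .errors import ConfigurationError
from .evaluation import compare_models, correlation_summary, residual_table
from .extraction import (DEFAULT_CUTOFF, DEFAULT_MAX_ROIS,
                         DEFAULT_POSITIVITY_THRESHOLD, extract_rois,
                         image_positive, match_rois_to_nodules)
from .models import save_model
from .serial import (DEFAULT_REL_THRESHOLD, assess_serial,
                     assessments_to_frame, concordance)
from .synthetic import (CohortConfig, generate_cohort, render_probability_map,
                        truth_to_nodules)

log = logging.getLogger("camvol.pipeline")


@dataclass
class PipelineConfig:
    """Paths, thresholds and fitting plan for an end-to-end run."""

    out_dir: Path = Path("camvol_run")
    maps_dir: Optional[Path] = None       # None → simulate
    tables_dir: Optional[Path] = None
    cutoff: float = DEFAULT_CUTOFF
    positivity_threshold: float = DEFAULT_POSITIVITY_THRESHOLD
    max_rois: int = DEFAULT_MAX_ROIS
    degrees: Sequence[float] = (1, 1.5, 2)
    variable_sets: Sequence[str] = ("area", "area+prob")
    rel_threshold: float = DEFAULT_REL_THRESHOLD
    seed: int = 42
    write_maps: bool = True
    cohort: CohortConfig = None  # type: ignore[assignment]
    log_level: str = "INFO"

    def __post_init__(self):
        for name in ("cutoff", "positivity_threshold", "rel_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")
        if self.cohort is None:
            self.cohort = CohortConfig(seed=self.seed)
        self.out_dir = Path(self.out_dir)


def simulate_stage(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the cohort and, optionally, render/write its maps."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    truth, params = generate_cohort(config.cohort)
    cio.write_table(truth, out / "truth.csv")
    cio.write_table(params, out / "cohort_params.csv")
    if config.write_maps:
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        nodules = truth_to_nodules(truth)
        by_image: dict[str, list] = {}
        for nd in nodules:
            by_image.setdefault(nd.image_id, []).append(nd)
        spacing = {}
        # deterministic per-image stream for optional manufacturer bias
        root = np.random.default_rng(config.cohort.seed + 1)
        for image_id in sorted(by_image):
            pmap = render_probability_map(by_image[image_id], config.cohort,
                                          image_id=image_id, rng=root)
            cio.write_probability_map(pmap, maps_dir / f"{image_id}.png")
            spacing[image_id] = config.cohort.pixel_spacing_mm
        cio.write_spacing_sidecar(spacing, maps_dir)
        log.info("simulate: wrote %d maps to %s", len(by_image), maps_dir)
    return truth, params


def extract_stage(config: PipelineConfig, maps_dir: Path) -> pd.DataFrame:
    """Run ROI extraction over every map in a directory."""
    maps_dir = Path(maps_dir)
    if not maps_dir.is_dir():
        raise ConfigurationError(f"maps directory not found: {maps_dir}")
    spacing = cio.read_spacing_sidecar(maps_dir)
    rows = []
    for png in sorted(maps_dir.glob("*.png")):
        image_id = png.stem
        pmap = cio.read_probability_map(png, spacing[image_id], image_id)
        if not image_positive(pmap, config.positivity_threshold):
            continue
        for roi in extract_rois(pmap, config.cutoff, config.max_rois):
            rows.append(dict(image_id=image_id, roi_id=roi.roi_id,
                             pixel_count=roi.pixel_count, area_mm2=roi.area_mm2,
                             woap=roi.woap, prob_mean=roi.prob_mean,
                             prob_median=roi.prob_median, prob_max=roi.prob_max,
                             centroid_row=roi.centroid[0],
                             centroid_col=roi.centroid[1]))
    df = pd.DataFrame(rows, columns=["image_id", "roi_id", "pixel_count",
                                     "area_mm2", "woap", "prob_mean",
                                     "prob_median", "prob_max",
                                     "centroid_row", "centroid_col"])
    log.info("extract: %d ROIs from %d images", len(df), df.image_id.nunique())
    return df


def join_rois_to_truth(rois: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Match extracted ROIs to ground-truth nodules per image.

    The match gate is twice each nodule's contour radius (in pixels);
    unmatched ROIs are dropped from the joined table.
    """
    from .extraction import RoiParams

    spacing_col = truth.get("pixel_spacing_mm")
    out = []
    for image_id, grp in rois.groupby("image_id", sort=True):
        tr = truth[truth.image_id == image_id]
        if tr.empty:
            continue
        roi_objs = [RoiParams(
            roi_id=int(r.roi_id), pixel_count=int(r.pixel_count),
            area_mm2=float(r.area_mm2), woap=float(r.woap),
            prob_mean=float(r.prob_mean), prob_median=float(r.prob_median),
            prob_max=float(r.prob_max),
            centroid=(float(r.centroid_row), float(r.centroid_col)))
            for r in grp.itertuples()]
        centers = list(zip(tr.center_row, tr.center_col))
        # gate in pixels; contour radius is stored in mm
        spacing = float(spacing_col.iloc[0]) if spacing_col is not None else None
        gates = None
        if "contour_radius_mm" in tr.columns and spacing:
            gates = (2.0 * tr.contour_radius_mm / spacing).tolist()
        mapping = match_rois_to_nodules(roi_objs, centers,
                                        tr.nodule_id.tolist(), gates)
        for r in grp.itertuples():
            nodule_id = mapping.get(int(r.roi_id))
            if nodule_id is None:
                continue
            tr_row = tr[tr.nodule_id == nodule_id].iloc[0]
            out.append(dict(
                patient_id=tr_row.patient_id, image_id=image_id,
                nodule_id=nodule_id, timepoint=int(tr_row.timepoint),
                area_mm2=float(r.area_mm2), prob_mean=float(r.prob_mean),
                prob_max=float(r.prob_max), woap_mm2=float(r.woap),
                true_volume_mm3=float(tr_row.true_volume_mm3)))
    return pd.DataFrame(out)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns a dict of the main artifacts."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if config.maps_dir is None:
            truth, _ = simulate_stage(config)
            maps_dir = out / "maps"
        else:
            maps_dir = Path(config.maps_dir)
            if not maps_dir.is_dir():
                raise ConfigurationError(f"maps directory not found: {maps_dir}")
            tables = Path(config.tables_dir or maps_dir.parent)
            truth = cio.read_table(tables / "truth.csv")

        stage = "extract"
        # spacing travels with the truth table for the matching gate
        truth = truth.assign(pixel_spacing_mm=config.cohort.pixel_spacing_mm)
        rois = extract_stage(config, maps_dir)
        cio.write_table(rois, out / "rois.csv")

        stage = "join"
        cohort = join_rois_to_truth(rois, truth)
        cio.write_table(cohort, out / "cohort_extracted.csv")

        stage = "fit"
        comparison = compare_models(cohort, config.degrees,
                                    config.variable_sets, cohort_id="extracted")
        cio.write_table(comparison.table, out / "model_comparison.csv")
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        for (deg, vs), fr in comparison.fits.items():
            tag = f"deg{str(deg).replace('.', 'p')}_{'uni' if vs == 'area' else 'multi'}"
            save_model(fr.model, models_dir / f"{tag}.json")

        stage = "evaluate"
        cio.write_table(correlation_summary(cohort), out / "correlations.csv")
        best = comparison.fits[comparison.best()]
        resid = residual_table(best, cohort)
        cio.write_table(resid, out / "residuals.csv")

        stage = "serial"
        assessments = assess_serial(cohort, best.model, config.rel_threshold)
        frame = assessments_to_frame(assessments)
        cio.write_table(frame, out / "serial_assessments.csv")
        agreement, confusion = concordance(assessments)
        confusion.to_csv(out / "serial_confusion.csv")

        cio.write_manifest(
            out / "manifest.json",
            seed=config.seed,
            config={k: v for k, v in dataclasses.asdict(config).items()},
            n_rois=len(rois), n_matched=len(cohort),
            best_model=comparison.best(), serial_agreement=agreement)
    except Exception as exc:
        exc.add_note(f"pipeline stage: {stage}; output dir: {out}")
        raise
    return {"truth": truth, "rois": rois, "cohort": cohort,
            "comparison": comparison, "residuals": resid,
            "assessments": frame, "agreement": agreement,
            "confusion": confusion}
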