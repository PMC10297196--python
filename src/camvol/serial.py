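"""Interval-change assessment of nodules on serial images.

Baseline/follow-up observations of the same nodule are paired by
consecutive timepoint; the relative change of predicted volume is
classified as increased / decreased / no change against a symmetric
relative threshold (default ±25%, consistent with accepted volumetry
repeatability limits).  Applying the same threshold to the true volumes
gives a truth class, so the concordance between the two isolates
prediction error rather than threshold disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .errors import DataIntegrityError, DomainError
from .models import VolumeModel, predict_volume

DEFAULT_REL_THRESHOLD = 0.25

CLASSES = ("decreased", "no change", "increased")


@dataclass(frozen=True)
class SerialAssessment:
    """One baseline/follow-up comparison of a nodule."""

    patient_id: str
    nodule_id: str
    baseline_timepoint: int
    followup_timepoint: int
    baseline_volume_mm3: float
    followup_volume_mm3: float
    relative_change: float
    predicted_class: str
    truth_class: Optional[str] = None


def classify_change(v0: float, v1: float,
                    rel_threshold: float = DEFAULT_REL_THRESHOLD) -> str:
    """Three-class interval change from relative volume change v1/v0 − 1."""
    if not v0 > 0:
        raise DomainError("baseline volume must be positive")
    rel = v1 / v0 - 1.0
    if rel > rel_threshold:
        return "increased"
    if rel < -rel_threshold:
        return "decreased"
    return "no change"


def pair_serial(cohort: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-timepoint (baseline, follow-up) pairs per nodule.

    Input rows must carry ``patient_id``, ``nodule_id``, ``timepoint``.
    A nodule seen at timepoints 0, 1, 2 yields the pairs (0, 1) and
    (1, 2); nodules observed once yield none.  Duplicate
    (nodule, timepoint) rows raise ``DataIntegrityError``.
    """
    needed = {"patient_id", "nodule_id", "timepoint"}
    if not needed.issubset(cohort.columns):
        raise DataIntegrityError(f"cohort must have columns {sorted(needed)}")
    if cohort.duplicated(subset=["nodule_id", "timepoint"]).any():
        dups = cohort[cohort.duplicated(subset=["nodule_id", "timepoint"], keep=False)]
        raise DataIntegrityError(
            f"duplicate (nodule, timepoint) rows: {sorted(dups.nodule_id.unique())}")
    rows = []
    for nodule_id, grp in cohort.sort_values("timepoint").groupby("nodule_id", sort=True):
        recs = grp.to_dict("records")
        for base, follow in zip(recs, recs[1:]):
            row = {"patient_id": base["patient_id"], "nodule_id": nodule_id}
            for tag, rec in (("baseline", base), ("followup", follow)):
                for col, val in rec.items():
                    if col not in ("patient_id", "nodule_id"):
                        row[f"{tag}_{col}"] = val
            rows.append(row)
    return pd.DataFrame(rows)


def assess_serial(cohort: pd.DataFrame, model: VolumeModel,
                  rel_threshold: float = DEFAULT_REL_THRESHOLD
                  ) -> list[SerialAssessment]:
    """Predict volumes at both timepoints of every pair and classify change.

    The cohort must carry ``area_mm2`` and ``prob_mean``; when
    ``true_volume_mm3`` is present a truth class is attached.  Predicted
    volumes are floored at a small positive value before forming the
    ratio, since extrapolation can produce non-positive predictions.
    """
    pairs = pair_serial(cohort)
    out = []
    floor = 1.0  # mm³; keeps ratios defined for degenerate predictions
    for row in pairs.itertuples():
        v0 = max(float(predict_volume(model, row.baseline_area_mm2,
                                      row.baseline_prob_mean)), floor)
        v1 = max(float(predict_volume(model, row.followup_area_mm2,
                                      row.followup_prob_mean)), floor)
        truth = None
        if hasattr(row, "baseline_true_volume_mm3"):
            truth = classify_change(row.baseline_true_volume_mm3,
                                    row.followup_true_volume_mm3, rel_threshold)
        out.append(SerialAssessment(
            patient_id=row.patient_id, nodule_id=row.nodule_id,
            baseline_timepoint=int(row.baseline_timepoint),
            followup_timepoint=int(row.followup_timepoint),
            baseline_volume_mm3=v0, followup_volume_mm3=v1,
            relative_change=v1 / v0 - 1.0,
            predicted_class=classify_change(v0, v1, rel_threshold),
            truth_class=truth))
    return out


def concordance(assessments: Sequence[SerialAssessment]
                ) -> tuple[float, pd.DataFrame]:
    """Agreement fraction and 3×3 confusion table (truth × predicted)."""
    if not assessments:
        raise DomainError("concordance undefined for an empty assessment list")
    if any(a.truth_class is None for a in assessments):
        raise DataIntegrityError("every assessment needs a truth class")
    confusion = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    agree = 0
    for a in assessments:
        confusion.loc[a.truth_class, a.predicted_class] += 1
        agree += a.truth_class == a.predicted_class
    return agree / len(assessments), confusion


def assessments_to_frame(assessments: Sequence[SerialAssessment]) -> pd.DataFrame:
    """Flatten assessments to a writable table."""
    return pd.DataFrame([a.__dict__ for a in assessments])
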