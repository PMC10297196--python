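"""Cohort-level statistics: rank correlations, model comparison, residuals.

Reproduces the study-style analysis on a cohort table: Spearman
correlations among (area, mean probability, volume), training RMSE for
the six regression variants (degrees 1 / 1.5 / 2, univariable and
multivariable), and per-observation residual diagnostics including the
count of large-volume outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataIntegrityError, DomainError, SingularFitError
from .models import BasisSpec, FitResult, fit_ols, predict_volume

#: Residuals beyond this magnitude (mm³) are flagged as outliers in the
#: residual summary — the region where a handful of large masses separate
#: from the fitted surface.
OUTLIER_VOLUME_MM3 = 40000.0

DEFAULT_DEGREES = (1, 1.5, 2)
DEFAULT_VARIABLE_SETS = ("area", "area+prob")

REQUIRED_COLUMNS = ("area_mm2", "prob_mean", "true_volume_mm3")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Raises ``DomainError`` for vectors shorter than 3 or constant input,
    where the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("inputs must be equal-length 1D vectors")
    if x.size < 3:
        raise DomainError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DomainError("correlation undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class ModelComparison:
    """RMSE (and correlation summaries) per fitted variant."""

    table: pd.DataFrame
    fits: dict[tuple[float, str], FitResult]
    cohort_id: str = ""
    n_obs: int = 0

    def best(self) -> tuple[float, str]:
        """(degree, variables) of the variant with minimum RMSE."""
        ok = self.table.dropna(subset=["rmse_mm3"])
        row = ok.loc[ok["rmse_mm3"].idxmin()]
        return float(row["degree"]), str(row["variables"])


def _validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise DataIntegrityError(f"cohort table missing columns: {missing}")
    ok = cohort.dropna(subset=list(REQUIRED_COLUMNS))
    ok = ok[(ok.area_mm2 > 0) & (ok.prob_mean > 0) & (ok.prob_mean <= 1)]
    return ok


def compare_models(cohort: pd.DataFrame,
                   degrees: Iterable[float] = DEFAULT_DEGREES,
                   variable_sets: Iterable[str] = DEFAULT_VARIABLE_SETS,
                   cohort_id: str = "") -> ModelComparison:
    """Fit every requested (degree, variable-set) variant; report training RMSE.

    Alongside RMSE, each row carries the Spearman correlation between
    prediction and observed volume and the coefficient of determination
    of the fit (labelled ``r_spearman`` and ``r_square``; study-style
    reports mix the two, so both are emitted explicitly).  Singular fits
    are reported as rows with NaN rather than aborting the comparison.
    """
    data = _validate_cohort(cohort)
    if len(data) < 20:
        raise DataIntegrityError(
            f"need >= 20 valid nodules to compare models, got {len(data)}")
    a = data.area_mm2.to_numpy()
    p = data.prob_mean.to_numpy()
    v = data.true_volume_mm3.to_numpy()
    rows, fits = [], {}
    for deg in degrees:
        for vs in variable_sets:
            spec = BasisSpec(degree=deg, variables=vs)
            try:
                fr = fit_ols(a, p, v, spec)
            except SingularFitError as exc:
                rows.append(dict(degree=deg, variables=vs, n_terms=spec.n_terms,
                                 rmse_mm3=np.nan, r_spearman=np.nan,
                                 r_square=np.nan, error=str(exc)))
                continue
            pred = v - fr.residuals
            ss_res = float(np.sum(fr.residuals ** 2))
            ss_tot = float(np.sum((v - v.mean()) ** 2))
            rows.append(dict(
                degree=deg, variables=vs, n_terms=spec.n_terms,
                rmse_mm3=fr.rmse,
                r_spearman=spearman_rho(pred, v),
                r_square=1.0 - ss_res / ss_tot,
                error=""))
            fits[(deg, vs)] = fr
    table = pd.DataFrame(rows)
    return ModelComparison(table=table, fits=fits, cohort_id=cohort_id,
                           n_obs=len(data))


def correlation_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman and Pearson correlations of the three analysis
    variables (area, mean probability, true volume)."""
    data = _validate_cohort(cohort)
    pairs = [("area_mm2", "true_volume_mm3"),
             ("area_mm2", "prob_mean"),
             ("prob_mean", "true_volume_mm3")]
    rows = []
    for x, y in pairs:
        rows.append(dict(
            x=x, y=y,
            spearman=spearman_rho(data[x], data[y]),
            pearson=float(stats.pearsonr(data[x], data[y]).statistic),
            n=len(data)))
    return pd.DataFrame(rows)


def residual_table(fit: FitResult, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-observation residuals (observed − predicted, mm³) with identity.

    The returned frame carries an ``is_outlier`` flag for residual
    magnitudes above 40,000 mm³ and exposes the outlier count in
    ``.attrs['n_outliers']``.
    """
    data = _validate_cohort(cohort).reset_index(drop=True)
    if len(data) != fit.n_obs:
        raise DataIntegrityError(
            f"fit used {fit.n_obs} observations, cohort has {len(data)} valid rows")
    pred = predict_volume(fit.model, data.area_mm2.to_numpy(),
                          data.prob_mean.to_numpy())
    pred = np.atleast_1d(pred)
    out = data.copy()
    out["predicted_volume_mm3"] = pred
    out["residual_mm3"] = out.true_volume_mm3 - pred
    out["is_outlier"] = out.residual_mm3.abs() > OUTLIER_VOLUME_MM3
    out["is_large_volume"] = out.true_volume_mm3 > OUTLIER_VOLUME_MM3
    out.attrs["n_outliers"] = int(out.is_outlier.sum())
    out.attrs["n_large_volume"] = int(out.is_large_volume.sum())
    return out
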