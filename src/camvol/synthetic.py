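"""Synthetic cohort generator for probability-map volumetry.

Emulates the statistical structure of a serial chest-radiograph nodule
cohort: 147 images from 72 patients (104/25/18 images holding 1/2/3
nodules, 208 nodule observations in total), nodule volumes following a
right-skewed distribution with observed mean 9.37 and SD 11.69 cm^3 over
the range 0.11-70.4 cm^3, and serial baseline/follow-up pairs whose
volumes grow or shrink by a bounded multiplicative factor.

The forward model maps a true 3D volume to the two parameters the
regression models consume:

* the projected radius is the sphere-equivalent ``r = (3V / 4 pi)^(1/3)``;
* the observed 0.2-contour radius is ``r`` inflated by lognormal noise, so
  the CAM area is ``pi r^2`` times a lognormal factor;
* the peak probability is a saturating logistic of a latent score mixing
  standardized log-volume, a per-nodule "conspicuity" factor shared with
  the area noise, and independent noise;
* the region-mean probability follows from the Gaussian blob profile in
  closed form: ``(peak - c) / ln(peak / c)`` at cutoff ``c = 0.2``.

The shared conspicuity factor is what lets the generator reproduce the
observed correlation triple (area-volume ~ 0.58, area-probability ~ 0.73,
probability-volume ~ 0.22): probability tracks how strongly the network
responds, which co-varies with the rendered extent much more than with
the true volume.  Noise defaults were calibrated once against those three
rank-correlation targets and are frozen; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .errors import ConfigurationError, PlacementError
from .extraction import ProbabilityMap

#: Cutoff defining the ROI contour in the rendered maps.
CONTOUR_CUTOFF = 0.2

#: Weight of standardized log-volume in the probability latent score.
VOLUME_PROB_WEIGHT = 0.25

#: Saturating map from latent score to peak probability.
PEAK_LOGISTIC_SLOPE = 1.2
PEAK_LOGISTIC_OFFSET = 0.8

#: Observed contour radii are capped at this fraction of the shorter grid
#: edge: the detector this generator emulates is trained on lesions of
#: bounded size, and an uncapped lognormal noise tail would occasionally
#: produce blobs larger than the radiograph.
MAX_CONTOUR_FRACTION = 0.2

#: Ladder of separation factors tried during placement, strictest first.
#: Separation is factor * (sum of contour radii); 1.0 still guarantees
#: non-merging ROIs.
_SEPARATION_LADDER = (2.0, 1.5, 1.2, 1.0)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition, volume distribution and noise settings.

    Image counts, patient count, volume moments and the volume range
    default to the published cohort.  ``area_noise_sd``,
    ``prob_noise_sd`` and ``prob_vol_decoupling`` are dimensionless noise
    scales (lognormal SD of the area factor, SD of the independent
    probability noise, and SD of the shared conspicuity factor); their
    defaults are the frozen calibration against the three observed
    rank correlations.
    """

    n_images_by_nodule_count: Mapping[int, int] = field(
        default_factory=lambda: {1: 104, 2: 25, 3: 18})
    n_patients: int = 72
    volume_mean_mm3: float = 9370.0
    volume_sd_mm3: float = 11690.0
    volume_min_mm3: float = 110.0
    volume_max_mm3: float = 70400.0
    area_noise_sd: float = 0.635
    prob_noise_sd: float = 0.369
    prob_vol_decoupling: float = 0.992
    followup_fraction_increase: float = 0.5
    growth_factor_range: tuple[float, float] = (1.3, 2.5)
    shrink_factor_range: tuple[float, float] = (0.4, 0.77)
    manufacturer_bias_sd: float = 0.0
    grid_size: tuple[int, int] = (512, 512)
    pixel_spacing_mm: float = 0.7
    seed: int = 42

    def __post_init__(self):
        for k, v in self.n_images_by_nodule_count.items():
            if k < 1 or v < 0:
                raise ConfigurationError("image counts must be non-negative, keys >= 1")
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be non-negative")
        if not (0 < self.volume_min_mm3 < self.volume_mean_mm3 < self.volume_max_mm3):
            raise ConfigurationError(
                "volume bounds must satisfy 0 < min < mean < max")
        if self.volume_sd_mm3 <= 0:
            raise ConfigurationError("volume SD must be positive")
        for name in ("area_noise_sd", "prob_noise_sd", "prob_vol_decoupling"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not (0.0 <= self.followup_fraction_increase <= 1.0):
            raise ConfigurationError("followup_fraction_increase must be in [0, 1]")
        if not (self.growth_factor_range[0] > 1.0 and
                self.growth_factor_range[1] >= self.growth_factor_range[0]):
            raise ConfigurationError("growth factors must exceed 1.0")
        if not (0.0 < self.shrink_factor_range[0] <=
                self.shrink_factor_range[1] < 1.0):
            raise ConfigurationError("shrink factors must lie in (0, 1)")
        if self.pixel_spacing_mm <= 0:
            raise ConfigurationError("pixel spacing must be positive")

    @property
    def total_images(self) -> int:
        return sum(self.n_images_by_nodule_count.values())

    @property
    def total_nodule_observations(self) -> int:
        return sum(k * v for k, v in self.n_images_by_nodule_count.items())


@dataclass(frozen=True)
class NoduleTruth:
    """Ground truth for one nodule on one image.

    ``projected_radius_mm`` is the sphere-equivalent radius of the true
    volume; ``contour_radius_mm`` is the radius of the 0.2 iso-contour in
    the rendered map (projected radius times the square root of the area
    noise factor).  ``center`` is (row, col) in pixels.
    """

    nodule_id: str
    patient_id: str
    image_id: str
    timepoint: int
    center: tuple[float, float]
    true_volume_mm3: float
    projected_radius_mm: float
    peak_probability: float
    contour_radius_mm: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if not self.true_volume_mm3 > 0:
            raise ConfigurationError("true volume must be positive")
        expected = projected_radius(self.true_volume_mm3)
        if abs(self.projected_radius_mm - expected) > 1e-6 * expected:
            raise ConfigurationError(
                "projected radius inconsistent with volume "
                f"({self.projected_radius_mm} vs {expected})")
        if not (CONTOUR_CUTOFF < self.peak_probability <= 1.0):
            raise ConfigurationError(
                "peak probability must lie in (0.2, 1.0] for a renderable nodule")
        if self.contour_radius_mm is None:
            object.__setattr__(self, "contour_radius_mm", self.projected_radius_mm)


def projected_radius(volume_mm3) -> float:
    """Sphere-equivalent radius (mm) of a volume (mm^3): (3V / 4 pi)^(1/3)."""
    return (3.0 * np.asarray(volume_mm3) / (4.0 * math.pi)) ** (1.0 / 3.0)


def blob_mean_probability(peak, cutoff: float = CONTOUR_CUTOFF):
    """Mean probability over the supra-cutoff disc of a Gaussian blob.

    For a radial profile ``p(d) = peak * exp(-d^2 / 2 sigma^2)`` the mean
    over the region where p > cutoff is ``(peak - cutoff) / ln(peak / cutoff)``
    independently of sigma.
    """
    peak = np.asarray(peak, dtype=float)
    return (peak - cutoff) / np.log(peak / cutoff)


def lognormal_moment_match(mean: float, sd: float) -> tuple[float, float]:
    """Closed-form (mu, sigma) of the lognormal with given mean and SD.

    sigma^2 = ln(1 + (sd/mean)^2), mu = ln(mean) - sigma^2 / 2.
    """
    if mean <= 0 or sd <= 0:
        raise ConfigurationError("mean and sd must be positive")
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


def _truncated_lognormal_moments(mu, sigma, lo, hi):
    la, lb = math.log(lo), math.log(hi)
    z = stats.norm.cdf((lb - mu) / sigma) - stats.norm.cdf((la - mu) / sigma)
    if z <= 0:
        return np.nan, np.nan

    def raw(k):
        return math.exp(k * mu + 0.5 * k * k * sigma * sigma) * (
            stats.norm.cdf((lb - mu - k * sigma * sigma) / sigma)
            - stats.norm.cdf((la - mu - k * sigma * sigma) / sigma)) / z

    m1, m2 = raw(1), raw(2)
    return m1, math.sqrt(max(m2 - m1 * m1, 0.0))


def truncated_lognormal_params(mean: float, sd: float, lo: float, hi: float
                               ) -> tuple[float, float]:
    """(mu, sigma) such that the lognormal truncated to [lo, hi] has the
    requested mean and SD.

    The published cohort moments describe range-limited observations, so
    the generator matches the truncated distribution rather than the
    parent.  Solved numerically from the closed-form parent match as the
    starting point.
    """
    mu0, sig0 = lognormal_moment_match(mean, sd)

    def resid(p):
        m, s = _truncated_lognormal_moments(p[0], p[1], lo, hi)
        return [m - mean, s - sd]

    sol = optimize.root(resid, [mu0, sig0], method="hybr")
    if not sol.success:
        raise ConfigurationError(
            f"no truncated lognormal matches mean={mean}, sd={sd} on [{lo}, {hi}]")
    return float(sol.x[0]), float(sol.x[1])


def _draw_truncated_lognormal(rng, mu, sigma, lo, hi, n):
    # inverse-CDF sampling keeps draws deterministic per generator state
    la, lb = math.log(lo), math.log(hi)
    fa = stats.norm.cdf((la - mu) / sigma)
    fb = stats.norm.cdf((lb - mu) / sigma)
    u = rng.uniform(size=n)
    return np.exp(mu + sigma * stats.norm.ppf(fa + u * (fb - fa)))


def sample_volumes(config: CohortConfig, n: int,
                   rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw ``n`` nodule volumes (mm^3) from the calibrated truncated lognormal."""
    if n < 0:
        raise ConfigurationError("n must be non-negative")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n == 0:
        return np.empty(0)
    mu, sigma = truncated_lognormal_params(
        config.volume_mean_mm3, config.volume_sd_mm3,
        config.volume_min_mm3, config.volume_max_mm3)
    return _draw_truncated_lognormal(
        rng, mu, sigma, config.volume_min_mm3, config.volume_max_mm3, n)


def _partition_patients(config: CohortConfig) -> dict[int, list[int]]:
    """Assign each patient a nodule multiplicity and a number of serial images.

    Every patient contributes at least two timepoints of the same
    multiplicity; the per-multiplicity image totals match the config
    exactly.  Returns {multiplicity: [images for each patient]}.
    """
    counts = {k: v for k, v in sorted(config.n_images_by_nodule_count.items()) if v > 0}
    if not counts:
        return {}
    for k, v in counts.items():
        if v < 2:
            raise ConfigurationError(
                f"need at least 2 images of multiplicity {k} for a serial pair")
    patients = {k: v // 2 for k, v in counts.items()}
    total = sum(patients.values())
    if total < config.n_patients:
        raise ConfigurationError(
            f"{config.n_patients} patients cannot all have >= 2 of "
            f"{config.total_images} images")
    while total > config.n_patients:
        k = max(patients, key=lambda m: (patients[m], -m))
        if patients[k] <= 1:
            raise ConfigurationError("cannot reduce patients further")
        patients[k] -= 1
        total -= 1
    out: dict[int, list[int]] = {}
    for k, npat in patients.items():
        per = [2] * npat
        extra = counts[k] - 2 * npat
        i = 0
        while extra > 0:
            per[i % npat] += 1
            extra -= 1
            i += 1
        out[k] = per
    return out


def _place_centers(rng, contour_radii_mm, config) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping centers (row, col) in pixels.

    Required pairwise separation starts at 2x the sum of contour radii
    and is relaxed stepwise to 1x (still non-merging) if the grid cannot
    accommodate the stricter spacing.
    """
    nrow, ncol = config.grid_size
    sp = config.pixel_spacing_mm
    radii_px = np.asarray(contour_radii_mm) / sp
    for factor in _SEPARATION_LADDER:
        for _ in range(2000):
            centers = []
            ok = True
            for r in radii_px:
                margin = min(r + 2.0, (min(nrow, ncol) - 1) / 2.0)
                cr = rng.uniform(margin, nrow - 1 - margin)
                cc = rng.uniform(margin, ncol - 1 - margin)
                centers.append((cr, cc))
            for i in range(len(centers)):
                for j in range(i + 1, len(centers)):
                    d = math.hypot(centers[i][0] - centers[j][0],
                                   centers[i][1] - centers[j][1])
                    if d < factor * (radii_px[i] + radii_px[j]):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                return centers
    raise PlacementError(
        f"could not place {len(radii_px)} nodules with contour radii "
        f"{list(np.round(contour_radii_mm, 1))} mm on the grid")


def generate_cohort(config: CohortConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the cohort: (truth table, CAM parameter table).

    One row per nodule per image.  Follow-up volumes are baseline
    volumes times a multiplicative change factor (growth with
    probability ``followup_fraction_increase``, shrinkage otherwise);
    the per-nodule conspicuity factor persists across timepoints while
    the remaining noise is drawn per observation.
    """
    rng = np.random.default_rng(config.seed)
    plan = _partition_patients(config)
    cols_truth = ["nodule_id", "patient_id", "image_id", "timepoint",
                  "center_row", "center_col", "true_volume_mm3",
                  "projected_radius_mm", "contour_radius_mm", "peak_probability"]
    cols_par = ["patient_id", "image_id", "nodule_id", "timepoint",
                "area_mm2", "prob_mean", "prob_max", "woap_mm2",
                "true_volume_mm3"]
    if not plan:
        return pd.DataFrame(columns=cols_truth), pd.DataFrame(columns=cols_par)

    mu, sigma = truncated_lognormal_params(
        config.volume_mean_mm3, config.volume_sd_mm3,
        config.volume_min_mm3, config.volume_max_mm3)
    lam = config.prob_vol_decoupling
    truth_rows, par_rows = [], []
    pat_idx = img_idx = 0
    for mult in sorted(plan):
        for n_tp in plan[mult]:
            pat_idx += 1
            patient_id = f"pt{pat_idx:03d}"
            base_vol = _draw_truncated_lognormal(
                rng, mu, sigma, config.volume_min_mm3, config.volume_max_mm3, mult)
            conspicuity = rng.standard_normal(mult)
            vols = base_vol.copy()
            for tp in range(n_tp):
                if tp > 0:
                    grow = rng.uniform(size=mult) < config.followup_fraction_increase
                    lo_g, hi_g = config.growth_factor_range
                    lo_s, hi_s = config.shrink_factor_range
                    factors = np.where(grow,
                                       rng.uniform(lo_g, hi_g, size=mult),
                                       rng.uniform(lo_s, hi_s, size=mult))
                    vols = vols * factors
                img_idx += 1
                image_id = f"img{img_idx:04d}"
                r_proj = projected_radius(vols)
                eta = lam * conspicuity + config.area_noise_sd * rng.standard_normal(mult)
                r_cap = MAX_CONTOUR_FRACTION * min(config.grid_size) * config.pixel_spacing_mm
                r_contour = np.minimum(r_proj * np.exp(eta / 2.0), r_cap)
                area = math.pi * r_contour ** 2
                z_v = (np.log(vols) - mu) / sigma
                t_lat = (VOLUME_PROB_WEIGHT * z_v + lam * conspicuity
                         + config.prob_noise_sd * rng.standard_normal(mult))
                peak = CONTOUR_CUTOFF + (1.0 - CONTOUR_CUTOFF) * expit(
                    PEAK_LOGISTIC_SLOPE * t_lat + PEAK_LOGISTIC_OFFSET)
                p_mean = blob_mean_probability(peak)
                centers = _place_centers(rng, r_contour, config)
                for j in range(mult):
                    nodule_id = f"{patient_id}_n{j + 1}"
                    truth_rows.append(dict(
                        nodule_id=nodule_id, patient_id=patient_id,
                        image_id=image_id, timepoint=tp,
                        center_row=centers[j][0], center_col=centers[j][1],
                        true_volume_mm3=float(vols[j]),
                        projected_radius_mm=float(r_proj[j]),
                        contour_radius_mm=float(r_contour[j]),
                        peak_probability=float(peak[j])))
                    par_rows.append(dict(
                        patient_id=patient_id, image_id=image_id,
                        nodule_id=nodule_id, timepoint=tp,
                        area_mm2=float(area[j]), prob_mean=float(p_mean[j]),
                        prob_max=float(peak[j]),
                        woap_mm2=float(p_mean[j] * area[j]),
                        true_volume_mm3=float(vols[j])))
    return (pd.DataFrame(truth_rows, columns=cols_truth),
            pd.DataFrame(par_rows, columns=cols_par))


def truth_to_nodules(truth: pd.DataFrame) -> list[NoduleTruth]:
    """Convert truth-table rows to NoduleTruth records."""
    return [NoduleTruth(
        nodule_id=row.nodule_id, patient_id=row.patient_id,
        image_id=row.image_id, timepoint=int(row.timepoint),
        center=(float(row.center_row), float(row.center_col)),
        true_volume_mm3=float(row.true_volume_mm3),
        projected_radius_mm=float(row.projected_radius_mm),
        contour_radius_mm=float(row.contour_radius_mm),
        peak_probability=float(row.peak_probability))
        for row in truth.itertuples()]


def render_probability_map(nodules: Sequence[NoduleTruth], config: CohortConfig,
                           image_id: str = "",
                           rng: Optional[np.random.Generator] = None
                           ) -> ProbabilityMap:
    """Render nodules as Gaussian blobs on a zero background.

    Each blob has the nodule's peak probability at its center and is
    scaled so its 0.2 iso-contour radius equals ``contour_radius_mm``.
    Overlapping tails combine by maximum.  With
    ``config.manufacturer_bias_sd > 0`` a per-image lognormal factor
    multiplies all probabilities (clipped to 1), emulating
    cross-manufacturer intensity inconsistency; the default leaves it off.
    """
    nrow, ncol = config.grid_size
    values = np.zeros((nrow, ncol))
    sp = config.pixel_spacing_mm
    rows = np.arange(nrow)[:, None]
    cols = np.arange(ncol)[None, :]
    for nd in nodules:
        cr, cc = nd.center
        if not (0 <= cr < nrow and 0 <= cc < ncol):
            raise PlacementError(
                f"nodule {nd.nodule_id} center {nd.center} outside grid {config.grid_size}")
        r_c_px = nd.contour_radius_mm / sp
        sigma2 = r_c_px ** 2 / (2.0 * math.log(nd.peak_probability / CONTOUR_CUTOFF))
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        blob = nd.peak_probability * np.exp(-d2 / (2.0 * sigma2))
        np.maximum(values, blob, out=values)
    if config.manufacturer_bias_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        values = values * math.exp(
            config.manufacturer_bias_sd * rng.standard_normal())
    np.clip(values, 0.0, 1.0, out=values)
    return ProbabilityMap(values=values, pixel_spacing_mm=sp, image_id=image_id)
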