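"""Polynomial volume-prediction models.

The regression family maps the two CAM parameters — ROI area A (mm²) and
region-mean probability P — to a 3D nodule volume (mm³).  Three degrees
are supported:

* degree 1: affine in (A, P);
* degree 2: full quadratic in (A, P);
* degree 1.5, the "unit-adjusted" model: the complete cubic in (√A, √P),
  i.e. every monomial ``A^(i/2) P^(j/2)`` with ``i + j <= 3``.  The
  half-power ladder converts a 2D area (mm²) toward a 3D response (mm³),
  the same dimensional argument as V ∝ A^{3/2} for a projected sphere.

Each basis comes in a univariable (area-only) and a multivariable
(area + probability) variant.  Two published fitted models are exposed as
frozen constants: the degree-1 plane and the 10-term degree-1.5
multivariable equation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import ConfigurationError, DomainError, ModelError, SingularFitError

Degree = Literal[1, 1.5, 2]
VariableSet = Literal["area", "area+prob"]

SUPPORTED_DEGREES = (1, 1.5, 2)
VARIABLE_SETS = ("area", "area+prob")


@dataclass(frozen=True)
class BasisSpec:
    """Degree and variable set; fully determines the ordered term list."""

    degree: float
    variables: str = "area+prob"

    def __post_init__(self):
        if self.degree not in SUPPORTED_DEGREES:
            raise ConfigurationError(
                f"degree must be one of {SUPPORTED_DEGREES}, got {self.degree}")
        if self.variables not in VARIABLE_SETS:
            raise ConfigurationError(
                f"variables must be one of {VARIABLE_SETS}, got {self.variables}")

    @property
    def n_terms(self) -> int:
        return len(basis_terms(self))


def basis_terms(spec: BasisSpec) -> list[tuple[float, float]]:
    """Ordered (area_exponent, prob_exponent) pairs for a basis.

    Terms are listed by ascending total degree, higher area power first
    within a level; the constant term comes first.  For degree 1.5 the
    step is 0.5 (all monomials in √A, √P of total half-degree <= 3), for
    degrees 1 and 2 it is 1 (ordinary polynomials).
    """
    step = 0.5 if spec.degree == 1.5 else 1.0
    max_units = round(spec.degree / step)
    terms = []
    for total in range(max_units + 1):
        level = []
        for j in range(total + 1):
            i = total - j
            ea, ep = i * step, j * step
            if spec.variables == "area" and ep > 0:
                continue
            level.append((ea, ep))
        terms.extend(level)
    return terms


def design_matrix(area_mm2, prob_mean, spec: BasisSpec) -> np.ndarray:
    """Evaluate the basis on per-nodule parameter rows.

    One column per basis term, ``A^e1 * P^e2``, in ``basis_terms`` order.
    """
    a = np.atleast_1d(np.asarray(area_mm2, dtype=float))
    p = np.atleast_1d(np.asarray(prob_mean, dtype=float))
    if a.shape != p.shape:
        raise DomainError("area and probability arrays must have equal length")
    terms = basis_terms(spec)
    frac = any(ea != int(ea) or ep != int(ep) for ea, ep in terms)
    if np.any(a <= 0) and frac:
        raise DomainError("non-positive area with fractional exponents")
    if frac and np.any(p < 0):
        raise DomainError("negative probability with fractional exponents")
    cols = [a ** ea * p ** ep for ea, ep in terms]
    return np.column_stack(cols)


@dataclass(frozen=True)
class VolumeModel:
    """A basis plus its coefficient vector; predicts volume in mm³."""

    basis: BasisSpec
    coefficients: np.ndarray
    provenance: str = "fitted"

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float)
        n = self.basis.n_terms
        if c.ndim != 1 or c.size != n:
            raise ModelError(
                f"basis has {n} terms but {c.size} coefficients given")
        object.__setattr__(self, "coefficients", c)

    def to_dict(self) -> dict:
        return {
            "basis": {"degree": self.basis.degree,
                      "variables": self.basis.variables,
                      "terms": [list(t) for t in basis_terms(self.basis)]},
            "coefficients": self.coefficients.tolist(),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeModel":
        spec = BasisSpec(degree=d["basis"]["degree"],
                         variables=d["basis"]["variables"])
        stored = [tuple(t) for t in d["basis"].get("terms", [])]
        if stored and stored != basis_terms(spec):
            raise ModelError("stored term list does not match basis spec")
        return cls(basis=spec,
                   coefficients=np.asarray(d["coefficients"], dtype=float),
                   provenance=d.get("provenance", "fitted"))


def save_model(model: VolumeModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1) + "\n")


def load_model(path) -> VolumeModel:
    return VolumeModel.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares fit: model, residuals and training RMSE."""

    model: VolumeModel
    residuals: np.ndarray
    rmse: float
    n_obs: int


def fit_ols(area_mm2, prob_mean, volume_mm3, spec: BasisSpec) -> FitResult:
    """Ordinary least squares on the requested basis.

    Columns span many orders of magnitude (A^1.5 vs P^1.5), so each is
    scaled to unit maximum absolute value before the SVD-based solve and
    the coefficients are rescaled afterwards; the result is the exact
    least-squares solution.  Rank deficiency after scaling raises a
    ``SingularFitError`` naming the offending columns.
    """
    X = design_matrix(area_mm2, prob_mean, spec)
    y = np.asarray(volume_mm3, dtype=float)
    n, k = X.shape
    if y.shape != (n,):
        raise DomainError("response length does not match parameter rows")
    if n < k:
        raise SingularFitError(f"{n} observations cannot identify {k} coefficients")
    scale = np.abs(X).max(axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale
    rank = np.linalg.matrix_rank(Xs)
    if rank < k:
        # identify dependent columns via the small right singular vectors
        _, s, vt = np.linalg.svd(Xs, full_matrices=False)
        bad = np.unique(np.abs(vt[rank:]).argmax(axis=1))
        terms = basis_terms(spec)
        raise SingularFitError(
            "design matrix rank deficient; dependent columns: "
            + ", ".join(f"A^{terms[i][0]} P^{terms[i][1]}" for i in bad),
            columns=bad)
    beta_s, *_ = np.linalg.lstsq(Xs, y, rcond=None)
    beta = beta_s / scale
    resid = y - X @ beta
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    model = VolumeModel(basis=spec, coefficients=beta, provenance="fitted")
    return FitResult(model=model, residuals=resid, rmse=rmse, n_obs=n)


def predict_volume(model: VolumeModel, area_mm2, prob_mean=None,
                   clamp_zero: bool = False):
    """Predicted volume(s) in mm³ for the given CAM parameters.

    ``prob_mean`` may be omitted for area-only models.  Predictions are
    not clamped by default; ``clamp_zero=True`` floors them at 0 (cubic
    extrapolation can go negative outside the calibration range).
    """
    if prob_mean is None:
        if model.basis.variables != "area":
            raise ModelError("multivariable model requires prob_mean")
        prob_mean = np.ones_like(np.atleast_1d(np.asarray(area_mm2, dtype=float)))
    X = design_matrix(area_mm2, prob_mean, model.basis)
    pred = X @ model.coefficients
    if clamp_zero:
        pred = np.maximum(pred, 0.0)
    return pred if pred.size > 1 else float(pred[0])


# --- published fitted models -------------------------------------------------

#: Coefficients of the published degree-1 plane:
#: Volume = 14886.637214 + 29.288656 * Area - 57206.109259 * MeanProb  (mm³)
_PLANE_COEFFS = (14886.637214, 29.288656, -57206.109259)

#: Coefficients of the published 10-term degree-1.5 multivariable model, in
#: basis_terms order (1, √A, √P, A, √A√P, P, A^1.5, A√P, √A P, P^1.5).
_MODEL15_COEFFS = (
    578437.473048,      # intercept
    52661.249342,       # A^0.5
    -4508167.245662,    # P^0.5
    826.73901,          # A
    -217913.487756,     # A^0.5 P^0.5
    10744046.813175,    # P
    -3.158884,          # A^1.5
    -804.666435,        # A P^0.5
    191918.949126,      # A^0.5 P
    -7729391.963889,    # P^1.5
)


def published_plane() -> VolumeModel:
    """The published degree-1 multivariable plane fit."""
    return VolumeModel(basis=BasisSpec(degree=1, variables="area+prob"),
                       coefficients=np.array(_PLANE_COEFFS),
                       provenance="published")


def published_model_15() -> VolumeModel:
    """The published unit-adjusted (degree-1.5) multivariable model."""
    return VolumeModel(basis=BasisSpec(degree=1.5, variables="area+prob"),
                       coefficients=np.array(_MODEL15_COEFFS),
                       provenance="published")
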