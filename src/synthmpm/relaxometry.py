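"""Linear relaxometry model: fitting, map synthesis and scenario logic.

Under fast exchange the measured longitudinal relaxation rate is a weighted
sum of compartment relaxivities.  Replacing the macromolecular and iron
contributions by their imaging surrogates (MT saturation and R2*) gives the
voxel-wise linear model

    R1(r) = beta0 + beta1 * MT(r) + beta2 * R2*(r) + eps(r)

with three global scalar coefficients pooled over GM and WM and a residual
field eps(r) absorbing unspecified contributions, noise and — crucially —
inter-volume inconsistencies such as intra-scan motion.  Because the model is
over-determined once the coefficients are known, a corrupted map can be
replaced by its synthetic counterpart:

    R1_hat = beta0 + beta1 * MT + beta2 * R2*          (synthetic R1)
    MT_hat = (R1 - beta0 - beta2 * R2*) / beta1        (synthetic MT)

The regression is exposed as a scikit-learn style estimator
(:class:`LinearRelaxometry`); the module-level functions operate on
:class:`~synthmpm.volumes.QuantitativeMap` objects and wrap it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .volumes import QuantitativeMap, check_aligned

__all__ = [
    "LinearRelaxometry",
    "RelaxometryCoefficients",
    "ScenarioDecision",
    "fit_model",
    "plan_correction",
    "residual_map",
    "residual_percent",
    "synthesize_mt",
    "synthesize_r1",
]


@dataclass
class RelaxometryCoefficients:
    """Global model coefficients (beta0 s^-1, beta1 s^-1 per p.u., beta2
    dimensionless) plus fit diagnostics."""

    beta0: float
    beta1: float
    beta2: float
    provenance: str = "user_supplied"   # or "fitted_subject"
    n_voxels: int = None
    residual_std: float = None

    def __post_init__(self):
        for name in ("beta0", "beta1", "beta2"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.beta1 == 0:
            raise ValueError("beta1 must be nonzero (required to invert for MT)")

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2])

    def to_json(self, path):
        payload = {"beta0": self.beta0, "beta1": self.beta1, "beta2": self.beta2,
                   "provenance": self.provenance, "n_voxels": self.n_voxels,
                   "residual_std": self.residual_std}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**{k: payload.get(k) for k in
                      ("beta0", "beta1", "beta2", "provenance",
                       "n_voxels", "residual_std")})


class LinearRelaxometry(BaseEstimator, RegressorMixin):
    """Ordinary least-squares fit of R1 on [1, MTsat, R2*].

    scikit-learn style estimator: ``X`` has two columns (MT saturation in
    p.u., R2* in s^-1) and ``y`` is R1 in s^-1.  Plain OLS, no
    regularization.  A rank-deficient design (e.g. MT proportional to R2*)
    raises ``ValueError`` instead of silently returning a minimum-norm
    solution, since a unique coefficient triple is required for synthesis.

    Attributes
    ----------
    intercept_ : float
        beta0, the free-water relaxation rate (s^-1).
    coef_ : ndarray, shape (2,)
        (beta1, beta2), the macromolecular and iron surrogate weights.
    residual_std_ : float
        Standard deviation of the fit residuals (s^-1).
    n_voxels_ : int
        Number of voxels entering the fit.
    """

    def __init__(self, min_voxels: int = 10):
        self.min_voxels = min_voxels

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: MTsat (p.u.), R2* (s^-1)")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of voxels")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in the fitting data; mask them out")
        if X.shape[0] < self.min_voxels:
            raise ValueError(f"need at least {self.min_voxels} voxels, got {X.shape[0]}")

        design = np.column_stack([np.ones(X.shape[0]), X])
        coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < 3:
            raise ValueError(
                "rank-deficient design: MTsat and R2* are collinear over the mask")
        self.intercept_ = float(coef[0])
        self.coef_ = coef[1:]
        residuals = y - design @ coef
        self.residual_std_ = float(residuals.std())
        self.n_voxels_ = int(X.shape[0])
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    @property
    def coefficients_(self) -> RelaxometryCoefficients:
        check_is_fitted(self, "coef_")
        return RelaxometryCoefficients(
            beta0=self.intercept_, beta1=float(self.coef_[0]),
            beta2=float(self.coef_[1]), provenance="fitted_subject",
            n_voxels=self.n_voxels_, residual_std=self.residual_std_)


def fit_model(r1: QuantitativeMap, mt: QuantitativeMap, r2star: QuantitativeMap,
              mask) -> RelaxometryCoefficients:
    """Fit the linear relaxometry model over ``mask`` (typically GM+WM).

    Voxels flagged invalid in any input map are excluded.  Returns the
    coefficient triple with diagnostics; the residual field is available via
    :func:`residual_map`.
    """
    check_aligned(r1.values, mt.values, r2star.values, mask)
    sel = (np.asarray(mask, dtype=bool) & r1.valid & mt.valid & r2star.valid)
    X = np.column_stack([mt.values[sel], r2star.values[sel]])
    est = LinearRelaxometry().fit(X, r1.values[sel])
    return est.coefficients_


def synthesize_r1(mt: QuantitativeMap, r2star: QuantitativeMap,
                  coeffs: RelaxometryCoefficients) -> QuantitativeMap:
    """Synthetic R1 = beta0 + beta1*MT + beta2*R2* (residual-free)."""
    check_aligned(mt.values, r2star.values)
    values = coeffs.beta0 + coeffs.beta1 * mt.values + coeffs.beta2 * r2star.values
    return QuantitativeMap(values, kind="R1", provenance="synthetic",
                           aux={"valid": mt.valid & r2star.valid})


def synthesize_mt(r1: QuantitativeMap, r2star: QuantitativeMap,
                  coeffs: RelaxometryCoefficients) -> QuantitativeMap:
    """Synthetic MT = (R1 - beta0 - beta2*R2*) / beta1 (residual-free)."""
    check_aligned(r1.values, r2star.values)
    values = (r1.values - coeffs.beta0 - coeffs.beta2 * r2star.values) / coeffs.beta1
    return QuantitativeMap(values, kind="MTsat", provenance="synthetic",
                           aux={"valid": r1.valid & r2star.valid})


def residual_map(r1: QuantitativeMap, mt: QuantitativeMap,
                 r2star: QuantitativeMap,
                 coeffs: RelaxometryCoefficients) -> QuantitativeMap:
    """Model residual eps(r) = R1 - beta0 - beta1*MT - beta2*R2*.

    Inter-volume inconsistencies (e.g. motion in one weighted acquisition)
    concentrate here, which is what makes the synthetic maps artefact-free.
    """
    check_aligned(r1.values, mt.values, r2star.values)
    values = (r1.values - coeffs.beta0 - coeffs.beta1 * mt.values
              - coeffs.beta2 * r2star.values)
    return QuantitativeMap(values, kind="residual", provenance="measured",
                           aux={"valid": r1.valid & mt.valid & r2star.valid})


def residual_percent(measured: QuantitativeMap, synthetic: QuantitativeMap,
                     rel_tol: float = 1e-6) -> QuantitativeMap:
    """Measured-vs-synthetic difference as a percentage of their mean.

    100 * (measured - synthetic) / (0.5 * (measured + synthetic)); voxels
    whose mean is near zero (below ``rel_tol`` times the masked mean scale)
    are flagged invalid rather than returned as huge percentages.
    """
    check_aligned(measured.values, synthetic.values)
    mean = 0.5 * (measured.values + synthetic.values)
    scale = np.nanmax(np.abs(mean))
    ok = np.abs(mean) > rel_tol * (scale if scale > 0 else 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (measured.values - synthetic.values) / mean
    return QuantitativeMap(np.where(ok, pct, np.nan), kind="residual",
                           provenance="measured",
                           aux={"valid": ok & measured.valid & synthetic.valid})


@dataclass(frozen=True)
class ScenarioDecision:
    """Deterministic correction plan for a given set of corrupted contrasts."""

    corrupted: tuple
    action: str       # synthesize_MT | synthesize_R1 | limited_correction | none
    rationale: str


def plan_correction(corrupted) -> ScenarioDecision:
    """Map the set of motion-corrupted weighted volumes to a correction action.

    * {MT}: only the MT map is affected — synthesize MT (optimal case).
    * {T1}: the R1 map is most degraded — synthesize R1.
    * any set containing PD, or {T1, MT}: every map is corrupted to some
      degree, so only limited correction is possible.
    * empty set: nothing to do.
    """
    corrupted = {str(c) for c in corrupted}
    unknown = corrupted - {"PD", "T1", "MT"}
    if unknown:
        raise ValueError(f"unknown contrast labels: {sorted(unknown)}")
    key = tuple(sorted(corrupted))
    if key == ():
        return ScenarioDecision((), "none", "no corrupted volumes; nothing to correct")
    if key == ("MT",):
        return ScenarioDecision(key, "synthesize_MT",
                                "the MT-weighted volume contributes only to the MT "
                                "map; MT_hat from R1 and R2* is artefact-free")
    if key == ("T1",):
        return ScenarioDecision(key, "synthesize_R1",
                                "the T1-weighted volume degrades mainly the R1 map; "
                                "R1_hat from MT and R2* reduces the artefact")
    return ScenarioDecision(key, "limited_correction",
                            "the PD-weighted volume (or both T1- and MT-weighted) "
                            "feeds every map, so all maps carry artefact and only "
                            "limited correction is possible")
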