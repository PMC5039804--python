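"""Regression-based strategies for extending an existing logistic model.

Given a prior model fitted elsewhere (linear predictor ``lp0``) and a new
dataset in which the marker is observed, the strategies are:

* model revision with extension — refit everything plus the marker (``lp1``)
* recalibration — refit only intercept + overall slope on ``lp0`` (``lp2``)
* model revision with shrinkage — blend ``lp3 = c*lp1 + (1-c)*lp2`` where
  ``c`` is the heuristic shrinkage factor from the likelihood-ratio
  chi-square between the two fits
* recalibration with extension — fit on ``(lp0, m)`` only (``lp4``)

All fits are plain maximum likelihood on the marker set; prediction never
refits.  ``parameter_count`` gives the number of estimated parameters per
strategy for ``p`` existing predictors and ``m`` markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from riskupdate.errors import FitError
from riskupdate.logistic import FitMeta, LogisticModel, _expit, fit_logistic
from riskupdate.schema import Dataset, _MODEL_REGISTRY, register_model

#: exact strategy tags used in CLI/config and model files
STRATEGY_TAGS = (
    "original",
    "revision",
    "revision_shrinkage",
    "recalibration",
    "recalibration_extension",
    "clr",
    "clr_simple",
    "imputation",
)


@register_model("recalibration")
@dataclass
class RecalibratedModel:
    """Intercept + overall slope on the prior linear predictor (``lp2``).

    Prediction for a row depends on the row only through ``lp0``.
    """

    alpha_hat: float
    beta_overall: float
    prior: LogisticModel
    fit_meta: FitMeta = field(default_factory=FitMeta)

    @property
    def n_parameters(self) -> int:
        return 2

    def linear_predictor(self, data: Dataset) -> np.ndarray:
        return self.alpha_hat + self.beta_overall * self.prior.linear_predictor(data)

    def predict_probability(self, data: Dataset) -> np.ndarray:
        return _expit(self.linear_predictor(data))

    def to_dict(self) -> dict:
        return {
            "alpha_hat": float(self.alpha_hat),
            "beta_overall": float(self.beta_overall),
            "prior": self.prior.to_dict(),
            "fit_meta": self.fit_meta.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RecalibratedModel":
        return cls(
            alpha_hat=d["alpha_hat"],
            beta_overall=d["beta_overall"],
            prior=LogisticModel.from_dict(d["prior"]),
            fit_meta=FitMeta.from_dict(d["fit_meta"]),
        )


@register_model("recalibration_extension")
@dataclass
class ExtendedRecalibratedModel:
    """Recalibration plus a marker term (``lp4``); depends on a row only
    through ``(lp0, m)``."""

    alpha_hat: float
    beta_overall: float
    beta_marker: float
    prior: LogisticModel
    fit_meta: FitMeta = field(default_factory=FitMeta)

    @property
    def n_parameters(self) -> int:
        return 3

    def linear_predictor(self, data: Dataset) -> np.ndarray:
        m = data.require_complete_marker()
        return (
            self.alpha_hat
            + self.beta_overall * self.prior.linear_predictor(data)
            + self.beta_marker * m
        )

    def predict_probability(self, data: Dataset) -> np.ndarray:
        return _expit(self.linear_predictor(data))

    def to_dict(self) -> dict:
        return {
            "alpha_hat": float(self.alpha_hat),
            "beta_overall": float(self.beta_overall),
            "beta_marker": float(self.beta_marker),
            "prior": self.prior.to_dict(),
            "fit_meta": self.fit_meta.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExtendedRecalibratedModel":
        return cls(
            alpha_hat=d["alpha_hat"],
            beta_overall=d["beta_overall"],
            beta_marker=d["beta_marker"],
            prior=LogisticModel.from_dict(d["prior"]),
            fit_meta=FitMeta.from_dict(d["fit_meta"]),
        )


@register_model("revision_shrinkage")
@dataclass
class ShrunkenModel:
    """Revision blended toward recalibration: ``lp3 = c*lp1 + (1-c)*lp2``.

    Since ``lp2`` carries no marker term, the effective marker coefficient
    is ``c_hat * revised.beta_marker`` — shrunk toward zero.
    """

    revised: LogisticModel
    recalibrated: RecalibratedModel
    chi2: float
    df: int
    c_hat: float

    @property
    def n_parameters(self) -> int:
        # same fits as plain revision; the blend adds no free parameter
        return self.revised.n_parameters

    @property
    def converged(self) -> bool:
        return self.revised.fit_meta.converged and self.recalibrated.fit_meta.converged

    @property
    def effective_marker_coefficient(self) -> float:
        return self.c_hat * float(self.revised.beta_marker)

    def linear_predictor(self, data: Dataset) -> np.ndarray:
        lp1 = self.revised.linear_predictor(data)
        lp2 = self.recalibrated.linear_predictor(data)
        return self.c_hat * lp1 + (1.0 - self.c_hat) * lp2

    def predict_probability(self, data: Dataset) -> np.ndarray:
        return _expit(self.linear_predictor(data))

    def to_dict(self) -> dict:
        return {
            "revised": self.revised.to_dict(),
            "recalibrated": self.recalibrated.to_dict(),
            "chi2": float(self.chi2),
            "df": int(self.df),
            "c_hat": float(self.c_hat),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShrunkenModel":
        return cls(
            revised=LogisticModel.from_dict(d["revised"]),
            recalibrated=RecalibratedModel.from_dict(d["recalibrated"]),
            chi2=d["chi2"],
            df=d["df"],
            c_hat=d["c_hat"],
        )


# the plain revision fit serializes as a LogisticModel under its own tag
_MODEL_REGISTRY["revision"] = LogisticModel


def revise_with_extension(marker_set: Dataset) -> LogisticModel:
    """Refit all coefficients plus the marker on the marker set (``lp1``)."""
    model = fit_logistic(marker_set, include_marker=True)
    model.strategy_tag = "revision"
    return model


def recalibrate(prior: LogisticModel, marker_set: Dataset) -> RecalibratedModel:
    """Logistic fit of the outcome on ``lp0`` alone (2 parameters, ``lp2``)."""
    lp0 = prior.linear_predictor(marker_set)
    fit = fit_logistic(marker_set, fixed_covariate=lp0)
    return RecalibratedModel(
        alpha_hat=float(fit.alpha),
        beta_overall=float(fit.betas[0]),
        prior=prior,
        fit_meta=fit.fit_meta,
    )


def recalibrate_with_extension(
    prior: LogisticModel, marker_set: Dataset
) -> ExtendedRecalibratedModel:
    """Logistic fit of the outcome on ``(lp0, m)`` (3 parameters, ``lp4``)."""
    lp0 = prior.linear_predictor(marker_set)
    fit = fit_logistic(marker_set, include_marker=True, fixed_covariate=lp0)
    return ExtendedRecalibratedModel(
        alpha_hat=float(fit.alpha),
        beta_overall=float(fit.betas[0]),
        beta_marker=float(fit.beta_marker),
        prior=prior,
        fit_meta=fit.fit_meta,
    )


def heuristic_shrinkage_factor(chi2: float, df: int) -> float:
    """``max(chi2 - df, 0) / chi2``; 0 when ``chi2 <= df`` (and when chi2 = 0)."""
    if chi2 < 0:
        raise FitError(f"negative chi-square {chi2}; upstream fit is inconsistent")
    if df < 0:
        raise FitError(f"negative degrees of freedom {df}")
    if chi2 == 0:
        return 0.0
    return max(chi2 - df, 0.0) / chi2


def revise_with_shrinkage(
    prior: LogisticModel,
    marker_set: Dataset,
    df_override: int | None = None,
) -> ShrunkenModel:
    """Fit ``lp1`` and ``lp2`` on the marker set and blend them by the
    heuristic shrinkage factor.

    ``chi2`` is the -2LL difference between the recalibrated and revised
    fits (each at its own ML optimum on the marker set).  ``df`` defaults
    to the difference in fitted-parameter counts, ``(p + 2) - 2 = p``;
    ``df_override`` can force another accounting.
    """
    revised = revise_with_extension(marker_set)
    recalibrated = recalibrate(prior, marker_set)
    chi2 = recalibrated.fit_meta.minus_two_ll - revised.fit_meta.minus_two_ll
    both_ok = revised.fit_meta.converged and recalibrated.fit_meta.converged
    if chi2 < 0:
        # nested models: impossible at joint convergence — flag, clamp
        if both_ok:
            revised.fit_meta.converged = False
            revised.fit_meta.message = (
                f"recalibrated fit beat the revised fit by {-chi2:.3g} in -2LL; "
                "treating as convergence failure"
            )
        chi2 = 0.0
    df = revised.n_parameters - recalibrated.n_parameters if df_override is None else df_override
    c_hat = heuristic_shrinkage_factor(chi2, df)
    return ShrunkenModel(
        revised=revised,
        recalibrated=recalibrated,
        chi2=float(chi2),
        df=int(df),
        c_hat=float(c_hat),
    )


def parameter_count(strategy: str, p: int, m: int = 1) -> int:
    """Number of parameters a strategy estimates for ``p`` predictors and
    ``m`` markers."""
    if p < 1 or m < 1:
        raise ValueError("parameter_count requires p >= 1 and m >= 1")
    if strategy == "original":
        return 0
    if strategy in ("revision", "revision_shrinkage", "imputation"):
        return p + m + 1
    if strategy == "recalibration":
        return 2
    if strategy == "recalibration_extension":
        return m + 2
    if strategy == "clr":
        return 2 * m * (p + 1) + m * (m + 1)
    if strategy == "clr_simple":
        return m * (p + 2) + m * (m + 1) // 2
    raise ValueError(f"unknown strategy tag {strategy!r}")
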