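"""Combine-and-impute strategy for a systematically missing marker.

The development set (no marker) is stacked on the marker set, the missing
marker values are multiply imputed (10 draws by default) and the extended
logistic model is fitted per completed dataset; pooled coefficients are the
coordinate-wise means (Rubin's rules for point estimates).

Because only one variable is ever incomplete, chained equations reduce to a
single imputation model: a Bayesian linear regression of the marker on the
encoded predictors AND the outcome.  Draws are proper — regression
parameters are drawn from their approximate posterior (scaled inverse
chi-square variance, then normal coefficients) and residual noise is added
— never conditional means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from riskupdate.errors import FitError, SchemaError
from riskupdate.logistic import FitMeta, LogisticModel, fit_logistic
from riskupdate.schema import Dataset, register_model, stack


@register_model("imputation")
@dataclass
class PooledModel:
    """Per-imputation extended-model fits and their coordinate-wise mean."""

    per_imputation: list[np.ndarray]  # each: intercept, p slopes, marker coef
    pooled: LogisticModel
    n_imputations: int
    fit_meta: FitMeta = field(default_factory=FitMeta)

    @property
    def n_parameters(self) -> int:
        return self.pooled.n_parameters

    def linear_predictor(self, data: Dataset) -> np.ndarray:
        return self.pooled.linear_predictor(data)

    def predict_probability(self, data: Dataset) -> np.ndarray:
        return self.pooled.predict_probability(data)

    def to_dict(self) -> dict:
        return {
            "per_imputation": [[float(c) for c in v] for v in self.per_imputation],
            "pooled": self.pooled.to_dict(),
            "n_imputations": int(self.n_imputations),
            "fit_meta": self.fit_meta.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PooledModel":
        return cls(
            per_imputation=[np.asarray(v, dtype=float) for v in d["per_imputation"]],
            pooled=LogisticModel.from_dict(d["pooled"]),
            n_imputations=d["n_imputations"],
            fit_meta=FitMeta.from_dict(d["fit_meta"]),
        )


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def impute_marker(
    dev_set: Dataset,
    marker_set: Dataset,
    n_imputations: int = 10,
    seed: int | np.random.Generator = 0,
) -> list[Dataset]:
    """Stack the two sets and multiply impute the development rows' marker.

    The imputation model regresses the observed marker on intercept,
    encoded predictors and outcome in the marker set; each of the J
    completed datasets keeps every observed marker value untouched and
    fills development rows with proper Bayesian draws.
    """
    if dev_set.schema != marker_set.schema:
        raise SchemaError("development and marker sets must share one schema")
    if dev_set.has_marker:
        raise SchemaError("development set must not carry marker values")
    m = marker_set.require_complete_marker()
    rng = _as_rng(seed)

    n_obs = marker_set.n
    design = np.column_stack([np.ones(n_obs), marker_set.X, marker_set.y.astype(float)])
    k = design.shape[1]  # p + 2
    if n_obs < marker_set.p + 3:
        raise FitError(
            f"marker set has {n_obs} rows; need at least p + 3 = {marker_set.p + 3} "
            "to fit the imputation model"
        )
    coef, _, rank, _ = np.linalg.lstsq(design, m, rcond=None)
    if rank < k:
        raise FitError("imputation model design is rank-deficient")
    resid = m - design @ coef
    dof = n_obs - k
    if dof < 1:
        raise FitError("no residual degrees of freedom for the imputation model")
    sigma2_hat = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(design.T @ design)

    stacked = stack(dev_set, marker_set)
    dev_rows = ~stacked.marker_observed
    dev_design = np.column_stack(
        [np.ones(dev_set.n), dev_set.X, dev_set.y.astype(float)]
    )

    completed: list[Dataset] = []
    chol = np.linalg.cholesky(xtx_inv)
    for _ in range(n_imputations):
        sigma2_draw = sigma2_hat * dof / rng.chisquare(dof)
        sigma_draw = np.sqrt(sigma2_draw)
        coef_draw = coef + sigma_draw * (chol @ rng.standard_normal(k))
        imputed = dev_design @ coef_draw + sigma_draw * rng.standard_normal(dev_set.n)
        marker = stacked.marker.copy()
        marker[dev_rows] = imputed
        completed.append(
            Dataset(schema=stacked.schema, X=stacked.X, y=stacked.y, marker=marker)
        )
    return completed


def fit_pooled(completed: list[Dataset]) -> PooledModel:
    """Fit the extended logistic model per completed set and average."""
    if not completed:
        raise FitError("no completed datasets to pool")
    per: list[np.ndarray] = []
    convergence: list[bool] = []
    fits = []
    for ds in completed:
        fit = fit_logistic(ds, include_marker=True)
        fits.append(fit)
        per.append(np.concatenate([[fit.alpha], fit.betas, [fit.beta_marker]]))
        convergence.append(fit.fit_meta.converged)
    pooled_vec = np.mean(np.vstack(per), axis=0)
    all_ok = all(convergence)
    meta = FitMeta(
        converged=all_ok,
        minus_two_ll=float("nan"),
        n_obs=completed[0].n,
        message="" if all_ok else (
            f"{convergence.count(False)}/{len(convergence)} per-imputation fits unconverged"
        ),
    )
    pooled = LogisticModel(
        alpha=float(pooled_vec[0]),
        betas=pooled_vec[1:-1],
        beta_marker=float(pooled_vec[-1]),
        schema=completed[0].schema,
        fit_meta=meta,
    )
    return PooledModel(
        per_imputation=per,
        pooled=pooled,
        n_imputations=len(completed),
        fit_meta=meta,
    )


def fit_imputation(
    dev_set: Dataset,
    marker_set: Dataset,
    n_imputations: int = 10,
    seed: int | np.random.Generator = 0,
) -> PooledModel:
    """Full strategy: impute the stacked data, fit per imputation, pool."""
    return fit_pooled(impute_marker(dev_set, marker_set, n_imputations, seed))
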