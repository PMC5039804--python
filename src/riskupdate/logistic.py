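"""Maximum-likelihood logistic regression: the substrate of every strategy.

Fitting uses damped Newton iterations (IRLS with step-halving), converging
on relative change in -2 log-likelihood.  No penalization is applied
anywhere: the point of the downstream comparisons is to expose overfitting
of unpenalized small-sample fits, so ridge-style fallbacks are deliberately
absent.  Separation and collinearity are flagged on the fitted model, never
silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from riskupdate.errors import DegenerateOutcomeError, FitError, SchemaError
from riskupdate.schema import Dataset, PredictorSchema, register_model

#: clamp for probabilities entering log-likelihoods
PROB_FLOOR = 1e-12
#: relative -2LL change declaring convergence
_TOL = 1e-8
_MAX_ITER = 100


@dataclass
class FitMeta:
    """Diagnostics recorded for every fit; unconverged models are never
    silently used downstream."""

    converged: bool = True
    minus_two_ll: float = float("nan")
    n_obs: int = 0
    n_iter: int = 0
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "converged": bool(self.converged),
            "minus_two_ll": float(self.minus_two_ll),
            "n_obs": int(self.n_obs),
            "n_iter": int(self.n_iter),
            "message": self.message,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitMeta":
        return cls(
            converged=d["converged"],
            minus_two_ll=d["minus_two_ll"],
            n_obs=d["n_obs"],
            n_iter=d["n_iter"],
            message=d.get("message", ""),
        )


@register_model("original")
@dataclass
class LogisticModel:
    """Logistic model on the logit scale: ``lp = alpha + X @ betas (+ beta_marker * m)``."""

    alpha: float
    betas: np.ndarray
    beta_marker: float | None = None
    schema: PredictorSchema | None = None
    fit_meta: FitMeta = field(default_factory=FitMeta)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 1:
            raise SchemaError("betas must be a 1-d vector")
        if self.schema is not None and self.betas.shape[0] != self.schema.encoded_width:
            raise SchemaError(
                f"betas length {self.betas.shape[0]} != schema encoded width "
                f"{self.schema.encoded_width}"
            )

    @property
    def includes_marker(self) -> bool:
        return self.beta_marker is not None

    @property
    def n_parameters(self) -> int:
        """Fitted parameters: intercept + slopes (+ marker coefficient)."""
        return 1 + self.betas.shape[0] + (1 if self.includes_marker else 0)

    def linear_predictor(self, data: Dataset) -> np.ndarray:
        return linear_predictor(self, data)

    def predict_probability(self, data: Dataset) -> np.ndarray:
        return predict_probability(self, data)

    def to_dict(self) -> dict:
        return {
            "alpha": float(self.alpha),
            "betas": [float(b) for b in self.betas],
            "beta_marker": None if self.beta_marker is None else float(self.beta_marker),
            "schema": None if self.schema is None else self.schema.to_dict(),
            "fit_meta": self.fit_meta.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        return cls(
            alpha=d["alpha"],
            betas=np.asarray(d["betas"], dtype=float),
            beta_marker=d["beta_marker"],
            schema=None if d["schema"] is None else PredictorSchema.from_dict(d["schema"]),
            fit_meta=FitMeta.from_dict(d["fit_meta"]),
        )


#: probabilities returned by _expit stay strictly inside (0, 1)
_P_LO = 1e-300
_P_HI = float(np.nextafter(1.0, 0.0))


def _expit(lp: np.ndarray) -> np.ndarray:
    # piecewise-stable inverse logit, clamped strictly inside (0, 1)
    lp = np.asarray(lp, dtype=float)
    out = np.empty_like(lp)
    pos = lp >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-lp[pos]))
    e = np.exp(lp[~pos])
    out[~pos] = e / (1.0 + e)
    return np.clip(out, _P_LO, _P_HI)


def _neg2ll(y: np.ndarray, prob: np.ndarray) -> float:
    p = np.clip(prob, PROB_FLOOR, 1.0 - PROB_FLOOR)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def fit_logistic_design(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray | None = None,
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
) -> tuple[np.ndarray, FitMeta]:
    """ML logistic fit of ``y`` on design ``X`` (intercept prepended here).

    Returns the coefficient vector (intercept first) and fit diagnostics.
    Raises :class:`DegenerateOutcomeError` for single-class outcomes;
    separation / collinearity / iteration exhaustion are reported through
    ``FitMeta.converged`` with a diagnostic message, not exceptions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if X.ndim != 2 or X.shape[0] != n:
        raise FitError("design/outcome shape mismatch")
    events = y.sum()
    if events == 0 or events == n:
        raise DegenerateOutcomeError(
            f"outcome is all {'events' if events else 'non-events'}; logistic fit undefined"
        )
    design = np.column_stack([np.ones(n), X])
    k = design.shape[1]
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    message = ""
    rank = np.linalg.matrix_rank(design)
    rank_deficient = rank < k
    if rank_deficient:
        message = f"collinear design: rank {rank} < {k} columns"

    coef = np.zeros(k)
    coef[0] = np.log(events / (n - events))  # start at the marginal log-odds
    lp = design @ coef + off
    prob = _expit(lp)
    dev = _neg2ll(y, prob)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = prob * (1.0 - prob)
        w = np.maximum(w, 1e-10)
        grad = design.T @ (y - prob)
        hess = (design * w[:, None]).T @ design
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # damped update: halve the step until -2LL does not increase
        scale = 1.0
        for _ in range(30):
            cand = coef + scale * step
            cand_dev = _neg2ll(y, _expit(design @ cand + off))
            if cand_dev <= dev + 1e-12:
                break
            scale *= 0.5
        else:
            message = message or "step-halving failed to decrease the deviance"
            break
        coef = cand
        new_dev = cand_dev
        lp = design @ coef + off
        prob = _expit(lp)
        if abs(dev - new_dev) / (0.1 + abs(new_dev)) < tol:
            dev = new_dev
            converged = True
            break
        dev = new_dev
    else:
        message = message or f"no convergence within {max_iter} iterations"

    # complete/quasi-complete separation: perfectly classified extreme rows
    extreme = np.abs(lp) > 20.0
    if extreme.any():
        agree = np.all((prob[extreme] > 0.5) == (y[extreme] > 0.5))
        if agree:
            converged = False
            message = "complete or quasi-complete separation detected"
    if rank_deficient:
        converged = False

    meta = FitMeta(
        converged=converged,
        minus_two_ll=dev,
        n_obs=n,
        n_iter=it,
        message=message,
    )
    return coef, meta


def fit_logistic(
    data: Dataset,
    include_marker: bool = False,
    offset: np.ndarray | None = None,
    fixed_covariate: np.ndarray | None = None,
) -> LogisticModel:
    """Fit a logistic model to a dataset.

    By default the design is the schema's encoded predictors; with
    ``include_marker`` the (fully observed) marker is appended as one more
    column.  ``fixed_covariate`` replaces the schema predictors by a single
    given column — the mechanism used to regress the outcome on a prior
    model's linear predictor (recalibration).  ``offset`` is added to the
    linear predictor without being estimated.
    """
    cols = []
    schema: PredictorSchema | None
    if fixed_covariate is not None:
        fc = np.asarray(fixed_covariate, dtype=float)
        if fc.shape != (data.n,):
            raise SchemaError("fixed_covariate length must match dataset rows")
        cols.append(fc[:, None])
        schema = None
    else:
        cols.append(data.X)
        schema = data.schema
    if include_marker:
        cols.append(data.require_complete_marker()[:, None])
    design = np.hstack(cols)

    coef, meta = fit_logistic_design(design, data.y, offset=offset)
    n_base = design.shape[1] - (1 if include_marker else 0)
    return LogisticModel(
        alpha=float(coef[0]),
        betas=coef[1 : 1 + n_base],
        beta_marker=float(coef[-1]) if include_marker else None,
        schema=schema,
        fit_meta=meta,
    )


def _check_compat(model: LogisticModel, data: Dataset) -> None:
    if model.schema is not None and model.schema != data.schema:
        raise SchemaError("model and dataset schemas differ")
    if model.betas.shape[0] != data.p:
        raise SchemaError(
            f"model expects {model.betas.shape[0]} encoded predictors, data has {data.p}"
        )


def linear_predictor(model: LogisticModel, data: Dataset) -> np.ndarray:
    """Per-row log-odds ``alpha + X @ betas (+ beta_marker * m)``."""
    _check_compat(model, data)
    lp = model.alpha + data.X @ model.betas
    if model.includes_marker:
        lp = lp + model.beta_marker * data.require_complete_marker()
    return lp


def predict_probability(model: LogisticModel, data: Dataset) -> np.ndarray:
    """Inverse-logit of the linear predictor; values strictly inside (0, 1)."""
    return _expit(linear_predictor(model, data))


def minus_two_log_likelihood(model, data: Dataset) -> float:
    """-2 sum[y log p + (1-y) log(1-p)], probabilities clamped at 1e-12."""
    prob = model.predict_probability(data)
    return _neg2ll(data.y, prob)
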