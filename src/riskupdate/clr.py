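"""Bayes-rule updating of prior predictions with conditional likelihood ratios.

The marker's distribution given the existing predictors is modelled as
normal, with means from per-outcome linear regressions of the marker on the
predictors.  The likelihood ratio

    LR = phi(m; mu_case(x), sigma_case) / phi(m; mu_control(x), sigma_control)

multiplies the prior odds ``exp(lp0)`` to give posterior odds.  The full
variant ("clr") fits separate regressions in the event and non-event
groups; the parsimonious variant ("clr_simple") fits one regression with an
outcome indicator, so the two conditional means differ only by the
indicator coefficient and share one residual SD.  All density arithmetic is
done in log space.  The prior model's coefficients are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from riskupdate.errors import FitError
from riskupdate.logistic import FitMeta, LogisticModel, _expit
from riskupdate.schema import Dataset, register_model

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class ConditionalMarkerModel:
    """Linear regression of the marker on the encoded predictors.

    ``coef`` holds the intercept followed by the p slopes; ``residual_sd``
    is the (unbiased, n - k denominator) standard deviation of the OLS
    residuals and must be strictly positive.
    """

    coef: np.ndarray
    residual_sd: float

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.ndim != 1 or self.coef.shape[0] < 1:
            raise FitError("conditional marker model needs intercept + slopes")
        if not self.residual_sd > 0:
            raise FitError(f"residual SD must be > 0, got {self.residual_sd}")

    def mean(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.coef[0] + X @ self.coef[1:]

    def log_density(self, m: np.ndarray, X: np.ndarray) -> np.ndarray:
        mu = self.mean(X)
        z = (np.asarray(m, dtype=float) - mu) / self.residual_sd
        return -np.log(self.residual_sd) - _LOG_SQRT_2PI - 0.5 * z * z

    def to_dict(self) -> dict:
        return {"coef": [float(c) for c in self.coef], "residual_sd": float(self.residual_sd)}

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionalMarkerModel":
        return cls(coef=np.asarray(d["coef"], dtype=float), residual_sd=d["residual_sd"])


@register_model("clr")
@dataclass
class ClrUpdater:
    """Prior logistic model plus conditional marker models for Bayes updating."""

    prior: LogisticModel
    variant: str  # "full" | "simple"
    case_model: ConditionalMarkerModel
    control_model: ConditionalMarkerModel
    fit_meta: FitMeta = field(default_factory=FitMeta)

    def __post_init__(self) -> None:
        if self.variant not in ("full", "simple"):
            raise FitError(f"unknown CLR variant {self.variant!r}")
        if self.case_model.coef.shape != self.control_model.coef.shape:
            raise FitError("case and control mean models must have equal width")
        if self.variant == "simple":
            if self.case_model.residual_sd != self.control_model.residual_sd:
                raise FitError("simple variant requires one shared residual SD")
            if not np.array_equal(self.case_model.coef[1:], self.control_model.coef[1:]):
                raise FitError("simple variant requires shared predictor slopes")

    @property
    def n_parameters(self) -> int:
        """Estimated parameters: 2(p+1) + 2 for full, (p+2) + 1 for simple."""
        p = self.case_model.coef.shape[0] - 1
        if self.variant == "full":
            return 2 * (p + 1) + 2
        return (p + 2) + 1

    @property
    def indicator_coefficient(self) -> float:
        """Simple variant's outcome-indicator coefficient (case/control mean shift)."""
        return float(self.case_model.coef[0] - self.control_model.coef[0])

    def log_likelihood_ratio(self, X: np.ndarray, m: np.ndarray) -> np.ndarray:
        # clipped so exp() stays strictly positive and finite at extreme markers
        raw = self.case_model.log_density(m, X) - self.control_model.log_density(m, X)
        return np.clip(raw, -700.0, 700.0)

    def linear_predictor(self, data: Dataset) -> np.ndarray:
        """Posterior log-odds ``lp0 + log LR`` per row."""
        m = data.require_complete_marker()
        return self.prior.linear_predictor(data) + self.log_likelihood_ratio(data.X, m)

    def predict_probability(self, data: Dataset) -> np.ndarray:
        return _expit(self.linear_predictor(data))

    def to_dict(self) -> dict:
        doc = {
            "prior": self.prior.to_dict(),
            "variant": self.variant,
            "fit_meta": self.fit_meta.to_dict(),
        }
        if self.variant == "full":
            doc["case_model"] = self.case_model.to_dict()
            doc["control_model"] = self.control_model.to_dict()
        else:
            # parsimonious storage: (p + 2) mean coefficients + 1 residual SD
            doc["shared_coef"] = [float(c) for c in self.control_model.coef]
            doc["indicator_coef"] = self.indicator_coefficient
            doc["residual_sd"] = float(self.control_model.residual_sd)
        return doc

    @classmethod
    def from_dict(cls, d: dict) -> "ClrUpdater":
        prior = LogisticModel.from_dict(d["prior"])
        meta = FitMeta.from_dict(d["fit_meta"])
        if d["variant"] == "full":
            return cls(
                prior=prior,
                variant="full",
                case_model=ConditionalMarkerModel.from_dict(d["case_model"]),
                control_model=ConditionalMarkerModel.from_dict(d["control_model"]),
                fit_meta=meta,
            )
        shared = np.asarray(d["shared_coef"], dtype=float)
        sd = d["residual_sd"]
        case_coef = shared.copy()
        case_coef[0] += d["indicator_coef"]
        return cls(
            prior=prior,
            variant="simple",
            case_model=ConditionalMarkerModel(case_coef, sd),
            control_model=ConditionalMarkerModel(shared, sd),
            fit_meta=meta,
        )


# the simple variant serializes under its own strategy tag
from riskupdate.schema import _MODEL_REGISTRY  # noqa: E402

_MODEL_REGISTRY["clr_simple"] = ClrUpdater


def _ols(design: np.ndarray, target: np.ndarray, label: str) -> tuple[np.ndarray, float]:
    """OLS coefficients and unbiased residual SD; errors name the group."""
    n, k = design.shape
    if n <= k:
        raise FitError(f"{label}: {n} rows cannot identify {k} mean parameters")
    coef, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < k:
        raise FitError(f"{label}: rank-deficient design (rank {rank} < {k})")
    resid = target - design @ coef
    var = float(resid @ resid) / (n - k)
    sd = np.sqrt(var)
    if not sd > 1e-8 * max(1.0, float(np.std(target))):
        raise FitError(f"{label}: zero residual variance gives a degenerate marker density")
    return coef, sd


def fit_clr(prior: LogisticModel, marker_set: Dataset) -> ClrUpdater:
    """Full CLR: separate marker regressions in the event and non-event groups."""
    m = marker_set.require_complete_marker()
    models = {}
    sizes = {}
    for value, label in ((1, "event group"), (0, "non-event group")):
        idx = marker_set.y == value
        design = np.column_stack([np.ones(int(idx.sum())), marker_set.X[idx]])
        coef, sd = _ols(design, m[idx], label)
        models[value] = ConditionalMarkerModel(coef=coef, residual_sd=sd)
        sizes[value] = int(idx.sum())
    meta = FitMeta(converged=True, n_obs=marker_set.n,
                   message=f"group sizes: {sizes[1]} events / {sizes[0]} non-events")
    return ClrUpdater(
        prior=prior, variant="full",
        case_model=models[1], control_model=models[0], fit_meta=meta,
    )


def fit_clr_simple(prior: LogisticModel, marker_set: Dataset) -> ClrUpdater:
    """Parsimonious CLR: one marker regression with an outcome indicator."""
    m = marker_set.require_complete_marker()
    y = marker_set.y
    if y.sum() == 0 or y.sum() == marker_set.n:
        raise FitError("both outcome groups must be non-empty")
    design = np.column_stack([np.ones(marker_set.n), marker_set.X, y.astype(float)])
    coef, sd = _ols(design, m, "pooled marker regression")
    control_coef = coef[:-1].copy()
    case_coef = coef[:-1].copy()
    case_coef[0] += coef[-1]
    meta = FitMeta(converged=True, n_obs=marker_set.n,
                   message=f"indicator coefficient: {coef[-1]:.6g}")
    updater = ClrUpdater(
        prior=prior, variant="simple",
        case_model=ConditionalMarkerModel(case_coef, sd),
        control_model=ConditionalMarkerModel(control_coef, sd),
        fit_meta=meta,
    )
    updater.strategy_tag = "clr_simple"
    return updater


def likelihood_ratio(updater: ClrUpdater, row: np.ndarray, m) -> np.ndarray | float:
    """Ratio of conditional normal densities, computed on the log scale.

    ``row`` may be a single encoded predictor vector or an (n, p) matrix;
    ``m`` a scalar or matching vector.  Always strictly positive and finite.
    """
    row = np.asarray(row, dtype=float)
    scalar = row.ndim == 1 and np.ndim(m) == 0
    lr = np.exp(updater.log_likelihood_ratio(np.atleast_2d(row), np.asarray(m, dtype=float)))
    return float(lr[0]) if scalar else lr


def update_prediction(updater: ClrUpdater, row: np.ndarray, m) -> np.ndarray | float:
    """Posterior probability from ``posterior odds = exp(lp0) * LR``."""
    row = np.asarray(row, dtype=float)
    scalar = row.ndim == 1 and np.ndim(m) == 0
    X = np.atleast_2d(row)
    lp0 = updater.prior.alpha + X @ updater.prior.betas
    log_odds = lp0 + updater.log_likelihood_ratio(X, np.asarray(m, dtype=float))
    post = _expit(log_odds)
    return float(post[0]) if scalar else post
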