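"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from riskupdate.schema import CATEGORICAL, CONTINUOUS, Dataset, PredictorSchema


@pytest.fixture
def clinical_schema() -> PredictorSchema:
    """PSA-like continuous, 3-level volume-like categorical, binary DRE-like."""
    return PredictorSchema(
        names=("psa", "volume", "dre"),
        kinds=(CONTINUOUS, CATEGORICAL, CONTINUOUS),
        levels={"volume": ("25cc", "40cc", "60cc")},
    )


def make_continuous_schema(p: int) -> PredictorSchema:
    return PredictorSchema(names=[f"x{i}" for i in range(p)], kinds=[CONTINUOUS] * p)


def make_logistic_dataset(
    n: int,
    alpha: float,
    betas,
    seed: int,
    beta_marker: float | None = None,
    marker_sd: float = 1.0,
) -> Dataset:
    """Dataset from a known logistic truth with standard-normal predictors
    (and, optionally, a marker correlated with the first predictor)."""
    rng = np.random.default_rng(seed)
    betas = np.asarray(betas, dtype=float)
    p = betas.shape[0]
    X = rng.standard_normal((n, p))
    marker = None
    lp = alpha + X @ betas
    if beta_marker is not None:
        marker = 0.5 * X[:, 0] + marker_sd * rng.standard_normal(n)
        lp = lp + beta_marker * marker
    prob = 1.0 / (1.0 + np.exp(-lp))
    y = (rng.random(n) < prob).astype(int)
    return Dataset(schema=make_continuous_schema(p), X=X, y=y, marker=marker)


def statsmodels_logit(X: np.ndarray, y: np.ndarray):
    """Independent ML oracle: statsmodels Logit fit (intercept prepended).

    Returns (coefficients, standard errors).
    """
    import statsmodels.api as sm

    design = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    fit = sm.Logit(np.asarray(y, dtype=float), design).fit(disp=0, method="newton")
    return np.asarray(fit.params), np.asarray(fit.bse)


def allpairs_concordance(y: np.ndarray, p: np.ndarray) -> float:
    """O(n^2) brute-force concordance oracle: ties count one half."""
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    events = p[y == 1]
    nonevents = p[y == 0]
    wins = 0.0
    for e in events:
        wins += np.sum(e > nonevents) + 0.5 * np.sum(e == nonevents)
    return wins / (len(events) * len(nonevents))
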