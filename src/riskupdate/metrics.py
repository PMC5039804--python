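"""Validation performance: concordance statistic and calibration slope."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from riskupdate.errors import FitError
from riskupdate.logistic import fit_logistic_design


@dataclass(frozen=True)
class PerformanceResult:
    """Discrimination and calibration of one model on one validation set."""

    c_statistic: float
    calibration_slope: float
    n_events: int
    n_nonevents: int
    slope_converged: bool


def concordance_statistic(y: np.ndarray, p: np.ndarray) -> float:
    """Fraction of event/non-event pairs where the event scores higher,
    ties counted 1/2.  Rank-based O(n log n) (equals the all-pairs count).
    """
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise FitError("y and p must have equal length")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise FitError("concordance needs both events and non-events")
    ranks = rankdata(p)  # midranks handle ties as half-wins
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def calibration_slope(y: np.ndarray, lp: np.ndarray) -> tuple[float, bool]:
    """Slope from the ML logistic regression of ``y`` on the log-odds ``lp``
    (intercept included).  Returns ``(slope, converged)``; 1.0 is ideal,
    below 1 signals overfitted (too extreme) predictions.
    """
    y = np.asarray(y)
    lp = np.asarray(lp, dtype=float)
    coef, meta = fit_logistic_design(lp[:, None], y)
    return float(coef[1]), bool(meta.converged)


def evaluate_predictions(y: np.ndarray, lp: np.ndarray) -> PerformanceResult:
    """Both measures from a log-odds vector (probabilities share its ranks)."""
    y = np.asarray(y)
    slope, ok = calibration_slope(y, lp)
    return PerformanceResult(
        c_statistic=concordance_statistic(y, lp),
        calibration_slope=slope,
        n_events=int((y == 1).sum()),
        n_nonevents=int((y == 0).sum()),
        slope_converged=ok,
    )
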