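"""Scenario runner: generate development/marker/test sets, fit the prior,
apply every updating strategy, and evaluate on independent test data.

Per replicate: a development set is drawn (its marker, if any, is discarded
before the prior fit), the prior covariate-only model is fitted on it, a
marker set is drawn and every configured strategy is applied, and one fresh
test set is drawn on which each strategy's c-statistic and calibration
slope are computed.  Replicates are seeded from a root ``SeedSequence``
spawn so runs are deterministic given the scenario seed and replicates are
independent.  Unconverged strategy fits are excluded from summaries and
counted, never silently used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from riskupdate.clr import fit_clr, fit_clr_simple
from riskupdate.errors import ConfigError, FitError
from riskupdate.impute import fit_imputation
from riskupdate.logistic import fit_logistic
from riskupdate.metrics import evaluate_predictions
from riskupdate.population import (
    PopulationConfig,
    default_clr_population,
    default_logistic_population,
    generate_dataset,
)
from riskupdate.schema import Dataset
from riskupdate.strategies import (
    STRATEGY_TAGS,
    recalibrate,
    recalibrate_with_extension,
    revise_with_extension,
    revise_with_shrinkage,
)

#: strategies evaluated when a scenario does not narrow the list
DEFAULT_STRATEGIES = (
    "original",
    "revision",
    "revision_shrinkage",
    "recalibration_extension",
    "clr",
    "clr_simple",
    "imputation",
)


@dataclass
class ScenarioConfig:
    """One simulation scenario; the three canonical size pairs are
    (500, 100), (100, 500) and (500, 500)."""

    n_dev: int
    n_marker: int
    truth_kind: str = "logistic"
    n_test: int = 100_000
    n_replicates: int = 500
    seed: int = 0
    strategies: tuple[str, ...] = DEFAULT_STRATEGIES
    population: PopulationConfig | None = None
    n_imputations: int = 10
    df_override: int | None = None

    def __post_init__(self) -> None:
        for size, name in ((self.n_dev, "n_dev"), (self.n_marker, "n_marker"),
                           (self.n_test, "n_test"), (self.n_replicates, "n_replicates")):
            if size < 1:
                raise ConfigError(f"{name} must be >= 1, got {size}")
        if self.truth_kind not in ("logistic", "clr"):
            raise ConfigError(f"unknown truth kind {self.truth_kind!r}")
        self.strategies = tuple(self.strategies)
        unknown = set(self.strategies) - set(STRATEGY_TAGS)
        if unknown:
            raise ConfigError(f"unknown strategy tags {sorted(unknown)}")
        if "recalibration" in self.strategies:
            raise ConfigError(
                "plain recalibration carries no marker; it is a component of "
                "revision_shrinkage, not a stand-alone scenario strategy"
            )
        if self.population is None:
            self.population = (
                default_logistic_population()
                if self.truth_kind == "logistic"
                else default_clr_population()
            )
        if self.population.truth.kind != self.truth_kind:
            raise ConfigError(
                f"population truth kind {self.population.truth.kind!r} does not "
                f"match scenario truth_kind {self.truth_kind!r}"
            )
        if self.n_imputations < 1:
            raise ConfigError("n_imputations must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.n_dev}/{self.n_marker}"

    def to_dict(self) -> dict:
        return {
            "n_dev": self.n_dev,
            "n_marker": self.n_marker,
            "truth_kind": self.truth_kind,
            "n_test": self.n_test,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "strategies": list(self.strategies),
            "population": self.population.to_dict(),
            "n_imputations": self.n_imputations,
            "df_override": self.df_override,
            "seeding": "numpy SeedSequence(seed).spawn(n_replicates), one child stream per replicate",
        }


@dataclass
class ScenarioResult:
    """Per-replicate, per-strategy metrics plus the generating config."""

    config: ScenarioConfig
    records: pd.DataFrame = field(repr=False)

    def summary(self) -> pd.DataFrame:
        return summarize(self)


def _strip_marker(data: Dataset) -> Dataset:
    return Dataset(schema=data.schema, X=data.X, y=data.y)


def _fit_strategy(tag, prior, dev_no_marker, marker_set, config, rng):
    if tag == "original":
        return prior
    if tag == "revision":
        return revise_with_extension(marker_set)
    if tag == "revision_shrinkage":
        return revise_with_shrinkage(prior, marker_set, df_override=config.df_override)
    if tag == "recalibration_extension":
        return recalibrate_with_extension(prior, marker_set)
    if tag == "clr":
        return fit_clr(prior, marker_set)
    if tag == "clr_simple":
        return fit_clr_simple(prior, marker_set)
    if tag == "imputation":
        return fit_imputation(dev_no_marker, marker_set, config.n_imputations, rng)
    raise ConfigError(f"unknown strategy tag {tag!r}")  # pre-validated; defensive


def _model_converged(model) -> bool:
    flag = getattr(model, "converged", None)
    if flag is not None:
        return bool(flag)
    return bool(model.fit_meta.converged)


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Run all replicates of a scenario; deterministic given ``config.seed``."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    rows: list[dict] = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        dev = _strip_marker(generate_dataset(config.population, config.n_dev, rng))
        marker_set = generate_dataset(config.population, config.n_marker, rng)
        test = generate_dataset(config.population, config.n_test, rng)
        try:
            prior = fit_logistic(dev)
            prior_ok = prior.fit_meta.converged
        except FitError:
            prior = None
            prior_ok = False
        for tag in config.strategies:
            c = slope = np.nan
            fit_ok = slope_ok = False
            if prior is not None:
                try:
                    model = _fit_strategy(tag, prior, dev, marker_set, config, rng)
                    fit_ok = prior_ok and _model_converged(model)
                    perf = evaluate_predictions(test.y, model.linear_predictor(test))
                    c, slope = perf.c_statistic, perf.calibration_slope
                    slope_ok = perf.slope_converged
                except FitError:
                    fit_ok = False
            rows.append(
                {
                    "replicate": rep,
                    "strategy": tag,
                    "c_statistic": c,
                    "calibration_slope": slope,
                    "fit_converged": fit_ok,
                    "slope_converged": slope_ok,
                    "converged": fit_ok and slope_ok,
                }
            )
    return ScenarioResult(config=config, records=pd.DataFrame(rows))


def summarize(result: ScenarioResult) -> pd.DataFrame:
    """Long-format summary: one row per strategy x metric with median and
    quartiles over converged replicates and the exclusion accounting."""
    if result.records.empty:
        raise ConfigError("cannot summarize an empty result")
    cfg = result.config
    out: list[dict] = []
    for tag in cfg.strategies:
        sub = result.records[result.records["strategy"] == tag]
        ok = sub[sub["converged"]]
        for metric in ("c_statistic", "calibration_slope"):
            vals = ok[metric].to_numpy()
            q25, med, q75 = (
                np.percentile(vals, (25, 50, 75)) if vals.size else (np.nan,) * 3
            )
            out.append(
                {
                    "scenario": cfg.label,
                    "truth": cfg.truth_kind,
                    "strategy": tag,
                    "metric": metric,
                    "median": med,
                    "q25": q25,
                    "q75": q75,
                    "n_converged": int(len(ok)),
                    "n_excluded": int(len(sub) - len(ok)),
                }
            )
    return pd.DataFrame(out)
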