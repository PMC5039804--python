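"""Dataset container, predictor schema/encoding, and CSV + model file I/O.

A :class:`PredictorSchema` declares the clinical predictors (continuous or
categorical); categorical predictors are dummy-encoded against their first
(reference) level, so the encoded design width ``p`` is the number of
continuous predictors plus ``levels - 1`` per categorical predictor.

A :class:`Dataset` holds the encoded design matrix ``X`` (n x p, no missing
entries), the binary outcome ``y`` (1 = event) and an optional marker
vector.  Marker missingness is carried as an explicit boolean mask, never
as a sentinel value: the marker may be absent entirely, fully observed, or
flagged per row (the stacked development + marker data used by the
imputation strategy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from riskupdate.errors import ParseError, SchemaError, SerializationError

MODEL_FORMAT_VERSION = 1

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class PredictorSchema:
    """Ordered predictor declaration shared by datasets and fitted models.

    Parameters
    ----------
    names:
        Unique, non-empty predictor names in design order.
    kinds:
        Per-predictor flag, ``"continuous"`` or ``"categorical"``.
    levels:
        For each categorical predictor, its ordered level labels; the first
        listed level is the reference (absorbed into the intercept).
    """

    names: tuple[str, ...]
    kinds: tuple[str, ...]
    levels: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __init__(
        self,
        names: Sequence[str],
        kinds: Sequence[str],
        levels: Mapping[str, Sequence[str]] | None = None,
    ) -> None:
        object.__setattr__(self, "names", tuple(names))
        object.__setattr__(self, "kinds", tuple(kinds))
        object.__setattr__(
            self,
            "levels",
            {k: tuple(str(level) for level in v) for k, v in (levels or {}).items()},
        )
        self._validate()

    def _validate(self) -> None:
        if not self.names:
            raise SchemaError("schema must declare at least one predictor")
        if len(set(self.names)) != len(self.names):
            raise SchemaError("predictor names must be unique")
        if any(not n for n in self.names):
            raise SchemaError("predictor names must be non-empty")
        if len(self.kinds) != len(self.names):
            raise SchemaError("kinds must align with names")
        for name, kind in zip(self.names, self.kinds):
            if kind not in (CONTINUOUS, CATEGORICAL):
                raise SchemaError(f"unknown predictor kind {kind!r} for {name!r}")
            if kind == CATEGORICAL:
                lv = self.levels.get(name)
                if lv is None or len(lv) < 2:
                    raise SchemaError(f"categorical predictor {name!r} needs >= 2 levels")
                if len(set(lv)) != len(lv):
                    raise SchemaError(f"duplicate levels for predictor {name!r}")
            elif name in self.levels:
                raise SchemaError(f"levels given for continuous predictor {name!r}")

    @property
    def encoded_width(self) -> int:
        """Width p of the dummy-encoded design matrix."""
        p = 0
        for name, kind in zip(self.names, self.kinds):
            p += 1 if kind == CONTINUOUS else len(self.levels[name]) - 1
        return p

    @property
    def encoded_names(self) -> tuple[str, ...]:
        """Column labels of the encoded design, in schema order."""
        cols: list[str] = []
        for name, kind in zip(self.names, self.kinds):
            if kind == CONTINUOUS:
                cols.append(name)
            else:
                cols.extend(f"{name}={lvl}" for lvl in self.levels[name][1:])
        return tuple(cols)

    def encode(self, columns: Mapping[str, Sequence]) -> np.ndarray:
        """Dummy-encode raw predictor columns into the n x p design matrix."""
        n = len(next(iter(columns.values())))
        X = np.empty((n, self.encoded_width), dtype=float)
        j = 0
        for name, kind in zip(self.names, self.kinds):
            raw = columns[name]
            if kind == CONTINUOUS:
                col = pd.to_numeric(pd.Series(raw), errors="coerce").to_numpy(dtype=float)
                bad = np.flatnonzero(np.isnan(col))
                if bad.size:
                    raise ParseError(
                        f"non-numeric value for continuous predictor {name!r} at row {bad[0]}"
                    )
                X[:, j] = col
                j += 1
            else:
                lv = self.levels[name]
                labels = pd.Series(raw).astype(str).to_numpy()
                unknown = set(labels) - set(lv)
                if unknown:
                    raise SchemaError(
                        f"unknown level(s) {sorted(unknown)} for categorical predictor {name!r}"
                    )
                for lvl in lv[1:]:
                    X[:, j] = (labels == lvl).astype(float)
                    j += 1
        return X

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "kinds": list(self.kinds),
            "levels": {k: list(v) for k, v in self.levels.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PredictorSchema":
        return cls(names=d["names"], kinds=d["kinds"], levels=d.get("levels") or {})


@dataclass
class Dataset:
    """Encoded design matrix, optional marker, and binary outcome.

    ``marker`` is ``None`` when the dataset carries no marker at all;
    otherwise ``marker_observed`` flags per row whether the marker value is
    real (missing rows hold 0.0 placeholders that must never be read).
    """

    schema: PredictorSchema
    X: np.ndarray
    y: np.ndarray
    marker: np.ndarray | None = None
    marker_observed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise SchemaError("X must be a 2-d matrix")
        n = self.X.shape[0]
        if n < 1:
            raise SchemaError("dataset must have at least one row")
        if self.X.shape[1] != self.schema.encoded_width:
            raise SchemaError(
                f"X has {self.X.shape[1]} columns but schema encodes {self.schema.encoded_width}"
            )
        if np.isnan(self.X).any():
            raise SchemaError("X must not contain missing entries")
        self.y = np.asarray(self.y)
        if self.y.shape != (n,):
            raise SchemaError("y length must match X rows")
        if not np.isin(self.y, (0, 1)).all():
            raise SchemaError("y entries must be 0 or 1")
        self.y = self.y.astype(np.int64)
        if self.marker is not None:
            self.marker = np.asarray(self.marker, dtype=float)
            if self.marker.shape != (n,):
                raise SchemaError("marker length must match X rows")
            if self.marker_observed is None:
                self.marker_observed = np.ones(n, dtype=bool)
            else:
                self.marker_observed = np.asarray(self.marker_observed, dtype=bool)
                if self.marker_observed.shape != (n,):
                    raise SchemaError("marker_observed length must match X rows")
            if not self.marker_observed.any():
                # all-missing marker degenerates to an absent marker
                self.marker = None
                self.marker_observed = None
            else:
                if np.isnan(self.marker[self.marker_observed]).any():
                    raise SchemaError("observed marker values must be numeric")
                self.marker = np.where(self.marker_observed, self.marker, 0.0)
        elif self.marker_observed is not None:
            raise SchemaError("marker_observed given without marker values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def has_marker(self) -> bool:
        return self.marker is not None

    @property
    def marker_complete(self) -> bool:
        return self.marker is not None and bool(self.marker_observed.all())

    def require_complete_marker(self) -> np.ndarray:
        if not self.marker_complete:
            raise SchemaError("operation requires a fully observed marker")
        return self.marker

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            schema=self.schema,
            X=self.X[idx],
            y=self.y[idx],
            marker=None if self.marker is None else self.marker[idx],
            marker_observed=None if self.marker_observed is None else self.marker_observed[idx],
        )


def stack(dev: Dataset, marker_set: Dataset) -> Dataset:
    """Stack a marker-free development set on top of a marker set.

    Development rows get per-row missing-marker flags; schemas must match.
    """
    if dev.schema != marker_set.schema:
        raise SchemaError("development and marker sets must share one schema")
    m_obs = marker_set.require_complete_marker()
    n_dev = dev.n
    marker = np.concatenate([np.zeros(n_dev), m_obs])
    observed = np.concatenate([np.zeros(n_dev, dtype=bool), np.ones(marker_set.n, dtype=bool)])
    return Dataset(
        schema=dev.schema,
        X=np.vstack([dev.X, marker_set.X]),
        y=np.concatenate([dev.y, marker_set.y]),
        marker=marker,
        marker_observed=observed,
    )


def read_dataset(
    path: str | Path,
    schema: PredictorSchema,
    column_map: Mapping[str, object],
) -> Dataset:
    """Read a header-ed CSV into an encoded :class:`Dataset`.

    ``column_map`` maps each schema predictor name to its CSV column and
    must additionally contain ``"outcome"`` (CSV column) and ``"event"``
    (the raw value coding an event — never inferred).  An optional
    ``"marker"`` key names the marker column; empty marker cells are
    flagged missing, not rejected.  Rows with missing predictor or outcome
    values are dropped.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    required = {name: column_map.get(name) for name in schema.names}
    required["outcome"] = column_map.get("outcome")
    for role, col in required.items():
        if col is None:
            raise SchemaError(f"column_map missing an entry for {role!r}")
        if col not in df.columns:
            raise SchemaError(f"CSV has no column {col!r} (mapped for {role!r})")
    if "event" not in column_map:
        raise SchemaError("column_map must declare the outcome value coding an event")
    marker_col = column_map.get("marker")
    if marker_col is not None and marker_col not in df.columns:
        raise SchemaError(f"CSV has no column {marker_col!r} (mapped for 'marker')")

    pred_cols = [str(column_map[name]) for name in schema.names]
    keep = df[pred_cols + [str(column_map["outcome"])]].notna().all(axis=1)
    df = df.loc[keep].reset_index(drop=True)
    if df.empty:
        raise ParseError("no complete rows after rejecting missing predictors/outcome")

    raw_outcome = df[str(column_map["outcome"])]
    distinct = sorted(raw_outcome.unique())
    if len(distinct) > 2:
        raise ParseError(f"outcome column has {len(distinct)} distinct values: {distinct}")
    event = str(column_map["event"])
    if event not in distinct:
        raise ParseError(f"declared event value {event!r} absent from outcome column {distinct}")
    y = (raw_outcome == event).astype(int).to_numpy()

    columns = {name: df[str(column_map[name])] for name in schema.names}
    X = schema.encode(columns)

    marker = observed = None
    if marker_col is not None:
        raw_marker = pd.to_numeric(df[str(marker_col)], errors="coerce")
        observed = raw_marker.notna().to_numpy()
        marker = raw_marker.fillna(0.0).to_numpy(dtype=float)
        if not observed.any():
            marker = observed = None

    return Dataset(schema=schema, X=X, y=y, marker=marker, marker_observed=observed)


def write_dataset(data: Dataset, path: str | Path, marker_name: str = "marker") -> None:
    """Write a dataset as CSV with encoded predictor columns.

    Encoded dummy columns are written as-is; round-tripping through
    :func:`read_dataset` then needs a schema treating them as continuous.
    """
    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(data.schema.encoded_names):
        cols[name] = data.X[:, j]
    if data.marker is not None:
        m = data.marker.astype(object)
        m[~data.marker_observed] = ""
        cols[marker_name] = m
    cols["outcome"] = data.y
    pd.DataFrame(cols).to_csv(path, index=False)


# --- model serialization -------------------------------------------------
#
# Model files are JSON with a format_version and a strategy tag; each model
# class contributes a payload via to_dict/from_dict.  Registration happens
# at import of the strategy modules (see _register below).

_MODEL_REGISTRY: dict[str, type] = {}


def register_model(tag: str):
    def deco(cls):
        _MODEL_REGISTRY[tag] = cls
        cls.strategy_tag = tag
        return cls

    return deco


def write_model(model, path: str | Path) -> None:
    """Serialize any fitted model to human-readable JSON."""
    tag = getattr(model, "strategy_tag", None)
    if tag is None or tag not in _MODEL_REGISTRY:
        raise SerializationError(f"object of type {type(model).__name__} is not serializable")
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "strategy": tag,
        "model": model.to_dict(),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_model(path: str | Path):
    """Read a model file written by :func:`write_model` (lossless round-trip)."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SerializationError(f"not a model file: {exc}") from exc
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise SerializationError(
            f"unsupported model format_version {version!r} (expected {MODEL_FORMAT_VERSION})"
        )
    tag = doc.get("strategy")
    cls = _MODEL_REGISTRY.get(tag)
    if cls is None:
        raise SerializationError(f"unknown strategy tag {tag!r}")
    model = cls.from_dict(doc["model"])
    model.strategy_tag = tag  # restore the instance tag (e.g. revision, clr_simple)
    return model
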