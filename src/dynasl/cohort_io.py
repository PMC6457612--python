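"""Cohort ingestion and predictor encoding.

Loads a wide longitudinal cohort table (CSV or Stata DTA), applies the
variability filter (every level of a discrete variable must be observed in
at least ``min_count`` patients), expands nominal variables to dummy
indicators, derives binary outcome labels from clinical thresholds, and
replaces incompletely observed predictors by the informative-missingness
basis: an observation indicator Delta and the product Delta*X.  Missingness
is encoded, never imputed, so the downstream learners can exploit the fact
that a value is absent as a predictor in its own right.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BASELINE = "baseline"

#: suffixes used for the missingness basis columns derived from variable X
OBS_SUFFIX = "__obs"      # Delta: 1 if X observed, else 0
OBSVAL_SUFFIX = "__obsval"  # Delta*X: X where observed, else 0


@dataclass(frozen=True)
class ColumnMeta:
    """Declared metadata for one cohort column.

    kind
        ``binary``, ``categorical`` or ``continuous``.
    time
        Measurement time in hours, or ``"baseline"`` for admission-fixed
        covariates (demographics, injury characteristics).
    role
        ``none`` (predictor), ``outcome`` (binary ever-indicator) or
        ``event_time`` (hours from admission to first event, NaN if none).
    missingness_indicator
        True for Delta columns emitted by :func:`build_missingness_basis`.
    source
        Original variable name for derived columns (dummies, Delta, Delta*X).
    """

    kind: str
    time: float | str = BASELINE
    role: str = "none"
    missingness_indicator: bool = False
    source: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical", "continuous"):
            raise ValueError(f"unknown column kind {self.kind!r}")
        if self.role not in ("none", "outcome", "event_time"):
            raise ValueError(f"unknown column role {self.role!r}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "time": self.time,
            "role": self.role,
            "missingness_indicator": self.missingness_indicator,
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ColumnMeta":
        return cls(
            kind=d["kind"],
            time=d.get("time", BASELINE),
            role=d.get("role", "none"),
            missingness_indicator=bool(d.get("missingness_indicator", False)),
            source=d.get("source"),
        )


@dataclass
class CohortTable:
    """Patients x variables with per-column metadata.

    ``data`` holds one row per patient with a ``patient_id`` column; every
    other column must have an entry in ``meta``.  Missing values use the
    single pandas NaN sentinel regardless of the on-disk format.
    """

    data: pd.DataFrame
    meta: dict[str, ColumnMeta] = field(default_factory=dict)

    ID = "patient_id"

    def __post_init__(self) -> None:
        if self.ID not in self.data.columns:
            raise ValueError(f"table lacks a {self.ID!r} column")
        ids = self.data[self.ID]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate patient_id: {dup!r}")
        undeclared = [c for c in self.data.columns if c != self.ID and c not in self.meta]
        if undeclared:
            raise ValueError(f"columns without declared type: {undeclared}")

    # -- convenience -----------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.data)

    def predictor_columns(self) -> list[str]:
        return [c for c, m in self.meta.items() if m.role == "none"]

    def columns_at_or_before(self, cutoff: float) -> list[str]:
        """Predictors measured at baseline or at a grid time <= cutoff."""
        out = []
        for c in self.predictor_columns():
            t = self.meta[c].time
            if t == BASELINE or float(t) <= cutoff:
                out.append(c)
        return out

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), dict(self.meta))

    # -- serialization ---------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write values to CSV and metadata to a ``.meta.json`` sidecar."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        payload = {c: m.to_dict() for c, m in self.meta.items()}
        sidecar.write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path, meta: Mapping[str, ColumnMeta] | None = None) -> "CohortTable":
        path = Path(path)
        if meta is None:
            sidecar = path.with_suffix(path.suffix + ".meta.json")
            if not sidecar.exists():
                raise FileNotFoundError(f"no metadata sidecar at {sidecar}")
            raw = json.loads(sidecar.read_text())
            meta = {c: ColumnMeta.from_dict(d) for c, d in raw.items()}
        return cls(pd.read_csv(path), dict(meta))


@dataclass
class FilterReport:
    """Per-variable retain/drop decision of the variability filter."""

    decisions: pd.DataFrame  # columns: variable, decision, reason

    RETAINED = "retained"
    DROPPED = "dropped"

    def retained(self) -> list[str]:
        d = self.decisions
        return d.loc[d["decision"] == self.RETAINED, "variable"].tolist()

    def dropped(self) -> list[str]:
        d = self.decisions
        return d.loc[d["decision"] == self.DROPPED, "variable"].tolist()

    def to_csv(self, path: str | Path) -> None:
        self.decisions.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# loading


def load_cohort(
    path: str | Path,
    fmt: str | None = None,
    metadata: Mapping[str, ColumnMeta] | str | Path | None = None,
) -> CohortTable:
    """Load a cohort from CSV or Stata DTA into a typed :class:`CohortTable`.

    ``metadata`` supplies :class:`ColumnMeta` for every non-id column, either
    as a mapping or as the path of a JSON sidecar; for CSV it may be omitted
    when a ``<path>.meta.json`` sidecar exists.  Stata extended missing codes
    are normalized to NaN by the reader.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    if fmt is None:
        fmt = "dta" if path.suffix.lower() == ".dta" else "csv"
    if fmt not in ("csv", "dta"):
        raise ValueError(f"unsupported format {fmt!r}")

    if isinstance(metadata, (str, Path)):
        raw = json.loads(Path(metadata).read_text())
        metadata = {c: ColumnMeta.from_dict(d) for c, d in raw.items()}

    if fmt == "csv":
        if metadata is None:
            return CohortTable.from_csv(path)
        frame = pd.read_csv(path)
    else:
        # pandas maps Stata missing codes (., .a ... .z) to NaN
        frame = pd.read_stata(path)
        if metadata is None:
            raise ValueError("DTA loading requires explicit column metadata")
    return CohortTable(frame, dict(metadata))


# ---------------------------------------------------------------------------
# variability filter


def filter_variability(
    table: CohortTable, min_count: int = 50
) -> tuple[CohortTable, FilterReport]:
    """Drop predictors without sufficient variability to inform prediction.

    Binary/categorical predictors are retained only when every observed level
    occurs in at least ``min_count`` patients; continuous predictors need at
    least ``min_count`` non-missing values and must not be constant.  Outcome
    and event-time columns are never filtered.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    rows = []
    keep: list[str] = []
    for col in table.meta:
        m = table.meta[col]
        if m.role != "none":
            keep.append(col)
            continue
        vals = table.data[col].dropna()
        decision, reason = _variability_decision(vals, m.kind, min_count)
        rows.append({"variable": col, "decision": decision, "reason": reason})
        if decision == FilterReport.RETAINED:
            keep.append(col)
    report = FilterReport(pd.DataFrame(rows, columns=["variable", "decision", "reason"]))
    new_meta = {c: table.meta[c] for c in keep}
    new_data = table.data[[CohortTable.ID] + keep]
    return CohortTable(new_data, new_meta), report


def _variability_decision(vals: pd.Series, kind: str, min_count: int) -> tuple[str, str]:
    n_levels = vals.nunique()
    if n_levels <= 1:
        return FilterReport.DROPPED, "constant"
    if kind in ("binary", "categorical"):
        counts = vals.value_counts()
        if (counts < min_count).any():
            return FilterReport.DROPPED, "level below threshold"
        return FilterReport.RETAINED, ""
    # continuous
    if len(vals) < min_count:
        return FilterReport.DROPPED, "insufficient non-missing"
    return FilterReport.RETAINED, ""


# ---------------------------------------------------------------------------
# dummy expansion


def expand_dummies(table: CohortTable, max_levels: int = 20) -> CohortTable:
    """Replace each k-level nominal predictor with k binary indicators.

    All levels are kept (no reference level is dropped): the pipeline's
    purpose is prediction, not coefficient inference, and the meta-learner
    tolerates the induced collinearity.  A missing nominal value propagates
    to every indicator of that variable.  Already-binary columns are left
    untouched, so the operation is idempotent.
    """
    frames = [table.data[[CohortTable.ID]]]
    meta: dict[str, ColumnMeta] = {}
    for col, m in table.meta.items():
        if m.role != "none" or m.kind != "categorical":
            frames.append(table.data[[col]])
            meta[col] = m
            continue
        vals = table.data[col]
        levels = sorted(vals.dropna().unique(), key=str)
        if len(levels) > max_levels:
            raise ValueError(
                f"column {col!r} has {len(levels)} levels, above the cap of {max_levels}"
            )
        block = pd.DataFrame(index=table.data.index)
        observed = vals.notna()
        for lev in levels:
            name = f"{col}={lev}"
            ind = (vals == lev).astype(float)
            ind[~observed] = np.nan
            block[name] = ind
            meta[name] = replace(m, kind="binary", source=col)
        frames.append(block)
    return CohortTable(pd.concat(frames, axis=1), meta)


# ---------------------------------------------------------------------------
# missingness basis


def build_missingness_basis(table: CohortTable) -> CohortTable:
    """Encode informative missingness as (Delta, Delta*X) column pairs.

    For every predictor X with at least one missing value, the raw column is
    replaced by an observation indicator ``X__obs`` (1 if observed, 0
    otherwise) and the product ``X__obsval`` (the observed value, 0 where
    missing).  Fully observed predictors pass through unchanged — a constant
    Delta carries no information.  The output has no missing predictor cells,
    and X is recoverable from the pair on all observed positions.
    """
    frames = [table.data[[CohortTable.ID]]]
    meta: dict[str, ColumnMeta] = {}
    for col, m in table.meta.items():
        if m.role != "none":
            frames.append(table.data[[col]])
            meta[col] = m
            continue
        vals = table.data[col]
        observed = vals.notna()
        if observed.all():
            frames.append(table.data[[col]])
            meta[col] = m
            continue
        delta = observed.astype(float)
        prod = vals.where(observed, 0.0).astype(float)
        block = pd.DataFrame(
            {col + OBS_SUFFIX: delta, col + OBSVAL_SUFFIX: prod}, index=table.data.index
        )
        frames.append(block)
        meta[col + OBS_SUFFIX] = replace(
            m, kind="binary", missingness_indicator=True, source=col
        )
        meta[col + OBSVAL_SUFFIX] = replace(m, source=col)
    return CohortTable(pd.concat(frames, axis=1), meta)


# ---------------------------------------------------------------------------
# outcome labels


@dataclass(frozen=True)
class OutcomeDefinition:
    """Threshold rule turning source lab/volume columns into a binary label.

    ``rule`` is a list of (source_column, operator, threshold) triples joined
    by OR; operators are ``>``, ``>=``, ``<``, ``<=``.  The printed clinical
    defaults: coagulopathy = INR > 1.4 or PTT >= 35; massive transfusion =
    transfused volume > 10 L in 24 h.
    """

    name: str
    rule: Sequence[tuple[str, str, float]]

    _OPS = {
        ">": np.greater,
        ">=": np.greater_equal,
        "<": np.less,
        "<=": np.less_equal,
    }

    def evaluate(self, frame: pd.DataFrame) -> pd.Series:
        missing = [c for c, _, _ in self.rule if c not in frame.columns]
        if missing:
            raise KeyError(f"outcome {self.name!r} requires missing column(s): {missing}")
        any_true = pd.Series(False, index=frame.index)
        any_missing = pd.Series(False, index=frame.index)
        for col, op, thr in self.rule:
            vals = frame[col]
            obs = vals.notna()
            any_missing |= ~obs
            hit = pd.Series(False, index=frame.index)
            hit[obs] = self._OPS[op](vals[obs].to_numpy(dtype=float), thr)
            any_true |= hit
        label = any_true.astype(float)
        label[any_missing] = np.nan  # rows with missing sources get missing labels
        return label


def coagulopathy_definition(
    inr_col: str = "inr", ptt_col: str = "ptt", inr_thr: float = 1.4, ptt_thr: float = 35.0
) -> OutcomeDefinition:
    """Coagulopathy: INR strictly above 1.4 and/or PTT at or above 35 s."""
    return OutcomeDefinition(
        "coagulopathy", [(inr_col, ">", inr_thr), (ptt_col, ">=", ptt_thr)]
    )


def massive_transfusion_definition(
    volume_col: str = "transfused_volume_24h", threshold_l: float = 10.0
) -> OutcomeDefinition:
    """Massive transfusion: more than 10 L of product in 24 h (or equivalent)."""
    return OutcomeDefinition("massive_transfusion", [(volume_col, ">", threshold_l)])


def derive_outcome_labels(
    table: CohortTable, definitions: Sequence[OutcomeDefinition]
) -> CohortTable:
    """Append binary outcome columns computed from threshold definitions."""
    out = table.copy()
    for d in definitions:
        out.data[d.name] = d.evaluate(out.data)
        out.meta[d.name] = ColumnMeta(kind="binary", role="outcome")
    return CohortTable(out.data, out.meta)
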