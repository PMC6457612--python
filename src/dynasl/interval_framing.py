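"""Discrete-time person-period restructuring of a longitudinal cohort.

Turns a wide one-row-per-patient table into the risk-set format used for
discrete-time hazard prediction: one row per (patient, interval) while the
patient is still at risk, a binary indicator of whether the event occurred
inside the interval, and only the predictors measured at or before the
interval's left endpoint (the history restriction that prevents leakage of
future measurements into a prediction).

Conventions fixed here:

* intervals are half-open ``(t_{j-1}, t_j]`` over the measurement grid and
  indexed ``j = 1..J``; an event stamped exactly at a cutoff belongs to the
  earlier interval ending there;
* death is terminal and censors every outcome's risk set; discharge or end
  of follow-up is treated as ordinary censoring;
* non-terminal outcomes are first-event processes: the patient leaves that
  outcome's risk set at the first observed event but stays in the others';
* a (patient, interval) whose outcome label is missing contributes no row
  for that interval — data with missing outcomes is dropped, not imputed —
  but the patient remains at risk in later intervals.

An outcome x interval cell supports model fitting only when it has enough
events; the support matrix records which cells do.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import BASELINE, CohortTable

OVERALL = 0  # interval code for the admission-predictors / ever-outcome frame


@dataclass
class PersonPeriodDataset:
    """Risk-set rows for one outcome, plus the bookkeeping to slice them.

    ``frame`` has columns ``patient_id``, ``interval`` (1-based; 0 means the
    one-row-per-patient "overall" frame), ``y`` and every predictor column.
    Predictors are *stored* for all rows; :meth:`design` applies the history
    restriction, returning only the columns measured at or before the
    requested interval's left endpoint.
    """

    frame: pd.DataFrame
    outcome: str
    mode: str                      # "interval" or "overall"
    grid: np.ndarray
    col_times: Mapping[str, float | str]  # predictor -> hours or "baseline"

    @property
    def n_intervals(self) -> int:
        return len(self.grid) - 1

    def predictors_for(self, interval: int) -> list[str]:
        if interval == OVERALL:
            cutoff = float(self.grid[0])
        else:
            cutoff = float(self.grid[interval - 1])
        return [
            c
            for c, t in self.col_times.items()
            if t == BASELINE or float(t) <= cutoff
        ]

    def design(self, interval: int | None = None) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
        """Return (X, y, patient_ids) for one interval (or the overall frame).

        Raises if the slice is empty or if any admitted predictor column is
        time-stamped after the interval cutoff (leakage guard).
        """
        if interval is None:
            interval = OVERALL if self.mode == "overall" else 1
        sub = self.frame[self.frame["interval"] == interval]
        if sub.empty:
            raise ValueError(f"no rows for outcome {self.outcome!r} interval {interval}")
        cols = self.predictors_for(interval)
        cutoff = float(self.grid[0] if interval == OVERALL else self.grid[interval - 1])
        for c in cols:
            t = self.col_times[c]
            if t != BASELINE and float(t) > cutoff:
                raise AssertionError(f"leakage: column {c!r} measured after {cutoff}h")
        return sub[cols], sub["y"].to_numpy(dtype=int), sub["patient_id"].to_numpy()

    def event_counts(self) -> pd.Series:
        """Events per interval among at-risk rows."""
        return self.frame.groupby("interval")["y"].sum().astype(int)

    def to_csv(self, path: str | Path) -> None:
        import json

        path = Path(path)
        self.frame.to_csv(path, index=False)
        manifest = {
            "outcome": self.outcome,
            "mode": self.mode,
            "grid": list(map(float, self.grid)),
            "col_times": {c: t for c, t in self.col_times.items()},
        }
        path.with_suffix(path.suffix + ".manifest.json").write_text(
            json.dumps(manifest, indent=1)
        )


def _interval_label_matrix(
    table: CohortTable, outcome: str, grid: np.ndarray
) -> np.ndarray:
    """(n x J) matrix of interval outcome labels in {0, 1, NaN}.

    Per-interval label columns ``<outcome>_int<j>`` take precedence (these
    carry observable missingness); otherwise labels are derived from the
    first-event time column ``<outcome>_time``.
    """
    n, J = table.n_patients, len(grid) - 1
    int_cols = {
        j: f"{outcome}_int{j}" for j in range(1, J + 1) if f"{outcome}_int{j}" in table.meta
    }
    if int_cols:
        Y = np.full((n, J), np.nan)
        for j, col in int_cols.items():
            Y[:, j - 1] = table.data[col].to_numpy(dtype=float)
        return Y
    time_col = f"{outcome}_time"
    if time_col not in table.meta:
        raise KeyError(
            f"outcome {outcome!r}: no event-time column {time_col!r} and no "
            f"per-interval label columns"
        )
    t = table.data[time_col].to_numpy(dtype=float)
    if np.any(~np.isnan(t) & ((t <= grid[0]) | (t > grid[-1]))):
        raise ValueError(f"outcome {outcome!r}: event time outside the grid span")
    Y = np.zeros((n, J))
    for j in range(J):
        Y[:, j] = ((t > grid[j]) & (t <= grid[j + 1])).astype(float)
    return Y


def build_person_periods(
    table: CohortTable,
    outcome: str,
    mode: str = "interval",
    grid: Sequence[float] | None = None,
    terminal_outcome: str = "death",
    censor_time_col: str | None = None,
) -> PersonPeriodDataset:
    """Restructure the cohort into risk-set rows for one outcome.

    ``mode="interval"`` emits one row per (patient, interval) while the
    patient is alive, uncensored and event-free at the interval's left
    endpoint; ``mode="overall"`` emits one row per patient with admission
    predictors only and y = outcome ever during follow-up.
    """
    if mode not in ("interval", "overall"):
        raise ValueError(f"unknown mode {mode!r}")
    if outcome not in table.meta and f"{outcome}_int1" not in table.meta:
        raise KeyError(f"outcome {outcome!r} not found in table")
    if grid is None:
        times = sorted(
            {float(m.time) for m in table.meta.values() if m.role == "none" and m.time != BASELINE}
        )
        if not times:
            raise ValueError("no measurement grid declared and none inferrable")
        grid = times
    grid = np.asarray(grid, dtype=float)
    pred_cols = table.predictor_columns()
    col_times = {c: table.meta[c].time for c in pred_cols}

    if mode == "overall":
        y = table.data[outcome]
        keep = y.notna()
        frame = table.data.loc[keep, [CohortTable.ID] + pred_cols].copy()
        frame.insert(1, "interval", OVERALL)
        frame.insert(2, "y", y[keep].to_numpy(dtype=float).astype(int))
        return PersonPeriodDataset(
            frame.reset_index(drop=True), outcome, mode, grid, col_times
        )

    n, J = table.n_patients, len(grid) - 1
    Y = _interval_label_matrix(table, outcome, grid)
    death_col = f"{terminal_outcome}_time"
    if death_col in table.meta:
        death_time = table.data[death_col].to_numpy(dtype=float)
    else:
        death_time = np.full(n, np.nan)
    if censor_time_col is not None:
        censor_time = table.data[censor_time_col].to_numpy(dtype=float)
    else:
        censor_time = np.full(n, np.nan)

    rows = []
    at_risk = np.full(n, True)
    for j in range(1, J + 1):
        t_left = grid[j - 1]
        alive = np.isnan(death_time) | (death_time > t_left)
        uncensored = np.isnan(censor_time) | (censor_time > t_left)
        risk = at_risk & alive & uncensored
        y_j = Y[:, j - 1]
        emit = risk & ~np.isnan(y_j)
        for i in np.flatnonzero(emit):
            rows.append((table.data[CohortTable.ID].iloc[i], j, int(y_j[i])))
        # observed events leave this outcome's risk set
        at_risk &= ~(risk & (y_j == 1.0))
    base = pd.DataFrame(rows, columns=[CohortTable.ID, "interval", "y"])
    frame = base.merge(
        table.data[[CohortTable.ID] + pred_cols], on=CohortTable.ID, how="left"
    )
    return PersonPeriodDataset(frame, outcome, mode, grid, col_times)


# ---------------------------------------------------------------------------
# support matrix


@dataclass
class SupportMatrix:
    """Which outcome x interval cells have enough events to model."""

    counts: pd.DataFrame     # outcomes x intervals, integer event counts
    min_events: int

    @property
    def supported(self) -> pd.DataFrame:
        return self.counts >= self.min_events

    def is_supported(self, outcome: str, interval: int) -> bool:
        return bool(self.supported.loc[outcome, interval])

    def marks(self) -> pd.DataFrame:
        """Render supported cells as 'X' and unsupported as '*'."""
        return self.supported.map(lambda s: "X" if s else "*")

    def to_csv(self, path: str | Path) -> None:
        out = self.marks()
        out.columns = [f"{t:g}h" for t in out.columns]
        out.to_csv(path, index_label="outcome")


def support_matrix(
    table: CohortTable,
    outcomes: Sequence[str],
    min_events: int = 50,
    grid: Sequence[float] | None = None,
    terminal_outcome: str = "death",
) -> SupportMatrix:
    """Count per-interval events and mark cells with >= ``min_events``.

    The default threshold of 50 events matches the variability floor used
    for predictors; it is configurable because sparser cells may still be
    of exploratory interest.
    """
    if min_events < 0:
        raise ValueError("min_events must be >= 0")
    counts = {}
    grid_arr = None
    for outcome in outcomes:
        pp = build_person_periods(
            table, outcome, mode="interval", grid=grid, terminal_outcome=terminal_outcome
        )
        grid_arr = pp.grid
        ev = pp.event_counts()
        counts[outcome] = [int(ev.get(j, 0)) for j in range(1, pp.n_intervals + 1)]
    cols = [float(t) for t in grid_arr[1:]]
    frame = pd.DataFrame.from_dict(counts, orient="index", columns=cols)
    return SupportMatrix(frame, min_events)
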