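"""Synthetic longitudinal trauma-like cohort generator with known truth.

Emulates the structure of a prospective critical-injury cohort: baseline
covariates (demographics, injury characteristics), repeated physiologic
measurements on a fixed post-admission grid, several binary outcome
processes (one terminal — death — which censors everything), and partly
informative missingness driven by a latent per-patient severity score.

The generative model, chosen as the simplest structure that induces both
temporal correlation and informative missingness:

* severity ``S_i ~ N(0, 1)`` — a scalar latent summarizing how sick the
  patient is;
* each time-varying signal follows a Gaussian AR(1) around a
  severity-loaded mean: ``X_t = load * S + e_t`` with
  ``e_t = rho * e_{t-1} + sigma * sqrt(1 - rho^2) * z_t``;
* each outcome is a discrete-time hazard process: in interval
  ``j = (t_{j-1}, t_j]`` an at-risk patient has event probability
  ``expit(intercept_j + beta . x(t_{j-1}))`` where the predictors are the
  baseline covariates, the time-varying values at the interval's left
  endpoint, and optionally the latent severity itself;
* a cell is missing with probability ``expit(logit(base) + c * S)`` — the
  severity coefficient ``c`` is the MNAR strength.

Non-terminal outcomes are first-event processes: a patient leaves that
outcome's risk set at first occurrence but stays in the others'.  Death
removes the patient from every risk set and blanks all later measurements.
Every random draw comes from one of three independent streams spawned from
the global seed (covariates, events, missingness), so e.g. switching
missingness off never changes which patients have events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import rankdata

from .cohort_io import BASELINE, CohortTable, ColumnMeta

DEFAULT_GRID = (0.0, 2.0, 3.0, 4.0, 6.0, 12.0, 24.0, 48.0, 72.0, 96.0, 120.0)

SEVERITY = "severity"  # reserved coefficient key for the latent score


def time_column(name: str, t: float) -> str:
    """Canonical column name for variable ``name`` measured at hour ``t``."""
    return f"{name}_t{t:g}"


@dataclass(frozen=True)
class BaselineSpec:
    """One admission-fixed covariate.

    kind 'binary' uses params {'p'}; 'categorical' uses {'probs': [...]}
    (levels are 0..k-1); 'continuous' uses {'mean', 'sd'}.
    """

    name: str
    kind: str
    params: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class TimeVaryingSpec:
    """One repeatedly measured signal: AR(1) around a severity-loaded mean."""

    name: str
    persistence: float = 0.7      # AR(1) rho in [0, 1]
    noise_scale: float = 1.0      # marginal sd of the AR component
    severity_loading: float = 0.0  # coefficient of the latent severity


@dataclass(frozen=True)
class OutcomeSpec:
    """One discrete-time hazard process on the interval grid.

    ``intercepts`` gives the per-interval baseline log-odds (a scalar is
    broadcast to every interval); ``coefficients`` maps predictor names —
    a baseline covariate, a time-varying signal (its value at the interval's
    left endpoint is used), or the reserved key ``"severity"`` — to log-odds
    slopes.  Exactly one outcome in a config must be ``terminal``.
    """

    name: str
    intercepts: float | Sequence[float] = -3.5
    coefficients: Mapping[str, float] = field(default_factory=dict)
    terminal: bool = False

    def intercept_vector(self, n_intervals: int) -> np.ndarray:
        arr = np.asarray(self.intercepts, dtype=float)
        if arr.ndim == 0:
            return np.full(n_intervals, float(arr))
        if arr.shape != (n_intervals,):
            raise ValueError(
                f"outcome_specs[{self.name}].intercepts: expected scalar or "
                f"{n_intervals} values, got shape {arr.shape}"
            )
        return arr


@dataclass(frozen=True)
class MissingnessSpec:
    """Per-variable MNAR mechanism: P(missing) = expit(logit(base) + coef*S)."""

    base_prob: float = 0.0
    severity_coef: float = 0.0


@dataclass
class SimulationConfig:
    n_patients: int = 1500  # mirrors the cohort scale
    time_grid: Sequence[float] = DEFAULT_GRID
    baseline_specs: Sequence[BaselineSpec] = ()
    timevarying_specs: Sequence[TimeVaryingSpec] = ()
    outcome_specs: Sequence[OutcomeSpec] = ()
    missingness_spec: Mapping[str, MissingnessSpec] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients <= 0:
            raise ValueError("n_patients: must be a positive integer")
        grid = np.asarray(self.time_grid, dtype=float)
        if grid.size < 2 or grid[0] != 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("time_grid: must start at 0 and be strictly increasing")
        for spec in self.baseline_specs:
            if spec.kind == "binary":
                p = float(spec.params.get("p", 0.5))
                if not 0 <= p <= 1:
                    raise ValueError(f"baseline_specs[{spec.name}].p: not in [0, 1]")
            elif spec.kind == "categorical":
                probs = np.asarray(spec.params.get("probs", []), dtype=float)
                if probs.size < 2 or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
                    raise ValueError(
                        f"baseline_specs[{spec.name}].probs: must be >=2 nonnegative "
                        "values summing to 1"
                    )
            elif spec.kind != "continuous":
                raise ValueError(f"baseline_specs[{spec.name}].kind: unknown {spec.kind!r}")
        for spec in self.timevarying_specs:
            if not 0 <= spec.persistence <= 1:
                raise ValueError(
                    f"timevarying_specs[{spec.name}].persistence: not in [0, 1]"
                )
            if spec.noise_scale < 0:
                raise ValueError(f"timevarying_specs[{spec.name}].noise_scale: negative")
        if not self.outcome_specs:
            raise ValueError("outcome_specs: at least one outcome required")
        n_terminal = sum(o.terminal for o in self.outcome_specs)
        if n_terminal != 1:
            raise ValueError(
                f"outcome_specs: exactly one terminal outcome required, got {n_terminal}"
            )
        names = [o.name for o in self.outcome_specs]
        if len(set(names)) != len(names):
            raise ValueError("outcome_specs: outcome names must be unique")
        for o in self.outcome_specs:
            o.intercept_vector(len(grid) - 1)
        known = {s.name for s in self.baseline_specs} | {
            s.name for s in self.timevarying_specs
        }
        for o in self.outcome_specs:
            unknown = set(o.coefficients) - known - {SEVERITY}
            if unknown:
                raise ValueError(
                    f"outcome_specs[{o.name}].coefficients: unknown predictors {sorted(unknown)}"
                )
        for var, m in self.missingness_spec.items():
            if var not in known:
                raise ValueError(f"missingness_spec[{var}]: unknown variable")
            if not 0 <= m.base_prob <= 1:
                raise ValueError(f"missingness_spec[{var}].base_prob: not in [0, 1]")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed: must be an integer")

    @property
    def grid(self) -> np.ndarray:
        return np.asarray(self.time_grid, dtype=float)

    @property
    def n_intervals(self) -> int:
        return len(self.time_grid) - 1

    def terminal_outcome(self) -> str:
        return next(o.name for o in self.outcome_specs if o.terminal)


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would not.

    ``severity`` — latent score per patient (aligned with cohort rows);
    ``event_probs`` — long frame (patient_id, interval, one column per
    outcome) of true hazards, NaN where the patient is not at risk;
    ``missing_probs`` — per patient x (variable, time) true missingness
    probability for variables with a missingness mechanism.
    """

    severity: pd.Series
    event_probs: pd.DataFrame
    missing_probs: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        wide = self.event_probs.copy()
        wide.insert(0, "severity", self.severity.reindex(wide["patient_id"]).to_numpy())
        wide.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# generation


def _spawn_rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    cov, ev, miss = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(cov),
        np.random.default_rng(ev),
        np.random.default_rng(miss),
    )


def generate_cohort(config: SimulationConfig) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort and its ground truth from the generative model.

    Identical config + seed yields bit-identical output.  After a terminal
    event, all later measurements and outcome evaluations are absent; an
    event inside interval ``(t_{j-1}, t_j]`` is stamped at the interval
    midpoint.
    """
    config.validate()
    n = int(config.n_patients)
    grid = config.grid
    J = config.n_intervals
    rng_cov, rng_ev, rng_miss = _spawn_rngs(config.seed)

    severity = rng_cov.standard_normal(n)
    frame = pd.DataFrame({CohortTable.ID: np.arange(n)})
    meta: dict[str, ColumnMeta] = {}

    for spec in config.baseline_specs:
        if spec.kind == "binary":
            vals = (rng_cov.random(n) < float(spec.params.get("p", 0.5))).astype(float)
        elif spec.kind == "categorical":
            probs = np.asarray(spec.params["probs"], dtype=float)
            vals = rng_cov.choice(len(probs), size=n, p=probs).astype(float)
        else:
            mu = float(spec.params.get("mean", 0.0))
            sd = float(spec.params.get("sd", 1.0))
            vals = mu + sd * rng_cov.standard_normal(n)
        frame[spec.name] = vals
        meta[spec.name] = ColumnMeta(kind=spec.kind, time=BASELINE)

    # time-varying signals: n x (J+1) value matrices on the full grid
    tv_values: dict[str, np.ndarray] = {}
    for spec in config.timevarying_specs:
        rho, sig = spec.persistence, spec.noise_scale
        e = np.empty((n, len(grid)))
        e[:, 0] = sig * rng_cov.standard_normal(n)
        innov_sd = sig * np.sqrt(max(0.0, 1.0 - rho**2))
        for k in range(1, len(grid)):
            e[:, k] = rho * e[:, k - 1] + innov_sd * rng_cov.standard_normal(n)
        tv_values[spec.name] = spec.severity_loading * severity[:, None] + e
        for k, t in enumerate(grid):
            col = time_column(spec.name, t)
            frame[col] = tv_values[spec.name][:, k]
            meta[col] = ColumnMeta(kind="continuous", time=float(t))

    # outcome hazard processes
    terminal = config.terminal_outcome()
    event_time = {o.name: np.full(n, np.nan) for o in config.outcome_specs}
    alive_at = np.full(n, True)          # alive at the current interval start
    at_risk = {o.name: np.full(n, True) for o in config.outcome_specs}
    prob_records = {o.name: np.full((n, J), np.nan) for o in config.outcome_specs}

    for j in range(J):
        t_left, t_right = grid[j], grid[j + 1]
        mid = 0.5 * (t_left + t_right)
        # one uniform draw per (interval, outcome, patient), consumed
        # regardless of risk status so risk-set changes never shift draws
        for o in config.outcome_specs:
            u = rng_ev.random(n)
            lin = np.full(n, o.intercept_vector(J)[j])
            for key, beta in o.coefficients.items():
                if key == SEVERITY:
                    lin = lin + beta * severity
                elif key in tv_values:
                    lin = lin + beta * tv_values[key][:, j]
                else:
                    lin = lin + beta * frame[key].to_numpy(dtype=float)
            p = expit(lin)
            risk = alive_at & at_risk[o.name]
            prob_records[o.name][risk, j] = p[risk]
            hit = risk & (u < p)
            event_time[o.name][hit] = mid
            at_risk[o.name][hit] = False
        died_now = ~np.isnan(event_time[terminal]) & alive_at & (
            event_time[terminal] > t_left
        )
        alive_at = alive_at & ~died_now

    death_time = event_time[terminal]
    for o in config.outcome_specs:
        frame[o.name] = (~np.isnan(event_time[o.name])).astype(float)
        frame[o.name + "_time"] = event_time[o.name]
        meta[o.name] = ColumnMeta(kind="binary", role="outcome")
        meta[o.name + "_time"] = ColumnMeta(kind="continuous", role="event_time")

    # censoring by death: measurements strictly after death are absent
    for spec in config.timevarying_specs:
        for t in grid:
            censored = ~np.isnan(death_time) & (t > death_time)
            if censored.any():
                frame.loc[censored, time_column(spec.name, t)] = np.nan

    # informative missingness (never applied to structurally censored cells)
    miss_records = {}
    for var, mspec in config.missingness_spec.items():
        if mspec.base_prob <= 0.0:
            p_miss = np.zeros(n)
        elif mspec.base_prob >= 1.0:
            p_miss = np.ones(n)
        else:
            p_miss = expit(logit(mspec.base_prob) + mspec.severity_coef * severity)
        miss_records[var] = p_miss
        cols = (
            [time_column(var, t) for t in grid]
            if var in tv_values
            else [var]
        )
        for col in cols:
            u = rng_miss.random(n)
            hide = (u < p_miss) & frame[col].notna().to_numpy()
            if hide.any():
                frame.loc[hide, col] = np.nan

    table = CohortTable(frame, meta)
    records = []
    for i in range(n):
        for j in range(J):
            rec = {"patient_id": i, "interval": j + 1}
            for o in config.outcome_specs:
                rec[o.name] = prob_records[o.name][i, j]
            records.append(rec)
    event_probs = pd.DataFrame(records)
    truth = GroundTruth(
        severity=pd.Series(severity, index=frame[CohortTable.ID], name="severity"),
        event_probs=event_probs,
        missing_probs=pd.DataFrame(miss_records, index=frame[CohortTable.ID]),
    )
    return table, truth


# ---------------------------------------------------------------------------
# oracle discrimination


def _pairwise_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC via average ranks (ties count one half)."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def true_discrimination(
    config: SimulationConfig, outcome: str, interval: int, n_mc: int = 20000
) -> float:
    """Monte-Carlo estimate of the Bayes-optimal AUC at one outcome x interval.

    Simulates ``n_mc`` patients from ``config`` and computes the probability
    that a randomly drawn event row in interval ``interval`` (1-based) has a
    higher *true* hazard than a randomly drawn non-event row, ties counted
    one half.  This is the discrimination ceiling no fitted model can beat
    in expectation.
    """
    if n_mc < 100:
        raise ValueError("n_mc must be >= 100")
    config.validate()
    if outcome not in {o.name for o in config.outcome_specs}:
        raise KeyError(f"unknown outcome {outcome!r}")
    if not 1 <= interval <= config.n_intervals:
        raise IndexError(f"interval {interval} outside 1..{config.n_intervals}")
    mc_config = SimulationConfig(
        n_patients=n_mc,
        time_grid=config.time_grid,
        baseline_specs=config.baseline_specs,
        timevarying_specs=config.timevarying_specs,
        outcome_specs=config.outcome_specs,
        missingness_spec={},
        seed=config.seed,
    )
    table, truth = generate_cohort(mc_config)
    probs = truth.event_probs
    sub = probs.loc[probs["interval"] == interval, ["patient_id", outcome]].dropna()
    t_left, t_right = config.grid[interval - 1], config.grid[interval]
    times = table.data.set_index(CohortTable.ID)[outcome + "_time"]
    ev_time = times.reindex(sub["patient_id"]).to_numpy()
    y = ((ev_time > t_left) & (ev_time <= t_right)).astype(int)
    p = sub[outcome].to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        return 0.5
    return _pairwise_auc(p, y)


# ---------------------------------------------------------------------------
# a trauma-flavoured default configuration


def default_config(n_patients: int = 1500, seed: int = 0) -> SimulationConfig:
    """A five-outcome configuration at the cohort's scale.

    Event rates are in the ballpark of a severely injured trauma population
    (cumulative mortality near 17%, multi-organ failure near 9%, late and
    rare venous thromboembolism); marginal realism beyond that is a
    non-goal.  Lactate and PTT are missing more often in sicker patients
    (informative missingness).
    """
    return SimulationConfig(
        n_patients=n_patients,
        baseline_specs=[
            BaselineSpec("age", "continuous", {"mean": 40.0, "sd": 17.0}),
            BaselineSpec("male", "binary", {"p": 0.82}),
            BaselineSpec("blunt_mechanism", "binary", {"p": 0.57}),
            BaselineSpec("iss", "continuous", {"mean": 16.0, "sd": 10.0}),
        ],
        timevarying_specs=[
            TimeVaryingSpec("sbp", persistence=0.7, noise_scale=0.7, severity_loading=-1.2),
            TimeVaryingSpec("lactate", persistence=0.8, noise_scale=0.7, severity_loading=1.5),
            TimeVaryingSpec("inr", persistence=0.85, noise_scale=0.7, severity_loading=1.0),
            TimeVaryingSpec("ptt", persistence=0.85, noise_scale=0.7, severity_loading=0.9),
        ],
        outcome_specs=[
            # most of the mortality signal flows through measured physiology
            # (lactate, pressure, coagulation); the residual latent term is
            # the part of severity charts never capture
            OutcomeSpec(
                "death",
                intercepts=[-5.8, -6.4, -6.6, -6.6, -6.8, -6.8, -7.0, -7.2, -7.4, -7.4],
                coefficients={SEVERITY: 0.4, "lactate": 0.9, "sbp": -0.7, "iss": 0.06},
                terminal=True,
            ),
            OutcomeSpec(
                "mof",
                intercepts=[-7.2, -7.2, -7.2, -6.7, -6.3, -5.9, -5.5, -5.5, -5.7, -5.7],
                coefficients={SEVERITY: 0.4, "lactate": 0.8, "iss": 0.07},
            ),
            OutcomeSpec(
                "ards",
                intercepts=[-6.4, -6.4, -6.2, -5.8, -5.4, -5.0, -4.8, -5.0, -5.2, -5.4],
                coefficients={SEVERITY: 0.5, "blunt_mechanism": 0.4, "lactate": 0.4, "iss": 0.04},
            ),
            OutcomeSpec(
                "vte",
                intercepts=[-12.0, -12.0, -12.0, -12.0, -10.0, -8.0, -6.5, -5.4, -4.1, -3.9],
                coefficients={SEVERITY: 0.3, "age": 0.03},
            ),
            OutcomeSpec(
                "transfusion",
                intercepts=[-3.4, -4.2, -4.6, -5.0, -5.4, -5.8, -6.4, -6.8, -7.3, -7.3],
                coefficients={SEVERITY: 0.3, "inr": 0.9, "sbp": -0.8},
            ),
        ],
        missingness_spec={
            "lactate": MissingnessSpec(base_prob=0.20, severity_coef=0.8),
            "ptt": MissingnessSpec(base_prob=0.10, severity_coef=0.5),
            "iss": MissingnessSpec(base_prob=0.05, severity_coef=0.0),
        },
        seed=seed,
    )
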