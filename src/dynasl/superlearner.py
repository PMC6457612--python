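"""Stacked ensemble ("super learner") with an NNLS convex meta-learner.

The ensemble is built in three steps: (1) a V-fold cross-validation plan,
stratified on the outcome so rare events appear in every fold; (2) an
out-of-fold prediction matrix Z — entry ``Z[i, l]`` is candidate learner
l's prediction for row i from the fit that excluded i's fold, so Z is an
honest picture of each candidate's performance; (3) non-negative least
squares of the outcome on Z, rescaled onto the probability simplex, giving
a sparse convex weighting of the candidates.  Candidates receiving weight
zero do not contribute to prediction.

The candidate families mirror a conventional clinical-prediction library:
plain logistic regression, a linear probability model, generalized additive
models at several smoothing levels, random forest, the lasso, and a
polynomial sieve whose degree is chosen by internal cross-validation.  A
candidate that fails to fit on some training fold is dropped and logged
rather than aborting the run — real cohorts routinely make some fits
singular and the ensemble should degrade gracefully.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression, LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler

logger = logging.getLogger("dynasl")

FAMILIES = (
    "logistic",
    "linear_probability",
    "gam",
    "random_forest",
    "lasso",
    "poly_sieve",
)


def _stable_seed(seed: int, *labels: object) -> int:
    """Deterministic child seed from a root seed and string labels.

    Depends on the labels, not on iteration order, so e.g. permuting the
    learner library leaves every learner's own randomness unchanged.
    """
    tag = zlib.crc32("|".join(str(x) for x in labels).encode())
    return int(np.random.SeedSequence([int(seed) % (2**31), tag]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class LearnerSpec:
    """Declaration of one candidate learner."""

    family: str
    params: Mapping[str, object] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")
        if not self.name:
            suffix = "_".join(f"{k}{v}" for k, v in sorted(self.params.items()))
            object.__setattr__(self, "name", self.family + (f"_{suffix}" if suffix else ""))


def default_library() -> list[LearnerSpec]:
    """Logistic + linear + three GAM smoothing levels + forest + lasso + sieve."""
    return [
        LearnerSpec("logistic"),
        LearnerSpec("linear_probability"),
        LearnerSpec("gam", {"df": 2}),
        LearnerSpec("gam", {"df": 4}),
        LearnerSpec("gam", {"df": 6}),
        LearnerSpec("random_forest", {"n_estimators": 200}),
        LearnerSpec("lasso"),
        LearnerSpec("poly_sieve", {"max_degree": 3}),
    ]


# ---------------------------------------------------------------------------
# candidate learner implementations


class _BaseLearner:
    def __init__(self, spec: LearnerSpec, seed: int):
        self.spec = spec
        self.seed = seed
        self.model = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BaseLearner":
        raise NotImplementedError

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @staticmethod
    def _clip(p: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)


class _ClassifierMixin:
    """predict_proba-based scoring, robust to single-class training folds."""

    def _proba(self, X: np.ndarray) -> np.ndarray:
        model = self.model
        if len(getattr(model, "classes_", [0, 1])) == 1:
            only = float(np.ravel(model.classes_)[0])
            return np.full(len(X), only)
        return model.predict_proba(X)[:, 1]


class LogisticLearner(_BaseLearner, _ClassifierMixin):
    def fit(self, X, y):
        # near-unregularized; scaling keeps lbfgs stable on collinear dummies
        self.model = make_pipeline(
            StandardScaler(), LogisticRegression(C=1e4, max_iter=5000)
        ).fit(X, y)
        return self

    def predict_scores(self, X):
        cls = self.model.named_steps["logisticregression"]
        if len(cls.classes_) == 1:
            return np.full(len(X), float(cls.classes_[0]))
        return self._clip(self.model.predict_proba(X)[:, 1])


class LinearProbabilityLearner(_BaseLearner):
    def fit(self, X, y):
        self.model = LinearRegression().fit(X, y)
        return self

    def predict_scores(self, X):
        return self._clip(self.model.predict(X))


class GAMLearner(_BaseLearner):
    """Additive logistic model on per-feature B-spline bases.

    ``df`` controls the knot count of the cubic spline basis, i.e. the
    smoothing level; binary/low-cardinality columns enter linearly.
    """

    def fit(self, X, y):
        df = int(self.spec.params.get("df", 4))
        X = np.asarray(X, dtype=float)
        self._smooth_cols = [
            j for j in range(X.shape[1]) if len(np.unique(X[:, j])) > max(10, df + 2)
        ]
        self._spline = None
        if self._smooth_cols:
            self._spline = SplineTransformer(
                n_knots=df + 2, degree=3, include_bias=False
            ).fit(X[:, self._smooth_cols])
        self.model = make_pipeline(
            StandardScaler(), LogisticRegression(C=1.0, max_iter=5000)
        ).fit(self._basis(X), y)
        return self

    def _basis(self, X):
        X = np.asarray(X, dtype=float)
        if self._spline is None:
            return X
        lin_cols = [j for j in range(X.shape[1]) if j not in self._smooth_cols]
        parts = [self._spline.transform(X[:, self._smooth_cols])]
        if lin_cols:
            parts.append(X[:, lin_cols])
        return np.hstack(parts)

    def predict_scores(self, X):
        cls = self.model.named_steps["logisticregression"]
        B = self._basis(X)
        if len(cls.classes_) == 1:
            return np.full(len(B), float(cls.classes_[0]))
        return self._clip(self.model.predict_proba(B)[:, 1])


class RandomForestLearner(_BaseLearner, _ClassifierMixin):
    def fit(self, X, y):
        self.model = RandomForestClassifier(
            n_estimators=int(self.spec.params.get("n_estimators", 200)),
            max_depth=self.spec.params.get("max_depth"),
            min_samples_leaf=int(self.spec.params.get("min_samples_leaf", 1)),
            random_state=self.seed,
            n_jobs=1,
        ).fit(X, y)
        return self

    def predict_scores(self, X):
        return self._clip(self._proba(X))


class LassoLearner(_BaseLearner):
    """L1-penalized logistic regression with the penalty path chosen by CV."""

    def fit(self, X, y):
        n_min = int(min(np.sum(np.asarray(y) == 0), np.sum(np.asarray(y) == 1)))
        self.model = make_pipeline(
            StandardScaler(),
            LogisticRegressionCV(
                l1_ratios=(1.0,),
                solver="liblinear",
                Cs=np.logspace(-3, 2, 8),
                cv=min(3, max(2, n_min)),
                scoring="roc_auc",
                max_iter=2000,
                random_state=self.seed,
                use_legacy_attributes=False,
            ),
        ).fit(X, y)
        return self

    def predict_scores(self, X):
        cls = self.model.named_steps["logisticregressioncv"]
        if len(cls.classes_) == 1:
            return np.full(len(X), float(cls.classes_[0]))
        return self._clip(self.model.predict_proba(X)[:, 1])


class PolySieveLearner(_BaseLearner):
    """Logistic regression on a polynomial sieve, degree chosen by inner CV."""

    _MAX_FEATURES = 2000

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        max_degree = int(self.spec.params.get("max_degree", 3))
        best = (None, -np.inf, 1)
        for degree in range(1, max_degree + 1):
            expander = PolynomialFeatures(degree=degree, include_bias=False)
            n_out = expander.fit(X[:1]).n_output_features_
            if n_out > self._MAX_FEATURES:
                break
            pipe = make_pipeline(
                StandardScaler(),
                expander,
                LogisticRegression(C=1.0, max_iter=2000),
            )
            score = self._cv_auc(pipe, X, y)
            if score > best[1]:
                best = (pipe, score, degree)
        self.degree_ = best[2]
        self.model = make_pipeline(
            StandardScaler(),
            PolynomialFeatures(degree=self.degree_, include_bias=False),
            LogisticRegression(C=1.0, max_iter=2000),
        ).fit(X, y)
        return self

    def _cv_auc(self, pipe, X, y):
        n_min = int(min(np.sum(y == 0), np.sum(y == 1)))
        if n_min < 3:
            return -np.inf
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=self.seed)
        aucs = []
        for tr, te in skf.split(X, y):
            fitted = pipe.fit(X[tr], y[tr])
            if len(np.unique(y[te])) < 2:
                continue
            aucs.append(roc_auc_score(y[te], fitted.predict_proba(X[te])[:, 1]))
        return float(np.mean(aucs)) if aucs else -np.inf

    def predict_scores(self, X):
        cls = self.model.named_steps["logisticregression"]
        if len(cls.classes_) == 1:
            return np.full(len(X), float(cls.classes_[0]))
        return self._clip(self.model.predict_proba(np.asarray(X, dtype=float))[:, 1])


_LEARNER_CLASSES = {
    "logistic": LogisticLearner,
    "linear_probability": LinearProbabilityLearner,
    "gam": GAMLearner,
    "random_forest": RandomForestLearner,
    "lasso": LassoLearner,
    "poly_sieve": PolySieveLearner,
}


def build_learner(spec: LearnerSpec, seed: int) -> _BaseLearner:
    """Instantiate a fresh, unfitted learner; its seed depends on its name."""
    return _LEARNER_CLASSES[spec.family](spec, _stable_seed(seed, spec.name))


# ---------------------------------------------------------------------------
# fold plan


@dataclass(frozen=True)
class FoldPlan:
    V: int
    fold: np.ndarray          # fold index per row, in 0..V-1
    stratified: bool
    seed: int

    def train_test(self, v: int) -> tuple[np.ndarray, np.ndarray]:
        return np.flatnonzero(self.fold != v), np.flatnonzero(self.fold == v)


def make_fold_plan(
    n: int, y: np.ndarray, V: int, seed: int = 0, stratified: bool = True
) -> FoldPlan:
    """Assign each row to one of V folds, stratified on the outcome.

    Stratification keeps per-fold event counts within one of proportional,
    which matters when events are rare; it requires at least V events.
    """
    y = np.asarray(y)
    if V < 2:
        raise ValueError("V must be >= 2")
    if n < V:
        raise ValueError(f"n={n} smaller than V={V}")
    if len(y) != n:
        raise ValueError("y length does not match n")
    fold = np.empty(n, dtype=int)
    if stratified:
        n_events = int(np.sum(y == 1))
        if n_events < V:
            raise ValueError(
                f"stratified plan needs >= V={V} events, got {n_events}"
            )
        skf = StratifiedKFold(n_splits=V, shuffle=True, random_state=seed % (2**32))
        for v, (_, test) in enumerate(skf.split(np.zeros(n), y)):
            fold[test] = v
    else:
        rng = np.random.default_rng(seed)
        fold[:] = rng.permutation(np.arange(n) % V)
    return FoldPlan(V=V, fold=fold, stratified=stratified, seed=seed)


# ---------------------------------------------------------------------------
# out-of-fold predictions


def oof_predictions(
    library: Sequence[LearnerSpec],
    X: np.ndarray,
    y: np.ndarray,
    plan: FoldPlan,
    seed: int = 0,
) -> tuple[np.ndarray, list[LearnerSpec], list[tuple[str, str]]]:
    """Cross-validated prediction matrix Z and the surviving learner specs.

    ``Z[i, l]`` comes from the fit of learner ``l`` that excluded row i's
    fold.  A learner that raises on any training fold is excluded entirely
    and returned in the failure list as (name, message); the run continues
    as long as one learner survives.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    columns, kept, failures = [], [], []
    for spec in library:
        z = np.empty(len(y))
        try:
            for v in range(plan.V):
                train, test = plan.train_test(v)
                learner = build_learner(spec, _stable_seed(seed, spec.name, "fold", v))
                learner.fit(X[train], y[train])
                z[test] = learner.predict_scores(X[test])
        except Exception as exc:  # noqa: BLE001 - drop-and-log policy
            failures.append((spec.name, f"{type(exc).__name__}: {exc}"))
            logger.warning("learner %s failed and was dropped: %s", spec.name, exc)
            continue
        columns.append(np.clip(z, 0.0, 1.0))
        kept.append(spec)
    if not kept:
        raise RuntimeError("all candidate learners failed")
    return np.column_stack(columns), kept, failures


# ---------------------------------------------------------------------------
# NNLS meta-learner


def nnls_meta_learn(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Convex stacking weights: argmin ||y - Z a||^2, a >= 0, then sum-to-1.

    NNLS induces sparsity — candidates that add nothing get exactly zero —
    and the rescaling onto the simplex makes the ensemble a convex
    combination without disturbing which weights are zero.  A degenerate Z
    (all candidates constant) or an all-zero solution falls back to uniform
    weights with a warning.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 1:
        raise ValueError("Z must be a 2-D matrix with >= 1 column")
    L = Z.shape[1]
    if np.all(np.ptp(Z, axis=0) == 0):
        logger.warning("degenerate Z (all-constant columns); uniform weights")
        return np.full(L, 1.0 / L)
    alpha, _ = nnls(Z, y)
    total = alpha.sum()
    if total <= 0:
        logger.warning("NNLS returned the zero vector; uniform weights")
        return np.full(L, 1.0 / L)
    return alpha / total


# ---------------------------------------------------------------------------
# the super learner


@dataclass
class SuperLearnerFit:
    """Fitted ensemble: candidate fits, convex weights, and the fold plan."""

    library: list[LearnerSpec]
    learners: dict[str, _BaseLearner]   # full-data refits of surviving learners
    alpha: np.ndarray                   # convex weights, aligned with library
    plan: FoldPlan
    Z: np.ndarray                       # out-of-fold prediction matrix
    feature_names: list[str] | None
    failures: list[tuple[str, str]]

    def weights(self) -> pd.Series:
        return pd.Series(self.alpha, index=[s.name for s in self.library], name="alpha")


def fit_super_learner(
    library: Sequence[LearnerSpec],
    X,
    y,
    V: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> SuperLearnerFit:
    """Fold plan -> out-of-fold Z -> NNLS weights -> full-data refits."""
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    plan = make_fold_plan(len(y), y, V, seed=_stable_seed(seed, "folds"), stratified=stratified)
    Z, kept, failures = oof_predictions(library, X, y, plan, seed=seed)
    alpha = nnls_meta_learn(Z, y)
    learners = {}
    for spec in kept:  # refit every survivor so candidates can also be scored
        learner = build_learner(spec, _stable_seed(seed, spec.name, "full"))
        learners[spec.name] = learner.fit(X, y)
    return SuperLearnerFit(
        library=list(kept),
        learners=learners,
        alpha=alpha,
        plan=plan,
        Z=Z,
        feature_names=feature_names,
        failures=failures,
    )


def predict(fit: SuperLearnerFit, X_new) -> np.ndarray:
    """Ensemble probability: clip(sum_l alpha_l f_l(X_new), 0, 1)."""
    if isinstance(X_new, pd.DataFrame) and fit.feature_names is not None:
        missing = [c for c in fit.feature_names if c not in X_new.columns]
        extra = [c for c in X_new.columns if c not in fit.feature_names]
        if missing or extra:
            raise ValueError(
                f"predictor mismatch: missing={missing}, extra={extra}"
            )
        X_new = X_new[fit.feature_names]
    X_new = np.asarray(X_new, dtype=float)
    out = np.zeros(len(X_new))
    for spec, a in zip(fit.library, fit.alpha):
        if a == 0:
            continue  # zero-weight candidates recorded but unused
        out += a * fit.learners[spec.name].predict_scores(X_new)
    return np.clip(out, 0.0, 1.0)


def discrete_super_learner(Z: np.ndarray, y: np.ndarray) -> int:
    """Index of the single candidate with the best cross-validated AUC.

    Ties break toward the lower index, so the choice is deterministic.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 1:
        raise ValueError("Z must be a non-empty 2-D matrix")
    aucs = np.array([roc_auc_score(y, Z[:, l]) for l in range(Z.shape[1])])
    return int(np.argmax(aucs))
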