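"""Cross-validated stacked ensemble ("SuperLearner") for regression.

The ensemble combines a library of prediction algorithms by a convex
weight vector chosen to minimize the K-fold cross-validated squared error
of the stacked out-of-fold predictions, then refits every learner on the
full sample.  Weights are solved by non-negative least squares followed by
normalization to the simplex; if the normalized solution would lose to the
best single learner on CV risk, the discrete winner is used instead, so
the ensemble CV risk never exceeds the best single learner's.

All eight library members are backed by scikit-learn estimators; the GAM
and polynomial-MARS entries use spline / degree-2 polynomial basis
expansions with (regularized) linear fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
import scipy.optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet, ElasticNetCV, LinearRegression, Ridge
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.svm import SVR

from mixglearn.preprocess import AnalysisDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CVScheme",
    "LearnerSpec",
    "SuperLearnerFit",
    "DEFAULT_LIBRARY",
    "FAST_LIBRARY",
    "build_learner",
    "cross_validate",
    "fit_full",
    "fit_superlearner",
    "make_folds",
    "risk_table",
    "sl_predict",
    "solve_weights",
]


@dataclass(frozen=True)
class LearnerSpec:
    """One library member: registry id, hyperparameter overrides, and an
    offset mixed into the master seed so learners draw distinct streams."""

    id: str
    hyperparameters: dict = field(default_factory=dict)
    seed_offset: int = 0

    def __post_init__(self) -> None:
        if self.id not in _REGISTRY:
            raise ValueError(
                f"unknown learner {self.id!r}; registry: {sorted(_REGISTRY)}"
            )


class _SplineGAM(BaseEstimator, RegressorMixin):
    """Additive spline model: cubic-spline basis on continuous features,
    passthrough on (near-)binary ones, ridge-penalized linear fit.

    Stands in for a smoothing-spline GAM; the ridge penalty plays the role
    of the smoothness criterion.
    """

    def __init__(self, n_knots: int = 5, degree: int = 3, alpha: float = 1.0):
        self.n_knots = n_knots
        self.degree = degree
        self.alpha = alpha

    def _expand(self, X: np.ndarray, fit: bool) -> np.ndarray:
        blocks = []
        for j, is_cont in enumerate(self.continuous_):
            col = X[:, [j]]
            if is_cont:
                if fit:
                    tr = SplineTransformer(
                        n_knots=self.n_knots,
                        degree=self.degree,
                        include_bias=False,
                    )
                    tr.fit(col)
                    self.transformers_[j] = tr
                blocks.append(self.transformers_[j].transform(col))
            else:
                blocks.append(col)
        return np.hstack(blocks)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        # spline knots need enough distinct values to be well defined
        self.continuous_ = [
            len(np.unique(X[:, j])) > max(self.n_knots, 10)
            for j in range(X.shape[1])
        ]
        self.transformers_: dict[int, SplineTransformer] = {}
        basis = self._expand(X, fit=True)
        self.model_ = Ridge(alpha=self.alpha)
        self.model_.fit(basis, y)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.model_.predict(self._expand(X, fit=False))


def _make_glm(hp, seed):
    return LinearRegression(**hp)


def _make_gam(hp, seed):
    return _SplineGAM(**hp)


def _make_elastic_net(hp, seed):
    params = {"l1_ratio": 0.5, "cv": 5, "alphas": 50, "max_iter": 5000}
    params.update(hp)
    if "alpha" in params:  # fixed-penalty variant, no internal CV
        params.pop("cv", None)
        params.pop("alphas", None)
        est = ElasticNet(**params)
    else:
        params["random_state"] = seed
        est = ElasticNetCV(**params)
    return Pipeline([("scale", StandardScaler()), ("enet", est)])


def _make_poly_mars(hp, seed):
    # degree-2 polynomial expansion with an L1/L2 penalty selecting terms;
    # a pragmatic stand-in for adaptive polynomial spline regression
    degree = hp.pop("degree", 2) if isinstance(hp, dict) else 2
    params = {"l1_ratio": 0.5, "cv": 5, "alphas": 30, "max_iter": 5000,
              "random_state": seed}
    params.update(hp)
    return Pipeline(
        [
            ("poly", PolynomialFeatures(degree=degree, include_bias=False)),
            ("scale", StandardScaler()),
            ("enet", ElasticNetCV(**params)),
        ]
    )


def _make_svm(hp, seed):
    params = {"kernel": "rbf", "C": 1.0}
    params.update(hp)
    return Pipeline([("scale", StandardScaler()), ("svr", SVR(**params))])


def _make_gbm(hp, seed):
    params = {"n_estimators": 500, "max_depth": 3, "learning_rate": 0.05}
    params.update(hp)
    return GradientBoostingRegressor(random_state=seed, **params)


def _make_random_forest(hp, seed):
    params = {"n_estimators": 500}
    params.update(hp)
    return RandomForestRegressor(random_state=seed, **params)


def _make_neural_net(hp, seed):
    params = {
        "hidden_layer_sizes": (5,),
        "alpha": 0.01,
        "max_iter": 2000,
        "solver": "lbfgs",
    }
    params.update(hp)
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("mlp", MLPRegressor(random_state=seed, **params)),
        ]
    )


class _MeanOnly(BaseEstimator, RegressorMixin):
    """Intercept-only learner, useful as a null benchmark."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.mean_)


def _make_mean(hp, seed):
    return _MeanOnly()


_REGISTRY = {
    "glm": _make_glm,
    "gam": _make_gam,
    "elastic_net": _make_elastic_net,
    "poly_mars": _make_poly_mars,
    "svm": _make_svm,
    "gbm": _make_gbm,
    "random_forest": _make_random_forest,
    "neural_net": _make_neural_net,
    "mean": _make_mean,
}

#: Full eight-member default library.
DEFAULT_LIBRARY: tuple[LearnerSpec, ...] = tuple(
    LearnerSpec(name, seed_offset=i)
    for i, name in enumerate(
        ("glm", "gam", "elastic_net", "poly_mars", "svm", "gbm",
         "random_forest", "neural_net")
    )
)

#: Reduced library for bootstrap runs and simulation studies: the
#: hyperparameters trade a little accuracy for large speedups.
FAST_LIBRARY: tuple[LearnerSpec, ...] = (
    LearnerSpec("glm"),
    LearnerSpec("elastic_net", {"alpha": 0.003}, seed_offset=1),
    LearnerSpec(
        "random_forest",
        {"n_estimators": 30, "max_depth": 6, "max_features": 0.5,
         "min_samples_leaf": 5},
        seed_offset=2,
    ),
)


def build_learner(spec: LearnerSpec, seed: int):
    """Instantiate the scikit-learn estimator for a library member."""
    return _REGISTRY[spec.id](dict(spec.hyperparameters), seed + spec.seed_offset)


@dataclass(frozen=True)
class CVScheme:
    """Fold assignment shared by every learner in the library."""

    k: int
    assignment: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        counts = np.bincount(self.assignment, minlength=self.k)
        if len(counts) != self.k or counts.max() - counts.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")

    def test_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


def make_folds(n: int, k: int = 10, seed: int = 0) -> CVScheme:
    """Random permutation split into k near-equal folds."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    for fold, rows in enumerate(np.array_split(rng.permutation(n), k)):
        assignment[rows] = fold
    return CVScheme(k=k, assignment=assignment, seed=seed)


def _resolve_xy(data, y):
    if isinstance(data, AnalysisDataset):
        return data.design(), data.Y
    X = np.asarray(data, dtype=float)
    if y is None:
        raise ValueError("y is required when data is a raw matrix")
    return X, np.asarray(y, dtype=float)


def cross_validate(
    library: Sequence[LearnerSpec],
    data,
    scheme: CVScheme,
    y=None,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold prediction matrix Z (n rows x L learners).

    Each learner is trained on the complement of each fold and predicts
    the held-out rows.  A learner failure on a fold falls back to the
    training-mean prediction for that fold (logged); if every learner
    fails on every fold the run aborts.
    """
    if not library:
        raise ValueError("learner library must be nonempty")
    X, yv = _resolve_xy(data, y)
    n = len(yv)
    Z = np.empty((n, len(library)))
    n_fail = 0
    for l, spec in enumerate(library):
        for fold in range(scheme.k):
            tr, te = scheme.train_rows(fold), scheme.test_rows(fold)
            try:
                est = build_learner(spec, seed)
                est.fit(X[tr], yv[tr])
                Z[te, l] = est.predict(X[te])
            except Exception as exc:  # noqa: BLE001 - fold-level fallback
                logger.warning(
                    "learner %s failed on fold %d (%s); using training mean",
                    spec.id, fold, exc,
                )
                Z[te, l] = yv[tr].mean()
                n_fail += 1
    if n_fail == len(library) * scheme.k:
        raise RuntimeError("all learners failed on all folds")
    if not np.all(np.isfinite(Z)):
        raise RuntimeError("non-finite cross-validated predictions")
    return Z


def solve_weights(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Convex stacking weights from non-negative least squares.

    NNLS coefficients are normalized onto the simplex; an all-zero NNLS
    solution, or a normalized solution with worse CV risk than the best
    single learner, falls back to full weight on the discrete CV winner.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != len(y):
        raise ValueError("Z must be n x L with n matching y")
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z must be finite")
    L = Z.shape[1]
    per_learner_mse = np.mean((y[:, None] - Z) ** 2, axis=0)
    best_single = int(np.argmin(per_learner_mse))

    def mse(a):
        return float(np.mean((y - Z @ a) ** 2))

    candidates = []
    coef, _ = scipy.optimize.nnls(Z, y)
    if coef.sum() > 0:
        candidates.append(coef / coef.sum())
    # the normalized NNLS point can be suboptimal on the simplex when the
    # unconstrained coefficient sum is far from 1; polish with the exact
    # simplex-constrained quadratic program
    start = candidates[0] if candidates else np.full(L, 1.0 / L)
    res = scipy.optimize.minimize(
        mse,
        start,
        jac=lambda a: (2.0 / len(y)) * (Z.T @ (Z @ a - y)),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * L,
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    if res.success and np.all(res.x >= -1e-8):
        polished = np.clip(res.x, 0.0, None)
        candidates.append(polished / polished.sum())
    unit = np.zeros(L)
    unit[best_single] = 1.0
    candidates.append(unit)
    return min(candidates, key=mse)


@dataclass
class SuperLearnerFit:
    """Fitted ensemble: convex weights, CV risks, and full-data learners."""

    library: tuple[LearnerSpec, ...]
    weights: np.ndarray
    cv_mse: np.ndarray
    ensemble_cv_mse: float
    models: list
    scheme: CVScheme
    feature_names: list[str]
    seed: int = 0

    def predict(self, Xnew) -> np.ndarray:
        return sl_predict(self, Xnew)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "SuperLearnerFit":
        return joblib.load(path)


def fit_full(
    library: Sequence[LearnerSpec],
    data,
    weights: np.ndarray,
    y=None,
    seed: int = 0,
    cv_mse: np.ndarray | None = None,
    ensemble_cv_mse: float = float("nan"),
    scheme: CVScheme | None = None,
    feature_names: Sequence[str] | None = None,
) -> SuperLearnerFit:
    """Refit every learner on the full sample under the given weights.

    A learner that fails on the full data keeps a None model and its
    weight is redistributed proportionally over the survivors (logged).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(library),):
        raise ValueError("one weight per library member required")
    if np.any(weights < -1e-8) or abs(weights.sum() - 1) > 1e-8:
        raise ValueError("weights must lie on the simplex")
    X, yv = _resolve_xy(data, y)
    models = []
    alive = np.ones(len(library), dtype=bool)
    for l, spec in enumerate(library):
        try:
            est = build_learner(spec, seed)
            est.fit(X, yv)
            models.append(est)
        except Exception as exc:  # noqa: BLE001
            logger.warning("learner %s failed on full data (%s)", spec.id, exc)
            models.append(None)
            alive[l] = False
    if not alive.any():
        raise RuntimeError("every learner failed on the full sample")
    w = weights * alive
    if w.sum() <= 0:
        w = alive.astype(float)
    w = w / w.sum()
    if feature_names is None:
        feature_names = (
            data.design_columns()
            if isinstance(data, AnalysisDataset)
            else [f"x{i}" for i in range(X.shape[1])]
        )
    return SuperLearnerFit(
        library=tuple(library),
        weights=w,
        cv_mse=np.full(len(library), np.nan) if cv_mse is None else cv_mse,
        ensemble_cv_mse=ensemble_cv_mse,
        models=models,
        scheme=scheme if scheme is not None else make_folds(len(yv), 2, 0),
        feature_names=list(feature_names),
        seed=seed,
    )


def sl_predict(fit: SuperLearnerFit, Xnew) -> np.ndarray:
    """Ensemble prediction: weighted sum of learner predictions."""
    if isinstance(Xnew, pd.DataFrame):
        if list(Xnew.columns) != fit.feature_names:
            raise ValueError("Xnew columns do not match training columns")
        Xnew = Xnew.to_numpy(dtype=float)
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.ndim != 2 or Xnew.shape[1] != len(fit.feature_names):
        raise ValueError(
            f"Xnew must have {len(fit.feature_names)} columns, got {Xnew.shape}"
        )
    out = np.zeros(Xnew.shape[0])
    for w, model in zip(fit.weights, fit.models):
        if w > 0 and model is not None:
            out += w * model.predict(Xnew)
    return out


def fit_superlearner(
    library: Sequence[LearnerSpec],
    data,
    y=None,
    k: int = 10,
    seed: int = 0,
) -> SuperLearnerFit:
    """folds -> cross-validate -> solve weights -> full refit."""
    X, yv = _resolve_xy(data, y)
    scheme = make_folds(len(yv), k, seed)
    Z = cross_validate(library, X, scheme, y=yv, seed=seed)
    alpha = solve_weights(Z, yv)
    cv_mse = np.mean((yv[:, None] - Z) ** 2, axis=0)
    ensemble_cv_mse = float(np.mean((yv - Z @ alpha) ** 2))
    feature_names = (
        data.design_columns() if isinstance(data, AnalysisDataset) else None
    )
    return fit_full(
        library,
        X,
        alpha,
        y=yv,
        seed=seed,
        cv_mse=cv_mse,
        ensemble_cv_mse=ensemble_cv_mse,
        scheme=scheme,
        feature_names=feature_names,
    )


def risk_table(fit: SuperLearnerFit) -> pd.DataFrame:
    """Per-learner CV risk and weight, plus the ensemble row."""
    rows = [
        {"learner": spec.id, "cv_mse": float(mse), "weight": float(w)}
        for spec, mse, w in zip(fit.library, fit.cv_mse, fit.weights)
    ]
    rows.append(
        {
            "learner": "super_learner",
            "cv_mse": float(fit.ensemble_cv_mse),
            "weight": float(np.sum(fit.weights)),
        }
    )
    return pd.DataFrame(rows)
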