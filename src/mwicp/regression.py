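"""The 25-preset regression zoo mapping selected features to pressure.

Seven families are represented with fixed presets (no hyperparameter
search): 3 linear models, 3 decision trees distinguished by leaf size, 6
support-vector machines, 2 tree ensembles, 4 Gaussian-process kernels, 5
neural networks and 2 kernel-approximation models. Hyperparameters that
the preset names do not pin down (box constraints, epochs, kernel scales)
sit at documented package defaults. Cross-validation and train/test
boundaries are always trial-disjoint: samples of one trial never appear on
both sides.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import BaggingRegressor, GradientBoostingRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process import kernels as gp_kernels
from sklearn.kernel_approximation import Nystroem
from sklearn.linear_model import HuberRegressor, LinearRegression, Ridge
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVR, LinearSVR
from sklearn.tree import DecisionTreeRegressor

from .core import InvalidConfigError

__all__ = [
    "RegressionModelSpec",
    "EvaluationReport",
    "registry",
    "train_models",
    "evaluate",
    "select_best",
]


class _ScaledGammaSVR(BaseEstimator, RegressorMixin):
    """Gaussian SVR whose kernel scale tracks the feature count.

    gamma = factor / n_features on standardized inputs, mirroring the
    fine/medium/coarse kernel-scale convention (sqrt(P)/4, sqrt(P),
    4*sqrt(P)).
    """

    def __init__(self, factor: float = 1.0):
        self.factor = factor

    def fit(self, X, y):
        gamma = self.factor / X.shape[1]
        self.model_ = SVR(kernel="rbf", gamma=gamma)
        self.model_.fit(X, y)
        return self

    def predict(self, X):
        return self.model_.predict(X)


def _scaled(est) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("model", est)])


@dataclass(frozen=True)
class RegressionModelSpec:
    """One catalog entry: a named preset and its estimator factory."""

    name: str
    family: str
    build: object = field(repr=False)  # callable(seed) -> estimator


def _gpr(kernel_factory):
    def build(seed):
        kernel = kernel_factory() + gp_kernels.WhiteKernel(
            noise_level=1e-4, noise_level_bounds=(1e-8, 1e1))
        return _scaled(GaussianProcessRegressor(
            kernel=kernel, alpha=1e-6, normalize_y=True,
            n_restarts_optimizer=0, random_state=seed))
    return build


def _mlp(sizes):
    def build(seed):
        return _scaled(MLPRegressor(
            hidden_layer_sizes=sizes, solver="lbfgs", max_iter=2000,
            random_state=seed))
    return build


def _specs() -> list[RegressionModelSpec]:
    s = RegressionModelSpec
    return [
        # linear family
        s("Linear", "linear", lambda seed: LinearRegression()),
        s("Interactions Linear", "linear", lambda seed: Pipeline([
            ("interact", PolynomialFeatures(
                degree=2, interaction_only=True, include_bias=False)),
            ("model", LinearRegression())])),
        s("Robust Linear", "linear",
          lambda seed: _scaled(HuberRegressor(max_iter=500))),
        # trees by leaf size
        s("Fine Tree", "tree", lambda seed: DecisionTreeRegressor(
            min_samples_leaf=4, random_state=seed)),
        s("Medium Tree", "tree", lambda seed: DecisionTreeRegressor(
            min_samples_leaf=12, random_state=seed)),
        s("Coarse Tree", "tree", lambda seed: DecisionTreeRegressor(
            min_samples_leaf=36, random_state=seed)),
        # support-vector machines
        s("Linear SVM", "svm", lambda seed: _scaled(SVR(kernel="linear"))),
        s("Quadratic SVM", "svm",
          lambda seed: _scaled(SVR(kernel="poly", degree=2))),
        s("Cubic SVM", "svm",
          lambda seed: _scaled(SVR(kernel="poly", degree=3))),
        s("Fine Gaussian SVM", "svm",
          lambda seed: _scaled(_ScaledGammaSVR(factor=16.0))),
        s("Medium Gaussian SVM", "svm",
          lambda seed: _scaled(_ScaledGammaSVR(factor=1.0))),
        s("Coarse Gaussian SVM", "svm",
          lambda seed: _scaled(_ScaledGammaSVR(factor=1.0 / 16.0))),
        # ensembles
        s("Boosted Trees", "ensemble",
          lambda seed: GradientBoostingRegressor(random_state=seed)),
        s("Bagged Trees", "ensemble", lambda seed: BaggingRegressor(
            estimator=DecisionTreeRegressor(min_samples_leaf=8),
            n_estimators=30, random_state=seed)),
        # Gaussian processes
        s("GPR Squared Exponential", "gpr", _gpr(gp_kernels.RBF)),
        s("GPR Matern 5/2", "gpr", _gpr(lambda: gp_kernels.Matern(nu=2.5))),
        s("GPR Exponential", "gpr", _gpr(lambda: gp_kernels.Matern(nu=0.5))),
        s("GPR Rational Quadratic", "gpr",
          _gpr(gp_kernels.RationalQuadratic)),
        # neural networks
        s("Narrow NN", "nn", _mlp((10,))),
        s("Medium NN", "nn", _mlp((25,))),
        s("Wide NN", "nn", _mlp((100,))),
        s("Bilayered NN", "nn", _mlp((10, 10))),
        s("Trilayered NN", "nn", _mlp((10, 10, 10))),
        # kernel-approximation models
        s("SVM Kernel", "kernel", lambda seed: _scaled(Pipeline([
            ("nystroem", Nystroem(n_components=50, random_state=seed)),
            ("svm", LinearSVR(max_iter=5000, random_state=seed))]))),
        s("LSR Kernel", "kernel", lambda seed: _scaled(Pipeline([
            ("nystroem", Nystroem(n_components=50, random_state=seed)),
            ("ridge", Ridge(alpha=1.0))]))),
    ]


def registry() -> dict[str, RegressionModelSpec]:
    """The fixed 25-preset catalog, keyed by preset name."""
    specs = _specs()
    out = {spec.name: spec for spec in specs}
    assert len(out) == len(specs), "preset names must be unique"
    return out


def get_spec(name: str) -> RegressionModelSpec:
    reg = registry()
    if name not in reg:
        raise KeyError(f"unknown preset {name!r}")
    return reg[name]


@dataclass
class FittedModel:
    spec: RegressionModelSpec
    estimator: object
    cv_rmse: float
    cv_mae: float
    training_time_s: float
    train_trial_ids: frozenset


@dataclass
class EvaluationReport:
    preset: str
    mae: float
    rmse: float
    r2: float
    residuals: np.ndarray
    predictions: np.ndarray
    prediction_speed_obs_per_s: float
    training_time_s: float
    cv_rmse: float
    cv_mae: float
    degenerate_r2: bool = False


def _group_folds(groups: np.ndarray, n_folds: int, seed: int):
    """Deterministic trial-disjoint folds: shuffled round-robin by group."""
    uniq = np.unique(groups)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    assignment = {uniq[g]: i % n_folds for i, g in enumerate(order)}
    fold_of = np.array([assignment[g] for g in groups])
    for k in range(n_folds):
        yield np.nonzero(fold_of != k)[0], np.nonzero(fold_of == k)[0]


def train_models(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                 presets: list[str] | None = None, cv_folds: int = 5,
                 seed: int = 0) -> dict[str, FittedModel]:
    """Fit presets on trial-grouped training data with grouped CV scores.

    ``groups`` carries the source trial id of every sample; CV folds are
    partitions of trials, never of samples, and are deterministic under
    ``seed``. No hyperparameter tuning happens: presets are fixed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if X.ndim != 2 or X.shape[1] == 0:
        raise InvalidConfigError("empty feature selection")
    if len(X) != len(y) or len(y) != len(groups):
        raise InvalidConfigError("X, y and groups must align")
    reg = registry()
    names = presets if presets is not None else list(reg)
    n_folds = min(cv_folds, len(np.unique(groups)))
    fitted = {}
    for name in names:
        spec = reg[name]
        fold_sq, fold_abs = [], []
        if n_folds >= 2:
            for tr, te in _group_folds(groups, n_folds, seed):
                est = spec.build(seed)
                est.fit(X[tr], y[tr])
                resid = est.predict(X[te]) - y[te]
                fold_sq.append(np.mean(resid ** 2))
                fold_abs.append(np.mean(np.abs(resid)))
        t0 = time.perf_counter()
        est = spec.build(seed)
        est.fit(X, y)
        elapsed = time.perf_counter() - t0
        fitted[name] = FittedModel(
            spec=spec,
            estimator=est,
            cv_rmse=float(np.sqrt(np.mean(fold_sq))) if fold_sq else np.nan,
            cv_mae=float(np.mean(fold_abs)) if fold_abs else np.nan,
            training_time_s=elapsed,
            train_trial_ids=frozenset(np.unique(groups).tolist()),
        )
    return fitted


def evaluate(fitted: FittedModel, X_test: np.ndarray, y_test: np.ndarray,
             test_trial_ids=()) -> EvaluationReport:
    """Score one fitted preset on held-out trials.

    Refuses any test trial id seen during training (leakage guard). R^2 is
    computed against the test-set mean; a zero-variance test target is
    flagged degenerate and reported as R^2 = 0.
    """
    overlap = fitted.train_trial_ids & frozenset(test_trial_ids)
    if overlap:
        raise InvalidConfigError(
            f"test trials overlap training trials: {sorted(overlap)}")
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    if len(X_test) != len(y_test):
        raise InvalidConfigError("test features and labels must align")
    t0 = time.perf_counter()
    pred = fitted.estimator.predict(X_test)
    elapsed = max(time.perf_counter() - t0, 1e-12)
    resid = pred - y_test
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    sst = float(np.sum((y_test - y_test.mean()) ** 2))
    degenerate = sst == 0.0
    r2 = 0.0 if degenerate else float(1.0 - np.sum(resid ** 2) / sst)
    return EvaluationReport(
        preset=fitted.spec.name,
        mae=mae,
        rmse=rmse,
        r2=r2,
        residuals=resid,
        predictions=pred,
        prediction_speed_obs_per_s=len(y_test) / elapsed,
        training_time_s=fitted.training_time_s,
        cv_rmse=fitted.cv_rmse,
        cv_mae=fitted.cv_mae,
        degenerate_r2=degenerate,
    )


def select_best(reports: dict[str, EvaluationReport] | list[EvaluationReport]
                ) -> str:
    """Best preset by lowest RMSE; ties by MAE, then catalog order."""
    if isinstance(reports, dict):
        items = list(reports.values())
    else:
        items = list(reports)
    if not items:
        raise InvalidConfigError("no reports to choose from")
    order = {name: i for i, name in enumerate(registry())}
    best = min(items, key=lambda rep: (
        rep.rmse, rep.mae, order.get(rep.preset, len(order))))
    return best.preset
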