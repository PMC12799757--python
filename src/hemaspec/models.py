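"""L1-regularized age regression and the three model architectures.

The core learner solves the lasso problem on per-band standardized features,

    min_{b0, b}  (1/2n) * sum_i (y_i - b0 - x_i b)^2  +  lambda * ||b||_1,

with the penalty weight chosen by subject-grouped inner cross-validation so
that no subject contributes to both sides of a validation split. The L1
penalty drives most band coefficients to exactly zero, i.e. the fit doubles
as wavelength-band selection. Coefficients are reported back on the original
feature scale; fitted band indices are 1-based to match how bands are quoted.

Three architectures wrap this learner:

* plain — one regressor over all samples;
* hierarchical — a gate decides whether a hematoma is younger or older than
  7 days (168 h), then routes to a branch regressor trained only on that age
  stratum (day-7 samples train both branches);
* gender-stratified — one regressor per sex, routed by the sample's sex.

All three are scikit-learn estimators (``get_params``/``set_params``,
``fit``/``predict``, trailing-underscore fitted attributes) and compose with
sklearn model selection; the module-level ``fit_*``/``predict_*`` functions
are thin wrappers over them.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.linear_model import LogisticRegression, lars_path
from sklearn.model_selection import GroupKFold, KFold

from .normalization import FeatureDataset

__all__ = [
    "LassoAgeRegressor",
    "HierarchicalAgeRegressor",
    "GenderStratifiedRegressor",
    "DAY7_HOURS",
    "fit_lasso",
    "predict",
    "fit_hierarchical",
    "predict_hierarchical",
    "fit_gender",
    "predict_gender",
    "fit_to_dict",
    "fit_from_dict",
    "save_fit",
    "load_fit",
]

#: The gate threshold between "young" and "old" hematomas: 7 days.
DAY7_HOURS = 168.0


def _check_X(X, n_features: int | None = None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if not np.all(np.isfinite(X)):
        raise ValueError("input features contain non-finite values")
    if n_features is not None and X.shape[1] != n_features:
        raise ValueError(f"expected {n_features} features, got {X.shape[1]}")
    return X


def _coefs_on_grid(Xc, yc, grid, max_iter) -> np.ndarray:
    """Lasso coefficients at each penalty in ``grid`` (descending).

    The lasso coefficient path is piecewise linear in the penalty, so the
    exact solution at every grid point follows from the LARS knots by linear
    interpolation; penalties at or above the first knot give the all-zero
    solution, penalties below the last computed knot clamp to it.
    ``Xc``/``yc`` must be column-centered.
    """
    knots, _, path = lars_path(
        Xc, yc, method="lasso", alpha_min=float(grid[-1]), max_iter=max_iter
    )
    out = np.empty((Xc.shape[1], len(grid)))
    for j, a in enumerate(grid):
        i = np.searchsorted(-knots, -a)
        if i == 0:
            out[:, j] = path[:, 0]
        elif i >= len(knots) or knots[i - 1] == knots[i]:
            out[:, j] = path[:, min(i, len(knots) - 1)]
        else:
            w = (knots[i - 1] - a) / (knots[i - 1] - knots[i])
            out[:, j] = path[:, i - 1] * (1 - w) + path[:, i] * w
    return out


def _cv_splits(n: int, groups, n_folds: int, random_state):
    """Subject-grouped splits; falls back to plain K-fold without groups."""
    if groups is None:
        folds = min(n_folds, n)
        return list(KFold(folds, shuffle=True, random_state=random_state).split(np.arange(n)))
    groups = np.asarray(groups)
    n_groups = len(np.unique(groups))
    if n_groups < 2:
        warnings.warn(
            "only one subject in this stratum; falling back to sample-level "
            "inner folds",
            stacklevel=3,
        )
        folds = min(n_folds, n)
        return list(KFold(folds, shuffle=True, random_state=random_state).split(np.arange(n)))
    folds = n_folds
    if n_groups < n_folds:
        warnings.warn(
            f"only {n_groups} subjects available; reducing inner folds "
            f"from {n_folds} to {n_groups}",
            stacklevel=3,
        )
        folds = n_groups
    return list(GroupKFold(folds).split(np.arange(n), groups=groups))


class LassoAgeRegressor(RegressorMixin, BaseEstimator):
    """Lasso age regressor with grouped inner CV over the penalty grid.

    Parameters
    ----------
    alpha_grid : array-like or None
        Explicit penalty grid. If None, a log-spaced grid of ``n_alphas``
        points over ``[alpha_min_ratio * alpha_max, alpha_max]`` is built,
        where ``alpha_max`` is the smallest penalty that zeroes every
        coefficient on the standardized training data.
    n_alphas : int, default 100
    alpha_min_ratio : float, default 1e-4
    inner_folds : int, default 5
        Subject-grouped folds for penalty selection; reduced with a warning
        when fewer subjects are available.
    rule : {"min", "1se"}, default "min"
        Pick the penalty minimizing mean validation MSE, or the largest
        penalty within one standard error of that minimum.
    max_iter : int
        Maximum number of path steps (active-set changes) per solve.
    random_state : int or None
        Seeds the fold shuffling used only when no groups are given.

    Attributes
    ----------
    intercept_ : float, original feature scale, hours.
    coef_ : ndarray (n_bands,), hours per original feature unit.
    alpha_ : float, selected penalty.
    selected_bands_ : ndarray of 1-based indices of nonzero coefficients.
    center_, scale_ : per-band standardization used at fit time.
    """

    def __init__(
        self,
        alpha_grid=None,
        n_alphas: int = 100,
        alpha_min_ratio: float = 1e-4,
        inner_folds: int = 5,
        rule: str = "min",
        max_iter: int = 2000,
        random_state=None,
    ):
        self.alpha_grid = alpha_grid
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.inner_folds = inner_folds
        self.rule = rule
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        X = _check_X(X)
        y = np.asarray(y, dtype=float)
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if np.ptp(y) == 0:
            raise ValueError("degenerate target: y is constant")
        if self.rule not in ("min", "1se"):
            raise ValueError(f"rule must be 'min' or '1se', got {self.rule!r}")
        n, p = X.shape
        self.n_features_in_ = p

        self.center_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.center_) / self.scale_

        alpha_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / n
        if self.alpha_grid is not None:
            grid = np.sort(np.asarray(self.alpha_grid, dtype=float))[::-1]
        else:
            if alpha_max == 0:  # no feature carries any signal
                self._finalize(np.zeros(p), float(y.mean()), 0.0, np.array([0.0]), None)
                return self
            grid = np.logspace(
                np.log10(alpha_max), np.log10(alpha_max * self.alpha_min_ratio), self.n_alphas
            )
        if np.any(grid <= 0):
            raise ValueError("penalty grid must be strictly positive")

        if len(grid) == 1:
            best = float(grid[0])
            mse_mean = None
        else:
            splits = _cv_splits(n, groups, self.inner_folds, self.random_state)
            fold_mse = np.empty((len(splits), len(grid)))
            for k, (tr, va) in enumerate(splits):
                x_mean = Xs[tr].mean(axis=0)
                y_mean = y[tr].mean()
                coefs = _coefs_on_grid(
                    Xs[tr] - x_mean, y[tr] - y_mean, grid, self.max_iter
                )
                pred = (Xs[va] - x_mean) @ coefs + y_mean  # (n_va, n_alphas)
                fold_mse[k] = ((pred - y[va, None]) ** 2).mean(axis=0)
            mse_mean = fold_mse.mean(axis=0)
            i_min = int(np.argmin(mse_mean))  # ties -> larger penalty (grid descends)
            if self.rule == "1se" and len(splits) > 1:
                se = fold_mse[:, i_min].std(ddof=1) / np.sqrt(len(splits))
                i_best = int(np.argmax(mse_mean <= mse_mean[i_min] + se))
            else:
                i_best = i_min
            best = float(grid[i_best])

        # Xs has zero column means, so the standardized-scale intercept is
        # mean(y) and the final solve only needs the path at `best`
        coef_std = _coefs_on_grid(Xs, y - y.mean(), np.array([best]), self.max_iter)[:, 0]
        self._finalize(coef_std, float(y.mean()), best, grid, mse_mean)
        return self

    def _finalize(self, coef_std, intercept_std, alpha, grid, mse_mean) -> None:
        self.coef_ = coef_std / self.scale_
        self.intercept_ = intercept_std - float((coef_std * self.center_ / self.scale_).sum())
        self.alpha_ = alpha
        self.alpha_grid_ = np.asarray(grid, dtype=float)
        self.cv_mse_mean_ = mse_mean
        self.selected_bands_ = np.flatnonzero(coef_std) + 1

    def predict(self, X):
        X = _check_X(X, self.n_features_in_)
        return self.intercept_ + X @ self.coef_


class HierarchicalAgeRegressor(RegressorMixin, BaseEstimator):
    """Two-stage model: a day-7 gate routing to per-stratum regressors.

    The gate decides whether a sample is younger or older than
    ``threshold_hours``. By default it is an L1-penalized logistic
    classifier (``gate="logistic"``); ``gate="regression"`` instead
    thresholds an age regression's output at ``threshold_hours``. The
    classifier is the default because the decision is a two-class problem
    and a regression trained on the full 0-21 d range compresses its
    output toward the cohort mean, misrouting fresh (near-skin) hematomas
    into the old branch where extrapolation is catastrophic. Samples at
    exactly the threshold train both branches; a regression-gate output of
    exactly the threshold routes to the old branch.
    """

    def __init__(self, estimator=None, threshold_hours: float = DAY7_HOURS, gate: str = "logistic"):
        self.estimator = estimator
        self.threshold_hours = threshold_hours
        self.gate = gate

    def _template(self):
        return clone(self.estimator) if self.estimator is not None else LassoAgeRegressor()

    def fit(self, X, y, groups=None):
        X = _check_X(X)
        y = np.asarray(y, dtype=float)
        if self.gate not in ("regression", "logistic"):
            raise ValueError(f"gate must be 'regression' or 'logistic', got {self.gate!r}")
        thr = self.threshold_hours
        young, old = y <= thr, y >= thr
        for name, m in (("young", young), ("old", old)):
            if not m.any():
                raise ValueError(f"empty {name} stratum (no samples on that side of {thr} h)")
            if groups is not None and len(np.unique(np.asarray(groups)[m])) < 2:
                raise ValueError(f"{name} stratum holds fewer than 2 subjects")

        if self.gate == "regression":
            self.gate_ = self._template().fit(X, y, groups=groups)
        else:
            splits = _cv_splits(len(y), groups, 5, None)
            self.gate_ = _fit_l1_logistic(X, (y >= thr).astype(int), splits)
        g = np.asarray(groups) if groups is not None else None
        self.young_ = self._template().fit(X[young], y[young], groups=None if g is None else g[young])
        self.old_ = self._template().fit(X[old], y[old], groups=None if g is None else g[old])
        self.n_features_in_ = X.shape[1]
        return self

    def gate_decision(self, X) -> np.ndarray:
        """Boolean per sample: True where the gate routes to the old branch."""
        X = _check_X(X, self.n_features_in_)
        if self.gate == "regression":
            return self.gate_.predict(X) >= self.threshold_hours
        return self.gate_.predict(X).astype(bool)

    def predict(self, X):
        X = _check_X(X, self.n_features_in_)
        to_old = self.gate_decision(X)
        # evaluate both branches on the full batch so each row's value is
        # independent of how the batch is split
        return np.where(to_old, self.old_.predict(X), self.young_.predict(X))


class _LogisticGate:
    """L1 logistic young/old classifier on per-band standardized features."""

    def __init__(self, center, scale, clf):
        self.center, self.scale, self.clf = center, scale, clf

    def predict(self, X) -> np.ndarray:
        return self.clf.predict((X - self.center) / self.scale)


def _l1_logistic(C: float) -> LogisticRegression:
    return LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", max_iter=1000)


def _fit_l1_logistic(X, labels, splits) -> _LogisticGate:
    """Fit the gate with penalty strength chosen on grouped splits."""
    center = X.mean(axis=0)
    sd = X.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    Xs = (X - center) / scale
    Cs = np.logspace(-2, 1, 6)
    acc = np.zeros(len(Cs))
    for tr, va in splits:
        for i, C in enumerate(Cs):
            clf = _l1_logistic(C).fit(Xs[tr], labels[tr])
            acc[i] += (clf.predict(Xs[va]) == labels[va]).mean()
    best = Cs[int(np.argmax(acc))]  # ties -> strongest penalty
    return _LogisticGate(center, scale, _l1_logistic(best).fit(Xs, labels))


class GenderStratifiedRegressor(RegressorMixin, BaseEstimator):
    """One age regressor per sex, routed by each sample's recorded sex."""

    def __init__(self, estimator=None):
        self.estimator = estimator

    def fit(self, X, y, groups=None, sex=None):
        if sex is None:
            raise ValueError("sex labels are required to fit the stratified model")
        X = _check_X(X)
        y = np.asarray(y, dtype=float)
        sex = np.asarray(sex)
        g = np.asarray(groups) if groups is not None else None
        self.estimators_ = {}
        for label in np.unique(sex):
            m = sex == label
            template = clone(self.estimator) if self.estimator is not None else LassoAgeRegressor()
            self.estimators_[str(label)] = template.fit(
                X[m], y[m], groups=None if g is None else g[m]
            )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X, sex=None):
        if sex is None:
            raise ValueError("sex labels are required to route predictions")
        X = _check_X(X, self.n_features_in_)
        sex = np.broadcast_to(np.asarray(sex), (X.shape[0],))
        out = np.empty(X.shape[0])
        for label in np.unique(sex):
            if str(label) not in self.estimators_:
                raise ValueError(f"no model fitted for sex label {label!r}")
            m = sex == label
            out[m] = self.estimators_[str(label)].predict(X[m])
        return out


# ---------------------------------------------------------------------------
# functional wrappers over FeatureDataset


def fit_lasso(dataset: FeatureDataset, **kwargs) -> LassoAgeRegressor:
    """Fit a :class:`LassoAgeRegressor` on a dataset, grouped by subject."""
    return LassoAgeRegressor(**kwargs).fit(dataset.X, dataset.y, groups=dataset.subject)


def predict(fit: LassoAgeRegressor, x) -> float:
    """Predicted age in hours for one feature row (unclipped)."""
    return float(fit.predict(np.atleast_2d(x))[0])


def fit_hierarchical(dataset: FeatureDataset, gate: str = "logistic", **kwargs) -> HierarchicalAgeRegressor:
    model = HierarchicalAgeRegressor(estimator=LassoAgeRegressor(**kwargs), gate=gate)
    return model.fit(dataset.X, dataset.y, groups=dataset.subject)


def predict_hierarchical(fit: HierarchicalAgeRegressor, x) -> float:
    return float(fit.predict(np.atleast_2d(x))[0])


def fit_gender(dataset: FeatureDataset, **kwargs) -> GenderStratifiedRegressor:
    model = GenderStratifiedRegressor(estimator=LassoAgeRegressor(**kwargs))
    return model.fit(dataset.X, dataset.y, groups=dataset.subject, sex=dataset.sex)


def predict_gender(fit: GenderStratifiedRegressor, x, sex: str) -> float:
    return float(fit.predict(np.atleast_2d(x), sex=[sex])[0])


# ---------------------------------------------------------------------------
# JSON serialization


def _lasso_to_dict(fit: LassoAgeRegressor) -> dict:
    return {
        "model": "lasso",
        "alpha": fit.alpha_,
        "intercept": fit.intercept_,
        "coef": {int(b): float(fit.coef_[b - 1]) for b in fit.selected_bands_},
        "center": fit.center_.tolist(),
        "scale": fit.scale_.tolist(),
        "n_features": fit.n_features_in_,
        "params": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in fit.get_params().items()},
    }


def _lasso_from_dict(d: dict) -> LassoAgeRegressor:
    fit = LassoAgeRegressor(**d["params"])
    p = d["n_features"]
    fit.n_features_in_ = p
    fit.center_ = np.asarray(d["center"], dtype=float)
    fit.scale_ = np.asarray(d["scale"], dtype=float)
    fit.alpha_ = d["alpha"]
    fit.intercept_ = d["intercept"]
    fit.coef_ = np.zeros(p)
    for band, w in d["coef"].items():
        fit.coef_[int(band) - 1] = w
    fit.selected_bands_ = np.flatnonzero(fit.coef_) + 1
    fit.alpha_grid_ = np.asarray([d["alpha"]])
    fit.cv_mse_mean_ = None
    return fit


def _logistic_gate_to_dict(gate: _LogisticGate) -> dict:
    return {
        "model": "logistic_gate",
        "center": gate.center.tolist(),
        "scale": gate.scale.tolist(),
        "coef": gate.clf.coef_.ravel().tolist(),
        "intercept": float(gate.clf.intercept_[0]),
        "C": float(gate.clf.C),
    }


def _logistic_gate_from_dict(d: dict) -> _LogisticGate:
    clf = _l1_logistic(d["C"])
    clf.coef_ = np.asarray([d["coef"]], dtype=float)
    clf.intercept_ = np.asarray([d["intercept"]], dtype=float)
    clf.classes_ = np.array([0, 1])
    return _LogisticGate(
        np.asarray(d["center"], dtype=float), np.asarray(d["scale"], dtype=float), clf
    )


def fit_to_dict(fit) -> dict:
    """Serialize a fitted model (any architecture) to a JSON-ready dict."""
    if isinstance(fit, LassoAgeRegressor):
        return _lasso_to_dict(fit)
    if isinstance(fit, HierarchicalAgeRegressor):
        gate = (
            _lasso_to_dict(fit.gate_)
            if fit.gate == "regression"
            else _logistic_gate_to_dict(fit.gate_)
        )
        return {
            "model": "hierarchical",
            "threshold_hours": fit.threshold_hours,
            "gate_variant": fit.gate,
            "gate": gate,
            "young": _lasso_to_dict(fit.young_),
            "old": _lasso_to_dict(fit.old_),
        }
    if isinstance(fit, GenderStratifiedRegressor):
        return {
            "model": "gender",
            "by_sex": {s: _lasso_to_dict(m) for s, m in fit.estimators_.items()},
        }
    raise TypeError(f"cannot serialize {type(fit).__name__}")


def fit_from_dict(d: dict):
    """Inverse of :func:`fit_to_dict`."""
    kind = d["model"]
    if kind == "lasso":
        return _lasso_from_dict(d)
    if kind == "hierarchical":
        variant = d.get("gate_variant", "regression")
        fit = HierarchicalAgeRegressor(threshold_hours=d["threshold_hours"], gate=variant)
        fit.gate_ = (
            _lasso_from_dict(d["gate"])
            if variant == "regression"
            else _logistic_gate_from_dict(d["gate"])
        )
        fit.young_ = _lasso_from_dict(d["young"])
        fit.old_ = _lasso_from_dict(d["old"])
        fit.n_features_in_ = fit.young_.n_features_in_
        return fit
    if kind == "gender":
        fit = GenderStratifiedRegressor()
        fit.estimators_ = {s: _lasso_from_dict(m) for s, m in d["by_sex"].items()}
        fit.n_features_in_ = next(iter(fit.estimators_.values())).n_features_in_
        return fit
    raise ValueError(f"unknown model kind {kind!r}")


def save_fit(fit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=2))


def load_fit(path: str | Path):
    return fit_from_dict(json.loads(Path(path).read_text()))
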