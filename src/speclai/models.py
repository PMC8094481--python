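"""Regression back-ends (PLSR, RBF support-vector regression, boosted trees)
behind a uniform fit/predict contract with seeded grid-search tuning.

Fold assignment for every cross-validation is keyed to sample identifiers
(when provided) rather than row positions, so permuting or duplicating
training rows leaves the chosen hyperparameters and predictions unchanged.
"""

from __future__ import annotations

import base64
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import GridSearchCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .boost import BoostedTreesRegressor
from .exceptions import AlignmentError, DegenerateTargetError, ParameterError

__all__ = [
    "ModelSpec",
    "FittedModel",
    "default_spec",
    "fit_plsr",
    "fit_svr",
    "fit_gbt",
    "fit_model",
    "predict",
    "save_model",
    "load_model",
]

METHODS = ("PLSR", "SVR", "GBT")

#: Default hyperparameter grids (the source campaign reports none).
DEFAULT_GRIDS: Dict[str, Dict[str, List]] = {
    "PLSR": {"n_components": list(range(1, 16))},
    "SVR": {"C": [0.1, 1.0, 10.0, 100.0], "gamma": [1e-3, 1e-2, 1e-1, 1.0]},
    "GBT": {
        "n_estimators": [100, 300],
        "max_depth": [2, 3],
        "min_child_weight": [1.0, 3.0],
        "gamma": [0.0],
        "subsample": [0.8],
        "colsample_bytree": [0.8],
        "learning_rate": [0.1],
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """Method name, hyperparameter grid, CV folds and seed for tuning."""

    method: str
    grid: Dict[str, List] = field(default_factory=dict)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ParameterError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.cv_folds < 2:
            raise ParameterError("cv_folds must be >= 2")
        for key, values in self.grid.items():
            if not values:
                raise ParameterError(f"grid dimension {key!r} is empty")

    def resolved_grid(self) -> Dict[str, List]:
        return self.grid or {k: list(v) for k, v in DEFAULT_GRIDS[self.method].items()}


def default_spec(method: str, cv_folds: int = 5, seed: int = 0) -> ModelSpec:
    return ModelSpec(method=method, grid={}, cv_folds=cv_folds, seed=seed)


@dataclass
class FittedModel:
    """A tuned regressor bound to the band wavelengths it was trained on."""

    spec: ModelSpec
    hyperparameters: Dict[str, Any]
    estimator: Any
    wavelengths: Optional[np.ndarray] = None

    def predict(self, X: np.ndarray, wavelengths: Optional[Sequence[float]] = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.wavelengths is not None:
            if X.shape[1] != len(self.wavelengths):
                raise AlignmentError(
                    f"model trained on {len(self.wavelengths)} bands, got {X.shape[1]}"
                )
            if wavelengths is not None:
                mismatched = [
                    (float(a), float(b))
                    for a, b in zip(wavelengths, self.wavelengths)
                    if abs(a - b) > 1e-9
                ]
                if mismatched:
                    raise AlignmentError(f"wavelength mismatch at columns: {mismatched[:5]}")
        out = np.asarray(self.estimator.predict(X), dtype=float).ravel()
        if not np.all(np.isfinite(out)):
            raise RuntimeError("model produced non-finite predictions")
        return out


def _fold_splits(
    n: int, n_folds: int, seed: int, sample_ids: Optional[Sequence] = None
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Seeded CV splits keyed to sample identity, not row position.

    Unique ids are sorted, shuffled with the seed, and dealt round-robin to
    folds; rows inherit the fold of their id, so duplicated rows share a
    fold and row permutations only permute the index arrays.
    """
    if sample_ids is None:
        sample_ids = np.arange(n)
    ids = np.asarray(sample_ids)
    if len(ids) != n:
        raise AlignmentError("sample_ids length does not match row count")
    uniq = np.unique(ids)
    rng = np.random.default_rng(seed)
    shuffled = uniq[rng.permutation(len(uniq))]
    fold_of_id = {uid: f % n_folds for f, uid in enumerate(shuffled)}
    folds = np.array([fold_of_id[i] for i in ids])
    splits = []
    for f in range(n_folds):
        test = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        if len(test) and len(train):
            splits.append((train, test))
    return splits


def _check_target(y: np.ndarray) -> None:
    if np.ptp(y) == 0:
        raise DegenerateTargetError("target is constant")


def _canonical_rows(X, y, sample_ids):
    """Sort rows by sample id and drop duplicate ids.

    A sample id names one observation, so rows sharing an id are redundant
    copies; keeping the first occurrence makes every fitter invariant to row
    permutation and duplication by construction.
    """
    if sample_ids is None:
        return X, y, None
    ids = np.asarray(sample_ids)
    _, first = np.unique(ids, return_index=True)
    keep = np.sort(first)
    order = keep[np.argsort(ids[keep], kind="stable")]
    return X[order], y[order], ids[order]


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    spec: Optional[ModelSpec] = None,
    wavelengths: Optional[Sequence[float]] = None,
    sample_ids: Optional[Sequence] = None,
) -> FittedModel:
    """PLS regression; the component count minimizes cross-validated RMSE."""
    spec = spec or default_spec("PLSR")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    X, y, sample_ids = _canonical_rows(X, y, sample_ids)
    _check_target(y)
    n, p = X.shape
    grid = spec.resolved_grid()
    comps = [c for c in grid["n_components"] if 1 <= c <= min(p, n - 1)]
    if not comps:
        raise ParameterError("no admissible component count in grid")
    splits = _fold_splits(n, spec.cv_folds, spec.seed, sample_ids)
    best = (float("inf"), comps[0])
    for c in comps:
        sq, m = 0.0, 0
        for train, test in splits:
            ncomp = min(c, len(train) - 1)
            pls = PLSRegression(n_components=ncomp, scale=False)
            pls.fit(X[train], y[train])
            pred = np.ravel(pls.predict(X[test]))
            sq += float(np.sum((pred - y[test]) ** 2))
            m += len(test)
        rmse = np.sqrt(sq / m)
        if rmse < best[0]:
            best = (rmse, c)
    n_components = best[1]
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    return FittedModel(
        spec=spec,
        hyperparameters={"n_components": int(n_components), "cv_rmse": float(best[0])},
        estimator=_Ravel(pls),
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, dtype=float),
    )


class _Ravel:
    """Flatten 2-D single-target predictions of sklearn regressors."""

    def __init__(self, inner):
        self.inner = inner

    def predict(self, X):
        return np.ravel(self.inner.predict(X))


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    spec: Optional[ModelSpec] = None,
    wavelengths: Optional[Sequence[float]] = None,
    sample_ids: Optional[Sequence] = None,
) -> FittedModel:
    """RBF-kernel support-vector regression, (C, gamma) grid-searched by CV.

    Bands are standardized with calibration statistics inside the pipeline.
    """
    spec = spec or default_spec("SVR")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    X, y, sample_ids = _canonical_rows(X, y, sample_ids)
    grid = spec.resolved_grid()
    if any(v <= 0 for v in grid["C"]) or any(v <= 0 for v in grid["gamma"]):
        raise ParameterError("SVR grid entries must be positive")
    pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])
    search = GridSearchCV(
        pipe,
        {"svr__C": grid["C"], "svr__gamma": grid["gamma"]},
        scoring="neg_root_mean_squared_error",
        cv=_fold_splits(len(y), spec.cv_folds, spec.seed, sample_ids),
    )
    search.fit(X, y)
    resolved = {
        "C": float(search.best_params_["svr__C"]),
        "gamma": float(search.best_params_["svr__gamma"]),
        "cv_rmse": float(-search.best_score_),
    }
    return FittedModel(
        spec=spec,
        hyperparameters=resolved,
        estimator=search.best_estimator_,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, dtype=float),
    )


def fit_gbt(
    X: np.ndarray,
    y: np.ndarray,
    spec: Optional[ModelSpec] = None,
    wavelengths: Optional[Sequence[float]] = None,
    sample_ids: Optional[Sequence] = None,
) -> FittedModel:
    """Second-order boosted trees with the seven-way hyperparameter grid."""
    spec = spec or default_spec("GBT")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    X, y, sample_ids = _canonical_rows(X, y, sample_ids)
    grid = spec.resolved_grid()
    search = GridSearchCV(
        BoostedTreesRegressor(random_state=spec.seed),
        grid,
        scoring="neg_root_mean_squared_error",
        cv=_fold_splits(len(y), spec.cv_folds, spec.seed, sample_ids),
    )
    search.fit(X, y)
    resolved = {k: v for k, v in search.best_params_.items()}
    resolved["cv_rmse"] = float(-search.best_score_)
    return FittedModel(
        spec=spec,
        hyperparameters=resolved,
        estimator=search.best_estimator_,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, dtype=float),
    )


_FITTERS = {"PLSR": fit_plsr, "SVR": fit_svr, "GBT": fit_gbt}


def fit_model(method: str, X, y, spec=None, wavelengths=None, sample_ids=None) -> FittedModel:
    if method not in _FITTERS:
        raise ParameterError(f"unknown method {method!r}")
    return _FITTERS[method](X, y, spec=spec, wavelengths=wavelengths, sample_ids=sample_ids)


def predict(model: FittedModel, X: np.ndarray, wavelengths=None) -> np.ndarray:
    """Module-level predict honoring the model's wavelength contract."""
    return model.predict(X, wavelengths=wavelengths)


def save_model(model: FittedModel, path) -> None:
    """Serialize spec, resolved hyperparameters, wavelengths and an opaque
    (base64) parameter blob to JSON."""
    blob = base64.b64encode(pickle.dumps(model.estimator)).decode("ascii")
    Path(path).write_text(
        json.dumps(
            {
                "method": model.spec.method,
                "grid": model.spec.grid,
                "cv_folds": model.spec.cv_folds,
                "seed": model.spec.seed,
                "hyperparameters": model.hyperparameters,
                "wavelengths": None
                if model.wavelengths is None
                else [float(w) for w in model.wavelengths],
                "estimator_blob": blob,
            },
            indent=2,
        )
    )


def load_model(path) -> FittedModel:
    d = json.loads(Path(path).read_text())
    spec = ModelSpec(d["method"], d["grid"], d["cv_folds"], d["seed"])
    estimator = pickle.loads(base64.b64decode(d["estimator_blob"]))
    wl = None if d["wavelengths"] is None else np.asarray(d["wavelengths"], dtype=float)
    return FittedModel(spec, d["hyperparameters"], estimator, wl)
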