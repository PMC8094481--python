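"""Characteristic-band selectors: successive projections (SPA), competitive
adaptive reweighted sampling (CARS), and the SPA-then-CARS chain.

All selectors speak 1-based column indices on the (trimmed) band grid and
are deterministic given their inputs and a seed.  Each returns a
:class:`SelectionResult` carrying per-iteration diagnostics.

SPA grows, from every possible starting column, a chain of minimally
collinear columns by repeatedly adding the column with the largest norm of
its projection onto the orthogonal complement of the chain's span; every
prefix of length ``k_min..k_max`` is scored by the validation RMSE of an
ordinary least-squares fit on a seeded calibration/validation split.

CARS runs ``n_runs`` Monte Carlo iterations.  Iteration ``i`` fits a PLS
model on a random sample of rows, weighs variables by absolute regression
coefficient, enforces the exponentially decreasing retention schedule

    r_i = a * exp(-k * i),   a = (p/2)^(1/(N-1)),   k = ln(p/2) / (N-1)

(so ``r_1 * p = p`` and ``ceil(r_N * p) = 2``), then applies adaptive
reweighted sampling (weighted draws with replacement; distinct draws
survive).  The surviving subset with the lowest k-fold RMSECV wins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .exceptions import ChainingError, ParameterError, SelectionError

__all__ = [
    "SelectionResult",
    "CARSTrace",
    "spa_select",
    "cars_select",
    "cars_spa_select",
    "edf_ratio",
    "edf_count",
]


@dataclass
class SelectionResult:
    """Outcome of a band selector.

    Attributes
    ----------
    method : {"FD", "SPA", "CARS", "CARS_SPA"}
    selected_indices : list of int
        Strictly increasing, unique, 1-based column indices.
    selected_wavelengths : list of float or None
        Band centers (nm) when a wavelength axis was supplied.
    score : float
        The minimized criterion (validation RMSE for SPA, RMSECV for CARS).
    trace : dict
        Method-specific per-candidate / per-iteration diagnostics.
    """

    method: str
    selected_indices: List[int]
    selected_wavelengths: Optional[List[float]] = None
    score: float = float("nan")
    trace: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = list(self.selected_indices)
        if idx != sorted(set(idx)):
            raise SelectionError("selected indices must be strictly increasing and unique")
        if any(i < 1 for i in idx):
            raise SelectionError("selected indices are 1-based; got index < 1")
        self.selected_indices = idx

    @property
    def n_selected(self) -> int:
        return len(self.selected_indices)

    def trace_frame(self):
        """Per-iteration (CARS) or per-subset-size (SPA) diagnostics table."""
        import pandas as pd

        trace = self.trace.get("cars", self.trace) if self.method == "CARS_SPA" else self.trace
        if "rmse_by_k" in trace:
            items = sorted(trace["rmse_by_k"].items())
            return pd.DataFrame({"n_bands": [k for k, _ in items],
                                 "rmse": [v for _, v in items]})
        cols = ["iteration", "ratio", "retained_count", "survivor_count", "rmsecv", "valid"]
        return pd.DataFrame({c: trace[c] for c in cols if c in trace})

    def to_json(self) -> str:
        def _clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        return json.dumps(
            {
                "method": self.method,
                "selected_indices": self.selected_indices,
                "selected_wavelengths": self.selected_wavelengths,
                "score": None if np.isnan(self.score) else float(self.score),
                "trace": _clean(self.trace),
            },
            indent=2,
        )


@dataclass
class CARSTrace:
    """Per-iteration CARS diagnostics (pre-ARS retention is monotone)."""

    iteration: List[int] = field(default_factory=list)
    ratio: List[float] = field(default_factory=list)
    retained_count: List[int] = field(default_factory=list)  # EDF count, pre-ARS
    survivor_count: List[int] = field(default_factory=list)  # post-ARS distinct
    rmsecv: List[float] = field(default_factory=list)
    survivors: List[List[int]] = field(default_factory=list)
    coefficients: List[Dict[int, float]] = field(default_factory=list)
    valid: List[bool] = field(default_factory=list)

    def as_dict(self) -> Dict[str, Any]:
        return {
            "iteration": self.iteration,
            "ratio": self.ratio,
            "retained_count": self.retained_count,
            "survivor_count": self.survivor_count,
            "rmsecv": self.rmsecv,
            "valid": self.valid,
        }


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def _spa_chain(X: np.ndarray, start: int, k_max: int) -> List[int]:
    """Projection chain of 0-based column indices, beginning at ``start``.

    Maintains residuals of all columns against the span of the chain; each
    step picks the column with maximal residual norm (ties: lowest index).
    Columns whose residual is numerically zero (collinear with the chain)
    never enter.
    """
    R = X.copy()
    norms0 = np.linalg.norm(X, axis=0)
    chain = [start]
    v = R[:, start].copy()
    for _ in range(k_max - 1):
        nv = v @ v
        if nv <= 0:
            break
        R -= np.outer(v, v @ R) / nv
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        # collinear columns: residual negligible relative to original norm
        norms[norms <= 1e-10 * np.maximum(norms0, 1e-30)] = -1.0
        j = int(np.argmax(norms))
        if norms[j] < 0:
            break
        chain.append(j)
        v = R[:, j].copy()
    return chain


def _ols_val_rmse(X_cal, y_cal, X_val, y_val) -> float:
    """Validation RMSE of an intercept-including least-squares fit."""
    A = np.column_stack([np.ones(len(y_cal)), X_cal])
    coef, _, rank, _ = np.linalg.lstsq(A, y_cal, rcond=None)
    if rank < A.shape[1]:
        return float("nan")  # rank-deficient candidate
    pred = np.column_stack([np.ones(len(y_val)), X_val]) @ coef
    return float(np.sqrt(np.mean((pred - y_val) ** 2)))


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    wavelengths: Optional[Sequence[float]] = None,
    k_min: int = 5,
    k_max: Optional[int] = None,
    val_fraction: float = 0.3,
    seed: int = 0,
) -> SelectionResult:
    """Successive-projections band selection scored by MLR validation RMSE.

    Parameters
    ----------
    X : ndarray (n_samples, p)
    y : ndarray (n_samples,)
    wavelengths : sequence of float, optional
        Band centers used to annotate the result.
    k_min, k_max : int
        Bounds on the selected-subset size; ``k_max`` defaults to ``p``.
    val_fraction : float
        Share of rows held out (seeded shuffle) for candidate scoring.
    seed : int
        Fixes the calibration/validation split.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if k_max is None:
        k_max = p
    if k_min > k_max:
        raise ParameterError(f"k_min={k_min} > k_max={k_max}")
    if not 1 <= k_min <= p or k_max > p:
        raise ParameterError("subset-size bounds outside [1, p]")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, cal_idx = perm[:n_val], perm[n_val:]
    if len(cal_idx) < 2:
        raise ParameterError("too few calibration rows for SPA scoring")

    best_rmse = float("inf")
    best_subset: List[int] = []
    rmse_by_k: Dict[int, float] = {}
    n_skipped = 0
    for start in range(p):
        chain = _spa_chain(X, start, k_max)
        for k in range(k_min, min(k_max, len(chain)) + 1):
            cols = sorted(chain[:k])
            rmse = _ols_val_rmse(X[np.ix_(cal_idx, cols)], y[cal_idx], X[np.ix_(val_idx, cols)], y[val_idx])
            if np.isnan(rmse):
                n_skipped += 1
                continue
            if rmse < rmse_by_k.get(k, float("inf")):
                rmse_by_k[k] = rmse
            if rmse < best_rmse:
                best_rmse = rmse
                best_subset = cols
    if n_skipped:
        warnings.warn(f"SPA skipped {n_skipped} rank-deficient candidate(s)", stacklevel=2)
    if not best_subset:
        raise SelectionError("SPA found no full-rank candidate subset")

    indices = [c + 1 for c in best_subset]
    return SelectionResult(
        method="SPA",
        selected_indices=indices,
        selected_wavelengths=(
            [float(wavelengths[c]) for c in best_subset] if wavelengths is not None else None
        ),
        score=best_rmse,
        trace={
            "rmse_by_k": {int(k): float(v) for k, v in sorted(rmse_by_k.items())},
            "k_min": k_min,
            "k_max": k_max,
            "n_validation_rows": int(n_val),
        },
    )


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------

def edf_ratio(i: int, p: int, n_runs: int) -> float:
    """Exponentially decreasing retention ratio at iteration ``i`` (1-based).

    Algebraically ``a * exp(-k * i)`` with ``a = (p/2)^(1/(N-1))`` and
    ``k = ln(p/2)/(N-1)`` collapses to ``(p/2)^((1-i)/(N-1))``, which is the
    form evaluated here so the endpoints ``r_1 = 1`` and ``r_N = 2/p`` are
    exact up to one rounding.
    """
    if n_runs < 2:
        raise ParameterError("n_runs must be >= 2")
    return float((p / 2.0) ** ((1.0 - i) / (n_runs - 1.0)))


def edf_count(i: int, p: int, n_runs: int) -> int:
    """Number of variables the EDF schedule retains at iteration ``i``.

    ``ceil(r_i * p)`` with a one-ulp-scale guard so the exact endpoint
    identities (``p`` at i=1, ``2`` at i=N) hold for any (p, n_runs).
    """
    return min(int(np.ceil(edf_ratio(i, p, n_runs) * p - 1e-9)), p)


def _pls_coefficients(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    return np.ravel(pls.coef_)


def _pls_rmsecv(
    X: np.ndarray, y: np.ndarray, n_components: int, n_folds: int, seed: int
) -> float:
    n = len(y)
    n_folds = min(n_folds, n)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    sq = 0.0
    for train, test in kf.split(X):
        ncomp = min(n_components, X.shape[1], len(train) - 1)
        pls = PLSRegression(n_components=ncomp, scale=False)
        pls.fit(X[train], y[train])
        pred = np.ravel(pls.predict(X[test]))
        sq += float(np.sum((pred - y[test]) ** 2))
    return float(np.sqrt(sq / n))


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    wavelengths: Optional[Sequence[float]] = None,
    n_runs: int = 50,
    mc_fraction: float = 0.8,
    n_folds: int = 10,
    max_pls_components: Optional[int] = None,
    seed: int = 0,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling over PLS coefficients.

    Returns the surviving variable subset of the iteration with minimal
    ``n_folds``-fold RMSECV; iterations whose survivors shrink below two
    variables are recorded as invalid and excluded from the argmin.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p < 3:
        raise ParameterError("CARS requires at least 3 columns")
    if n_runs < 2:
        raise ParameterError("n_runs must be >= 2")
    if not 0 < mc_fraction <= 1:
        raise ParameterError("mc_fraction must be in (0, 1]")
    cap = max_pls_components if max_pls_components is not None else min(10, p - 1, n - 1)

    rng = np.random.default_rng(seed)
    current = np.arange(p)
    trace = CARSTrace()
    best_rmsecv = float("inf")
    best_survivors: Optional[np.ndarray] = None

    n_mc = int(np.ceil(mc_fraction * n))
    for i in range(1, n_runs + 1):
        ratio = edf_ratio(i, p, n_runs)
        n_keep = edf_count(i, p, n_runs)
        trace.iteration.append(i)
        trace.ratio.append(ratio)
        trace.retained_count.append(n_keep)

        if len(current) < 2:
            trace.survivor_count.append(len(current))
            trace.rmsecv.append(float("nan"))
            trace.survivors.append(current.tolist())
            trace.coefficients.append({})
            trace.valid.append(False)
            continue

        rows = rng.choice(n, size=n_mc, replace=False)
        ncomp = min(cap, len(current), n_mc - 1)
        b = _pls_coefficients(X[np.ix_(rows, current)], y[rows], ncomp)
        absb = np.abs(b)
        total = absb.sum()
        weights = absb / total if total > 0 else np.full(len(current), 1.0 / len(current))

        # EDF: forced retention of the top-weight variables
        n_edf = min(n_keep, len(current))
        order = np.lexsort((current, -weights))  # weight desc, index asc on ties
        edf_kept = order[:n_edf]

        # ARS: weighted draws with replacement; distinct draws survive
        w_edf = weights[edf_kept]
        w_sum = w_edf.sum()
        w_norm = w_edf / w_sum if w_sum > 0 else np.full(len(edf_kept), 1.0 / len(edf_kept))
        drawn = rng.choice(edf_kept, size=n_keep, replace=True, p=w_norm)
        survivors = np.unique(current[drawn])

        coef_map = {int(current[j]) + 1: float(b[j]) for j in edf_kept}
        trace.survivor_count.append(int(len(survivors)))
        trace.survivors.append((survivors + 1).tolist())
        trace.coefficients.append(coef_map)

        if len(survivors) < 2:
            trace.rmsecv.append(float("nan"))
            trace.valid.append(False)
            current = survivors
            continue

        rmsecv = _pls_rmsecv(
            X[:, survivors], y, min(cap, len(survivors)), n_folds, seed
        )
        trace.rmsecv.append(rmsecv)
        trace.valid.append(True)
        if rmsecv < best_rmsecv:
            best_rmsecv = rmsecv
            best_survivors = survivors
        current = survivors

    if best_survivors is None:
        raise SelectionError("all CARS iterations were invalid")

    indices = (best_survivors + 1).tolist()
    return SelectionResult(
        method="CARS",
        selected_indices=indices,
        selected_wavelengths=(
            [float(wavelengths[j]) for j in best_survivors] if wavelengths is not None else None
        ),
        score=best_rmsecv,
        trace=trace.as_dict(),
    )


def cars_spa_select(
    X: np.ndarray,
    y: np.ndarray,
    wavelengths: Optional[Sequence[float]] = None,
    spa_params: Optional[Dict[str, Any]] = None,
    cars_params: Optional[Dict[str, Any]] = None,
) -> SelectionResult:
    """SPA on the full matrix, then CARS restricted to the SPA columns.

    The result's indices refer to the original columns; the trace keeps both
    stages.  Raises :class:`ChainingError` when SPA returns fewer than three
    bands (CARS needs at least three columns).
    """
    spa_params = dict(spa_params or {})
    cars_params = dict(cars_params or {})
    spa_res = spa_select(X, y, wavelengths=wavelengths, **spa_params)
    if spa_res.n_selected < 3:
        raise ChainingError(
            f"SPA stage returned {spa_res.n_selected} band(s); need >= 3 to chain CARS"
        )
    cols0 = [i - 1 for i in spa_res.selected_indices]
    sub_wl = [wavelengths[c] for c in cols0] if wavelengths is not None else None
    cars_res = cars_select(X[:, cols0], y, wavelengths=sub_wl, **cars_params)
    final0 = [cols0[j - 1] for j in cars_res.selected_indices]
    return SelectionResult(
        method="CARS_SPA",
        selected_indices=[c + 1 for c in final0],
        selected_wavelengths=(
            [float(wavelengths[c]) for c in final0] if wavelengths is not None else None
        ),
        score=cars_res.score,
        trace={"spa": spa_res.trace | {"selected_indices": spa_res.selected_indices},
               "cars": cars_res.trace},
    )
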