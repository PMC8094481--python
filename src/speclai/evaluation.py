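"""Accuracy metrics (R^2, RMSE, RPD), RPD quality banding, the area-based
calibration/validation split, and the 15-row method x variable-set
comparison."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    DegenerateTargetError,
    ParameterError,
    SplitError,
)
from .models import default_spec, fit_model
from .preprocessing import correlation_spectrum, fd_select_bands, first_derivative
from .selection import cars_select, cars_spa_select, spa_select
from .sensors import SpectraSet

__all__ = [
    "EvaluationReport",
    "ComparisonTable",
    "r_squared",
    "rmse",
    "rpd",
    "rpd_class",
    "split_by_area",
    "evaluate_predictions",
    "run_comparison",
    "RPD_CAP",
    "VARIABLE_SETS",
]

#: Sentinel reported when RMSE is exactly zero (RPD would be infinite).
RPD_CAP = 999.0

VARIABLE_SETS = ("Full_spectrum", "FD", "SPA", "CARS", "CARS_SPA")
MODEL_METHODS = ("PLSR", "SVR", "GBT")


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation between measured ``x`` and predicted ``y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AlignmentError("measured and predicted vectors differ in length")
    if len(x) < 2:
        raise ParameterError("need at least 2 points")
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = float(xc @ xc), float(yc @ yc)
    if sx == 0 or sy == 0:
        raise DegenerateTargetError("zero variance in measured or predicted values")
    return float((xc @ yc) ** 2 / (sx * sy))


def rmse(x: Sequence[float], y: Sequence[float]) -> float:
    """Root mean square error between measured ``x`` and predicted ``y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AlignmentError("measured and predicted vectors differ in length")
    if len(x) < 1:
        raise ParameterError("need at least 1 point")
    return float(np.sqrt(np.mean((y - x) ** 2)))


def rpd(x: Sequence[float], rmse_value: float) -> float:
    """Sample SD (n-1 denominator) of measured values divided by RMSE."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ParameterError("need at least 2 points")
    if rmse_value < 0:
        raise ParameterError("rmse must be >= 0")
    sd = float(np.std(x, ddof=1))
    if rmse_value == 0:
        return RPD_CAP
    return sd / rmse_value


def rpd_class(value: float) -> str:
    """Qualitative prediction-quality band of an RPD value.

    Boundaries belong to the upper class; values <= 1.0 are below-scale.
    """
    if value <= 0:
        raise ParameterError("rpd must be positive")
    if value < 1.4:
        return "below-scale" if value <= 1.0 else "poor"
    if value < 1.8:
        return "correlation-assessment"
    if value < 2.0:
        return "quantitative"
    if value < 2.5:
        return "accurate-quantitative"
    return "better"


@dataclass
class EvaluationReport:
    """Calibration + validation metrics for one fitted model."""

    calibration: Dict[str, float]
    validation: Dict[str, float]
    rpd_class: str

    def to_dict(self) -> Dict[str, Any]:
        return {
            "calibration": self.calibration,
            "validation": self.validation,
            "rpd_class": self.rpd_class,
        }


def evaluate_predictions(
    x_cal, y_cal, x_val, y_val
) -> EvaluationReport:
    """Metrics on both sets; the quality class is the validation RPD's."""
    cal = {
        "r2": r_squared(x_cal, y_cal),
        "rmse": rmse(x_cal, y_cal),
        "n": int(len(np.asarray(x_cal))),
    }
    cal["rpd"] = rpd(x_cal, cal["rmse"])
    val = {
        "r2": r_squared(x_val, y_val),
        "rmse": rmse(x_val, y_val),
        "n": int(len(np.asarray(x_val))),
    }
    val["rpd"] = rpd(x_val, val["rmse"])
    return EvaluationReport(cal, val, rpd_class(val["rpd"]))


def split_by_area(
    spectra: SpectraSet,
    calibration_areas: Tuple[int, ...] = (1, 3),
    validation_areas: Tuple[int, ...] = (2,),
) -> Tuple[SpectraSet, SpectraSet]:
    """Partition samples by experimental area (default: 1 and 3 calibrate,
    2 validates).  Quality-flagged samples are assumed already excluded."""
    if "area" not in spectra.metadata.columns:
        raise SplitError("metadata lacks an 'area' column")
    areas = spectra.metadata["area"].to_numpy()
    known = set(calibration_areas) | set(validation_areas)
    if not set(np.unique(areas)).issubset(known):
        raise SplitError(f"samples with area outside {sorted(known)}")
    cal_mask = np.isin(areas, calibration_areas)
    val_mask = np.isin(areas, validation_areas)
    if not val_mask.any():
        raise SplitError("validation set is empty")
    if not cal_mask.any():
        raise SplitError("calibration set is empty")
    return spectra.subset_rows(cal_mask), spectra.subset_rows(val_mask)


@dataclass
class ComparisonTable:
    """Rows: modeling method x variable-extraction set, with per-set metrics."""

    frame: pd.DataFrame
    selections: Dict[str, List[int]] = field(default_factory=dict)

    COLUMNS = [
        "modeling_method",
        "variable_extraction",
        "wavelengths_number",
        "cal_r2",
        "cal_rmse",
        "cal_rpd",
        "val_r2",
        "val_rmse",
        "val_rpd",
        "status",
    ]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __str__(self) -> str:
        return self.frame.to_string(index=False, float_format=lambda v: f"{v:.3f}")


def _select_variable_sets(
    cal: SpectraSet,
    fd_threshold: float,
    spa_params: Dict[str, Any],
    cars_params: Dict[str, Any],
    seed: int,
) -> Dict[str, List[int]]:
    """Run all four selectors on the calibration set (validation untouched).

    Returns 1-based column indices into the trimmed grid per variable set.
    """
    p = cal.grid.n_bands
    X, y = cal.reflectance, cal.lai
    wl = cal.wavelengths

    fd = first_derivative(cal)
    fd_corr = correlation_spectrum(fd, source="fd")
    fd_wl = fd_select_bands(fd_corr, threshold=fd_threshold)
    fd_idx = sorted(cal.grid.band_index(w) for w in fd_wl)

    spa_kwargs = {"k_min": 5, "k_max": p, "seed": seed, **spa_params}
    cars_kwargs = {"seed": seed, **cars_params}
    spa_res = spa_select(X, y, wavelengths=wl, **spa_kwargs)
    cars_res = cars_select(X, y, wavelengths=wl, **cars_kwargs)
    chain_res = cars_spa_select(
        X, y, wavelengths=wl, spa_params=spa_kwargs, cars_params=cars_kwargs
    )
    return {
        "Full_spectrum": list(range(1, p + 1)),
        "FD": fd_idx,
        "SPA": spa_res.selected_indices,
        "CARS": cars_res.selected_indices,
        "CARS_SPA": chain_res.selected_indices,
    }


def run_comparison(
    spectra: SpectraSet,
    lai: Optional[np.ndarray] = None,
    methods: Sequence[str] = MODEL_METHODS,
    variable_sets: Sequence[str] = VARIABLE_SETS,
    model_specs: Optional[Dict[str, Any]] = None,
    fd_threshold: float = 0.6,
    spa_params: Optional[Dict[str, Any]] = None,
    cars_params: Optional[Dict[str, Any]] = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> ComparisonTable:
    """Fit every requested method on every variable set and tabulate metrics.

    Band selection and hyperparameter tuning use the calibration areas only;
    the validation area is scored once per row.  A failing selector or model
    marks its row(s) ``failed`` without aborting the table.
    """
    if lai is not None:
        spectra = SpectraSet(spectra.grid, spectra.reflectance, spectra.metadata, lai)
    if spectra.lai is None:
        raise ParameterError("spectra set carries no LAI target")
    cal, val = split_by_area(spectra)
    sample_ids = (
        cal.metadata["sample_id"].to_numpy() if "sample_id" in cal.metadata.columns else None
    )

    selections: Dict[str, List[int]] = {}
    selection_errors: Dict[str, str] = {}
    try:
        selections = _select_variable_sets(
            cal, fd_threshold, spa_params or {}, cars_params or {}, seed
        )
    except Exception as exc:  # pragma: no cover - defensive
        selection_errors["__all__"] = str(exc)

    rows = []
    for method in methods:
        for varset in variable_sets:
            row: Dict[str, Any] = {
                "modeling_method": method,
                "variable_extraction": varset,
            }
            try:
                if varset not in selections:
                    raise RuntimeError(
                        selection_errors.get("__all__", f"no selection for {varset}")
                    )
                idx = selections[varset]
                if not idx:
                    raise RuntimeError("empty variable set")
                cols = [i - 1 for i in idx]
                wl = cal.wavelengths[cols]
                spec = (model_specs or {}).get(method) or default_spec(
                    method, cv_folds=cv_folds, seed=seed
                )
                model = fit_model(
                    method, cal.reflectance[:, cols], cal.lai,
                    spec=spec, wavelengths=wl, sample_ids=sample_ids,
                )
                report = evaluate_predictions(
                    cal.lai, model.predict(cal.reflectance[:, cols]),
                    val.lai, model.predict(val.reflectance[:, cols]),
                )
                row.update(
                    wavelengths_number=len(idx),
                    cal_r2=report.calibration["r2"],
                    cal_rmse=report.calibration["rmse"],
                    cal_rpd=report.calibration["rpd"],
                    val_r2=report.validation["r2"],
                    val_rmse=report.validation["rmse"],
                    val_rpd=report.validation["rpd"],
                    status="ok",
                )
            except Exception as exc:
                row.update(
                    wavelengths_number=len(selections.get(varset, [])),
                    cal_r2=np.nan, cal_rmse=np.nan, cal_rpd=np.nan,
                    val_r2=np.nan, val_rmse=np.nan, val_rpd=np.nan,
                    status=f"failed: {exc}",
                )
            rows.append(row)
    frame = pd.DataFrame(rows, columns=ComparisonTable.COLUMNS)
    return ComparisonTable(frame, selections)
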