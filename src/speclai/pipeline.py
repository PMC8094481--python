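"""End-to-end orchestration: config, artifact directory, and the per-pixel
LAI map demonstration on a synthetic image cube."""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import AlignmentError, ParameterError
from .evaluation import run_comparison, split_by_area
from .models import FittedModel, fit_model, save_model
from .sensors import BandGrid, SpectraSet, trim_reliable, write_spectra_csv
from .synthetic import (
    CanopyParams,
    LAIParams,
    simulate_canopy_spectrum,
    simulate_dataset,
    simulate_design,
    simulate_lai,
)

__all__ = ["PipelineConfig", "run_pipeline", "predict_map", "simulate_cube"]

log = logging.getLogger("speclai")


@dataclass
class PipelineConfig:
    """Fully serializable run configuration (archived beside the outputs)."""

    n_plots: int = 44
    seed: int = 0
    grid: Dict[str, float] = field(
        default_factory=lambda: {"start_nm": 450.0, "step_nm": 4.0, "n_bands": 125, "fwhm_nm": 8.0}
    )
    trim: Tuple[int, int] = (3, 96)
    srf: str = "gaussian"
    lai_params: Dict[str, Any] = field(default_factory=dict)
    canopy_params: Dict[str, Any] = field(default_factory=dict)
    fd_threshold: float = 0.6
    spa_params: Dict[str, Any] = field(default_factory=dict)
    cars_params: Dict[str, Any] = field(default_factory=dict)
    methods: Tuple[str, ...] = ("PLSR", "SVR", "GBT")
    variable_sets: Tuple[str, ...] = ("Full_spectrum", "FD", "SPA", "CARS", "CARS_SPA")
    cv_folds: int = 5
    out_dir: str = "speclai_run"

    def band_grid(self) -> BandGrid:
        g = self.grid
        return BandGrid(g["start_nm"], g["step_nm"], int(g["n_bands"]), g["fwhm_nm"])

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("trim", "methods", "variable_sets"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _make_dataset(config: PipelineConfig) -> SpectraSet:
    design = simulate_design(config.n_plots, seed=config.seed)
    lai_params = LAIParams(**config.lai_params) if config.lai_params else None
    canopy_params = CanopyParams(**config.canopy_params) if config.canopy_params else None
    samples = simulate_lai(design, seed=config.seed, params=lai_params)
    return simulate_dataset(
        design, samples, config.band_grid(),
        seed=config.seed, canopy_params=canopy_params, srf=config.srf,
    )


def run_pipeline(config: PipelineConfig, spectra: Optional[SpectraSet] = None) -> Path:
    """Generate (or accept) spectra, trim, select, fit, evaluate, and write
    all artifacts to the configured output directory.

    Returns the artifact directory.  Individual row failures are recorded in
    the comparison table; the run only fails if no row completes.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("speclai %s on python %s", __version__, platform.python_version())
        log.info("seed=%d n_plots=%d", config.seed, config.n_plots)
        config.to_yaml(out / "config.yaml")

        if spectra is None:
            spectra = _make_dataset(config)
            log.info("simulated %d usable samples", spectra.n_samples)
        write_spectra_csv(spectra, out / "spectra.csv")

        trimmed = trim_reliable(spectra, *config.trim)
        log.info("trimmed to %d bands (%g-%g nm)", trimmed.grid.n_bands,
                 trimmed.wavelengths[0], trimmed.wavelengths[-1])

        table = run_comparison(
            trimmed,
            methods=config.methods,
            variable_sets=config.variable_sets,
            fd_threshold=config.fd_threshold,
            spa_params=config.spa_params,
            cars_params=config.cars_params,
            cv_folds=config.cv_folds,
            seed=config.seed,
        )
        table.to_csv(out / "comparison.csv")
        (out / "selections.json").write_text(
            json.dumps({k: v for k, v in table.selections.items()}, indent=2)
        )

        ok = table.frame[table.frame["status"] == "ok"]
        if ok.empty:
            raise RuntimeError("no comparison row completed")

        # refit the best row (by validation RMSE) and dump scatter data
        best = ok.sort_values("val_rmse").iloc[0]
        idx = table.selections[best["variable_extraction"]]
        cols = [i - 1 for i in idx]
        cal, val = split_by_area(trimmed)
        model = fit_model(
            best["modeling_method"], cal.reflectance[:, cols], cal.lai,
            wavelengths=cal.wavelengths[cols],
            sample_ids=cal.metadata.get("sample_id"),
        )
        save_model(model, out / "best_model.json")
        scatter = []
        for name, part in (("calibration", cal), ("validation", val)):
            pred = model.predict(part.reflectance[:, cols])
            for m, p_, sid in zip(part.lai, pred, part.metadata["sample_id"]):
                scatter.append({"set": name, "sample_id": sid, "measured": m, "predicted": p_})
        pd.DataFrame(scatter).to_csv(out / "scatter.csv", index=False)
        log.info(
            "best row: %s x %s (validation RMSE %.3f); done in %.1f s",
            best["modeling_method"], best["variable_extraction"],
            best["val_rmse"], time.time() - t0,
        )
        return out
    finally:
        log.removeHandler(handler)
        handler.close()


def simulate_cube(
    lai_field: np.ndarray,
    n_rate: float,
    grid: BandGrid,
    seed: int = 0,
    canopy_params: Optional[CanopyParams] = None,
) -> np.ndarray:
    """Build a (height, width, bands) reflectance cube from a known LAI field."""
    lai_field = np.asarray(lai_field, dtype=float)
    h, w = lai_field.shape
    from .sensors import resample_to_grid

    cube = np.empty((h, w, grid.n_bands))
    for i in range(h):
        for j in range(w):
            fine = simulate_canopy_spectrum(
                lai_field[i, j], n_rate, seed=seed * 1000003 + i * w + j,
                params=canopy_params,
            )
            cube[i, j] = resample_to_grid(fine, grid)
    return cube


def predict_map(
    model: FittedModel,
    cube: np.ndarray,
    grid: BandGrid,
) -> np.ndarray:
    """Per-pixel LAI prediction over a reflectance cube.

    Pixels with any band outside [0, 1] are masked (NaN).  The model's
    training wavelengths must be a subset of the cube's band centers.
    """
    cube = np.asarray(cube, dtype=float)
    if cube.ndim != 3 or cube.shape[2] != grid.n_bands:
        raise AlignmentError(
            f"cube has {cube.shape[2] if cube.ndim == 3 else '?'} bands, "
            f"grid declares {grid.n_bands}"
        )
    wl = grid.wavelengths
    if model.wavelengths is None:
        cols = np.arange(grid.n_bands)
    else:
        cols = []
        for w in model.wavelengths:
            hits = np.flatnonzero(np.isclose(wl, w))
            if hits.size == 0:
                raise AlignmentError(f"model wavelength {w} nm not present in cube grid")
            cols.append(hits[0])
        cols = np.asarray(cols)
    h, w_ = cube.shape[:2]
    flat = cube.reshape(-1, grid.n_bands)
    valid = np.all((flat >= 0.0) & (flat <= 1.0), axis=1)
    out = np.full(h * w_, np.nan)
    if valid.any():
        out[valid] = model.predict(flat[np.ix_(valid, cols)])
    return out.reshape(h, w_)
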