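"""Synthetic field campaign: designs, LAI values and canopy spectra.

The generator stands in for an undeposited field dataset.  It produces a
replicated cultivar x nitrogen plot design observed at three growth stages,
log-normal LAI values whose pooled moments match the campaign summary
(mean ~5.4, SD ~1.7), and fine-grid canopy reflectance spectra built from a
two-flux Beer-Lambert soil/canopy mixture:

    R(lambda) = R_soil(lambda) * exp(-G * LAI)
              + R_canopy(lambda) * (1 - exp(-G * LAI))

``R_canopy`` carries the qualitative structure of a wheat canopy: blue and
red (674 nm) chlorophyll absorption wells deepening with nitrogen rate, a
green peak near 550 nm, a logistic red edge over 690-790 nm, and a NIR
plateau rising with nitrogen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import DesignError, ParameterError
from .sensors import BandGrid, SpectraSet, resample_to_grid

__all__ = [
    "CULTIVARS",
    "N_TREATMENTS",
    "STAGES",
    "Plot",
    "ExperimentalDesign",
    "LAISample",
    "FineSpectrum",
    "LAIParams",
    "CanopyParams",
    "simulate_design",
    "simulate_lai",
    "simulate_canopy_spectrum",
    "simulate_dataset",
]

CULTIVARS: Tuple[str, ...] = ("AK58", "ZM27", "XN509", "YM49-198")
#: Treatment label -> nitrogen application rate in kg/hm^2.
N_TREATMENTS: Dict[str, int] = {"N0": 0, "N8": 120, "N15": 225, "N22": 330}
STAGES: Tuple[str, ...] = ("jointing", "booting", "filling")


@dataclass(frozen=True)
class Plot:
    plot_id: str
    cultivar: str
    n_treatment: str
    area: int

    @property
    def n_rate(self) -> int:
        return N_TREATMENTS[self.n_treatment]


@dataclass(frozen=True)
class ExperimentalDesign:
    """Plot layout across three experimental areas plus the stage sequence."""

    plots: Tuple[Plot, ...]
    stages: Tuple[str, ...] = STAGES

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def n_samples(self) -> int:
        return len(self.plots) * len(self.stages)

    def plot(self, plot_id: str) -> Plot:
        for p in self.plots:
            if p.plot_id == plot_id:
                return p
        raise KeyError(plot_id)


@dataclass(frozen=True)
class LAISample:
    plot_id: str
    stage: str
    lai: float
    quality_flag: bool = True  # False = excluded from analysis


@dataclass(frozen=True)
class FineSpectrum:
    """1-nm-step reflectance spectrum on a window covering 400-1000 nm."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if wl.shape != r.shape:
            raise ParameterError("wavelengths and reflectance differ in length")
        if np.any(np.diff(wl) <= 0):
            raise ParameterError("wavelengths must be strictly increasing")
        if np.any((r < 0) | (r > 1)):
            raise ParameterError("reflectance outside [0, 1]")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", r)


def simulate_design(n_plots: int = 44, seed: int = 0) -> ExperimentalDesign:
    """Assign cultivar x nitrogen combinations to plots in three areas.

    The 16 combinations are cycled over a seeded shuffle so every
    combination is covered whenever ``n_plots >= 16`` and counts stay
    balanced (no combination appears more than one time above any other).
    Areas receive near-equal contiguous blocks of plots.
    """
    combos = [(c, t) for c in CULTIVARS for t in N_TREATMENTS]
    if n_plots < len(combos):
        raise DesignError(
            f"n_plots={n_plots} cannot cover all {len(combos)} cultivar x "
            "treatment combinations"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))
    assigned = [combos[order[i % len(combos)]] for i in range(n_plots)]

    base, extra = divmod(n_plots, 3)
    area_sizes = [base + (1 if a < extra else 0) for a in range(3)]
    plots: List[Plot] = []
    i = 0
    for area, size in enumerate(area_sizes, start=1):
        for _ in range(size):
            cultivar, treatment = assigned[i]
            plots.append(Plot(f"P{i + 1:03d}", cultivar, treatment, area))
            i += 1
    return ExperimentalDesign(tuple(plots))


@dataclass(frozen=True)
class LAIParams:
    """Generative parameters of the LAI model
    ``lai = base(stage) * g(N) * cultivar_factor * exp(eps)``.

    Defaults are tuned so the pooled usable sample has mean ~5.4 and
    SD ~1.7 with values inside [1.5, 8.8].
    """

    stage_base: Dict[str, float] = field(
        default_factory=lambda: {"jointing": 4.5, "booting": 7.0, "filling": 5.0}
    )
    # monotone nondecreasing in N with a plateau between N15 and N22
    n_response: Dict[str, float] = field(
        default_factory=lambda: {"N0": 0.65, "N8": 0.93, "N15": 1.14, "N22": 1.18}
    )
    cultivar_factor: Dict[str, float] = field(
        default_factory=lambda: {"AK58": 0.95, "ZM27": 1.00, "XN509": 1.02, "YM49-198": 1.05}
    )
    sigma: float = 0.14
    n_flagged: int = 8
    lai_range: Tuple[float, float] = (1.55, 8.75)


def simulate_lai(
    design: ExperimentalDesign,
    seed: int = 0,
    params: Optional[LAIParams] = None,
) -> List[LAISample]:
    """Draw one LAI per plot x stage; flag a seeded random subset unusable.

    The stage base peaks at booting (rise then fall through the season) and
    the nitrogen response plateaus between the two highest rates.
    """
    params = params or LAIParams()
    if params.sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {params.sigma}")
    rng = np.random.default_rng(seed)
    samples: List[LAISample] = []
    lo, hi = params.lai_range
    for stage in design.stages:
        for plot in design.plots:
            eps = rng.normal(0.0, params.sigma)
            lai = (
                params.stage_base[stage]
                * params.n_response[plot.n_treatment]
                * params.cultivar_factor[plot.cultivar]
                * np.exp(eps)
            )
            samples.append(LAISample(plot.plot_id, stage, float(np.clip(lai, lo, hi))))
    n_flag = params.n_flagged
    if n_flag > len(samples):
        raise ParameterError("cannot flag more samples than exist")
    flagged = set(rng.choice(len(samples), size=n_flag, replace=False).tolist())
    return [
        LAISample(s.plot_id, s.stage, s.lai, quality_flag=i not in flagged)
        for i, s in enumerate(samples)
    ]


@dataclass(frozen=True)
class CanopyParams:
    """Shape parameters of the two-flux canopy reflectance model."""

    window: Tuple[float, float] = (400.0, 1000.0)  # fine grid, 1 nm step
    extinction: float = 0.5  # Beer-Lambert G
    visible_level: float = 0.105
    visible_n_drop: float = 0.030  # visible darkening per unit nitrogen fraction
    green_peak: Tuple[float, float, float] = (550.0, 18.0, 0.055)  # center, sd, height
    blue_well: Tuple[float, float, float] = (470.0, 22.0, 0.030)
    blue_well_n_gain: float = 0.015
    red_well: Tuple[float, float, float] = (674.0, 11.0, 0.055)
    red_well_n_gain: float = 0.020
    red_edge_center: float = 720.0
    red_edge_width: float = 15.0
    nir_level: float = 0.44
    nir_n_gain: float = 0.050
    soil_intercept: float = 0.12
    soil_slope: float = 0.00025  # per nm above 400
    noise_sd: float = 0.002


def _gauss(wl: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sd) ** 2)


def canopy_reflectance(wl: np.ndarray, n_rate: float, params: CanopyParams) -> np.ndarray:
    """Asymptotic (dense-canopy) reflectance curve for a nitrogen rate."""
    f = n_rate / max(N_TREATMENTS.values())
    c, s, h = params.green_peak
    vis = params.visible_level - params.visible_n_drop * f + h * _gauss(wl, c, s)
    c, s, h = params.blue_well
    vis = vis - (h + params.blue_well_n_gain * f) * _gauss(wl, c, s)
    c, s, h = params.red_well
    vis = vis - (h + params.red_well_n_gain * f) * _gauss(wl, c, s)
    edge = 1.0 / (1.0 + np.exp(-(wl - params.red_edge_center) / params.red_edge_width))
    nir = params.nir_level + params.nir_n_gain * f
    return (1.0 - edge) * vis + edge * nir


def soil_reflectance(wl: np.ndarray, params: CanopyParams) -> np.ndarray:
    return params.soil_intercept + params.soil_slope * (wl - 400.0)


def simulate_canopy_spectrum(
    lai: float,
    n_rate: float,
    seed: int = 0,
    params: Optional[CanopyParams] = None,
) -> FineSpectrum:
    """Simulate a fine-grid (1 nm) canopy reflectance spectrum.

    Soil and dense-canopy end members are mixed with Beer-Lambert weights
    ``exp(-G * LAI)``; seeded Gaussian noise (default SD 0.002) is added per
    wavelength and the result clipped to [0, 1].

    Raises
    ------
    ParameterError
        If ``lai <= 0`` or ``n_rate`` is negative.
    """
    params = params or CanopyParams()
    if lai <= 0:
        raise ParameterError(f"lai must be positive, got {lai}")
    if n_rate < 0:
        raise ParameterError(f"n_rate must be >= 0, got {n_rate}")
    lo, hi = params.window
    wl = np.arange(lo, hi + 0.5, 1.0)
    weight = np.exp(-params.extinction * lai)
    r = soil_reflectance(wl, params) * weight + canopy_reflectance(wl, n_rate, params) * (
        1.0 - weight
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, params.noise_sd, size=r.shape)
    return FineSpectrum(wl, np.clip(r, 0.0, 1.0))


def simulate_dataset(
    design: ExperimentalDesign,
    samples: Sequence[LAISample],
    grid: BandGrid,
    seed: int = 0,
    lai_params: Optional[LAIParams] = None,
    canopy_params: Optional[CanopyParams] = None,
    srf: str = "gaussian",
) -> SpectraSet:
    """Resample one simulated fine spectrum per usable sample onto ``grid``.

    Returns a :class:`SpectraSet` with full metadata and the LAI vector;
    quality-flagged samples are excluded.  Per-sample noise seeds are
    derived from ``seed`` so the output is reproducible as a whole.
    """
    usable = [s for s in samples if s.quality_flag]
    rows, meta, lai = [], [], []
    for i, s in enumerate(usable):
        plot = design.plot(s.plot_id)
        fine = simulate_canopy_spectrum(
            s.lai, plot.n_rate, seed=seed * 100003 + i, params=canopy_params
        )
        rows.append(resample_to_grid(fine, grid, srf=srf))
        meta.append(
            {
                "sample_id": f"{s.plot_id}-{s.stage}",
                "plot_id": s.plot_id,
                "stage": s.stage,
                "cultivar": plot.cultivar,
                "n_treatment": plot.n_treatment,
                "area": plot.area,
            }
        )
        lai.append(s.lai)
    return SpectraSet(grid, np.vstack(rows), pd.DataFrame(meta), np.asarray(lai))
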