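"""First-derivative transform, band-wise LAI correlation, and the
correlation-threshold band-picking rule applied to derivative spectra."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DegenerateTargetError, GridError
from .sensors import SpectraSet

__all__ = [
    "CorrelationSpectrum",
    "first_derivative",
    "correlation_spectrum",
    "fd_select_bands",
]


@dataclass(frozen=True)
class CorrelationSpectrum:
    """Per-band Pearson correlation against the target.

    ``source`` records whether the bands are raw reflectance ("raw") or
    first-derivative transformed ("fd"); ``degenerate`` flags bands whose
    reflectance had zero variance (their r is recorded as 0).
    """

    wavelengths: np.ndarray
    r: np.ndarray
    source: str = "raw"
    degenerate: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.r, dtype=float)
        if wl.shape != r.shape:
            raise AlignmentError("wavelengths and r differ in length")
        if np.any(np.abs(r) > 1 + 1e-12):
            raise ValueError("correlation outside [-1, 1]")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "r", r)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "r": self.r, "source": self.source}
        )


def first_derivative(spectra: SpectraSet, scheme: str = "central") -> SpectraSet:
    """Differentiate reflectance with respect to wavelength (units 1/nm).

    The default central-difference stencil
    ``(R[k+1] - R[k-1]) / (wl[k+1] - wl[k-1])`` is exact for quadratics; the
    two edge bands are dropped.  ``scheme="forward"`` uses
    ``(R[k+1] - R[k]) / step`` and drops only the last band.
    """
    wl = spectra.wavelengths
    if spectra.grid.n_bands < 3:
        raise GridError("first derivative needs at least 3 bands")
    steps = np.diff(wl)
    if not np.allclose(steps, steps[0]):
        raise GridError("first derivative requires a uniform band grid")
    R = spectra.reflectance
    if scheme == "central":
        fd = (R[:, 2:] - R[:, :-2]) / (wl[2:] - wl[:-2])
        new_grid = replace(spectra.grid, start_nm=float(wl[1]), n_bands=spectra.grid.n_bands - 2)
    elif scheme == "forward":
        fd = (R[:, 1:] - R[:, :-1]) / steps
        new_grid = replace(spectra.grid, start_nm=float(wl[0]), n_bands=spectra.grid.n_bands - 1)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return SpectraSet(new_grid, fd, spectra.metadata, spectra.lai)


def correlation_spectrum(
    spectra: SpectraSet, lai: Optional[np.ndarray] = None, source: str = "raw"
) -> CorrelationSpectrum:
    """Pearson correlation of every band column with the LAI vector.

    Zero-variance bands get ``r = 0`` with a warning and are flagged in the
    result's ``degenerate`` mask.
    """
    y = np.asarray(spectra.lai if lai is None else lai, dtype=float)
    X = spectra.reflectance
    if y.shape != (X.shape[0],):
        raise AlignmentError("lai vector does not match sample count")
    if X.shape[0] < 3:
        raise DegenerateTargetError("need at least 3 samples for correlation")
    if np.var(y) == 0:
        raise DegenerateTargetError("lai has zero variance")
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    degenerate = sx == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance band(s); r recorded as 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r = np.where(degenerate, 0.0, r)
    return CorrelationSpectrum(spectra.wavelengths, np.clip(r, -1.0, 1.0), source, degenerate)


def fd_select_bands(corr: CorrelationSpectrum, threshold: float = 0.6) -> List[float]:
    """Pick one peak band per contiguous run of high-correlation bands.

    Bands with ``|r| >= threshold`` are partitioned into maximal runs of
    consecutive band indices; from each run the band with the largest |r| is
    returned (ties broken toward the lower wavelength).  An empty selection
    is returned, not raised, when no band passes.
    """
    passing = np.flatnonzero(np.abs(corr.r) >= threshold)
    if passing.size == 0:
        return []
    # a run breaks on non-adjacent band indices or a wavelength gap larger
    # than one grid step
    step = float(np.median(np.diff(corr.wavelengths))) if len(corr.wavelengths) > 1 else 1.0
    gap = np.diff(corr.wavelengths[passing])
    selected: List[float] = []
    breaks = np.flatnonzero((np.diff(passing) > 1) | (gap > 1.5 * step))
    bounds = np.concatenate([[-1], breaks, [passing.size - 1]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        run = passing[a + 1 : b + 1]
        peak = run[np.argmax(np.abs(corr.r[run]))]  # argmax takes first on ties
        selected.append(float(corr.wavelengths[peak]))
    return selected
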