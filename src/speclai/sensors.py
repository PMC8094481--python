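"""Sensor band grids, spectral resampling, band trimming and tabular I/O.

A :class:`BandGrid` describes an imaging spectrometer as a uniformly sampled
set of band centers (1-based indexing at every public interface).  Fine
(spectroradiometer-style) spectra are resampled onto a grid through a
Gaussian spectral response function, or optionally a boxcar mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, CoverageError, GridError

__all__ = [
    "BandGrid",
    "SpectraSet",
    "UHD185_GRID",
    "ASD_VNIR_GRID",
    "band_wavelength",
    "band_index",
    "resample_to_grid",
    "trim_reliable",
    "cross_sensor_r2",
    "write_spectra_csv",
    "read_spectra_csv",
    "write_grid_descriptor",
    "read_grid_descriptor",
]

#: Metadata columns stored alongside reflectance in the CSV layout.
METADATA_COLUMNS = ("sample_id", "plot_id", "stage", "cultivar", "n_treatment", "area")


@dataclass(frozen=True)
class BandGrid:
    """Uniform band-center grid of an imaging spectrometer.

    Band ``k`` (1-based) has center ``start_nm + step_nm * (k - 1)`` and a
    Gaussian response of full width at half maximum ``fwhm_nm``.
    """

    start_nm: float
    step_nm: float
    n_bands: int
    fwhm_nm: float

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise GridError(f"step_nm must be positive, got {self.step_nm}")
        if self.n_bands < 1:
            raise GridError(f"n_bands must be >= 1, got {self.n_bands}")
        if self.fwhm_nm <= 0:
            raise GridError(f"fwhm_nm must be positive, got {self.fwhm_nm}")

    @property
    def wavelengths(self) -> np.ndarray:
        """Band centers in nm for bands 1..n_bands."""
        return self.start_nm + self.step_nm * np.arange(self.n_bands)

    def band_wavelength(self, k: int) -> float:
        """Center wavelength (nm) of 1-based band index ``k``."""
        if not 1 <= k <= self.n_bands:
            raise IndexError(f"band index {k} outside [1, {self.n_bands}]")
        return float(self.start_nm + self.step_nm * (k - 1))

    def band_index(self, nm: float) -> int:
        """Inverse of :meth:`band_wavelength` for on-grid wavelengths."""
        k = (nm - self.start_nm) / self.step_nm + 1
        k_round = int(round(k))
        if abs(k - k_round) > 1e-9 or not 1 <= k_round <= self.n_bands:
            raise IndexError(f"{nm} nm is not a band center of this grid")
        return k_round


#: 125-band VNIR imaging-spectrometer grid: 450 nm start, 4 nm sampling,
#: 8 nm FWHM.  Band 3 -> 458 nm, band 96 -> 830 nm, band 125 -> 946 nm.
UHD185_GRID = BandGrid(start_nm=450.0, step_nm=4.0, n_bands=125, fwhm_nm=8.0)

#: Fine field-spectroradiometer stand-in, restricted to the VNIR window the
#: synthetic fine spectra cover (410-990 nm at 1 nm, 3 nm resolution).
ASD_VNIR_GRID = BandGrid(start_nm=410.0, step_nm=1.0, n_bands=581, fwhm_nm=3.0)


@dataclass
class SpectraSet:
    """Reflectance matrix plus per-sample metadata on a common band grid.

    Attributes
    ----------
    grid : BandGrid
        Band definition; ``reflectance`` has one column per band.
    reflectance : ndarray, shape (n_samples, grid.n_bands)
    metadata : DataFrame, length n_samples
        Columns from :data:`METADATA_COLUMNS` (extra columns are preserved).
    lai : ndarray or None
        Measured target aligned to rows, optional.
    """

    grid: BandGrid
    reflectance: np.ndarray
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    lai: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 2:
            raise AlignmentError("reflectance must be 2-D (samples x bands)")
        if self.reflectance.shape[1] != self.grid.n_bands:
            raise AlignmentError(
                f"reflectance has {self.reflectance.shape[1]} columns, "
                f"grid declares {self.grid.n_bands} bands"
            )
        n = self.reflectance.shape[0]
        if len(self.metadata) not in (0, n):
            raise AlignmentError("metadata length does not match sample count")
        if self.lai is not None:
            self.lai = np.asarray(self.lai, dtype=float)
            if self.lai.shape != (n,):
                raise AlignmentError("lai vector does not match sample count")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def subset_rows(self, mask: np.ndarray) -> "SpectraSet":
        """Row-subset preserving metadata/lai alignment."""
        mask = np.asarray(mask)
        meta = self.metadata.iloc[mask].reset_index(drop=True) if len(self.metadata) else self.metadata
        lai = self.lai[mask] if self.lai is not None else None
        return SpectraSet(self.grid, self.reflectance[mask], meta, lai)


def band_wavelength(grid: BandGrid, k: int) -> float:
    """Center wavelength of 1-based band ``k`` — module-level convenience."""
    return grid.band_wavelength(k)


def band_index(grid: BandGrid, nm: float) -> int:
    return grid.band_index(nm)


def _srf_weights(fine_wl: np.ndarray, center: float, fwhm: float, kind: str) -> np.ndarray:
    """Spectral-response weights on the fine grid, truncated at +/- 2 FWHM."""
    if kind == "gaussian":
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        w = np.exp(-0.5 * ((fine_wl - center) / sigma) ** 2)
        w[np.abs(fine_wl - center) > 2.0 * fwhm] = 0.0
    elif kind == "boxcar":
        w = (np.abs(fine_wl - center) <= fwhm / 2.0).astype(float)
    else:
        raise ValueError(f"unknown SRF kind {kind!r}")
    return w


def resample_to_grid(fine, grid: BandGrid, srf: str = "gaussian") -> np.ndarray:
    """Resample a fine spectrum onto a sensor band grid.

    Each band value is the SRF-weighted average of the fine reflectance,
    centered at the band center with FWHM ``grid.fwhm_nm``; weights are
    normalised to sum to one and truncated at ``+/- 2 * FWHM``.

    Parameters
    ----------
    fine
        Object with ``wavelengths`` (nm, strictly increasing) and
        ``reflectance`` arrays of equal length.
    grid : BandGrid
        Target sensor definition.
    srf : {"gaussian", "boxcar"}
        Response shape; boxcar averages over one FWHM-wide interval.

    Returns
    -------
    ndarray of shape (grid.n_bands,)

    Raises
    ------
    CoverageError
        If the fine grid does not span ``center +/- 2 * FWHM`` for a band.
    """
    wl = np.asarray(fine.wavelengths, dtype=float)
    refl = np.asarray(fine.reflectance, dtype=float)
    if wl.shape != refl.shape:
        raise AlignmentError("fine spectrum arrays differ in length")
    out = np.empty(grid.n_bands)
    half_support = 2.0 * grid.fwhm_nm
    for j, center in enumerate(grid.wavelengths):
        if wl[0] > center - half_support or wl[-1] < center + half_support:
            raise CoverageError(
                f"fine grid [{wl[0]}, {wl[-1]}] nm does not cover band "
                f"{j + 1} ({center} nm) +/- {half_support} nm"
            )
        w = _srf_weights(wl, center, grid.fwhm_nm, srf)
        out[j] = np.sum(w * refl) / np.sum(w)
    return out


def resample_set(fine_spectra: Sequence, grid: BandGrid, srf: str = "gaussian") -> np.ndarray:
    """Vector version of :func:`resample_to_grid` over many fine spectra."""
    return np.vstack([resample_to_grid(f, grid, srf=srf) for f in fine_spectra])


def trim_reliable(spectra: SpectraSet, k_lo: int = 3, k_hi: int = 96) -> SpectraSet:
    """Restrict a spectra set to the reliable band range [k_lo, k_hi].

    With the default 125-band grid this keeps 94 bands spanning 458-830 nm.
    Row order, metadata and the target vector are preserved.
    """
    n = spectra.grid.n_bands
    if not (1 <= k_lo <= k_hi <= n):
        raise IndexError(f"band range [{k_lo}, {k_hi}] invalid for {n}-band grid")
    new_grid = replace(
        spectra.grid,
        start_nm=spectra.grid.band_wavelength(k_lo),
        n_bands=k_hi - k_lo + 1,
    )
    return SpectraSet(
        new_grid,
        spectra.reflectance[:, k_lo - 1 : k_hi],
        spectra.metadata,
        spectra.lai,
    )


def cross_sensor_r2(a: SpectraSet, b: SpectraSet) -> float:
    """Squared Pearson correlation between two aligned spectra sets.

    All (sample, band) reflectance pairs are pooled; both sets must share
    the grid and the sample order.
    """
    if a.grid != b.grid or a.reflectance.shape != b.reflectance.shape:
        raise AlignmentError("spectra sets differ in grid or shape")
    x = a.reflectance.ravel()
    y = b.reflectance.ravel()
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


# ---------------------------------------------------------------------------
# File formats: CSV spectra table + JSON grid descriptor sidecar
# ---------------------------------------------------------------------------

def write_spectra_csv(spectra: SpectraSet, path) -> None:
    """Write one row per sample: metadata, lai, then ``w<nm>`` band columns."""
    path = Path(path)
    cols = {}
    n = spectra.n_samples
    for name in METADATA_COLUMNS:
        if name in spectra.metadata.columns:
            cols[name] = spectra.metadata[name].to_numpy()
        else:
            cols[name] = np.full(n, "", dtype=object)
    cols["lai"] = spectra.lai if spectra.lai is not None else np.full(n, np.nan)
    frame = pd.DataFrame(cols)
    band_names = [_band_column(w) for w in spectra.wavelengths]
    frame = pd.concat(
        [frame, pd.DataFrame(spectra.reflectance, columns=band_names)], axis=1
    )
    frame.to_csv(path, index=False)
    write_grid_descriptor(spectra.grid, path.with_suffix(".grid.json"))


def _band_column(wavelength: float) -> str:
    if float(wavelength).is_integer():
        return f"w{int(wavelength)}"
    return f"w{wavelength:g}"


def read_spectra_csv(path, grid: Optional[BandGrid] = None) -> SpectraSet:
    """Read a spectra table written by :func:`write_spectra_csv`.

    The grid is taken from the ``.grid.json`` sidecar unless given explicitly.
    """
    path = Path(path)
    if grid is None:
        grid = read_grid_descriptor(path.with_suffix(".grid.json"))
    frame = pd.read_csv(path)
    band_names = [_band_column(w) for w in grid.wavelengths]
    missing = [c for c in band_names if c not in frame.columns]
    if missing:
        raise AlignmentError(f"spectra table lacks band columns: {missing[:5]} ...")
    refl = frame[band_names].to_numpy(dtype=float)
    meta = frame[[c for c in METADATA_COLUMNS if c in frame.columns]].copy()
    lai = frame["lai"].to_numpy(dtype=float) if "lai" in frame.columns else None
    if lai is not None and np.all(np.isnan(lai)):
        lai = None
    return SpectraSet(grid, refl, meta, lai)


def write_grid_descriptor(grid: BandGrid, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "start_nm": grid.start_nm,
                "step_nm": grid.step_nm,
                "n_bands": grid.n_bands,
                "fwhm_nm": grid.fwhm_nm,
            },
            indent=2,
        )
    )


def read_grid_descriptor(path) -> BandGrid:
    d = json.loads(Path(path).read_text())
    return BandGrid(d["start_nm"], d["step_nm"], int(d["n_bands"]), d["fwhm_nm"])
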