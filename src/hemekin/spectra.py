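"""Wavelength-indexed spectra and time-ordered spectral series.

These are the substrate of all band arithmetic and unmixing math in the
package: a :class:`Spectrum` is a strictly increasing wavelength grid (nm)
with one signal value per point (absorbance or MCD instrument units), and a
:class:`SpectralSeries` is a time-ordered collection of spectra sharing a
common grid, as produced by repeated scans of a single cuvette.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = ["Spectrum", "SpectralSeries"]


@dataclass(frozen=True)
class Spectrum:
    """A single spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : array-like
        Wavelengths in nm, strictly increasing, length >= 2.
    values : array-like
        Signal at each wavelength (absorbance or MCD units).
    pathlength_cm : float
        Optical pathlength, default 1 cm (10 mm cuvette convention).
    time_min : float, optional
        Acquisition time in minutes for spectra that belong to a series.
    label : str
        Free-text label (sample name, redox state, ...).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    pathlength_cm: float = 1.0
    time_min: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if wl.size != vals.size:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths vs {vals.size} values"
            )
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(vals))):
            raise ValueError("wavelengths and values must be finite")
        if self.pathlength_cm <= 0:
            raise ValueError("pathlength_cm must be positive")

    # -- basic queries -------------------------------------------------
    @property
    def wl_min(self) -> float:
        return float(self.wavelengths[0])

    @property
    def wl_max(self) -> float:
        return float(self.wavelengths[-1])

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def interpolate(self, wl: float | np.ndarray) -> float | np.ndarray:
        """Signal at ``wl`` by linear interpolation.

        Raises ``ValueError`` outside the grid range: spectra are never
        extrapolated.
        """
        wl_arr = np.asarray(wl, dtype=float)
        if np.any(wl_arr < self.wl_min) or np.any(wl_arr > self.wl_max):
            raise ValueError(
                f"wavelength {wl} nm outside grid range "
                f"[{self.wl_min}, {self.wl_max}] nm"
            )
        out = np.interp(wl_arr, self.wavelengths, self.values)
        return float(out) if np.isscalar(wl) or wl_arr.ndim == 0 else out

    def scaled(self, factor: float) -> "Spectrum":
        """Return a copy with the signal multiplied by ``factor``."""
        return replace(self, values=self.values * factor)

    def restricted(self, wl_lo: float, wl_hi: float) -> "Spectrum":
        """Return the sub-spectrum on grid points within [wl_lo, wl_hi]."""
        mask = (self.wavelengths >= wl_lo) & (self.wavelengths <= wl_hi)
        if mask.sum() < 2:
            raise ValueError(
                f"window [{wl_lo}, {wl_hi}] nm contains fewer than 2 grid points"
            )
        return replace(
            self, wavelengths=self.wavelengths[mask], values=self.values[mask]
        )


@dataclass(frozen=True)
class SpectralSeries:
    """Time-ordered spectra on a common wavelength grid."""

    spectra: tuple[Spectrum, ...]
    times_min: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        spectra = tuple(self.spectra)
        object.__setattr__(self, "spectra", spectra)
        if len(spectra) == 0:
            raise ValueError("a series needs at least one spectrum")
        grid = spectra[0].wavelengths
        for i, s in enumerate(spectra[1:], start=1):
            if s.wavelengths.size != grid.size or not np.allclose(
                s.wavelengths, grid
            ):
                raise ValueError(f"spectrum {i} is not on the common grid")
        if self.times_min is None:
            times = np.array(
                [np.nan if s.time_min is None else s.time_min for s in spectra]
            )
        else:
            times = np.asarray(self.times_min, dtype=float)
            if times.size != len(spectra):
                raise ValueError("times_min length must match number of spectra")
        object.__setattr__(self, "times_min", times)
        finite = times[np.isfinite(times)]
        if finite.size == times.size and times.size > 1:
            if not np.all(np.diff(times) > 0):
                raise ValueError("series times must be strictly increasing")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    @property
    def values_matrix(self) -> np.ndarray:
        """(n_times, n_wavelengths) signal matrix."""
        return np.vstack([s.values for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    def scaled(self, factor: float) -> "SpectralSeries":
        return SpectralSeries(
            tuple(s.scaled(factor) for s in self.spectra), self.times_min
        )

    @classmethod
    def from_matrix(
        cls,
        wavelengths: Sequence[float],
        matrix: np.ndarray,
        times_min: Sequence[float],
        pathlength_cm: float = 1.0,
    ) -> "SpectralSeries":
        matrix = np.asarray(matrix, dtype=float)
        times = np.asarray(times_min, dtype=float)
        spectra = tuple(
            Spectrum(wavelengths, row, pathlength_cm=pathlength_cm, time_min=t)
            for row, t in zip(matrix, times)
        )
        return cls(spectra, times)
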