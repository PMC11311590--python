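"""Two-component decomposition of MCD spectral series.

The cyanide complex of ferrous cytochrome c (CytC²⁺–CN) is unstable: after
reduction of the heme iron the MCD spectrum evolves in minutes from the
complex's derivative-shaped band (maximum 550 nm / minimum 555 nm) to the
free ferrous form (maximum 545 nm / minimum 550 nm).  Because the first
usable scan already contains some free form, the pure complex basis cannot
be measured directly.  This module

1. *reconstructs* the complex basis from the first spectrum by symmetry
   restoration — subtracting the fraction of the final (free-form) spectrum
   that makes the remainder maximally antisymmetric about its zero
   crossing, the shape expected for a clean MCD derivative band;
2. *unmixes* every spectrum of the series into a fraction of complex under
   the closed-system constraint f_complex + f_free = 1 (closed-form least
   squares); and
3. locates *isosbestic points*, the wavelengths where all spectra of a
   clean two-state interconversion intersect.

A statsmodels-style :class:`TwoStateUnmixingModel` wraps the three steps:
``fit()`` returns an :class:`UnmixingResults` with per-time percent
complex, residuals, the basis set, and a ``summary()`` table.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .spectra import Spectrum, SpectralSeries

__all__ = [
    "BasisSet",
    "UnmixingResult",
    "UnmixingResults",
    "TwoStateUnmixingModel",
    "normalize_to_concentration",
    "reconstruct_complex_basis",
    "asymmetry_score",
    "unmix",
    "find_isosbestic",
]

DEFAULT_WINDOW = (530.0, 565.0)
#: residual RMS above this fraction of the signal range flags a likely
#: third component (e.g. a degradation product)
RESIDUAL_FLAG_FRACTION = 0.05


@dataclass(frozen=True)
class BasisSet:
    """The two pure-component spectra of the interconversion.

    basis_complex
        Symmetry-restored CytC²⁺–CN spectrum.
    basis_free
        Free ferrous CytC spectrum (end of the experiment).
    zero_cross_nm
        Wavelength of the complex basis' sign change between its extrema.
    f0
        Fraction of complex assigned to the first observed spectrum.
    asymmetry_score
        Residual asymmetry of the reconstructed basis (0 = perfectly
        antisymmetric about the zero crossing).
    """

    basis_complex: Spectrum
    basis_free: Spectrum
    zero_cross_nm: float
    f0: float
    asymmetry_score: float

    def __post_init__(self) -> None:
        if not 0 < self.f0 <= 1:
            raise ValueError("f0 must be in (0, 1]")
        if not np.allclose(
            self.basis_complex.wavelengths, self.basis_free.wavelengths
        ):
            raise ValueError("bases must share a wavelength grid")


@dataclass(frozen=True)
class UnmixingResult:
    """Per-time composition of the series.

    ``fraction_complex`` is clipped to [0, 1]; ``fraction_raw`` keeps the
    unconstrained least-squares value (useful for diagnostics — its
    residual is orthogonal to the basis difference).
    """

    times_min: np.ndarray
    fraction_complex: np.ndarray
    fraction_raw: np.ndarray
    percent_complex: np.ndarray
    residual_rms: np.ndarray
    high_residual_flag: bool = False


def normalize_to_concentration(
    series: SpectralSeries, cytc_uM: float
) -> SpectralSeries:
    """Divide every signal by the protein concentration (µM).

    Puts series recorded on different samples on a common per-µM scale;
    two-component fractions are invariant to this scaling when bases and
    series are scaled together.
    """
    if cytc_uM <= 0:
        raise ValueError("CytC concentration must be positive")
    return series.scaled(1.0 / cytc_uM)


# ----------------------------------------------------------------------
# symmetry-restoration basis reconstruction
# ----------------------------------------------------------------------

def _zero_crossing(wl: np.ndarray, vals: np.ndarray) -> float:
    """Sign-change wavelength between the global max and min, linearly
    interpolated.  Raises if the signal does not change sign there."""
    i_max, i_min = int(np.argmax(vals)), int(np.argmin(vals))
    lo, hi = sorted((i_max, i_min))
    seg = vals[lo : hi + 1]
    sign_change = np.nonzero(np.diff(np.sign(seg)) != 0)[0]
    if sign_change.size == 0:
        raise ValueError("no zero crossing between the spectral extrema")
    j = lo + int(sign_change[0])
    y1, y2 = vals[j], vals[j + 1]
    return float(wl[j] + (wl[j + 1] - wl[j]) * y1 / (y1 - y2))


def asymmetry_score(spectrum: Spectrum) -> float:
    """Deviation of a derivative-shaped band from odd symmetry.

    With λ₀ the zero crossing between the extrema, a perfect MCD
    derivative band satisfies B(λ₀+δ) = −B(λ₀−δ).  The score is

        Σ_δ |B(λ₀+δ) + B(λ₀−δ)| / Σ_δ (|B(λ₀+δ)| + |B(λ₀−δ)|)

    over a dense symmetric offset grid that stays inside the recorded
    range: 0 for an antisymmetric band, up to 1 for an even one.
    """
    wl, vals = spectrum.wavelengths, spectrum.values
    lam0 = _zero_crossing(wl, vals)
    return _asymmetry(wl, vals, lam0)


def _asymmetry(wl: np.ndarray, vals: np.ndarray, lam0: float) -> float:
    max_delta = min(lam0 - wl[0], wl[-1] - lam0)
    if max_delta <= 0:
        return 1.0
    step = np.min(np.diff(wl)) / 2.0
    deltas = np.arange(step, max_delta + step / 2, step)
    right = np.interp(lam0 + deltas, wl, vals)
    left = np.interp(lam0 - deltas, wl, vals)
    denom = np.sum(np.abs(right)) + np.sum(np.abs(left))
    if denom == 0:
        return 0.0
    return float(np.sum(np.abs(right + left)) / denom)


def reconstruct_complex_basis(
    first: Spectrum,
    free: Spectrum,
    window: tuple[float, float] = DEFAULT_WINDOW,
    f_bounds: tuple[float, float] = (0.5, 1.0),
    grid_step: float = 1e-3,
) -> BasisSet:
    """Recover the pure complex basis from the first recorded spectrum.

    Models the first spectrum as ``f·B_complex + (1−f)·B_free`` and
    searches f for the candidate

        B_c(λ; f) = [first(λ) − (1−f)·free(λ)] / f

    with the smallest asymmetry score — restoring the complete odd
    symmetry expected of the pure complex band.  f is scanned on a coarse
    grid over ``f_bounds`` and refined by golden-section search.
    """
    first_w = first.restricted(*window)
    free_w = free.restricted(*window)
    if not np.allclose(first_w.wavelengths, free_w.wavelengths):
        raise ValueError("first and free spectra must share a grid")
    if np.ptp(free_w.values) == 0:
        raise ValueError("free spectrum is flat; cannot reconstruct")
    wl = first_w.wavelengths
    a, b = first_w.values, free_w.values

    def candidate(f: float) -> np.ndarray:
        return (a - (1.0 - f) * b) / f

    def score(f: float) -> float:
        c = candidate(f)
        try:
            lam0 = _zero_crossing(wl, c)
        except ValueError:
            return np.inf
        return _asymmetry(wl, c, lam0)

    lo, hi = f_bounds
    fs = np.arange(lo, hi + grid_step / 2, grid_step)
    scores = np.array([score(f) for f in fs])
    if not np.isfinite(scores).any():
        raise ValueError("no candidate basis has a zero crossing")
    i_best = int(np.nanargmin(scores))
    # golden-section refinement in the bracketing interval
    f_lo = fs[max(i_best - 1, 0)]
    f_hi = fs[min(i_best + 1, fs.size - 1)]
    if f_hi > f_lo:
        res = minimize_scalar(
            score, bounds=(f_lo, f_hi), method="bounded",
            options={"xatol": 1e-7},
        )
        f_hat = float(res.x) if res.fun <= scores[i_best] else float(fs[i_best])
    else:
        f_hat = float(fs[i_best])
    f_hat = float(np.clip(f_hat, lo, min(hi, 1.0)))
    basis_vals = candidate(f_hat)
    lam0 = _zero_crossing(wl, basis_vals)
    basis_complex = Spectrum(wl, basis_vals, label="CytC2+-CN (reconstructed)")
    return BasisSet(
        basis_complex=basis_complex,
        basis_free=Spectrum(wl, free_w.values, label="free CytC2+"),
        zero_cross_nm=lam0,
        f0=f_hat,
        asymmetry_score=_asymmetry(wl, basis_vals, lam0),
    )


# ----------------------------------------------------------------------
# closed-form two-component unmixing
# ----------------------------------------------------------------------

def unmix(series: SpectralSeries, basis: BasisSet) -> UnmixingResult:
    """Fraction of complex at each time by constrained least squares.

    Under f_c + f_f = 1 the fit is one-dimensional and closed-form:

        f* = ⟨s − B_f, B_c − B_f⟩ / ‖B_c − B_f‖²

    per spectrum s, clipped to [0, 1].  Residual RMS per time point is
    reported; an overall flag is raised when any residual exceeds 5% of
    the series' signal range, suggesting a third component.
    """
    wl = basis.basis_complex.wavelengths
    if series.wavelengths.size != wl.size or not np.allclose(
        series.wavelengths, wl
    ):
        raise ValueError("series and basis must share a wavelength grid")
    b_c = basis.basis_complex.values
    b_f = basis.basis_free.values
    d = b_c - b_f
    norm2 = float(d @ d)
    if norm2 == 0:
        raise ValueError("bases are indistinguishable (B_c == B_f)")
    s_mat = series.values_matrix
    f_raw = (s_mat - b_f) @ d / norm2
    f_clip = np.clip(f_raw, 0.0, 1.0)
    recon = np.outer(f_clip, b_c) + np.outer(1.0 - f_clip, b_f)
    resid = s_mat - recon
    rms = np.sqrt(np.mean(resid**2, axis=1))
    signal_range = float(np.ptp(s_mat))
    flag = bool(
        signal_range > 0 and np.any(rms > RESIDUAL_FLAG_FRACTION * signal_range)
    )
    return UnmixingResult(
        times_min=series.times_min,
        fraction_complex=f_clip,
        fraction_raw=f_raw,
        percent_complex=100.0 * f_clip,
        residual_rms=rms,
        high_residual_flag=flag,
    )


# ----------------------------------------------------------------------
# isosbestic points
# ----------------------------------------------------------------------

def find_isosbestic(
    series: SpectralSeries, tol: float | None = None
) -> list[float]:
    """Wavelengths where all spectra of the series intersect.

    At an isosbestic point the across-time standard deviation of the
    signal has a sharp local minimum.  Minima below ``tol`` (default: 10%
    of the largest across-time SD) are refined to sub-grid precision by
    parabolic interpolation.  A degenerate series (identical spectra at
    every wavelength) returns an empty list with a warning, since every
    point would qualify.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 spectra to locate isosbestic points")
    wl = series.wavelengths
    sd = series.values_matrix.std(axis=0)
    sd_max = float(sd.max())
    if sd_max == 0:
        warnings.warn(
            "degenerate series: all spectra identical, every wavelength is "
            "trivially isosbestic",
            stacklevel=2,
        )
        return []
    if tol is None:
        tol = 0.1 * sd_max
    points: list[float] = []
    for i in range(1, wl.size - 1):
        if sd[i] <= sd[i - 1] and sd[i] <= sd[i + 1] and sd[i] < tol:
            # parabolic refinement through the three neighbouring SDs
            denom = sd[i - 1] - 2 * sd[i] + sd[i + 1]
            shift = 0.0 if denom == 0 else 0.5 * (sd[i - 1] - sd[i + 1]) / denom
            shift = float(np.clip(shift, -1.0, 1.0))
            points.append(float(wl[i] + shift * (wl[i + 1] - wl[i])))
    return points


# ----------------------------------------------------------------------
# model/results wrapper
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class UnmixingResults:
    """Fitted two-state decomposition of an MCD series."""

    basis: BasisSet
    composition: UnmixingResult
    isosbestic_nm: list[float]
    cytc_uM: float | None = None
    series: SpectralSeries = field(repr=False, default=None)  # type: ignore

    @property
    def times_min(self) -> np.ndarray:
        return self.composition.times_min

    @property
    def percent_complex(self) -> np.ndarray:
        return self.composition.percent_complex

    def decay_fit(self):
        """Monoexponential fit of the complex fraction vs time."""
        from .kinetics import fit_exponential

        return fit_exponential(
            self.composition.times_min,
            self.composition.fraction_complex,
            direction="decay",
        )

    def to_frame(self):
        """Percent-complex table (time, percent, residual RMS)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": self.composition.times_min,
                "percent_complex": self.composition.percent_complex,
                "residual_rms": self.composition.residual_rms,
            }
        )

    def summary(self) -> str:
        iso = ", ".join(f"{w:.1f}" for w in self.isosbestic_nm) or "none found"
        lines = [
            "Two-state MCD unmixing",
            "-" * 52,
            f"f0 (first spectrum)      {self.basis.f0:8.4f}",
            f"basis zero crossing      {self.basis.zero_cross_nm:8.2f} nm",
            f"basis asymmetry score    {self.basis.asymmetry_score:8.2e}",
            f"isosbestic points        {iso} nm",
            f"high-residual flag       {self.composition.high_residual_flag}",
            "",
            "  time_min  %complex  resid_rms",
        ]
        for t, p, r in zip(
            self.composition.times_min,
            self.composition.percent_complex,
            self.composition.residual_rms,
        ):
            lines.append(f"  {t:8.2f}  {p:8.2f}  {r:9.3g}")
        return "\n".join(lines)


class TwoStateUnmixingModel:
    """Two-state spectral decomposition of a timed MCD series.

    Parameters
    ----------
    series : SpectralSeries
        Timed spectra of the decaying complex, first scan earliest.
    cytc_uM : float, optional
        Protein concentration; when given, spectra are normalized to a
        per-µM scale before fitting (fractions are invariant to this).
    basis : BasisSet, optional
        Use a known basis instead of reconstructing one from the first
        and last spectra.

    ``fit()`` reconstructs the complex basis by symmetry restoration
    (unless a basis is supplied), unmixes every time point, locates the
    isosbestic points, and returns :class:`UnmixingResults`.
    """

    def __init__(
        self,
        series: SpectralSeries,
        cytc_uM: float | None = None,
        basis: BasisSet | None = None,
    ) -> None:
        if len(series) < 2:
            raise ValueError("need at least two spectra (first and free)")
        self.series = series
        self.cytc_uM = cytc_uM
        self.basis = basis

    def fit(
        self,
        window: tuple[float, float] = DEFAULT_WINDOW,
        f_bounds: tuple[float, float] = (0.5, 1.0),
    ) -> UnmixingResults:
        series = self.series
        if self.cytc_uM is not None:
            series = normalize_to_concentration(series, self.cytc_uM)
        wl_lo = max(window[0], series.wavelengths[0])
        wl_hi = min(window[1], series.wavelengths[-1])
        series_w = SpectralSeries(
            tuple(s.restricted(wl_lo, wl_hi) for s in series), series.times_min
        )
        basis = self.basis
        if basis is None:
            basis = reconstruct_complex_basis(
                series_w[0], series_w[-1], window=(wl_lo, wl_hi),
                f_bounds=f_bounds,
            )
        composition = unmix(series_w, basis)
        try:
            iso = find_isosbestic(series_w)
        except ValueError:
            iso = []
        return UnmixingResults(
            basis=basis,
            composition=composition,
            isosbestic_nm=iso,
            cytc_uM=self.cytc_uM,
            series=series_w,
        )
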