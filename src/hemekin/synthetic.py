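"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here with the
true parameters recorded, so each stage is testable end-to-end without
instrument data:

* two-state MCD decay series — Gaussian derivative-shaped bands of the
  CytC²⁺–CN complex (max 550 / min 555 nm) interconverting exponentially
  with the free ferrous form (max 545 / min 550 nm) on a 530–565 nm grid;
* peroxidase assay traces — linear ferricyanide production with an
  optional smooth lag phase, expressed as ΔA through Δε = 1040 M⁻¹cm⁻¹;
* Soret "butterfly" difference-spectrum series (min 403 / max 417 nm)
  growing with first-order cyanide-binding kinetics;
* Gaussian-fluctuation coordinate ensembles for RMSF profiling.

Noise is additive i.i.d. Gaussian; identical seed and arguments give
bit-identical output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assay import KineticTrace
from .flexibility import Ensemble
from .spectra import SpectralSeries, Spectrum

__all__ = [
    "BandModel",
    "GroundTruth",
    "complex_basis_bands",
    "free_basis_bands",
    "mcd_grid",
    "gen_two_state_mcd_series",
    "gen_assay_trace",
    "gen_butterfly_series",
    "gen_ensemble",
]

LN2 = math.log(2.0)
#: default MCD wavelength window (nm) and digitization step
MCD_GRID = (530.0, 565.0, 0.5)
#: default Soret window for butterfly difference spectra
SORET_GRID = (380.0, 440.0, 0.5)
#: Gaussian lobe width (nm) giving clearly resolved 5 nm-split extrema
DEFAULT_SIGMA_NM = 1.8


@dataclass(frozen=True)
class BandModel:
    """A signed Gaussian band: amplitude · exp(−(λ−center)²/(2·width²))."""

    center_nm: float
    width_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("band width must be positive")

    def evaluate(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        return self.amplitude * np.exp(
            -((wl - self.center_nm) ** 2) / (2.0 * self.width_nm**2)
        )


def _eval_bands(bands: list[BandModel], wl: np.ndarray) -> np.ndarray:
    out = np.zeros_like(wl, dtype=float)
    for b in bands:
        out += b.evaluate(wl)
    return out


def complex_basis_bands(
    sigma_nm: float = DEFAULT_SIGMA_NM, amplitude: float = 1.0
) -> list[BandModel]:
    """CytC²⁺–CN derivative band: maximum 550 nm, minimum 555 nm."""
    return [
        BandModel(550.0, sigma_nm, amplitude),
        BandModel(555.0, sigma_nm, -amplitude),
    ]


def free_basis_bands(
    sigma_nm: float = DEFAULT_SIGMA_NM, amplitude: float = 1.0
) -> list[BandModel]:
    """Free ferrous CytC band: maximum 545 nm, minimum 550 nm."""
    return [
        BandModel(545.0, sigma_nm, amplitude),
        BandModel(550.0, sigma_nm, -amplitude),
    ]


def mcd_grid(
    lo: float = MCD_GRID[0], hi: float = MCD_GRID[1], step: float = MCD_GRID[2]
) -> np.ndarray:
    return np.arange(lo, hi + step / 2, step)


@dataclass(frozen=True)
class GroundTruth:
    """True parameters behind a generated dataset."""

    seed: int
    true_fractions: np.ndarray | None = None
    true_rate_constant_per_min: float | None = None
    true_half_time_min: float | None = None
    true_assay_slope_uM_min: float | None = None
    true_lag_duration_min: float | None = None
    true_rmsf_A: np.ndarray | None = None
    basis_complex: Spectrum | None = field(default=None, repr=False)
    basis_free: Spectrum | None = field(default=None, repr=False)
    true_amplitude: float | None = None

    def to_dict(self) -> dict:
        """JSON-ready representation (spectra omitted)."""
        out: dict = {"seed": self.seed}
        for name in (
            "true_rate_constant_per_min",
            "true_half_time_min",
            "true_assay_slope_uM_min",
            "true_lag_duration_min",
            "true_amplitude",
        ):
            v = getattr(self, name)
            if v is not None:
                out[name] = float(v)
        for name in ("true_fractions", "true_rmsf_A"):
            v = getattr(self, name)
            if v is not None:
                out[name] = np.asarray(v).tolist()
        return out


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must not be empty")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    return times


def gen_two_state_mcd_series(
    basis_complex: list[BandModel] | None = None,
    basis_free: list[BandModel] | None = None,
    k_per_min: float = LN2 / 2.8,
    times_min: np.ndarray | None = None,
    f0: float = 0.95,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid: tuple[float, float, float] = MCD_GRID,
) -> tuple[SpectralSeries, GroundTruth]:
    """Exponentially decaying two-component MCD series with known fractions.

    Spectrum at time t is ``f(t)·B_complex + (1−f(t))·B_free + noise``
    with ``f(t) = f0·exp(−k·t)``.  Defaults mirror the experimental
    conditions of the cyanide-complex decay: extrema at 550/555 nm
    (complex) and 545/550 nm (free), scan times 0.3–14.1 min roughly
    every 0.8 min, decay half-time 2.8 min, 95% complex in the first scan.
    """
    if k_per_min < 0:
        raise ValueError("rate constant must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not 0 < f0 <= 1:
        raise ValueError("f0 must be in (0, 1]")
    if basis_complex is None:
        basis_complex = complex_basis_bands()
    if basis_free is None:
        basis_free = free_basis_bands()
    if times_min is None:
        times_min = np.arange(0.3, 14.2, 0.8)
    times = _check_times(times_min)
    wl = mcd_grid(*grid)
    b_c = _eval_bands(basis_complex, wl)
    b_f = _eval_bands(basis_free, wl)
    fractions = f0 * np.exp(-k_per_min * times)
    clean = np.outer(fractions, b_c) + np.outer(1.0 - fractions, b_f)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    series = SpectralSeries.from_matrix(wl, noisy, times)
    truth = GroundTruth(
        seed=seed,
        true_fractions=fractions,
        true_rate_constant_per_min=k_per_min,
        true_half_time_min=(LN2 / k_per_min if k_per_min > 0 else math.inf),
        basis_complex=Spectrum(wl, b_c, label="true complex basis"),
        basis_free=Spectrum(wl, b_f, label="true free basis"),
    )
    return series, truth


def gen_assay_trace(
    slope_uM_min: float,
    lag_min: float = 0.0,
    duration_min: float = 10.0,
    dt_min: float = 0.05,
    noise_sd: float = 0.0,
    delta_eps_M_cm: float = 1040.0,
    seed: int = 0,
) -> tuple[KineticTrace, GroundTruth]:
    """Linear peroxidase assay trace with an optional smooth lag phase.

    Product concentration is zero-slope at t = 0, accelerates through a
    quadratic onset of duration ``lag_min`` (C¹-continuous), then grows
    linearly at ``slope_uM_min``; the trace is expressed as
    ΔA = Δε·l·C·10⁻⁶ plus Gaussian noise.
    """
    if duration_min <= 0 or dt_min <= 0:
        raise ValueError("duration and dt must be positive")
    if lag_min < 0 or duration_min <= lag_min:
        raise ValueError("need duration > lag >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    times = np.arange(0.0, duration_min + dt_min / 2, dt_min)
    if lag_min > 0:
        conc = np.where(
            times <= lag_min,
            slope_uM_min * times**2 / (2.0 * lag_min),
            slope_uM_min * (times - lag_min / 2.0),
        )
    else:
        conc = slope_uM_min * times
    delta_a = delta_eps_M_cm * 1.0 * conc * 1e-6
    rng = np.random.default_rng(seed)
    delta_a = delta_a + rng.normal(0.0, noise_sd, size=delta_a.shape)
    trace = KineticTrace(
        times, delta_a, measure_wl=420.0, reference_wl=500.0,
        label="synthetic assay",
    )
    truth = GroundTruth(
        seed=seed,
        true_assay_slope_uM_min=slope_uM_min,
        true_lag_duration_min=lag_min,
    )
    return trace, truth


def gen_butterfly_series(
    min_wl: float = 403.0,
    max_wl: float = 417.0,
    k_on_per_min: float = LN2 / 3.3,
    times_min: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 1.0,
    sigma_nm: float = 6.0,
    grid: tuple[float, float, float] = SORET_GRID,
) -> tuple[SpectralSeries, GroundTruth]:
    """Soret butterfly difference spectra growing with binding kinetics.

    Difference spectrum at time t is ``A_max·(1−exp(−k_on·t))`` times the
    unit butterfly (negative Gaussian lobe at ``min_wl``, positive at
    ``max_wl``), emulating cyanide binding monitored against the original
    oxidized spectrum.  Default half-amplitude time 3.3 min.
    """
    if k_on_per_min < 0:
        raise ValueError("rate constant must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if times_min is None:
        times_min = np.arange(0.0, 20.1, 1.0)
    times = _check_times(times_min)
    wl = np.arange(grid[0], grid[1] + grid[2] / 2, grid[2])
    shape = (
        BandModel(max_wl, sigma_nm, amplitude).evaluate(wl)
        + BandModel(min_wl, sigma_nm, -amplitude).evaluate(wl)
    )
    progress = 1.0 - np.exp(-k_on_per_min * times)
    clean = np.outer(progress, shape)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    series = SpectralSeries.from_matrix(wl, noisy, times)
    truth = GroundTruth(
        seed=seed,
        true_rate_constant_per_min=k_on_per_min,
        true_half_time_min=(
            LN2 / k_on_per_min if k_on_per_min > 0 else math.inf
        ),
        true_fractions=progress,
        true_amplitude=amplitude,
    )
    return series, truth


def gen_ensemble(
    n_residues: int,
    n_frames: int,
    sigma_A: float | np.ndarray = 0.5,
    seed: int = 0,
) -> tuple[Ensemble, GroundTruth]:
    """Gaussian-fluctuation Cα ensemble with known expected RMSF.

    Each Cα fluctuates isotropically about its mean position with per-axis
    SD σ_r (scalar or per-residue profile), so the expected RMSF is
    √3·σ_r.  Mean positions trace an extended helix-like curve at 3.8 Å
    Cα–Cα spacing.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if n_residues < 1:
        raise ValueError("need at least 1 residue")
    sigma = np.broadcast_to(
        np.asarray(sigma_A, dtype=float), (n_residues,)
    ).copy()
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    # idealized alpha-helical backbone trace (100 deg turn, 1.5 A rise)
    idx = np.arange(n_residues)
    theta = np.deg2rad(100.0) * idx
    mean = np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * idx]
    )
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=(n_frames, n_residues, 3)) * sigma[None, :, None]
    coords = mean[None, :, :] + noise
    ensemble = Ensemble(
        coords=coords,
        atom_names=np.full(n_residues, "CA"),
        residue_ids=idx + 1,
        ca_mask=np.ones(n_residues, dtype=bool),
    )
    truth = GroundTruth(seed=seed, true_rmsf_A=np.sqrt(3.0) * sigma)
    return ensemble, truth
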