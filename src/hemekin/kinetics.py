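"""Single-exponential kinetics and model-free half-time extraction.

Ligand binding and complex decay in this package are described by the
monoexponential

    y(t) = y_inf + (y0 − y_inf) · exp(−k·t)

fitted by nonlinear least squares.  The headline time constant is the
half-time t½ = ln2/k — the time for the monitored reaction to progress
halfway — rather than the e-folding time 1/k; both are carried on the
results object.  A model-free counterpart, :func:`half_time`, interpolates
the first crossing of the halfway level directly from the data.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ExponentialFitResults",
    "ExponentialDecayModel",
    "fit_exponential",
    "half_time",
]

LN2 = math.log(2.0)


def _model(t: np.ndarray, y0: float, y_inf: float, k: float) -> np.ndarray:
    return y_inf + (y0 - y_inf) * np.exp(-k * t)


@dataclass(frozen=True)
class ExponentialFitResults:
    """Parameters of a monoexponential fit.

    Attributes
    ----------
    y0, y_inf : float
        Signal at t = 0 and the plateau.
    k_per_min : float
        Rate constant, min⁻¹.
    tau_half_min : float
        Half-time ln2/k, min (``tau_half·k = ln 2`` exactly).
    direction : str
        "decay" or "association".
    rmse : float
        Root-mean-square residual of the fit.
    converged : bool
        False when the optimizer failed or the data carry no decay;
        parameter values are then NaN.
    stderr : tuple
        Asymptotic standard errors of (y0, y_inf, k) from the fit
        covariance (NaN when unavailable).
    """

    y0: float
    y_inf: float
    k_per_min: float
    tau_half_min: float
    direction: str
    rmse: float
    converged: bool
    stderr: tuple[float, float, float] = (float("nan"),) * 3
    n_obs: int = 0

    def predict(self, times_min: np.ndarray) -> np.ndarray:
        """Fitted curve evaluated at ``times_min``."""
        return _model(np.asarray(times_min, float), self.y0, self.y_inf, self.k_per_min)

    def summary(self) -> str:
        se = self.stderr
        lines = [
            f"Monoexponential {self.direction} fit  (n = {self.n_obs})",
            "-" * 52,
            f"y0        {self.y0:12.5g}   +/- {se[0]:.3g}",
            f"y_inf     {self.y_inf:12.5g}   +/- {se[1]:.3g}",
            f"k         {self.k_per_min:12.5g}   +/- {se[2]:.3g}  1/min",
            f"t_half    {self.tau_half_min:12.5g}  min   (ln2/k)",
            f"RMSE      {self.rmse:12.5g}",
            f"converged {self.converged}",
        ]
        return "\n".join(lines)


class ExponentialDecayModel:
    """Monoexponential decay/association model for one kinetic record.

    Parameters
    ----------
    times_min, values : array-like
        Strictly increasing times (min) and the monitored signal.
    direction : {"auto", "decay", "association"}
        "auto" infers the direction from the sign of the overall change.

    Initial guesses come from log-linearizing the data against an
    endpoint-based plateau estimate; the nonlinear fit then refines
    (y0, y_inf, k) jointly.
    """

    def __init__(
        self,
        times_min: np.ndarray,
        values: np.ndarray,
        direction: str = "auto",
    ) -> None:
        t = np.asarray(times_min, dtype=float)
        y = np.asarray(values, dtype=float)
        if t.size != y.size:
            raise ValueError("times and values must have equal length")
        if t.size < 4:
            raise ValueError("need at least 4 points for a 3-parameter fit")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if direction not in ("auto", "decay", "association"):
            raise ValueError(f"unknown direction {direction!r}")
        self.times = t
        self.values = y
        if direction == "auto":
            direction = "decay" if y[-1] < y[0] else "association"
        self.direction = direction

    def _initial_guess(self) -> tuple[float, float, float]:
        t, y = self.times, self.values
        y0_g, yinf_g = float(y[0]), float(y[-1])
        amp = y - yinf_g
        # log-linearize where the sign matches the initial amplitude
        sign = np.sign(y0_g - yinf_g) or 1.0
        good = sign * amp > 1e-12 * max(1.0, abs(y0_g - yinf_g))
        if good.sum() >= 2:
            slope, _ = np.polyfit(t[good], np.log(sign * amp[good]), 1)
            k_g = max(-float(slope), 1e-6)
        else:
            k_g = 1.0 / max(float(t[-1] - t[0]), 1e-6)
        return y0_g, yinf_g, k_g

    def fit(self, robust: bool = False) -> ExponentialFitResults:
        t, y = self.times, self.values
        failed = ExponentialFitResults(
            y0=float("nan"),
            y_inf=float("nan"),
            k_per_min=float("nan"),
            tau_half_min=float("nan"),
            direction=self.direction,
            rmse=float("nan"),
            converged=False,
            n_obs=t.size,
        )
        if np.ptp(y) == 0:  # constant record: no rate to estimate
            return failed
        p0 = self._initial_guess()
        kwargs: dict = {"maxfev": 20000}
        if robust:
            kwargs = {"method": "trf", "loss": "soft_l1", "max_nfev": 20000}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(_model, t, y, p0=p0, **kwargs)
        except (RuntimeError, ValueError):
            return failed
        y0, y_inf, k = (float(v) for v in popt)
        if not np.isfinite(k) or k <= 0:
            return failed
        resid = y - _model(t, *popt)
        rmse = float(np.sqrt(np.mean(resid**2)))
        with np.errstate(invalid="ignore"):
            stderr = tuple(float(s) for s in np.sqrt(np.diag(pcov)))
        self._warn_if_nonmonotone(rmse)
        return ExponentialFitResults(
            y0=y0,
            y_inf=y_inf,
            k_per_min=k,
            tau_half_min=LN2 / k,
            direction=self.direction,
            rmse=rmse,
            converged=True,
            stderr=stderr,  # type: ignore[arg-type]
            n_obs=t.size,
        )

    def _warn_if_nonmonotone(self, noise_scale: float) -> None:
        dy = np.diff(self.values)
        expected = -1.0 if self.direction == "decay" else 1.0
        # a step between samples has noise SD sqrt(2)*rmse; flag only
        # excursions beyond ~3 sigma of that
        bad = dy * expected < -4.5 * max(noise_scale, 1e-15)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} step(s) violate {self.direction} "
                "monotonicity beyond noise",
                stacklevel=3,
            )


def fit_exponential(
    times_min: np.ndarray,
    values: np.ndarray,
    direction: str = "auto",
    robust: bool = False,
) -> ExponentialFitResults:
    """Fit ``y(t) = y_inf + (y0 − y_inf)·exp(−k·t)`` and return the results."""
    return ExponentialDecayModel(times_min, values, direction).fit(robust=robust)


def half_time(
    times_min: np.ndarray,
    values: np.ndarray,
    level: float = 0.5,
    y0: float | None = None,
    y_inf: float = 0.0,
) -> float:
    """Model-free time of the first crossing of the halfway level.

    The target level is ``y0 + level·(y_inf − y0)`` with ``y0`` defaulting
    to the first observation; the crossing time is linearly interpolated
    between the bracketing samples.  For percent-complex records on a
    0–100 scale pass ``y0=100`` so "half-way" means 50%.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("need >= 2 equal-length points")
    if y0 is None:
        y0 = float(y[0])
    target = y0 + level * (y_inf - y0)
    start_sign = y0 - y_inf
    if start_sign == 0:
        raise ValueError("y0 equals y_inf: halfway level undefined")
    # signed distance from target, positive on the starting side
    d = (y - target) * np.sign(start_sign)
    if d[0] <= 0:
        raise ValueError(
            "record is already at or past the halfway level at the first point"
        )
    crossings = np.nonzero((d[:-1] > 0) & (d[1:] <= 0))[0]
    if crossings.size == 0:
        raise ValueError("record never crosses the halfway level")
    i = int(crossings[0])
    frac = d[i] / (d[i] - d[i + 1])
    return float(t[i] + frac * (t[i + 1] - t[i]))
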