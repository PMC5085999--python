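"""Gating-kinetics quantification: Hill dose-response fits and half-amplitude times.

Dose-response curves (e.g. diC8-PIP₂ activation of Kir currents) are fitted
with the Hill equation

    I(c) = I_max · cⁿ / (EC₅₀ⁿ + cⁿ)

by nonlinear least squares, yielding the half-maximal concentration EC₅₀
(μM), the Hill coefficient n and the maximal response I_max.

Time-course traces are summarised by half-amplitude time constants read
directly off the trace, not from an exponential fit:

* τ_off — time for an inhibition trace to fall to half of its initial
  amplitude (initial amplitude = mean of the first three samples, to damp
  single-sample noise);
* τ_on — time for an activation trace to rise to half of its maximum
  amplitude.  "Maximum amplitude" means the steady-state current: on a
  finite recording the raw trace maximum systematically undershoots the
  plateau while the current is still rising, so the plateau is estimated by
  Aitken Δ² extrapolation on three tail samples (exact for a
  single-exponential approach), falling back to the observed maximum when
  the extrapolation is ill-conditioned.

Crossing times are linearly interpolated between the bracketing samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponse",
    "HillFit",
    "HalfTime",
    "NonIdentifiableError",
    "NoCrossingError",
    "hill_response",
    "fit_hill",
    "half_time",
]


class NonIdentifiableError(ValueError):
    """Dose-response data that cannot pin down the Hill parameters."""


class NoCrossingError(ValueError):
    """A trace that never crosses its half-amplitude level."""


@dataclass
class DoseResponse:
    """Ascending concentrations (μM) with matching responses (μA or normalised)."""

    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must have equal length")
        if (self.concentrations < 0).any():
            raise ValueError("concentrations must be non-negative")
        if not np.all(np.diff(self.concentrations) > 0):
            raise ValueError("concentrations must be strictly ascending")


def hill_response(c, ec50: float, hill_n: float, i_max: float):
    """Hill equation I(c) = i_max·cⁿ/(ec50ⁿ + cⁿ); I(0) = 0."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cn = np.where(c > 0, c**hill_n, 0.0)
    return i_max * cn / (ec50**hill_n + cn)


@dataclass
class HillFit:
    """Fitted Hill parameters; the model response at ec50 is i_max/2 exactly."""

    ec50: float
    hill_n: float
    i_max: float
    residual_rms: float
    converged: bool

    def predict(self, c):
        return hill_response(c, self.ec50, self.hill_n, self.i_max)

    def summary(self) -> str:
        return (
            f"Hill fit: EC50 = {self.ec50:.4g} uM, n = {self.hill_n:.4g}, "
            f"Imax = {self.i_max:.4g}, residual RMS = {self.residual_rms:.3g}"
            f"{'' if self.converged else ' (NOT CONVERGED)'}"
        )


def _initial_ec50(c: np.ndarray, resp: np.ndarray) -> float:
    """Concentration where the response first crosses half its maximum,
    linearly interpolated — the fit's starting point for EC50."""
    half = resp.max() / 2.0
    above = resp >= half
    k = int(np.argmax(above))
    if k == 0:
        return float(c[0] if c[0] > 0 else c[c > 0][0])
    c0, c1 = c[k - 1], c[k]
    r0, r1 = resp[k - 1], resp[k]
    if r1 == r0:
        return float(c1)
    return float(c0 + (half - r0) * (c1 - c0) / (r1 - r0))


def fit_hill(
    data: DoseResponse, fix_n: float | None = None
) -> HillFit:
    """Least-squares Hill fit of a dose-response curve.

    Requires >=4 points with responses on both sides of half-max (otherwise
    EC50 is not identifiable).  ``fix_n`` pins the Hill coefficient instead
    of fitting it.  Fitting uses the raw responses; any I/I_max
    normalisation is display-only.
    """
    c, resp = data.concentrations, data.responses
    if len(c) < 4:
        raise NonIdentifiableError("need at least 4 dose-response points")
    half = resp.max() / 2.0
    if not ((resp < half).any() and (resp > half).any()):
        raise NonIdentifiableError(
            "responses do not span both sides of the half-maximal response"
        )
    ec50_0 = max(_initial_ec50(c, resp), 1e-9)
    imax_0 = float(resp.max())

    if fix_n is None:
        x0 = np.array([np.log(ec50_0), 1.0, imax_0])

        def resid(x):
            return hill_response(c, np.exp(x[0]), x[1], x[2]) - resp

        lb = [-np.inf, 1e-3, -np.inf]
        ub = [np.inf, 50.0, np.inf]
    else:
        x0 = np.array([np.log(ec50_0), imax_0])

        def resid(x):
            return hill_response(c, np.exp(x[0]), fix_n, x[1]) - resp

        lb = [-np.inf, -np.inf]
        ub = [np.inf, np.inf]

    sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if fix_n is None:
        ec50, n, imax = float(np.exp(sol.x[0])), float(sol.x[1]), float(sol.x[2])
    else:
        ec50, imax = float(np.exp(sol.x[0])), float(sol.x[1])
        n = float(fix_n)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return HillFit(ec50=ec50, hill_n=n, i_max=imax, residual_rms=rms, converged=sol.success)


@dataclass
class HalfTime:
    """A half-amplitude crossing time (s), measured from the trace start."""

    tau: float
    mode: str  # "on" | "off"
    level_crossed: float
    amplitude: float  # initial amplitude (off) or estimated max amplitude (on)

    def summary(self) -> str:
        name = "tau_off" if self.mode == "off" else "tau_on"
        return f"{name} = {self.tau:.4g} s (half level {self.level_crossed:.4g})"


def _aitken_plateau(times: np.ndarray, currents: np.ndarray) -> float | None:
    """Δ² extrapolation of the steady-state level from three tail samples.

    For I(t) approaching a plateau exponentially, samples at equally spaced
    times t, t+Δ, t+2Δ satisfy I_ss = (I₁I₃ − I₂²)/(I₁ + I₃ − 2I₂)… with the
    sign arranged so the estimate is exact for a single exponential.
    Returns None when the three points are too close to collinear-flat for a
    stable estimate.
    """
    n = len(times)
    i1 = n // 2
    d = (n - 1 - i1) // 2
    if d < 1:
        return None
    i2, i3 = i1 + d, i1 + 2 * d  # equal index spacing => exact for uniform sampling

    y1, y2, y3 = currents[i1], currents[i2], currents[i3]
    denom = y3 - 2 * y2 + y1
    if abs(denom) < 1e-12 * max(abs(y3), 1.0):
        return None
    est = y3 - (y3 - y2) ** 2 / denom
    if not np.isfinite(est) or est < currents.max():
        return None
    return float(est)


def half_time(
    times: np.ndarray, currents: np.ndarray, mode: str
) -> HalfTime:
    """First half-amplitude crossing of a current trace.

    mode "off": level = half the initial amplitude (mean of first 3
    samples); the trace must decay below it.  mode "on": level = half the
    maximum (steady-state) amplitude; the trace must rise above it.  The
    crossing time is linearly interpolated between bracketing samples.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(currents, dtype=float)
    if t.shape != y.shape or t.ndim != 1 or len(t) < 4:
        raise ValueError("trace needs matching 1-D times/currents with >=4 samples")
    if mode == "off":
        amplitude = float(y[:3].mean())
        level = amplitude / 2.0
        crossed = y <= level
    elif mode == "on":
        plateau = _aitken_plateau(t, y)
        amplitude = float(plateau) if plateau is not None else float(y.max())
        level = amplitude / 2.0
        crossed = y >= level
    else:
        raise ValueError(f"mode must be 'on' or 'off', got {mode!r}")
    if not crossed.any():
        raise NoCrossingError(f"trace never crosses the half level {level:.6g}")
    k = int(np.argmax(crossed))
    if k == 0:
        tau = float(t[0])
    else:
        y0, y1 = y[k - 1], y[k]
        tau = float(t[k - 1] + (level - y0) * (t[k] - t[k - 1]) / (y1 - y0))
    return HalfTime(tau=tau, mode=mode, level_crossed=level, amplitude=amplitude)
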