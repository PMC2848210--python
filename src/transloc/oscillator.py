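"""One-variable delay model of the IκBα / nuclear-p65 negative feedback loop.

The state variable is the IκBα level ``x``.  A stimulus accelerates IκBα
degradation; free NF-κB (the fraction not sequestered by IκBα) drives delayed
resynthesis of IκBα.  Nuclear p65 is an instantaneous, strictly decreasing
function of IκBα, so the model stays one-dimensional:

    dx/dt = -k_deg * S(t) * x - k_turn * x + k_basal_syn
            + k_syn * n(x(t - tau))

    n(x)  = 1 / (1 + (x / K_i)**h)

Integration uses the method of steps with a fixed-step classical Runge-Kutta
scheme and linear interpolation of the delayed state, which keeps runs exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "OscillatorParams",
    "StimulusProfile",
    "Trace",
    "nuclear_fraction",
    "steady_state",
    "simulate_cell",
    "simulate_cells",
    "dominant_period",
]


@dataclass(frozen=True)
class OscillatorParams:
    """Rate constants of the delay oscillator.

    Defaults are calibrated (not measured) so that a sustained stimulus gives
    damped oscillations of nuclear p65 with a dominant period inside the
    80-100 min band, and so that the default cell-to-cell heterogeneity
    spreads peak-to-peak intervals over roughly 40-140 min.
    """

    k_deg: float = 0.4  # stimulus-driven IκBα degradation, 1/min
    k_syn: float = 0.5  # maximal delayed IκBα synthesis, conc/min
    k_basal_syn: float = 0.04  # basal IκBα synthesis, conc/min
    k_turn: float = 0.02  # basal IκBα turnover, 1/min
    tau: float = 43.0  # transcription/translation delay, min
    K_i: float = 0.5  # inhibition constant, conc
    h: float = 2.0  # Hill coefficient
    theta_nuc: float = 0.6  # threshold on n_p65 for the binary "nuclear" call

    def __post_init__(self) -> None:
        for name in ("k_deg", "k_syn", "k_basal_syn", "k_turn", "tau", "K_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.h < 1:
            raise ValueError(f"h must be >= 1, got {self.h}")
        if not 0.0 < self.theta_nuc < 1.0:
            raise ValueError(f"theta_nuc must be in (0, 1), got {self.theta_nuc}")

    def with_multipliers(self, tau_mult: float = 1.0, k_deg_mult: float = 1.0) -> "OscillatorParams":
        """Per-cell parameter variant used by the population simulation."""
        return replace(self, tau=self.tau * tau_mult, k_deg=self.k_deg * k_deg_mult)


@dataclass(frozen=True)
class StimulusProfile:
    """Time course of the external stimulus S(t) in [0, 1]."""

    kind: str = "sustained"  # one of sustained | pulse | none
    onset_min: float = 0.0
    duration_min: float = 10.0  # used by kind="pulse" only
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("sustained", "pulse", "none"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError(f"amplitude must be in [0, 1], got {self.amplitude}")
        if self.kind == "pulse" and self.duration_min <= 0:
            raise ValueError("pulse duration_min must be > 0")

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "none":
            return np.zeros_like(t)
        if self.kind == "sustained":
            return np.where(t >= self.onset_min, self.amplitude, 0.0)
        on = (t >= self.onset_min) & (t < self.onset_min + self.duration_min)
        return np.where(on, self.amplitude, 0.0)


@dataclass
class Trace:
    """Time series of IκBα level and nuclear-p65 fraction."""

    t_min: np.ndarray
    x_ikba: np.ndarray
    n_p65: np.ndarray

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.x_ikba = np.asarray(self.x_ikba, dtype=float)
        self.n_p65 = np.asarray(self.n_p65, dtype=float)
        if not (len(self.t_min) == len(self.x_ikba) == len(self.n_p65)):
            raise ValueError("t_min, x_ikba, n_p65 must have equal length")
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError("t_min must be strictly increasing")


def nuclear_fraction(x_ikba: float | np.ndarray, params: OscillatorParams) -> float | np.ndarray:
    """Nuclear-p65 fraction ``1 / (1 + (x/K_i)**h)`` for IκBα level ``x``.

    Strictly decreasing in ``x`` with ``n(0) = 1`` and ``n(K_i) = 0.5``.
    """
    x = np.asarray(x_ikba, dtype=float)
    if np.any(x < 0):
        raise ValueError("x_ikba must be nonnegative")
    n = 1.0 / (1.0 + (x / params.K_i) ** params.h)
    return float(n) if np.isscalar(x_ikba) else n


def steady_state(params: OscillatorParams) -> tuple[float, float]:
    """Pre-stimulus fixed point (x*, n*) with S = 0.

    Solves ``k_basal_syn + k_syn * n(x) = k_turn * x`` by bracketed root
    finding; the root is unique because the production side is decreasing and
    the loss side increasing in x.
    """
    from scipy.optimize import brentq

    def residual(x: float) -> float:
        return params.k_basal_syn + params.k_syn * nuclear_fraction(x, params) - params.k_turn * x

    hi = 1.0
    while residual(hi) > 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("no steady state found in [0, 1e6]")
    x_star = float(brentq(residual, 0.0, hi, xtol=1e-12, rtol=1e-14))
    return x_star, float(nuclear_fraction(x_star, params))


def _integrate_dde(
    t: np.ndarray,
    dt: float,
    k_deg: np.ndarray,
    tau: np.ndarray,
    params: OscillatorParams,
    x0: np.ndarray,
    stimulus_at: Callable[[float], np.ndarray],
) -> tuple[np.ndarray, int]:
    """Vectorised method-of-steps RK4 over a bank of cells.

    ``k_deg``, ``tau`` and ``x0`` are per-cell arrays of shape (n,);
    ``stimulus_at(t)`` returns the per-cell stimulus at scalar time ``t``.
    Returns the history matrix X of shape (len(t), n) and the number of
    negative-state clip events.
    """
    n_cells = len(x0)
    n_steps = len(t) - 1
    X = np.empty((len(t), n_cells), dtype=float)
    X[0] = x0
    clip_events = 0

    def delayed(k: int, t_stage: float) -> np.ndarray:
        # x(t_stage - tau) per cell, linear interpolation on the stored grid;
        # times at or before the grid start use the pre-stimulus state x0.
        s = t_stage - tau
        pos = np.clip(s / dt, 0.0, None)
        i0 = np.floor(pos).astype(int)
        frac = pos - i0
        i0 = np.minimum(i0, k - 1)  # tau >= 20*dt guarantees i0 + 1 <= k
        cols = np.arange(n_cells)
        xd = X[i0, cols] * (1.0 - frac) + X[i0 + 1, cols] * frac
        return np.where(s <= 0.0, x0, xd)

    def rhs(x: np.ndarray, S: np.ndarray, xd: np.ndarray) -> np.ndarray:
        n_del = 1.0 / (1.0 + (np.maximum(xd, 0.0) / params.K_i) ** params.h)
        return -(k_deg * S + params.k_turn) * x + params.k_basal_syn + params.k_syn * n_del

    for k in range(1, n_steps + 1):
        tk = t[k - 1]
        x = X[k - 1]
        S0 = stimulus_at(tk)
        Sh = stimulus_at(tk + 0.5 * dt)
        S1 = stimulus_at(tk + dt)
        xd0 = delayed(k, tk)
        xdh = delayed(k, tk + 0.5 * dt)
        xd1 = delayed(k, tk + dt)
        k1 = rhs(x, S0, xd0)
        k2 = rhs(x + 0.5 * dt * k1, Sh, xdh)
        k3 = rhs(x + 0.5 * dt * k2, Sh, xdh)
        k4 = rhs(x + dt * k3, S1, xd1)
        x_new = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        neg = x_new < 0.0
        if np.any(neg):
            clip_events += int(np.count_nonzero(neg))
            x_new = np.maximum(x_new, 0.0)
        X[k] = x_new
    return X, clip_events


def simulate_cell(
    params: OscillatorParams,
    stimulus: StimulusProfile,
    t_end_min: float,
    dt_min: float,
) -> Trace:
    """Integrate one cell from its pre-stimulus steady state on a fixed grid.

    Raises ``ValueError`` when ``dt_min > tau / 20`` (the method-of-steps
    interpolation relies on the delay spanning many steps).
    """
    if t_end_min <= 0:
        raise ValueError("t_end_min must be > 0")
    if dt_min <= 0:
        raise ValueError("dt_min must be > 0")
    if dt_min > params.tau / 20.0:
        raise ValueError(
            f"dt_min={dt_min} too large: must be <= tau/20 = {params.tau / 20.0:g}"
        )
    x_star, _ = steady_state(params)
    n_steps = int(round(t_end_min / dt_min))
    t = np.arange(n_steps + 1) * dt_min
    k_deg = np.array([params.k_deg])
    tau = np.array([params.tau])
    x0 = np.array([x_star])

    def stim(tq: float) -> np.ndarray:
        return np.atleast_1d(stimulus(tq))

    X, _ = _integrate_dde(t, dt_min, k_deg, tau, params, x0, stim)
    x = X[:, 0]
    return Trace(t_min=t, x_ikba=x, n_p65=np.asarray(nuclear_fraction(x, params)))


def simulate_cells(
    params: OscillatorParams,
    tau_mults: Sequence[float],
    k_deg_mults: Sequence[float],
    onsets_min: Sequence[float],
    t_end_min: float,
    dt_min: float,
    amplitude: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a heterogeneous bank of cells on one shared grid.

    Each cell i receives a sustained stimulus of the given amplitude starting
    at ``onsets_min[i]`` (``inf`` = never) and runs with per-cell multipliers
    on tau and k_deg.  Returns ``(t_min, N)`` where N has shape
    (len(t_min), n_cells) and holds the nuclear-p65 fraction.
    """
    tau_mults = np.asarray(tau_mults, dtype=float)
    k_deg_mults = np.asarray(k_deg_mults, dtype=float)
    onsets = np.asarray(onsets_min, dtype=float)
    if not (len(tau_mults) == len(k_deg_mults) == len(onsets)):
        raise ValueError("per-cell arrays must share length")
    tau = params.tau * tau_mults
    if np.any(tau <= 0) or np.any(k_deg_mults <= 0):
        raise ValueError("multipliers must be positive")
    if dt_min > tau.min() / 20.0:
        raise ValueError(f"dt_min={dt_min} must be <= min(tau)/20 = {tau.min() / 20.0:g}")
    x_star, _ = steady_state(params)
    n_steps = int(round(t_end_min / dt_min))
    t = np.arange(n_steps + 1) * dt_min
    x0 = np.full(len(onsets), x_star)
    k_deg = params.k_deg * k_deg_mults

    def stim(tq: float) -> np.ndarray:
        return np.where(tq >= onsets, amplitude, 0.0)

    X, _ = _integrate_dde(t, dt_min, k_deg, tau, params, x0, stim)
    N = 1.0 / (1.0 + (X / params.K_i) ** params.h)
    return t, N


def dominant_period(trace: Trace, **peak_kwargs) -> float | None:
    """Mean peak-to-peak interval of ``n_p65``; ``None`` with < 2 peaks."""
    from .traces import detect_peaks

    peaks = detect_peaks(trace.t_min, trace.n_p65, **peak_kwargs)
    if len(peaks.peak_times_min) < 2:
        return None
    return float(np.mean(peaks.intervals_min))
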