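"""Pegfilgrastim-like pharmacokinetics and feedback coupling.

The drug is injected into a subcutaneous depot and absorbed into plasma at
rate ``ka``; elimination from plasma is first order with rate ``ke``.  For
a unit dose at time 0 the plasma concentration has the closed form

    C(t) = ka/(ka - ke) * (exp(-ke t) - exp(-ka t)),

with the limit ``ka * t * exp(-ka t)`` when the rates coincide.  The
exogenous cytokine acts exactly like the endogenous systemic signal: the
effective stimulus is ``min(1, s_endo + gamma * C(t))`` for wildtype and
mutated cells alike.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .params import PKParams


def unit_dose_concentration(dt, ka: float, ke: float):
    """Plasma concentration at time ``dt`` after a unit dose (0 for dt < 0)."""
    dt = np.asarray(dt, dtype=float)
    if abs(ka - ke) < 1e-10 * ka:
        c = ka * dt * np.exp(-ka * dt)
    else:
        c = ka / (ka - ke) * (np.exp(-ke * dt) - np.exp(-ka * dt))
    return np.where(dt >= 0, c, 0.0)


def plasma_concentration(t, params: PKParams):
    """Superposition of all doses in ``params.doses`` at time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    c = np.zeros_like(t)
    for t0, amount in params.doses:
        c = c + amount * unit_dose_concentration(t - t0, params.ka, params.ke)
    return c


def peak_time(ka: float, ke: float) -> float:
    """Closed-form time of the single-dose concentration maximum."""
    if abs(ka - ke) < 1e-10 * ka:
        return 1.0 / ka
    return math.log(ka / ke) / (ka - ke)


def half_decay_time(ka: float, ke: float) -> float:
    """Time from the single-dose peak until the concentration halves."""
    tmax = peak_time(ka, ke)
    cmax = float(unit_dose_concentration(tmax, ka, ke))

    def deficit(dt):
        return float(unit_dose_concentration(tmax + dt, ka, ke)) - 0.5 * cmax

    hi = 1.0
    while deficit(hi) > 0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("half-decay search did not bracket")
    return brentq(deficit, 1e-9, hi, xtol=1e-10)


def calibrate_pk(target_tmax: float = 2.0,
                 target_half_decay_window: tuple[float, float] = (3.0, 4.0),
                 gamma: float | None = None) -> PKParams:
    """Solve for (ka, ke) hitting the peak-time and post-peak decay targets.

    The post-peak half-decay target is taken as the window midpoint.  The
    absorption/elimination roles are fixed by requiring ka > ke (flip-flop
    ambiguity).  Raises :class:`ValueError` if no solution exists.
    """
    if target_tmax <= 0 or target_half_decay_window[0] <= 0:
        raise ValueError("calibration targets must be positive")
    lo, hi = target_half_decay_window
    if lo > hi:
        raise ValueError("half-decay window must be ordered")
    target_half = 0.5 * (lo + hi)

    def ka_for_ke(ke):
        # solve peak_time(ka, ke) = target_tmax for ka > ke
        def f(ka):
            return peak_time(ka, ke) - target_tmax
        lo_ka, hi_ka = ke * (1 + 1e-6), ke + 50.0
        if f(lo_ka) * f(hi_ka) > 0:
            raise ValueError("infeasible peak-time target")
        return brentq(f, lo_ka, hi_ka, xtol=1e-12)

    def half_residual(ke):
        return half_decay_time(ka_for_ke(ke), ke) - target_half

    ke_lo, ke_hi = 1e-3, 1.0 / target_tmax * 0.999
    if half_residual(ke_lo) * half_residual(ke_hi) > 0:
        raise ValueError("infeasible half-decay target")
    ke = brentq(half_residual, ke_lo, ke_hi, xtol=1e-10)
    ka = ka_for_ke(ke)

    tmax = peak_time(ka, ke)
    if abs(tmax - target_tmax) > 0.05:
        raise ValueError(f"calibration failed: tmax={tmax}")
    half = half_decay_time(ka, ke)
    if not lo - 1e-6 <= half <= hi + 1e-6:
        raise ValueError(f"calibration failed: half-decay={half}")
    kwargs = {} if gamma is None else {"gamma": gamma}
    return PKParams(ka=ka, ke=ke, **kwargs)


def effective_signal(s_endo, concentration, gamma: float):
    """Combine endogenous signal and exogenous cytokine, clipped at 1."""
    return np.minimum(1.0, np.asarray(s_endo, dtype=float) + gamma * np.asarray(concentration, dtype=float))


def single_dose_schedule(day: float = 3.0) -> list[tuple[float, float]]:
    """The standard growth-factor arm: one unit dose on the given day."""
    return [(float(day), 1.0)]
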