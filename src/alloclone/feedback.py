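"""Feedback signals and regulated rate schedules.

Both regulatory signals are first-order Hill functions of a cell count,
``s = 1/(1 + k*x)``: the systemic signal of the mature neutrophil count,
the niche signal of the HSC count.  With gains ``k_sys = 1/M*`` and
``k_niche = 1/H*`` both signals equal 1/2 at homeostasis.

Responses to the signals:

* HSC self-renewal: ``a_0(x) = clip(a_hsc_max * x, 0, 1)``; with
  ``a_hsc_max = 1`` this passes exactly through ``a_0(s*) = 1/2``, the value
  forced by the HSC steady state.
* HPC self-renewal (equivalently, the number of divisions before terminal
  differentiation): affine around the operating point,
  ``a(x) = clip(a_hpc_hom + beta*(x - s*), 0, a_cap)``.  The slope ``beta``
  is the calibrated strength of the amplification feedback; it sets the
  speed of post-transplant recovery.
* Proliferation: ``p(x) = p_hom * g(x)`` with a piecewise-linear monotone
  ``g``, ``g(s*) = 1``, ``g(1) = prolif_fold_max``, floor ``g >= prolif_floor``
  below the operating point.
"""

from __future__ import annotations

import numpy as np

from .params import S_STAR, ModelParams

_SIGNAL_FLOOR = 1e-9


def feedback_signal(total_cells, gain):
    """First-order Hill signal ``1/(1 + gain*total_cells)``.

    Strictly decreasing in the cell count, equal to 1 for an empty system.
    """
    total_cells = np.asarray(total_cells, dtype=float)
    if np.any(total_cells < 0):
        raise ValueError("total_cells must be non-negative")
    if np.any(np.asarray(gain) <= 0):
        raise ValueError("gain must be positive")
    return 1.0 / (1.0 + gain * total_cells)


def prolif_response(x, fold_max: float, floor: float = 0.25, s_star: float = S_STAR):
    """Fold change ``g(x)`` of proliferation relative to homeostasis."""
    x = np.asarray(x, dtype=float)
    below = floor + (1.0 - floor) * x / s_star
    above = 1.0 + (fold_max - 1.0) * (x - s_star) / (1.0 - s_star)
    return np.where(x < s_star, below, above)


def hsc_selfrenewal_response(x, a_max: float):
    """HSC self-renewal probability ``clip(a_max * x, 0, 1)``."""
    return np.clip(a_max * np.asarray(x, dtype=float), 0.0, 1.0)


def hpc_selfrenewal_response(x, a_hom: float, slope: float, cap: float,
                             s_star: float = S_STAR):
    """HPC self-renewal probability, affine in the signal around ``s*``."""
    x = np.asarray(x, dtype=float)
    return np.clip(a_hom + slope * (x - s_star), 0.0, cap)


def transform_signal(s, sigma, s_star: float = S_STAR):
    """Aberrant-sensitivity transform of a feedback signal.

    A clone with sensitivity ``sigma`` perceives the signal
    ``s* + sigma*(s - s*)``, clipped to (0, 1]: the response is steepened
    around the homeostatic point but unchanged at it, so mutant and
    wildtype kinetics coincide at homeostasis for any ``sigma``.
    """
    s = np.asarray(s, dtype=float)
    return np.clip(s_star + sigma * (s - s_star), _SIGNAL_FLOOR, 1.0)


def _check_signal(s) -> None:
    if np.any(np.asarray(s) <= 0) or np.any(np.asarray(s) > 1):
        raise ValueError("feedback signals must lie in (0, 1]")


def regulated_rates(s_sys: float, s_niche: float, params: ModelParams,
                    p_hom: np.ndarray, a_hpc_hom: float):
    """Wildtype per-stage (proliferation, self-renewal) schedule.

    Returns arrays ``p`` and ``a`` of length ``n_stages + 1`` (index 0 is
    the HSC).  Which signal regulates which property depends on the
    feedback variant: in ``niche_selfrenewal`` the HSC self-renewal listens
    to the niche; in ``niche_selfrenewal_proliferation`` HSC proliferation
    does as well.  HPC properties always follow the systemic signal.
    """
    _check_signal(s_sys)
    _check_signal(s_niche)
    if params.variant == "baseline":
        s_sr_hsc = s_p_hsc = s_sys
    elif params.variant == "niche_selfrenewal":
        s_sr_hsc, s_p_hsc = s_niche, s_sys
    else:  # niche_selfrenewal_proliferation
        s_sr_hsc = s_p_hsc = s_niche

    n = params.n_stages
    a = np.empty(n + 1)
    a[0] = hsc_selfrenewal_response(s_sr_hsc, params.a_hsc_max)
    a[1:] = hpc_selfrenewal_response(
        s_sys, a_hpc_hom, params.selfrenewal_feedback_slope, params.a_hpc_cap)
    p = np.empty(n + 1)
    p[0] = p_hom[0] * prolif_response(s_p_hsc, params.prolif_fold_max, params.prolif_floor)
    p[1:] = p_hom[1:] * prolif_response(s_sys, params.prolif_fold_max, params.prolif_floor)
    return p, a
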