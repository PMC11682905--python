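"""Homeostatic calibration of the compartment model.

The calibration fixes the free kinetic parameters so that the system has an
equilibrium with the target mature neutrophil concentration ``M*`` and HSC
concentration ``H*``:

1. Feedback gains ``k_sys = 1/M*`` and ``k_niche = 1/H*`` put both signals
   at ``s* = 1/2`` at the target state; with ``a_hsc_max = 1`` the HSC
   self-renewal probability is then exactly 1/2, which makes the HSC
   equation ``du0/dt = (2a0 - 1) p0 u0`` stationary.
2. Homeostatic per-stage proliferation rates increase in equal arithmetic
   steps from ``p_hsc_hom`` to ``p_last_hom``.
3. A progenitor stage with self-renewal ``a < 1/2`` amplifies the cell flux
   passing through it by ``r = 2(1-a)/(1-2a)`` (stage-wise flux balance).
   The uniform ``a_hpc_hom`` is chosen so that the product of the stage
   amplifications equals the total amplification
   ``d * M* / (2(1-a0) p0 H*)`` required to turn the HSC efflux into the
   mature turnover.
4. Stage concentrations follow from the same flux balances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .params import S_STAR, ModelParams


class CalibrationError(ValueError):
    """Raised when the homeostatic targets are infeasible."""


def stage_amplification(a: float) -> float:
    """Flux amplification ``2(1-a)/(1-2a)`` of a stage with self-renewal a < 1/2."""
    if a >= 0.5:
        raise CalibrationError(
            f"stage amplification undefined for self-renewal a={a} >= 0.5")
    return 2.0 * (1.0 - a) / (1.0 - 2.0 * a)


@dataclass(frozen=True)
class CalibratedModel:
    """A parameter set together with its derived homeostatic quantities."""

    params: ModelParams
    p_hom: np.ndarray            # (n_stages+1,) homeostatic proliferation rates
    a_hom: np.ndarray            # (n_stages+1,) homeostatic self-renewal probabilities
    equilibrium: np.ndarray      # (n_stages+2,) homeostatic concentrations, cells/kg
    s_star: float = S_STAR

    @property
    def n_stages(self) -> int:
        return self.params.n_stages

    @property
    def n_compartments(self) -> int:
        return self.params.n_stages + 2

    def marrow_profile(self) -> np.ndarray:
        """Homeostatic HPC stage distribution (normalized, length n_stages)."""
        hpc = self.equilibrium[1:-1]
        return hpc / hpc.sum()


def homeostatic_prolif_rates(params: ModelParams) -> np.ndarray:
    """Arithmetically increasing rates from the HSC to the last mitotic stage."""
    return np.linspace(params.p_hsc_hom, params.p_last_hom, params.n_stages + 1)


def calibrate_homeostasis(params: ModelParams) -> CalibratedModel:
    """Fill in gains and ``a_hpc_hom`` and return the calibrated model."""
    n = params.n_stages
    updates: dict = {}
    if params.k_sys is None:
        updates["k_sys"] = 1.0 / params.M_star
    if params.k_niche is None:
        updates["k_niche"] = 1.0 / params.H_star
    # the operating point must sit at s* for the chosen a_hsc_max
    a0_star = params.a_hsc_max * S_STAR
    if abs(a0_star - 0.5) > 1e-12:
        raise CalibrationError(
            "HSC steady state requires a_hsc_max * s* = 1/2; "
            f"got {a0_star} (a_hsc_max={params.a_hsc_max})")

    p_hom = homeostatic_prolif_rates(params)
    # required total amplification of the HSC efflux into mature turnover
    hsc_efflux = 2.0 * (1.0 - a0_star) * p_hom[0] * params.H_star
    required = params.d_mature * params.M_star / hsc_efflux
    if required <= 1.0:
        raise CalibrationError(
            f"required amplification {required} <= 1; targets infeasible")
    r = required ** (1.0 / n)
    # invert r = 2(1-a)/(1-2a)  ->  a = (2-r)/(2-2r)
    a_hpc = (2.0 - r) / (2.0 - 2.0 * r)
    if not 0.0 < a_hpc < 0.5:
        raise CalibrationError(
            f"calibrated a_hpc_hom={a_hpc} violates 0 < a < 0.5 "
            f"(per-stage amplification r={r})")
    if params.a_hpc_hom is not None and abs(params.a_hpc_hom - a_hpc) > 1e-9:
        raise CalibrationError(
            f"a_hpc_hom={params.a_hpc_hom} inconsistent with calibration ({a_hpc})")
    updates["a_hpc_hom"] = a_hpc
    cal_params = params.model_copy(update=updates)

    a_hom = np.full(n + 1, a_hpc)
    a_hom[0] = a0_star
    # back-solve stage concentrations from flux balance
    u = np.empty(n + 2)
    u[0] = params.H_star
    influx = hsc_efflux
    for i in range(1, n + 1):
        u[i] = influx / ((1.0 - 2.0 * a_hpc) * p_hom[i])
        influx *= r
    u[n + 1] = influx / params.d_mature
    return CalibratedModel(params=cal_params, p_hom=p_hom, a_hom=a_hom,
                           equilibrium=u)
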