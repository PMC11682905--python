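"""Multi-clone dynamics: right-hand side, stiff integration, engraftment.

State layout: ``u[j, i]`` is the concentration (cells/kg) of clone ``j``
in compartment ``i``, with ``i = 0`` the HSC, ``1..n_stages`` the HPC
stages and ``n_stages + 1`` the mature neutrophils.  The compartment
equations per clone are

    du0/dt = (2 a0 - 1) p0 u0
    dui/dt = (2 ai - 1) pi ui + 2 (1 - a_{i-1}) p_{i-1} u_{i-1}
    dum/dt = 2 (1 - an) pn un - d um

Feedback signals are computed from the clone-summed totals; each clone
then perceives the signals through its own sensitivity transform and
applies its kinetic multipliers, so clones compete only through the
shared feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import inflammation as infl
from .calibrate import CalibratedModel
from .feedback import prolif_response, transform_signal
from .params import CloneSpec, InflammationParams, PKParams, S_STAR, wildtype_clone
from .pk import plasma_concentration
from .units import ENGRAFTMENT_THRESHOLD_PER_L, per_kg_to_per_liter, per_liter_to_per_kg


class IntegrationError(RuntimeError):
    """Solver failure or state leaving the physical domain."""


@dataclass
class Trajectory:
    """Dense simulation output on a uniform grid (plus event information)."""

    t: np.ndarray                       # (nt,) days since transplantation
    u: np.ndarray                       # (nt, n_clones, n_compartments) cells/kg
    model: CalibratedModel
    clones: list[CloneSpec]
    inflammation: Optional[InflammationParams] = None
    engraftment_day: Optional[float] = None     # event-located crossing, if requested
    threshold_per_kg: Optional[float] = None

    def mature_total(self) -> np.ndarray:
        return self.u[:, :, -1].sum(axis=1)

    def hsc_total(self) -> np.ndarray:
        return self.u[:, :, 0].sum(axis=1)

    def mature(self, clone_index: int) -> np.ndarray:
        return self.u[:, clone_index, -1]

    def vaf(self, clone_index: int = 1) -> np.ndarray:
        """Peripheral-blood VAF of one clone along the trajectory."""
        from .clones import vaf as _vaf
        c_mut = self.u[:, clone_index, -1]
        c_rest = self.mature_total() - c_mut
        return _vaf(c_mut, c_rest, self.clones[clone_index].zygosity)

    def vaf_at(self, t_days: float, clone_index: int = 1) -> float:
        return float(np.interp(t_days, self.t, self.vaf(clone_index)))

    def hsc_vaf(self, clone_index: int = 1) -> np.ndarray:
        from .clones import vaf as _vaf
        c_mut = self.u[:, clone_index, 0]
        c_rest = self.hsc_total() - c_mut
        return _vaf(c_mut, c_rest, self.clones[clone_index].zygosity)

    def burden(self) -> np.ndarray:
        """Inflammatory burden along the trajectory (zeros when mode is off)."""
        if self.inflammation is None or self.inflammation.mode == "off":
            return np.zeros_like(self.t)
        mut = _mutant_mask(self.clones)
        c_mut = self.u[:, mut, -1].sum(axis=1)
        return infl.burden(c_mut, self.inflammation)

    def to_frame(self):
        """Long-format table: time_days, clone_id, compartment_index, cells_per_kg."""
        import pandas as pd
        nt, nc, ncomp = self.u.shape
        rows = {
            "time_days": np.repeat(self.t, nc * ncomp),
            "clone_id": np.tile(np.repeat([c.clone_id for c in self.clones], ncomp), nt),
            "compartment_index": np.tile(np.arange(ncomp), nt * nc),
            "cells_per_kg": self.u.reshape(-1),
        }
        frame = pd.DataFrame(rows)
        b = self.burden()
        frame["burden"] = np.repeat(b, nc * ncomp)
        return frame


def _mutant_mask(clones: Sequence[CloneSpec]) -> np.ndarray:
    return np.array([c.clone_id != "wildtype" for c in clones])


def build_rhs(model: CalibratedModel, clones: Sequence[CloneSpec],
              pk: Optional[PKParams] = None,
              inflammation_params: Optional[InflammationParams] = None):
    """Compile the ODE right-hand side for a fixed clone configuration."""
    params = model.params
    n = params.n_stages
    nc = len(clones)
    p_hom = model.p_hom
    a_hpc_hom = float(params.a_hpc_hom)
    slope = params.selfrenewal_feedback_slope
    cap = params.a_hpc_cap
    fold, floor = params.prolif_fold_max, params.prolif_floor
    k_sys, k_niche = params.k_sys, params.k_niche
    variant = params.variant

    sens_hsc = np.array([c.sens_hsc for c in clones])
    sens_hpc = np.array([c.sens_hpc for c in clones])
    m_p_hsc = np.array([c.mult_prolif_hsc for c in clones])
    m_p_hpc = np.array([c.mult_prolif_hpc for c in clones])
    m_sr_hsc = np.array([c.mult_selfrenewal_hsc for c in clones])
    m_sr_hpc = np.array([c.mult_selfrenewal_hpc for c in clones])
    d = params.d_mature * np.array([c.mult_clearance for c in clones])
    mut = _mutant_mask(clones)
    wt = ~mut

    use_pk = pk is not None and pk.gamma > 0 and len(pk.doses) > 0
    ip = inflammation_params
    use_infl = ip is not None and ip.mode != "off"

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        u = y.reshape(nc, n + 2)
        M = max(u[:, -1].sum(), 0.0)
        H = max(u[:, 0].sum(), 0.0)
        s_sys = 1.0 / (1.0 + k_sys * M)
        if use_pk:
            s_sys = min(1.0, s_sys + pk.gamma * float(plasma_concentration(t, pk)))
        s_niche = 1.0 / (1.0 + k_niche * H)
        if variant == "baseline":
            s_sr_hsc = s_p_hsc = s_sys
        elif variant == "niche_selfrenewal":
            s_sr_hsc, s_p_hsc = s_niche, s_sys
        else:
            s_sr_hsc = s_p_hsc = s_niche

        x_sr_hsc = transform_signal(s_sr_hsc, sens_hsc)
        x_p_hsc = transform_signal(s_p_hsc, sens_hsc)
        x_hpc = transform_signal(s_sys, sens_hpc)

        a0 = np.clip(m_sr_hsc * params.a_hsc_max * x_sr_hsc, 0.0, 1.0)
        ah = np.clip(m_sr_hpc * (a_hpc_hom + slope * (x_hpc - S_STAR)), 0.0, cap)
        p0 = p_hom[0] * m_p_hsc * prolif_response(x_p_hsc, fold, floor)
        ph = p_hom[1:][None, :] * (m_p_hpc * prolif_response(x_hpc, fold, floor))[:, None]

        if use_infl:
            c_mut = max(u[mut, -1].sum(), 0.0)
            e = infl.effect(infl.burden(c_mut, ip), ip.hill_theta)
            if ip.mode == "mutant_boost":
                f_sr, f_p, f_amp = infl.mutant_factors(e, ip)
                a0 = np.where(mut, np.clip(a0 * f_sr, 0.0, 1.0), a0)
                ah = np.where(mut, np.clip(ah * f_amp, 0.0, cap), ah)
                p0 = np.where(mut, p0 * f_p, p0)
                ph = np.where(mut[:, None], ph * f_p, ph)
            else:  # wildtype_exhaustion
                f_sr, f_amp, f_p = infl.wildtype_factors(e, ip)
                a0 = np.where(wt, np.clip(a0 * f_sr, 0.0, 1.0), a0)
                ah = np.where(wt, np.clip(ah * f_amp, 0.0, cap), ah)
                p0 = np.where(wt, p0 * f_p, p0)
                ph = np.where(wt[:, None], ph * f_p, ph)

        uh = u[:, 1:-1]
        outflux = 2.0 * (1.0 - ah)[:, None] * ph * uh
        du = np.empty_like(u)
        du[:, 0] = (2.0 * a0 - 1.0) * p0 * u[:, 0]
        du[:, 1:-1] = (2.0 * ah - 1.0)[:, None] * ph * uh
        du[:, 1] += 2.0 * (1.0 - a0) * p0 * u[:, 0]
        du[:, 2:-1] += outflux[:, :-1]
        du[:, -1] = outflux[:, -1] - d * u[:, -1]
        return du.reshape(-1)

    return rhs


def _as_state(initial, n_compartments: int) -> np.ndarray:
    state = np.atleast_2d(np.asarray(initial, dtype=float))
    if state.shape[1] != n_compartments:
        raise ValueError(
            f"state must have {n_compartments} compartments, got {state.shape[1]}")
    return state


def simulate(initial, model: CalibratedModel,
             clones: Optional[Sequence[CloneSpec]] = None,
             horizon: float = 365.0,
             pk: Optional[PKParams] = None,
             inflammation_params: Optional[InflammationParams] = None,
             rtol: float = 1e-6, atol: float = 1e-3,
             grid_dt: float = 1.0,
             threshold_per_l: Optional[float] = None,
             stop_at_threshold: bool = False,
             method: str = "LSODA") -> Trajectory:
    """Integrate the stiff system and return a daily-grid trajectory.

    ``threshold_per_l`` turns on event location of the engraftment
    crossing of the total mature count; with ``stop_at_threshold`` the
    integration terminates there (cheap engraftment-only runs).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    state0 = _as_state(initial, model.n_compartments)
    nc = state0.shape[0]
    if clones is None:
        if nc != 1:
            raise ValueError("clones must be given for a multi-clone state")
        clones = [wildtype_clone()]
    clones = list(clones)
    if len(clones) != nc:
        raise ValueError("number of clones does not match state")
    if not np.all(np.isfinite(state0)):
        raise IntegrationError("non-finite initial state")
    if np.any(state0 < 0):
        raise IntegrationError("negative initial state")

    rhs = build_rhs(model, clones, pk=pk, inflammation_params=inflammation_params)

    thr_kg = per_liter_to_per_kg(threshold_per_l) if threshold_per_l is not None else None
    events = None
    if thr_kg is not None:
        def crossing(t, y):
            return y.reshape(nc, -1)[:, -1].sum() - thr_kg
        crossing.direction = 1.0
        crossing.terminal = stop_at_threshold
        events = [crossing]

    # split the horizon at dose times (derivative kinks)
    breaks = [0.0, float(horizon)]
    if pk is not None and pk.gamma > 0:
        breaks += [float(t0) for t0, _ in pk.doses if 0.0 < t0 < horizon]
    breaks = sorted(set(breaks))

    grid = np.arange(0.0, horizon + 0.5 * grid_dt, grid_dt)
    if grid[-1] < horizon:
        grid = np.append(grid, horizon)

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    y = state0.reshape(-1)
    engraft_day = None
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        t_eval = grid[(grid >= t0) & (grid <= t1)]
        if len(t_eval) == 0 or t_eval[0] > t0:
            t_eval = np.insert(t_eval, 0, t0)
        if t_eval[-1] < t1:
            t_eval = np.append(t_eval, t1)
        sol = solve_ivp(rhs, (t0, t1), y, method=method, rtol=rtol, atol=atol,
                        t_eval=t_eval, events=events, dense_output=False)
        if not sol.success:
            raise IntegrationError(f"solver failed on [{t0}, {t1}]: {sol.message}")
        ts.append(sol.t)
        ys.append(sol.y.T)
        if events is not None and engraft_day is None and len(sol.t_events[0]) > 0:
            engraft_day = float(sol.t_events[0][0])
        if sol.status == 1:  # terminated at the threshold event
            break
        y = sol.y[:, -1]

    t_all = np.concatenate(ts)
    u_all = np.concatenate(ys).reshape(-1, nc, model.n_compartments)
    t_all, idx = np.unique(np.round(t_all, 10), return_index=True)
    u_all = u_all[idx]

    umax = u_all.max() if u_all.size else 0.0
    neg_tol = max(10.0 * atol, 1e-9 * umax)
    if u_all.min() < -neg_tol:
        raise IntegrationError(
            f"state left the nonnegative domain (min {u_all.min():g}, tol {neg_tol:g})")
    np.clip(u_all, 0.0, None, out=u_all)

    if thr_kg is not None and engraft_day is None and u_all[0, :, -1].sum() >= thr_kg:
        engraft_day = 0.0
    return Trajectory(t=t_all, u=u_all, model=model, clones=clones,
                      inflammation=inflammation_params,
                      engraftment_day=engraft_day, threshold_per_kg=thr_kg)


def engraftment_time(trajectory: Trajectory,
                     threshold_per_l: float = ENGRAFTMENT_THRESHOLD_PER_L) -> float:
    """First upward crossing of the mature-count threshold, in days.

    Uses the event-located time when the simulation tracked the same
    threshold; otherwise interpolates linearly on the output grid.
    Returns ``nan`` when the threshold is never reached.
    """
    if trajectory.t.size == 0:
        raise ValueError("empty trajectory")
    thr_kg = per_liter_to_per_kg(threshold_per_l)
    if (trajectory.threshold_per_kg is not None
            and abs(trajectory.threshold_per_kg - thr_kg) < 1e-9 * thr_kg):
        if trajectory.engraftment_day is not None:
            return trajectory.engraftment_day
    M = trajectory.mature_total()
    if M[0] >= thr_kg:
        return 0.0
    above = np.nonzero(M >= thr_kg)[0]
    if len(above) == 0:
        if trajectory.engraftment_day is not None:
            return trajectory.engraftment_day
        return float("nan")
    i = above[0]
    t0, t1 = trajectory.t[i - 1], trajectory.t[i]
    m0, m1 = M[i - 1], M[i]
    return float(t0 + (thr_kg - m0) / (m1 - m0) * (t1 - t0))
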