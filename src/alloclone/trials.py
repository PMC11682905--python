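"""Virtual-patient cohorts and in-silico transplantation trials.

Each virtual patient is a multiplicative uniform perturbation of the
reference parameter set, recalibrated to its own homeostasis, plus a
randomly drawn CHIP clone and donor PB VAF.  One root seed feeds a
deterministic per-patient substream (``SeedSequence.spawn``), so the same
cohort is reproducible bit-for-bit and extending a cohort never changes
existing patients.  The perturbation widths are frozen so that the
1000-patient cohort's times to neutrophil engraftment at the reference
dose cover the 11-25 day clinical range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .calibrate import CalibratedModel, calibrate_homeostasis
from .clones import expansion_metrics_from_series
from .dynamics import engraftment_time, simulate
from .params import CloneSpec, InflammationParams, ModelParams, PKParams
from .pk import single_dose_schedule
from .transplant import donor_course, make_graft
from .units import DAYS_PER_YEAR, ENGRAFTMENT_THRESHOLD_PER_L

REFERENCE_DOSE = 4.7e6
DOSE_ARMS = (1.0e6, 5.0e6, 1.0e7, 1.5e7)

#: calibrated uniform perturbation ranges; a float w means factors in
#: [1-w, 1+w], a pair gives the factor bounds directly (engraftment time
#: responds asymmetrically to the feedback slope, so its range is skewed)
DEFAULT_WIDTHS: dict = {
    "selfrenewal_feedback_slope": (0.70, 1.08),
    "p_last_hom": 0.03,
    "prolif_fold_max": 0.03,
    "d_mature": 0.05,
    "homing": 0.10,
    "hsc_fraction": 0.4,
}

#: mutant parameter ranges per cohort archetype.  Saturated clones carry a
#: stress-only advantage (aberrant signal sensitivity, stronger at the
#: progenitor level); persistent clones add a permanent HSC self-renewal
#: and proliferation advantage on top of progenitor-level sensitivity.
CLONE_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "saturated": {"sens_hsc": (1.0, 1.2), "sens_hpc": (1.5, 2.5)},
    "persistent": {"mult_selfrenewal_hsc": (1.03, 1.08),
                   "mult_prolif_hsc": (1.0, 1.5),
                   "sens_hpc": (1.4, 2.0)},
}

DONOR_VAF_RANGE = (0.005, 0.125)


@dataclass
class VirtualPatient:
    patient_id: int
    model: CalibratedModel
    clone: Optional[CloneSpec]
    donor_vaf: float
    homing: float           # wildtype homing fraction
    hsc_fraction: float     # HSC fraction of the CD34+ graft


def _uniform_factor(rng: np.random.Generator, width) -> float:
    if isinstance(width, tuple):
        lo, hi = width
    else:
        lo, hi = 1.0 - width, 1.0 + width
    return float(rng.uniform(lo, hi))


def sample_cohort(n: int,
                  reference: Optional[ModelParams] = None,
                  widths: Optional[dict[str, float]] = None,
                  archetype: Optional[str] = None,
                  clone_ranges: Optional[dict[str, tuple[float, float]]] = None,
                  seed: int = 0,
                  donor_vaf_range: tuple[float, float] = DONOR_VAF_RANGE
                  ) -> list[VirtualPatient]:
    """Draw a reproducible cohort of ``n`` virtual patients.

    ``archetype`` selects the CHIP-clone draw (``"saturated"`` or
    ``"persistent"``); ``None`` gives clone-free patients (engraftment
    studies).  With all widths zero every patient equals the reference.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    reference = reference if reference is not None else ModelParams()
    widths = dict(DEFAULT_WIDTHS if widths is None else widths)
    if archetype is not None and clone_ranges is None:
        clone_ranges = CLONE_RANGES[archetype]

    base_graft_fraction = 1250.0 / 4.7e6
    cohort: list[VirtualPatient] = []
    for pid, child in enumerate(np.random.SeedSequence(seed).spawn(n)):
        rng = np.random.default_rng(child)
        updates = {}
        for key in ("selfrenewal_feedback_slope", "p_last_hom",
                    "prolif_fold_max", "d_mature"):
            updates[key] = getattr(reference, key) * _uniform_factor(rng, widths.get(key, 0.0))
        homing = float(np.clip(0.5 * _uniform_factor(rng, widths.get("homing", 0.0)), 0.0, 1.0))
        hsc_fraction = base_graft_fraction * _uniform_factor(rng, widths.get("hsc_fraction", 0.0))
        params = reference.model_copy(update=updates)
        model = calibrate_homeostasis(params)

        donor_vaf = float(rng.uniform(*donor_vaf_range))
        clone = None
        if clone_ranges is not None:
            fields = {key: float(rng.uniform(lo, hi))
                      for key, (lo, hi) in sorted(clone_ranges.items())}
            clone = CloneSpec(clone_id="mutant", homing_hsc=homing,
                              homing_hpc=homing, **fields)
        cohort.append(VirtualPatient(patient_id=pid, model=model, clone=clone,
                                     donor_vaf=donor_vaf, homing=homing,
                                     hsc_fraction=hsc_fraction))
    return cohort


def _gcsf_pk(gcsf_day: Optional[float], pk_params: Optional[PKParams]) -> Optional[PKParams]:
    if gcsf_day is None:
        return None
    pk = pk_params if pk_params is not None else PKParams()
    return pk.model_copy(update={"doses": single_dose_schedule(gcsf_day)})


def engraftment_study(cohort: Sequence[VirtualPatient],
                      dose: float = REFERENCE_DOSE,
                      gcsf_day: Optional[float] = None,
                      pk_params: Optional[PKParams] = None,
                      horizon: float = 120.0,
                      threshold_per_l: float = ENGRAFTMENT_THRESHOLD_PER_L
                      ) -> pd.DataFrame:
    """Time to neutrophil engraftment per patient (clone-free runs)."""
    pk = _gcsf_pk(gcsf_day, pk_params)
    rows = []
    for pat in cohort:
        graft = make_graft(pat.model, dose, hsc_fraction=pat.hsc_fraction,
                           wildtype_homing=pat.homing)
        traj = simulate(graft.homed(), pat.model, clones=graft.clones,
                        horizon=horizon, pk=pk,
                        threshold_per_l=threshold_per_l, stop_at_threshold=True)
        rows.append({"patient_id": pat.patient_id,
                     "engraftment_days": engraftment_time(traj, threshold_per_l)})
    return pd.DataFrame(rows)


def _clone_run(pat: VirtualPatient, graft, pk, inflammation_params, horizon):
    traj = simulate(graft.homed(), pat.model, clones=graft.clones,
                    horizon=horizon, pk=pk,
                    inflammation_params=inflammation_params,
                    threshold_per_l=ENGRAFTMENT_THRESHOLD_PER_L)
    return traj


def _patient_record(pat, donor_traj, recip_traj):
    metrics = expansion_metrics_from_series(
        donor_traj.t, donor_traj.vaf(1), recip_traj.t, recip_traj.vaf(1))
    return {
        "patient_id": pat.patient_id,
        "donor_vaf": metrics.vaf_donor,
        "vaf_100d": metrics.vaf_100d,
        "vaf_1y": metrics.vaf_1y,
        "engraftment_days": engraftment_time(recip_traj),
        "delta_R_100d": metrics.delta_R_100d,
        "pi_R_100d": metrics.pi_R_100d,
        "delta_D_1y": metrics.delta_D_1y,
        "pi_D_1y": metrics.pi_D_1y,
    }


def run_dose_trial(cohort: Sequence[VirtualPatient],
                   doses: Sequence[float] = DOSE_ARMS,
                   gcsf_day: Optional[float] = None,
                   pk_params: Optional[PKParams] = None,
                   inflammation_params: Optional[InflammationParams] = None,
                   horizon: float = 1.05 * DAYS_PER_YEAR) -> pd.DataFrame:
    """Transplant every patient once per dose arm; summarize clone dynamics.

    Requires a cohort with clones.  The donor is simulated over the year
    before donation; the graft composition follows the donor's
    per-compartment clonal fractions at donation.
    """
    pk = _gcsf_pk(gcsf_day, pk_params)
    rows = []
    for pat in cohort:
        if pat.clone is None:
            raise ValueError("dose trial requires a cohort with clones")
        donor = donor_course(pat.model, pat.clone, pat.donor_vaf,
                             inflammation_params=inflammation_params)
        donor_state = donor.u[-1]
        for dose in doses:
            graft = make_graft(pat.model, dose, clone=pat.clone,
                               hsc_fraction=pat.hsc_fraction,
                               donor_state=donor_state,
                               donor_vaf=float(donor.vaf(1)[-1]),
                               wildtype_homing=pat.homing)
            recip = _clone_run(pat, graft, pk, inflammation_params, horizon)
            rec = _patient_record(pat, donor, recip)
            rec["dose"] = dose
            rows.append(rec)
    return pd.DataFrame(rows)


def run_composition_trial(cohort: Sequence[VirtualPatient],
                          base_dose: float = 5.0e6,
                          ratios: Sequence[float] = (1.0, 5.0, 10.0, 15.0),
                          inflammation_params: Optional[InflammationParams] = None,
                          horizon: float = 1.05 * DAYS_PER_YEAR) -> pd.DataFrame:
    """Two arms varying graft composition at the donor's expense of nothing.

    Arm ``hsc``: HSC content scaled by ``ratios`` (relative to 1/5 of the
    reference graft's HSC content) at fixed HPC content; total dose stays
    at ``base_dose``.  Arm ``hpc``: HPC content scaled the same way at
    fixed HSC content; totals then span 1/5 to 3 times ``base_dose``.
    Graft 2 of the first arm and graft 2 of the second are identical.
    """
    rows = []
    for pat in cohort:
        if pat.clone is None:
            raise ValueError("composition trial requires a cohort with clones")
        donor = donor_course(pat.model, pat.clone, pat.donor_vaf,
                             inflammation_params=inflammation_params)
        donor_state = donor.u[-1]
        donor_vaf_now = float(donor.vaf(1)[-1])
        hsc_ref = base_dose * pat.hsc_fraction
        hpc_ref = base_dose * (1.0 - pat.hsc_fraction)
        for arm in ("hsc", "hpc"):
            for gi, ratio in enumerate(ratios, start=1):
                if arm == "hsc":
                    hsc, hpc = hsc_ref * ratio / 5.0, hpc_ref
                else:
                    hsc, hpc = hsc_ref, hpc_ref * ratio / 5.0
                dose = hsc + hpc
                graft = make_graft(pat.model, dose, clone=pat.clone,
                                   hsc_fraction=hsc / dose,
                                   donor_state=donor_state,
                                   donor_vaf=donor_vaf_now,
                                   wildtype_homing=pat.homing)
                recip = _clone_run(pat, graft, None, inflammation_params, horizon)
                rec = _patient_record(pat, donor, recip)
                rec.update({"arm": arm, "graft": gi, "hsc_per_kg": hsc,
                            "hpc_per_kg": hpc, "dose": dose})
                rows.append(rec)
    return pd.DataFrame(rows)


CORRELATION_PAIRS = [
    ("donor_vaf", "vaf_100d"),
    ("donor_vaf", "delta_R_100d"),
    ("donor_vaf", "pi_R_100d"),
    ("delta_D_1y", "delta_R_100d"),
    ("pi_D_1y", "pi_R_100d"),
    ("delta_D_1y", "vaf_100d"),
]


class UndefinedCorrelationError(ValueError):
    """A correlation input vector is constant."""


def correlate(table: pd.DataFrame,
              pairs: Sequence[tuple[str, str]] = tuple(CORRELATION_PAIRS)
              ) -> pd.DataFrame:
    """Spearman rank correlations (average-rank ties) for the metric pairs."""
    if len(table) < 3:
        raise ValueError("need at least 3 patients")
    rows = []
    for x, y in pairs:
        xv = table[x].to_numpy(dtype=float)
        yv = table[y].to_numpy(dtype=float)
        if not (np.all(np.isfinite(xv)) and np.all(np.isfinite(yv))):
            raise ValueError(f"non-finite values in pair ({x}, {y})")
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            raise UndefinedCorrelationError(f"constant input in pair ({x}, {y})")
        rho = spearmanr(xv, yv).statistic
        rows.append({"x": x, "y": y, "rho": float(rho)})
    return pd.DataFrame(rows)


def find_expansion_threshold(model: CalibratedModel, clone: CloneSpec,
                             inflammation_params: InflammationParams,
                             vaf_lo: float, vaf_hi: float,
                             dose: float = REFERENCE_DOSE,
                             hsc_fraction: float = 1250.0 / 4.7e6,
                             horizon: float = DAYS_PER_YEAR,
                             n_iter: int = 12) -> float:
    """Bisect the graft VAF separating clone decline from clone expansion.

    Applies to self-sustaining inflammation configurations (production > 0
    together with a fitness deficit off inflammation).  Requires that the
    low end declines and the high end expands; raises otherwise.
    """
    def expands(v: float) -> bool:
        graft = make_graft(model, dose, donor_vaf=v, clone=clone,
                           hsc_fraction=hsc_fraction)
        traj = simulate(graft.homed(), model, clones=graft.clones,
                        horizon=horizon, inflammation_params=inflammation_params)
        return traj.vaf(1)[-1] > v

    lo, hi = float(vaf_lo), float(vaf_hi)
    if expands(lo) or not expands(hi):
        raise ValueError("bracket does not separate decline from expansion")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if expands(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
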