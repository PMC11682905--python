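"""Graft construction, homing, and the donor's pre-donation course.

A CD34+ graft of ``dose`` cells/kg is split into an HSC portion
(``hsc_fraction``) and an HPC portion spread over the immature stages.
Each compartment is divided between the clones: proportionally to the
donor's per-compartment clonal fractions when a donor state is given,
otherwise uniformly at the mutant cell fraction implied by the donor PB
VAF (``2*VAF`` for a heterozygous clone).  Homing is instantaneous: the
recipient's initial state is the homing fraction times the graft, with
the mature compartment set to zero (circulating donor neutrophils are
cleared too quickly to matter).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .calibrate import CalibratedModel
from .dynamics import Trajectory, simulate
from .params import CloneSpec, GraftParams, InflammationParams, wildtype_clone
from .units import DAYS_PER_YEAR


@dataclass
class Graft:
    """Pre-homing cell content of a transplant, per clone and compartment."""

    dose_cd34_per_kg: float
    cells: np.ndarray              # (n_clones, n_compartments), mature row zero
    clones: list[CloneSpec]
    donor_vaf: float

    def homed(self) -> np.ndarray:
        """Recipient initial state: per-clone homing applied, mature zeroed."""
        state = np.zeros_like(self.cells)
        for j, clone in enumerate(self.clones):
            state[j, 0] = self.cells[j, 0] * clone.homing_hsc
            state[j, 1:-1] = self.cells[j, 1:-1] * clone.homing_hpc
        return state

    def not_homed(self) -> np.ndarray:
        return self.cells - self.homed() - self._mature_part()

    def _mature_part(self) -> np.ndarray:
        part = np.zeros_like(self.cells)
        part[:, -1] = self.cells[:, -1]
        return part


def mutant_cell_fraction(donor_vaf: float, zygosity: str) -> float:
    """Fraction of cells carrying the mutation for a given PB VAF."""
    frac = 2.0 * donor_vaf if zygosity == "heterozygous" else donor_vaf
    return min(frac, 1.0)


def _hpc_distribution(model: CalibratedModel, spec) -> np.ndarray:
    if isinstance(spec, str):
        if spec != "marrow":
            raise ValueError(f"unknown HPC distribution '{spec}'")
        return model.marrow_profile()
    dist = np.asarray(spec, dtype=float)
    if dist.shape != (model.n_stages,) or not np.isclose(dist.sum(), 1.0):
        raise ValueError("explicit HPC distribution must have n_stages entries summing to 1")
    return dist


def make_graft(model: CalibratedModel,
               dose_cd34_per_kg: float,
               donor_vaf: float = 0.0,
               clone: Optional[CloneSpec] = None,
               hsc_fraction: float = GraftParams().hsc_fraction,
               hpc_distribution="marrow",
               donor_state: Optional[np.ndarray] = None,
               wildtype_homing: float = 0.5) -> Graft:
    """Allocate a CD34+ dose across compartments and clones.

    With ``donor_state`` (shape (n_clones, n_compartments)) the clonal
    split follows the donor's per-compartment fractions; otherwise it is
    uniform at the mutant cell fraction implied by ``donor_vaf``.
    """
    if dose_cd34_per_kg <= 0:
        raise ValueError("dose must be positive")
    ncomp = model.n_compartments
    dist = _hpc_distribution(model, hpc_distribution)
    total = np.zeros(ncomp)
    total[0] = dose_cd34_per_kg * hsc_fraction
    total[1:-1] = dose_cd34_per_kg * (1.0 - hsc_fraction) * dist

    wt = wildtype_clone(homing=wildtype_homing)
    if donor_vaf == 0.0 and clone is None and donor_state is None:
        return Graft(dose_cd34_per_kg, total[None, :].copy(), [wt], 0.0)
    if clone is None:
        clone = CloneSpec()

    if donor_state is not None:
        ds = np.asarray(donor_state, dtype=float)
        if ds.shape != (2, ncomp):
            raise ValueError("donor_state must have shape (2, n_compartments)")
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_mut = np.where(ds.sum(axis=0) > 0,
                                ds[1] / np.maximum(ds.sum(axis=0), 1e-300), 0.0)
    else:
        frac_mut = np.full(ncomp, mutant_cell_fraction(donor_vaf, clone.zygosity))
    cells = np.vstack([(1.0 - frac_mut) * total, frac_mut * total])
    return Graft(dose_cd34_per_kg, cells, [wt, clone], donor_vaf)


def apply_homing(graft: Graft) -> np.ndarray:
    """Recipient initial state (cells/kg) after instantaneous homing."""
    return graft.homed()


def donor_equilibrium_state(model: CalibratedModel, donor_vaf: float,
                            clone: CloneSpec) -> np.ndarray:
    """Calibrated equilibrium split between wildtype and mutant clone.

    The mutant cell fraction (``2*VAF`` heterozygous) is applied uniformly
    across compartments; for a non-neutral clone this is the state of a
    donor whose clone reached the given VAF, not a true equilibrium.
    """
    frac = mutant_cell_fraction(donor_vaf, clone.zygosity)
    eq = model.equilibrium
    return np.vstack([(1.0 - frac) * eq, frac * eq])


def donor_course(model: CalibratedModel, clone: CloneSpec, donor_vaf: float,
                 years_before_donation: float = 1.0,
                 inflammation_params: Optional[InflammationParams] = None,
                 rtol: float = 1e-6, atol: float = 1e-3) -> Trajectory:
    """Simulate the donor from ``years_before_donation`` up to donation.

    The donor starts from the calibrated equilibrium carrying the clone at
    ``donor_vaf``; the trajectory's last time point is the donation.  The
    final state seeds :func:`make_graft` via ``donor_state``.
    """
    state0 = donor_equilibrium_state(model, donor_vaf, clone)
    horizon = years_before_donation * DAYS_PER_YEAR
    return simulate(state0, model, clones=[wildtype_clone(), clone],
                    horizon=horizon, inflammation_params=inflammation_params,
                    rtol=rtol, atol=atol)
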