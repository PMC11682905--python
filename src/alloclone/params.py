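"""Parameter schemas for the hematopoiesis model and its extensions.

The wildtype model describes one hematopoietic stem cell (HSC) compartment,
``n_stages`` progenitor/precursor (HPC) compartments and one mature
polymorphonuclear neutrophil (PMN) compartment.  Cell kinetics are set by
proliferation rates ``p`` (divisions per day), self-renewal probabilities
``a`` (probability that a daughter cell keeps its parent's compartment) and
the mature-cell clearance rate ``d``.  Two first-order Hill signals regulate
the kinetics: a systemic signal driven by the mature cell count (the
G-CSF-like cytokine axis) and a niche signal driven by the HSC count.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .units import DAYS_PER_YEAR

FeedbackVariant = Literal[
    "baseline", "niche_selfrenewal", "niche_selfrenewal_proliferation"
]

Zygosity = Literal["heterozygous", "homozygous"]

#: homeostatic value of both feedback signals; fixed by the gain choice
#: k_sys = 1/M*, k_niche = 1/H* so that s(M*) = s(H*) = 1/2.
S_STAR = 0.5


class ModelParams(BaseModel):
    """Wildtype model parameters.

    Rates are per day, concentrations per kg of body weight.  ``a_hpc_hom``
    and the feedback gains are usually left ``None`` and filled in by
    :func:`alloclone.calibrate.calibrate_homeostasis`.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    n_stages: int = Field(15, ge=1, description="immature non-HSC compartments")
    p_hsc_hom: float = Field(2.0 / DAYS_PER_YEAR, gt=0,
                             description="homeostatic HSC proliferation rate, 1/day")
    p_last_hom: float = Field(1.0, gt=0,
                              description="homeostatic proliferation of the last mitotic stage, 1/day")
    prolif_fold_max: float = Field(4.0, gt=1,
                                   description="maximal fold-increase of immature proliferation under full stimulation")
    prolif_floor: float = Field(0.25, gt=0, le=1,
                                description="lower bound of the proliferation response below the homeostatic signal")
    a_hsc_max: float = Field(1.0, gt=0.5, le=1.0,
                             description="maximal HSC self-renewal probability")
    a_hpc_hom: Optional[float] = Field(None, gt=0, lt=0.5,
                                       description="homeostatic HPC self-renewal probability (uniform across stages); solved by calibration when None")
    selfrenewal_feedback_slope: float = Field(0.12, gt=0,
                                              description="slope of the HPC self-renewal (amplification) response per unit signal; calibrated to post-transplant recovery")
    a_hpc_cap: float = Field(0.99, gt=0.5, lt=1.0,
                             description="upper clip of the stimulated HPC self-renewal probability")
    d_mature: float = Field(2.3, gt=0, description="mature neutrophil clearance rate, 1/day")
    M_star: float = Field(3.1e8, gt=0, description="homeostatic mature neutrophil concentration, cells/kg")
    H_star: float = Field(100000.0 / 80.0, gt=0, description="homeostatic HSC concentration, cells/kg")
    k_sys: Optional[float] = Field(None, gt=0, description="systemic feedback gain, 1/(cells/kg); default 1/M_star")
    k_niche: Optional[float] = Field(None, gt=0, description="niche feedback gain, 1/(cells/kg); default 1/H_star")
    variant: FeedbackVariant = "baseline"

    @model_validator(mode="after")
    def _check_rates(self) -> "ModelParams":
        if not self.p_hsc_hom < self.p_last_hom:
            raise ValueError("p_hsc_hom must be smaller than p_last_hom")
        if self.a_hpc_hom is not None and not (0 < self.a_hpc_hom < 0.5):
            raise ValueError("a_hpc_hom must lie in (0, 0.5)")
        return self


class CloneSpec(BaseModel):
    """Properties of one clone relative to the wildtype.

    Multipliers act on the wildtype kinetic parameters; sensitivity factors
    ``sens_*`` steepen the response to deviations of the feedback signals
    from their homeostatic value (1 = wildtype response).  Homing fractions
    are the fractions of transplanted cells of this clone that lodge in the
    marrow and contribute to blood formation.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    clone_id: str = "mutant"
    mult_prolif_hsc: float = Field(1.0, gt=0)
    mult_prolif_hpc: float = Field(1.0, gt=0)
    mult_selfrenewal_hsc: float = Field(1.0, gt=0)
    mult_selfrenewal_hpc: float = Field(1.0, gt=0)
    mult_clearance: float = Field(1.0, gt=0)
    sens_hsc: float = Field(1.0, ge=0)
    sens_hpc: float = Field(1.0, ge=0)
    homing_hsc: float = Field(0.5, ge=0, le=1)
    homing_hpc: float = Field(0.5, ge=0, le=1)
    zygosity: Zygosity = "heterozygous"


def wildtype_clone(homing: float = 0.5) -> CloneSpec:
    """The reference clone: all multipliers and sensitivities equal 1."""
    return CloneSpec(clone_id="wildtype", homing_hsc=homing, homing_hpc=homing)


class InflammationParams(BaseModel):
    """CHIP-driven systemic inflammatory burden and its couplings.

    The mediator is assumed short-lived, so its level is the quasi-steady
    state of linear production/decay: ``I = B0 + alpha * c_mut_mature``.
    Its effect saturates through a first-order Hill term ``e = I/(I+theta)``.
    ``mutant_boost`` multiplies mutant kinetics by ``(1 - disadvantage_delta
    + lambda*e)``; ``wildtype_exhaustion`` multiplies wildtype self-renewal
    and amplification by ``(1 - mu*e)``.  Burden units are arbitrary; theta
    normalizes them.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    mode: Literal["off", "mutant_boost", "wildtype_exhaustion"] = "off"
    host_baseline: float = Field(0.0, ge=0, description="CHIP-independent burden B0")
    production: float = Field(0.0, ge=0, description="burden per mutated mature cell per kg (alpha)")
    hill_theta: float = Field(1.0, gt=0, description="half-saturation burden (theta)")
    lambda_selfrenewal: float = Field(0.0, ge=0)
    lambda_prolif: float = Field(0.0, ge=0)
    lambda_amplification: float = Field(0.0, ge=0)
    mu_selfrenewal: float = Field(0.0, ge=0, le=1)
    mu_amplification: float = Field(0.0, ge=0, le=1)
    disadvantage_delta: float = Field(0.0, ge=0, lt=1,
                                      description="fitness deficit of the mutant clone in the absence of inflammation")
    wildtype_prolif_boost: float = Field(0.0, ge=0,
                                         description="optional increase of wildtype proliferation with burden in exhaustion mode")


class PKParams(BaseModel):
    """Pegfilgrastim-like two-compartment pharmacokinetics.

    A dose enters a subcutaneous depot and is absorbed into plasma at rate
    ``ka``; elimination from plasma is first order with rate ``ke``.  Dose
    amounts are normalized to 1; ``gamma`` converts plasma concentration to
    feedback-signal units.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # defaults solved by calibrate_pk: single-dose peak at 2 days,
    # post-peak half-decay 3.5 days
    ka: float = Field(0.6679553344659718, gt=0, description="absorption rate from the depot, 1/day")
    ke: float = Field(0.3628779314281144, gt=0, description="plasma elimination rate, 1/day")
    gamma: float = Field(0.5, ge=0, description="stimulus units per concentration unit")
    doses: list[tuple[float, float]] = Field(default_factory=list,
                                             description="(time in days, dose amount) pairs")


class GraftParams(BaseModel):
    """Composition of a CD34+ graft before homing.

    ``hsc_fraction`` is the fraction of the CD34+ dose that behaves as true
    HSCs; the default puts 1250 HSC/kg into the reference 4.7e6/kg dose
    (1e5 HSCs per 80 kg body).  The HPC remainder is spread over the
    immature stages either proportionally to the homeostatic marrow profile
    (``"marrow"``) or by an explicit distribution vector.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    dose_cd34_per_kg: float = Field(4.7e6, gt=0)
    hsc_fraction: float = Field(1250.0 / 4.7e6, gt=0, lt=1)
    hpc_distribution: str | list[float] = "marrow"
    donor_vaf: float = Field(0.0, ge=0, le=1)
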