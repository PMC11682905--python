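"""Named scenario presets covering the canonical clonal-dynamics regimes.

Each preset is a complete :class:`~alloclone.config.ScenarioConfig`
together with the qualitative VAF pattern its recipient trajectory is
expected to show under :func:`alloclone.clones.classify_pattern`.
"""

from __future__ import annotations

from .config import ScenarioConfig
from .params import CloneSpec, GraftParams, InflammationParams, PKParams
from .pk import single_dose_schedule
from .units import DAYS_PER_YEAR

_FIVE_YEARS = 5 * DAYS_PER_YEAR


def _preset_reference() -> ScenarioConfig:
    return ScenarioConfig(name="reference_engraftment", horizon_days=120.0,
                          expected_pattern=None)


def _preset_reference_gcsf() -> ScenarioConfig:
    return ScenarioConfig(name="reference_engraftment_gcsf", horizon_days=120.0,
                          pk=PKParams(doses=single_dose_schedule(3.0)),
                          expected_pattern=None)


def _preset_saturated_sensitivity() -> ScenarioConfig:
    # mutated stem and progenitor cells respond more sensitively to the
    # systemic signal; no advantage at homeostasis -> expansion saturates
    clone = CloneSpec(sens_hsc=2.5, sens_hpc=2.5)
    return ScenarioConfig(name="saturated_sensitivity", clone=clone,
                          graft=GraftParams(donor_vaf=0.05),
                          horizon_days=_FIVE_YEARS,
                          expected_pattern="saturated")


def _preset_transient_progenitor() -> ScenarioConfig:
    # only progenitors respond more sensitively: no stem-cell advantage,
    # so the VAF rise is temporary
    clone = CloneSpec(sens_hpc=2.5)
    return ScenarioConfig(name="transient_progenitor", clone=clone,
                          graft=GraftParams(donor_vaf=0.05),
                          horizon_days=_FIVE_YEARS,
                          expected_pattern="transient")


def _preset_saturated_homing() -> ScenarioConfig:
    # kinetically neutral clone whose HSCs home better than its HPCs
    clone = CloneSpec(homing_hsc=0.9, homing_hpc=0.7)
    return ScenarioConfig(name="saturated_homing", clone=clone,
                          graft=GraftParams(donor_vaf=0.05),
                          horizon_days=_FIVE_YEARS,
                          expected_pattern="saturated")


def _preset_persistent_selfrenewal() -> ScenarioConfig:
    # permanent increase of mutant HSC self-renewal (and proliferation)
    clone = CloneSpec(mult_selfrenewal_hsc=1.2, mult_prolif_hsc=1.5)
    return ScenarioConfig(name="persistent_selfrenewal", clone=clone,
                          graft=GraftParams(donor_vaf=0.04),
                          horizon_days=_FIVE_YEARS, donor_years=1.0,
                          expected_pattern="persistent")


def _preset_persistent_inflammation() -> ScenarioConfig:
    # mutant mature cells sustain an inflammatory burden that boosts
    # mutant self-renewal, proliferation and amplification
    clone = CloneSpec()
    infl = InflammationParams(mode="mutant_boost", host_baseline=0.5,
                              production=1.6e-8, hill_theta=1.0,
                              lambda_selfrenewal=0.2, lambda_prolif=0.5,
                              lambda_amplification=0.1)
    return ScenarioConfig(name="persistent_inflammation", clone=clone,
                          inflammation=infl, graft=GraftParams(donor_vaf=0.04),
                          horizon_days=_FIVE_YEARS, donor_years=1.0,
                          expected_pattern="persistent")


def _preset_wildtype_exhaustion() -> ScenarioConfig:
    # inflammation driven by the mutant clone exhausts wildtype stem cells
    clone = CloneSpec()
    infl = InflammationParams(mode="wildtype_exhaustion", production=1.6e-8,
                              hill_theta=1.0, mu_selfrenewal=0.3,
                              mu_amplification=0.2)
    return ScenarioConfig(name="wildtype_exhaustion", clone=clone,
                          inflammation=infl, graft=GraftParams(donor_vaf=0.1),
                          horizon_days=_FIVE_YEARS, donor_years=1.0,
                          expected_pattern="persistent")


def _preset_donor_recipient() -> ScenarioConfig:
    cfg = _preset_persistent_selfrenewal()
    return cfg.model_copy(update={"name": "donor_recipient_divergence",
                                  "horizon_days": 15 * DAYS_PER_YEAR})


def _preset_inflammation_threshold() -> ScenarioConfig:
    # inflammation-dependent clone: fitness deficit off inflammation,
    # self-sustaining burden production; the donor's host baseline keeps
    # it growing, the recipient's lower baseline may not
    clone = CloneSpec()
    recipient = InflammationParams(mode="mutant_boost", host_baseline=0.2,
                                   production=1.6e-8, hill_theta=1.0,
                                   lambda_selfrenewal=0.08, lambda_prolif=0.08,
                                   lambda_amplification=0.08,
                                   disadvantage_delta=0.02)
    donor = recipient.model_copy(update={"host_baseline": 1.0})
    return ScenarioConfig(name="inflammation_threshold", clone=clone,
                          inflammation=recipient, donor_inflammation=donor,
                          graft=GraftParams(donor_vaf=0.08),
                          horizon_days=_FIVE_YEARS, donor_years=1.0,
                          expected_pattern="persistent")


_BUILDERS = {
    "reference_engraftment": _preset_reference,
    "reference_engraftment_gcsf": _preset_reference_gcsf,
    "saturated_sensitivity": _preset_saturated_sensitivity,
    "transient_progenitor": _preset_transient_progenitor,
    "saturated_homing": _preset_saturated_homing,
    "persistent_selfrenewal": _preset_persistent_selfrenewal,
    "persistent_inflammation": _preset_persistent_inflammation,
    "wildtype_exhaustion": _preset_wildtype_exhaustion,
    "donor_recipient_divergence": _preset_donor_recipient,
    "inflammation_threshold": _preset_inflammation_threshold,
}


def preset_names() -> list[str]:
    return sorted(_BUILDERS)


def get_preset(name: str) -> ScenarioConfig:
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise KeyError(f"unknown preset '{name}'; available: {preset_names()}") from None
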