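"""Scenario configuration: schema, YAML round-trip, scenario runner."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .calibrate import calibrate_homeostasis
from .dynamics import Trajectory, simulate
from .params import (CloneSpec, GraftParams, InflammationParams, ModelParams,
                     PKParams)
from .transplant import donor_course, make_graft
from .units import DAYS_PER_YEAR


class ConfigError(ValueError):
    """Configuration file invalid; message names the offending field."""


class ScenarioConfig(BaseModel):
    """Complete description of one transplantation scenario."""

    model_config = ConfigDict(extra="forbid")

    name: str = "scenario"
    model: ModelParams = ModelParams()
    clone: Optional[CloneSpec] = None
    graft: GraftParams = GraftParams()
    pk: Optional[PKParams] = None
    inflammation: Optional[InflammationParams] = None
    donor_inflammation: Optional[InflammationParams] = None
    horizon_days: float = 365.0
    donor_years: float = 0.0
    expected_pattern: Optional[str] = None


def load_config(path) -> ScenarioConfig:
    """Read and schema-validate a YAML scenario file (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    try:
        return ScenarioConfig.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigError(f"{loc}: {first['msg']}") from exc


def save_config(config: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(
        json.loads(config.model_dump_json()), sort_keys=True))


def config_hash(config: ScenarioConfig) -> str:
    """Stable content hash of a configuration."""
    canonical = json.dumps(json.loads(config.model_dump_json()), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def run_scenario(config: ScenarioConfig,
                 rtol: float = 1e-6, atol: float = 1e-3
                 ) -> dict[str, Trajectory]:
    """Simulate a scenario: optional donor pre-course, then the recipient.

    Returns ``{"recipient": ..., "donor": ...}`` (donor only when
    ``donor_years > 0`` and a clone is present).
    """
    model = calibrate_homeostasis(config.model)
    out: dict[str, Trajectory] = {}
    donor_state = None
    donor_vaf = config.graft.donor_vaf
    if config.clone is not None and config.donor_years > 0:
        donor_infl = config.donor_inflammation or config.inflammation
        donor = donor_course(model, config.clone, config.graft.donor_vaf,
                             years_before_donation=config.donor_years,
                             inflammation_params=donor_infl,
                             rtol=rtol, atol=atol)
        out["donor"] = donor
        donor_state = donor.u[-1]
        donor_vaf = float(donor.vaf(1)[-1])
    graft = make_graft(model, config.graft.dose_cd34_per_kg,
                       donor_vaf=donor_vaf, clone=config.clone,
                       hsc_fraction=config.graft.hsc_fraction,
                       hpc_distribution=config.graft.hpc_distribution,
                       donor_state=donor_state)
    out["recipient"] = simulate(
        graft.homed(), model, clones=graft.clones,
        horizon=config.horizon_days, pk=config.pk,
        inflammation_params=config.inflammation,
        threshold_per_l=5.0e8, rtol=rtol, atol=atol)
    return out
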