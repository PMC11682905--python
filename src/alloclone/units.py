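"""Unit conventions.

All cell quantities in the model are concentrations in cells per kg of body
weight.  Clinical neutrophil counts are reported per liter of blood; the two
scales are linked by the reference anthropometry of an 80 kg adult with 5 l
of blood, so 1 cell/l corresponds to 5/80 = 1/16 cell/kg.
"""

BODY_WEIGHT_KG = 80.0
BLOOD_VOLUME_L = 5.0

#: multiply a per-kg concentration by this to obtain a per-liter count
KG_PER_L = BODY_WEIGHT_KG / BLOOD_VOLUME_L

#: clinical engraftment threshold: 5x10^8 neutrophils per liter of blood
ENGRAFTMENT_THRESHOLD_PER_L = 5.0e8

DAYS_PER_YEAR = 365.25


def per_liter_to_per_kg(value_per_liter: float) -> float:
    """Convert a blood concentration (cells/l) to a body-weight concentration."""
    return value_per_liter / KG_PER_L


def per_kg_to_per_liter(value_per_kg: float) -> float:
    """Convert a body-weight concentration (cells/kg) to a blood concentration."""
    return value_per_kg * KG_PER_L
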