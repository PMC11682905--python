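"""CHIP-driven systemic inflammation.

Mutated mature cells overexpress pro-inflammatory mediators.  Assuming the
mediators are short-lived and degraded cell-independently, their level is
the quasi-steady state of linear production and decay,

    I = B0 + alpha * c_mut_mature,

where ``B0`` is a CHIP-independent host burden (atherosclerosis,
inflammaging, ...).  The impact on cell kinetics saturates through a
first-order Hill term ``e = I/(I + theta)``.  Two coupling modes exist:
``mutant_boost`` (inflammation confers a growth advantage to mutated
cells) and ``wildtype_exhaustion`` (inflammation drives wildtype cells
into replicative exhaustion, sparing the resistant mutant clone).
"""

from __future__ import annotations

import numpy as np

from .params import InflammationParams


def burden(c_mut_mature, params: InflammationParams):
    """Quasi-steady-state inflammatory burden for a mutant mature count."""
    c = np.asarray(c_mut_mature, dtype=float)
    if np.any(c < 0):
        raise ValueError("mutant mature concentration must be non-negative")
    return params.host_baseline + params.production * c


def effect(I, theta):
    """Saturating effect ``I/(I + theta)`` of the burden, in [0, 1)."""
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("burden must be non-negative")
    if theta <= 0:
        raise ValueError("theta must be positive")
    return I / (I + theta)


def mutant_factors(e: float, params: InflammationParams):
    """Multiplicative factors (self-renewal, proliferation, amplification)
    applied to mutant kinetics in ``mutant_boost`` mode.

    Each factor is ``1 - disadvantage_delta + lambda * e``: the clone pays
    its fitness deficit unconditionally and recovers it only when the
    inflammatory effect is large enough.
    """
    d = params.disadvantage_delta
    return (1.0 - d + params.lambda_selfrenewal * e,
            1.0 - d + params.lambda_prolif * e,
            1.0 - d + params.lambda_amplification * e)


def wildtype_factors(e: float, params: InflammationParams):
    """Multiplicative factors (self-renewal, amplification, proliferation)
    applied to wildtype kinetics in ``wildtype_exhaustion`` mode."""
    return (1.0 - params.mu_selfrenewal * e,
            1.0 - params.mu_amplification * e,
            1.0 + params.wildtype_prolif_boost * e)
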