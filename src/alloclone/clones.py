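"""Variant-allele-frequency computation, trajectory patterns, metrics.

The peripheral-blood VAF of a heterozygous clone is
``c_M / (c_WT + c_M) / 2`` (mature cells only; the factor 1/2 reflects
that only one allele carries the mutation), bounded by 0.5.  For a
homozygous clone the factor is dropped.

Post-transplant VAF trajectories fall into qualitative patterns:
*saturated* (fast early expansion that levels off), *persistent*
(approximately constant expansion rate over years), *transient* (rise
followed by return toward the donor VAF) and *none*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import S_STAR, Zygosity
from .units import DAYS_PER_YEAR


def vaf(c_mut_mature, c_wt_mature, zygosity: Zygosity = "heterozygous"):
    """Variant allele frequency from mutant and wildtype mature counts."""
    c_m = np.asarray(c_mut_mature, dtype=float)
    c_w = np.asarray(c_wt_mature, dtype=float)
    if np.any(c_m < 0) or np.any(c_w < 0):
        raise ValueError("cell concentrations must be non-negative")
    total = c_m + c_w
    scalar = np.isscalar(c_mut_mature) and np.isscalar(c_wt_mature)
    if scalar and total == 0:
        raise ValueError("VAF undefined: no mature cells")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, c_m / np.where(total > 0, total, 1.0), np.nan)
    out = frac / 2.0 if zygosity == "heterozygous" else frac
    return float(out) if scalar else out


def mutant_response(s, s_star: float, sigma: float, base_response):
    """Evaluate a wildtype response at the sensitivity-transformed signal.

    Returns ``base_response(s* + sigma*(s - s*))`` with the transformed
    signal clipped to (0, 1]; identical to the wildtype value at ``s = s*``
    for any sigma, and to the wildtype response everywhere for sigma = 1.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    x = np.clip(s_star + sigma * (np.asarray(s, dtype=float) - s_star), 1e-9, 1.0)
    return base_response(x)


@dataclass(frozen=True)
class ExpansionMetrics:
    """Donor/recipient expansion summary at fixed horizons."""

    vaf_donor: float          # donor PB VAF at donation
    vaf_100d: float           # recipient PB VAF 100 days post transplant
    vaf_1y: float             # recipient PB VAF 1 year post transplant
    delta_R_100d: float       # vaf_100d - vaf_donor
    pi_R_100d: float          # vaf_100d / vaf_donor
    delta_D_1y: float         # donor VAF change over the pre-donation year
    pi_D_1y: float            # donor VAF ratio over the pre-donation year


def expansion_metrics_from_series(t_donor, v_donor, t_recipient, v_recipient
                                  ) -> ExpansionMetrics:
    """Metrics by linear interpolation at the exact horizons.

    The donor series must cover at least one year before its last point
    (the donation); the recipient series at least one year.
    """
    t_d = np.asarray(t_donor, dtype=float)
    v_d = np.asarray(v_donor, dtype=float)
    t_r = np.asarray(t_recipient, dtype=float)
    v_r = np.asarray(v_recipient, dtype=float)
    if t_d[-1] - t_d[0] < DAYS_PER_YEAR - 1e-9:
        raise ValueError("donor trajectory must cover >= 1 year before donation")
    if t_r[-1] - t_r[0] < DAYS_PER_YEAR - 1e-9:
        raise ValueError("recipient trajectory must cover >= 1 year")
    vaf_donor = float(v_d[-1])
    vaf_prior = float(np.interp(t_d[-1] - DAYS_PER_YEAR, t_d, v_d))
    vaf_100d = float(np.interp(t_r[0] + 100.0, t_r, v_r))
    vaf_1y = float(np.interp(t_r[0] + DAYS_PER_YEAR, t_r, v_r))
    return ExpansionMetrics(
        vaf_donor=vaf_donor,
        vaf_100d=vaf_100d,
        vaf_1y=vaf_1y,
        delta_R_100d=vaf_100d - vaf_donor,
        pi_R_100d=vaf_100d / vaf_donor if vaf_donor > 0 else float("nan"),
        delta_D_1y=vaf_donor - vaf_prior,
        pi_D_1y=vaf_donor / vaf_prior if vaf_prior > 0 else float("nan"),
    )


def expansion_metrics(donor_trajectory, recipient_trajectory,
                      clone_index: int = 1) -> ExpansionMetrics:
    """Trajectory wrapper around :func:`expansion_metrics_from_series`."""
    return expansion_metrics_from_series(
        donor_trajectory.t, donor_trajectory.vaf(clone_index),
        recipient_trajectory.t, recipient_trajectory.vaf(clone_index))


def classify_pattern(t_days, vaf_series, donor_vaf: float, *,
                     none_band: float = 0.005,
                     persistent_slope_per_year: float = 0.005,
                     plateau_fraction: float = 0.1) -> str:
    """Rule-based pattern label for a recipient VAF trajectory.

    ``none``: the VAF never leaves a band around the donor VAF.
    ``persistent``: the mean slope over years 2-5 exceeds
    ``persistent_slope_per_year``.  ``saturated``: the trajectory plateaus
    above the donor VAF (late slope below ``plateau_fraction`` of the
    early expansion rate).  ``transient``: everything else, i.e. a rise
    (or fall) that reverts toward the donor VAF.
    """
    t = np.asarray(t_days, dtype=float)
    v = np.asarray(vaf_series, dtype=float)
    if t[-1] - t[0] < 2 * DAYS_PER_YEAR - 1e-9:
        raise ValueError("trajectory must cover at least 2 years")
    dev = v - donor_vaf
    if np.nanmax(np.abs(dev)) < none_band:
        return "none"

    late = (t - t[0] >= 2 * DAYS_PER_YEAR) & (t - t[0] <= 5 * DAYS_PER_YEAR)
    late_slope = np.polyfit(t[late] / DAYS_PER_YEAR, v[late], 1)[0]
    if late_slope > persistent_slope_per_year:
        return "persistent"

    early = t - t[0] <= 100.0
    dv = np.gradient(v[early], t[early] / DAYS_PER_YEAR)
    early_rate = float(np.nanmax(np.abs(dv))) if np.count_nonzero(early) > 2 else 0.0
    plateaued = early_rate > 0 and abs(late_slope) < plateau_fraction * early_rate
    if plateaued and v[-1] > donor_vaf + none_band:
        return "saturated"
    return "transient"
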