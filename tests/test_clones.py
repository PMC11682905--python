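import numpy as np
import pytest

from alloclone import CloneSpec, make_graft, simulate, vaf
from alloclone.clones import (classify_pattern, expansion_metrics_from_series,
                              mutant_response)
from alloclone.units import DAYS_PER_YEAR


class TestVAF:
    @pytest.mark.parametrize("c_mut,c_wt,zyg,expected", [
        (1e7, 0.0, "heterozygous", 0.5),     # all neutrophils mutated
        (0.0, 1e7, "heterozygous", 0.0),
        (5e6, 5e6, "heterozygous", 0.25),
        (1e7, 0.0, "homozygous", 1.0),
        (5e6, 5e6, "homozygous", 0.5),
    ])
    def test_formula(self, c_mut, c_wt, zyg, expected):
        assert vaf(c_mut, c_wt, zyg) == pytest.approx(expected)

    def test_undefined_for_empty_blood(self):
        with pytest.raises(ValueError):
            vaf(0.0, 0.0)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            vaf(-1.0, 1.0)


class TestMutantResponse:
    def test_identity_at_homeostatic_signal(self):
        base = lambda x: 3.0 * x + 1.0
        assert mutant_response(0.5, 0.5, 7.0, base) == pytest.approx(base(0.5))

    def test_sigma_one_recovers_wildtype_everywhere(self):
        base = lambda x: x ** 2
        for s in np.linspace(0.1, 1.0, 7):
            assert mutant_response(s, 0.5, 1.0, base) == pytest.approx(base(s))

    def test_steeper_response_above_operating_point(self):
        base = lambda x: x
        assert mutant_response(0.8, 0.5, 2.0, base) > base(0.8)


class TestNeutrality:
    def test_neutral_clone_vaf_constant_over_ten_years(self, model):
        graft = make_graft(model, 4.7e6, donor_vaf=0.05, clone=CloneSpec())
        traj = simulate(graft.homed(), model, clones=graft.clones,
                        horizon=10 * 365.25, grid_dt=10.0)
        v = traj.vaf(1)
        v = v[np.isfinite(v)]
        assert np.max(np.abs(v - 0.05)) / 0.05 < 1e-6

    def test_heterozygous_vaf_never_exceeds_half(self, model):
        # aggressive clone that takes over the system
        clone = CloneSpec(mult_selfrenewal_hsc=1.3, mult_prolif_hsc=3.0,
                          sens_hpc=2.0)
        graft = make_graft(model, 4.7e6, donor_vaf=0.2, clone=clone)
        traj = simulate(graft.homed(), model, clones=graft.clones,
                        horizon=8 * 365.25, grid_dt=10.0)
        v = traj.vaf(1)
        assert np.nanmax(v) <= 0.5 + 1e-12
        assert np.nanmax(v) > 0.45   # it does take over


class TestClassifyPattern:
    def _t(self, years=6.0):
        return np.linspace(0, years * DAYS_PER_YEAR, 400)

    def test_constant_at_donor_vaf_is_none(self):
        t = self._t()
        assert classify_pattern(t, np.full_like(t, 0.06), 0.06) == "none"

    def test_steady_rise_is_persistent(self):
        t = self._t()
        v = 0.05 + 0.02 * t / DAYS_PER_YEAR
        assert classify_pattern(t, v, 0.05) == "persistent"

    def test_plateau_above_donor_is_saturated(self):
        t = self._t()
        v = 0.05 + 0.05 * (1 - np.exp(-t / 50.0))
        assert classify_pattern(t, v, 0.05) == "saturated"

    def test_rise_and_return_is_transient(self):
        t = self._t()
        v = 0.05 + 0.08 * (t / 100.0) * np.exp(1 - t / 100.0)
        assert classify_pattern(t, v, 0.05) == "transient"

    def test_short_trajectory_rejected(self):
        t = np.linspace(0, 300, 50)
        with pytest.raises(ValueError):
            classify_pattern(t, np.full_like(t, 0.1), 0.05)

    def test_simulated_selfrenewal_mutant_is_persistent(self, model):
        clone = CloneSpec(mult_selfrenewal_hsc=1.2, mult_prolif_hsc=1.5)
        graft = make_graft(model, 4.7e6, donor_vaf=0.04, clone=clone)
        traj = simulate(graft.homed(), model, clones=graft.clones,
                        horizon=5 * 365.25, grid_dt=5.0)
        assert classify_pattern(traj.t, traj.vaf(1), 0.04) == "persistent"

    def test_simulated_progenitor_sensitivity_is_transient(self, model):
        clone = CloneSpec(sens_hpc=2.5)
        graft = make_graft(model, 4.7e6, donor_vaf=0.05, clone=clone)
        traj = simulate(graft.homed(), model, clones=graft.clones,
                        horizon=5 * 365.25, grid_dt=5.0)
        assert classify_pattern(traj.t, traj.vaf(1), 0.05) == "transient"


class TestExpansionMetrics:
    def test_constant_equal_vafs_give_null_metrics(self):
        t = np.linspace(0, 400, 100)
        v = np.full_like(t, 0.07)
        m = expansion_metrics_from_series(t, v, t, v)
        assert m.delta_R_100d == pytest.approx(0.0, abs=1e-15)
        assert m.pi_R_100d == pytest.approx(1.0)

    def test_linear_donor_growth_arithmetic(self):
        t = np.linspace(0, DAYS_PER_YEAR, 200)
        v_d = 0.04 + 0.01 * t / DAYS_PER_YEAR   # 0.04 -> 0.05 over the year
        v_r = np.full_like(t, 0.05)
        m = expansion_metrics_from_series(t, v_d, t, v_r)
        assert m.delta_D_1y == pytest.approx(0.01, rel=1e-6)
        assert m.pi_D_1y == pytest.approx(1.25, rel=1e-6)

    def test_insufficient_coverage_rejected(self):
        t = np.linspace(0, 100, 20)
        with pytest.raises(ValueError):
            expansion_metrics_from_series(t, t * 0 + 0.1, t, t * 0 + 0.1)

    def test_saturated_simulation_expands_relative(self, model):
        clone = CloneSpec(sens_hsc=1.15, sens_hpc=2.0)
        graft = make_graft(model, 4.7e6, donor_vaf=0.05, clone=clone)
        recip = simulate(graft.homed(), model, clones=graft.clones,
                         horizon=380.0)
        t_d = np.linspace(0, 380, 50)
        donor_v = np.full_like(t_d, 0.05)
        m = expansion_metrics_from_series(t_d, donor_v, recip.t, recip.vaf(1))
        assert m.pi_R_100d > 1.0
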