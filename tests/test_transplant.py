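import numpy as np
import pytest

from alloclone import (CloneSpec, apply_homing, donor_course, engraftment_time,
                       make_graft, simulate)


class TestMakeGraft:
    def test_dose_allocated_exactly(self, model):
        graft = make_graft(model, 4.7e6)
        assert graft.cells.sum() == pytest.approx(4.7e6, rel=1e-12)
        assert graft.cells[:, -1].sum() == 0.0   # no mature cells in the graft

    def test_low_vaf_graft_still_carries_over_thousand_mutant_hscs(self, model):
        # 1e5 transplanted HSCs at donor VAF 0.005 (heterozygous)
        dose = 4.7e6
        graft = make_graft(model, dose, donor_vaf=0.005, clone=CloneSpec(),
                           hsc_fraction=1e5 / dose)
        mutant_hsc = graft.cells[1, 0]
        assert graft.cells[:, 0].sum() == pytest.approx(1e5)
        assert mutant_hsc == pytest.approx(2 * 0.005 * 1e5)
        assert mutant_hsc >= 1000

    def test_zero_vaf_gives_single_wildtype_clone(self, model):
        graft = make_graft(model, 4.7e6, donor_vaf=0.0)
        assert len(graft.clones) == 1
        assert graft.clones[0].clone_id == "wildtype"

    def test_rejects_nonpositive_dose(self, model):
        with pytest.raises(ValueError):
            make_graft(model, 0.0)


class TestHoming:
    def test_dose_conservation(self, model):
        clone = CloneSpec(homing_hsc=0.8, homing_hpc=0.3)
        graft = make_graft(model, 4.7e6, donor_vaf=0.1, clone=clone)
        total = graft.homed() + graft.not_homed()
        np.testing.assert_allclose(total, graft.cells, rtol=1e-12)

    def test_equal_homing_preserves_donor_vaf(self, model):
        graft = make_graft(model, 4.7e6, donor_vaf=0.05, clone=CloneSpec())
        state = apply_homing(graft)
        frac = state[1].sum() / state.sum()
        assert frac / 2 == pytest.approx(0.05, rel=1e-12)

    def test_preferential_mutant_homing_arithmetic(self, model):
        # wildtype 50%, mutant 80%, graft VAF 0.05: marrow mutant cell
        # fraction 0.08/0.53, i.e. VAF ~ 0.0755
        clone = CloneSpec(homing_hsc=0.8, homing_hpc=0.8)
        graft = make_graft(model, 4.7e6, donor_vaf=0.05, clone=clone)
        state = apply_homing(graft)
        frac = state[1].sum() / state.sum()
        assert frac == pytest.approx(0.08 / 0.53, rel=1e-9)

    def test_hsc_homing_advantage_raises_vaf_monotonically(self, model):
        clone = CloneSpec(homing_hsc=0.9, homing_hpc=0.7)
        graft = make_graft(model, 4.7e6, donor_vaf=0.05, clone=clone)
        traj = simulate(graft.homed(), model, clones=graft.clones,
                        horizon=1200.0, grid_dt=2.0)
        v = traj.vaf(1)
        v = v[np.isfinite(v)]
        dv = np.diff(v)
        assert v[-1] > v[0]
        assert np.all(dv > -1e-10)                    # monotone rise
        assert abs(v[-1] - v[-50]) < 1e-4             # converged to a constant


class TestEngraftmentDose:
    def test_larger_dose_never_engrafts_later(self, model):
        times = []
        for dose in (1e6, 4.7e6, 1.5e7):
            graft = make_graft(model, dose)
            traj = simulate(graft.homed(), model, clones=graft.clones,
                            horizon=90.0, threshold_per_l=5e8,
                            stop_at_threshold=True)
            times.append(engraftment_time(traj))
        assert times[0] >= times[1] >= times[2]

    def test_global_homing_shifts_timing_not_pattern(self, model):
        # different overall homing percentages: engraftment moves, the
        # qualitative VAF course of a sensitivity clone does not
        from alloclone.clones import classify_pattern
        labels, times = [], []
        for homing in (0.3, 0.5, 0.7):
            clone = CloneSpec(sens_hpc=2.0, sens_hsc=1.3,
                              homing_hsc=homing, homing_hpc=homing)
            graft = make_graft(model, 4.7e6, donor_vaf=0.05, clone=clone,
                               wildtype_homing=homing)
            traj = simulate(graft.homed(), model, clones=graft.clones,
                            horizon=3 * 365.25, grid_dt=2.0,
                            threshold_per_l=5e8)
            labels.append(classify_pattern(traj.t, traj.vaf(1), 0.05))
            times.append(engraftment_time(traj))
        assert len(set(labels)) == 1
        assert times[0] > times[-1]


class TestDonorCourse:
    def test_neutral_clone_donor_vaf_constant(self, model):
        traj = donor_course(model, CloneSpec(), donor_vaf=0.06)
        v = traj.vaf(1)
        assert np.max(np.abs(v - 0.06)) < 1e-8

    def test_persistent_clone_donor_expands_before_donation(self, model):
        clone = CloneSpec(mult_selfrenewal_hsc=1.1, mult_prolif_hsc=1.5)
        traj = donor_course(model, clone, donor_vaf=0.04)
        v = traj.vaf(1)
        assert v[-1] > 0.04
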