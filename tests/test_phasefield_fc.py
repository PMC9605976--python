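import numpy as np
import pytest

from eggchamber import phasefield_fc as pf
from eggchamber.affinity_schedules import ConstantSchedule, ScenarioSpec


SMALL = dict(nx=96, ny=48)


def constant_scenario(levels_eya):
    """FC scenario with per-cell constant Eya levels."""
    scheds = {i + 1: ConstantSchedule(v) for i, v in enumerate(levels_eya)}
    return ScenarioSpec(model="fc", name="const", schedules=scheds)


def small_state(n=3, **over):
    params = pf.FCParams(**{**SMALL, **over})
    return pf.init_fc(n, affine_fraction=1.0, params=params)


class TestInit:
    def test_reinit_bitwise_identical(self):
        a = pf.init_fc(14, seed=3)
        b = pf.init_fc(14, seed=3)
        assert np.array_equal(a.phi, b.phi)

    def test_small_patch_uses_periodic_ring(self):
        st = small_state(3)
        assert st.boundary == "periodic"
        aff, _ = st.contact_lengths()
        assert np.allclose(aff, aff[0], rtol=0.02)  # congruent cells

    def test_chamber_uses_mirror_with_half_end_cells(self):
        st = pf.init_fc(14)
        assert st.boundary == "mirror"
        aff, non = st.contact_lengths()
        total = aff + non
        assert total[0] == pytest.approx(total[1] / 2, rel=0.1)
        assert total[-1] == pytest.approx(total[1] / 2, rel=0.15)

    def test_domain_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            pf.init_fc(14, domain=(40, 32))

    def test_bad_affine_fraction_rejected(self):
        with pytest.raises(ValueError):
            pf.init_fc(3, affine_fraction=0.0)


class TestEnergy:
    def test_empty_fields_energy_terms(self):
        st = small_state(3)
        st.phi = np.zeros_like(st.phi)
        e = pf.energy(st, np.array([1.0, 1.0, 1.0]))
        assert e["interfacial"] == 0.0
        assert e["overlap"] == 0.0
        assert e["contact"] == 0.0
        p = st.params
        assert e["volume"] == pytest.approx(
            p.lambda_v * np.sum(st.target_volumes**2)
        )

    def test_contact_term_linear_in_affinity(self):
        st = small_state(3)
        a = np.array([0.5, 1.0, 0.2])
        e1 = pf.energy(st, a)["contact"]
        e2 = pf.energy(st, 2 * a)["contact"]
        base = pf.energy(st, 0 * a)["contact"]
        assert e2 - base == pytest.approx(2 * (e1 - base), rel=1e-10)

    def test_contact_term_rewards_boundary_occupancy(self):
        st = small_state(3)
        lifted = st.phi.copy()
        lifted[:] = np.roll(lifted, 5, axis=1)  # shift cells off the boundary
        lifted[:, :5, :] = 0.0
        e_on = pf.energy(st, np.ones(3))["contact"]
        st_off = pf.init_fc(3, affine_fraction=1.0, params=st.params)
        st_off.phi = lifted
        e_off = pf.energy(st_off, np.ones(3))["contact"]
        assert e_on < e_off  # boundary contact lowers the energy


class TestThreeCellBehaviour:
    def test_equal_low_affinities_equal_contacts(self):
        # low and equal affinities: an even distribution with equal
        # germline-contacting surfaces
        st = small_state(3)
        traj = pf.evolve_fc(st, constant_scenario([45, 45, 45]), t_end=8.0,
                            dt=0.1)
        aff = traj.contact_affine[-1]
        assert np.ptp(aff) / aff.mean() < 0.05

    def test_raised_central_affinity_expands_centre(self):
        st = small_state(3)
        traj = pf.evolve_fc(st, constant_scenario([60, 140, 60]), t_end=8.0)
        aff = traj.contact_affine[-1]
        assert aff[1] > aff[0] and aff[1] > aff[2]

    def test_graded_affinities_order_contacts(self):
        st = small_state(3)
        traj = pf.evolve_fc(st, constant_scenario([150, 110, 70]), t_end=8.0)
        aff = traj.contact_affine[-1]
        assert aff[0] > aff[1] > aff[2]

    def test_contact_monotone_in_own_affinity(self):
        finals = []
        for mid in (80.0, 110.0, 140.0):
            st = small_state(3)
            traj = pf.evolve_fc(st, constant_scenario([100, mid, 100]),
                                t_end=8.0)
            finals.append(traj.contact_affine[-1][1])
        assert finals[0] <= finals[1] + 0.5 <= finals[2] + 1.0

    def test_label_permutation_symmetry(self):
        st = small_state(3)
        t1 = pf.evolve_fc(st, constant_scenario([110, 70, 70]), t_end=4.0,
                          dt=0.1)
        st2 = small_state(3)
        t2 = pf.evolve_fc(st2, constant_scenario([70, 110, 70]), t_end=4.0,
                          dt=0.1)
        # periodic ring: raising cell 2 instead of cell 1 cyclically shifts
        # the outcome
        a1 = t1.contact_affine[-1]
        a2 = t2.contact_affine[-1]
        assert np.allclose(np.roll(a1, 1), a2, rtol=0.10, atol=1.0)


class TestSolverGuarantees:
    def test_energy_nonincreasing_under_frozen_affinities(self):
        st = small_state(3)
        # completes without SolverError: every checked step decreases energy
        # (stable step size, constant affinities)
        pf.evolve_fc(st, constant_scenario([50, 50, 50]), t_end=2.0, dt=0.08,
                     energy_check_every=50)

    def test_volume_conserved_in_calm_regime(self):
        st = small_state(3)
        traj = pf.evolve_fc(st, constant_scenario([60, 50, 40]), t_end=8.0,
                            dt=0.1)
        drift = np.abs(traj.volumes / st.target_volumes - 1.0)
        assert drift.max() < 0.02

    def test_unstable_dt_rejected(self):
        st = small_state(3)
        with pytest.raises(pf.SolverError, match="unstable"):
            pf.evolve_fc(st, constant_scenario([100, 100, 100]), t_end=1.0,
                         dt=5.0)

    def test_missing_schedules_rejected(self):
        st = small_state(3)
        with pytest.raises(ValueError, match="lacks schedules"):
            pf.evolve_fc(st, constant_scenario([100.0]), t_end=1.0)

    def test_germline_scenario_rejected(self):
        st = small_state(3)
        with pytest.raises(ValueError, match="not an FC-model"):
            pf.evolve_fc(st, "germline_wt", t_end=1.0)


class TestChamberScaleRuns:
    def test_wt_posterior_cells_stay_over_oocyte(self, fc_scenario_runs):
        _, ro = fc_scenario_runs["wt"]
        assert set(ro.on_nonaffine_final) == {9, 10, 11, 12, 13, 14}

    def test_wt_apical_gradient_appears_mid_development(self, fc_scenario_runs):
        traj, ro = fc_scenario_runs["wt"]
        ext = ro.apical_extent_sq
        # by stage-8 times the anterior rows exceed the posterior AFC rows
        mid = ext[(ext.t_h > 16) & (ext.t_h < 22)]
        by_cell = mid.groupby("cell")["extent_sq"].mean()
        assert by_cell.loc[1:3].mean() > by_cell.loc[9:14].mean()

    def test_rows6to8_never_on_oocyte_compartment(self, fc_scenario_runs):
        traj, ro = fc_scenario_runs["rows6to8_ectopic"]
        thresh = traj.state.params.detach_rel * 4.0 * np.sqrt(
            traj.state.target_volumes
        )
        for cell in (6, 7, 8):
            assert np.all(
                traj.contact_nonaffine[:, cell - 1] < thresh[cell - 1]
            )
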