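"""Starting-parameter sampling, integration, convergence detection,
freeze verification and the elevated-potassium perturbation."""

import math

import numpy as np
import pytest

from homeoburst import engine as eng
from homeoburst.channels import MembraneParams, MembraneState
from homeoburst.regulation import RegulationConfig
from homeoburst.sensors import SensorConfig, SensorState


class TestSampling:
    def test_determinism(self):
        a = eng.sample_starting_parameters(np.random.default_rng(42))
        b = eng.sample_starting_parameters(np.random.default_rng(42))
        np.testing.assert_array_equal(a[2].gbar, b[2].gbar)
        np.testing.assert_array_equal(a[0].m, b[0].m)

    def test_distribution_ranges(self):
        rng = np.random.default_rng(0)
        g = np.array([eng.sample_starting_parameters(rng)[2].gbar for _ in range(2000)])
        assert g.min() >= 0.3e-3 and g.max() <= 0.9e-3  # nS range, in uS
        s = np.array([eng.sample_starting_parameters(rng)[2].shift_m for _ in range(2000)])
        assert s.min() >= -0.5 and s.max() <= 0.5
        # mean shift ~ 0 within 3 standard errors of U(-0.5, 0.5)
        se = (1.0 / math.sqrt(12)) / math.sqrt(s.size)
        assert abs(s.mean()) < 3 * se

    def test_fixed_initial_values(self):
        mem, sens, _ = eng.sample_starting_parameters(np.random.default_rng(7))
        assert mem.v == -50.0
        assert mem.ca == 0.4
        assert np.all((mem.m >= 0.2) & (mem.m <= 0.3))
        assert sens.e_f == sens.e_s == sens.e_d == sens.alpha == 1.0
        assert (sens.m_f, sens.h_f) == (1.0, 0.0)


class TestRunSimulation:
    def test_state_vector_has_forty_components(self):
        rng = np.random.default_rng(0)
        mem, sens, params = eng.sample_starting_parameters(rng)
        y = eng.pack_state(mem, sens, params)
        assert y.shape == (40,)
        m2, s2, p2 = eng.unpack_state(y, params)
        np.testing.assert_array_equal(eng.pack_state(m2, s2, p2), y)

    def test_leak_only_relaxes_to_leak_reversal(self):
        params = MembraneParams(gbar=np.zeros(7), shift_m=np.zeros(7), shift_h=np.zeros(4))
        mem = MembraneState(v=-30.0, m=np.full(7, 0.3), h=np.full(4, 0.5), ca=0.4)
        y0 = eng.pack_state(mem, SensorState(), params)
        traj = eng.run_simulation(y0, params, SensorConfig(),
                                  RegulationConfig(math.inf, math.inf), 2000.0)
        assert traj.v[-1] == pytest.approx(params.e_leak, abs=0.01)

    def test_save_grid_is_half_millisecond(self):
        params = MembraneParams(gbar=np.zeros(7), shift_m=np.zeros(7), shift_h=np.zeros(4))
        mem = MembraneState(v=-50.0, m=np.full(7, 0.3), h=np.full(4, 0.5), ca=0.4)
        y0 = eng.pack_state(mem, SensorState(), params)
        traj = eng.run_simulation(y0, params, SensorConfig(),
                                  RegulationConfig(math.inf, math.inf), 100.0)
        np.testing.assert_allclose(np.diff(traj.t_ms), 0.5, atol=1e-12)
        assert traj.t_ms[0] == 0.0

    def test_tolerance_refinement_changes_little(self, reference_params):
        """Halving rtol moves the 10-s endpoint of a bursting run by a
        bounded amount (adaptive-solver consistency)."""
        mem = MembraneState(v=-50.0, m=np.full(7, 0.05), h=np.full(4, 0.9), ca=0.4)
        y0 = eng.pack_state(mem, SensorState(), reference_params)
        frozen = RegulationConfig(math.inf, math.inf)
        va = {}
        for rtol in (1e-4, 5e-5):
            traj = eng.run_simulation(y0, reference_params, SensorConfig(), frozen,
                                      10_000.0, eng.SimulationConfig(rtol=rtol))
            va[rtol] = traj.ca[-1]
        # chaotic spike timing prevents pointwise V agreement; calcium at the
        # trajectory end is a smoother functional of the solution
        assert va[1e-4] == pytest.approx(va[5e-5], rel=0.5)

    def test_nonfinite_initial_state_rejected(self, reference_params):
        y0 = np.full(40, np.nan)
        with pytest.raises(ValueError):
            eng.run_simulation(y0, reference_params, SensorConfig(),
                               RegulationConfig(), 10.0)


class TestFrozenRegulation:
    def test_regulated_parameters_bit_constant(self, reference_params):
        """With both mechanisms frozen the 18 regulated parameters are
        bit-identical across 20 s of bursting."""
        mem = MembraneState(v=-50.0, m=np.full(7, 0.05), h=np.full(4, 0.9), ca=0.4)
        y0 = eng.pack_state(mem, SensorState(), reference_params)
        traj = eng.run_simulation(y0, reference_params, SensorConfig(),
                                  RegulationConfig(math.inf, math.inf), 20_000.0)
        np.testing.assert_array_equal(traj.final_state[22:], y0[22:])
        for snap in traj.snapshots:
            np.testing.assert_array_equal(snap[22:], y0[22:])

    def test_half_only_frozen(self, reference_params):
        """tau_half = inf freezes shifts while conductances may still move."""
        mem = MembraneState(v=-50.0, m=np.full(7, 0.05), h=np.full(4, 0.9), ca=0.4)
        y0 = eng.pack_state(mem, SensorState(), reference_params)
        traj = eng.run_simulation(y0, reference_params, SensorConfig(),
                                  RegulationConfig(tau_g_s=60.0, tau_half_s=math.inf,
                                                   gamma=1e-6),
                                  20_000.0)
        np.testing.assert_array_equal(traj.final_state[29:40], y0[29:40])


class TestFreezeVerification:
    def _params(self, y):
        return MembraneParams(gbar=y[22:29], shift_m=y[29:36], shift_h=y[36:40])

    def test_assembled_burster_passes(self, assembled_state):
        """A self-assembled, target-satisfying burster holds smoothed alpha
        below threshold with both mechanisms frozen."""
        ok = eng.verify_frozen(assembled_state, self._params(assembled_state),
                               SensorConfig(), duration_s=30.0)
        assert ok

    def test_unsatisfied_state_fails(self, assembled_state):
        """Starting the frozen check with alpha pinned high reports failure."""
        y = assembled_state.copy()
        y[21] = 1.0  # activity sensor far from satisfied
        ok = eng.verify_frozen(y, self._params(y), SensorConfig(), duration_s=12.0)
        assert not ok


class TestConvergenceDetection:
    def test_all_zero_alpha_converges(self):
        alpha = np.zeros(int(15 * 60_000 / 0.5))
        ok, t = eng.detect_convergence(alpha, sustain_min=10.0)
        assert ok and t == 0.0

    def test_all_one_alpha_does_not_converge(self):
        alpha = np.ones(int(15 * 60_000 / 0.5))
        ok, _ = eng.detect_convergence(alpha, sustain_min=10.0)
        assert not ok

    def test_final_crossing_and_filter_lag(self):
        """alpha = 0.5 for 20 min then 0.01 for 15 min: converged, with the
        crossing just after the 20-min mark (trailing-mean lag < 8 s)."""
        n1, n2 = int(20 * 60_000 / 0.5), int(15 * 60_000 / 0.5)
        alpha = np.concatenate([np.full(n1, 0.5), np.full(n2, 0.01)])
        ok, t = eng.detect_convergence(alpha, sustain_min=10.0)
        assert ok
        assert 20.0 <= t <= 20.0 + 8.0 / 60.0 + 1e-6

    def test_brief_dip_does_not_count(self):
        n = int(5 * 60_000 / 0.5)
        alpha = np.concatenate([np.full(n, 0.5), np.full(n, 0.01), np.full(n, 0.5)])
        ok, _ = eng.detect_convergence(alpha, sustain_min=2.0)
        assert not ok

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            eng.smoothed_alpha(np.array([]), 0.5)


class TestPerturbation:
    def test_leak_reversal_worked_value(self):
        # potassium fraction 8/11 gives -350/11 mV
        v = eng.perturbed_leak_reversal(-50.0, -80.0, 30.0, -55.0)
        assert v == pytest.approx(-350.0 / 11.0, rel=1e-12)
        assert round(v) == -32

    def test_identity_when_ek_unchanged(self):
        assert eng.perturbed_leak_reversal(-50.0, -80.0, 30.0, -80.0) == pytest.approx(-50.0)

    def test_pure_potassium_leak(self):
        v = eng.perturbed_leak_reversal(-80.0 + 1e-9, -80.0, 30.0, -55.0)
        assert v == pytest.approx(-55.0, abs=1e-6)

    def test_out_of_range_leak_rejected(self):
        with pytest.raises(ValueError):
            eng.perturbed_leak_reversal(-90.0, -80.0, 30.0, -55.0)

    def test_apply_perturbation_protocol(self, reference_params):
        p2, s2 = eng.apply_potassium_perturbation(reference_params, SensorConfig())
        assert p2.e_k == -55.0
        assert p2.e_leak == pytest.approx(-350.0 / 11.0)
        assert s2.delta_d == 0.035
        # everything else untouched
        assert p2.e_na == reference_params.e_na
        assert p2.e_h == reference_params.e_h
        np.testing.assert_array_equal(p2.gbar, reference_params.gbar)
        assert s2.target_d == SensorConfig().target_d

    def test_restore_is_identity(self, reference_params):
        p2, _ = eng.apply_potassium_perturbation(reference_params, SensorConfig())
        p3 = eng.apply_potassium_perturbation(
            p2, SensorConfig(), e_k_new=reference_params.e_k
        )[0]
        # restoring E_K recomputes the same leak reversal back
        assert p3.e_k == reference_params.e_k
        assert p3.e_leak == pytest.approx(reference_params.e_leak)

    def test_perturbation_depolarizes_and_abolishes_bursting(self, reference_params,
                                                             reference_trajectory):
        """Elevated potassium with frozen regulation leaves the reference
        burster depolarized: the deep interburst hyperpolarizations vanish
        and the mean potential rises far above the unperturbed one."""
        p2, s2 = eng.apply_potassium_perturbation(reference_params, SensorConfig())
        traj = eng.run_simulation(
            reference_trajectory.final_state, p2, s2,
            RegulationConfig(math.inf, math.inf), 30_000.0,
        )
        tail = traj.v[-20_000:]
        base = reference_trajectory.v[-20_000:]
        assert tail.min() > -55.0  # no hyperpolarized interburst phase left
        assert tail.mean() > base.mean() + 5.0
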