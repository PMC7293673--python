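from dataclasses import replace

import numpy as np
import pytest

from photofenton.experiments import get_experiment
from photofenton.kinetics import DEFAULT_CORE, CoreRateConstants, TARGET_CONSTANTS
from photofenton.reactor import (
    ExperimentSpec,
    FeedSchedule,
    PlantSpec,
    CompartmentSpec,
    default_plant,
    simulate,
    step,
)

ZERO_CORE = CoreRateConstants(k0=0.0, k1=0.0, k2=0.0, k_elim=0.0)


def _short(exp_id, minutes, **overrides):
    return replace(get_experiment(exp_id), duration_min=minutes, **overrides)


class TestPlantSpec:
    def test_default_plant_geometry(self):
        plant = default_plant(irradiated=True)
        assert plant.volumes.tolist() == [9.00, 2.25, 1.50, 2.25]
        assert plant.total_volume == pytest.approx(15.0)
        assert plant.recirculation_flow == 12.0
        assert plant.irradiated_mask.tolist() == [False, False, True, False]

    def test_dark_plant_has_no_irradiated_compartment(self):
        assert not default_plant(irradiated=False).irradiated_mask.any()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CompartmentSpec(volume=0.0)
        with pytest.raises(ValueError):
            PlantSpec(compartments=default_plant(False).compartments,
                      recirculation_flow=0.0)
        with pytest.raises(ValueError):
            FeedSchedule(total_h2o2_mmol=10.0, duration_s=0.0)

    def test_irradiation_flag_must_match_plant(self):
        exp = get_experiment("EXP13_PCT")  # irradiated
        with pytest.raises(ValueError):
            simulate(exp, plant=default_plant(irradiated=False))


class TestAdvection:
    def test_pure_advection_conserves_moles(self):
        plant = default_plant(False)
        states = np.zeros((4, 6))
        states[:, 2] = [3.0e-3, 1.0e-3, 0.0, 0.5e-3]  # unequal tracer
        total0 = states[:, 2] @ plant.volumes
        y = states
        for _ in range(50):
            y = step(y, plant, ZERO_CORE, None, None, dt=0.5)
        assert y[:, 2] @ plant.volumes == pytest.approx(total0, rel=1e-12)

    def test_tracer_equilibrates_to_volume_ratio(self):
        """1 mmol/L in the 9-L tank dilutes to 9/15 = 0.6 mmol/L."""
        plant = default_plant(False)
        y = np.zeros((4, 6))
        y[0, 2] = 1.0e-3
        for _ in range(3600):  # 30 min at dt = 0.5 s
            y = step(y, plant, ZERO_CORE, None, None, dt=0.5)
        assert y[:, 2] * 1e3 == pytest.approx(np.full(4, 0.6), abs=1e-6)

    def test_step_rejects_excessive_courant_number(self):
        plant = default_plant(False)
        with pytest.raises(ValueError):
            step(np.zeros((4, 6)), plant, ZERO_CORE, None, None, dt=600.0)


class TestKernelAgainstReferenceStep:
    def test_kernel_matches_python_step(self, warm_kernel):
        """The compiled integrator and the pure-Python reference step
        built from the kinetics functions produce identical states."""
        exp = _short("EXP4_PCT", 60.0 / 60.0)  # 1 min
        dt, nsteps = 0.5, 120
        traj = simulate(exp, dt=dt, record_interval_s=dt,
                        feed_duration_s=30.0, auto_halve_dt=False)
        plant = traj.plant
        from photofenton.mechanism import build_mechanism
        from photofenton.compounds import get_compound

        mech = build_mechanism(get_compound("PCT"))
        kt = TARGET_CONSTANTS["PCT"]
        y = np.zeros((4, 10))
        y[:, 0] = exp.fe2_0 * 1e-3
        y[:, 5] = exp.target0 * 1e-3
        feed_rate = exp.h2o2_0 * plant.total_volume * 1e-3 / 30.0 / 9.00
        feed_steps = int(round(30.0 / dt))
        for n in range(nsteps):
            y = step(y, plant, DEFAULT_CORE, mech, kt, dt,
                     feed_rate=feed_rate if n < feed_steps else 0.0)
        np.testing.assert_allclose(y, traj.states[-1], rtol=1e-9, atol=1e-18)


class TestSimulation:
    def test_all_zero_experiment_stays_zero(self, warm_kernel):
        exp = ExperimentSpec(id="NULL", compound=None, duration_min=2.0)
        traj = simulate(exp, dt=0.5)
        assert not traj.states.any()

    def test_zero_kinetics_constant_after_feed(self, warm_kernel):
        exp = _short("BLANK_3", 5.0)
        traj = simulate(exp, core=ZERO_CORE, dt=0.5, feed_duration_s=30.0)
        h2o2_total = traj.total_moles(2) * 1e3  # mmol
        # After the feed window the plant holds the full dose, unchanged.
        after = h2o2_total[traj.times_min > 1.0]
        assert after == pytest.approx(11.12 * 15.0, rel=1e-9)

    def test_h2o2_total_nonincreasing_after_feed(self, warm_kernel):
        exp = _short("BLANK_3", 10.0)
        traj = simulate(exp, dt=0.25)
        totals = traj.total_moles(2)
        mask = traj.times_s > 30.0
        assert np.all(np.diff(totals[mask]) <= 1e-15)

    def test_blank_dark_h2o2_monotone_and_in_range(self, warm_kernel):
        """Dark reagent blank: the oxidant decays monotonically and the
        10-min consumption lands in the tens of percent."""
        exp = _short("BLANK_3", 12.0)
        traj = simulate(exp, dt=0.25)
        h = traj.series("H2O2").values
        assert np.all(np.diff(h[traj.times_s > 30.0]) <= 1e-12)
        cons10 = 1.0 - traj.sample("H2O2", [10.0])[0] / 11.12
        assert 0.3 < cons10 < 0.8

    def test_iron_conserved_along_trajectory(self, warm_kernel):
        exp = _short("EXP4_PCT", 10.0)
        traj = simulate(exp, dt=0.25)
        fe_total = traj.total_moles(0) + traj.total_moles(1)
        assert fe_total == pytest.approx(fe_total[0], rel=1e-9)

    def test_halving_dt_changes_little(self, warm_kernel):
        """Trajectories at dt and dt/2 agree within 0.5% over 10 min."""
        exp = _short("EXP13_PCT", 10.0)
        t_obs = [2.0, 5.0, 10.0]
        a = simulate(exp, dt=0.05)
        b = simulate(exp, dt=0.025)
        for kind, scale in [("target", 0.26), ("TOC", 2.08), ("H2O2", 5.56)]:
            va = a.sample(kind, t_obs) / scale
            vb = b.sample(kind, t_obs) / scale
            assert np.max(np.abs(va - vb)) < 0.005

    def test_trajectory_accessors(self, warm_kernel):
        exp = _short("EXP4_PCT", 5.0)
        traj = simulate(exp, dt=0.5)
        assert traj.conversion("target", 5.0) > 0
        s = traj.series("TOC")
        assert s.values[0] == pytest.approx(0.26 * 8, rel=1e-6)
        assert traj.fragment_concentration(1, 5.0) >= 0
        with pytest.raises(ValueError):
            traj.fragment_concentration(7)
        va = traj.volume_average("H2O2")
        assert va.shape == traj.times_min.shape

    def test_blank_trajectory_has_no_target_series(self, warm_kernel):
        traj = simulate(_short("BLANK_3", 2.0), dt=0.5)
        with pytest.raises(ValueError):
            traj.series("target")
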