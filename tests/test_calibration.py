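from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from photofenton.calibration import (
    CoreKineticsModel,
    DegenerateDataError,
    IdentifiabilityError,
    SAMPLING_GRIDS,
    TargetKineticsModel,
    generate_synthetic,
)
from photofenton.experiments import get_experiment
from photofenton.kinetics import DEFAULT_CORE, TARGET_CONSTANTS
from photofenton.reactor import simulate

DT = 0.25  # calibration runs many simulations; coarser step, same scheme


@pytest.fixture(scope="module")
def blank_dataset(warm_kernel):
    return generate_synthetic(
        ["BLANK_3", "BLANK_4"], noise_sigma=0.0, seed=7, dt=DT
    )


@pytest.fixture(scope="module")
def pct_dataset(warm_kernel):
    return generate_synthetic(
        ["EXP4_PCT", "EXP13_PCT"], noise_sigma=0.0, seed=7, dt=DT
    )


class TestSyntheticGenerator:
    def test_zero_noise_equals_simulation_at_grid(self, warm_kernel):
        ds = generate_synthetic(["EXP4_PCT"], noise_sigma=0.0, seed=3, dt=DT)
        traj = simulate(get_experiment("EXP4_PCT"), dt=DT)
        sub = ds.series("EXP4_PCT", "target")
        np.testing.assert_allclose(
            sub["value"].to_numpy(),
            traj.sample("target", sub["time_min"].to_numpy()),
            rtol=1e-12,
        )

    def test_same_seed_reproduces_dataset(self, warm_kernel):
        a = generate_synthetic(["BLANK_3"], noise_sigma=0.05, seed=11, dt=DT)
        b = generate_synthetic(["BLANK_3"], noise_sigma=0.05, seed=11, dt=DT)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_different_seed_differs(self, warm_kernel):
        a = generate_synthetic(["BLANK_3"], noise_sigma=0.05, seed=11, dt=DT)
        b = generate_synthetic(["BLANK_3"], noise_sigma=0.05, seed=12, dt=DT)
        assert not np.allclose(a.data["value"], b.data["value"])

    def test_noise_level_matches_sigma(self, warm_kernel):
        """Pooled relative deviations have std close to the nominal 5%."""
        ids = ["EXP4_PCT", "EXP13_PCT", "EXP5_PCT", "EXP14_PCT"]
        noisy = generate_synthetic(ids, noise_sigma=0.05, seed=5, dt=DT,
                                   detection_limit=0.0)
        clean = generate_synthetic(ids, noise_sigma=0.0, seed=5, dt=DT,
                                   detection_limit=0.0)
        merged = noisy.data.merge(
            clean.data, on=["experiment_id", "time_min", "kind"],
            suffixes=("_noisy", "_clean"),
        )
        merged = merged[merged["value_clean"] > 1e-6]
        rel = merged["value_noisy"] / merged["value_clean"] - 1.0
        assert len(rel) >= 100
        assert 0.04 < rel.std() < 0.06

    def test_sampling_grids_follow_assay_protocol(self, warm_kernel):
        ds = generate_synthetic(["EXP4_PCT"], noise_sigma=0.0, seed=0, dt=DT)
        toc_times = ds.series("EXP4_PCT", "TOC")["time_min"].tolist()
        assert toc_times == [float(t) for t in range(0, 121, 15)]
        h_times = ds.series("EXP4_PCT", "H2O2")["time_min"].tolist()
        assert h_times[:7] == [0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0]
        assert h_times[7:] == [45.0, 60.0, 75.0, 90.0, 105.0, 120.0]

    def test_formic_acid_has_no_target_series(self, warm_kernel):
        ds = generate_synthetic(["EXP2_FA"], noise_sigma=0.0, seed=0, dt=DT)
        assert "target" not in set(ds.data["kind"])
        assert {"TOC", "H2O2"} <= set(ds.data["kind"])

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic(["BLANK_3"], noise_sigma=-0.1, seed=0)


class TestCoreStage:
    def test_zero_noise_round_trip(self, blank_dataset):
        res = CoreKineticsModel(blank_dataset.data, dt=DT).fit()
        for name in ("k0", "k1", "k2", "k_elim"):
            est = getattr(res.params, name)
            truth = getattr(DEFAULT_CORE, name)
            assert abs(est - truth) / truth < 0.01

    def test_requires_blank_assays(self, pct_dataset):
        with pytest.raises(ValueError, match="blank"):
            CoreKineticsModel(pct_dataset.data, dt=DT)

    def test_dark_only_with_free_k0_is_unidentifiable(self, warm_kernel):
        ds = generate_synthetic(["BLANK_3"], noise_sigma=0.0, seed=2, dt=DT)
        with pytest.raises(IdentifiabilityError):
            CoreKineticsModel(ds.data, dt=DT)

    def test_dark_only_with_fixed_k0_is_allowed(self, warm_kernel):
        ds = generate_synthetic(["BLANK_3"], noise_sigma=0.0, seed=2, dt=DT)
        model = CoreKineticsModel(ds.data, dt=DT, fixed={"k0": DEFAULT_CORE.k0})
        res = model.fit()
        assert res.params.k0 == DEFAULT_CORE.k0
        assert abs(res.params.k1 - DEFAULT_CORE.k1) / DEFAULT_CORE.k1 < 0.01

    def test_blank_h2o2_is_invariant_to_k_elim(self, warm_kernel):
        """The radical sink feeds nothing back, so blank oxidant series
        cannot carry information about the elimination constant."""
        spec = replace(get_experiment("BLANK_4"), duration_min=20.0)
        lo = simulate(spec, core=DEFAULT_CORE.replace(k_elim=7.5e-3), dt=DT)
        hi = simulate(spec, core=DEFAULT_CORE.replace(k_elim=7.5e-1), dt=DT)
        np.testing.assert_allclose(
            lo.series("H2O2").values, hi.series("H2O2").values, rtol=1e-10
        )

    def test_fit_reproducible_for_same_seed(self, blank_dataset):
        m = CoreKineticsModel(blank_dataset.data, dt=DT)
        a = m.fit(n_starts=2, seed=5)
        b = CoreKineticsModel(blank_dataset.data, dt=DT).fit(n_starts=2, seed=5)
        assert a.params == b.params and a.cost == b.cost

    def test_multistart_never_increases_cost(self, blank_dataset):
        res = CoreKineticsModel(blank_dataset.data, dt=DT).fit(n_starts=3, seed=1)
        for start in res.starts:
            assert start["cost"] <= start["cost0"] + 1e-12

    def test_summary_mentions_all_parameters(self, blank_dataset):
        res = CoreKineticsModel(blank_dataset.data, dt=DT).fit()
        text = res.summary()
        for name in ("k0", "k1", "k2", "k_elim"):
            assert name in text


class TestTargetStage:
    def test_zero_noise_round_trip(self, pct_dataset):
        model = TargetKineticsModel("PCT", pct_dataset.data, core=DEFAULT_CORE, dt=DT)
        res = model.fit()
        truth = TARGET_CONSTANTS["PCT"]
        assert abs(res.params.k_target - truth.k_target) / truth.k_target < 0.01
        assert (
            abs(res.params.k_fragment - truth.k_fragment) / truth.k_fragment < 0.01
        )

    def test_reference_constants_ratio(self):
        kt = TARGET_CONSTANTS["PCT"]
        assert kt.k_target / kt.k_fragment == pytest.approx(10.0)

    def test_rejects_foreign_experiments(self, pct_dataset):
        with pytest.raises(ValueError):
            TargetKineticsModel(
                "SQX", pct_dataset.data, core=DEFAULT_CORE,
                experiments=["EXP4_PCT"], dt=DT,
            )

    def test_all_zero_series_is_degenerate(self):
        data = pd.DataFrame(
            {
                "experiment_id": ["EXP4_PCT"] * 3,
                "time_min": [0.0, 15.0, 30.0],
                "kind": ["TOC"] * 3,
                "value": [0.0, 0.0, 0.0],
            }
        )
        with pytest.raises(DegenerateDataError):
            TargetKineticsModel("PCT", data, core=DEFAULT_CORE, dt=DT)

    def test_weights_must_be_positive(self, pct_dataset):
        with pytest.raises(ValueError):
            TargetKineticsModel(
                "PCT", pct_dataset.data, core=DEFAULT_CORE,
                weights={"TOC": -1.0}, dt=DT,
            )

    def test_default_weights_encode_priority(self, pct_dataset):
        model = TargetKineticsModel("PCT", pct_dataset.data, core=DEFAULT_CORE, dt=DT)
        w = model.weights
        assert w["TOC"] > w["target"] > w["H2O2"]

    def test_results_simulate_uses_fitted_constants(self, pct_dataset):
        model = TargetKineticsModel("PCT", pct_dataset.data, core=DEFAULT_CORE, dt=DT)
        res = model.fit()
        traj = res.simulate("EXP4_PCT", dt=DT)
        assert traj.conversion("TOC", 30.0) > 0
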