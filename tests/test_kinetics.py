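import numpy as np
import pytest
from hypothesis import given, strategies as st

from photofenton.compounds import get_compound
from photofenton.kinetics import (
    DEFAULT_CORE,
    TARGET_CONSTANTS,
    CoreRateConstants,
    RateSet,
    SpeciesState,
    assemble_derivatives,
    competing_rates,
    core_rates,
    normalize_competition,
)
from photofenton.mechanism import build_mechanism

PCT_MECH = build_mechanism(get_compound("PCT"))


def _pct_state(**kw):
    defaults = dict(
        fe2=1e-4, fe3=5e-5, h2o2=5e-3, ho=1e-6,
        organics=np.array([2.6e-4, 1e-5, 1e-5, 1e-5]),
    )
    defaults.update(kw)
    return SpeciesState(**defaults)


class TestCoreRates:
    def test_all_zero_state_gives_zero_rates(self):
        st0 = SpeciesState(organics=np.zeros(4))
        rs = core_rates(st0, DEFAULT_CORE, irradiated=True)
        assert rs.r0 == rs.r1 == rs.r2 == 0.0

    def test_fenton_rate_value(self):
        # r2 = k2 [Fe2+] [H2O2] evaluated directly.
        st0 = SpeciesState(fe2=1.8e-4, h2o2=1.112e-2)
        rs = core_rates(st0, DEFAULT_CORE, irradiated=False)
        assert rs.r2 == pytest.approx(1.261e-4, rel=1e-3)

    def test_photo_rate_requires_irradiation(self):
        st0 = SpeciesState(fe3=1e-4, h2o2=1e-3)
        assert core_rates(st0, DEFAULT_CORE, irradiated=False).r0 == 0.0
        assert core_rates(st0, DEFAULT_CORE, irradiated=True).r0 == pytest.approx(
            DEFAULT_CORE.k0 * 1e-4
        )

    def test_negative_constants_rejected(self):
        with pytest.raises(ValueError):
            CoreRateConstants(k0=-1.0, k1=1.0, k2=1.0, k_elim=1.0)


class TestCompetingRates:
    def test_no_radicals_no_competition(self):
        st0 = _pct_state(ho=0.0)
        r_elim, r_b = competing_rates(
            st0, PCT_MECH, TARGET_CONSTANTS["PCT"], DEFAULT_CORE.k_elim
        )
        assert r_elim == 0.0 and not r_b.any()

    def test_elimination_rate_value(self):
        st0 = _pct_state(ho=1e-6)
        r_elim, _ = competing_rates(st0, None, None, 7.5e-2)
        assert r_elim == pytest.approx(7.5e-8)

    def test_target_breakage_rate_value(self):
        st0 = _pct_state(ho=1e-6, organics=np.array([2.6e-4, 0, 0, 0]))
        _, r_b = competing_rates(
            st0, PCT_MECH, TARGET_CONSTANTS["PCT"], DEFAULT_CORE.k_elim
        )
        assert r_b[0] == pytest.approx(3.9e-7)

    def test_dimension_mismatch_rejected(self):
        st0 = SpeciesState(ho=1e-6, organics=np.array([1e-4, 1e-4]))
        with pytest.raises(ValueError):
            competing_rates(st0, PCT_MECH, TARGET_CONSTANTS["PCT"], 0.075)


class TestNormalization:
    def test_single_competitor_unchanged(self):
        r_elim, r_b = normalize_competition(3.0, np.zeros(0))
        assert r_elim == pytest.approx(3.0)

    def test_two_equal_competitors_halve(self):
        r_elim, r_b = normalize_competition(2.0, np.array([2.0]))
        assert r_elim == pytest.approx(1.0)
        assert r_b[0] == pytest.approx(1.0)

    def test_all_zero_is_safe(self):
        r_elim, r_b = normalize_competition(0.0, np.zeros(3))
        assert r_elim == 0.0 and not r_b.any()

    def test_proportional_mode_keeps_raw_rates(self):
        r_elim, r_b = normalize_competition(
            2.0, np.array([2.0]), mode="proportional"
        )
        assert (r_elim, r_b[0]) == (2.0, 2.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            normalize_competition(1.0, np.zeros(1), mode="bogus")

    @given(
        rates=st.lists(
            st.floats(0.0, 1e3, allow_nan=False), min_size=1, max_size=6
        )
    )
    def test_normalization_never_increases_any_rate(self, rates):
        r_elim, *r_b = rates
        out_elim, out_b = normalize_competition(r_elim, np.array(r_b))
        assert out_elim <= r_elim + 1e-12
        assert np.all(out_b <= np.array(r_b) + 1e-12)


class TestDerivatives:
    def test_zero_rates_zero_derivatives(self):
        d = assemble_derivatives(
            _pct_state(), RateSet(r_b=np.zeros(4), normalized=True), PCT_MECH
        )
        assert d.fe2 == d.fe3 == d.h2o2 == d.ho == d.mineral_c == 0.0
        assert not d.organics.any()

    @given(
        r0=st.floats(0, 1e-3),
        r1=st.floats(0, 1e-3),
        r2=st.floats(0, 1e-3),
        r_elim=st.floats(0, 1e-3),
        rb=st.lists(st.floats(0, 1e-3), min_size=4, max_size=4),
    )
    def test_iron_and_carbon_conservation(self, r0, r1, r2, r_elim, rb):
        """The Fe cycle and the weighted carbon balance both close."""
        rates = RateSet(
            r0=r0, r1=r1, r2=r2, r_elim=r_elim, r_b=np.array(rb), normalized=True
        )
        d = assemble_derivatives(_pct_state(), rates, PCT_MECH)
        assert d.fe2 + d.fe3 == pytest.approx(0.0, abs=1e-15)
        fncs = np.asarray(PCT_MECH.chain.fncs)
        carbon_flux = fncs @ d.organics + d.mineral_c
        assert carbon_flux == pytest.approx(0.0, abs=1e-12)

    def test_single_carbon_chain_conserves_carbon(self):
        mech = build_mechanism(get_compound("FA"))
        rates = RateSet(r_b=np.array([3e-6, 1e-6]), normalized=True)
        st0 = SpeciesState(organics=np.array([8.7e-4, 1e-5]))
        d = assemble_derivatives(st0, rates, mech)
        fncs = np.asarray(mech.chain.fncs)
        assert fncs @ d.organics + d.mineral_c == pytest.approx(0.0, abs=1e-18)

    def test_ph_clamp(self):
        st0 = SpeciesState(ph=2.8)
        assert st0.hp == pytest.approx(1.585e-3, rel=1e-3)
        assert st0.ohn == pytest.approx(1e-14 / 1.585e-3, rel=1e-3)
        assert st0.h2o == 55.5

    def test_blank_state_needs_no_mechanism(self):
        st0 = SpeciesState(fe2=1e-4, h2o2=1e-2, ho=1e-7)
        r_elim, r_b = competing_rates(st0, None, None, 0.075)
        rates = RateSet(r_elim=r_elim, r_b=r_b, normalized=True)
        d = assemble_derivatives(st0, rates, None)
        assert d.organics.size == 0 and d.mineral_c == 0.0
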