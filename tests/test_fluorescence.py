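"""Fluorescence physics chain: yield, collection, detection, occupancy,
photodamage exposure."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import constants

from polarcyte.fluorescence import (
    CollectionGeometry,
    FluorescenceParams,
    collection_fraction,
    detector_voltage,
    exposure_check,
    fluorescence_yield,
    interception_factor,
    occupancy,
    photon_flux_to_watts,
    physics_chain,
)

FOUR_PI = 4 * np.pi


class TestYield:
    def test_unit_factors_give_unit_yield(self):
        p = FluorescenceParams(par=1, chla=1, a_star=1, qa_star=1, phi_f=1)
        assert fluorescence_yield(p) == 1.0

    @pytest.mark.parametrize("zeroed", ["par", "chla", "a_star", "qa_star", "phi_f"])
    def test_any_zero_factor_kills_yield(self, zeroed):
        kwargs = dict(par=100.0, chla=2.0, a_star=0.02, qa_star=0.8, phi_f=0.03)
        kwargs[zeroed] = 0.0
        assert fluorescence_yield(FluorescenceParams(**kwargs)) == 0.0

    @given(scale=st.floats(1.0, 100.0))
    def test_monotone_in_each_factor(self, scale):
        base = dict(par=10.0, chla=1.0, a_star=0.01, qa_star=0.5, phi_f=0.05)
        f0 = fluorescence_yield(FluorescenceParams(**base))
        for key in ("par", "chla", "a_star"):
            bigger = dict(base)
            bigger[key] *= scale
            assert fluorescence_yield(FluorescenceParams(**bigger)) >= f0

    def test_high_light_regime_yield_is_finite_positive(self):
        # PAR at the focused-illumination level with plausible literature-scale
        # pigment parameters; only finiteness/positivity is asserted (the
        # instrument's own end-to-end power depends on unpublished parameters)
        p = FluorescenceParams(par=2.22e10, chla=5.0, a_star=0.02,
                               qa_star=0.6, phi_f=0.03)
        f = fluorescence_yield(p)
        assert np.isfinite(f) and f > 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FluorescenceParams(par=-1, chla=1, a_star=1, qa_star=1, phi_f=1)
        with pytest.raises(ValueError):
            FluorescenceParams(par=1, chla=1, a_star=1, qa_star=1.5, phi_f=1)


class TestCollection:
    @pytest.mark.parametrize("omega, expected", [
        (FOUR_PI, 1.0),
        (2 * np.pi, 0.5),
        (0.014, 0.014 / FOUR_PI),   # the instrument's 0.014 sr → 0.11%
    ])
    def test_fraction_values(self, omega, expected):
        assert collection_fraction(omega) == pytest.approx(expected, rel=1e-12)

    def test_instrument_solid_angle_is_0_11_percent(self):
        assert collection_fraction(0.014) * 100 == pytest.approx(0.11, abs=0.005)

    @given(omega=st.floats(1e-6, FOUR_PI))
    def test_linear_in_solid_angle(self, omega):
        assert collection_fraction(omega) == pytest.approx(
            omega * collection_fraction(1.0), rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            collection_fraction(0.0)
        with pytest.raises(ValueError):
            collection_fraction(4 * np.pi + 1)


class TestDetector:
    def test_radiant_sensitivity(self):
        assert detector_voltage(1.0, 5.0) == 5.0
        assert detector_voltage(0.0, 5.0) == 0.0

    def test_chain_product_with_collection(self):
        # 9.75 nW isotropic source seen through 0.11%: ~0.054 V at 5 V/nW
        v = detector_voltage(9.75 * collection_fraction(0.014), 5.0)
        assert v == pytest.approx(0.0543, abs=0.001)

    def test_daq_gain_multiplies(self):
        assert detector_voltage(1.0, 5.0, daq_gain=3.0) == 15.0

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            detector_voltage(-1.0, 5.0)


class TestPhotonConversion:
    def test_micromole_flux_to_watts(self):
        # independent closed form: 1 μmol photons/s at 685 nm
        expected = 1e-6 * constants.N_A * constants.h * constants.c / 685e-9
        assert photon_flux_to_watts(1.0, 685.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.1746, abs=0.001)

    def test_physics_chain_is_consistent_product(self):
        p = FluorescenceParams(par=1e9, chla=5.0, a_star=0.02, qa_star=0.6,
                               phi_f=0.03)
        geom = CollectionGeometry()
        chain = physics_chain(p, geom)
        assert chain["voltage_v"] == pytest.approx(
            chain["collected_power_nw"] * geom.detector_sensitivity, rel=1e-12)
        assert chain["collected_power_nw"] == pytest.approx(
            chain["total_power_nw"] * chain["collection_fraction"], rel=1e-12)


class TestOccupancy:
    def test_single_particle_regime_boundary(self):
        lam, _ = occupancy(1e5, 0.01)
        assert lam == pytest.approx(1.0, rel=1e-12)

    def test_dilute_regime_poisson_tail(self):
        lam, p2 = occupancy(1e3, 0.01)
        assert lam == pytest.approx(0.01, rel=1e-12)
        assert p2 == pytest.approx(4.97e-5, rel=0.01)

    @given(c=st.floats(1e2, 1e5), v=st.floats(1e-3, 1e-1))
    def test_bilinear_and_tail_bound(self, c, v):
        lam, p2 = occupancy(c, v)
        assert lam == pytest.approx(c * v * 1e-3, rel=1e-9)
        if lam < 1:
            assert p2 < lam**2

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            occupancy(0, 0.01)
        with pytest.raises(ValueError):
            occupancy(1e5, 0)


class TestExposure:
    def test_zero_dwell_is_safe(self):
        energy, safe = exposure_check(300.0, 0.0)
        assert energy == 0.0 and safe

    def test_transit_exposure_below_damage_threshold(self):
        # 300 mW for one 0.1 ms transit, full interception: 30 μJ << 816.43 μJ
        energy, safe = exposure_check(300.0, 0.1, damage_threshold_uj=816.43)
        assert energy == pytest.approx(30.0)
        assert safe

    def test_sub_microjoule_exposure_safe(self):
        energy, safe = exposure_check(300.0, 0.1, interception=0.1 / 30.0)
        assert energy == pytest.approx(0.1)
        assert safe

    def test_interception_factor_cross_section_ratio(self):
        assert interception_factor(5.0, 10.0) == 0.25
        assert interception_factor(20.0, 10.0) == 1.0   # capped

    def test_unsafe_above_threshold(self):
        energy, safe = exposure_check(300.0, 10.0, damage_threshold_uj=816.43)
        assert energy == pytest.approx(3000.0)
        assert not safe
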