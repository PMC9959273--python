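"""Forward DLVO model and physical-constant calculators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chiralloid import (
    CODATA,
    DLVOParameters,
    HamakerInputs,
    Medium,
    ProbeGeometry,
    SternPotential,
    dlvo_force,
    edl_force,
    hamaker_constant,
    kappa_from_ionic_strength,
    limit_distance,
    vdw_force,
    z_from_stern_potential,
)


def edl_only_limit_distance(params, threshold):
    """Closed-form oracle neglecting VDW: D = ln(kappa^2 r Z / s) / kappa."""
    r = params.geometry.sphere_radius
    return math.log(params.kappa**2 * r * params.z_const / threshold) / params.kappa


class TestComponentForces:
    def test_edl_matches_hand_evaluation(self, cnc_params):
        # kappa*r*Z*exp(-kappa D) at the CNC-CNC mean limit distance
        assert edl_force(cnc_params, 94.43) == pytest.approx(0.0390, abs=1e-4)

    def test_edl_zero_interaction_constant(self):
        p = DLVOParameters(kappa=0.04, z_const=0.0, hamaker=0.0)
        assert edl_force(p, 50.0) == 0.0

    def test_edl_decays_to_zero(self, cnc_params):
        assert edl_force(cnc_params, 2000.0) < 1e-30

    def test_vdw_hand_evaluations(self):
        p = DLVOParameters(kappa=0.04, z_const=1e-3, hamaker=3.6e-21,
                           geometry=ProbeGeometry(5000.0))
        assert vdw_force(p, 10.0) == pytest.approx(-0.030, rel=1e-9)
        # 100x the distance -> 1e-4 x the force (inverse square)
        assert vdw_force(p, 100.0) == pytest.approx(-3.0e-4, rel=1e-9)

    def test_vdw_zero_hamaker(self):
        p = DLVOParameters(kappa=0.04, z_const=1e-3, hamaker=0.0)
        assert vdw_force(p, 10.0) == 0.0

    def test_dlvo_is_exact_sum(self, cnc_params):
        d = np.linspace(5.0, 300.0, 257)
        np.testing.assert_array_equal(
            dlvo_force(cnc_params, d), edl_force(cnc_params, d) + vdw_force(cnc_params, d)
        )

    def test_dlvo_attractive_when_uncharged(self):
        p = DLVOParameters(kappa=0.04, z_const=0.0, hamaker=3.6e-21)
        assert dlvo_force(p, 5.0) < 0

    def test_nonpositive_distance_rejected(self, cnc_params):
        for bad in (0.0, -1.0):
            with pytest.raises(ValueError):
                dlvo_force(cnc_params, bad)

    def test_log_edl_is_affine_with_slope_minus_kappa(self, cnc_params):
        d = np.linspace(30.0, 150.0, 100)
        y = np.log(edl_force(cnc_params, d))
        slope, intercept = np.polyfit(d, y, 1)
        assert slope == pytest.approx(-cnc_params.kappa, rel=1e-12)
        resid = y - (slope * d + intercept)
        assert np.max(np.abs(resid)) < 1e-12 * np.max(np.abs(y))


class TestDebyeAndZ:
    def test_debye_length_textbook_oracle(self):
        # 1:1 electrolyte: lambda_D = 0.304 / sqrt(c[M]) nm
        for c_mm, expected in [(1.0, 9.6), (100.0, 0.96)]:
            kappa = kappa_from_ionic_strength(Medium(ionic_strength=c_mm))
            assert 1.0 / kappa == pytest.approx(expected, rel=0.01)

    def test_kappa_square_root_scaling(self):
        k1 = kappa_from_ionic_strength(Medium(ionic_strength=2.0))
        k4 = kappa_from_ionic_strength(Medium(ionic_strength=8.0))
        assert k4 == pytest.approx(2.0 * k1, rel=1e-12)

    def test_zero_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            kappa_from_ionic_strength(Medium(ionic_strength=0.0))

    def test_z_zero_potential(self):
        assert z_from_stern_potential(Medium(), SternPotential(0.0)) == 0.0

    def test_z_hand_evaluation_thermal_potential(self):
        # psi = RT/F = 25.69 mV -> tanh^2(1/4) factor; same order as the
        # measured pair series (6.3e-3 .. 11.2e-3 nN)
        z = z_from_stern_potential(Medium(), SternPotential(25.69e-3))
        assert z == pytest.approx(5.5e-3, rel=0.01)
        assert 1e-3 < z < 2e-2

    def test_z_saturates_at_large_potential(self):
        m = Medium()
        cap = (
            64.0 * math.pi * m.rel_permittivity * CODATA.vacuum_permittivity
            * (CODATA.gas_constant * m.temperature / CODATA.faraday) ** 2 * 1e9
        )
        z = z_from_stern_potential(m, SternPotential(5.0))
        assert z == pytest.approx(cap, rel=1e-6)

    @given(psi=st.floats(1e-4, 0.3))
    @settings(max_examples=50, deadline=None)
    def test_z_even_and_monotone_in_magnitude(self, psi):
        m = Medium()
        z_pos = z_from_stern_potential(m, SternPotential(psi))
        z_neg = z_from_stern_potential(m, SternPotential(-psi))
        assert z_pos == pytest.approx(z_neg, rel=1e-12)
        assert z_from_stern_potential(m, SternPotential(psi * 1.5)) > z_pos


class TestHamaker:
    def test_index_matched_media_vanish(self):
        hi = HamakerInputs(eps1=5.0, eps2=5.0, eps3=5.0, n1=1.5, n2=1.5, n3=1.5)
        assert hamaker_constant(hi) == 0.0

    def test_symmetric_media_positive(self):
        hi = HamakerInputs(eps1=4.0, eps2=4.0, eps3=78.5, n1=1.5, n2=1.5, n3=1.333)
        assert hamaker_constant(hi) > 0

    def test_swap_symmetry(self):
        a = hamaker_constant(HamakerInputs(eps1=4.0, eps2=9.0, eps3=78.5,
                                           n1=1.5, n2=1.7, n3=1.333))
        b = hamaker_constant(HamakerInputs(eps1=9.0, eps2=4.0, eps3=78.5,
                                           n1=1.7, n2=1.5, n3=1.333))
        assert a == pytest.approx(b, rel=1e-15)

    def test_symmetric_reduction_closed_form(self):
        """For identical bodies the standard reduced formula must hold."""
        hi = HamakerInputs(eps1=6.0, eps2=6.0, eps3=78.5, n1=1.56, n2=1.56, n3=1.333)
        kT = CODATA.boltzmann * hi.temperature
        term1 = 0.75 * kT * ((hi.eps1 - hi.eps3) / (hi.eps1 + hi.eps3)) ** 2
        term2 = (
            3 * CODATA.planck * hi.nu_e / (16 * math.sqrt(2))
            * (hi.n1**2 - hi.n3**2) ** 2 / (hi.n1**2 + hi.n3**2) ** 1.5
        )
        assert hamaker_constant(hi) == pytest.approx(term1 + term2, rel=1e-12)

    def test_cellulose_water_cellulose_order_of_magnitude(self):
        # standard static/optical constants for cellulose across water;
        # literature full-spectrum value is 3.6e-21 J
        hi = HamakerInputs(eps1=6.0, eps2=6.0, eps3=78.5, n1=1.56, n2=1.56, n3=1.333)
        a = hamaker_constant(hi)
        assert 3.6e-22 < a < 3.6e-20


class TestLimitDistance:
    def test_matches_edl_only_oracle(self, cnc_params):
        threshold = 1.8e-3
        d = limit_distance(cnc_params, threshold)
        oracle = edl_only_limit_distance(cnc_params, threshold)
        # the VDW slope contribution at the solution is <1% of the threshold,
        # so the EDL-only closed form must agree to <0.5%
        vdw_slope = cnc_params.hamaker * 5000.0 / (3.0 * oracle**3) * 1e18
        assert vdw_slope < 0.01 * threshold
        assert d == pytest.approx(oracle, rel=5e-3)
        assert d == pytest.approx(92.0, abs=1.0)

    def test_monotone_in_threshold(self, cnc_params):
        d1 = limit_distance(cnc_params, 1.8e-3)
        d2 = limit_distance(cnc_params, 0.9e-3)
        assert d2 > d1

    def test_doubling_z_shifts_by_ln2_over_kappa(self, cnc_params):
        # exact on the pure-EDL profile (the closed-form oracle's regime)
        p1 = DLVOParameters(kappa=cnc_params.kappa, z_const=cnc_params.z_const,
                            hamaker=0.0, geometry=cnc_params.geometry)
        p2 = DLVOParameters(kappa=cnc_params.kappa, z_const=2 * cnc_params.z_const,
                            hamaker=0.0, geometry=cnc_params.geometry)
        d1 = limit_distance(p1, 1.8e-3)
        d2 = limit_distance(p2, 1.8e-3)
        assert d2 - d1 == pytest.approx(math.log(2) / cnc_params.kappa, rel=1e-6)

    def test_no_root_reports_interval(self, cnc_params):
        with pytest.raises(ValueError, match=r"\["):
            limit_distance(cnc_params, 1e6)

    def test_requires_repulsion(self):
        p = DLVOParameters(kappa=0.04, z_const=0.0, hamaker=3.6e-21)
        with pytest.raises(ValueError):
            limit_distance(p)


class TestInvariantValidation:
    @pytest.mark.parametrize(
        "ctor",
        [
            lambda: Medium(temperature=0.0),
            lambda: Medium(ionic_strength=-1.0),
            lambda: Medium(rel_permittivity=0.9),
            lambda: ProbeGeometry(0.0),
            lambda: DLVOParameters(kappa=0.0, z_const=1e-3),
            lambda: DLVOParameters(kappa=0.04, z_const=-1e-3),
            lambda: DLVOParameters(kappa=0.04, z_const=1e-3, hamaker=-1e-21),
            lambda: HamakerInputs(eps1=0.5, eps2=5, eps3=5, n1=1.5, n2=1.5, n3=1.5),
            lambda: SternPotential(float("nan")),
        ],
    )
    def test_bad_constructions_rejected(self, ctor):
        with pytest.raises(ValueError):
            ctor()
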