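"""Closed-form crack openings, the fiber-reinforced law, and Hooke strains."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from embryomech.plane_elasticity import (
    BiaxialLoad,
    ComplianceMatrix,
    IsotropicSheet,
    build_fiber_reinforced,
    crack_opening_factor,
    hooke_fiber_reinforced_strains,
    hooke_isotropic_strains,
    opening_anisotropic,
    opening_isotropic,
    opening_orthotropic_comparison,
    opening_pair_fiber_reinforced,
)


class TestOpeningIsotropic:
    def test_unloaded_sheet_does_not_open(self):
        assert opening_isotropic(0.0, 4.0).b_over_l == 0.0

    def test_forced_by_linear_law(self):
        op = opening_isotropic(0.05, 5.0)
        assert op.b_um == pytest.approx(0.5)

    @pytest.mark.parametrize("l", [3.0, 4.0, 5.0, 6.0])
    def test_scaled_opening_independent_of_cut_length(self, l):
        assert opening_isotropic(0.07, l).b_over_l == pytest.approx(0.14)

    def test_compressive_load_rejected(self):
        with pytest.raises(ValueError, match="compressive"):
            opening_isotropic(-0.01, 5.0)

    def test_major_axis_carries_parallel_strain(self):
        op = opening_isotropic(0.05, 5.0, nu=0.5, load_parallel=0.04)
        assert op.a_over_l == pytest.approx(1.0 + 0.04 - 0.5 * 0.05)

    @given(
        sigma=st.floats(0.0, 0.2),
        E=st.floats(0.1, 10.0),
        l=st.floats(1.0, 10.0),
    )
    def test_opening_scales_as_stress_over_modulus(self, sigma, E, l):
        assert opening_isotropic(sigma / E, l).b_over_l == pytest.approx(2 * sigma / E)


class TestFiberReinforcedConstitutive:
    def test_no_fibers_is_isotropic_matrix(self):
        sheet = build_fiber_reinforced(2.0, 0.4, 0.0)
        assert sheet.E_DV == pytest.approx(2.0)
        assert sheet.E_AP == pytest.approx(2.0)
        assert sheet.omega == pytest.approx(1.0)

    def test_fiber_modulus_exactly_linear_in_K(self):
        K = np.linspace(0, 10, 21)
        e_dv = np.array([build_fiber_reinforced(1.0, 0.5, k).E_DV for k in K])
        coeffs, residuals, *_ = np.polyfit(K, e_dv, 1, full=True)
        assert coeffs[0] == pytest.approx(1.0, abs=1e-12)  # slope = E0
        assert residuals[0] == pytest.approx(0.0, abs=1e-20)

    def test_transverse_modulus_closed_form_and_plateau(self):
        sheet = build_fiber_reinforced(1.0, 0.5, 4.0)
        assert sheet.E_AP == pytest.approx(1.25)
        plateau = 1.0 / (1 - 0.5**2)
        ks = [0, 1, 2, 4, 8, 100, 1e4]
        e_ap = [build_fiber_reinforced(1.0, 0.5, k).E_AP for k in ks]
        assert all(np.diff(e_ap) > 0), "E_AP must increase with K"
        assert all(e < plateau for e in e_ap)
        assert e_ap[-1] == pytest.approx(plateau, rel=1e-3)

    def test_directional_moduli_match_matrix_inversion_oracle(self):
        # independently assemble the 3x3 stiffness and invert numerically
        E0, nu0, K = 1.0, 0.5, 4.0
        c = E0 / (1 - nu0**2)
        Q = np.array(
            [[c, nu0 * c, 0], [nu0 * c, c + K * E0, 0], [0, 0, E0 / (2 * (1 + nu0))]]
        )
        S = np.linalg.inv(Q)
        sheet = build_fiber_reinforced(E0, nu0, K)
        assert sheet.E_AP == pytest.approx(1.0 / S[0, 0])
        assert sheet.E_DV == pytest.approx(1.0 / S[1, 1])
        assert sheet.E_DV == pytest.approx(E0 * (1 + K))

    def test_omega_monotone_in_K(self):
        omegas = [build_fiber_reinforced(1.0, 0.5, k).omega for k in (0, 1, 2, 4, 8)]
        assert omegas[0] == pytest.approx(1.0)
        assert all(np.diff(omegas) > 0)

    def test_singular_poisson_rejected(self):
        with pytest.raises(ValueError, match="nu0"):
            build_fiber_reinforced(1.0, 1.0, 2.0)


class TestAnisotropicOpening:
    @pytest.mark.parametrize("nu", [0.0, 0.3, 0.5, 0.9])
    def test_isotropic_limit_recovers_linear_law(self, nu):
        comp = IsotropicSheet(E=2.0, nu=nu).compliance()
        op = opening_anisotropic(comp, 0.05, "AP")
        assert op.b_over_l == pytest.approx(2 * 0.05 / 2.0, rel=1e-12)

    def test_opening_factor_decreases_with_reinforcement(self):
        hs = [
            crack_opening_factor(build_fiber_reinforced(1.0, 0.5, k).compliance, "DV")
            for k in (0, 1, 2, 4, 8)
        ]
        assert hs[0] == pytest.approx(1.0)
        assert all(np.diff(hs) < 0)

    def test_non_positive_definite_compliance_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            ComplianceMatrix(s11=1.0, s12=-1.5, s22=1.0, s66=1.0)

    @pytest.mark.parametrize("l", [3.0, 4.0, 5.0, 6.0])
    def test_scale_invariance(self, l):
        comp = build_fiber_reinforced(1.0, 0.5, 3.0).compliance
        assert opening_anisotropic(comp, 0.05, "DV", l).b_over_l == pytest.approx(
            opening_anisotropic(comp, 0.05, "DV", 1.0).b_over_l
        )


class TestOpeningPair:
    def test_no_fibers_both_cuts_isotropic(self):
        sheet = build_fiber_reinforced(1.0, 0.3, 0.0)
        load = BiaxialLoad(sigma_AP=0.04, sigma_DV=0.06)
        ap_cut, dv_cut = opening_pair_fiber_reinforced(sheet, load)
        assert ap_cut.b_over_l == pytest.approx(2 * 0.06)
        assert dv_cut.b_over_l == pytest.approx(2 * 0.04)

    @pytest.mark.parametrize("K", [0.0, 1.0, 4.0, 8.0])
    def test_dv_opening_ignores_fibers(self, K):
        # the AP cut severs the fibers: opening set by sigma_DV / E0 alone
        sheet = build_fiber_reinforced(1.0, 0.5, K)
        ap_cut, _ = opening_pair_fiber_reinforced(sheet, BiaxialLoad(0.05, 0.08))
        assert ap_cut.b_over_l == pytest.approx(2 * 0.08)

    def test_equal_loads_open_more_across_than_along_fibers(self):
        sheet = build_fiber_reinforced(1.0, 0.5, 2.0)
        ap_cut, dv_cut = opening_pair_fiber_reinforced(sheet, BiaxialLoad(0.06, 0.06))
        assert ap_cut.b_over_l > dv_cut.b_over_l


class TestOrthotropicComparison:
    def test_equal_moduli_reduce_to_isotropic(self):
        op = opening_orthotropic_comparison(2.0, 2.0, 0.4, 0.06, "AP", 5.0)
        assert op.b_over_l == pytest.approx(2 * 0.06 / 2.0)

    def test_zero_load_zero_opening(self):
        assert opening_orthotropic_comparison(1.25, 5.0, 0.5, 0.0, "DV").b_over_l == 0.0

    def test_prediction_differs_from_fiber_reinforced_model(self):
        # same directional moduli as K = 4, nu0 = 0.5, but no fiber destruction
        sheet = build_fiber_reinforced(1.0, 0.5, 4.0)
        load = BiaxialLoad(sigma_AP=0.05, sigma_DV=0.08)
        ap_cut, dv_cut = opening_pair_fiber_reinforced(sheet, load)
        fiber_ratio = ap_cut.b_over_l / dv_cut.b_over_l
        o_ap = opening_orthotropic_comparison(sheet.E_AP, sheet.E_DV, 0.5, 0.08, "AP")
        o_dv = opening_orthotropic_comparison(sheet.E_AP, sheet.E_DV, 0.5, 0.05, "DV")
        ortho_ratio = o_ap.b_over_l / o_dv.b_over_l
        assert fiber_ratio != pytest.approx(ortho_ratio, rel=0.05)


class TestHookeStrains:
    def test_incompressible_isotropic_contraction_is_shape_preserving(self):
        eps_ap, eps_dv = hooke_isotropic_strains(0.1, 1.0, 1.0)
        assert eps_ap == pytest.approx(0.0)
        assert eps_dv == pytest.approx(0.0)

    def test_stress_anisotropy_elongates_seam_cell(self):
        eps_ap, eps_dv = hooke_isotropic_strains(0.1, 2.0, 1.0)
        assert eps_ap == pytest.approx(0.1)
        assert eps_dv == pytest.approx(-0.1)

    def test_ap_strain_increases_with_stress_anisotropy(self):
        eps = [hooke_isotropic_strains(0.1, a, 0.8)[0] for a in (1.0, 1.4, 1.8, 2.2)]
        assert all(np.diff(eps) > 0)

    def test_fiber_threshold_for_ap_extension(self):
        # omega = nu1 * AS is the zero of the AP strain
        eps_ap, _ = hooke_fiber_reinforced_strains(0.1, AS=1.6, omega=1.6, nu1=1.0)
        assert eps_ap == pytest.approx(0.0)

    def test_stiffness_anisotropy_drives_ap_extension_dv_shrinkage(self):
        omegas = (1.5, 2.0, 3.0, 4.0)
        eps_ap = [hooke_fiber_reinforced_strains(0.1, 1.8, w)[0] for w in omegas]
        eps_dv = [hooke_fiber_reinforced_strains(0.1, 1.8, w)[1] for w in omegas]
        assert all(np.diff(eps_ap) > 0)
        assert all(np.diff(eps_dv) < 0)

    def test_stress_anisotropy_opposes_ap_extension_in_dv_cells(self):
        eps_ap = [
            hooke_fiber_reinforced_strains(0.1, a, 3.0)[0] for a in (1.0, 1.5, 2.0)
        ]
        assert all(np.diff(eps_ap) < 0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            hooke_fiber_reinforced_strains(0.1, 0.0, 2.0)
        with pytest.raises(ValueError):
            hooke_fiber_reinforced_strains(0.1, 1.5, 0.0)

    @given(nu=st.floats(0.0, 1.0), AS=st.floats(0.5, 2.5))
    def test_strains_vanish_without_load(self, nu, AS):
        assert hooke_isotropic_strains(0.0, AS, nu) == (0.0, 0.0)
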