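"""Matrix-ratio, K and omega inference from paired seam / DV-cell openings."""

import numpy as np
import pytest

from embryomech.stiffness_inference import (
    fiber_factor_opening_factor,
    infer_K,
    matrix_modulus_ratio,
    opening_ratio_report,
    stiffness_anisotropy,
)
from embryomech.synthetic_data import GroundTruth, gen_paired_cohort


class TestMatrixModulusRatio:
    def test_identical_openings_unit_ratio(self):
        x = np.array([0.1, 0.15, 0.2])
        assert matrix_modulus_ratio(x, x).value == pytest.approx(1.0)

    def test_inverse_proportionality(self):
        h1 = np.array([0.09, 0.12, 0.15, 0.18])
        assert matrix_modulus_ratio(h1, h1 * 2 / 3).value == pytest.approx(1.5)

    def test_all_zero_h1_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            matrix_modulus_ratio(np.zeros(3), np.array([0.1, 0.2, 0.3]))

    def test_noisy_recovery_within_ten_percent(self):
        truths = [
            GroundTruth(stage=s, sigma_dv_over_e=sv, AS=a, matrix_ratio=1.5, K=k)
            for s, sv, a, k in [("1.3F", 0.055, 1.0, 0.6), ("1.5F", 0.075, 1.5, 2.0),
                                ("1.7F", 0.100, 1.8, 4.0)]
        ]
        cohort = gen_paired_cohort(truths, n_embryos=20, noise_cv=0.10, seed=9)
        df = cohort.openings
        piv = df[df.cut_direction == "AP"].pivot_table(
            index=["stage", "embryo"], columns="cell", values="b_over_l"
        )
        est = matrix_modulus_ratio(piv["H1"].to_numpy(), piv["HYP7"].to_numpy())
        assert est.value == pytest.approx(1.5, rel=0.10)


class TestInferK:
    def test_isotropic_openings_give_zero_K(self):
        # DV-cut/AP-cut = 1/AS is the isotropic signature
        AS = 1.6
        ap_cut = 0.16
        dv_cut = ap_cut / AS
        est = infer_K(ap_cut, dv_cut, AS, 0.5)
        assert est.value == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("K_true", [0.0, 1.0, 2.0, 4.0, 8.0])
    @pytest.mark.parametrize("AS", [1.0, 1.3, 1.8])
    def test_noiseless_roundtrip_identity(self, K_true, AS):
        sigma_dv = 0.08
        sigma_ap = sigma_dv / AS
        ap_cut = 2 * sigma_dv
        dv_cut = 2 * sigma_ap * fiber_factor_opening_factor(K_true, 0.5)
        est = infer_K(ap_cut, dv_cut, AS, 0.5)
        assert est.value == pytest.approx(K_true, rel=1e-6, abs=1e-6)

    def test_inconsistent_openings_rejected(self):
        # DV-cut opening larger than the unreinforced prediction -> K < 0
        with pytest.raises(ValueError, match="inconsistent"):
            infer_K(0.16, 0.2, 1.0, 0.5)

    def test_noisy_median_within_fifteen_percent(self):
        n_rep, cv, n_embryos = 200, 0.10, 20
        rng = np.random.default_rng(3)
        sigma_ln = np.sqrt(np.log1p(cv**2))
        K_true, AS, nu0 = 4.0, 1.6, 0.5
        sigma_dv = 0.08
        ap_true = 2 * sigma_dv
        dv_true = 2 * (sigma_dv / AS) * fiber_factor_opening_factor(K_true, nu0)
        estimates = []
        for _ in range(n_rep):
            noise = rng.lognormal(-0.5 * sigma_ln**2, sigma_ln, size=(2, n_embryos))
            ap = float((ap_true * noise[0]).mean())
            dv = float((dv_true * noise[1]).mean())
            try:
                estimates.append(infer_K(ap, dv, AS, nu0).value)
            except ValueError:
                estimates.append(0.0)
        estimates = np.array(estimates)
        assert np.all(estimates >= 0)
        assert np.median(estimates) == pytest.approx(K_true, rel=0.15)


class TestStiffnessAnisotropy:
    def test_no_fibers_isotropic(self):
        assert stiffness_anisotropy(0.0, 0.5).value == pytest.approx(1.0)

    def test_closed_form_at_K4(self):
        # omega = E_DV/E_AP = (5 E0) / (1.25 E0) = 4
        assert stiffness_anisotropy(4.0, 0.5).value == pytest.approx(4.0)

    def test_monotone_in_K(self):
        vals = [stiffness_anisotropy(k, 0.5).value for k in (0, 0.5, 1, 2, 4, 8)]
        assert all(np.diff(vals) > 0)


class TestOpeningRatioReport:
    def test_equal_ratios_no_flag(self):
        cohort = gen_paired_cohort(
            [GroundTruth(stage="1.3F", AS=1.2, K=0.0)], n_embryos=5, noise_cv=0.0
        )
        rep = opening_ratio_report(cohort.paired("1.3F"))
        assert rep["h1_ratio"] == pytest.approx(rep["hyp7_ratio"])
        assert not rep["hyp7_exceeds_h1"]

    def test_fiber_reinforced_hyp7_flagged(self):
        cohort = gen_paired_cohort(
            [GroundTruth(stage="1.7F", AS=1.6, K=4.0)], n_embryos=5, noise_cv=0.0
        )
        rep = opening_ratio_report(cohort.paired("1.7F"))
        assert rep["hyp7_ratio"] > rep["h1_ratio"]
        assert rep["hyp7_exceeds_h1"]

    def test_missing_direction_errors(self):
        cohort = gen_paired_cohort(n_embryos=3, noise_cv=0.0)
        paired = cohort.paired("1.3F")
        bad = type(paired)(
            stage="1.3F",
            h1_ap_cut=paired.h1_ap_cut, h1_ap_cut_se=0.0,
            h1_dv_cut=0.0, h1_dv_cut_se=0.0,
            hyp7_ap_cut=paired.hyp7_ap_cut, hyp7_ap_cut_se=0.0,
            hyp7_dv_cut=paired.hyp7_dv_cut, hyp7_dv_cut_se=0.0,
        )
        with pytest.raises(ValueError, match="positive"):
            opening_ratio_report(bad)


class TestOmegaVersusAS:
    def test_omega_exceeds_AS_detected_reliably(self):
        # scenario built with omega > AS: the pipeline must say so almost always
        truth = GroundTruth(stage="1.7F", AS=1.6, K=4.0)  # omega = 4
        detected = 0
        n_rep = 60
        for rep in range(n_rep):
            cohort = gen_paired_cohort([truth], n_embryos=20, noise_cv=0.10, seed=100 + rep)
            p = cohort.paired("1.7F")
            AS = p.h1_ap_cut / p.h1_dv_cut
            try:
                K = infer_K(p.hyp7_ap_cut, p.hyp7_dv_cut, AS, 0.5).value
            except ValueError:
                K = 0.0
            omega = stiffness_anisotropy(K, 0.5).value
            detected += omega > AS
        assert detected / n_rep >= 0.95
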