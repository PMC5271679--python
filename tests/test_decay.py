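"""Sustained-NPQ correction and exponential photoinactivation fits."""

import dataclasses

import numpy as np
import pytest

import photoinact as pi
from photoinact.decay import _fit_points


def _manual_tc(fv, protocol=None, ci=1e-3, sigma=170.0):
    if protocol is None:
        protocol = pi.TreatmentProtocol.standard(260.0, 1200.0)
    n = protocol.n_periods
    return pi.TreatmentTimeCourse(
        protocol=protocol, fv_fm_2s=np.asarray(fv, dtype=float),
        fv_fm_2s_ci95=np.full(n, ci), sigma_psii_2s=np.full(n, sigma))


class TestSustainedNpqInfluence:
    def test_direct_subtraction(self):
        assert pi.sustained_npq_influence(0.40, 0.35) == pytest.approx(0.05)

    def test_floored_at_zero(self):
        assert pi.sustained_npq_influence(0.30, 0.35) == 0.0

    def test_equal_inputs_zero(self):
        assert pi.sustained_npq_influence(0.42, 0.42) == 0.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            pi.sustained_npq_influence(1.2, 0.5)


class TestApplyNpqCorrection:
    def test_zero_influence_is_identity(self):
        tc = pi.make_timecourse(
            dataclasses.replace(pi.FIG3_BLUE.noiseless(), npq_influence=0.0))
        out = pi.apply_npq_correction(tc)
        np.testing.assert_array_equal(out.fv_fm_2s, tc.fv_fm_2s)
        assert out.npq_influence_applied == 0.0

    def test_elementwise_addition_on_treatment_periods(self):
        protocol = pi.TreatmentProtocol(
            (pi.Period("dark", 327, 0.0),)
            + tuple(pi.Period("treatment", 327, 500.0, "red_655nm")
                    for _ in range(3))
            + (pi.Period("recovery", 327, 20.0),))
        tc = _manual_tc([0.6, 0.5, 0.4, 0.35, 0.40], protocol)
        out = pi.apply_npq_correction(tc)
        assert out.npq_influence_applied == pytest.approx(0.05)
        np.testing.assert_allclose(out.fv_fm_2s, [0.6, 0.55, 0.45, 0.40, 0.40])
        # CIs untouched
        np.testing.assert_array_equal(out.fv_fm_2s_ci95, tc.fv_fm_2s_ci95)

    def test_missing_recovery_period_raises(self):
        protocol = pi.TreatmentProtocol(
            (pi.Period("dark", 327, 0.0),)
            + tuple(pi.Period("treatment", 327, 500.0, "red_655nm")
                    for _ in range(4)))
        tc = _manual_tc([0.6, 0.5, 0.45, 0.42, 0.40], protocol)
        with pytest.raises(pi.MissingRecoveryPeriodError, match="npq_influence=0"):
            pi.apply_npq_correction(tc)
        out = pi.apply_npq_correction(tc, npq_influence=0.0)
        np.testing.assert_array_equal(out.fv_fm_2s, tc.fv_fm_2s)


class TestDecayFits:
    def test_noiseless_recovery_both_bases(self, noiseless_preset):
        tc = pi.apply_npq_correction(pi.make_timecourse(noiseless_preset))
        sig = pi.fit_sigma_i(tc)
        phi = pi.fit_phi_i(tc)
        assert sig.rate == pytest.approx(noiseless_preset.sigma_i, rel=1e-6)
        assert phi.rate == pytest.approx(noiseless_preset.phi_i, rel=1e-6)
        assert sig.amplitude == pytest.approx(noiseless_preset.amplitude, rel=1e-6)
        assert phi.amplitude == pytest.approx(noiseless_preset.amplitude, rel=1e-6)
        assert sig.basis == "incident" and phi.basis == "delivered"
        assert sig.r_squared > 0.999999

    def test_phi_sigma_identity_constant_cross_section(self, noiseless_preset):
        """With constant sigma_PSII'2s, Phi_i x sigma = sigma_i."""
        tc = pi.apply_npq_correction(pi.make_timecourse(noiseless_preset))
        sig = pi.fit_sigma_i(tc)
        phi = pi.fit_phi_i(tc)
        assert phi.rate * noiseless_preset.sigma_psii_2s == \
            pytest.approx(sig.rate, rel=1e-6)

    def test_weighting_invariant_to_ci_scaling(self):
        tc = pi.make_timecourse(dataclasses.replace(pi.FIG3_BLUE, seed=11))
        scaled = dataclasses.replace(tc, fv_fm_2s_ci95=tc.fv_fm_2s_ci95 * 13.0)
        a = pi.fit_sigma_i(tc)
        b = pi.fit_sigma_i(scaled)
        assert b.rate == pytest.approx(a.rate, rel=1e-9)
        assert b.amplitude == pytest.approx(a.amplitude, rel=1e-9)

    def test_inverse_ci_squared_option_changes_weighting(self):
        tc = pi.make_timecourse(dataclasses.replace(pi.FIG3_BLUE, seed=12))
        a = pi.fit_sigma_i(tc, weighting="inverse_ci")
        b = pi.fit_sigma_i(tc, weighting="inverse_ci_squared")
        assert a.rate != b.rate  # heteroscedastic CIs -> different estimates
        with pytest.raises(ValueError):
            pi.fit_sigma_i(tc, weighting="bogus")

    def test_constant_series_rate_zero(self):
        tc = _manual_tc(np.full(10, 0.5))
        fit = pi.fit_sigma_i(tc)
        assert fit.rate == pytest.approx(0.0, abs=1e-12)
        assert fit.amplitude == pytest.approx(0.5, rel=1e-9)

    def test_rising_series_pinned_at_zero_with_warning(self):
        fv = np.linspace(0.4, 0.6, 10)
        tc = _manual_tc(fv)
        with pytest.warns(UserWarning, match="pinned"):
            fit = pi.fit_sigma_i(tc)
        assert fit.rate == pytest.approx(0.0, abs=1e-12)

    def test_correction_reduces_fitted_sigma_i(self):
        """Adding back sustained NPQ flattens the decay: sigma_i shrinks."""
        preset = dataclasses.replace(pi.FIG3_BLUE.noiseless(), npq_influence=0.04)
        tc = pi.make_timecourse(preset)
        uncorrected = pi.fit_sigma_i(tc)
        corrected = pi.fit_sigma_i(pi.apply_npq_correction(tc))
        assert corrected.rate < uncorrected.rate
        assert corrected.rate == pytest.approx(preset.sigma_i, rel=1e-6)

    def test_fit_points_exclude_recovery(self, noiseless_blue_tc):
        idx = _fit_points(noiseless_blue_tc)
        kinds = np.array(noiseless_blue_tc.protocol.kinds)
        assert "recovery" not in kinds[idx]
        assert 0 in idx  # dark anchor

    def test_too_few_points_rejected(self):
        protocol = pi.TreatmentProtocol(
            (pi.Period("dark", 327, 0.0),
             pi.Period("treatment", 327, 500.0, "red_655nm"),
             pi.Period("recovery", 327, 20.0)))
        tc = _manual_tc([0.6, 0.5, 0.55], protocol)
        with pytest.raises(ValueError, match="at least 4"):
            pi.fit_sigma_i(tc)

    def test_sigma_ci_coverage_over_noisy_seeds(self):
        """95% CI of the weighted fit covers truth in >= 90% of 100 seeds."""
        hits = 0
        for seed in range(100):
            preset = dataclasses.replace(pi.FIG3_BLUE, seed=seed,
                                         npq_influence=0.0)
            fit = pi.fit_sigma_i(pi.make_timecourse(preset))
            hits += abs(fit.rate - preset.sigma_i) <= fit.rate_ci95
        assert hits >= 90
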