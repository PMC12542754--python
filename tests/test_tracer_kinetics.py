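"""Counts-to-rate conversion: quench correction, the rate equation and its
uncertainty propagation, treatment contrasts."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as hs

from springtracer import (ComputationError, ConfigurationError, DataError,
                          QuenchCurve, RateInputs, TracerSpike, UFloat,
                          UsageError, assimilation_rate, compare_treatments,
                          dissimilation_rate, dpm_from_cpm,
                          headspace_fraction, light_driven_rate,
                          replicate_mean, total_substrate_mmol)
from springtracer.tracer_kinetics import RateResult

IDENTITY_CURVE = QuenchCurve.constant(1.0)


def make_inputs(**overrides):
    """The worked DIC-assay example: evaluates to 7.0 mg C (g C)^-1 h^-1."""
    base = dict(dpm_T=UFloat(98600.0), dpm_K=UFloat(500.0),
                mmol_substrate=UFloat(0.1213), dpm_added=UFloat(1.1766e7),
                gdw=UFloat(0.020), wt_pct_C=UFloat(9.11), t_hours=1.0,
                F_s=1.0, nu_C=1, alpha=1.05)
    base.update(overrides)
    return RateInputs(**base)


class TestDpmFromCpm:
    @pytest.mark.parametrize("cpm,background,efficiency,expected", [
        (1000.0, 0.0, 1.0, 1000.0),     # identity efficiency
        (930.0, 30.0, 0.90, 1000.0),    # (930-30)/0.9 by hand
        (30.0, 30.0, 0.90, 0.0),        # cpm equal to background
        (10.0, 30.0, 0.90, 0.0),        # below background clips at zero
    ])
    def test_examples(self, cpm, background, efficiency, expected):
        curve = QuenchCurve.constant(efficiency)
        assert dpm_from_cpm(cpm, background, curve, 0.5) == pytest.approx(expected)

    def test_interpolates_and_clips_quench_indicator(self):
        curve = QuenchCurve(((0.0, 0.5), (1.0, 0.9)))
        assert curve.efficiency(0.5) == pytest.approx(0.7)
        assert curve.efficiency(-5.0) == pytest.approx(0.5)
        assert curve.efficiency(5.0) == pytest.approx(0.9)

    @given(cpm=hs.floats(0, 1e6), eff=hs.floats(0.1, 1.0))
    def test_monotone_in_cpm_and_efficiency(self, cpm, eff):
        curve = QuenchCurve.constant(eff)
        d = dpm_from_cpm(cpm, 25.0, curve, 0.0)
        assert dpm_from_cpm(cpm + 10.0, 25.0, curve, 0.0) >= d
        lower_eff = QuenchCurve.constant(eff * 0.9)
        assert dpm_from_cpm(cpm, 25.0, lower_eff, 0.0) >= d

    def test_invalid_curves_rejected(self):
        with pytest.raises(ConfigurationError):
            QuenchCurve(((0.0, 0.9),))                 # single point
        with pytest.raises(ConfigurationError):
            QuenchCurve(((0.0, 0.9), (0.0, 0.8)))      # non-increasing indicator
        with pytest.raises(DataError):
            QuenchCurve(((0.0, 0.0), (1.0, 0.9)))      # efficiency out of range
        with pytest.raises(DataError):
            dpm_from_cpm(-1.0, 0.0, IDENTITY_CURVE, 0.0)


class TestHeadspaceFraction:
    def test_quarter_sample(self):
        # 26.3 mL bottle, 11.3 mL liquids, 5 mL syringe -> 5/(15+5)
        assert headspace_fraction(126.3, 100.0, 1.0, 11.3, 5.0) == pytest.approx(0.25)

    def test_large_syringe_limit(self):
        f = headspace_fraction(126.3, 100.0, 1.0, 11.3, 1e9)
        assert f == pytest.approx(1.0, abs=1e-7)

    def test_degenerate_inputs(self):
        with pytest.raises(DataError):
            headspace_fraction(100.0, 100.0, 1.0, 5.0, 5.0)
        with pytest.raises(DataError):
            headspace_fraction(110.0, 100.0, 1.0, 15.0, 5.0)  # no headspace


class TestTotalSubstrate:
    def test_acetate_microcosm_concentration(self):
        # 0.83 uM native acetate in 11 mL plus a 0.71 uCi spike at
        # 110 mCi/mmol gives ~1.4 uM in the 11.2 mL microcosm
        spike = TracerSpike("acetate", 0.71, 110.0, 2)
        mmol = total_substrate_mmol(8.3e-7, 11.0, spike)
        assert mmol.value == pytest.approx(9.13e-6 + 6.4545e-6, rel=1e-3)
        conc_uM = mmol.value / 11.2 * 1e6  # mmol/mL == mol/L -> uM
        assert conc_uM == pytest.approx(1.4, abs=0.05)

    def test_no_spike_leaves_native_pool(self):
        assert total_substrate_mmol(0.011, 11.0, None).value == pytest.approx(0.121)

    def test_dic_spike_is_tiny_fraction_of_pool(self):
        spike = TracerSpike("DIC", 5.3, 54.0, 1)
        mmol = total_substrate_mmol(0.011, 11.0, spike)
        assert spike.mmol_added == pytest.approx(9.8e-5, rel=1e-2)
        assert spike.mmol_added / mmol.value < 1e-3

    def test_negative_inputs_rejected(self):
        with pytest.raises(DataError):
            total_substrate_mmol(-0.01, 11.0, None)


class TestAssimilationRate:
    def test_worked_example(self):
        res = assimilation_rate(make_inputs())
        assert res.rate.value == pytest.approx(7.0, abs=0.01)
        assert res.net_dpm == pytest.approx(98100.0)

    def test_null_net_conversion(self):
        res = assimilation_rate(make_inputs(dpm_T=UFloat(500.0, 50.0),
                                            dpm_K=UFloat(500.0, 50.0)))
        assert res.rate.value == 0.0
        assert res.rate.sd > 0
        assert not res.distinguishable_from_zero

    def test_agrees_with_brute_force_oracle(self):
        # independent plain-float recomputation on random input vectors
        rng = np.random.default_rng(7)
        for _ in range(10):
            v = rng.uniform(0.1, 10.0, size=9)
            dpm_t, dpm_k, mmol, dpm_add, gdw, wtc, t, fs, alpha = v
            fs = fs / 10.0  # into (0, 1]
            expected = ((dpm_t - dpm_k) * mmol * 12.011 * 1 * alpha
                        / (dpm_add * gdw * (wtc / 100.0) * t * fs))
            res = assimilation_rate(RateInputs(
                dpm_T=UFloat(dpm_t), dpm_K=UFloat(dpm_k),
                mmol_substrate=UFloat(mmol), dpm_added=UFloat(dpm_add),
                gdw=UFloat(gdw), wt_pct_C=UFloat(wtc), t_hours=t, F_s=fs,
                alpha=alpha))
            assert res.rate.value == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("field,factor", [
        ("mmol_substrate", 3.0), ("alpha", 2.0)])
    def test_linear_in_numerator_factors(self, field, factor):
        base = assimilation_rate(make_inputs()).rate.value
        if field == "mmol_substrate":
            scaled = make_inputs(mmol_substrate=UFloat(0.1213 * factor))
        else:
            scaled = make_inputs(alpha=1.05 * factor)
        assert assimilation_rate(scaled).rate.value == pytest.approx(
            base * factor, rel=1e-12)

    def test_linear_in_net_dpm_and_inverse_in_fs(self):
        base = assimilation_rate(make_inputs()).rate.value
        doubled_net = make_inputs(dpm_T=UFloat(500.0 + 2 * 98100.0))
        assert assimilation_rate(doubled_net).rate.value == pytest.approx(
            2 * base, rel=1e-12)
        halved_fs = assimilation_rate(make_inputs(F_s=0.5)).rate.value
        assert halved_fs == pytest.approx(2 * base, rel=1e-12)

    def test_propagated_error_matches_monte_carlo(self):
        # all input CVs <= 10%: first-order propagation vs 1e5-draw MC
        rng = np.random.default_rng(42)
        n = 100_000
        spec = dict(dpm_t=(98600.0, 5000.0), dpm_k=(500.0, 40.0),
                    mmol=(0.1213, 0.004), dpm_add=(1.1766e7, 1e5),
                    gdw=(0.020, 0.001), wtc=(9.11, 0.07))
        draws = {k: rng.normal(m, s, n) for k, (m, s) in spec.items()}
        mc = ((draws["dpm_t"] - draws["dpm_k"]) * draws["mmol"] * 12.011 * 1.05
              / (draws["dpm_add"] * draws["gdw"] * (draws["wtc"] / 100.0)))
        res = assimilation_rate(make_inputs(
            dpm_T=UFloat(*spec["dpm_t"]), dpm_K=UFloat(*spec["dpm_k"]),
            mmol_substrate=UFloat(*spec["mmol"]),
            dpm_added=UFloat(*spec["dpm_add"]), gdw=UFloat(*spec["gdw"]),
            wt_pct_C=UFloat(*spec["wtc"])))
        assert res.rate.sd == pytest.approx(mc.std(), rel=0.10)

    def test_zero_denominator_terms_raise(self):
        with pytest.raises(ComputationError):
            assimilation_rate(make_inputs(gdw=UFloat(0.0)))
        with pytest.raises(DataError):
            make_inputs(t_hours=0.0)
        with pytest.raises(DataError):
            make_inputs(F_s=0.0)


class TestDissimilationRate:
    def test_quarter_sampling_quadruples_rate(self):
        full = dissimilation_rate(make_inputs(F_s=1.0)).rate.value
        quarter = dissimilation_rate(make_inputs(F_s=0.25)).rate.value
        assert quarter == pytest.approx(4.0 * full, rel=1e-12)

    def test_killed_exceeding_treatment_flagged(self):
        res = dissimilation_rate(make_inputs(dpm_T=UFloat(400.0, 30.0),
                                             dpm_K=UFloat(500.0, 30.0),
                                             F_s=0.25))
        assert res.rate.value < 0
        assert not res.distinguishable_from_zero

    def test_worked_example_mirrors_assimilation(self):
        # same DPM provenance arithmetic; hand value is 4x the F_s=1 rate
        res = dissimilation_rate(make_inputs(F_s=0.25))
        assert res.rate.value == pytest.approx(28.0, abs=0.05)
        assert res.assay_mode == "dissimilation"


class TestLightDrivenRate:
    @staticmethod
    def result(value, sd, **kw):
        return RateResult(rate=UFloat(value, sd), net_dpm=0.0,
                          distinguishable_from_zero=True, **kw)

    def test_identical_results_cancel(self):
        x = self.result(5.0, 1.0)
        assert light_driven_rate(x, x).rate.value == 0.0

    def test_quadrature_error(self):
        diff = light_driven_rate(self.result(9.0, 1.5), self.result(2.0, 1.3))
        assert diff.rate.value == pytest.approx(7.0)
        assert diff.rate.sd == pytest.approx(math.hypot(1.5, 1.3))

    def test_dark_exceeding_light_not_clipped(self):
        diff = light_driven_rate(self.result(2.0, 0.5), self.result(5.0, 0.5))
        assert diff.rate.value == pytest.approx(-3.0)
        assert not diff.distinguishable_from_zero

    def test_substrate_mismatch_rejected(self):
        with pytest.raises(UsageError):
            light_driven_rate(self.result(9.0, 1.0, substrate="DIC"),
                              self.result(2.0, 1.0, substrate="acetate"))


class TestCompareTreatments:
    def test_identical_groups_p_half(self):
        cmp = compare_treatments([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        assert cmp.p_value == pytest.approx(0.5)
        assert not cmp.significant

    def test_clear_separation_significant(self):
        cmp = compare_treatments([9.0, 10.0, 11.0], [1.0, 2.0, 3.0])
        assert cmp.significant
        assert cmp.p_value < 0.01

    def test_zero_variance_groups_guarded(self):
        equal = compare_treatments([4.0, 4.0], [4.0, 4.0])
        assert equal.p_value == pytest.approx(0.5)
        higher = compare_treatments([5.0, 5.0], [4.0, 4.0])
        assert higher.p_value == 0.0

    def test_single_replicate_rejected(self):
        with pytest.raises(UsageError):
            compare_treatments([5.0], [4.0, 3.0])


class TestReplicateMean:
    def test_single_replicate_has_zero_sd(self):
        u = replicate_mean([123.0])
        assert u.value == 123.0 and u.sd == 0.0

    def test_triplicate_sd_of_mean_with_bias_correction(self):
        # s=1 over {9,10,11}; sd of mean = 1/(c4(3)*sqrt(3))
        u = replicate_mean([9.0, 10.0, 11.0])
        c4 = math.sqrt(2.0 / 2.0) * math.gamma(1.5) / math.gamma(1.0)
        assert u.value == pytest.approx(10.0)
        assert u.sd == pytest.approx(1.0 / (c4 * math.sqrt(3)))
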