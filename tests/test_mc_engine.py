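"""Distribution fitting, seeded sampling, class probabilities, exceedance."""

import numpy as np
import pytest
from scipy import stats

import sedrisk as sr
from sedrisk.mc_engine import element_seed


def tn(loc, scale, lo, hi):
    """Independent scipy truncated normal used as the closed-form oracle."""
    return stats.truncnorm((lo - loc) / scale, (hi - loc) / scale, loc=loc, scale=scale)


class TestFitFromSamples:
    def test_constant_sample_collapses_to_point_mass(self):
        spec = sr.fit_from_samples("Cd", [3.3, 3.3, 3.3])
        assert spec.family == "point_mass" and spec.location == 3.3

    def test_too_few_values_rejected(self):
        with pytest.raises(sr.InsufficientDataError):
            sr.fit_from_samples("Cd", [1.0])

    def test_negative_values_reject_lognormal(self):
        with pytest.raises(sr.DistributionError):
            sr.fit_from_samples("Cd", [1.0, -1.0, 2.0], family="lognormal")

    def test_normal_parameter_recovery(self):
        """Moment fit on 10,000 normal(100, 15) draws recovers both
        parameters to within 0.5."""
        rng = np.random.default_rng(42)
        values = rng.normal(100.0, 15.0, size=10_000)
        spec = sr.fit_from_samples("Zn", values, family="normal")
        assert spec.location == pytest.approx(100.0, abs=0.5)
        assert spec.scale == pytest.approx(15.0, abs=0.5)

    def test_truncated_normal_takes_observed_support(self):
        values = [10.0, 12.0, 20.0, 30.0]
        spec = sr.fit_from_samples("Zn", values)
        assert spec.family == "truncated_normal"
        assert spec.support == (10.0, 30.0)
        assert spec.location == pytest.approx(np.mean(values))


class TestFitFromSummary:
    def test_degenerate_summary_is_point_mass(self):
        spec = sr.fit_from_summary("Cd", 5.0, 5.0, 5.0)
        assert spec.family == "point_mass" and spec.location == 5.0

    def test_zn_summary_with_range_rule(self):
        spec = sr.fit_from_summary("Zn", 66.6, 1095.0, 353.0)
        assert spec.family == "truncated_normal"
        assert spec.location == 353.0
        assert spec.scale == pytest.approx((1095.0 - 66.6) / 4.0)  # 257.1
        assert spec.support == (66.6, 1095.0)

    def test_mean_outside_range_rejected(self):
        with pytest.raises(sr.DistributionError):
            sr.fit_from_summary("Cd", 0.0, 10.0, 11.0)

    def test_explicit_sd_and_named_rules(self):
        assert sr.fit_from_summary("Cd", 0.0, 12.0, 6.0, sd_rule="range6").scale == 2.0
        assert sr.fit_from_summary("Cd", 0.0, 12.0, 6.0, sd_rule=1.5).scale == 1.5


class TestDrawConcentrations:
    def test_point_mass_draws(self):
        spec = sr.DistributionSpec("Cd", "point_mass", 5.0, 0.0)
        assert sr.draw_concentrations(spec, 3, seed=0).tolist() == [5.0, 5.0, 5.0]

    def test_same_seed_gives_bitwise_identical_sequences(self):
        spec = sr.fit_from_summary("Zn", 66.6, 1095.0, 353.0)
        a = sr.draw_concentrations(spec, 10_000, seed=123)
        b = sr.draw_concentrations(spec, 10_000, seed=123)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, sr.draw_concentrations(spec, 10_000, seed=124))

    def test_truncated_draws_stay_in_support_with_correct_mean(self):
        """All draws inside [min, max]; empirical mean within 3 standard
        errors of the analytic truncated-normal mean."""
        spec = sr.fit_from_summary("Zn", 66.6, 1095.0, 353.0)
        draws = sr.draw_concentrations(spec, 100_000, seed=5)
        assert draws.min() >= 66.6 and draws.max() <= 1095.0
        oracle = tn(353.0, 257.1, 66.6, 1095.0)
        se = oracle.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - oracle.mean()) < 3 * se

    def test_plain_normal_rejects_negative_draws(self):
        spec = sr.DistributionSpec("As", "normal", 2.0, 3.0)
        draws = sr.draw_concentrations(spec, 50_000, seed=9)
        assert draws.min() >= 0.0

    def test_almost_surely_negative_normal_is_infeasible(self):
        spec = sr.DistributionSpec("As", "normal", -100.0, 1.0)
        with pytest.raises(sr.DistributionError):
            sr.draw_concentrations(spec, 100, seed=0)

    def test_empirical_bootstraps_stored_values(self):
        spec = sr.fit_from_samples("Cd", [1.0, 2.0, 4.0], family="empirical")
        draws = sr.draw_concentrations(spec, 1000, seed=3)
        assert set(np.unique(draws)) <= {1.0, 2.0, 4.0}


class TestClassProbabilities:
    def test_point_mass_low_risk_is_certain(self, reference_map):
        spec = sr.DistributionSpec("Zn", "point_mass", 66.6 * 10, 0.0)  # Er = 10
        result = sr.simulate_element_risk(spec, reference_map["Zn"], sr.MCConfig(iterations=1000, seed=1))
        assert result.class_probabilities.tolist() == [100.0, 0.0, 0.0, 0.0, 0.0]

    def test_probabilities_match_closed_form_cdf(self, reference_map):
        """MC class probabilities for a truncated-normal Cd-like law agree
        with the analytic CDF within 3*sqrt(p(1-p)/n) per class."""
        lo, hi, mean = 1.28, 10.5, 4.82
        sd = (hi - lo) / 4
        spec = sr.fit_from_summary("Cd", lo, hi, mean)
        ref = reference_map["Cd"]
        n = 100_000
        result = sr.simulate_element_risk(spec, ref, sr.MCConfig(iterations=n, seed=11))

        oracle = tn(mean, sd, lo, hi)
        bounds = [t * ref.background / ref.toxic_response for t in sr.DEFAULT_SCHEME.er_thresholds]
        cdf = np.concatenate([[0.0], oracle.cdf(bounds), [1.0]])
        analytic = 100.0 * np.diff(cdf)
        for p_mc, p in zip(result.class_probabilities, analytic):
            tol = 100.0 * 3.0 * np.sqrt((p / 100) * (1 - p / 100) / n)
            assert abs(p_mc - p) <= max(tol, 1e-9)

    def test_probabilities_sum_to_100_before_and_after_rounding(self, reference_map):
        spec = sr.fit_from_summary("Cd", 1.28, 10.5, 4.82)
        result = sr.simulate_element_risk(
            spec, reference_map["Cd"], sr.MCConfig(iterations=30_000, seed=2)
        )
        assert result.class_probabilities.sum() == pytest.approx(100.0, abs=1e-9)
        assert result.class_probabilities_rounded.sum() == pytest.approx(100.0, abs=0.05)

    def test_doubling_iterations_moves_probabilities_within_mc_error(self, reference_map):
        """Convergence: halving the MC error band brackets both runs."""
        spec = sr.fit_from_summary("Cd", 1.28, 10.5, 4.82)
        n = 50_000
        a = sr.simulate_element_risk(spec, reference_map["Cd"], sr.MCConfig(iterations=n, seed=21))
        b = sr.simulate_element_risk(spec, reference_map["Cd"], sr.MCConfig(iterations=2 * n, seed=22))
        bound = 3.0 * np.sqrt(0.25 / n) * 100.0
        assert np.all(np.abs(a.class_probabilities - b.class_probabilities) <= bound)

    def test_missing_reference_fields_excluded(self):
        spec = sr.fit_from_summary("Ni", 33.2, 274.0, 77.8)
        with pytest.raises(sr.ExcludedElementError):
            sr.simulate_element_risk(spec, sr.ReferenceEntry("Ni", None, 5.0))


class TestTotalRisk:
    def test_point_masses_reproduce_deterministic_index(self, reference):
        """Collapsing every law to a point mass at a site's measured
        concentrations makes the MC pipeline reproduce the deterministic
        assessment exactly (Er, RI and class labels)."""
        concentrations = {"Cd": 4.82, "Cr": 113.0, "Cu": 78.5, "Pb": 132.0, "Zn": 353.0}
        measurements = [
            sr.SampleMeasurement("S1", "r", "s", el, c) for el, c in concentrations.items()
        ]
        (det,), _ = sr.assess_sites(measurements, reference)

        specs = {el: sr.DistributionSpec(el, "point_mass", c, 0.0) for el, c in concentrations.items()}
        mc = sr.simulate_total_risk(specs, reference, sr.MCConfig(iterations=500, seed=3))

        for el, er in mc.elements.items():
            assert np.all(er.er_draws == det.elements[el].er)
        assert np.all(mc.ri_draws == det.ri)
        assert sr.classify_ri(mc.ri_draws[0]) == det.ri_class
        ri_idx = list(mc.ri_class_probabilities).index(100.0)
        assert sr.DEFAULT_SCHEME.ri_labels[ri_idx] == det.ri_class

    def test_single_element_ri_equals_its_er_draws(self, reference):
        specs = {"Cd": sr.fit_from_summary("Cd", 1.28, 10.5, 4.82)}
        mc = sr.simulate_total_risk(specs, reference, sr.MCConfig(iterations=5_000, seed=4))
        assert np.array_equal(mc.ri_draws, mc.elements["Cd"].er_draws)

    def test_ri_mean_is_sum_of_er_means(self, reference):
        """Linearity of expectation: MC mean of RI within 3 standard errors
        of the sum of the analytic Er means."""
        n = 50_000
        specs = {
            "Cd": sr.fit_from_summary("Cd", 1.28, 10.5, 4.82),
            "Zn": sr.fit_from_summary("Zn", 66.6, 1095.0, 353.0),
        }
        ref = sr.reference_by_element(reference)
        mc = sr.simulate_total_risk(specs, reference, sr.MCConfig(iterations=n, seed=6))
        analytic_mean = sum(
            ref[el].toxic_response * specs[el].mean() / ref[el].background for el in specs
        )
        analytic_var = sum(
            (ref[el].toxic_response / ref[el].background * specs[el].sd()) ** 2 for el in specs
        )
        se = np.sqrt(analytic_var / n)
        assert abs(mc.ri_draws.mean() - analytic_mean) < 3 * se

    def test_identical_config_reproduces_result_bitwise(self, reference):
        specs = sr.default_laws(["Cd", "Zn", "Pb"])
        a = sr.simulate_total_risk(specs, reference, sr.MCConfig(iterations=2_000, seed=8))
        b = sr.simulate_total_risk(specs, reference, sr.MCConfig(iterations=2_000, seed=8))
        assert np.array_equal(a.ri_draws, b.ri_draws)
        assert a.er_table().equals(b.er_table())

    def test_adding_an_element_never_perturbs_other_substreams(self, reference):
        small = sr.simulate_total_risk(
            sr.default_laws(["Cd", "Zn"]), reference, sr.MCConfig(iterations=2_000, seed=8)
        )
        big = sr.simulate_total_risk(
            sr.default_laws(["Cd", "Zn", "Pb", "Cu"]), reference, sr.MCConfig(iterations=2_000, seed=8)
        )
        for el in ("Cd", "Zn"):
            assert np.array_equal(small.elements[el].er_draws, big.elements[el].er_draws)

    def test_ineligible_elements_reported_not_simulated(self, reference):
        specs = sr.default_laws(["Cd", "Ni", "Co"])
        mc = sr.simulate_total_risk(specs, reference, sr.MCConfig(iterations=1_000, seed=1))
        assert set(mc.elements) == {"Cd"}
        assert mc.excluded == {
            "Ni": "background absent",
            "Co": "toxic_response absent",
        }

    def test_correlation_hook_inflates_ri_variance(self, reference):
        """With strongly positively correlated concentrations the RI
        variance exceeds the independent case."""
        specs = {
            "Cd": sr.fit_from_summary("Cd", 1.28, 10.5, 4.82),
            "Cu": sr.fit_from_summary("Cu", 11.5, 870.0, 78.5),
        }
        cfg = sr.MCConfig(iterations=20_000, seed=13)
        indep = sr.simulate_total_risk(specs, reference, cfg)
        corr = sr.simulate_total_risk(
            specs, reference, cfg, correlation=np.array([[1.0, 0.95], [0.95, 1.0]])
        )
        assert corr.ri_draws.var() > 1.5 * indep.ri_draws.var()


class TestExceedanceCurve:
    def test_single_draw(self):
        curve = sr.exceedance_curve([7.0])
        assert curve.values.tolist() == [[7.0, 1.0]]

    def test_counting_example(self):
        curve = sr.exceedance_curve([1.0, 2.0, 3.0, 4.0])
        assert curve["exceedance_probability"].tolist() == [1.0, 0.75, 0.5, 0.25]

    def test_empty_input_rejected(self):
        with pytest.raises(sr.SedRiskError):
            sr.exceedance_curve([])

    def test_curve_nonincreasing_and_starts_at_one(self, rng):
        for _ in range(20):
            draws = rng.lognormal(2.0, 1.0, size=rng.integers(1, 500))
            curve = sr.exceedance_curve(draws)
            probs = curve["exceedance_probability"].to_numpy()
            assert probs[0] == 1.0
            assert np.all(np.diff(probs) <= 0)
            assert curve["value"].is_monotonic_increasing


class TestSubstreams:
    def test_element_seed_is_stable_and_element_specific(self):
        a = element_seed(7, "Cd").generate_state(4)
        b = element_seed(7, "Cd").generate_state(4)
        c = element_seed(7, "Zn").generate_state(4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
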