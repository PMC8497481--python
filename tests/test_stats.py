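"""Population error decomposition and hypothesis-test tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import itvmargin as m
from itvmargin.exceptions import InsufficientDataError, UndefinedStatisticError
from itvmargin.stats import PopulationError


def tidy(values_by_patient, component="baseline"):
    """Build a tidy delta table from {patient: [values]}, same values on every axis."""
    rows = []
    for pid, vals in values_by_patient.items():
        for k, v in enumerate(vals, start=2):
            for axis in ("LR", "SI", "AP"):
                rows.append(
                    {
                        "patient_id": pid,
                        "fraction": k,
                        "axis": axis,
                        "baseline_delta_mm": v if component == "baseline" else 0.0,
                        "amplitude_delta_mm": v if component == "amplitude" else 0.0,
                    }
                )
    return pd.DataFrame(rows)


def brute_force_sigma(values_by_patient):
    """Independent oracle: Sigma = SD over patients of per-patient means."""
    means = [np.mean(v) for v in values_by_patient.values()]
    return float(np.std(means, ddof=1))


def brute_force_rms_sd(values_by_patient):
    """Independent oracle: sigma = RMS over patients of per-patient sample SDs."""
    sds = [np.std(v, ddof=1) for v in values_by_patient.values()]
    return float(np.sqrt(np.mean(np.square(sds))))


class TestPatientSummaries:
    def test_textbook_values(self):
        d = tidy({"P1": [1, 2, 3]})
        summ = m.patient_summaries(d)
        row = summ[summ.axis == "SI"].iloc[0]
        assert row["mean_mm"] == pytest.approx(2.0)
        assert row["sd_mm"] == pytest.approx(1.0)

    def test_identical_deltas_have_zero_sd(self):
        summ = m.patient_summaries(tidy({"P1": [2, 2, 2]}))
        assert summ[summ.axis == "SI"]["sd_mm"].iloc[0] == 0.0

    def test_two_point_sd(self):
        summ = m.patient_summaries(tidy({"P1": [-2, 2]}))
        row = summ[summ.axis == "SI"].iloc[0]
        assert row["mean_mm"] == pytest.approx(0.0)
        assert row["sd_mm"] == pytest.approx(np.sqrt(8.0))  # 2.828...

    def test_single_row_raises_unless_population_mode(self):
        with pytest.raises(InsufficientDataError):
            m.patient_summaries(tidy({"P1": [1.0]}))
        summ = m.patient_summaries(tidy({"P1": [1.0]}), ddof=0)
        assert summ["sd_mm"].iloc[0] == 0.0


class TestSigmaAndSigmaRand:
    def test_sigma_textbook(self):
        d = tidy({"P1": [1, 1], "P2": [2, 2], "P3": [3, 3]})
        summ = m.patient_summaries(d)
        assert m.systematic_error(summ)["SI"] == pytest.approx(1.0)

    def test_sigma_zero_for_identical_patients(self):
        d = tidy({"P1": [1, 3], "P2": [3, 1], "P3": [2, 2]})
        assert m.systematic_error(m.patient_summaries(d))["SI"] == pytest.approx(0.0)

    def test_random_error_rms(self):
        # patient SDs 3 and 4 -> RMS sqrt(12.5)
        d = tidy({"P1": [0, 3 * np.sqrt(2)], "P2": [0, 4 * np.sqrt(2)]})
        assert m.random_error(m.patient_summaries(d))["SI"] == pytest.approx(np.sqrt(12.5))

    def test_all_equal_sds_give_that_sd(self):
        d = tidy({"P1": [0, 2], "P2": [5, 7], "P3": [-3, -1]})
        sd = np.std([0, 2], ddof=1)
        assert m.random_error(m.patient_summaries(d))["SI"] == pytest.approx(sd)

    def test_fewer_than_two_patients_raises(self):
        with pytest.raises(InsufficientDataError):
            m.systematic_error(m.patient_summaries(tidy({"P1": [1, 2]})))

    def test_matches_brute_force_on_random_toy_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            vals = {f"P{i}": rng.normal(0, 3, rng.integers(2, 7)).tolist() for i in range(5)}
            d = tidy(vals)
            err = m.population_error(d, "baseline")
            j = 1  # SI index
            assert err.systematic_mm[j] == pytest.approx(brute_force_sigma(vals), rel=1e-12)
            assert err.random_mm[j] == pytest.approx(brute_force_rms_sd(vals), rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        vals = {f"P{i}": rng.normal(0, 2, 4).tolist() for i in range(6)}
        err1 = m.population_error(tidy(vals), "baseline")
        shuffled = {pid: list(reversed(v)) for pid, v in reversed(list(vals.items()))}
        err2 = m.population_error(tidy(shuffled), "baseline")
        assert np.allclose(err1.systematic_mm, err2.systematic_mm)
        assert np.allclose(err1.random_mm, err2.random_mm)

    def test_monte_carlo_recovery_pure_systematic(self):
        cfg = m.CohortConfig(
            n_patients=1000, n_fractions=5,
            baseline_mean=0, baseline_systematic=2.0, baseline_random=0,
            amplitude_mean=0, amplitude_systematic=0, amplitude_random=1.0,
            rho=0, seed=21,
        )
        err = m.population_error(m.delta_table(m.simulate_cohort(cfg)), "baseline")
        # per-axis sampling SE of Sigma_hat is ~2/sqrt(2*999) ~ 0.045; the three
        # axes are iid replicates, so the 5% check applies to their mean
        assert np.mean(err.systematic_mm) == pytest.approx(2.0, rel=0.05)
        assert np.allclose(err.systematic_mm, 2.0, rtol=0.10)
        assert np.allclose(err.random_mm, 0.0, atol=1e-9)

    def test_monte_carlo_recovery_pure_random(self):
        cfg = m.CohortConfig(
            n_patients=2000, n_fractions=9,
            baseline_mean=0, baseline_systematic=0, baseline_random=2.0,
            amplitude_mean=0, amplitude_systematic=0, amplitude_random=1.0,
            rho=0, seed=23,
        )
        err = m.population_error(m.delta_table(m.simulate_cohort(cfg)), "baseline")
        assert np.allclose(err.random_mm, 2.0, rtol=0.05)

    def test_sigma_hat_carries_finite_fraction_bias(self):
        # E[Sigma_hat^2] = Sigma^2 + sigma^2/(F-1): with Sigma=1, sigma=2, F=5
        # deltas per patient = 4, so Sigma_hat -> sqrt(1 + 1) = sqrt(2), not 1.
        cfg = m.CohortConfig(
            n_patients=3000, n_fractions=5,
            baseline_mean=0, baseline_systematic=1.0, baseline_random=2.0,
            amplitude_mean=0, amplitude_systematic=0, amplitude_random=1.0,
            rho=0, seed=29,
        )
        err = m.population_error(m.delta_table(m.simulate_cohort(cfg)), "baseline")
        assert np.allclose(err.systematic_mm, np.sqrt(2.0), rtol=0.06)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(scale=st.floats(0.1, 10), seed=st.integers(0, 1000))
    def test_scale_equivariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        vals = {f"P{i}": rng.normal(0, 2, 4).tolist() for i in range(4)}
        scaled = {pid: [scale * v for v in vs] for pid, vs in vals.items()}
        e1 = m.population_error(tidy(vals), "baseline")
        e2 = m.population_error(tidy(scaled), "baseline")
        assert np.allclose(e2.systematic_mm, scale * e1.systematic_mm, rtol=1e-9)
        assert np.allclose(e2.random_mm, scale * e1.random_mm, rtol=1e-9)


class TestCombineComponents:
    def test_quadrature_of_printed_lr_components(self):
        base = PopulationError("baseline", (0.6, 0, 0), (0.7, 0, 0))
        amp = PopulationError("amplitude", (0.9, 0, 0), (0.9, 0, 0))
        comb = m.combine_components(base, amp)
        assert comb.systematic_mm[0] == pytest.approx(np.sqrt(0.6**2 + 0.9**2))  # ~1.082
        assert comb.random_mm[0] == pytest.approx(np.sqrt(0.7**2 + 0.9**2))  # ~1.140

    def test_zero_second_component_is_identity(self):
        base = PopulationError("baseline", (1, 2, 3), (0.5, 0.6, 0.7))
        zero = PopulationError("amplitude", (0, 0, 0), (0, 0, 0))
        comb = m.combine_components(base, zero)
        assert np.allclose(comb.systematic_mm, base.systematic_mm)
        assert np.allclose(comb.random_mm, base.random_mm)

    def test_commutative_and_bounded(self):
        rng = np.random.default_rng(3)
        a = PopulationError("baseline", rng.uniform(0, 3, 3), rng.uniform(0, 3, 3))
        b = PopulationError("amplitude", rng.uniform(0, 3, 3), rng.uniform(0, 3, 3))
        ab = m.combine_components(a, b)
        ba = m.combine_components(b, a)
        assert np.allclose(ab.systematic_mm, ba.systematic_mm)
        lo = np.maximum(a.systematic_mm, b.systematic_mm)
        hi = a.systematic_mm + b.systematic_mm
        assert np.all(ab.systematic_mm >= lo - 1e-12) and np.all(ab.systematic_mm <= hi + 1e-12)


class TestPairedDirectionTest:
    @staticmethod
    def _pairs(a_vals, b_vals, axis_a="SI", axis_b="AP"):
        rows = []
        for k, (a, b) in enumerate(zip(a_vals, b_vals), start=2):
            for axis, v in ((axis_a, a), (axis_b, b)):
                rows.append(
                    {
                        "patient_id": "P1",
                        "fraction": k,
                        "axis": axis,
                        "baseline_delta_mm": v,
                        "amplitude_delta_mm": 0.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_samples_give_t0_p1(self):
        d = self._pairs([1, 2, 3], [1, 2, 3])
        res = m.paired_direction_test(d, "baseline", "SI", "AP")
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_closed_form_t(self):
        # |pairs| (1,0),(2,0),(3,0): differences 1,2,3 -> t = 2/(1/sqrt(3)) = sqrt(12)
        d = self._pairs([1, 2, 3], [0, 0, 0])
        res = m.paired_direction_test(d, "baseline", "SI", "AP")
        assert res.statistic == pytest.approx(np.sqrt(12.0))
        assert res.pvalue == pytest.approx(0.0742, abs=2e-4)

    def test_absolute_flag(self):
        d = self._pairs([-3, -4, -5], [1, 1, 1])
        res_abs = m.paired_direction_test(d, "baseline", "SI", "AP", absolute=True)
        res_signed = m.paired_direction_test(d, "baseline", "SI", "AP", absolute=False)
        assert res_abs.statistic > 0  # |SI| exceeds |AP|
        assert res_signed.statistic < 0  # signed SI below AP

    def test_larger_magnitude_axis_detected(self):
        rng = np.random.default_rng(31)
        d = self._pairs(rng.normal(0, 3, 60), rng.normal(0, 1, 60))
        res = m.paired_direction_test(d, "baseline", "SI", "AP")
        assert res.statistic > 0 and res.pvalue < 0.01

    def test_too_few_pairs_raise(self):
        with pytest.raises(InsufficientDataError):
            m.paired_direction_test(self._pairs([1], [2]), "baseline", "SI", "AP")


class TestCorrelationAndNormality:
    def test_exact_linear_relation_gives_r1(self):
        rows = []
        for k, v in enumerate([1.0, 2.0, 3.0, 4.0], start=2):
            rows.append(
                {"patient_id": "P1", "fraction": k, "axis": "SI",
                 "baseline_delta_mm": v, "amplitude_delta_mm": 2 * v}
            )
        res = m.baseline_amplitude_correlation(pd.DataFrame(rows), "SI")
        assert res.statistic == pytest.approx(1.0)

    def test_independent_large_n_near_zero(self):
        rng = np.random.default_rng(37)
        n = 10_000
        rows = pd.DataFrame(
            {"patient_id": "P1", "fraction": np.arange(2, n + 2), "axis": "SI",
             "baseline_delta_mm": rng.normal(0, 1, n), "amplitude_delta_mm": rng.normal(0, 1, n)}
        )
        assert abs(m.baseline_amplitude_correlation(rows, "SI").statistic) < 0.05

    def test_zero_variance_raises(self):
        rows = pd.DataFrame(
            {"patient_id": "P1", "fraction": [2, 3, 4], "axis": "SI",
             "baseline_delta_mm": [1.0, 1.0, 1.0], "amplitude_delta_mm": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(UndefinedStatisticError):
            m.baseline_amplitude_correlation(rows, "SI")

    def test_normality_flags(self):
        rng = np.random.default_rng(41)
        normal_flags = []
        for trial in range(10):
            d = tidy({"P1": rng.standard_normal(76).tolist()})
            normal_flags.append(m.normality_check(d, "baseline", "SI").normal)
        assert sum(normal_flags) >= 9  # standard-normal draws accepted as normal
        d_exp = tidy({"P1": rng.exponential(1.0, 500).tolist()})
        assert m.normality_check(d_exp, "baseline", "SI").normal is False

    def test_constant_input_not_evaluable(self):
        res = m.normality_check(tidy({"P1": [1.0, 1.0, 1.0]}), "baseline", "SI")
        assert res.normal is None and np.isnan(res.statistic)
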