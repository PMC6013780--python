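"""Analytic birth-death clone model: propagator, fixation, induction, fit."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryptdrift.drift import (
    ClonePMF,
    CryptDriftModel,
    DriftParams,
    InductionParams,
    calibrate_induction,
    class_probabilities,
    clone_size_distribution,
    expected_class_fractions,
    expected_size_masses,
    fit_analytic,
    fixation_probability,
    induction_rate,
    quasi_steady_partial_pmf,
)

AGES = np.array([18.5, 25.5, 35.5, 45.5, 55.5, 65.5, 75.5])


class TestParams:
    def test_rates(self):
        p = DriftParams(n_sc=5, lambda_rate=0.6, bias=0.2)
        assert p.up_rate == pytest.approx(0.72)
        assert p.down_rate == pytest.approx(0.48)

    @pytest.mark.parametrize(
        "kwargs",
        [{"n_sc": 1}, {"lambda_rate": -0.1}, {"bias": 1.0}, {"bias": -1.5}],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            DriftParams(**kwargs)

    def test_induction_validation(self):
        with pytest.raises(ValueError):
            InductionParams(r0=-1.0)

    def test_clone_pmf_must_normalise(self):
        with pytest.raises(ValueError):
            ClonePMF(np.array([0.5, 0.4]))
        with pytest.raises(ValueError):
            ClonePMF(np.array([1.5, -0.5]))


class TestInductionLaw:
    def test_rate_at_age_20(self):
        assert induction_rate(20.0, InductionParams()) == pytest.approx(
            0.05 * np.e, rel=1e-12
        )

    def test_rate_at_age_70(self):
        assert induction_rate(70.0, InductionParams()) == pytest.approx(
            0.05 * np.exp(3.5), rel=1e-12
        )

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            induction_rate(-1.0, InductionParams())

    def test_cumulative_matches_numeric_integral(self):
        ind = InductionParams(r0=0.05, eta=0.05)
        t = np.linspace(0, 80, 20001)
        numeric = np.trapezoid(ind.absolute_rate(t), t)
        assert ind.cumulative_absolute(80.0) == pytest.approx(numeric, rel=1e-6)

    def test_calibration_recovers_constants(self):
        truth = InductionParams(r0=0.05, eta=0.05)
        ages = np.arange(10.0, 81.0, 5.0)
        y = [truth.cumulative_absolute(a) for a in ages]
        est = calibrate_induction(ages, y)
        assert est.r0 == pytest.approx(truth.r0, rel=1e-4)
        assert est.eta == pytest.approx(truth.eta, rel=1e-4)


def _gillespie(params: DriftParams, t_end: float, n0: int, reps: int, rng):
    """Direct stochastic simulation of the birth-death chain (MC oracle)."""
    n = params.n_sc
    out = np.empty(reps, dtype=int)
    up, down = params.up_rate, params.down_rate
    for i in range(reps):
        state, t = n0, 0.0
        while 0 < state < n:
            total = up + down
            t += rng.exponential(1.0 / total)
            if t > t_end:
                break
            state += 1 if rng.random() < up / total else -1
        out[i] = state
    return out


class TestPropagator:
    def test_pmf_normalised_and_initial_condition(self):
        p = DriftParams()
        pmf0 = clone_size_distribution(p, 0.0, 2)
        assert pmf0[2] == pytest.approx(1.0)
        pmf = clone_size_distribution(p, 3.0, 1)
        assert pmf.probabilities.sum() == pytest.approx(1.0)
        assert np.all(pmf.probabilities >= 0)

    def test_long_time_neutral_absorption(self):
        p = DriftParams(n_sc=5, lambda_rate=0.6, bias=0.0)
        pmf = clone_size_distribution(p, 500.0, 2)
        assert pmf[5] == pytest.approx(2.0 / 5.0, abs=1e-6)
        assert pmf[0] == pytest.approx(3.0 / 5.0, abs=1e-6)

    def test_matches_gillespie_oracle(self, rng):
        """Stochastic simulation of the chain agrees with the matrix
        propagator state by state within 3 MC standard errors."""
        p = DriftParams(n_sc=5, lambda_rate=0.6, bias=0.2)
        t, reps = 2.0, 20_000
        sim = _gillespie(p, t, 1, reps, rng)
        pmf = clone_size_distribution(p, t, 1).probabilities
        for state in range(6):
            frac = np.mean(sim == state)
            se = max(np.sqrt(pmf[state] * (1 - pmf[state]) / reps), 1e-4)
            assert abs(frac - pmf[state]) < 3 * se

    def test_invalid_arguments(self):
        p = DriftParams()
        with pytest.raises(ValueError):
            clone_size_distribution(p, -1.0, 1)
        with pytest.raises(ValueError):
            clone_size_distribution(p, 1.0, 9)


class TestFixation:
    @pytest.mark.parametrize("n_sc", [3, 5, 7])
    def test_neutral_case_is_n0_over_n(self, n_sc):
        p = DriftParams(n_sc=n_sc, bias=0.0)
        for n0 in range(n_sc + 1):
            assert fixation_probability(p, n0) == pytest.approx(n0 / n_sc)

    def test_biased_case_matches_linear_solve(self):
        """Closed form vs the first-step (harmonic) linear system."""
        p = DriftParams(n_sc=6, lambda_rate=1.0, bias=0.3)
        n = p.n_sc
        a = np.zeros((n + 1, n + 1))
        b = np.zeros(n + 1)
        a[0, 0] = 1.0
        a[n, n] = 1.0
        b[n] = 1.0
        tot = p.up_rate + p.down_rate
        for i in range(1, n):
            a[i, i] = 1.0
            a[i, i + 1] = -p.up_rate / tot
            a[i, i - 1] = -p.down_rate / tot
        h = np.linalg.solve(a, b)
        for n0 in range(n + 1):
            assert fixation_probability(p, n0) == pytest.approx(h[n0], rel=1e-10)

    @given(
        bias=st.floats(-0.9, 0.9),
        n0=st.integers(0, 5),
    )
    @settings(max_examples=60, deadline=None)
    def test_bounds_and_monotonicity_in_n0(self, bias, n0):
        p = DriftParams(n_sc=5, bias=bias)
        f = fixation_probability(p, n0)
        assert 0.0 <= f <= 1.0
        if n0 < 5:
            assert fixation_probability(p, n0 + 1) >= f


class TestQuasiSteady:
    def test_neutral_shape_is_linear_decay(self):
        pmf = quasi_steady_partial_pmf(DriftParams(n_sc=5, lambda_rate=0.6))
        np.testing.assert_allclose(pmf, np.array([4, 3, 2, 1]) / 10.0, atol=1e-12)

    def test_shape_is_independent_of_lambda(self):
        a = quasi_steady_partial_pmf(DriftParams(lambda_rate=0.3))
        b = quasi_steady_partial_pmf(DriftParams(lambda_rate=3.0))
        np.testing.assert_allclose(a, b, atol=1e-12)

    @pytest.mark.parametrize("n_sc", [3, 5, 8])
    def test_modal_size_is_one(self, n_sc):
        """Surviving partial clones peak at a single stem cell, i.e. a
        fraction 1/N of the circumference."""
        pmf = quasi_steady_partial_pmf(DriftParams(n_sc=n_sc, lambda_rate=0.6))
        assert np.argmax(pmf) == 0


class TestExpectedMasses:
    def test_zero_at_birth(self):
        m = expected_size_masses(DriftParams(), InductionParams(), 0.0)
        assert np.all(m == 0)

    def test_matches_brute_force_quadrature(self):
        drift, ind = DriftParams(), InductionParams()
        age = 60.0
        m = expected_size_masses(drift, ind, age)
        t = np.linspace(0, age, 4001)
        rows = np.vstack(
            [clone_size_distribution(drift, age - s, 1).probabilities for s in t]
        )
        brute = np.trapezoid(ind.absolute_rate(t)[:, None] * rows, t, axis=0)
        np.testing.assert_allclose(m, brute, rtol=1e-4, atol=1e-10)

    def test_class_probabilities_are_coherent(self):
        p = class_probabilities(DriftParams(), InductionParams(), 70.0)
        assert 0 <= p["partial"] <= 1 and 0 <= p["full"] <= 1
        assert p["normal"] + p["partial"] + p["full"] == pytest.approx(1.0)
        assert p["partial_k"].sum() == pytest.approx(p["partial"], abs=1e-9)

    def test_small_induction_limit(self):
        """When induction is rare, P(full) reduces to the expected number of
        fixed clones."""
        ind = InductionParams(r0=1e-4, eta=0.05)
        m = expected_size_masses(DriftParams(), ind, 70.0)
        p = class_probabilities(DriftParams(), ind, 70.0)
        assert p["full"] == pytest.approx(m[-1], rel=1e-3)

    def test_overlap_warning_when_induction_heavy(self):
        with pytest.warns(RuntimeWarning, match="cumulative induction"):
            expected_class_fractions(DriftParams(), InductionParams(r0=0.5), 80.0)

    def test_fixed_fraction_is_monotone_in_bias(self):
        """A fate bias towards the clone raises the fixed-crypt fraction."""
        fulls = [
            class_probabilities(
                DriftParams(bias=b), InductionParams(), 70.0
            )["full"]
            for b in (-0.2, 0.0, 0.2)
        ]
        assert fulls[0] < fulls[1] < fulls[2]


class TestModelResults:
    def _noiseless_data(self, params=None):
        model = CryptDriftModel(
            __import__("pandas").DataFrame({"age": AGES, "pct_partial": 0.0,
                                            "pct_full": 0.0})
        )
        pred = model.predict(params or model.start)
        pred["n_patients"] = [2, 10, 25, 44, 37, 21, 9]
        return pred

    def test_lambda_recovered_from_noiseless_data(self):
        data = self._noiseless_data()
        res = fit_analytic(
            data,
            free=("lambda_rate",),
            fixed={"lambda_rate": 1.2, "bias": 0.0, "r0": 0.05, "eta": 0.05},
        )
        assert res.success
        assert res.params["lambda_rate"] == pytest.approx(0.6, rel=1e-3)
        assert res.rss < 1e-10

    def test_neutral_bias_recovered_near_zero(self):
        data = self._noiseless_data()
        res = fit_analytic(
            data,
            free=("bias",),
            fixed={"lambda_rate": 0.6, "bias": 0.3, "r0": 0.05, "eta": 0.05},
        )
        assert abs(res.params["bias"]) < 0.05

    def test_profile_has_minimum_at_fit(self):
        data = self._noiseless_data()
        res = fit_analytic(
            data,
            free=("lambda_rate",),
            fixed={"lambda_rate": 1.0, "bias": 0.0, "r0": 0.05, "eta": 0.05},
        )
        prof = res.profile("lambda_rate", [0.3, 0.6, 1.2])
        assert prof["rss"].idxmin() == 1

    def test_summary_reports_parameters(self):
        data = self._noiseless_data()
        res = fit_analytic(data, free=("lambda_rate",))
        text = res.summary()
        for name in ("lambda_rate", "bias", "r0", "eta"):
            assert name in text
        assert "converged" in text

    def test_model_validation(self):
        import pandas as pd

        with pytest.raises(ValueError, match="age"):
            CryptDriftModel(pd.DataFrame({"pct_full": [1.0, 2.0]}))
        with pytest.raises(ValueError, match="pct_partial"):
            CryptDriftModel(pd.DataFrame({"age": [30.0, 50.0], "pct_full": [1, 2]}))
        small = pd.DataFrame(
            {"age": [30.0, 50.0], "pct_partial": [1, 2], "pct_full": [1, 2]}
        )
        with pytest.raises(ValueError, match="unknown parameter"):
            CryptDriftModel(small).fit(free=("bogus",))
        with pytest.raises(ValueError, match="non-identifiable"):
            CryptDriftModel(small).fit(free=("lambda_rate", "r0", "eta"))


class TestRatioNearConstancy:
    def test_partial_full_ratio_varies_slowly_with_age(self):
        """At the default parameters the model's partial:full ratio changes
        far more slowly than either prevalence across adulthood."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            probs = [
                class_probabilities(DriftParams(), InductionParams(), a)
                for a in np.arange(40.0, 81.0, 5.0)
            ]
        partial = np.array([p["partial"] for p in probs])
        full = np.array([p["full"] for p in probs])
        ratio = partial / full
        fold_ratio = ratio.max() / ratio.min()
        fold_full = full.max() / full.min()
        assert fold_ratio < 2.0
        assert fold_ratio < 0.25 * fold_full
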