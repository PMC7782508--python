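"""Psychometric functions and the spatiotemporal visibility map."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from elmsearch.evidence import evidence_moments
from elmsearch.synthetic import make_contrast_trials, noiseless_visibility_samples
from elmsearch.visibility import (
    PsychometricCurve,
    TemporalVisibility,
    VisibilityFieldParams,
    dprime_from_rates,
    dprime_timecourse,
    fit_visibility_field,
    fit_weibull,
    visibility_params_at,
    weibull_rate,
)


class TestWeibullRate:
    @pytest.mark.parametrize(
        "contrast, expected",
        [
            (0.0, 0.5),
            (10.0, 1.0),  # far above threshold: exponential vanishes
            (0.08, 0.5 + 0.5 * (1 - np.exp(-1.0))),  # at threshold, any s
        ],
    )
    def test_values(self, contrast, expected):
        curve = PsychometricCurve(threshold=0.08, steepness=2.5)
        assert weibull_rate(contrast, curve) == pytest.approx(expected, abs=1e-9)

    @given(st.floats(0.01, 0.5), st.floats(0.5, 6.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_nondecreasing(self, ct, s):
        curve = PsychometricCurve(threshold=ct, steepness=s)
        grid = np.linspace(0.0, 1.0, 200)
        rates = weibull_rate(grid, curve)
        assert np.all(np.diff(rates) >= -1e-12)
        assert rates[0] == pytest.approx(0.5)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PsychometricCurve(threshold=-0.1, steepness=2.0)
        with pytest.raises(ValueError):
            PsychometricCurve(threshold=0.1, steepness=0.0)


class TestFitWeibull:
    def test_parameter_recovery(self, rng):
        truth = PsychometricCurve(threshold=0.08, steepness=2.5)
        trials = make_contrast_trials(
            truth, [0.03, 0.05, 0.08, 0.10, 0.12], 1000, rng
        )
        fit = fit_weibull(trials, which="hit")
        assert fit.threshold == pytest.approx(truth.threshold, rel=0.10)
        assert fit.steepness == pytest.approx(truth.steepness, rel=0.10)

    def test_exact_rates_reproduced(self):
        # two levels whose empirical rates sit exactly on a Weibull curve:
        # the two-parameter MLE reproduces them to numerical precision
        c1, c2, n = 0.08, 0.16, 1000
        s = np.log(np.log(10) / np.log(2)) / np.log(2)
        ct = c1 / np.log(2) ** (1 / s)
        p1, p2 = 0.75, 0.95  # rates implied by (ct, s) at c1, c2
        rows = []
        for c, p in ((c1, p1), (c2, p2)):
            k = int(round(n * p))
            rows.append(pd.DataFrame({
                "contrast": c,
                "interval_with_target": 1,
                "response_interval": [1] * k + [2] * (n - k),
            }))
        fit = fit_weibull(pd.concat(rows, ignore_index=True), which="hit")
        assert weibull_rate(c1, fit) == pytest.approx(p1, abs=1e-6)
        assert weibull_rate(c2, fit) == pytest.approx(p2, abs=1e-6)

    def test_degenerate_tables_rejected(self):
        all_correct = pd.DataFrame({
            "contrast": [0.05] * 50 + [0.1] * 50,
            "interval_with_target": 1,
            "response_interval": 1,
        })
        with pytest.raises(ValueError, match="identical"):
            fit_weibull(all_correct, which="hit")
        single_level = pd.DataFrame({
            "contrast": 0.05,
            "interval_with_target": [1] * 100,
            "response_interval": [1] * 50 + [2] * 50,
        })
        with pytest.raises(ValueError, match="distinct contrast"):
            fit_weibull(single_level, which="hit")


class TestDprimeFromRates:
    def test_chance_gives_zero(self):
        assert dprime_from_rates(0.5, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_two_sigma(self):
        r = stats.norm.cdf(2.0)
        assert dprime_from_rates(r, r) == pytest.approx(4 / np.sqrt(2), abs=1e-9)

    def test_against_tabulated_inverse_normal(self):
        # z(0.9) = 1.2815515655... (standard normal table)
        assert dprime_from_rates(0.9, 0.5) == pytest.approx(
            1.2815515655 / np.sqrt(2), abs=1e-8
        )

    @given(st.floats(0.01, 0.99))
    @settings(max_examples=25, deadline=None)
    def test_antisymmetry(self, f):
        assert dprime_from_rates(f, f) == pytest.approx(
            -dprime_from_rates(1 - f, 1 - f), abs=1e-9
        )

    def test_boundary_rate_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            d = dprime_from_rates(1.0, 0.9, n_trials=100)
        assert np.isfinite(d)
        with pytest.raises(ValueError, match="n_trials"):
            dprime_from_rates(1.0, 0.9)


class TestDprimeTimecourse:
    def test_zero_exposure(self):
        tv = TemporalVisibility(a=5.0, k=8.0)
        assert dprime_timecourse(0.0, tv) == 0.0

    def test_monotone_to_asymptote(self):
        tv = TemporalVisibility(a=5.0, k=8.0)
        ts = np.linspace(0, 5, 500)
        d = dprime_timecourse(ts, tv)
        assert np.all(np.diff(d) > -1e-12)
        assert d[-1] == pytest.approx(tv.steady_state_dprime, rel=1e-6)

    def test_perfect_integration_limit(self):
        # k -> 0 recovers the diffusive growth a sqrt(T/2)
        tv = TemporalVisibility(a=3.0, k=1e-8)
        T = 0.7
        assert dprime_timecourse(T, tv) == pytest.approx(
            3.0 * np.sqrt(T / 2), rel=1e-6
        )

    def test_matches_evidence_moment_dprime(self, rng):
        # d'(T) must equal 2 * mean / sd of the accumulated evidence
        for _ in range(100):
            a = rng.uniform(0.5, 15)
            k = rng.uniform(0.5, 40)
            T = rng.uniform(0.01, 1.5)
            tv = TemporalVisibility(a=a, k=k)
            mean, var = evidence_moments(T, tv, target_present=True)
            assert dprime_timecourse(T, tv) == pytest.approx(
                2 * mean / np.sqrt(var), abs=1e-9, rel=1e-9
            )


class TestVisibilityField:
    def test_foveal_values(self):
        p = VisibilityFieldParams(10.0, 0.3, 12.0, 0.2, 1.5)
        tv = visibility_params_at(0.0, 0.0, p)
        assert (tv.a, tv.k) == (10.0, 12.0)

    def test_vertical_anisotropy(self):
        p = VisibilityFieldParams(10.0, 0.3, 12.0, 0.2, 1.5)
        for e in (1.0, 3.0, 6.0):
            assert visibility_params_at(e, 0, p).a > visibility_params_at(0, e, p).a

    def test_weighted_radius(self):
        p = VisibilityFieldParams(10.0, 0.3, 12.0, 0.2, 1.0)
        tv = visibility_params_at(3.0, 4.0, p)  # radius 5 for p5 = 1
        assert tv.a == pytest.approx(10.0 * np.exp(-0.3 * 5.0), rel=1e-12)

    def test_nonpositive_params_rejected(self):
        with pytest.raises(ValueError):
            VisibilityFieldParams(10.0, 0.0, 12.0, 0.2, 1.5)


class TestFitVisibilityField:
    TRUTH = VisibilityFieldParams(9.0, 0.35, 11.0, 0.22, 1.3)

    def test_noiseless_recovery_within_5pct(self):
        samples = noiseless_visibility_samples(self.TRUTH)
        fit, mse = fit_visibility_field(samples, n_starts=24, seed=0)
        for name in ("p1", "p2", "p3", "p4", "p5"):
            assert getattr(fit, name) == pytest.approx(
                getattr(self.TRUTH, name), rel=0.05
            ), name

    def test_objective_not_worse_than_truth(self):
        samples = noiseless_visibility_samples(self.TRUTH)
        _, mse = fit_visibility_field(samples, n_starts=24, seed=0)
        assert mse <= 1e-8  # the generating parameters give exactly 0

    def test_weight_duplication_invariance(self):
        samples = noiseless_visibility_samples(self.TRUTH)
        doubled = pd.concat([samples, samples], ignore_index=True)
        f1, _ = fit_visibility_field(samples, n_starts=8, seed=3)
        f2, _ = fit_visibility_field(doubled, n_starts=8, seed=3)
        assert f1.as_array() == pytest.approx(f2.as_array(), rel=1e-4)

    def test_noisy_recovery_of_foveal_steady_dprime(self, rng):
        samples = noiseless_visibility_samples(self.TRUTH)
        samples = samples.copy()
        samples["dprime"] = np.maximum(
            samples["dprime"] + rng.normal(0, 0.2, len(samples)), 0.0
        )
        fit, _ = fit_visibility_field(samples, n_starts=16, seed=1)
        truth_ss = self.TRUTH.p1 / np.sqrt(self.TRUTH.p3)
        assert fit.p1 / np.sqrt(fit.p3) == pytest.approx(truth_ss, rel=0.10)

    def test_two_stage_close_to_truth(self):
        samples = noiseless_visibility_samples(self.TRUTH)
        fit, _ = fit_visibility_field(samples, two_stage=True, seed=0)
        for name in ("p1", "p2", "p3", "p4", "p5"):
            assert getattr(fit, name) == pytest.approx(
                getattr(self.TRUTH, name), rel=0.05
            ), name

    def test_insufficient_coverage_rejected(self):
        samples = noiseless_visibility_samples(self.TRUTH)
        one_exposure = samples[samples["exposure_s"] == 0.2]
        with pytest.raises(ValueError, match="non-identifiable"):
            fit_visibility_field(one_exposure)
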