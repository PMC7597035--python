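"""Cosinor engine: design, fits, curve parameters, tests, selection, FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rhythmfit as rf
from rhythmfit.synth import SignalSpec

from conftest import noiseless_cosine


class TestBuildDesign:
    @pytest.mark.parametrize("t,n_comp,expected", [
        (0.0, 1, (0.0, 1.0)),    # sin 0, cos 0
        (6.0, 1, (1.0, 0.0)),    # quarter period
        (6.0, 2, (0.0, -1.0)),   # second harmonic: period 12 -> half cycle
    ])
    def test_trigonometric_columns(self, t, n_comp, expected):
        times = np.linspace(0, 48, 25)
        times[0] = t
        X = rf.build_design(times, rf.CosinorModelSpec(24.0, n_comp))
        pair = X[0, 2 * n_comp - 1 : 2 * n_comp + 1]
        np.testing.assert_allclose(pair, expected, atol=1e-12)

    def test_shape_and_bounds(self):
        X = rf.build_design(np.linspace(0, 48, 30), rf.CosinorModelSpec(24.0, 3))
        assert X.shape == (30, 7)
        assert np.all(X[:, 0] == 1)
        assert np.all(np.abs(X[:, 1:]) <= 1 + 1e-12)

    def test_too_few_observations(self):
        with pytest.raises(rf.FittingError, match="8"):
            rf.build_design(np.arange(5.0), rf.CosinorModelSpec(24.0, 3))


class TestFitModel:
    def test_exact_cosine_identity(self):
        t = np.arange(0, 47, 2.0)
        y = 2 + np.cos(2 * np.pi * t / 24)
        fit = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 1))
        np.testing.assert_allclose(fit.coefficients, [2.0, 0.0, 1.0], atol=1e-10)
        assert fit.ssr < 1e-16

    def test_nested_fit_zeroes_absent_harmonics(self):
        t = np.arange(0, 47, 2.0)
        y = 2 + np.cos(2 * np.pi * t / 24)
        fit = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 3))
        np.testing.assert_allclose(fit.coefficients[3:], 0.0, atol=1e-8)
        assert fit.ssr < 1e-12

    def test_ssr_monotone_in_components(self, benchmark):
        t, y, _ = benchmark.measurements.group_arrays("test3")
        ssrs = [rf.fit_model(t, y, rf.CosinorModelSpec(24.0, n)).ssr
                for n in (1, 2, 3, 4)]
        assert all(a >= b - 1e-10 for a, b in zip(ssrs, ssrs[1:]))

    def test_single_time_point_is_rank_deficient(self):
        t = np.full(8, 3.0)
        with pytest.raises(rf.FittingError, match="rank"):
            rf.fit_model(t, np.arange(8.0), rf.CosinorModelSpec(24.0, 1))

    def test_poisson_glm_recovers_log_linear_coefficients(self, rng):
        t = rng.uniform(0, 48, 200)
        eta = 0.5 + 0.8 * np.cos(2 * np.pi * t / 24)
        y = rng.poisson(np.exp(eta)).astype(float)
        fit = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 1, "poisson"))
        se = np.sqrt(np.diag(fit.cov))
        truth = np.array([0.5, 0.0, 0.8])
        assert np.all(np.abs(fit.coefficients - truth) < 3 * se)
        assert fit.p_overall < 1e-6

    @pytest.mark.parametrize("family", ["generalized_poisson", "negative_binomial"])
    def test_overdispersed_families_fit_counts(self, family, rng):
        t = rng.uniform(0, 48, 300)
        eta = 1.0 + 0.6 * np.cos(2 * np.pi * t / 24)
        y = rng.negative_binomial(5, 5 / (5 + np.exp(eta))).astype(float)
        fit = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 1, family))
        _, phi = rf.polar_params(*fit.component_pair(1))
        assert abs(phi) < 0.5 or abs(phi + 2 * np.pi) < 0.5
        assert fit.p_overall < 1e-3

    def test_count_family_rejects_non_integer_data(self):
        t, y = noiseless_cosine(mesor=5.0)
        with pytest.raises(rf.ValidationError, match="integer"):
            rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 1, "poisson"))

    def test_gaussian_requires_identity_link(self):
        with pytest.raises(rf.ValidationError):
            rf.CosinorModelSpec(24.0, 1, "gaussian", link="log")


class TestRhythmParams:
    def test_pure_cosine(self):
        t, y = noiseless_cosine()
        fit = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 1))
        p = rf.rhythm_params(fit)
        assert p.amplitude == pytest.approx(1.0, abs=1e-4)
        assert p.acrophase_rad == pytest.approx(0.0, abs=2 * np.pi / 1000)
        assert p.peak_times_hours[0] == pytest.approx(0.0, abs=0.05)

    def test_matches_closed_form_for_equal_coefficients(self):
        # A1 = A2 = 1: amplitude sqrt(2), acrophase -pi/4 per the case table
        t = np.arange(0, 47, 2.0)
        y = np.sin(2 * np.pi * t / 24) + np.cos(2 * np.pi * t / 24)
        fit = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 1))
        p = rf.rhythm_params(fit)
        assert p.amplitude == pytest.approx(np.sqrt(2), abs=1e-4)
        assert p.acrophase_rad == pytest.approx(-np.pi / 4, abs=2 * np.pi / 1000)

    def test_two_harmonics_against_brute_force_grid(self):
        spec = SignalSpec(n_components=2, component_amplitudes=(1.0, 1.0),
                          noise_amplitude=0.0, n_replicates=1, step_hours=1.0)
        df = rf.generate_signal(spec, seed=0)
        fit = rf.fit_model(df["x"].to_numpy(), df["y"].to_numpy(),
                           rf.CosinorModelSpec(24.0, 2))
        p = rf.rhythm_params(fit)
        grid = np.linspace(0, 24, 10_000, endpoint=False)
        brute = spec.curve(grid)
        assert p.amplitude == pytest.approx((brute.max() - brute.min()) / 2, abs=1e-3)
        assert p.mesor == pytest.approx((brute.max() + brute.min()) / 2, abs=1e-3)

    def test_multicomponent_reports_curve_midline_and_intercept(self, benchmark):
        t, y, _ = benchmark.measurements.group_arrays("test3")
        fit = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 3))
        p = rf.rhythm_params(fit)
        assert p.mesor != pytest.approx(p.mesor_intercept, abs=1e-6)

    def test_coarse_grid_rejected(self):
        t, y = noiseless_cosine()
        fit = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 1))
        with pytest.raises(rf.ResolutionError):
            rf.rhythm_params(fit, grid_step_hours=7.0)


class TestOverallSignificance:
    def test_perfect_fit_flags_p_zero(self):
        t, y = noiseless_cosine()
        fit = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 1))
        res = rf.overall_significance(fit)
        assert res.p_value == 0.0 and res.note

    def test_benchmark_groups_all_significant(self, benchmark):
        for lab, n in (("test1", 1), ("test2", 1), ("test3", 3), ("test4", 3)):
            t, y, _ = benchmark.measurements.group_arrays(lab)
            fit = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, n))
            assert rf.overall_significance(fit).p_value < 0.05


class TestLackOfFit:
    def test_one_component_rejected_on_three_harmonic_truth(self):
        spec = SignalSpec(n_components=3, noise_amplitude=0.05, n_replicates=3,
                          step_hours=2.0)
        df = rf.generate_signal(spec, seed=1)
        t, y = df["x"].to_numpy(), df["y"].to_numpy()
        fit = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 1))
        assert rf.lack_of_fit(fit).p_value < 0.01

    def test_well_specified_model_not_rejected(self, benchmark):
        t, y, _ = benchmark.measurements.group_arrays("test1")
        fit = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 1))
        assert rf.lack_of_fit(fit).p_value > 0.001

    def test_requires_replicates(self):
        t, y = noiseless_cosine(step=2.0)
        fit = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 1))
        with pytest.raises(rf.ValidationError, match="replicates"):
            rf.lack_of_fit(fit)

    def test_degenerate_perfect_replicates_not_applicable(self):
        t0, y0 = noiseless_cosine(step=4.0)
        t = np.concatenate([t0, t0])
        y = np.concatenate([y0, y0])
        fit = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 1))
        res = rf.lack_of_fit(fit)
        assert not res.applicable and "not applicable" in res.note


class TestExtraSSR:
    def test_direct_substitution(self):
        # SSR1=12, SSR2=6, DoF1=20, DoF2=15 -> F = (6/6)/(5/15) = 3
        spec1 = rf.CosinorModelSpec(24.0, 1)
        spec2 = rf.CosinorModelSpec(24.0, 2)
        t = np.linspace(0, 48, 24)
        base = dict(cov=np.eye(3), n_obs=24, t=t, y=np.zeros(24))
        f1 = rf.CosinorFit(spec=spec1, coefficients=np.zeros(3), ssr=12.0,
                           dof=20, **base)
        f2 = rf.CosinorFit(spec=spec2, coefficients=np.zeros(5), ssr=6.0,
                           dof=15, **base)
        res = rf.extra_ssr_test(f1, f2)
        assert res.statistic == pytest.approx(3.0)
        assert res.df == (5, 15)

    def test_no_improvement_gives_p_one(self):
        t, y, _ = rf.generate_benchmark_suite(0).measurements.group_arrays("test1")
        f1 = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 1))
        f2 = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 2))
        forced = rf.CosinorFit(spec=f2.spec, coefficients=f2.coefficients,
                               cov=f2.cov, ssr=f1.ssr, dof=f2.dof,
                               n_obs=f2.n_obs, t=f2.t, y=f2.y)
        res = rf.extra_ssr_test(f1, forced)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_three_harmonic_truth_prefers_rich_model(self, benchmark):
        t, y, _ = benchmark.measurements.group_arrays("test3")
        f1 = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 1))
        f3 = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 3))
        assert rf.extra_ssr_test(f1, f3).p_value < 0.05

    def test_different_data_rejected(self, benchmark):
        t, y, _ = benchmark.measurements.group_arrays("test1")
        t3, y3, _ = benchmark.measurements.group_arrays("test3")
        f1 = rf.fit_model(t, y, rf.CosinorModelSpec(24.0, 1))
        f2 = rf.fit_model(t3, y3, rf.CosinorModelSpec(24.0, 2))
        with pytest.raises(rf.ValidationError):
            rf.extra_ssr_test(f1, f2)


class TestSelection:
    def test_benchmark_component_counts(self, benchmark):
        expected = {"test1": 1, "test2": 1, "test3": 3, "test4": 3}
        for lab, n in expected.items():
            t, y, _ = benchmark.measurements.group_arrays(lab)
            best = rf.select_best_model(t, y, [24.0], max_components=3)
            assert best.spec.n_components == n, lab

    def test_noiseless_period_scan_wins_truth(self):
        t, y = noiseless_cosine(step=1.0)
        best = rf.select_best_model(t, y, [20.0, 24.0, 28.0], max_components=3)
        assert best.spec.period_hours == 24.0
        assert best.ssr < 1e-10
        assert best.selection_trace is not None

    def test_empty_period_list_rejected(self):
        t, y = noiseless_cosine()
        with pytest.raises(rf.ValidationError):
            rf.select_best_model(t, y, [])


class TestEstimatePeriod:
    def test_noiseless_cosine_peaks_at_truth(self):
        t, y = noiseless_cosine(step=1.0)
        ranked = rf.estimate_period(t, y, (18, 30), 25)
        assert abs(ranked[0][0] - 24.0) <= 0.5
        assert ranked[0][1] >= ranked[-1][1]

    def test_two_groups_with_different_periods(self, rng):
        t = np.arange(0, 96, 1.0)
        for period in (20.0, 24.0):
            y = np.cos(2 * np.pi * t / period) + rng.normal(0, 0.3, t.size)
            ranked = rf.estimate_period(t, y, (16, 30), 29)
            assert abs(ranked[0][0] - period) <= 0.5

    def test_white_noise_top_period_uniform_over_fourier_grid(self):
        # candidate periods at Fourier frequencies k/T are independent, so the
        # argmax under white noise should be uniform across them
        rng = np.random.default_rng(1)
        T, k_range = 720.0, np.arange(24, 41)
        periods = T / k_range
        t = np.arange(0, T, 1.0)
        counts = np.zeros(periods.size)
        sorted_periods = np.sort(periods)
        for _ in range(400):
            y = rng.normal(0, 1, t.size)
            ranked = rf.estimate_period(t, y, periods)
            counts[np.argmin(np.abs(sorted_periods - ranked[0][0]))] += 1
        from scipy.stats import chisquare
        assert chisquare(counts).pvalue > 0.01

    def test_empty_range_rejected(self):
        t, y = noiseless_cosine()
        with pytest.raises(rf.ValidationError):
            rf.estimate_period(t, y, (30, 18))


class TestAdjustFdr:
    def test_bh_arithmetic(self):
        np.testing.assert_allclose(rf.adjust_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])
        np.testing.assert_allclose(rf.adjust_fdr([0.05]), [0.05])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_brute_force_definition(self, pvals):
        p = np.asarray(pvals)
        q = rf.adjust_fdr(p)
        m = p.size
        order = np.argsort(p, kind="stable")
        # brute force: q_(i) = min over j >= i of m * p_(j) / j, capped at 1
        brute = np.empty(m)
        for rank, idx in enumerate(order, start=1):
            tail = [m * p[order[j - 1]] / j for j in range(rank, m + 1)]
            brute[idx] = min(1.0, min(tail))
        np.testing.assert_allclose(q, brute, atol=1e-12)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1)

    def test_out_of_range_rejected(self):
        with pytest.raises(rf.ValidationError):
            rf.adjust_fdr([0.5, 1.5])


class TestAnalyzeAll:
    def test_benchmark_suite_all_detected(self, benchmark):
        table = rf.analyze_all(benchmark.measurements, periods=[24.0])
        assert len(table) == 4
        assert (table["q"] < 0.05).all()
        assert list(table["n_components"]) == [1, 1, 3, 3]

    def test_noise_groups_rank_below_signal(self, rng):
        records = []
        gen = rf.generate_benchmark_suite(7)
        records.append(gen.measurements.to_dataframe())
        import pandas as pd
        t = np.arange(0, 49, 2.0)
        for i in range(4):
            records.append(pd.DataFrame({
                "test": f"noise{i}", "x": np.tile(t, 3),
                "y": rng.normal(0, 0.5, t.size * 3), "individual": None,
            }))
        mset = rf.MeasurementSet(pd.concat(records, ignore_index=True))
        table = rf.analyze_all(mset, periods=[24.0]).set_index("test")
        signal_q = table.loc[["test1", "test2", "test3", "test4"], "q"]
        noise_q = table.loc[[f"noise{i}" for i in range(4)], "q"]
        assert signal_q.max() < noise_q.min()

    def test_failing_group_isolated(self, benchmark):
        import pandas as pd
        df = benchmark.measurements.to_dataframe()
        bad = pd.DataFrame({"test": ["tiny"] * 2, "x": [0.0, 1.0],
                            "y": [0.0, 1.0], "individual": None})
        mset = rf.MeasurementSet(pd.concat([df, bad], ignore_index=True))
        table = rf.analyze_all(mset, periods=[24.0]).set_index("test")
        assert table.loc["tiny", "error"] != ""
        assert (table.drop(index="tiny")["q"] < 0.05).all()
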