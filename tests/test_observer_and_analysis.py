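import numpy as np
import pytest
from scipy.special import expit

from partmorph.experiment_designs import build_experiment1
from partmorph.morphing import MorphSpec, build_morph_sequence
from partmorph.observer_and_analysis import (
    ObserverModel,
    analyze_2afc,
    analyze_slider,
    binomial_preference,
    cue_features,
    fit_psychometric,
    jzs_bayes_factor,
    measure_cues,
    one_sample_t,
    one_way_anova,
    recover_observer_weights,
    simulate_2afc,
    simulate_slider,
    tukey_posthoc,
)
from partmorph.part_manipulation import (
    DisplacementSpec,
    StraightenSpec,
    straighten_limb,
)
from partmorph.part_manipulation import displace_limb
from partmorph.skeleton_core import compose_shape


class TestMeasureCues:
    def test_symmetric_sproutless_shape(self, two_pair_shape):
        cues = measure_cues(two_pair_shape)
        assert cues.asymmetry == 0.0
        assert cues.sprout_prominence == 0.0
        assert cues.curvedness > 0

    def test_straightening_scales_curvedness_exactly(self, two_pair_shape):
        factor = 0.3
        parts = [
            straighten_limb(p, StraightenSpec(factor)) for p in two_pair_shape.parts
        ]
        out = compose_shape(two_pair_shape.body, parts)
        assert measure_cues(out).curvedness == pytest.approx(
            factor * measure_cues(two_pair_shape).curvedness, abs=1e-9
        )

    def test_single_displacement_mean_over_pairs(self, two_pair_shape, rng):
        """Displacing one limb of one of k pairs by d gives asymmetry d/k."""
        d = 0.08
        out = displace_limb(two_pair_shape, 0, DisplacementSpec(d, "down"), rng)
        k = 2
        assert measure_cues(out).asymmetry == pytest.approx(d / k, abs=1e-6)

    def test_no_pairs_marked_undefined(self, body):
        shape = compose_shape(body, [])
        assert np.isnan(measure_cues(shape).asymmetry)


@pytest.fixture(scope="module")
def small_pairs():
    return build_experiment1("symmetry", seed=40, n_reps=2)


class TestSimulate2afc:
    def test_chance_level_with_zero_weights(self, small_pairs):
        model = ObserverModel(weights=(0, 0, 0), bias=0.0, lapse=0.0)
        rng = np.random.default_rng(0)
        table = simulate_2afc(small_pairs, model, 10, rng)
        prop = table["chose_manipulated"].mean()
        n = len(table)
        assert abs(prop - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_saturation_with_huge_weight(self, small_pairs):
        model = ObserverModel(weights=(1e6, 0, 0), lapse=0.04)
        rng = np.random.default_rng(1)
        table = simulate_2afc(small_pairs, model, 10, rng)
        prop = table["chose_manipulated"].mean()
        assert prop == pytest.approx(1.0 - model.lapse / 2.0, abs=0.02)

    def test_weight_recovery_smoke(self, small_pairs):
        true_w = np.array([1.0, 1.0, 1.5])
        model = ObserverModel(weights=tuple(true_w), noise=1.0, lapse=0.0)
        rng = np.random.default_rng(2)
        table = simulate_2afc(small_pairs, model, 40, rng)
        # symmetry-only pairs identify only the asymmetry weight
        w = recover_observer_weights(table)
        assert abs(w[0] - true_w[0]) / true_w[0] < 0.2


@pytest.fixture(scope="module")
def sequence_shapes():
    seq = build_morph_sequence(MorphSpec(4, "growing", seed=55))
    return seq.steps


class TestSimulateSlider:
    def test_ratings_within_unit_interval(self, sequence_shapes):
        model = ObserverModel(noise=3.0)
        table = simulate_slider(
            sequence_shapes, model, 20, np.random.default_rng(0)
        )
        assert table["rating"].between(0, 1).all()

    def test_zero_noise_deterministic(self, sequence_shapes):
        model = ObserverModel(noise=0.0)
        t1 = simulate_slider(sequence_shapes, model, 2, np.random.default_rng(0))
        t2 = simulate_slider(sequence_shapes, model, 2, np.random.default_rng(9))
        np.testing.assert_array_equal(t1["rating"], t2["rating"])
        by_p = t1.groupby("participant")["rating"].apply(list)
        assert by_p.iloc[0] == by_p.iloc[1]

    def test_mean_rating_increases_across_steps(self, sequence_shapes):
        model = ObserverModel()
        table = simulate_slider(
            sequence_shapes, model, 50, np.random.default_rng(3)
        )
        means = table.groupby("step")["rating"].mean().to_numpy()
        assert np.all(np.diff(means) > 0)


class TestBinomial:
    def test_null_centre(self):
        prop, p = binomial_preference(50, 100)
        assert prop == 0.5
        assert 0.5 < p < 0.56  # exact test sits just above one half

    def test_upper_tail_against_direct_sum(self):
        from scipy.stats import binom

        K, N = 61, 90
        _, p = binomial_preference(K, N)
        direct = binom.sf(K - 1, N, 0.5)
        assert p == pytest.approx(direct, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_preference(1, 0)
        with pytest.raises(ValueError):
            binomial_preference(5, 4)


class TestAnovaFamily:
    def test_identical_groups_give_zero_F(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = one_way_anova([g, g, g])
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equal_squared_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = one_way_anova([a, b])
        from scipy.stats import ttest_ind

        t = ttest_ind(a, b).statistic
        assert res.F == pytest.approx(t**2, abs=1e-9)

    def test_brute_force_sums_of_squares(self):
        """Direct SS decomposition reproduces the F statistic."""
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 1.3, rng.integers(5, 12)) for m in (0, 0.4, 1.1)]
        res = one_way_anova(groups)
        allv = np.concatenate(groups)
        grand = allv.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        k, n = len(groups), len(allv)
        F = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert res.F == pytest.approx(F, abs=1e-9)
        assert (res.df_between, res.df_within) == (k - 1, n - k)

    def test_degenerate_variance_errors(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 1.0], [1.0, 1.0]])

    def test_tukey_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(6)
        groups = [rng.normal(m, 1, 20) for m in (0.0, 0.6, 1.4, 1.5)]
        ours = tukey_posthoc(groups)
        data = np.concatenate(groups)
        labels = np.repeat(np.arange(4), 20)
        sm_res = pairwise_tukeyhsd(data, labels)
        np.testing.assert_allclose(
            ours["p"].to_numpy(), sm_res.pvalues, atol=1e-6
        )


class TestOneSampleT:
    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(7)
        v = rng.normal(0.6, 0.2, 40)
        t, df, p = one_sample_t(v, 0.5)
        manual = (v.mean() - 0.5) / (v.std(ddof=1) / np.sqrt(len(v)))
        assert t == pytest.approx(manual, abs=1e-12)
        assert df == 39

    def test_sign_flips_under_reflection(self):
        rng = np.random.default_rng(8)
        v = rng.normal(0.7, 0.1, 25)
        t1, _, p1 = one_sample_t(v, 0.5)
        t2, _, p2 = one_sample_t(1.0 - v, 0.5)
        assert t2 == pytest.approx(-t1, abs=1e-9)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            one_sample_t([0.5, 0.5, 0.5], 0.5)


class TestJzsBayesFactor:
    def test_null_data_favour_null(self):
        assert jzs_bayes_factor(0.0, 500) < 1.0

    def test_monotone_in_t(self):
        bfs = [jzs_bayes_factor(t, 40) for t in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(b > a for a, b in zip(bfs, bfs[1:]))

    @pytest.mark.parametrize("t", [0.0, 0.8, 2.5, 5.0])
    @pytest.mark.parametrize("n", [10, 50, 200])
    def test_matches_high_resolution_quadrature(self, t, n):
        """Independent fixed-grid quadrature of the JZS marginal ratio."""
        r2 = 0.707**2
        nu = n - 1
        # substitute g = u / (1 - u) and integrate on a dense uniform grid
        u = np.linspace(1e-9, 1 - 1e-9, 400_001)
        g = u / (1 - u)
        jac = 1.0 / (1 - u) ** 2
        c = 1 + n * g * r2
        integrand = (
            c**-0.5
            * (1 + t * t / (c * nu)) ** (-(nu + 1) / 2)
            * (2 * np.pi) ** -0.5
            * g**-1.5
            * np.exp(-1 / (2 * g))
            * jac
        )
        num = np.trapezoid(integrand, u)
        den = (1 + t * t / nu) ** (-(nu + 1) / 2)
        oracle = num / den
        assert jzs_bayes_factor(t, n) == pytest.approx(oracle, rel=1e-6)

    def test_matches_pingouin(self):
        import pingouin as pg

        for t, n in [(1.5, 10), (2.5, 50), (3.0, 100)]:
            assert jzs_bayes_factor(t, n) == pytest.approx(
                float(pg.bayesfactor_ttest(t, n)), rel=1e-9
            )


class TestPsychometricFit:
    def test_recovers_noiseless_logistic(self):
        x = np.repeat(np.arange(1, 6), 50).astype(float)
        loc, slope, guess, lapse = 3.0, 1.6, 0.05, 0.08
        y = guess + (1 - guess - lapse) * expit(slope * (x - loc))
        fit = fit_psychometric(x, y)
        assert fit.location == pytest.approx(loc, rel=0.01)
        assert fit.slope == pytest.approx(slope, rel=0.01)
        assert fit.guess == pytest.approx(guess, abs=0.01)
        assert fit.lapse == pytest.approx(lapse, abs=0.01)

    def test_flat_data_warns_not_crashes(self):
        x = np.repeat(np.arange(1, 6), 3).astype(float)
        y = np.full_like(x, 0.5)
        fit = fit_psychometric(x, y)
        assert fit.flat_warning
        assert fit.slope == pytest.approx(0.0, abs=1e-3)

    def test_monotone_slope_recovery(self):
        x = np.repeat(np.arange(1, 6), 80).astype(float)
        rng = np.random.default_rng(9)
        fitted = []
        for slope in (0.5, 1.0, 2.0, 4.0):
            y = np.clip(
                expit(slope * (x - 3.0)) + rng.normal(0, 0.05, x.size), 0, 1
            )
            fitted.append(fit_psychometric(x, y).slope)
        assert all(b > a for a, b in zip(fitted, fitted[1:]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_psychometric([1, 1, 1, 1], [0.1, 0.2, 0.3, 0.4])


class TestReportBatteries:
    def test_analyze_2afc_structure(self, small_pairs):
        model = ObserverModel()
        table = simulate_2afc(small_pairs, model, 4, np.random.default_rng(10))
        report = analyze_2afc(table)
        assert set(report["participants"]) == {0, 1, 2, 3}
        assert report["pooled"]["N"] == len(table)
        assert report["pooled"]["proportion"] > 0.5  # plant-positive observer
        assert "anova" in report

    def test_analyze_slider_structure(self):
        seqs = [
            build_morph_sequence(MorphSpec(n, cond, seed=60 + n))
            for n in (2, 5)
            for cond in ("growing", "symmetrical")
        ]
        shapes = [s for q in seqs for s in q.steps]
        for i, q in enumerate(seqs):
            for k, s in enumerate(q.steps):
                s.meta["sequence_id"] = f"s{i}"
                s.meta["shape_id"] = f"s{i}-{k}"
        table = simulate_slider(
            shapes, ObserverModel(), 12, np.random.default_rng(11)
        )
        report = analyze_slider(table)
        assert report["bias"]["mean"] > 0.5
        assert report["sprouting_style"]["BF10"] >= 0
        assert report["fits"]["limbs:5"]["slope"] > report["fits"]["limbs:2"]["slope"]
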