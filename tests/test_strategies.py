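"""The five strategies, the MI engine, and Rubin's-rules pooling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from delirimpute import (
    MissingnessSpec,
    NonEstimableError,
    active_mi,
    adhoc_impute,
    complete_case,
    fit_analysis_model,
    generate_outcome,
    impose_missingness,
    impute_binary_daily,
    passive_mi,
    rubins_pool,
)
from delirimpute.strategies import STRATEGIES

from conftest import cohort_from_statuses


@pytest.fixture(scope="module")
def masked_cohort(outcome_cohort):
    return impose_missingness(outcome_cohort, MissingnessSpec("MCAR", 0.2), rng=20)


class TestAnalysisModel:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(21)
        x = rng.integers(0, 10, 50).astype(float)
        y = 80.0 - x + rng.normal(0, 12, 50)
        est = fit_analysis_model(x, y)
        # independent closed-form oracle
        xc = x - x.mean()
        slope = (xc @ y) / (xc @ xc)
        resid = y - y.mean() - slope * xc
        se = np.sqrt(resid @ resid / 48.0 / (xc @ xc))
        assert est.beta_hat == pytest.approx(slope, abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)
        assert est.df == 48
        assert est.n_used == 50

    def test_three_collinear_points(self):
        with pytest.warns(UserWarning, match="exact linear"):
            est = fit_analysis_model([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert est.beta_hat == pytest.approx(1.0, abs=1e-12)

    def test_perfect_fit_reports_zero_se_with_warning(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="exact linear"):
            est = fit_analysis_model(x, 5.0 - x)
        assert est.se == 0.0

    def test_constant_duration_not_estimable(self):
        with pytest.raises(NonEstimableError, match="constant"):
            fit_analysis_model([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_too_few_participants_not_estimable(self):
        with pytest.raises(NonEstimableError):
            fit_analysis_model([1.0, 2.0], [1.0, 2.0])


class TestRubinsPool:
    def test_forced_arithmetic_example(self):
        pool = rubins_pool([(1.0, np.sqrt(0.5)), (2.0, np.sqrt(0.5)),
                            (3.0, np.sqrt(0.5))])
        assert pool.q_bar == pytest.approx(2.0)
        assert pool.w == pytest.approx(0.5)
        assert pool.b_var == pytest.approx(1.0)
        assert pool.t_var == pytest.approx(0.5 + (4.0 / 3.0), abs=1e-12)
        assert pool.se == pytest.approx(1.3540, abs=5e-5)

    def test_identical_estimates_give_infinite_df(self):
        pool = rubins_pool([(1.5, 0.3)] * 5)
        assert pool.b_var == 0.0
        assert pool.t_var == pool.w
        assert np.isinf(pool.df)

    def test_matches_textbook_formula_oracle(self):
        rng = np.random.default_rng(22)
        pairs = [(rng.normal(), rng.uniform(0.1, 2.0)) for _ in range(10)]
        pool = rubins_pool(pairs)
        # independently coded oracle
        q = np.array([p[0] for p in pairs])
        u = np.array([p[1] ** 2 for p in pairs])
        n_imp = len(q)
        w = u.mean()
        b = ((q - q.mean()) ** 2).sum() / (n_imp - 1)
        t = w + (1 + 1 / n_imp) * b
        df = (n_imp - 1) * (1 + w / ((1 + 1 / n_imp) * b)) ** 2
        assert pool.q_bar == pytest.approx(q.mean(), abs=1e-12)
        assert pool.t_var == pytest.approx(t, abs=1e-12)
        assert pool.df == pytest.approx(df, abs=1e-9)

    def test_fewer_than_two_imputations_rejected(self):
        with pytest.raises(ValueError):
            rubins_pool([(1.0, 0.5)])

    @given(
        st.lists(
            st.tuples(st.floats(-5, 5), st.floats(0.01, 3.0)),
            min_size=2,
            max_size=20,
        )
    )
    def test_total_variance_dominates_within_variance(self, pairs):
        pool = rubins_pool(pairs)
        assert pool.t_var >= pool.w - 1e-15


class TestAdhoc:
    def test_table_example_worst_and_best(self):
        cohort = cohort_from_statuses(
            [[True, True, None, True, False], [False] * 3, [True, True]],
            outcomes=[70.0, 85.0, 78.0],
        )
        worst = adhoc_impute(cohort, "worst")
        best = adhoc_impute(cohort, "best")
        assert worst.n_used == best.n_used == 3
        # durations forced by the fill rule: worst -> 4, best -> 3 for participant 0
        deli = cohort.days
        w_dur = deli.assign(delirium=deli["delirium"].fillna(1.0)) \
            .groupby("participant_id")["delirium"].sum()
        b_dur = deli.assign(delirium=deli["delirium"].fillna(0.0)) \
            .groupby("participant_id")["delirium"].sum()
        assert w_dur.loc[0] == 4 and b_dur.loc[0] == 3

    def test_worst_duration_dominates_best(self, masked_cohort):
        deli = masked_cohort.days
        w_dur = deli.assign(delirium=deli["delirium"].fillna(1.0)) \
            .groupby("participant_id")["delirium"].sum()
        b_dur = deli.assign(delirium=deli["delirium"].fillna(0.0)) \
            .groupby("participant_id")["delirium"].sum()
        gap = w_dur - b_dur
        assert (gap >= 0).all()
        # equality exactly where no days are missing
        missing = masked_cohort.has_missing_days().reindex(gap.index)
        assert ((gap == 0) == ~missing).all()

    def test_invalid_fill_rejected(self, masked_cohort):
        with pytest.raises(ValueError):
            adhoc_impute(masked_cohort, "median")


class TestCompleteCase:
    def test_single_partially_missing_participant_dropped(self):
        cohort = cohort_from_statuses(
            [[True, None], [False, False], [True, True], [False, True]],
            outcomes=[70.0, 85.0, 78.0, 80.0],
        )
        est = complete_case(cohort)
        assert est.n_used == 3

    def test_mcar_retention_matches_binomial_oracle(self):
        # 5-day stays, 20% MCAR: P(complete) = 0.8^5 ~ 0.328
        from delirimpute import BaseCohortParams, generate_base_cohort

        params = BaseCohortParams(n_base=4000, los_min=5, los_max=5, los_mean=5)
        cohort = generate_outcome(generate_base_cohort(params, rng=23), rng=23)
        masked = impose_missingness(cohort, MissingnessSpec("MCAR", 0.2), rng=24)
        est = complete_case(masked)
        expected = 0.8**5
        tol = 3.29 * np.sqrt(expected * (1 - expected) / 4000)
        assert abs(est.n_used / 4000 - expected) < tol

    def test_too_few_complete_participants_not_estimable(self):
        cohort = cohort_from_statuses(
            [[None, True]] * 4 + [[True, False]] * 2,
            outcomes=[70.0] * 4 + [80.0, 75.0],
        )
        with pytest.raises(NonEstimableError):
            complete_case(cohort)


class TestZeroMissingnessCoincidence:
    def test_all_five_strategies_agree_to_1e10(self, outcome_cohort):
        rng = np.random.default_rng(25)
        estimates = {
            name: fn(outcome_cohort, rng=rng, b=5)
            for name, fn in STRATEGIES.items()
        }
        betas = {n: e.beta_hat for n, e in estimates.items()}
        ses = {n: e.se for n, e in estimates.items()}
        ref_b = betas["complete_case"]
        ref_s = ses["complete_case"]
        for name in estimates:
            assert betas[name] == pytest.approx(ref_b, abs=1e-10), name
            assert ses[name] == pytest.approx(ref_s, abs=1e-10), name
            assert estimates[name].n_used == outcome_cohort.n_participants


class TestDailyImputation:
    def test_no_missing_days_returns_cohort_unchanged(self, outcome_cohort):
        completed = impute_binary_daily(outcome_cohort, rng=26)
        np.testing.assert_array_equal(
            completed.days["delirium"], outcome_cohort.days["delirium"]
        )

    def test_completion_fills_every_missing_day(self, masked_cohort):
        completed = impute_binary_daily(masked_cohort, rng=27)
        assert completed.days["delirium"].notna().all()
        obs = masked_cohort.days["delirium"].notna()
        np.testing.assert_array_equal(
            completed.days.loc[obs, "delirium"],
            masked_cohort.days.loc[obs, "delirium"],
        )

    def test_separating_predictor_recovers_the_rule(self):
        # delirium == 1 exactly when SOFA > 12: the fit is separated, the
        # ridge fallback engages, and imputed values follow the rule
        rng = np.random.default_rng(28)
        statuses, sofas = [], []
        for _ in range(300):
            sofa = rng.integers(0, 25, 6).tolist()
            statuses.append([s > 12 for s in sofa])
            sofas.append(sofa)
        cohort = cohort_from_statuses(
            statuses, outcomes=[0.0] * 300, sofa_lists=sofas
        )
        masked = impose_missingness(cohort, MissingnessSpec("MCAR", 0.3), rng=29)
        with pytest.warns(UserWarning, match="ridge|unstable"):
            completed = impute_binary_daily(masked, predictors=("sofa",), rng=30)
        miss = masked.days["delirium"].isna()
        agree = (
            completed.days.loc[miss, "delirium"]
            == (masked.days.loc[miss, "sofa"] > 12).astype(float)
        ).mean()
        assert agree > 0.97

    def test_intercept_only_imputation_reproduces_prevalence(self):
        # delirium independent of everything at prevalence 0.4: long-run
        # imputed prevalence must calibrate to 0.4
        from delirimpute import BaseCohortParams, generate_base_cohort

        params = BaseCohortParams(
            n_base=2000, p_init=0.4, p_stay_del=0.4, p_new_del=0.4,
            sofa_del_shift=0.0,
        )
        cohort = generate_outcome(
            generate_base_cohort(params, rng=31), beta_del=0.0, rng=31
        )
        masked = impose_missingness(cohort, MissingnessSpec("MCAR", 0.3), rng=32)
        rng = np.random.default_rng(33)
        rates = [
            impute_binary_daily(masked, predictors=(), rng=rng)
            .days.loc[masked.days["delirium"].isna(), "delirium"]
            .mean()
            for _ in range(20)
        ]
        assert np.mean(rates) == pytest.approx(0.4, abs=0.02)


class TestMultipleImputation:
    def test_passive_requires_at_least_two_imputations(self, masked_cohort):
        with pytest.raises(ValueError):
            passive_mi(masked_cohort, b=1, rng=0)
        with pytest.raises(ValueError):
            active_mi(masked_cohort, b=1, rng=0)

    def test_passive_pooled_variance_exceeds_within(self, masked_cohort):
        est = passive_mi(masked_cohort, b=10, rng=34)
        assert est.b_imputations == 10
        assert np.isfinite(est.df) and est.df >= 1
        assert est.se > 0

    def test_active_all_durations_missing_not_estimable(self):
        cohort = cohort_from_statuses(
            [[True, None], [None, False], [None, None], [True, None]],
            outcomes=[70.0, 80.0, 75.0, 72.0],
        )
        with pytest.raises(NonEstimableError):
            active_mi(cohort, b=2, rng=0)

    def test_active_pmm_donates_observed_durations(self, masked_cohort):
        est = active_mi(masked_cohort, b=5, rng=35, method="pmm")
        assert est.se > 0 and est.n_used == masked_cohort.n_participants

    def test_information_loss_monotone_in_missingness(self, outcome_cohort):
        # mean pooled SE at 35% missingness >= at 5%, same seeds, both MI
        from delirimpute import Scenario, collect_estimates

        means = {}
        for p in (0.05, 0.35):
            sc = Scenario("MCAR", p, n_participants=200, n_replicates=40)
            est = collect_estimates(
                outcome_cohort, sc, seed=36,
                strategies=["passive_mi", "active_mi"],
            )
            for name, lst in est.items():
                ses = [e.se for e in lst if e is not None]
                means[(name, p)] = np.mean(ses)
        assert means[("passive_mi", 0.35)] >= means[("passive_mi", 0.05)]
        assert means[("active_mi", 0.35)] >= means[("active_mi", 0.05)]
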