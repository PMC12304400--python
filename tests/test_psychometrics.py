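"""Model-free measures, inclusion thresholds, ICC, and validity matrices."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from banditx import (
    chance_inclusion_threshold,
    convergent_matrix,
    icc,
    p_optimal,
    switch_probability,
)
from banditx.psychometrics import measure_table, session_pair_table
from banditx.simulate import SessionData


def _session(choices_by_round, task="twoarmed", forced_by_round=None):
    rows = []
    for r, choices in enumerate(choices_by_round, start=1):
        forced = forced_by_round[r - 1] if forced_by_round else [0] * len(choices)
        for t, (c, f) in enumerate(zip(choices, forced), start=1):
            rows.append((r, t, "", f, c, 50.0))
    return SessionData(
        subject=1, session=1, task=task,
        trials=pd.DataFrame(
            rows, columns=["round", "trial", "condition", "forced", "choice", "reward"]
        ),
    )


class TestSwitchProbability:
    def test_extremes(self):
        assert switch_probability(_session([[1, 1, 1, 1]])) == 0.0
        assert switch_probability(_session([[1, 2, 1, 2]])) == 1.0

    def test_hand_count(self):
        assert switch_probability(_session([[1, 1, 2, 2, 1]])) == pytest.approx(0.5)

    def test_cross_round_pairs_excluded(self):
        # last choice of round 1 differs from first of round 2: not a switch pair
        s = _session([[1, 1], [2, 2]])
        assert switch_probability(s) == 0.0

    def test_forced_trials_excluded(self):
        s = _session([[1, 2, 2, 2]], forced_by_round=[[1, 1, 0, 0]])
        assert switch_probability(s) == 0.0

    def test_uniform_four_arm_expectation(self, restless_rewardset, restless_cfg):
        from banditx import RestlessParams, simulate_session

        s = simulate_session(
            restless_rewardset, RestlessParams(0.0, 0.0), restless_cfg, seed=5
        )
        assert switch_probability(s) == pytest.approx(0.75, abs=0.09)

    def test_no_pairs_raises(self):
        with pytest.raises(ValueError):
            switch_probability(_session([[1]]))


class TestPOptimal:
    def test_always_optimal_agent(self, twoarmed_rewardset, twoarmed_cfg):
        from banditx import TwoArmedParams, simulate_session

        s = simulate_session(
            twoarmed_rewardset, TwoArmedParams(0.0, 0.0, 0.0), twoarmed_cfg, seed=1
        )
        best = np.argmax(
            twoarmed_rewardset.latent_means[
                s.trials["round"] - 1, s.trials["trial"] - 1
            ],
            axis=1,
        )
        s.trials["choice"] = best + 1
        assert p_optimal(s, twoarmed_rewardset) == 1.0

    def test_uniform_agent_near_half(self, twoarmed_rewardset, twoarmed_cfg):
        from banditx import TwoArmedParams, simulate_session

        s = simulate_session(
            twoarmed_rewardset, TwoArmedParams(0.0, 0.0, 0.0), twoarmed_cfg, seed=2
        )
        assert p_optimal(s, twoarmed_rewardset) == pytest.approx(0.5, abs=0.08)

    def test_hand_built_fraction(self, twoarmed_rewardset):
        best_first = int(np.argmax(twoarmed_rewardset.latent_means[0, 0])) + 1
        worst_first = 3 - best_first
        s = _session([[best_first, worst_first, best_first, best_first, worst_first]])
        assert p_optimal(s, twoarmed_rewardset) == pytest.approx(0.6)


class TestChanceThreshold:
    def test_single_trial(self):
        assert chance_inclusion_threshold(1, 2, 0.95) == 1

    @pytest.mark.parametrize("n,arms", [(300, 2), (200, 4), (80, 2), (37, 3)])
    def test_matches_brute_force_cdf(self, n, arms):
        p = 1.0 / arms
        cdf = np.cumsum([binom.pmf(k, n, p) for k in range(n + 1)])
        brute = int(np.argmax(cdf >= 0.95))
        assert chance_inclusion_threshold(n, arms, 0.95) == brute

    def test_monotone_in_trials(self):
        ks = [chance_inclusion_threshold(n, 2, 0.95) for n in range(1, 400, 7)]
        assert all(b >= a for a, b in zip(ks, ks[1:]))

    def test_invalid_percentile(self):
        with pytest.raises(ValueError):
            chance_inclusion_threshold(10, 2, 1.5)


class TestICC:
    def test_perfect_agreement(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0], [3.0, 3.0]])
        est = icc(x)
        assert est.icc_consistency == pytest.approx(1.0, abs=1e-12)
        assert est.icc_agreement == pytest.approx(1.0, abs=1e-12)

    def test_constant_shift_consistency_vs_agreement(self):
        base = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        x = np.column_stack([base, base + 10.0])
        est = icc(x)
        assert est.icc_consistency == pytest.approx(1.0, abs=1e-12)
        assert est.icc_agreement < 1.0

    def test_matches_anova_oracle_on_random_tables(self):
        """Brute-force two-way ANOVA decomposition by explicit sums."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = rng.normal(size=(10, 2))
            n, k = X.shape
            grand = X.sum() / X.size
            ss_rows = sum(
                k * (X[i].sum() / k - grand) ** 2 for i in range(n)
            )
            ss_cols = sum(
                n * (X[:, j].sum() / n - grand) ** 2 for j in range(k)
            )
            ss_err = sum(
                (X[i, j] - X[i].mean() - X[:, j].mean() + grand) ** 2
                for i in range(n)
                for j in range(k)
            )
            msr, msc, mse = ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))
            expect_c = (msr - mse) / (msr + (k - 1) * mse)
            expect_a = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
            est = icc(X)
            assert est.icc_consistency == pytest.approx(expect_c, abs=1e-10)
            assert est.icc_agreement == pytest.approx(expect_a, abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "session": np.tile([1, 2], 12),
                "value": X.ravel(),
            }
        )
        table = pg.intraclass_corr(
            long, targets="subject", raters="session", ratings="value"
        ).set_index("Type")
        est = icc(X)
        assert est.icc_consistency == pytest.approx(table.loc["ICC(C,1)", "ICC"], abs=1e-9)
        assert est.icc_agreement == pytest.approx(table.loc["ICC(A,1)", "ICC"], abs=1e-9)

    def test_shift_invariance_of_consistency_only(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1))
        shifted = X.copy()
        shifted[:, 1] += 5.0
        assert icc(shifted).icc_consistency == pytest.approx(
            icc(X).icc_consistency, abs=1e-12
        )
        assert icc(shifted).icc_agreement < icc(X).icc_agreement

    def test_degenerate_table_flagged(self):
        est = icc(np.ones((5, 2)))
        assert est.degenerate
        assert np.isnan(est.icc_consistency)

    def test_too_few_subjects_raise(self):
        with pytest.raises(ValueError):
            icc(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_difference_scores_less_reliable_than_components(self):
        # long and short scores share a reliable common component; the
        # difference cancels it and keeps mostly noise
        rng = np.random.default_rng(3)
        n = 400
        common = rng.normal(size=n)
        delta = 0.4 * rng.normal(size=n)
        long_scores = np.column_stack(
            [common + delta + 0.5 * rng.normal(size=n) for _ in range(2)]
        )
        short_scores = np.column_stack(
            [common + 0.5 * rng.normal(size=n) for _ in range(2)]
        )
        diff = long_scores - short_scores
        assert icc(diff).icc_consistency < icc(long_scores).icc_consistency


class TestConvergentMatrix:
    def _measures(self, columns: dict) -> pd.DataFrame:
        rows = []
        for (task, measure), values in columns.items():
            for s, v in enumerate(values, start=1):
                rows.append((s, 1, task, measure, v))
        return pd.DataFrame(
            rows, columns=["subject", "session", "task", "measure", "value"]
        )

    def test_diagonal_is_one(self):
        rng = np.random.default_rng(0)
        m = self._measures(
            {("restless", "tau"): rng.normal(size=50), ("twoarmed", "w_value"): rng.normal(size=50)}
        )
        corr = convergent_matrix(m, [("restless", "tau"), ("twoarmed", "w_value")])
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.shape == (2, 2)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(4)
        m = self._measures(
            {
                ("restless", "tau"): rng.normal(size=10_000),
                ("twoarmed", "w_value"): rng.normal(size=10_000),
            }
        )
        corr = convergent_matrix(m, [("restless", "tau"), ("twoarmed", "w_value")])
        assert abs(corr.iloc[0, 1]) < 0.05

    def test_factor_loadings_recovered(self):
        from banditx import CohortSpec, generate_synthetic_cohort

        cohort = generate_synthetic_cohort(
            CohortSpec(n_subjects=5000, loading=0.9, factor_corr=0.0, seed=6),
            simulate=False,
        )
        tp = cohort.true_params[cohort.true_params.session == 1]
        m = tp.rename(columns={"parameter": "measure"})
        corr = convergent_matrix(m, [("restless", "tau"), ("twoarmed", "w_value")])
        assert corr.iloc[0, 1] == pytest.approx(0.81, abs=0.04)

    def test_constant_column_flagged_nan(self):
        m = self._measures(
            {
                ("restless", "tau"): [1.0] * 10,
                ("twoarmed", "w_value"): list(np.arange(10.0)),
            }
        )
        corr = convergent_matrix(m, [("restless", "tau"), ("twoarmed", "w_value")])
        assert np.isnan(corr.iloc[0, 1])


def test_measure_table_and_pairing(small_cohort):
    measures = measure_table(small_cohort.sessions, small_cohort.rewardsets)
    assert set(measures["measure"]) == {"p_switch", "p_optimal"}
    pair = session_pair_table(measures, "restless", "p_switch")
    assert pair.shape == (30, 2)
    est = icc(pair)
    assert -1.0 <= est.icc_consistency <= 1.0
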