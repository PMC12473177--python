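"""Proportional-odds model: likelihood, MLE, and the three tests.

The independent oracles live inside the tests: a from-scratch cumulative
logit likelihood maximized by Nelder-Mead, closed-form 2x2 logistic
formulas, and statsmodels' ordinal regression as an external cross-check.
"""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special, stats

from ordshift import (
    OrdinalScale,
    TwoArmCounts,
    fit_po,
    fit_saturated,
    loglik_po,
    lr_test_effect,
    lr_test_po_assumption,
    wald_test_effect,
)
from ordshift.model import ProportionalOddsModel

from conftest import random_table


def oracle_loglik(params, counts):
    """Independent cumulative-logit multinomial log-likelihood (best-first counts)."""
    k = counts.shape[1]
    alpha, beta = np.asarray(params[: k - 1]), params[k - 1]
    total = 0.0
    for g, x in enumerate([0.0, 1.0]):
        gamma = np.concatenate([[0.0], 1 / (1 + np.exp(-(alpha + beta * x))), [1.0]])
        p = np.diff(gamma)
        for j in range(k):
            if counts[g, j] > 0:
                total += counts[g, j] * np.log(p[j])
    return total


def oracle_mle(counts):
    """Nelder-Mead maximization over the unconstrained (a1, log-diffs, beta) space."""
    k = counts.shape[1]

    def unpack(t):
        alpha = t[0] + np.concatenate([[0.0], np.cumsum(np.exp(t[1 : k - 1]))])
        return np.concatenate([alpha, [t[k - 1]]])

    def neg(t):
        return -oracle_loglik(unpack(t), counts)

    best = None
    for start_beta in (-1.0, 0.0, 1.0):
        t0 = np.concatenate([[-0.5], np.full(k - 2, np.log(0.5)), [start_beta]])
        res = optimize.minimize(neg, t0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    return unpack(best.x), -best.fun


class TestLoglik:
    def test_uniform_bernoulli_value(self):
        d = TwoArmCounts(OrdinalScale(("0", "1")), [[1, 1], [1, 1]])
        assert loglik_po([0.0, 0.0], d) == pytest.approx(4 * np.log(0.5), abs=1e-12)

    def test_beta_zero_at_pooled_logits_equals_pooled_null(self, toy3):
        pooled = toy3.pooled()
        gamma = np.cumsum(pooled)[:-1] / pooled.sum()
        params = np.concatenate([special.logit(gamma), [0.0]])
        expected = float(np.sum(pooled * np.log(pooled / pooled.sum())))
        assert loglik_po(params, toy3) == pytest.approx(expected, abs=1e-10)
        assert ProportionalOddsModel(toy3).null_loglik() == pytest.approx(expected)

    def test_non_monotone_thresholds_rejected(self, toy3):
        with pytest.raises(ValueError, match="increasing"):
            loglik_po([0.5, -0.5, 0.0], toy3)

    def test_matches_oracle_on_toy(self, toy3):
        params = np.array([-0.7, 0.8, 0.3])
        ours = loglik_po(params, toy3)
        theirs = oracle_loglik(params, toy3.goodness_counts())
        assert ours == pytest.approx(theirs, abs=1e-10)


class TestFitPO:
    def test_2x2_closed_form(self, table_2x2):
        res = fit_po(table_2x2)
        assert res.beta == pytest.approx(np.log(4.0), abs=1e-8)
        assert res.common_or == pytest.approx(4.0, rel=1e-7)
        # Woolf log-OR standard error
        assert res.se_beta == pytest.approx(
            np.sqrt(1 / 10 + 1 / 20 + 1 / 20 + 1 / 10), abs=1e-6
        )

    def test_identical_arms_give_null_effect(self, identical5):
        res = fit_po(identical5)
        assert res.beta == pytest.approx(0.0, abs=1e-7)
        assert res.common_or == pytest.approx(1.0, abs=1e-7)

    def test_matches_nelder_mead_oracle_on_toy_tables(self, toy3):
        tables = [
            toy3,
            TwoArmCounts(OrdinalScale(("0", "1", "2")), [[3, 9, 17], [12, 8, 4]]),
            TwoArmCounts(
                OrdinalScale(tuple("0123")), [[6, 11, 4, 9], [10, 5, 8, 7]]
            ),
        ]
        for table in tables:
            res = fit_po(table)
            params, ll = oracle_mle(table.goodness_counts().astype(float))
            assert res.beta == pytest.approx(params[-1], abs=1e-5)
            assert res.loglik == pytest.approx(ll, abs=1e-7)

    def test_higher_better_orientation_flips_beta_sign(self, toy3):
        flipped = TwoArmCounts(
            OrdinalScale(toy3.scale.labels, "higher_better"),
            toy3.counts,
            toy3.arm_names,
        )
        res, res_f = fit_po(toy3), fit_po(flipped)
        assert res_f.beta == pytest.approx(-res.beta, abs=1e-8)
        assert res_f.loglik == pytest.approx(res.loglik, abs=1e-8)

    def test_reversal_symmetry(self, toy3):
        res, res_r = fit_po(toy3), fit_po(toy3.reversed())
        assert res_r.beta == pytest.approx(res.beta, abs=1e-8)  # orientation follows
        assert res_r.loglik == pytest.approx(res.loglik, abs=1e-8)
        # Same counts reversed *without* flipping the orientation metadata:
        hard_flip = TwoArmCounts(toy3.scale, toy3.counts[:, ::-1])
        res_h = fit_po(hard_flip)
        assert res_h.beta == pytest.approx(-res.beta, abs=1e-8)
        assert np.allclose(
            np.sort(res_h.thresholds), np.sort(-res.thresholds[::-1]), atol=1e-7
        )

    def test_separation_flagged(self):
        d = TwoArmCounts(OrdinalScale(("0", "1")), [[20, 0], [0, 20]])
        with pytest.warns(RuntimeWarning):
            res = fit_po(d)
        assert res.separation and not res.converged
        assert res.conf_int_common_or() == (0.0, float("inf"))

    def test_cross_check_against_statsmodels(self):
        OrderedModel = pytest.importorskip(
            "statsmodels.miscmodels.ordinal_model"
        ).OrderedModel
        rng = np.random.default_rng(20240917)
        worst = 0.0
        for _ in range(50):
            table = random_table(rng, k_range=(3, 7), n_range=(5, 40))
            res = fit_po(table)
            n = table.counts
            y = np.concatenate(
                [np.repeat(np.arange(table.k), n[0]), np.repeat(np.arange(table.k), n[1])]
            )
            x = np.repeat([0.0, 1.0], n.sum(axis=1))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sm_fit = OrderedModel(y, x[:, None], distr="logit").fit(
                    disp=0, method="bfgs", gtol=1e-10, maxiter=2000
                )
            # statsmodels models P(Y <= j) = sigma(alpha_j - x beta) on the
            # raw label order (label 0 = clinically best here), so its beta
            # is the negative of ours.
            worst = max(worst, abs(res.beta - (-sm_fit.params[0])))
        assert worst < 1e-5

    def test_parameter_recovery_under_po_shift(self):
        from ordshift import Scenario, po_shift_distribution, sample_trial

        b = 0.5
        control = (0.2,) * 5
        scenario = Scenario(
            control, tuple(po_shift_distribution(control, np.exp(b))), 5000, 5000
        )
        rng_seq = np.random.SeedSequence(11).spawn(200)
        betas = [
            fit_po(sample_trial(scenario, np.random.default_rng(s))).beta
            for s in rng_seq
        ]
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - b) < 3 * mc_se


class TestSaturated:
    def test_closed_form_proportions(self, toy3):
        sat = fit_saturated(toy3)
        assert np.allclose(sat.probs[0], [1 / 3, 1 / 3, 1 / 3])
        assert np.allclose(sat.probs[1], [0.5, 1 / 3, 1 / 6])
        expected = 30 * np.log(1 / 3) + (
            15 * np.log(0.5) + 10 * np.log(1 / 3) + 5 * np.log(1 / 6)
        )
        assert sat.loglik == pytest.approx(expected, abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_nesting_inequalities(self, seed):
        table = random_table(np.random.default_rng(seed))
        model = ProportionalOddsModel(table)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit()
        assert model.null_loglik() <= res.loglik + 1e-7
        assert res.loglik <= model.fit_saturated().loglik + 1e-7
        assert model.fit_saturated().loglik <= 0.0 + 1e-12


class TestEffectTests:
    def test_identical_arms_null(self, identical5):
        lr = lr_test_effect(identical5)
        assert lr.statistic == pytest.approx(0.0, abs=1e-7)
        assert lr.p_value == pytest.approx(1.0, abs=1e-3)
        assert wald_test_effect(identical5).statistic == pytest.approx(0.0, abs=1e-7)

    def test_k2_equals_binary_logistic_lr(self, table_2x2):
        # independent 2x2 LR: 2 * (sum n log(n/row) - sum col log(col/N))
        n = table_2x2.counts.astype(float)
        ll_sat = np.sum(n * np.log(n / n.sum(axis=1, keepdims=True)))
        col = n.sum(axis=0)
        ll_null = np.sum(col * np.log(col / n.sum()))
        expected = 2 * (ll_sat - ll_null)
        got = lr_test_effect(table_2x2)
        assert got.statistic == pytest.approx(expected, abs=1e-7)
        assert got.df == 1

    def test_statistic_invariant_under_category_reversal(self, toy3):
        hard_flip = TwoArmCounts(toy3.scale, toy3.counts[:, ::-1])
        assert lr_test_effect(hard_flip).statistic == pytest.approx(
            lr_test_effect(toy3).statistic, abs=1e-7
        )

    def test_wald_and_lr_agree_at_large_n(self):
        from ordshift import Scenario, po_shift_distribution, sample_trial

        control = (0.2,) * 5
        scenario = Scenario(
            control, tuple(po_shift_distribution(control, 1.4)), 500, 500
        )
        table = sample_trial(scenario, np.random.default_rng(3))
        res = fit_po(table)
        p_lr = res.lr_test_effect().p_value
        p_wald = res.wald_test_effect().p_value
        assert p_wald == pytest.approx(p_lr, rel=0.05)


class TestPOAssumptionTest:
    def test_binary_outcome_rejected(self, table_2x2):
        with pytest.raises(ValueError, match="undefined for binary"):
            lr_test_po_assumption(table_2x2)

    def test_zero_statistic_under_exact_po(self):
        # exact-PO integer table: control (10,10,10), treatment (5,3,2) has
        # both cut-point ORs equal to 2, so the saturated fit satisfies PO
        d = TwoArmCounts(OrdinalScale(("0", "1", "2")), [[10, 10, 10], [5, 3, 2]])
        res = lr_test_po_assumption(d)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-4)

    def test_statistic_from_oracle_loglikelihoods(self, toy3):
        _, ll_po = oracle_mle(toy3.goodness_counts().astype(float))
        ll_sat = fit_saturated(toy3).loglik
        res = lr_test_po_assumption(toy3)
        assert res.statistic == pytest.approx(2 * (ll_sat - ll_po), abs=1e-6)

    def test_degrees_of_freedom_formula(self):
        k = 6
        rng = np.random.default_rng(5)
        table = TwoArmCounts(
            OrdinalScale(tuple(map(str, range(k)))),
            rng.integers(5, 30, size=(2, k)),
        )
        assert lr_test_po_assumption(table).df == k - 2


class TestSummary:
    def test_summary_mentions_key_quantities(self, toy3):
        text = fit_po(toy3).summary()
        assert "Common odds ratio" in text and "beta" in text
        assert "PO assumption" in text
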