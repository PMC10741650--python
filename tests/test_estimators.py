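"""Univariable MR estimators against closed-form and enumeration oracles."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from mrmediate.errors import InsufficientInstrumentsError
from mrmediate.estimators import (
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    mr_presso,
    steiger,
    wald_ratio,
    weighted_median,
)

from conftest import make_instruments


def wls_oracle(X, y, w):
    """Independent weighted-least-squares oracle via lstsq on the
    sqrt(w)-scaled system (no normal-equation sharing with the code
    under test)."""
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


class TestWaldRatio:
    def test_division_and_first_order_se(self):
        inst = make_instruments([0.1], [0.01], [0.02], [0.01]).instruments[0]
        est = wald_ratio(inst)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_sign(self):
        inst = make_instruments([-0.1], [0.01], [0.02], [0.01]).instruments[0]
        est = wald_ratio(inst)
        assert est.beta == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.1)

    def test_zero_exposure_effect_raises(self):
        inst = make_instruments([0.0], [0.01], [0.02], [0.01]).instruments[0]
        with pytest.raises(ValueError):
            wald_ratio(inst)

    def test_second_order_se_matches_monte_carlo(self):
        # well-conditioned instance (beta_x 10 SEs from zero) so the ratio
        # has stable moments
        bx, se_x, by, se_y = 0.1, 0.01, 0.02, 0.01
        inst = make_instruments([bx], [se_x], [by], [se_y]).instruments[0]
        est = wald_ratio(inst, second_order=True)
        rng = np.random.default_rng(7)
        draws = rng.normal(by, se_y, 10**6) / rng.normal(bx, se_x, 10**6)
        assert est.se == pytest.approx(np.std(draws), rel=0.02)

    def test_odds_ratio_ci_consistency(self):
        inst = make_instruments([0.1], [0.01], [0.02], [0.01]).instruments[0]
        est = wald_ratio(inst)
        assert est.odds_ratio == pytest.approx(math.exp(est.beta))
        assert est.ci_low < est.odds_ratio < est.ci_high


class TestIVW:
    def test_equal_ratios_give_that_ratio(self):
        inst = make_instruments(
            [0.1, 0.2, 0.3], [0.01] * 3, [0.02, 0.04, 0.06], [0.01] * 3
        )
        est = ivw(inst, mode="fixed")
        assert est.beta == pytest.approx(0.2)
        assert cochran_q(inst, est.beta).Q == pytest.approx(0.0, abs=1e-20)

    def test_two_instrument_closed_form(self, two_instruments):
        # weights 100 and 400, ratios 0.3 and 0.1 -> 0.14
        assert ivw(two_instruments, mode="fixed").beta == pytest.approx(0.14)

    def test_fixed_se_is_inverse_root_weight_sum(self, two_instruments):
        assert ivw(two_instruments, mode="fixed").se == pytest.approx(1 / math.sqrt(500))

    def test_random_effects_inflate_only_when_overdispersed(self, two_instruments):
        fixed = ivw(two_instruments, mode="fixed")
        random = ivw(two_instruments, mode="random")
        q = cochran_q(two_instruments, fixed.beta).Q
        assert random.se == pytest.approx(fixed.se * math.sqrt(q / 1))

    def test_matches_wls_oracle(self, random_instruments):
        est = ivw(random_instruments, mode="fixed")
        coef = wls_oracle(
            random_instruments.beta_exposure[:, None],
            random_instruments.beta_outcome,
            1.0 / random_instruments.se_outcome**2,
        )
        assert est.beta == pytest.approx(coef[0], rel=1e-10)

    def test_permutation_invariance(self, random_instruments):
        est = ivw(random_instruments)
        shuffled = dataclasses.replace(
            random_instruments, instruments=list(reversed(random_instruments.instruments))
        )
        est2 = ivw(shuffled)
        assert (est.beta, est.se, est.pvalue) == (est2.beta, est2.se, est2.pvalue)

    def test_sign_flip_invariance(self, random_instruments):
        flipped = [
            dataclasses.replace(i, beta_exposure=-i.beta_exposure, beta_outcome=-i.beta_outcome)
            if j % 2
            else i
            for j, i in enumerate(random_instruments.instruments)
        ]
        inst2 = dataclasses.replace(random_instruments, instruments=flipped)
        assert ivw(inst2).beta == pytest.approx(ivw(random_instruments).beta, rel=1e-12)

    def test_insufficient_instruments(self):
        inst = make_instruments([0.1], [0.01], [0.02], [0.01])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(inst)


class TestEgger:
    def test_exact_linear_fit(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        inst = make_instruments(bx, [0.01] * 4, 0.3 * bx, [0.01] * 4)
        est, pleio = egger(inst)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert pleio.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_fit_recovers_intercept(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        inst = make_instruments(bx, [0.01] * 4, 0.01 + 0.3 * bx, [0.01] * 4)
        est, pleio = egger(inst)
        assert pleio.intercept == pytest.approx(0.01, abs=1e-12)
        assert est.beta == pytest.approx(0.3, abs=1e-12)

    def test_matches_wls_oracle_with_orientation(self, random_instruments):
        est, pleio = egger(random_instruments)
        sign = np.sign(random_instruments.beta_exposure)
        sign[sign == 0] = 1.0
        X = np.column_stack(
            [np.ones(len(random_instruments)), random_instruments.beta_exposure * sign]
        )
        coef = wls_oracle(
            X,
            random_instruments.beta_outcome * sign,
            1.0 / random_instruments.se_outcome**2,
        )
        assert pleio.intercept == pytest.approx(coef[0], rel=1e-10)
        assert est.beta == pytest.approx(coef[1], rel=1e-10)

    def test_insufficient_instruments(self, two_instruments):
        with pytest.raises(InsufficientInstrumentsError):
            egger(two_instruments)


class TestWeightedMedian:
    def test_equal_weights_take_middle_ratio(self):
        inst = make_instruments(
            [0.1, 0.1, 0.1], [0.01] * 3, [0.01, 0.02, 0.03], [0.01] * 3
        )
        assert weighted_median(inst, n_boot=100, seed=0).beta == pytest.approx(0.2)

    def test_majority_weight_breakdown(self):
        # 6 instruments with ratio 0.25 hold >50% of the weight
        bx = [0.2] * 6 + [0.05] * 4
        by = [0.05] * 6 + [0.05, 0.04, 0.06, 0.07]
        inst = make_instruments(bx, [0.01] * 10, by, [0.01] * 10)
        assert weighted_median(inst, n_boot=100, seed=0).beta == pytest.approx(0.25)

    def test_seeded_bootstrap_reproducible(self, random_instruments):
        a = weighted_median(random_instruments, n_boot=200, seed=11)
        b = weighted_median(random_instruments, n_boot=200, seed=11)
        assert a == b

    def test_low_n_boot_warns(self, random_instruments):
        with pytest.warns(UserWarning, match="n_boot"):
            weighted_median(random_instruments, n_boot=50, seed=0)

    def test_contamination_below_half_weight_stays_in_clean_range(self):
        rng = np.random.default_rng(5)
        clean_ratios = rng.uniform(0.1, 0.3, 6)
        bx = np.full(11, 0.1)
        by = np.concatenate([clean_ratios * 0.1, np.full(5, 50.0 * 0.1)])
        inst = make_instruments(bx, [0.01] * 11, by, [0.01] * 11)
        est = weighted_median(inst, n_boot=100, seed=0)
        assert clean_ratios.min() <= est.beta <= clean_ratios.max()


class TestCochranQ:
    def test_hand_arithmetic(self, two_instruments):
        het = cochran_q(two_instruments, beta_ref=0.14)
        assert het.Q == pytest.approx(3.2)
        assert het.df == 1
        assert het.pvalue == pytest.approx(stats.chi2.sf(3.2, 1))

    def test_q_at_ivw_beta_equals_weighted_rss(self, random_instruments):
        beta = ivw(random_instruments, mode="fixed").beta
        resid = random_instruments.beta_outcome - beta * random_instruments.beta_exposure
        rss = np.sum(resid**2 / random_instruments.se_outcome**2)
        assert cochran_q(random_instruments, beta).Q == pytest.approx(rss, rel=1e-10)


class TestLeaveOneOut:
    def test_cardinality_and_labels(self, random_instruments):
        results = leave_one_out(random_instruments)
        assert [vid for vid, _ in results] == random_instruments.variant_ids

    def test_homogeneous_ratios_invariant(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        inst = make_instruments(bx, [0.01] * 4, 0.2 * bx, [0.01] * 4)
        for _, est in leave_one_out(inst):
            assert est.beta == pytest.approx(0.2)

    def test_each_estimate_equals_recomputed_subset_ivw(self, random_instruments):
        for vid, est in leave_one_out(random_instruments):
            manual = ivw(random_instruments.drop([vid]))
            assert est.beta == pytest.approx(manual.beta, rel=1e-12)
            assert est.se == pytest.approx(manual.se, rel=1e-12)


class TestMRPresso:
    def test_seeded_reproducibility(self, random_instruments):
        a = mr_presso(random_instruments, n_sim=500, seed=3)
        b = mr_presso(random_instruments, n_sim=500, seed=3)
        assert a == b

    def test_null_global_p_rarely_significant(self):
        """Zero-pleiotropy data should pass the global RSS test in at
        least 90% of replicates."""
        from mrmediate.experiments import child_seeds
        from mrmediate.simulate import SimulationConfig, simulate_study
        from mrmediate.experiments import univariable_instruments
        from dataclasses import replace

        base = SimulationConfig(n_variants=20, n_mediator_variants=0, pleiotropy_sd=0.0)
        ok = 0
        for s in child_seeds(99, 100):
            inst = univariable_instruments(simulate_study(replace(base, seed=s)), "outcome")
            ok += mr_presso(inst, n_sim=500, seed=s).global_rss_p > 0.05
        assert ok >= 90

    def test_corrected_estimate_present_iff_outliers(self, random_instruments):
        res = mr_presso(random_instruments, n_sim=500, seed=3)
        assert (res.corrected is not None) == bool(res.outliers)

    def test_insufficient_instruments(self):
        inst = make_instruments([0.1] * 3, [0.01] * 3, [0.02] * 3, [0.01] * 3)
        with pytest.raises(InsufficientInstrumentsError):
            mr_presso(inst)


class TestSteiger:
    def test_direction_from_variance_explained(self):
        inst = make_instruments([0.1], [0.01], [0.005], [0.01])
        res = steiger(inst, n_exposure=100_000, n_outcome=100_000)
        assert res.direction_correct
        assert res.r2_exposure > res.r2_outcome

    def test_identical_tables_give_equal_r2(self):
        inst = make_instruments([0.1, 0.2], [0.01, 0.02], [0.1, 0.2], [0.01, 0.02])
        res = steiger(inst, n_exposure=50_000, n_outcome=50_000)
        assert res.r2_exposure == pytest.approx(res.r2_outcome)
        assert not res.direction_correct

    def test_r2_formula_matches_individual_level_regression(self):
        """t²/(t² + n − 2) equals the squared sample correlation from a
        single-variant regression on individual-level data."""
        rng = np.random.default_rng(12)
        n = 5000
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.12 * g + rng.normal(0, 1, n)
        fit = stats.linregress(g, y)
        t2 = (fit.slope / fit.stderr) ** 2
        assert t2 / (t2 + n - 2) == pytest.approx(fit.rvalue**2, rel=1e-9)

    def test_small_sample_raises(self):
        inst = make_instruments([0.1], [0.01], [0.005], [0.01])
        with pytest.raises(ValueError):
            steiger(inst, n_exposure=2, n_outcome=100)
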