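"""Estimator correctness against closed-form and simulation oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rnafep.constants import kt
from rnafep.estimators import (
    bar_estimate,
    combine_bidirectional,
    estimate_step,
    fep_window_estimate,
    leg_estimate,
    ti_estimate,
    ti_step_estimate,
)
from rnafep.synthetic import gen_fep_window, gen_step_legs, gen_ti_profile
from rnafep.types import (
    Direction,
    Environment,
    LambdaWindow,
    StepEstimate,
    StepId,
    TIProfile,
)

T = 298.0


def window(du, direction=Direction.FORWARD, temperature=T, discard=0.0, bounds=(0.0, 1.0)):
    return LambdaWindow(bounds[0], bounds[1], direction, np.asarray(du, float), temperature, discard)


class TestFepWindow:
    def test_constant_integrand_is_exact(self):
        dg, se = fep_window_estimate(window([1.0] * 50))
        assert dg == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_closed_form(self, rng):
        # dG = mu - sigma^2/(2kT) for Gaussian dU
        mu, sigma, n = 1.0, 0.5, 100_000
        du = rng.normal(mu, sigma, n)
        dg, se = fep_window_estimate(window(du))
        expected = mu - sigma**2 / (2 * kt(T))
        assert expected == pytest.approx(0.789, abs=5e-4)
        assert abs(dg - expected) < 3 * max(se, 1e-4)

    def test_discard_is_applied(self):
        # equilibration junk at the head must not bias the estimate
        du = np.concatenate([np.full(20, 100.0), np.full(80, 1.0)])
        dg, _ = fep_window_estimate(window(du, discard=0.2))
        assert dg == pytest.approx(1.0, abs=1e-12)

    def test_empty_after_discard_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            fep_window_estimate(window([1.0], discard=0.0))

    def test_nonfinite_samples_reported_with_indices(self):
        du = [1.0, np.nan, 2.0, np.inf]
        with pytest.raises(ValueError, match=r"\[1, 3\]"):
            fep_window_estimate(window(du))

    def test_antisymmetry_on_negation(self, rng):
        # for constant dU negation flips the estimate exactly; for
        # spread-out dU the exponential average carries a Jensen gap
        # g(dU) + g(-dU) <= 0 that closes quadratically as the spread
        # shrinks -- antisymmetry is asymptotic, not an identity
        dg_f, _ = fep_window_estimate(window([0.7] * 10))
        dg_b, _ = fep_window_estimate(window([-0.7] * 10, Direction.BACKWARD))
        assert dg_f == pytest.approx(-dg_b, abs=1e-14)

        base = rng.standard_normal(2000)
        gaps = []
        for sigma in (0.4, 0.2, 0.1):
            du = 0.5 + sigma * base
            f, _ = fep_window_estimate(window(du))
            b, _ = fep_window_estimate(window(-du, Direction.BACKWARD))
            gap = f + b
            assert gap <= 1e-12  # Jensen: never positive
            gaps.append(-gap)
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.02

    @given(perm_seed=st.integers(0, 1000))
    def test_order_invariance(self, perm_seed):
        base = np.random.default_rng(0).normal(1.0, 0.4, 200)
        shuffled = np.random.default_rng(perm_seed).permutation(base)
        dg1, _ = fep_window_estimate(window(base))
        dg2, _ = fep_window_estimate(window(shuffled))
        assert dg1 == pytest.approx(dg2, abs=1e-12)


class TestLeg:
    def test_additivity(self):
        w1 = window([0.3, 0.3], bounds=(0.0, 0.5))
        w2 = window([-0.1, -0.1], bounds=(0.5, 1.0))
        leg = gen_leg([w1, w2])
        est = leg_estimate(leg)
        assert est.delta_g == pytest.approx(0.2, abs=1e-12)
        assert len(est.per_window) == 2

    def test_single_window_equals_leg(self):
        w = window([1.0, 2.0, 3.0])
        est = leg_estimate(gen_leg([w]))
        assert est.delta_g == pytest.approx(fep_window_estimate(w)[0])

    def test_generated_leg_recovers_truth(self):
        fwd, _ = gen_step_legs(
            StepId.STEP3, Environment.COMPLEX, 3.0, 10, 0.5, 5000, T, seed=1,
            discard_fraction=0.0,
        )
        est = leg_estimate(fwd)
        assert abs(est.delta_g - 3.0) < 3 * est.stderr

    def test_gap_in_coverage_raises(self):
        w1 = window([1.0, 1.0], bounds=(0.0, 0.4))
        w2 = window([1.0, 1.0], bounds=(0.6, 1.0))
        with pytest.raises(ValueError, match="gap"):
            gen_leg([w1, w2])


def gen_leg(windows, step=StepId.STEP3, env=Environment.COMPLEX):
    from rnafep.types import TransformationLeg

    return TransformationLeg(step, env, windows[0].direction, windows)


class TestBidirectionalCombine:
    @pytest.mark.parametrize(
        "fwd,bwd,combined,hyst",
        [(2.0, -2.0, 2.0, 0.0), (2.0, -1.0, 1.5, 1.0)],
    )
    def test_combination_rule(self, fwd, bwd, combined, hyst):
        f = StepEstimate(StepId.STEP2, fwd, 0.1, temperature=T)
        b = StepEstimate(StepId.STEP2, bwd, 0.1, temperature=T)
        est = combine_bidirectional(f, b)
        assert est.delta_g == pytest.approx(combined)
        assert est.hysteresis == pytest.approx(hyst)

    def test_mismatched_step_raises(self):
        f = StepEstimate(StepId.STEP2, 1.0, 0.1)
        b = StepEstimate(StepId.STEP3, -1.0, 0.1)
        with pytest.raises(ValueError, match="step mismatch"):
            combine_bidirectional(f, b)

    def test_exactly_negated_leg_hysteresis(self, rng):
        # constant samples: perfect reversibility, zero to machine
        # precision; noisy samples: hysteresis equals the (small,
        # nonnegative) Jensen gap of the exponential average
        const_f = gen_leg([window([1.0] * 20)])
        const_b = gen_leg([window([-1.0] * 20, Direction.BACKWARD, bounds=(1.0, 0.0))])
        assert estimate_step(const_f, const_b).hysteresis < 1e-13

        sigma = 0.2
        du = rng.normal(1.0, sigma, 5000)
        fwd = gen_leg([window(du)])
        bwd = gen_leg([window(-du, Direction.BACKWARD, bounds=(1.0, 0.0))])
        est = estimate_step(fwd, bwd)
        jensen_gap = sigma**2 / kt(T)  # leading-order gap for Gaussian dU
        assert est.hysteresis == pytest.approx(jensen_gap, rel=0.3)

    def test_hysteresis_shrinks_with_sampling(self):
        medians = []
        for n in (100, 1000, 10000):
            hs = []
            for seed in range(7):
                fwd, bwd = gen_step_legs(
                    StepId.STEP3, Environment.COMPLEX, 3.0, 10, 0.5, n, T,
                    seed=seed, discard_fraction=0.0,
                )
                hs.append(estimate_step(fwd, bwd).hysteresis)
            medians.append(np.median(hs))
        assert medians[0] > medians[1] > medians[2]


class TestBAR:
    def test_symmetric_distributions_give_zero(self, rng):
        f = rng.normal(0.3, 0.8, 20000)
        b = rng.normal(0.3, 0.8, 20000)  # same law: dG_true = 0
        dg = bar_estimate(f, b, T)
        assert abs(dg) < 3 * 0.8 / math.sqrt(20000) * 3

    def test_crooks_pair_recovery_and_fep_agreement(self):
        truth = 1.5
        diffs = []
        for n in (1000, 100_000):
            f, b = gen_fep_window(truth, 0.5, n, n, T, seed=42)
            bar = bar_estimate(f, b, T)
            fep, se = fep_window_estimate(window(f))
            assert abs(bar - truth) < 3 * max(se, 0.01)
            diffs.append(abs(bar - fep))
        assert diffs[1] < diffs[0]  # the two estimators converge together

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            bar_estimate([1.0], [], T)


class TestTI:
    def test_constant_profile(self):
        prof = TIProfile(np.linspace(0, 1, 5), np.full(5, 2.5), np.zeros(5), np.full(5, 10))
        dg, se = ti_estimate(prof)
        assert dg == pytest.approx(2.5, abs=1e-12)
        assert se == 0.0

    def test_two_point_linear_profile_is_exact(self):
        prof = TIProfile([0.0, 1.0], [0.0, 2.0], [0.0, 0.0], [10, 10])
        assert ti_estimate(prof)[0] == pytest.approx(1.0, abs=1e-12)

    def test_harmonic_closed_form(self):
        # (kT/2) ln(1 + beta k sigma^2) = 0.489 kcal/mol at k=10, sigma=0.5 A
        prof, truth = gen_ti_profile(10.0, 0.5, np.linspace(0, 1, 101), 0.0, seed=0)
        dg, _ = ti_estimate(prof)
        assert truth == pytest.approx(0.489, abs=5e-4)
        assert dg == pytest.approx(truth, abs=1e-3)

    def test_nonfinite_mean_raises(self):
        prof = TIProfile([0.0, 1.0], [0.0, 2.0], [0.0, 0.0], [10, 10])
        prof.mean_dudl[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            ti_estimate(prof)

    def test_bidirectional_ti_step(self):
        from rnafep.synthetic import gen_restraint_step_profiles

        fwd, bwd = gen_restraint_step_profiles(-2.5, 0.02, seed=9, temperature=T)
        est = ti_step_estimate(fwd, bwd, StepId.STEP1, temperature=T)
        assert abs(est.delta_g - (-2.5)) < 3 * max(est.stderr, 0.01)
        assert est.hysteresis < 0.2


class TestEstimatorAgreement:
    def test_fep_bar_agree_within_3se_at_large_n(self):
        f, b = gen_fep_window(2.0, 0.5, 10_000, 10_000, T, seed=7)
        fep_f, se_f = fep_window_estimate(window(f))
        fep_b, se_b = fep_window_estimate(window(b, Direction.BACKWARD))
        bar = bar_estimate(f, b, T)
        combined_se = math.hypot(se_f, se_b)
        assert abs(fep_f - bar) < 3 * max(combined_se, 0.01)
        assert abs(-fep_b - bar) < 3 * max(combined_se, 0.01)
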