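import numpy as np
import pytest
from scipy import stats

from mtdel.caller import DeletionCandidate
from mtdel.errormodel import (
    ErrorModel,
    ModelFitError,
    apply_prefilters,
    benjamini_hochberg,
    betabin_logpmf,
    betabin_tail_p,
    filter_calls,
    fit_beta_binomial_mom,
    select_noise_set,
)


def cand(s, w, f=None, cell_type="p"):
    if f is None:
        f = s / (s + w)
    return DeletionCandidate(cell_type, 100, 500, False, s=s, w=w, f=f)


class TestNoiseSelection:
    def test_threshold_is_strict(self):
        cands = [cand(1, 0, f) for f in (0.002, 0.05, 0.009, 0.01)]
        assert [c.f for c in select_noise_set(cands)] == [0.002, 0.009]

    def test_all_above_threshold(self):
        assert select_noise_set([cand(1, 0, 0.5)]) == []


class TestMethodOfMoments:
    def test_hand_computed_example(self):
        # mean 0.005; unbiased variance 6.6667e-6; c = mu(1-mu)/var - 1
        model = fit_beta_binomial_mom([0.002, 0.004, 0.006, 0.008], min_noise=4)
        assert model.mu == pytest.approx(0.005)
        assert model.sigma2 == pytest.approx(6.666667e-6, rel=1e-6)
        assert model.alpha == pytest.approx(3.72625, rel=1e-5)
        assert model.beta == pytest.approx(741.52375, rel=1e-5)
        assert not model.fallback

    def test_symmetric_case(self):
        # mu=0.5, unbiased sigma2=0.125 -> c=1 -> alpha=beta=0.5
        model = fit_beta_binomial_mom([0.25, 0.75], min_noise=2)
        assert model.mu == pytest.approx(0.5)
        assert model.sigma2 == pytest.approx(0.125)
        assert model.alpha == pytest.approx(0.5, rel=1e-9)
        assert model.beta == pytest.approx(0.5, rel=1e-9)

    def test_underdispersion_triggers_fallback(self):
        # variance >= mu(1-mu) makes the shape parameters non-positive
        model = fit_beta_binomial_mom([0.01, 0.99], min_noise=2)
        assert model.fallback

    def test_too_few_noise_variants(self):
        with pytest.raises(ModelFitError):
            fit_beta_binomial_mom([0.001] * 9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ModelFitError):
            fit_beta_binomial_mom([0.25] * 12)

    def test_parameter_recovery_from_beta_samples(self):
        # frequencies drawn from Beta(2, 500) recover the shapes within 15%
        rng = np.random.default_rng(2024)
        freqs = rng.beta(2.0, 500.0, size=5000)
        model = fit_beta_binomial_mom(freqs)
        assert abs(model.alpha - 2.0) / 2.0 < 0.15
        assert abs(model.beta - 500.0) / 500.0 < 0.15


class TestBetaBinomialTail:
    def test_x_zero_is_one(self):
        model = ErrorModel(2.0, 50.0, 0.04, 1e-4, 20)
        assert betabin_tail_p(0, 37, model) == 1.0

    def test_uniform_prior_closed_form(self):
        # alpha=beta=1: P(X>=x) = (n-x+1)/(n+1)
        model = ErrorModel(1.0, 1.0, 0.5, 0.1, 20)
        assert betabin_tail_p(5, 9, model) == pytest.approx(0.5, abs=1e-12)

    def test_three_point_pmf_example(self):
        # alpha=beta=2, n=2: pmf(2) = B(4,2)/B(2,2) = 0.3
        model = ErrorModel(2.0, 2.0, 0.5, 0.01, 20)
        assert betabin_tail_p(2, 2, model) == pytest.approx(0.3, abs=1e-12)

    def test_pmf_sums_to_one(self):
        for n in (1, 17, 200):
            for a, b in ((0.5, 3.0), (2.0, 300.0), (5.0, 5.0)):
                total = np.exp(betabin_logpmf(np.arange(n + 1), n, a, b)).sum()
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_non_increasing_in_x(self):
        model = ErrorModel(2.0, 300.0, 0.0066, 2e-5, 20)
        tails = [betabin_tail_p(x, 50, model) for x in range(51)]
        assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))

    def test_binomial_limit(self):
        # alpha = p*kappa, beta = (1-p)*kappa with huge kappa -> binomial
        p, kappa = 0.02, 1e6
        model = ErrorModel(p * kappa, (1 - p) * kappa, p, 1e-9, 20)
        for n in (10, 50):
            for x in range(0, n + 1, 5):
                expected = stats.binom.sf(x - 1, n, p)
                assert betabin_tail_p(x, n, model) == pytest.approx(expected, abs=1e-3)

    def test_agrees_with_scipy_betabinom(self):
        model = ErrorModel(3.7, 740.0, 0.005, 6.7e-6, 20)
        for n, x in ((40, 2), (200, 7), (500, 1)):
            expected = stats.betabinom.sf(x - 1, n, model.alpha, model.beta)
            assert betabin_tail_p(x, n, model) == pytest.approx(expected, rel=1e-9)

    def test_fallback_uses_binomial(self):
        model = ErrorModel(float("nan"), float("nan"), 0.005, 0.0, 0, fallback=True)
        assert betabin_tail_p(3, 100, model) == pytest.approx(
            stats.binom.sf(2, 100, 0.005)
        )

    def test_invalid_arguments(self):
        model = ErrorModel(1.0, 1.0, 0.5, 0.1, 20)
        with pytest.raises(ValueError):
            betabin_tail_p(5, 4, model)
        with pytest.raises(ValueError):
            betabin_tail_p(-1, 4, model)


class TestPrefilters:
    def test_exclusion_rules(self):
        kept = apply_prefilters([cand(1, 10), cand(3, 0), cand(3, 9)])
        assert [(c.s, c.w) for c in kept] == [(3, 9)]

    def test_excluded_candidates_flagged(self):
        c1, c2 = cand(1, 10), cand(3, 0)
        apply_prefilters([c1, c2])
        assert c1.reason == "single_read_support"
        assert c2.reason == "no_wildtype_reads"
        assert not c1.passed and not c2.passed


class TestBenjaminiHochberg:
    def test_hand_computed_table(self):
        q = benjamini_hochberg([0.01, 0.02, 0.04])
        assert q == pytest.approx([0.03, 0.03, 0.04])

    def test_single_value(self):
        assert benjamini_hochberg([1.0]) == pytest.approx([1.0])

    def test_sorted_input_gives_monotone_q(self):
        rng = np.random.default_rng(5)
        p = np.sort(rng.random(40))
        q = benjamini_hochberg(p)
        assert np.all(np.diff(q) >= -1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(6)
        p = rng.random(100)
        assert np.all(benjamini_hochberg(p) >= p - 1e-12)

    def test_stable_on_constant_sequences(self):
        # adjusting a flat sequence changes nothing: m*p/j is minimized at
        # j=m where it equals p
        p = np.full(20, 0.2)
        q = benjamini_hochberg(p)
        assert q == pytest.approx(p)
        assert benjamini_hochberg(q) == pytest.approx(q)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(8)
        p = rng.random(200)
        expected = sm.multipletests(p, method="fdr_bh")[1]
        assert benjamini_hochberg(p) == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    def test_property_q_bounds_and_order_equivariance(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=50, derandomize=True, deadline=None)
        @given(
            st.lists(
                st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                min_size=1,
                max_size=60,
            )
        )
        def check(p):
            q = benjamini_hochberg(p)
            p_arr = np.asarray(p)
            assert np.all(q >= p_arr - 1e-12)
            assert np.all(q <= 1.0 + 1e-12)
            # adjusting a permutation permutes the adjustment
            order = np.argsort(p_arr, kind="stable")
            assert benjamini_hochberg(p_arr[order]) == pytest.approx(q[order])

        check()


class TestFilterCalls:
    def _noise(self, n=30):
        rng = np.random.default_rng(9)
        out = []
        for _ in range(n):
            w = int(rng.integers(200, 400))
            out.append(cand(1, w))
        return out

    def test_single_strong_survivor_passes(self):
        cands = self._noise() + [cand(40, 160)]
        passing, model = filter_calls(cands)
        assert [c.s for c in passing] == [40]
        assert passing[0].q < 0.05
        assert model.n_noise == 30

    def test_boundary_q_fails_strictly(self):
        model = ErrorModel(1.0, 1.0, 0.5, 0.1, 20)
        c = cand(5, 5)
        c.q = 0.05
        # strict inequality: a q exactly at the threshold is not a call
        passing, _ = filter_calls([cand(2, 1)], model=model, fdr=0.5001)
        assert all(x.q < 0.5001 for x in passing)

    def test_zero_survivors_ok(self):
        passing, model = filter_calls(self._noise() + [cand(1, 50)])
        assert passing == []

    def test_unfitted_without_noise_raises(self):
        with pytest.raises(ModelFitError):
            filter_calls([cand(5, 10)])


def test_fdr_controlled_on_simulated_null_junctions():
    """Noise-only candidate sets simulated from the fitted model keep the
    empirical false-discovery proportion within the nominal level.

    Every injected junction is tested (support pre-filters disabled) so the
    multiplicity correction sees the entire null family; with all-null
    input the false-discovery proportion per replicate is 1 whenever any
    candidate is rejected.
    """
    rng = np.random.default_rng(11)
    fit_freqs = rng.beta(2.0, 400.0, size=500)
    model = fit_beta_binomial_mom(fit_freqs)
    n_rep, fdp = 200, []
    for _ in range(n_rep):
        n = rng.integers(100, 400, size=100)
        pi = rng.beta(model.alpha, model.beta, size=100)
        s = rng.binomial(n, pi)
        cands = [
            cand(int(si), int(ni - si), si / ni) for si, ni in zip(s, n)
        ]
        passing, _ = filter_calls(
            cands, model=model, min_support=0, min_wildtype=0
        )
        fdp.append(1.0 if passing else 0.0)  # all candidates are null
    se = np.sqrt(0.05 * 0.95 / n_rep)
    assert np.mean(fdp) <= 0.05 + 2 * se
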