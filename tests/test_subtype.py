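"""Four-model Bayesian classifier, difference test and direction tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from _oracles import quad_log_ml
from migwas.subtype import (MODELS, DomainError, InsufficientDataError,
                            SubtypePrior, classify_table, classify_variant,
                            difference_test, direction_concordance,
                            estimate_correlation, log_marginal_likelihoods,
                            posterior_probabilities)
from migwas.synth import SimConfig, simulate_subtype_pairs


class TestClassifier:
    def test_precise_null_dominates(self):
        """Exact zeros favor NULL; certainty saturates near tau/se.

        The Bayes factor for a zero coordinate against a N(0, tau^2) effect
        is bounded by sqrt(se^2 + tau^2)/se, so NULL is always the argmax at
        (0, 0) but only crosses 95% posterior once se << tau.
        """
        post = classify_variant(0.0, 0.01, 0.0, 0.01, SubtypePrior(corr=0.0))
        assert max(post.posterior, key=post.posterior.get) == "NULL"
        post = classify_variant(0.0, 0.001, 0.0, 0.001,
                                SubtypePrior(corr=0.0))
        assert post.label == "NULL"
        assert post.posterior["NULL"] > 0.95

    def test_one_sided_effect_favors_that_subtype(self):
        post = classify_variant(0.2, 0.02, 0.0, 0.02, SubtypePrior(corr=0.0))
        assert max(post.posterior, key=post.posterior.get) == "MO"

    def test_uninformative_data_returns_the_prior(self):
        post = classify_variant(0.0, 10.0, 0.0, 10.0)
        for m in MODELS:
            assert post.posterior[m] == pytest.approx(0.25, abs=1e-3)
        assert post.label == "unresolved"

    def test_label_swap_symmetry(self):
        a = classify_variant(0.13, 0.021, -0.05, 0.034)
        b = classify_variant(-0.05, 0.034, 0.13, 0.021)
        assert a.posterior["MO"] == pytest.approx(b.posterior["MA"], rel=1e-12)
        assert a.posterior["MA"] == pytest.approx(b.posterior["MO"], rel=1e-12)
        assert a.posterior["NULL"] == pytest.approx(b.posterior["NULL"], rel=1e-12)
        assert a.posterior["BOTH"] == pytest.approx(b.posterior["BOTH"], rel=1e-12)

    def test_shrinking_se_concentrates_on_generating_model(self):
        prior = SubtypePrior()
        last = 0.0
        for se in (0.05, 0.01, 0.002):
            post = classify_variant(0.3, se, 0.3, se, prior)
            assert post.posterior["BOTH"] >= last
            last = post.posterior["BOTH"]
        assert last > 0.999

    def test_closed_form_matches_quadrature_oracle(self, rng):
        """Analytic log marginal likelihoods vs 2-D adaptive integration."""
        prior_grid = []
        for _ in range(40):
            b1 = float(rng.uniform(-0.4, 0.4))
            b2 = float(rng.uniform(-0.4, 0.4))
            # keep |z| moderate so the linear-space quadrature cannot
            # underflow; the closed form itself works at any magnitude
            s_floor = max(abs(b1), abs(b2)) / 20 + 0.01
            prior_grid.append((
                b1, b2,
                float(rng.uniform(s_floor, 0.3)),
                float(rng.uniform(s_floor, 0.3)),
                float(rng.uniform(-0.8, 0.8)), float(rng.uniform(0.05, 0.4))))
        for b1, b2, s1, s2, c, tau in prior_grid:
            closed = log_marginal_likelihoods(b1, s1, b2, s2,
                                              SubtypePrior(tau=tau, corr=c))
            reference = quad_log_ml(b1, b2, s1, s2, c, tau)
            for m in MODELS:
                assert float(closed[m]) == pytest.approx(reference[m],
                                                         abs=1e-6)

    def test_hand_example_against_quadrature(self):
        closed = log_marginal_likelihoods(0.2, 0.02, 0.0, 0.02,
                                          SubtypePrior(corr=0.0))
        reference = quad_log_ml(0.2, 0.0, 0.02, 0.02, 0.0, 0.2)
        for m in MODELS:
            assert float(closed[m]) == pytest.approx(reference[m], abs=1e-6)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(b1=st.floats(-1, 1), b2=st.floats(-1, 1),
           s1=st.floats(1e-4, 10), s2=st.floats(1e-4, 10),
           c=st.floats(-0.99, 0.99), tau=st.floats(1e-3, 1))
    def test_posteriors_normalize(self, b1, b2, s1, s2, c, tau):
        prior = SubtypePrior(tau=tau, corr=c)
        post = posterior_probabilities(
            log_marginal_likelihoods(b1, s1, b2, s2, prior), prior)
        total = sum(float(post[m]) for m in MODELS)
        assert abs(total - 1) < 1e-12

    @pytest.mark.parametrize("bad", [
        dict(corr=1.0), dict(tau=-0.1),
        dict(model_prior=(0.5, 0.5, 0.5, 0.5)),
        dict(both_mixture=(0.7, 0.7)),
    ])
    def test_invalid_priors_rejected(self, bad):
        with pytest.raises(DomainError):
            SubtypePrior(**bad)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(DomainError):
            classify_variant(0.1, 0.0, 0.1, 0.02)

    def test_argmax_label_recovery_on_strong_effects(self, rng):
        """Strong effects (|effect| = 2 tau, se = tau/10): the highest-
        posterior model matches the generating model in >= 90% per class.

        At this noise level the Bayes factor toward an exactly-zero
        coordinate saturates near tau/se, so NULL rarely exceeds the 95%
        labelling threshold; the argmax recovers all classes, and assigned
        >= 95% labels are essentially always correct (checked below).
        """
        tau, c = 0.2, 0.148
        se = tau / 10
        n_per = 400
        cov = np.array([[se ** 2, c * se ** 2], [c * se ** 2, se ** 2]])
        L = np.linalg.cholesky(cov)
        correct_argmax = {}
        wrong_assigned = 0
        n_assigned = 0
        for model in MODELS:
            mu = np.zeros((n_per, 2))
            signs = rng.choice([-1.0, 1.0], size=(n_per, 2))
            if model == "MO":
                mu[:, 0] = 2 * tau * signs[:, 0]
            elif model == "MA":
                mu[:, 1] = 2 * tau * signs[:, 1]
            elif model == "BOTH":
                mu[:, 0] = 2 * tau * signs[:, 0]
                mu[: n_per // 2, 1] = mu[: n_per // 2, 0]
                mu[n_per // 2:, 1] = 2 * tau * signs[n_per // 2:, 1]
            b = mu + rng.standard_normal((n_per, 2)) @ L.T
            lm = log_marginal_likelihoods(b[:, 0], np.full(n_per, se),
                                          b[:, 1], np.full(n_per, se))
            post = posterior_probabilities(lm)
            pp = np.stack([post[m] for m in MODELS])
            argmax = np.array(MODELS, dtype=object)[pp.argmax(0)]
            correct_argmax[model] = (argmax == model).mean()
            assigned = pp.max(0) > 0.95
            n_assigned += assigned.sum()
            wrong_assigned += (assigned & (argmax != model)).sum()
        for model, frac in correct_argmax.items():
            assert frac >= 0.90, f"{model}: argmax recovery {frac:.3f}"
        assert n_assigned > 0
        assert wrong_assigned / n_assigned < 0.01


class TestDifferenceTest:
    def test_equal_effects_give_null(self):
        z, p, flag = difference_test(0.1, 0.02, 0.1, 0.03)
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)
        assert not flag

    def test_independence_limit_matches_two_sample_z(self):
        z, p, _ = difference_test(0.15, 0.02, 0.05, 0.04, corr=0.0)
        z_ref = (0.15 - 0.05) / np.sqrt(0.02 ** 2 + 0.04 ** 2)
        assert z == pytest.approx(z_ref, rel=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z_ref)), rel=1e-12)

    def test_hand_computed_correlated_case(self):
        z, p, _ = difference_test(0.10, 0.02, 0.02, 0.02, corr=0.148)
        var = 0.02 ** 2 + 0.02 ** 2 - 2 * 0.148 * 0.02 * 0.02
        z_ref = 0.08 / np.sqrt(var)
        assert z == pytest.approx(z_ref, rel=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(z_ref), rel=1e-12)

    def test_degenerate_variance_is_an_error(self):
        # var = (s1-s2)^2 + 2 s1 s2 (1-c) is zero only at c = 1, s1 = s2
        with pytest.raises(DomainError):
            difference_test(0.1, 0.01, 0.2, 0.01, corr=1.0)


class TestCorrelationEstimate:
    def test_identical_tables_give_unit_correlation(self):
        cfg = SimConfig(n_variants=500, subtype_model_probs=(1, 0, 0, 0),
                        seed=5)
        _, mo, _ = simulate_subtype_pairs(cfg)
        assert estimate_correlation(mo, mo) == pytest.approx(1.0)

    def test_generator_correlation_recovered(self):
        cfg = SimConfig(n_variants=50_000,
                        subtype_model_probs=(1, 0, 0, 0), seed=8)
        _, mo, ma = simulate_subtype_pairs(cfg)
        c = estimate_correlation(mo, ma)
        mc_se = (1 - 0.148 ** 2) / np.sqrt(50_000)
        assert abs(c - 0.148) < 3 * mc_se

    def test_associated_and_rare_variants_excluded(self):
        cfg = SimConfig(n_variants=2_000, seed=6)
        _, mo, ma = simulate_subtype_pairs(cfg)
        # force every variant rare: nothing qualifies
        mo_rare = mo.assign(EAF=0.01)
        ma_rare = ma.assign(EAF=0.01)
        with pytest.raises(InsufficientDataError):
            estimate_correlation(mo_rare, ma_rare)


class TestDirectionConcordance:
    def test_half_agreement_is_exactly_null(self):
        a = np.r_[np.ones(50), np.ones(50)]
        b = np.r_[np.ones(50), -np.ones(50)]
        assert direction_concordance(a, b).p == pytest.approx(1.0)

    def test_full_agreement_exact_tail(self):
        a = np.ones(100)
        res = direction_concordance(a, a)
        assert res.p == pytest.approx(2 * 0.5 ** 100, rel=1e-9)
        assert res.n_agree == 100

    def test_two_sided_symmetry(self):
        none = direction_concordance(np.ones(10), -np.ones(10))
        all_ = direction_concordance(np.ones(10), np.ones(10))
        assert none.p == pytest.approx(all_.p, rel=1e-12)

    def test_zero_effects_dropped(self):
        res = direction_concordance([1.0, 0.0, -1.0], [1.0, 1.0, -1.0])
        assert res.n_total == 2 and res.n_agree == 2


def test_classify_table_round_trip():
    cfg = SimConfig(n_variants=300, seed=12, subtype_se=0.02)
    truth, mo, ma = simulate_subtype_pairs(cfg)
    out = classify_table(mo, ma)
    assert len(out) == 300
    assert set(out["LABEL"]).issubset(set(MODELS) | {"unresolved"})
    pp = out[[f"PP_{m}" for m in MODELS]].to_numpy()
    np.testing.assert_allclose(pp.sum(axis=1), 1.0, atol=1e-12)
    labelled = out["LABEL"] != "unresolved"
    assert (pp.max(axis=1)[labelled] > 0.95).all()
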