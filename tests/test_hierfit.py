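"""Hierarchical DE-MCMC machinery: densities, determinism, sampler
correctness on prior-only data, contraction, and summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import halfnorm, norm, truncnorm

import emolba.lba as lba
from emolba.design import CELLS, NULL_MODEL
from emolba.hierfit import (
    PosteriorFit,
    SamplerConfig,
    SubjectData,
    log_posterior,
    prepare_subject_data,
    sample_posterior,
    truncnorm_logpdf,
)
from emolba.simulate import GeneratorConfig, gen_dataset

TINY = SamplerConfig(n_chains=12, n_burn=40, n_sample=80, thin=2, seed=5)


def tiny_dataset(n_participants=3, blocks=2, trials_per_block=12, seed=0):
    cfg = GeneratorConfig(
        n_participants=n_participants, blocks=blocks, trials_per_block=trials_per_block
    )
    trials, truth = gen_dataset(cfg, seed=seed)
    return prepare_subject_data(trials), truth


class TestTruncnormLogpdf:
    def test_matches_scipy(self, rng):
        x = rng.normal(1.0, 1.0, size=50)
        for lower in (0.0, -np.inf):
            ours = truncnorm_logpdf(x, 0.8, 0.5, lower)
            a = (lower - 0.8) / 0.5 if np.isfinite(lower) else -np.inf
            ref = truncnorm.logpdf(x, a, np.inf, loc=0.8, scale=0.5)
            np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_outside_support_is_minus_inf(self):
        assert truncnorm_logpdf(-0.1, 1.0, 1.0, 0.0) == -np.inf
        assert truncnorm_logpdf(1.0, 1.0, 0.0, 0.0) == -np.inf


class TestLogPosterior:
    def test_outside_support_is_minus_inf(self):
        data, _ = tiny_dataset(2)
        spec = NULL_MODEL
        theta = np.tile([2.0, -0.5, 0.3, 2.0, 0.5], (2, 1))  # B <= 0
        assert log_posterior(theta, np.full(5, 2.0), np.full(5, 0.3), data, spec) == -np.inf

    def test_matches_independent_recomputation(self):
        """Brute-force recomputation through the scipy code path: per-trial
        defective densities + truncated-Normal and half-Normal prior terms."""
        data, _ = tiny_dataset(2, blocks=2, trials_per_block=12, seed=4)
        spec = NULL_MODEL
        rng = np.random.default_rng(8)
        theta = np.abs(rng.normal([2, 2, 0.3, 2, 0.5], 0.1, size=(2, 5)))
        phi_loc = np.array([2.0, 1.9, 0.3, 2.1, 0.4])
        phi_scale = np.array([0.3, 0.3, 0.1, 0.4, 0.4])

        expected = 0.0
        mu0, sd0 = spec.prior_loc_sd()
        lb = spec.lower_bounds()
        for d in range(5):
            if np.isfinite(lb[d]):
                a = (lb[d] - phi_loc[d]) / phi_scale[d]
                a0 = (lb[d] - mu0[d]) / sd0[d]
            else:
                a = a0 = -np.inf
            expected += truncnorm.logpdf(
                phi_loc[d], a0, np.inf, loc=mu0[d], scale=sd0[d]
            )
            expected += halfnorm.logpdf(phi_scale[d])
            for s in range(2):
                expected += truncnorm.logpdf(
                    theta[s, d], a, np.inf, loc=phi_loc[d], scale=phi_scale[d]
                )
        for s, sd_ in enumerate(data):
            cells = spec.expand_subject_params(theta[s])
            trials = [
                lba.ChoiceRT(
                    "aberrant" if sd_.resp[i] else "normative",
                    sd_.rt[i],
                    cell=CELLS[sd_.cell[i]],
                )
                for i in range(sd_.n_trials)
            ]
            expected += lba.dataset_loglik(trials, cells)

        actual = log_posterior(theta, phi_loc, phi_scale, data, spec)
        assert actual == pytest.approx(expected, abs=1e-6)

    def test_prior_mode_recovered_without_data(self):
        """With no trials the subject-level conditional mode sits at the
        population location."""
        from scipy.optimize import minimize

        empty = [SubjectData("s1", np.empty(0), np.empty(0, np.int64), np.empty(0, np.int64)),
                 SubjectData("s2", np.empty(0), np.empty(0, np.int64), np.empty(0, np.int64))]
        spec = NULL_MODEL
        loc = np.array([2.0, 2.0, 0.3, 2.0, 0.5])
        scale = np.full(5, 0.5)

        def neg(th):
            v = log_posterior(np.tile(th, (2, 1)), loc, scale, empty, spec)
            return -v if np.isfinite(v) else 1e9

        res = minimize(neg, loc + 0.1, method="Nelder-Mead", options={"xatol": 1e-6})
        np.testing.assert_allclose(res.x, loc, atol=1e-3)


class TestSampler:
    def test_deterministic_under_seed(self):
        data, _ = tiny_dataset(2, seed=1)
        fit_a = sample_posterior(data, "null", TINY)
        fit_b = sample_posterior(data, "null", TINY)
        np.testing.assert_array_equal(fit_a.theta, fit_b.theta)
        np.testing.assert_array_equal(fit_a.phi_loc, fit_b.phi_loc)
        np.testing.assert_array_equal(fit_a.loglik, fit_b.loglik)

    def test_needs_two_subjects(self):
        data, _ = tiny_dataset(3, seed=1)
        with pytest.raises(ValueError):
            sample_posterior(data[:1], "null", TINY)

    def test_prior_only_sampling_reproduces_prior(self):
        """With empty data the population-location marginals must match
        their priors — a standard sampler-correctness check."""
        empty = [
            SubjectData(f"s{i}", np.empty(0), np.empty(0, np.int64), np.empty(0, np.int64))
            for i in range(4)
        ]
        cfg = SamplerConfig(
            n_chains=16, n_burn=300, n_sample=900, thin=3, seed=2, init="prior"
        )
        fit = sample_posterior(empty, "null", cfg)
        pooled = fit.pooled_phi_loc()
        mu0, sd0 = NULL_MODEL.prior_loc_sd()
        lb = NULL_MODEL.lower_bounds()
        for d, name in enumerate(fit.param_names):
            a = (lb[d] - mu0[d]) / sd0[d] if np.isfinite(lb[d]) else -np.inf
            ref = truncnorm(a, np.inf, loc=mu0[d], scale=sd0[d])
            assert pooled[:, d].mean() == pytest.approx(ref.mean(), abs=0.3 * sd0[d]), name
            assert pooled[:, d].std() == pytest.approx(ref.std(), rel=0.35), name

    def test_posterior_contraction_with_more_trials(self):
        """Doubling trials per subject shrinks the average population-location
        posterior SD."""
        sds = {}
        for blocks in (1, 4):
            cfg = GeneratorConfig(n_participants=5, blocks=blocks, trials_per_block=24)
            trials, _ = gen_dataset(cfg, seed=6)
            fit = sample_posterior(
                prepare_subject_data(trials),
                "null",
                SamplerConfig(n_chains=16, n_burn=150, n_sample=300, thin=2, seed=6),
            )
            sds[blocks] = fit.summary()["sd"].mean()
        assert sds[4] < sds[1]


@pytest.fixture(scope="module")
def fit():
    cfg = GeneratorConfig(n_participants=3, blocks=2, trials_per_block=24)
    trials, _ = gen_dataset(cfg, seed=11)
    return sample_posterior(prepare_subject_data(trials), "core", TINY)


class TestPosteriorSummaries:
    def test_draw_counts(self, fit):
        assert fit.theta.shape[:2] == (TINY.n_chains, TINY.n_sample // TINY.thin)

    def test_pooled_mean_equals_weighted_chain_means(self, fit):
        pooled = fit.pooled_phi_loc()[:, 0].mean()
        per_chain = fit.phi_loc[:, :, 0].mean(axis=1)
        assert pooled == pytest.approx(per_chain.mean(), abs=1e-12)

    def test_summaries_invariant_to_chain_order(self, fit):
        perm = np.random.default_rng(0).permutation(fit.theta.shape[0])
        shuffled = PosteriorFit(
            model=fit.model,
            param_names=fit.param_names,
            subject_ids=fit.subject_ids,
            theta=fit.theta[perm],
            phi_loc=fit.phi_loc[perm],
            phi_scale=fit.phi_scale[perm],
            loglik=fit.loglik[perm],
            config=fit.config,
            fingerprint=fit.fingerprint,
        )
        pd.testing.assert_frame_equal(fit.summary(), shuffled.summary())

    def test_constant_chains_degenerate_summary(self, fit):
        const = PosteriorFit(
            model=fit.model,
            param_names=fit.param_names,
            subject_ids=fit.subject_ids,
            theta=np.full_like(fit.theta, 1.7),
            phi_loc=np.full_like(fit.phi_loc, 1.7),
            phi_scale=np.full_like(fit.phi_scale, 0.2),
            loglik=np.zeros_like(fit.loglik),
            config=fit.config,
            fingerprint=fit.fingerprint,
        )
        row = const.summary().iloc[0]
        assert row["mean"] == pytest.approx(1.7)
        assert row["ci2.5"] == row["ci97.5"] == pytest.approx(1.7)

    def test_banova_table_shape_and_errors(self, fit):
        table = fit.banova_table("mean_v.normative")
        assert table.shape == (3, 4)
        assert not table.isna().any().any()
        with pytest.raises(ValueError):
            fit.banova_table("A")  # not cell-split

    def test_save_load_round_trip(self, fit, tmp_path):
        fit.save(tmp_path / "fit")
        back = PosteriorFit.load(tmp_path / "fit")
        np.testing.assert_array_equal(back.theta, fit.theta)
        assert back.model == fit.model
        assert back.fingerprint == fit.fingerprint
        assert back.param_names == fit.param_names
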