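"""Baseline MLE, boosting selection, pruning and MCMC estimation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import nutrimap as nm
from nutrimap import simulate as sim
from nutrimap.distribution import PARAM_LABELS, RESPONSES
from nutrimap.fitting import SelectionFrequencies, fit_baseline
from nutrimap.terms import ModelSpec, pspline


class TestBaseline:
    def test_matches_sample_moment_oracle(self, plain_survey):
        tab = plain_survey.observations
        fit = fit_baseline(tab)
        params = fit.predict_mvn(tab.head(1))
        y = tab[list(RESPONSES)].to_numpy()
        assert np.allclose(params.mu[0], y.mean(axis=0), atol=1e-6)
        assert np.allclose(params.sigma[0], np.cov(y.T, ddof=0), atol=1e-6)

    def test_monte_carlo_recovery(self, plain_config):
        cfg = dataclasses.replace(plain_config, n_clusters=2000, children_per_cluster=(25, 25))
        out = sim.simulate_survey(cfg, seed=31)  # 50,000 children
        fit = fit_baseline(out.observations)
        params = fit.predict_mvn(out.observations.head(1))
        base = plain_config.base_sigma
        sd = np.sqrt(np.diag(base))
        assert np.abs((params.mu[0] - plain_config.base_mu) / sd).max() < 0.02
        assert np.abs((params.sigma[0] - base) / np.outer(sd, sd)).max() < 0.02

    def test_minimal_input_returns_14_intercepts(self, plain_config):
        cfg = dataclasses.replace(plain_config, n_clusters=1, children_per_cluster=(20, 20))
        tab = sim.simulate_survey(cfg, seed=1).observations
        fit = fit_baseline(tab)
        assert sorted(fit.coefficients) == sorted(PARAM_LABELS)
        assert all(len(v) == 1 and v[0].size == 1 for v in fit.coefficients.values())

    def test_too_few_rows_raise(self, plain_survey):
        with pytest.raises(ValueError, match="at least 20"):
            fit_baseline(plain_survey.observations.head(5))

    def test_degenerate_responses_raise(self, plain_survey):
        tab = plain_survey.observations.head(100).copy()
        for r in RESPONSES:
            tab[r] = 1.0
        with pytest.raises(ValueError, match="singular"):
            fit_baseline(tab)


@pytest.fixture(scope="module")
def effectful_data(plain_config):
    """mu_haz driven by age (1 SD of HAZ across the age range) + noise covariates."""
    cfg = dataclasses.replace(
        plain_config,
        effects=[sim.Effect("mu_haz", "age", "linear", 1.1, center=32.5, scale=26.5)],
    )
    tab = sim.simulate_survey(cfg, seed=41).observations
    rng = np.random.default_rng(42)
    for i in range(5):
        tab[f"noise{i}"] = rng.normal(size=len(tab))
    spec = ModelSpec.with_terms(
        {
            label: [pspline("age")] + [pspline(f"noise{i}") for i in range(5)]
            for label in PARAM_LABELS
        }
    )
    return tab, spec


class TestBoosting:
    def test_zero_iterations_select_nothing(self, effectful_data):
        tab, spec = effectful_data
        freqs = nm.boost_select(tab.head(500), spec, n_iter=0, seed=0)
        assert (freqs.table["frequency"] == 0).all()

    def test_true_age_effect_outranks_noise(self, effectful_data):
        tab, spec = effectful_data
        freqs = nm.boost_select(tab.head(5000), spec, n_iter=300, seed=1)
        age = freqs.frequency("mu_haz", "pspline(age)")
        noise = [freqs.frequency("mu_haz", f"pspline(noise{i})") for i in range(5)]
        assert age > max(noise)
        assert age > 0.05

    def test_training_loglik_monotone(self, effectful_data):
        tab, spec = effectful_data
        freqs = nm.boost_select(tab.head(2000), spec, n_iter=60, seed=2)
        trace = freqs.train_trace
        assert trace is not None and len(trace) == 60
        assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[:-1]))

    def test_holdout_trace_reports_best_iteration(self, effectful_data):
        tab, spec = effectful_data
        freqs = nm.boost_select(tab.head(3000), spec, n_iter=40, seed=3, holdout_frac=0.1)
        assert freqs.holdout_trace is not None and len(freqs.holdout_trace) == 40
        assert 1 <= freqs.best_n_iter <= 40


class TestPruning:
    def make_freqs(self, mapping):
        rows = [
            {"parameter": p, "term": t, "frequency": f} for (p, t), f in mapping.items()
        ]
        return SelectionFrequencies(table=pd.DataFrame(rows), n_iter=100)

    def test_zero_threshold_keeps_everything(self):
        spec = ModelSpec.with_terms({"mu_haz": [pspline("age")]})
        freqs = self.make_freqs({("mu_haz", "pspline(age)"): 0.0})
        assert nm.prune_spec(spec, freqs, threshold=0.0) == spec

    def test_above_one_threshold_gives_intercept_only(self):
        spec = ModelSpec.with_terms({"mu_haz": [pspline("age")]})
        freqs = self.make_freqs({("mu_haz", "pspline(age)"): 0.9})
        pruned = nm.prune_spec(spec, freqs, threshold=1.0 + 1e-9)
        assert pruned == ModelSpec.intercept_only()

    def test_threshold_rule(self):
        spec = ModelSpec.with_terms({"mu_haz": [pspline("age"), pspline("noise")]})
        freqs = self.make_freqs(
            {("mu_haz", "pspline(age)"): 0.4, ("mu_haz", "pspline(noise)"): 0.01}
        )
        pruned = nm.prune_spec(spec, freqs, threshold=0.05)
        labels = [t.label for t in pruned.parameter_terms["mu_haz"]]
        assert labels == ["intercept", "pspline(age)"]


class TestMCMC:
    def test_identical_seed_identical_chains(self, plain_survey):
        tab = plain_survey.observations.head(1500)
        spec = ModelSpec.intercept_only()
        a = nm.fit_mcmc(tab, spec, n_iter=120, burn_in=60, thin=3, seed=5)
        b = nm.fit_mcmc(tab, spec, n_iter=120, burn_in=60, thin=3, seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_posterior_means_match_mle(self, plain_survey):
        tab = plain_survey.observations.head(4000)
        fit = nm.fit_mcmc(tab, ModelSpec.intercept_only(), n_iter=600, burn_in=300, thin=3, seed=6)
        mle = fit_baseline(tab)
        for label, t, lo, hi in fit.sample_index:
            post = fit.samples[:, lo]
            psd = post.std(ddof=1)
            assert abs(post.mean() - mle.coefficients[label][0][0]) < max(2 * psd, 1e-3)

    def test_posterior_sd_clt_scaling(self, plain_config):
        """Posterior SD of the Hb mean shrinks ~2x when n grows 4x."""
        cfg_small = dataclasses.replace(plain_config, n_clusters=100)
        cfg_big = dataclasses.replace(plain_config, n_clusters=400)
        sds = []
        for cfg, seed in [(cfg_small, 51), (cfg_big, 52)]:
            tab = sim.simulate_survey(cfg, seed=seed).observations
            fit = nm.fit_mcmc(
                tab, ModelSpec.intercept_only(), n_iter=700, burn_in=300, thin=2, seed=8
            )
            lo = [x for x in fit.sample_index if x[0] == "mu_hb"][0][2]
            sds.append(fit.samples[:, lo].std(ddof=1))
        ratio = sds[0] / sds[1]
        assert 1.4 < ratio < 2.9

    def test_heldout_score_beats_baseline_on_effectful_data(self, effectful_data):
        tab, _ = effectful_data
        train, test = tab.head(4000), tab.tail(2000)
        spec = ModelSpec.with_terms({"mu_haz": [pspline("age")]})
        fit = nm.fit_mcmc(train, spec, n_iter=400, burn_in=200, thin=4, seed=9, test=test)
        assert fit.final_loglik is not None
        assert fit.final_loglik >= fit.baseline_loglik

    def test_bad_burn_in_rejected(self, plain_survey):
        with pytest.raises(ValueError):
            nm.fit_mcmc(
                plain_survey.observations.head(100),
                ModelSpec.intercept_only(),
                n_iter=10,
                burn_in=20,
            )


def test_full_pipeline_effect_curve_recovery(plain_config):
    """Boosting -> pruning -> MCMC recovers a smooth age effect, a spatial
    field and a covariate-dependent Cholesky coefficient to well under 25% of
    each effect's range."""
    from nutrimap.terms import spatial2d

    cfg = dataclasses.replace(
        plain_config,
        n_clusters=400,
        children_per_cluster=(25, 25),
        bbox=(0.0, 8.0, 0.0, 8.0),
        effect_lengthscale=3.0,
        effects=[
            sim.Effect("mu_haz", "age", "rise_plateau", -0.8),
            sim.Effect("mu_hb", "lonlat", "spatial", 5.0),
            sim.Effect("phi_43", "age", "linear", 0.3, center=32.5, scale=26.5),
        ],
    )
    out = sim.simulate_survey(cfg, seed=21)
    tab = out.observations  # 10,000 children
    rng = np.random.default_rng(5)
    for i in range(3):
        tab[f"noise{i}"] = rng.normal(size=len(tab))
    candidates = ModelSpec.with_terms(
        {
            label: [pspline("age")]
            + [pspline(f"noise{i}") for i in range(3)]
            + [spatial2d(basis_size=8)]
            for label in PARAM_LABELS
        }
    )
    freqs = nm.boost_select(tab, candidates, n_iter=300, seed=0)
    pruned = nm.prune_spec(candidates, freqs, threshold=0.05)
    assert any(t.label == "pspline(age)" for t in pruned.parameter_terms["mu_haz"])
    fit = nm.fit_mcmc(tab, pruned, n_iter=600, burn_in=300, thin=6, seed=9)

    ages = np.arange(6, 60)
    ref = tab.head(1).loc[tab.head(1).index.repeat(len(ages))].reset_index(drop=True)
    ref["age"] = ages
    mu, lam, phi = fit.predict_params(ref)
    tmu, _, tphi = out.generator.true_params(ref)

    est = mu[:, 1] - mu[:, 1].mean()
    true = tmu[:, 1] - tmu[:, 1].mean()
    assert np.sqrt(((est - true) ** 2).mean()) < 0.25 * np.ptp(true)

    est43 = phi[:, 3, 2] - phi[:, 3, 2].mean()
    true43 = tphi[:, 3, 2] - tphi[:, 3, 2].mean()
    assert np.sqrt(((est43 - true43) ** 2).mean()) < 0.25 * np.ptp(true43)

    sub = tab.head(2000)
    mu_s, _, _ = fit.predict_params(sub)
    tmu_s, _, _ = out.generator.true_params(sub)
    est_sp = mu_s[:, 0] - mu_s[:, 0].mean()
    true_sp = tmu_s[:, 0] - tmu_s[:, 0].mean()
    assert np.sqrt(((est_sp - true_sp) ** 2).mean()) < 0.25 * np.ptp(true_sp)
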