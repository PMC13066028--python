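"""Design-matrix construction and additive predictor evaluation."""

import numpy as np
import pandas as pd
import pytest

from nutrimap import distribution as dist
from nutrimap.terms import (
    DesignSet,
    ModelSpec,
    TermSpec,
    default_candidate_spec,
    eta_to_params,
    evaluate_predictor,
    intercept,
    linear,
    pspline,
    pspline_basis,
    spatial2d,
    spatial2d_basis,
)


@pytest.fixture
def small_table():
    rng = np.random.default_rng(0)
    n = 200
    return pd.DataFrame(
        {
            "age": rng.uniform(6, 59, n),
            "lon": rng.uniform(0, 10, n),
            "lat": rng.uniform(0, 10, n),
            "sex": rng.choice(["female", "male"], n),
            "x1": rng.normal(size=n),
        }
    )


class TestPsplineBasis:
    def test_partition_of_unity(self):
        x = np.random.default_rng(1).uniform(-3, 7, 500)
        blk = pspline_basis(x, basis_size=15)
        assert np.allclose(blk.matrix.sum(axis=1), 1.0)

    def test_difference_penalty_annihilates_linear_coefficients(self):
        blk = pspline_basis(np.linspace(0, 1, 50), basis_size=12, penalty_order=2)
        j = np.arange(12, dtype=float)
        c = 2.0 + 3.0 * j  # linear in knot index: in the order-2 null space
        assert c @ blk.penalty @ c == pytest.approx(0.0, abs=1e-10)
        c2 = j**2
        assert c2 @ blk.penalty @ c2 > 0

    def test_penalty_is_symmetric_psd(self):
        blk = pspline_basis(np.linspace(0, 1, 50), basis_size=10, penalty_order=1)
        assert np.allclose(blk.penalty, blk.penalty.T)
        assert np.linalg.eigvalsh(blk.penalty).min() >= -1e-10

    def test_constant_covariate_warns_and_stays_constant(self, small_table):
        tab = small_table.assign(const=1.0)
        with pytest.warns(UserWarning, match="rank deficient"):
            pspline_basis(tab["const"].to_numpy(), basis_size=8)
        # built term: centred design of a constant covariate is identically zero,
        # so the fitted smooth contributes a constant (absorbed by the intercept)
        from nutrimap.terms import BuiltTerm

        bt = BuiltTerm(pspline("const", basis_size=8), tab)
        assert np.allclose(bt.design(tab), 0.0)

    def test_prediction_clamps_to_training_range(self, small_table):
        from nutrimap.terms import BuiltTerm

        bt = BuiltTerm(pspline("age"), small_table)
        inside = bt.design(pd.DataFrame({"age": [small_table["age"].max()]}))
        outside = bt.design(pd.DataFrame({"age": [200.0]}))
        assert np.allclose(inside, outside)


class TestSpatialBasis:
    def test_constant_surface_recovered(self):
        rng = np.random.default_rng(2)
        lon, lat = rng.uniform(0, 5, 300), rng.uniform(0, 5, 300)
        blk = spatial2d_basis(lon, lat, basis_size=6)
        x = np.column_stack([np.ones(300), blk.matrix])
        c, *_ = np.linalg.lstsq(x, np.full(300, 3.7), rcond=None)
        assert np.allclose(x @ c, 3.7, atol=1e-8)

    def test_smooth_surface_fit(self):
        # noiseless sin*cos surface, grid-searched ridge on the tensor penalty
        rng = np.random.default_rng(3)
        lon, lat = rng.uniform(0, 6, 2000), rng.uniform(0, 6, 2000)
        f = np.sin(lon) * np.cos(lat)
        blk = spatial2d_basis(lon, lat, basis_size=10)
        best = np.inf
        for lam in 10.0 ** np.arange(-6, 4):
            q = blk.matrix.T @ blk.matrix + lam * blk.penalty + 1e-10 * np.eye(100)
            c = np.linalg.solve(q, blk.matrix.T @ f)
            best = min(best, float(np.sqrt(((blk.matrix @ c - f) ** 2).mean())))
        assert best < 0.05

    def test_rowwise_equals_batched(self, small_table):
        from nutrimap.terms import BuiltTerm

        bt = BuiltTerm(spatial2d(basis_size=5), small_table)
        batched = bt.design(small_table)
        rows = np.vstack([bt.design(small_table.iloc[[i]]) for i in range(20)])
        assert np.array_equal(batched[:20], rows)

    def test_degenerate_coordinates_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            spatial2d_basis(np.ones(10), np.ones(10))


class TestModelSpec:
    def test_requires_all_fourteen_parameters(self):
        with pytest.raises(ValueError, match="14"):
            ModelSpec({"mu_hb": [intercept()]})

    def test_requires_intercepts(self):
        terms = {label: [intercept()] for label in dist.PARAM_LABELS}
        terms["mu_hb"] = [linear("age")]
        with pytest.raises(ValueError, match="intercept"):
            ModelSpec(terms)

    def test_yaml_round_trip(self):
        spec = default_candidate_spec()
        again = ModelSpec.from_yaml(spec.to_yaml())
        assert again == spec

    def test_term_validation(self):
        with pytest.raises(ValueError):
            TermSpec("pspline", ("age",), basis_size=2, degree=3)
        with pytest.raises(ValueError):
            TermSpec("spatial2d", ("lon",))
        with pytest.raises(ValueError):
            TermSpec("wiggly", ("age",))


class TestPredictorEvaluation:
    def test_intercept_only_zero_coefs(self, small_table):
        spec = ModelSpec.intercept_only()
        coefs = {label: [np.zeros(1)] for label in dist.PARAM_LABELS}
        eta, params = evaluate_predictor(spec, small_table, coefs)
        assert np.allclose(eta, 0.0)
        assert np.allclose(params.mu, 0.0)
        assert np.allclose(params.sigma, np.eye(4))

    def test_linear_age_effect_scales_with_age_difference(self, small_table):
        spec = ModelSpec.with_terms({"mu_haz": [linear("age")]})
        design = DesignSet(spec, small_table)
        coefs = design.zero_coefs()
        beta = 0.8
        coefs["mu_haz"][1][0] = beta
        eta = design.evaluate_eta(coefs)
        k = dist.PARAM_LABELS.index("mu_haz")
        scale = design.terms["mu_haz"][1].state["scale"]
        ages = small_table["age"].to_numpy()
        expect = beta * (ages[3] - ages[5]) / scale
        assert eta[3, k] - eta[5, k] == pytest.approx(expect)

    def test_linearity_in_coefficients(self, small_table):
        spec = ModelSpec.with_terms(
            {"mu_hb": [pspline("age", basis_size=8)], "lam_waz": [linear("x1")]}
        )
        design = DesignSet(spec, small_table)
        rng = np.random.default_rng(4)
        c1 = {k: [rng.normal(size=v.size) for v in vs] for k, vs in design.zero_coefs().items()}
        c2 = {k: [rng.normal(size=v.size) for v in vs] for k, vs in design.zero_coefs().items()}
        combo = {k: [2.0 * a + 3.0 * b for a, b in zip(c1[k], c2[k])] for k in c1}
        eta = design.evaluate_eta(combo)
        assert np.allclose(eta, 2.0 * design.evaluate_eta(c1) + 3.0 * design.evaluate_eta(c2))

    def test_zero_coefficient_term_changes_nothing(self, small_table):
        base = ModelSpec.intercept_only()
        extended = ModelSpec.with_terms({"mu_whz": [pspline("age", basis_size=8)]})
        d1, d2 = DesignSet(base, small_table), DesignSet(extended, small_table)
        c1, c2 = d1.zero_coefs(), d2.zero_coefs()
        c1["mu_whz"][0][0] = c2["mu_whz"][0][0] = -0.3
        assert np.allclose(d1.evaluate_eta(c1), d2.evaluate_eta(c2))

    def test_missing_covariate_names_column(self, small_table):
        spec = ModelSpec.with_terms({"mu_hb": [linear("rainfall")]})
        with pytest.raises(KeyError, match="rainfall"):
            DesignSet(spec, small_table)

    def test_sigma_matches_term_accumulation_oracle(self, small_table):
        # brute-force oracle: accumulate each term's contribution separately,
        # then build Sigma via the dense reconstruction identity
        spec = ModelSpec.with_terms(
            {
                "mu_haz": [pspline("age", basis_size=8)],
                "lam_hb": [linear("x1")],
                "phi_43": [linear("age"), TermSpec("factor", ("sex",))],
            }
        )
        design = DesignSet(spec, small_table)
        rng = np.random.default_rng(5)
        coefs = {
            k: [rng.normal(scale=0.3, size=v.size) for v in vs]
            for k, vs in design.zero_coefs().items()
        }
        eta = design.evaluate_eta(coefs)
        mu, lam, phi = eta_to_params(eta)
        for i in [0, 17, 111]:
            eta_i = np.zeros(14)
            for k, label in enumerate(dist.PARAM_LABELS):
                for bt, c in zip(design.terms[label], coefs[label]):
                    eta_i[k] += float((bt.design(small_table.iloc[[i]]) @ c)[0])
            mu_i, lam_i, phi_i = dist.unpack_params(eta_i)
            t = np.eye(4) - phi_i
            sigma_oracle = np.linalg.inv(t) @ np.diag(np.exp(2 * lam_i)) @ np.linalg.inv(t).T
            f = dist.CholeskyFactors(phi=phi[i], lam=lam[i])
            assert np.allclose(dist.build_sigma(f), sigma_oracle, atol=1e-10)
            assert np.allclose(mu[i], mu_i)
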