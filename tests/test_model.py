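"""Sampler building blocks and short-chain behaviour of the full fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import invgamma, kstest

from geociaf.graphs import RegionGraph
from geociaf.model import (
    ChainConfig,
    GeoAdditiveLogisticRegression,
    ModelSpec,
    SmoothTerm,
    SpatialTerm,
    bernoulli_deviance,
    build_blocks,
    fit,
    gmrf_conditional,
    linear_predictor,
    update_variance,
)
from geociaf.synthetic import make_lattice_graph

from conftest import RECOVERY_BETA, RECOVERY_SPEC


class TestLinearPredictor:
    def test_toy_hand_product(self):
        data = pd.DataFrame({"g": ["a", "b", "a"], "ciaf": [0, 1, 0]})
        spec = ModelSpec(fixed_terms=(("g", "a"),))
        eta = linear_predictor(spec, {"fixed": np.array([0.5, 1.0])}, data)
        assert np.allclose(eta, [0.5, 1.5, 0.5])

    def test_zero_params_zero_eta_and_block_additivity(self, recovery_dataset, lattice12):
        data = recovery_dataset.records
        spec = RECOVERY_SPEC
        blocks = build_blocks(spec, data, lattice12)
        rng = np.random.default_rng(0)
        params = {b.label: rng.standard_normal(b.n_columns) for b in blocks}
        zeros = {b.label: np.zeros(b.n_columns) for b in blocks}
        assert np.allclose(linear_predictor(spec, zeros, data, lattice12), 0.0)
        full = linear_predictor(spec, params, data, lattice12)
        parts = sum(
            linear_predictor(
                spec, {lbl: params[lbl]}, data, lattice12
            )
            for lbl in params
        )
        assert np.allclose(full, parts, atol=1e-10)

    def test_dimension_mismatch_errors(self):
        data = pd.DataFrame({"g": ["a", "b"], "ciaf": [0, 1]})
        spec = ModelSpec(fixed_terms=(("g", "a"),))
        with pytest.raises(ValueError, match="coefficients"):
            linear_predictor(spec, {"fixed": np.zeros(5)}, data)


class TestDeviance:
    def test_closed_form_and_bounds(self):
        assert bernoulli_deviance([1, 0], [0.0, 0.0]) == pytest.approx(
            -4.0 * np.log(0.5), abs=1e-10
        )
        assert bernoulli_deviance([1.0], [80.0]) == pytest.approx(0.0, abs=1e-8)
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50).astype(float)
        assert bernoulli_deviance(y, rng.standard_normal(50)) >= 0.0

    def test_extreme_eta_stays_finite(self):
        assert np.isfinite(bernoulli_deviance([0.0, 1.0], [1e4, -1e4]))


class TestGmrfConditional:
    def test_examples(self):
        g = make_lattice_graph(1, 3)
        ids = g.region_ids
        effects = {ids[0]: 1.0, ids[1]: 0.0, ids[2]: 3.0}
        mean, var = gmrf_conditional(ids[1], effects, g, variance=2.0)
        assert (mean, var) == (2.0, 1.0)
        mean, var = gmrf_conditional(ids[0], effects, g, variance=2.0)
        assert (mean, var) == (0.0, 2.0)  # single neighbour

    def test_matches_joint_density_brute_force(self):
        """Conditional from Eq-style local form vs the joint exp(-f'Kf/2s2)."""
        g = make_lattice_graph(1, 3)
        K = np.array([[1.0, -1.0, 0.0], [-1.0, 2.0, -1.0], [0.0, -1.0, 1.0]])
        s2 = 0.7
        f_others = {"R00": 0.4, "R02": -1.1}
        grid = np.linspace(-4, 4, 2001)
        log_joint = np.array(
            [
                -np.array([f_others["R00"], fm, f_others["R02"]])
                @ K
                @ np.array([f_others["R00"], fm, f_others["R02"]])
                / (2 * s2)
                for fm in grid
            ]
        )
        w = np.exp(log_joint - log_joint.max())
        w /= w.sum()
        mean_bf = float(grid @ w)
        var_bf = float(((grid - mean_bf) ** 2) @ w)
        mean, var = gmrf_conditional("R01", {**f_others, "R01": 0.0}, g, s2)
        assert mean == pytest.approx(mean_bf, abs=1e-3)
        assert var == pytest.approx(var_bf, rel=1e-3)

    def test_isolated_region_errors(self):
        g = make_lattice_graph(1, 2)
        iso = RegionGraph(("A", "B", "C"), frozenset([frozenset(("A", "B"))]))
        with pytest.raises(ValueError, match="no neighbours"):
            gmrf_conditional("C", {"A": 0.0, "B": 0.0}, iso, 1.0)


class TestVarianceUpdate:
    def test_conjugate_distribution_ks(self):
        """50,000 draws vs the analytic IG(a + rank/2, b + b'Kb/2)."""
        K = np.eye(1)
        beta = np.array([2.0])
        a = b = 0.001
        rng = np.random.default_rng(17)
        draws = np.array([update_variance(beta, K, a, b, rng) for _ in range(50_000)])
        shape, scale = a + 0.5, b + 2.0
        stat = kstest(draws, invgamma(shape, scale=scale).cdf).statistic
        assert stat < 0.02
        assert (draws > 0).all()

    def test_moment_oracle_when_shape_large(self):
        K = np.eye(4)
        beta = np.full(4, 1.5)
        a, b = 3.0, 1.0
        rng = np.random.default_rng(2)
        draws = np.array([update_variance(beta, K, a, b, rng) for _ in range(50_000)])
        shape, scale = a + 2.0, b + 4 * 1.5**2 / 2
        assert draws.mean() == pytest.approx(scale / (shape - 1), rel=0.03)

    def test_zero_coefficients_reduce_to_prior_scale(self):
        rng = np.random.default_rng(0)
        K = np.diag([1.0, 1.0, 0.0])  # rank 2
        draws = np.array(
            [update_variance(np.zeros(3), K, 2.0, 3.0, rng) for _ in range(50_000)]
        )
        assert draws.mean() == pytest.approx(3.0 / (3.0 - 1.0), rel=0.05)

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            update_variance([1.0], np.eye(1), 0.0, 1.0, 0)


class TestFit:
    def test_storage_arithmetic_and_determinism(self, recovery_dataset, lattice12):
        config = ChainConfig(iterations=130, burnin=40, thin=7, seed=5)
        data = recovery_dataset.records.iloc[:400]
        r1 = fit(RECOVERY_SPEC, data, lattice12, config)
        r2 = fit(RECOVERY_SPEC, data, lattice12, config)
        assert r1.n_stored == (130 - 40) // 7
        assert len(r1.deviance_trace) == r1.n_stored
        for lbl in r1.block_draws:
            assert np.array_equal(r1.block_draws[lbl], r2.block_draws[lbl])
        for lbl in r1.variance_samples:
            assert np.array_equal(r1.variance_samples[lbl], r2.variance_samples[lbl])
            assert (r1.variance_samples[lbl] > 0).all()

    def test_fixed_effect_recovery_single_replicate(self, fitted_m3):
        """Posterior means within 3 posterior SDs of the generating truth."""
        draws = fitted_m3.fixed_effect_draws()
        for term, true_val in RECOVERY_BETA.items():
            if term == "intercept":
                continue
            d = draws[term]
            assert abs(d.mean() - true_val) <= 3 * d.std(), term

    def test_outcome_must_be_binary(self, lattice12):
        data = pd.DataFrame(
            {"region": [lattice12.region_ids[0]] * 3, "ciaf": [0, 1, 2]}
        )
        with pytest.raises(ValueError, match="binary"):
            fit(ModelSpec(), data, None, ChainConfig(iterations=10, burnin=0, thin=1))

    def test_region_missing_from_graph(self, lattice12):
        data = pd.DataFrame({"region": ["nowhere"] * 4, "ciaf": [0, 1, 0, 1]})
        spec = ModelSpec(spatial_term=SpatialTerm("region"))
        with pytest.raises(ValueError, match="missing from graph"):
            fit(spec, data, lattice12, ChainConfig(iterations=10, burnin=0, thin=1))

    def test_separation_warns_but_fits(self):
        g = make_lattice_graph(1, 2)
        n = 60
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            {
                "region": rng.choice(g.region_ids, n),
                "x": ["a"] * (n // 2) + ["b"] * (n // 2),
                "ciaf": [0] * (n // 2) + [1] * (n // 2),
            }
        )
        spec = ModelSpec(fixed_terms=(("x", "a"),))
        with pytest.warns(UserWarning, match="separation"):
            res = fit(spec, data, None, ChainConfig(iterations=60, burnin=20, thin=1))
        assert np.isfinite(res.fixed_effect_draws().to_numpy()).all()


class TestEstimatorInterface:
    def test_get_set_params_round_trip(self):
        est = GeoAdditiveLogisticRegression(iterations=100, burnin=10, thin=1)
        params = est.get_params()
        assert params["iterations"] == 100
        est.set_params(thin=2, random_state=9)
        assert est.thin == 2 and est.random_state == 9
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_fit_predict_shapes(self, recovery_dataset, lattice12):
        data = recovery_dataset.records.iloc[:600]
        est = GeoAdditiveLogisticRegression(
            fixed=[("gender", "female"), ("diarrhoea", "no")],
            smooth=["child_age"],
            spatial="region",
            graph=lattice12,
            segments=8,
            iterations=200,
            burnin=50,
            thin=3,
            random_state=1,
        )
        est.fit(data, "ciaf")
        assert est.result_.n_stored == 50
        proba = est.predict_proba(data.iloc[:50])
        assert proba.shape == (50, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert set(est.predict(data.iloc[:50])) <= {0, 1}
        # in-sample posterior probabilities should correlate with outcomes
        p_all = est.predict_proba(data)[:, 1]
        assert p_all[data["ciaf"] == 1].mean() > p_all[data["ciaf"] == 0].mean()

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError):
            GeoAdditiveLogisticRegression().predict_proba(pd.DataFrame())
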