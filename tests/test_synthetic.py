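"""Ground-truth generators: GMRF fields, covariates, outcomes, z-scores."""

import numpy as np
import pandas as pd
import pytest

from geociaf.ciaf import CIAFClassifier
from geociaf.design import gmrf_precision
from geociaf.synthetic import (
    DEFAULT_CATEGORY_MIX,
    default_truth,
    linear_predictor_from_truth,
    make_lattice_graph,
    sample_structured_field,
    simulate_covariates,
    simulate_dataset,
    simulate_outcomes,
    simulate_zscores,
)


class TestStructuredField:
    def test_sum_to_zero_and_determinism(self):
        g = make_lattice_graph(3, 3)
        f1 = sample_structured_field(g, 0.5, seed=3)
        f2 = sample_structured_field(g, 0.5, seed=3)
        assert f1 == f2
        assert abs(sum(f1.values())) < 1e-10

    def test_zero_variance_degenerate(self):
        g = make_lattice_graph(2, 2)
        assert all(v == 0.0 for v in sample_structured_field(g, 0.0, seed=0).values())

    def test_empirical_covariance_matches_pseudoinverse(self):
        """10,000 draws on a 3x3 lattice: cov ~= variance * pinv(K)."""
        g = make_lattice_graph(3, 3)
        K = gmrf_precision(g)
        var = 0.8
        draws = np.array(
            [
                list(sample_structured_field(g, var, seed=rng).values())
                for rng in [np.random.default_rng(99)] * 10_000
            ]
        )
        emp = np.cov(draws.T)
        target = var * np.linalg.pinv(K)
        assert np.abs(emp - target).max() < 0.05

    def test_quadratic_form_has_rank_degrees_of_freedom(self):
        """On the constrained subspace, f'Kf / var ~ chi^2 with rank(K) df."""
        g = make_lattice_graph(1, 6)
        K = gmrf_precision(g)
        var = 0.7
        rng = np.random.default_rng(4)
        draws = np.array(
            [
                list(sample_structured_field(g, var, seed=rng).values())
                for _ in range(20_000)
            ]
        )
        qf = np.einsum("ij,jk,ik->i", draws, K, draws) / var
        df = g.n_regions - 1
        assert qf.mean() == pytest.approx(df, rel=0.05)
        assert qf.var() == pytest.approx(2.0 * df, rel=0.1)


class TestCovariates:
    def test_determinism_and_supports(self):
        g = make_lattice_graph(2, 3)
        a = simulate_covariates(1000, g, seed=5)
        b = simulate_covariates(1000, g, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert a["child_age"].between(0, 59).all()
        assert a["mother_age"].between(15, 49).all()
        assert a["region"].isin(g.region_ids).all()

    def test_category_frequencies_near_targets(self):
        g = make_lattice_graph(2, 2)
        n = 20_000
        df = simulate_covariates(n, g, seed=1)
        for var, probs in DEFAULT_CATEGORY_MIX.items():
            freq = df[var].value_counts(normalize=True)
            for level, p in probs.items():
                tol = 3 * np.sqrt(p * (1 - p) / n)
                assert abs(freq.get(level, 0.0) - p) < tol, (var, level)

    def test_invalid_probabilities_rejected(self):
        g = make_lattice_graph(1, 2)
        with pytest.raises(ValueError, match="sum to"):
            simulate_covariates(10, g, mix={"x": {"a": 0.5, "b": 0.4}}, seed=0)


class TestOutcomes:
    def _null_truth(self, g, intercept=0.0):
        return default_truth(
            g, seed=0, var_str=0.0, var_unstr=0.0, intercept=intercept,
            beta={"intercept": intercept}, nonlinear=False,
        )

    def test_zero_predictor_gives_half(self):
        g = make_lattice_graph(2, 2)
        cov = simulate_covariates(20_000, g, seed=2)
        ds = simulate_outcomes(cov, self._null_truth(g), seed=3, graph=g)
        assert abs(ds.records["ciaf"].mean() - 0.5) < 3 * np.sqrt(0.25 / 20_000)

    def test_saturating_intercept(self):
        g = make_lattice_graph(2, 2)
        cov = simulate_covariates(3000, g, seed=2)
        ds = simulate_outcomes(cov, self._null_truth(g, intercept=10.0), seed=3, graph=g)
        assert ds.records["ciaf"].mean() > 0.999

    def test_binary_covariate_log_odds_recovered(self):
        """Empirical contingency-table log-odds ~ ln 2 at n = 50,000."""
        g = make_lattice_graph(1, 2)
        truth = default_truth(
            g, seed=0, var_str=0.0, var_unstr=0.0,
            beta={"intercept": -0.4, "gender=male": np.log(2.0)}, nonlinear=False,
        )
        cov = simulate_covariates(
            50_000, g, mix={"gender": {"female": 0.5, "male": 0.5}}, seed=8
        )
        ds = simulate_outcomes(cov, truth, seed=9, graph=g)
        tab = pd.crosstab(ds.records["gender"], ds.records["ciaf"])
        lor = np.log(tab.loc["male", 1] * tab.loc["female", 0]) - np.log(
            tab.loc["male", 0] * tab.loc["female", 1]
        )
        # MC error of a log-odds-ratio: sqrt(sum of reciprocal cell counts)
        se = np.sqrt((1.0 / tab.to_numpy()).sum())
        assert abs(lor - np.log(2.0)) < 4 * se

    def test_mean_probability_matches_outcome_mean(self):
        g = make_lattice_graph(3, 2)
        ds = simulate_dataset(15_000, g, seed=21)
        p = 1.0 / (1.0 + np.exp(-ds.eta))
        mc_se = np.sqrt(np.sum(p * (1 - p))) / len(p)
        assert abs(ds.records["ciaf"].mean() - p.mean()) < 4 * mc_se

    def test_truth_missing_covariate_errors(self):
        g = make_lattice_graph(1, 2)
        cov = simulate_covariates(10, g, mix={}, seed=0)
        truth = default_truth(g, seed=0, beta={"nope=yes": 1.0}, nonlinear=False)
        with pytest.raises(ValueError, match="absent"):
            linear_predictor_from_truth(cov, truth)


class TestZscores:
    def test_prevalence_calibration(self):
        zs = simulate_zscores(20_000, target_prevalence=0.413, seed=3)
        out = CIAFClassifier().fit_transform(zs)
        assert abs(out["ciaf"].mean() - 0.413) < 0.02

    def test_independent_scores_factorise(self):
        zs = simulate_zscores(
            200_000, target_prevalence=0.3, correlation=np.eye(3), seed=4
        )
        out = CIAFClassifier(drop_invalid=False).fit_transform(zs)
        p_all = (out[["stunted", "wasted", "underweight"]].all(axis=1)).mean()
        marg = [out[c].mean() for c in ("stunted", "wasted", "underweight")]
        assert p_all == pytest.approx(np.prod(marg), abs=0.003)

    def test_determinism_and_validation(self):
        a = simulate_zscores(500, seed=11)
        b = simulate_zscores(500, seed=11)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            simulate_zscores(100, target_prevalence=1.5, seed=0)
        with pytest.raises(ValueError, match="positive definite"):
            simulate_zscores(100, correlation=np.ones((3, 3)), seed=0)


def test_simulate_dataset_pure_function_of_seed(lattice12):
    d1 = simulate_dataset(400, lattice12, seed=13, include_zscores=True)
    d2 = simulate_dataset(400, lattice12, seed=13, include_zscores=True)
    pd.testing.assert_frame_equal(d1.records, d2.records)
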