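"""Bayesian geo-additive logistic regression by MCMC.

The model for a binary outcome :math:`y_{hi}` of child *i* in region *h* is

.. math::

    \\operatorname{logit} P(y_{hi}=1) = v_i'\\beta + \\sum_r f_r(x_{ir})
        + f_{str}(s_h) + f_{unstr}(s_h)

with diffuse Gaussian priors on the fixed effects :math:`\\beta`, Bayesian
P-spline priors (B-spline basis, random-walk difference penalty) on the
smooth functions, an intrinsic GMRF prior on the structured spatial effect,
iid Gaussian priors on the unstructured effect, and conjugate inverse-gamma
IG(a, b) hyperpriors on every variance component.

Posterior sampling uses Pólya-Gamma latent-variable augmentation: given
:math:`\\omega_i \\sim PG(1, \\eta_i)` the Bernoulli-logit likelihood is
conditionally Gaussian in every coefficient block, so each sweep makes one
exact multivariate-normal draw per block (fixed -> smooths -> structured ->
unstructured) followed by conjugate inverse-gamma variance updates.  The
contract is on the posterior, not the update scheme.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import expit

from .design import (
    DesignBlock,
    apply_sum_to_zero,
    bspline_basis,
    difference_penalty,
    dummy_code,
    gmrf_precision,
)
from .graphs import RegionGraph
from .io import DEFAULT_SCHEMA, ChildTableSchema, data_digest
from .polya_gamma import random_polya_gamma

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothTerm",
    "SpatialTerm",
    "ModelSpec",
    "ChainConfig",
    "FitResult",
    "GeoAdditiveLogisticRegression",
    "fit",
    "build_blocks",
    "linear_predictor",
    "bernoulli_deviance",
    "gmrf_conditional",
    "update_variance",
]

_DIFFUSE_PRECISION = 1e-8  # fixed effects: N(0, 1e8) proper diffuse prior
_PROB_CLAMP = 1e-12


@dataclass(frozen=True)
class SmoothTerm:
    variable: str
    segments: int = 20
    degree: int = 3
    order: int = 2
    a: float = 0.001
    b: float = 0.001


@dataclass(frozen=True)
class SpatialTerm:
    variable: str = "region"
    structured: bool = True
    unstructured: bool = True
    a: float = 0.001
    b: float = 0.001


@dataclass(frozen=True)
class ModelSpec:
    """Term structure of the additive predictor.

    ``fixed_terms`` are (variable, reference) pairs; a ``None`` reference
    marks a continuous covariate entered as a single standardised linear
    column (so that linear and smooth versions of the same covariate live
    on comparable scales).
    """

    outcome: str = "ciaf"
    fixed_terms: tuple = ()
    smooth_terms: tuple = ()
    spatial_term: SpatialTerm | None = None
    intercept: bool = True

    def __post_init__(self):
        for term in self.smooth_terms:
            if term.a <= 0 or term.b <= 0:
                raise ValueError("inverse-gamma hyperparameters must be positive")
        if self.spatial_term is not None and (
            self.spatial_term.a <= 0 or self.spatial_term.b <= 0
        ):
            raise ValueError("inverse-gamma hyperparameters must be positive")


@dataclass(frozen=True)
class ChainConfig:
    iterations: int = 12000
    burnin: int = 2000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.burnin < self.iterations:
            raise ValueError("need 0 <= burnin < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.iterations - self.burnin) // self.thin


@dataclass
class FitResult:
    """Stored posterior draws and everything needed to summarise them."""

    spec: ModelSpec
    config: ChainConfig
    blocks: list[DesignBlock] = field(repr=False, default_factory=list)
    block_draws: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    variance_samples: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    deviance_trace: np.ndarray = field(repr=False, default=None)
    region_ids: tuple[str, ...] = ()
    data_digest: str = ""
    y: np.ndarray = field(repr=False, default=None)

    @property
    def n_stored(self) -> int:
        return len(self.deviance_trace)

    def _block(self, label: str) -> DesignBlock:
        for blk in self.blocks:
            if blk.label == label:
                return blk
        raise KeyError(f"no block labelled {label!r}")

    @property
    def samples(self) -> dict[str, np.ndarray]:
        """Per-block draws mapped to the original (unconstrained) basis."""
        out = {}
        for label, draws in self.block_draws.items():
            out[label] = self._block(label).coefficients_in_original_space(draws)
        return out

    def fixed_effect_draws(self) -> pd.DataFrame:
        blk = self._block("fixed")
        return pd.DataFrame(self.block_draws["fixed"], columns=blk.column_names)

    def spatial_effect_draws(self, which: str = "total") -> pd.DataFrame:
        """(n_draws, n_regions) log-odds draws of the regional effect."""
        parts = []
        labels = {
            "structured": ["spatial_str"],
            "unstructured": ["spatial_unstr"],
            "total": ["spatial_str", "spatial_unstr"],
        }[which]
        for label in labels:
            if label in self.block_draws:
                blk = self._block(label)
                parts.append(blk.coefficients_in_original_space(self.block_draws[label]))
        if not parts:
            raise ValueError(f"fit has no {which} spatial draws")
        return pd.DataFrame(sum(parts), columns=list(self.region_ids))

    def smooth_labels(self) -> list[str]:
        return [b.label for b in self.blocks if b.label.startswith("s(")]

    def posterior_mean_eta(self) -> np.ndarray:
        eta = np.zeros(self.blocks[0].matrix.shape[0])
        for blk in self.blocks:
            eta += blk.matrix @ self.block_draws[blk.label].mean(axis=0)
        return eta


def bernoulli_deviance(y, eta) -> float:
    """-2 log-likelihood of a Bernoulli-logit model, clamped to stay finite."""
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if y.shape != eta.shape:
        raise ValueError("outcome and predictor lengths differ")
    p = np.clip(expit(eta), _PROB_CLAMP, 1.0 - _PROB_CLAMP)
    return float(-2.0 * np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def gmrf_conditional(
    region: str, effects: dict[str, float], graph: RegionGraph, variance: float
) -> tuple[float, float]:
    """Full conditional N(neighbour average, variance / N_s) of one region."""
    nbs = graph.neighbors(region)
    if not nbs:
        raise ValueError(f"region {region!r} has no neighbours")
    mean = float(np.mean([effects[t] for t in nbs]))
    return mean, variance / len(nbs)


def update_variance(
    coeffs, penalty, a: float, b: float, seed: int | np.random.Generator
) -> float:
    """Conjugate draw of a variance component.

    Full conditional is IG(a + rank(K)/2, b + beta' K beta / 2); rank(K)
    rather than the block dimension because the penalty's null space carries
    no information about the variance.
    """
    if a <= 0 or b <= 0:
        raise ValueError("inverse-gamma hyperparameters must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    beta = np.atleast_1d(np.asarray(coeffs, dtype=float))
    K = np.atleast_2d(np.asarray(penalty, dtype=float))
    rank = np.linalg.matrix_rank(K, tol=1e-8 * max(1.0, np.abs(K).max()))
    shape = a + rank / 2.0
    scale = b + float(beta @ K @ beta) / 2.0
    return float(scale / rng.gamma(shape, 1.0))


def _standardise(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu, sd = float(np.mean(x)), float(np.std(x))
    sd = sd if sd > 0 else 1.0
    return (x - mu) / sd, mu, sd


def build_blocks(
    spec: ModelSpec,
    data: pd.DataFrame,
    graph: RegionGraph | None = None,
    schema: ChildTableSchema = DEFAULT_SCHEMA,
) -> list[DesignBlock]:
    """Assemble the per-term design blocks for a model spec on a dataset."""
    n = len(data)

    # ---- fixed block: intercept + continuous linear + dummy-coded terms ----
    cols, names = [], []
    meta_terms = []
    if spec.intercept:
        cols.append(np.ones(n))
        names.append("intercept")
        meta_terms.append(("intercept",))
    for item in spec.fixed_terms:
        var, ref = item if isinstance(item, (tuple, list)) else (item, "__auto__")
        if var not in data.columns:
            raise ValueError(f"fixed term {var!r} not in data")
        if ref is None:  # continuous linear
            z, mu, sd = _standardise(data[var].to_numpy(dtype=float))
            cols.append(z)
            names.append(var)
            meta_terms.append(("linear", var, mu, sd))
        else:
            if ref == "__auto__":
                ref = (
                    schema.reference(var)
                    if var in schema.categorical
                    else sorted(map(str, pd.unique(data[var])))[0]
                )
            levels = (
                schema.levels(var)
                if var in schema.categorical
                else sorted(map(str, pd.unique(data[var])))
            )
            blk = dummy_code(data[var].astype(str).to_numpy(), levels, ref)
            for j, lv in enumerate(blk.column_names):
                cols.append(blk.matrix[:, j])
                names.append(f"{var}={lv}")
            meta_terms.append(("categorical", var, tuple(levels), ref))
    p = len(cols)
    fixed = DesignBlock(
        matrix=np.column_stack(cols) if p else np.empty((n, 0)),
        penalty=np.zeros((p, p)),
        penalty_rank=0,
        label="fixed",
        column_names=names,
        meta={"terms": meta_terms},
    )
    blocks = [fixed]

    # ---- P-spline smooth blocks ----
    for term in spec.smooth_terms:
        x = data[term.variable].to_numpy(dtype=float)
        blk = bspline_basis(x, segments=term.segments, degree=term.degree)
        K = difference_penalty(term.order, blk.n_columns)
        blk.penalty = K
        blk.penalty_rank = blk.n_columns - term.order
        blk.label = f"s({term.variable})"
        blk.meta.update({"variable": term.variable, "a": term.a, "b": term.b})
        blk = apply_sum_to_zero(blk, over="observations")
        blocks.append(blk)

    # ---- spatial blocks ----
    if spec.spatial_term is not None:
        st = spec.spatial_term
        if graph is None:
            raise ValueError("spatial term requested but no region graph supplied")
        graph.require_connected()
        observed = set(map(str, pd.unique(data[st.variable])))
        missing = observed - set(graph.region_ids)
        if missing:
            raise ValueError(f"regions in data missing from graph: {sorted(missing)}")
        R = graph.n_regions
        pos = {r: i for i, r in enumerate(graph.region_ids)}
        idx = data[st.variable].astype(str).map(pos).to_numpy()
        incidence = np.zeros((n, R))
        incidence[np.arange(n), idx] = 1.0
        if st.structured:
            blk = DesignBlock(
                matrix=incidence,
                penalty=gmrf_precision(graph),
                penalty_rank=R - 1,
                label="spatial_str",
                column_names=list(graph.region_ids),
                meta={"variable": st.variable, "a": st.a, "b": st.b},
            )
            blocks.append(apply_sum_to_zero(blk, over="coefficients"))
        if st.unstructured:
            blk = DesignBlock(
                matrix=incidence,
                penalty=np.eye(R),
                penalty_rank=R,
                label="spatial_unstr",
                column_names=list(graph.region_ids),
                meta={"variable": st.variable, "a": st.a, "b": st.b},
            )
            blocks.append(apply_sum_to_zero(blk, over="coefficients"))

    return blocks


def term_matrix(block: DesignBlock, data: pd.DataFrame, region_ids=None) -> np.ndarray:
    """Rebuild a block's (reduced) design matrix for new data."""
    n = len(data)
    if block.label == "fixed":
        cols = []
        for term in block.meta["terms"]:
            if term[0] == "intercept":
                cols.append(np.ones(n))
            elif term[0] == "linear":
                _, var, mu, sd = term
                cols.append((data[var].to_numpy(dtype=float) - mu) / sd)
            else:
                _, var, levels, ref = term
                sub = dummy_code(data[var].astype(str).to_numpy(), list(levels), ref)
                cols.extend(sub.matrix.T)
        return np.column_stack(cols) if cols else np.empty((n, 0))
    if block.label.startswith("s("):
        from scipy.interpolate import BSpline

        knots = block.meta["knots"]
        degree = block.meta["degree"]
        lo, hi = block.meta["domain"]
        x = data[block.meta["variable"]].to_numpy(dtype=float)
        if np.any(x < lo) or np.any(x > hi):
            raise ValueError(
                f"values of {block.meta['variable']!r} outside the fitted "
                f"knot range [{lo}, {hi}]"
            )
        B = BSpline.design_matrix(np.clip(x, lo, hi), knots, degree).toarray()
        return B @ block.transform
    if block.label.startswith("spatial"):
        ids = list(region_ids)
        pos = {r: i for i, r in enumerate(ids)}
        idx = data[block.meta["variable"]].astype(str).map(pos)
        if idx.isna().any():
            raise ValueError("new data contains regions unseen at fit time")
        inc = np.zeros((n, len(ids)))
        inc[np.arange(n), idx.to_numpy(dtype=int)] = 1.0
        return inc @ block.transform
    raise KeyError(block.label)


def linear_predictor(
    spec: ModelSpec,
    params: dict[str, np.ndarray],
    data: pd.DataFrame,
    graph: RegionGraph | None = None,
) -> np.ndarray:
    """Additive predictor eta for given per-block coefficient vectors."""
    blocks = build_blocks(spec, data, graph)
    eta = np.zeros(len(data))
    for blk in blocks:
        beta = np.asarray(params.get(blk.label, np.zeros(blk.n_columns)), dtype=float)
        if beta.shape != (blk.n_columns,):
            raise ValueError(
                f"block {blk.label!r} expects {blk.n_columns} coefficients, "
                f"got {beta.shape}"
            )
        eta += blk.matrix @ beta
    return eta


def _check_separation(fixed: DesignBlock, y: np.ndarray) -> None:
    for j, name in enumerate(fixed.column_names):
        col = fixed.matrix[:, j]
        uniq = np.unique(col)
        if set(uniq) <= {0.0, 1.0} and name != "intercept":
            for v in uniq:
                sub = y[col == v]
                if sub.size and (sub.min() == sub.max()):
                    warnings.warn(
                        f"possible separation: outcome is constant where "
                        f"{name} == {int(v)}; priors keep the posterior proper",
                        stacklevel=3,
                    )
                    return


def _gibbs(
    blocks: list[DesignBlock],
    y: np.ndarray,
    config: ChainConfig,
) -> tuple[dict, dict, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    n = y.size
    kappa = y - 0.5

    penalized = [b for b in blocks if b.penalty_rank > 0]
    beta = {b.label: np.zeros(b.n_columns) for b in blocks}
    tau2 = {b.label: 0.1 for b in penalized}

    eta = np.zeros(n)
    stored: dict[str, list] = {b.label: [] for b in blocks}
    stored_tau: dict[str, list] = {b.label: [] for b in penalized}
    dev_trace: list[float] = []

    eye_cache = {b.label: np.eye(b.n_columns) for b in blocks}

    for it in range(config.iterations):
        omega = random_polya_gamma(eta, rng)
        for blk in blocks:
            X = blk.matrix
            lbl = blk.label
            eta -= X @ beta[lbl]
            Xw = X * omega[:, None]
            Q = X.T @ Xw
            if blk.penalty_rank > 0:
                Q += blk.penalty / tau2[lbl]
            Q += _DIFFUSE_PRECISION * eye_cache[lbl]
            rhs = X.T @ (kappa - omega * eta)
            c, low = cho_factor(Q, lower=True, check_finite=False)
            mean = cho_solve((c, low), rhs, check_finite=False)
            noise = solve_triangular(
                c.T, rng.standard_normal(blk.n_columns), lower=False, check_finite=False
            )
            beta[lbl] = mean + noise
            eta += X @ beta[lbl]
        for blk in penalized:
            bvec = beta[blk.label]
            quad = float(bvec @ blk.penalty @ bvec)
            a, b = blk.meta.get("a", 0.001), blk.meta.get("b", 0.001)
            tau2[blk.label] = (b + quad / 2.0) / rng.gamma(a + blk.penalty_rank / 2.0, 1.0)

        if it >= config.burnin and (it - config.burnin) % config.thin == config.thin - 1:
            for blk in blocks:
                stored[blk.label].append(beta[blk.label].copy())
            for blk in penalized:
                stored_tau[blk.label].append(tau2[blk.label])
            dev_trace.append(bernoulli_deviance(y, eta))

    draws = {k: np.asarray(v) for k, v in stored.items()}
    tau_draws = {k: np.asarray(v) for k, v in stored_tau.items()}
    return draws, tau_draws, np.asarray(dev_trace)


def fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    graph: RegionGraph | None = None,
    config: ChainConfig = ChainConfig(),
    schema: ChildTableSchema = DEFAULT_SCHEMA,
) -> FitResult:
    """Run the block Gibbs sampler and return stored draws.

    Identical seeds give identical chains; stored draw count is
    ``floor((iterations - burnin) / thin)``.
    """
    y = data[spec.outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {spec.outcome!r} must be binary 0/1")
    blocks = build_blocks(spec, data, graph, schema=schema)
    _check_separation(blocks[0], y)
    logger.info(
        "fitting %d records, blocks: %s",
        len(y),
        [(b.label, b.n_columns) for b in blocks],
    )
    draws, tau_draws, dev = _gibbs(blocks, y, config)
    # variance components keyed by readable names
    var_names = {"spatial_str": "structured", "spatial_unstr": "unstructured"}
    variance_samples = {var_names.get(k, k): v for k, v in tau_draws.items()}
    return FitResult(
        spec=spec,
        config=config,
        blocks=blocks,
        block_draws=draws,
        variance_samples=variance_samples,
        deviance_trace=dev,
        region_ids=graph.region_ids if graph is not None else (),
        data_digest=data_digest(data),
        y=y,
    )


class GeoAdditiveLogisticRegression:
    """Sklearn-style estimator for the Bayesian geo-additive logistic model.

    Parameters
    ----------
    fixed : list of covariate names or (name, reference) pairs; a ``None``
        reference marks a continuous covariate entered linearly.
    smooth : list of continuous covariate names given P-spline smooths.
    spatial : name of the region column, or None for no spatial term.
    graph : RegionGraph backing the GMRF prior (required with ``spatial``).
    structured, unstructured : which spatial components to include.
    segments, degree, penalty_order : P-spline basis/penalty settings.
    a, b : inverse-gamma hyperparameters of every variance component.
    iterations, burnin, thin : MCMC schedule.
    random_state : chain seed.

    Attributes (after ``fit``)
    --------------------------
    result_ : FitResult with all stored draws.
    samples_, variance_samples_, deviance_trace_ : convenience views.
    """

    def __init__(
        self,
        fixed=None,
        smooth=None,
        spatial=None,
        graph=None,
        structured=True,
        unstructured=True,
        intercept=True,
        segments=20,
        degree=3,
        penalty_order=2,
        a=0.001,
        b=0.001,
        iterations=12000,
        burnin=2000,
        thin=10,
        random_state=0,
        schema=DEFAULT_SCHEMA,
    ):
        self.fixed = fixed
        self.smooth = smooth
        self.spatial = spatial
        self.graph = graph
        self.structured = structured
        self.unstructured = unstructured
        self.intercept = intercept
        self.segments = segments
        self.degree = degree
        self.penalty_order = penalty_order
        self.a = a
        self.b = b
        self.iterations = iterations
        self.burnin = burnin
        self.thin = thin
        self.random_state = random_state
        self.schema = schema

    _param_names = (
        "fixed", "smooth", "spatial", "graph", "structured", "unstructured",
        "intercept", "segments", "degree", "penalty_order", "a", "b",
        "iterations", "burnin", "thin", "random_state", "schema",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "GeoAdditiveLogisticRegression":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _make_spec(self, outcome: str = "ciaf") -> ModelSpec:
        fixed_terms = []
        for item in self.fixed or ():
            fixed_terms.append(tuple(item) if isinstance(item, (tuple, list)) else (item, "__auto__"))
        smooth_terms = tuple(
            SmoothTerm(
                variable=v,
                segments=self.segments,
                degree=self.degree,
                order=self.penalty_order,
                a=self.a,
                b=self.b,
            )
            for v in (self.smooth or ())
        )
        spatial = (
            SpatialTerm(
                variable=self.spatial,
                structured=self.structured,
                unstructured=self.unstructured,
                a=self.a,
                b=self.b,
            )
            if self.spatial
            else None
        )
        return ModelSpec(
            outcome=outcome,
            fixed_terms=tuple(fixed_terms),
            smooth_terms=smooth_terms,
            spatial_term=spatial,
            intercept=self.intercept,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "GeoAdditiveLogisticRegression":
        """Fit on a child table; ``y`` may be a vector or an outcome column name."""
        data = X.copy()
        if y is None:
            outcome = "ciaf"
        elif isinstance(y, str):
            outcome = y
        else:
            data = data.assign(_outcome=np.asarray(y))
            outcome = "_outcome"
        spec = self._make_spec(outcome)
        config = ChainConfig(
            iterations=self.iterations,
            burnin=self.burnin,
            thin=self.thin,
            seed=self.random_state if self.random_state is not None else 0,
        )
        self.result_ = fit(spec, data, self.graph, config, schema=self.schema)
        self.spec_ = spec
        self.samples_ = self.result_.samples
        self.variance_samples_ = self.result_.variance_samples
        self.deviance_trace_ = self.result_.deviance_trace
        self.n_features_in_ = X.shape[1]
        return self

    def _eta_draws(self, X: pd.DataFrame) -> np.ndarray:
        res = self.result_
        eta = np.zeros((res.n_stored, len(X)))
        for blk in res.blocks:
            M = term_matrix(blk, X, region_ids=res.region_ids)
            eta += res.block_draws[blk.label] @ M.T
        return eta

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-mean event probability, column-stacked sklearn style."""
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        p = (1.0 / (1.0 + np.exp(-self._eta_draws(X)))).mean(axis=0)
        return np.column_stack([1.0 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
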