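"""Synthetic DHS-like child datasets with known ground truth.

The restricted survey microdata behind studies of child anthropometric
failure cannot be redistributed, so every downstream stage here is exercised
on simulated data: children are placed on a region graph, covariates are
drawn from survey-like marginals, and the binary outcome follows the same
geo-additive logistic model the inference module fits,

    logit P(y=1) = v' beta + f_age(child_age) + f_mage(mother_age)
                   + f_str(region) + f_unstr(region),

with f_str one draw of an intrinsic GMRF on the graph, f_unstr iid Gaussian
noise per region, and the smooth functions centred over the sampled
covariate values.  Default effect sizes are set to the posterior estimates a
national survey analysis of this outcome reports (odds ratios around
0.4-1.5, structured spatial variance ~0.32, unstructured ~0.01), so the
default generator emulates the study conditions rather than a convenient
toy.

Trivariate z-score records for the CIAF classifier are generated separately
as correlated Gaussians calibrated so the implied CIAF prevalence hits a
target (default 41.3%); they are plumbing for the classification pipeline
and are not linked record-by-record to the regression outcome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .design import gmrf_precision
from .graphs import RegionGraph

__all__ = [
    "TrueParams",
    "SyntheticDataset",
    "make_lattice_graph",
    "sample_structured_field",
    "simulate_covariates",
    "simulate_outcomes",
    "simulate_zscores",
    "simulate_dataset",
    "default_truth",
    "DEFAULT_CATEGORY_MIX",
]

# Survey-like marginals for the categorical covariates (reference level
# first).  Probabilities are round numbers in the range national DHS reports
# show; the exact values are not material, they only set covariate balance.
DEFAULT_CATEGORY_MIX: dict[str, dict[str, float]] = {
    "diarrhoea": {"no": 0.87, "yes": 0.13},
    "cough": {"no": 0.83, "yes": 0.17},
    "fever": {"no": 0.78, "yes": 0.22},
    "vitamin_a": {"no": 0.55, "yes": 0.45},
    "birth_order": {"1st": 0.25, "2nd-3rd": 0.35, "4th+": 0.40},
    "gender": {"female": 0.49, "male": 0.51},
    "size_at_birth": {"very_small": 0.08, "small": 0.17, "average_or_larger": 0.75},
    "breastfeeding": {"no": 0.55, "yes": 0.45},
    "education": {"none": 0.38, "primary": 0.17, "secondary+": 0.45},
    "bmi": {"normal": 0.72, "thin": 0.10, "obese": 0.18},
    "working": {"no": 0.32, "yes": 0.68},
    "toilet": {"unimproved": 0.45, "improved": 0.55},
    "water": {"unimproved": 0.35, "improved": 0.65},
    "residence": {"rural": 0.60, "urban": 0.40},
    "wealth": {"poorest": 0.24, "poorer": 0.22, "middle": 0.20, "richer": 0.18, "richest": 0.16},
    "media_exposure": {"no": 0.40, "yes": 0.60},
}

# Default fixed-effect log-odds: log posterior odds ratios reported for this
# outcome at national scale (child-level and household/maternal tables).
DEFAULT_LOG_ODDS: dict[str, float] = {
    "breastfeeding=yes": np.log(1.128),
    "size_at_birth=small": np.log(0.673),
    "size_at_birth=average_or_larger": np.log(0.436),
    "gender=male": np.log(1.315),
    "birth_order=2nd-3rd": np.log(1.124),
    "birth_order=4th+": np.log(1.454),
    "vitamin_a=yes": np.log(0.983),
    "fever=yes": np.log(1.018),
    "cough=yes": np.log(0.979),
    "diarrhoea=yes": np.log(1.256),
    "wealth=poorer": np.log(0.941),
    "wealth=middle": np.log(0.889),
    "wealth=richer": np.log(0.672),
    "wealth=richest": np.log(0.515),
    "working=yes": np.log(1.063),
    "bmi=thin": np.log(1.216),
    "bmi=obese": np.log(0.691),
    "residence=urban": np.log(0.948),
    "education=primary": np.log(0.801),
    "education=secondary+": np.log(0.622),
    "water=improved": np.log(0.941),
    "toilet=improved": np.log(1.109),
    "media_exposure=yes": np.log(0.858),
}


def _f_child_age_raw(age: np.ndarray) -> np.ndarray:
    """Inverse-U child-age effect: rise to ~30 months, dip to 48, rise after.

    Piecewise quadratic; an explicit formula is our choice, only the shape is
    dictated by what national analyses of this outcome find.
    """
    age = np.asarray(age, dtype=float)
    out = np.where(
        age <= 30.0,
        1.0 - ((age - 30.0) / 30.0) ** 2,
        np.where(
            age <= 48.0,
            1.0 - 0.8 * ((age - 30.0) / 18.0) ** 2,
            0.2 + 0.5 * ((age - 48.0) / 11.0) ** 2,
        ),
    )
    return 0.8 * out


def _f_mother_age_raw(mage: np.ndarray) -> np.ndarray:
    """Approximately linear decline with mother's age (-0.015 per year)."""
    return -0.015 * np.asarray(mage, dtype=float)


@dataclass
class TrueParams:
    """Ground-truth parameters of the generating geo-additive model.

    ``beta`` maps "variable=level" (and "intercept") to log-odds; smooth
    functions are centred over the sampled covariate values at simulation
    time; ``f_str`` sums to zero over regions.
    """

    beta: dict[str, float]
    f_child_age: Callable[[np.ndarray], np.ndarray] | None
    f_mother_age: Callable[[np.ndarray], np.ndarray] | None
    f_str: dict[str, float]
    f_unstr: dict[str, float]
    var_str: float
    var_unstr: float

    def centred_smooth(self, fn, values: np.ndarray) -> np.ndarray:
        if fn is None:
            return np.zeros(len(values))
        v = np.asarray(fn(values), dtype=float)
        return v - v.mean()


@dataclass
class SyntheticDataset:
    records: pd.DataFrame
    truth: TrueParams
    graph: RegionGraph
    seed: int
    eta: np.ndarray = field(repr=False, default=None)

    def truth_to_json(self, path: str | Path) -> None:
        """Write the ground truth to a JSON sidecar for recovery tests."""
        obj = {
            "seed": self.seed,
            "beta": self.truth.beta,
            "f_str": self.truth.f_str,
            "f_unstr": self.truth.f_unstr,
            "var_str": self.truth.var_str,
            "var_unstr": self.truth.var_unstr,
        }
        Path(path).write_text(json.dumps(obj, indent=1) + "\n")


def make_lattice_graph(rows: int, cols: int) -> RegionGraph:
    """Rook-adjacency lattice of rows x cols regions (stand-in for a map)."""
    if rows * cols < 2:
        raise ValueError("need at least two regions")
    ids = [f"R{i * cols + j:02d}" for i in range(rows) for j in range(cols)]
    pairs = set()
    for i in range(rows):
        for j in range(cols):
            if j + 1 < cols:
                pairs.add(frozenset((ids[i * cols + j], ids[i * cols + j + 1])))
            if i + 1 < rows:
                pairs.add(frozenset((ids[i * cols + j], ids[(i + 1) * cols + j])))
    return RegionGraph(tuple(ids), frozenset(pairs))


def sample_structured_field(
    graph: RegionGraph, variance: float, seed: int | np.random.Generator
) -> dict[str, float]:
    """One sum-to-zero draw from the intrinsic GMRF on the graph.

    Sampling uses the spectral decomposition of the Laplacian K with the
    null eigenvector (constants) removed, so the sum-to-zero constraint is
    exact and the covariance of repeated draws is ``variance * pinv(K)``.
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    K = gmrf_precision(graph)
    if variance == 0.0:
        return {r: 0.0 for r in graph.region_ids}
    w, V = np.linalg.eigh(K)
    keep = w > 1e-10 * w.max()
    z = rng.standard_normal(int(keep.sum()))
    f = V[:, keep] @ (np.sqrt(variance / w[keep]) * z)
    f -= f.mean()  # exact to rounding; the null space was already removed
    return dict(zip(graph.region_ids, f))


def simulate_covariates(
    n: int,
    graph: RegionGraph,
    mix: dict[str, dict[str, float]] | None = None,
    seed: int | np.random.Generator = 0,
    region_probs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw covariate records: ages uniform, categoricals per ``mix``."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mix = DEFAULT_CATEGORY_MIX if mix is None else mix
    for var, probs in mix.items():
        total = sum(probs.values())
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"probabilities for {var!r} sum to {total}, not 1")
    data = {
        "region": rng.choice(graph.region_ids, size=n, p=region_probs),
        "child_age": rng.integers(0, 60, size=n),
        "mother_age": rng.integers(15, 50, size=n),
    }
    for var, probs in mix.items():
        levels = list(probs)
        data[var] = rng.choice(levels, size=n, p=[probs[lv] for lv in levels])
    return pd.DataFrame(data)


def default_truth(
    graph: RegionGraph,
    seed: int | np.random.Generator = 0,
    var_str: float = 0.323,
    var_unstr: float = 0.009,
    intercept: float = -0.35,
    beta: dict[str, float] | None = None,
    nonlinear: bool = True,
) -> TrueParams:
    """Ground truth at the study's reported effect sizes."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    b = dict(DEFAULT_LOG_ODDS) if beta is None else dict(beta)
    b.setdefault("intercept", intercept)
    f_str = sample_structured_field(graph, var_str, rng)
    f_unstr = {
        r: float(v)
        for r, v in zip(
            graph.region_ids,
            np.sqrt(var_unstr) * rng.standard_normal(graph.n_regions),
        )
    }
    return TrueParams(
        beta=b,
        f_child_age=_f_child_age_raw if nonlinear else None,
        f_mother_age=_f_mother_age_raw if nonlinear else None,
        f_str=f_str,
        f_unstr=f_unstr,
        var_str=var_str,
        var_unstr=var_unstr,
    )


def linear_predictor_from_truth(records: pd.DataFrame, truth: TrueParams) -> np.ndarray:
    """Evaluate the generating predictor eta for each record."""
    n = len(records)
    eta = np.full(n, truth.beta.get("intercept", 0.0))
    for key, coef in truth.beta.items():
        if key == "intercept":
            continue
        var, _, level = key.partition("=")
        if var not in records.columns:
            raise ValueError(f"truth references covariate {var!r} absent from records")
        eta += coef * (records[var].to_numpy() == level)
    if truth.f_child_age is not None:
        eta += truth.centred_smooth(truth.f_child_age, records["child_age"].to_numpy())
    if truth.f_mother_age is not None:
        eta += truth.centred_smooth(truth.f_mother_age, records["mother_age"].to_numpy())
    if truth.f_str:
        eta += records["region"].map(truth.f_str).to_numpy(dtype=float)
    if truth.f_unstr:
        eta += records["region"].map(truth.f_unstr).to_numpy(dtype=float)
    return eta


def simulate_outcomes(
    records: pd.DataFrame,
    truth: TrueParams,
    seed: int | np.random.Generator = 0,
    graph: RegionGraph | None = None,
) -> SyntheticDataset:
    """Bernoulli outcomes through the logistic link of the true predictor."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    eta = linear_predictor_from_truth(records, truth)
    prob = 1.0 / (1.0 + np.exp(-eta))
    out = records.copy()
    out["ciaf"] = (rng.random(len(out)) < prob).astype(int)
    if graph is None:
        ids = tuple(pd.unique(records["region"]))
        graph = RegionGraph(ids)  # placeholder, no adjacency
    seed_int = seed if isinstance(seed, (int, np.integer)) else -1
    return SyntheticDataset(records=out, truth=truth, graph=graph, seed=int(seed_int), eta=eta)


def simulate_zscores(
    n: int,
    target_prevalence: float = 0.413,
    correlation: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Correlated (HAZ, WHZ, WAZ) records with a target CIAF prevalence.

    Records are trivariate normal with unit variances and a common mean mu
    chosen so that P(any z-score < -2) equals the target.  On the sample's
    empirical law the calibration equation  P(min_k e_k < -2 - mu) = p  is
    solved exactly by the (1-p) order-statistic of the per-record minimum:
    mu = -2 - quantile_p(min_k e_k), so the achieved prevalence is within
    1/n of the target by construction.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")
    if correlation is None:
        # typical anthropometric z-score correlations: HAZ/WAZ and WHZ/WAZ
        # strongly positive, HAZ/WHZ weakly negative
        correlation = np.array(
            [
                [1.0, -0.1, 0.6],
                [-0.1, 1.0, 0.65],
                [0.6, 0.65, 1.0],
            ]
        )
    correlation = np.asarray(correlation, dtype=float)
    try:
        L = np.linalg.cholesky(correlation)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix must be positive definite") from exc
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    e = rng.standard_normal((n, 3)) @ L.T
    m = e.min(axis=1)
    mu = -2.0 - float(np.quantile(m, target_prevalence))
    z = e + mu
    return pd.DataFrame(z, columns=["haz", "whz", "waz"])


def simulate_dataset(
    n: int,
    graph: RegionGraph,
    truth: TrueParams | None = None,
    seed: int = 0,
    include_zscores: bool = False,
    mix: dict | None = None,
) -> SyntheticDataset:
    """Full pipeline: covariates, truth (if not given), outcomes, z-scores.

    All randomness flows from one Generator seeded with ``seed``, so the
    dataset is a pure function of its arguments.
    """
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = default_truth(graph, seed=rng)
    cov = simulate_covariates(n, graph, mix=mix, seed=rng)
    ds = simulate_outcomes(cov, truth, seed=rng, graph=graph)
    ds.seed = seed
    if include_zscores:
        # plumbing for the CIAF classifier; not linked per-record to `ciaf`
        zs = simulate_zscores(n, seed=rng)
        for col in zs.columns:
            ds.records[col] = zs[col].to_numpy()
    return ds
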