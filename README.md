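# geociaf

Bayesian geo-additive modelling of child anthropometric failure.

## The problem

Stunting (low height-for-age), wasting (low weight-for-height) and
underweight (low weight-for-age) each capture a different facet of child
undernutrition, and none alone measures its overall burden. The **Composite
Index of Anthropometric Failure (CIAF)** aggregates them: a child fails an
index when the corresponding z-score (HAZ, WHZ, WAZ, against the WHO 2006
growth standards) is below −2 SD, and the CIAF is 1 when *any* failure is
present. The mutually exclusive failure combinations form groups A–G
(A = no failure, B = stunting only, …, D = all three).

Undernutrition risk is also strongly spatial: prevalence varies across
administrative regions in ways that covariates do not fully explain. This
package fits the **structured additive (geo-additive) logistic regression**
used for such analyses: for child *i* in region *s*,

```
logit P(y_i = 1) = v_i'β + Σ_r f_r(x_ir) + f_str(s_i) + f_unstr(s_i)
```

with linear fixed effects `β` for categorical covariates, penalised
B-spline (P-spline) smooths `f_r` for continuous covariates (child age,
mother's age), an intrinsic Gaussian Markov random field (GMRF) prior on
the spatially *structured* region effect `f_str` (neighbouring regions are
similar), and iid Gaussian *unstructured* region heterogeneity `f_unstr`.
Every variance component carries an inverse-gamma IG(a, b) hyperprior
(default a = b = 0.001). Inference is exact MCMC via Pólya-Gamma
latent-variable augmentation, which makes every coefficient block
conditionally Gaussian and every variance update conjugate.

Model complexity is compared over a nested hierarchy — M0 (linear fixed
effects only), M1 (+ smooths), M2 (+ spatial), M3 (full) — by the deviance
information criterion `DIC = D̄ + pD` with `pD = D̄ − D(θ̄)`.

It is intended for biostatisticians and epidemiologists analysing
survey-style child anthropometry on a region adjacency graph; because such
microdata are usually access-controlled, the package ships a synthetic-data
module that generates survey-like datasets with known ground truth
(including a GMRF-distributed spatial field) for validation and method
studies.

## Worked example

Twelve regions on a 4×3 lattice, ground truth at survey-scale effect sizes
(male OR 1.315, diarrhoea OR 1.256, media exposure OR 0.858, structured
spatial variance 0.323), n = 6000 children:

```python
import numpy as np
from geociaf import (
    ChainConfig, ModelSpec, SmoothTerm, SpatialTerm,
    CIAFClassifier, prevalence_table,
    make_lattice_graph, default_truth, simulate_dataset,
    fit, compute_dic, odds_ratio_table, variance_summary, spatial_table,
)

graph = make_lattice_graph(4, 3)
beta = {"intercept": -0.35, "gender=male": np.log(1.315),
        "diarrhoea=yes": np.log(1.256), "media_exposure=yes": np.log(0.858)}
truth = default_truth(graph, seed=1, beta=beta)
data = simulate_dataset(
    6000, graph, truth=truth, seed=2, include_zscores=True,
    mix={"gender": {"female": .49, "male": .51},
         "diarrhoea": {"no": .87, "yes": .13},
         "media_exposure": {"no": .4, "yes": .6}})

classified = CIAFClassifier().fit_transform(data.records)
print(prevalence_table(classified).head(3).round(3).to_string(index=False))

spec = ModelSpec(
    fixed_terms=(("gender", "female"), ("diarrhoea", "no"), ("media_exposure", "no")),
    smooth_terms=(SmoothTerm("child_age"),),
    spatial_term=SpatialTerm("region"))
res = fit(spec, data.records, graph,
          ChainConfig(iterations=2000, burnin=500, thin=3, seed=3))
print(odds_ratio_table(res).round(3).to_string(index=False))
print(variance_summary(res).round(3).to_string(index=False))
dic = compute_dic(res)
print(f"DIC = {dic.dic:.2f}  (pD = {dic.pD:.2f}, Deviance = {dic.dhat:.2f})")
print("spatial codes:", spatial_table(res, which="total")["code"].tolist())
```

prints

```
       status  prevalence  ci_low  ci_high    n
         CIAF       0.413   0.400    0.425 5999
   No failure       0.587   0.575    0.600 5999
Stunting Only       0.213   0.202    0.223 5999

              term  or_mean  cri_low  cri_high  significant
       gender=male    1.331    1.203     1.472         True
     diarrhoea=yes    1.260    1.078     1.458         True
media_exposure=yes    0.891    0.792     0.993         True

   component  mean    sd  cri_low  cri_high
s(child_age) 0.004 0.004    0.001     0.016
  structured 0.101 0.117    0.001     0.431
unstructured 0.061 0.061    0.001     0.223

DIC = 8020.05  (pD = 19.29, Deviance = 7981.47)
spatial codes: [1, 0, -1, -1, -1, -1, 0, -1, 0, 1, 1, 1]
```

The CIAF prevalence matches the 41.3% calibration target of the z-score
generator (one implausible record was dropped by validation, hence
n = 5999); the posterior odds ratios recover the generating values within
their credible intervals; and the −1/0/+1 spatial significance codes track
the sign pattern of the true structured field (compare
`[0.41, 0.12, -0.29, -0.16, -0.32, -0.27, 0.12, -0.2, -0.06, 0.46, 0.08, 0.12]`).

A `geociaf` command-line interface wraps the same pipeline:
`geociaf simulate`, `classify`, `fit`, `compare` (M0–M3 DIC table),
`summarize` (odds-ratio / variance / spatial tables) and `recover`
(end-to-end parameter-recovery check). See `geociaf --help`.

## Layout

- `src/geociaf/ciaf.py` — z-score validation, failure flags, CIAF groups,
  prevalence tables; `CIAFClassifier` transformer.
- `src/geociaf/design.py` — dummy coding, B-spline bases, difference
  penalties, GMRF precision, sum-to-zero reparameterisation.
- `src/geociaf/model.py` — `GeoAdditiveLogisticRegression` estimator and
  the Pólya-Gamma block Gibbs sampler.
- `src/geociaf/model_selection.py` — DIC and the M0–M3 hierarchy.
- `src/geociaf/reporting.py` — odds-ratio tables, smooth-effect curves,
  spatial significance, variance summaries, plotting helpers.
- `src/geociaf/synthetic.py` — ground-truth generators (lattice graphs,
  GMRF fields, covariates, outcomes, calibrated z-scores).
- `src/geociaf/graphs.py`, `src/geociaf/io.py`, `src/geociaf/cli.py` —
  region-graph and child-table IO, schema validation, CLI.

See `docs/methods.md` for the statistical details and design choices.
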