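"""DIC-based comparison of the nested model hierarchy M0-M3.

Four nested specifications of the additive predictor are fitted:

    M0  linear fixed effects only (continuous covariates as linear columns)
    M1  linear fixed effects + P-spline smooths of the continuous covariates
    M2  linear fixed effects + spatial effects
    M3  full geo-additive model (fixed + smooths + spatial)

and compared by the deviance information criterion

    DIC = Dbar + pD,   pD = Dbar - Dhat,

where Dbar is the posterior mean of the deviance over the stored draws and
Dhat the deviance at the posterior means of the coefficient blocks (the
classical plug-in definition), so DIC = Dhat + 2 pD.  Smaller is better.
Continuous covariates entering M0/M2 linearly use the same standardisation
as their smooth versions, keeping fitted predictors comparable across the
hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .model import (
    ChainConfig,
    FitResult,
    ModelSpec,
    SmoothTerm,
    SpatialTerm,
    bernoulli_deviance,
    fit,
)
from .graphs import RegionGraph

__all__ = ["DicReport", "compute_dic", "hierarchy_specs", "fit_hierarchy"]

MODEL_LABELS = ("M0", "M1", "M2", "M3")


@dataclass(frozen=True)
class DicReport:
    dic: float
    pD: float
    dbar: float
    dhat: float

    def __post_init__(self):
        if abs((self.dbar - self.dhat) - self.pD) > 1e-9:
            raise ValueError("pD must equal dbar - dhat")
        if abs((self.dbar + self.pD) - self.dic) > 1e-9:
            raise ValueError("dic must equal dbar + pD")

    @classmethod
    def from_components(cls, dbar: float, dhat: float) -> "DicReport":
        pD = dbar - dhat
        return cls(dic=dbar + pD, pD=pD, dbar=dbar, dhat=dhat)


def compute_dic(fit_result: FitResult, data: pd.DataFrame | None = None) -> DicReport:
    """DIC of a fitted model from its stored deviance trace and draws."""
    if fit_result.deviance_trace is None or len(fit_result.deviance_trace) == 0:
        raise ValueError("fit contains no stored deviance trace")
    y = (
        data[fit_result.spec.outcome].to_numpy(dtype=float)
        if data is not None
        else fit_result.y
    )
    dbar = float(fit_result.deviance_trace.mean())
    dhat = bernoulli_deviance(y, fit_result.posterior_mean_eta())
    return DicReport.from_components(dbar=dbar, dhat=dhat)


def hierarchy_specs(
    base: ModelSpec,
    continuous: tuple[str, ...] = ("child_age", "mother_age"),
) -> dict[str, ModelSpec]:
    """Derive the M0-M3 specs from a full (M3-style) spec.

    ``continuous`` names the covariates that are smooth terms in M1/M3 and
    single linear columns in M0/M2.
    """
    smooth_vars = tuple(t.variable for t in base.smooth_terms) or continuous
    linear_fixed = base.fixed_terms + tuple((v, None) for v in smooth_vars)
    m0 = replace(base, fixed_terms=linear_fixed, smooth_terms=(), spatial_term=None)
    m1 = replace(base, smooth_terms=base.smooth_terms, spatial_term=None)
    m2 = replace(base, fixed_terms=linear_fixed, smooth_terms=())
    m3 = base
    return {"M0": m0, "M1": m1, "M2": m2, "M3": m3}


def fit_hierarchy(
    data: pd.DataFrame,
    graph: RegionGraph,
    config: ChainConfig = ChainConfig(),
    base: ModelSpec | None = None,
) -> tuple[dict[str, DicReport], str, dict[str, FitResult]]:
    """Fit M0-M3 and select the smallest-DIC model.

    Returns (reports keyed M0-M3, label of the argmin-DIC model, fits).
    """
    if base is None:
        base = ModelSpec(
            outcome="ciaf",
            fixed_terms=tuple(
                (v, "__auto__")
                for v in data.columns
                if v not in ("ciaf", "region", "child_age", "mother_age", "haz", "whz", "waz")
            ),
            smooth_terms=(SmoothTerm("child_age"), SmoothTerm("mother_age")),
            spatial_term=SpatialTerm("region"),
        )
    specs = hierarchy_specs(base)
    reports: dict[str, DicReport] = {}
    fits: dict[str, FitResult] = {}
    for label in MODEL_LABELS:
        spec = specs[label]
        res = fit(spec, data, graph if spec.spatial_term is not None else None, config)
        fits[label] = res
        reports[label] = compute_dic(res)
    best = min(reports, key=lambda k: reports[k].dic)
    return reports, best, fits


def dic_table(reports: dict[str, DicReport]) -> pd.DataFrame:
    """Goodness-of-fit comparison table (rows DIC, pD, Deviance)."""
    return pd.DataFrame(
        {
            label: [reports[label].dic, reports[label].pD, reports[label].dhat]
            for label in reports
        },
        index=["DIC", "pD", "Deviance"],
    )
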