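"""Composite Index of Anthropometric Failure (CIAF).

Child nutritional status is screened with three z-scores against the WHO
2006 growth-standard medians: height-for-age (HAZ, stunting), weight-for-
height (WHZ, wasting) and weight-for-age (WAZ, underweight).  A child fails
an index when the z-score is strictly below -2 SD.  The CIAF aggregates the
three binary failures into mutually exclusive groups:

    A  no failure                      E  wasting + underweight
    B  stunting only                   F  wasting only
    C  stunting + underweight          G  underweight only
    D  stunting + wasting + underweight

and a binary indicator (1 = any failure, i.e. any group other than A).  The
eighth flag combination — stunted and wasted but not underweight — has no
conventional letter; it is physiologically rare (stunting plus wasting
almost always drags weight-for-age down) and is labelled H here and counted
as failure, since the index is defined as *any* anthropometric failure.

Plausibility windows for valid measurements follow standard DHS/WHO
flagging practice: HAZ in [-6, 6], WHZ in [-5, 5], WAZ in [-6, 5].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "AnthroZscores",
    "FailureFlags",
    "CIAFResult",
    "PrevalenceEstimate",
    "CIAFClassifier",
    "validate_zscores",
    "flag_failures",
    "classify_group",
    "ciaf_indicator",
    "prevalence_ci",
    "prevalence_table",
    "GROUP_LABELS",
]

ZSCORE_WINDOWS = {"haz": (-6.0, 6.0), "whz": (-5.0, 5.0), "waz": (-6.0, 5.0)}

# (stunted, wasted, underweight) -> group
_GROUP_MAP = {
    (False, False, False): "A",
    (True, False, False): "B",
    (True, False, True): "C",
    (True, True, True): "D",
    (False, True, True): "E",
    (False, True, False): "F",
    (False, False, True): "G",
    (True, True, False): "H",
}

GROUP_LABELS = {
    "A": "No failure",
    "B": "Stunting Only",
    "C": "Stunting + Underweight",
    "D": "Wasting + Stunting + Underweight",
    "E": "Wasting + Underweight",
    "F": "Wasting Only",
    "G": "Underweight only",
    "H": "Stunting + Wasting (no underweight)",
}


@dataclass(frozen=True)
class AnthroZscores:
    haz: float
    whz: float
    waz: float


@dataclass(frozen=True)
class FailureFlags:
    stunted: bool
    wasted: bool
    underweight: bool


@dataclass(frozen=True)
class CIAFResult:
    group: str
    ciaf: int


@dataclass(frozen=True)
class PrevalenceEstimate:
    proportion: float
    ci_low: float
    ci_high: float
    n: int


def validate_zscores(z: AnthroZscores) -> bool:
    """True iff all three z-scores fall inside the plausibility windows."""
    vals = {"haz": z.haz, "whz": z.whz, "waz": z.waz}
    for name, v in vals.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite {name} z-score: {v!r}")
    return all(lo <= vals[k] <= hi for k, (lo, hi) in ZSCORE_WINDOWS.items())


def flag_failures(z: AnthroZscores, cutoff: float = -2.0) -> FailureFlags:
    """Binary failure flags; the comparison is strictly below the cut-off."""
    return FailureFlags(
        stunted=bool(z.haz < cutoff),
        wasted=bool(z.whz < cutoff),
        underweight=bool(z.waz < cutoff),
    )


def classify_group(flags: FailureFlags) -> str:
    """CIAF group letter for a flag combination."""
    key = (bool(flags.stunted), bool(flags.wasted), bool(flags.underweight))
    group = _GROUP_MAP[key]
    if group == "H":
        logger.warning(
            "flag combination stunted+wasted without underweight has no "
            "conventional CIAF group; classified as failure under label H"
        )
    return group


def ciaf_indicator(group: str) -> int:
    """1 for any anthropometric failure (groups B-H), 0 for group A."""
    if group not in _GROUP_MAP.values():
        raise ValueError(f"unknown CIAF group {group!r}")
    return 0 if group == "A" else 1


def classify(flags: FailureFlags) -> CIAFResult:
    group = classify_group(flags)
    return CIAFResult(group=group, ciaf=ciaf_indicator(group))


def prevalence_ci(indicator, level: float = 0.95) -> PrevalenceEstimate:
    """Wald normal-approximation interval for a binary prevalence.

    p_hat +/- z * sqrt(p_hat (1 - p_hat) / n), clipped to [0, 1].
    """
    ind = np.asarray(indicator, dtype=float)
    if ind.size == 0:
        raise ValueError("cannot estimate a prevalence from an empty vector")
    n = ind.size
    p = float(ind.mean())
    zq = norm.ppf(0.5 + level / 2.0)
    half = zq * np.sqrt(p * (1.0 - p) / n)
    return PrevalenceEstimate(
        proportion=p,
        ci_low=float(max(0.0, p - half)),
        ci_high=float(min(1.0, p + half)),
        n=n,
    )


class CIAFClassifier:
    """Deterministic z-score -> CIAF transformer (sklearn transform style).

    ``transform`` maps a DataFrame with ``haz``/``whz``/``waz`` columns to
    one with added ``stunted``/``wasted``/``underweight``/``group``/``ciaf``
    columns.  ``fit`` is a no-op kept for pipeline compatibility.

    Parameters
    ----------
    cutoff : failure threshold in SD units (strict ``<``); default -2.
    drop_invalid : drop rows outside the plausibility windows (logged),
        mirroring the exclusion of implausible measurements from analytic
        samples.
    """

    def __init__(self, cutoff: float = -2.0, drop_invalid: bool = True):
        self.cutoff = cutoff
        self.drop_invalid = drop_invalid

    def get_params(self, deep: bool = True) -> dict:
        return {"cutoff": self.cutoff, "drop_invalid": self.drop_invalid}

    def set_params(self, **params) -> "CIAFClassifier":
        for k, v in params.items():
            if k not in ("cutoff", "drop_invalid"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "CIAFClassifier":
        self.n_features_in_ = 3
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        for col in ("haz", "whz", "waz"):
            if col not in X.columns:
                raise ValueError(f"missing z-score column {col!r}")
            if not np.all(np.isfinite(X[col].to_numpy(dtype=float))):
                raise ValueError(f"non-finite values in column {col!r}")
        out = X.copy()
        valid = np.ones(len(out), dtype=bool)
        for col, (lo, hi) in ZSCORE_WINDOWS.items():
            v = out[col].to_numpy(dtype=float)
            valid &= (v >= lo) & (v <= hi)
        if self.drop_invalid:
            dropped = int((~valid).sum())
            if dropped:
                logger.info("dropped %d rows with implausible z-scores", dropped)
            out = out.loc[valid].copy()
        out["stunted"] = out["haz"].to_numpy(dtype=float) < self.cutoff
        out["wasted"] = out["whz"].to_numpy(dtype=float) < self.cutoff
        out["underweight"] = out["waz"].to_numpy(dtype=float) < self.cutoff
        keys = list(zip(out["stunted"], out["wasted"], out["underweight"]))
        out["group"] = [_GROUP_MAP[k] for k in keys]
        out["ciaf"] = (out["group"] != "A").astype(int)
        return out

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


def prevalence_table(classified: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Prevalence with CIs per anthropometric status, one row per status.

    Rows mirror the conventional reporting layout: overall CIAF, no failure,
    then each mutually exclusive failure group that occurs.  Note the
    "only"/"+" groups are the exclusive CIAF groups, while a separate
    aggregate row is emitted for each simple index (stunting = any HAZ
    failure, etc.) since both conventions appear in the literature.
    """
    rows = []

    def add(status, ind):
        est = prevalence_ci(ind, level=level)
        rows.append(
            {
                "status": status,
                "prevalence": est.proportion,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n": est.n,
            }
        )

    add("CIAF", classified["ciaf"])
    add("No failure", 1 - classified["ciaf"])
    add("Stunting Only", classified["stunted"].astype(int))
    add("Wasting Only", classified["wasted"].astype(int))
    add("Underweight only", classified["underweight"].astype(int))
    add("Wasting + Underweight", (classified["group"] == "E").astype(int))
    add("Stunting + Underweight", (classified["group"] == "C").astype(int))
    add("Wasting + Stunting + Underweight", (classified["group"] == "D").astype(int))
    return pd.DataFrame(rows)
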