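"""Model-matrix construction for structured additive predictors.

Every term of the additive predictor — linear fixed effects, penalised
B-spline smooths, structured (GMRF) and unstructured (iid) region effects —
is represented by a :class:`DesignBlock`: an n x r design matrix together
with an r x r symmetric positive-semidefinite penalty.  The penalty acts as
the prior precision of the block's coefficients up to a variance component,
so a zero penalty means diffuse fixed effects, a difference penalty means a
random-walk prior on adjacent spline coefficients, and the graph Laplacian
means an intrinsic GMRF over regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import BSpline

from .graphs import RegionGraph

__all__ = [
    "DesignBlock",
    "dummy_code",
    "bspline_basis",
    "difference_penalty",
    "gmrf_precision",
    "apply_sum_to_zero",
]

_EIG_TOL = 1e-8


@dataclass
class DesignBlock:
    """A design matrix with its quadratic penalty.

    Attributes
    ----------
    matrix : (n, r) array — term design matrix.
    penalty : (r, r) array — symmetric PSD penalty (prior precision shape).
    penalty_rank : int — rank of the penalty; its nullity is the dimension of
        the unpenalised subspace (constants for RW1, linear trends for RW2).
    label : term name.
    constraint : "none" or "sum-to-zero".
    column_names : per-column labels (dummy levels, basis index, region id).
    transform : optional (r_orig, r) map from the reduced (constrained)
        coefficients back to the original parameterisation.
    meta : free-form term metadata (knots, levels, reference, ...).
    """

    matrix: np.ndarray
    penalty: np.ndarray
    penalty_rank: int
    label: str
    constraint: str = "none"
    column_names: list[str] = field(default_factory=list)
    transform: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.penalty = np.asarray(self.penalty, dtype=float)
        r = self.matrix.shape[1]
        if self.penalty.shape != (r, r):
            raise ValueError(
                f"{self.label}: penalty shape {self.penalty.shape} does not match "
                f"{r} design columns"
            )
        if not np.allclose(self.penalty, self.penalty.T, atol=1e-10):
            raise ValueError(f"{self.label}: penalty is not symmetric")
        if not self.column_names:
            self.column_names = [f"{self.label}[{i}]" for i in range(r)]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def coefficients_in_original_space(self, coefs: np.ndarray) -> np.ndarray:
        """Map (constrained) coefficients back to the unconstrained basis."""
        if self.transform is None:
            return np.asarray(coefs)
        return np.asarray(coefs) @ self.transform.T


def _penalty_rank(K: np.ndarray) -> int:
    if K.size == 0:
        return 0
    ev = np.linalg.eigvalsh((K + K.T) / 2.0)
    scale = max(ev.max(), 1.0)
    return int(np.sum(ev > _EIG_TOL * scale))


def dummy_code(values, levels, reference) -> DesignBlock:
    """Reference-coded indicators for a categorical covariate.

    One column per non-reference level; a record at the reference level gets
    an all-zero row.  The penalty is the zero matrix: fixed effects carry
    independent diffuse priors, not a smoothing penalty.
    """
    levels = list(levels)
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among levels {levels}")
    values = np.asarray(values, dtype=object)
    unknown = set(values) - set(levels)
    if unknown:
        raise ValueError(f"unseen categorical level(s): {sorted(map(str, unknown))}")
    others = [lv for lv in levels if lv != reference]
    mat = np.column_stack([(values == lv).astype(float) for lv in others]) if others else np.empty((len(values), 0))
    r = len(others)
    return DesignBlock(
        matrix=mat,
        penalty=np.zeros((r, r)),
        penalty_rank=0,
        label="fixed",
        column_names=[str(lv) for lv in others],
        meta={"levels": levels, "reference": reference},
    )


def bspline_basis(
    x, segments: int = 20, degree: int = 3, domain: tuple[float, float] | None = None
) -> DesignBlock:
    """Equidistant B-spline basis on the observed range of ``x``.

    The knot grid divides ``[min(x), max(x)]`` (or the given ``domain``) into
    ``segments`` equal intervals and is augmented by ``degree`` exterior
    knots on each side, giving ``segments + degree`` basis functions that
    sum to one everywhere on the interior (partition of unity).
    """
    if segments < 1:
        raise ValueError("segments must be >= 1")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    x = np.asarray(x, dtype=float)
    lo, hi = domain if domain is not None else (x.min(), x.max())
    if not hi > lo:
        raise ValueError("degenerate covariate range for spline basis")
    n_basis = segments + degree
    if np.unique(x).size < n_basis:
        warnings.warn(
            f"fewer distinct covariate values ({np.unique(x).size}) than basis "
            f"functions ({n_basis}); penalty carries the fit",
            stacklevel=2,
        )
    h = (hi - lo) / segments
    knots = lo + h * np.arange(-degree, segments + degree + 1)
    # clip to the closed domain so the right boundary point is representable
    mat = BSpline.design_matrix(
        np.clip(x, lo, hi), knots, degree, extrapolate=False
    ).toarray()
    return DesignBlock(
        matrix=mat,
        penalty=np.zeros((n_basis, n_basis)),
        penalty_rank=0,
        label="spline",
        meta={"knots": knots, "degree": degree, "segments": segments, "domain": (lo, hi)},
    )


def difference_penalty(order: int, size: int) -> np.ndarray:
    """Random-walk penalty K = D'D with D the ``order``-th difference matrix.

    RW1 penalises jumps between adjacent coefficients (constants are free);
    RW2 penalises curvature (constants and linear trends are free).  The rank
    is ``size - order``.
    """
    if order not in (1, 2):
        raise ValueError("only first- and second-order penalties are supported")
    if size <= order:
        raise ValueError(f"need more than {order} coefficients for an order-{order} penalty")
    D = np.diff(np.eye(size), n=order, axis=0)
    return D.T @ D


def gmrf_precision(graph: RegionGraph) -> np.ndarray:
    """Intrinsic GMRF precision (graph Laplacian) over the regions.

    Diagonal entries hold neighbour counts N_s, off-diagonals are -1 for
    adjacent pairs; every row sums to zero and, on a connected graph, the
    rank is (number of regions) - 1.  The implied full conditional of region
    s given the rest is Gaussian with mean the neighbour average and
    variance ``sigma2 / N_s``.
    """
    graph.require_connected()
    ids = graph.region_ids
    pos = {r: i for i, r in enumerate(ids)}
    n = len(ids)
    K = np.zeros((n, n))
    for pair in graph.adjacency:
        a, b = tuple(pair)
        i, j = pos[a], pos[b]
        K[i, j] = K[j, i] = -1.0
        K[i, i] += 1.0
        K[j, j] += 1.0
    return K


def apply_sum_to_zero(block: DesignBlock, over: str = "observations") -> DesignBlock:
    """Reparameterise a block so its fitted effect sums to zero.

    ``over="observations"`` constrains the fitted values (the standard
    identifiability constraint for smooths when an intercept is present);
    ``over="coefficients"`` constrains the coefficient vector itself (used
    for region effects, where each coefficient is one region's effect).
    The block loses exactly one column; with a free intercept the fitted
    predictor is unchanged.
    """
    X, K = block.matrix, block.penalty
    r = X.shape[1]
    if over == "observations":
        c = X.sum(axis=0)
    elif over == "coefficients":
        c = np.ones(r)
    else:
        raise ValueError("over must be 'observations' or 'coefficients'")
    c = c / np.linalg.norm(c)
    # orthonormal basis of the null space of c' via full QR
    q, _ = np.linalg.qr(np.column_stack([c, np.eye(r)]), mode="complete")
    Z = q[:, 1:r]  # r x (r-1), columns orthogonal to c
    Kc = Z.T @ K @ Z
    Kc = (Kc + Kc.T) / 2.0
    prev = block.transform if block.transform is not None else np.eye(r)
    return replace(
        block,
        matrix=X @ Z,
        penalty=Kc,
        penalty_rank=_penalty_rank(Kc),
        constraint="sum-to-zero",
        column_names=[f"{block.label}~{i}" for i in range(r - 1)],
        transform=prev @ Z,
    )
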