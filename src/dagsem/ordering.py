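"""Stage 1: vertex or layer ordering of the variables.

Two routes are supported:

* **knowledge-based** -- a prior directed graph (e.g. a curated pathway)
  is converted to a DAG and its topological vertex order (TO) or unique
  layer decomposition (TL) is used;
* **bottom-up, data-driven** -- the precision matrix (inverse covariance)
  is estimated by the graphical lasso,

      Omega_hat = argmin_{Omega > 0}  tr(Omega S) - log det(Omega)
                                      + lambda * sum_{j != k} |omega_jk|,

  and the node whose precision diagonal ``omega_jj`` is smallest -- i.e.
  whose full conditional variance ``var(Y_j | rest)`` is largest -- is
  designated terminal.  That node (or, in layer mode, every node within
  ``eta`` of the minimum) is removed from the data and the step repeats
  until a single source node (or the top layer) remains; the reverse of
  the removal order is the estimated causal ordering.

Under the equal-error-variance linear SEM the sink of the graph has the
largest full conditional variance, which is why the backward sweep
recovers a valid topological order in population.  Note that this signal
lives on the *covariance* scale: rescaling variables to unit variance
(correlation input) distorts the precision diagonal by each variable's
marginal variance and can invert the selection, so the default here is the
covariance matrix; correlation input remains available via ``scale=True``
for pipelines that require scale invariance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .graph import (
    DirectedGraph,
    LayerAssignment,
    NodeOrdering,
    layer_decomposition,
    topological_sort,
)

__all__ = [
    "PrecisionEstimate",
    "OrderingSpec",
    "GlassoConvergenceError",
    "correlation_matrix",
    "glasso_precision",
    "default_glasso_lambda",
    "bottomup_order",
    "bottomup_order_from_covariance",
    "adaptive_eta",
    "knowledge_order",
]


class GlassoConvergenceError(RuntimeError):
    """Graphical-lasso solver failed to converge."""

    def __init__(self, lam: float, max_iter: int, detail: str = ""):
        self.lam = lam
        self.max_iter = max_iter
        msg = f"graphical lasso did not converge (lambda={lam:g}, max_iter={max_iter})"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


@dataclass(frozen=True)
class PrecisionEstimate:
    """Estimated precision matrix Omega_hat with its diagonal and penalty."""

    matrix: pd.DataFrame
    lambda_used: float

    @property
    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.matrix.to_numpy()), index=self.matrix.index)


@dataclass(frozen=True)
class OrderingSpec:
    """Configuration of the stage-1 ordering search.

    Parameters
    ----------
    source
        ``"knowledge"`` (prior graph) or ``"bottomup"`` (data-driven).
    granularity
        ``"vertex"`` for a full permutation, ``"layer"`` for the layer
        partition.  ``eta`` is ignored in vertex mode.
    eta
        Layer-mode tolerance: every node whose precision diagonal lies
        within ``eta`` of the minimum joins the current terminal layer.
        ``"adaptive"`` estimates it by split-half stability (n > 100).
    glasso_lambda
        Penalty for the graphical lasso; ``None`` selects the default rule
        (0.001 for n > p, sqrt(log p / n) otherwise).  Ignored for
        knowledge orderings.
    scale
        If True, run on the correlation rather than covariance matrix.
    """

    source: Literal["knowledge", "bottomup"] = "bottomup"
    granularity: Literal["vertex", "layer"] = "vertex"
    eta: float | Literal["adaptive"] | None = None
    glasso_lambda: float | None = None
    scale: bool = False
    seed: int = 0


DEFAULT_ETA = 0.05


def correlation_matrix(data: pd.DataFrame, scale: bool = True) -> pd.DataFrame:
    """Sample covariance S = (Y'Y)/n after column centering; correlation if ``scale``.

    Divides by n (not n-1), matching the moment definition; with
    ``scale=True`` columns are standardised first so the result has unit
    diagonal.  A zero-variance column is an error when scaling.
    """
    if data.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    X = data.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("data contains non-finite values")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0)  # ddof=0, consistent with /n
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(f"zero-variance column(s): {list(data.columns[zero])}")
        Xc = Xc / sd
    S = (Xc.T @ Xc) / X.shape[0]
    return pd.DataFrame(S, index=data.columns, columns=data.columns)


# below this penalty the L1 term perturbs the solution by at most O(lam),
# so the exact MLE S^{-1} is an acceptable stand-in when the iterative
# solver breaks down numerically
_MLE_FALLBACK_LAMBDA = 0.01


def glasso_precision(S: pd.DataFrame, lam: float, n: int | None = None) -> PrecisionEstimate:
    """L1-penalised precision estimate (off-diagonal penalty only).

    Delegates to the graphical-lasso coordinate-descent solver; for
    ``lam -> 0`` on a well-conditioned S the result approaches the MLE
    ``S^{-1}``.  The solver can fail numerically on some matrices at
    near-zero penalties even when S is comfortably invertible; in that
    regime (``lam <= 0.01``) the exact MLE inverse is returned with a
    warning, since it differs from the penalised optimum by at most
    O(lam).  At larger penalties, or when S is effectively singular,
    :class:`GlassoConvergenceError` is raised.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    labels = list(S.index)
    arr = np.asarray(S, dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    arr = (arr + arr.T) / 2.0
    max_iter = 500
    try:
        with warnings.catch_warnings():
            # near-zero penalties can stall at a tiny (even slightly negative)
            # dual gap; the estimate is still usable, so only hard numerical
            # failures are escalated
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, precision = graphical_lasso(arr, alpha=lam, max_iter=max_iter)
    except FloatingPointError as exc:
        precision = None
        if lam <= _MLE_FALLBACK_LAMBDA:
            eig = np.linalg.eigvalsh(arr)
            if eig.min() > 1e-12 * max(eig.max(), 1.0):
                precision = np.linalg.inv(arr)
                warnings.warn(
                    f"graphical lasso failed numerically at lambda={lam:g}; "
                    "using the MLE inverse (difference bounded by the penalty)",
                    RuntimeWarning,
                    stacklevel=2,
                )
        if precision is None:
            raise GlassoConvergenceError(lam, max_iter, str(exc)) from exc
    return PrecisionEstimate(
        matrix=pd.DataFrame(precision, index=labels, columns=labels),
        lambda_used=lam,
    )


def default_glasso_lambda(n: int, p: int, hd_rule: Literal["sqrt", "flat"] = "sqrt") -> float:
    """Default graphical-lasso penalty: 0.001 for n > p, else sqrt(log p / n).

    The high-dimensional branch follows the square-root rate of the sparse
    inverse-covariance literature; ``hd_rule="flat"`` gives the plain
    ``log(p)/n`` reading instead.
    """
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    if n > p:
        return 0.001
    val = math.log(p) / n
    return math.sqrt(val) if hd_rule == "sqrt" else val


def _terminal_set(diag: pd.Series, granularity: str, eta: float) -> list[str]:
    """Node(s) with (near-)minimal precision diagonal = maximal conditional variance."""
    m = float(diag.min())
    if granularity == "vertex":
        # smallest label among exact minima
        return [sorted(diag.index[diag == m])[0]]
    return sorted(diag.index[diag <= m + eta])


def bottomup_order_from_covariance(
    S: pd.DataFrame,
    spec: OrderingSpec = OrderingSpec(),
    eta: float | None = None,
) -> NodeOrdering | LayerAssignment:
    """Run the bottom-up sweep on a fixed (e.g. exact population) covariance.

    The covariance of a variable subset is the corresponding submatrix, so
    each iteration simply drops the selected rows/columns and re-runs the
    graphical lasso — no data resampling involved.  Used directly as the
    population-level oracle path in tests.
    """
    if S.shape[0] < 2:
        raise ValueError("need at least 2 variables")
    lam = spec.glasso_lambda if spec.glasso_lambda is not None else 1e-8
    if eta is None:
        eta = spec.eta if isinstance(spec.eta, (int, float)) and spec.eta is not None else DEFAULT_ETA
    reversed_groups: list[list[str]] = []
    remaining = list(S.index)
    while len(remaining) > 1:
        prec = glasso_precision(S.loc[remaining, remaining], lam)
        picked = _terminal_set(prec.diagonal, spec.granularity, eta)
        if len(picked) == len(remaining):
            # everything ties: the remainder is the top layer
            break
        reversed_groups.append(picked)
        remaining = [v for v in remaining if v not in picked]
    if remaining:
        reversed_groups.append(sorted(remaining))
    groups = list(reversed(reversed_groups))
    if spec.granularity == "vertex":
        return NodeOrdering(v for g in groups for v in g)
    return LayerAssignment(groups)


def bottomup_order(
    data: pd.DataFrame, spec: OrderingSpec = OrderingSpec()
) -> NodeOrdering | LayerAssignment:
    """Data-driven bottom-up ordering by iterative precision estimation.

    At each step the covariance (or correlation, per ``spec.scale``) of
    the *remaining* columns is formed, the graphical lasso is fitted, the
    terminal node(s) are appended to the reversed ordering and their
    columns dropped; the reverse of the removal order is returned, as a
    :class:`NodeOrdering` (vertex mode) or :class:`LayerAssignment`
    (layer mode).  Ties in the minimum are broken by ascending label.
    """
    if spec.source != "bottomup":
        raise ValueError("spec.source must be 'bottomup'")
    n, p = data.shape
    if p < 2:
        raise ValueError("need at least 2 variables")
    lam = spec.glasso_lambda if spec.glasso_lambda is not None else default_glasso_lambda(n, p)
    if spec.eta == "adaptive":
        eta = adaptive_eta(data, lam, seed=spec.seed, scale=spec.scale)
    elif spec.eta is None:
        eta = DEFAULT_ETA
    else:
        eta = float(spec.eta)

    reversed_groups: list[list[str]] = []
    remaining = list(data.columns)
    while len(remaining) > 1:
        S = correlation_matrix(data[remaining], scale=spec.scale)
        prec = glasso_precision(S, lam, n)
        picked = _terminal_set(prec.diagonal, spec.granularity, eta)
        if len(picked) == len(remaining):
            break
        reversed_groups.append(picked)
        remaining = [v for v in remaining if v not in picked]
    if remaining:
        reversed_groups.append(sorted(remaining))
    groups = list(reversed(reversed_groups))
    if spec.granularity == "vertex":
        return NodeOrdering(v for g in groups for v in g)
    return LayerAssignment(groups)


def adaptive_eta(
    data: pd.DataFrame,
    glasso_lambda: float,
    seed: int = 0,
    scale: bool = False,
    shuffle: bool = True,
) -> float:
    """Split-half estimate of the layer tolerance ``eta``.

    The rows are split into two halves (a seeded shuffle by default;
    ``shuffle=False`` splits first vs. second half), the precision
    diagonal is estimated on each half, and the mean absolute half-vs-half
    difference over nodes is returned — a data-driven gauge of how far
    apart two diagonal entries must be before the difference is more than
    sampling noise.  Requires n > 100.
    """
    n = data.shape[0]
    if n <= 100:
        raise ValueError("adaptive eta needs n > 100; set eta explicitly for small samples")
    idx = np.arange(n)
    if shuffle:
        np.random.default_rng(seed).shuffle(idx)
    half = n // 2
    diags = []
    for rows in (idx[:half], idx[half : 2 * half]):
        S = correlation_matrix(data.iloc[rows], scale=scale)
        diags.append(glasso_precision(S, glasso_lambda).diagonal)
    return float((diags[0] - diags[1]).abs().mean())


def knowledge_order(
    g: DirectedGraph, granularity: Literal["vertex", "layer"] = "vertex"
) -> NodeOrdering | LayerAssignment:
    """Ordering read off a prior DAG: topological sort or layer partition."""
    if granularity == "vertex":
        return topological_sort(g)
    if granularity == "layer":
        return layer_decomposition(g)
    raise ValueError(f"unknown granularity {granularity!r}")
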