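"""Evaluation of recovered graph structures.

Structural Hamming distance (SHD) counts the edge additions/deletions
needed to turn one directed graph into another on a shared node set; a
reversed edge costs 2 (one deletion plus one addition).  The normalised
variant divides by the number of ordered node pairs p(p-1), guaranteeing a
value in [0, 1]; division by p alone is available for compatibility but
can exceed 1.

The Matthews correlation coefficient (MCC) scores binary edge (or class)
predictions symmetrically in all four confusion-matrix cells and stays
honest under class imbalance: +1 is perfect agreement, 0 no better than
random, -1 complete disagreement.

For prediction-based evaluation, the path coefficients of a fitted DAG
are the per-node OLS estimates of each child on its parents (the MLE for
the linear Gaussian SEM), and scores are the linear reconstructions
Y_hat = Y B_hat, with train-set column means applied to any test data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import DirectedGraph, is_acyclic

__all__ = [
    "ConfusionCounts",
    "PathCoefficients",
    "shd",
    "normalized_shd",
    "mcc",
    "edge_confusion",
    "fit_path_coefficients",
    "predict_scores",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class PathCoefficients:
    """Fitted path-coefficient matrix B_hat with its edge support and train means."""

    B_hat: pd.DataFrame
    support: frozenset[tuple[str, str]]
    means: pd.Series


def _check_same_nodes(g1: DirectedGraph, g2: DirectedGraph) -> None:
    if set(g1.nodes) != set(g2.nodes):
        raise ValueError("graphs must share the same node set")


def shd(g1: DirectedGraph, g2: DirectedGraph) -> int:
    """Structural Hamming distance: differing directed adjacency entries."""
    _check_same_nodes(g1, g2)
    return len(g1.edges ^ g2.edges)


def normalized_shd(
    g1: DirectedGraph, g2: DirectedGraph, divisor: str = "ordered_pairs"
) -> float:
    """SHD scaled to [0, 1] by p(p-1); ``divisor="nodes"`` divides by p instead."""
    _check_same_nodes(g1, g2)
    p = g1.n_nodes
    if p < 2:
        raise ValueError("need at least 2 nodes")
    if divisor == "ordered_pairs":
        return shd(g1, g2) / (p * (p - 1))
    if divisor == "nodes":
        return shd(g1, g2) / p
    raise ValueError(f"unknown divisor {divisor!r}")


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 by convention on degenerate margins."""
    tp, fp, fn, tn = c.TP, c.FP, c.FN, c.TN
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def edge_confusion(g_true: DirectedGraph, g_est: DirectedGraph) -> ConfusionCounts:
    """Directed-edge confusion counts over all ordered node pairs."""
    _check_same_nodes(g_true, g_est)
    p = g_true.n_nodes
    tp = len(g_true.edges & g_est.edges)
    fp = len(g_est.edges - g_true.edges)
    fn = len(g_true.edges - g_est.edges)
    tn = p * (p - 1) - tp - fp - fn
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def fit_path_coefficients(dag: DirectedGraph, data: pd.DataFrame) -> PathCoefficients:
    """Per-node OLS of each child on its parents: the Gaussian-SEM MLE of B.

    Entries off the DAG's edge support are exactly zero; source nodes have
    all-zero columns.  Data are centred; the column means are stored so
    test data can be centred identically at prediction time.
    """
    if not is_acyclic(dag):
        raise ValueError("dag must be acyclic")
    missing = set(dag.nodes) - set(data.columns)
    if missing:
        raise ValueError(f"data lacks columns for nodes: {sorted(missing)}")
    nodes = list(dag.nodes)
    Y = data[nodes].to_numpy(dtype=float)
    means = pd.Series(Y.mean(axis=0), index=nodes)
    Yc = Y - means.to_numpy()
    idx = {v: i for i, v in enumerate(nodes)}
    B = pd.DataFrame(0.0, index=nodes, columns=nodes)
    for j in nodes:
        parents = sorted(dag.parents(j))
        if not parents:
            continue
        Xp = Yc[:, [idx[k] for k in parents]]
        if Y.shape[0] <= len(parents) or np.linalg.matrix_rank(Xp) < len(parents):
            raise ValueError(f"rank-deficient parent matrix for node {j!r}")
        coef, *_ = np.linalg.lstsq(Xp, Yc[:, idx[j]], rcond=None)
        for k, b in zip(parents, coef):
            B.loc[k, j] = b
    return PathCoefficients(B_hat=B, support=frozenset(dag.edges), means=means)


def predict_scores(data: pd.DataFrame, B: PathCoefficients) -> pd.DataFrame:
    """Linear reconstruction Y_hat = Y_c B_hat using the stored train means.

    Source-node columns (all-zero columns of B_hat) come out identically
    zero.  ``B`` is not modified — no refitting happens at prediction
    time.
    """
    nodes = list(B.B_hat.index)
    missing = set(nodes) - set(data.columns)
    if missing:
        raise ValueError(f"data lacks columns: {sorted(missing)}")
    Yc = data[nodes].to_numpy(dtype=float) - B.means.to_numpy()
    Yhat = Yc @ B.B_hat.to_numpy()
    return pd.DataFrame(Yhat, index=data.index, columns=nodes)
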