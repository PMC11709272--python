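"""Synthetic linear Gaussian SEMs with equal error variances.

The generative model is the one the learner assumes: given a DAG with
coefficient ``beta_jk`` on each edge ``k -> j``,

    Y_j = sum_{k in pa(j)} beta_jk * Y_k + U_j,     U_j ~ N(0, sigma^2) i.i.d.

with a single common error s.d. ``sigma`` (the equal-error-variance regime
that makes the exact DAG, not just its Markov equivalence class,
identifiable).  Writing B for the p x p matrix with B[k, j] = beta_jk, the
system is Y = B'Y + U and the population covariance has the closed form

    Sigma = (I - B')^{-1} sigma^2 (I - B')^{-T},

which serves as an exact oracle in tests: the bottom-up ordering search can
be run on Sigma directly, bypassing sampling noise.

Default edge magnitudes are drawn uniformly from +/-[0.5, 1.0] with a fair
sign coin: large enough to be detectable at moderate n, sign-balanced to
avoid variance blow-up along long paths, and bounded away from zero so
every edge is identifiable in principle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import DirectedGraph, topological_sort

__all__ = [
    "SEMParameters",
    "random_dag",
    "draw_weights",
    "population_covariance",
    "simulate_sem",
]

DEFAULT_MAGNITUDE_RANGE = (0.5, 1.0)


@dataclass(frozen=True)
class SEMParameters:
    """A parameterised linear SEM: DAG, edge coefficients, common error s.d.

    ``error_sd`` may be overridden per node (mapping label -> s.d.) only to
    demonstrate violation of the equal-variance assumption in tests.
    """

    dag: DirectedGraph
    coefficients: dict[tuple[str, str], float]
    error_sd: float = 1.0
    error_sd_per_node: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.coefficients) != self.dag.edges:
            raise ValueError("coefficient support must equal the edge set")
        if self.error_sd <= 0:
            raise ValueError("error_sd must be positive")

    def sd_of(self, node: str) -> float:
        return self.error_sd_per_node.get(node, self.error_sd)

    def coefficient_matrix(self) -> pd.DataFrame:
        """B with B[k, j] = beta_jk (rows = parent k, columns = child j)."""
        nodes = list(self.dag.nodes)
        B = pd.DataFrame(0.0, index=nodes, columns=nodes)
        for (k, j), b in self.coefficients.items():
            B.loc[k, j] = b
        return B


def random_dag(p: int, edge_prob: float, seed: int) -> DirectedGraph:
    """Erdos–Renyi-style random DAG on ``p`` labelled nodes.

    A uniform node permutation is drawn, and each forward pair (with
    respect to that permutation) is included independently with
    probability ``edge_prob`` — acyclic by construction, deterministic per
    seed.  Labels are ``Y1 .. Yp``.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = [f"Y{i + 1}" for i in range(p)]
    perm = rng.permutation(p)
    order = [labels[i] for i in perm]
    edges = []
    for a in range(p):
        for b in range(a + 1, p):
            if rng.random() < edge_prob:
                edges.append((order[a], order[b]))
    return DirectedGraph(labels, edges)


def draw_weights(
    dag: DirectedGraph,
    magnitude_range: tuple[float, float] = DEFAULT_MAGNITUDE_RANGE,
    seed: int = 0,
    error_sd: float = 1.0,
) -> SEMParameters:
    """Draw edge coefficients uniformly on +/-[lo, hi] with fair random sign."""
    lo, hi = magnitude_range
    if not 0 < lo <= hi:
        raise ValueError("need 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    coefs = {}
    for edge in sorted(dag.edges):
        mag = rng.uniform(lo, hi)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        coefs[edge] = sign * mag
    return SEMParameters(dag=dag, coefficients=coefs, error_sd=error_sd)


def population_covariance(params: SEMParameters) -> pd.DataFrame:
    """Exact covariance of the SEM: ``(I - B')^{-1} D (I - B')^{-T}``.

    D is the diagonal of error variances (``sigma^2 I`` in the
    equal-variance regime).  ``I - B'`` is unit-triangular under any
    topological order, hence always invertible.
    """
    nodes = list(params.dag.nodes)
    B = params.coefficient_matrix().to_numpy()
    p = len(nodes)
    A = np.linalg.inv(np.eye(p) - B.T)
    d = np.array([params.sd_of(v) ** 2 for v in nodes])
    sigma = A @ np.diag(d) @ A.T
    return pd.DataFrame(sigma, index=nodes, columns=nodes)


def simulate_sem(params: SEMParameters, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` i.i.d. samples, generating nodes in topological order.

    Returns an n x p DataFrame with columns in the DAG's node order;
    bit-identical across runs with the same seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = list(params.dag.nodes)
    order = topological_sort(params.dag)
    cols = {v: None for v in nodes}
    # errors drawn in stable node order so the draw is independent of the DAG shape
    noise = {v: rng.normal(0.0, params.sd_of(v), size=n) for v in nodes}
    for j in order:
        y = noise[j].copy()
        for k in params.dag.parents(j):
            y += params.coefficients[(k, j)] * cols[k]
        cols[j] = y
    return pd.DataFrame({v: cols[v] for v in nodes})
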