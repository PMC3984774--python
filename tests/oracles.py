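"""Independent oracles used by the test suite.

These deliberately avoid the library's solver paths: the fit oracle builds the
design matrix sample by sample with explicit Python loops and solves the
normal equations through a pseudoinverse; the completion oracle enumerates
every per-node budget decomposition and every edge choice directly.
"""

from __future__ import annotations

import itertools
from math import inf

import numpy as np

from grncomplete import CompletionSpec, ExpressionMatrix, GeneNetwork, node_error


def normal_equations_fit(expr: ExpressionMatrix, node: str, parents) -> tuple[np.ndarray, float]:
    """Least-squares fit of the quadratic model via pinv of the Gram matrix."""
    parents = list(parents)
    y = expr.row(node)
    rows = []
    for s in range(expr.n_samples):
        vals = [expr.row(p)[s] for p in parents]
        row = [1.0] + vals
        for j in range(len(vals)):
            for k in range(j, len(vals)):
                row.append(vals[j] * vals[k])
        rows.append(row)
    x = np.array(rows)
    beta = np.linalg.pinv(x.T @ x, rcond=1e-12) @ (x.T @ y)
    resid = y - x @ beta
    return beta, float(resid @ resid)


def enumerate_node_minimum(
    expr: ExpressionMatrix,
    network: GeneNetwork,
    node: str,
    k_j: int,
    h_j: int,
    spec: CompletionSpec,
    allow_self_loops: bool = False,
) -> float:
    """Minimal error over all disjoint (add, delete) choices, or +inf."""
    deg = network.indegree(node)
    n = network.n
    if k_j > spec.K or h_j > spec.H:
        return inf
    if not 0 <= k_j - h_j + deg < n:
        return inf
    parents = set(network.parents(node))
    cand = set(network.genes) - parents
    if not allow_self_loops:
        cand.discard(node)
    if h_j > len(parents) or k_j > len(cand):
        return inf
    best = inf
    for dels in itertools.combinations(sorted(parents), h_j):
        for adds in itertools.combinations(sorted(cand), k_j):
            err = node_error(expr, node, sorted((parents - set(dels)) | set(adds)))
            best = min(best, err)
    return best


def enumerate_global_optimum(
    expr: ExpressionMatrix,
    network: GeneNetwork,
    spec: CompletionSpec,
    allow_self_loops: bool = False,
) -> float:
    """Exhaustive optimum over all per-node budget decompositions.

    For every way to write k = Σ k_j and h = Σ h_j over the nodes, sums the
    enumerated per-node minima; returns the global minimum (or +inf).
    """
    genes = network.genes
    n = len(genes)
    per_node: list[dict[tuple[int, int], float]] = []
    for g in genes:
        d = {}
        for kj in range(min(spec.k, spec.K) + 1):
            for hj in range(min(spec.h, spec.H) + 1):
                d[(kj, hj)] = enumerate_node_minimum(
                    expr, network, g, kj, hj, spec, allow_self_loops
                )
        per_node.append(d)

    def decompositions(total: int, parts: int, cap: int):
        if parts == 1:
            if total <= cap:
                yield (total,)
            return
        for first in range(min(total, cap) + 1):
            for rest in decompositions(total - first, parts - 1, cap):
                yield (first,) + rest

    best = inf
    for ks in decompositions(spec.k, n, min(spec.k, spec.K)):
        for hs in decompositions(spec.h, n, min(spec.h, spec.H)):
            total = 0.0
            for j in range(n):
                v = per_node[j][(ks[j], hs[j])]
                if v == inf:
                    total = inf
                    break
                total += v
            best = min(best, total)
    return best


def random_instance(
    rng: np.random.Generator, n: int, m: int, edge_prob: float = 0.35
) -> tuple[ExpressionMatrix, GeneNetwork]:
    """A random expression matrix and a random directed network over it."""
    genes = [f"g{i + 1}" for i in range(n)]
    expr = ExpressionMatrix(rng.normal(size=(n, m)), genes)
    edges = [
        (u, v)
        for u in genes
        for v in genes
        if rng.random() < edge_prob
    ]
    return expr, GeneNetwork(genes, edges)
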