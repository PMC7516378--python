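"""Independent reference implementations used only for cross-checking.

These deliberately avoid the package's own code paths: exact rational
enumeration for the 2x2 tests, a topological-order pass for knockdown
propagation, and a damped fixed-point solver for the signed-network
ranking.
"""

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact enumeration of the hypergeometric support."""
    N, K, n = a + b + c + d, a + b, a + c
    lo, hi = max(0, K + n - N), min(K, n)
    denom = comb(N, n)
    pmf = {k: Fraction(comb(K, k) * comb(N - K, n - k), denom) for k in range(lo, hi + 1)}
    pobs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= pobs))


def hypergeom_upper_tail_exact(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ HG(N, K, n), by exact partial summation."""
    denom = comb(N, n)
    hi = min(K, n)
    return float(sum(Fraction(comb(K, j) * comb(N - K, n - j), denom) for j in range(k, hi + 1)))


def topological_knockdown(fvals, expr, seed_tf: str, factor: float):
    """Propagate a knockdown through an acyclic TF graph in topological order.

    Recomputes every gene reachable from the seed once, from the final
    levels of its regulators, using the saturable regulation model in
    log2 space.  Returns the new gene x sample table.
    """
    regs: dict = {}
    tfset = set()
    for tf, g in fvals.f.index:
        regs.setdefault(g, []).append(tf)
        tfset.add(tf)
    G = nx.DiGraph()
    G.add_nodes_from(tfset)
    for tf, g in fvals.f.index:
        if g in tfset:
            G.add_edge(tf, g)
    reach = {seed_tf} | nx.descendants(G, seed_tf)
    new = expr.values.copy()
    new.loc[seed_tf] = new.loc[seed_tf] * factor

    def recompute(gene):
        lp = np.full(new.shape[1], np.log2(fvals.basal.loc[gene]))
        for tf in sorted(regs[gene]):
            x = new.loc[tf].to_numpy(dtype=float)
            F = fvals.f.loc[(tf, gene)]
            lp = lp + np.log2((1.0 + F * x) / (1.0 + x))
        new.loc[gene] = 2.0**lp

    for t in nx.topological_sort(G.subgraph(reach)):
        if t != seed_tf:
            recompute(t)
    leaves = sorted(
        {g for t in reach for (tf, g) in fvals.f.index if tf == t and g not in tfset and g in new.index}
    )
    for g in leaves:
        recompute(g)
    return new


def damped_ranking_fixed_point(A: np.ndarray, mu: float, damping=0.5, tol=1e-12, max_iter=500_000):
    """Fixed point of p = normalize(exp(A^T p / mu)) by damped iteration."""
    n = A.shape[0]
    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        z = A.T @ p / mu
        z -= z.max()
        q = np.exp(z)
        q /= q.sum()
        new = (1 - damping) * p + damping * q
        if np.linalg.norm(new - p) < tol:
            return new
        p = new
    return p


def random_regulatory_system(n_nodes: int, cyclic: bool, rng: np.random.Generator, n_leaves=5):
    """Random TF graph (+ leaf genes) packaged as an F matrix and expression."""
    import pandas as pd

    from tfregnet.containers import ExpressionMatrix, FValueMatrix

    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    edges = []
    if cyclic:
        for _ in range(n_nodes * 2):
            a, b = rng.choice(n_nodes, 2, replace=False)
            edges.append((nodes[a], nodes[b]))
    else:
        order = rng.permutation(n_nodes)
        for _ in range(n_nodes * 2):
            i, j = sorted(rng.choice(n_nodes, 2, replace=False))
            edges.append((nodes[order[i]], nodes[order[j]]))
    edges = sorted(set(edges))
    for g in [f"g{i:02d}" for i in range(n_leaves)]:
        for tf in rng.choice(nodes, min(2, n_nodes), replace=False):
            edges.append((tf, g))
    idx = pd.MultiIndex.from_tuples(edges, names=["tf", "gene"])
    f = pd.Series(2.0 ** rng.uniform(-2, 2, len(edges)), index=idx)
    genes = sorted({g for _, g in edges})
    basal = pd.Series(2.0 ** rng.normal(2, 1, len(genes)), index=genes)
    all_rows = sorted(set(nodes) | set(genes))
    expr = ExpressionMatrix(
        pd.DataFrame(
            2.0 ** rng.normal(0, 1, (len(all_rows), 3)),
            index=all_rows,
            columns=["s1", "s2", "s3"],
        )
    )
    return FValueMatrix(f=f, basal=basal), expr, nodes
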