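"""In-silico TF knockdown with recursive propagation (hPerturb).

Knocking down a TF changes its targets' steady-state expression via
the thermodynamic model; targets that are themselves TFs propagate the
change further.  Propagation is a modified breadth-first traversal in
which every TF is perturbed at most once: a target TF is deferred until
all of its regulators on the path from the seed TF have been updated
(so diamonds resolve with final upstream values, exactly as a
topological-order pass would on an acyclic graph), and feedback edges
to already-updated TFs are truncated, which guarantees termination on
cyclic graphs.  Deferred TFs are revisited from a queue keyed by their
remaining count of unperturbed on-path regulators; when a cycle leaves
no TF with count zero, the pending TF discovered earliest (breadth
first from the seed) is released, its unperturbed regulators entering
at baseline levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FValueMatrix
from .model import predict_log2_gene

__all__ = ["PerturbationResult", "h_perturb", "do_not_perturb", "perturb_all_tfs", "tf_subgraph"]


@dataclass
class PerturbationResult:
    new_expression: pd.DataFrame
    updated_genes: list = field(default_factory=list)
    loop_truncations: list = field(default_factory=list)


def _structures(fvals: FValueMatrix):
    regulators: dict[str, list[str]] = {}
    targets: dict[str, set[str]] = {}
    for tf, gene in fvals.f.index:
        regulators.setdefault(gene, []).append(tf)
        targets.setdefault(tf, set()).add(gene)
    for g in regulators:
        regulators[g] = sorted(regulators[g])
    tf_universe = set(targets)
    return regulators, targets, tf_universe


def tf_subgraph(fvals: FValueMatrix) -> nx.DiGraph:
    """Directed TF -> TF subnetwork of the backbone."""
    _, targets, tf_universe = _structures(fvals)
    G = nx.DiGraph()
    G.add_nodes_from(tf_universe)
    for tf, tgts in targets.items():
        for t in tgts:
            if t in tf_universe:
                G.add_edge(tf, t)
    return G


def do_not_perturb(topmost: str, current: str, graph: nx.DiGraph, flags: set) -> set:
    """Target TFs of ``current`` that must not be perturbed now.

    The union of (a) already-perturbed target TFs with a feedback path
    back to ``current`` and (b) target TFs having a regulator on the
    path from ``topmost`` (i.e. reachable from the seed) that has not
    been perturbed yet.
    """
    on_path = {topmost} | nx.descendants(graph, topmost) if topmost in graph else {topmost}
    blocked = set()
    for t in graph.successors(current) if current in graph else ():
        if t in flags:
            if t in graph and nx.has_path(graph, t, current):
                blocked.add(t)
            else:
                blocked.add(t)  # perturbed once is final regardless
            continue
        regs_on_path = {r for r in graph.predecessors(t)} & on_path
        if any(r not in flags for r in regs_on_path):
            blocked.add(t)
    return blocked


def _recompute_gene(gene, fvals, regulators, expr_df):
    regs = regulators[gene]
    f = np.array([fvals.f.loc[(tf, gene)] for tf in regs], dtype=float)
    x = expr_df.loc[regs].to_numpy(dtype=float)
    lp = predict_log2_gene(np.log2(fvals.basal.loc[gene]), f, x)
    return 2.0**lp


def h_perturb(
    fvals: FValueMatrix,
    expr: ExpressionMatrix,
    tf: str,
    knockdown_factor: float = 0.0,
) -> PerturbationResult:
    """Knock down ``tf`` and propagate through the regulatory network.

    The seed TF's expression is multiplied by ``knockdown_factor``
    (default 0: full silencing); every reachable TF is updated exactly
    once with the thermodynamic model once its on-path regulators are
    final, and affected non-TF targets are recomputed last from the
    final TF levels.  Genes not downstream of the seed are unchanged.
    """
    if not (0 <= knockdown_factor <= 1):
        raise ValueError("knockdown_factor must be in [0, 1]")
    regulators, targets, tf_universe = _structures(fvals)
    if tf not in tf_universe:
        raise KeyError(f"unknown TF: {tf}")
    new = expr.values.copy()
    if knockdown_factor == 1.0:  # identity perturbation
        return PerturbationResult(new_expression=new, updated_genes=[], loop_truncations=[])

    G = tf_subgraph(fvals)
    reach = {tf} | nx.descendants(G, tf)
    new.loc[tf] = new.loc[tf] * knockdown_factor
    finalized = {tf}
    updated_order = [tf]
    truncations: list[tuple[str, str]] = []

    # breadth-first discovery depth, used only to break cycles deterministically
    depth = dict(nx.single_source_shortest_path_length(G, tf))
    pending: dict[str, set] = {}
    for t in sorted(reach - {tf}):
        rel = {r for r in regulators.get(t, []) if r in reach}
        pending[t] = rel - finalized  # contains t itself on a self-loop

    while pending:
        ready = sorted(t for t, rem in pending.items() if not rem)
        if ready:
            nxt = ready[0]
        else:
            breakable = sorted(
                (t for t in pending if t not in pending[t]),
                key=lambda t: (depth.get(t, len(depth) + 1), t),
            )
            if not breakable:
                for t in sorted(pending):
                    truncations.append((t, "self-feedback: never perturbed"))
                break
            nxt = breakable[0]
            missing = sorted(pending[nxt])
            truncations.append((nxt, f"cycle broken; regulators at baseline: {missing}"))
        pending.pop(nxt)
        if nxt in new.index:
            new.loc[nxt] = _recompute_gene(nxt, fvals, regulators, new)
        finalized.add(nxt)
        updated_order.append(nxt)
        for rem in pending.values():
            rem.discard(nxt)

    # record feedback edges truncated because the target was already final
    pos = {t: i for i, t in enumerate(updated_order)}
    for u in updated_order:
        for t in targets.get(u, ()):
            if t in pos and pos[t] < pos[u] and G.has_edge(u, t):
                truncations.append((t, f"feedback from {u}: already perturbed"))

    affected = sorted(
        {
            g
            for u in updated_order
            for g in targets.get(u, ())
            if g not in tf_universe and g in new.index and g in fvals.basal.index
        }
    )
    for g in affected:
        new.loc[g] = _recompute_gene(g, fvals, regulators, new)
    return PerturbationResult(
        new_expression=new,
        updated_genes=updated_order + affected,
        loop_truncations=truncations,
    )


def perturb_all_tfs(
    fvals: FValueMatrix, expr: ExpressionMatrix, knockdown_factor: float = 0.0
) -> dict[str, PerturbationResult]:
    """Independent knockdown of every TF from the same baseline."""
    _, _, tf_universe = _structures(fvals)
    results: dict[str, PerturbationResult] = {}
    for tf in sorted(tf_universe):
        try:
            results[tf] = h_perturb(fvals, expr, tf, knockdown_factor)
        except Exception as exc:  # pragma: no cover - isolation contract
            results[tf] = PerturbationResult(
                new_expression=expr.values.copy(),
                loop_truncations=[(tf, f"failed: {exc}")],
            )
    return results
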