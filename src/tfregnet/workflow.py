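"""Cross-layer helpers chaining regression, perturbation, and ranking.

These glue functions implement the essentiality feature pipeline: for
each TF, knock it down, re-rank protein activity per sample, and
collect the per-protein activity deltas used as elastic-net features.
"""

from __future__ import annotations

import pandas as pd

from .activity import ActivityScores, activity_delta, build_transition_matrix, exponential_ranking
from .containers import ExpressionMatrix, FValueMatrix, SignedProteinNetwork
from .perturb import perturb_all_tfs

__all__ = ["rank_sample", "rank_all_samples", "compute_activity_deltas"]


def rank_sample(
    net: SignedProteinNetwork,
    expr_col: pd.Series,
    tolerance: float = 1e-6,
    max_iter: int = 10_000,
) -> ActivityScores:
    """Exponential Ranking of one sample's expression over the interactome.

    The initial score vector is the sample's expression scaled to sum 1
    when all entries are positive, otherwise uniform (the fixed point
    does not depend on the start).
    """
    x = expr_col.reindex(net.proteins).fillna(0.0)
    T = build_transition_matrix(net, x)
    p0 = x / x.sum() if (x > 0).all() else None
    return exponential_ranking(T, p0=p0, tolerance=tolerance, max_iter=max_iter)


def rank_all_samples(
    net: SignedProteinNetwork, expr: pd.DataFrame, tolerance: float = 1e-6
) -> dict[str, ActivityScores]:
    return {s: rank_sample(net, expr[s], tolerance=tolerance) for s in expr.columns}


def compute_activity_deltas(
    fvals: FValueMatrix,
    expr: ExpressionMatrix,
    net: SignedProteinNetwork,
    knockdown_factor: float = 0.0,
    tolerance: float = 1e-6,
) -> dict[str, pd.DataFrame]:
    """Per-TF activity deltas: knockdown -> re-rank -> transformed-score change.

    Returns tf -> (sample x protein) DataFrame.  Baseline ranking uses
    the supplied expression; each TF's perturbed ranking uses the
    hPerturb output under the same scaling.
    """
    baseline = rank_all_samples(net, expr.values, tolerance=tolerance)
    results = perturb_all_tfs(fvals, expr, knockdown_factor)
    deltas: dict[str, pd.DataFrame] = {}
    for tf, res in results.items():
        rows = {}
        for s in expr.values.columns:
            perturbed = rank_sample(net, res.new_expression[s], tolerance=tolerance)
            rows[s] = activity_delta(baseline[s], perturbed)
        deltas[tf] = pd.DataFrame.from_dict(rows, orient="index")[net.proteins]
    return deltas
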