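"""Protein signaling activity by Exponential Ranking on a signed interactome.

The transition matrix is the signed, likelihood-weighted adjacency B
augmented with expression, A = x x^T o B (A_ij = x_i x_j sign_ij w_ij
for edge i -> j), and scores iterate

    p(t+1) = exp((1/mu) A^T p(t)) / || exp((1/mu) A^T p(t)) ||_1

with mu = max_ij A_ij - min_ij A_ij, until the l2 change between
consecutive iterates falls below tolerance (default 1e-6).  Rank flows
along edge direction (A^T p sums incoming contributions).  The exp is
max-stabilized, which leaves the normalized iterate unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SignedProteinNetwork

__all__ = [
    "TransitionMatrix",
    "ActivityScores",
    "build_transition_matrix",
    "exponential_ranking",
    "transform_scores",
    "activity_delta",
]


@dataclass
class TransitionMatrix:
    A: pd.DataFrame  # protein x protein
    mu: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive (constant transition matrix?)")


@dataclass
class ActivityScores:
    p: pd.Series
    iterations: int
    converged: bool
    transformed: pd.Series


def build_transition_matrix(net: SignedProteinNetwork, expr: pd.Series) -> TransitionMatrix:
    """Expression-augmented transition matrix A = x x^T o B.

    ``expr`` must cover every protein with nonnegative values; mu is
    the spread max(A) - min(A) over all entries (structural zeros
    included).
    """
    missing = set(net.proteins) - set(expr.index)
    if missing:
        raise KeyError(f"expression missing for proteins: {sorted(missing)[:10]}")
    x = expr.reindex(net.proteins).to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("expression must be nonnegative")
    n = len(net.proteins)
    pos = {p: i for i, p in enumerate(net.proteins)}
    A = np.zeros((n, n))
    for src, dst, sign, weight in net.edges[["src", "dst", "sign", "weight"]].itertuples(index=False):
        i, j = pos[src], pos[dst]
        A[i, j] = x[i] * x[j] * sign * weight
    mu = float(A.max() - A.min())
    if mu == 0:
        raise ValueError("transition matrix is constant; cannot rank")
    return TransitionMatrix(A=pd.DataFrame(A, index=net.proteins, columns=net.proteins), mu=mu)


def exponential_ranking(
    A: TransitionMatrix,
    p0: pd.Series | None = None,
    tolerance: float = 1e-6,
    max_iter: int = 10_000,
) -> ActivityScores:
    """Iterate the exponential-ranking update to a fixed point.

    ``p0`` defaults to uniform; when given it must be positive and is
    normalized to sum 1.  After every step ||p||_1 = 1.  Stops when the
    l2 norm of the change drops below ``tolerance`` (converged) or at
    ``max_iter``.
    """
    mat = A.A.to_numpy(dtype=float)
    n = mat.shape[0]
    if p0 is None:
        p = np.full(n, 1.0 / n)
    else:
        p = p0.reindex(A.A.index).to_numpy(dtype=float)
        if (p <= 0).any():
            raise ValueError("initial scores must be positive")
        p = p / p.sum()
    At = mat.T / A.mu
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = At @ p
        z -= z.max()  # stabilized exp; cancels in the normalization
        q = np.exp(z)
        q /= q.sum()
        if np.linalg.norm(q - p) < tolerance:
            p = q
            converged = True
            break
        p = q
    scores = pd.Series(p, index=A.A.index)
    return ActivityScores(
        p=scores, iterations=it, converged=converged, transformed=transform_scores(scores)
    )


def transform_scores(p: pd.Series) -> pd.Series:
    """Signed log transform: ln p for p > 0, -ln|p| for p < 0, 0 stays 0.

    The sign is preserved so inhibition-dominated (negative) score
    variants remain interpretable.
    """
    vals = p.to_numpy(dtype=float)
    out = np.zeros_like(vals)
    pos, neg = vals > 0, vals < 0
    out[pos] = np.log(vals[pos])
    out[neg] = -np.log(np.abs(vals[neg]))
    if (vals == 0).any():
        warnings.warn("zero scores transformed to 0")
    return pd.Series(out, index=p.index)


def activity_delta(baseline: ActivityScores, perturbed: ActivityScores) -> pd.Series:
    """Per-protein change in transformed activity, perturbed - baseline."""
    if not baseline.p.index.equals(perturbed.p.index):
        raise ValueError("baseline and perturbed cover different protein universes")
    return perturbed.transformed - baseline.transformed
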