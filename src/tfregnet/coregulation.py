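"""TF-TF co-regulation from robust correlation of regulatory profiles.

Two TFs that partner on the same targets tend to receive correlated F
values across those targets, because each gene is fitted independently.
Correlation is computed on log2 F (activation/repression symmetric
around 0) after dropping targets that neither TF regulates, with
RANSAC-based outlier rejection so a handful of extreme F values cannot
dominate.  Pairs with 3 or fewer usable shared targets score exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression, RANSACRegressor

from .containers import FValueMatrix

__all__ = [
    "CorrelationMatrix",
    "InteractionReference",
    "ransac_correlation",
    "all_pairs_coregulation",
    "interaction_enrichment",
    "interaction_pr_auc",
]

#: |log2 F| above which an edge counts as "regulated" (zero-inflation filter)
REGULATION_THRESHOLD = 0.1


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame  # symmetric TF x TF, 0 where undefined
    n_shared: pd.DataFrame  # counts of shared regulated targets

    def defined_pairs(self):
        """Unordered TF pairs with more than 3 shared regulated targets."""
        tfs = list(self.r.index)
        return [
            (a, b) for a, b in combinations(tfs, 2) if self.n_shared.loc[a, b] > 3
        ]


@dataclass
class InteractionReference:
    pairs: set  # unordered pairs as frozensets

    def __post_init__(self) -> None:
        self.pairs = {frozenset(p) for p in self.pairs}
        if any(len(p) != 2 for p in self.pairs):
            raise ValueError("self-pairs are not allowed in the reference")

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def ransac_correlation(
    f_a: pd.Series,
    f_b: pd.Series,
    min_inlier_fraction: float = 0.8,
    seed: int = 0,
    regulation_threshold: float = REGULATION_THRESHOLD,
    prefiltered: bool = False,
) -> float:
    """Robust Pearson correlation of two log2 F profiles.

    ``f_a`` and ``f_b`` are log2 F values indexed by target gene.
    Targets not regulated by both TFs (|log2 F| <= threshold) are
    dropped; RANSAC (seeded, consensus sets of ``min_inlier_fraction``
    of the points, residual threshold = MAD of the initial
    least-squares residuals) flags outliers.  At most a
    ``1 - min_inlier_fraction`` fraction of points may be discarded:
    when the consensus set is smaller than that floor it is expanded to
    the best-fitting points, which keeps the statistic calibrated on
    unrelated profiles.  The Pearson r of the inliers is returned when
    more than 3 remain, otherwise 0.
    """
    shared = f_a.index.intersection(f_b.index)
    a = f_a.loc[shared].to_numpy(dtype=float)
    b = f_b.loc[shared].to_numpy(dtype=float)
    if not prefiltered:
        mask = (np.abs(a) > regulation_threshold) & (np.abs(b) > regulation_threshold)
        a, b = a[mask], b[mask]
    n = len(a)
    if n <= 3:
        return 0.0
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    X = a.reshape(-1, 1)
    init = LinearRegression().fit(X, b)
    resid = b - init.predict(X)
    mad = float(np.median(np.abs(resid - np.median(resid))))
    if mad == 0:
        mad = max(1e-12, float(np.abs(resid).max()))
    k = max(2, ceil(min_inlier_fraction * n))
    try:
        ransac = RANSACRegressor(
            estimator=LinearRegression(),
            min_samples=k,
            residual_threshold=mad,
            random_state=seed,
            max_trials=200,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny held-out sets in trial scoring
            ransac.fit(X, b)
        inliers = ransac.inlier_mask_
        abs_resid = np.abs(b - ransac.estimator_.predict(X))
    except ValueError:  # no consensus set found
        inliers = np.ones(n, dtype=bool)
        abs_resid = np.abs(resid)
    if inliers.sum() < k:  # never discard more than the allowed fraction
        inliers = np.zeros(n, dtype=bool)
        inliers[np.argsort(abs_resid, kind="stable")[:k]] = True
    if inliers.sum() <= 3:
        return 0.0
    ai, bi = a[inliers], b[inliers]
    if np.ptp(ai) == 0 or np.ptp(bi) == 0:
        return 0.0
    return float(stats.pearsonr(ai, bi)[0])


def _profile(fvals: FValueMatrix, tf: str) -> pd.Series:
    mask = fvals.f.index.get_level_values(0) == tf
    sub = fvals.f[mask]
    return pd.Series(np.log2(sub.values), index=sub.index.get_level_values(1))


def all_pairs_coregulation(
    fvals: FValueMatrix,
    min_inlier_fraction: float = 0.8,
    seed: int = 0,
    regulation_threshold: float = REGULATION_THRESHOLD,
) -> CorrelationMatrix:
    """Robust correlation of every unordered pair of TF regulatory profiles."""
    tfs = fvals.tfs
    if len(tfs) < 2:
        raise ValueError("need at least 2 TFs")
    profiles = {tf: _profile(fvals, tf) for tf in tfs}
    regulated = {tf: p[np.abs(p) > regulation_threshold] for tf, p in profiles.items()}
    r = pd.DataFrame(0.0, index=tfs, columns=tfs)
    n_shared = pd.DataFrame(0, index=tfs, columns=tfs, dtype=int)
    for tf in tfs:
        n = len(regulated[tf])
        n_shared.loc[tf, tf] = n
        r.loc[tf, tf] = 1.0 if n > 3 else 0.0
    for a, b in combinations(tfs, 2):
        shared = regulated[a].index.intersection(regulated[b].index)
        n_shared.loc[a, b] = n_shared.loc[b, a] = len(shared)
        val = ransac_correlation(
            regulated[a].loc[shared],
            regulated[b].loc[shared],
            min_inlier_fraction=min_inlier_fraction,
            seed=seed,
            prefiltered=True,
        )
        r.loc[a, b] = r.loc[b, a] = val
    return CorrelationMatrix(r=r, n_shared=n_shared)


def interaction_enrichment(
    corr: CorrelationMatrix, reference: InteractionReference, top_fraction: float = 0.01
):
    """Fisher's exact enrichment of reference interactions in the top |r| pairs.

    Builds the 2x2 table (top vs rest) x (in reference vs not) over the
    defined pairs (n_shared > 3) and returns (odds_ratio, p, table).
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    if len(reference) == 0:
        raise ValueError("reference is empty")
    pairs = corr.defined_pairs()
    if not pairs:
        raise ValueError("no defined pairs to test")
    scores = np.array([abs(corr.r.loc[a, b]) for a, b in pairs])
    k = max(1, ceil(top_fraction * len(pairs)))
    cutoff = np.sort(scores)[::-1][k - 1]
    in_top = scores >= cutoff
    in_ref = np.array([(a, b) in reference for a, b in pairs])
    table = np.array(
        [
            [int((in_top & in_ref).sum()), int((in_top & ~in_ref).sum())],
            [int((~in_top & in_ref).sum()), int((~in_top & ~in_ref).sum())],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table


def interaction_pr_auc(corr: CorrelationMatrix, reference: InteractionReference) -> float:
    """Precision-recall AUC for recovering reference pairs ranked by |r|.

    Trapezoidal integration over the precision-recall points at every
    unique |r| threshold (descending).
    """
    pairs = [(a, b) for a, b in combinations(list(corr.r.index), 2)]
    scores = np.array([abs(corr.r.loc[a, b]) for a, b in pairs])
    labels = np.array([(a, b) in reference for a, b in pairs], dtype=bool)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("no positive pairs scored")
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    recalls, precisions = [0.0], [1.0]
    tp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:
            j += 1
        tp += int(labels[i:j].sum())
        recalls.append(tp / n_pos)
        precisions.append(tp / j if j else 1.0)
        i = j
    return float(np.trapezoid(precisions, recalls))
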