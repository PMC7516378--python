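"""Cohort utilities: nearest-centroid subtype assignment and linear
batch-effect removal, so external cohorts and cell lines can be pushed
through models fitted on a reference cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = ["Centroids", "nearest_centroid_classify", "remove_batch_effects", "standardize"]


@dataclass
class Centroids:
    """Reference expression centroids: one gene-indexed column per subtype."""

    centers: pd.DataFrame  # signature genes x subtypes

    def __post_init__(self) -> None:
        if self.centers.shape[1] < 2:
            raise ValueError("need at least 2 subtype centroids")

    @property
    def signature_genes(self) -> pd.Index:
        return self.centers.index

    @property
    def subtypes(self) -> list[str]:
        return list(self.centers.columns)


def nearest_centroid_classify(expr: ExpressionMatrix, centroids: Centroids) -> pd.Series:
    """Assign each sample the subtype whose centroid it correlates with best.

    Correlation is Pearson over the signature genes present in ``expr``
    (at least 50% coverage required).  Ties break to the
    lexicographically first subtype with a warning.
    """
    present = [g for g in centroids.signature_genes if g in expr.values.index]
    coverage = len(present) / len(centroids.signature_genes)
    if coverage < 0.5:
        missing = [g for g in centroids.signature_genes if g not in expr.values.index]
        raise ValueError(
            f"only {coverage:.0%} of signature genes present; missing e.g. {missing[:10]}"
        )
    sub = expr.values.loc[present].to_numpy(dtype=float)
    cen = centroids.centers.loc[present].to_numpy(dtype=float)
    # center per column to turn dot products into Pearson correlations
    sub_c = sub - sub.mean(axis=0)
    cen_c = cen - cen.mean(axis=0)
    sub_n = sub_c / np.where(np.linalg.norm(sub_c, axis=0) == 0, 1, np.linalg.norm(sub_c, axis=0))
    cen_n = cen_c / np.where(np.linalg.norm(cen_c, axis=0) == 0, 1, np.linalg.norm(cen_c, axis=0))
    corr = sub_n.T @ cen_n  # samples x subtypes
    labels = {}
    subtypes = sorted(centroids.subtypes)
    order = [centroids.subtypes.index(s) for s in subtypes]
    for i, sample in enumerate(expr.values.columns):
        row = corr[i, order]
        best = row.max()
        winners = [subtypes[j] for j in range(len(subtypes)) if row[j] == best]
        if len(winners) > 1:
            warnings.warn(f"sample {sample}: centroid correlation tie {winners}, taking {winners[0]}")
        labels[sample] = winners[0]
    return pd.Series(labels, name="subtype")


def remove_batch_effects(expr: ExpressionMatrix, batch: pd.Series | None = None) -> ExpressionMatrix:
    """Location-only batch correction in log2 space.

    Per gene, least squares reduces to subtracting each batch's mean
    offset from the grand mean, so batch means coincide afterwards and
    the per-gene grand mean is preserved.  Values are back-transformed
    to linear scale.
    """
    if batch is None:
        batch = expr.batch
    if batch is None:
        raise ValueError("no batch tags supplied")
    batch = batch.reindex(expr.values.columns)
    counts = batch.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 batches")
    if (counts < 2).any():
        raise ValueError(f"singleton batches not allowed: {list(counts[counts < 2].index)}")
    log = np.log2(expr.values.to_numpy(dtype=float) + 1e-300)
    grand = log.mean(axis=1, keepdims=True)
    corrected = log.copy()
    total_shift = np.zeros_like(grand)
    for tag in counts.index:
        cols = np.flatnonzero((batch == tag).to_numpy())
        offset = log[:, cols].mean(axis=1, keepdims=True) - grand
        corrected[:, cols] -= offset
        total_shift += offset * len(cols)
    # re-center so the per-gene grand mean is bit-stably preserved
    corrected += (grand - corrected.mean(axis=1, keepdims=True))
    out = pd.DataFrame(2.0**corrected, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(out, sample_labels=expr.sample_labels, batch=batch)


def standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scores (mean 0, SD 1 across samples); constant genes dropped.

    Output lives in classification/embedding space only — it is not a
    valid input to the thermodynamic regression, which needs
    nonnegative linear-scale values.
    """
    vals = expr.values.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=0)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} constant gene(s)")
    z = (vals[keep] - vals[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    out = pd.DataFrame(z, index=expr.values.index[keep], columns=expr.values.columns)
    em = ExpressionMatrix.__new__(ExpressionMatrix)  # bypass nonnegativity check
    em.values = out
    em.sample_labels = expr.sample_labels
    em.batch = expr.batch
    return em
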