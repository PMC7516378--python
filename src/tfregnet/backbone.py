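"""Candidate TF -> gene backbone assembly.

Builds the unsigned regulatory backbone from motif binding-score tables
(thresholded per cell line), closest-gene assignment of motif hits to
TSSs, union with tissue regulatory networks, and filtering to genes
with expression data.

Coordinates follow the BED dialect: 0-based, half-open intervals; a
motif is summarized by its integer midpoint floor((start + end) / 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .containers import CandidateNetwork, ExpressionMatrix

__all__ = [
    "BindingScoreTable",
    "GeneAnnotation",
    "threshold_binding_scores",
    "assign_motifs_to_genes",
    "union_networks",
    "filter_by_expression",
    "threshold_tissue_network",
]


@dataclass
class BindingScoreTable:
    """Motif occurrence intervals with binding likelihood scores.

    ``records`` columns: tf, chrom, start, end, score (BED-like,
    0-based half-open).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"tf", "chrom", "start", "end", "score"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"binding table needs columns {sorted(required)}")
        if len(self.records) and (self.records["start"] >= self.records["end"]).any():
            raise ValueError("intervals must satisfy start < end")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneAnnotation:
    """One strand-resolved TSS per gene: columns gene, chrom, tss, strand."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "chrom", "tss", "strand"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        if self.records["gene"].duplicated().any():
            raise ValueError("one TSS per gene required")


def threshold_binding_scores(table: BindingScoreTable, top_fraction: float) -> BindingScoreTable:
    """Keep records in the top ``top_fraction`` of scores (ties at the cutoff kept).

    The cutoff is the k-th largest score with k = ceil(top_fraction * n),
    i.e. the (1 - top_fraction) quantile; all records scoring >= it are
    retained, so ties never split.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    if len(table) == 0:
        return BindingScoreTable(table.records.copy())
    scores = table.records["score"].to_numpy(dtype=float)
    k = ceil(top_fraction * len(scores))
    cutoff = np.sort(scores)[::-1][k - 1]
    return BindingScoreTable(table.records[table.records["score"] >= cutoff].reset_index(drop=True))


def assign_motifs_to_genes(
    table: BindingScoreTable, genes: GeneAnnotation, window_bp: int = 10_000
) -> CandidateNetwork:
    """Map each motif hit to its closest TSS(s) within +/- ``window_bp``.

    Distance is |motif midpoint - TSS| on the same chromosome; exact
    ties go to every tied gene.  Records on chromosomes absent from the
    annotation are skipped with a warning.  Strand does not enter the
    distance (the window is symmetric around the TSS).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    by_chrom = {c: grp.reset_index(drop=True) for c, grp in genes.records.groupby("chrom")}
    edges: set[tuple[str, str]] = set()
    provenance: dict = {}
    skipped_chroms = set()
    for rec in table.records.itertuples(index=False):
        grp = by_chrom.get(rec.chrom)
        if grp is None:
            skipped_chroms.add(rec.chrom)
            continue
        mid = (int(rec.start) + int(rec.end)) // 2
        dist = np.abs(grp["tss"].to_numpy(dtype=int) - mid)
        in_window = dist <= window_bp
        if not in_window.any():
            continue
        best = dist[in_window].min()
        for gene in grp["gene"].to_numpy()[in_window & (dist == best)]:
            edge = (rec.tf, gene)
            edges.add(edge)
            provenance.setdefault(edge, ("binding",))
    if skipped_chroms:
        warnings.warn(f"chromosomes absent from annotation, records skipped: {sorted(skipped_chroms)}")
    return CandidateNetwork(edges=edges, provenance=provenance)


def union_networks(nets: list[CandidateNetwork]) -> CandidateNetwork:
    """Union of candidate edge sets; provenance tags are concatenated."""
    if not nets:
        raise ValueError("need at least one network")
    edges: set = set()
    provenance: dict = {}
    for net in nets:
        edges |= net.edges
        for e in net.edges:
            provenance[e] = provenance.get(e, ()) + net.provenance.get(e, ())
    return CandidateNetwork(edges=edges, provenance=provenance)


def filter_by_expression(net: CandidateNetwork, expr: ExpressionMatrix) -> CandidateNetwork:
    """Keep edges whose TF and target both have expression rows."""
    present = set(expr.values.index)
    edges = {(tf, g) for tf, g in net.edges if tf in present and g in present}
    return CandidateNetwork(edges=edges, provenance={e: net.provenance.get(e, ()) for e in edges})


def threshold_tissue_network(
    edges: pd.DataFrame, top_fraction: float = 0.10, tag: str = "tissue"
) -> CandidateNetwork:
    """Top-weight filter of a (tf, target, weight) tissue network.

    The cutoff is the per-network weight quantile analogue of
    :func:`threshold_binding_scores` (ties at the cutoff kept).
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    if not {"tf", "target", "weight"}.issubset(edges.columns):
        raise ValueError("tissue network needs columns tf, target, weight")
    if len(edges) == 0:
        return CandidateNetwork(edges=set())
    w = edges["weight"].to_numpy(dtype=float)
    k = ceil(top_fraction * len(w))
    cutoff = np.sort(w)[::-1][k - 1]
    kept = edges[edges["weight"] >= cutoff]
    e = {(tf, tg) for tf, tg in zip(kept["tf"], kept["target"])}
    return CandidateNetwork(edges=e, provenance={edge: (tag,) for edge in e})
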