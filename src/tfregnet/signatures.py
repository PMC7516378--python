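"""Subtype-specific ("repurposed") regulatory signatures.

A TF-target edge is signature for a subtype when its fitted log2 F
deviates from a label-permutation null by at least ``sd_threshold``
standard deviations.  The null is built by shuffling subtype labels
(preserving group sizes) and refitting; a TF whose majority of
signature targets is unique to one subtype becomes that subtype's
signature TF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CandidateNetwork, ExpressionMatrix, FValueMatrix
from .model import FitConfig, fit_subtype_model

__all__ = [
    "PermutationNull",
    "SignatureAssignment",
    "permute_and_refit",
    "call_signature_edges",
    "build_assignment",
    "participation_scores",
    "differential_regulation_enrichment",
    "tf_target_correlation_shift",
]

#: floor added to a degenerate null SD before division
SD_FLOOR = 1e-6


@dataclass
class PermutationNull:
    mean: pd.DataFrame  # edge (tf, gene) MultiIndex x subtype: null mean of log2 F
    sd: pd.DataFrame  # same shape: null SD (ddof=1)
    n_shuffles: int

    def __post_init__(self) -> None:
        if self.n_shuffles < 2:
            raise ValueError("need at least 2 shuffles")
        if (self.sd.values < 0).any():
            raise ValueError("null SD must be nonnegative")


@dataclass
class SignatureAssignment:
    signature_edges: set  # {(tf, gene, subtype)}
    signature_tf_of: dict = field(default_factory=dict)  # tf -> subtype
    z: pd.DataFrame | None = None


def permute_and_refit(
    backbone: CandidateNetwork,
    expr: ExpressionMatrix,
    n_shuffles: int = 30,
    seed: int = 0,
    config: FitConfig | None = None,
) -> PermutationNull:
    """Label-permutation null of per-edge, per-subtype log2 F.

    Each shuffle permutes subtype labels across samples (group sizes
    preserved by construction), refits every subtype model, and records
    log2 F per edge; the per-edge mean and SD across shuffles form the
    null.  Shuffles whose fit fails are dropped with a warning.
    """
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    if expr.sample_labels is None:
        raise ValueError("expression must carry subtype labels")
    config = config or FitConfig()
    rng = np.random.default_rng(seed)
    subtypes = sorted(expr.sample_labels.unique())
    labels = expr.sample_labels.to_numpy()
    samples = list(expr.values.columns)

    collected: dict[str, list[pd.Series]] = {s: [] for s in subtypes}
    kept = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(labels)
        shuffled = ExpressionMatrix(expr.values, sample_labels=pd.Series(perm, index=samples))
        try:
            fits = {
                s: fit_subtype_model(backbone, shuffled, s, config).fvals.log2_f for s in subtypes
            }
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"shuffle dropped after fit failure: {exc}")
            continue
        for s in subtypes:
            collected[s].append(fits[s])
        kept += 1
    if kept < 2:
        raise RuntimeError("fewer than 2 successful shuffles")

    edge_index = collected[subtypes[0]][0].index
    mean = pd.DataFrame(index=edge_index, columns=subtypes, dtype=float)
    sd = pd.DataFrame(index=edge_index, columns=subtypes, dtype=float)
    for s in subtypes:
        stack = np.vstack([ser.reindex(edge_index).to_numpy() for ser in collected[s]])
        mean[s] = stack.mean(axis=0)
        sd[s] = stack.std(axis=0, ddof=1)
    return PermutationNull(mean=mean, sd=sd, n_shuffles=kept)


def call_signature_edges(
    fvals_by_subtype: dict[str, FValueMatrix],
    null: PermutationNull,
    sd_threshold: float = 5.0,
) -> SignatureAssignment:
    """Flag edges whose unshuffled log2 F deviates >= ``sd_threshold`` null SDs.

    Deviation is measured on log2 F.  A null SD below ``SD_FLOOR`` is
    floored before division; edges whose null SD is exactly 0 are never
    flagged (no variation under permutation means no calibrated scale).
    """
    edges: set = set()
    z_rows = {}
    for s, fvals in sorted(fvals_by_subtype.items()):
        log2f = fvals.log2_f.reindex(null.mean.index)
        dev = (log2f - null.mean[s]).abs()
        sd = null.sd[s]
        z = dev / np.maximum(sd, SD_FLOOR)
        z_rows[s] = z
        flagged = (z >= sd_threshold) & (sd > 0)
        for tf, gene in null.mean.index[flagged.to_numpy(dtype=bool)]:
            edges.add((tf, gene, s))
    z_table = pd.DataFrame(z_rows)
    return build_assignment(edges, z=z_table)


def build_assignment(signature_edges: set, z: pd.DataFrame | None = None) -> SignatureAssignment:
    """Assign each TF its signature subtype by the majority rule.

    A TF's signature subtype is the arg-max of its participation row
    (fraction of signature targets unique to that subtype) and must
    exceed 0.5; ties or no majority leave the TF unassigned.
    """
    assignment = SignatureAssignment(signature_edges=set(signature_edges), z=z)
    part = participation_scores(assignment)
    for tf in part.index:
        row = part.loc[tf]
        best = row.max()
        winners = list(row.index[row == best])
        if best > 0.5 and len(winners) == 1:
            assignment.signature_tf_of[tf] = winners[0]
    return assignment


def participation_scores(assignment: SignatureAssignment) -> pd.DataFrame:
    """Per-TF fraction of signature targets unique to each subtype.

    Entry (tf, s) = #targets whose signature subtype set is exactly {s}
    divided by #targets with any signature edge for that TF.  Rows sum
    to 1 when every edge is single-subtype and to < 1 otherwise
    (multi-subtype targets enter only the denominator).
    """
    if not assignment.signature_edges:
        return pd.DataFrame(dtype=float)
    subtypes = sorted({s for _, _, s in assignment.signature_edges})
    by_tf: dict[str, dict[str, set]] = {}
    for tf, gene, s in assignment.signature_edges:
        by_tf.setdefault(tf, {}).setdefault(gene, set()).add(s)
    rows = {}
    for tf, genes in sorted(by_tf.items()):
        total = len(genes)
        counts = {s: 0 for s in subtypes}
        for subs in genes.values():
            if len(subs) == 1:
                counts[next(iter(subs))] += 1
        rows[tf] = {s: counts[s] / total for s in subtypes}
    return pd.DataFrame.from_dict(rows, orient="index")[subtypes]


def hypergeom_upper_p(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric p: P(X >= k) for X ~ HG(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def differential_regulation_enrichment(
    assignment: SignatureAssignment,
    expression_signature_genes: dict[str, set],
    universe: set,
) -> pd.DataFrame:
    """Hypergeometric enrichment of differentially regulated genes in
    each subtype's expression signature.

    For subtype s let D = genes with >= 1 signature edge in s and S =
    that subtype's expression-signature genes; the upper-tail p is
    P(X >= |D & S|) for X hypergeometric(|universe|, |S|, |D|).
    Returns a table with columns overlap, expected, fold, p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    rows = {}
    for s, sig_genes in sorted(expression_signature_genes.items()):
        sig_genes = set(sig_genes) & universe
        if not set(sig_genes).issubset(universe):
            raise ValueError("signature genes must be contained in the universe")
        diff_reg = {g for _, g, sub in assignment.signature_edges if sub == s} & universe
        k = len(diff_reg & sig_genes)
        N, K, n = len(universe), len(sig_genes), len(diff_reg)
        expected = K * n / N if N else 0.0
        p = hypergeom_upper_p(k, N, K, n) if n and K else 1.0
        rows[s] = {
            "overlap": k,
            "expected": expected,
            "fold": (k / expected) if expected > 0 else float("nan"),
            "p": p,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def tf_target_correlation_shift(
    expr: ExpressionMatrix,
    backbone: CandidateNetwork,
    differentially_regulated: set,
):
    """Compare TF-target expression correlation between gene groups.

    Per target gene, the mean Pearson r between its expression and each
    of its regulator TFs' expression; the distribution over
    differentially regulated genes is compared with the remaining
    regulated genes by a two-sided Mann-Whitney test.

    Returns (r_diff, r_rest, p).
    """
    vals = expr.values
    present_tfs = backbone.tfs & set(vals.index)
    gene_regs: dict[str, list[str]] = {}
    for tf, g in backbone.edges:
        if tf in present_tfs and g in vals.index:
            gene_regs.setdefault(g, []).append(tf)
    mean_r = {}
    for g, regs in gene_regs.items():
        y = vals.loc[g].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            continue
        rs = []
        for tf in sorted(regs):
            x = vals.loc[tf].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                continue
            rs.append(stats.pearsonr(x, y)[0])
        if rs:
            mean_r[g] = float(np.mean(rs))
    diff = np.array([v for g, v in mean_r.items() if g in differentially_regulated])
    rest = np.array([v for g, v in mean_r.items() if g not in differentially_regulated])
    if len(diff) == 0 or len(rest) == 0:
        raise ValueError("both gene groups must be non-empty")
    p = float(stats.mannwhitneyu(diff, rest, alternative="two-sided").pvalue)
    return diff, rest, p
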