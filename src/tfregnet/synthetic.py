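"""Synthetic regulatory systems and cohorts.

Generates ground-truth regulatory capacities, subtype-structured
expression via the forward thermodynamic model, small signed protein
networks, and essentiality scores that are sparse linear functions of
protein-activity changes.  Every generator is deterministic under its
seed, so downstream inference stages can be benchmarked against known
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FValueMatrix, SignedProteinNetwork
from .model import predict_expression

__all__ = [
    "GroundTruth",
    "SyntheticCohort",
    "generate_regulatory_truth",
    "simulate_expression",
    "sample_tf_expression",
    "simulate_cohort",
    "generate_signed_protein_network",
    "simulate_essentiality",
]

# log2 F for active edges: uniform on +/-[0.1, 2.5]; identifiable but not extreme
_F_LOG2_MIN, _F_LOG2_MAX = 0.1, 2.5
# |log2 F| range of a signature edge's subtype-unique value; a repurposed
# edge switches regulatory mode (activation <-> repression), so the unique
# value flips the sign of the shared value with a clearly active magnitude
_SIGNATURE_MAG_MIN, _SIGNATURE_MAG_MAX = 1.0, 2.5


@dataclass
class GroundTruth:
    """True regulatory system underlying a synthetic cohort."""

    backbone: set  # {(tf, gene)}
    f_true: dict  # (tf, gene, subtype) -> F > 0
    basal: dict  # gene -> x0 > 0
    subtypes: list
    noise_sd: float
    seed: int
    signature_edges: set = field(default_factory=set)  # {(tf, gene, subtype)}
    subtype_of: dict = field(default_factory=dict)  # sample -> subtype (filled on simulate)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.f_true.values()):
            raise ValueError("true F values must be positive")
        if any(v <= 0 for v in self.basal.values()):
            raise ValueError("basal levels must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        edges = {(tf, g) for tf, g, _ in self.f_true}
        if not edges.issubset(self.backbone):
            raise ValueError("every f_true key must be a backbone edge")

    @property
    def tfs(self) -> list:
        return sorted({tf for tf, _ in self.backbone})

    @property
    def genes(self) -> list:
        return sorted({g for _, g in self.backbone} | set(self.basal))

    def fvalues(self, subtype: str) -> FValueMatrix:
        """True parameters of one subtype packaged for the forward model."""
        idx, vals = [], []
        for tf, g in sorted(self.backbone):
            idx.append((tf, g))
            vals.append(self.f_true[(tf, g, subtype)])
        return FValueMatrix(
            f=pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["tf", "gene"]), dtype=float),
            basal=pd.Series(self.basal, dtype=float).sort_index(),
            subtype=subtype,
        )


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    truth: GroundTruth
    protein_net: Optional[SignedProteinNetwork] = None
    essentiality: Optional[dict] = None


def _draw_active_log2f(rng: np.random.Generator, size: int) -> np.ndarray:
    """Symmetric around 0, |log2 F| in [0.1, 2.5]."""
    mag = rng.uniform(_F_LOG2_MIN, _F_LOG2_MAX, size=size)
    sign = rng.choice([-1.0, 1.0], size=size)
    return mag * sign


def generate_regulatory_truth(
    n_tfs: int,
    n_genes: int,
    subtypes,
    edge_density: float = 0.3,
    frac_signature_edges: float = 0.2,
    seed: int = 0,
    noise_sd: float = 0.1,
) -> GroundTruth:
    """Draw a bipartite TF -> gene backbone with subtype-structured F values.

    A ``frac_signature_edges`` fraction of edges is "repurposed": its F
    differs in exactly one (randomly chosen) subtype, where it switches
    regulatory mode — the subtype-unique log2 F flips the sign of the
    shared value with magnitude in [1, 2.5].  All remaining edges share
    one F across subtypes.
    """
    if not (0 < edge_density <= 1):
        raise ValueError("edge_density must be in (0, 1]")
    if not (0 <= frac_signature_edges <= 1):
        raise ValueError("frac_signature_edges must be in [0, 1]")
    if n_tfs < 1 or n_genes < 1:
        raise ValueError("need at least one TF and one gene")
    subtypes = list(subtypes)
    if not subtypes:
        raise ValueError("need at least one subtype")

    rng = np.random.default_rng(seed)
    tfs = [f"tf{i:03d}" for i in range(n_tfs)]
    genes = [f"g{i:04d}" for i in range(n_genes)]
    all_pairs = [(tf, g) for tf in tfs for g in genes]
    if edge_density == 1.0:
        backbone = list(all_pairs)
    else:
        keep = rng.random(len(all_pairs)) < edge_density
        backbone = [p for p, k in zip(all_pairs, keep) if k]
        if not backbone:  # ensure a non-empty system at tiny sizes
            backbone = [all_pairs[rng.integers(len(all_pairs))]]

    base_log2f = _draw_active_log2f(rng, len(backbone))
    n_sig = int(round(frac_signature_edges * len(backbone)))
    sig_positions = rng.choice(len(backbone), size=n_sig, replace=False) if n_sig else []

    f_true: dict = {}
    signature_edges: set = set()
    sig_set = set(np.atleast_1d(sig_positions).tolist()) if n_sig else set()
    for i, (tf, g) in enumerate(backbone):
        shared = base_log2f[i]
        if i in sig_set and len(subtypes) > 1:
            s_unique = subtypes[rng.integers(len(subtypes))]
            unique = -np.sign(shared) * rng.uniform(_SIGNATURE_MAG_MIN, _SIGNATURE_MAG_MAX)
            signature_edges.add((tf, g, s_unique))
            for s in subtypes:
                f_true[(tf, g, s)] = 2.0 ** (unique if s == s_unique else shared)
        else:
            for s in subtypes:
                f_true[(tf, g, s)] = 2.0**shared

    basal = {g: 2.0 ** rng.normal(3.0, 1.0) for g in genes}
    return GroundTruth(
        backbone=set(backbone),
        f_true=f_true,
        basal=basal,
        subtypes=subtypes,
        noise_sd=noise_sd,
        seed=seed,
        signature_edges=signature_edges,
    )


def sample_tf_expression(truth: GroundTruth, samples, seed: int = 0) -> pd.DataFrame:
    """I.i.d. lognormal TF expression (log2 mean 0, sd 1); TFs are exogenous."""
    rng = np.random.default_rng(seed)
    vals = 2.0 ** rng.normal(0.0, 1.0, size=(len(truth.tfs), len(samples)))
    return pd.DataFrame(vals, index=truth.tfs, columns=list(samples))


def simulate_expression(
    truth: GroundTruth,
    tf_expression: pd.DataFrame,
    samples_per_subtype: int,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Forward-simulate target expression from the true parameters.

    ``tf_expression`` must be TF x sample with columns ordered as
    subtype blocks of ``samples_per_subtype`` samples each (use
    :func:`simulate_cohort` to build everything in one call).  Noise is
    additive Gaussian in log2 space with SD ``truth.noise_sd``.
    """
    if (tf_expression.values < 0).any():
        raise ValueError("TF expression must be nonnegative")
    n_expected = samples_per_subtype * len(truth.subtypes)
    if tf_expression.shape[1] != n_expected:
        raise ValueError(f"expected {n_expected} sample columns, got {tf_expression.shape[1]}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    blocks = []
    col = 0
    for s in truth.subtypes:
        cols = tf_expression.columns[col : col + samples_per_subtype]
        col += samples_per_subtype
        pred = predict_expression(truth.fvalues(s), tf_expression[cols])
        if truth.noise_sd > 0:
            noise = rng.normal(0.0, truth.noise_sd, size=pred.shape)
            pred = pred * 2.0**noise
        blocks.append(pred)
        for c in cols:
            truth.subtype_of[c] = s
    target = pd.concat(blocks, axis=1)
    full = pd.concat([tf_expression.loc[[t for t in truth.tfs if t not in target.index]], target])
    labels = pd.Series({c: truth.subtype_of[c] for c in full.columns})
    return ExpressionMatrix(full, sample_labels=labels)


def simulate_cohort(
    n_tfs: int = 5,
    n_genes: int = 20,
    subtypes=("A", "B"),
    samples_per_subtype: int = 100,
    edge_density: float = 0.3,
    frac_signature_edges: float = 0.2,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SyntheticCohort:
    """One-call cohort: truth + lognormal TF inputs + forward-simulated targets."""
    truth = generate_regulatory_truth(
        n_tfs, n_genes, list(subtypes), edge_density, frac_signature_edges, seed=seed, noise_sd=noise_sd
    )
    samples = [f"{s}_{i:03d}" for s in truth.subtypes for i in range(samples_per_subtype)]
    tf_expr = sample_tf_expression(truth, samples, seed=seed + 1)
    expr = simulate_expression(truth, tf_expr, samples_per_subtype, seed=seed + 2)
    return SyntheticCohort(expression=expr, truth=truth)


def generate_signed_protein_network(
    n_proteins: int,
    n_edges: int,
    frac_inhibitory: float = 0.3,
    seed: int = 0,
    proteins=None,
) -> SignedProteinNetwork:
    """Random simple directed graph with signed, likelihood-weighted edges."""
    if proteins is not None:
        proteins = list(proteins)
        n_proteins = len(proteins)
    else:
        proteins = [f"p{i:03d}" for i in range(n_proteins)]
    max_edges = n_proteins * (n_proteins - 1)
    if n_edges > max_edges:
        raise ValueError(f"at most {max_edges} directed edges among {n_proteins} proteins")
    if not (0 <= frac_inhibitory <= 1):
        raise ValueError("frac_inhibitory must be in [0, 1]")
    rng = np.random.default_rng(seed)
    all_pairs = [(a, b) for a in proteins for b in proteins if a != b]
    chosen = rng.choice(len(all_pairs), size=n_edges, replace=False)
    rows = []
    for k in chosen:
        src, dst = all_pairs[k]
        sign = -1 if rng.random() < frac_inhibitory else 1
        weight = rng.uniform(np.nextafter(0.0, 1.0), 1.0)
        rows.append((src, dst, sign, weight))
    edges = pd.DataFrame(rows, columns=["src", "dst", "sign", "weight"])
    return SignedProteinNetwork(proteins=proteins, edges=edges)


def simulate_essentiality(
    activity_deltas: dict,
    n_true_predictors: int,
    coef_scale: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Essentiality as a sparse linear readout of protein-activity changes.

    ``activity_deltas`` maps each TF to a (cell_line x protein)
    DataFrame of activity changes under that TF's knockdown.  For each
    TF, ``n_true_predictors`` proteins are chosen as distinct drivers:
    responsive (delta SD across lines at least 5% of the TF's maximum
    column SD — a protein whose activity never changes cannot drive
    differential essentiality) and mutually non-redundant (greedy
    draw rejecting candidates with |Pearson r| > 0.8 to an already
    chosen driver, relaxed only if too few candidates remain).  Each
    driver gets a coefficient of magnitude ``coef_scale`` with random
    sign; the score per line is their linear combination plus
    N(0, noise_sd^2).

    Returns (scores, support): scores maps (tf, cell_line) -> value and
    support maps tf -> {true predictor proteins, coefficient dict}.
    """
    rng = np.random.default_rng(seed)
    scores: dict = {}
    support: dict = {}
    for tf in sorted(activity_deltas):
        deltas = activity_deltas[tf]
        proteins = list(deltas.columns)
        if n_true_predictors > len(proteins):
            raise ValueError("n_true_predictors exceeds the protein count")
        sds = deltas.std(axis=0, ddof=0).to_numpy(dtype=float)
        responsive = np.flatnonzero(sds >= 0.05 * sds.max()) if sds.max() > 0 else np.arange(len(proteins))
        if len(responsive) < n_true_predictors:
            responsive = np.argsort(-sds)[:n_true_predictors]
        chosen: list[int] = []
        X = deltas.to_numpy(dtype=float)

        def safe_corr(i: int, j: int) -> float:
            xi, xj = X[:, i], X[:, j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                return 0.0
            return float(np.corrcoef(xi, xj)[0, 1])

        for cap in (0.8, 0.95, 1.01):  # relax redundancy cap only if needed
            chosen = []
            for i in rng.permutation(responsive):
                if all(abs(safe_corr(int(i), j)) <= cap for j in chosen):
                    chosen.append(int(i))
                if len(chosen) == n_true_predictors:
                    break
            if len(chosen) == n_true_predictors:
                break
        chosen = sorted(chosen)
        coef = {proteins[i]: coef_scale * rng.choice([-1.0, 1.0]) for i in chosen}
        support[tf] = coef
        base = np.zeros(len(deltas.index))
        for p, c in coef.items():
            base = base + c * deltas[p].to_numpy(dtype=float)
        if noise_sd > 0:
            base = base + rng.normal(0.0, noise_sd, size=len(base))
        for line, val in zip(deltas.index, base):
            scores[(tf, line)] = float(val)
    return scores, support
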