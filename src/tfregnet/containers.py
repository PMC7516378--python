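"""Core in-memory containers shared across the pipeline.

All containers are thin dataclasses around pandas/numpy objects so that
every stage (backbone assembly, regression, perturbation, ranking,
essentiality) exchanges the same validated structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CandidateNetwork",
    "FValueMatrix",
    "SignedProteinNetwork",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample expression on a nonnegative linear scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with one column per sample.
        Values must be nonnegative and on a linear (not log) scale,
        e.g. ``2**RMA`` intensities or linear TPM.
    sample_labels
        Optional per-sample subtype label (index = sample IDs).
    batch
        Optional per-sample batch tag.
    """

    values: pd.DataFrame
    sample_labels: Optional[pd.Series] = None
    batch: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        if self.values.index.has_duplicates:
            raise ValueError("gene IDs must be unique")
        if self.sample_labels is not None:
            missing = self.values.columns.difference(self.sample_labels.index)
            if len(missing):
                raise ValueError(f"samples without subtype label: {list(missing)[:5]}")
            self.sample_labels = self.sample_labels.reindex(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, samples) -> "ExpressionMatrix":
        labels = self.sample_labels.loc[samples] if self.sample_labels is not None else None
        batch = self.batch.loc[samples] if self.batch is not None else None
        return ExpressionMatrix(self.values[list(samples)], labels, batch)

    def samples_of(self, subtype: str) -> list[str]:
        if self.sample_labels is None:
            raise ValueError("no subtype labels attached")
        return list(self.sample_labels.index[self.sample_labels == subtype])


@dataclass
class CandidateNetwork:
    """Unsigned directed TF -> target candidate edge set (the backbone).

    ``provenance`` maps each edge to the tags of the sources that
    contributed it (e.g. which binding-score table or tissue network).
    """

    edges: set[tuple[str, str]]
    provenance: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = set(self.edges)

    @property
    def tfs(self) -> set[str]:
        return {tf for tf, _ in self.edges}

    @property
    def targets(self) -> set[str]:
        return {g for _, g in self.edges}

    def targets_of(self, tf: str) -> set[str]:
        return {g for t, g in self.edges if t == tf}

    def regulators_of(self, gene: str) -> set[str]:
        return {t for t, g in self.edges if g == gene}

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class FValueMatrix:
    """Fitted regulatory capacities for one subtype.

    ``f`` is a Series of F values (strictly positive) indexed by a
    (tf, gene) MultiIndex over backbone edges; F > 1 means the TF
    activates the target, F < 1 represses, F = 1 no effect.  ``basal``
    holds the per-gene basal expression level x0 (expression in the
    absence of all modeled regulation).
    """

    f: pd.Series
    basal: pd.Series
    subtype: str = ""
    lambda_used: float = 0.0

    def __post_init__(self) -> None:
        if (np.asarray(self.f.values, dtype=float) <= 0).any():
            raise ValueError("F values must be strictly positive")
        if (np.asarray(self.basal.values, dtype=float) <= 0).any():
            raise ValueError("basal levels must be strictly positive")
        if not isinstance(self.f.index, pd.MultiIndex) or self.f.index.nlevels != 2:
            raise ValueError("f must be indexed by a (tf, gene) MultiIndex")

    @property
    def log2_f(self) -> pd.Series:
        return np.log2(self.f)

    @property
    def tfs(self) -> list[str]:
        return sorted(set(self.f.index.get_level_values(0)))

    @property
    def genes(self) -> pd.Index:
        return self.basal.index

    def regulators_of(self, gene: str) -> list[str]:
        mask = self.f.index.get_level_values(1) == gene
        return sorted(self.f.index.get_level_values(0)[mask])

    def edge_f(self, tf: str, gene: str) -> float:
        return float(self.f.loc[(tf, gene)])


@dataclass
class SignedProteinNetwork:
    """Directed protein-protein signaling network with signed, weighted edges.

    ``edges`` has columns [src, dst, sign, weight]; sign is +1
    (activating) or -1 (inhibitory) and weight an interaction
    likelihood in (0, 1].
    """

    proteins: list[str]
    edges: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"src", "dst", "sign", "weight"}
        if not required.issubset(self.edges.columns):
            raise ValueError(f"edge table needs columns {sorted(required)}")
        if not set(self.edges["sign"]).issubset({1, -1}):
            raise ValueError("edge signs must be +1 or -1")
        w = self.edges["weight"].to_numpy(dtype=float)
        if (w <= 0).any() or (w > 1).any():
            raise ValueError("edge weights must lie in (0, 1]")
        pairs = list(zip(self.edges["src"], self.edges["dst"]))
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate edges: graph must be simple")
        known = set(self.proteins)
        if not (set(self.edges["src"]) | set(self.edges["dst"])).issubset(known):
            raise ValueError("edge endpoints must appear in the protein list")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> pd.DataFrame:
        """Signed, weighted adjacency B with B[i, j] = sign*weight for edge i->j."""
        idx = pd.Index(self.proteins)
        B = pd.DataFrame(0.0, index=idx, columns=idx)
        for src, dst, sign, weight in self.edges[["src", "dst", "sign", "weight"]].itertuples(index=False):
            B.loc[src, dst] = sign * weight
        return B
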