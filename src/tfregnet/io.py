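"""Tab-separated readers and writers for every pipeline artifact.

All floats are written with 12 significant digits, which makes
read/write round trips bit-stable at that precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .backbone import BindingScoreTable, GeneAnnotation
from .cohort import Centroids
from .containers import CandidateNetwork, ExpressionMatrix, FValueMatrix, SignedProteinNetwork
from .coregulation import InteractionReference
from .essentiality import EssentialityModel

FLOAT_FMT = "%.12g"


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")
    if expr.sample_labels is not None:
        side = Path(path).with_suffix(".labels.tsv")
        expr.sample_labels.rename("subtype").to_csv(side, sep="\t", index_label="sample")


def read_expression(path, labels_path=None) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    labels = None
    side = Path(labels_path) if labels_path else Path(path).with_suffix(".labels.tsv")
    if side.exists():
        labels = pd.read_csv(side, sep="\t", index_col=0)["subtype"]
    return ExpressionMatrix(values, sample_labels=labels)


def write_fvalues(fvals: FValueMatrix, path) -> None:
    df = pd.DataFrame(
        {
            "tf": fvals.f.index.get_level_values(0),
            "gene": fvals.f.index.get_level_values(1),
            "subtype": fvals.subtype,
            "F": fvals.f.values,
            "log2F": np.log2(fvals.f.values),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    fvals.basal.rename("basal").to_csv(
        Path(path).with_suffix(".basal.tsv"), sep="\t", index_label="gene", float_format=FLOAT_FMT
    )


def read_fvalues(path, basal_path=None) -> FValueMatrix:
    df = pd.read_csv(path, sep="\t")
    basal = pd.read_csv(
        Path(basal_path) if basal_path else Path(path).with_suffix(".basal.tsv"),
        sep="\t",
        index_col=0,
    )["basal"]
    subtype = str(df["subtype"].iloc[0]) if len(df) else ""
    f = pd.Series(
        df["F"].to_numpy(dtype=float),
        index=pd.MultiIndex.from_arrays([df["tf"], df["gene"]], names=["tf", "gene"]),
    )
    lam = float(df["lambda"].iloc[0]) if "lambda" in df.columns and len(df) else 0.0
    return FValueMatrix(f=f, basal=basal, subtype=subtype, lambda_used=lam)


def write_network(net: CandidateNetwork, path) -> None:
    rows = sorted(net.edges)
    df = pd.DataFrame(rows, columns=["tf", "target"])
    df["sources"] = [",".join(net.provenance.get(e, ())) for e in rows]
    df.to_csv(path, sep="\t", index=False)


def read_network(path) -> CandidateNetwork:
    df = pd.read_csv(path, sep="\t")
    edges = set(zip(df["tf"], df["target"]))
    provenance = {}
    if "sources" in df.columns:
        for tf, tg, src in zip(df["tf"], df["target"], df["sources"].fillna("")):
            provenance[(tf, tg)] = tuple(s for s in str(src).split(",") if s)
    return CandidateNetwork(edges=edges, provenance=provenance)


def read_tissue_network(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"tf", "target", "weight"}.issubset(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["tf", "target", "weight"])
    return df


def write_protein_network(net: SignedProteinNetwork, path) -> None:
    net.edges.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_protein_network(path) -> SignedProteinNetwork:
    edges = pd.read_csv(path, sep="\t")
    proteins = sorted(set(edges["src"]) | set(edges["dst"]))
    return SignedProteinNetwork(proteins=proteins, edges=edges)


def read_binding_scores(path) -> BindingScoreTable:
    """BED6-like: chrom, start, end, name (= TF), score[, strand]."""
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, :5]
    df.columns = ["chrom", "start", "end", "tf", "score"]
    return BindingScoreTable(df[["tf", "chrom", "start", "end", "score"]])


def read_gene_annotation(path) -> GeneAnnotation:
    """BED-like: chrom, start, end, gene, score, strand; TSS = strand-aware end."""
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "gene", "score", "strand"]
    tss = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
    return GeneAnnotation(
        pd.DataFrame({"gene": df["gene"], "chrom": df["chrom"], "tss": tss, "strand": df["strand"]})
    )


def read_centroids(path) -> Centroids:
    return Centroids(pd.read_csv(path, sep="\t", index_col=0))


def read_reference_pairs(path) -> InteractionReference:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return InteractionReference({frozenset((a, b)) for a, b in zip(df[0], df[1]) if a != b})


def write_essentiality_model(model: EssentialityModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tf={model.tf}\talpha={model.alpha:.12g}\tl1_ratio={model.l1_ratio:.12g}")
        fh.write(f"\tintercept={model.intercept:.12g}\tcv_rmse={model.cv_rmse:.12g}\n")
        fh.write("protein\tcoefficient\tfeature_mean\tfeature_scale\n")
        for p in model.coefficients.index:
            fh.write(
                f"{p}\t{model.coefficients[p]:.12g}\t{model.feature_mean[p]:.12g}"
                f"\t{model.feature_scale[p]:.12g}\n"
            )


def write_table(df: pd.DataFrame, path, index: bool = True, index_label=None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index, index_label=index_label)
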