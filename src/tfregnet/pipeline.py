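"""End-to-end pipeline orchestration on a synthetic cohort.

Runs the stages in dependency order (simulate -> fit -> coreg ->
signatures -> perturb -> rank -> essentiality), writes each stage's
outputs into its own subdirectory of the run directory, and records a
manifest of parameters and output file hashes.  Every random stage
derives its seed deterministically from the global seed, so reruns
with an identical configuration produce byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import io as tio
from .coregulation import all_pairs_coregulation
from .essentiality import predict_essentiality, train_essentiality_model
from .model import FitConfig, fit_subtype_model
from .signatures import call_signature_edges, permute_and_refit
from .synthetic import generate_signed_protein_network, simulate_cohort, simulate_essentiality
from .workflow import compute_activity_deltas

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "stage_seed"]

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": ["simulate", "fit", "coreg", "signatures", "perturb", "rank", "essentiality"],
    "simulate": {
        "n_tfs": 4,
        "n_genes": 12,
        "subtypes": ["A", "B"],
        "samples_per_subtype": 30,
        "edge_density": 0.4,
        "frac_signature_edges": 0.2,
        "noise_sd": 0.1,
        "protein_edges": 60,
        "frac_inhibitory": 0.3,
    },
    "fit": {"lambda": 0.1, "max_iter": 500},
    "coreg": {"min_inlier_fraction": 0.8},
    "signatures": {"n_shuffles": 10, "sd_threshold": 5.0},
    "perturb": {"knockdown_factor": 0.0},
    "rank": {"tolerance": 1e-6},
    "essentiality": {"n_true_predictors": 3, "noise_sd": 0.05, "train_fraction": 0.75, "cv_folds": 4},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def run_pipeline(config: dict | None = None, out_dir: str | Path = "run") -> Path:
    """Execute the configured stages; returns the run directory.

    Stage toggling: stages absent from ``config['stages']`` are
    skipped; downstream stages consume whatever in-memory outputs the
    executed upstream stages produced (skipping a producer skips its
    consumers).
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    seed = int(cfg["seed"])
    stages = list(cfg["stages"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "stages": stages, "outputs": {}}

    def record(stage: str, params: dict, files: list[Path]) -> None:
        manifest["outputs"][stage] = {
            "params": params,
            "files": {f.name: _sha256(f) for f in sorted(files)},
        }

    cohort = None
    net = None
    models: dict = {}
    corr = None
    deltas = None

    if "simulate" in stages:
        p = cfg["simulate"]
        sdir = out / "simulate"
        sdir.mkdir(exist_ok=True)
        cohort = simulate_cohort(
            n_tfs=p["n_tfs"],
            n_genes=p["n_genes"],
            subtypes=p["subtypes"],
            samples_per_subtype=p["samples_per_subtype"],
            edge_density=p["edge_density"],
            frac_signature_edges=p["frac_signature_edges"],
            noise_sd=p["noise_sd"],
            seed=stage_seed(seed, "simulate"),
        )
        proteins = sorted(set(cohort.expression.values.index))
        net = generate_signed_protein_network(
            len(proteins),
            min(p["protein_edges"], len(proteins) * (len(proteins) - 1)),
            p["frac_inhibitory"],
            seed=stage_seed(seed, "protein_net"),
            proteins=proteins,
        )
        tio.write_expression(cohort.expression, sdir / "expression.tsv")
        tio.write_protein_network(net, sdir / "protein_net.tsv")
        truth_rows = pd.DataFrame(
            [(tf, g, s, f) for (tf, g, s), f in sorted(cohort.truth.f_true.items())],
            columns=["tf", "gene", "subtype", "F"],
        )
        tio.write_table(truth_rows, sdir / "truth_f.tsv", index=False)
        record(
            "simulate",
            p,
            [sdir / "expression.tsv", sdir / "expression.labels.tsv", sdir / "protein_net.tsv", sdir / "truth_f.tsv"],
        )

    backbone_net = None
    if cohort is not None:
        from .containers import CandidateNetwork

        backbone_net = CandidateNetwork(edges=set(cohort.truth.backbone))

    if "fit" in stages and cohort is not None:
        p = cfg["fit"]
        fdir = out / "fit"
        fdir.mkdir(exist_ok=True)
        files = []
        for s in cohort.truth.subtypes:
            res = fit_subtype_model(
                backbone_net,
                cohort.expression,
                s,
                FitConfig(lam=p["lambda"], max_iter=p["max_iter"], seed=stage_seed(seed, "fit")),
            )
            models[s] = res.fvals
            tio.write_fvalues(res.fvals, fdir / f"fvalues_{s}.tsv")
            files += [fdir / f"fvalues_{s}.tsv", fdir / f"fvalues_{s}.basal.tsv"]
        record("fit", p, files)

    if "coreg" in stages and models:
        p = cfg["coreg"]
        cdir = out / "coreg"
        cdir.mkdir(exist_ok=True)
        first = sorted(models)[0]
        corr = all_pairs_coregulation(
            models[first], min_inlier_fraction=p["min_inlier_fraction"], seed=stage_seed(seed, "coreg")
        )
        tio.write_table(corr.r, cdir / "correlation.tsv", index_label="tf")
        record("coreg", p, [cdir / "correlation.tsv"])

    if "signatures" in stages and models and cohort is not None:
        p = cfg["signatures"]
        gdir = out / "signatures"
        gdir.mkdir(exist_ok=True)
        null = permute_and_refit(
            backbone_net,
            cohort.expression,
            n_shuffles=p["n_shuffles"],
            seed=stage_seed(seed, "signatures"),
            config=FitConfig(lam=cfg["fit"]["lambda"]),
        )
        assignment = call_signature_edges(models, null, sd_threshold=p["sd_threshold"])
        rows = pd.DataFrame(sorted(assignment.signature_edges), columns=["tf", "gene", "subtype"])
        tio.write_table(rows, gdir / "signature_edges.tsv", index=False)
        record("signatures", p, [gdir / "signature_edges.tsv"])

    if "perturb" in stages and "rank" in stages and models and net is not None:
        p = cfg["perturb"]
        rp = cfg["rank"]
        rdir = out / "rank"
        rdir.mkdir(exist_ok=True)
        first = sorted(models)[0]
        samples = cohort.expression.samples_of(first)[:8]
        sub = cohort.expression.subset_samples(samples)
        deltas = compute_activity_deltas(
            models[first], sub, net, knockdown_factor=p["knockdown_factor"], tolerance=rp["tolerance"]
        )
        files = []
        for tf, table in sorted(deltas.items()):
            path = rdir / f"deltas_{tf}.tsv"
            tio.write_table(table, path, index_label="sample")
            files.append(path)
        record("rank", {**p, **rp}, files)

    if "essentiality" in stages and deltas:
        p = cfg["essentiality"]
        edir = out / "essentiality"
        edir.mkdir(exist_ok=True)
        signal_sd = float(
            pd.concat([d.stack() for d in deltas.values()]).std() or 1.0
        )
        scores, support = simulate_essentiality(
            deltas,
            n_true_predictors=min(p["n_true_predictors"], len(net.proteins)),
            coef_scale=1.0,
            noise_sd=p["noise_sd"] * signal_sd,
            seed=stage_seed(seed, "essentiality"),
        )
        rows = []
        for tf, table in sorted(deltas.items()):
            measured = pd.Series({line: scores[(tf, line)] for line in table.index})
            model = train_essentiality_model(
                tf,
                table,
                measured,
                train_fraction=p["train_fraction"],
                cv_folds=p["cv_folds"],
                seed=stage_seed(seed, "essentiality_cv"),
            )
            pred = predict_essentiality(model, table)
            degenerate = pred.nunique() <= 1 or measured.nunique() <= 1
            rows.append(
                {
                    "tf": tf,
                    "cv_rmse": model.cv_rmse,
                    "alpha": model.alpha,
                    "l1_ratio": model.l1_ratio,
                    "n_nonzero": int((model.coefficients != 0).sum()),
                    "train_r": float("nan") if degenerate else float(pred.corr(measured)),
                }
            )
        tio.write_table(pd.DataFrame(rows), edir / "models.tsv", index=False)
        record("essentiality", p, [edir / "models.tsv"])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
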