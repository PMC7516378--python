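"""Per-TF elastic-net models mapping protein-activity deltas to essentiality.

For each TF, knockdown-induced changes in protein activity (features:
cell line x protein) are regressed on measured depletion scores with an
elastic net (L1 + L2) whose penalty strength and L1/L2 mix are chosen
by seeded k-fold cross-validation on a training split; held-out lines
never touch hyperparameter selection.  Scores follow the depletion
convention: more negative = more essential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

__all__ = [
    "EssentialityModel",
    "train_essentiality_model",
    "predict_essentiality",
    "subtype_specificity",
    "ALPHA_GRID",
    "L1_RATIO_GRID",
]

ALPHA_GRID = tuple(np.logspace(-3, 1, 7))
L1_RATIO_GRID = (0.1, 0.5, 0.9)


@dataclass
class EssentialityModel:
    tf: str
    coefficients: pd.Series  # per protein, on the standardized feature scale
    intercept: float
    alpha: float
    l1_ratio: float
    cv_rmse: float
    feature_mean: pd.Series = field(default=None)
    feature_scale: pd.Series = field(default=None)
    holdout_lines: list = field(default_factory=list)

    @property
    def support(self) -> list[str]:
        return sorted(self.coefficients.index[self.coefficients != 0])


def _standardize_train(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale == 0, 1.0, scale)
    return (X - mean) / scale, mean, scale


def train_essentiality_model(
    tf: str,
    deltas: pd.DataFrame,
    measured: pd.Series,
    train_fraction: float = 0.75,
    cv_folds: int = 4,
    seed: int = 0,
    alpha_grid=ALPHA_GRID,
    l1_ratio_grid=L1_RATIO_GRID,
) -> EssentialityModel:
    """Fit one TF's essentiality model with CV-selected elastic-net penalties.

    ``deltas``: cell line x protein activity changes; ``measured``:
    per-line depletion scores.  Lines are split train/hold-out by
    ``train_fraction`` (seeded); the (alpha, l1_ratio) grid is scored
    by ``cv_folds``-fold CV RMSE on the training lines only.
    """
    lines = [l for l in deltas.index if l in measured.index]
    if len(lines) < cv_folds + 1:
        raise ValueError("not enough cell lines for the requested folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(lines))
    n_train = max(cv_folds, int(round(train_fraction * len(lines))))
    train_lines = [lines[i] for i in sorted(order[:n_train])]
    holdout = [lines[i] for i in sorted(order[n_train:])]

    X = deltas.loc[train_lines].to_numpy(dtype=float)
    y = measured.loc[train_lines].to_numpy(dtype=float)
    proteins = list(deltas.columns)

    if np.ptp(y) == 0:
        warnings.warn(f"{tf}: constant response, intercept-only model")
        return EssentialityModel(
            tf=tf,
            coefficients=pd.Series(0.0, index=proteins),
            intercept=float(y[0]) if len(y) else 0.0,
            alpha=float("nan"),
            l1_ratio=float("nan"),
            cv_rmse=0.0,
            feature_mean=pd.Series(0.0, index=proteins),
            feature_scale=pd.Series(1.0, index=proteins),
            holdout_lines=holdout,
        )

    Xs, mean, scale = _standardize_train(X)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xs))
    best = None
    for alpha in alpha_grid:
        for l1_ratio in l1_ratio_grid:
            errs = []
            for tr, te in splits:
                m = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=50_000)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m.fit(Xs[tr], y[tr])
                pred = m.predict(Xs[te])
                errs.append(np.sqrt(np.mean((pred - y[te]) ** 2)))
            rmse = float(np.mean(errs))
            key = (rmse, alpha, l1_ratio)
            if best is None or key < best[0]:
                best = (key, alpha, l1_ratio)
    _, alpha, l1_ratio = best
    final = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=100_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(Xs, y)
    return EssentialityModel(
        tf=tf,
        coefficients=pd.Series(final.coef_, index=proteins),
        intercept=float(final.intercept_),
        alpha=float(alpha),
        l1_ratio=float(l1_ratio),
        cv_rmse=float(best[0][0]),
        feature_mean=pd.Series(mean, index=proteins),
        feature_scale=pd.Series(scale, index=proteins),
        holdout_lines=holdout,
    )


def predict_essentiality(model: EssentialityModel, deltas: pd.DataFrame) -> pd.Series:
    """Linear prediction for new samples from their activity deltas."""
    missing = set(model.coefficients.index) - set(deltas.columns)
    if missing:
        raise KeyError(f"deltas missing proteins: {sorted(missing)[:10]}")
    X = deltas[list(model.coefficients.index)].to_numpy(dtype=float)
    Xs = (X - model.feature_mean.to_numpy()) / model.feature_scale.to_numpy()
    pred = Xs @ model.coefficients.to_numpy() + model.intercept
    return pd.Series(pred, index=deltas.index)


def subtype_specificity(predicted: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Which subtype depends most on each TF, with a Welch one-way test.

    ``predicted``: TF x sample essentiality scores; ``labels``: sample
    -> subtype.  Per TF, returns the subtype with the minimum mean
    score (depletion convention: lower = more essential), the Welch
    analysis-of-means p-value, and per-subtype mean +/- SEM columns.
    Mean ties break lexicographically with a warning.
    """
    from statsmodels.stats.oneway import anova_oneway

    labels = labels.reindex(predicted.columns)
    groups = sorted(labels.dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 subtypes")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"subtype {g!r} has fewer than 2 samples")
    rows = {}
    for tf in predicted.index:
        vals = {g: predicted.loc[tf, labels.index[labels == g]].to_numpy(dtype=float) for g in groups}
        means = {g: float(v.mean()) for g, v in vals.items()}
        sems = {g: float(stats.sem(v)) if len(v) > 1 else 0.0 for g, v in vals.items()}
        if all(np.ptp(v) == 0 for v in vals.values()) and len(set(means.values())) == 1:
            p = 1.0
        else:
            try:
                res = anova_oneway(list(vals.values()), use_var="unequal", welch_correction=True)
                p = float(res.pvalue)
            except Exception:
                p = 1.0
        lo = min(means.values())
        winners = [g for g in groups if means[g] == lo]
        if len(winners) > 1:
            warnings.warn(f"{tf}: mean ties {winners}, taking {winners[0]}")
        row = {"most_dependent": winners[0], "p": p}
        for g in groups:
            row[f"mean_{g}"] = means[g]
            row[f"sem_{g}"] = sems[g]
        rows[tf] = row
    return pd.DataFrame.from_dict(rows, orient="index")
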