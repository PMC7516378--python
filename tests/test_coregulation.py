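"""Robust F-profile correlation and interaction benchmarking."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfregnet.containers import FValueMatrix
from tfregnet.coregulation import (
    CorrelationMatrix,
    InteractionReference,
    all_pairs_coregulation,
    interaction_enrichment,
    interaction_pr_auc,
    ransac_correlation,
)


def series(vals, prefix="g"):
    return pd.Series(np.asarray(vals, dtype=float), index=[f"{prefix}{i}" for i in range(len(vals))])


class TestRansacCorrelation:
    def test_identical_vectors_give_one(self):
        v = series(np.linspace(0.5, 3.0, 10))
        assert ransac_correlation(v, v, prefiltered=True) == pytest.approx(1.0)

    def test_three_shared_targets_return_zero(self):
        a, b = series([1.0, 2.0, 3.0]), series([1.0, 2.0, 3.0])
        assert ransac_correlation(a, b, prefiltered=True) == 0.0

    def test_outliers_are_rejected(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(-3, 3, 50)
        y = 2 * x + rng.normal(0, 0.1, 50)
        out_idx = rng.choice(50, 5, replace=False)
        y_dirty = y.copy()
        y_dirty[out_idx] += 10.0
        clean = np.setdiff1d(np.arange(50), out_idx)
        r_clean = stats.pearsonr(x[clean], y[clean])[0]
        r = ransac_correlation(series(x), series(y_dirty), 0.8, seed=1, prefiltered=True)
        assert abs(r - r_clean) < 0.05

    def test_regulation_filter_drops_near_one_f(self):
        # only 3 targets pass |log2 F| > 0.1 for both -> 0
        a = series([0.05, 0.05, 1.0, 2.0, 3.0])
        b = series([1.0, 2.0, 0.0, 1.5, 2.5])
        assert ransac_correlation(a, b) == 0.0

    def test_common_scale_change_leaves_r_invariant(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0.2, 3, 30)
        y = 1.5 * x + rng.normal(0, 0.2, 30)
        r1 = ransac_correlation(series(x), series(y), seed=2, prefiltered=True)
        r2 = ransac_correlation(series(3 * x), series(3 * y), seed=2, prefiltered=True)
        assert r1 == pytest.approx(r2, abs=1e-9)


def fvals_from_profiles(profiles: dict) -> FValueMatrix:
    idx, vals = [], []
    genes = set()
    for tf, prof in profiles.items():
        for g, v in prof.items():
            idx.append((tf, g))
            vals.append(2.0**v)
            genes.add(g)
    return FValueMatrix(
        f=pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["tf", "gene"])),
        basal=pd.Series(1.0, index=sorted(genes)),
    )


class TestAllPairs:
    def test_disjoint_target_sets_give_zero(self):
        fv = fvals_from_profiles(
            {
                "T1": {f"g{i}": 1.0 for i in range(5)},
                "T2": {f"h{i}": 1.0 for i in range(5)},
            }
        )
        corr = all_pairs_coregulation(fv, seed=0)
        assert corr.r.loc["T1", "T2"] == 0.0
        assert corr.n_shared.loc["T1", "T2"] == 0

    def test_diagonal_is_one_when_enough_targets(self):
        fv = fvals_from_profiles(
            {
                "T1": {f"g{i}": 1.0 + 0.1 * i for i in range(6)},
                "T2": {"g0": 1.0, "g1": 1.0},
            }
        )
        corr = all_pairs_coregulation(fv, seed=0)
        assert corr.r.loc["T1", "T1"] == 1.0
        assert corr.r.loc["T2", "T2"] == 0.0  # only 2 regulated targets

    def test_matches_pairwise_loop_oracle(self, two_subtype_cohort):
        from tfregnet.model import FitConfig, fit_subtype_model

        from .conftest import backbone_of

        fv = fit_subtype_model(
            backbone_of(two_subtype_cohort.truth),
            two_subtype_cohort.expression,
            "A",
            FitConfig(lam=0.1),
        ).fvals
        corr = all_pairs_coregulation(fv, seed=3)
        log2f = fv.log2_f
        for a, b in combinations(fv.tfs, 2):
            pa = log2f[log2f.index.get_level_values(0) == a]
            pa.index = pa.index.get_level_values(1)
            pb = log2f[log2f.index.get_level_values(0) == b]
            pb.index = pb.index.get_level_values(1)
            pa = pa[pa.abs() > 0.1]
            pb = pb[pb.abs() > 0.1]
            shared = pa.index.intersection(pb.index)
            expected = ransac_correlation(pa.loc[shared], pb.loc[shared], seed=3, prefiltered=True)
            assert corr.r.loc[a, b] == pytest.approx(expected, abs=1e-12)
            assert corr.r.loc[a, b] == corr.r.loc[b, a]

    def test_symmetry_and_range(self, two_subtype_cohort):
        from tfregnet.model import FitConfig, fit_subtype_model

        from .conftest import backbone_of

        fv = fit_subtype_model(
            backbone_of(two_subtype_cohort.truth),
            two_subtype_cohort.expression,
            "B",
            FitConfig(lam=0.1),
        ).fvals
        corr = all_pairs_coregulation(fv, seed=0)
        assert np.allclose(corr.r.values, corr.r.values.T)
        assert (corr.r.abs().values <= 1.0 + 1e-12).all()


def corr_from_scores(scores: dict) -> CorrelationMatrix:
    tfs = sorted({t for pair in scores for t in pair})
    r = pd.DataFrame(0.0, index=tfs, columns=tfs)
    n = pd.DataFrame(10, index=tfs, columns=tfs, dtype=int)
    for (a, b), v in scores.items():
        r.loc[a, b] = r.loc[b, a] = v
    np.fill_diagonal(r.values, 1.0)
    return CorrelationMatrix(r=r, n_shared=n)


class TestEnrichment:
    def test_hand_built_contingency_table_odds_ratio(self):
        # directly check the 2x2 arithmetic on the documented example
        table = np.array([[10, 90], [40, 3960]])
        odds, p = stats.fisher_exact(table)
        assert odds == pytest.approx(11.0)
        # oracle: exact enumeration of the hypergeometric support
        from .oracles import fisher_two_sided_exact

        assert p == pytest.approx(fisher_two_sided_exact(10, 90, 40, 3960), rel=1e-8)

    def test_reference_covering_all_pairs_gives_p_one(self):
        scores = {(f"T{i}", f"T{j}"): 0.1 * (i + j) for i in range(5) for j in range(i + 1, 5)}
        corr = corr_from_scores(scores)
        ref = InteractionReference({frozenset(p) for p in scores})
        odds, p, table = interaction_enrichment(corr, ref, top_fraction=0.2)
        assert p == pytest.approx(1.0)
        assert table[0, 1] == 0 and table[1, 1] == 0

    def test_empty_reference_rejected(self):
        corr = corr_from_scores({("T0", "T1"): 0.5})
        with pytest.raises(ValueError):
            interaction_enrichment(corr, InteractionReference(set()), 0.5)


class TestPrAuc:
    def test_perfect_ranking_gives_auc_one(self):
        scores = {("T0", "T1"): 0.9, ("T0", "T2"): 0.8, ("T1", "T2"): 0.1, ("T0", "T3"): 0.05,
                  ("T1", "T3"): 0.02, ("T2", "T3"): 0.01}
        corr = corr_from_scores(scores)
        ref = InteractionReference({frozenset(("T0", "T1")), frozenset(("T0", "T2"))})
        assert interaction_pr_auc(corr, ref) == pytest.approx(1.0)

    def test_matches_brute_force_threshold_oracle(self):
        rng = np.random.default_rng(12)
        tfs = [f"T{i}" for i in range(7)]  # 21 pairs
        pairs = list(combinations(tfs, 2))
        scores = {p: float(rng.uniform(-1, 1)) for p in pairs}
        corr = corr_from_scores(scores)
        positives = set(rng.choice(len(pairs), 6, replace=False))
        ref = InteractionReference({frozenset(pairs[i]) for i in positives})
        auc = interaction_pr_auc(corr, ref)

        # oracle: trapezoid over every unique |r| threshold
        absr = {p: abs(v) for p, v in scores.items()}
        labels = {p: frozenset(p) in ref.pairs for p in pairs}
        pts = [(0.0, 1.0)]
        n_pos = sum(labels.values())
        for t in sorted(set(absr.values()), reverse=True):
            sel = [p for p in pairs if absr[p] >= t]
            tp = sum(labels[p] for p in sel)
            pts.append((tp / n_pos, tp / len(sel)))
        expected = np.trapezoid([pr for _, pr in pts], [rc for rc, _ in pts])
        assert auc == pytest.approx(expected, abs=1e-12)

    def test_random_ranking_approximates_positive_fraction(self):
        rng = np.random.default_rng(13)
        tfs = [f"T{i}" for i in range(20)]  # 190 pairs
        pairs = list(combinations(tfs, 2))
        pi = 0.3
        aucs = []
        for _ in range(200):
            scores = {p: float(rng.uniform(0, 1)) for p in pairs}
            corr = corr_from_scores(scores)
            pos = rng.choice(len(pairs), int(pi * len(pairs)), replace=False)
            ref = InteractionReference({frozenset(pairs[i]) for i in pos})
            aucs.append(interaction_pr_auc(corr, ref))
        assert abs(np.mean(aucs) - pi) < 0.05

    def test_no_positives_rejected(self):
        corr = corr_from_scores({("T0", "T1"): 0.5})
        with pytest.raises(ValueError):
            interaction_pr_auc(corr, InteractionReference({frozenset(("X", "Y"))}))


class TestNullCalibration:
    def test_independent_profiles_rarely_exceed_high_correlation(self):
        """On random, unrelated F profiles |r| > 0.8 is rare at 50 shared targets."""
        rng = np.random.default_rng(14)
        n_high, n_tot = 0, 200
        for rep in range(n_tot):
            a = series(rng.normal(0, 1, 50) + np.sign(rng.normal(size=50)) * 0.2)
            b = series(rng.normal(0, 1, 50) + np.sign(rng.normal(size=50)) * 0.2)
            if abs(ransac_correlation(a, b, seed=rep, prefiltered=True)) > 0.8:
                n_high += 1
        assert n_high / n_tot < 0.01
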