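"""AUC threshold selection, DM-DE gene sets, LFC clustering, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twindiff.datasets import (
    PUBLISHED_DELTA_THRESHOLDS,
    load_kidney_dmde,
    load_wholeblood_dmde,
)
from twindiff.integration import (
    auc_for_threshold,
    cluster_lfc,
    condition_correlations,
    optimize_threshold,
    select_dmde,
)


def table(delta, logfc):
    return pd.DataFrame({"mean_delta": delta, "logfc": logfc})


class TestAUC:
    def test_perfect_separation(self):
        t = table([-0.2, -0.15, -0.01, 0.0], [1.0, 2.0, -1.0, -0.5])
        assert auc_for_threshold(t, -0.05) == 1.0

    def test_constant_classifier_is_chance(self):
        t = table([-0.2, -0.1, -0.05, -0.01], [1.0, -1.0, 1.0, -1.0])
        assert auc_for_threshold(t, 0.0) == 0.5  # all deltas < 0 -> X all 1

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(0)
        t = table(rng.uniform(-0.15, 0, 4000), rng.choice([-1.0, 1.0], 4000))
        assert auc_for_threshold(t, -0.075) == pytest.approx(0.5, abs=0.03)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            auc_for_threshold(table([-0.1, -0.2], [1.0, 2.0]), -0.05)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_flip_symmetry(self, seed):
        # flipping the outcome maps AUC -> 1 - AUC
        rng = np.random.default_rng(seed)
        n = 40
        t = table(rng.uniform(-0.15, 0, n), rng.normal(0.2, 1.0, n))
        y = t["logfc"] > 0
        if y.all() or not y.any():
            return
        a = auc_for_threshold(t, -0.06)
        flipped = t.assign(logfc=-t["logfc"])
        yf = flipped["logfc"] > 0
        if (~yf).all() or yf.all():
            return
        b = auc_for_threshold(flipped, -0.06)
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestOptimizeThreshold:
    def test_grid_includes_endpoints_and_is_regular(self):
        t = table([-0.12, -0.11, -0.02, -0.01], [1.0, 1.0, -1.0, -1.0])
        scan = optimize_threshold(t)
        assert scan.thresholds[0] == pytest.approx(-0.15)
        assert scan.thresholds[-1] == pytest.approx(0.0)
        assert np.allclose(np.diff(scan.thresholds), 0.005)
        assert scan.auc.max() == auc_for_threshold(t, scan.selected)

    def test_perfectly_separated_toy_selects_least_stringent_max(self):
        t = table([-0.2, -0.15, -0.01, 0.0], [1.0, 2.0, -1.0, -0.5])
        scan = optimize_threshold(t)
        assert auc_for_threshold(t, scan.selected) == 1.0
        # ties broken toward 0: nothing below the selected point does better
        later = scan.thresholds > scan.selected
        assert (scan.auc[later] < scan.auc.max()).all()

    def test_planted_cutoff_recovered_median_within_one_step(self):
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            delta = rng.uniform(-0.15, 0.0, 300)
            y = delta < -0.08
            flip = rng.random(300) < 0.05
            y = np.where(flip, ~y, y)
            t = table(delta, np.where(y, 1.0, -1.0))
            scan = optimize_threshold(t)
            errs.append(abs(scan.selected - (-0.08)))
        assert np.median(errs) <= 0.005 + 1e-12

    def test_published_thresholds_are_on_the_grid(self):
        scan = optimize_threshold(table([-0.1, -0.1, -0.01, -0.01], [1, 1, -1, -1.0]))
        grid = np.round(scan.thresholds, 10)
        for t in PUBLISHED_DELTA_THRESHOLDS.values():
            assert np.isclose(grid, t).any()


class TestSelectDMDE:
    def test_wholeblood_fixture_yields_43_genes(self):
        t2 = load_wholeblood_dmde()
        dm = t2.rename(columns={"meth_p": "p"})[["gene", "mean_delta", "p"]]
        de = t2.rename(columns={"lfc_expt1_active": "logfc"})[["gene", "logfc"]]
        out = select_dmde(dm, de, PUBLISHED_DELTA_THRESHOLDS["whole_blood"])
        assert len(out) == 43
        assert out["gene"].is_unique

    def test_monotone_in_both_thresholds(self):
        t2 = load_wholeblood_dmde()
        dm = t2.rename(columns={"meth_p": "p"})[["gene", "mean_delta", "p"]]
        de = t2.rename(columns={"lfc_expt1_active": "logfc"})[["gene", "logfc"]]
        tight = select_dmde(dm, de, -0.15, meth_p_max=1e-6)
        loose = select_dmde(dm, de, -0.05, meth_p_max=0.01)
        assert set(tight["gene"]) <= set(loose["gene"])

    def test_gene_without_expression_record_excluded(self):
        dm = pd.DataFrame({"gene": ["A", "B"], "mean_delta": [-0.2, -0.2], "p": [1e-4, 1e-4]})
        de = pd.DataFrame({"gene": ["A"], "logfc": [1.0]})
        out = select_dmde(dm, de, -0.085)
        assert list(out["gene"]) == ["A"]

    def test_downregulated_gene_retained_with_flag(self):
        dm = pd.DataFrame({"gene": ["A"], "mean_delta": [-0.2], "p": [1e-4]})
        de = pd.DataFrame({"gene": ["A"], "logfc": [-1.0]})
        out = select_dmde(dm, de, -0.085)
        assert len(out) == 1 and not out["upregulated"].iloc[0]


def complete_linkage_oracle(X):
    """Naive agglomeration: merge the closest pair (complete linkage) each step."""
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = max(
                np.linalg.norm(X[a] - X[b]) for a in clusters[i] for b in clusters[j]
            )
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


class TestClusterLFC:
    def test_two_planted_blocks_separate(self):
        rng = np.random.default_rng(0)
        hi = rng.normal(3.0, 0.1, size=(9, 6))
        lo = rng.normal(0.5, 0.1, size=(20, 6))
        lfc = pd.DataFrame(np.vstack([hi, lo]), index=[f"g{i}" for i in range(29)])
        _, labels = cluster_lfc(lfc, k=2)
        assert labels.iloc[:9].nunique() == 1
        assert labels.iloc[9:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_duplicate_rows_merge_at_height_zero(self):
        lfc = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        Z, _ = cluster_lfc(lfc)
        assert Z[0, 2] == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_merge_heights_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 3))
        Z, _ = cluster_lfc(pd.DataFrame(X))
        assert np.allclose(sorted(Z[:, 2]), complete_linkage_oracle(X), atol=1e-10)

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            cluster_lfc(pd.DataFrame([[1.0, 2.0]]))


class TestConditionCorrelations:
    def test_within_experiment_published_values(self):
        t2 = load_wholeblood_dmde()
        r1, _, n1 = condition_correlations(t2["lfc_expt1_active"], t2["lfc_expt1_inactive"])
        r2, _, n2 = condition_correlations(t2["lfc_expt2_active"], t2["lfc_expt2_inactive"])
        assert round(r1, 2) == 0.95 and n1 == 38
        assert round(r2, 2) == 0.99 and n2 == 38

    def test_cross_tissue_published_value(self):
        t3 = load_kidney_dmde()
        r, p, n = condition_correlations(
            t3["lfc_glomerulus"], t3["lfc_tubulointerstitium"]
        )
        assert round(r, 2) == 0.66
        assert p < 1e-3
        assert n == 28

    def test_identical_columns(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, _, _ = condition_correlations(x, x)
        assert r == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            condition_correlations([1.0, 2.0], [2.0, 1.0])
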