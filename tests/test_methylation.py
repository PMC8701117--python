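"""Paired differential methylation: deltas, t-test, FDR, DM calling, masking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from twindiff.containers import BetaMatrix, DMConfig, SimConfig
from twindiff.datasets import load_twin_dm_sites
from twindiff.methylation import (
    bh_fdr,
    call_dm,
    dm_table,
    ifn_mask_reanalysis,
    paired_deltas,
    paired_ttest,
    qc_filter_probes,
)
from twindiff.synthetic import generate_manifest_and_genome, generate_twin_beta


def bh_oracle(p):
    """Independent step-up implementation: q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        prev = min(prev, m * p[idx] / rank)
        q[idx] = min(prev, 1.0)
    return q


class TestPairedDeltas:
    def test_printed_worked_examples(self):
        # two published rows: per-pair deltas -> printed 2-dp means
        assert np.mean([-0.5, -0.35, -0.57]) == pytest.approx(-0.47, abs=0.005)
        assert np.mean([-0.24, -0.27, -0.37]) == pytest.approx(-0.29, abs=0.005)

    def test_sign_convention_and_mean(self, small_beta):
        deltas = paired_deltas(small_beta)
        v = small_beta.values
        for pid, (aff, unaff) in small_beta.pairs.items():
            assert np.allclose(deltas[pid], v[aff] - v[unaff])
        pair_cols = deltas.drop(columns="mean_delta")
        assert np.allclose(deltas["mean_delta"], pair_cols.mean(axis=1))

    def test_identical_twins_zero_delta(self, small_beta):
        v = small_beta.values.copy()
        for aff, unaff in small_beta.pairs.values():
            v[aff] = v[unaff]
        deltas = paired_deltas(BetaMatrix(v, small_beta.pairs))
        assert np.allclose(deltas.to_numpy(), 0.0)

    def test_missing_pair_member_raises(self, small_beta):
        pairs = dict(small_beta.pairs)
        pairs["p4"] = ("a1", "nope")
        with pytest.raises(KeyError):
            BetaMatrix(small_beta.values, pairs)


class TestPairedTTest:
    def test_closed_form_example(self):
        res = paired_ttest(np.array([[-0.24, -0.27, -0.37]]))
        assert res["t"].iloc[0] == pytest.approx(-7.46406, abs=1e-4)
        assert res["df"].iloc[0] == 2
        assert res["p"].iloc[0] == pytest.approx(0.0174801, abs=1e-6)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0, 0.1, size=(50, 5))
        res = paired_ttest(pd.DataFrame(d))
        oracle = stats.ttest_1samp(d, 0.0, axis=1)
        assert np.allclose(res["t"], oracle.statistic, atol=1e-12)
        assert np.allclose(res["p"], oracle.pvalue, atol=1e-12)

    def test_degenerate_rows(self):
        res = paired_ttest(np.array([[0.0, 0.0, 0.0], [-0.1, -0.1, -0.1]]))
        assert res["degenerate"].all()
        assert res["p"].tolist() == [1.0, 0.0]

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest(np.array([[0.1]]))


class TestBHFdr:
    def test_single_p(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_computed_chain(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_permutations_of_six_match_oracle(self):
        base = [0.001, 0.01, 0.04, 0.2, 0.5, 0.9]
        for perm in itertools.permutations(base):
            assert np.allclose(bh_fdr(perm), bh_oracle(perm), atol=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=25))
    def test_oracle_agreement_and_dominance(self, p):
        q = bh_fdr(p)
        assert np.allclose(q, bh_oracle(p), atol=1e-12)
        assert (q >= np.asarray(p) - 1e-15).all()
        assert (q <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])


class TestQCFilter:
    def test_removes_probe_failing_in_one_sample(self, small_beta):
        det = pd.DataFrame(0.0, index=small_beta.values.index, columns=small_beta.values.columns)
        det.iloc[1, 3] = 2e-5
        beta = BetaMatrix(small_beta.values, small_beta.pairs, det)
        filtered, removed = qc_filter_probes(beta)
        assert removed == 1
        assert "cg1" not in filtered.probe_ids

    def test_all_zero_detection_keeps_everything(self, small_beta):
        det = pd.DataFrame(0.0, index=small_beta.values.index, columns=small_beta.values.columns)
        beta = BetaMatrix(small_beta.values, small_beta.pairs, det)
        filtered, removed = qc_filter_probes(beta)
        assert removed == 0 and len(filtered.probe_ids) == 4

    def test_known_violation_count(self, small_beta):
        rng = np.random.default_rng(3)
        det = pd.DataFrame(
            rng.uniform(0, 5e-6, size=small_beta.values.shape),
            index=small_beta.values.index,
            columns=small_beta.values.columns,
        )
        det.iloc[[0, 2], 0] = 1e-3
        beta = BetaMatrix(small_beta.values, small_beta.pairs, det)
        _, removed = qc_filter_probes(beta)
        assert removed == 2

    def test_passthrough_without_detection(self, small_beta):
        filtered, removed = qc_filter_probes(small_beta)
        assert removed == 0 and filtered is small_beta


class TestCallDM:
    def test_printed_table_thresholds_retain_all_59(self):
        t1 = load_twin_dm_sites()
        mean = t1[["pair1", "pair2", "pair3"]].mean(axis=1)
        keep = (t1["p"] < 1.06e-7) & (mean.abs() > 0.085)
        assert keep.sum() == 59
        assert (mean > 0).sum() == 2  # only two hypermethylated sites

    def test_boundary_is_strict(self):
        rec = pd.DataFrame({"mean_delta": [-0.085], "q": [0.01], "direction": ["hypo"]})
        dm, summary = call_dm(rec, DMConfig())
        assert summary["n_sites"] == 0

    def test_monotone_in_both_thresholds(self, default_sim):
        _, beta, _ = default_sim
        rec = dm_table(beta)
        base, _ = call_dm(rec, DMConfig())
        looser_q, _ = call_dm(rec, DMConfig(q_max=0.2))
        looser_d, _ = call_dm(rec, DMConfig(abs_delta_min=0.01))
        assert set(base.index) <= set(looser_q.index)
        assert set(base.index) <= set(looser_d.index)


class TestRecoveryAndMasking:
    def test_planted_signal_recovered(self, default_sim):
        cfg, beta, truth = default_sim
        man, _, _ = generate_manifest_and_genome(cfg)
        dm, _ = call_dm(dm_table(beta, man), DMConfig())
        signal = set(truth.signal_probes)
        hits = set(dm.index)
        assert len(hits & signal) / len(signal) >= 0.9
        assert len(hits - signal) / (cfg.n_probes - len(signal)) <= 0.01

    def test_single_factor_signal_fully_masked(self, default_sim):
        cfg, beta, truth = default_sim
        man, _, _ = generate_manifest_and_genome(cfg)
        dm, _ = call_dm(dm_table(beta, man), DMConfig())
        _, n_sig = ifn_mask_reanalysis(beta, dm)
        assert n_sig == 0

    def test_factor_independent_block_survives_masking(self):
        # A factor-independent effect is only separable from the IFN signature
        # when the latent factor varies within groups (otherwise the masking
        # covariate is collinear with disease status and absorbs every group
        # effect); use a larger cohort with a dispersed factor.
        cfg = SimConfig(seed=5, n_pairs=20, latent_ifn_sd=0.5)
        beta, truth = generate_twin_beta(cfg)
        man, _, _ = generate_manifest_and_genome(cfg)
        v = beta.values.copy()
        indep = [p for p in v.index if p not in truth.signal_probes][:25]
        for aff, _ in beta.pairs.values():
            v.loc[indep, aff] = np.clip(v.loc[indep, aff] - 0.15, 0, 1)
        beta2 = BetaMatrix(v, beta.pairs)
        dm, _ = call_dm(dm_table(beta2, man), DMConfig())
        masked, n_sig = ifn_mask_reanalysis(beta2, dm)
        surviving = masked[masked["q"] < 0.05].index
        assert len(set(surviving) & set(indep)) >= 20
        assert not set(surviving) & set(truth.signal_probes)

    def test_constant_covariate_equals_centering(self, small_beta):
        from twindiff.methylation import _residualize

        cov = pd.Series(0.5, index=small_beta.values.columns)
        resid = _residualize(small_beta.values, cov)
        centered = small_beta.values.sub(small_beta.values.mean(axis=1), axis=0)
        assert np.allclose(resid, centered, atol=1e-12)

    def test_no_irg_probes_raises(self, small_beta):
        rec = dm_table(small_beta)
        rec["irg"] = False
        rec["gene"] = "G"
        with pytest.raises(ValueError):
            ifn_mask_reanalysis(small_beta, rec)
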