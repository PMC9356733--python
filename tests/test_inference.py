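import numpy as np
import pandas as pd
import pytest
from oracles import bh_stepup_reference, pooled_t_reference
from statsmodels.stats.multitest import multipletests

from dynrecon.inference import (AgeBinning, age_stratified_comparison,
                                bh_fdr, network_level_comparison,
                                replication_run, roi_followup, two_sample_t)
from dynrecon.metrics import metric_table
from dynrecon.community import AllegianceMatrix
from dynrecon.partition import demo_partition


class TestTwoSampleT:
    def test_identical_samples(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # pooled sp^2 = 1, se = sqrt(2/3), df = 4
        t, p = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742346142, abs=1e-9)
        assert p == pytest.approx(0.0213116411, abs=1e-9)
        assert t == pytest.approx(pooled_t_reference([1, 2, 3], [4, 5, 6]),
                                  abs=1e-12)

    def test_scale_invariance(self):
        x, y = [1.0, 2.0, 5.0, 3.0], [4.0, 6.0, 7.0]
        t1, p1 = two_sample_t(x, y)
        t2, p2 = two_sample_t([10 * v for v in x], [10 * v for v in y])
        assert t1 == pytest.approx(t2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_sign_convention(self):
        t, _ = two_sample_t([0.0, 0.1, 0.2], [1.0, 1.1, 1.2])
        assert t < 0  # case mean below control mean

    def test_small_sample_error(self):
        with pytest.raises(ValueError, match="n >= 2"):
            two_sample_t([1.0], [1.0, 2.0])

    def test_welch_differs_under_unequal_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 5, 10)
        y = rng.normal(0, 0.5, 40)
        tp, _ = two_sample_t(x, y, welch=False)
        tw, _ = two_sample_t(x, y, welch=True)
        assert tp != pytest.approx(tw)


class TestBhFdr:
    def test_stepup_example_all_rejected(self):
        q, reject = bh_fdr([0.001, 0.01, 0.02, 0.05], 0.05)
        assert reject.all()
        assert q[3] == pytest.approx(0.05)

    def test_all_ones(self):
        q, reject = bh_fdr([1.0, 1.0, 1.0], 0.05)
        assert not reject.any()
        np.testing.assert_allclose(q, 1.0)

    def test_single_p(self):
        q, reject = bh_fdr([0.04], 0.05)
        assert q[0] == pytest.approx(0.04)
        assert reject[0]

    def test_empty(self):
        q, reject = bh_fdr([], 0.05)
        assert q.size == 0 and reject.size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])

    def test_matches_naive_reference_and_statsmodels(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.uniform(0, 1, m)
            q, reject = bh_fdr(p, 0.05)
            np.testing.assert_allclose(q, bh_stepup_reference(p), atol=1e-12)
            sm_reject, sm_q, *_ = multipletests(p, alpha=0.05,
                                                method="fdr_bh")
            np.testing.assert_allclose(q, sm_q, atol=1e-12)


def synthetic_metric_frame(rng, n_per_group, effect=None, part=None,
                           age_rng=(8, 25)):
    """Tidy metric + meta tables with Gaussian values; ``effect`` maps
    (metric_type, network_1, network_2) -> additive case shift."""
    part = part or demo_partition(2)
    effect = effect or {}
    features = [("recruitment", n, "") for n in part.networks]
    from itertools import combinations
    features += [("integration", a, b)
                 for a, b in combinations(part.networks, 2)]
    rows, meta = [], []
    k = 0
    for group in ("case", "control"):
        for _ in range(n_per_group):
            k += 1
            sid = f"s{k:03d}"
            meta.append((sid, group, "site1", float(rng.uniform(*age_rng))))
            for feat in features:
                v = rng.normal(0.5, 0.1)
                if group == "case":
                    v += effect.get(feat, 0.0)
                rows.append((sid, *feat, v))
    metrics = pd.DataFrame(
        rows, columns=["subject_id", "metric_type", "network_1", "network_2",
                       "value"])
    meta = pd.DataFrame(meta, columns=["subject_id", "group", "site", "age"])
    return metrics, meta


class TestNetworkLevelComparison:
    def test_emits_45_results(self):
        rng = np.random.default_rng(2)
        metrics, meta = synthetic_metric_frame(rng, 10)
        res = network_level_comparison(metrics, meta)
        assert len(res) == 45
        assert (res["metric_type"] == "recruitment").sum() == 9
        assert (res["metric_type"] == "integration").sum() == 36
        assert (res["q"] >= res["p"] - 1e-15).all()
        assert (res["reject"] == (res["q"] <= 0.05)).all()

    def test_detects_planted_effect(self):
        rng = np.random.default_rng(3)
        metrics, meta = synthetic_metric_frame(
            rng, 30, effect={("recruitment", "DMN", ""): -0.2})
        res = network_level_comparison(metrics, meta)
        row = res[(res["metric_type"] == "recruitment")
                  & (res["network_1"] == "DMN")].iloc[0]
        assert row["t"] < 0 and row["reject"]

    def test_missing_metric_errors_with_subject(self):
        rng = np.random.default_rng(4)
        metrics, meta = synthetic_metric_frame(rng, 5)
        metrics = metrics.drop(metrics.index[3])
        with pytest.raises(ValueError, match="missing metric"):
            network_level_comparison(metrics, meta)

    def test_group_too_small(self):
        rng = np.random.default_rng(5)
        metrics, meta = synthetic_metric_frame(rng, 5)
        meta.loc[meta["group"] == "case", "group"] = "control"
        with pytest.raises(ValueError, match="n >= 2"):
            network_level_comparison(metrics, meta)


class TestAgeBinning:
    def test_edge_semantics(self):
        bins = AgeBinning((7, 12, 18, 25))
        assert list(bins.assign([7, 11.9, 12, 17.9, 18, 25, 25.5, 6])) == \
            [0, 0, 1, 1, 2, 2, -1, -1]

    def test_labels(self):
        assert AgeBinning((7, 12, 18, 25)).labels == \
            ("[7,12)", "[12,18)", "[18,25]")

    def test_unordered_edges_rejected(self):
        with pytest.raises(ValueError):
            AgeBinning((12, 7))


class TestAgeStratified:
    def test_counts_three_bins(self):
        rng = np.random.default_rng(6)
        metrics, meta = synthetic_metric_frame(rng, 60, age_rng=(8, 24.9))
        res = age_stratified_comparison(metrics, meta)
        assert set(res) == {"[7,12)", "[12,18)", "[18,25]"}
        assert all(len(tab) == 45 for tab in res.values())

    def test_all_out_of_range_errors(self):
        rng = np.random.default_rng(7)
        metrics, meta = synthetic_metric_frame(rng, 5, age_rng=(30, 40))
        with pytest.raises(ValueError, match="no age bin"):
            with pytest.warns(UserWarning):
                age_stratified_comparison(metrics, meta)

    def test_underfilled_bin_skipped_with_warning(self):
        rng = np.random.default_rng(8)
        metrics, meta = synthetic_metric_frame(rng, 20, age_rng=(13, 17))
        with pytest.warns(UserWarning, match="under-filled"):
            res = age_stratified_comparison(metrics, meta)
        assert set(res) == {"[12,18)"}

    def test_effect_concentrated_in_one_bin(self):
        rng = np.random.default_rng(9)
        metrics, meta = synthetic_metric_frame(rng, 120, age_rng=(8, 24.9))
        # plant the effect only for cases aged 12-18
        idx = meta.set_index("subject_id")
        sel = metrics[(metrics["metric_type"] == "recruitment")
                      & (metrics["network_1"] == "DMN")]
        for i, row in sel.iterrows():
            m = idx.loc[row["subject_id"]]
            if m["group"] == "case" and 12 <= m["age"] < 18:
                metrics.loc[i, "value"] -= 0.3
        res = age_stratified_comparison(metrics, meta)

        def dmn_reject(tab):
            r = tab[(tab["metric_type"] == "recruitment")
                    & (tab["network_1"] == "DMN")].iloc[0]
            return bool(r["reject"])

        assert dmn_reject(res["[12,18)"])
        assert not dmn_reject(res["[7,12)"])
        assert not dmn_reject(res["[18,25]"])


def node_metric_frame(rng, n_per_group, nodes, effect_nodes=(), shift=0.0):
    rows, meta = [], []
    k = 0
    for group in ("case", "control"):
        for _ in range(n_per_group):
            k += 1
            sid = f"s{k:03d}"
            meta.append((sid, group, "site1", 20.0))
            for node, net in nodes:
                for mtype in ("recruitment", "integration"):
                    v = rng.normal(0.5, 0.1)
                    if group == "case" and node in effect_nodes \
                            and mtype == "recruitment":
                        v += shift
                    rows.append((sid, mtype, node, net, v))
    node_metrics = pd.DataFrame(
        rows, columns=["subject_id", "metric_type", "node_id", "network",
                       "value"])
    meta = pd.DataFrame(meta, columns=["subject_id", "group", "site", "age"])
    return node_metrics, meta


class TestRoiFollowup:
    def _sig_results(self, metric_type="recruitment", n1="DMN", n2=""):
        return pd.DataFrame([{
            "metric_type": metric_type, "network_1": n1, "network_2": n2,
            "t": -4.0, "p": 1e-4, "q": 1e-3, "reject": True,
            "mean_case": 0.4, "mean_control": 0.5,
            "n_case": 30, "n_control": 30,
        }])

    def test_empty_when_nothing_significant(self):
        res = self._sig_results()
        res["reject"] = False
        rng = np.random.default_rng(10)
        nodes = [(f"d{i}", "DMN") for i in range(4)]
        nm, meta = node_metric_frame(rng, 5, nodes)
        out = roi_followup(nm, meta, res)
        assert out.empty

    def test_flags_affected_nodes(self):
        rng = np.random.default_rng(11)
        nodes = [(f"d{i}", "DMN") for i in range(8)] + \
                [(f"m{i}", "MFN") for i in range(8)]
        affected = {"d0", "d1", "d2", "d3"}
        nm, meta = node_metric_frame(rng, 40, nodes,
                                     effect_nodes=affected, shift=-0.25)
        out = roi_followup(nm, meta, self._sig_results())
        assert not out.empty
        assert set(out["network"]) == {"DMN"}  # restricted to significant net
        hits = set(out["node_id"])
        assert len(hits & affected) >= 0.7 * len(affected)

    def test_null_rate_low(self):
        rng = np.random.default_rng(12)
        nodes = [(f"d{i}", "DMN") for i in range(60)]
        nm, meta = node_metric_frame(rng, 30, nodes)
        out = roi_followup(nm, meta, self._sig_results())
        # expected false-positive count 60 * 0.001 = 0.06
        assert len(out) <= 2

    def test_integration_pair_covers_both_networks(self):
        rng = np.random.default_rng(13)
        nodes = [(f"d{i}", "DMN") for i in range(3)] + \
                [(f"m{i}", "MFN") for i in range(3)] + \
                [(f"f{i}", "FPN") for i in range(3)]
        nm, meta = node_metric_frame(rng, 40, nodes)
        nm.loc[(nm["metric_type"] == "integration")
               & (nm["network"].isin(["DMN", "MFN"]))
               & (nm["subject_id"].isin(meta[meta["group"] == "case"]
                                        ["subject_id"])), "value"] -= 0.3
        res = self._sig_results("integration", "DMN", "MFN")
        out = roi_followup(nm, meta, res)
        assert set(out["network"]) <= {"DMN", "MFN"}
        assert len(out) > 0


class TestReplication:
    def test_same_effect_replicates(self):
        rng = np.random.default_rng(14)
        effect = {("recruitment", "DMN", ""): -0.2}
        m_a, meta_a = synthetic_metric_frame(rng, 40, effect=effect)
        m_b, meta_b = synthetic_metric_frame(rng, 40, effect=effect)
        res_a = network_level_comparison(m_a, meta_a)
        rep = replication_run(res_a, m_b, meta_b)
        row = rep[(rep["metric_type"] == "recruitment")
                  & (rep["network_1"] == "DMN")].iloc[0]
        assert row["sign_agrees"] and row["replicated"]

    def test_null_cohort_does_not_replicate(self):
        rng = np.random.default_rng(15)
        effect = {("recruitment", "DMN", ""): -0.3}
        m_a, meta_a = synthetic_metric_frame(rng, 40, effect=effect)
        m_b, meta_b = synthetic_metric_frame(rng, 40)  # null
        res_a = network_level_comparison(m_a, meta_a)
        rep = replication_run(res_a, m_b, meta_b)
        assert not rep["replicated"].any()

    def test_no_discovery_significance_empty(self):
        rng = np.random.default_rng(16)
        m_a, meta_a = synthetic_metric_frame(rng, 10)
        res_a = network_level_comparison(m_a, meta_a)
        res_a["reject"] = False
        m_b, meta_b = synthetic_metric_frame(rng, 10)
        rep = replication_run(res_a, m_b, meta_b)
        assert rep.empty
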