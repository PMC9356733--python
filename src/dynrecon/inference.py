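"""Two-group network-level inference with FDR control.

The primary family is the 45 network-level coefficients (9 recruitment +
36 pairwise integration for a 9-network partition), compared between the
case and control groups with independent-sample t-tests and joint
Benjamini-Hochberg correction. ROI-level follow-up is run uncorrected at a
stricter per-test threshold, restricted to nodes of significant networks.
Age-stratified analysis repeats the network-level family within age bins;
a replication run re-tests, in an independent cohort, only the parameters
that were significant in the discovery cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgeBinning",
    "two_sample_t",
    "bh_fdr",
    "network_level_comparison",
    "roi_followup",
    "age_stratified_comparison",
    "replication_run",
]

RESULT_COLUMNS = [
    "metric_type", "network_1", "network_2", "t", "p", "q", "reject",
    "mean_case", "mean_control", "n_case", "n_control",
]


@dataclass(frozen=True)
class AgeBinning:
    """Ordered, non-overlapping age bins.

    ``edges = [7, 12, 18, 25]`` yields [7,12), [12,18), [18,25] — every bin
    half-open except the last, which is closed.
    """

    edges: tuple = (7.0, 12.0, 18.0, 25.0)

    def __post_init__(self):
        e = tuple(float(x) for x in self.edges)
        if len(e) < 2 or any(a >= b for a, b in zip(e, e[1:])):
            raise ValueError("edges must be strictly increasing, length >= 2")
        object.__setattr__(self, "edges", e)

    @property
    def labels(self) -> tuple:
        e = self.edges
        out = []
        for i in range(len(e) - 1):
            closer = "]" if i == len(e) - 2 else ")"
            out.append(f"[{e[i]:g},{e[i + 1]:g}{closer}")
        return tuple(out)

    def assign(self, ages) -> np.ndarray:
        """Bin index per age; -1 for ages outside every bin."""
        ages = np.asarray(ages, dtype=float)
        out = np.full(ages.shape, -1, dtype=int)
        e = self.edges
        for i in range(len(e) - 1):
            if i == len(e) - 2:
                mask = (ages >= e[i]) & (ages <= e[i + 1])
            else:
                mask = (ages >= e[i]) & (ages < e[i + 1])
            out[mask] = i
        return out


def two_sample_t(x, y, welch: bool = False):
    """Two-sided independent-sample t-test; pooled variance by default.

    Called as ``(case, control)``, t < 0 means the case mean is lower.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvals, q_threshold: float = 0.05):
    """Benjamini-Hochberg step-up.

    Returns ``(qvals, reject)`` with q_(i) = min_{j >= i} m * p_(j) / j.
    Rejection uses the canonical step-up boundary (q <= threshold, i.e.
    p_(i) <= i/m * threshold).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= q_threshold


def _wide_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy metric table to one row per (metric, networks) feature,
    one column per subject; errors name any subject missing a feature."""
    df = metrics.copy()
    df["network_2"] = df["network_2"].fillna("")
    wide = df.pivot_table(
        index=["metric_type", "network_1", "network_2"],
        columns="subject_id", values="value", aggfunc="first",
    )
    if wide.isna().any().any():
        na = wide.columns[wide.isna().any(axis=0)]
        feat = wide.index[wide.isna().any(axis=1)][0]
        raise ValueError(
            f"subject {na[0]!r} is missing metric {feat}"
        )
    return wide


def network_level_comparison(metrics: pd.DataFrame, meta: pd.DataFrame,
                             q_threshold: float = 0.05,
                             welch: bool = False) -> pd.DataFrame:
    """One t-test per network-level coefficient, BH-FDR across the family.

    ``metrics`` is the tidy table from :func:`dynrecon.metrics.metric_table`
    (possibly harmonized); ``meta`` must hold subject_id and group columns.
    """
    wide = _wide_metrics(metrics)
    groups = meta.set_index("subject_id")["group"]
    missing = [s for s in wide.columns if s not in groups.index]
    if missing:
        raise ValueError(f"subjects without metadata: {missing}")
    case_ids = [s for s in wide.columns if groups[s] == "case"]
    ctrl_ids = [s for s in wide.columns if groups[s] == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("both groups need n >= 2")
    rows = []
    for (mtype, n1, n2), vals in wide.iterrows():
        x = vals[case_ids].to_numpy(dtype=float)
        y = vals[ctrl_ids].to_numpy(dtype=float)
        t, p = two_sample_t(x, y, welch=welch)
        rows.append([mtype, n1, n2, t, p, np.nan, False,
                     x.mean(), y.mean(), len(case_ids), len(ctrl_ids)])
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    q, reject = bh_fdr(out["p"].to_numpy(), q_threshold)
    out["q"], out["reject"] = q, reject
    return out


def roi_followup(node_metrics: pd.DataFrame, meta: pd.DataFrame,
                 results: pd.DataFrame, p_threshold: float = 0.001,
                 welch: bool = False) -> pd.DataFrame:
    """Per-node t-tests within significant networks/pairs (uncorrected).

    For a significant recruitment coefficient, node recruitment of that
    network's members is tested; for a significant integration pair, node
    integration of both networks' members. Returns only nodes with
    p < ``p_threshold``. Empty when nothing was significant.
    """
    sig = results[results["reject"]]
    cols = ["metric_type", "network", "node_id", "t", "p",
            "mean_case", "mean_control"]
    if sig.empty:
        return pd.DataFrame(columns=cols)
    groups = meta.set_index("subject_id")["group"]
    targets = []  # (metric_type, network)
    for _, row in sig.iterrows():
        if row["metric_type"] == "recruitment":
            targets.append(("recruitment", row["network_1"]))
        else:
            targets.append(("integration", row["network_1"]))
            targets.append(("integration", row["network_2"]))
    rows = []
    seen = set()
    for mtype, net in targets:
        if (mtype, net) in seen:
            continue
        seen.add((mtype, net))
        sub = node_metrics[(node_metrics["metric_type"] == mtype)
                           & (node_metrics["network"] == net)]
        for node, nd in sub.groupby("node_id", sort=True):
            by = nd.set_index("subject_id")["value"]
            x = by[[s for s in by.index if groups[s] == "case"]].to_numpy()
            y = by[[s for s in by.index if groups[s] == "control"]].to_numpy()
            t, p = two_sample_t(x, y, welch=welch)
            if p < p_threshold:
                rows.append([mtype, net, node, t, p, x.mean(), y.mean()])
    return pd.DataFrame(rows, columns=cols)


def age_stratified_comparison(metrics: pd.DataFrame, meta: pd.DataFrame,
                              bins: AgeBinning | None = None,
                              q_threshold: float = 0.05,
                              welch: bool = False) -> dict:
    """Run the network-level family independently within each age bin.

    Bins with fewer than 2 subjects in either group are skipped with a
    warning; if no bin is testable an error is raised. Returns a dict
    mapping bin label -> result table.
    """
    bins = bins or AgeBinning()
    idx = bins.assign(meta["age"].to_numpy())
    out = {}
    for i, label in enumerate(bins.labels):
        sub_meta = meta[idx == i]
        counts = sub_meta["group"].value_counts()
        if counts.get("case", 0) < 2 or counts.get("control", 0) < 2:
            warnings.warn(f"age bin {label} under-filled; skipped",
                          stacklevel=2)
            continue
        sub_metrics = metrics[metrics["subject_id"].isin(sub_meta["subject_id"])]
        out[label] = network_level_comparison(
            sub_metrics, sub_meta, q_threshold=q_threshold, welch=welch)
    if not out:
        raise ValueError("no age bin has >= 2 subjects per group")
    return out


def replication_run(results_a: pd.DataFrame, metrics_b: pd.DataFrame,
                    meta_b: pd.DataFrame, q_threshold: float = 0.05,
                    welch: bool = False) -> pd.DataFrame:
    """Re-test cohort A's significant parameters in independent cohort B.

    BH-FDR is applied within the re-tested family only. ``replicated`` is
    true when the cohort-B effect has the same sign and survives FDR.
    Empty result when A had no significant parameters.
    """
    sig = results_a[results_a["reject"]]
    cols = ["metric_type", "network_1", "network_2", "t_discovery",
            "t", "p", "q", "sign_agrees", "replicated"]
    if sig.empty:
        return pd.DataFrame(columns=cols)
    full_b = network_level_comparison(metrics_b, meta_b,
                                      q_threshold=q_threshold, welch=welch)
    key = ["metric_type", "network_1", "network_2"]
    merged = sig[key + ["t"]].rename(columns={"t": "t_discovery"}).merge(
        full_b[key + ["t", "p"]], on=key, how="left", validate="1:1")
    if merged["t"].isna().any():
        raise ValueError(
            "cohort B metrics lack parameters tested in cohort A; "
            "replication requires identical configuration"
        )
    q, reject = bh_fdr(merged["p"].to_numpy(), q_threshold)
    merged["q"] = q
    merged["sign_agrees"] = np.sign(merged["t"]) == np.sign(merged["t_discovery"])
    merged["replicated"] = merged["sign_agrees"] & reject
    return merged[cols]
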