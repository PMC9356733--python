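"""File formats, run configuration, and end-to-end pipeline orchestration.

Everything on disk is plain delimited text (CSV) or JSON. A run writes a
manifest recording the configuration, package version, SHA-256 checksums of
stage outputs, and the master seed, which is also used to resume a run
whose earlier stages are already on disk.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import AllegianceMatrix, ModularityParams, consensus_allegiance
from .harmonize import BatchDesign, combat_adjust
from .inference import (AgeBinning, age_stratified_comparison,
                        network_level_comparison, roi_followup)
from .metrics import metric_table, node_metric_table
from .network import make_windows, window_connectivity
from .partition import NodePartition, from_frame
from .synthetic import SubjectRecord

__all__ = [
    "RunConfig", "read_timeseries", "write_timeseries", "read_partition",
    "write_partition", "write_cohort", "read_cohort", "read_metrics",
    "write_metrics", "run_pipeline",
]


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration; defaults follow the reference protocol:
    window length 20 with 50 % overlap, gamma 1, omega 0.4, 100 optimizer
    runs, q < 0.05 network-level FDR, ROI p < 0.001 uncorrected."""

    window_length: int = 20
    window_step: int = 10
    gamma: float = 1.0
    omega: float = 0.4
    n_runs: int = 100
    seed: int = 0
    q_threshold: float = 0.05
    roi_p_threshold: float = 0.001
    age_bins: tuple = (7.0, 12.0, 18.0, 25.0)
    harmonize: bool = True
    harmonize_age: bool = False
    welch: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_bins"] = list(self.age_bins)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "age_bins" in d:
            d["age_bins"] = tuple(float(x) for x in d["age_bins"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


# ---------------------------------------------------------------------------
# readers / writers

def write_timeseries(path, ts: np.ndarray, node_ids) -> None:
    pd.DataFrame(ts, columns=list(node_ids)).to_csv(path, index=False)


def read_timeseries(path, partition: NodePartition | None = None):
    """Read a T x K delimited time-series file.

    Returns ``(matrix, node_ids)``. With a partition, columns are reordered
    to the partition's analysed-node order; mismatched node sets raise with
    the difference listed.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    ids = [h.strip() for h in header]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate node ids in header")
    df = pd.read_csv(path)
    df.columns = ids  # undo pandas' mangling of any odd header strings
    try:
        mat = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise ValueError(f"{path}: non-numeric cell in body ({e})") from None
    if np.isnan(mat).any():
        raise ValueError(f"{path}: missing values in body")
    if partition is not None:
        want, have = set(partition.nodes), set(ids)
        if want - have:
            raise ValueError(f"{path}: nodes missing from file: {sorted(want - have)}")
        extra = have - set(partition.node_ids)
        if extra:
            raise ValueError(f"{path}: nodes absent from partition: {sorted(extra)}")
        df = df[list(partition.nodes)]
        mat = df.to_numpy(dtype=float)
        ids = list(partition.nodes)
    return mat, tuple(ids)


def write_partition(path, part: NodePartition) -> None:
    part.to_frame().to_csv(path, index=False)


def read_partition(path) -> NodePartition:
    return from_frame(pd.read_csv(path))


def write_cohort(out_dir, subjects, truths=None,
                 partition: NodePartition | None = None) -> None:
    """Write per-subject series, the metadata table, and optional sidecars."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    meta = []
    for s in subjects:
        write_timeseries(out / "timeseries" / f"{s.subject_id}.csv",
                         s.timeseries,
                         partition.nodes if partition else
                         [f"n{i + 1:03d}" for i in range(s.timeseries.shape[1])])
        meta.append((s.subject_id, s.group, s.site, s.age))
    pd.DataFrame(meta, columns=["subject_id", "group", "site", "age"]).to_csv(
        out / "meta.csv", index=False)
    if partition is not None:
        write_partition(out / "partition.csv", partition)
    if truths is not None:
        gt = {
            s.subject_id: {
                "state_of_timepoint": t.state_of_timepoint.tolist(),
                "community_of": t.community_of.tolist(),
            }
            for s, t in zip(subjects, truths)
        }
        (out / "ground_truth.json").write_text(json.dumps(gt))


def read_cohort(cohort_dir, partition: NodePartition | None = None):
    """Read a cohort directory written by :func:`write_cohort`.

    Returns ``(subjects, meta_frame, partition)``.
    """
    d = Path(cohort_dir)
    meta = pd.read_csv(d / "meta.csv")
    if partition is None and (d / "partition.csv").exists():
        partition = read_partition(d / "partition.csv")
    subjects = []
    for row in meta.itertuples(index=False):
        ts, _ = read_timeseries(d / "timeseries" / f"{row.subject_id}.csv",
                                partition)
        subjects.append(SubjectRecord(subject_id=row.subject_id,
                                      group=row.group, site=str(row.site),
                                      age=float(row.age), timeseries=ts))
    return subjects, meta, partition


def write_metrics(path, metrics: pd.DataFrame) -> None:
    metrics.to_csv(path, index=False)


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    df["value"] = pd.to_numeric(df["value"])
    return df


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# harmonization on tidy metric tables

def _tidy_to_matrix(metrics: pd.DataFrame, id_cols):
    wide = metrics.pivot_table(index=id_cols, columns="subject_id",
                               values="value", aggfunc="first")
    if wide.isna().any().any():
        raise ValueError("metric table has missing subject/feature cells")
    return wide


def harmonize_metrics(metrics: pd.DataFrame, meta: pd.DataFrame,
                      id_cols, with_age: bool = False) -> pd.DataFrame:
    """ComBat-adjust a tidy metric table across sites, preserving diagnosis
    (and optionally age). Returns a tidy table of the same shape."""
    wide = _tidy_to_matrix(metrics, id_cols)
    m = meta.set_index("subject_id").loc[list(wide.columns)]
    if m["site"].nunique() < 2:
        warnings.warn("single site: harmonization skipped", stacklevel=2)
        return metrics.copy()
    design = BatchDesign(batch=tuple(str(x) for x in m["site"]),
                         diagnosis=tuple(m["group"]),
                         age=tuple(float(a) for a in m["age"]) if with_age
                         else None)
    adjusted = combat_adjust(wide.to_numpy(), design)
    out = pd.DataFrame(adjusted, index=wide.index, columns=wide.columns)
    tidy = out.stack().rename("value").reset_index()
    tidy = tidy.rename(columns={"level_%d" % len(id_cols): "subject_id"})
    cols = ["subject_id"] + list(id_cols) + ["value"]
    return tidy[cols]


# ---------------------------------------------------------------------------
# orchestration

STAGES = ("metrics", "harmonize", "compare")


def compute_subject_metrics(subjects, partition: NodePartition,
                            config: RunConfig, progress=None):
    """Stages construct -> detect -> metrics for a list of subjects.

    Returns ``(network_metrics, node_metrics)`` tidy tables. The optimizer
    sub-stream for each subject is keyed by its rank in the sorted id list,
    so results do not depend on subject order.
    """
    params = ModularityParams(gamma=config.gamma, omega=config.omega,
                              n_runs=config.n_runs, seed=config.seed)
    order = {sid: k for k, sid in
             enumerate(sorted(s.subject_id for s in subjects))}
    net_rows, node_rows = [], []
    for s in subjects:
        scheme = make_windows(s.timeseries.shape[0], config.window_length,
                              config.window_step)
        net = window_connectivity(s.timeseries, scheme,
                                  node_ids=partition.nodes)
        P = consensus_allegiance(net, params, subject_tag=order[s.subject_id])
        net_rows.append(metric_table(s.subject_id, P, partition))
        node_rows.append(node_metric_table(s.subject_id, P, partition))
        if progress is not None:
            progress(s.subject_id)
    return (pd.concat(net_rows, ignore_index=True),
            pd.concat(node_rows, ignore_index=True))


def run_pipeline(config: RunConfig, cohort_dir, out_dir,
                 partition: NodePartition | None = None) -> dict:
    """Full analysis: construct, detect, metrics, harmonize, compare.

    Emits metrics tables, the 45-row comparison table, ROI follow-up,
    age-stratified tables, and a manifest. If a metrics file from a previous
    run with the same configuration digest is present, the detection stage
    is skipped (checksum-verified resume).

    Returns a dict with the in-memory results and output paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, meta, partition = read_cohort(cohort_dir, partition)
    if partition is None:
        raise ValueError("no partition: provide partition.csv or an argument")

    manifest_path = out / "manifest.json"
    metrics_path = out / "metrics_raw.csv"
    node_metrics_path = out / "node_metrics_raw.csv"
    digest = config.digest()

    resumed = False
    if manifest_path.exists() and metrics_path.exists():
        old = json.loads(manifest_path.read_text())
        if (old.get("config_digest") == digest
                and old.get("checksums", {}).get("metrics_raw.csv")
                == _sha256(metrics_path)):
            metrics = read_metrics(metrics_path)
            node_metrics = read_metrics(node_metrics_path)
            resumed = True
    if not resumed:
        metrics, node_metrics = compute_subject_metrics(subjects, partition,
                                                        config)
        write_metrics(metrics_path, metrics)
        write_metrics(node_metrics_path, node_metrics)

    if config.harmonize:
        metrics_h = harmonize_metrics(
            metrics, meta, ["metric_type", "network_1", "network_2"],
            with_age=config.harmonize_age)
        node_metrics_h = harmonize_metrics(
            node_metrics, meta, ["metric_type", "node_id", "network"],
            with_age=config.harmonize_age)
    else:
        metrics_h, node_metrics_h = metrics, node_metrics
    write_metrics(out / "metrics_harmonized.csv", metrics_h)

    results = network_level_comparison(metrics_h, meta,
                                       q_threshold=config.q_threshold,
                                       welch=config.welch)
    results.to_csv(out / "results.csv", index=False)
    roi = roi_followup(node_metrics_h, meta, results,
                       p_threshold=config.roi_p_threshold,
                       welch=config.welch)
    roi.to_csv(out / "roi_results.csv", index=False)

    age_results = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            age_results = age_stratified_comparison(
                metrics_h, meta, AgeBinning(config.age_bins),
                q_threshold=config.q_threshold, welch=config.welch)
        except ValueError:
            age_results = {}
    for label, table in age_results.items():
        safe = label.replace("[", "").replace("]", "").replace(",", "-")
        table.to_csv(out / f"results_age_{safe}.csv", index=False)

    outputs = sorted(p.name for p in out.glob("*.csv"))
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_digest": digest,
        "seed": config.seed,
        "n_subjects": len(subjects),
        "resumed_detection": resumed,
        "checksums": {name: _sha256(out / name) for name in outputs},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "metrics": metrics, "metrics_harmonized": metrics_h,
        "node_metrics": node_metrics_h, "results": results, "roi": roi,
        "age_results": age_results, "out_dir": out, "meta": meta,
        "manifest": manifest,
    }
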