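"""Synthetic multi-site, two-group cohorts with planted community dynamics.

Time series are piecewise-stationary: time is divided into equal-length
latent states. Within a state every node belongs to one latent community
(its home network, unless it "detaches" for that state), and nodes sharing
a community mix a common latent signal so their pairwise correlation is
approximately ``rho_in``. Group differences are planted through
group/network-specific detachment probabilities; site effects are per-node
affine perturbations (mean shift + variance scaling) of the raw signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .partition import NodePartition, demo_partition

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "GroundTruth",
    "generate_subject",
    "generate_cohort",
    "default_spec",
    "coassignment_frequency",
]

GROUPS = ("case", "control")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters for cohort generation. See module docstring for semantics."""

    n_per_group: int = 20
    n_sites: int = 2
    T: int = 200
    partition: NodePartition = field(default_factory=demo_partition)
    state_length: int = 40
    rho_in: float = 0.9
    p_detach: dict = field(default_factory=dict)  # (group, network) -> prob
    site_shift: float = 0.5
    site_scale: float = 0.15
    noise_sd: float = 0.1
    age_range: dict = field(default_factory=lambda: {"case": (8.0, 25.0),
                                                     "control": (8.0, 25.0)})
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.rho_in <= 1.0):
            raise ValueError("rho_in must lie in [0, 1]")
        for key, p in self.p_detach.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p_detach{key} = {p} outside [0, 1]")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 for group inference")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.T % self.state_length != 0 or self.T // self.state_length < 2:
            raise ValueError(
                f"T={self.T} must divide into >= 2 states of length "
                f"{self.state_length}"
            )
        if self.noise_sd < 0 or self.site_scale < 0:
            raise ValueError("noise_sd and site_scale must be non-negative")

    @property
    def n_states(self) -> int:
        return self.T // self.state_length

    def detach_prob(self, group: str, network: str) -> float:
        return float(self.p_detach.get((group, network), 0.0))


def default_spec(**overrides) -> CohortSpec:
    """Cohort spec with the default planted effect: cases detach from the
    DMN- and BGN-like networks far more often than controls."""
    p = {(g, net): 0.05 for g in GROUPS
         for net in demo_partition().networks}
    p[("case", "DMN")] = 0.40
    p[("control", "DMN")] = 0.05
    p[("case", "BGN")] = 0.35
    p[("control", "BGN")] = 0.05
    base = dict(p_detach=p)
    base.update(overrides)
    return CohortSpec(**base)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    site: str
    age: float
    timeseries: np.ndarray  # T x K

    def __post_init__(self):
        ts = np.asarray(self.timeseries, dtype=float)
        if ts.ndim != 2:
            raise ValueError("timeseries must be a T x K matrix")
        if not np.isfinite(ts).all():
            raise ValueError("timeseries contains non-finite values")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")


@dataclass(frozen=True)
class GroundTruth:
    """Latent community structure behind one subject's time series."""

    state_of_timepoint: np.ndarray  # length T, state index per timepoint
    community_of: np.ndarray        # n_states x K integer community labels

    def __post_init__(self):
        if self.community_of.ndim != 2:
            raise ValueError("community_of must be n_states x K")


def coassignment_frequency(gt: GroundTruth, idx: np.ndarray) -> float:
    """Fraction of (state, pair) combinations within ``idx`` sharing a latent
    community — an estimation-noise-free analogue of network recruitment."""
    idx = np.asarray(idx)
    if idx.size < 2:
        raise ValueError("need at least two nodes")
    labs = gt.community_of[:, idx]  # S x m
    same = labs[:, :, None] == labs[:, None, :]
    m = idx.size
    off = (same.sum() - labs.shape[0] * m) / (labs.shape[0] * m * (m - 1))
    return float(off)


def _site_params(spec: CohortSpec, site_index: int, K: int):
    """Per-node affine perturbation shared by all subjects of one site.

    Deterministic in (spec.seed, site_index) so a site is a coherent batch.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 7301, int(site_index)])
    )
    shift = rng.normal(0.0, spec.site_shift, size=K)
    scale = np.exp(rng.normal(0.0, spec.site_scale, size=K))
    return shift, scale


def generate_subject(spec: CohortSpec, group: str, site_index: int,
                     rng: np.random.Generator):
    """Generate one subject's time series and its ground truth.

    Returns ``(timeseries, GroundTruth)`` where timeseries is T x K.
    Community labels: 0..8 are the home networks (in partition order);
    a detached node adopts a uniformly chosen *foreign* home label for
    the whole state.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    part = spec.partition
    K = part.n_nodes
    home = part.labels_array()
    n_net = len(part.networks)
    S, L = spec.n_states, spec.state_length

    community_of = np.empty((S, K), dtype=np.intp)
    ts = np.empty((spec.T, K), dtype=float)
    p_by_node = np.array(
        [spec.detach_prob(group, part.network_of[n]) for n in part.nodes]
    )
    for s in range(S):
        labels = home.copy()
        detach = rng.random(K) < p_by_node
        for i in np.flatnonzero(detach):
            foreign = [c for c in range(n_net) if c != home[i]]
            labels[i] = foreign[rng.integers(len(foreign))]
        community_of[s] = labels
        common = rng.standard_normal((n_net, L))
        idio = rng.standard_normal((L, K))
        block = (np.sqrt(spec.rho_in) * common[labels].T
                 + np.sqrt(1.0 - spec.rho_in) * idio)
        ts[s * L:(s + 1) * L] = block
    if spec.noise_sd > 0:
        ts += spec.noise_sd * rng.standard_normal(ts.shape)
    shift, scale = _site_params(spec, site_index, K)
    ts = ts * scale + shift
    gt = GroundTruth(
        state_of_timepoint=np.repeat(np.arange(S), L),
        community_of=community_of,
    )
    return ts, gt


def generate_cohort(spec: CohortSpec):
    """Generate a full two-group cohort.

    Sites are balanced within each group (subject ``i`` of a group goes to
    site ``i mod n_sites``). Deterministic for a fixed spec (seeded by
    ``spec.seed``).

    Returns ``(subjects, truths)`` — parallel lists of :class:`SubjectRecord`
    and :class:`GroundTruth`.
    """
    ss = np.random.SeedSequence([int(spec.seed), 101])
    children = ss.spawn(2 * spec.n_per_group)
    subjects, truths = [], []
    k = 0
    for group in GROUPS:
        lo, hi = spec.age_range[group]
        for i in range(spec.n_per_group):
            rng = np.random.default_rng(children[k])
            site_index = i % spec.n_sites
            age = float(rng.uniform(lo, hi))
            ts, gt = generate_subject(spec, group, site_index, rng)
            subjects.append(SubjectRecord(
                subject_id=f"sub-{k + 1:04d}",
                group=group,
                site=f"site{site_index + 1}",
                age=age,
                timeseries=ts,
            ))
            truths.append(gt)
            k += 1
    return subjects, truths
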