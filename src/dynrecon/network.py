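"""Sliding-window connectivity: from one time series to a multilayer network.

Each layer is the pairwise Pearson correlation matrix of one time window,
with negative entries set to zero and a zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WindowScheme", "MultilayerNetwork", "make_windows",
           "window_connectivity"]

DEFAULT_WINDOW_LENGTH = 20
DEFAULT_WINDOW_STEP = 10  # 50 % overlap


@dataclass(frozen=True)
class WindowScheme:
    """Ordered, equal-length, 0-based half-open windows over ``T`` timepoints."""

    length: int
    step: int
    windows: tuple  # of (start, end)

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass(frozen=True)
class MultilayerNetwork:
    """Ordered stack of symmetric non-negative K x K connectivity layers."""

    layers: np.ndarray  # L x K x K
    scheme: WindowScheme | None = None
    node_ids: tuple | None = None

    def __post_init__(self):
        a = np.asarray(self.layers, dtype=float)
        if a.ndim != 3 or a.shape[1] != a.shape[2]:
            raise ValueError("layers must be an L x K x K array")
        object.__setattr__(self, "layers", a)

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]


def make_windows(T: int, length: int = DEFAULT_WINDOW_LENGTH,
                 step: int | None = None) -> WindowScheme:
    """Sliding windows starting at 0, step, 2*step, ...

    Trailing timepoints not covered by a full window are dropped. The
    default step is ``length // 2`` (50 % overlap).
    """
    if step is None:
        step = length // 2
    if length < 1 or step < 1:
        raise ValueError("length and step must be >= 1")
    if T < length:
        raise ValueError(
            f"time series too short: T={T} < window length {length}"
        )
    n = (T - length) // step + 1
    windows = tuple((k * step, k * step + length) for k in range(n))
    return WindowScheme(length=length, step=step, windows=windows)


def window_connectivity(ts: np.ndarray, scheme: WindowScheme,
                        node_ids: tuple | None = None) -> MultilayerNetwork:
    """Per-window Pearson correlation with negatives zeroed and zero diagonal.

    Raises
    ------
    ValueError
        If the series contains non-finite values, or a node has zero
        variance within some window (the error names both).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("ts must be a T x K matrix")
    if not np.isfinite(ts).all():
        raise ValueError("time series contains missing/non-finite values")
    T, K = ts.shape
    if scheme.windows and scheme.windows[-1][1] > T:
        raise ValueError("window scheme extends past the end of the series")
    layers = np.empty((scheme.n_windows, K, K), dtype=float)
    for w, (start, end) in enumerate(scheme.windows):
        seg = ts[start:end]
        sd = seg.std(axis=0)
        bad = np.flatnonzero(sd == 0.0)
        if bad.size:
            name = node_ids[bad[0]] if node_ids is not None else f"column {bad[0]}"
            raise ValueError(
                f"zero variance in window {w} [{start},{end}) for node {name}"
            )
        r = np.corrcoef(seg, rowvar=False)
        r = (r + r.T) / 2.0  # enforce exact symmetry (fp round-off)
        np.maximum(r, 0.0, out=r)
        np.fill_diagonal(r, 0.0)
        layers[w] = r
    return MultilayerNetwork(layers=layers, scheme=scheme, node_ids=node_ids)
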