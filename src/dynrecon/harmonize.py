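"""Parametric empirical-Bayes batch harmonization (ComBat).

Removes per-batch location and scale effects from a features x subjects
matrix while preserving designated biological covariates (by default the
diagnosis indicator alone). Per-batch, per-feature location estimates get a
normal prior and scale estimates an inverse-gamma prior; hyperparameters
come from the method of moments and the conditional posterior is solved
iteratively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BatchDesign", "combat_adjust", "CombatFit"]


@dataclass(frozen=True)
class BatchDesign:
    """Site labels plus biological covariates to preserve."""

    batch: tuple  # site label per subject
    diagnosis: tuple  # group label per subject (biological covariate)
    age: tuple | None = None  # optional second covariate

    def __post_init__(self):
        if len(self.batch) != len(self.diagnosis):
            raise ValueError("batch and diagnosis must have equal length")
        if self.age is not None and len(self.age) != len(self.batch):
            raise ValueError("age must match batch length")
        counts = pd.Series(self.batch).value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"batch(es) with a single subject: {small}")
        # warn when a batch holds only one diagnostic group (confounding risk)
        df = pd.DataFrame({"b": self.batch, "d": self.diagnosis})
        for b, sub in df.groupby("b"):
            if sub["d"].nunique() < 2:
                warnings.warn(
                    f"batch {b!r} contains a single diagnostic group; "
                    "batch and diagnosis effects may be confounded",
                    stacklevel=2,
                )

    @property
    def n_subjects(self) -> int:
        return len(self.batch)


@dataclass(frozen=True)
class CombatFit:
    """Diagnostics from one adjustment (per-batch EB estimates)."""

    batches: tuple
    gamma_hat: np.ndarray   # raw standardized batch locations (batch x feature)
    gamma_star: np.ndarray  # shrunken locations
    gamma_bar: np.ndarray   # prior means per batch
    delta2_hat: np.ndarray
    delta2_star: np.ndarray
    constant_features: np.ndarray = field(default=None)


def _design_matrix(design: BatchDesign):
    batches = tuple(pd.unique(np.asarray(design.batch)))
    n = design.n_subjects
    Xb = np.zeros((n, len(batches)))
    for j, b in enumerate(batches):
        Xb[[i for i, x in enumerate(design.batch) if x == b], j] = 1.0
    groups = sorted(set(design.diagnosis))
    cov_cols = []
    for g in groups[1:]:  # reference coding on the first group
        cov_cols.append(np.array([1.0 if d == g else 0.0
                                  for d in design.diagnosis]))
    if design.age is not None:
        age = np.asarray(design.age, dtype=float)
        cov_cols.append(age - age.mean())
    Xc = np.column_stack(cov_cols) if cov_cols else np.zeros((n, 0))
    return batches, Xb, Xc


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum_sq, n, a, b):
    return (0.5 * sum_sq + b) / (n / 2.0 + a - 1.0)


def _aprior(d2):
    # zero dispersion -> inverse-gamma prior degenerate at the mean; a large
    # finite concentration keeps the iterative solution well defined
    m, s2 = d2.mean(), d2.var(ddof=1) if d2.size > 1 else 0.0
    if s2 <= 1e-12 * max(m * m, 1e-300):
        return 1e9
    return (2.0 * s2 + m ** 2) / s2


def _bprior(d2):
    m, s2 = d2.mean(), d2.var(ddof=1) if d2.size > 1 else 0.0
    if s2 <= 1e-12 * max(m * m, 1e-300):
        return (1e9 - 1.0) * m
    return (m * s2 + m ** 3) / s2


def _it_sol(Z_b, g_hat, d2_hat, g_bar, t2, a, b, tol=1e-4, max_iter=100):
    """Iterative conditional solution of the EB posteriors for one batch."""
    n = Z_b.shape[1]
    g_old, d_old = g_hat.copy(), d2_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum_sq = ((Z_b - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum_sq, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / np.maximum(np.abs(g_old), 1e-12).max(),
            np.abs(d_new - d_old).max() / np.maximum(np.abs(d_old), 1e-12).max(),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def combat_adjust(data: np.ndarray, design: BatchDesign,
                  return_fit: bool = False):
    """Harmonize a features x subjects matrix across batches.

    Returns the adjusted matrix (same shape); with ``return_fit=True``
    returns ``(adjusted, CombatFit)``. Constant features pass through with
    a warning; a single batch returns the input unchanged with a warning.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be features x subjects")
    if data.shape[1] != design.n_subjects:
        raise ValueError("data column count must equal number of subjects")
    if not np.isfinite(data).all():
        raise ValueError("data contains missing/non-finite values")

    batches, Xb, Xc = _design_matrix(design)
    if len(batches) < 2:
        warnings.warn("single batch: nothing to harmonize", stacklevel=2)
        return (data.copy(), None) if return_fit else data.copy()

    G, n = data.shape
    const = data.std(axis=1) == 0.0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant feature(s) passed through unadjusted",
            stacklevel=2,
        )
    work = data[~const]

    X = np.hstack([Xb, Xc])
    beta = np.linalg.solve(X.T @ X, X.T @ work.T)   # (p, G')
    n_b = Xb.sum(axis=0)
    grand = (n_b / n) @ beta[:len(batches)]         # weighted grand mean
    cov_part = (Xc @ beta[len(batches):]).T if Xc.shape[1] else 0.0
    fitted = (X @ beta).T
    var_pooled = ((work - fitted) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-24)
    sd = np.sqrt(var_pooled)[:, None]
    Z = (work - (grand[:, None] + cov_part)) / sd

    gamma_hat = np.empty((len(batches), work.shape[0]))
    delta2_hat = np.empty_like(gamma_hat)
    members = []
    for j, b in enumerate(batches):
        cols = np.flatnonzero(Xb[:, j] == 1.0)
        members.append(cols)
        gamma_hat[j] = Z[:, cols].mean(axis=1)
        # ddof=0 matches the 1/n pooled variance, so statistically identical
        # batches give delta2_hat = 1 exactly (a fixed point of adjustment)
        delta2_hat[j] = Z[:, cols].var(axis=1, ddof=0)

    gamma_bar = gamma_hat.mean(axis=1)        # prior mean per batch
    if work.shape[0] > 1:
        tau2 = gamma_hat.var(axis=1, ddof=1)  # prior variance per batch
    else:
        tau2 = np.full(len(batches), 1e12)    # one feature: no shrinkage
    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    for j in range(len(batches)):
        a, b_ = _aprior(delta2_hat[j]), _bprior(delta2_hat[j])
        g, d = _it_sol(Z[:, members[j]], gamma_hat[j], delta2_hat[j],
                       gamma_bar[j], tau2[j], a, b_)
        gamma_star[j], delta2_star[j] = g, d

    adjusted_work = Z.copy()
    for j in range(len(batches)):
        cols = members[j]
        adjusted_work[:, cols] = (
            (Z[:, cols] - gamma_star[j][:, None])
            / np.sqrt(np.maximum(delta2_star[j], 1e-24))[:, None]
        )
    adjusted_work = adjusted_work * sd + grand[:, None] + cov_part

    out = data.copy()
    out[~const] = adjusted_work
    if return_fit:
        fit = CombatFit(batches=batches, gamma_hat=gamma_hat,
                        gamma_star=gamma_star,
                        gamma_bar=gamma_bar, delta2_hat=delta2_hat,
                        delta2_star=delta2_star, constant_features=const)
        return out, fit
    return out
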