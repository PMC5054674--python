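"""Permutation-based group inference and correlation utilities.

Group differences are tested with permutation ANOVA / MANOVA using an
R-squared effect size: the between-group sum of squares (for MANOVA, the
trace of the between-group cross-product on the Euclidean embedding — a
Goodall-type statistic, the morphometric convention) over the total sum
of squares. P-values are the standard permutation estimate
``(1 + #{permuted R2 >= observed}) / (1 + n_perm)``, so the smallest
attainable p is ``1/(n_perm + 1)``. All tests are seeded and exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal
import warnings

import numpy as np
from scipy import stats as sps

from .errors import InvalidDesignError

__all__ = [
    "PermTestResult",
    "perm_anova",
    "perm_manova",
    "spearman",
    "mean_centered_correlation",
    "benjamini_hochberg",
]

DEFAULT_N_PERM = 999


@dataclass
class PermTestResult:
    """Effect size and permutation p-value of one group test."""

    r_squared: float
    p_value: float
    n_perm: int
    kind: Literal["univariate", "multivariate"]


def _prepare(Y: np.ndarray, groups) -> tuple[np.ndarray, np.ndarray]:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    labels = np.asarray(groups)
    uniq, inv = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise InvalidDesignError("group testing needs at least 2 groups")
    counts = np.bincount(inv)
    if np.any(counts < 2):
        raise InvalidDesignError("every group needs at least 2 observations")
    if Y.shape[0] != labels.shape[0]:
        raise InvalidDesignError("response and group label lengths differ")
    return Y, inv


def _r2_trace(Y: np.ndarray, inv: np.ndarray) -> float:
    """trace(between-group SSCP) / trace(total SSCP)."""
    grand = Y.mean(axis=0)
    sst = float(((Y - grand) ** 2).sum())
    if sst == 0:
        raise InvalidDesignError("constant response: R-squared undefined")
    ssb = 0.0
    for g in range(inv.max() + 1):
        m = Y[inv == g].mean(axis=0)
        ssb += (inv == g).sum() * float(((m - grand) ** 2).sum())
    return ssb / sst


def _permuted_r2(Y: np.ndarray, inv: np.ndarray, n_perm: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Vectorized permuted R2 values (binary fast path, generic fallback)."""
    n = Y.shape[0]
    grand = Y.mean(axis=0)
    sst = float(((Y - grand) ** 2).sum())
    n_groups = inv.max() + 1
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    if n_groups == 2:
        n1 = int(inv.sum())
        n0 = n - n1
        mask = inv[perm_idx].astype(bool)          # (n_perm, n)
        tot = Y.sum(axis=0)
        s1 = mask.astype(float) @ Y                # (n_perm, p)
        m1 = s1 / n1
        m0 = (tot - s1) / n0
        ssb = n1 * ((m1 - grand) ** 2).sum(axis=1) + n0 * ((m0 - grand) ** 2).sum(axis=1)
        return ssb / sst
    out = np.empty(n_perm)
    for b in range(n_perm):
        out[b] = _r2_trace(Y, inv[perm_idx[b]])
    return out


def _perm_test(Y, groups, n_perm, seed, kind) -> PermTestResult:
    Y, inv = _prepare(Y, groups)
    observed = _r2_trace(Y, inv)
    rng = np.random.default_rng(seed)
    perm = _permuted_r2(Y, inv, n_perm, rng)
    p = (1.0 + np.count_nonzero(perm >= observed - 1e-12)) / (1.0 + n_perm)
    return PermTestResult(r_squared=observed, p_value=p, n_perm=n_perm, kind=kind)


def perm_anova(y, groups, n_perm: int = DEFAULT_N_PERM,
               seed: int | None = 0) -> PermTestResult:
    """Univariate permutation ANOVA with R-squared effect size.

    For two groups the R-squared equals the squared point-biserial
    correlation between the response and the group indicator.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise InvalidDesignError("perm_anova expects a scalar response")
    return _perm_test(y, groups, n_perm, seed, "univariate")


def perm_manova(Y, groups, n_perm: int = DEFAULT_N_PERM,
                seed: int | None = 0) -> PermTestResult:
    """Permutation MANOVA with trace-based (Goodall-type) multivariate R-squared.

    With a single response column this reduces exactly to
    :func:`perm_anova`.
    """
    return _perm_test(Y, groups, n_perm, seed, "multivariate")


def spearman(x, y, n_perm: int = DEFAULT_N_PERM,
             seed: int | None = 0) -> tuple[float, float]:
    """Spearman rank correlation with a seeded permutation p-value.

    Ties get midranks. The permutation p (two-sided, on |rho|) is exact in
    expectation at small n where the t-approximation misbehaves.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0] or x.shape[0] < 4:
        raise InvalidDesignError("spearman needs matched samples with n >= 4")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.linalg.norm(rxc) * np.linalg.norm(ryc)
    if denom == 0:
        raise InvalidDesignError("constant input: rho undefined")
    rho = float(rxc @ ryc / denom)
    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_perm, x.shape[0])), axis=1)
    rho_perm = (ryc[perm_idx] @ rxc) / denom
    p = (1.0 + np.count_nonzero(np.abs(rho_perm) >= abs(rho) - 1e-12)) / (1.0 + n_perm)
    return rho, p


def mean_centered_correlation(x, y, subjects) -> float:
    """Within-subject (per-individual mean-centered) correlation.

    Each subject's series of ``x`` and ``y`` is centered on its own mean
    before pooling, so stable between-subject level differences cannot
    inflate the correlation: what remains is the within-cycle association.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    if not (x.shape == y.shape == subjects.shape):
        raise InvalidDesignError("x, y and subjects must be aligned 1-D arrays")
    xc = np.empty_like(x)
    yc = np.empty_like(y)
    for sid in np.unique(subjects):
        m = subjects == sid
        if m.sum() == 1:
            warnings.warn(
                f"subject {sid} has a single observation; it contributes zeros",
                RuntimeWarning,
                stacklevel=2,
            )
        xc[m] = x[m] - x[m].mean()
        yc[m] = y[m] - y[m].mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom == 0:
        raise InvalidDesignError("no within-subject variation")
    return float(xc @ yc / denom)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional multiplicity control)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj
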