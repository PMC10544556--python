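"""Resampling and exact tests for small-sample group comparisons.

The comparisons this pipeline feeds are tiny (a handful of dyads per group),
so asymptotic tests are avoided: a label-permutation test on the Welch t
statistic, exact / enumerated rank tests, and Fisher exact tests (full
enumeration for 2x2, fixed-margin Monte Carlo for larger tables).  All
resampling is seed-deterministic and all p-values use the
(1 + count) / (n + 1) convention, which keeps them valid (never 0) at finite
resampling sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .errors import ValidationError


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str
    n1: int
    n2: int
    n_resamples: int | None = None   # None => exact / closed form
    seed: int | None = None


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    denom = np.sqrt(vx / nx + vy / ny)
    if denom == 0:
        return 0.0 if x.mean() == y.mean() else np.inf
    return (x.mean() - y.mean()) / denom


def permutation_two_sample(x, y, n_perm: int = 999, seed=None) -> TestResult:
    """Two-sided label-permutation test on the Welch t statistic.

    Group labels are permuted ``n_perm`` times; the two-sided p-value is
    (1 + #{|t*| >= |t_obs|}) / (n_perm + 1).  Two constant, equal groups give
    p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    t_obs = _welch_t(x, y)
    if t_obs == 0.0 and x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        return TestResult(0.0, 1.0, "permutation-welch-t", x.size, y.size,
                          n_perm, seed)
    rng = np.random.default_rng(seed)
    # Canonical pooled order and split so the p-value is symmetric in the
    # arguments: |t| is invariant to which group is called x.
    pooled = np.sort(np.concatenate([x, y]))
    n_small = min(x.size, y.size)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        t_star = _welch_t(perm[:n_small], perm[n_small:])
        if abs(t_star) >= abs(t_obs) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return TestResult(float(t_obs), float(p), "permutation-welch-t",
                      x.size, y.size, n_perm, seed)


def rank_test_paired_or_grouped(x, y, mode: str = "grouped") -> TestResult:
    """Wilcoxon signed-rank (paired) or rank-sum (grouped) test.

    The exact null distribution is enumerated for n <= 25 without ties; the
    normal approximation with tie correction is used otherwise.  Paired data
    with all-zero differences return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if mode == "paired":
        if x.size != y.size:
            raise ValidationError("paired mode needs equal-length samples")
        d = x - y
        if np.all(d == 0):
            return TestResult(0.0, 1.0, "wilcoxon-signed-rank", x.size, y.size)
        exact = x.size <= 25 and np.unique(np.abs(d[d != 0])).size == np.sum(d != 0)
        res = sps.wilcoxon(x, y, method="exact" if exact else "approx")
        return TestResult(float(res.statistic), float(res.pvalue),
                          "wilcoxon-signed-rank", x.size, y.size)
    if mode == "grouped":
        exact = (max(x.size, y.size) <= 25
                 and np.unique(np.concatenate([x, y])).size == x.size + y.size)
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="exact" if exact else "asymptotic")
        return TestResult(float(res.statistic), float(res.pvalue),
                          "wilcoxon-rank-sum", x.size, y.size)
    raise ValidationError(f"unknown mode {mode!r}")


def _log_table_prob(table: np.ndarray) -> float:
    """Log hypergeometric probability of an r x c table with fixed margins."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(gammaln(r + 1).sum() + gammaln(c + 1).sum()
                 - gammaln(n + 1) - gammaln(table + 1).sum())


def fisher_exact_rxc(table, n_mc: int = 100_000, seed=None) -> TestResult:
    """Fisher exact test of independence for an r x c count table.

    2x2 tables use the closed-form hypergeometric enumeration; larger tables
    use fixed-margin Monte Carlo (random re-pairing of row and column
    labels), counting resampled tables no more probable than the observed
    one.  A zero row or column margin is degenerate and returns p = 1 with a
    warning.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or min(table.shape) < 2 or np.any(table < 0):
        raise ValidationError("need a non-negative table of at least 2x2")
    r, c = table.sum(axis=1), table.sum(axis=0)
    if np.any(r == 0) or np.any(c == 0):
        warnings.warn("zero margin; test is degenerate", stacklevel=2)
        return TestResult(np.nan, 1.0, "fisher-exact", *table.shape)
    if table.shape == (2, 2):
        stat, p = sps.fisher_exact(table, alternative="two-sided")
        return TestResult(float(stat), float(p), "fisher-exact", 2, 2)
    rng = np.random.default_rng(seed)
    logp_obs = _log_table_prob(table)
    row_labels = np.repeat(np.arange(table.shape[0]), r)
    col_labels = np.repeat(np.arange(table.shape[1]), c)
    count = 0
    flat_shape = table.shape
    for _ in range(n_mc):
        perm = rng.permutation(col_labels)
        t = np.zeros(flat_shape, dtype=int)
        np.add.at(t, (row_labels, perm), 1)
        if _log_table_prob(t) <= logp_obs + 1e-9:
            count += 1
    p = (1 + count) / (n_mc + 1)
    return TestResult(float(np.exp(logp_obs)), float(p), "fisher-mc",
                      *table.shape, n_resamples=n_mc, seed=seed)
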