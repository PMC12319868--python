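"""Full-information maximum likelihood over missing-data patterns.

Rows are grouped by their missingness pattern; each pattern contributes
through its per-pattern sufficient statistics (count, mean, scatter), so a
likelihood evaluation costs O(#patterns * p^3) regardless of n.  On
complete data this reduces exactly to the complete-data multivariate
normal log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MissingnessPattern",
    "PatternData",
    "pattern_split",
    "fiml_loglik",
    "saturated_loglik",
    "independence_loglik",
    "em_mvn",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class MissingnessPattern:
    """One observed-variable pattern and its sufficient statistics."""

    mask: np.ndarray        # bool, True where observed
    row_indices: np.ndarray
    count: int
    mean: np.ndarray        # mean of observed sub-vector
    scatter: np.ndarray     # sum (x - mean)(x - mean)^T over rows
    rows: np.ndarray        # (count, k) raw observed values


@dataclass
class PatternData:
    """A dataset split into missingness patterns.

    ``patterns`` partition the retained rows; rows with no observed
    variables are dropped (with a warning) and counted in ``n_empty``.
    """

    patterns: list[MissingnessPattern]
    n_used: int
    n_empty: int
    p: int


def pattern_split(x: np.ndarray) -> PatternData:
    """Group the rows of ``x`` (NaN = missing) by missingness pattern."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be 2-D (rows x variables)")
    obs = ~np.isnan(x)
    empty = ~obs.any(axis=1)
    n_empty = int(empty.sum())
    if n_empty:
        warnings.warn(f"{n_empty} rows with no observed variables skipped", stacklevel=2)
    keep = np.flatnonzero(~empty)
    masks, inverse = np.unique(obs[keep], axis=0, return_inverse=True)
    patterns = []
    for k in range(masks.shape[0]):
        rows_idx = keep[inverse == k]
        mask = masks[k]
        sub = x[np.ix_(rows_idx, np.flatnonzero(mask))]
        mean = sub.mean(axis=0)
        centered = sub - mean
        patterns.append(
            MissingnessPattern(
                mask=mask,
                row_indices=rows_idx,
                count=len(rows_idx),
                mean=mean,
                scatter=centered.T @ centered,
                rows=sub,
            )
        )
    return PatternData(patterns=patterns, n_used=len(keep), n_empty=n_empty, p=x.shape[1])


def _pattern_loglik(pat: MissingnessPattern, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Log-likelihood contribution of one pattern; -inf if sub-block not PD."""
    o = np.flatnonzero(pat.mask)
    sub = sigma[np.ix_(o, o)]
    try:
        chol = np.linalg.cholesky(sub)
    except np.linalg.LinAlgError:
        return -np.inf
    k, n = len(o), pat.count
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    d = pat.mean - mu[o]
    inv = np.linalg.inv(sub)
    quad = float(np.sum(inv * pat.scatter)) + n * float(d @ inv @ d)
    return -0.5 * (n * (k * _LOG_2PI + logdet) + quad)


def fiml_loglik(x: np.ndarray | PatternData, mu: np.ndarray, sigma: np.ndarray) -> float:
    """FIML log-likelihood of data under N(mu, sigma).

    Each row contributes the log-density of its observed sub-vector under
    the corresponding marginal normal (valid under MAR).  Returns -inf when
    any pattern's covariance sub-block is not positive definite, which the
    optimizer treats as a rejected step rather than an error.
    """
    pd = x if isinstance(x, PatternData) else pattern_split(x)
    return float(sum(_pattern_loglik(pat, mu, sigma) for pat in pd.patterns))


def em_mvn(
    pd: PatternData, tol: float = 1e-9, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray, float]:
    """Saturated (unstructured) MVN estimate under missingness, via EM.

    Returns ``(mu, sigma, loglik)`` — the FIML estimate of an unrestricted
    mean vector and covariance matrix.  With complete data this is the
    closed-form sample mean / (biased) sample covariance in one step.
    """
    p, n = pd.p, pd.n_used
    if len(pd.patterns) == 1 and pd.patterns[0].mask.all():
        pat = pd.patterns[0]
        mu = pat.mean.copy()
        sigma = pat.scatter / n
        return mu, sigma, fiml_loglik(pd, mu, sigma)
    # initialize from available-case moments
    mu = np.zeros(p)
    var = np.ones(p)
    cnt = np.zeros(p)
    ssq = np.zeros(p)
    for pat in pd.patterns:
        o = np.flatnonzero(pat.mask)
        mu[o] += pat.count * pat.mean
        cnt[o] += pat.count
        ssq[o] += np.diag(pat.scatter) + pat.count * pat.mean**2
    good = cnt > 0
    mu[good] /= cnt[good]
    var[good] = np.maximum(ssq[good] / cnt[good] - mu[good] ** 2, 1e-6)
    sigma = np.diag(var)
    prev = -np.inf
    loglik = -np.inf
    for _ in range(max_iter):
        t1 = np.zeros(p)
        t2 = np.zeros((p, p))
        loglik = 0.0
        for pat in pd.patterns:
            o = np.flatnonzero(pat.mask)
            miss = np.flatnonzero(~pat.mask)
            loglik += _pattern_loglik(pat, mu, sigma)
            if miss.size == 0:
                t1[o] += pat.count * pat.mean
                t2[np.ix_(o, o)] += pat.scatter + pat.count * np.outer(pat.mean, pat.mean)
                continue
            s_oo = sigma[np.ix_(o, o)]
            s_mo = sigma[np.ix_(miss, o)]
            reg = np.linalg.solve(s_oo, s_mo.T).T          # regression of missing on observed
            cond_cov = sigma[np.ix_(miss, miss)] - reg @ s_mo.T
            xo = pat.rows
            xm_hat = mu[miss] + (xo - mu[o]) @ reg.T       # (count, |miss|)
            t1[o] += xo.sum(axis=0)
            t1[miss] += xm_hat.sum(axis=0)
            t2[np.ix_(o, o)] += xo.T @ xo
            cross = xo.T @ xm_hat
            t2[np.ix_(o, miss)] += cross
            t2[np.ix_(miss, o)] += cross.T
            t2[np.ix_(miss, miss)] += xm_hat.T @ xm_hat + pat.count * cond_cov
        mu = t1 / n
        sigma = t2 / n - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2.0
        if loglik - prev < tol * (abs(loglik) + 1.0) and np.isfinite(loglik):
            break
        prev = loglik
    return mu, sigma, fiml_loglik(pd, mu, sigma)


def saturated_loglik(pd: PatternData) -> float:
    """Log-likelihood of the saturated (unstructured mean+covariance) model."""
    return em_mvn(pd)[2]


def independence_loglik(pd: PatternData) -> tuple[float, int]:
    """FIML log-likelihood and free-parameter count of the independence model.

    Free means and variances, zero covariances: the likelihood factorizes
    per column, so each column's MLE is the observed-case mean and (biased)
    variance.
    """
    total = 0.0
    q = 0
    for j in range(pd.p):
        vals = np.concatenate(
            [pat.rows[:, list(np.flatnonzero(pat.mask)).index(j)]
             for pat in pd.patterns if pat.mask[j]]
        ) if any(pat.mask[j] for pat in pd.patterns) else np.array([])
        if vals.size == 0:
            continue
        m = vals.mean()
        v = max(vals.var(), 1e-12)
        total += float(-0.5 * (vals.size * (_LOG_2PI + np.log(v)) + ((vals - m) ** 2).sum() / v))
        q += 2
    return total, q
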