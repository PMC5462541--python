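"""Exact-test machinery for binned methylation counts.

Every 100-bp bin contributes one 2x2 table of pooled read counts
(methylated / unmethylated, mutant vs control).  A genome-scale run tests
hundreds of thousands of such tables per context, so the two-sided Fisher
exact test is evaluated in a vectorised form: for each table the full
hypergeometric support is enumerated and the probabilities of all outcomes
no more likely than the observed one are summed.  Log-probabilities come
from a shared log-factorial table (``gammaln``), which keeps the whole
computation in fused numpy operations.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

# Relative tolerance for the "as or less probable" tie rule.  Outcomes with
# pmf <= pmf(observed) * (1 + 1e-7) are included in the two-sided tail; the
# slack absorbs floating-point noise on mathematically tied outcomes (the
# same convention R and scipy use).
_TIE_REL_EPS = 1e-7

__all__ = ["fisher_exact_two_sided", "bh_adjust"]


def fisher_exact_two_sided(m1, n1, m2, n2, batch_size: int = 8192):
    """Two-sided Fisher exact p-values for 2x2 count tables, vectorised.

    Parameters
    ----------
    m1, n1 : array-like of int
        Methylated and total read counts in the first sample; the table row
        is ``(m1, n1 - m1)``.
    m2, n2 : array-like of int
        Same for the second sample.
    batch_size : int
        Tables are processed in batches to bound the (tables x support)
        scratch matrix.

    Returns
    -------
    numpy.ndarray of float
        One p-value per table.  Scalars in, scalar-shaped (1,) array out.
    """
    m1 = np.atleast_1d(np.asarray(m1, dtype=np.int64))
    n1 = np.atleast_1d(np.asarray(n1, dtype=np.int64))
    m2 = np.atleast_1d(np.asarray(m2, dtype=np.int64))
    n2 = np.atleast_1d(np.asarray(n2, dtype=np.int64))
    if not (m1.shape == n1.shape == m2.shape == n2.shape):
        raise ValueError("count arrays must share a shape")
    if (m1 < 0).any() or (m2 < 0).any() or (m1 > n1).any() or (m2 > n2).any():
        raise ValueError("need 0 <= m <= n in both samples")

    total = n1 + n2
    if total.size == 0:
        return np.empty(0)
    # log k! for every k we can encounter
    lf = gammaln(np.arange(int(total.max()) + 1, dtype=np.float64) + 1.0)

    out = np.empty(m1.shape, dtype=np.float64)
    for lo_i in range(0, m1.size, batch_size):
        sl = slice(lo_i, min(lo_i + batch_size, m1.size))
        out[sl] = _fisher_batch(m1[sl], n1[sl], m2[sl], n2[sl], lf)
    return out


def _fisher_batch(m1, n1, m2, n2, lf):
    N = n1 + n2
    k = m1 + m2
    lo = np.maximum(0, k - n2)
    hi = np.minimum(k, n1)
    width = int((hi - lo).max()) + 1

    x = lo[:, None] + np.arange(width, dtype=np.int64)[None, :]
    valid = x <= hi[:, None]
    x = np.minimum(x, hi[:, None])  # clamp so indexing stays in range
    kx = k[:, None] - x

    # log pmf of Hypergeom(N, k, n1) at x
    lognorm = (lf[N] - lf[k] - lf[N - k])[:, None]
    logpmf = (
        lf[n1][:, None] - lf[x] - lf[n1[:, None] - x]
        + lf[n2][:, None] - lf[kx] - lf[n2[:, None] - kx]
        - lognorm
    )
    log_obs = (
        lf[n1] - lf[m1] - lf[n1 - m1]
        + lf[n2] - lf[m2] - lf[n2 - m2]
        - lognorm[:, 0]
    )
    include = valid & (logpmf <= (log_obs + np.log1p(_TIE_REL_EPS))[:, None])
    p = np.where(include, np.exp(logpmf), 0.0).sum(axis=1)
    return np.minimum(p, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (q-values) for one test family."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return np.empty(0)
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
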