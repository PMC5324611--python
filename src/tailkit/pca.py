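"""Genotype PCA with Tracy-Widom significance of leading components.

Follows the smartpca recipe of Patterson, Price & Reich (2006): sites are
screened on call fraction, missing dosages are mean-imputed, each site is
centred and divided by its binomial standard deviation sqrt(p(1-p)) with
p the sample allele frequency, and the individual x individual covariance of
the normalised matrix is eigendecomposed.  Each leading eigenvalue is tested
against the Tracy-Widom (beta = 1) null: the remaining spectrum supplies a
moment-based estimate of the effective number of independent markers, the
eigenvalue is shifted and scaled by the corresponding Wishart edge
parameters, and the statistic is referred to the TW1 distribution.

The TW1 cumulative distribution is evaluated through Chiani's (2014)
shifted-gamma approximation (shape 46.446, scale 0.18605, shift -9.84801),
which matches the exact distribution to about 1e-4 in probability — far
inside anything that matters for a p < 0.05 decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .variants import MISSING, VariantTable

# Chiani (2014) shifted-gamma parameters for the beta=1 Tracy-Widom law.
_TW1_SHAPE = 46.44604884387787
_TW1_SCALE = 0.18605402228279682
_TW1_SHIFT = 9.84801130943552


def tw1_cdf(x) -> np.ndarray:
    """CDF of the Tracy-Widom distribution with beta = 1."""
    return stats.gamma.cdf(np.asarray(x, float) + _TW1_SHIFT,
                           a=_TW1_SHAPE, scale=_TW1_SCALE)


def tw1_sf(x) -> np.ndarray:
    """Upper tail probability of TW1 (survival function)."""
    return stats.gamma.sf(np.asarray(x, float) + _TW1_SHIFT,
                          a=_TW1_SHAPE, scale=_TW1_SCALE)


@dataclass
class PCAResult:
    ids: list
    eigenvalues: np.ndarray   # descending, nonnegative
    scores: np.ndarray        # individuals x components, U * sqrt(lambda)
    tw_stats: np.ndarray      # Tracy-Widom statistic per leading component
    tw_pvalues: np.ndarray
    k_significant: int        # leading components with TW p < alpha
    n_sites_used: int


def normalized_genotypes(v: VariantTable, min_call_frac: float = 0.5):
    """Patterson-normalised genotype matrix (individuals x sites).

    Sites genotyped in no more than ``min_call_frac`` of individuals and
    monomorphic sites are dropped; missing entries are imputed at the site
    mean before centring.
    """
    called = v.dosage != MISSING
    keep = called.mean(axis=1) > min_call_frac
    d = v.dosage[keep].astype(float)
    called = called[keep]
    n_called = called.sum(axis=1)
    mean = np.where(called, d, 0.0).sum(axis=1) / n_called
    p = mean / 2.0
    poly = (p > 0.0) & (p < 1.0)
    d, called, mean, p = d[poly], called[poly], mean[poly], p[poly]
    d = np.where(called, d, mean[:, None])
    m = (d - mean[:, None]) / np.sqrt(p * (1.0 - p))[:, None]
    return m.T, int(poly.sum())


def tracy_widom_pvalues(eigenvalues: np.ndarray, max_k: int | None = None):
    """Patterson-style TW statistics and p-values for leading eigenvalues.

    For component k the top k-1 eigenvalues are removed, the effective
    marker count n' is estimated from the remaining spectrum as
    n' = (m+1) * (sum l)^2 / (m * sum l^2 - (sum l)^2), obtained by matching
    the first two spectral moments of a white Wishart(n', m) matrix (m = the
    number of remaining eigenvalues), and the leading remaining eigenvalue
    is standardised with the (n', m) Wishart edge mean and scale.
    """
    lam = np.asarray(eigenvalues, float)
    lam = lam[lam > 1e-12]
    if max_k is None:
        max_k = max(len(lam) - 1, 1)
    max_k = min(max_k, len(lam) - 1) if len(lam) > 1 else 0
    x = np.full(max_k, np.nan)
    for k in range(max_k):
        rest = lam[k:]
        m = len(rest)
        s1, s2 = rest.sum(), (rest ** 2).sum()
        denom = m * s2 - s1 ** 2
        if denom <= 0:
            break
        n_eff = (m + 1) * s1 ** 2 / denom
        ell = m * rest[0] / s1
        sq_n = np.sqrt(n_eff - 1.0)
        sq_m = np.sqrt(m)
        mu = (sq_n + sq_m) ** 2 / n_eff
        sigma = (sq_n + sq_m) / n_eff * (1.0 / sq_n + 1.0 / sq_m) ** (1.0 / 3.0)
        x[k] = (ell - mu) / sigma
    p = np.where(np.isnan(x), np.nan, tw1_sf(np.nan_to_num(x)))
    return x, p


def genotype_pca(v: VariantTable, min_call_frac: float = 0.5,
                 alpha: float = 0.05) -> PCAResult:
    """PCA of a variant table with Tracy-Widom component significance."""
    if v.n_individuals < 3:
        raise ValueError("PCA requires at least three individuals")
    m, n_used = normalized_genotypes(v, min_call_frac)
    if n_used < 2:
        raise ValueError("fewer than two informative sites after filtering")
    if not np.any(np.abs(m) > 1e-12):
        raise ValueError("degenerate input: zero variance after normalisation")
    cov = m @ m.T / n_used
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vec = vec[:, order]
    scores = vec * np.sqrt(lam)[None, :]
    tw, pvals = tracy_widom_pvalues(lam)
    k_sig = 0
    for pk in pvals:
        if np.isfinite(pk) and pk < alpha:
            k_sig += 1
        else:
            break
    return PCAResult(ids=list(v.ids), eigenvalues=lam, scores=scores,
                     tw_stats=tw, tw_pvalues=pvals, k_significant=k_sig,
                     n_sites_used=n_used)
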