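"""Habitat-trait association under genetic non-independence.

Tests whether habitat (forest vs nonforest) predicts the tail/body ratio
while absorbing genetic similarity as a random effect:

    y = X beta + u + e,   u ~ N(0, sigma_g^2 * S),   e ~ N(0, sigma_e^2 * I)

where S is either twice the pairwise kinship matrix (individual-level
analysis; the numerator relationship matrix, diagonal 1) or a similarity
matrix derived from pairwise F_ST between populations (population-level
analysis on population mean ratios, S_ij = 1 - F_ST(i, j)).

Fitting is exact restricted maximum likelihood via the spectral trick: with
S = U D U', rotating y and X by U' diagonalises the covariance, and the REML
criterion can be profiled down to a one-dimensional search over the variance
ratio lambda = sigma_g^2 / sigma_e^2.  The habitat effect is tested with a
Wald t statistic on Satterthwaite degrees of freedom (the lmerTest
convention): when the habitat contrast aligns with a high-eigenvalue
direction of S — precisely the confounded situation the model exists for —
the residual df n - rank(X) overstates the information about the contrast
and inflates the type-I error, whereas the Satterthwaite df reflect how
imprecisely the relevant variance component is estimated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

log = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    labels: list
    s: np.ndarray
    provenance: str          # "kinship" or "fst_derived"
    min_eig_before_repair: float = 0.0

    def __post_init__(self):
        self.s = np.asarray(self.s, float)
        if self.s.shape != (len(self.labels), len(self.labels)):
            raise ValueError("similarity matrix shape does not match labels")
        if not np.allclose(self.s, self.s.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")


def _psd_repair(s: np.ndarray):
    """Clip negative eigenvalues to zero; returns (repaired, min_eig)."""
    w, u = np.linalg.eigh((s + s.T) / 2.0)
    min_eig = float(w.min())
    if min_eig < 0:
        s = (u * np.clip(w, 0.0, None)) @ u.T
        s = (s + s.T) / 2.0
    return s, min_eig


def kinship_similarity(kin) -> SimilarityMatrix:
    """Numerator relationship matrix S = 2*phi from a KinshipMatrix.

    NaN pairs (no shared sites) are set to 0 before the PSD repair.
    """
    s = 2.0 * np.nan_to_num(kin.phi, nan=0.0)
    s, min_eig = _psd_repair(s)
    return SimilarityMatrix(labels=list(kin.ids), s=s, provenance="kinship",
                            min_eig_before_repair=min_eig)


def fst_similarity(fst_table) -> SimilarityMatrix:
    """Similarity S_ij = 1 - F_ST(i, j) from a pairwise F_ST table.

    ``fst_table`` maps unordered population pairs to weighted F_ST values
    (a dict {(a, b): fst} or an iterable of FstResult).  Slightly negative
    estimates are floored at zero; the matrix is PSD-repaired by clipping
    negative eigenvalues.
    """
    if isinstance(fst_table, dict):
        pairs = dict(fst_table)
    else:
        pairs = {tuple(r.pair): r.weighted_global for r in fst_table}
    labels: list = []
    for a, b in pairs:
        for x in (a, b):
            if x not in labels:
                labels.append(x)
    n = len(labels)
    s = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            key = (labels[i], labels[j])
            rkey = (labels[j], labels[i])
            if key in pairs:
                f = pairs[key]
            elif rkey in pairs:
                f = pairs[rkey]
            else:
                raise ValueError(f"missing F_ST for pair {key}")
            if f < -0.05 or f > 1.0:
                raise ValueError(f"F_ST {f} for pair {key} outside [-0.05, 1]")
            if f < 0:
                log.info("negative F_ST %.4f for %s floored at 0", f, key)
                f = 0.0
            s[i, j] = s[j, i] = 1.0 - f
    s, min_eig = _psd_repair(s)
    return SimilarityMatrix(labels=labels, s=s, provenance="fst_derived",
                            min_eig_before_repair=min_eig)


@dataclass
class LMMFit:
    beta: np.ndarray          # (intercept, habitat)
    se: np.ndarray
    sigma_g2: float
    sigma_e2: float
    wald_t: float
    df: float                 # Satterthwaite df, capped at n - rank(X)
    p_value: float
    converged: bool
    boundary: bool            # variance ratio pinned at the search boundary
    reml_loglik: float
    fitted: np.ndarray


def _kenward_roger(d, xt, sigma_g2, sigma_e2, df_resid):
    """Kenward-Roger (1997) small-sample test of the last fixed effect.

    Works in the rotated space where V = diag(sigma_g2 * d + sigma_e2),
    which is linear in theta = (sigma_g2, sigma_e2) so the KR adjusted
    covariance Phi_A = Phi + 2 Phi [sum_ij W_ij (Q_ij - P_i Phi P_j)] Phi is
    exact (no second-derivative terms).  Returns
    (denominator df, scale factor, adjusted variance of the last effect) for
    the scaled F test, or None when the REML information is numerically
    singular (e.g. at a variance boundary) — callers then fall back to the
    residual-df Wald test.
    """
    v = sigma_g2 * d + sigma_e2
    w = 1.0 / v
    xtw = xt * w[:, None]
    a = xtw.T @ xt               # X' V^-1 X
    phi = np.linalg.inv(a)
    mults = (d, np.ones_like(d))

    # REML information: I_jk = 0.5 tr(P D_j P D_k) with the REML projector P
    p_mat = np.diag(w) - xtw @ phi @ xtw.T
    pd = [p_mat * m[None, :] for m in mults]          # P @ D_k
    info = np.empty((2, 2))
    for i in range(2):
        for j in range(i, 2):
            info[i, j] = info[j, i] = 0.5 * np.sum(pd[i] * pd[j].T)
    try:
        w_cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(w_cov)):
        return None

    p_list = [-(xt.T @ (xt * (m / v ** 2)[:, None])) for m in mults]
    q_mats = {(i, j): xt.T @ (xt * (mults[i] * mults[j] / v ** 3)[:, None])
              for i in range(2) for j in range(2)}
    lam_mat = np.zeros_like(a)
    for i in range(2):
        for j in range(2):
            lam_mat += w_cov[i, j] * (q_mats[i, j]
                                      - p_list[i] @ phi @ p_list[j])
    phi_adj = phi + 2.0 * phi @ lam_mat @ phi
    var_adj = float(phi_adj[-1, -1])
    if not np.isfinite(var_adj) or var_adj <= 0:
        return None

    # Denominator df for the 1-df contrast L = (0, ..., 0, 1).  For a single
    # contrast the KR A1/A2 quantities coincide and their df formula reduces
    # to the Satterthwaite form 2*C^2 / (grad C' W grad C) evaluated at the
    # unadjusted variance C, with F-scale factor exactly 1.
    c = phi[-1, -1]
    grad = np.array([(phi @ p @ phi)[-1, -1] for p in p_list])  # = -dC/dtheta
    denom = float(grad @ w_cov @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return None
    df = 2.0 * c ** 2 / denom
    return float(min(max(df, 1.0), df_resid)), 1.0, var_adj


def _reml_neg_loglik(log_lam, d, yt, xt, n, p):
    lam = np.exp(log_lam)
    w = 1.0 / (lam * d + 1.0)
    xtw = xt * w[:, None]
    xwx = xt.T @ xtw
    beta = np.linalg.solve(xwx, xtw.T @ yt)
    resid = yt - xt @ beta
    rss = float(resid @ (w * resid))
    sigma_e2 = rss / (n - p)
    _, logdet_xwx = np.linalg.slogdet(xwx)
    ll = -0.5 * ((n - p) * np.log(sigma_e2) - np.log(w).sum() + logdet_xwx)
    return -ll, beta, sigma_e2, xwx


def relatedness_lmm(y, habitat, similarity: SimilarityMatrix) -> LMMFit:
    """REML fit of the habitat effect with a genetic random effect.

    ``y`` and ``habitat`` follow the order of ``similarity.labels``; habitat
    is 0/1 (nonforest/forest).  Raises on non-PSD similarity or dimension
    mismatch.
    """
    y = np.asarray(y, float)
    h = np.asarray(habitat, float)
    s = similarity.s
    n = len(y)
    if h.shape != (n,) or s.shape != (n, n):
        raise ValueError("y, habitat and similarity must be conformable")
    d, u = np.linalg.eigh(s)
    if d.min() < -1e-8 * max(1.0, d.max()):
        raise ValueError("similarity matrix is not positive semi-definite")
    d = np.clip(d, 0.0, None)
    x = np.column_stack([np.ones(n), h])
    p = np.linalg.matrix_rank(x)
    if n <= p:
        raise ValueError("more fixed-effect parameters than observations")
    yt = u.T @ y
    xt = u.T @ x

    lo, hi = -12.0, 12.0
    res = optimize.minimize_scalar(
        lambda ll: _reml_neg_loglik(ll, d, yt, xt, n, p)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8})
    log_lam = float(res.x)
    # lambda -> 0 (pure OLS) is a legitimate boundary solution; compare
    nll_hat, *_ = _reml_neg_loglik(log_lam, d, yt, xt, n, p)
    nll_zero, *_ = _reml_neg_loglik(-np.inf, d, yt, xt, n, p)
    if nll_zero <= nll_hat:
        log_lam = -np.inf
    nll, beta, sigma_e2, xwx = _reml_neg_loglik(log_lam, d, yt, xt, n, p)
    lam = np.exp(log_lam) if np.isfinite(log_lam) else 0.0
    boundary = bool(np.isfinite(log_lam) and
                    (abs(log_lam - lo) < 1e-3 or abs(log_lam - hi) < 1e-3))

    cov_beta = sigma_e2 * np.linalg.inv(xwx)
    se = np.sqrt(np.diag(cov_beta))
    sigma_g2 = lam * sigma_e2
    df = float(n - p)
    scale = 1.0
    if sigma_g2 > 0:
        kr = _kenward_roger(d, xt, sigma_g2, sigma_e2, n - p)
        if kr is not None:
            df, scale, var_adj = kr
            se = se.copy()
            se[1] = np.sqrt(var_adj)
    t = float(beta[1] / se[1])
    # KR scaled F on (1, df): F* = scale * t^2
    p_val = float(stats.f.sf(scale * t * t, 1, df))
    fitted = x @ beta
    return LMMFit(beta=beta, se=se, sigma_g2=sigma_g2,
                  sigma_e2=sigma_e2, wald_t=t, df=df,
                  p_value=max(p_val, np.finfo(float).tiny),
                  converged=bool(res.success), boundary=boundary,
                  reml_loglik=-float(nll), fitted=fitted)


def population_lmm(pop_means, habitat, similarity: SimilarityMatrix,
                   allow_small: bool = False) -> LMMFit:
    """Population-level fit on mean ratios with an F_ST-derived similarity.

    Refuses fewer than four populations (residual df would be below two)
    unless ``allow_small`` is set.
    """
    n = len(pop_means)
    if n < 4 and not allow_small:
        raise ValueError("population-level model needs at least 4 populations")
    if n < 3:
        raise ValueError("cannot fit with fewer populations than parameters + 1")
    return relatedness_lmm(pop_means, habitat, similarity)


def ols_habitat_test(y, habitat):
    """Naive two-group comparison ignoring relatedness (for contrast).

    Equivalent to the equal-variance two-sample t test; returns
    (beta, t, df, p).
    """
    y = np.asarray(y, float)
    h = np.asarray(habitat, float)
    n = len(y)
    x = np.column_stack([np.ones(n), h])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df = n - 2
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(x.T @ x)
    t = float(beta[1] / np.sqrt(cov[1, 1]))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(beta[1]), t, df, p
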