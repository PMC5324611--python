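"""Site and genotype filtering for SNP call sets.

Implements the hard-filter stage of a GATK/VCFtools-style pipeline: per-call
masking on genotype quality and depth, removal of clustered variants, INFO
threshold filters (strand bias FS, mapping quality MQ, mean genotype
quality), a missingness ceiling, and an exact Hardy-Weinberg equilibrium
test.  Rules are applied in a fixed, logged order:

1. per-call masking (GQ < gq_call_min or DP < dp_call_min -> missing)
2. non-biallelic sites removed
3. clustered sites removed (>= cluster_k variants inside any window of
   cluster_window_bp containing the site)
4. INFO thresholds: FS > fs_max, MQ < mq_min, mean GQ < gq_mean_min
5. missingness: site missing fraction > max_missing_frac, or fewer than
   min_informative genotyped individuals
6. HWE exact test p < hwe_alpha (pooled across all individuals)

The HWE test is the exact conditional test of Wigginton, Cutler & Abecasis
(2005): conditioning on the observed allele counts, heterozygote counts with
the same parity are enumerated and the p-value is the summed probability of
all outcomes no more probable than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variants import MISSING, VariantTable


@dataclass
class FilterConfig:
    """Thresholds for :func:`apply_variant_filters`.

    Defaults are the hard-filter values used for capture-based SNP data:
    cluster 3-in-10bp, FS > 60, MQ < 60, mean GQ < 20, per-call GQ < 20 or
    DP < 4, HWE p < 0.01, site retained when genotyped in more than half of
    the individuals and in at least ``min_informative`` of them.
    """

    cluster_k: int = 3
    cluster_window_bp: int = 10
    fs_max: float = 60.0
    mq_min: float = 60.0
    gq_mean_min: float = 20.0
    gq_call_min: int = 20
    dp_call_min: int = 4
    hwe_alpha: float = 0.01
    max_missing_frac: float = 0.5
    min_informative: int = 4

    def __post_init__(self):
        if not (0.0 < self.hwe_alpha < 1.0):
            raise ValueError("hwe_alpha must lie in (0, 1)")
        for name in ("cluster_k", "cluster_window_bp", "fs_max", "mq_min",
                     "gq_mean_min", "gq_call_min", "dp_call_min",
                     "max_missing_frac", "min_informative"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def permissive(cls) -> "FilterConfig":
        """A configuration under which every rule is a no-op."""
        return cls(cluster_k=10 ** 9, cluster_window_bp=0, fs_max=np.inf,
                   mq_min=0.0, gq_mean_min=0.0, gq_call_min=0, dp_call_min=0,
                   hwe_alpha=1e-300, max_missing_frac=1.0, min_informative=0)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value for one biallelic site.

    Conditions on the observed counts of the two alleles; the null
    distribution over heterozygote counts (same parity as observed) is

        P(n_het = h | n, n_a) prop. 2**h * n! / (h! * n_AA! * n_aa!)

    normalised over admissible h.  Returns the sum of probabilities of all
    heterozygote counts whose probability does not exceed the observed one.
    Monomorphic sites return 1.0 by convention.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_a = 2 * n_hom_alt + n_het  # minor-orientation is irrelevant: symmetric
    n_A = 2 * n_hom_ref + n_het
    if n_a == 0 or n_A == 0:
        return 1.0
    rare = min(n_a, n_A)
    # Probabilities over h = rare, rare-2, ..., via the ratio recurrence
    #   P(h-2)/P(h) = h*(h-1) / (4 * (n_AA+1) * (n_aa+1))   (unnormalised).
    hs = np.arange(rare % 2, rare + 1, 2)
    probs = np.empty(len(hs))
    probs[-1] = 1.0
    for k in range(len(hs) - 1, 0, -1):
        h = hs[k]
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        probs[k - 1] = probs[k] * h * (h - 1) / (4.0 * (hom_rare + 1) * (hom_common + 1))
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hs, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _cluster_mask(chrom: np.ndarray, pos: np.ndarray, k: int, window: int) -> np.ndarray:
    """True where a site belongs to a run of >= k sites spanning < window bp."""
    bad = np.zeros(len(pos), dtype=bool)
    if k <= 0 or len(pos) < k:
        return bad
    chrom = np.asarray(chrom)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        p = pos[idx]
        for i in range(len(p) - k + 1):
            if p[i + k - 1] - p[i] < window:
                bad[idx[i: i + k]] = True
    return bad


def site_genotype_counts(dosage: np.ndarray):
    """Per-site (n_hom_ref, n_het, n_hom_alt) over non-missing calls."""
    called = dosage != MISSING
    n_het = ((dosage == 1) & called).sum(axis=1)
    n_hom_alt = ((dosage == 2) & called).sum(axis=1)
    n_hom_ref = ((dosage == 0) & called).sum(axis=1)
    return n_hom_ref, n_het, n_hom_alt


def apply_variant_filters(v: VariantTable, f: FilterConfig | None = None):
    """Mask low-quality calls and drop failing sites.

    Returns ``(filtered_table, log)`` where ``log`` is a dict with the number
    of calls masked and, in application order, the number of sites removed by
    each rule (a site is charged to the first rule that removes it).
    """
    f = f or FilterConfig()
    v = v.copy()
    log = {"order": ["biallelic", "cluster", "fs", "mq", "gq_mean",
                     "missingness", "min_informative", "hwe"],
           "sites_in": v.n_sites}

    # 1. per-call masking; GQ/DP thresholds of 0 disable the mask
    called = v.dosage != MISSING
    bad_call = called & ((v.gq < f.gq_call_min) | (v.dp < f.dp_call_min))
    v.dosage[bad_call] = MISSING
    v.gq[bad_call] = MISSING
    v.dp[bad_call] = MISSING
    log["calls_masked"] = int(bad_call.sum())

    removed = np.zeros(v.n_sites, dtype=bool)

    def charge(rule: str, mask: np.ndarray):
        fresh = mask & ~removed
        log[f"removed_{rule}"] = int(fresh.sum())
        removed[:] = removed | fresh

    # 2. biallelic
    alts = np.asarray(v.alt)
    charge("biallelic", np.array([("," in a) or (a == ".") for a in alts]))
    # 3. clustered variants (positions of all input sites, as a caller sees them)
    charge("cluster", _cluster_mask(v.chrom, v.pos, f.cluster_k, f.cluster_window_bp))
    # 4. INFO thresholds
    fs = np.asarray(v.info.get("FS", np.zeros(v.n_sites)), float)
    mq = np.asarray(v.info.get("MQ", np.full(v.n_sites, np.inf)), float)
    charge("fs", fs > f.fs_max)
    charge("mq", mq < f.mq_min)
    gq_f = np.where(v.gq == MISSING, np.nan, v.gq.astype(float))
    with np.errstate(invalid="ignore"):
        gq_mean = np.nanmean(gq_f, axis=1)
    charge("gq_mean", np.nan_to_num(gq_mean, nan=0.0) < f.gq_mean_min)
    # 5. missingness after masking
    n_called = (v.dosage != MISSING).sum(axis=1)
    miss_frac = 1.0 - n_called / v.n_individuals
    charge("missingness", miss_frac > f.max_missing_frac)
    charge("min_informative", n_called < f.min_informative)
    # 6. HWE exact test, pooled across individuals
    n_rr, n_het, n_aa = site_genotype_counts(v.dosage)
    hwe_bad = np.zeros(v.n_sites, dtype=bool)
    for i in np.flatnonzero(~removed):
        if n_rr[i] + n_het[i] + n_aa[i] >= 1:
            hwe_bad[i] = hwe_exact_test(n_rr[i], n_het[i], n_aa[i]) < f.hwe_alpha
    charge("hwe", hwe_bad)

    out = v.take_sites(~removed)
    log["sites_out"] = out.n_sites
    return out, log
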