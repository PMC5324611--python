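"""Weir-Cockerham F_ST from genotype dosages.

Per-site variance components a (between populations), b (between individuals
within populations), and c (within individuals) are computed from allele
frequencies and observed heterozygosity with the unequal-sample-size
corrections of the 1984 estimator.  Two global summaries are returned: the
"weighted" estimate sum(a)/sum(a+b+c) and the "mean" estimate, the average
of per-site ratios a/(a+b+c) — the same pair VCFtools prints as weighted and
mean F_ST.  Sites that are monomorphic across the pooled sample carry no
information and are excluded from both summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .variants import MISSING, VariantTable


@dataclass
class FstResult:
    pair: tuple
    a: np.ndarray            # per-site between-population component
    b: np.ndarray            # per-site between-individual component
    c: np.ndarray            # per-site within-individual component
    informative: np.ndarray  # mask of polymorphic sites entering the summaries
    weighted_global: float
    mean_global: float
    n_sites_used: int


def wc_fst_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Weir-Cockerham per-site components for r populations.

    Parameters are per-population arrays (sites x r): ``n`` genotyped
    individuals, ``p`` alternate-allele frequency, ``h`` observed
    heterozygote frequency.  Returns (a, b, c) arrays per site.
    """
    n = np.asarray(n, float)
    p = np.asarray(p, float)
    h = np.asarray(h, float)
    r = n.shape[1]
    n_tot = n.sum(axis=1)
    n_bar = n_tot / r
    n_c = (n_tot - (n ** 2).sum(axis=1) / n_tot) / (r - 1)
    p_bar = (n * p).sum(axis=1) / n_tot
    s2 = (n * (p - p_bar[:, None]) ** 2).sum(axis=1) / ((r - 1) * n_bar)
    h_bar = (n * h).sum(axis=1) / n_tot

    pq = p_bar * (1.0 - p_bar)
    a = (n_bar / n_c) * (
        s2 - (pq - s2 * (r - 1) / r - h_bar / 4.0) / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        pq - s2 * (r - 1) / r - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
    )
    c = h_bar / 2.0
    return a, b, c


def wc_fst(v: VariantTable, pop_labels, pop_pair=None) -> FstResult:
    """Weir-Cockerham F_ST between two populations of a variant table.

    ``pop_labels`` assigns a population to each individual (order of
    ``v.ids``); ``pop_pair`` names the two populations to compare (default:
    the two distinct labels present).  Raises ``ValueError`` when any
    retained site lacks a genotyped individual in either population, or when
    no polymorphic site is shared.
    """
    labels = np.asarray(pop_labels)
    if len(labels) != v.n_individuals:
        raise ValueError("one population label per individual required")
    if pop_pair is None:
        uniq = list(dict.fromkeys(labels.tolist()))
        if len(uniq) != 2:
            raise ValueError("pop_pair required when labels are not exactly two")
        pop_pair = tuple(uniq)

    cols = [np.flatnonzero(labels == g) for g in pop_pair]
    n = np.empty((v.n_sites, 2))
    p = np.empty((v.n_sites, 2))
    h = np.empty((v.n_sites, 2))
    for k, idx in enumerate(cols):
        d = v.dosage[:, idx]
        called = d != MISSING
        nk = called.sum(axis=1)
        if np.any(nk == 0):
            raise ValueError(
                f"population {pop_pair[k]} has sites with no genotyped individual"
            )
        n[:, k] = nk
        p[:, k] = np.where(called, d, 0).sum(axis=1) / (2.0 * nk)
        h[:, k] = (d == 1).sum(axis=1) / nk

    a, b, c = wc_fst_components(n, p, h)
    n_tot = n.sum(axis=1)
    p_bar = (n * p).sum(axis=1) / n_tot
    informative = (p_bar > 0.0) & (p_bar < 1.0)
    if not informative.any():
        raise ValueError("no shared polymorphic sites; F_ST undefined")

    denom = (a + b + c)[informative]
    weighted = float(a[informative].sum() / denom.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = a[informative] / denom
    mean = float(np.nanmean(np.where(denom != 0, ratios, np.nan)))
    return FstResult(pair=tuple(pop_pair), a=a, b=b, c=c,
                     informative=informative, weighted_global=weighted,
                     mean_global=mean, n_sites_used=int(informative.sum()))


def pairwise_fst_table(v: VariantTable, pop_labels) -> "list[FstResult]":
    """All pairwise Weir-Cockerham comparisons among population labels."""
    uniq = list(dict.fromkeys(np.asarray(pop_labels).tolist()))
    out = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            out.append(wc_fst(v, pop_labels, (uniq[i], uniq[j])))
    return out
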