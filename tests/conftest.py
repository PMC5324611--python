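"""Shared fixtures and helpers for the tailkit test suite."""

import numpy as np
import pytest

from tailkit import VariantTable
from tailkit.variants import MISSING


def make_table(dosage, pos=None, chrom=None, gq=None, dp=None, fs=None,
               mq=None, ids=None):
    """Build a VariantTable from a dosage matrix with benign metadata."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_ind = dosage.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 1000
    if gq is None:
        gq = np.full(dosage.shape, 60, dtype=np.int16)
    if dp is None:
        dp = np.full(dosage.shape, 20, dtype=np.int16)
    gq = np.asarray(gq, np.int16).copy()
    dp = np.asarray(dp, np.int16).copy()
    gq[dosage == MISSING] = MISSING
    dp[dosage == MISSING] = MISSING
    return VariantTable(
        chrom=np.asarray(chrom if chrom is not None
                         else np.full(n_sites, "1"), dtype=object),
        pos=np.asarray(pos, np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        info={"FS": np.asarray(fs if fs is not None else np.zeros(n_sites), float),
              "MQ": np.asarray(mq if mq is not None
                               else np.full(n_sites, 60.0), float)},
        ids=list(ids) if ids is not None
        else [f"ind{j:03d}" for j in range(n_ind)],
        dosage=dosage, gq=gq, dp=dp)


def hwe_genotypes(rng, n_ind, n_sites, freq_range=(0.1, 0.9)):
    """Panmictic Hardy-Weinberg dosages, sites x individuals."""
    p = rng.uniform(*freq_range, n_sites)
    return rng.binomial(2, p[:, None], (n_sites, n_ind)).astype(np.int8), p


def mendelian_offspring(rng, mother, father):
    """Child dosage: one allele transmitted from each parental dosage vector."""
    ma = (rng.random(len(mother)) < mother / 2.0).astype(np.int8)
    pa = (rng.random(len(father)) < father / 2.0).astype(np.int8)
    return ma + pa


@pytest.fixture
def rng():
    return np.random.default_rng(2016)
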