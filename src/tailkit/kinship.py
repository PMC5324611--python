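"""KING-robust pairwise kinship from genotype dosages.

The between-family (robust) estimator of Manichaikul et al. (2010), the same
quantity VCFtools reports as ``--relatedness2``:

    phi_ij = (N_Aa,Aa - 2 * N_AA,aa) / (N_Aa(i) + N_Aa(j))

where, over the sites at which both individuals are genotyped, N_Aa,Aa is
the count of sites where both are heterozygous, N_AA,aa the count of
opposite homozygotes, and N_Aa(i) the count of heterozygous sites of
individual i.  The estimator is robust to population structure in the sense
that it requires no allele-frequency estimates; unrelated pairs drawn from
distinct demes can legitimately have negative phi.  Expected values: 0.5 for
self/duplicates (the diagonal is set to 0.5 by convention), 0.25 for
parent-offspring or full sibs, ~0 for unrelated individuals from one deme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import MISSING, VariantTable


@dataclass
class KinshipMatrix:
    ids: list
    phi: np.ndarray       # symmetric, diagonal 0.5, NaN where no shared sites
    n_shared: np.ndarray  # per-pair count of jointly genotyped sites

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, index_col=0)
        phi = df.to_numpy(float)
        n = np.full_like(phi, -1, dtype=np.int64)
        return cls(ids=list(df.index.astype(str)), phi=phi, n_shared=n)


def king_kinship(v: VariantTable) -> KinshipMatrix:
    """KING-robust kinship matrix over all pairs of individuals.

    Only jointly genotyped sites enter each pairwise estimate.  Pairs with
    zero shared sites, or in which neither individual carries a heterozygous
    call, get ``NaN`` with a warning.
    """
    if v.n_individuals < 2:
        raise ValueError("kinship requires at least two individuals")
    d = v.dosage
    called = (d != MISSING).astype(np.float64)
    het = ((d == 1) & (d != MISSING)).astype(np.float64)
    hom0 = (d == 0).astype(np.float64)
    hom2 = (d == 2).astype(np.float64)

    # site x individual indicator products give all pairwise counts at once
    n_hethet = het.T @ het
    n_opp = hom0.T @ hom2 + hom2.T @ hom0
    het_shared = het.T @ called          # het in i among sites called in j
    denom = het_shared + het_shared.T
    n_shared = called.T @ called

    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_hethet - 2.0 * n_opp) / denom, np.nan)
    np.fill_diagonal(phi, 0.5)

    bad = (n_shared == 0) | np.isnan(phi)
    np.fill_diagonal(bad, False)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum() // 2)} pair(s) with no usable shared sites; "
            "kinship set to NaN", stacklevel=2)
    phi = (phi + phi.T) / 2.0
    np.fill_diagonal(phi, 0.5)
    return KinshipMatrix(ids=list(v.ids), phi=phi,
                         n_shared=n_shared.astype(np.int64))
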