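"""Genotype container and VCF I/O.

The central in-memory object is :class:`VariantTable`: a sites x individuals
matrix of biallelic genotype dosages (0, 1, 2 copies of the alternate allele,
``MISSING`` = -1 where no call was made) together with per-call quality
metadata (GQ, DP) and per-site INFO annotations (FS, MQ).  All downstream
population-genetic estimators (filtering, F_ST, kinship, PCA) operate on this
container.  Files on disk are plain VCF v4.2 with ``GT:GQ:DP`` FORMAT fields,
read through cyvcf2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

#: Sentinel for a missing genotype call; distinct from any valid dosage.
MISSING: int = -1

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=tailkit
##contig=<ID={chrom},length={length}>
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand-bias Fisher exact test">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS read mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Phred-scaled genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


@dataclass
class VariantTable:
    """Biallelic SNP genotypes for a panel of individuals.

    Attributes
    ----------
    chrom : np.ndarray of str, one label per site
    pos : np.ndarray of int, 1-based coordinates, strictly increasing within
        each chromosome
    ref, alt : np.ndarray of str, single-base alleles
    info : dict of per-site float arrays (keys include "FS" and "MQ")
    ids : list of individual identifiers (column order of ``dosage``)
    dosage : (n_sites, n_individuals) int8 array in {0, 1, 2, MISSING}
    gq : (n_sites, n_individuals) int16 array, phred genotype quality
        (MISSING where no call)
    dp : (n_sites, n_individuals) int16 array, read depth (MISSING where no
        call)
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    info: dict
    ids: list
    dosage: np.ndarray
    gq: np.ndarray
    dp: np.ndarray

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (self.n_sites, self.n_individuals):
            raise ValueError("dosage shape does not match sites x individuals")
        for c in np.unique(np.asarray(self.chrom)):
            p = self.pos[np.asarray(self.chrom) == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls, sites x individuals."""
        return self.dosage != MISSING

    def allele_freq(self) -> np.ndarray:
        """Per-site alternate-allele frequency over called genotypes."""
        called = self.called
        n = called.sum(axis=1)
        alt = np.where(called, self.dosage, 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def take_sites(self, index) -> "VariantTable":
        index = np.asarray(index)
        return VariantTable(
            chrom=np.asarray(self.chrom)[index],
            pos=self.pos[index],
            ref=np.asarray(self.ref)[index],
            alt=np.asarray(self.alt)[index],
            info={k: np.asarray(v)[index] for k, v in self.info.items()},
            ids=list(self.ids),
            dosage=self.dosage[index],
            gq=self.gq[index],
            dp=self.dp[index],
        )

    def take_individuals(self, index) -> "VariantTable":
        index = np.asarray(index)
        return VariantTable(
            chrom=np.asarray(self.chrom).copy(),
            pos=self.pos.copy(),
            ref=np.asarray(self.ref).copy(),
            alt=np.asarray(self.alt).copy(),
            info={k: np.asarray(v).copy() for k, v in self.info.items()},
            ids=[self.ids[i] for i in index],
            dosage=self.dosage[:, index],
            gq=self.gq[:, index],
            dp=self.dp[:, index],
        )

    def copy(self) -> "VariantTable":
        return self.take_sites(np.arange(self.n_sites))

    # ------------------------------------------------------------------
    def to_vcf(self, path) -> None:
        """Write as uncompressed VCF v4.2 with GT:GQ:DP calls."""
        chroms = np.asarray(self.chrom)
        with open(path, "w") as fh:
            length = int(self.pos.max()) + 1000 if self.n_sites else 1000
            fh.write(_VCF_HEADER.format(chrom=chroms[0] if self.n_sites else "1",
                                        length=length))
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.ids) + "\n")
            fs = self.info.get("FS", np.zeros(self.n_sites))
            mq = self.info.get("MQ", np.full(self.n_sites, 60.0))
            for i in range(self.n_sites):
                calls = []
                for j in range(self.n_individuals):
                    d = int(self.dosage[i, j])
                    if d == MISSING:
                        calls.append("./.:.:.")
                    else:
                        calls.append(f"{_GT_STR[d]}:{int(self.gq[i, j])}:{int(self.dp[i, j])}")
                fh.write(
                    f"{chroms[i]}\t{int(self.pos[i])}\t.\t{self.ref[i]}\t{self.alt[i]}"
                    f"\t.\t.\tFS={fs[i]:.3f};MQ={mq[i]:.3f}\tGT:GQ:DP\t"
                    + "\t".join(calls) + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "VariantTable":
        """Read a VCF (v4.2, GT:GQ:DP) into a :class:`VariantTable`.

        Multiallelic records are kept with ``alt`` joined by commas so the
        biallelic filter can identify and drop them.
        """
        reader = VCF(str(path))
        ids = list(reader.samples)
        chrom, pos, ref, alt, fs, mq, dos, gq, dp = [], [], [], [], [], [], [], [], []
        for rec in reader:
            chrom.append(rec.CHROM)
            pos.append(rec.POS)
            ref.append(rec.REF)
            alt.append(",".join(rec.ALT) if rec.ALT else ".")
            fs.append(rec.INFO.get("FS", 0.0))
            mq.append(rec.INFO.get("MQ", 60.0))
            row = np.full(len(ids), MISSING, dtype=np.int8)
            for j, g in enumerate(rec.genotypes):
                a = [x for x in g[:-1] if x >= 0]
                if len(a) == 2:
                    row[j] = a[0] + a[1]
            dos.append(row)
            for buf, name in ((gq, "GQ"), (dp, "DP")):
                vals = rec.format(name)
                if vals is None:
                    buf.append(np.full(len(ids), MISSING, dtype=np.int16))
                else:
                    v = vals.astype(np.int64).ravel()
                    v[(v < 0) | (v > 32000)] = MISSING  # cyvcf2 encodes '.' as INT_MIN
                    buf.append(v.astype(np.int16))
        reader.close()
        n = len(pos)
        return cls(
            chrom=np.asarray(chrom, dtype=object),
            pos=np.asarray(pos, dtype=np.int64),
            ref=np.asarray(ref, dtype=object),
            alt=np.asarray(alt, dtype=object),
            info={"FS": np.asarray(fs, float), "MQ": np.asarray(mq, float)},
            ids=ids,
            dosage=np.vstack(dos) if n else np.empty((0, len(ids)), np.int8),
            gq=np.vstack(gq) if n else np.empty((0, len(ids)), np.int16),
            dp=np.vstack(dp) if n else np.empty((0, len(ids)), np.int16),
        )
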