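"""Synthetic data with known ground truth for the whole pipeline.

Generates the four kinds of input the analysis consumes:

* **Genotypes** — biallelic SNP dosages under a hierarchical Balding-Nichols
  model: an ancestral allele frequency per site, a clade frequency drawn
  around it with drift coefficient ``F_clade``, a deme frequency drawn
  around that with ``F_deme``, and Hardy-Weinberg draws per individual, plus
  i.i.d. missingness and optional genotyping error.  The two-level design
  mirrors the east/west clade split with forest and prairie demes nested
  inside each clade.
* **Tail/body traits** — the ratio is a baseline plus an additive forest
  effect plus a genetic value with covariance proportional to twice the
  realized kinship of the simulated genotypes plus i.i.d. noise.  Because
  forest demes can be nested inside clades, the habitat effect is
  confounded with genetic structure by construction — exactly the situation
  the mixed-model stage is meant to handle.
* **Vertebral columns** — six sacral vertebrae plus a caudal series whose
  count is a discretised normal (truncated at 10) and whose per-position
  lengths follow a unimodal deme profile, scaled by an individual lognormal
  body-size factor (allometry) and, in forest demes, stretched by an
  elongation factor on a contiguous window of caudal positions.
* **F2 intercross** — two unlinked (by default) diallelic loci, one per
  trait, with configurable dominance (d/a) per locus; parental lines fixed
  for alternative alleles, F1 fully heterozygous, F2 assembled from F1
  gametes with a configurable recombination fraction.

All simulators are deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import king_kinship
from .lmm import kinship_similarity
from .variants import MISSING, VariantTable

# ---------------------------------------------------------------------------
# configuration

#: Piecewise-linear template for mean caudal vertebra length (mm) by caudal
#: position: rises to a peak around positions 5-8 and tapers down the tail.
_PROFILE_ANCHORS = ((1, 2.8), (6, 4.2), (16, 3.6), (30, 1.2))


def default_caudal_profile(n_positions: int = 30) -> np.ndarray:
    pos = np.arange(1, n_positions + 1, dtype=float)
    xs = [a[0] for a in _PROFILE_ANCHORS]
    ys = [a[1] for a in _PROFILE_ANCHORS]
    return np.interp(pos, xs, ys)


@dataclass
class DemeConfig:
    """One deme: its clade, habitat, sample size, and vertebral parameters."""

    label: str
    clade: str
    habitat: str                      # "forest" | "nonforest"
    n_individuals: int = 10
    mu_count: float = 20.0            # mean caudal vertebra count
    sd_count: float = 1.0
    profile: np.ndarray = field(default_factory=default_caudal_profile)
    elongation_factor: float = 1.0
    elongation_window: tuple = (4, 16)  # 1-based caudal positions, inclusive
    sacral_mu: float = 2.8            # mean single sacral vertebra length, mm
    allometry_slope: float = 1.0      # vertebra length ~ size**slope

    def __post_init__(self):
        self.profile = np.asarray(self.profile, float)
        if self.habitat not in ("forest", "nonforest"):
            raise ValueError(f"deme {self.label}: habitat must be forest or nonforest")
        if self.n_individuals < 1:
            raise ValueError(f"deme {self.label}: n_individuals must be >= 1")
        if np.any(self.profile <= 0):
            raise ValueError(f"deme {self.label}: profile lengths must be > 0")
        if self.mu_count + 6.0 * self.sd_count > len(self.profile):
            raise ValueError(
                f"deme {self.label}: caudal profile ({len(self.profile)} positions) "
                "shorter than the maximum plausible count")


@dataclass
class WorldConfig:
    """Parameters of the synthetic world.

    The defaults describe two clades (east and west), each containing one
    forest and one nonforest deme; forest demes carry three extra caudal
    vertebrae and a 1.3x elongation on caudal positions 4-16, and a +0.15
    additive forest effect on the tail/body ratio.
    """

    demes: list = field(default_factory=list)
    n_sites: int = 2000
    ancestral_freq_range: tuple = (0.1, 0.9)
    F_clade: float = 0.1
    F_deme: float = 0.05
    missing_rate: float = 0.02
    geno_error_rate: float = 0.005
    trait_mu: float = 0.75            # baseline (nonforest) tail/body ratio
    beta_habitat: float = 0.15        # additive forest effect on the ratio
    sigma_g: float = 0.05             # genetic SD of the ratio
    sigma_e: float = 0.04             # residual SD of the ratio
    body_mu_mm: float = 80.0          # median body length (lognormal)
    body_sigma: float = 0.06          # lognormal sigma of body length
    size_sigma: float = 0.06          # lognormal sigma of the skeletal size factor
    sacral_sd_frac: float = 0.05      # sacral length CV around the deme mean
    measurement_sd_mm: float = 0.15   # per-vertebra measurement noise
    seed: int = 0

    def __post_init__(self):
        for name in ("missing_rate", "geno_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("F_clade", "F_deme"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must lie inside (0, 1)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name in ("sigma_g", "sigma_e", "body_sigma", "size_sigma",
                     "sacral_sd_frac", "measurement_sd_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # -- canonical worlds ------------------------------------------------
    @classmethod
    def default(cls, n_per_deme: int = 10, **kwargs) -> "WorldConfig":
        """Two clades x (forest + nonforest): habitat balanced across clades."""
        demes = []
        for clade in ("east", "west"):
            for habitat in ("forest", "nonforest"):
                demes.append(_make_deme(f"{clade}_{habitat}", clade, habitat,
                                        n_per_deme))
        return cls(demes=demes, **kwargs)

    @classmethod
    def confounded(cls, n_per_deme: int = 10, **kwargs) -> "WorldConfig":
        """Habitat perfectly aligned with clade: both forest demes in one
        clade, both nonforest demes in the other.  The stress case for a
        naive habitat test."""
        demes = [
            _make_deme("east_forest_a", "east", "forest", n_per_deme),
            _make_deme("east_forest_b", "east", "forest", n_per_deme),
            _make_deme("west_prairie_a", "west", "nonforest", n_per_deme),
            _make_deme("west_prairie_b", "west", "nonforest", n_per_deme),
        ]
        return cls(demes=demes, **kwargs)

    @property
    def n_individuals(self) -> int:
        return sum(d.n_individuals for d in self.demes)

    @property
    def clades(self) -> list:
        return list(dict.fromkeys(d.clade for d in self.demes))

    def individual_table(self) -> pd.DataFrame:
        rows = []
        for d in self.demes:
            for i in range(d.n_individuals):
                rows.append({"individual_id": f"{d.label}_{i:02d}",
                             "population": d.label, "clade": d.clade,
                             "habitat": d.habitat})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for d in out["demes"]:
            d["profile"] = [round(float(x), 6) for x in d["profile"]]
            d["elongation_window"] = list(d["elongation_window"])
        out["ancestral_freq_range"] = list(out["ancestral_freq_range"])
        return out


def _make_deme(label: str, clade: str, habitat: str, n: int) -> DemeConfig:
    forest = habitat == "forest"
    return DemeConfig(label=label, clade=clade, habitat=habitat,
                      n_individuals=n,
                      mu_count=23.0 if forest else 20.0,
                      elongation_factor=1.3 if forest else 1.0)


@dataclass
class CrossSpec:
    """Two-locus genetic model of the prairie x forest intercross."""

    mu_count_prairie: float = 20.0
    mu_count_forest: float = 23.0
    mu_len_prairie: float = 4.2       # longest caudal vertebra, mm
    mu_len_forest: float = 5.5
    d_over_a_count: float = 0.0       # semidominant count locus
    d_over_a_len: float = 1.0         # forest-dominant length locus
    recomb_fraction: float = 0.5      # unlinked by default
    env_sd_count: float = 1.0
    env_sd_len: float = 0.35
    n_parental: int = 12              # per parental line
    n_F1: int = 10
    n_F2: int = 96
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.recomb_fraction <= 0.5):
            raise ValueError("recomb_fraction must lie in [0, 0.5]")
        if self.env_sd_count < 0 or self.env_sd_len < 0:
            raise ValueError("environmental SDs must be >= 0")
        for n in (self.n_parental, self.n_F1, self.n_F2):
            if n < 1:
                raise ValueError("generation sizes must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# genotypes


def _balding_nichols(rng, p_parent: np.ndarray, f: float) -> np.ndarray:
    """Daughter frequencies around parent frequencies with drift f."""
    if f == 0.0:
        return p_parent.copy()
    scale = (1.0 - f) / f
    return rng.beta(p_parent * scale, (1.0 - p_parent) * scale)


def simulate_genotypes(config: WorldConfig, seed: int | None = None) -> VariantTable:
    """Hierarchical Balding-Nichols genotypes for every configured deme."""
    if not config.demes:
        raise ValueError("world has no demes")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_sites = config.n_sites
    lo, hi = config.ancestral_freq_range
    p0 = rng.uniform(lo, hi, n_sites)

    clade_freq = {c: _balding_nichols(rng, p0, config.F_clade)
                  for c in config.clades}
    cols = []
    for deme in config.demes:
        p = _balding_nichols(rng, clade_freq[deme.clade], config.F_deme)
        p = np.clip(p, 1e-9, 1.0 - 1e-9)
        cols.append(rng.binomial(2, p[:, None], (n_sites, deme.n_individuals)))
    dosage = np.concatenate(cols, axis=1).astype(np.int8)
    n_ind = dosage.shape[1]

    if config.geno_error_rate > 0:
        err = rng.random((n_sites, n_ind)) < config.geno_error_rate
        shift = rng.integers(1, 3, size=err.sum())
        dosage[err] = ((dosage[err] + shift) % 3).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random((n_sites, n_ind)) < config.missing_rate
        dosage[miss] = MISSING

    pos = np.cumsum(rng.integers(20, 200, n_sites)).astype(np.int64)
    gq = np.clip(rng.normal(60.0, 15.0, (n_sites, n_ind)), 0, 99).astype(np.int16)
    dp = rng.poisson(20.0, (n_sites, n_ind)).astype(np.int16)
    gq[dosage == MISSING] = MISSING
    dp[dosage == MISSING] = MISSING
    fs = rng.exponential(5.0, n_sites)
    mq = np.where(rng.random(n_sites) < 0.02, 45.0, 60.0)

    ids = config.individual_table()["individual_id"].tolist()
    bases = np.array(["A", "C", "G", "T"], dtype=object)
    ref = bases[rng.integers(0, 4, n_sites)]
    alt = np.array([bases[(list(bases).index(r) + int(k)) % 4]
                    for r, k in zip(ref, rng.integers(1, 4, n_sites))],
                   dtype=object)
    return VariantTable(chrom=np.full(n_sites, "1", dtype=object), pos=pos,
                        ref=ref, alt=alt,
                        info={"FS": np.round(fs, 3), "MQ": mq},
                        ids=ids, dosage=dosage, gq=gq, dp=dp)


# ---------------------------------------------------------------------------
# traits


def simulate_traits(config: WorldConfig, variants: VariantTable,
                    seed: int | None = None) -> pd.DataFrame:
    """Sample records (tail/body ratio, tail, body) for the genotyped panel.

    ratio = trait_mu + beta_habitat * 1[forest] + g + e with
    g ~ N(0, sigma_g^2 * S) where S is twice the realized KING kinship of
    ``variants`` (PSD-repaired), and e ~ N(0, sigma_e^2).  Body length is
    lognormal; tail = ratio * body.
    """
    meta = config.individual_table()
    if list(meta["individual_id"]) != list(variants.ids):
        raise ValueError("variant table individuals do not match the world config")
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    n = len(meta)
    forest = (meta["habitat"] == "forest").to_numpy(float)

    if config.sigma_g > 0:
        sim = kinship_similarity(king_kinship(variants))
        w, u = np.linalg.eigh(sim.s)
        root = u * np.sqrt(np.clip(w, 0.0, None))
        g = config.sigma_g * (root @ rng.standard_normal(n))
    else:
        g = np.zeros(n)
    e = rng.normal(0.0, config.sigma_e, n)
    ratio = config.trait_mu + config.beta_habitat * forest + g + e
    body = config.body_mu_mm * np.exp(rng.normal(0.0, config.body_sigma, n))
    out = meta.copy()
    out["body_mm"] = np.round(body, 3)
    out["tail_mm"] = np.round(ratio * body, 3)
    return out


# ---------------------------------------------------------------------------
# vertebral columns

from .vertebrae import N_SACRAL, VertebralColumn  # noqa: E402  (shared constant)


def simulate_columns(config: WorldConfig, seed: int | None = None,
                     id_prefix: str = "V") -> list:
    """Vertebral columns (6 sacral + caudal series) for every deme."""
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    columns = []
    for deme in config.demes:
        prof = deme.profile
        w0, w1 = deme.elongation_window
        factor = np.ones(len(prof))
        factor[w0 - 1: w1] = deme.elongation_factor
        for i in range(deme.n_individuals):
            size = float(np.exp(rng.normal(0.0, config.size_sigma)))
            sacral = rng.normal(deme.sacral_mu * size,
                                config.sacral_sd_frac * deme.sacral_mu,
                                N_SACRAL)
            count = int(round(rng.normal(deme.mu_count, deme.sd_count)))
            count = max(count, 10)
            if count > len(prof):
                raise ValueError(
                    f"deme {deme.label}: drew caudal count {count} beyond the "
                    f"{len(prof)}-position profile")
            mean_caudal = prof[:count] * factor[:count] * size ** deme.allometry_slope
            caudal = mean_caudal + rng.normal(0.0, config.measurement_sd_mm, count)
            lengths = np.clip(np.concatenate([sacral, caudal]), 0.05, None)
            columns.append(VertebralColumn(
                individual_id=f"{id_prefix}_{deme.label}_{i:02d}",
                lengths_mm=np.round(lengths, 4),
                population=deme.label, habitat=deme.habitat))
    return columns


def columns_to_frame(columns) -> pd.DataFrame:
    """Long-format table: individual_id, population, habitat, position, length_mm."""
    rows = []
    for c in columns:
        for p, length in enumerate(c.lengths_mm, start=1):
            rows.append({"individual_id": c.individual_id,
                         "population": c.population, "habitat": c.habitat,
                         "position": p, "length_mm": float(length)})
    return pd.DataFrame(rows)


def columns_from_frame(df: pd.DataFrame) -> list:
    cols = []
    for ind, grp in df.groupby("individual_id", sort=False):
        grp = grp.sort_values("position")
        if list(grp["position"]) != list(range(1, len(grp) + 1)):
            raise ValueError(f"{ind}: positions must be 1..N without gaps")
        cols.append(VertebralColumn(
            individual_id=str(ind),
            lengths_mm=grp["length_mm"].to_numpy(float),
            population=str(grp["population"].iloc[0]) if "population" in grp else "",
            habitat=str(grp["habitat"].iloc[0]) if "habitat" in grp else ""))
    return cols


# ---------------------------------------------------------------------------
# intercross

from .intercross import F2Dataset  # noqa: E402


def _genotypic_value(g: np.ndarray, mid: float, a: float, d: float) -> np.ndarray:
    return np.where(g == 1, mid + d, mid + a * (g - 1.0))


def simulate_intercross(spec: CrossSpec, seed: int | None = None,
                        pleiotropic: bool = False) -> F2Dataset:
    """Simulate the reciprocal intercross under the two-locus model.

    With ``pleiotropic=True`` a single shared locus drives both traits
    (using the per-trait effect sizes of ``spec``); otherwise the count and
    length loci are separate, with gametes recombining at
    ``spec.recomb_fraction``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mid_c = (spec.mu_count_forest + spec.mu_count_prairie) / 2.0
    a_c = (spec.mu_count_forest - spec.mu_count_prairie) / 2.0
    d_c = spec.d_over_a_count * a_c
    mid_l = (spec.mu_len_forest + spec.mu_len_prairie) / 2.0
    a_l = (spec.mu_len_forest - spec.mu_len_prairie) / 2.0
    d_l = spec.d_over_a_len * a_l

    def gametes(n):
        """Alleles at the two loci for n F1 gametes (AB/ab haplotypes)."""
        a1 = rng.integers(0, 2, n)
        recomb = rng.random(n) < spec.recomb_fraction
        a2 = np.where(recomb, 1 - a1, a1)
        return a1, a2

    rows = []

    def add(generation, g_count, g_len):
        n = len(g_count)
        counts = _genotypic_value(g_count, mid_c, a_c, d_c) \
            + rng.normal(0.0, spec.env_sd_count, n)
        lens = _genotypic_value(g_len, mid_l, a_l, d_l) \
            + rng.normal(0.0, spec.env_sd_len, n)
        for i in range(n):
            rows.append({"generation": generation,
                         "caudal_count": max(int(round(counts[i])), 1),
                         "longest_caudal_mm": round(max(float(lens[i]), 0.1), 4),
                         "geno_count": int(g_count[i]),
                         "geno_len": int(g_len[i])})

    zeros = np.zeros(spec.n_parental, int)
    add("P_prairie", zeros, zeros)
    add("P_forest", zeros + 2, zeros + 2)
    ones = np.ones(spec.n_F1, int)
    add("F1", ones, ones)
    if pleiotropic:
        g = rng.integers(0, 2, spec.n_F2) + rng.integers(0, 2, spec.n_F2)
        add("F2", g, g)
    else:
        m1, m2 = gametes(spec.n_F2)
        p1, p2 = gametes(spec.n_F2)
        add("F2", m1 + p1, m2 + p2)
    return F2Dataset(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixtures(directory, variants: VariantTable | None = None,
                   samples: pd.DataFrame | None = None,
                   columns=None, cross: F2Dataset | None = None,
                   config: WorldConfig | None = None,
                   cross_spec: CrossSpec | None = None) -> dict:
    """Write world outputs in the formats the pipeline reads.

    Produces (for whichever inputs are given) ``genotypes.vcf``,
    ``samples.csv``, ``vertebrae.csv`` (long format), ``cross.csv`` and
    ``truth.json`` holding the generating parameters.  Returns a dict of
    written paths.  All files round-trip losslessly through the package's
    readers.
    """
    os.makedirs(directory, exist_ok=True)
    written = {}

    def path(name):
        return os.path.join(directory, name)

    if variants is not None:
        variants.to_vcf(path("genotypes.vcf"))
        written["vcf"] = path("genotypes.vcf")
    if samples is not None:
        samples.to_csv(path("samples.csv"), index=False, float_format="%.4f")
        written["samples"] = path("samples.csv")
    if columns is not None:
        columns_to_frame(columns).to_csv(path("vertebrae.csv"), index=False,
                                         float_format="%.4f")
        written["vertebrae"] = path("vertebrae.csv")
    if cross is not None:
        cross.to_csv(path("cross.csv"))
        written["cross"] = path("cross.csv")

    truth: dict = {}
    if config is not None:
        truth["world"] = config.to_dict()
        truth["seed"] = config.seed
    if cross_spec is not None:
        truth["cross"] = cross_spec.to_dict()
    if truth:
        with open(path("truth.json"), "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written["truth"] = path("truth.json")
    return written
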