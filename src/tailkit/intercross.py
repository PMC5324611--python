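"""F2 intercross analysis: dominance, trait decoupling, and power.

A prairie x forest cross produces F1 hybrids and, by sib-mating F1s, an F2
generation in which recombination reshuffles unlinked loci.  If caudal
vertebra *number* and caudal vertebra *length* are controlled by different
genomic regions, the two traits should be uncorrelated among F2s; a
significant F2 correlation would instead point to pleiotropy or tight
linkage.  The module classifies dominance from the parental/F1 means,
runs the F2 Pearson correlation test, and computes the power of that test
both analytically (Fisher z) and by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GENERATIONS = ("P_prairie", "P_forest", "F1", "F2")


@dataclass
class F2Dataset:
    """Phenotypes of a two-line intercross.

    ``table`` columns: ``generation`` in {P_prairie, P_forest, F1, F2},
    ``caudal_count`` (positive integer), ``longest_caudal_mm`` (> 0); for
    synthetic data, optional true genotype columns ``geno_count`` and
    ``geno_len`` (0/1/2 forest-allele dosages).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        unknown = set(t["generation"]) - set(GENERATIONS)
        if unknown:
            raise ValueError(f"unknown generation labels: {sorted(unknown)}")
        if (t["caudal_count"] <= 0).any() or (t["longest_caudal_mm"] <= 0).any():
            raise ValueError("counts and lengths must be positive")

    def generation(self, label: str) -> pd.DataFrame:
        return self.table[self.table["generation"] == label]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "F2Dataset":
        return cls(pd.read_csv(path))


@dataclass
class DominanceResult:
    trait: str
    a: float                # half the parental difference (forest - prairie)
    d: float                # F1 deviation from the midparent
    d_over_a: float
    classification: str


def dominance_index(data: F2Dataset, trait: str = "caudal_count") -> DominanceResult:
    """Dominance ratio d/a of the forest allele for one trait.

    a = (forest parental mean - prairie parental mean) / 2, d = F1 mean -
    midparent.  Classification: |d/a| <= 0.25 "semidominant/additive",
    d/a >= 0.75 "forest-dominant", d/a <= -0.75 "prairie-dominant",
    otherwise "partial".  Raises when the parental lines are
    indistinguishable (a ~ 0) or any required generation has < 2 animals.
    """
    for gen in ("P_prairie", "P_forest", "F1"):
        if len(data.generation(gen)) < 2:
            raise ValueError(f"generation {gen} needs at least two individuals")
    mean_p = data.generation("P_prairie")[trait].mean()
    mean_f = data.generation("P_forest")[trait].mean()
    mean_f1 = data.generation("F1")[trait].mean()
    a = (mean_f - mean_p) / 2.0
    scale = max(abs(mean_f), abs(mean_p), 1e-12)
    if abs(a) < 1e-8 * scale:
        raise ValueError("parental lines indistinguishable; d/a undefined")
    d = mean_f1 - (mean_f + mean_p) / 2.0
    ratio = d / a
    if abs(ratio) <= 0.25:
        label = "semidominant/additive"
    elif ratio >= 0.75:
        label = "forest-dominant"
    elif ratio <= -0.75:
        label = "prairie-dominant"
    else:
        label = "partial"
    return DominanceResult(trait=trait, a=float(a), d=float(d),
                           d_over_a=float(ratio), classification=label)


@dataclass
class DecouplingResult:
    r: float
    t: float
    df: int
    p_value: float
    n: int


def decoupling_test(data: F2Dataset) -> DecouplingResult:
    """Pearson correlation of caudal count and longest vertebra among F2s.

    t = r * sqrt(df / (1 - r^2)) with df = n - 2, two-sided p.  Parental and
    F1 animals are excluded: only the recombinant generation is informative
    about linkage.
    """
    f2 = data.generation("F2")
    n = len(f2)
    if n < 4:
        raise ValueError("decoupling test needs at least four F2 individuals")
    x = f2["caudal_count"].to_numpy(float)
    y = f2["longest_caudal_mm"].to_numpy(float)
    if np.var(x) <= 0 or np.var(y) <= 0:
        raise ValueError("zero variance in a trait; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return DecouplingResult(r=r, t=float(t), df=df, p_value=p, n=n)


def correlation_power(n: int, rho: float, alpha: float = 0.05,
                      method: str = "analytic", sides: int = 1,
                      reps: int = 20000, seed: int | None = None) -> float:
    """Power of the Pearson correlation test to detect a true rho.

    Analytic: the Fisher z approximation — atanh(r) of a bivariate-normal
    sample is approximately N(atanh(rho), 1/(n-3)), so one-sided power is
    Phi(atanh(rho) * sqrt(n-3) - z_{1-alpha}); the two-sided version uses
    z_{1-alpha/2} and adds the (usually negligible) opposite tail.
    Simulation: the rejection fraction of ``decoupling_test``-style t tests
    over ``reps`` bivariate-normal samples of size n.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")

    if method == "analytic":
        shift = np.arctanh(rho) * np.sqrt(n - 3.0)
        if sides == 1:
            return float(stats.norm.cdf(shift - stats.norm.ppf(1.0 - alpha)))
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return float(stats.norm.cdf(shift - z) + stats.norm.cdf(-shift - z))
    if method != "simulation":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    df = n - 2
    x = rng.standard_normal((reps, n))
    e = rng.standard_normal((reps, n))
    y = rho * x + np.sqrt(1.0 - rho * rho) * e
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = (xc * yc).sum(axis=1) / np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    t = r * np.sqrt(df / (1.0 - r ** 2))
    if sides == 1:
        reject = t > stats.t.ppf(1.0 - alpha, df)
    else:
        reject = np.abs(t) > stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(reject.mean())


def decoupling_power_curve(spec, pleiotropy: bool = False, reps: int = 1000,
                           seed: int | None = None, alpha: float = 0.05) -> float:
    """Rejection rate of the F2 decoupling test under a genetic model.

    Simulates the full cross ``reps`` times.  Under ``pleiotropy=True`` a
    single locus drives both traits (one shared genotype per F2, with the
    count-locus and length-locus effect sizes from ``spec``); otherwise the
    two-locus model of ``spec`` applies, with its recombination fraction.
    Returns the fraction of replicates in which the Pearson test rejects at
    ``alpha``.
    """
    from .synthetic import simulate_intercross  # local import: avoid cycle

    ss = np.random.SeedSequence(seed)
    n_reject = 0
    for child in ss.spawn(reps):
        child_seed = int(child.generate_state(1)[0] % (2 ** 31))
        d = simulate_intercross(spec, seed=child_seed, pleiotropic=pleiotropy)
        if decoupling_test(d).p_value < alpha:
            n_reject += 1
    return n_reject / reps
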