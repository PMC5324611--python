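# Methods

This note documents the statistical machinery in `tailkit`: the models and
their assumptions, the defaults and why they were chosen, what the
synthetic world does and does not emulate, and the numerical conventions.

## Variant filtering

Calls are masked to missing when GQ < 20 or DP < 4; sites are then removed,
in a fixed and logged order, when they are non-biallelic, belong to a run of
≥ 3 variants spanning < 10 bp, have FS > 60 or MQ < 60 or mean GQ < 20, are
missing in more than half of the individuals (or genotyped in fewer than 4),
or fail the exact Hardy–Weinberg test at p < 0.01. These thresholds are the
standard hard-filter values for capture-based SNP data and are all
configurable (`FilterConfig`). Masking precedes the site-level statistics,
so missingness and HWE see the post-masking calls. Each site is charged to
the first rule that removes it; the filter is idempotent because the cluster
rule removes every member of a qualifying run.

The HWE test is the exact conditional test: holding the allele counts
fixed, heterozygote counts of the same parity are enumerated with weights
2^h · n! / (n_AA! h! n_aa!), and the p-value sums the probabilities of all
outcomes no more probable than the observed one (evaluated with a stable
ratio recurrence). The test is pooled across all individuals rather than
stratified by population; under structure this removes more sites (a
Wahlund effect), which is the desired conservative behaviour for
tree-building but should be kept in mind when interpreting filter logs.

## F_ST and kinship

Weir–Cockerham variance components are computed per site with the
unequal-sample-size corrections; both the weighted global estimate
Σa/Σ(a+b+c) and the mean of per-site ratios are reported, since the two can
differ appreciably when many sites are weakly informative. Monomorphic
sites are excluded from both. The estimator carries O(1/n) finite-sample
corrections, so duplicating every individual shifts the estimate slightly;
this is a property of the estimator, not a bug.

Kinship uses the robust between-family KING estimator from
heterozygote/opposite-homozygote counts over jointly genotyped sites. It
needs no allele-frequency estimates, which makes it robust to structure;
the price is that unrelated pairs from different demes get *negative*
estimates. The diagonal is 0.5 by convention. For use as a mixed-model
covariance the matrix 2φ̂ is repaired to positive semi-definiteness by
clipping negative eigenvalues at zero.

## PCA and Tracy–Widom significance

Sites genotyped in more than half the individuals are mean-imputed,
centred, and scaled by the binomial SD √(p(1−p)); the individual-level
covariance is eigendecomposed, and scores are eigenvectors scaled by the
square root of their eigenvalues. Each leading eigenvalue is tested against
the Tracy–Widom (β = 1) edge law: the remaining spectrum gives a
moment-matching estimate of the effective marker count,
n′ = (m+1)(Σλ)² / (mΣλ² − (Σλ)²), and the eigenvalue is standardised with
the (n′, m) Wishart edge mean and scale. (The m — not m−1 — in the
denominator matters: it follows from E tr W = mn′σ² and
E tr W² = n′m(n′+m+1)σ⁴ for a white Wishart, and the variant with m−1
overstates n′ badly when n ≲ m², declaring every component significant.)
The TW1 CDF is evaluated with Chiani's shifted-gamma closed form
(shape 46.446, scale 0.18605, shift −9.84801), accurate to ~10⁻⁴ in
probability; the unit tests pin it against published quantiles (0.9793 at
95%, 2.0234 at 99%) and numerically integrated moments. `k_significant`
counts the leading run of components with p < 0.05; under panmictic nulls
the per-component size measures ≈ 0.03–0.05.

## Trees and monophyly

Neighbor joining (Saitou–Nei with Studier–Keppler updates, via scikit-bio)
is applied to Euclidean distances over the significant PC scores. NJ
reproduces any additive metric exactly; slightly negative branch lengths on
noisy input are clamped to zero and counted. Monophyly of a tip set on the
unrooted tree holds iff some edge bipartitions exactly that set against the
rest — no rooting assumptions are involved.

## Independent contrasts and the mixed model

PIC uses the Felsenstein pruning recursion (daughter-weighted node values,
branch adjustment v′ = v + v₁v₂/(v₁+v₂), standardisation by √(v₁+v₂)) on
the midpoint-rooted tree with polytomies resolved by zero-length edges;
branch lengths are floored at 10⁻¹² so zero-length resolutions stay
numerically safe. The contrast regression is through the origin, and its
slope is algebraically identical to phylogenetic GLS with the tree
covariance (tested to 10⁻⁸ against a dense GLS oracle). Because the
predictor here is a binary habitat indicator, the Brownian assumption is
only an approximation for it; the package reports the ratio-on-habitat
regression as primary and the reversed ordering is a column swap away.

The mixed model y = Xβ + u + e with u ~ N(0, σ²_g S) is fitted by exact
REML: S = UDU′ rotates the problem to a diagonal covariance and the
criterion is profiled to a one-dimensional search over
λ = σ²_g/σ²_e (log-scale bounded search, with the λ = 0 boundary checked
explicitly). The habitat effect is tested with a Wald statistic using the
Kenward–Roger small-sample machinery: the adjusted fixed-effect covariance
(exact here because the covariance is linear in the variance parameters)
and the Satterthwaite-form denominator df, to which the KR formulas reduce
exactly for a single-df contrast (scale factor 1). The residual-df
convention n − rank(X) was evaluated first and rejected: with habitat
aligned to clade — the very confound the model exists to absorb — it gave a
type-I error of ~0.15 at n = 40, because the information about the habitat
contrast comes from effectively two clade-level observations. The KR test
measures ~0.07 over 1500 simulated confounded nulls, against ~0.33 for the
naive regression, and it reduces exactly to OLS (residual df) when S = I.
With S = cS the fitted λ rescales by 1/c, leaving β̂, the Wald statistic
and fitted values unchanged.

Population-level fits use mean ratios of populations with ≥ 3 individuals
and the similarity S = 1 − F_ST (diagonal 1, PSD-repaired). That transform
is one defensible mapping from differentiation to covariance, not the only
one; since the population-level model has very few residual df, it is
refused below four populations unless explicitly overridden.

## Vertebral morphometrics

All analyses apply the fixed sacral convention (positions 1–6 sacral,
caudal positions re-indexed from 1), which makes counts comparable even
when the anatomical boundary is ambiguous. Size correction regresses a
response on the sacral sum in one pooled OLS (with intercept) across all
individuals, attaching residuals; group tests then use residuals so that
body-size differences cannot masquerade as tail differences. Group
comparisons: two-sided Mann–Whitney rank-sum tests with mid-rank tie
handling, Kruskal–Wallis across all groups on the caudal count, and a
two-way ANCOVA of log totals and log longest vertebra on habitat,
population, and log sacral length.

Per-position medians are computed only where at least half of a group
possesses that vertebra; ragged trailing positions are flagged. The
elongated segment is the maximal contiguous run of positions where the
longer-tailed group's median exceeds the reference value (the median over
the shorter-tailed group of each individual's longest vertebra); with
identical groups it is empty by construction, since each individual's
maximum bounds its value at any position.

The insertion counterfactual gives each short-tailed individual k extra
copies of its own longest caudal vertebra at caudal position ⌊N/2⌋ (k
defaults to the rounded group difference in mean counts). Using the
individual's longest vertebra makes the compensation fraction an upper
bound on the contribution of vertebra *number*; a `local_median` mode
inserts the group median length at the insertion point instead. The
fraction is exactly 1 when the groups differ only by k copies of the
longest vertebra, equals kE[longest]/Δ under pure elongation, is monotone
nondecreasing in k, and is reported with its numerator and denominator;
when the "long" group is not actually longer the statistic is undefined
and returned as such, never as a number.

## Intercross analysis

Dominance: a = half the parental difference, d = F1 deviation from the
midparent; |d/a| ≤ 0.25 is called semidominant/additive, ≥ 0.75
forest-dominant, ≤ −0.75 prairie-dominant, otherwise partial. The
thresholds are this package's convention for turning a continuous ratio
into the qualitative labels used in the field.

The decoupling test is the Pearson correlation between caudal count and
longest vertebra among F2 individuals only (t = r√(df/(1−r²)), df = n − 2,
two-sided); parental and F1 animals are excluded because only the
recombinant generation is informative about linkage. Power: the Fisher-z
analytic form Φ(atanh ρ·√(n−3) − z₁₋α) one-sided, with the two-sided
analogue adding the opposite tail at z₁₋α/₂. For the design of record
(n = 96, ρ = 0.25, α = 0.05) the one-sided analytic power is 79.3% and a
20,000-replicate simulation gives ~80.1%; the two-sided version is ~70%,
so the conventional "80% power" planning number corresponds to the
one-sided calculation. Both sidednesses are exposed.

## The synthetic world

The generator emulates the statistical structure the analyses assume, with
known ground truth; defaults (all in `WorldConfig`/`CrossSpec`):

* **Genotypes**: 2 clades × (forest + nonforest) demes, 10 individuals per
  deme, 2000 sites; ancestral frequencies U(0.1, 0.9); Balding–Nichols
  drift F_clade = 0.1 and F_deme = 0.05 (clade-level differentiation of
  ~0.13 and within-clade ~0.05, a nested structure of the kind seen in
  continent-wide small-mammal samples); missingness 2%, genotype error
  0.5%; GQ ~ N(60, 15), DP ~ Poisson(20), FS ~ Exp(5), 2% of sites with
  MQ 45 — so the default filters have genuine work to do.
* **Traits**: tail/body ratio = 0.75 + 0.15·1[forest] + g + e with
  σ_g = 0.05, σ_e = 0.04 and g drawn with covariance σ²_g · 2φ̂ computed
  from the *realized* simulated genotypes by the package's own KING
  estimator (PSD-repaired). Tying the generating covariance to the realized
  kinship makes the mixed-model calibration experiment exact by
  construction: the model fitted is the model simulated. Body length is
  lognormal (median 80 mm, σ = 0.06); tail = ratio × body. The
  `confounded()` world puts both forest demes in one clade, which is the
  stress case where the naive two-group test is badly anticonservative.
* **Vertebrae**: caudal counts are discretised normals (prairie mean 20,
  forest 23, SD 1) truncated at 10; per-position mean lengths follow a
  piecewise-linear unimodal template (2.8 mm at position 1, peaking at
  4.2 mm at position 6, tapering to 1.2 mm at position 30), scaled by a
  lognormal individual size factor (σ = 0.06) that also scales the six
  sacral vertebrae (allometry exponent 1), with forest columns stretched by
  1.3× on caudal positions 4–16 and 0.15 mm measurement noise per
  vertebra. These values produce prairie tails of ~72 mm and forest tails
  of ~95 mm with a detectable elongated segment matching the generating
  window.
* **Cross**: parental lines fixed at a semidominant count locus
  (20 vs 23 vertebrae, d/a = 0) and a forest-dominant length locus
  (4.2 vs 5.5 mm, d/a = 1), unlinked by default (recombination fraction
  0.5); 12 animals per parental line, 10 F1s, 96 F2s; residual SDs 1
  vertebra and 0.35 mm. Counts are rounded to integers after adding noise.

What the generator does **not** emulate: linkage disequilibrium and
physical linkage maps (sites are exchangeable), sequencing reads and
capture efficiency, selection, migration after divergence, measurement
drift between radiographs, or polygenic architectures in the cross (one
locus per trait plus noise). Passing tests therefore certify the
statistical machinery under the stated generative models — not the
idiosyncrasies of any real capture dataset.

## Numerical conventions and edge cases

* Missing dosage is a dedicated sentinel (−1); mean imputation happens only
  inside PCA, never in F_ST or kinship.
* NJ branch lengths < 0 are clamped to 0 and counted.
* PSD repairs clip eigenvalues at 0 and record the pre-repair minimum.
* The REML search runs over log λ ∈ [−12, 12] with an explicit λ = 0
  comparison; hitting the bounds sets a `boundary` flag on the fit.
* Degenerate inputs raise rather than return numbers: monomorphic F_ST
  panels, zero-variance PCA input, all-zero contrast predictors, collinear
  decomposition predictors, negative compensation denominators.
* All simulators are deterministic given (config, seed); the pipeline
  splits one root seed per stage via `SeedSequence`, reports carry no
  timestamps, and the canonical fixture set reproduces recorded SHA-256
  checksums.

## Problem sizes

Default study sizes — 40 genotyped individuals × 2000 sites, 60 x-rayed
individuals (15 per deme), and a 12+12/10/96 cross — were chosen to match
the scale of the motivating system while keeping every simulation-based
check (hundreds of replicate worlds) comfortably runnable on a laptop.
Calibration experiments use 500–1500 replicates, which puts Monte-Carlo
standard errors near 0.01 on rejection rates.
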