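# tailkit

Tools for dissecting the evolution of tail length in deer mice
(*Peromyscus maniculatus*), a classic case of repeated local adaptation:
forest-dwelling populations have convergently evolved longer tails than
nearby prairie populations. `tailkit` implements the full inference chain a
study of this system needs, end to end:

1. **Population genetics** — hard filtering of biallelic SNP calls
   (clustered variants, strand bias FS, mapping quality MQ, genotype
   quality, depth, missingness, exact Hardy–Weinberg test), Weir–Cockerham
   F<sub>ST</sub> (per-site variance components *a*, *b*, *c*; weighted
   Σa/Σ(a+b+c) and mean-of-ratios summaries), KING-robust pairwise kinship
   φ̂ = (N<sub>Aa,Aa</sub> − 2N<sub>AA,aa</sub>) / (N<sub>Aa</sub><sup>(i)</sup> + N<sub>Aa</sub><sup>(j)</sup>),
   genotype PCA with Patterson normalisation and Tracy–Widom significance of
   leading components, and neighbor-joining trees from Euclidean distances
   in the significant PC subspace, with monophyly checks for the forest
   tips.
2. **Comparative analysis** — does habitat predict the tail/body ratio once
   genetic non-independence is accounted for? Phylogenetically independent
   contrasts (Felsenstein pruning, through-origin contrast regression) and a
   REML linear mixed model y = Xβ + u + e with u ~ N(0, σ²_g S), where S is
   the numerator relationship matrix 2φ̂ (individual level) or 1 −
   F<sub>ST</sub> (population level), tested with a Kenward–Roger
   small-sample Wald test.
3. **Vertebral morphometrics** — decomposing tail-length differences into
   *number* versus *length* of caudal vertebrae: the fixed sacral convention
   (first six vertebrae from the first sacral are "sacral", the rest
   caudal), allometric size correction on sacral length, rank and ANCOVA
   group tests, per-position median profiles with elongated-segment
   detection, the counterfactual "prairie + k" vertebra-insertion statistic
   (what fraction of the group difference in total caudal length is
   compensated by giving each short-tailed individual k extra copies of its
   longest vertebra), and the decomposition model
   `total ~ longest vertebra + caudal count`.
4. **F2 intercross genetics** — dominance classification (d/a) from
   parental and F1 means, the trait-decoupling Pearson test among F2
   recombinants (if vertebra number and length are controlled by unlinked
   loci, recombination makes them uncorrelated in the F2), and analytic
   (Fisher z) plus simulation power for that test.
5. **Synthetic world** — a ground-truthed generator for all of the above:
   hierarchical Balding–Nichols genotypes (clade then deme drift), traits
   with a genetic covariance tied to the realized kinship and a habitat
   effect confounded with structure, vertebral columns with
   population-specific counts and an elongation window, and a two-locus
   F1/F2 cross with configurable dominance and linkage. Everything is
   written in standard formats (VCF v4.2, CSV, Newick, JSON) and is
   byte-reproducible from a seed.

## Worked example

Run the whole pipeline on a synthetic world (two clades, each with one
forest and one prairie deme; forest demes carry +3 caudal vertebrae, a 1.3×
elongation on caudal positions 4–16, and a +0.15 habitat effect on the
tail/body ratio):

```bash
tailkit run --out demo_run --seed 11
```

The Markdown report (`demo_run/report.md`) prints:

```
## Population genetics
- sites in/out: 2000 / 1915
- significant PCs (Tracy-Widom p < 0.05): 3
- forest tips monophyletic: 0
- F_ST east_forest|east_nonforest: weighted 0.0486
- F_ST east_forest|west_forest: weighted 0.1338
...
## Habitat association
- kinship LMM habitat effect: 0.1721 (p = 2.11e-06)
...
## Vertebral morphometrics
- elongated caudal segment: [4, 16]
- prairie+4 compensation: 0.628
- total ~ longest + count R2: 0.989

## F2 intercross
- length locus d/a: 1.239 (forest-dominant)
- F2 decoupling: r = -0.096, t = -0.94, df = 94, p = 0.352
- power to detect r > 0.25 (one-sided): 0.793
```

Reading this: the two simulated clades (three significant PCs — the
four-deme structure) each contain forest mice, so the forest tips are not
monophyletic; the mixed model recovers the simulated +0.15 habitat effect
(β̂ = 0.172) despite the genetic confounding; the elongated caudal segment
is recovered exactly at positions 4–16; adding the count difference back to
prairie tails compensates 63% of the total difference (the rest is vertebra
elongation); the two-predictor decomposition explains 99% of tail-length
variance; and in the F2 the count and length traits are uncorrelated
(p = 0.35), as expected when separate unlinked loci control them.

Every subcommand is also available on its own (`tailkit filter`, `fst`,
`kinship`, `pca`, `tree`, `pic`, `lmm-individual`, `lmm-population`,
`summarize`, `compare`, `counterfactual`, `decompose`, `dominance`,
`decouple`, `power`, `fixtures`), reading the standard on-disk formats, so
real data can be substituted for any stage.

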