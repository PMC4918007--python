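# sulfidiv

Multivariate phenotypic divergence and gene flow across replicated
sulfidic/non-sulfidic fish population pairs.

## The problem

Hydrogen-sulfide-rich springs are toxic to most freshwater fish: H₂S
blocks oxidative phosphorylation, and resident livebearing fishes
(poeciliids of the genera *Gambusia* and *Poecilia*) evolve a
characteristic syndrome — larger but fewer offspring, enlarged heads for
aquatic surface respiration — in replicated population pairs that
straddle the spring/non-spring boundary. How strongly divergent
selection moves such pairs along the speciation continuum can be read
from three coupled signals: divergence in life histories, divergence in
body shape, and neutral genetic differentiation (reduced gene flow)
between adjacent habitats.

`sulfidiv` implements the full analysis chain for this kind of study as
a tested Python library:

- **Geometric morphometrics** — TPS landmark I/O, generalized
  Procrustes analysis (GPA), and relative warps (principal components of
  the aligned shapes in the tangent space), the shape variables of the
  downstream models.
- **Nested MANCOVAs** — Type-III SSCPs with sum-to-zero contrasts;
  Wilks' Λ with Rao's F approximation; partial η² = 1 − Λ^(1/s) and
  relative variance (partial variance / max partial variance per model);
  hierarchical backward pruning of interactions at P > 0.1; site-level
  tests of the between-site factors with site as the unit of
  replication.
- **Divergence vectors** — the canonical axis of the H₂S term of each
  MANCOVA, i.e. the first eigenvector of E⁻¹H: the linear combination of
  responses separating sulfidic from non-sulfidic habitats most strongly
  while controlling for the other model terms, with per-individual
  scores and projection of new individuals via the stored eigenvector
  coefficients.
- **Population genetics** — GenePop I/O, observed/unbiased expected
  heterozygosity, pairwise Weir–Cockerham θ (ratio-of-sums multilocus
  estimator, negative components retained), and Mantel / partial Mantel
  permutation tests (F_ST ~ habitat difference, controlling for clade).
- **Integration** — per-system divergence scores (mean non-sulfidic −
  sulfidic), a correlation-matrix PCA combining the life-history and
  shape axes into a single phenotypic-divergence variable (eigenvalue
  1 + |r|, variance fraction (1 + |r|)/2), and one-tailed
  Spearman/Pearson correlations of that variable with θ to the
  geographically closest non-sulfidic site and with H₂S concentration.
- **Synthetic data** — a generator that emulates the replicated study
  design (clades × paired systems), habitat effects scaling with H₂S,
  allometry, sexual dimorphism, a latent offspring size–number
  trade-off, head-enlargement landmark deformation, and Balding–Nichols
  genetic differentiation, so the entire pipeline is testable without
  any field data.

## Worked example

`examples/05_full_pipeline.py` generates the default ten-system study
and runs everything end to end:

```text
systems analysed: 10
phenotypic PC1 eigenvalue 1.89 (94.3 % of variance)
lh_vs_morph  rho = +0.867, one-tailed p = 0.0006, n = 10
phen_vs_fst  rho = +0.745, one-tailed p = 0.0067, n = 10
phen_vs_h2s  rho = +0.952, one-tailed p = 0.0000, n = 10
partial Mantel: r = +0.375, p = 0.0050
```

Reading: life-history and body-shape divergence rise together across
the ten sulfide systems (ρ = 0.87); their shared axis (PC1, 94 % of the
variance of the two standardized measures) increases with both neutral
genetic differentiation (ρ = 0.75 — stronger divergence, less gene
flow) and H₂S concentration (ρ = 0.95 — stronger selection, stronger
divergence). The partial Mantel test shows cross-habitat site pairs are
more differentiated than same-habitat pairs after controlling for
clade. The other examples exercise each capability separately
(`01` generator, `02` morphometrics, `03` MANCOVA + divergence vector,
`04` F_ST + Mantel).

A thin CLI wraps the same library:

```bash
sulfidiv generate --seed 42 --out bundle/          # CSV + TPS + GenePop
sulfidiv run --config run.yaml --out results/      # full pipeline
sulfidiv report --report results/report.json       # headline stats
```

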