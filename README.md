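# ppi-evorate

Tools for asking a classic question in molecular systems biology: **what
determines how fast a protein evolves?** In yeast protein–protein
interaction (PPI) networks, a protein's evolutionary rate has been linked to
its expression level, its connectivity (degree), the features of its
interaction partners, and — critically — its propensity to act as a subunit
of protein complexes. This package implements the full analysis chain used
to disentangle those candidate determinants, plus a synthetic-data generator
that plants the expected statistical structure so the whole pipeline can be
exercised and validated without any external database downloads.

It is aimed at researchers studying rate determinants in interaction
networks who want a tested, scriptable re-implementation of the standard
feature definitions and inference steps.

## What it computes

Per-protein features from a simple undirected PPI network:

- **Degree** *v* — number of distinct interaction partners.
- **Clustering coefficient** `2l / (v(v−1))`, with *l* the number of
  interactions among the protein's *v* neighbours; undefined for *v* < 2.
  Proteins at/above the dataset-mean coefficient are **dense-part (DP)**,
  below it **sparse-part (SP)**.
- **Coefficient of functionality** `n/m` — of a protein's *m* partners, the
  number *n* sharing one of its functional classes (17 MIPS top-level
  classes by default), maximized over the protein's own classes
  (largest-value class rule). At/above the dataset mean → **same-functional
  (SF)**, below → **different-functional (DF)**.
- **Complex number** — count of protein complexes containing the protein as
  a subunit; complex-forming ⇔ complex number ≥ 1.
- **Kimura protein distance** from an aligned ortholog pair: with *p* the
  proportion of differing ungapped columns,
  `d = −ln(1 − p − 0.2 p²)`.
  Ortholog pairs are screened first (E ≤ 10⁻⁵, similarity ≥ 75%,
  overlap ≥ 80%, gaps < 3%; all configurable).

Inference on the joined feature table:

- Spearman correlations of distance with expression, degree and complex
  number; **partial Spearman** correlations of each determinant controlling
  the other two (precision-matrix and residualization routes, cross-checked);
- multivariate OLS regression of distance on the three determinants;
- PCA of the determinants on the correlation matrix with the
  eigenvalue ≥ 1 retention rule, and the correlation of PC1 scores with
  distance;
- Mann–Whitney *U* group comparisons (SF vs DF and DP vs SP, overall and
  within complex/non-complex strata; complex vs non-complex on distance,
  expression and degree) and a two-sided Fisher exact test.

## Worked example

```python
from ppi_evorate import GeneratorConfig, generate
from ppi_evorate.pipeline import run_on_dataset

ds = generate(GeneratorConfig(n_proteins=500, seed=7))
features, report = run_on_dataset(ds)

for v in ("expression", "degree", "complex_number"):
    c = report.correlation(v, "kimura_distance")
    pc = report.partial_correlation(v, "kimura_distance")
    print(f"{v:15s} rho = {c.rho:+.3f} (p = {c.p_value:.2e})   "
          f"partial rho = {pc.rho:+.3f} (p = {pc.p_value:.2e})")
```

prints

```
expression      rho = -0.615 (p = 1.87e-53)   partial rho = -0.475 (p = 2.30e-29)
degree          rho = -0.309 (p = 1.60e-12)   partial rho = -0.106 (p = 1.80e-02)
complex_number  rho = -0.467 (p = 1.66e-28)   partial rho = -0.235 (p = 1.08e-07)
```

All three determinants correlate negatively with the re-estimated Kimura
distance, and each retains a negative partial correlation when the other two
are controlled — the signature of independent contributions. Continuing,

```
PC1: eigenvalue 1.84, 61% of variance, retained: True
PC1 loadings: {'expression': 0.61, 'degree': 0.5, 'complex_number': 0.61}
complex-forming mean distance 0.123 vs non-complex 0.191 (Mann-Whitney p = 1.60e-18)
```

the single retained principal component is led by expression and complex
number (degree loads lower), and complex-forming proteins evolve
significantly more slowly than non-complex-forming ones — exactly the
structure the generator plants via its latent constraint variable.

## Command line

```bash
ppi-evorate generate --seed 1 --n-proteins 2000 --out data/
ppi-evorate run --edges data/edges.tsv --annotations data/annotations.tsv \
    --complexes data/complexes.tsv --expression data/expression.tsv \
    --alignments data/alignments.fasta --out results/
ppi-evorate report --in results/
```

`run` writes `features.tsv`, `report.json` and flat `tables/*.tsv`; cutoffs
for the SF/DF and SP/DP classifications default to the dataset mean but can
be set with `--func-cutoff` / `--clust-cutoff`.

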