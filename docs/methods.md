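# Methods

## The analysis model

The unit of analysis is a protein in a simple undirected PPI network
(self-interactions removed, duplicate and reversed edges collapsed). Four
feature families are joined on protein ID:

1. **Local topology.** Degree *v*; clustering coefficient
   `C = 2l / (v(v−1))` where *l* counts interactions among the protein's
   neighbours. `C` is undefined for *v* < 2: a protein with zero or one
   partner contributes no neighbour-pair information, and including such
   proteins (as zeros) would drag the dataset-mean cutoff down and bias the
   sparse/dense split. These proteins are excluded both from the SP/DP
   labelling and from the mean used as its cutoff. Ties at the cutoff go to
   DP (the "at or above" rule).

2. **Partner functional composition.** With the protein's own class set
   drawn from a 17-class vocabulary (the MIPS top-level functional
   catalogue by default), the coefficient of functionality is
   `max_c n_c / m` over the protein's own classes *c*, where *m* is its
   partner count and *n_c* the partners carrying *c*. Two conventions are
   deliberately explicit because published descriptions leave them open:
   - *m* counts **all** partners by default, annotated or not (an
     unannotated partner can only dilute the coefficient, never raise it);
     `count_unannotated_partners=False` restricts *m* to annotated partners.
   - Ties among a protein's own classes resolve to the lexicographically
     smallest label, so results are order-independent and reproducible.
   SF/DF uses the same at-or-above-the-mean rule as SP/DP; both cutoffs are
   plain parameters because the downstream comparisons are known to be
   robust over a range of cutoff values.

3. **Complex membership.** The complex number is the count of catalog
   complexes containing the protein; absence from the catalog means
   complex number 0 and non-complex-forming.

4. **Evolutionary distance.** Ortholog alignments are screened on four
   summary thresholds (defaults: E ≤ 10⁻⁵, percent similarity ≥ 75,
   percent overlap ≥ 80, percent gaps strictly < 3). From an accepted
   aligned pair, *p* is the fraction of differing columns after pairwise
   gap exclusion, and the distance is Kimura's approximation
   `d = −ln(1 − p − 0.2 p²)`, valid for
   *p* < (√1.8 − 1)/0.4 ≈ 0.8541. Saturated pairs raise an error and are
   excluded from batch output rather than capped: a silent cap would
   compress the upper tail and bias every downstream correlation toward
   zero.

## The inference chain

- **Spearman correlation**: Pearson correlation of average ranks. The
  two-sided p-value uses the t transform with n−2 df for n > 10 and exact
  enumeration of all n! pairings for n ≤ 10 (vectorized with a cached
  permutation-index table; the two-sided region is |S − n·mean(r_x)·mean(r_y)|
  at least the observed value, with a 10⁻¹² relative slack against
  floating-point ties).
- **Partial correlation** is partial *Spearman*: all vectors are ranked
  first, then the Pearson partial correlation of the ranks is taken given
  the control ranks. Two algebraically equivalent routes are implemented —
  precision-matrix inversion and double residualization — and the test
  suite requires them to agree to 10⁻¹⁰; the inversion route additionally
  rejects control structures with condition number above 10¹². p-values use
  the t transform with n − 2 − k df for k controls. A Pearson (unranked)
  partial is available by passing raw values through the same machinery.
- **Multivariate regression**: OLS of distance on the determinants, by
  default after z-scoring response and predictors so coefficients are
  comparable across scales (t and p are invariant to this rescaling).
- **PCA** runs on the **correlation** matrix, not the covariance matrix:
  complex counts, expression levels and degrees live on wildly different
  scales, and covariance PCA would simply recover the largest-variance
  column. Components with eigenvalue ≥ 1 are flagged retained (the
  average-eigenvalue rule for standardized data). Each component is
  sign-oriented so its largest-magnitude loading is positive, which makes
  planted-structure assertions deterministic; PC1 scores are correlated
  (Spearman) with distance downstream.
- **Mann–Whitney U**: exact enumeration when n₁+n₂ ≤ 12 and the pooled
  sample is tie-free, tie-corrected normal approximation otherwise.
- **Fisher exact test**: two-sided, summing hypergeometric probabilities of
  same-margin tables no more probable than the observed one.

Every statistic restricts itself to the complete cases of its own
variables and reports the n it actually used; no imputation anywhere.

## The synthetic-data generator

A single latent per-protein "constraint" value c ~ N(0, 1) drives all
observables, each with its own independent noise:

| observable | mechanism | default |
|---|---|---|
| expression | `exp(a_expr·c + ε)`, ε ~ N(0, σ_expr) | a_expr = 0.8, σ = 0.6 |
| complex membership | per-complex inclusion prob ∝ `exp(a_complex·c)` (mean-calibrated) | a_complex = 0.9, 1 complex per 10 proteins, mean complex number 1.5 |
| network edges | pair probability ∝ `exp(a_degree·(c_i + c_j))`, calibrated to mean degree 4 | a_degree = 0.25 |
| distance | `softplus(b₀ − b_dist·c + ε)` | b₀ = −2.0, b_dist = 0.5, σ = 0.3 |
| classes | one random class; complex members adopt their complex's "theme" class with prob 0.7 | 17 classes |

This is the simplest mechanism that reproduces the qualitative result
pattern the analysis is designed to detect — distance negatively correlated
with expression, degree and complex number, with all partials remaining
nonzero (each observable keeps private noise, so no determinant is a
deterministic function of another). The latent weights deliberately order
the signal strengths expression ≈ complex number > degree, so the retained
PC1 should load complex number and expression above degree; mean degree ~4
and ~0.1–0.2 mean distances echo the sparsity and divergence scale of
curated yeast interaction data against its closest sequenced relative.

Sequence pairs invert the Kimura correction: planted d maps to
`p* = (−1 + √(1 + 0.8(1 − e^{−d})))/0.4`, an ancestral sequence of length
L = 400 is drawn uniformly over the 20 residues, and Binomial(L, p*) sites
are substituted with a uniformly random different residue. Distances are
planted per focal protein (the ortholog is a device for re-estimation, not
a second unit of analysis). Substitution is site-independent with no rate
heterogeneity and no indels by default (a gap-injection option exists for
exercising the gap-exclusion rule): only the p → d correction is under
test, not a realistic evolutionary model.

**What passing tests do and do not show.** The generator emulates the
*statistical* structure of real yeast data — sign pattern, latent
confounding, positivity and scale of distances — but not scale-free
topology, realistic complex-size laws, amino-acid exchangeability biases,
annotation incompleteness, or alignment error. Recovery on synthetic data
validates the machinery (feature definitions, estimators, test
calibration), not any biological claim about a particular dataset.

## Numerical and design choices

- One `numpy` Generator seeded from the single config seed produces every
  draw in a fixed order; identical seeds give byte-identical written
  datasets.
- Feature assembly sorts proteins by ID, so input row order never affects
  output.
- Calibration checks run the generator with all latent weights at zero and
  assert each test's type-I error at α = 0.05 lies in [0.03, 0.07]. We use
  1000 replicates at n = 200: with a 5% target, 1000 Bernoulli replicates
  put ±2 binomial standard errors (~±1.4 points) comfortably inside the
  band, so the check measures calibration rather than replicate noise.
  These replicates feed planted distances directly into the statistics
  (sequence re-estimation is validated separately by the round-trip and
  recovery tests), keeping the whole calibration under ~15 s.
- The end-to-end recovery check uses the generator defaults (n = 2000) with
  full sequence re-estimation; small fixture exactness is checked on a
  10-protein network worked out by hand.
- Spearman p-values can optionally be floored (e.g. at 10⁻⁶) purely for
  display parity with statistics packages that report a floor; computations
  always use the actual value.

## Known limitations

- The ortholog screen consumes alignment *summary* records; running the
  aligner or the homology search is out of scope, as are reciprocal-best-hit
  logic, nucleotide distances and dN/dS.
- "Percent similarity" is taken as supplied in the record; when derived
  from an alignment it defaults to identity, since similarity-group
  definitions vary between tools.
- The regression applies no variable transformations by default (log /
  z-score switches exist); with heavily skewed real expression data the
  rank-based results are the more robust ones.
- No multiple-testing correction is applied across the report; the report
  is a description of one analysis, not a screen.
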