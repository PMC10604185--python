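# Methods

This note documents the statistical models behind each stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that make results reproducible.

## Neutral genetic differentiation

**Pairwise Fst (Nei 1987).** For a pair of populations, per locus, the mean
within-population expected heterozygosity is
`H_S = mean_i [ 2 p_i (1 − p_i) · 2n_i/(2n_i − 1) ]` (the factor corrects the
plug-in heterozygosity for the 2n sampled alleles) and the total
heterozygosity is `H_T = 2 p̄ (1 − p̄)` with `p̄` the unweighted mean of the
two sample frequencies. Heterozygosities are averaged across loci *before*
forming `(H_T − H_S)/H_T` (a ratio of averages, not an average of ratios,
which keeps low-polymorphism loci from dominating). A locus enters a pair
only when both populations have at least one call (pairwise-complete
handling of missing genotypes; no imputation). Negative estimates are
reported as computed (a truncation flag exists) so bootstrap distributions
are not distorted.

A caveat worth knowing: this raw two-population ratio is downward-biased —
roughly F/2 when the true dispersal parameter is F — because H_T is built
from the mean of only two population frequencies. Variants that additionally
correct for the number of sampled populations (Nei's `D'_ST = s/(s−1)·D_ST`)
remove most of that bias; we keep the plain ratio because it is the most
literal reading of "Fst according to Nei" and the pairwise matrix is used
downstream only through its *relative* structure (Mantel tests), which the
monotone bias does not disturb. The global estimate used in the drift
criterion does not share this bias (below).

**Global Fst.** Multi-locus Weir–Cockerham (1984) θ: per-locus variance
components a (among populations), b (among individuals within populations)
and c (within individuals) computed from sample sizes, allele frequencies
and observed heterozygote proportions, combined as `Σa / Σ(a+b+c)` over
loci. Under the Balding–Nichols generator E(θ) ≈ F across the tested range
(F = 0.01–0.2), which is what makes the Pst–Fst comparison calibrated. The
confidence interval is a percentile bootstrap resampling loci with
replacement (default 1000 replicates, 99% level), mirroring the
locus-resampling convention of variance-component bootstrap routines.

**Evanno ΔK.** A helper for externally produced clustering log-likelihood
tables: `ΔK = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K))` with the
sample sd over replicate runs; requires ≥3 consecutive K and ≥2 replicates,
and errors on zero sd (the ratio is undefined). No clustering is run here.

## Trait refinement

Order of operations, fixed for reproducibility:

1. Listwise deletion of individuals with any missing measurement (recorded
   in the output).
2. Per trait, Brown–Forsythe (Levene-with-median) at α = 0.05 routes to a
   parametric (one-way ANOVA + Tukey–Kramer) or non-parametric
   (Kruskal–Wallis + pairwise Mann–Whitney U, Bonferroni over all pairs)
   among-population test. A trait is kept iff the omnibus p < 0.01; the
   post hoc matrices are reported but do not drive dropping. A constant
   trait is non-discriminating, not an error.
3. Population means of the retained traits.
4. Greedy correlation pruning on the means: while any pair has
   |Pearson r| > 0.8, the worst pair is located and the member with the
   larger mean |r| against all remaining traits is dropped; exact ties go
   to the trait appearing later in the measurement protocol. Greedy with a
   deterministic tie-break because "drop one of each highly correlated
   pair" does not otherwise determine a unique retained set.
5. z-scoring of each retained column across populations (sample sd,
   ddof = 1).

**PCA** is an SVD of the centered z-scored population-mean matrix; all
non-zero components are kept, so explained proportions sum to one and
`scores · loadingsᵀ` reconstructs the centered input. Sign convention: the
largest-magnitude loading of each component is positive.

**Elevation associations** use Spearman's ρ (robust to monotone
transformations) plus an OLS polynomial fit of degree 1 or 2 with
`adj R² = 1 − (1 − R²)(n−1)/(n−p−1)` and the overall F test. Populations
can be excluded (e.g. a known outlier site) before both statistics; at
least four points must remain. Degrees above 2 are refused — with ~12
populations anything higher is noise-fitting.

## Spatial distances and the Mantel test

Geographic distances are great-circle (haversine) on a sphere of radius
6371.0088 km; at a few-hundred-km extent the sphere–ellipsoid discrepancy
(<0.5%) is irrelevant to rank-based association tests. Elevational distance
is `|e_i − e_j|` in metres; morphometric distance is Euclidean on the
z-scored population means.

The Mantel statistic is the Pearson correlation of the lower-triangle
entries; the null distribution jointly permutes rows and columns of the
second matrix. The alternative is one-sided "greater" (the biological
hypotheses are directional), with `p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1)`
for sampled permutations (default 9999). With ≤7 populations all `n!`
relabelings are enumerated instead, removing Monte-Carlo noise where it is
cheap (≤5040 permutations). Tie comparisons use a 1e-12 tolerance so the
identity permutation always counts.

## Pst and the drift criterion

Variance components come from the unbalanced one-way random-effects ANOVA:
`σ²_W = MS_within`, `σ²_B = (MS_between − MS_within)/n0`,
`n0 = (N − Σn_i²/N)/(k−1)`; a negative between-component is truncated to
zero and flagged. Then

    Pst(x) = x σ²_B / (x σ²_B + 2 σ²_W),   x = c/h².

Pst is scanned over the inclusive grid x ∈ {0, 0.05, …, 2}; the grid
resolves the decision threshold x = 0.5 exactly. Note the exact identity
`Pst/(1 − Pst) = x · σ²_B/(2σ²_W)`: odds are linear in x, so a Pst known at
one ratio determines the whole curve (`pst_from_reference`), and the scan's
point estimates are a deterministic transform of one pair of components.

**Bootstrap.** Individuals are resampled with replacement within each
population (stratified; preserves the design and keeps every population
represented), components and Pst recomputed per replicate, and percentile
bounds taken at the requested level. One replicate set is shared across the
whole grid — re-resampling per grid point would add noise without
information, and it makes the per-replicate curves monotone so the CI bands
are monotone too. A pooled (unstratified) scheme that keeps labels but lets
group sizes vary is available behind a flag.

Two properties of this bootstrap to keep in mind when interpreting CIs:

- It is *conditional* on the sampled populations. With k = 12 populations
  the sampling of population effects is the dominant uncertainty in the
  generative Pst, and no individual-level resampling can reflect it. The
  CI is calibrated for the realized differentiation of the populations at
  hand (our simulations show essentially full coverage of the realized Pst
  and far lower coverage of the generative value). This matches how such
  intervals are used in practice — the populations are the study, not a
  random sample to be re-drawn — but it means CI widths should not be read
  as uncertainty about a species-wide parameter.
- The plug-in Pst is a ratio, hence slightly biased toward zero at small k
  (about −0.03 at k = 12 for a true value near 0.64 in our simulations);
  negligible against the effect sizes the method is meant to flag.

**Drift criterion.** Given the global Fst result, the critical ratio is the
smallest grid x at which the Pst lower bound exceeds the Fst upper bound;
drift is "excluded" for the trait when that ratio is ≤ 0.5. The lower the
critical ratio, the less has to be assumed about c/h² to argue for
selection. No crossing means no verdict against drift.

## Synthetic data

- **Genotypes** follow Balding–Nichols: ancestral frequency
  p ~ U(0.1, 0.9) per locus, population frequency
  ~ Beta(p(1−F)/F, (1−p)(1−F)/F) (mean p, variance p(1−p)F), genotypes
  Binomial(2, ·). E(Fst) = F in closed form, which is the backbone of the
  recovery tests. Optional uniform missingness (the study-scale preset uses
  4%, matching low-coverage RAD datasets) and an optional
  isolation-by-distance mode in which population frequencies are a spatial
  Gaussian field with covariance exp(−d/ℓ) matched to the Balding–Nichols
  variance.
- **Traits** are `μ + b_pop + e_ind` with Normal components; the recorded
  truth includes both the generative components and the realized
  (finite-sample) ones, the latter being the right referent for the
  conditional bootstrap. The shared within-population variance matches the
  homoscedasticity assumption that the refinement stage screens for.
- **Landscapes** place populations uniformly in a ~300 km square at
  mid-latitudes, with elevations (39–1874 m) drawn independently of
  position so elevational and geographic distances do not covary — the
  situation in which IBD and IBE are separable.
- **Study preset** (`make_study_fixture`): 12 populations × 20 individuals,
  654 SNPs at F = 0.05, 24 traits: three with theoretical Pst ≈ 0.93 at
  c/h² = 1 whose population means track elevation negatively, two with no
  among-population signal, four noisy near-duplicates (|r| > 0.8), the rest
  with moderate signal.

What the generators deliberately do **not** emulate: demographic history
(bottlenecks, admixture, migration matrices), linkage between loci,
genotyping error, trait non-normality/allometry, and phenotypic plasticity.
Passing recovery tests therefore shows the estimators are correct under the
stated models, not that real data meet those models.

## Reproducibility conventions

Every stochastic routine takes an explicit seed. The pipeline derives
per-stage seeds from one master seed via a BLAKE2 hash of
`"{master}:{stage}"` (stable across runs and platforms, below 2³¹), so the
orchestrated run and a standalone stage run with the derived seed produce
identical numbers. Matrix TSVs round-trip at ≥12 significant digits.
Validation is front-loaded into the container types (biallelic dosages,
coordinate ranges, symmetry to 1e-12, non-negative distances), so analysis
code can assume its invariants.

Default problem sizes for the statistical test suite were chosen to resolve
each assertion's tolerance: 20 simulation replicates for Fst recovery
(Monte-Carlo SE ≪ the ±0.01 band), 1000 cheap replicates for the Pst mean
(the ratio bias is comparable to the band, so the mean must be measured
precisely), 50 bootstrap-bearing replicates for CI coverage, and 200
replicates for the Mantel type-I rate.

## Known limitations

- The pairwise Nei ratio's two-population bias (documented above) makes its
  absolute values smaller than population-number-corrected variants;
  comparisons across studies should use the global θ.
- c and h² are assumed, not estimated; the scan quantifies sensitivity to
  that assumption but cannot remove it. Pst–Fst separation generates a
  selection hypothesis, it does not test one.
- The Mantel battery tests marginal associations only; no partial Mantel or
  matrix regression is provided.
- Bootstrap CIs are conditional on the sampled populations (see above).
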