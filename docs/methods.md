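# Methods

`polyqst` implements a quantitative-genetic differentiation analysis for
clonal, hexaploid plants genotyped at codominant microsatellite loci and
phenotyped in a common-garden (growth-chamber) design. This note documents
the statistical models, the conventions adopted where the design was
genuinely open, and what the synthetic-data studies do and do not show.

## The data model and dosage masking

A hexaploid individual carries six allele copies per locus, but fragment
analysis only reveals which distinct fragment lengths are present (one to
six per cell). All marker statistics therefore operate on *allelic
phenotypes*. The default frequency estimator counts each distinct allele
once per individual; within-individual frequencies are presence/|set|.
This is known to inflate rare-allele and deflate common-allele
frequencies; consequences are handled explicitly below.

## F_ST under dosage masking

`fst_global` uses an ANOVA (Weir–Cockerham-style) decomposition of
per-allele indicator variables with **individuals as the exchangeable
unit**: the among-population component is a one-way ANOVA of
within-individual allele frequencies with the unequal-n coefficient `n_c`,
and the within-population total is the unbiased per-population estimate of
μ(1−μ) (μ the expected within-individual frequency). A naive ANOVA over
the pooled stream of allele observations is biased downward at realistic
sample sizes because the distinct alleles carried by one individual are
not independent draws; the nested formulation removes that bias. The
multilocus value is a ratio of summed components with a delete-one-locus
jackknife SE.

Gene-level F_ST is *unidentifiable* from allelic phenotypes. The
observable-scale estimand is smaller than the gene-level island-model
target (at a gene-level target of 0.05 with six-copy masking and the
default locus panel it sits near 0.033), which is the same direction of
distortion described for real hexaploid data. `synthetic.fst_truth`
computes this estimand *exactly* from the generator's drawn population
frequencies via an exponential-generating-function dynamic program for the
moments of 1[a∈S]/|S| under multinomial sampling; the estimator is
unbiased against that truth at all tested targets.

R_ST keeps the classical pooled-observation ANOVA of allele sizes in
repeat units (within-individual size variance belongs in the denominator
of a size-based index); its accuracy is exercised on exact small-sample
oracles rather than a recovery study.

## Loiselle kinship

Pairwise kinship is the frequency-centered cross-product estimator on
within-individual allele frequencies,

F_ij = Σ_l Σ_a [(p_ila − p̄_la)(p_jla − p̄_la) + c_la] / Σ_l Σ_a p̄_la(1 − p̄_la).

The small-sample correction c_la is, by default, the empirical variance of
the individual frequencies divided by (N_l − 1). For gene-copy data this
reduces exactly to the classical p̄(1−p̄)/(n−1) term; for dosage-masked
frequency-valued observations it is the version that makes the mean over
all pairs exactly zero when the reference is the sample itself (an
identity the tests assert at 1e-10). `correction="loiselle"` selects the
literal gene-copy term. The diagonal stores the estimator's self-kinship;
the animal model forms its relationship matrix as 2F, symmetrized and
floored to positive semidefinite by eigenvalue clipping (an error is
raised if the most negative eigenvalue exceeds half the largest — the
matrix is then not trustworthy).

## Bruvo distances

Per locus, allele distance is 1 − 2^(−|Δ|/repeat). Dosage ambiguity is
resolved genome-addition style: the smaller allele set is padded with
copies of its own alleles, exhaustively over fill-ins (sets have ≤ 6
distinct alleles), each padded pair scored by the minimum-weight perfect
matching (`scipy.optimize.linear_sum_assignment`), and the minimum over
fill-ins taken. Individual distance is the mean over loci observed in
both individuals.

## Mixed models, Q_ST and P_ST

Two REML models are fitted per trait:

* **population model** y = Xβ + Z_p u_p + ε with chamber as unordered
  fixed factor; components σ_b² (between populations) and σ_w²;
* **animal model** y = Xβ + Z_p u_p + Z_a u_a + ε, u_a ~ N(0, 2G σ_a²)
  with G the marker kinship; components σ_p², σ_a², σ_e².

The restricted likelihood is evaluated in the q-dimensional random-effect
space via the Woodbury identity (O(q³) per evaluation), optimized over
log-variances by L-BFGS-B with three deterministic restarts (equal split,
residual-heavy, genetic-heavy), gradient tolerance 1e-8, components
floored at 1e-10 relative to the response variance, and a boundary flag
below 1e-6 of the total variance. Standard errors come from the
finite-difference observed information at the optimum; identifiability is
judged on the correlation-normalized information of the non-boundary
components (a near-zero eigenvalue means a flat direction, e.g. σ_a² vs
σ_e² when 2G = I with single records — that case is flagged rather than
silently reported).

Q_ST defaults to σ_p²/(σ_p² + σ_a²) — the convention kept for
comparability with common-garden studies that report it without the
factor two — and the textbook narrow-sense form σ_p²/(σ_p² + 2σ_a²) is
available everywhere as `variant="textbook"`. P_ST defaults to the
Brommer form c·σ_b²/(c·σ_b² + 2h²·σ_w²) with c = h² = 1 (heritability in
the denominator is the only reading under which P_ST is a lower bound of
Q_ST obtained by maximizing the within-population additive variance); the
alternative c·h²·σ_b²/(c·h²·σ_b² + σ_w²) is a flag. Q_ST/P_ST standard
errors use the first-order delta method on the component covariance.
Estimates are NA when the components are jointly non-identifiable or
jointly at the zero boundary.

Trait plasticity is (max − min)/max per genotype across chambers; it is
undefined for negative trait values, NA when fewer than two chambers were
observed or the maximum is zero. Plasticity models carry no chamber fixed
effect (one record per genotype); their identifiability rests entirely on
the kinship structure.

## Neutral Q_ST − F_ST tests

Each null replicate draws V_b* = (2F̂/(1−F̂))·V̂_a·χ²_{r−1}/(r−1),
V_a* = V̂_a·χ²_{df}/df and a Lewontin–Krakauer F* =
F̂·χ²_{(r−1)L}/((r−1)L), forms Q* under the configured variant and stores
Q* − F*. Tests are one-sided (divergent-selection alternative) with
add-one smoothing, default 20,000 replicates. Both variance draws carry
information-based degrees of freedom rather than nominal counts:

* V_a*'s df defaults to the Satterthwaite-style effective df 2(σ̂_a²/SE)²
  implied by the REML information — with only four microsatellite loci
  behind the kinship matrix the additive variance is estimated far less
  precisely than a genotype-count df would suggest, and using the count
  df makes the test sharply anticonservative (measured ~15% rejection at
  α = 5%);
* V_b*'s df combines drift sampling with the REML estimation noise of
  σ̂_p²: matching the variance of a scaled chi-square gives
  k_eff = 2σ̂_p⁴ / (2σ̂_p⁴/(r−1) + SE_p²), capped at the drift df r−1.
  At the study shape the per-population sample mean carries noise
  comparable to the neutral between-population variance itself, so a pure
  χ²_{r−1} draw understates the spread of σ̂_p² (measured ~10% rejection
  at α = 5% versus 5.0% with the combined df, power at strong divergent
  selection unchanged).

R_ST swaps in for F̂ through the same code path.

A remaining caveat the simulations make explicit: dosage masking shrinks
F̂ below gene-level differentiation, so on real data the neutral baseline
itself is conservative-shifted; the type-I study calibrates against the
masked-scale truth the estimator can see.

## Ordinations, co-inertia, climate ANOVA

Trait means (averaged over chambers) are z-scored before PCA — the traits
have incommensurable units. Markers are ordinated by principal
coordinates of individual Bruvo distances (a "Nei-like" allele-frequency
PCA is available by flag); a Lingoes correction is applied when negative
eigenvalue mass exceeds 20%. Two retained axes each feed the co-inertia;
strength is the RV coefficient and significance comes from 999 row
permutations with add-one smoothing. The first co-inertia axis is
regressed on ordinal climate codes (temperature 1–3, precipitation 1–4,
plus product) with sequential sums of squares and explained variation
SS/SS_total·100; a one-way locality ANOVA adds Tukey HSD compact letter
groups (insert-and-absorb construction).

## Mantel tests, diversity, MANOVA

Mantel r is the Pearson correlation of upper-triangle vectors; partial
Mantel residualizes both on the conditioning matrix before correlating;
p-values permute rows/columns of the first matrix (999 default, exact
enumeration for ≤ 8 labels). Environmental distances are Euclidean on
per-variable-standardized ordinal climate codes at the individual level;
geographic distances are great-circle from optional site lon/lat and the
IBD test is skipped with a message when coordinates are absent.

Diversity per population and locus: allele count A, effective alleles
1/Σp², hypergeometric rarefied richness, and unbiased gene diversity
n/(n−1)(1−Σp²) — for non-ordered alleles the Pons–Petit within-population
estimator coincides with this form, and it is reported as `v` with plain
averaging over loci. Diversity–trait relations are Pearson correlations
with two-sided t-based p-values.

The allele–trait screen keeps alleles present in ≥ 7 populations, or
rarer ones above 5% frequency somewhere, and drops alleles carried by
≥ 95% of individuals in every population (no contrast). Predictors are
presence/absence — dosage being unobservable. Forward selection per locus
uses the Pillai trace on sequential residual SSCP differences with the
standard F approximation (cross-checked against `statsmodels` MANOVA);
retained alleles pool into a joint model whose order robustness is probed
by permuting the introduction order (all orders up to 5,000, always
including the discovery order; the worst-case p per allele is reported),
and per-trait slopes come from a joint linear regression on the retained
presence indicators.

## Synthetic data

Genotypes follow a Balding–Nichols island model (population frequencies
Dirichlet(p̄(1−F)/F) around Dirichlet(1) ancestral frequencies) on a
four-locus dinucleotide panel shaped like the study's (20/16/15/11
alleles), six copies per individual, dosage masked. Phenotypes add a
fixed chamber effect, population effects N(0, σ_p²), additive values
MVN(0, 2Ĝσ_a²) conditional on the *realized* Loiselle kinship (so animal-
model recovery is a fair test, not a pedigree tautology), optional
genotype×chamber interaction, and residual noise, on a baseline of 10 so
traits stay positive for the plasticity index. Default variance scales
(σ_a² = 0.3, σ_e² = 0.6, neutral σ_p² = 2F/(1−F)·σ_a²) give heritability
and differentiation in the range reported for perennial grasses.

What the generator does **not** emulate: mutation (allele ladders are
fixed, so stepwise-mutation effects on R_ST are untested), null alleles
and scoring error, non-additive genetic variance, selfing/clonal
structure within populations, and environment-of-origin maternal effects.
Passing tests therefore demonstrate internal statistical correctness
under the stated model, not robustness to those artefacts.

## Problem sizes and numerical choices

Simulation studies run at scaled-down study shapes chosen once: type-I
calibration at 11 populations × 25 genotypes × 4 chambers (500 runs,
2,000-replicate nulls), Q_ST recovery at 11 × 15 × 4 (50 replicates per
grid cell), F_ST recovery at 12 × 25 (50 replicates), end-to-end
detection at 11 × 15 × 2 with a 25× neutral between-population variance
for selected traits. Permutation defaults: 999 (Mantel, co-inertia),
20,000 (neutral nulls). Ties and degenerate inputs: monomorphic loci drop
out of F_ST with a flag; an F̂ of zero must be floored by the caller
before null simulation (the pipeline uses 1e-4); zero-variance responses
raise rather than return NaN F statistics.

## Known limitations

* The Q_ST "printed" default omits the factor two of the narrow-sense
  definition; switch to `textbook` for cross-study comparison.
* The neutral test inherits the approximations of the chi-square
  (Lewontin–Krakauer-style) null: component uncertainty enters only
  through V̂_a's effective df, and σ̂_p estimation noise beyond the
  among-population χ² is not propagated; calibration was verified at the
  study shape, not for radically smaller designs.
* With four loci the kinship matrix is noisy; σ_a² SEs are wide and
  plasticity-model Q_ST values (single record per genotype) are fragile,
  mirroring the wide plasticity SEs the study design implies.
* Exact reproduction of the published numbers requires the original
  deposited dataset; the repository ships only its converter target
  format (see README) and fails the corresponding acceptance test loudly
  when the data are absent.
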