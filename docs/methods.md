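# Methods

This note documents the models, algorithms, defaults and design choices in
`hlafinemap`, and what the synthetic-data experiments do and do not
demonstrate.

## Dosage model

Imputation output is a genotype posterior: for individual *i* and gene *g*, a
set of unordered classical-allele pairs with probabilities summing to 1.  The
dosage of allele *a* is the posterior expectation of its copy count,
d_i(a) = Σ_genotypes P(genotype) × copies of *a*, and the dosage of residue
*r* at aligned position *p* is the sum of d_i(a) over alleles carrying *r*
at *p*.  Two conservation identities follow and are enforced as invariants:
allele dosages at a gene sum to 2 per individual, and residue dosages at a
position — counting the gap `_` as a residue level — sum to 2.  Positions are
integers, negative for leader-peptide numbering; position 0 does not exist.
Monomorphic positions are excluded from association pools but retained in the
alignment.  A best-guess mode keeps only the argmax genotype when its
posterior exceeds a cutoff (default 0.8) and marks the entry missing
otherwise; missing entries are dropped predictor-wise (complete case), since
dosage mode is the primary analysis and best-guess is a side analysis.

## Logistic fitting

All association tests are maximum-likelihood logistic regressions fit by
IRLS: at most 50 iterations, convergence at 1e-8 on the deviance, with step
halving if a Newton step worsens the deviance.  Separation is flagged
heuristically at |β| > 15 — extreme odds ratios do occur with rare imputed
alleles.  The headline p-value is the Wald test of the dosage coefficient;
the likelihood-ratio p is always computed against the covariates-only model
and substitutes the headline (flagged `lrt-substituted`) when the fit did not
converge or separated.  AIC = deviance + 2 × (fitted parameters), an exact
identity in every result.  Under a retrospective case/control design the
logistic slope for a genetic predictor remains consistent; only the intercept
absorbs the sampling fractions, which is why the simulator can fill exact
case/control quotas by rejection without biasing planted odds ratios.

Omnibus (multi-df) tests include all residues at a position (or alleles at a
gene) with combined-sample imputed frequency above `min_freq` (default 0.5%),
drop the most frequent level as the reference — required because levels sum
to 2 — and report the LRT with df = retained − 1.  The conditional gene
variant adds all non-rare alleles at every other gene, each gene
reference-dropped, as covariates.  Non-multiplicative codings are posterior
expectations of genotype indicators: dominant P(≥1 copy), recessive
P(2 copies), genotypic both; models are ranked by AIC and the smallest wins.
Interaction scans add the dosage-scale product term (the expected-count
product, not the expectation of the genotype product — consistent with the
dosage framework throughout) and report a 1-df LRT with a Bonferroni line at
0.05 / n_pairs.

## Stepwise selection and haplogroups

Forward selection refits every remaining predictor conditional on those
entered (coefficients of entered predictors refit freely, the standard
choice) and admits the smallest-p candidate while p < `p_enter`.  The default
`p_enter` is 0.05 over the realized pool size rather than a hard-coded
constant, so 1028 polymorphic residues give 4.87e-5; a stricter 1e-8 variant
and a backward pass (drop any selected predictor whose conditional p reaches
the threshold, iterated to a fixed point) are provided.  Ties break by larger
|β| then lexicographic id, making traces fully deterministic.  Candidates
collinear with the current model (e.g. the mirror residue of one already
entered) are skipped.  `max_steps` defaults to 20, the depth used by the
stability analysis.

Haplogroups cluster marginally associated classical alleles: the best
unassigned predictor seeds a group, and each remaining predictor joins it iff
its p in the pairwise model (group lead + candidate) rises above `p_sep`
(default 1e-4) — its signal absorbed by the lead.  Conditioning is strictly
pairwise, not joint.

## Sequence-assignment permutation null

The null asks: could the apparent residue-level parsimony arise from chance
tagging of classical alleles?  Within each gene the allele→sequence map is
permuted uniformly (single-allele genes are left alone, logged).  This
preserves every allele's frequency and its association with disease and the
per-gene multiset of sequences, while breaking the residue–allele link.
Permutation is within-gene because position sets are gene-specific; all genes
are permuted jointly per replicate.  Per replicate the residue dosages are
re-derived and the best k residues re-selected by unthresholded forward
search (the deviance-maximizing reading; holding the observed residues'
identities fixed is available via `reselect=False`).  D = null deviance −
residual deviance of the k-residue model, covariate-adjusted when covariates
are supplied (the primary analysis uses none).  Empirical
p = (1 + #{D_perm ≥ D_obs}) / (B + 1); B defaults to 10,000, at which the
add-one convention is invisible at printed precision.  Replicate seeds come
from a spawned seed sequence, so results are independent of any parallel
worker count.

## Stability selection and exhaustive search

Each bootstrap replicate draws ⌊fraction × n_cases⌋ cases and
⌊fraction × n_controls⌋ controls without replacement (defaults: fraction
2/3, B = 1,000) and runs forward selection to `top_k` (default 20); the
summary is the predictor × entry-rank frequency matrix.  Predictors constant
within a subsample simply cannot enter that replicate.

The exhaustive search fits every pair or triple of residues (k df) or of
multi-df positions (each position contributing its retained
reference-dropped residues) and ranks by AIC, ties broken by smaller df then
lexicographic combination.  Collinear subsets get AIC = +∞ and a flag.  A
budget guard (default 10^6 models) refuses oversized searches unless forced;
orders beyond 3 are out of scope (stochastic searches such as FINEMAP /
GUESSFM serve that regime and are deliberately not reimplemented here).

Correlation screening uses squared Pearson correlation of dosages.  Pruning
keeps a predictor iff its r² with every kept predictor is below `r2_max`;
tag groups are single-linkage components at r² ≥ `tag_r2`, default
0.9604 = 0.98².  Whether the upstream convention filtered on r or on r² is
ambiguous, so both thresholds are plain config values.

## Synthetic cohort generator

The generator is the package's study design, not a tuning knob.  Defaults:
eight genes named for the classical loci (A, B, C, DRB1, DQA1, DQB1, DPA1,
DPB1) with 10–25 alleles each, frequencies from a symmetric Dirichlet
(concentration 0.8, sorted descending — a realistic skew with a common lead
allele); cross-gene LD from a 60-haplotype table mixed with independent
per-gene draws by weight λ (λ = 0.3 default; λ = 1 gives independence,
λ = 0 pure haplotype structure); random allele→sequence maps of 40 positions
per gene (1–4 residue levels per position, 10% leader-peptide negative
numbering, occasional gaps), giving on the order of 10³ residue predictors
across genes, the dimensionality of a real class-I/II panel.  Disease status
follows a multiplicative logistic model on true residue dosages (intercept
−1.5; planted per-copy ORs 1.77, 3.07, 0.79, 1.26, 2.00 in DPB1, DRB1, DQB1,
C, DQA1 — magnitudes of the strongest class-II effects such an analysis
targets), with optional allele-level effects used to construct the
chance-tagging null.  Individuals are drawn until exact case/control quotas
fill (2,861 / 8,514 by default).  Imputation noise redistributes posterior
mass over the true genotype plus all genotypes sharing an allele with it via
a Dirichlet draw with concentration 1/temperature on the truth (default
temperature 0.05, keeping the argmax on the truth for ≥95% of entries,
comparable to a good imputer); temperature 0 means point masses.

What the generator does not emulate: real MHC recombination maps and
fine-scale LD, population stratification (beyond optional covariates),
allele-frequency differences between cohorts, genotyping error correlated
with allele identity, and the actual IMGT alignment.  Passing tests
therefore demonstrate correctness and calibration of the machinery under the
assumed data-generating model, not accuracy of any particular real-data
estimate, and the synthetic LD level is a design choice, not an estimate of
any real cohort.

## Experiment sizes

The packaged experiments (`hlafinemap.experiments`) run at sizes chosen to
give stable rates on a single CPU: type-I error over 500 null cohorts of
500+500; permutation-p uniformity over 100 datasets at B = 99; OR-3 recovery
over 50 replicates at 5,000+5,000; five-signal stepwise recovery over 25
replicates; bootstrap rank-1 stability at B = 100; permutation power and
null behaviour over 20 runs at B = 200 and 1,000+1,000; best-pair recovery
over 25 replicates with 50 decoys.  The chance-tagging null for the
uniformity experiment keeps residue levels biallelic over a 12-allele pool,
so every residue is shared across several alleles and no single residue can
tag the causal allele exactly; exact ties between observed and permuted
deviances (which would make the add-one empirical p conservative rather than
uniform) are then vanishingly rare.  The demo analysis scripts likewise run
the permutation and stability stages on reduced slices (three genes,
1,500+1,500; top-150 pool) while the library itself scales to the full
design with larger B.  Recovery is counted up to statistically
indistinguishable predictors (r² > 0.99 with the planted residue): at a
biallelic position the two residue labels are mirror codings of one test,
so either counts as finding the signal.

## Numerical notes

- Posterior sums are validated to 1e-6; dosage conservation asserted to
  1e-6; the brute-force dosage oracle agrees to 1e-10.
- IRLS agrees with an independent ML fit to |Δβ| < 1e-6 on random fixtures;
  mirror-residue fits agree (OR inverted, p equal) to 1e-10 because the two
  parametrizations traverse numerically equivalent IRLS paths.
- Degenerate inputs are errors, not silent results: constant predictors,
  single-class phenotypes, zero posterior mass, position 0, thresholds
  outside their ranges, unreachable case quotas.
- 0.05/1028 = 4.8638e-5; the conventional printed figure 4.87e-5 reflects
  rounding up, and checks compare at that printed granularity.
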