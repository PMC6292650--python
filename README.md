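# hlafinemap

Fine-mapping HLA case/control association down to individual amino-acid
residues.

Classical HLA alleles are, in effect, names for particular combinations of
amino acids along an HLA protein.  When a disease associates with classical
alleles across the MHC, the mechanistic question is whether a small number of
residue substitutions — shared across several alleles and genes — can account
for the signal.  `hlafinemap` implements the statistical machinery for that
question on imputed genotypes:

- **Dosage construction.** From an imputer's genotype posteriors
  (per individual and gene, unordered allele pairs with probabilities, the
  shape of HIBAG / HLA\*IMP:02 output) and an allele→peptide alignment, build
  expected copy counts in [0, 2] for every classical allele and every residue
  at every aligned position.  The gap symbol `_` is a first-class residue
  level; per individual, allele dosages at a gene and residue dosages at a
  position each sum to 2.
- **Association models.** Single-predictor logistic regression on dosages
  (Wald p, LRT recorded and substituted on separation), multi-df omnibus
  likelihood-ratio tests of all non-rare residues at a position or alleles at
  a gene (marginal or conditional on other genes), dominant / recessive /
  genotypic codings ranked by AIC, pairwise interaction scans, and
  principal-component covariates from LD-pruned SNPs.
- **Stepwise conditional selection.** Forward entry at the Bonferroni
  threshold 0.05/m over the realized pool of m polymorphic residues (4.87e-5
  when m = 1028), with a backward check, conditional scans given the selected
  set, mixed residue/allele/SNP pools, and the pairwise-conditioning
  haplogroup rule for clustering marginally associated alleles.
- **Sequence-assignment permutation null.** To ask whether residues
  out-explain chance tagging of classical alleles, the allele→sequence map is
  permuted within each gene (preserving each allele's frequency and its
  relationship with disease), residue dosages re-derived, the best k residues
  re-selected, and the deviance explained compared with the observed value;
  empirical p = (1 + r)/(B + 1).
- **Stability and search.** Bootstrap stability selection (forward selection
  on 2/3-subsamples of cases and controls, entry-rank frequencies) and
  exhaustive best-pair / best-triple searches over residues or multi-df
  positions ranked by AIC (C(1028, 2) = 527,878 pair models at full scale).

No real genotypes ship with the package.  A synthetic cohort generator
(`hlafinemap.synthetic_cohort`) produces case/control data with the structure
the analysis assumes — per-gene allele pools, cross-gene haplotype LD under a
single mixing weight, planted causal residues under a multiplicative logistic
model, and Dirichlet blurring of posteriors to emulate imputation
uncertainty — so the whole pipeline is exercised end to end.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
cohort of 2,861 cases and 8,514 controls across eight HLA genes with five
planted causal residues (per-copy ORs 1.77, 3.07, 0.79, 1.26, 2.00):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_marginal_association.py
python analysis/03_stepwise_selection.py
python analysis/04_permutation_null.py
python analysis/05_stability_and_search.py
```

With the default seed, script 03 prints the forward-stepwise trace

```
step     predictor    type       p_enter      beta
   1 HLA-DRB1@14:M residue 1.254358e-176  1.662703
   2 HLA-DQA1@36:A residue  2.775248e-66  0.874948
   3 HLA-DPB1@28:S residue  1.812271e-49  0.943632
   4    HLA-C@24:K residue  1.046996e-11  0.383206
   5  HLA-DQB1@4:C residue  9.270850e-09 -0.377690
```

— exactly the five planted residues, each entering below the pool-size
Bonferroni threshold (0.05/727 = 6.88e-5 here), none dropped by the backward
pass, and no residual residue significant after conditioning (minimum
residual p = 2.7e-3).  Script 04 then reports, for the top k = 1..3
residues, deviance explained 260.9 / 353.0 / 391.7 with empirical
permutation p = 0.0099 at B = 100: the residue-level model explains far more
of the allele-level signal than chance sequence tagging does.  Script 05
finds the top residue entering first in 100% of 100 bootstrap replicates and
the exhaustive pair search choosing two of the planted residues as the best
pair.  Summary tables land in `results/`; large intermediates (the simulated
posterior table, the dosage matrix) go to `scratch/`.

A `hla-finemap` command-line tool exposes the same steps over TSV inputs
(`simulate`, `assoc`, `select`, `scan`, `haplogroups`, `permtest`,
`stability`, `search`, `run --config`).

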