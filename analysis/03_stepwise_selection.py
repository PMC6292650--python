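#!/usr/bin/env python
"""Forward stepwise selection of residues at the pool-size Bonferroni
threshold and at the stricter 1e-8 cutoff, with a backward check, conditional
scans given the selected set, and haplogroup assignment of the top classical
alleles.

Writes results/stepwise_trace.tsv, results/conditional_scan.tsv and
results/haplogroups.tsv.
"""

from pathlib import Path

from hlafinemap.alignment import PeptideAlignment
from hlafinemap.association import bonferroni_threshold, marginal_scan
from hlafinemap.hla_data import cohort_allele_dosages, drop_monomorphic, read_dosage_tsv
from hlafinemap.stepwise import (
    assign_haplogroups,
    backward_check,
    conditional_scan,
    forward_stepwise,
)
from hlafinemap.synthetic_cohort import read_phenotypes_tsv, read_posteriors_tsv

ROOT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    residues = read_dosage_tsv(SCRATCH / "residue_dosages.tsv")
    y = read_phenotypes_tsv(SCRATCH / "cohort" / "phenotypes.tsv")
    p_enter = bonferroni_threshold(residues.shape[1])
    print(f"entry threshold 0.05/{residues.shape[1]} = {p_enter:.3e}")

    trace = forward_stepwise(residues, y, p_enter=p_enter)
    strict = forward_stepwise(residues, y, p_enter=1e-8)
    retained = backward_check(trace, residues, y)
    frame = trace.to_frame()
    frame["retained_after_backward"] = [p in retained for p in trace.predictors]
    frame["significant_at_1e-8"] = [p in strict.predictors for p in trace.predictors]
    frame.to_csv(ROOT / "stepwise_trace.tsv", sep="\t", index=False)
    print(f"selected {len(trace.entries)} residues at the Bonferroni threshold, "
          f"{len(strict.entries)} at 1e-8; backward pass kept {len(retained)}")
    print(frame.to_string(index=False))

    selected = residues[trace.predictors]
    scan = conditional_scan(residues, selected, y)
    scan.head(100).to_csv(ROOT / "conditional_scan.tsv", sep="\t", index=False)
    if len(scan):
        print(f"\nminimum residual residue p after conditioning on the selected "
              f"set: {scan.attrs['min_p']:.3e}")

    posteriors = read_posteriors_tsv(SCRATCH / "cohort" / "posteriors.tsv")
    alleles = drop_monomorphic(cohort_allele_dosages(posteriors))
    allele_scan = marginal_scan(alleles, y)
    sig = list(allele_scan.loc[allele_scan["p"] < 1e-6, "predictor"])
    if sig:
        groups = assign_haplogroups(alleles, y, predictors=sig)
        groups.to_frame().to_csv(ROOT / "haplogroups.tsv", sep="\t", index=False)
        print(f"\n{len(sig)} classical alleles with marginal p < 1e-6 fall into "
              f"{len(groups.groups)} haplogroups:")
        print(groups.to_frame().to_string(index=False))
    else:
        print("\nno classical allele reached marginal p < 1e-6")


if __name__ == "__main__":
    main()
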