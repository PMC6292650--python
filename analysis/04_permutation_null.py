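#!/usr/bin/env python
"""Sequence-assignment permutation null: does the deviance explained by the
top k residues exceed what chance tagging of classical alleles produces?

For k = 1..3, permutes the allele-to-sequence map within each gene B times,
re-derives residue dosages, re-selects the best k residues and records the
deviance explained.  Because every permutation repeats the forward search,
this demo runs on the three class-II genes carrying the strongest planted
effects and a 1500+1500 subsample; the library handles any scale and
defaults to B = 10,000.  Writes results/permutation_null.tsv (summary) and
results/permutation_deviances.tsv (null draws).
"""

from pathlib import Path

import pandas as pd

from hlafinemap.alignment import PeptideAlignment
from hlafinemap.hla_data import cohort_allele_dosages
from hlafinemap.resampling import permutation_null
from hlafinemap.synthetic_cohort import read_phenotypes_tsv, read_posteriors_tsv

ROOT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
B = 100  # demo scale; the library default is 10,000
MAX_K = 3
GENES = ["HLA-DPB1", "HLA-DRB1", "HLA-DQB1"]
N_PER_ARM = 1500


def main(seed: int = 1) -> None:
    posteriors = read_posteriors_tsv(SCRATCH / "cohort" / "posteriors.tsv")
    full_alignment = PeptideAlignment.from_tsv(SCRATCH / "cohort" / "alignment.tsv")
    alignment = PeptideAlignment({g: full_alignment.table(g) for g in GENES})
    y_full = read_phenotypes_tsv(SCRATCH / "cohort" / "phenotypes.tsv")
    keep = (y_full[y_full == 1].index[:N_PER_ARM]
            .append(y_full[y_full == 0].index[:N_PER_ARM]))
    y = y_full.loc[keep]
    posteriors = posteriors[
        posteriors["gene"].isin(GENES) & posteriors["individual_id"].isin(keep)
    ]
    allele_dos = cohort_allele_dosages(posteriors)

    rows, draws = [], {}
    for k in range(1, MAX_K + 1):
        res = permutation_null(k, allele_dos, alignment, y, B=B, seed=seed + k)
        rows.append({"k": k, "d_obs": res.d_obs, "empirical_p": res.p, "B": res.B,
                     "top_residues": ";".join(res.observed_predictors)})
        draws[f"k{k}"] = res.d_perm
        print(f"k={k}: deviance explained {res.d_obs:8.2f}, empirical p {res.p:.4f}"
              f"  (top: {', '.join(res.observed_predictors)})")
    pd.DataFrame(rows).to_csv(ROOT / "permutation_null.tsv", sep="\t", index=False)
    pd.DataFrame(draws).to_csv(ROOT / "permutation_deviances.tsv", sep="\t", index=False)
    print("small empirical p means the residue-level model explains more than "
          "chance tagging of classical alleles would")


if __name__ == "__main__":
    main()
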