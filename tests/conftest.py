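"""Shared fixtures: small simulated cohorts and their dosage matrices.

Everything is generated programmatically at fixed seeds so the suite needs
no data files and is fully reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import hlafinemap as hf
from hlafinemap.synthetic_cohort import (
    DiseaseModel,
    random_haplotype_model,
    random_peptide_alignment,
)


def make_scenario(
    genes=("HLA-DPB1", "HLA-DRB1", "HLA-DQB1"),
    n_alleles=6,
    n_positions=10,
    lam=0.3,
    seed=101,
):
    pools = {
        g: hf.build_allele_pool(g, n_alleles, 1.0, seed=seed + i)
        for i, g in enumerate(genes)
    }
    hap = random_haplotype_model(pools, 20, lam=lam, seed=seed + 50)
    aln = random_peptide_alignment(pools, n_positions, seed=seed + 60)
    return pools, hap, aln


def pick_causal(aln, pools, gene, target_freq=0.25):
    """A polymorphic (gene, pos, res) whose population frequency is closest
    to target_freq — deterministic, independent of any fitted model."""
    pool = pools[gene]
    best = None
    for pos in aln.positions(gene):
        col = aln.residues_at(gene, pos)
        for res in sorted(col.unique()):
            freq = float(pool.frequencies[[r == res for r in col]].sum())
            if 0.0 < freq < 1.0:
                score = abs(freq - target_freq)
                if best is None or score < best[0]:
                    best = (score, pos, res)
    assert best is not None
    return gene, best[1], best[2]


@pytest.fixture(scope="session")
def small_scenario():
    return make_scenario()


@pytest.fixture(scope="session")
def small_cohort(small_scenario):
    pools, hap, aln = small_scenario
    gene, pos, res = pick_causal(aln, pools, "HLA-DPB1")
    disease = DiseaseModel(intercept=-1.0, residue_effects={(gene, pos, res): np.log(2.5)})
    cohort = hf.simulate_cohort(pools, hap, aln, disease, 400, 400, seed=7)
    return cohort, (gene, pos, res)


@pytest.fixture(scope="session")
def small_dosages(small_scenario, small_cohort):
    pools, _, aln = small_scenario
    cohort, _ = small_cohort
    allele_dos = hf.cohort_allele_dosages(
        cohort.posteriors,
        genes=list(pools),
        alleles_by_gene={g: p.alleles for g, p in pools.items()},
    )
    residue_dos = hf.residue_dosage(allele_dos, aln)
    return allele_dos, residue_dos


def random_posterior_table(n_individuals, alleles, rng, gene="HLA-X", max_genotypes=3):
    """A valid posterior table with 1-3 candidate genotypes per individual."""
    rows = []
    for i in range(n_individuals):
        k = int(rng.integers(1, max_genotypes + 1))
        pairs = set()
        while len(pairs) < k:
            a, b = rng.choice(alleles, 2)
            pairs.add(tuple(sorted((a, b))))
        w = rng.dirichlet(np.ones(len(pairs)))
        for (a, b), p in zip(sorted(pairs), w):
            rows.append((f"ind{i:04d}", gene, a, b, p))
    return pd.DataFrame(
        rows, columns=["individual_id", "gene", "allele1", "allele2", "posterior"]
    )


def brute_force_residue_dosage(posteriors, alignment, gene):
    """Independent oracle: enumerate posterior-weighted genotypes directly."""
    sub = posteriors[posteriors["gene"] == gene]
    out: dict[str, dict[str, float]] = {}
    for _, row in sub.iterrows():
        ind = row["individual_id"]
        out.setdefault(ind, {})
        for pos in alignment.positions(gene):
            col = alignment.residues_at(gene, pos)
            for allele in (row["allele1"], row["allele2"]):
                key = hf.residue_key(gene, pos, col[allele])
                out[ind][key] = out[ind].get(key, 0.0) + row["posterior"]
    return pd.DataFrame(out).T.fillna(0.0)
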