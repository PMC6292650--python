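"""Case/control cohort simulator for HLA fine-mapping.

The generator produces the statistical structure the downstream analyses
assume: per-gene classical-allele pools with Dirichlet-distributed
frequencies, cross-gene haplotype LD controlled by a single mixing weight
``lam`` (``lam=1`` gives independent genes, ``lam=0`` pure haplotype draws),
random allele-to-peptide alignments, disease status from a multiplicative
(per-copy log-odds) logistic model on true residue dosages, and optional
Dirichlet blurring of the genotype posteriors to emulate imputation
uncertainty.  Sampling continues until exact case and control quotas are
filled, matching a retrospective case/control design.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import GAP, PeptideAlignment
from .errors import InvalidConfigError, SimulationError

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class AllelePool:
    """Allele names and population frequencies for one gene."""

    gene: str
    alleles: tuple[str, ...]
    frequencies: np.ndarray

    def __post_init__(self):
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if len(self.alleles) != len(set(self.alleles)):
            raise InvalidConfigError(f"{self.gene}: duplicate allele names")
        if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
            raise InvalidConfigError(f"{self.gene}: frequencies must be >=0 and sum to 1")


@dataclass(frozen=True)
class HaplotypeModel:
    """Cross-gene haplotypes with a recombination-style mixing weight.

    Each haplotype is a tuple of allele names following ``gene_order``.  A
    drawn haplotype is taken from the table with probability ``1 - lam`` and
    assembled from independent per-gene draws with probability ``lam``.
    """

    gene_order: tuple[str, ...]
    haplotypes: tuple[tuple[str, ...], ...]
    frequencies: np.ndarray
    lam: float = 0.0

    def __post_init__(self):
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if not 0.0 <= self.lam <= 1.0:
            raise InvalidConfigError("lam must lie in [0, 1]")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise InvalidConfigError("haplotype frequencies must sum to 1")
        for hap in self.haplotypes:
            if len(hap) != len(self.gene_order):
                raise InvalidConfigError("haplotype arity does not match gene order")

    def validate_against(self, pools: Mapping[str, AllelePool]) -> None:
        for hap in self.haplotypes:
            for gene, allele in zip(self.gene_order, hap):
                if allele not in pools[gene].alleles:
                    raise InvalidConfigError(f"haplotype allele {gene}*{allele} not in pool")


@dataclass(frozen=True)
class DiseaseModel:
    """Logistic disease model on true residue (and optionally allele) dosages.

    ``residue_effects`` maps ``(gene, position, residue)`` to a per-copy
    log-odds; ``allele_effects`` maps ``(gene, allele)`` likewise and exists
    so that allele-level signals not attributable to any single residue can
    be planted (the null regime of the sequence-assignment permutation test).
    """

    intercept: float
    residue_effects: Mapping[tuple[str, int, str], float] = field(default_factory=dict)
    allele_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        betas = [self.intercept, *self.residue_effects.values(), *self.allele_effects.values()]
        if not np.all(np.isfinite(betas)):
            raise InvalidConfigError("all disease-model coefficients must be finite")


@dataclass
class SimulatedCohort:
    """Phenotypes, true diplotypes and (possibly blurred) genotype posteriors."""

    phenotype: pd.Series  # index individual_id, values 0/1
    diplotypes: dict[str, pd.DataFrame]  # gene -> columns allele1, allele2
    posteriors: pd.DataFrame  # individual_id, gene, allele1, allele2, posterior
    seed: int
    config: dict = field(default_factory=dict)
    snps: pd.DataFrame | None = None

    @property
    def individuals(self) -> pd.Index:
        return self.phenotype.index

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.phenotype).sum())


# ---------------------------------------------------------------- generators
def build_allele_pool(
    gene: str, n_alleles: int, concentration: float, seed: int
) -> AllelePool:
    """Draw an allele pool with symmetric-Dirichlet frequencies, sorted descending."""
    if n_alleles < 2:
        raise InvalidConfigError("n_alleles must be >= 2")
    if concentration <= 0:
        raise InvalidConfigError("concentration must be positive")
    rng = np.random.default_rng(seed)
    freqs = np.sort(rng.dirichlet(np.full(n_alleles, float(concentration))))[::-1]
    freqs = freqs / freqs.sum()
    names = tuple(f"{i + 1:02d}:01" for i in range(n_alleles))
    return AllelePool(gene=gene, alleles=names, frequencies=freqs)


def random_haplotype_model(
    pools: Mapping[str, AllelePool],
    n_haplotypes: int,
    lam: float,
    seed: int,
    concentration: float = 1.0,
) -> HaplotypeModel:
    """Assemble a haplotype table by independent per-gene draws with Dirichlet
    frequencies; LD strength is then governed solely by ``lam``."""
    if n_haplotypes < 1:
        raise InvalidConfigError("n_haplotypes must be >= 1")
    rng = np.random.default_rng(seed)
    order = tuple(pools)
    haps = set()
    attempts = 0
    while len(haps) < n_haplotypes:
        hap = tuple(
            pools[g].alleles[rng.choice(len(pools[g].alleles), p=pools[g].frequencies)]
            for g in order
        )
        haps.add(hap)
        attempts += 1
        if attempts > 200 * n_haplotypes:
            break  # pool too small for the requested number of distinct haplotypes
    haps = tuple(sorted(haps))
    freqs = rng.dirichlet(np.full(len(haps), float(concentration)))
    return HaplotypeModel(gene_order=order, haplotypes=haps, frequencies=freqs, lam=lam)


def random_peptide_alignment(
    pools: Mapping[str, AllelePool],
    n_positions: int,
    seed: int,
    max_levels: int = 4,
    p_gap: float = 0.05,
    negative_fraction: float = 0.1,
) -> PeptideAlignment:
    """Random allele-to-sequence maps.

    Per position the residue alphabet size is drawn from {1..max_levels}
    (size 1 yields a monomorphic position); a fraction of positions uses
    leader-peptide (negative) numbering; the gap symbol can be one level.
    Sequences are i.i.d. across alleles, so they carry no information about
    allele frequency or disease effect by construction.
    """
    rng = np.random.default_rng(seed)
    genes = {}
    for gene, pool in pools.items():
        n_neg = int(round(negative_fraction * n_positions))
        positions = list(range(-n_neg, 0)) + list(range(1, n_positions - n_neg + 1))
        data = {}
        for pos in positions:
            n_levels = int(rng.integers(1, max_levels + 1))
            letters = list(rng.choice(list(_AA20), size=n_levels, replace=False))
            if n_levels > 1 and rng.random() < p_gap:
                letters[-1] = GAP
            data[pos] = rng.choice(letters, size=len(pool.alleles))
        genes[gene] = pd.DataFrame(data, index=list(pool.alleles))
    return PeptideAlignment(genes)


# ---------------------------------------------------------------- simulation
def _draw_diplotypes(
    pools: Mapping[str, AllelePool],
    model: HaplotypeModel,
    n: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw ``n`` individuals x 2 haplotypes; returns gene -> (n, 2) allele-index array."""
    order = model.gene_order
    hap_table = {
        g: np.array([pools[g].alleles.index(h[j]) for h in model.haplotypes])
        for j, g in enumerate(order)
    }
    n_hap = len(model.haplotypes)
    hap_idx = rng.choice(n_hap, p=model.frequencies, size=(n, 2))
    independent = rng.random((n, 2)) < model.lam
    out = {}
    for g in order:
        from_hap = hap_table[g][hap_idx]
        indep = rng.choice(
            len(pools[g].alleles), p=pools[g].frequencies, size=(n, 2)
        )
        out[g] = np.where(independent, indep, from_hap)
    return out


def _risk_eta(
    diplo_idx: Mapping[str, np.ndarray],
    pools: Mapping[str, AllelePool],
    alignment: PeptideAlignment,
    disease: DiseaseModel,
) -> np.ndarray:
    n = next(iter(diplo_idx.values())).shape[0]
    eta = np.full(n, disease.intercept, dtype=float)
    for (gene, pos, res), beta in disease.residue_effects.items():
        carriers = np.array(
            [alignment.residues_at(gene, pos)[a] == res for a in pools[gene].alleles]
        )
        eta += beta * carriers[diplo_idx[gene]].sum(axis=1)
    for (gene, allele), beta in disease.allele_effects.items():
        idx = pools[gene].alleles.index(allele)
        eta += beta * (diplo_idx[gene] == idx).sum(axis=1)
    return eta


def simulate_cohort(
    pools: Mapping[str, AllelePool],
    haplotype_model: HaplotypeModel,
    peptide_alignment: PeptideAlignment,
    disease_model: DiseaseModel,
    n_cases: int,
    n_controls: int,
    seed: int,
    max_draw_factor: int = 500,
) -> SimulatedCohort:
    """Simulate a retrospective case/control cohort with point-mass posteriors.

    Diplotypes are two independent haplotype draws; disease status follows the
    logistic model on true residue (and allele) dosages; individuals are
    accumulated until both quotas are filled exactly.  Raises
    :class:`SimulationError` after ``max_draw_factor * (n_cases + n_controls)``
    draws if a quota is unreachable.
    """
    if n_cases < 1 or n_controls < 1:
        raise InvalidConfigError("n_cases and n_controls must be >= 1")
    for gene, pos, res in disease_model.residue_effects:
        if res not in set(peptide_alignment.residues_at(gene, pos)):
            raise InvalidConfigError(
                f"causal residue {gene}@{pos}:{res} absent from the alignment"
            )
    haplotype_model.validate_against(pools)
    rng = np.random.default_rng(seed)
    need = {1: n_cases, 0: n_controls}
    kept: dict[int, dict[str, list]] = {
        1: {g: [] for g in pools},
        0: {g: [] for g in pools},
    }
    total = n_cases + n_controls
    drawn = 0
    while need[1] > 0 or need[0] > 0:
        if drawn >= max_draw_factor * total:
            raise SimulationError(
                f"case/control quotas unreachable after {drawn} draws "
                f"(still need {need[1]} cases, {need[0]} controls)"
            )
        batch = max(256, 2 * (need[1] + need[0]))
        diplo = _draw_diplotypes(pools, haplotype_model, batch, rng)
        eta = _risk_eta(diplo, pools, peptide_alignment, disease_model)
        status = (rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        drawn += batch
        for s in (1, 0):
            take = np.flatnonzero(status == s)[: need[s]]
            need[s] -= len(take)
            for g in pools:
                kept[s][g].append(diplo[g][take])

    phen = np.concatenate([np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)])
    order = rng.permutation(total)
    ids = pd.Index([f"ind{i + 1:05d}" for i in range(total)], name="individual_id")
    phenotype = pd.Series(phen[order], index=ids, name="status")

    diplotypes: dict[str, pd.DataFrame] = {}
    post_rows = []
    for g, pool in pools.items():
        idx = np.concatenate(kept[1][g] + kept[0][g])[order]
        names = np.array(pool.alleles)
        a1 = names[np.minimum(idx[:, 0], idx[:, 1])]
        a2 = names[np.maximum(idx[:, 0], idx[:, 1])]
        diplotypes[g] = pd.DataFrame({"allele1": a1, "allele2": a2}, index=ids)
        post_rows.append(
            pd.DataFrame(
                {
                    "individual_id": ids,
                    "gene": g,
                    "allele1": a1,
                    "allele2": a2,
                    "posterior": 1.0,
                }
            )
        )
    posteriors = pd.concat(post_rows, ignore_index=True)
    config = {
        "n_cases": n_cases,
        "n_controls": n_controls,
        "lam": haplotype_model.lam,
        "genes": list(pools),
        "intercept": disease_model.intercept,
        "residue_effects": {
            f"{g}@{p}:{r}": b for (g, p, r), b in disease_model.residue_effects.items()
        },
        "allele_effects": {
            f"{g}*{a}": b for (g, a), b in disease_model.allele_effects.items()
        },
    }
    return SimulatedCohort(
        phenotype=phenotype,
        diplotypes=diplotypes,
        posteriors=posteriors,
        seed=seed,
        config=config,
    )


def blur_posteriors(
    cohort: SimulatedCohort,
    temperature: float,
    seed: int,
    pools: Mapping[str, AllelePool] | None = None,
) -> SimulatedCohort:
    """Spread posterior mass around the true genotype to emulate imputation noise.

    For each individual/gene the candidate set is the true genotype plus every
    unordered pair sharing at least one allele with it (the sparse shape of
    real imputer output); weights are a Dirichlet draw with concentration
    ``1/temperature`` on the truth and 1 on each alternative.  ``temperature=0``
    returns the cohort unchanged.
    """
    if temperature < 0:
        raise InvalidConfigError("temperature must be >= 0")
    if temperature == 0:
        return cohort
    rng = np.random.default_rng(seed)
    alleles_by_gene = {
        g: (list(pools[g].alleles) if pools is not None
            else sorted(set(df["allele1"]) | set(df["allele2"])))
        for g, df in cohort.diplotypes.items()
    }
    rows = []
    alpha_true = 1.0 / temperature
    for gene, diplo in cohort.diplotypes.items():
        alleles = alleles_by_gene[gene]
        for ind, a, b in zip(diplo.index, diplo["allele1"], diplo["allele2"]):
            cands = {tuple(sorted((a, x))) for x in alleles}
            cands |= {tuple(sorted((b, x))) for x in alleles}
            cands = sorted(cands)
            true = tuple(sorted((a, b)))
            alpha = np.ones(len(cands))
            alpha[cands.index(true)] = alpha_true
            w = rng.dirichlet(alpha)
            for (c1, c2), wt in zip(cands, w):
                rows.append((ind, gene, c1, c2, wt))
    posteriors = pd.DataFrame(
        rows, columns=["individual_id", "gene", "allele1", "allele2", "posterior"]
    )
    config = dict(cohort.config, blur_temperature=temperature, blur_seed=seed)
    return SimulatedCohort(
        phenotype=cohort.phenotype,
        diplotypes=cohort.diplotypes,
        posteriors=posteriors,
        seed=cohort.seed,
        config=config,
        snps=cohort.snps,
    )


def simulate_snps(
    n: int,
    m: int,
    seed: int,
    positions: Sequence[int] | None = None,
    chrom: str = "6",
    subpop: np.ndarray | None = None,
    fst: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Independent biallelic SNP dosages (0/1/2) with positional metadata.

    With ``subpop`` (0/1 labels per individual) and ``fst > 0``, per-SNP
    subpopulation frequencies diverge via a Balding-Nichols draw, giving the
    stratification signal principal components should recover.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.05, 0.95, size=m)
    ids = pd.Index([f"ind{i + 1:05d}" for i in range(n)], name="individual_id")
    snp_names = [f"snp{j + 1:05d}" for j in range(m)]
    if positions is None:
        positions = np.sort(rng.choice(10_000_000, size=m, replace=False)) + 20_000_000
    if subpop is not None and fst > 0:
        a = base * (1 - fst) / fst
        b = (1 - base) * (1 - fst) / fst
        f0 = rng.beta(a, b)
        f1 = rng.beta(a, b)
        freq = np.where(subpop[:, None] == 0, f0[None, :], f1[None, :])
        dos = rng.binomial(2, freq).astype(float)
    else:
        dos = rng.binomial(2, base, size=(n, m)).astype(float)
    snps = pd.DataFrame(dos, index=ids, columns=snp_names)
    meta = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(positions, dtype=int)}, index=snp_names
    )
    return snps, meta


def tag_snps(
    source: pd.DataFrame, noise_sd: float, seed: int, prefix: str = "tag"
) -> pd.DataFrame:
    """SNP-like dosage columns tagging the given predictors with additive noise,
    clipped to [0, 2] — a cheap stand-in for SNPs in LD with HLA variation."""
    rng = np.random.default_rng(seed)
    vals = source.to_numpy(dtype=float) + rng.normal(0, noise_sd, size=source.shape)
    vals = np.clip(vals, 0.0, 2.0)
    cols = [f"{prefix}_{i + 1:03d}" for i in range(source.shape[1])]
    return pd.DataFrame(vals, index=source.index, columns=cols)


# ----------------------------------------------------------------------- I/O
def _write_with_header(path, frame: pd.DataFrame, comments: Sequence[str], index: bool):
    buf = io.StringIO()
    for line in comments:
        buf.write(f"# {line}\n")
    frame.to_csv(buf, sep="\t", index=index)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_posteriors_tsv(cohort: SimulatedCohort, path) -> None:
    comments = [f"{k}={v}" for k, v in cohort.config.items()] + [f"seed={cohort.seed}"]
    _write_with_header(path, cohort.posteriors, comments, index=False)


def write_phenotypes_tsv(cohort: SimulatedCohort, path) -> None:
    comments = [f"seed={cohort.seed}"]
    _write_with_header(path, cohort.phenotype.to_frame(), comments, index=True)


def read_posteriors_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"allele1": str, "allele2": str})


def read_phenotypes_tsv(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", comment="#", index_col="individual_id")
    return frame["status"]
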