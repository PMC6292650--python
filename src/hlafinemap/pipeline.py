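"""Config-driven orchestration: simulate -> dosages -> marginal -> stepwise ->
permutation/stability -> exhaustive search, with input validation and a run
manifest (config echo, per-stage seeds, output checksums).

All stage randomness is derived from one master seed by stable hashing of
stage names, so toggling one stage never shifts another's random stream and
reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import PeptideAlignment, parse_residue_key
from .association import marginal_scan, omnibus_gene_test, bonferroni_threshold
from .errors import DependencyError, InvalidConfigError, InvalidInputError
from .hla_data import (
    cohort_allele_dosages,
    drop_monomorphic,
    residue_dosage,
    validate_posteriors,
    write_dosage_tsv,
)
from .resampling import bootstrap_stability, permutation_null
from .search import exhaustive_residue_search
from .stepwise import backward_check, forward_stepwise
from .synthetic_cohort import (
    AllelePool,
    DiseaseModel,
    blur_posteriors,
    build_allele_pool,
    random_haplotype_model,
    random_peptide_alignment,
    read_phenotypes_tsv,
    read_posteriors_tsv,
    simulate_cohort,
    write_phenotypes_tsv,
    write_posteriors_tsv,
)

#: Gene names mirroring the marginal-association tables of the study design,
#: with allele-pool sizes in the realistic 10-25 range.
DEFAULT_GENES: dict[str, int] = {
    "HLA-A": 18,
    "HLA-B": 25,
    "HLA-C": 16,
    "HLA-DRB1": 22,
    "HLA-DQA1": 12,
    "HLA-DQB1": 14,
    "HLA-DPA1": 10,
    "HLA-DPB1": 16,
}

#: Planted per-copy odds ratios for the five causal residues, one per gene —
#: the magnitudes of the five top stepwise hits the analysis is built to find.
DEFAULT_CAUSAL_ORS: dict[str, float] = {
    "HLA-DPB1": 1.77,
    "HLA-DRB1": 3.07,
    "HLA-DQB1": 0.79,
    "HLA-C": 1.26,
    "HLA-DQA1": 2.0,
}

DEFAULT_THRESHOLDS = {
    "p_strict": 1e-8,
    "p_sep": 1e-4,
    "min_freq": 0.005,
    "best_guess": 0.8,
    "tag_r2": 0.9604,  # = 0.98**2
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed from the master seed by stable hashing of the stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "results/run"
    n_cases: int = 2861
    n_controls: int = 8514
    genes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GENES))
    causal_ors: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CAUSAL_ORS))
    n_positions: int = 40
    n_haplotypes: int = 60
    lam: float = 0.3
    intercept: float = -1.5
    blur_temperature: float = 0.05
    concentration: float = 0.8
    p_enter: float | None = None  # None -> Bonferroni over the realized pool
    p_strict: float = DEFAULT_THRESHOLDS["p_strict"]
    p_sep: float = DEFAULT_THRESHOLDS["p_sep"]
    min_freq: float = DEFAULT_THRESHOLDS["min_freq"]
    best_guess: float = DEFAULT_THRESHOLDS["best_guess"]
    tag_r2: float = DEFAULT_THRESHOLDS["tag_r2"]
    permutation_B: int = 200
    permutation_k: int = 2
    stability_B: int = 100
    stability_fraction: float = 2.0 / 3.0
    stability_top_k: int = 20
    search_k: int = 2
    search_pool_size: int = 40
    stages: tuple[str, ...] = ("simulate", "dosage", "marginal", "stepwise")

    def __post_init__(self):
        for name, lo, hi in [
            ("p_strict", 0, 1), ("p_sep", 0, 1), ("min_freq", 0, 0.5),
            ("best_guess", 0, 1), ("tag_r2", 0, 1), ("stability_fraction", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo < v <= hi:
                raise InvalidConfigError(f"{name}={v} outside ({lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_seeds: dict[str, int]
    outputs: dict[str, str]  # path -> sha256
    wall: dict[str, float]
    completed: list[str]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_scenario(
    config: RunConfig,
) -> tuple[dict[str, AllelePool], object, PeptideAlignment, DiseaseModel]:
    """Pools, haplotype model, alignment and disease model for a config.

    Causal residues are chosen deterministically: in each designated gene, the
    polymorphic mature-protein position whose most balanced residue has
    population frequency closest to 0.2 carries the planted effect.
    """
    seed = stage_seed(config.seed, "scenario")
    pools = {
        gene: build_allele_pool(gene, n, config.concentration, seed + i)
        for i, (gene, n) in enumerate(config.genes.items())
    }
    hap_model = random_haplotype_model(
        pools, config.n_haplotypes, config.lam, seed + 1000
    )
    alignment = random_peptide_alignment(
        pools, config.n_positions, seed + 2000
    )
    effects: dict[tuple[str, int, str], float] = {}
    for gene, or_ in config.causal_ors.items():
        pool = pools[gene]
        best = None
        for pos in alignment.positions(gene):
            col = alignment.residues_at(gene, pos)
            for res in sorted(col.unique()):
                freq = float(pool.frequencies[[r == res for r in col]].sum())
                if 0.0 < freq < 1.0:
                    score = abs(freq - 0.2)
                    if best is None or score < best[0]:
                        best = (score, pos, res)
        if best is None:
            raise InvalidConfigError(f"gene {gene} has no polymorphic position")
        _, pos, res = best
        effects[(gene, pos, res)] = float(np.log(or_))
    disease = DiseaseModel(intercept=config.intercept, residue_effects=effects)
    return pools, hap_model, alignment, disease


def validate_inputs(
    posterior_path=None, alignment_path=None, phenotype_path=None
) -> list[str]:
    """Schema and invariant checks on the TSV inputs; returns a list of
    human-readable problems (empty when clean)."""
    problems: list[str] = []
    posteriors = phenotype = None
    if posterior_path is not None:
        try:
            posteriors = read_posteriors_tsv(posterior_path)
            required = {"individual_id", "gene", "allele1", "allele2", "posterior"}
            missing = required - set(posteriors.columns)
            if missing:
                problems.append(f"{posterior_path}: missing columns {sorted(missing)}")
            else:
                validate_posteriors(posteriors)
        except Exception as exc:
            problems.append(f"{posterior_path}: {exc}")
    if alignment_path is not None:
        try:
            alignment = PeptideAlignment.from_tsv(alignment_path)
            if posteriors is not None and not problems:
                for gene in posteriors["gene"].unique():
                    if gene not in alignment.genes:
                        problems.append(f"{alignment_path}: gene {gene} absent")
        except Exception as exc:
            problems.append(f"{alignment_path}: {exc}")
    if phenotype_path is not None:
        try:
            phenotype = read_phenotypes_tsv(phenotype_path)
            if not set(phenotype.unique()) <= {0, 1}:
                problems.append(f"{phenotype_path}: status must be 0/1")
            if posteriors is not None:
                extra = set(posteriors["individual_id"]) - set(phenotype.index)
                if extra:
                    problems.append(
                        f"{phenotype_path}: {len(extra)} individuals lack phenotypes"
                    )
        except Exception as exc:
            problems.append(f"{phenotype_path}: {exc}")
    return problems


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in dependency order and write a manifest."""
    stages = list(config.stages)
    order = ["simulate", "dosage", "marginal", "stepwise", "permtest", "stability", "search"]
    deps = {
        "dosage": ["simulate"],
        "marginal": ["dosage"],
        "stepwise": ["dosage"],
        "permtest": ["stepwise"],
        "stability": ["stepwise"],
        "search": ["stepwise"],
    }
    for s in stages:
        if s not in order:
            raise InvalidConfigError(f"unknown stage {s!r}")
        for d in deps.get(s, []):
            if d not in stages:
                raise DependencyError(f"stage {s!r} requires stage {d!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.seed, s) for s in order}
    outputs: dict[str, str] = {}
    wall: dict[str, float] = {}
    completed: list[str] = []
    state: dict = {}

    def record(path: Path):
        outputs[str(path)] = _sha256(path)

    for s in [s for s in order if s in stages]:
        t0 = time.time()
        if s == "simulate":
            pools, hap_model, alignment, disease = build_scenario(config)
            cohort = simulate_cohort(
                pools, hap_model, alignment, disease,
                config.n_cases, config.n_controls, seeds[s],
            )
            if config.blur_temperature > 0:
                cohort = blur_posteriors(
                    cohort, config.blur_temperature, seeds[s] + 1, pools
                )
            state.update(pools=pools, alignment=alignment, cohort=cohort, disease=disease)
            write_posteriors_tsv(cohort, out / "posteriors.tsv")
            write_phenotypes_tsv(cohort, out / "phenotypes.tsv")
            alignment.to_tsv(out / "alignment.tsv", [f"seed={config.seed}"])
            for p in ("posteriors.tsv", "phenotypes.tsv", "alignment.tsv"):
                record(out / p)
        elif s == "dosage":
            cohort, alignment = state["cohort"], state["alignment"]
            allele_dos = cohort_allele_dosages(
                cohort.posteriors,
                genes=list(state["pools"]),
                alleles_by_gene={g: p.alleles for g, p in state["pools"].items()},
            )
            residue_dos = drop_monomorphic(residue_dosage(allele_dos, alignment))
            state.update(allele_dos=allele_dos, residue_dos=residue_dos)
            write_dosage_tsv(residue_dos, out / "residue_dosages.tsv",
                             [f"seed={config.seed}", f"predictors={residue_dos.shape[1]}"])
            record(out / "residue_dosages.tsv")
        elif s == "marginal":
            scan = marginal_scan(state["residue_dos"], state["cohort"].phenotype)
            state["marginal"] = scan
            scan.to_csv(out / "marginal.tsv", sep="\t", index=False)
            record(out / "marginal.tsv")
        elif s == "stepwise":
            y = state["cohort"].phenotype
            pool = state["residue_dos"]
            p_enter = config.p_enter or bonferroni_threshold(pool.shape[1])
            trace = forward_stepwise(pool, y, p_enter=p_enter)
            retained = backward_check(trace, pool, y, p_stay=p_enter)
            state.update(trace=trace, retained=retained, p_enter=p_enter)
            frame = trace.to_frame()
            frame["retained_after_backward"] = [
                p in retained for p in trace.predictors
            ]
            frame.to_csv(out / "stepwise_trace.tsv", sep="\t", index=False)
            record(out / "stepwise_trace.tsv")
        elif s == "permtest":
            y = state["cohort"].phenotype
            result = permutation_null(
                config.permutation_k, state["allele_dos"], state["alignment"], y,
                B=config.permutation_B, seed=seeds[s],
            )
            pd.DataFrame({"d_perm": result.d_perm}).to_csv(
                out / "permutation_deviances.tsv", sep="\t", index=False
            )
            with open(out / "permutation_summary.json", "w") as fh:
                json.dump(
                    {"k": result.k, "d_obs": result.d_obs, "p": result.p,
                     "B": result.B, "seed": result.seed,
                     "top_residues": list(result.observed_predictors)},
                    fh, indent=2,
                )
            record(out / "permutation_deviances.tsv")
            record(out / "permutation_summary.json")
        elif s == "stability":
            y = state["cohort"].phenotype
            result = bootstrap_stability(
                state["residue_dos"], y, B=config.stability_B,
                fraction=config.stability_fraction,
                top_k=config.stability_top_k, p_enter=state.get("p_enter"),
                seed=seeds[s],
            )
            result.rank_freq.to_csv(out / "stability_rank_freq.tsv", sep="\t")
            record(out / "stability_rank_freq.tsv")
        elif s == "search":
            y = state["cohort"].phenotype
            scan = state.get("marginal")
            pool = state["residue_dos"]
            if scan is not None and len(scan):
                top = list(scan["predictor"].head(config.search_pool_size))
                pool = pool[top]
            else:
                pool = pool.iloc[:, : config.search_pool_size]
            result = exhaustive_residue_search(pool, y, k=config.search_k)
            result.table.head(100).to_csv(out / "search_top.tsv", sep="\t", index=False)
            record(out / "search_top.tsv")
        wall[s] = time.time() - t0
        completed.append(s)

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        stage_seeds={s: seeds[s] for s in completed},
        outputs=outputs,
        wall=wall,
        completed=completed,
    )
    manifest.write(out / "manifest.json")
    return manifest
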