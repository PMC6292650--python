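"""Sequence-assignment permutation null and bootstrap stability selection.

The permutation null asks whether the deviance explained by the best k amino
acids could have arisen by chance tagging of classical alleles: within each
gene the allele-to-sequence map is permuted uniformly, preserving every
allele's frequency and its relationship with disease while breaking the link
between residues and alleles.  Per permutation the residue dosages are
re-derived and the best k residues re-selected by unthresholded forward
search; the empirical p uses the add-one convention (1 + r) / (B + 1).

Stability selection repeats forward stepwise selection on subsamples (a
fixed fraction of cases and of controls, without replacement) and tabulates
how often each predictor enters at each rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import PeptideAlignment
from .errors import InvalidConfigError, SimulationError
from .hla_data import drop_monomorphic, residue_dosage
from .stepwise import StepwiseTrace, forward_stepwise
from .association import fit_joint

logger = logging.getLogger(__name__)

DEFAULT_B_PERMUTATIONS = 10_000
DEFAULT_B_BOOTSTRAP = 1_000
DEFAULT_FRACTION = 2.0 / 3.0
DEFAULT_TOP_K = 20


@dataclass
class PermutationNullResult:
    k: int
    d_obs: float
    d_perm: np.ndarray
    p: float
    seed: int
    scope: str = "within-gene sequence reassignment"
    observed_predictors: tuple[str, ...] = ()

    @property
    def B(self) -> int:
        return len(self.d_perm)


@dataclass
class StabilityResult:
    replicates: list[list[str]]
    rank_freq: pd.DataFrame  # predictors x rank, selection frequency
    B: int
    fraction: float

    def entry_frequency(self, predictor: str, rank: int) -> float:
        if predictor in self.rank_freq.index and rank in self.rank_freq.columns:
            return float(self.rank_freq.at[predictor, rank])
        return 0.0


def permute_sequence_assignment(
    alignment: PeptideAlignment, seed: int | np.random.Generator
) -> PeptideAlignment:
    """Permute the allele-to-sequence map uniformly within each gene.

    The multiset of sequences per gene is preserved; allele dosages (and thus
    allele-disease association results) are untouched.  Single-allele genes
    are left unpermuted with a log entry.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = {}
    for gene in alignment.genes:
        k = len(alignment.alleles(gene))
        if k < 2:
            logger.info("permute_sequence_assignment: gene %s has one allele; unpermuted", gene)
            continue
        perms[gene] = rng.permutation(k)
    return alignment.reassigned(perms)


def deviance_explained(
    selected: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> float:
    """Null deviance minus residual deviance of the joint logistic fit (the
    null model is covariates-only, so D is covariate-adjusted when given)."""
    fit = fit_joint(selected, y, covariates)
    return fit.deviance_explained


def best_k_deviance(
    pool: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame | None,
    k: int,
) -> tuple[float, StepwiseTrace]:
    trace = forward_stepwise(pool, y, covariates, force_k=k)
    if not trace.entries:
        return 0.0, trace
    d = deviance_explained(pool[trace.predictors], y, covariates)
    return d, trace


def permutation_null(
    k: int,
    allele_dosages: pd.DataFrame,
    alignment: PeptideAlignment,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    B: int = DEFAULT_B_PERMUTATIONS,
    seed: int = 0,
    reselect: bool = True,
    max_retries: int = 10,
) -> PermutationNullResult:
    """Empirical null for the deviance explained by the top-k residues.

    With ``reselect`` (the default, the deviance-maximizing reading), the top
    k residues are re-chosen by unthresholded forward search in each
    permutation; otherwise the observed residues' identities are held fixed
    and only their permuted dosages refit.
    """
    if k < 1 or B < 1:
        raise InvalidConfigError("k and B must be >= 1")
    observed = drop_monomorphic(residue_dosage(allele_dosages, alignment))
    d_obs, trace = best_k_deviance(observed, y, covariates, k)
    if len(trace.entries) < k:
        raise InvalidConfigError(f"fewer than k={k} polymorphic residues available")
    seq = np.random.SeedSequence(seed)
    children = seq.spawn(B)
    d_perm = np.empty(B)
    for b in range(B):
        rng = np.random.default_rng(children[b])
        for attempt in range(max_retries):
            perm_alignment = permute_sequence_assignment(alignment, rng)
            pool = drop_monomorphic(residue_dosage(allele_dosages, perm_alignment))
            if reselect:
                d, t = best_k_deviance(pool, y, covariates, k)
                if len(t.entries) == k:
                    d_perm[b] = d
                    break
            else:
                cols = [c for c in trace.predictors if c in pool.columns]
                d_perm[b] = (
                    deviance_explained(pool[cols], y, covariates) if cols else 0.0
                )
                break
        else:
            raise SimulationError(
                f"permutation replicate {b}: fewer than {k} polymorphic residues "
                f"after {max_retries} re-permutations"
            )
    r = int(np.sum(d_perm >= d_obs - 1e-12))
    p = (1 + r) / (B + 1)
    return PermutationNullResult(
        k=k,
        d_obs=d_obs,
        d_perm=d_perm,
        p=p,
        seed=seed,
        observed_predictors=tuple(trace.predictors),
    )


def bootstrap_stability(
    pool: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    B: int = DEFAULT_B_BOOTSTRAP,
    fraction: float = DEFAULT_FRACTION,
    top_k: int = DEFAULT_TOP_K,
    p_enter: float | None = None,
    seed: int = 0,
) -> StabilityResult:
    """Stability of stepwise selection under case/control subsampling.

    Each replicate draws floor(fraction x n_cases) cases and
    floor(fraction x n_controls) controls without replacement and runs forward
    selection for up to ``top_k`` steps at ``p_enter`` (pool-size Bonferroni
    by default); the summary tabulates per predictor the frequency of entering
    at each rank.  Predictors constant within a subsample simply cannot enter
    that replicate (logged at debug level by the selector).
    """
    if not 0.0 < fraction <= 1.0:
        raise InvalidConfigError("fraction must lie in (0, 1]")
    if B < 1:
        raise InvalidConfigError("B must be >= 1")
    cases = y.index[y == 1]
    controls = y.index[y == 0]
    n_case_sub = int(np.floor(fraction * len(cases)))
    n_ctrl_sub = int(np.floor(fraction * len(controls)))
    children = np.random.SeedSequence(seed).spawn(B)
    replicates: list[list[str]] = []
    for b in range(B):
        rng = np.random.default_rng(children[b])
        take = np.concatenate(
            [
                rng.choice(len(cases), size=n_case_sub, replace=False),
                len(cases) + rng.choice(len(controls), size=n_ctrl_sub, replace=False),
            ]
        )
        idx = cases.append(controls)[take]
        trace = forward_stepwise(
            pool.loc[idx], y.loc[idx],
            None if covariates is None else covariates.loc[idx],
            p_enter=p_enter, max_steps=top_k,
        )
        replicates.append(trace.predictors)
    ranks = range(1, top_k + 1)
    preds = sorted({p for rep in replicates for p in rep})
    freq = pd.DataFrame(0.0, index=preds, columns=list(ranks))
    for rep in replicates:
        for r, p in enumerate(rep, start=1):
            freq.at[p, r] += 1.0
    freq /= B
    return StabilityResult(replicates=replicates, rank_freq=freq, B=B, fraction=fraction)
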