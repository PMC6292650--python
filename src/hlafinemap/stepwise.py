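"""Forward/backward stepwise conditional selection and conditional scans.

At each forward step every remaining predictor is refit conditional on the
predictors already in the model; the smallest-p candidate enters while its p
stays below the entry threshold.  The entry statistic is the same headline
used by ``fit_logistic`` (Wald, with LRT substituted on non-convergence or
separation).  Ties are broken by larger |beta| then lexicographic id, making
traces fully deterministic.  The default entry threshold is the Bonferroni
cutoff 0.05 over the realized pool size, which prints as 4.87e-5 when the
pool holds 1028 polymorphic residues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    AssociationResult,
    fit_logistic,
    irls_logistic,
    _prepare,
    _check_phenotype,
)
from .errors import InvalidConfigError

logger = logging.getLogger(__name__)

DEFAULT_MAX_STEPS = 20
DEFAULT_P_SEP = 1e-4
STRICT_P_ENTER = 1e-8


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class StepEntry:
    step: int
    predictor: str
    ptype: str
    p_enter: float
    beta: float
    deviance: float


@dataclass
class StepwiseTrace:
    entries: list[StepEntry]
    threshold: float | None
    pool_description: str = ""

    @property
    def predictors(self) -> list[str]:
        return [e.predictor for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        columns = ["step", "predictor", "type", "p_enter", "beta", "deviance"]
        if not self.entries:
            return pd.DataFrame(columns=columns)
        return pd.DataFrame(
            [
                {
                    "step": e.step,
                    "predictor": e.predictor,
                    "type": e.ptype,
                    "p_enter": e.p_enter,
                    "beta": e.beta,
                    "deviance": e.deviance,
                }
                for e in self.entries
            ]
        )


@dataclass
class Haplogroups:
    groups: dict[int, list[str]]
    leads: dict[int, str]
    conditional_p: dict[str, float] = field(default_factory=dict)
    marginal_p: dict[str, float] = field(default_factory=dict)

    def group_of(self, predictor: str) -> int | None:
        for g, members in self.groups.items():
            if predictor in members:
                return g
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, members in self.groups.items():
            for m in members:
                rows.append(
                    {
                        "predictor": m,
                        "group": g,
                        "lead": self.leads[g],
                        "p_marginal": self.marginal_p.get(m, np.nan),
                        "p_conditional_on_lead": self.conditional_p.get(m, np.nan),
                    }
                )
        return pd.DataFrame(rows)


# ----------------------------------------------------------------- internals
def _candidate_stats(
    yv: np.ndarray,
    base: np.ndarray,
    xcol: np.ndarray,
    reduced_dev: float,
) -> tuple[float, float, bool]:
    """(headline p, beta, collinear?) for one candidate given the base design."""
    X = np.hstack([base, xcol[:, None]])
    fit = irls_logistic(X, yv)
    if fit.collinear:
        return np.inf, np.nan, True
    beta = float(fit.beta[-1])
    se = float(np.sqrt(fit.cov[-1, -1])) if fit.cov is not None else np.nan
    if fit.ok and np.isfinite(se) and se > 0:
        p = float(stats.chi2.sf((beta / se) ** 2, 1))
    else:
        p = float(stats.chi2.sf(max(reduced_dev - fit.deviance, 0.0), 1))
    return p, beta, False


def forward_stepwise(
    pool: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    p_enter: float | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
    force_k: int | None = None,
    pool_types: Mapping[str, str] | None = None,
) -> StepwiseTrace:
    """Forward stepwise selection over a dosage pool.

    ``p_enter=None`` defaults to the Bonferroni cutoff over the realized pool
    size.  With ``force_k`` set, exactly the best ``force_k`` predictors are
    selected with no threshold (the deviance-maximizing best-k used by the
    permutation null).
    """
    cols = [c for c in pool.columns if np.ptp(pool[c].dropna().to_numpy()) > 0]
    if p_enter is None:
        p_enter = 0.05 / max(len(cols), 1)
    if not 0.0 < p_enter < 1.0 and force_k is None:
        raise InvalidConfigError("p_enter must lie in (0, 1)")
    yv, cov, extra, _ = _prepare(y, covariates, *[pool[c] for c in cols])
    _check_phenotype(yv)
    n = len(yv)
    X = extra  # n x m candidate matrix, complete-case aligned
    ones = np.ones((n, 1))
    entered: list[int] = []
    entries: list[StepEntry] = []
    limit = force_k if force_k is not None else max_steps
    remaining = list(range(len(cols)))
    while len(entered) < limit and remaining:
        base = np.hstack([ones, cov, X[:, entered]]) if entered else np.hstack([ones, cov])
        reduced = irls_logistic(base, yv)
        best = None
        for j in remaining:
            p, beta, collinear = _candidate_stats(yv, base, X[:, j], reduced.deviance)
            if collinear:
                continue
            key = (p, -abs(beta) if np.isfinite(beta) else 0.0, cols[j])
            if best is None or key < best[0]:
                best = (key, j, p, beta)
        if best is None:
            break
        _, j, p, beta = best
        if force_k is None and p >= p_enter:
            break
        entered.append(j)
        remaining.remove(j)
        model_fit = irls_logistic(np.hstack([ones, cov, X[:, entered]]), yv)
        entries.append(
            StepEntry(
                step=len(entered),
                predictor=cols[j],
                ptype=(pool_types or {}).get(cols[j], "residue"),
                p_enter=p,
                beta=beta,
                deviance=model_fit.deviance,
            )
        )
    return StepwiseTrace(
        entries=entries,
        threshold=None if force_k is not None else p_enter,
        pool_description=f"{len(cols)} polymorphic predictors",
    )


def backward_check(
    trace: StepwiseTrace | Sequence[str],
    pool: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    p_stay: float | None = None,
) -> list[str]:
    """Iteratively drop any selected predictor whose p conditional on all the
    others reaches ``p_stay``; returns the fixed-point retained set."""
    selected = list(trace.predictors if isinstance(trace, StepwiseTrace) else trace)
    if p_stay is None:
        p_stay = trace.threshold if isinstance(trace, StepwiseTrace) else None
    if p_stay is None:
        raise InvalidConfigError("p_stay required when trace carries no threshold")
    changed = True
    while changed and selected:
        changed = False
        worst = None
        for name in selected:
            others = [c for c in selected if c != name]
            covs = pd.concat(
                ([covariates] if covariates is not None else []) + [pool[others]], axis=1
            ) if others else covariates
            try:
                res = fit_logistic(pool[name], y, covs)
                p = res.p
            except Exception:
                p = 1.0
            if p >= p_stay and (worst is None or p > worst[1]):
                worst = (name, p)
        if worst is not None:
            selected.remove(worst[0])
            changed = True
    return selected


def conditional_scan(
    targets: pd.DataFrame,
    conditioning: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit every target with the conditioning set as fixed covariates.

    Targets identical to a conditioning predictor (same name, or numerically
    identical column) are skipped with a log entry.  The per-scan minimum p
    is attached as ``.attrs["min_p"]``.
    """
    cond_cols = list(conditioning.columns)
    covs_parts = ([covariates] if covariates is not None else []) + (
        [conditioning] if cond_cols else []
    )
    covs = pd.concat(covs_parts, axis=1) if covs_parts else None
    rows = []
    for col in targets.columns:
        x = targets[col]
        duplicate = col in cond_cols or any(
            np.array_equal(x.to_numpy(), conditioning[c].to_numpy()) for c in cond_cols
        )
        if duplicate:
            logger.info("conditional_scan: target %s is in the conditioning set; skipped", col)
            continue
        try:
            res = fit_logistic(x, y, covs)
        except Exception as exc:  # collinear with the conditioning set
            logger.info("conditional_scan: target %s skipped (%s)", col, exc)
            continue
        rows.append(res.as_row())
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("p").reset_index(drop=True)
        out.attrs["min_p"] = float(out["p"].min())
    return out


def mixed_pool_stepwise(
    pools: Mapping[str, pd.DataFrame],
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    p_enter: float | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> StepwiseTrace:
    """Forward stepwise over the concatenation of several typed pools
    (e.g. residues, classical alleles, SNPs), recording each entry's type.

    A predictor appearing in more than one pool (same column name, or a
    numerically identical column) is kept once, from the first pool in
    mapping order.
    """
    frames = []
    types: dict[str, str] = {}
    seen: list[np.ndarray] = []
    for ptype, frame in pools.items():
        for col in frame.columns:
            arr = frame[col].to_numpy(dtype=float)
            if col in types or any(np.array_equal(arr, s) for s in seen):
                logger.info("mixed pool: duplicate predictor %s (%s) dropped", col, ptype)
                continue
            frames.append(frame[col])
            types[col] = ptype
            seen.append(arr)
    combined = pd.concat(frames, axis=1)
    return forward_stepwise(
        combined, y, covariates, p_enter=p_enter, max_steps=max_steps, pool_types=types
    )


def assign_haplogroups(
    dosages: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    predictors: Sequence[str] | None = None,
    p_sep: float = DEFAULT_P_SEP,
) -> Haplogroups:
    """Greedy haplogroup assignment under pairwise conditioning.

    Predictors (marginally significant, sorted by marginal p ascending — the
    sort is recomputed here if ``predictors`` is None) are assigned so that
    the best unassigned predictor seeds a new group and every remaining one
    joins it iff its p conditional on the group's lead (pairwise model
    lead + candidate) reaches ``p_sep`` — its signal absorbed by the lead.
    """
    marginal: dict[str, float] = {}
    cols = list(predictors) if predictors is not None else list(dosages.columns)
    for c in cols:
        marginal[c] = fit_logistic(dosages[c], y, covariates).p
    order = sorted(cols, key=lambda c: (marginal[c], c))
    unassigned = list(order)
    groups: dict[int, list[str]] = {}
    leads: dict[int, str] = {}
    cond_p: dict[str, float] = {}
    gid = 0
    while unassigned:
        gid += 1
        lead = unassigned.pop(0)
        groups[gid] = [lead]
        leads[gid] = lead
        lead_cov = pd.concat(
            ([covariates] if covariates is not None else []) + [dosages[[lead]]], axis=1
        )
        still = []
        for cand in unassigned:
            try:
                p = fit_logistic(dosages[cand], y, lead_cov).p
            except Exception:
                p = 1.0  # collinear with the lead: fully absorbed
            if p >= p_sep:
                groups[gid].append(cand)
                cond_p[cand] = p
            else:
                still.append(cand)
        unassigned = still
    return Haplogroups(groups=groups, leads=leads, conditional_p=cond_p, marginal_p=marginal)
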