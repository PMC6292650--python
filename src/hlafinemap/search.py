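"""Exhaustive best-pair and best-triple searches over residues and positions.

Greedy stepwise selection is conditional by construction; the exhaustive
search instead fits every k-subset (k = 2 or 3) of residue predictors — or of
multi-df amino-acid positions — jointly and ranks the models by AIC, so the
best combination is found regardless of entry order.  Search-space sizes are
exact binomial coefficients; a budget guard refuses runs that would fit more
models than the configured limit unless forced.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import (
    DEFAULT_MIN_FREQ,
    _check_phenotype,
    _prepare,
    _drop_reference,
    _retain_non_rare,
    irls_logistic,
)
from .errors import InvalidConfigError, InvalidInputError, SearchBudgetError
from .hla_data import position_groups

DEFAULT_BUDGET = 10**6


def count_combinations(n: int, k: int) -> int:
    """Exact binomial coefficient C(n, k) in integer arithmetic."""
    if n < 0 or k < 0:
        raise InvalidConfigError("n and k must be non-negative")
    if k > n:
        raise InvalidConfigError(f"k={k} exceeds n={n}")
    return math.comb(n, k)


@dataclass
class SearchResult:
    table: pd.DataFrame  # rank, combination, aic, deviance, df
    space_size: int
    level: str  # "residue" or "position"

    @property
    def best(self) -> tuple[str, ...]:
        return tuple(self.table.iloc[0]["combination"].split(" + "))


def _rank_models(rows: list[dict]) -> pd.DataFrame:
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        ["aic", "df", "combination"], kind="mergesort"
    ).reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame


def exhaustive_residue_search(
    pool: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    k: int = 2,
    budget: int = DEFAULT_BUDGET,
    force: bool = False,
) -> SearchResult:
    """Fit every k-subset of residue columns jointly and rank by AIC.

    Collinear subsets are kept in the table with AIC = +inf and flagged.
    """
    if k not in (2, 3):
        raise InvalidConfigError("combination order k must be 2 or 3")
    cols = [c for c in pool.columns if np.ptp(pool[c].dropna().to_numpy()) > 0]
    if len(cols) < k:
        raise InvalidInputError(f"need >= {k} non-constant predictors")
    size = count_combinations(len(cols), k)
    if size > budget and not force:
        raise SearchBudgetError(f"{size} models exceed the budget of {budget}")
    yv, cov, X, _ = _prepare(y, covariates, *[pool[c] for c in cols])
    _check_phenotype(yv)
    ones = np.ones((len(yv), 1))
    base = np.hstack([ones, cov])
    n_params = base.shape[1] + k
    rows = []
    for combo in itertools.combinations(range(len(cols)), k):
        fit = irls_logistic(np.hstack([base, X[:, combo]]), yv)
        name = " + ".join(cols[j] for j in combo)
        if fit.collinear:
            rows.append(
                {"combination": name, "aic": np.inf, "deviance": np.nan, "df": k,
                 "flag": "collinear"}
            )
        else:
            rows.append(
                {"combination": name, "aic": fit.deviance + 2 * n_params,
                 "deviance": fit.deviance, "df": k, "flag": ""}
            )
    return SearchResult(table=_rank_models(rows), space_size=size, level="residue")


def exhaustive_position_search(
    residue_dosages: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    k: int = 2,
    min_freq: float = DEFAULT_MIN_FREQ,
    budget: int = DEFAULT_BUDGET,
    force: bool = False,
) -> SearchResult:
    """Exhaustive search over multi-df amino-acid positions.

    Each candidate model includes, for every position in the combination, all
    residues with frequency above ``min_freq`` minus a reference level (the
    most frequent residue), since residue dosages at a position sum to 2.
    """
    if k not in (2, 3):
        raise InvalidConfigError("combination order k must be 2 or 3")
    designs: dict[str, pd.DataFrame] = {}
    for (gene, pos), cols in position_groups(residue_dosages).items():
        retained = _retain_non_rare(residue_dosages[cols], min_freq)
        if retained.shape[1] < 2:
            continue  # monomorphic or effectively monomorphic position
        designs[f"{gene}@{pos}"] = _drop_reference(retained)
    names = sorted(designs)
    if len(names) < k:
        raise InvalidInputError(f"need >= {k} polymorphic positions")
    size = count_combinations(len(names), k)
    if size > budget and not force:
        raise SearchBudgetError(f"{size} models exceed the budget of {budget}")
    yv, cov, _, idx = _prepare(y, covariates)
    _check_phenotype(yv)
    ones = np.ones((len(yv), 1))
    base = np.hstack([ones, cov])
    mats = {name: designs[name].loc[idx].to_numpy(dtype=float) for name in names}
    rows = []
    for combo in itertools.combinations(names, k):
        X = np.hstack([mats[name] for name in combo])
        df = X.shape[1]
        fit = irls_logistic(np.hstack([base, X]), yv)
        name = " + ".join(combo)
        if fit.collinear:
            rows.append(
                {"combination": name, "aic": np.inf, "deviance": np.nan, "df": df,
                 "flag": "collinear"}
            )
        else:
            n_params = base.shape[1] + df
            rows.append(
                {"combination": name, "aic": fit.deviance + 2 * n_params,
                 "deviance": fit.deviance, "df": df, "flag": ""}
            )
    return SearchResult(table=_rank_models(rows), space_size=size, level="position")
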