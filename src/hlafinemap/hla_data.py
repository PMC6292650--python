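"""From genotype posteriors to allele- and residue-dosage matrices, plus the
r-squared machinery used for alternative-explanation screening and pruning.

Dosages are expected copy counts in [0, 2]: the posterior-weighted average of
the number of copies of an allele (or of a residue at an aligned position)
carried by an individual.  Per individual, allele dosages at a gene sum to 2,
and residue dosages at a position (gap included) sum to 2 — conservation
identities exploited throughout as invariants.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import PeptideAlignment, allele_key, parse_allele_key, parse_residue_key
from .errors import (
    InvalidConfigError,
    InvalidInputError,
    MissingDataError,
    UnresolvableAlleleError,
)

POSTERIOR_SUM_TOL = 1e-6


def validate_posteriors(posteriors: pd.DataFrame, tol: float = POSTERIOR_SUM_TOL) -> None:
    """Check per individual/gene posterior sums; raise naming offenders."""
    if ((posteriors["posterior"] < -1e-12) | (posteriors["posterior"] > 1 + 1e-12)).any():
        raise InvalidInputError("posterior probabilities must lie in [0, 1]")
    sums = posteriors.groupby(["individual_id", "gene"], sort=False)["posterior"].sum()
    bad = sums[(sums - 1.0).abs() > tol]
    if len(bad):
        examples = ", ".join(f"{i}/{g}={v:.4f}" for (i, g), v in bad.head(5).items())
        raise MissingDataError(
            f"{len(bad)} individual-gene posteriors do not sum to 1 (e.g. {examples})"
        )


def allele_dosage(
    posteriors: pd.DataFrame, gene: str, alleles: Sequence[str] | None = None
) -> pd.DataFrame:
    """Expected allele copy counts for one gene.

    dosage(a) for individual i = sum over genotypes g of posterior(g) x copies
    of a in g.  Columns are labelled ``gene*allele``.
    """
    sub = posteriors[posteriors["gene"] == gene]
    if sub.empty:
        raise InvalidInputError(f"gene {gene} not present in posterior table")
    sums = sub.groupby("individual_id", sort=False)["posterior"].sum()
    bad = sums[sums.abs() < POSTERIOR_SUM_TOL]
    if len(bad):
        raise MissingDataError(
            f"zero posterior mass at {gene} for individuals: {list(bad.index[:5])}"
        )
    melted = pd.concat(
        [
            sub[["individual_id", "allele1", "posterior"]].rename(columns={"allele1": "allele"}),
            sub[["individual_id", "allele2", "posterior"]].rename(columns={"allele2": "allele"}),
        ]
    )
    dos = (
        melted.groupby(["individual_id", "allele"], sort=False)["posterior"]
        .sum()
        .unstack(fill_value=0.0)
    )
    dos = dos.reindex(sums.index)
    if alleles is not None:
        dos = dos.reindex(columns=list(alleles), fill_value=0.0)
    dos.columns = [allele_key(gene, a) for a in dos.columns]
    dos.index.name = "individual_id"
    return dos


def cohort_allele_dosages(
    posteriors: pd.DataFrame,
    genes: Iterable[str] | None = None,
    alleles_by_gene: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Allele dosages for several genes, column-concatenated."""
    if genes is None:
        genes = posteriors["gene"].unique()
    parts = [
        allele_dosage(
            posteriors,
            g,
            None if alleles_by_gene is None else alleles_by_gene.get(g),
        )
        for g in genes
    ]
    return pd.concat(parts, axis=1)


def residue_dosage(
    allele_dosages: pd.DataFrame, alignment: PeptideAlignment
) -> pd.DataFrame:
    """Residue dosages from allele dosages via the alignment's indicator matrix.

    dosage(gene, pos, res) = sum over alleles of that gene carrying res at pos
    of the allele dosage; the gap is a residue level like any other.
    """
    by_gene: dict[str, list[str]] = {}
    for col in allele_dosages.columns:
        gene, allele = parse_allele_key(col)
        by_gene.setdefault(gene, []).append(allele)
    parts = []
    for gene, alleles in by_gene.items():
        if gene not in alignment.genes:
            raise UnresolvableAlleleError(f"gene {gene} absent from alignment")
        known = set(alignment.alleles(gene))
        missing = [a for a in alleles if a not in known]
        if missing:
            raise UnresolvableAlleleError(
                f"alleles absent from {gene} alignment: {missing[:5]}"
            )
        ind = alignment.indicator_matrix(gene).loc[alleles]
        cols = [allele_key(gene, a) for a in alleles]
        parts.append(
            pd.DataFrame(
                allele_dosages[cols].to_numpy() @ ind.to_numpy(),
                index=allele_dosages.index,
                columns=ind.columns,
            )
        )
    return pd.concat(parts, axis=1)


def monomorphic_columns(dosages: pd.DataFrame, tol: float = 1e-12) -> list[str]:
    """Columns with (numerically) constant dosage across individuals."""
    arr = dosages.to_numpy()
    const = np.nanmax(arr, axis=0) - np.nanmin(arr, axis=0) <= tol
    return [c for c, m in zip(dosages.columns, const) if m]


def drop_monomorphic(dosages: pd.DataFrame, tol: float = 1e-12) -> pd.DataFrame:
    return dosages.drop(columns=monomorphic_columns(dosages, tol))


def best_guess_filter(posteriors: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Keep only the argmax genotype as a point mass when its posterior exceeds
    ``threshold``; individual/gene entries below it become missing (dropped)."""
    if not 0.0 < threshold <= 1.0:
        raise InvalidConfigError("best-guess threshold must lie in (0, 1]")
    idx = posteriors.groupby(["individual_id", "gene"], sort=False)["posterior"].idxmax()
    best = posteriors.loc[idx]
    best = best[best["posterior"] > threshold].copy()
    best["posterior"] = 1.0
    return best.reset_index(drop=True)


def residue_frequency(
    dosages: pd.DataFrame, subset: pd.Index | Sequence | None = None
) -> pd.Series:
    """Imputed frequency per predictor: mean dosage / 2 over the subset."""
    if subset is not None:
        if len(subset) == 0:
            raise InvalidInputError("frequency subset must be non-empty")
        dosages = dosages.loc[subset]
    return dosages.mean(axis=0) / 2.0


def correlation_r2(dosages: pd.DataFrame) -> pd.DataFrame:
    """Pairwise squared Pearson correlation of dosage columns.

    Constant columns yield NaN rows/columns (flagged, not errors).
    """
    if len(dosages) < 2:
        raise InvalidInputError("correlation requires >= 2 individuals")
    arr = dosages.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr, rowvar=False)
    r2 = r**2
    r2[sd == 0, :] = np.nan
    r2[:, sd == 0] = np.nan
    np.fill_diagonal(r2, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(r2, index=dosages.columns, columns=dosages.columns)


def prune_index_set(
    corr: pd.DataFrame, r2_max: float, order: Sequence[str]
) -> list[str]:
    """Greedy pass in ``order`` keeping a predictor iff its r2 with every
    already-kept predictor is below ``r2_max``; deterministic given order."""
    if not 0.0 < r2_max <= 1.0:
        raise InvalidConfigError("r2_max must lie in (0, 1]")
    kept: list[str] = []
    for p in order:
        vals = corr.loc[p, kept] if kept else pd.Series(dtype=float)
        if np.all(np.nan_to_num(vals.to_numpy(), nan=0.0) < r2_max):
            kept.append(p)
    return kept


def tag_groups(corr: pd.DataFrame, tag_r2: float) -> list[set[str]]:
    """Single-linkage grouping at r2 >= tag_r2, after discarding predictors
    whose correlation is undefined (monomorphic)."""
    if not 0.0 < tag_r2 <= 1.0:
        raise InvalidConfigError("tag_r2 must lie in (0, 1]")
    cols = [c for c in corr.columns if not np.isnan(corr.at[c, c])]
    parent = {c: c for c in cols}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(cols):
        row = corr.loc[a, cols]
        for b in cols[i + 1 :]:
            v = row[b]
            if not np.isnan(v) and v >= tag_r2:
                parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for c in cols:
        groups.setdefault(find(c), set()).add(c)
    return sorted(groups.values(), key=lambda s: sorted(s)[0])


def position_groups(residue_dosages: pd.DataFrame) -> dict[tuple[str, int], list[str]]:
    """Group residue columns by (gene, position)."""
    out: dict[tuple[str, int], list[str]] = {}
    for col in residue_dosages.columns:
        gene, pos, _res = parse_residue_key(col)
        out.setdefault((gene, pos), []).append(col)
    return out


def write_dosage_tsv(dosages: pd.DataFrame, path, comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        dosages.to_csv(fh, sep="\t")


def read_dosage_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_r2_long_tsv(corr: pd.DataFrame, path, comments: Sequence[str] = ()) -> None:
    long = corr.stack().rename("r2").rename_axis(["predictor1", "predictor2"]).reset_index()
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        long.to_csv(fh, sep="\t", index=False)
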