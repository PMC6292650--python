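"""Peptide alignments mapping classical HLA alleles to residues at aligned positions.

Within a gene every classical allele is a row of a rectangular table whose
columns are aligned peptide positions.  Positions are integers and may be
negative (leader-peptide numbering); position 0 does not exist.  The gap
symbol ``"_"`` marks absence of a residue at a position and is treated as a
first-class residue level throughout the package: it participates in the
per-position dosage conservation (residue dosages at a position, including
the gap, sum to two copies per individual) and may itself be tested for
association.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError

#: The 20 standard amino-acid one-letter codes plus the gap symbol.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"_"}

GAP = "_"


def residue_key(gene: str, position: int, residue: str) -> str:
    """Canonical predictor label for a residue, e.g. ``HLA-DPB1@11:L``."""
    return f"{gene}@{position}:{residue}"


def parse_residue_key(key: str) -> tuple[str, int, str]:
    gene, rest = key.split("@", 1)
    pos, res = rest.rsplit(":", 1)
    return gene, int(pos), res


def allele_key(gene: str, allele: str) -> str:
    """Canonical predictor label for a classical allele, e.g. ``HLA-DQA1*04:01``."""
    return f"{gene}*{allele}"


def parse_allele_key(key: str) -> tuple[str, str]:
    gene, allele = key.split("*", 1)
    return gene, allele


class PeptideAlignment:
    """Per-gene allele-to-sequence tables.

    Parameters
    ----------
    genes
        Mapping ``gene -> DataFrame``; each frame is indexed by allele name,
        has integer (nonzero) position columns and single-character residue
        values from the amino-acid alphabet (gap ``"_"`` allowed).
    """

    def __init__(self, genes: Mapping[str, pd.DataFrame]):
        cleaned: dict[str, pd.DataFrame] = {}
        for gene, frame in genes.items():
            frame = frame.copy()
            frame.columns = [int(c) for c in frame.columns]
            if any(c == 0 for c in frame.columns):
                raise InvalidInputError(f"gene {gene}: position 0 is not a valid position")
            if frame.index.has_duplicates:
                raise InvalidInputError(f"gene {gene}: duplicate allele rows")
            values = frame.to_numpy(dtype=object)
            bad = {v for v in values.ravel() if v not in AA_ALPHABET}
            if bad:
                raise InvalidInputError(f"gene {gene}: invalid residue symbols {sorted(bad)!r}")
            cleaned[gene] = frame.sort_index(axis=1)
        self._genes = cleaned

    @property
    def genes(self) -> list[str]:
        return list(self._genes)

    def table(self, gene: str) -> pd.DataFrame:
        return self._genes[gene]

    def alleles(self, gene: str) -> list[str]:
        return list(self._genes[gene].index)

    def positions(self, gene: str) -> list[int]:
        return list(self._genes[gene].columns)

    def residues_at(self, gene: str, position: int) -> pd.Series:
        """Allele -> residue character at one aligned position."""
        return self._genes[gene][int(position)]

    def monomorphic_positions(self, gene: str) -> list[int]:
        frame = self._genes[gene]
        return [p for p in frame.columns if frame[p].nunique() == 1]

    def sequence_of(self, gene: str, allele: str) -> str:
        return "".join(self._genes[gene].loc[allele])

    def indicator_matrix(self, gene: str) -> pd.DataFrame:
        """Alleles x residue-level 0/1 matrix with ``gene@pos:res`` columns.

        Every position contributes one column per residue level observed at
        that position (gap included), so a matrix product with allele dosages
        yields residue dosages directly.
        """
        frame = self._genes[gene]
        blocks = []
        for pos in frame.columns:
            col = frame[pos]
            for res in sorted(col.unique()):
                blocks.append(
                    pd.Series((col == res).astype(float), name=residue_key(gene, pos, res))
                )
        return pd.concat(blocks, axis=1)

    def reassigned(self, gene_permutations: Mapping[str, np.ndarray]) -> "PeptideAlignment":
        """Return a copy where allele i of gene g carries the sequence of
        allele ``perm[i]``; genes absent from the mapping are untouched."""
        out = {}
        for gene, frame in self._genes.items():
            if gene in gene_permutations:
                perm = np.asarray(gene_permutations[gene])
                new = frame.iloc[perm].copy()
                new.index = frame.index
                out[gene] = new
            else:
                out[gene] = frame
        return PeptideAlignment(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeptideAlignment):
            return NotImplemented
        if self.genes != other.genes:
            return False
        return all(self._genes[g].equals(other._genes[g]) for g in self._genes)

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path, header_comments: Iterable[str] = ()) -> None:
        """Write the long-format TSV dialect: gene, allele, position, residue."""
        rows = []
        for gene, frame in self._genes.items():
            for allele in frame.index:
                for pos in frame.columns:
                    rows.append((gene, allele, pos, frame.at[allele, pos]))
        long = pd.DataFrame(rows, columns=["gene", "allele", "position", "residue"])
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            long.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PeptideAlignment":
        long = pd.read_csv(path, sep="\t", comment="#", dtype={"allele": str, "residue": str})
        genes = {}
        for gene, sub in long.groupby("gene", sort=False):
            frame = sub.pivot(index="allele", columns="position", values="residue")
            if frame.isna().any().any():
                raise InvalidInputError(
                    f"gene {gene}: alleles do not cover the same position set"
                )
            genes[gene] = frame
        return cls(genes)
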