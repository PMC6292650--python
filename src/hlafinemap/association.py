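"""Logistic-regression engine for dosage association testing.

Single-predictor dosage tests, multi-df omnibus tests per amino-acid position
or per gene, non-multiplicative genetic-model codings, pairwise interaction
scans and principal-component covariates.  Fitting is by iteratively
reweighted least squares (IRLS): at most 50 iterations, convergence declared
at 1e-8 on the deviance, separation flagged when any |beta| exceeds 15.  The
headline p-value is the Wald test; the likelihood-ratio p is always recorded
and substitutes (flagged) when the fit did not converge or separated, since
extreme odds ratios do occur in imputed HLA data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import PeptideAlignment, parse_allele_key, parse_residue_key
from .errors import DegeneratePredictorError, InvalidConfigError, InvalidInputError

MAX_ITER = 50
DEV_TOL = 1e-8
SEPARATION_BETA = 15.0
DEFAULT_MIN_FREQ = 0.005  # "non-rare" = combined-sample imputed frequency > 0.5%

_MU_EPS = 1e-10


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance cutoff alpha / n_tests."""
    if n_tests < 1:
        raise InvalidConfigError("n_tests must be >= 1")
    return alpha / n_tests


# ------------------------------------------------------------------ IRLS core
@dataclass
class GlmFit:
    beta: np.ndarray
    cov: np.ndarray | None
    deviance: float
    converged: bool
    separated: bool
    collinear: bool
    n_iter: int

    @property
    def ok(self) -> bool:
        return self.converged and not self.separated and not self.collinear


def _binom_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def irls_logistic(X: np.ndarray, y: np.ndarray) -> GlmFit:
    """Maximum-likelihood logistic fit by IRLS.  X must include the intercept."""
    n, p = X.shape
    if n <= p:
        return GlmFit(np.zeros(p), None, np.nan, False, False, True, 0)
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        return GlmFit(np.zeros(p), None, np.nan, False, False, True, 0)
    beta = np.zeros(p)
    ybar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    beta[0] = math.log(ybar / (1 - ybar))
    dev_old = np.inf
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            return GlmFit(beta, None, _binom_deviance(y, mu), False, False, True, it)
        # step-halving if the deviance worsens (rare, keeps extreme fits stable)
        dev = _binom_deviance(y, 1.0 / (1.0 + np.exp(-np.clip(X @ beta_new, -35, 35))))
        step = 1.0
        while dev > dev_old + 1e-8 and step > 1e-4:
            step /= 2.0
            trial = beta + step * (beta_new - beta)
            dev = _binom_deviance(y, 1.0 / (1.0 + np.exp(-np.clip(X @ trial, -35, 35))))
            beta_new = trial
        beta = beta_new
        if abs(dev_old - dev) < DEV_TOL:
            converged = True
            dev_old = dev
            break
        dev_old = dev
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = None
    separated = bool(np.max(np.abs(beta)) > SEPARATION_BETA)
    return GlmFit(beta, cov, dev_old, converged, separated, False, it)


# --------------------------------------------------------------------- types
@dataclass
class AssociationResult:
    """One fitted effect: per-unit-dosage log-odds and its tests."""

    predictor: str
    beta: float
    or_: float
    se: float
    p_wald: float
    p_lrt: float
    p: float  # headline: Wald, or LRT when flagged
    df: int
    deviance: float
    null_deviance: float
    aic: float
    n: int
    n_params: int
    converged: bool
    note: str = ""
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "predictor": self.predictor,
            "n": self.n,
            "beta": self.beta,
            "OR": self.or_,
            "SE": self.se,
            "p_wald": self.p_wald,
            "p_lrt": self.p_lrt,
            "p": self.p,
            "df": self.df,
            "deviance": self.deviance,
            "aic": self.aic,
            "converged": self.converged,
            "note": self.note,
        }


@dataclass
class JointFit:
    """A multi-column logistic fit relative to the covariates-only model."""

    predictors: tuple[str, ...]
    betas: np.ndarray
    deviance: float
    null_deviance: float
    df: int
    p_lrt: float
    aic: float
    n: int
    n_params: int
    converged: bool
    collinear: bool

    @property
    def deviance_explained(self) -> float:
        return self.null_deviance - self.deviance


def _prepare(
    y: pd.Series, covariates: pd.DataFrame | None, *columns: pd.Series
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.Index]:
    """Align, complete-case filter and assemble (y, cov_design, X_extra, index)."""
    frames = [y.rename("__y__")]
    if covariates is not None and covariates.shape[1] > 0:
        frames.append(covariates)
    frames.extend(columns)
    joined = pd.concat(frames, axis=1, join="inner").dropna()
    yv = joined["__y__"].to_numpy(dtype=float)
    ncov = 0 if covariates is None else covariates.shape[1]
    cov = joined.iloc[:, 1 : 1 + ncov].to_numpy(dtype=float)
    extra = joined.iloc[:, 1 + ncov :].to_numpy(dtype=float)
    return yv, cov, extra, joined.index


def _check_phenotype(yv: np.ndarray) -> None:
    classes = np.unique(yv)
    if not np.all(np.isin(classes, [0.0, 1.0])) or len(classes) < 2:
        raise InvalidInputError("phenotype must be binary with both classes present")


def _chi2_sf(x: float, df: int) -> float:
    return float(stats.chi2.sf(max(x, 0.0), df))


def fit_joint(
    X: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> JointFit:
    """Fit covariates + all columns of X jointly; LRT against covariates-only."""
    yv, cov, extra, _ = _prepare(y, covariates, *[X[c] for c in X.columns])
    _check_phenotype(yv)
    n = len(yv)
    ones = np.ones((n, 1))
    reduced = irls_logistic(np.hstack([ones, cov]), yv)
    full = irls_logistic(np.hstack([ones, cov, extra]), yv)
    k = X.shape[1]
    n_params = 1 + cov.shape[1] + k
    if full.collinear:
        return JointFit(
            tuple(X.columns), np.full(k, np.nan), np.nan, reduced.deviance, k,
            np.nan, np.inf, n, n_params, False, True,
        )
    lrt = reduced.deviance - full.deviance
    return JointFit(
        predictors=tuple(X.columns),
        betas=full.beta[-k:] if k else full.beta[:0],
        deviance=full.deviance,
        null_deviance=reduced.deviance,
        df=k,
        p_lrt=_chi2_sf(lrt, k) if k else 1.0,
        aic=full.deviance + 2 * n_params,
        n=n,
        n_params=n_params,
        converged=full.converged and not full.separated,
        collinear=False,
    )


def fit_logistic(
    x: pd.Series,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    name: str | None = None,
) -> AssociationResult:
    """Single-predictor dosage logistic regression.

    Wald p by default; LRT p recorded alongside and promoted to the headline
    (with a note) when the fit fails to converge or separates.
    """
    name = name or str(x.name)
    yv, cov, extra, _ = _prepare(y, covariates, x)
    _check_phenotype(yv)
    xv = extra[:, 0]
    if np.ptp(xv) == 0:
        raise DegeneratePredictorError(f"predictor {name} is constant")
    n = len(yv)
    ones = np.ones((n, 1))
    reduced = irls_logistic(np.hstack([ones, cov]), yv)
    full = irls_logistic(np.hstack([ones, cov, extra]), yv)
    if full.collinear:
        raise DegeneratePredictorError(f"predictor {name} is collinear with covariates")
    beta = float(full.beta[-1])
    se = float(np.sqrt(full.cov[-1, -1])) if full.cov is not None else np.nan
    zsq = (beta / se) ** 2 if se and np.isfinite(se) and se > 0 else np.nan
    p_wald = _chi2_sf(zsq, 1) if np.isfinite(zsq) else np.nan
    p_lrt = _chi2_sf(reduced.deviance - full.deviance, 1)
    flagged = (not full.converged) or full.separated or not np.isfinite(p_wald)
    n_params = full.beta.size
    return AssociationResult(
        predictor=name,
        beta=beta,
        or_=math.exp(beta),
        se=se,
        p_wald=p_wald,
        p_lrt=p_lrt,
        p=p_lrt if flagged else p_wald,
        df=1,
        deviance=full.deviance,
        null_deviance=reduced.deviance,
        aic=full.deviance + 2 * n_params,
        n=n,
        n_params=n_params,
        converged=full.converged and not full.separated,
        note="lrt-substituted" if flagged else "",
    )


def marginal_scan(
    dosages: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Single-predictor tests for every non-constant column; a Table-2-style
    machine-readable table with case/control imputed frequencies."""
    cases = y[y == 1].index
    controls = y[y == 0].index
    rows = []
    for col in dosages.columns:
        x = dosages[col]
        if np.ptp(x.dropna().to_numpy()) == 0:
            continue
        res = fit_logistic(x, y, covariates)
        row = res.as_row()
        row["freq_cases"] = float(x.reindex(cases).mean() / 2)
        row["freq_controls"] = float(x.reindex(controls).mean() / 2)
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values("p").reset_index(drop=True) if len(out) else out


# ------------------------------------------------------------- omnibus tests
def _retain_non_rare(dosages: pd.DataFrame, min_freq: float) -> pd.DataFrame:
    freq = dosages.mean(axis=0) / 2.0
    keep = freq[freq > min_freq].index
    return dosages[list(keep)]


def _drop_reference(dosages: pd.DataFrame) -> pd.DataFrame:
    """Drop the most frequent level — levels sum to 2 per individual, so one
    must go for the design matrix to be full rank."""
    freq = dosages.mean(axis=0)
    return dosages.drop(columns=[freq.idxmax()])


def omnibus_position_test(
    position_dosages: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    min_freq: float = DEFAULT_MIN_FREQ,
    label: str | None = None,
) -> JointFit | None:
    """Multi-df LRT of all non-rare residues at a position jointly.

    Returns None (not testable) when fewer than two residue levels survive
    the frequency filter.
    """
    retained = _retain_non_rare(position_dosages, min_freq)
    if retained.shape[1] < 2:
        return None
    design = _drop_reference(retained)
    fit = fit_joint(design, y, covariates)
    return replace(fit, predictors=(label,) if label else fit.predictors)


def omnibus_gene_test(
    gene_dosages: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    min_freq: float = DEFAULT_MIN_FREQ,
    conditional_on: Sequence[pd.DataFrame] = (),
    label: str | None = None,
) -> JointFit | None:
    """As the position omnibus, over a gene's allele dosages; the conditional
    variant includes all non-rare alleles at the other genes (each gene
    reference-dropped) as additional covariates."""
    extra = []
    for other in conditional_on:
        other_kept = _retain_non_rare(other, min_freq)
        if other_kept.shape[1] >= 2:
            extra.append(_drop_reference(other_kept))
        elif other_kept.shape[1] == 1:
            extra.append(other_kept)
    covs = covariates
    if extra:
        covs = pd.concat(([covariates] if covariates is not None else []) + extra, axis=1)
    return omnibus_position_test(gene_dosages, y, covs, min_freq, label=label)


# ------------------------------------------------------- genetic-model codings
def genotype_copy_probs(
    posteriors: pd.DataFrame,
    gene: str,
    carrier_alleles: set[str],
) -> pd.DataFrame:
    """P(0/1/2 copies) of "an allele in ``carrier_alleles``" per individual,
    averaging over the genotype posterior."""
    sub = posteriors[posteriors["gene"] == gene]
    if sub.empty:
        raise InvalidInputError(f"gene {gene} not present in posterior table")
    copies = (
        sub["allele1"].isin(carrier_alleles).astype(int)
        + sub["allele2"].isin(carrier_alleles).astype(int)
    )
    probs = (
        pd.DataFrame({"individual_id": sub["individual_id"], "copies": copies,
                      "posterior": sub["posterior"]})
        .groupby(["individual_id", "copies"], sort=False)["posterior"]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(columns=[0, 1, 2], fill_value=0.0)
    )
    probs.columns = ["p0", "p1", "p2"]
    return probs


def model_codings(probs: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Dosage-scale codings for the four genetic models from genotype-level
    copy probabilities: allelic (expected copies), dominant (P of >=1 copy),
    recessive (P of 2 copies), genotypic (both indicator expectations)."""
    allelic = probs["p1"] + 2 * probs["p2"]
    return {
        "allelic": allelic.rename("allelic").to_frame(),
        "dominant": (probs["p1"] + probs["p2"]).rename("dominant").to_frame(),
        "recessive": probs["p2"].rename("recessive").to_frame(),
        "genotypic": pd.DataFrame({"het": probs["p1"], "hom": probs["p2"]}),
    }


def carriers_of_residue(
    alignment: PeptideAlignment, gene: str, position: int, residue: str
) -> set[str]:
    col = alignment.residues_at(gene, position)
    return set(col.index[col == residue])


def genetic_model_compare(
    probs: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit allelic/dominant/recessive/genotypic models; rank by AIC ascending,
    so the first row is the preferred model."""
    rows = []
    for model, design in model_codings(probs).items():
        if any(np.ptp(design[c].to_numpy()) == 0 for c in design.columns):
            continue
        fit = fit_joint(design, y, covariates)
        rows.append(
            {
                "model": model,
                "df": fit.df,
                "deviance": fit.deviance,
                "aic": fit.aic,
                "p_lrt": fit.p_lrt,
                "converged": fit.converged,
                "betas": tuple(np.round(fit.betas, 6)),
            }
        )
    return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)


# ------------------------------------------------------------ interaction scan
def interaction_scan(
    dosages: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """1-df LRT of the dosage-scale product term for every predictor pair.

    The Bonferroni threshold 0.05 / n_pairs is attached as ``.attrs``;
    perfectly collinear pairs are skipped with a note row.
    """
    cols = list(dosages.columns)
    if len(cols) < 2:
        raise InvalidInputError("interaction scan needs >= 2 predictors")
    rows = []
    n_pairs = 0
    for a, b in itertools.combinations(cols, 2):
        n_pairs += 1
        xa, xb = dosages[a], dosages[b]
        r = np.corrcoef(xa, xb)[0, 1] if xa.std() > 0 and xb.std() > 0 else np.nan
        if not np.isfinite(r) or r**2 > 1 - 1e-10:
            rows.append({"a": a, "b": b, "p_interaction": np.nan, "note": "collinear-skipped"})
            continue
        main = pd.DataFrame({a: xa, b: xb})
        prod = (xa * xb).rename(f"{a}x{b}")
        fit_main = fit_joint(main, y, covariates)
        fit_full = fit_joint(pd.concat([main, prod], axis=1), y, covariates)
        lrt = fit_main.deviance - fit_full.deviance
        rows.append(
            {
                "a": a,
                "b": b,
                "beta_interaction": float(fit_full.betas[-1]),
                "p_interaction": _chi2_sf(lrt, 1),
                "note": "",
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni"] = 0.05 / n_pairs
    return out


# ------------------------------------------------------- principal components
def compute_pcs(
    snps: pd.DataFrame,
    snp_meta: pd.DataFrame,
    exclude_region: tuple[str, int, int],
    n_pcs: int = 10,
    prune_r2: float = 0.2,
) -> pd.DataFrame:
    """Top principal-component scores from an LD-pruned SNP set with the
    extended HLA region removed.

    SNPs inside ``exclude_region`` (chrom, start, end) and constant SNPs are
    dropped, a greedy sequential r2 pruning pass is applied, columns are
    standardized and scores taken from the SVD; each component's sign is fixed
    so that its largest-magnitude loading is positive.
    """
    chrom, start, end = exclude_region
    inside = (
        (snp_meta["chrom"].astype(str) == str(chrom))
        & (snp_meta["pos"] >= start)
        & (snp_meta["pos"] <= end)
    )
    keep = [s for s in snps.columns if s in snp_meta.index and not inside.get(s, False)]
    mat = snps[keep]
    mat = mat.loc[:, mat.std(axis=0) > 0]
    if mat.shape[1] == 0:
        raise InvalidInputError("no SNPs remain outside the exclusion region")
    # greedy sequential LD pruning in map order
    ordered = sorted(mat.columns, key=lambda s: (str(snp_meta.at[s, "chrom"]), snp_meta.at[s, "pos"]))
    std = (mat - mat.mean()) / mat.std(axis=0)
    kept: list[str] = []
    arr = std.to_numpy()
    colpos = {c: i for i, c in enumerate(std.columns)}
    n = arr.shape[0]
    for s in ordered:
        v = arr[:, colpos[s]]
        ok = True
        for t in kept[-50:]:  # local window is enough for a pruning pass
            r = v @ arr[:, colpos[t]] / n
            if r**2 >= prune_r2:
                ok = False
                break
        if ok:
            kept.append(s)
    if len(kept) < n_pcs:
        raise InvalidInputError(
            f"only {len(kept)} SNPs remain after filtering; cannot compute {n_pcs} PCs"
        )
    X = arr[:, [colpos[s] for s in kept]]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_pcs] * S[:n_pcs]
    for j in range(n_pcs):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(
        scores, index=snps.index, columns=[f"PC{j + 1}" for j in range(n_pcs)]
    )
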