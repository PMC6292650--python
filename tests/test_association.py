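"""Regression engine: closed-form and IRLS oracles, omnibus tests, genetic
models, interactions and principal components."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import hlafinemap as hf
from hlafinemap.association import (
    DEFAULT_MIN_FREQ,
    genotype_copy_probs,
    model_codings,
    omnibus_position_test,
)
from hlafinemap.errors import DegeneratePredictorError, InvalidInputError
from hlafinemap.hla_data import position_groups


def _binary_design(n11, n10, n01, n00):
    """Cases with/without the variant, controls with/without."""
    x = np.concatenate([np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)])
    y = np.concatenate([np.ones(n11 + n10), np.zeros(n01 + n00)])
    return pd.Series(x, name="x"), pd.Series(y, name="y")


class TestFitLogistic:
    def test_two_by_two_closed_form_odds_ratio(self):
        # cases 30 exposed / 70 unexposed, controls 10 / 90: OR = 27/7
        x, y = _binary_design(30, 70, 10, 90)
        res = hf.fit_logistic(x, y)
        assert res.or_ == pytest.approx(27 / 7, rel=1e-6)

    def test_matches_statsmodels_irls_oracle(self):
        """|delta beta| < 1e-6 against an independent ML fit on 20 random fixtures."""
        rng = np.random.default_rng(2024)
        for _ in range(20):
            n = int(rng.integers(80, 200))
            x = pd.Series(rng.uniform(0, 2, n), name="x")
            c = pd.DataFrame({"c1": rng.normal(size=n)})
            eta = -0.3 + 0.8 * x + 0.4 * c["c1"]
            y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float), name="y")
            if y.nunique() < 2:
                continue
            res = hf.fit_logistic(x, y, covariates=c)
            X = sm.add_constant(np.column_stack([c["c1"], x]))
            oracle = sm.Logit(y.to_numpy(), X).fit(disp=0)
            assert abs(res.beta - oracle.params[-1]) < 1e-6

    def test_duplicated_data_halves_variance(self):
        x, y = _binary_design(25, 75, 15, 85)
        res1 = hf.fit_logistic(x, y)
        x2 = pd.concat([x, x], ignore_index=True)
        y2 = pd.concat([y, y], ignore_index=True)
        res2 = hf.fit_logistic(x2, y2)
        assert res2.or_ == pytest.approx(res1.or_, rel=1e-8)
        assert res2.se == pytest.approx(res1.se / np.sqrt(2), rel=1e-6)

    def test_null_wald_calibration(self):
        """Type-I error close to alpha over 500 independent null predictors."""
        rng = np.random.default_rng(5)
        n = 1000
        y = pd.Series(np.repeat([1.0, 0.0], n // 2), name="y")
        hits = 0
        for _ in range(500):
            x = pd.Series(rng.binomial(2, 0.3, size=n).astype(float), name="x")
            if x.nunique() < 2:
                continue
            hits += hf.fit_logistic(x, y).p_wald < 0.05
        assert 0.03 < hits / 500 < 0.07

    def test_constant_predictor_rejected(self):
        y = pd.Series([1.0, 0.0, 1.0, 0.0])
        with pytest.raises(DegeneratePredictorError):
            hf.fit_logistic(pd.Series([1.0, 1.0, 1.0, 1.0], name="x"), y)

    def test_single_class_phenotype_rejected(self):
        with pytest.raises(InvalidInputError):
            hf.fit_logistic(
                pd.Series([0.0, 1.0, 2.0], name="x"), pd.Series([1.0, 1.0, 1.0])
            )

    def test_aic_identity(self):
        x, y = _binary_design(40, 60, 20, 80)
        res = hf.fit_logistic(x, y)
        assert res.aic == pytest.approx(res.deviance + 2 * res.n_params, abs=1e-12)

    def test_mirror_residues_equivalent(self):
        """At a biallelic position OR(L) = 1/OR(G) and the p-values agree."""
        rng = np.random.default_rng(17)
        n = 600
        xl = pd.Series(rng.uniform(0, 2, n), name="L")
        xg = (2 - xl).rename("G")
        eta = -0.5 + 0.7 * xl
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float), name="y")
        rl = hf.fit_logistic(xl, y)
        rg = hf.fit_logistic(xg, y)
        assert rl.or_ == pytest.approx(1 / rg.or_, rel=1e-8)
        assert abs(rl.p_wald - rg.p_wald) < 1e-10

    def test_noise_covariates_leave_estimate_unchanged(self):
        rng = np.random.default_rng(23)
        n = 2000
        x = pd.Series(rng.binomial(2, 0.3, n).astype(float), name="x")
        eta = -0.5 + 0.6 * x
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float), name="y")
        base = hf.fit_logistic(x, y)
        noise = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"z{i}" for i in range(5)])
        adjusted = hf.fit_logistic(x, y, covariates=noise)
        assert abs(adjusted.beta - base.beta) < 3 * base.se

    def test_separation_flagged_and_lrt_substituted(self):
        x = pd.Series(np.r_[np.ones(30), np.zeros(30)], name="x")
        y = pd.Series(np.r_[np.ones(30), np.zeros(30)], name="y")
        res = hf.fit_logistic(x, y)
        assert not res.converged or res.note == "lrt-substituted"
        assert res.p == res.p_lrt


class TestOmnibus:
    def test_biallelic_position_equals_single_residue_lrt(self, small_dosages):
        _, rd = small_dosages
        y_idx = rd.index
        rng = np.random.default_rng(3)
        y = pd.Series(rng.integers(0, 2, len(y_idx)).astype(float), index=y_idx)
        for (_, _), cols in position_groups(rd).items():
            sub = rd[cols]
            freq = sub.mean() / 2
            common = sub.loc[:, freq > DEFAULT_MIN_FREQ]
            if common.shape[1] == 2 and all(common.std() > 0):
                fit = omnibus_position_test(sub, y)
                single = hf.fit_logistic(common.iloc[:, 0], y)
                assert fit.df == 1
                assert fit.p_lrt == pytest.approx(single.p_lrt, abs=1e-9)
                break
        else:
            pytest.skip("no biallelic position in fixture")

    def test_rare_levels_filtered_before_df(self):
        rng = np.random.default_rng(4)
        n = 1000
        common1 = rng.uniform(0, 2, n)
        common2 = rng.uniform(0, 2 - common1)
        rare = np.full(n, 0.0)
        rare[:3] = 0.01
        rest = 2 - common1 - common2 - rare
        dos = pd.DataFrame({"G@1:A": common1, "G@1:B": common2, "G@1:C": rare, "G@1:D": rest})
        y = pd.Series(rng.integers(0, 2, n).astype(float))
        fit = omnibus_position_test(dos, y)
        assert fit.df == 2  # three retained levels minus reference

    def test_monomorphic_position_not_testable(self):
        dos = pd.DataFrame({"G@1:A": [2.0] * 10})
        y = pd.Series([1.0, 0.0] * 5)
        assert omnibus_position_test(dos, y) is None

    def test_omnibus_lrt_null_calibration(self):
        """3-residue position with no effect: LRT p approximately uniform."""
        rng = np.random.default_rng(6)
        n = 500
        hits = 0
        reps = 400
        for _ in range(reps):
            a = rng.dirichlet([1, 1, 1], size=n) * 2
            dos = pd.DataFrame(a, columns=["G@5:A", "G@5:B", "G@5:C"])
            y = pd.Series(rng.integers(0, 2, n).astype(float))
            fit = omnibus_position_test(dos, y)
            hits += fit.p_lrt < 0.05
        assert 0.03 < hits / reps < 0.07

    def test_conditional_gene_omnibus_removes_ld_signal(self):
        """With pure haplotype LD, conditioning on the causal gene's alleles
        removes the bystander gene's association."""
        from conftest import make_scenario, pick_causal
        from hlafinemap.synthetic_cohort import DiseaseModel

        pools, hap, aln = make_scenario(genes=("HLA-DRB1", "HLA-DQB1"), seed=91, lam=0.0)
        key = pick_causal(aln, pools, "HLA-DRB1")
        cohort = hf.simulate_cohort(
            pools, hap, aln,
            DiseaseModel(intercept=-1.0, residue_effects={key: np.log(2.5)}),
            2000, 2000, seed=14,
        )
        dos = hf.cohort_allele_dosages(cohort.posteriors)
        drb = dos[[c for c in dos.columns if c.startswith("HLA-DRB1")]]
        dqb = dos[[c for c in dos.columns if c.startswith("HLA-DQB1")]]
        y = cohort.phenotype
        marginal = hf.omnibus_gene_test(dqb, y)
        conditional = hf.omnibus_gene_test(dqb, y, conditional_on=[drb])
        assert marginal.p_lrt < 1e-4  # LD-driven signal present marginally
        assert conditional.p_lrt > 1e-3 * marginal.p_lrt  # and much weaker conditionally
        assert conditional.p_lrt > 0.001


class TestGeneticModels:
    def test_point_mass_codings_are_indicators(self, small_cohort, small_scenario):
        cohort, (gene, pos, res) = small_cohort
        _, _, aln = small_scenario
        carriers = hf.association.carriers_of_residue(aln, gene, pos, res)
        probs = genotype_copy_probs(cohort.posteriors, gene, carriers)
        codings = model_codings(probs)
        assert set(np.unique(codings["dominant"])) <= {0.0, 1.0}
        assert set(np.unique(codings["recessive"])) <= {0.0, 1.0}
        assert set(np.unique(codings["allelic"])) <= {0.0, 1.0, 2.0}

    def test_dominant_truth_preferred_by_aic(self):
        """Data generated under a dominant effect: dominant model wins on AIC
        in most replicates."""
        rng = np.random.default_rng(31)
        n = 6000
        wins = 0
        reps = 12
        for _ in range(reps):
            g = rng.binomial(2, 0.3, n)
            eta = -1.0 + np.log(2.5) * (g >= 1)
            y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float))
            probs = pd.DataFrame(
                {"p0": g == 0, "p1": g == 1, "p2": g == 2}, dtype=float
            )
            table = hf.genetic_model_compare(probs, y)
            wins += table.iloc[0]["model"] == "dominant"
        assert wins / reps >= 0.8

    def test_multiplicative_truth_with_few_homozygotes_ambiguous(self):
        """Rare variant under multiplicative truth: multiplicative and dominant
        fits are nearly indistinguishable (|dAIC| small)."""
        rng = np.random.default_rng(37)
        n = 8000
        g = rng.binomial(2, 0.03, n)  # few homozygotes
        eta = -1.0 + np.log(1.5) * g
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float))
        probs = pd.DataFrame({"p0": g == 0, "p1": g == 1, "p2": g == 2}, dtype=float)
        table = hf.genetic_model_compare(probs, y).set_index("model")
        assert abs(table.at["allelic", "aic"] - table.at["dominant", "aic"]) < 2.0


class TestInteractions:
    def test_null_interactions_uniform(self):
        rng = np.random.default_rng(41)
        n = 1500
        hits = 0
        reps = 200
        for _ in range(reps):
            dos = pd.DataFrame(
                {"a": rng.binomial(2, 0.4, n), "b": rng.binomial(2, 0.3, n)}, dtype=float
            )
            eta = -0.5 + 0.3 * dos["a"] + 0.2 * dos["b"]  # main effects only
            y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float))
            table = hf.interaction_scan(dos, y)
            hits += table["p_interaction"].iloc[0] < 0.05
        assert 0.02 < hits / reps < 0.09

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(43)
        n = 10_000
        detected = 0
        reps = 10
        for _ in range(reps):
            dos = pd.DataFrame(
                {"a": rng.binomial(2, 0.4, n), "b": rng.binomial(2, 0.4, n)}, dtype=float
            )
            eta = -1.0 + 0.2 * dos["a"] + 0.2 * dos["b"] + np.log(2.0) * dos["a"] * dos["b"] / 2
            y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float))
            table = hf.interaction_scan(dos, y)
            detected += table["p_interaction"].iloc[0] < table.attrs["bonferroni"]
        assert detected / reps >= 0.8

    def test_collinear_pair_skipped(self):
        rng = np.random.default_rng(47)
        x = rng.uniform(0, 2, 100)
        dos = pd.DataFrame({"a": x, "b": 2 - x})
        y = pd.Series(rng.integers(0, 2, 100).astype(float))
        table = hf.interaction_scan(dos, y)
        assert table.iloc[0]["note"] == "collinear-skipped"


class TestPrincipalComponents:
    def test_all_snps_excluded_raises(self):
        from hlafinemap.synthetic_cohort import simulate_snps

        snps, meta = simulate_snps(100, 20, seed=1, positions=range(100, 120))
        with pytest.raises(InvalidInputError):
            hf.compute_pcs(snps, meta, ("6", 0, 10_000), n_pcs=2)

    def test_scores_orthogonal(self):
        from hlafinemap.synthetic_cohort import simulate_snps

        snps, meta = simulate_snps(300, 120, seed=2)
        pcs = hf.compute_pcs(snps, meta, ("6", 25_650_000, 33_426_000), n_pcs=5)
        gram = pcs.to_numpy().T @ pcs.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_pc1_separates_subpopulations(self):
        from hlafinemap.synthetic_cohort import simulate_snps

        rng = np.random.default_rng(3)
        subpop = rng.integers(0, 2, 400)
        snps, meta = simulate_snps(400, 300, seed=4, subpop=subpop, fst=0.1)
        pcs = hf.compute_pcs(snps, meta, ("6", 25_650_000, 33_426_000), n_pcs=2)
        r = np.corrcoef(pcs["PC1"], subpop)[0, 1]
        assert abs(r) > 0.9
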