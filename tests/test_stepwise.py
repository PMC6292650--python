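"""Forward/backward stepwise selection, conditional scans and haplogroups."""

import numpy as np
import pandas as pd
import pytest

import hlafinemap as hf
from hlafinemap.errors import InvalidConfigError
from hlafinemap.hla_data import drop_monomorphic
from hlafinemap.synthetic_cohort import DiseaseModel

from conftest import make_scenario, pick_causal


@pytest.fixture(scope="module")
def planted_pool():
    """Cohort with one strong planted residue and its residue-dosage pool."""
    pools, hap, aln = make_scenario(seed=301, lam=0.5)
    key = pick_causal(aln, pools, "HLA-DQB1")
    cohort = hf.simulate_cohort(
        pools, hap, aln,
        DiseaseModel(intercept=-1.0, residue_effects={key: np.log(3.0)}),
        1200, 1200, seed=15,
    )
    rd = drop_monomorphic(
        hf.residue_dosage(hf.cohort_allele_dosages(cohort.posteriors), aln)
    )
    return rd, cohort.phenotype, hf.residue_key(*key)


def _tag_group_of(rd, key):
    """Predictors statistically indistinguishable (r2 ~ 1) from key."""
    r2 = hf.correlation_r2(rd)
    row = r2.loc[key]
    return set(row.index[row > 0.9999])


class TestThresholds:
    def test_bonferroni_matches_printed_residue_threshold(self):
        # 0.05 over 1028 residue tests: 4.8638e-5, i.e. 4.87e-5 at the printed
        # granularity of 0.01e-5
        t = hf.bonferroni_threshold(1028)
        assert t == pytest.approx(0.05 / 1028, rel=1e-12)
        assert abs(t - 4.87e-5) < 1e-7

    def test_bonferroni_matches_printed_position_threshold(self):
        # 0.05 over 368 position tests prints as 0.000136
        t = hf.bonferroni_threshold(368)
        assert round(t, 6) == 0.000136

    def test_tag_r2_default_is_r_squared(self):
        from hlafinemap.pipeline import DEFAULT_THRESHOLDS

        assert DEFAULT_THRESHOLDS["tag_r2"] == pytest.approx(0.98**2) == 0.9604


class TestForwardStepwise:
    def test_planted_residue_enters_first(self, planted_pool):
        rd, y, key = planted_pool
        trace = hf.forward_stepwise(rd, y)
        assert trace.entries
        assert trace.entries[0].predictor in _tag_group_of(rd, key)

    def test_threshold_monotonicity(self, planted_pool):
        rd, y, _ = planted_pool
        loose = hf.forward_stepwise(rd, y, p_enter=4.87e-5)
        strict = hf.forward_stepwise(rd, y, p_enter=1e-8)
        assert len(strict.entries) <= len(loose.entries)
        assert set(strict.predictors) <= set(loose.predictors)

    def test_trace_is_deterministic(self, planted_pool):
        rd, y, _ = planted_pool
        a = hf.forward_stepwise(rd, y)
        b = hf.forward_stepwise(rd, y)
        assert a.entries == b.entries

    def test_recorded_p_below_threshold_and_steps_consecutive(self, planted_pool):
        rd, y, _ = planted_pool
        trace = hf.forward_stepwise(rd, y)
        assert all(e.p_enter < trace.threshold for e in trace.entries)
        assert [e.step for e in trace.entries] == list(range(1, len(trace.entries) + 1))

    def test_bad_threshold_rejected(self, planted_pool):
        rd, y, _ = planted_pool
        with pytest.raises(InvalidConfigError):
            hf.forward_stepwise(rd, y, p_enter=1.5)

    def test_force_k_ignores_threshold(self, planted_pool):
        rd, y, _ = planted_pool
        trace = hf.forward_stepwise(rd, y, force_k=3)
        assert len(trace.entries) == 3


class TestBackwardCheck:
    def test_strong_independent_predictors_all_retained(self):
        rng = np.random.default_rng(51)
        n = 4000
        pool = pd.DataFrame(
            {"a": rng.binomial(2, 0.3, n), "b": rng.binomial(2, 0.4, n)}, dtype=float
        )
        eta = -1.0 + 0.8 * pool["a"] + 0.7 * pool["b"]
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float))
        trace = hf.forward_stepwise(pool, y, p_enter=1e-4)
        retained = hf.backward_check(trace, pool, y)
        assert set(retained) == {"a", "b"}

    def test_near_duplicate_forced_pair_loses_one(self):
        rng = np.random.default_rng(53)
        n = 3000
        a = rng.binomial(2, 0.3, n).astype(float)
        pool = pd.DataFrame({"a": a, "a_copy": a + rng.normal(0, 1e-3, n)})
        eta = -1.0 + 0.9 * a
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float))
        retained = hf.backward_check(["a", "a_copy"], pool, y, p_stay=1e-4)
        assert len(retained) == 1

    def test_empty_trace_gives_empty_set(self, planted_pool):
        rd, y, _ = planted_pool
        empty = hf.StepwiseTrace(entries=[], threshold=1e-5)
        assert hf.backward_check(empty, rd, y) == []


class TestConditionalScan:
    def test_no_conditioning_reproduces_marginal(self, planted_pool):
        rd, y, _ = planted_pool
        sub = rd.iloc[:, :5]
        scan = hf.conditional_scan(sub, rd.iloc[:, :0], y)
        for _, row in scan.iterrows():
            marg = hf.fit_logistic(rd[row["predictor"]], y)
            assert row["p"] == pytest.approx(marg.p, rel=1e-9)

    def test_target_in_conditioning_set_skipped(self, planted_pool):
        rd, y, key = planted_pool
        scan = hf.conditional_scan(rd.iloc[:, :6], rd[[rd.columns[0]]], y)
        assert rd.columns[0] not in set(scan["predictor"])

    def test_conditioning_on_causal_removes_ld_signal(self):
        """A bystander gene's top residue loses significance once the causal
        residue is conditioned on, under pure haplotype LD."""
        pools, hap, aln = make_scenario(genes=("HLA-DRB1", "HLA-DQB1"), seed=311, lam=0.0)
        key = pick_causal(aln, pools, "HLA-DRB1")
        cohort = hf.simulate_cohort(
            pools, hap, aln,
            DiseaseModel(intercept=-1.0, residue_effects={key: np.log(2.5)}),
            2000, 2000, seed=19,
        )
        rd = drop_monomorphic(
            hf.residue_dosage(hf.cohort_allele_dosages(cohort.posteriors), aln)
        )
        y = cohort.phenotype
        bystander = rd[[c for c in rd.columns if c.startswith("HLA-DQB1")]]
        marg = hf.conditional_scan(bystander, rd.iloc[:, :0], y)
        cond = hf.conditional_scan(bystander, rd[[hf.residue_key(*key)]], y)
        assert marg.attrs["min_p"] < 1e-6
        assert cond.attrs["min_p"] > 1e-3 * 0 + 0.001

    def test_self_scan_after_full_conditioning(self, planted_pool):
        rd, y, _ = planted_pool
        trace = hf.forward_stepwise(rd, y)
        selected = rd[trace.predictors]
        scan = hf.conditional_scan(selected, selected, y)
        assert scan.empty  # every target is in the conditioning set


class TestMixedPool:
    def test_single_pool_reduces_to_forward(self, planted_pool):
        rd, y, _ = planted_pool
        mixed = hf.mixed_pool_stepwise({"residue": rd}, y)
        plain = hf.forward_stepwise(rd, y)
        assert mixed.predictors == plain.predictors

    def test_duplicate_predictor_entered_once(self, planted_pool):
        rd, y, _ = planted_pool
        mixed = hf.mixed_pool_stepwise({"residue": rd, "snp": rd.iloc[:, :3]}, y)
        assert len(mixed.predictors) == len(set(mixed.predictors))

    def test_shared_residue_beats_classical_alleles(self):
        """A residue carried by two alleles with opposite-frequency backgrounds
        enters before either allele."""
        pools, hap, aln = make_scenario(
            genes=("HLA-DRB1",), n_alleles=8, seed=321, lam=1.0
        )
        gene = "HLA-DRB1"
        # find a residue carried by >= 2 alleles but not all
        target = None
        for pos in aln.positions(gene):
            col = aln.residues_at(gene, pos)
            for res in col.unique():
                k = (col == res).sum()
                if 2 <= k <= 4:
                    target = (gene, pos, res)
                    break
            if target:
                break
        assert target is not None
        wins = 0
        reps = 10
        for r in range(reps):
            cohort = hf.simulate_cohort(
                pools, hap, aln,
                DiseaseModel(intercept=-1.0, residue_effects={target: np.log(2.5)}),
                1500, 1500, seed=400 + r,
            )
            allele_dos = drop_monomorphic(hf.cohort_allele_dosages(cohort.posteriors))
            rd = drop_monomorphic(
                hf.residue_dosage(
                    hf.cohort_allele_dosages(cohort.posteriors), aln
                )
            )
            mixed = hf.mixed_pool_stepwise(
                {"residue": rd, "allele": allele_dos}, cohort.phenotype, max_steps=1
            )
            wins += mixed.entries[0].ptype == "residue"
        assert wins / reps >= 0.8


class TestHaplogroups:
    def test_perfectly_correlated_predictors_share_group(self):
        rng = np.random.default_rng(61)
        n = 2000
        a = rng.binomial(2, 0.3, n).astype(float)
        eta = -1.0 + 0.8 * a
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float))
        dos = pd.DataFrame({"a": a, "mirror": 2 - a})
        groups = hf.assign_haplogroups(dos, y)
        assert groups.group_of("a") == groups.group_of("mirror")

    def test_independent_signals_split_groups(self):
        rng = np.random.default_rng(63)
        n = 4000
        a = rng.binomial(2, 0.3, n).astype(float)
        b = rng.binomial(2, 0.4, n).astype(float)
        eta = -1.2 + 0.8 * a + 0.8 * b
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float))
        groups = hf.assign_haplogroups(pd.DataFrame({"a": a, "b": b}), y)
        assert groups.group_of("a") != groups.group_of("b")
        assert len(groups.groups) == 2

    def test_single_predictor_is_its_own_lead(self):
        rng = np.random.default_rng(67)
        n = 500
        a = rng.binomial(2, 0.3, n).astype(float)
        y = pd.Series(rng.integers(0, 2, n).astype(float))
        groups = hf.assign_haplogroups(pd.DataFrame({"a": a}), y)
        assert groups.groups == {1: ["a"]} and groups.leads[1] == "a"
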