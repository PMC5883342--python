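"""Chi-squared association, effective test counts, and the interaction model."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnvgeno import (
    ContingencyTable2x2,
    Diagnosis,
    GenotypeState,
    MeffScope,
    NonDiploidCall,
    PhenotypeRecord,
    bonferroni_adjust,
    chisq_2x2,
    dosage_matrix,
    effective_num_tests,
    logistic_interaction,
    majority_allele_coding,
    manhattan_table,
    nagelkerke_r2,
    region_scan,
    significance_threshold,
)


def pearson_rxc_oracle(table):
    """Generic Pearson statistic from expected counts (independent of the closed form)."""
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    expected = rows @ cols / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


class TestChisq:
    def test_reconstructed_peak_table(self):
        chi2, p = chisq_2x2(ContingencyTable2x2(4, 1, 3, 16))
        assert chi2 == pytest.approx(7.8995, abs=1e-4)
        assert float(f"{p:.2g}") == 0.0049

    def test_no_association(self):
        assert chisq_2x2(ContingencyTable2x2(5, 5, 5, 5)) == (0.0, 1.0)

    def test_perfect_association_closed_form(self):
        chi2, _ = chisq_2x2(ContingencyTable2x2(10, 0, 0, 10))
        assert chi2 == pytest.approx(20.0)

    def test_degenerate_margin_warns_and_returns_null(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert chisq_2x2(ContingencyTable2x2(3, 4, 0, 0)) == (0.0, 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)

    def test_agrees_with_pearson_oracle_on_1000_random_tables(self):
        rng = np.random.default_rng(2024)
        n_checked = 0
        while n_checked < 1000:
            a, b, c, d = rng.integers(0, 40, size=4)
            table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            if 0 in table.margins:
                continue
            chi2, _ = chisq_2x2(table)
            assert chi2 == pytest.approx(pearson_rxc_oracle(table), rel=1e-10, abs=1e-12)
            n_checked += 1


def exact_corr_pair(rho, n=16):
    """Two columns with sample Pearson correlation exactly rho (up to fp)."""
    u = np.tile([1.0, -1.0], n // 2)
    v = np.repeat([1.0, -1.0], n // 2)
    return pd.DataFrame({"x": u, "y": rho * u + math.sqrt(1 - rho**2) * v})


class TestMeff:
    def test_uncorrelated_snps_count_fully(self):
        # three exactly orthogonal contrast columns -> identity correlation
        df = pd.DataFrame({
            "s1": [1, 1, -1, -1], "s2": [1, -1, 1, -1], "s3": [1, -1, -1, 1],
        })
        assert effective_num_tests(df).meff == pytest.approx(3.0)

    def test_perfectly_correlated_pair_counts_once(self):
        x = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        df = pd.DataFrame({"a": x, "b": x})
        # eigenvalues {2, 0}: f(2) + f(0) = 1
        assert effective_num_tests(df).meff == pytest.approx(1.0)

    def test_half_correlated_pair(self):
        est = effective_num_tests(exact_corr_pair(0.5))
        # eigenvalues {1.5, 0.5}: f(1.5) + f(0.5) = 2.0
        assert est.meff == pytest.approx(2.0, abs=1e-9)
        assert sorted(est.eigenvalues, reverse=True) == pytest.approx([1.5, 0.5], abs=1e-9)

    def test_eigenvalues_trace_to_snp_count(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(30, 8)))
        est = effective_num_tests(df)
        assert sum(est.eigenvalues) == pytest.approx(est.m_snps, abs=1e-8)

    def test_monomorphic_snps_dropped(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"poly": rng.integers(0, 2, 20).astype(float), "mono": np.zeros(20)})
        assert effective_num_tests(df).m_snps == 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            effective_num_tests(pd.DataFrame({"a": [1.0]}))

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="polymorphic"):
            effective_num_tests(pd.DataFrame({"a": [1.0, 1.0, 1.0]}))

    @given(st.integers(0, 2**31 - 1), st.integers(2, 8), st.integers(5, 25))
    @settings(max_examples=30, deadline=None)
    def test_bounds_and_permutation_invariance(self, seed, m, n):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.integers(0, 4, size=(n, m)).astype(float))
        df = df.loc[:, df.var() > 0]
        if df.shape[1] < 1:
            return
        est = effective_num_tests(df)
        assert 1.0 <= est.meff <= est.m_snps + 1e-9
        # permutation invariance in SNP order
        perm = df.sample(frac=1, axis=1, random_state=0)
        assert effective_num_tests(perm).meff == pytest.approx(est.meff, abs=1e-8)

    @given(st.integers(2, 6))
    @settings(max_examples=10, deadline=None)
    def test_duplicating_an_independent_snp_does_not_inflate_meff(self, m):
        # Walsh +/-1 columns: exactly orthogonal, zero mean; duplicating one
        # merges its eigenvalue to 2 (f(2)=1), leaving Meff at m
        bits = (np.arange(2**m)[:, None] >> np.arange(m)) & 1
        df = pd.DataFrame((2 * bits - 1).astype(float))
        assert effective_num_tests(df).meff == pytest.approx(m, abs=1e-8)
        dup = df.copy()
        dup["dup0"] = df.iloc[:, 0]
        assert effective_num_tests(dup).meff == pytest.approx(m, abs=1e-8)


class TestBonferroni:
    def test_adjustment_reproduces_two_sig_figs(self):
        assert float(f"{bonferroni_adjust(0.0049, 5.35):.2g}") == 0.026

    @pytest.mark.parametrize("p,meff,out", [(0.5, 5, 1.0), (0.0, 100, 0.0)])
    def test_capping_and_zero(self, p, meff, out):
        assert bonferroni_adjust(p, meff) == out

    @pytest.mark.parametrize(
        "alpha,meff,expected,tol",
        [(0.05, 5.35, 0.0094, 1e-4), (0.05, 112, 4.46e-4, 5e-7), (0.05, 1, 0.05, 0)],
    )
    def test_threshold(self, alpha, meff, expected, tol):
        assert significance_threshold(alpha, meff) == pytest.approx(expected, abs=tol)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(0.1, 0.5)
        with pytest.raises(ValueError):
            significance_threshold(1.5, 5)

    @given(st.floats(1e-12, 1.0), st.floats(1.0, 200.0), st.floats(1e-6, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_adjust_and_threshold_are_equivalent_decisions(self, p, meff, alpha):
        lhs = p * meff < alpha
        rhs = p < significance_threshold(alpha, meff)
        assert lhs == rhs


def call(sample, snp, state, cn=1, pos=100):
    return NonDiploidCall(sample, snp, "chr7", pos, state, cn)


class TestRegionScan:
    def test_planted_risk_snp_ranks_first(self, planted_risk_cohort):
        calls, phenotypes, _, risk_snp = planted_risk_cohort
        results = region_scan(calls, phenotypes)
        assert results[0].snp_id == risk_snp

    def test_monomorphic_snp_flagged_untestable(self):
        phen = [PhenotypeRecord(f"S{i}", Diagnosis.DEL, i % 2 == 0) for i in range(4)]
        calls = [call(f"S{i}", "rs1", GenotypeState.A) for i in range(4)]
        (r,) = region_scan(calls, phen)
        assert r.untestable and r.p_uncorrected is None

    def test_mixed_diagnosis_groups_rejected(self):
        phen = [PhenotypeRecord("S0", Diagnosis.DEL, True), PhenotypeRecord("S1", Diagnosis.DUP, False)]
        calls = [call("S0", "rs1", GenotypeState.A), call("S1", "rs1", GenotypeState.AAB, cn=3)]
        with pytest.raises(ValueError, match="single diagnosis"):
            region_scan(calls, phen)

    def test_nocall_dropped_pairwise(self):
        phen = [PhenotypeRecord(f"S{i}", Diagnosis.DEL, i < 2) for i in range(4)]
        calls = [
            call("S0", "rs1", GenotypeState.B), call("S1", "rs1", GenotypeState.NOCALL),
            call("S2", "rs1", GenotypeState.A), call("S3", "rs1", GenotypeState.A),
        ]
        (r,) = region_scan(calls, phen)
        assert r.table.n == 3  # S1 excluded from this SNP only

    def test_scopes_assign_meff_by_gene(self):
        phen = [PhenotypeRecord(f"S{i}", Diagnosis.DEL, i < 3) for i in range(8)]
        calls = [call(f"S{i}", "rs1", GenotypeState.B if i % 2 else GenotypeState.A) for i in range(8)]
        calls += [call(f"S{i}", "rs2", GenotypeState.B if i < 4 else GenotypeState.A, pos=200) for i in range(8)]
        scopes = [MeffScope(meff=5.35, genes=frozenset({"ELN"}), label="ELN"),
                  MeffScope(meff=112.0, genes=None, label="locus")]
        results = region_scan(calls, phen, gene_map={"rs1": "ELN", "rs2": "CLIP2"}, scopes=scopes)
        by_id = {r.snp_id: r for r in results}
        assert by_id["rs1"].meff_used == 5.35
        assert by_id["rs2"].meff_used == 112.0
        for r in results:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p_uncorrected * r.meff_used))

    def test_triploid_majority_allele_grouping(self):
        phen = [PhenotypeRecord(f"S{i}", Diagnosis.DUP, i < 2) for i in range(4)]
        calls = [
            call("S0", "rs1", GenotypeState.BBB, cn=3), call("S1", "rs1", GenotypeState.ABB, cn=3),
            call("S2", "rs1", GenotypeState.AAB, cn=3), call("S3", "rs1", GenotypeState.AAA, cn=3),
        ]
        (r,) = region_scan(calls, phen)
        # >=2 B copies vs otherwise: rows (2,0) / (0,2)
        assert (r.table.a, r.table.b, r.table.c, r.table.d) == (2, 0, 0, 2)

    def test_power_non_decreasing_in_odds_ratio(self):
        from conftest import cohort_calls
        from cnvgeno import SimParams

        detections = []
        threshold = significance_threshold(0.05, 112)
        for odds_ratio in (1.0, 3.0, 10.0):
            hits = 0
            reps = 8
            for rep in range(reps):
                freqs = np.random.default_rng(900 + rep).uniform(0.3, 0.7, 40)
                params = SimParams(
                    n_del_samples=150, n_dup_samples=0, n_snps=40, flank_snps=0,
                    allele_freqs=freqs, risk_snp_index=20,
                    effect_log_odds=math.log(odds_ratio), baseline_prevalence=0.2,
                    baf_sd=0.03, lrr_sd=0.0, nocall_rate=0.0, seed=3000 + rep,
                )
                calls, phen, _ = cohort_calls(params)
                results = region_scan(calls, phen)
                top = results[0]
                if top.snp_id == "rs000020" and top.p_uncorrected < threshold:
                    hits += 1
            detections.append(hits / reps)
        assert detections == sorted(detections)
        assert detections[-1] == 1.0

    def test_manhattan_table_sorted_by_position(self, planted_risk_cohort):
        calls, phenotypes, _, _ = planted_risk_cohort
        results = region_scan(calls, phenotypes)
        mtab = manhattan_table(results)
        assert mtab["pos"].is_monotonic_increasing
        assert len(mtab) == sum(not r.untestable for r in results)


def group_phenotypes(groups):
    """groups: list of (n, diagnosis, genotype, affected) -> (records, coding)."""
    phen, coding, i = [], {}, 0
    for n, diag, g, affected in groups:
        for _ in range(n):
            sid = f"s{i}"
            i += 1
            phen.append(PhenotypeRecord(sid, diag, affected))
            coding[sid] = g
    return phen, coding


class TestLogisticInteraction:
    def test_null_groups_give_zero_interaction_and_r2(self):
        phen, coding = group_phenotypes([
            (5, Diagnosis.DEL, 1, True), (5, Diagnosis.DEL, 1, False),
            (5, Diagnosis.DEL, 0, True), (5, Diagnosis.DEL, 0, False),
            (5, Diagnosis.DUP, 1, True), (5, Diagnosis.DUP, 1, False),
            (5, Diagnosis.DUP, 0, True), (5, Diagnosis.DUP, 0, False),
        ])
        fit = logistic_interaction(phen, coding)
        assert fit.coefficients["interaction"] == pytest.approx(0.0, abs=1e-6)
        assert fit.nagelkerke_r2 == pytest.approx(0.0, abs=1e-9)

    def test_saturated_fit_reproduces_group_proportions(self):
        phen, coding = group_phenotypes([
            (4, Diagnosis.DEL, 1, True), (1, Diagnosis.DEL, 1, False),
            (3, Diagnosis.DEL, 0, True), (16, Diagnosis.DEL, 0, False),
            (4, Diagnosis.DUP, 0, True), (6, Diagnosis.DUP, 0, False),
            (2, Diagnosis.DUP, 1, True), (3, Diagnosis.DUP, 1, False),
        ])
        fit = logistic_interaction(phen, coding)
        probs = dict(zip((p.sample_id for p in phen if p.sample_id in coding), fit.fitted_probs))
        expected = {(0, 1): 4 / 5, (0, 0): 3 / 19, (1, 0): 4 / 10, (1, 1): 2 / 5}
        for p in phen:
            dx = 1 if p.diagnosis is Diagnosis.DUP else 0
            assert probs[p.sample_id] == pytest.approx(expected[(dx, coding[p.sample_id])], abs=1e-6)

    def test_empty_group_sets_separation_flag(self):
        phen, coding = group_phenotypes([
            (4, Diagnosis.DEL, 1, True), (1, Diagnosis.DEL, 1, False),
            (3, Diagnosis.DEL, 0, True), (16, Diagnosis.DEL, 0, False),
            (4, Diagnosis.DUP, 0, True), (6, Diagnosis.DUP, 0, False),
            (3, Diagnosis.DUP, 1, False),  # zero affected in this cell
        ])
        fit = logistic_interaction(phen, coding)
        assert fit.separation_flag

    def test_single_group_rejected(self):
        phen, coding = group_phenotypes([(5, Diagnosis.DEL, 1, True), (5, Diagnosis.DEL, 0, False)])
        with pytest.raises(ValueError, match="both diagnosis groups"):
            logistic_interaction(phen, coding)

    def test_loglik_matches_direct_binomial_evaluation(self):
        phen, coding = group_phenotypes([
            (6, Diagnosis.DEL, 1, True), (2, Diagnosis.DEL, 1, False),
            (3, Diagnosis.DEL, 0, True), (9, Diagnosis.DEL, 0, False),
            (2, Diagnosis.DUP, 0, True), (7, Diagnosis.DUP, 0, False),
            (4, Diagnosis.DUP, 1, True), (5, Diagnosis.DUP, 1, False),
        ])
        fit = logistic_interaction(phen, coding)
        beta = fit.coefficients
        ll = 0.0
        for p in phen:
            dx = 1 if p.diagnosis is Diagnosis.DUP else 0
            g = coding[p.sample_id]
            eta = beta["intercept"] + beta["diagnosis"] * dx + beta["genotype"] * g + beta["interaction"] * dx * g
            prob = 1.0 / (1.0 + math.exp(-eta))
            ll += math.log(prob if p.affected else 1.0 - prob)
        assert fit.loglik_full == pytest.approx(ll, abs=1e-8)


class TestNagelkerke:
    def test_equal_likelihoods_give_zero(self):
        assert nagelkerke_r2(-10.0, -10.0, 20) == 0.0

    def test_perfect_prediction_gives_one(self):
        assert nagelkerke_r2(0.0, -13.86, 20) == pytest.approx(1.0)

    def test_reconstruction_value(self):
        # direct evaluation of the two formulas at the reconstructed group likelihoods
        assert nagelkerke_r2(-17.52, -22.52, 37) == pytest.approx(0.3363, abs=5e-4)

    def test_null_loglik_zero_undefined(self):
        with pytest.warns(UserWarning):
            assert nagelkerke_r2(0.0, 0.0, 10) is None

    def test_full_worse_than_null_rejected(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-12.0, -10.0, 20)


class TestDosageAndCoding:
    def test_dosage_matrix_codes_b_counts_and_nocalls(self):
        calls = [
            call("S0", "rs1", GenotypeState.B), call("S1", "rs1", GenotypeState.A),
            call("S0", "rs2", GenotypeState.ABB, cn=3, pos=200),
            call("S1", "rs2", GenotypeState.NOCALL, cn=3, pos=200),
        ]
        m = dosage_matrix(calls)
        assert m.loc["S0", "rs1"] == 1.0 and m.loc["S1", "rs1"] == 0.0
        assert m.loc["S0", "rs2"] == 2.0 and np.isnan(m.loc["S1", "rs2"])

    def test_majority_allele_coding_risk_allele_choice(self):
        calls = [
            call("S0", "rs1", GenotypeState.B), call("S1", "rs1", GenotypeState.A),
            call("S2", "rs1", GenotypeState.ABB, cn=3), call("S3", "rs1", GenotypeState.AAB, cn=3),
            call("S4", "rs1", GenotypeState.NOCALL),
        ]
        assert majority_allele_coding(calls, "rs1", "B") == {"S0": 1, "S1": 0, "S2": 1, "S3": 0}
        assert majority_allele_coding(calls, "rs1", "A") == {"S0": 0, "S1": 1, "S2": 0, "S3": 1}
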