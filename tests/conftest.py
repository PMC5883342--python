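import math

import numpy as np
import pytest

from cnvgeno import SimParams, ThresholdScheme, call_region, simulate_cohort


@pytest.fixture(scope="session")
def scheme():
    return ThresholdScheme()


def cohort_calls(params, scheme=None):
    """Simulate a cohort and call genotypes over the planted segments.

    Returns (calls, phenotypes, truth).  Used by tests that exercise calling
    and association without the LRR segmentation step.
    """
    signals, phenotypes, truth = simulate_cohort(params, scheme=scheme)
    calls = []
    for sig in signals:
        calls.extend(call_region(sig, truth.segments[sig.sample_id], scheme=scheme))
    return calls, phenotypes, truth


@pytest.fixture(scope="session")
def small_noiseless_cohort():
    """4 deletion + 3 duplication carriers, 120 SNPs, zero noise."""
    params = SimParams(
        n_del_samples=4, n_dup_samples=3, n_snps=120, flank_snps=25, flank_bp=50_000,
        baf_sd=0.0, lrr_sd=0.0, nocall_rate=0.0, seed=101,
    )
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def study_sized_cohort():
    """25 deletion + 13 duplication carriers at realistic noise (seeded)."""
    params = SimParams(baf_sd=0.03, lrr_sd=0.15, nocall_rate=0.01, n_snps=400,
                       flank_snps=50, flank_bp=100_000, seed=202)
    return cohort_calls(params)


@pytest.fixture(scope="session")
def planted_risk_cohort():
    """200 deletion carriers, 300 SNPs, one risk SNP at allelic odds ratio 10."""
    freqs = np.random.default_rng(7).uniform(0.2, 0.8, 300)
    freqs[150] = 0.5
    params = SimParams(
        n_del_samples=200, n_dup_samples=0, n_snps=300, flank_snps=0,
        allele_freqs=freqs, risk_snp_index=150, effect_log_odds=math.log(10),
        baseline_prevalence=0.2, baf_sd=0.03, lrr_sd=0.15, nocall_rate=0.01, seed=11,
    )
    calls, phenotypes, truth = cohort_calls(params)
    return calls, phenotypes, truth, "rs000150"
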