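"""Synthetic SNP-chip cohorts with known CNVs, genotypes and phenotype effects.

The generator emulates the signal model of an Illumina-style array over a
CNV locus: every deletion-carrier sample gets one copy-number-1 segment
spanning the region and every duplication carrier a copy-number-3 segment,
with diploid flanking probes on both sides.  Per SNP, the haploid B-allele
is drawn Bernoulli(f), the triploid B-count Binomial(3, f), and diploid
flanks follow Hardy-Weinberg Binomial(2, f).  Emitted BAF is the canonical
cluster mean (haploid 0/1; triploid 0, 1/3, 2/3, 1; diploid 0, 1/2, 1) plus
Gaussian noise truncated to [0, 1]; LRR is a per-copy-number mean plus
Gaussian noise.  A configurable fraction of region SNPs has its BAF
resampled uniformly into the no-call gaps of the threshold scheme, emulating
the sporadic non-called probes of real chips without deleting records.

An optional risk SNP couples genotype to a binary phenotype through a
logistic model: affected ~ Bernoulli(logistic(logit(prevalence) +
effect_log_odds * risk_group)), where risk_group is the binary B-allele
group (haploid: carries B; triploid: at least 2 B copies).

Default cohort sizes (25 deletion and 13 duplication carriers, 1540 SNPs in
a 1.4-Mb region) are typical of a single-locus microdeletion study.
Everything is reproducible from one integer seed; per-sample substreams are
spawned deterministically so results do not depend on iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calling import ThresholdScheme
from .types import (
    CnvSegment,
    Diagnosis,
    GenotypeState,
    NonDiploidCall,
    PhenotypeRecord,
    Region,
    SampleSignal,
    SnpRecord,
)

_HAPLOID_STATES = {0: GenotypeState.A, 1: GenotypeState.B}
_TRIPLOID_STATES = {
    0: GenotypeState.AAA,
    1: GenotypeState.AAB,
    2: GenotypeState.ABB,
    3: GenotypeState.BBB,
}

DEFAULT_REGION = Region("chr7", 72_700_000, 74_100_000)


@dataclass
class SimParams:
    """Generative parameters for one synthetic cohort."""

    n_del_samples: int = 25
    n_dup_samples: int = 13
    region: Region = DEFAULT_REGION
    n_snps: int = 1540
    flank_snps: int = 150          # diploid probes on each side of the region
    flank_bp: int = 250_000        # width of each flank
    allele_freqs: Optional[np.ndarray] = None  # per-SNP B-allele freq; drawn U(0.05,0.95) if None
    lrr_means: dict = dc_field(default_factory=lambda: {1: -0.66, 2: 0.0, 3: 0.40})
    lrr_sd: float = 0.15
    baf_sd: float = 0.03
    nocall_rate: float = 0.01
    risk_snp_index: Optional[int] = None
    effect_log_odds: float = 0.0
    baseline_prevalence: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.lrr_sd < 0 or self.baf_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not (0.0 < self.baseline_prevalence < 1.0):
            raise ValueError("baseline_prevalence must lie in (0, 1)")
        if not (0.0 <= self.nocall_rate < 1.0):
            raise ValueError("nocall_rate must lie in [0, 1)")
        if self.region.length < self.n_snps:
            raise ValueError(
                f"region of {self.region.length} bp cannot hold {self.n_snps} SNPs at >=1 bp spacing"
            )
        if self.allele_freqs is not None:
            self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
            if len(self.allele_freqs) != self.n_snps:
                raise ValueError("allele_freqs length must equal n_snps")
            if np.any((self.allele_freqs <= 0) | (self.allele_freqs >= 1)):
                raise ValueError("allele frequencies must lie strictly in (0, 1)")
        if self.risk_snp_index is not None and not (0 <= self.risk_snp_index < self.n_snps):
            raise ValueError("risk_snp_index out of range")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, self-consistent with the signals at zero noise."""

    segments: dict[str, CnvSegment]          # per-sample true CNV segment
    genotypes: pd.DataFrame                  # sample_id, snp_id, chrom, pos, copy_number, b_count, state
    phenotypes: pd.DataFrame                 # sample_id, diagnosis, linear_predictor, affected
    allele_freqs: np.ndarray
    params: SimParams


def _positions(params: SimParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(region positions, left-flank positions, right-flank positions), all unique ints."""
    region = params.region
    pos = np.unique(np.linspace(region.start, region.end, params.n_snps).round().astype(int))
    # rounding collisions are only possible at extreme densities; repair by shifting
    while len(pos) < params.n_snps:
        extra = np.setdiff1d(np.arange(region.start, region.end + 1), pos)[: params.n_snps - len(pos)]
        pos = np.unique(np.concatenate([pos, extra]))
    if params.flank_snps > 0:
        left = np.unique(
            np.linspace(region.start - params.flank_bp, region.start - 1, params.flank_snps)
            .round().astype(int)
        )
        right = np.unique(
            np.linspace(region.end + 1, region.end + params.flank_bp, params.flank_snps)
            .round().astype(int)
        )
    else:
        left = right = np.array([], dtype=int)
    return pos, left, right


def _noisy_baf(mean: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return mean.copy()
    return np.clip(mean + rng.normal(0.0, sd, size=mean.shape), 0.0, 1.0)


def simulate_cohort(
    params: SimParams,
    scheme: Optional[ThresholdScheme] = None,
) -> tuple[list[SampleSignal], list[PhenotypeRecord], SimTruth]:
    """Generate a full cohort: per-sample signals, phenotypes, and the ground truth."""
    scheme = scheme or ThresholdScheme()
    n_samples = params.n_del_samples + params.n_dup_samples
    ss = np.random.SeedSequence(params.seed)
    cohort_ss, *sample_ss = ss.spawn(1 + n_samples)
    cohort_rng = np.random.default_rng(cohort_ss)

    freqs = params.allele_freqs
    if freqs is None:
        freqs = cohort_rng.uniform(0.05, 0.95, size=params.n_snps)

    region_pos, left_pos, right_pos = _positions(params)
    region_ids = np.array([f"rs{i:06d}" for i in range(params.n_snps)])
    left_ids = np.array([f"fl{i:06d}" for i in range(len(left_pos))])
    right_ids = np.array([f"fr{i:06d}" for i in range(len(right_pos))])
    n_flank = len(left_pos) + len(right_pos)
    flank_freqs = cohort_rng.uniform(0.05, 0.95, size=n_flank) if n_flank else np.array([])

    base_logit = math.log(params.baseline_prevalence / (1.0 - params.baseline_prevalence))

    sample_defs = [(f"WS{i + 1:03d}", Diagnosis.DEL) for i in range(params.n_del_samples)] + [
        (f"DUP{i + 1:03d}", Diagnosis.DUP) for i in range(params.n_dup_samples)
    ]

    signals: list[SampleSignal] = []
    phenotypes: list[PhenotypeRecord] = []
    truth_segments: dict[str, CnvSegment] = {}
    truth_rows: list[dict] = []
    pheno_rows: list[dict] = []

    for (sample_id, diagnosis), child in zip(sample_defs, sample_ss):
        rng = np.random.default_rng(child)
        cn = 1 if diagnosis is Diagnosis.DEL else 3
        b_count = rng.binomial(cn, freqs)
        baf_mean = b_count / cn
        baf = _noisy_baf(baf_mean, params.baf_sd, rng)
        lrr = np.full(params.n_snps, params.lrr_means[cn], dtype=float)
        if params.lrr_sd > 0:
            lrr += rng.normal(0.0, params.lrr_sd, size=params.n_snps)

        # planted no-calls: resample BAF uniformly inside the scheme's no-call gaps
        if params.nocall_rate > 0:
            gaps = scheme.nocall_gaps(cn)
            widths = np.array([hi - lo for lo, hi in gaps])
            mask = rng.random(params.n_snps) < params.nocall_rate
            idx = np.flatnonzero(mask)
            if len(idx):
                which = rng.choice(len(gaps), size=len(idx), p=widths / widths.sum())
                u = rng.random(len(idx))
                baf[idx] = np.array([gaps[w][0] + ui * (gaps[w][1] - gaps[w][0]) for w, ui in zip(which, u)])

        # diploid flanks under Hardy-Weinberg
        flank_pos = np.concatenate([left_pos, right_pos])
        flank_ids = np.concatenate([left_ids, right_ids])
        if n_flank:
            fb = rng.binomial(2, flank_freqs)
            fbaf = _noisy_baf(fb / 2.0, params.baf_sd, rng)
            flrr = np.full(n_flank, params.lrr_means[2], dtype=float)
            if params.lrr_sd > 0:
                flrr += rng.normal(0.0, params.lrr_sd, size=n_flank)
        else:
            fbaf = flrr = np.array([])

        records = [
            SnpRecord(snp_id=sid, chrom=params.region.chrom, pos=int(p), baf=float(b), lrr=float(v))
            for sid, p, b, v in zip(region_ids, region_pos, baf, lrr)
        ] + [
            SnpRecord(snp_id=sid, chrom=params.region.chrom, pos=int(p), baf=float(b), lrr=float(v))
            for sid, p, b, v in zip(flank_ids, flank_pos, fbaf, flrr)
        ]
        signals.append(SampleSignal(sample_id=sample_id, records=records))

        truth_segments[sample_id] = CnvSegment(
            sample_id=sample_id,
            chrom=params.region.chrom,
            start=int(region_pos[0]),
            end=int(region_pos[-1]),
            copy_number=cn,
            n_snps=params.n_snps,
        )
        states = _HAPLOID_STATES if cn == 1 else _TRIPLOID_STATES
        for sid, p, b in zip(region_ids, region_pos, b_count):
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "snp_id": sid,
                    "chrom": params.region.chrom,
                    "pos": int(p),
                    "copy_number": cn,
                    "b_count": int(b),
                    "state": states[int(b)].value,
                }
            )

        if params.risk_snp_index is not None:
            rb = int(b_count[params.risk_snp_index])
            risk_group = rb if cn == 1 else int(rb >= 2)
        else:
            risk_group = 0
        eta = base_logit + params.effect_log_odds * risk_group
        affected = bool(rng.random() < 1.0 / (1.0 + math.exp(-eta)))
        phenotypes.append(PhenotypeRecord(sample_id=sample_id, diagnosis=diagnosis, affected=affected))
        pheno_rows.append(
            {
                "sample_id": sample_id,
                "diagnosis": diagnosis.value,
                "linear_predictor": eta,
                "affected": affected,
            }
        )

    truth = SimTruth(
        segments=truth_segments,
        genotypes=pd.DataFrame(truth_rows),
        phenotypes=pd.DataFrame(pheno_rows),
        allele_freqs=freqs,
        params=params,
    )
    return signals, phenotypes, truth


@dataclass
class ConcordanceReport:
    """Agreement between planted genotypes and pipeline calls."""

    confusion: pd.DataFrame          # rows: true state; columns: called state; counts
    concordance: Optional[float]     # fraction of truth SNPs called correctly (no-call counts as miss)
    concordance_called: Optional[float]  # fraction correct among called SNPs only
    n_compared: int


def plant_truth_check(truth: SimTruth, calls: Sequence[NonDiploidCall]) -> ConcordanceReport:
    """Compare calls against the planted genotypes of their (sample, SNP) pairs."""
    if not calls:
        return ConcordanceReport(confusion=pd.DataFrame(), concordance=None, concordance_called=None, n_compared=0)
    known = set(truth.segments)
    bad = {c.sample_id for c in calls} - known
    if bad:
        raise ValueError(f"calls reference samples absent from the simulation truth: {sorted(bad)}")

    call_df = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "snp_id": [c.snp_id for c in calls],
            "called": [c.state.value for c in calls],
        }
    )
    merged = truth.genotypes.merge(call_df, on=["sample_id", "snp_id"], how="inner")
    if merged.empty:
        return ConcordanceReport(confusion=pd.DataFrame(), concordance=None, concordance_called=None, n_compared=0)
    confusion = pd.crosstab(merged["state"], merged["called"])
    correct = (merged["state"] == merged["called"]).sum()
    called = merged[merged["called"] != GenotypeState.NOCALL.value]
    return ConcordanceReport(
        confusion=confusion,
        concordance=float(correct / len(merged)),
        concordance_called=float((called["state"] == called["called"]).mean()) if len(called) else None,
        n_compared=len(merged),
    )
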