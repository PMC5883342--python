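"""Haploid and triploid genotype calling from B-allele frequency.

Inside a copy-number-1 (hemideleted) segment a SNP carries a single allele,
so its BAF clusters near 0 (A) or 1 (B).  Inside a copy-number-3 (duplicated)
segment the BAF estimates the fraction of B alleles among three chromosomal
copies and clusters near 0, 1/3, 2/3 and 1 (AAA, AAB, ABB, BBB).  Calling
maps each SNP's BAF to the genotype state whose fixed threshold interval
contains it; BAFs falling in the gaps between intervals — or missing — are
no-calls.

The default thresholds (haploid A: 0-0.25, B: 0.75-1; triploid AAA: 0-0.12,
AAB: 0.2-0.45, ABB: 0.55-0.8, BBB: 0.88-1) are the kind of cutoffs chosen by
visual review of cohort BAF plots; they are dataset-specific in principle and
fully configurable here.  Interval endpoints are inclusive, so the gaps
between them are open intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    CallRateSummary,
    CnvSegment,
    GenotypeState,
    NonDiploidCall,
    Region,
    SampleSignal,
)

Interval = tuple[float, float]


def _check_intervals(name: str, intervals: dict[GenotypeState, Interval]) -> None:
    ordered = sorted(intervals.items(), key=lambda kv: (kv[1][0] + kv[1][1]) / 2)
    prev_hi: Optional[float] = None
    for state, (lo, hi) in ordered:
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"{name} interval for {state.value} not within [0,1]: [{lo}, {hi}]")
        if prev_hi is not None and lo <= prev_hi:
            raise ValueError(f"{name} intervals overlap or touch near BAF={lo} (no no-call gap)")
        prev_hi = hi


@dataclass(frozen=True)
class ThresholdScheme:
    """Closed BAF intervals mapping signal to haploid and triploid genotype states."""

    haploid: dict[GenotypeState, Interval] = field(
        default_factory=lambda: {
            GenotypeState.A: (0.0, 0.25),
            GenotypeState.B: (0.75, 1.0),
        }
    )
    triploid: dict[GenotypeState, Interval] = field(
        default_factory=lambda: {
            GenotypeState.AAA: (0.0, 0.12),
            GenotypeState.AAB: (0.2, 0.45),
            GenotypeState.ABB: (0.55, 0.8),
            GenotypeState.BBB: (0.88, 1.0),
        }
    )

    def __post_init__(self):
        _check_intervals("haploid", self.haploid)
        _check_intervals("triploid", self.triploid)

    def intervals_for(self, copy_number: int) -> dict[GenotypeState, Interval]:
        if copy_number == 1:
            return self.haploid
        if copy_number == 3:
            return self.triploid
        raise ValueError(
            f"no genotype scheme for copy number {copy_number}: "
            "calling is defined only for hemideletions (cn=1) and duplications (cn=3)"
        )

    def nocall_gaps(self, copy_number: int) -> list[Interval]:
        """Open intervals of BAF that yield NOCALL, in ascending order."""
        ivals = sorted(self.intervals_for(copy_number).values())
        gaps: list[Interval] = []
        if ivals[0][0] > 0.0:
            gaps.append((0.0, ivals[0][0]))
        for (_, hi), (lo, _) in zip(ivals, ivals[1:]):
            gaps.append((hi, lo))
        if ivals[-1][1] < 1.0:
            gaps.append((ivals[-1][1], 1.0))
        return gaps

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdScheme":
        """Build from a plain mapping, e.g. loaded from YAML:
        ``{"haploid": {"A": [0, 0.25], ...}, "triploid": {...}}``."""
        kw = {}
        for ploidy in ("haploid", "triploid"):
            if ploidy in d:
                kw[ploidy] = {
                    GenotypeState(state): (float(lo), float(hi))
                    for state, (lo, hi) in d[ploidy].items()
                }
        return cls(**kw)

    def to_dict(self) -> dict:
        return {
            ploidy: {s.value: [lo, hi] for s, (lo, hi) in getattr(self, ploidy).items()}
            for ploidy in ("haploid", "triploid")
        }


def _call(baf: Optional[float], intervals: dict[GenotypeState, Interval]) -> GenotypeState:
    if baf is None or (isinstance(baf, float) and math.isnan(baf)):
        return GenotypeState.NOCALL
    if not (0.0 <= baf <= 1.0):
        raise ValueError(f"BAF must lie in [0, 1], got {baf}")
    for state, (lo, hi) in intervals.items():
        if lo <= baf <= hi:
            return state
    return GenotypeState.NOCALL


def call_haploid(baf: Optional[float], scheme: Optional[ThresholdScheme] = None) -> GenotypeState:
    """Map one BAF value to a haploid genotype state (A, B or NOCALL)."""
    scheme = scheme or ThresholdScheme()
    return _call(baf, scheme.haploid)


def call_triploid(baf: Optional[float], scheme: Optional[ThresholdScheme] = None) -> GenotypeState:
    """Map one BAF value to a triploid genotype state (AAA, AAB, ABB, BBB or NOCALL)."""
    scheme = scheme or ThresholdScheme()
    return _call(baf, scheme.triploid)


def call_region(
    signal: SampleSignal,
    segment: CnvSegment,
    scheme: Optional[ThresholdScheme] = None,
) -> list[NonDiploidCall]:
    """Call every SNP of ``signal`` lying inside ``segment``.

    Uses the haploid scheme for cn=1 segments and the triploid scheme for
    cn=3; other copy numbers are rejected (no genotype model is defined for
    homozygous deletions or four-copy states).
    """
    scheme = scheme or ThresholdScheme()
    intervals = scheme.intervals_for(segment.copy_number)
    calls = []
    for rec in signal.records:
        if rec.chrom != segment.chrom or not (segment.start <= rec.pos <= segment.end):
            continue
        calls.append(
            NonDiploidCall(
                sample_id=signal.sample_id,
                snp_id=rec.snp_id,
                chrom=rec.chrom,
                pos=rec.pos,
                state=_call(rec.baf, intervals),
                copy_number=segment.copy_number,
            )
        )
    return calls


def call_rate(calls: Iterable[NonDiploidCall]) -> CallRateSummary:
    """Fraction of SNPs receiving a genotype (state != NOCALL), as a percentage."""
    n_total = 0
    n_called = 0
    for c in calls:
        n_total += 1
        if c.is_called:
            n_called += 1
    return CallRateSummary(n_called=n_called, n_total=n_total)


@dataclass
class BafSummary:
    """Per-SNP, per-sample BAF values plus histogram counts for threshold review."""

    table: pd.DataFrame  # columns: sample_id, snp_id, chrom, pos, baf
    bin_edges: np.ndarray
    bin_counts: np.ndarray

    @property
    def n_values(self) -> int:
        return int(self.table["baf"].notna().sum())


def inspect_baf(
    signals: Sequence[SampleSignal],
    region: Optional[Region] = None,
    n_bins: int = 100,
) -> BafSummary:
    """Tabulate and histogram BAF across samples, optionally within a region.

    Supports manual threshold review (the decision itself is left to the
    analyst): the returned table can be scatter-plotted per position and the
    histogram shows where the BAF clusters sit.
    """
    rows = []
    for sig in signals:
        for rec in sig.records:
            if region is not None and not region.contains(rec.chrom, rec.pos):
                continue
            rows.append(
                {
                    "sample_id": sig.sample_id,
                    "snp_id": rec.snp_id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "baf": np.nan if rec.baf_missing else rec.baf,
                }
            )
    table = pd.DataFrame(rows, columns=["sample_id", "snp_id", "chrom", "pos", "baf"])
    values = table["baf"].dropna().to_numpy()
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    return BafSummary(table=table, bin_edges=edges, bin_counts=counts)
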