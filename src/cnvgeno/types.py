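"""Shared domain types for CNV genotyping and association analysis.

Coordinates are 1-based and inclusive throughout (the convention of PennCNV
segment files), so a segment's length is ``end - start + 1``.  Missing BAF or
LRR values are represented as ``None`` (or ``NaN`` in array form), never as 0 —
0 is a legal B-allele frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Optional, Sequence


class Diagnosis(str, Enum):
    """CNV carrier group: hemideletion (copy number 1) or duplication (copy number 3)."""

    DEL = "DEL"
    DUP = "DUP"


class GenotypeState(str, Enum):
    """Haploid (A/B) or triploid (AAA..BBB) genotype state of a SNP in a CNV region."""

    A = "A"
    B = "B"
    AAA = "AAA"
    AAB = "AAB"
    ABB = "ABB"
    BBB = "BBB"
    NOCALL = "NOCALL"

    @property
    def copy_number(self) -> Optional[int]:
        if self in (GenotypeState.A, GenotypeState.B):
            return 1
        if self is GenotypeState.NOCALL:
            return None
        return 3

    @property
    def b_allele_count(self) -> Optional[int]:
        counts = {
            GenotypeState.A: 0,
            GenotypeState.B: 1,
            GenotypeState.AAA: 0,
            GenotypeState.AAB: 1,
            GenotypeState.ABB: 2,
            GenotypeState.BBB: 3,
        }
        return counts.get(self)


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class SnpRecord:
    """One probe's signal: identifier, genomic position, BAF and LRR.

    ``baf`` is the B-allele frequency in [0, 1]; ``lrr`` is the log R ratio
    (log-scaled total intensity relative to a diploid reference).  Either may
    be missing (``None``).
    """

    snp_id: str
    chrom: str
    pos: int
    baf: Optional[float] = None
    lrr: Optional[float] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos} for {self.snp_id}")
        if not _is_missing(self.baf) and not (0.0 <= self.baf <= 1.0):
            raise ValueError(f"BAF must lie in [0, 1], got {self.baf} for {self.snp_id}")

    @property
    def baf_missing(self) -> bool:
        return _is_missing(self.baf)

    @property
    def lrr_missing(self) -> bool:
        return _is_missing(self.lrr)


@dataclass
class SampleSignal:
    """All SNP records for one sample, sorted by (chromosome, position)."""

    sample_id: str
    records: list[SnpRecord] = field(default_factory=list)

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda r: (r.chrom, r.pos))
        seen = set()
        for r in self.records:
            if r.snp_id in seen:
                raise ValueError(f"duplicate snp_id {r.snp_id!r} in sample {self.sample_id}")
            seen.add(r.snp_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class PhenotypeRecord:
    """Per-sample diagnosis (DEL/DUP carrier) and binary arteriopathy status."""

    sample_id: str
    diagnosis: Diagnosis
    affected: bool


@dataclass(frozen=True)
class Region:
    """A genomic interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class CnvSegment:
    """A called CNV segment for one sample.

    ``copy_number`` follows SNP-array conventions: 0/1 deletions, 2 diploid,
    3/4 duplications.  ``n_snps`` is the number of array probes supporting the
    segment.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    n_snps: int
    start_snp: Optional[str] = None
    end_snp: Optional[str] = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.copy_number not in (0, 1, 2, 3, 4):
            raise ValueError(f"copy number must be in 0..4, got {self.copy_number}")
        if self.n_snps < 1:
            raise ValueError(f"n_snps must be >= 1, got {self.n_snps}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, region: Region) -> bool:
        return (
            self.chrom == region.chrom
            and self.start <= region.end
            and self.end >= region.start
        )


@dataclass(frozen=True)
class NonDiploidCall:
    """Genotype state of one SNP in one sample's CNV segment.

    For called states the copy number and B-allele count are implied by the
    state; for NOCALL the copy number is that of the containing segment and
    the B-allele count is undefined.
    """

    sample_id: str
    snp_id: str
    chrom: str
    pos: int
    state: GenotypeState
    copy_number: int

    def __post_init__(self):
        if self.copy_number not in (1, 3):
            raise ValueError(f"calls are defined only for copy numbers 1 and 3, got {self.copy_number}")
        implied = self.state.copy_number
        if implied is not None and implied != self.copy_number:
            raise ValueError(
                f"state {self.state.value} implies copy number {implied}, got {self.copy_number}"
            )

    @property
    def b_allele_count(self) -> Optional[int]:
        return self.state.b_allele_count

    @property
    def is_called(self) -> bool:
        return self.state is not GenotypeState.NOCALL


@dataclass(frozen=True)
class CallRateSummary:
    """Genotype call rate: called / total, as a percentage rounded half-up to one decimal."""

    n_called: int
    n_total: int

    def __post_init__(self):
        if not (0 <= self.n_called <= self.n_total):
            raise ValueError(f"need 0 <= n_called <= n_total, got {self.n_called}/{self.n_total}")

    @property
    def rate_percent(self) -> Optional[float]:
        if self.n_total == 0:
            return None
        exact = Decimal(100 * self.n_called) / Decimal(self.n_total)
        return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))

    def __str__(self) -> str:
        if self.n_total == 0:
            return "call rate undefined (0 SNPs)"
        return f"{self.rate_percent}% ({self.n_called}/{self.n_total})"


def sort_segments(segments: Sequence[CnvSegment]) -> list[CnvSegment]:
    """Sort segments by (sample, chromosome, start, end)."""
    return sorted(segments, key=lambda s: (s.sample_id, s.chrom, s.start, s.end))
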