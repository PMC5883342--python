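"""Working-set construction for CNV segments.

Filters called segments by probe support and physical size, merges nearby
same-state segments, restricts to a target locus, and — for self-contained
end-to-end runs on synthetic data — provides a deliberately simple
run-length LRR segmenter.  The segmenter is a stand-in for a dedicated
HMM-based CNV caller whose text output this package otherwise imports; it
is not a reimplementation of one.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .types import CnvSegment, Region, SampleSignal

logger = logging.getLogger(__name__)


def filter_cnvs(
    segments: Sequence[CnvSegment],
    min_snps: int = 10,
    min_length: int = 10_000,
) -> list[CnvSegment]:
    """Keep segments supported by at least ``min_snps`` probes and spanning at
    least ``min_length`` bp (both boundaries inclusive).  Order is preserved.

    Defaults follow common SNP-array CNV quality practice: 10 consecutive
    SNPs and 10 kb.
    """
    if min_snps < 0 or min_length < 0:
        raise ValueError("thresholds must be non-negative")
    kept = [s for s in segments if s.n_snps >= min_snps and s.length >= min_length]
    logger.info("filter_cnvs: kept %d of %d segments", len(kept), len(segments))
    return kept


def merge_cnvs(segments: Sequence[CnvSegment], max_gap: int = 1_000) -> list[CnvSegment]:
    """Merge same-chromosome, same-copy-number segments separated by at most
    ``max_gap`` uncovered basepairs.

    The gap between consecutive segments is ``next.start - prev.end - 1``
    (the count of basepairs strictly between them); overlapping or abutting
    segments always merge.  Merging runs to a fixed point, SNP counts are
    summed, and the output is sorted by position.  All input segments must
    belong to one sample; segments of different copy number never merge.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    if not segments:
        return []
    samples = {s.sample_id for s in segments}
    if len(samples) > 1:
        raise ValueError(f"merge_cnvs expects one sample, got {sorted(samples)}")

    merged: list[CnvSegment] = []
    groups: dict[tuple[str, int], list[CnvSegment]] = {}
    for s in segments:
        groups.setdefault((s.chrom, s.copy_number), []).append(s)

    for (_, _), group in sorted(groups.items()):
        group = sorted(group, key=lambda s: (s.start, s.end))
        current = group[0]
        for nxt in group[1:]:
            gap = nxt.start - current.end - 1
            if gap <= max_gap:
                current = CnvSegment(
                    sample_id=current.sample_id,
                    chrom=current.chrom,
                    start=current.start,
                    end=max(current.end, nxt.end),
                    copy_number=current.copy_number,
                    n_snps=current.n_snps + nxt.n_snps,
                    start_snp=current.start_snp,
                    end_snp=nxt.end_snp if nxt.end >= current.end else current.end_snp,
                )
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
    merged.sort(key=lambda s: (s.chrom, s.start, s.end, s.copy_number))
    return merged


def restrict_to_region(
    segments: Sequence[CnvSegment],
    region: Region,
    intersect: bool = False,
) -> list[CnvSegment]:
    """Return segments overlapping ``region`` by at least 1 bp.

    With ``intersect=True`` the returned intervals are clipped to the region;
    by default the whole overlapping segment is kept intact.
    """
    out: list[CnvSegment] = []
    for s in segments:
        if not s.overlaps(region):
            continue
        if intersect and (s.start < region.start or s.end > region.end):
            out.append(
                CnvSegment(
                    sample_id=s.sample_id,
                    chrom=s.chrom,
                    start=max(s.start, region.start),
                    end=min(s.end, region.end),
                    copy_number=s.copy_number,
                    n_snps=s.n_snps,
                    start_snp=None,
                    end_snp=None,
                )
            )
        else:
            out.append(s)
    return out


def segment_lrr(
    signal: SampleSignal,
    cn1_cut: float = -0.3,
    cn3_cut: float = 0.2,
    min_run: int = 10,
) -> list[CnvSegment]:
    """Threshold run-length segmentation of LRR into cn=1 and cn=3 segments.

    Maximal runs of at least ``min_run`` consecutive SNPs with LRR below
    ``cn1_cut`` become deletion (cn=1) segments; runs above ``cn3_cut``
    become duplication (cn=3) segments.  Segment bounds are the first/last
    SNP positions of the run; SNPs with missing LRR break runs.  Default
    cutpoints sit roughly midway between canonical per-copy-number LRR means
    (cn=1 about -0.66, cn=2 at 0, cn=3 about +0.40).
    """
    segments: list[CnvSegment] = []
    run: list = []
    run_state: int | None = None  # 1 or 3

    def flush():
        nonlocal run
        if run_state is not None and len(run) >= min_run:
            segments.append(
                CnvSegment(
                    sample_id=signal.sample_id,
                    chrom=run[0].chrom,
                    start=run[0].pos,
                    end=run[-1].pos,
                    copy_number=run_state,
                    n_snps=len(run),
                    start_snp=run[0].snp_id,
                    end_snp=run[-1].snp_id,
                )
            )
        run = []

    prev_chrom = None
    for rec in signal.records:
        if rec.lrr_missing:
            state = None
        elif rec.lrr < cn1_cut:
            state = 1
        elif rec.lrr > cn3_cut:
            state = 3
        else:
            state = None
        if state != run_state or rec.chrom != prev_chrom:
            flush()
            run_state = state
        if state is not None:
            run.append(rec)
        prev_chrom = rec.chrom
    flush()
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments
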