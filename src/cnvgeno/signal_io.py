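"""Readers and writers for the external file formats.

Supported formats:

* per-sample SNP signal tables — tab-separated with a header row, in the
  dialect of Illumina GenomeStudio "Final Report" exports (column names are
  configurable; defaults are the GenomeStudio ones);
* PennCNV ``.rawcnv`` segment files (read) and a BED-like TSV (write);
* phenotype tables (sample, diagnosis, affected);
* genotype-call and association-result tables (TSV, fixed columns);
* gene maps (BED-like TSV: chrom, start, end, gene).

All TSV writers/readers round-trip losslessly, and parsing never silently
drops rows: unparseable numeric fields are kept with the value flagged
missing, and the count of flagged rows is reported via logging.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .types import (
    CnvSegment,
    Diagnosis,
    GenotypeState,
    NonDiploidCall,
    PhenotypeRecord,
    SampleSignal,
    SnpRecord,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when an input file does not match its expected layout."""


#: GenomeStudio Final-Report default column names.
DEFAULT_SIGNAL_COLUMNS = {
    "snp_id": "SNP Name",
    "chrom": "Chr",
    "pos": "Position",
    "baf": "B Allele Freq",
    "lrr": "Log R Ratio",
    "sample": "Sample ID",
}


def _parse_float(text) -> Optional[float]:
    """Parse a float field; unparseable or non-finite values become missing."""
    try:
        v = float(text)
    except (TypeError, ValueError):
        return None
    return v if math.isfinite(v) else None


def read_signal_table(
    path: PathLike,
    sample_id: str,
    columns: Optional[dict] = None,
) -> SampleSignal:
    """Read a per-sample SNP signal table.

    Parameters
    ----------
    path:
        Tab-separated file with a header naming at least the SNP-id,
        chromosome, position, BAF and LRR columns.
    sample_id:
        Identifier assigned to the returned :class:`SampleSignal`.  If the
        table has a sample column, rows are filtered to this sample.
    columns:
        Mapping overriding the default GenomeStudio column names, keyed by
        ``snp_id``/``chrom``/``pos``/``baf``/``lrr``/``sample``.

    Returns
    -------
    SampleSignal with records sorted by (chromosome, position).  Rows whose
    BAF or LRR does not parse are retained with the value flagged missing.
    """
    cols = dict(DEFAULT_SIGNAL_COLUMNS)
    if columns:
        cols.update(columns)

    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty signal table") from None

    for key in ("snp_id", "chrom", "pos", "baf", "lrr"):
        if cols[key] not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {cols[key]!r}")

    if cols["sample"] in df.columns:
        df = df[df[cols["sample"]] == sample_id]

    records = []
    n_flagged = 0
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        try:
            pos = int(str(row[cols["pos"]]).strip())
        except (TypeError, ValueError):
            raise FormatError(f"{path}: unparseable position {row[cols['pos']]!r}")
        baf = _parse_float(row[cols["baf"]])
        lrr = _parse_float(row[cols["lrr"]])
        if baf is not None and not (0.0 <= baf <= 1.0):
            baf = None
        if baf is None or lrr is None:
            n_flagged += 1
        records.append(
            SnpRecord(
                snp_id=str(row[cols["snp_id"]]),
                chrom=str(row[cols["chrom"]]),
                pos=pos,
                baf=baf,
                lrr=lrr,
            )
        )
    if n_flagged:
        logger.info("%s: %d of %d rows have missing/unparseable BAF or LRR", path, n_flagged, len(records))
    return SampleSignal(sample_id=sample_id, records=records)


def write_signal_table(signal: SampleSignal, path: PathLike, columns: Optional[dict] = None) -> None:
    """Write a SampleSignal as a GenomeStudio-dialect TSV (paired with :func:`read_signal_table`)."""
    cols = dict(DEFAULT_SIGNAL_COLUMNS)
    if columns:
        cols.update(columns)
    rows = [
        {
            cols["sample"]: signal.sample_id,
            cols["snp_id"]: r.snp_id,
            cols["chrom"]: r.chrom,
            cols["pos"]: r.pos,
            cols["baf"]: "NaN" if r.baf_missing else repr(r.baf),
            cols["lrr"]: "NaN" if r.lrr_missing else repr(r.lrr),
        }
        for r in signal.records
    ]
    order = [cols[k] for k in ("sample", "snp_id", "chrom", "pos", "baf", "lrr")]
    pd.DataFrame(rows, columns=order).to_csv(path, sep="\t", index=False)


# PennCNV .rawcnv line, e.g.:
#   chr7:72700000-74100000  numsnp=1500  length=1,400,001  state2,cn=1 WS01 startsnp=rsA endsnp=rsB
_RAWCNV_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>[\d,]+)-(?P<end>[\d,]+)\s+"
    r"numsnp=(?P<numsnp>[\d,]+)\s+"
    r"length=(?P<length>[\d,]+)\s+"
    r"state(?P<state>\d+),cn=(?P<cn>\d+)\s+"
    r"(?P<sample>\S+)"
    r"(?:\s+startsnp=(?P<startsnp>\S+))?"
    r"(?:\s+endsnp=(?P<endsnp>\S+))?"
)


def _int_field(text: str) -> int:
    # PennCNV writes thousands separators, e.g. length=1,412,813
    return int(text.replace(",", "").strip())


def read_penncnv_rawcnv(path: PathLike) -> list[CnvSegment]:
    """Parse a PennCNV ``.rawcnv`` file into CnvSegment records.

    Intervals are taken as 1-based inclusive (PennCNV's convention); the
    sample identifier is the file/sample token of each line.  Raises
    :class:`FormatError` with the line number on malformed lines, and
    ValueError for copy numbers outside 0..4.
    """
    segments: list[CnvSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            m = _RAWCNV_RE.match(line)
            if m is None:
                raise FormatError(f"{path}:{lineno}: malformed .rawcnv line: {line!r}")
            cn = int(m.group("cn"))
            if cn not in (0, 1, 2, 3, 4):
                raise ValueError(f"{path}:{lineno}: copy number {cn} outside 0-4")
            segments.append(
                CnvSegment(
                    sample_id=m.group("sample"),
                    chrom=m.group("chrom"),
                    start=_int_field(m.group("start")),
                    end=_int_field(m.group("end")),
                    copy_number=cn,
                    n_snps=_int_field(m.group("numsnp")),
                    start_snp=m.group("startsnp"),
                    end_snp=m.group("endsnp"),
                )
            )
    return segments


_SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "copy_number", "n_snps", "start_snp", "end_snp"]


def write_segments_table(segments: Sequence[CnvSegment], path: PathLike) -> None:
    """Write segments as a BED-like TSV.  Coordinates are 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("# CNV segments; start/end are 1-based inclusive basepair coordinates\n")
        fh.write("\t".join(_SEGMENT_COLUMNS) + "\n")
        for s in segments:
            fh.write(
                "\t".join(
                    [
                        s.sample_id,
                        s.chrom,
                        str(s.start),
                        str(s.end),
                        str(s.copy_number),
                        str(s.n_snps),
                        s.start_snp or ".",
                        s.end_snp or ".",
                    ]
                )
                + "\n"
            )


def read_segments_table(path: PathLike) -> list[CnvSegment]:
    """Read the BED-like segments TSV written by :func:`write_segments_table`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(_SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CnvSegment(
                sample_id=row.sample_id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                copy_number=int(row.copy_number),
                n_snps=int(row.n_snps),
                start_snp=None if row.start_snp == "." else row.start_snp,
                end_snp=None if row.end_snp == "." else row.end_snp,
            )
        )
    return out


_CALL_COLUMNS = ["sample_id", "snp_id", "chrom", "pos", "state", "b_allele_count", "copy_number"]


def write_calls_table(calls: Sequence[NonDiploidCall], path: PathLike) -> None:
    """Write genotype calls as TSV; round-trips losslessly through :func:`read_calls_table`."""
    with open(path, "w") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            bac = c.b_allele_count
            fh.write(
                "\t".join(
                    [
                        c.sample_id,
                        c.snp_id,
                        c.chrom,
                        str(c.pos),
                        c.state.value,
                        "." if bac is None else str(bac),
                        str(c.copy_number),
                    ]
                )
                + "\n"
            )


def read_calls_table(path: PathLike) -> list[NonDiploidCall]:
    """Read a genotype-call TSV written by :func:`write_calls_table`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_CALL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        NonDiploidCall(
            sample_id=row.sample_id,
            snp_id=row.snp_id,
            chrom=row.chrom,
            pos=int(row.pos),
            state=GenotypeState(row.state),
            copy_number=int(row.copy_number),
        )
        for row in df.itertuples(index=False)
    ]


def read_phenotype_table(path: PathLike) -> list[PhenotypeRecord]:
    """Read a phenotype TSV: columns sample_id, diagnosis (DEL/DUP), affected (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "diagnosis", "affected"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    return [
        PhenotypeRecord(
            sample_id=row.sample_id,
            diagnosis=Diagnosis(row.diagnosis),
            affected=row.affected.strip() in ("1", "True", "true", "TRUE"),
        )
        for row in df.itertuples(index=False)
    ]


def write_phenotype_table(phenotypes: Sequence[PhenotypeRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tdiagnosis\taffected\n")
        for p in phenotypes:
            fh.write(f"{p.sample_id}\t{p.diagnosis.value}\t{int(p.affected)}\n")


def read_gene_map(path: PathLike) -> pd.DataFrame:
    """Read a BED-like gene map TSV (chrom, start, end, gene; 1-based inclusive)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str, "start": int, "end": int, "gene": str},
    )
    if df.empty:
        raise FormatError(f"{path}: empty gene map")
    return df


def genes_for_positions(positions: pd.DataFrame, gene_map: pd.DataFrame) -> dict[str, str]:
    """Map SNP ids to gene labels by positional overlap.

    ``positions`` needs columns snp_id, chrom, pos.  SNPs outside every gene
    interval are labelled ``"intergenic"``.  If gene intervals overlap, the
    first (by file order) wins.
    """
    labels: dict[str, str] = {}
    for row in positions.itertuples(index=False):
        hit = gene_map[
            (gene_map["chrom"] == row.chrom)
            & (gene_map["start"] <= row.pos)
            & (gene_map["end"] >= row.pos)
        ]
        labels[row.snp_id] = hit["gene"].iloc[0] if len(hit) else "intergenic"
    return labels


def write_association_table(results, path: PathLike) -> None:
    """Write association results as TSV, including the 2x2 counts so every p is auditable."""
    cols = [
        "snp_id", "gene", "chrom", "pos",
        "n_risk_affected", "n_risk_unaffected", "n_other_affected", "n_other_unaffected",
        "chi2", "p_uncorrected", "meff_used", "p_bonferroni", "neglog10_p", "untestable",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in results:
            t = r.table
            fh.write(
                "\t".join(
                    [
                        r.snp_id,
                        r.gene,
                        r.chrom or ".",
                        str(r.pos) if r.pos is not None else ".",
                        str(t.a), str(t.b), str(t.c), str(t.d),
                        _fmt(r.chi2), _fmt(r.p_uncorrected), _fmt(r.meff_used),
                        _fmt(r.p_bonferroni), _fmt(r.neglog10_p), str(int(r.untestable)),
                    ]
                )
                + "\n"
            )


def _fmt(x) -> str:
    # fixed 6-significant-digit serialization keeps reruns byte-stable
    if x is None:
        return "."
    return f"{x:.6g}"
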