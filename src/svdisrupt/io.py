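"""Readers and writers for the standard formats the pipeline touches.

One internal convention: 0-based half-open coordinates everywhere; VCF's
1-based POS is converted on read and restored on write.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .intervals import Interval, IntervalSet
from .records import (
    COHORTS,
    SUPPORTED_SVTYPES,
    UNSUPPORTED_RAW_TYPES,
    CREint,
    ExpressionRecord,
    LoopRecord,
    SVRecord,
)


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


# --- structural variants --------------------------------------------------

SV_TSV_COLUMNS = ["chrom", "start", "end", "svtype", "subject", "cohort", "alt_sequence"]


def _normalize_svtype(raw: str) -> tuple[str, str | None]:
    raw = raw.upper()
    if raw in SUPPORTED_SVTYPES:
        return raw, None
    if raw in UNSUPPORTED_RAW_TYPES:
        return "UNSUPPORTED", raw
    return "UNSUPPORTED", raw


def read_sv_records(path: str, dialect: str | None = None, default_cohort: str = "proband") -> list[SVRecord]:
    """Load structural variants from a VCF (symbolic-allele SVs) or TSV table.

    Insertion-class and translocation calls (ALU, LINE1, SVA, INS, CTX, ...)
    are retained with ``svtype="UNSUPPORTED"`` so exclusion accounting can
    report them, rather than silently dropped.
    """
    if dialect is None:
        dialect = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if dialect == "vcf":
        return _read_sv_vcf(path, default_cohort)
    if dialect == "tsv":
        return _read_sv_tsv(path)
    raise ValueError(f"unknown SV dialect {dialect!r}")


def _read_sv_vcf(path: str, default_cohort: str) -> list[SVRecord]:
    out: list[SVRecord] = []
    with pysam.VariantFile(path) as vcf:
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            try:
                info = rec.info
                if "SVTYPE" not in info:
                    raise FormatError("missing SVTYPE INFO field")
                svtype, raw = _normalize_svtype(str(info["SVTYPE"]))
                start = rec.start  # pysam already 0-based
                end = info.get("END", rec.stop)
                if end is None or end <= start:
                    svlen = info.get("SVLEN")
                    if svlen is None:
                        raise FormatError("missing END/SVLEN")
                    end = start + abs(int(svlen if np.isscalar(svlen) else svlen[0]))
                alt_seq = None
                if rec.alts and not rec.alts[0].startswith("<"):
                    alt_seq = rec.alts[0].upper()
                cohort = str(info.get("COHORT", default_cohort))
                if cohort not in COHORTS:
                    raise FormatError(f"unknown cohort label {cohort!r}")
                out.append(
                    SVRecord(
                        id=rec.id or f"sv{i}",
                        span=Interval(rec.chrom, start, int(end)),
                        svtype=svtype,
                        subject_id=str(info.get("SUBJECT", "unknown")),
                        cohort=cohort,
                        alt_sequence=alt_seq,
                        raw_type=raw,
                    )
                )
            except (FormatError, ValueError, KeyError) as exc:
                raise FormatError(f"{path}: bad VCF record {i} ({rec.chrom}:{rec.pos}): {exc}") from exc
    return out


def _read_sv_tsv(path: str) -> list[SVRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chrom", "start", "end", "svtype", "subject", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out: list[SVRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            svtype, raw = _normalize_svtype(str(row.svtype))
            alt = getattr(row, "alt_sequence", None)
            if isinstance(alt, float) or alt in (None, "", "nan", "."):
                alt = None
            cohort = str(row.cohort)
            if cohort not in COHORTS:
                raise FormatError(f"unknown cohort label {cohort!r}")
            rid = getattr(row, "id", None) or f"sv{i - 1}"
            out.append(
                SVRecord(
                    id=str(rid),
                    span=Interval(str(row.chrom), int(row.start), int(row.end)),
                    svtype=svtype,
                    subject_id=str(row.subject),
                    cohort=cohort,
                    alt_sequence=alt,
                    raw_type=raw,
                )
            )
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
    return out


def write_sv_tsv(records: list[SVRecord], path: str) -> None:
    rows = [
        {
            "id": r.id,
            "chrom": r.span.chrom,
            "start": r.span.start,
            "end": r.span.end,
            "svtype": r.raw_type if r.svtype == "UNSUPPORTED" else r.svtype,
            "subject": r.subject_id,
            "cohort": r.cohort,
            "alt_sequence": r.alt_sequence or ".",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_sv_vcf(records: list[SVRecord], path: str, contig_lengths: dict[str, int]) -> None:
    """Write SVs as a minimal VCF 4.2 with symbolic alleles."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SUBJECT,Number=1,Type=String,Description="Subject id">\n')
        fh.write('##INFO=<ID=COHORT,Number=1,Type=String,Description="proband or sibling">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            svtype = r.raw_type if r.svtype == "UNSUPPORTED" else r.svtype
            alt = r.alt_sequence if (r.svtype == "CPX" and r.alt_sequence) else f"<{svtype}>"
            info = (
                f"SVTYPE={svtype};END={r.span.end};"
                f"SUBJECT={r.subject_id};COHORT={r.cohort}"
            )
            fh.write(
                f"{r.span.chrom}\t{r.span.start + 1}\t{r.id}\tN\t{alt}\t.\t.\t{info}\n"
            )


# --- loops / BEDPE --------------------------------------------------------


def read_loops_bedpe(path: str) -> list[LoopRecord]:
    """Load loops from 6+ column BEDPE; anchors ordered left-before-right.

    Inter-chromosomal pairs are retained but flagged for later filtering.
    """
    out: list[LoopRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}: line {lineno}: BEDPE needs >= 6 columns")
            try:
                left = Interval(fields[0], int(fields[1]), int(fields[2]))
                right = Interval(fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            name = fields[6] if len(fields) > 6 and fields[6] != "." else f"loop{lineno}"
            out.append(LoopRecord(anchor_left=left, anchor_right=right, source_ids=[name]))
    return out


def write_loops_bedpe(loops: list[LoopRecord], path: str) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            fh.write(
                f"{lp.anchor_left.chrom}\t{lp.anchor_left.start}\t{lp.anchor_left.end}\t"
                f"{lp.anchor_right.chrom}\t{lp.anchor_right.start}\t{lp.anchor_right.end}\t"
                f"{','.join(lp.source_ids) or '.'}\n"
            )


def write_creints_bedpe(creints: list[CREint], path: str) -> None:
    with open(path, "w") as fh:
        for c in creints:
            fh.write(
                f"{c.anchor_left.chrom}\t{c.anchor_left.start}\t{c.anchor_left.end}\t"
                f"{c.anchor_right.chrom}\t{c.anchor_right.start}\t{c.anchor_right.end}\t"
                f"{c.id}\t{c.merged_from}\t{','.join(c.promoter_genes) or '.'}\n"
            )


def read_creints_bedpe(path: str) -> list[CREint]:
    out: list[CREint] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}: line {lineno}: needs >= 6 columns")
            out.append(
                CREint(
                    id=f[6] if len(f) > 6 else f"creint{lineno}",
                    anchor_left=Interval(f[0], int(f[1]), int(f[2])),
                    anchor_right=Interval(f[3], int(f[4]), int(f[5])),
                    merged_from=int(f[7]) if len(f) > 7 else 1,
                    promoter_genes=[g for g in (f[8].split(",") if len(f) > 8 else []) if g != "."],
                )
            )
    return out


# --- BED / annotations ----------------------------------------------------


def read_bed(path: str) -> list[Interval]:
    """BED3+; name/score columns ignored, strand honoured when present."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}: line {lineno}: BED needs >= 3 columns")
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            out.append(Interval(f[0], int(f[1]), int(f[2]), strand))
    return out


def read_named_bed(path: str) -> list[tuple[str, Interval]]:
    """BED4+ keeping the name column (gene/exon identifiers)."""
    out: list[tuple[str, Interval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"{path}: line {lineno}: named BED needs >= 4 columns")
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            out.append((f[3], Interval(f[0], int(f[1]), int(f[2]), strand)))
    return out


def write_bed(intervals: list[Interval], path: str, names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand if iv.strand != '.' else '+'}\n"
                     if names or iv.strand != "." else f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_expression_tsv(path: str) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "tpm"} <= set(df.columns):
        raise FormatError(f"{path}: expression TSV needs columns gene_id, tpm")
    recs = {str(r.gene_id): ExpressionRecord(str(r.gene_id), float(r.tpm)).tpm
            for r in df.itertuples(index=False)}
    return recs


def tss_from_gene(gene: Interval) -> int:
    """Transcription start: interval start on +, last base on -."""
    return gene.start if gene.strand != "-" else gene.end - 1


@dataclass
class AnnotationBundle:
    """Keyed interval sets plus the expression table, as one unit."""

    ctcf_peaks: IntervalSet = field(default_factory=IntervalSet)
    h3k27ac: IntervalSet = field(default_factory=IntervalSet)
    h3k4me1: IntervalSet = field(default_factory=IntervalSet)
    h3k27me3: IntervalSet = field(default_factory=IntervalSet)
    asd_gene_exons: IntervalSet = field(default_factory=IntervalSet)
    genes: list[tuple[str, Interval]] = field(default_factory=list)
    gene_exons: list[tuple[str, Interval]] = field(default_factory=list)
    expression: dict[str, float] = field(default_factory=dict)

    @property
    def gene_tss(self) -> dict[str, tuple[str, int, str]]:
        """gene_id -> (chrom, tss position, strand)."""
        return {
            name: (iv.chrom, tss_from_gene(iv), iv.strand) for name, iv in self.genes
        }


REQUIRED_ANNOTATION_KEYS = (
    "ctcf_peaks", "h3k27ac", "h3k4me1", "h3k27me3", "asd_gene_exons", "genes", "gene_exons",
)


def read_annotation_inputs(bed_paths: dict[str, str], expression_path: str) -> AnnotationBundle:
    """Assemble the annotation bundle from named BED paths + expression TSV.

    ``bed_paths`` must provide every key in ``REQUIRED_ANNOTATION_KEYS``;
    ``genes`` and ``gene_exons`` are BED6 with gene ids in the name column.
    """
    missing = [k for k in REQUIRED_ANNOTATION_KEYS if k not in bed_paths]
    if missing:
        raise FormatError(f"missing annotation inputs: {missing}")
    return AnnotationBundle(
        ctcf_peaks=IntervalSet(read_bed(bed_paths["ctcf_peaks"])),
        h3k27ac=IntervalSet(read_bed(bed_paths["h3k27ac"])),
        h3k4me1=IntervalSet(read_bed(bed_paths["h3k4me1"])),
        h3k27me3=IntervalSet(read_bed(bed_paths["h3k27me3"])),
        asd_gene_exons=IntervalSet(read_bed(bed_paths["asd_gene_exons"])),
        genes=read_named_bed(bed_paths["genes"]),
        gene_exons=read_named_bed(bed_paths["gene_exons"]),
        expression=read_expression_tsv(expression_path),
    )


# --- contact matrices -----------------------------------------------------


@dataclass
class DenseContactMatrix:
    """Pre-binned, pre-normalised (log-scaled) experimental contact matrix."""

    region: Interval
    bin_bp: int
    values: np.ndarray  # square; NaN marks missing entries

    def __post_init__(self) -> None:
        n = int(np.ceil(len(self.region) / self.bin_bp))
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} != expected ({n}, {n}) "
                f"for region of {len(self.region)} bp at {self.bin_bp} bp bins"
            )


def read_contact_matrix(path: str) -> DenseContactMatrix:
    """Dense tab-delimited matrix with header line ``#chrom start end bin_bp``."""
    with open(path) as fh:
        header = fh.readline().strip().lstrip("#").split()
        if len(header) != 4:
            raise FormatError(f"{path}: header must be '#chrom start end bin_bp'")
        chrom, start, end, bin_bp = header[0], int(header[1]), int(header[2]), int(header[3])
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    return DenseContactMatrix(Interval(chrom, start, end), bin_bp, values)


def write_contact_matrix(matrix: DenseContactMatrix, path: str) -> None:
    with open(path, "w") as fh:
        r = matrix.region
        fh.write(f"#{r.chrom} {r.start} {r.end} {matrix.bin_bp}\n")
        np.savetxt(fh, matrix.values, fmt="%.6g", delimiter="\t")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
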