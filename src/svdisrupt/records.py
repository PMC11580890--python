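"""Core record types: structural variants, loops, expression."""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import Interval

#: SV classes whose alternate allele can be reconstructed from the reference.
SUPPORTED_SVTYPES = ("DEL", "DUP", "INV", "CPX")

#: Raw call types whose alternate allele sequence is unknown (insertions of
#: mobile elements, novel insertions, translocations); loaded but flagged.
UNSUPPORTED_RAW_TYPES = ("ALU", "LINE1", "SVA", "INS", "CTX", "BND")

COHORTS = ("proband", "sibling")


@dataclass
class SVRecord:
    """One structural variant call with subject and cohort labels."""

    id: str
    span: Interval
    svtype: str  # DEL | DUP | INV | CPX | UNSUPPORTED
    subject_id: str = "unknown"
    cohort: str = "proband"
    alt_sequence: str | None = None
    raw_type: str | None = None  # original type label for UNSUPPORTED calls

    def __post_init__(self) -> None:
        if self.svtype not in SUPPORTED_SVTYPES + ("UNSUPPORTED",):
            raise ValueError(f"unknown svtype {self.svtype!r} for {self.id}")
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort label {self.cohort!r} for {self.id}")
        if self.svtype == "CPX" and not self.alt_sequence:
            raise ValueError(f"CPX variant {self.id} requires alt_sequence")

    @property
    def length(self) -> int:
        return len(self.span)


@dataclass
class LoopRecord:
    """A chromatin loop: two anchors, left preceding right."""

    anchor_left: Interval
    anchor_right: Interval
    source_ids: list[str] = field(default_factory=list)
    inter_chromosomal: bool = False

    def __post_init__(self) -> None:
        self.inter_chromosomal = self.anchor_left.chrom != self.anchor_right.chrom
        if not self.inter_chromosomal and self.anchor_left.start > self.anchor_right.start:
            self.anchor_left, self.anchor_right = self.anchor_right, self.anchor_left

    @property
    def anchor_distance(self) -> int:
        """Inner-edge to inner-edge distance between anchors (bp)."""
        return max(0, self.anchor_right.start - self.anchor_left.end)


@dataclass
class CREint:
    """A merged loop whose anchor set marks a putative cis-regulatory
    interaction; at least one anchor overlaps the promoter of an expressed
    gene (unless the promoter filter was deliberately skipped)."""

    id: str
    anchor_left: Interval
    anchor_right: Interval
    promoter_genes: list[str] = field(default_factory=list)
    merged_from: int = 1

    @property
    def anchor_distance(self) -> int:
        return max(0, self.anchor_right.start - self.anchor_left.end)

    @property
    def span(self) -> Interval:
        return Interval(
            self.anchor_left.chrom,
            self.anchor_left.start,
            max(self.anchor_right.end, self.anchor_left.end),
        )


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError(f"negative TPM for {self.gene_id}")
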