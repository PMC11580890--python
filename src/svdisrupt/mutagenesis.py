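"""Prediction windows, allele sequence construction, augmentation, exclusions.

For each variant a fixed-length window is placed around it, a reference /
alternate sequence pair is built per SV type, and four augmentations
(identity, +-1 bp window shifts, reverse complement) are generated.  The
exclusion filters mirror the scoring pipeline's rules: unsupported allele
types, absolute and relative length caps, off-contig windows, and N-rich
reference sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import GenomeSource
from .geometry import PredictorGeometry
from .predictor import reverse_complement
from .records import SVRecord

#: Exclusion codes in the order the checks run; first failing check wins.
EXCLUSION_CODES = ("UNKNOWN_ALT", "TOO_LONG_ABS", "TOO_LONG_REL", "OFF_CONTIG", "N_CONTENT")

DEFAULT_MAX_ABS_LEN = 700_000
DEFAULT_MAX_REL_LEN = 2.0 / 3.0
DEFAULT_MAX_N_FRAC = 0.05


@dataclass(frozen=True)
class ExclusionReason:
    code: str
    detail: str

    def __post_init__(self) -> None:
        if self.code not in EXCLUSION_CODES:
            raise ValueError(f"unknown exclusion code {self.code!r}")


class ExclusionError(ValueError):
    def __init__(self, reason: ExclusionReason):
        super().__init__(f"{reason.code}: {reason.detail}")
        self.reason = reason


@dataclass
class PredictionWindow:
    """A fixed-length genomic window feeding the predictor."""

    span_chrom: str
    start: int
    end: int
    shift_bp: int
    variant: SVRecord
    clamp_bp: int = 0  # how far the window was pushed back inside the contig

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def clamped(self) -> bool:
        return self.clamp_bp != 0


@dataclass
class SequencePair:
    """Reference / alternate sequences of identical length for one window."""

    ref_seq: str
    alt_seq: str
    variant_offset: int  # variant start within ref_seq
    ref_span_len: int  # variant length on the reference
    length_delta: int  # alt allele length minus ref allele length
    augmentation: str = "identity"
    clamped: bool = False

    def __post_init__(self) -> None:
        if len(self.ref_seq) != len(self.alt_seq):
            raise ValueError(
                f"ref/alt length mismatch: {len(self.ref_seq)} vs {len(self.alt_seq)}"
            )


AUGMENTATION_LABELS = ("identity", "shift_plus1", "shift_minus1", "revcomp")


def build_prediction_window(
    variant: SVRecord,
    geometry: PredictorGeometry,
    shift_bp: int = 0,
    chrom_length: int | None = None,
) -> PredictionWindow:
    """Place the prediction window: variant midpoint centred, then shifted.

    Positive ``shift_bp`` moves the window downstream (so the variant sits
    upstream of centre).  Windows running off a contig end are clamped back
    inside with the clamp amount recorded.
    """
    span = geometry.input_span_bp
    if abs(shift_bp) >= span // 2:
        raise ValueError(f"|shift_bp|={abs(shift_bp)} must be < input_span/2")
    if chrom_length is not None and chrom_length < span:
        raise ExclusionError(
            ExclusionReason(
                "OFF_CONTIG",
                f"contig {variant.span.chrom} ({chrom_length} bp) shorter than window ({span} bp)",
            )
        )
    start = variant.span.midpoint - span // 2 + shift_bp
    clamp = 0
    if start < 0:
        clamp = -start
        start = 0
    if chrom_length is not None and start + span > chrom_length:
        clamp = chrom_length - span - start  # negative: pushed upstream
        start = chrom_length - span
    return PredictionWindow(
        span_chrom=variant.span.chrom,
        start=start,
        end=start + span,
        shift_bp=shift_bp,
        variant=variant,
        clamp_bp=clamp,
    )


def _substitute(
    window: PredictionWindow,
    genome: GenomeSource,
    ref_seq: str,
    offset: int,
    ref_len: int,
    replacement: str,
    span: int,
) -> str:
    """Replace ``ref_len`` bp at ``offset`` with ``replacement`` and restore
    the window to ``span`` bp: surplus trimmed evenly from both edges,
    deficit refilled evenly from flanking reference sequence."""
    core = ref_seq[:offset] + replacement + ref_seq[offset + ref_len:]
    delta = len(replacement) - ref_len
    if delta == 0:
        return core
    if delta > 0:  # longer allele: trim evenly back to span
        left = delta // 2
        return core[left: left + span]
    # shorter allele: extend evenly with reference flanks
    need = -delta
    ext_left = need // 2
    ext_right = need - ext_left
    chrom = window.span_chrom
    if window.start - ext_left < 0 or window.end + ext_right > genome.chrom_length(chrom):
        raise ExclusionError(
            ExclusionReason(
                "OFF_CONTIG",
                f"flank extension of {need} bp for {window.variant.id} runs off {chrom}",
            )
        )
    left_flank = genome.fetch(chrom, window.start - ext_left, window.start)
    right_flank = genome.fetch(chrom, window.end, window.end + ext_right)
    return left_flank + core + right_flank


def construct_allele_sequences(window: PredictionWindow, genome: GenomeSource) -> SequencePair:
    """Build the reference/alternate pair for the window's variant.

    DEL: the allele is removed and the window refilled evenly from both
    reference flanks.  DUP: an extra copy of the duplicated sequence is
    inserted immediately 5' of the original and the window trimmed evenly.
    INV: the span is reverse-complemented in place.  CPX: the supplied
    alternate sequence replaces the span, with DEL/DUP-style rebalancing.
    """
    v = window.variant
    span = window.length
    offset = v.span.start - window.start
    if offset < 0 or offset + v.length > span:
        raise ExclusionError(
            ExclusionReason("OFF_CONTIG", f"variant {v.id} not fully inside its window")
        )
    ref_seq = genome.fetch(window.span_chrom, window.start, window.end)

    if v.svtype == "DEL":
        replacement = ""
    elif v.svtype == "DUP":
        dup = ref_seq[offset: offset + v.length]
        replacement = dup + dup
    elif v.svtype == "INV":
        replacement = reverse_complement(ref_seq[offset: offset + v.length])
    elif v.svtype == "CPX":
        replacement = (v.alt_sequence or "").upper()
    else:
        raise ExclusionError(
            ExclusionReason("UNKNOWN_ALT", f"unsupported SV type for {v.id}: {v.raw_type or v.svtype}")
        )

    alt_seq = _substitute(window, genome, ref_seq, offset, v.length, replacement, span)
    return SequencePair(
        ref_seq=ref_seq,
        alt_seq=alt_seq,
        variant_offset=offset,
        ref_span_len=v.length,
        length_delta=len(replacement) - v.length,
        clamped=window.clamped,
    )


def revcomp_pair(pair: SequencePair) -> SequencePair:
    """Reverse-complement both sequences; the variant offset mirrors."""
    span = len(pair.ref_seq)
    return SequencePair(
        ref_seq=reverse_complement(pair.ref_seq),
        alt_seq=reverse_complement(pair.alt_seq),
        variant_offset=span - (pair.variant_offset + pair.ref_span_len),
        ref_span_len=pair.ref_span_len,
        length_delta=pair.length_delta,
        augmentation="revcomp",
        clamped=pair.clamped,
    )


def make_augmentations(
    pair: SequencePair, window: PredictionWindow, genome: GenomeSource
) -> list[SequencePair]:
    """The four scoring augmentations: identity, +-1 bp shift, revcomp.

    At a contig edge where a 1 bp shift is impossible, that augmentation is
    replaced by the identity pair and flagged via ``clamped`` so averaging
    can drop it.
    """
    out = [pair]
    chrom_len = genome.chrom_length(window.span_chrom)
    for delta, label in ((1, "shift_plus1"), (-1, "shift_minus1")):
        sp = None
        if 0 <= window.start + delta and window.end + delta <= chrom_len:
            shifted = PredictionWindow(
                window.span_chrom, window.start + delta, window.end + delta,
                window.shift_bp + delta, window.variant, window.clamp_bp,
            )
            try:
                sp = construct_allele_sequences(shifted, genome)
                sp.augmentation = label
            except ExclusionError:
                sp = None  # e.g. flank refill runs off the contig
        if sp is None:
            sp = SequencePair(
                pair.ref_seq, pair.alt_seq, pair.variant_offset, pair.ref_span_len,
                pair.length_delta, augmentation=label, clamped=True,
            )
        out.append(sp)
    out.append(revcomp_pair(pair))
    return out


def _first_exclusion(
    variant: SVRecord,
    genome: GenomeSource,
    geometry: PredictorGeometry,
    max_abs_len: int,
    max_rel_len: float,
    max_n_frac: float,
) -> ExclusionReason | None:
    if variant.svtype == "UNSUPPORTED":
        return ExclusionReason(
            "UNKNOWN_ALT",
            f"alternate allele sequence unknown for type {variant.raw_type or '?'}",
        )
    if variant.length > max_abs_len:
        return ExclusionReason(
            "TOO_LONG_ABS", f"length {variant.length} > {max_abs_len} bp cap"
        )
    if variant.length > max_rel_len * geometry.input_span_bp:
        return ExclusionReason(
            "TOO_LONG_REL",
            f"length {variant.length} > {max_rel_len:.4g} of input span "
            f"{geometry.input_span_bp}",
        )
    chrom = variant.span.chrom
    if chrom not in genome.chromosomes():
        return ExclusionReason("OFF_CONTIG", f"unknown contig {chrom}")
    chrom_len = genome.chrom_length(chrom)
    try:
        window = build_prediction_window(variant, geometry, 0, chrom_len)
        construct_allele_sequences(window, genome)
    except ExclusionError as exc:
        return exc.reason
    ref = genome.fetch(chrom, window.start, window.end)
    n_frac = ref.count("N") / len(ref)
    if n_frac > max_n_frac:
        return ExclusionReason(
            "N_CONTENT", f"window N fraction {n_frac:.3f} > {max_n_frac}"
        )
    return None


def apply_exclusion_filters(
    variants: list[SVRecord],
    genome: GenomeSource,
    geometry: PredictorGeometry | None = None,
    max_abs_len: int = DEFAULT_MAX_ABS_LEN,
    max_rel_len: float = DEFAULT_MAX_REL_LEN,
    max_n_frac: float = DEFAULT_MAX_N_FRAC,
) -> tuple[list[SVRecord], list[tuple[SVRecord, ExclusionReason]]]:
    """Partition variants into scoreable and excluded-with-reason.

    Checks run in a fixed order (UNKNOWN_ALT, TOO_LONG_ABS, TOO_LONG_REL,
    OFF_CONTIG, N_CONTENT) and the first failure wins, so the reported
    reason is deterministic.
    """
    geometry = geometry or PredictorGeometry()
    kept: list[SVRecord] = []
    excluded: list[tuple[SVRecord, ExclusionReason]] = []
    for v in variants:
        reason = _first_exclusion(v, genome, geometry, max_abs_len, max_rel_len, max_n_frac)
        if reason is None:
            kept.append(v)
        else:
            excluded.append((v, reason))
    return kept, excluded


def write_exclusion_ledger(
    excluded: list[tuple[SVRecord, ExclusionReason]], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("id\tcode\tdetail\n")
        for v, reason in excluded:
            fh.write(f"{v.id}\t{reason.code}\t{reason.detail}\n")
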