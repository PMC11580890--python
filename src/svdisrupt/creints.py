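"""From raw loops to CREints, and from CREints to scored variant pairs.

Loops (paired peak regions) are filtered to intra-chromosomal pairs that fit
the prediction window, merged when redundant within a 10 kb radius, and
restricted to those whose anchors touch the promoter of an expressed gene —
the resulting units are putative cis-regulatory element interactions
(CREints).  Variants are then paired with every CREint they can share a
window with, and the window is shifted so the variant+CREint union span sits
at its centre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .geometry import PredictorGeometry
from .intervals import Interval
from .records import CREint, LoopRecord, SVRecord
from .scoring import ScoreRecord

logger = logging.getLogger(__name__)

DEFAULT_MAX_SPAN = 900_000
DEFAULT_MERGE_RADIUS = 10_000
DEFAULT_PROMOTER_BP = 2_000


def filter_loops(loops: list[LoopRecord], max_span: int = DEFAULT_MAX_SPAN) -> list[LoopRecord]:
    """Keep intra-chromosomal loops whose anchors are closer than ``max_span``."""
    return [
        lp
        for lp in loops
        if not lp.inter_chromosomal and lp.anchor_distance < max_span
    ]


def _near(a: Interval, b: Interval, radius: int) -> bool:
    """Overlapping, or separated by a gap of at most ``radius`` bp."""
    return a.chrom == b.chrom and a.start - radius <= b.end and b.start - radius <= a.end


def _cluster_intervals(items: list[tuple[int, Interval]], radius: int) -> list[list[int]]:
    """Single-linkage clusters of intervals with gap <= radius; returns
    index groups."""
    order = sorted(range(len(items)), key=lambda k: (items[k][1].start, items[k][1].end))
    clusters: list[list[int]] = []
    cur: list[int] = []
    cur_end = None
    for k in order:
        iv = items[k][1]
        if cur and iv.start - cur_end <= radius:
            cur.append(k)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                clusters.append(cur)
            cur = [k]
            cur_end = iv.end
    if cur:
        clusters.append(cur)
    return clusters


def _union(intervals: list[Interval]) -> Interval:
    return Interval(
        intervals[0].chrom,
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
    )


def _merge_pass(loops: list[LoopRecord], radius: int, on_left: bool) -> list[LoopRecord]:
    """One merge pass: among loops sharing one anchor (within ``radius``),
    replace nearby opposite anchors with their union interval."""
    by_chrom: dict[str, list[LoopRecord]] = {}
    for lp in loops:
        by_chrom.setdefault(lp.anchor_left.chrom, []).append(lp)
    out: list[LoopRecord] = []
    for chrom in sorted(by_chrom):
        group_source = by_chrom[chrom]
        shared = [
            (i, lp.anchor_left if on_left else lp.anchor_right)
            for i, lp in enumerate(group_source)
        ]
        for shared_cluster in _cluster_intervals(shared, radius):
            members = [group_source[i] for i in shared_cluster]
            opposite = [
                (k, lp.anchor_right if on_left else lp.anchor_left)
                for k, lp in enumerate(members)
            ]
            for opp_cluster in _cluster_intervals(opposite, radius):
                sub = [members[k] for k in opp_cluster]
                merged_opp = _union(
                    [lp.anchor_right if on_left else lp.anchor_left for lp in sub]
                )
                for lp in sub:
                    if on_left:
                        out.append(
                            LoopRecord(lp.anchor_left, merged_opp, list(lp.source_ids))
                        )
                    else:
                        out.append(
                            LoopRecord(merged_opp, lp.anchor_right, list(lp.source_ids))
                        )
    return _dedupe(out)


def _dedupe(loops: list[LoopRecord]) -> list[LoopRecord]:
    seen: dict[tuple, LoopRecord] = {}
    for lp in loops:
        key = (
            lp.anchor_left.chrom, lp.anchor_left.start, lp.anchor_left.end,
            lp.anchor_right.chrom, lp.anchor_right.start, lp.anchor_right.end,
        )
        if key in seen:
            seen[key].source_ids = sorted(set(seen[key].source_ids) | set(lp.source_ids))
        else:
            seen[key] = LoopRecord(lp.anchor_left, lp.anchor_right, list(lp.source_ids))
    return [seen[k] for k in sorted(seen)]


def merge_redundant_loops(
    loops: list[LoopRecord], radius: int = DEFAULT_MERGE_RADIUS, max_rounds: int = 100
) -> list[LoopRecord]:
    """Group loops within ``radius`` of each other and union their anchors.

    Alternating left/right passes are repeated to a fixed point, so the
    output contains no two loops whose corresponding anchors are both
    within ``radius``; every source anchor is contained in its merged
    anchor.  Idempotent by construction.
    """
    current = _dedupe(loops)
    for _ in range(max_rounds):
        after = _merge_pass(current, radius, on_left=True)
        after = _merge_pass(after, radius, on_left=False)
        if _loop_keys(after) == _loop_keys(current):
            return after
        current = after
    raise RuntimeError(f"loop merging did not converge within {max_rounds} rounds")


def _loop_keys(loops: list[LoopRecord]) -> set[tuple]:
    return {
        (
            lp.anchor_left.chrom, lp.anchor_left.start, lp.anchor_left.end,
            lp.anchor_right.start, lp.anchor_right.end,
        )
        for lp in loops
    }


def promoter_interval(chrom: str, tss: int, strand: str, promoter_bp: int = DEFAULT_PROMOTER_BP) -> Interval:
    """Strand-aware promoter: ``promoter_bp`` immediately upstream of the TSS."""
    if strand == "-":
        return Interval(chrom, tss + 1, tss + 1 + promoter_bp)
    return Interval(chrom, max(0, tss - promoter_bp), max(1, tss))


def filter_promoter_loops(
    loops: list[LoopRecord],
    gene_tss: dict[str, tuple[str, int, str]],
    expression: dict[str, float],
    promoter_bp: int = DEFAULT_PROMOTER_BP,
    min_tpm: float = 0.0,
) -> list[CREint]:
    """Keep loops with >= 1 anchor overlapping the promoter of an expressed
    gene (TPM strictly above ``min_tpm``); record those genes.

    Genes present in the TSS set but absent from the expression table are
    treated as unexpressed and logged.
    """
    promoters: list[tuple[str, Interval]] = []
    for gene, (chrom, tss, strand) in gene_tss.items():
        tpm = expression.get(gene)
        if tpm is None:
            logger.info("gene %s missing from expression table; treated as TPM 0", gene)
            continue
        if tpm > min_tpm:
            promoters.append((gene, promoter_interval(chrom, tss, strand, promoter_bp)))

    out: list[CREint] = []
    for i, lp in enumerate(loops):
        genes = sorted(
            {
                gene
                for gene, prom in promoters
                if prom.overlaps(lp.anchor_left) or prom.overlaps(lp.anchor_right)
            }
        )
        if genes:
            out.append(
                CREint(
                    id=f"creint{i + 1}",
                    anchor_left=lp.anchor_left,
                    anchor_right=lp.anchor_right,
                    promoter_genes=genes,
                    merged_from=max(1, len(lp.source_ids)),
                )
            )
    return out


def creints_without_promoter_filter(loops: list[LoopRecord]) -> list[CREint]:
    """Wrap merged loops as CREints with no promoter restriction (used for
    plotting/reporting, which skips that filter)."""
    return [
        CREint(
            id=f"creint{i + 1}",
            anchor_left=lp.anchor_left,
            anchor_right=lp.anchor_right,
            promoter_genes=[],
            merged_from=max(1, len(lp.source_ids)),
        )
        for i, lp in enumerate(loops)
    ]


@dataclass
class VariantCREintPair:
    """A variant paired with one nearby CREint, plus the centering shift."""

    variant: SVRecord
    creint: CREint
    shift_bp: int
    scores: ScoreRecord | None = None


def pair_variant_creints(
    variants: list[SVRecord],
    creints: list[CREint],
    geometry: PredictorGeometry | None = None,
    max_span: int = DEFAULT_MAX_SPAN,
) -> list[VariantCREintPair]:
    """Pair each variant with every CREint it can share a window with.

    A pair forms iff the union span of (variant, both anchors) is shorter
    than ``max_span`` and the variant overlaps neither anchor.  The shift
    re-centres the window on the union span's midpoint.
    """
    out: list[VariantCREintPair] = []
    for v in variants:
        for c in creints:
            if v.span.chrom != c.anchor_left.chrom:
                continue
            if v.span.overlaps(c.anchor_left) or v.span.overlaps(c.anchor_right):
                continue
            union = v.span.union_span(c.span)
            if len(union) >= max_span:
                continue
            shift = union.midpoint - v.span.midpoint
            out.append(VariantCREintPair(variant=v, creint=c, shift_bp=shift))
    return out


def summarize_variant_scores(pairs: list[VariantCREintPair]) -> dict[str, ScoreRecord]:
    """One score per variant: the maximum of each field across its pairs.

    The CREint contributing the maximum weighted score is recorded in the
    ``reason`` field for traceability.
    """
    by_variant: dict[str, list[VariantCREintPair]] = {}
    for p in pairs:
        if p.scores is None:
            continue
        by_variant.setdefault(p.variant.id, []).append(p)
    out: dict[str, ScoreRecord] = {}
    for vid, vps in by_variant.items():
        rec = ScoreRecord(variant_id=vid, augmentation="max-over-pairs")
        best_creint, best_weighted = None, None
        for p in vps:
            for f in ScoreRecord.SCORE_FIELDS:
                val = getattr(p.scores, f)
                if val is None:
                    continue
                cur = getattr(rec, f)
                if cur is None or val > cur:
                    setattr(rec, f, val)
            w = p.scores.weighted_track_score
            if w is not None and (best_weighted is None or w > best_weighted):
                best_weighted, best_creint = w, p.creint.id
        if best_creint is not None:
            rec.reason = f"weighted max from {best_creint}"
        out[vid] = rec
    return out
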