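"""Map alignment and disruption scoring.

The reference and alternate contact maps live on slightly different
coordinate systems whenever the variant changes sequence length.  Alignment
pads the shorter allele's map with masked bins at the variant and trims both
back to the native bin count, so that every unmasked bin pair corresponds to
similar reference sequence.  Scores are then computed over the comparable
entries only: globally (1 - Spearman, MSE), per bin (the disruption track),
and with region-of-interest weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome import GenomeSource
from .geometry import PredictorGeometry
from .intervals import Interval
from .mutagenesis import PredictionWindow, SequencePair, build_prediction_window, construct_allele_sequences
from .predictor import ContactMap, Predictor
from .records import SVRecord

DEFAULT_ROI_SCALE = 10.0


@dataclass
class AlignedMapPair:
    """Reference/alternate maps on a shared bin frame with a joint mask."""

    ref_map: ContactMap
    alt_map: ContactMap
    joint_mask: np.ndarray  # per-bin: usable in both maps, outside the variant
    variant_bins: tuple[int, int]  # half-open bin range masked for the variant

    @property
    def n_bins(self) -> int:
        return self.ref_map.n_bins


class AlignmentError(ValueError):
    pass


def _insert_masked_bins(cmap: ContactMap, at: int, count: int) -> ContactMap:
    """Insert ``count`` masked rows+columns at bin ``at``."""
    n = cmap.n_bins
    new_n = n + count
    values = np.full((new_n, new_n), np.nan)
    mask = np.zeros(new_n, dtype=bool)
    keep = np.r_[np.arange(at), np.arange(at + count, new_n)]
    values[np.ix_(keep, keep)] = cmap.values
    mask[keep] = cmap.bin_mask
    geom = PredictorGeometry(
        input_span_bp=(new_n + 2 * cmap.geometry.crop_bins_per_side) * cmap.geometry.bin_bp,
        bin_bp=cmap.geometry.bin_bp,
        n_bins=new_n,
        crop_bins_per_side=cmap.geometry.crop_bins_per_side,
    )
    return ContactMap(geom, values, mask, cmap.diagonal_offset)


def _trim(cmap: ContactMap, left: int, n_bins: int, geometry: PredictorGeometry) -> ContactMap:
    sel = np.arange(left, left + n_bins)
    return ContactMap(
        geometry,
        cmap.values[np.ix_(sel, sel)],
        cmap.bin_mask[sel],
        cmap.diagonal_offset,
    )


def align_allele_maps(
    ref_map: ContactMap,
    alt_map: ContactMap,
    pair: SequencePair,
    geometry: PredictorGeometry,
    guard_bins: int = 1,
) -> AlignedMapPair:
    """Pad, trim and mask the two maps onto one comparable bin frame.

    The map of the shorter allele receives ``b`` masked bins inserted at
    the variant bin, with ``b = |length_delta| / bin_bp`` rounded to the
    nearest whole bin, and is trimmed evenly back to ``n_bins``; this keeps
    the residual misalignment of every comparable bin at most half a bin,
    and leaves sub-half-bin length changes unpadded.  Bins overlapping the
    variant span, plus ``guard_bins`` on each side, are masked in both
    maps — partially overlapping bins are not comparable between alleles.
    """
    B, n, crop = geometry.bin_bp, geometry.n_bins, geometry.crop_bp
    delta = pair.length_delta
    b = int(abs(delta) / B + 0.5)
    v_bin = int(np.clip((pair.variant_offset - crop) // B, 0, n))

    ref_aligned, alt_aligned = ref_map, alt_map
    if b > 0:
        left = b // 2
        if delta < 0:  # alternate allele shorter: pad the alt map
            padded = _insert_masked_bins(alt_map, v_bin, b)
            alt_aligned = _trim(padded, left, n, geometry)
        else:  # alternate allele longer: pad the reference map
            padded = _insert_masked_bins(ref_map, v_bin, b)
            ref_aligned = _trim(padded, left, n, geometry)

    # variant-region bins on the shared frame (reference coordinates)
    lo_bin = (pair.variant_offset - crop) // B
    ref_end = pair.variant_offset + max(pair.ref_span_len, pair.ref_span_len + delta)
    hi_bin = (ref_end - 1 - crop) // B
    lo = int(np.clip(lo_bin - guard_bins, 0, n))
    hi = int(np.clip(hi_bin + guard_bins + 1, 0, n))

    joint = ref_aligned.bin_mask & alt_aligned.bin_mask
    joint[lo:hi] = False
    # a bin whose column holds NaN from an unmasked partner is unusable
    offdiag = ref_aligned.offdiag_selector()
    for m in (ref_aligned, alt_aligned):
        bad = np.any(np.isnan(m.values) & offdiag & m.bin_mask[:, None], axis=0)
        joint &= ~bad

    if not joint.any():
        raise AlignmentError("nothing left to compare: variant masks every bin")
    return AlignedMapPair(ref_aligned, alt_aligned, joint, (lo, hi))


@dataclass
class GlobalScores:
    spearman_score: float | None
    mse_score: float | None
    reason: str | None = None


def _comparable_entries(aligned: AlignedMapPair) -> tuple[np.ndarray, np.ndarray]:
    n = aligned.n_bins
    i, j = np.triu_indices(n, k=aligned.ref_map.diagonal_offset)
    ok = aligned.joint_mask[i] & aligned.joint_mask[j]
    x = aligned.ref_map.values[i[ok], j[ok]]
    y = aligned.alt_map.values[i[ok], j[ok]]
    finite = np.isfinite(x) & np.isfinite(y)
    return x[finite], y[finite]


def score_global(aligned: AlignedMapPair) -> GlobalScores:
    """Global disruption: (1 - Spearman rho, MSE) over comparable entries.

    Spearman uses average ranks for ties.  A map that is constant over the
    comparable entries has no defined rank correlation; the score is
    reported missing with the reason rather than silently zeroed.
    """
    x, y = _comparable_entries(aligned)
    if x.size < 3:
        return GlobalScores(None, None, f"only {x.size} comparable entries (< 3)")
    mse = float(np.mean((x - y) ** 2))
    if np.all(x == x[0]) or np.all(y == y[0]):
        return GlobalScores(None, mse, "constant map: Spearman undefined")
    rho = stats.spearmanr(x, y).statistic
    return GlobalScores(float(1.0 - rho), mse, None)


@dataclass
class DisruptionTrack:
    """Per-bin disruption: each bin's map column compared between alleles."""

    values: np.ndarray  # NaN at masked / undefined bins
    metric: str  # "mse" | "spearman"
    mask: np.ndarray  # True where the value is defined

    def __len__(self) -> int:
        return len(self.values)


def disruption_track(aligned: AlignedMapPair, metric: str = "mse") -> DisruptionTrack:
    """Compare each 1-bin-wide map column between alleles.

    For bin ``j`` the vectors ``ref[:, j]`` and ``alt[:, j]`` over unmasked
    partners ``i`` (outside the excluded diagonal bands) are reduced with
    the chosen metric.  Masked bins and bins with fewer than 3 usable
    partners carry NaN.
    """
    if metric not in ("mse", "spearman"):
        raise ValueError(f"unknown track metric {metric!r}")
    n = aligned.n_bins
    ref, alt = aligned.ref_map.values, aligned.alt_map.values
    offdiag = aligned.ref_map.offdiag_selector()
    valid = offdiag & aligned.joint_mask[:, None] & aligned.joint_mask[None, :]
    valid &= np.isfinite(ref) & np.isfinite(alt)

    values = np.full(n, np.nan)
    counts = valid.sum(axis=0)
    if metric == "mse":
        sq = np.where(valid, (ref - alt) ** 2, 0.0)
        with np.errstate(invalid="ignore"):
            values = np.where(counts >= 3, sq.sum(axis=0) / np.maximum(counts, 1), np.nan)
    else:
        for j in range(n):
            sel = valid[:, j]
            if sel.sum() < 3:
                continue
            x, y = ref[sel, j], alt[sel, j]
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            values[j] = 1.0 - stats.spearmanr(x, y).statistic
    values = np.where(aligned.joint_mask, values, np.nan)
    return DisruptionTrack(values=values, metric=metric, mask=np.isfinite(values))


@dataclass
class WeightTrack:
    """Per-bin weights: ``scale`` at ROI-overlapping bins, 1 elsewhere."""

    values: np.ndarray
    scale: float

    def __len__(self) -> int:
        return len(self.values)

    @property
    def roi_bins(self) -> np.ndarray:
        return self.values > 1


def build_weight_track(
    rois: list[Interval],
    window: PredictionWindow,
    geometry: PredictorGeometry,
    scale: float = DEFAULT_ROI_SCALE,
) -> WeightTrack:
    """Weight ``scale`` at every bin overlapping >= 1 bp of any ROI."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    n, B = geometry.n_bins, geometry.bin_bp
    out_start = window.start + geometry.crop_bp
    values = np.ones(n)
    for roi in rois:
        if roi.chrom != window.span_chrom:
            continue
        lo = (roi.start - out_start) // B
        hi = (roi.end - 1 - out_start) // B
        lo, hi = max(lo, 0), min(hi, n - 1)
        if lo <= hi:
            values[lo: hi + 1] = scale
    return WeightTrack(values=values, scale=scale)


class ScoreUndefined(ValueError):
    pass


def weighted_score(
    track: DisruptionTrack,
    weights: WeightTrack | None = None,
    mode: str = "weighted",
    normalize: bool = True,
) -> float:
    """Summarise a disruption track, optionally with ROI weighting.

    ``weighted``: sum(d*w)/sum(w) over defined bins (``normalize=False``
    gives the plain mean of d*w instead); ``roi_only``: mean of d over
    ROI bins only.  With all-ones weights both reduce to the unweighted
    track mean.
    """
    d = track.values
    ok = track.mask
    w = np.ones_like(d) if weights is None else weights.values
    if len(w) != len(d):
        raise ValueError("track and weight lengths differ")
    if mode == "roi_only":
        if weights is None:
            raise ScoreUndefined("roi_only mode requires a weight track")
        sel = ok & (w > 1)
        if not sel.any():
            raise ScoreUndefined("no unmasked ROI bins in window")
        return float(np.mean(d[sel]))
    if mode != "weighted":
        raise ValueError(f"unknown mode {mode!r}")
    if not ok.any():
        raise ScoreUndefined("no defined bins in disruption track")
    num = float(np.sum(d[ok] * w[ok]))
    if normalize:
        return num / float(np.sum(w[ok]))
    return num / int(ok.sum())


@dataclass
class ScoreRecord:
    """Per-variant disruption scores (one augmentation or their average)."""

    variant_id: str
    spearman_score: float | None = None
    mse_score: float | None = None
    unweighted_track_score: float | None = None
    weighted_track_score: float | None = None
    roi_only_score: float | None = None
    augmentation: str = "single"
    reason: str | None = None

    SCORE_FIELDS = (
        "spearman_score",
        "mse_score",
        "unweighted_track_score",
        "weighted_track_score",
        "roi_only_score",
    )


def average_augmented(records: list[ScoreRecord]) -> ScoreRecord:
    """Arithmetic mean of each score field across augmentations.

    When an edge-clamped window removed some augmentations, the mean is
    over the available ones and the tag records how many.
    """
    if not records:
        raise ValueError("no augmentation records to average")
    out = ScoreRecord(variant_id=records[0].variant_id)
    for f in ScoreRecord.SCORE_FIELDS:
        vals = [getattr(r, f) for r in records if getattr(r, f) is not None]
        setattr(out, f, float(np.mean(vals)) if vals else None)
    out.augmentation = f"averaged-of-{len(records)}"
    return out


def score_sequence_pair(
    pair: SequencePair,
    predictor: Predictor,
    geometry: PredictorGeometry,
    window: PredictionWindow | None = None,
    rois: list[Interval] | None = None,
    scale: float = DEFAULT_ROI_SCALE,
    track_metric: str = "mse",
    mirror_weights: bool = False,
) -> ScoreRecord:
    """Predict both alleles, align, and compute every score for one pair.

    ``mirror_weights`` flips the weight track for reverse-complement
    augmentations, whose maps are anti-transposed relative to the genome.
    """
    ref_map = predictor(pair.ref_seq)
    alt_map = predictor(pair.alt_seq)
    rec = ScoreRecord(variant_id="", augmentation=pair.augmentation)
    try:
        aligned = align_allele_maps(ref_map, alt_map, pair, geometry)
    except AlignmentError as exc:
        rec.reason = str(exc)
        return rec
    g = score_global(aligned)
    rec.spearman_score, rec.mse_score, rec.reason = g.spearman_score, g.mse_score, g.reason
    track = disruption_track(aligned, metric=track_metric)
    try:
        rec.unweighted_track_score = weighted_score(track, None, "weighted")
    except ScoreUndefined as exc:
        rec.reason = rec.reason or str(exc)
        return rec
    if rois is not None and window is not None:
        wt = build_weight_track(rois, window, geometry, scale)
        if mirror_weights:
            wt = WeightTrack(values=wt.values[::-1].copy(), scale=wt.scale)
        rec.weighted_track_score = weighted_score(track, wt, "weighted")
        try:
            rec.roi_only_score = weighted_score(track, wt, "roi_only")
        except ScoreUndefined:
            rec.roi_only_score = None
    return rec


def tiled_deletion_scan(
    region: Interval,
    genome: GenomeSource,
    predictor: Predictor,
    geometry: PredictorGeometry,
    scan_cap: int = 5_000,
) -> np.ndarray:
    """Per-position 1 bp deletion disruption profile across a region.

    Each position is scored unaugmented with the window centred on it;
    the global (1 - Spearman) score is reported.  Positions where the
    score is undefined carry NaN.
    """
    if len(region) > scan_cap:
        raise ValueError(f"region of {len(region)} bp exceeds scan cap {scan_cap}")
    chrom_len = genome.chrom_length(region.chrom)
    profile = np.full(len(region), np.nan)
    for k, p in enumerate(range(region.start, region.end)):
        sv = SVRecord(
            id=f"scan_{p}", span=Interval(region.chrom, p, p + 1), svtype="DEL"
        )
        window = build_prediction_window(sv, geometry, 0, chrom_len)
        pair = construct_allele_sequences(window, genome)
        rec = score_sequence_pair(pair, predictor, geometry)
        if rec.spearman_score is not None:
            profile[k] = rec.spearman_score
    return profile
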