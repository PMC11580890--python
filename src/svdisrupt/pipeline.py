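"""End-to-end orchestration: score, pair, prioritize, enrich, cohort, scan.

The in-memory functions do the work; the file-based stage runners wrap them
for the CLI, writing one TSV per stage plus a log of counts so totals
reconcile at every boundary (input = scored + excluded).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .creints import (
    VariantCREintPair,
    creints_without_promoter_filter,
    filter_loops,
    filter_promoter_loops,
    merge_redundant_loops,
    pair_variant_creints,
    summarize_variant_scores,
)
from .genome import FastaGenome, GenomeSource
from .geometry import PredictorGeometry
from .intervals import Interval
from .io import (
    AnnotationBundle,
    ensure_dir,
    read_annotation_inputs,
    read_contact_matrix,
    read_loops_bedpe,
    read_sv_records,
    write_creints_bedpe,
)
from .intervals import IntervalSet
from .mutagenesis import (
    ExclusionError,
    ExclusionReason,
    apply_exclusion_filters,
    build_prediction_window,
    construct_allele_sequences,
    make_augmentations,
    write_exclusion_ledger,
)
from .predictor import Predictor, get_predictor
from .prioritize import (
    CriteriaConfig,
    PrioritizationContext,
    cohort_length_quantile_test,
    criteria_report,
    enrichment_chisq_1mb,
    prediction_quality,
)
from .records import CREint, SVRecord
from .scoring import (
    DEFAULT_ROI_SCALE,
    ScoreRecord,
    average_augmented,
    score_sequence_pair,
    tiled_deletion_scan,
)

logger = logging.getLogger(__name__)


def score_variant(
    variant: SVRecord,
    genome: GenomeSource,
    predictor: Predictor,
    geometry: PredictorGeometry,
    rois: list[Interval] | None = None,
    scale: float = DEFAULT_ROI_SCALE,
    augment: bool = True,
    shift_bp: int = 0,
    track_metric: str = "mse",
) -> ScoreRecord:
    """Score one variant: window, allele pair, (optionally) 4 augmentations,
    averaged.  Edge-clamped augmentations are dropped from the average."""
    chrom_len = genome.chrom_length(variant.span.chrom)
    window = build_prediction_window(variant, geometry, shift_bp, chrom_len)
    pair = construct_allele_sequences(window, genome)
    pairs = make_augmentations(pair, window, genome) if augment else [pair]
    usable = [p for p in pairs if not p.clamped] or [pair]
    recs = []
    for p in usable:
        rec = score_sequence_pair(
            p, predictor, geometry,
            window=window, rois=rois, scale=scale,
            track_metric=track_metric,
            mirror_weights=(p.augmentation == "revcomp"),
        )
        rec.variant_id = variant.id
        recs.append(rec)
    out = average_augmented(recs) if augment else recs[0]
    out.variant_id = variant.id
    return out


def score_cohort(
    variants: list[SVRecord],
    genome: GenomeSource,
    predictor: Predictor,
    geometry: PredictorGeometry | None = None,
    rois: list[Interval] | None = None,
    scale: float = DEFAULT_ROI_SCALE,
    augment: bool = True,
) -> tuple[dict[str, ScoreRecord], list[tuple[SVRecord, ExclusionReason]]]:
    """Exclusion-filter then score every variant (variant-centred windows)."""
    geometry = geometry or PredictorGeometry()
    kept, excluded = apply_exclusion_filters(variants, genome, geometry)
    scores: dict[str, ScoreRecord] = {}
    for v in kept:
        scores[v.id] = score_variant(
            v, genome, predictor, geometry, rois=rois, scale=scale, augment=augment
        )
    logger.info("scored %d variants, excluded %d", len(scores), len(excluded))
    return scores, excluded


def build_creints(
    loops,
    gene_tss: dict[str, tuple[str, int, str]],
    expression: dict[str, float],
    max_span: int = 900_000,
    merge_radius: int = 10_000,
    promoter_bp: int = 2_000,
    min_tpm: float = 0.0,
    promoter_filter: bool = True,
) -> list[CREint]:
    """Loops -> CREints: span filter, redundancy merge, promoter filter."""
    merged = merge_redundant_loops(filter_loops(loops, max_span), merge_radius)
    if not promoter_filter:
        return creints_without_promoter_filter(merged)
    return filter_promoter_loops(merged, gene_tss, expression, promoter_bp, min_tpm)


def score_pairs(
    pairs: list[VariantCREintPair],
    creints: list[CREint],
    genome: GenomeSource,
    predictor: Predictor,
    geometry: PredictorGeometry,
    scale: float = DEFAULT_ROI_SCALE,
    weighting: str = "all",  # "all": every CREint anchor in the window; "paired": only the pair's
    track_metric: str = "mse",
) -> list[VariantCREintPair]:
    """Score each variant-CREint pair on its re-centred window.

    Complex variants are excluded from the weighted analyses (their alt
    sequence handling is bespoke); pairs are scored unaugmented.
    """
    all_anchors = [a for c in creints for a in (c.anchor_left, c.anchor_right)]
    for p in pairs:
        if p.variant.svtype == "CPX":
            continue
        chrom_len = genome.chrom_length(p.variant.span.chrom)
        try:
            window = build_prediction_window(p.variant, geometry, p.shift_bp, chrom_len)
            pair_seq = construct_allele_sequences(window, genome)
        except ExclusionError as exc:
            logger.info("pair %s/%s unscoreable: %s", p.variant.id, p.creint.id, exc)
            continue
        rois = (
            all_anchors
            if weighting == "all"
            else [p.creint.anchor_left, p.creint.anchor_right]
        )
        rec = score_sequence_pair(
            pair_seq, predictor, geometry,
            window=window, rois=rois, scale=scale, track_metric=track_metric,
        )
        rec.variant_id = p.variant.id
        p.scores = rec
    return pairs


def creint_weighted_scores(
    variants: list[SVRecord],
    creints: list[CREint],
    genome: GenomeSource,
    predictor: Predictor,
    geometry: PredictorGeometry | None = None,
    scale: float = DEFAULT_ROI_SCALE,
    max_span: int = 900_000,
    weighting: str = "all",
) -> tuple[list[VariantCREintPair], dict[str, ScoreRecord]]:
    """Pair variants with nearby CREints, score each pair on a re-centred
    window, and summarise to one record per variant (max over pairs)."""
    geometry = geometry or PredictorGeometry()
    pairs = pair_variant_creints(variants, creints, geometry, max_span)
    pairs = score_pairs(pairs, creints, genome, predictor, geometry, scale, weighting)
    return pairs, summarize_variant_scores(pairs)


def scores_to_frame(
    scores: dict[str, ScoreRecord],
    variants: list[SVRecord],
    excluded: list[tuple[SVRecord, ExclusionReason]] | None = None,
) -> pd.DataFrame:
    """Flat score table: one row per variant, exclusions included."""
    by_id = {v.id: v for v in variants}
    reasons = {v.id: r.code for v, r in (excluded or [])}
    rows = []
    for vid, v in by_id.items():
        rec = scores.get(vid)
        rows.append(
            {
                "variant_id": vid,
                "cohort": v.cohort,
                "svtype": v.svtype,
                "length": v.length,
                "spearman_score": rec.spearman_score if rec else np.nan,
                "mse_score": rec.mse_score if rec else np.nan,
                "unweighted": rec.unweighted_track_score if rec else np.nan,
                "weighted": rec.weighted_track_score if rec else np.nan,
                "roi_only": rec.roi_only_score if rec else np.nan,
                "augmentation": rec.augmentation if rec else "",
                "exclusion_code": reasons.get(vid, ""),
            }
        )
    return pd.DataFrame(rows)


# --- file-based stage runners --------------------------------------------


@dataclass
class RunConfig:
    """Paths and knobs for a file-driven pipeline run."""

    genome: str
    variants: str
    outdir: str
    loops: str | None = None
    annotations: dict[str, str] = field(default_factory=dict)  # named BED paths
    expression: str | None = None
    experimental_maps: str | None = None  # dir of <variant_id>.tsv matrices
    predictor: str = "surrogate"
    geometry: dict = field(default_factory=dict)
    scale: float = DEFAULT_ROI_SCALE
    shifts: str = "pair-centered"  # centered | pair-centered
    roi_mode: str = "bedpe"  # bedpe | bed | genes
    roi_bed: str | None = None
    criteria: dict = field(default_factory=dict)
    seed: int = 0
    force: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def make_geometry(self) -> PredictorGeometry:
        return PredictorGeometry(**self.geometry) if self.geometry else PredictorGeometry()


STAGES = ("score", "pair", "prioritize", "enrich", "cohort")
_DEPS = {"pair": ("score",), "prioritize": ("score", "pair"), "cohort": ("score",)}


class StageError(RuntimeError):
    pass


def _out(cfg: RunConfig, name: str) -> str:
    return os.path.join(cfg.outdir, name)


def _fresh(cfg: RunConfig, name: str) -> bool:
    return cfg.force or not os.path.exists(_out(cfg, name))


def _load_inputs(cfg: RunConfig):
    genome = FastaGenome(cfg.genome)
    variants = read_sv_records(cfg.variants)
    return genome, variants


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> str:
    """Run the requested stages in dependency order; existing outputs from
    earlier runs are reused unless ``force`` is set."""
    stages = list(stages or STAGES)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
        for dep in _DEPS.get(s, ()):
            if dep not in stages and not os.path.exists(_out(cfg, _STAGE_OUTPUT[dep])):
                raise StageError(f"stage {s!r} needs {dep!r}: run it first")
    ensure_dir(cfg.outdir)
    ordered = [s for s in STAGES if s in stages]
    counts: dict[str, dict] = {}
    for s in ordered:
        counts[s] = _STAGE_FN[s](cfg)
    with open(_out(cfg, "run_log.json"), "w") as fh:
        json.dump(counts, fh, indent=2, default=str)
    return cfg.outdir


def stage_score(cfg: RunConfig) -> dict:
    if not _fresh(cfg, "scores.tsv"):
        logger.info("scores.tsv exists; reusing")
        return {"reused": True}
    genome, variants = _load_inputs(cfg)
    geometry = cfg.make_geometry()
    predictor = get_predictor(cfg.predictor, geometry)
    scores, excluded = score_cohort(variants, genome, predictor, geometry)
    df = scores_to_frame(scores, variants, excluded)
    df.to_csv(_out(cfg, "scores.tsv"), sep="\t", index=False)
    write_exclusion_ledger(excluded, _out(cfg, "exclusions.tsv"))
    return {"input": len(variants), "scored": len(scores), "excluded": len(excluded)}


def stage_pair(cfg: RunConfig) -> dict:
    if not _fresh(cfg, "creint_scores.tsv"):
        return {"reused": True}
    if cfg.loops is None or cfg.expression is None or "genes" not in cfg.annotations:
        raise StageError("pair stage needs loops, expression and a genes BED")
    genome, variants = _load_inputs(cfg)
    geometry = cfg.make_geometry()
    predictor = get_predictor(cfg.predictor, geometry)
    ann = read_annotation_inputs(cfg.annotations, cfg.expression)
    loops = read_loops_bedpe(cfg.loops)
    creints = build_creints(loops, ann.gene_tss, ann.expression)
    write_creints_bedpe(creints, _out(cfg, "creints.bedpe"))
    kept, _ = apply_exclusion_filters(variants, genome, geometry)
    pairs, summary = creint_weighted_scores(
        kept, creints, genome, predictor, geometry, cfg.scale
    )
    pd.DataFrame(
        [
            {
                "variant_id": p.variant.id,
                "creint_id": p.creint.id,
                "shift_bp": p.shift_bp,
                "weighted": p.scores.weighted_track_score if p.scores else np.nan,
                "roi_only": p.scores.roi_only_score if p.scores else np.nan,
                "unweighted": p.scores.unweighted_track_score if p.scores else np.nan,
            }
            for p in pairs
        ]
    ).to_csv(_out(cfg, "pair_scores.tsv"), sep="\t", index=False)
    scores_to_frame(summary, [v for v in kept if v.id in summary]).to_csv(
        _out(cfg, "creint_scores.tsv"), sep="\t", index=False
    )
    return {"loops": len(loops), "creints": len(creints), "pairs": len(pairs),
            "variants_with_pairs": len(summary)}


def _read_score_records(path: str, fields: dict[str, str]) -> dict[str, ScoreRecord]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, ScoreRecord] = {}
    for row in df.itertuples(index=False):
        rec = ScoreRecord(variant_id=row.variant_id)
        for col, attr in fields.items():
            val = getattr(row, col, np.nan)
            setattr(rec, attr, None if pd.isna(val) else float(val))
        out[row.variant_id] = rec
    return out


def stage_prioritize(cfg: RunConfig) -> dict:
    if not _fresh(cfg, "report.tsv"):
        return {"reused": True}
    genome, variants = _load_inputs(cfg)
    ann = read_annotation_inputs(cfg.annotations, cfg.expression)
    standard = _read_score_records(
        _out(cfg, "scores.tsv"),
        {"spearman_score": "spearman_score", "mse_score": "mse_score",
         "unweighted": "unweighted_track_score"},
    )
    standard = {k: v for k, v in standard.items() if v.spearman_score is not None}
    creint = _read_score_records(
        _out(cfg, "creint_scores.tsv"),
        {"weighted": "weighted_track_score", "roi_only": "roi_only_score",
         "unweighted": "unweighted_track_score"},
    )
    prediction_mse = {}
    if cfg.experimental_maps:
        geometry = cfg.make_geometry()
        predictor = get_predictor(cfg.predictor, geometry)
        by_id = {v.id: v for v in variants}
        for fname in sorted(os.listdir(cfg.experimental_maps)):
            vid = os.path.splitext(fname)[0]
            if vid not in by_id or vid not in standard:
                continue
            v = by_id[vid]
            window = build_prediction_window(
                v, geometry, 0, genome.chrom_length(v.span.chrom)
            )
            ref_map = predictor(construct_allele_sequences(window, genome).ref_seq)
            region = Interval(
                v.span.chrom, window.start + geometry.crop_bp,
                window.start + geometry.crop_bp + geometry.output_span_bp,
            )
            exp = read_contact_matrix(os.path.join(cfg.experimental_maps, fname))
            prediction_mse[vid] = prediction_quality(ref_map, region, exp)
    ctx = PrioritizationContext(
        annotations=ann,
        standard_scores=standard,
        creint_scores=creint,
        all_variants=variants,
        prediction_mse=prediction_mse,
    )
    cfg_criteria = CriteriaConfig(**cfg.criteria) if cfg.criteria else CriteriaConfig()
    scored = [v for v in variants if v.id in standard]
    report = criteria_report(scored, ctx, cfg_criteria)
    report.to_csv(_out(cfg, "report.tsv"), sep="\t", index=False)
    return {"evaluated": len(report)}


def stage_enrich(cfg: RunConfig) -> dict:
    if not _fresh(cfg, "enrichment.tsv"):
        return {"reused": True}
    genome, variants = _load_inputs(cfg)
    ann = read_annotation_inputs(cfg.annotations, cfg.expression)
    loops = read_loops_bedpe(cfg.loops)
    creints = build_creints(loops, ann.gene_tss, ann.expression)
    sizes = {c: genome.chrom_length(c) for c in genome.chromosomes()}
    res = enrichment_chisq_1mb(variants, creints, sizes)
    pd.DataFrame(
        [{
            "chi2": res.chi2, "p": res.p, "odds_ratio": res.odds_ratio,
            "n_bins": res.n_bins,
            "sv_and_cre": res.contingency[0, 0], "sv_only": res.contingency[0, 1],
            "cre_only": res.contingency[1, 0], "neither": res.contingency[1, 1],
            "note": res.reason or "",
        }]
    ).to_csv(_out(cfg, "enrichment.tsv"), sep="\t", index=False)
    return {"n_bins": res.n_bins}


def stage_cohort(cfg: RunConfig) -> dict:
    if not _fresh(cfg, "cohort_tests.tsv"):
        return {"reused": True}
    df = pd.read_csv(_out(cfg, "scores.tsv"), sep="\t")
    df = df.rename(columns={"spearman_score": "score"})
    genome, variants = _load_inputs(cfg)
    ctcf = None
    if "ctcf_peaks" in cfg.annotations:
        from .io import read_bed

        peaks = IntervalSet(read_bed(cfg.annotations["ctcf_peaks"]))
        flags = {v.id: peaks.any_overlap(v.span) for v in variants}
        df["ctcf_overlap"] = df["variant_id"].map(flags)
        ctcf = True
    res = cohort_length_quantile_test(df, by_ctcf=bool(ctcf))
    res.to_csv(_out(cfg, "cohort_tests.tsv"), sep="\t", index=False)
    return {"strata": len(res), "length_cutoffs": res.attrs.get("length_cutoffs")}


_STAGE_OUTPUT = {
    "score": "scores.tsv",
    "pair": "creint_scores.tsv",
    "prioritize": "report.tsv",
    "enrich": "enrichment.tsv",
    "cohort": "cohort_tests.tsv",
}
_STAGE_FN = {
    "score": stage_score,
    "pair": stage_pair,
    "prioritize": stage_prioritize,
    "enrich": stage_enrich,
    "cohort": stage_cohort,
}
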