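"""Variant prioritization: the 12-criterion engine, percentile thresholds,
sibling-similarity exclusion, 1 Mb-bin enrichment, and cohort comparisons.

Seven required criteria pick disruptive variants near (but not on) disease
genes, with trustworthy predictions and no competing explanation elsewhere
in the subject's genome; five optional criteria favour cleanly testable
candidates (e.g. deletions clipping a CTCF site without swallowing it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Interval, IntervalSet
from .io import AnnotationBundle, DenseContactMatrix
from .predictor import ContactMap
from .records import CREint, SVRecord
from .scoring import ScoreRecord


@dataclass(frozen=True)
class CriteriaConfig:
    near_asd_bp: int = 500_000
    mse_pctl: float = 85.0
    score_pctl: float = 65.0
    expressed_tpm: float = 0.5
    sibling_overlap_frac: float = 0.5
    ctcf_overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.mse_pctl, self.score_pctl):
            if not 0 < p < 100:
                raise ValueError("percentiles must be in (0, 100)")
        for f in (self.sibling_overlap_frac, self.ctcf_overlap_frac):
            if not 0 < f <= 1:
                raise ValueError("fractions must be in (0, 1]")


REQUIRED_CRITERIA = (
    "not_on_asd_gene",
    "no_causal_dnsv",
    "good_prediction",
    "no_sibling_dnsv",
    "disrupts_creint",
    "near_asd_gene",
    "disruptive",
)
OPTIONAL_CRITERIA = (
    "not_on_expressed_gene",
    "not_on_exn_re",
    "change_on_creint",
    "on_ctcf",
    "deletion",
)
ALL_CRITERIA = REQUIRED_CRITERIA + OPTIONAL_CRITERIA


@dataclass
class CriterionResult:
    variant_id: str
    criterion: str
    passed: bool | None  # None: unevaluable (missing input), never silently passed
    evidence: str


def compute_percentile_thresholds(scores: list[float], pctl: float) -> float:
    """Linear-interpolation percentile of the finite scores."""
    finite = [s for s in scores if s is not None and np.isfinite(s)]
    if not finite:
        raise ValueError("no finite scores to take a percentile of")
    return float(np.percentile(finite, pctl, method="linear"))


def prediction_quality(
    predicted: "ContactMap",
    predicted_region: Interval,
    experimental: "DenseContactMatrix",
) -> float:
    """MSE between a predicted map and an experimental matrix on the
    predicted bins.

    The experimental matrix (pre-binned, log-scaled) is block-averaged to
    the predicted bin width and cropped to the predicted region; entries on
    jointly valid bins outside the excluded diagonal bands contribute.
    """
    g = predicted.geometry
    e = experimental.bin_bp
    if g.bin_bp % e != 0:
        raise ValueError(f"experimental bin {e} does not divide predicted bin {g.bin_bp}")
    off_bp = predicted_region.start - experimental.region.start
    if off_bp < 0 or off_bp % e != 0:
        raise ValueError("experimental matrix does not cover/align with the predicted region")
    ratio = g.bin_bp // e
    off = off_bp // e
    need = off + g.n_bins * ratio
    if need > experimental.values.shape[0]:
        raise ValueError("experimental matrix too small for the predicted region")
    sub = experimental.values[off:need, off:need]
    # block-average down to the predicted bin width
    reb = np.nanmean(
        sub.reshape(g.n_bins, ratio, g.n_bins, ratio), axis=(1, 3)
    )
    i, j = np.triu_indices(g.n_bins, k=predicted.diagonal_offset)
    ok = predicted.bin_mask[i] & predicted.bin_mask[j]
    x = predicted.values[i[ok], j[ok]]
    y = reb[i[ok], j[ok]]
    fin = np.isfinite(x) & np.isfinite(y)
    if fin.sum() < 3:
        raise ValueError("fewer than 3 jointly valid entries")
    return float(np.mean((x[fin] - y[fin]) ** 2))


def sibling_similarity(
    proband_sv: SVRecord, sibling_svs: list[SVRecord], frac: float = 0.5
) -> bool:
    """True iff some sibling variant reciprocally overlaps the proband
    variant by more than ``frac`` of *both* variant lengths."""
    for s in sibling_svs:
        ov = proband_sv.span.overlap_bp(s.span)
        if ov > frac * proband_sv.length and ov > frac * s.length:
            return True
    return False


@dataclass
class PrioritizationContext:
    """Everything the criteria engine reads: annotations, score tables,
    the full cohort (for subject and sibling lookups), and optional
    prediction-quality MSEs against experimental maps."""

    annotations: AnnotationBundle
    standard_scores: dict[str, ScoreRecord]  # variant-centred global scores
    creint_scores: dict[str, ScoreRecord] = field(default_factory=dict)  # max-over-pairs
    all_variants: list[SVRecord] = field(default_factory=list)
    prediction_mse: dict[str, float] = field(default_factory=dict)

    def score_threshold(self, pctl: float) -> float:
        vals = [r.spearman_score for r in self.standard_scores.values()
                if r.spearman_score is not None]
        return compute_percentile_thresholds(vals, pctl)

    def mse_threshold(self, pctl: float) -> float:
        return compute_percentile_thresholds(list(self.prediction_mse.values()), pctl)


def _expressed_exons(ann: AnnotationBundle, min_tpm: float) -> IntervalSet:
    return IntervalSet(
        [iv for gene, iv in ann.gene_exons if ann.expression.get(gene, 0.0) > min_tpm]
    )


def evaluate_criteria(
    variant: SVRecord,
    context: PrioritizationContext,
    config: CriteriaConfig | None = None,
) -> list[CriterionResult]:
    """Evaluate all 12 criteria for one variant.

    Criteria whose inputs are missing come back with ``passed=None`` and an
    explanatory evidence string.
    """
    cfg = config or CriteriaConfig()
    ann = context.annotations
    span = variant.span
    results: list[CriterionResult] = []

    def add(criterion: str, passed: bool | None, evidence: str) -> None:
        results.append(CriterionResult(variant.id, criterion, passed, evidence))

    # 1. not on an ASD gene exon
    hit = ann.asd_gene_exons.any_overlap(span)
    add("not_on_asd_gene", not hit, "overlaps ASD gene exon" if hit else "no ASD exon overlap")

    # 2. the subject carries no variant on an ASD gene exon
    subject_svs = [v for v in context.all_variants if v.subject_id == variant.subject_id]
    causal = [v.id for v in subject_svs if ann.asd_gene_exons.any_overlap(v.span)]
    add(
        "no_causal_dnsv",
        not causal,
        f"subject variants on ASD exons: {causal}" if causal else "subject has no ASD-exon variant",
    )

    # 3. prediction quality: reference-map MSE below the cohort percentile
    if variant.id in context.prediction_mse and len(context.prediction_mse) >= 2:
        thr = context.mse_threshold(cfg.mse_pctl)
        mse = context.prediction_mse[variant.id]
        add("good_prediction", mse < thr, f"map MSE {mse:.4g} vs P{cfg.mse_pctl:g} {thr:.4g}")
    else:
        add("good_prediction", None, "no experimental map comparison available")

    # 4. no reciprocally similar sibling variant
    siblings = [v for v in context.all_variants if v.cohort == "sibling" and v.id != variant.id]
    similar = sibling_similarity(variant, siblings, cfg.sibling_overlap_frac)
    add("no_sibling_dnsv", not similar,
        "similar sibling variant exists" if similar else "no similar sibling variant")

    # shared score threshold over all standard scores
    try:
        score_thr = context.score_threshold(cfg.score_pctl)
    except ValueError:
        score_thr = None

    # 5. CREint-only score above the standard-score percentile
    roi = context.creint_scores.get(variant.id)
    if roi is None or roi.roi_only_score is None or score_thr is None:
        add("disrupts_creint", None, "no CREint-pair score for this variant")
    else:
        add(
            "disrupts_creint",
            roi.roi_only_score > score_thr,
            f"ROI-only {roi.roi_only_score:.4g} vs P{cfg.score_pctl:g} {score_thr:.4g}",
        )

    # 6. within 500 kb of an ASD gene
    dist = ann.asd_gene_exons.nearest_distance(span)
    if dist is None:
        add("near_asd_gene", False, "no ASD gene on this chromosome")
    else:
        add("near_asd_gene", dist <= cfg.near_asd_bp, f"nearest ASD exon {dist} bp away")

    # 7. globally disruptive
    std = context.standard_scores.get(variant.id)
    if std is None or std.spearman_score is None or score_thr is None:
        add("disruptive", None, "no standard score for this variant")
    else:
        add(
            "disruptive",
            std.spearman_score > score_thr,
            f"score {std.spearman_score:.4g} vs P{cfg.score_pctl:g} {score_thr:.4g}",
        )

    # 8. not on an expressed gene's exon
    expressed = _expressed_exons(ann, cfg.expressed_tpm)
    hit = expressed.any_overlap(span)
    add("not_on_expressed_gene", not hit,
        "overlaps expressed-gene exon" if hit else f"no exon of TPM>{cfg.expressed_tpm} gene")

    # 9. not on a regulatory-element peak
    marks = [("H3K27Ac", ann.h3k27ac), ("H3K4me1", ann.h3k4me1), ("H3K27me3", ann.h3k27me3)]
    on = [name for name, peaks in marks if peaks.any_overlap(span)]
    add("not_on_exn_re", not on, f"overlaps {on}" if on else "no regulatory peak overlap")

    # 10. disruption focused on CREints (weighted beats unweighted)
    cr = context.creint_scores.get(variant.id)
    if cr is None or cr.weighted_track_score is None or cr.unweighted_track_score is None:
        add("change_on_creint", None, "no weighted/unweighted pair scores")
    else:
        add(
            "change_on_creint",
            cr.weighted_track_score > cr.unweighted_track_score,
            f"weighted {cr.weighted_track_score:.4g} vs unweighted {cr.unweighted_track_score:.4g}",
        )

    # 11. clips but does not swallow CTCF sites
    touched = ann.ctcf_peaks.overlapping(span)
    swallowed = [p for p in touched if span.overlap_bp(p) >= cfg.ctcf_overlap_frac * len(p)]
    add(
        "on_ctcf",
        not swallowed,
        f"covers >= {cfg.ctcf_overlap_frac:g} of {len(swallowed)} CTCF peak(s)"
        if swallowed
        else f"touches {len(touched)} CTCF peak(s), none covered >= {cfg.ctcf_overlap_frac:g}",
    )

    # 12. deletions are the most tractable to engineer
    add("deletion", variant.svtype == "DEL", f"svtype {variant.svtype}")

    assert [r.criterion for r in results] == list(ALL_CRITERIA)
    return results


def criteria_report(
    variants: list[SVRecord],
    context: PrioritizationContext,
    config: CriteriaConfig | None = None,
) -> pd.DataFrame:
    """Per-variant criteria table with required/optional pass counts and rank."""
    rows = []
    for v in variants:
        res = {r.criterion: r for r in evaluate_criteria(v, context, config)}
        row: dict = {"variant_id": v.id, "cohort": v.cohort, "svtype": v.svtype}
        for c in ALL_CRITERIA:
            row[c] = res[c].passed
        row["n_required_passed"] = sum(bool(res[c].passed) for c in REQUIRED_CRITERIA)
        row["n_optional_passed"] = sum(bool(res[c].passed) for c in OPTIONAL_CRITERIA)
        std = context.standard_scores.get(v.id)
        row["score"] = std.spearman_score if std else None
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["n_required_passed", "n_optional_passed", "score"],
            ascending=False,
            kind="mergesort",
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass
class EnrichmentResult:
    contingency: np.ndarray  # 2x2: rows SV overlap yes/no, cols CREint yes/no
    chi2: float | None
    p: float | None
    odds_ratio: float | None
    n_bins: int
    reason: str | None = None


def enrichment_chisq_1mb(
    variants: list[SVRecord],
    creints: list[CREint],
    genome_sizes: dict[str, int],
    bin_bp: int = 1_000_000,
) -> EnrichmentResult:
    """Chi-squared association between variant and CREint occupancy of
    fixed genome bins (last partial bin kept; 1 df, no continuity
    correction; odds ratio ad/bc)."""
    sv_set = IntervalSet([v.span for v in variants])
    cre_set = IntervalSet(
        [c.anchor_left for c in creints] + [c.anchor_right for c in creints]
    )
    counts = np.zeros((2, 2), dtype=np.int64)
    n_bins = 0
    for chrom, size in genome_sizes.items():
        for start in range(0, size, bin_bp):
            b = Interval(chrom, start, min(start + bin_bp, size))
            i = 0 if sv_set.any_overlap(b) else 1
            j = 0 if cre_set.any_overlap(b) else 1
            counts[i, j] += 1
            n_bins += 1
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        return EnrichmentResult(counts, None, None, None, n_bins, "zero margin")
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    a, b_, c, d = counts[0, 0], counts[0, 1], counts[1, 0], counts[1, 1]
    odds = float(a * d / (b_ * c)) if b_ * c > 0 else np.inf
    return EnrichmentResult(counts, float(chi2), float(p), odds, n_bins)


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U, normal approximation with tie correction."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def cohort_length_quantile_test(
    table: pd.DataFrame, n_quantiles: int = 4, by_ctcf: bool = False
) -> pd.DataFrame:
    """Proband-vs-sibling score comparisons within pooled length quantiles.

    ``table`` needs columns cohort, length, score (and ctcf_overlap when
    ``by_ctcf``).  Quantile cutoffs are linear-interpolation percentiles of
    the pooled length distribution.  With ``by_ctcf`` the comparison is
    CTCF-overlapping vs not, within each cohort and quantile.
    """
    df = table.dropna(subset=["score"]).copy()
    pct = np.linspace(0, 100, n_quantiles + 1)[1:-1]
    cutoffs = np.percentile(df["length"].to_numpy(float), pct, method="linear")
    df["quantile"] = np.searchsorted(cutoffs, df["length"].to_numpy(float), side="right") + 1

    rows = []

    def run(stratum: str, q: int, a: pd.Series, b: pd.Series, labels: tuple[str, str]) -> None:
        row = {
            "stratum": stratum, "quantile": q,
            "n_" + labels[0]: len(a), "n_" + labels[1]: len(b),
            "U": np.nan, "p": np.nan, "note": "",
        }
        if len(a) < 2 or len(b) < 2:
            row["note"] = "skipped: fewer than 2 per group"
        else:
            row["U"], row["p"] = mann_whitney(a.to_numpy(float), b.to_numpy(float))
        rows.append(row)

    for q in range(1, n_quantiles + 1):
        sub = df[df["quantile"] == q]
        run(
            "proband_vs_sibling", q,
            sub.loc[sub.cohort == "proband", "score"],
            sub.loc[sub.cohort == "sibling", "score"],
            ("proband", "sibling"),
        )
        if by_ctcf:
            for cohort in ("proband", "sibling"):
                cs = sub[sub.cohort == cohort]
                run(
                    f"{cohort}_ctcf_vs_not", q,
                    cs.loc[cs.ctcf_overlap.astype(bool), "score"],
                    cs.loc[~cs.ctcf_overlap.astype(bool), "score"],
                    ("ctcf", "noctcf"),
                )
    out = pd.DataFrame(rows)
    out.attrs["length_cutoffs"] = list(map(float, cutoffs))
    return out
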