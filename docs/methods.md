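# Methods

This note documents the models, parameters and design choices behind
svdisrupt: what each stage computes, which knobs matter, what the synthetic
data generator does and does not emulate, and where the design was genuinely
open.

## Coordinates and geometry

All coordinates are 0-based half-open internally; VCF's 1-based positions
are converted at the file boundary and nowhere else. The predictor geometry
is parameterised by four mutually constrained quantities:

    input_span_bp = (n_bins + 2 * crop_bins_per_side) * bin_bp

with defaults 1,048,576 = (448 + 64) × 2,048, i.e. the predictor reads a
~1 Mb window and emits a 448-bin map over the central 917,504 bp. The crop
of 32 bins per side is a geometry default, overridable for models with a
different receptive-field margin. A miniature geometry (64 bp in, 8 × 4 bp
bins out) backs the unit tests so expected sequences and masks can be
written out by hand.

## Allele construction

Windows are centred on the variant midpoint and may be shifted (positive =
downstream). The alternate sequence is built per SV type and always restored
to exactly `input_span_bp`:

- **DEL** — the span is removed and the window refilled from the two
  reference flanks, the deficit split evenly (`len//2` left, remainder
  right). The even split keeps the variant midpoint centred; the split
  itself is a design choice, any fixed convention would do.
- **DUP** — treated as an insertion of the duplicated sequence immediately
  5′ of the original copy; the surplus is trimmed evenly from both window
  edges.
- **INV** — the span is reverse-complemented in place (no length change).
- **CPX** — a caller-supplied alternate sequence replaces the span, with
  DEL/DUP-style rebalancing depending on the sign of the length change.
  Complex variants are excluded from the CREint-weighted analyses, whose
  windows are built by the standard path only.

Exclusion filters run in a fixed order so the reported reason is
deterministic: UNKNOWN_ALT (insertion/translocation calls whose alternate
sequence is unknown), TOO_LONG_ABS (> 700 kb), TOO_LONG_REL (> ⅔ of the
input span), OFF_CONTIG (window or flank refill cannot fit on the contig),
N_CONTENT (> 5% N in the reference window). There is no minimum-length
filter by default (1 bp deletions are legitimate inputs for the tiled scan).

Four augmentations are scored and averaged: identity, window shifted ±1 bp,
and the reverse complement of both sequences. At a contig edge where a
shift (or its flank refill) is impossible, that augmentation falls back to
a flagged copy of the identity pair and is dropped from the average, which
is then tagged `averaged-of-N`.

## The surrogate predictor

The trained contact-map network is out of scope by design; the package
defines the predictor contract (fixed-length ACGTN sequence → symmetric
log-O/E map with per-bin validity) and ships a deterministic surrogate:

    value(i, j) = -alpha * log(|i - j| + 1) - sigma * B(i, j)

where `B(i, j)` counts occurrences of a fixed 19-bp boundary motif (a
CTCF-like core consensus, searched on both strands) in bins strictly
between `i` and `j`. Defaults: `alpha = 0.25`, `sigma = 1.0`, frozen so
derived test expectations stay stable. The surrogate reproduces the three
properties the pipeline relies on: distance decay, block insulation at
boundaries (deleting a motif merges two domains), and exact
anti-transposition under reverse complement — the equivariance that makes
augmentation averaging meaningful. Motifs are assigned to bins by their
centre, which makes the equivariance exact rather than approximate. It is
a caricature of a learned model: no A/B compartments, no loop dots, no
sequence features beyond the single motif — results on synthetic data
demonstrate pipeline correctness, not biological realism. Real predictors
register under a name in the predictor registry and are selected by
configuration.

## Map alignment and scoring

When the variant changes sequence length, the two maps cover slightly
different reference spans. Alignment inserts `b` masked bins at the variant
position into the shorter allele's map, with `b = |Δ| / bin_bp` rounded to
the nearest whole bin, then trims both maps evenly back to `n_bins`. The
rounding (rather than ceiling) keeps the residual per-bin misalignment at
most half a bin and leaves sub-half-bin length changes unpadded — with a
ceiling, a 1 bp deletion would shift every downstream bin by a nearly full
bin and a motif-free tiled-scan profile would not be zero. Bins overlapping
the variant, plus one guard bin on each side, are masked in both maps:
bins partially covering the variant are not comparable between alleles.
Two near-diagonal bands are additionally excluded from every comparison
(`diagonal_offset = 2`), the standard treatment for this map type.

Global scores over the comparable upper-triangle entries:

- `spearman_score = 1 - ρ` with average ranks for ties (range [0, 2]);
  reported missing (with the reason) when either map is constant over the
  comparable entries, never silently zeroed;
- `mse_score` — the mean squared difference.

The per-bin disruption track compares each 1-bin-wide map column between
alleles over its unmasked partners; the default per-column metric is MSE,
which stays defined when a column is nearly constant, with 1 − ρ per column
available. Which metric produced the published per-bin tracks is not
stated in the source work; MSE is this package's default. Masked bins and
columns with fewer than 3 usable partners carry NaN, excluded from all
means.

Weighting: bins overlapping ≥ 1 bp of any region of interest get weight
`scale` (default 10), the rest 1. The weighted score is the *normalized*
weighted mean Σ(d·w)/Σ(w). The unnormalized form mean(d·w) is available
behind `normalize=False`; the normalized form is the default because it is
the one that equals the unweighted mean when disruption is uniform across
ROI and non-ROI bins, which is the behaviour the method advertises. The
ROI-only score is the plain mean of the track over ROI bins.

The tiled deletion scan scores an unaugmented 1 bp deletion at every
position of a region, window re-centred per position; augmentation is
orthogonal to the scan's purpose and quadruples its cost, so it is off.

## CREints: loops → regions of interest

1. **Span filter** — intra-chromosomal loops with anchor distance
   (inner edge to inner edge) under 900 kb, so both anchors fit one
   917 kb output window. Distance could also be measured
   midpoint-to-midpoint; inner-edge is this package's convention.
2. **Redundancy merge** — loops within 10 kb are grouped: among loops
   sharing a left anchor (gap ≤ 10 kb counts as shared), right anchors
   within 10 kb are replaced by their union; then symmetrically for left
   anchors; passes repeat to a fixed point. The result is idempotent and
   every source anchor is contained in its merged anchor.
3. **Promoter filter** — keep loops where ≥ 1 anchor overlaps the promoter
   — the 2 kb immediately upstream of the TSS, strand-aware — of a gene
   with TPM strictly above 0 (threshold configurable). Genes missing from
   the expression table count as unexpressed and are logged. The separate
   `genes` ROI mode uses a 2 kb window *centred* on each TSS instead.
   CREints produced for plotting/reporting skip the promoter filter.

Variants pair with every CREint where the union span of variant and both
anchors is under 900 kb and the variant overlaps neither anchor. The window
shift re-centres on the union-span midpoint, placing it within half a bin
of the window centre. Pair windows are weighted with *all* CREint anchors
in the window by default ("paired-only" mode is available; in the source
study both gave the same trends). Pairs are scored unaugmented — the
augmentation average is a refinement of the per-variant headline score, and
the pair stage's max-over-pairs summarisation would otherwise multiply the
predictor cost by four for little ranking change. Per-variant summaries
take the maximum of each score field across pairs, recording the CREint
contributing the weighted maximum.

## Prioritization

Twelve criteria, seven required and five optional, each with a pass/fail
and a human-readable evidence string; criteria whose inputs are missing are
marked unevaluable (`None`), never silently passed. Thresholds
(configurable): 85th percentile for the prediction-quality MSE, 65th for
the disruption-score criteria, 500 kb proximity to a disease gene,
TPM > 0.5 for "expressed", reciprocal half-overlap for sibling similarity,
half-of-peak for the CTCF clip rule. Notes on interpretation:

- "standard scores" for the CREint-disruption percentile are the unweighted
  global (1 − ρ) scores of all scored variants, over both cohorts (whether
  the original computed them over probands only is not stated; both cohorts
  is the choice here).
- the CTCF criterion is read as "the variant clips but does not swallow a
  CTCF site": every touched peak must be overlapped over less than half its
  length, vacuously true when no peak is touched.
- prediction quality compares the reference-allele prediction with an
  experimental matrix block-averaged onto the predicted bins; both must be
  log-scaled and pre-normalized (matrix balancing is out of scope).
- the final qualitative selection (visual inspection of maps) is out of
  scope; the engine emits the ranked report.

The enrichment test tiles the genome into 1 Mb bins (last partial bin
kept), marks each bin for variant and CREint occupancy, and applies a 1-df
Pearson chi-squared without continuity correction (odds ratio ad/bc).
Cohort comparisons use the two-sided Mann-Whitney U with normal
approximation and tie correction, within pooled length quantiles (cutoffs
by linear-interpolation percentiles over both cohorts, since single cutoffs
are reported) and optionally stratified by CTCF-peak overlap; strata with
fewer than two observations in either group are skipped with a reason.
Whether the original rank tests were one- or two-sided is not stated;
two-sided is the conservative choice used throughout.

## Synthetic data

The generator produces, deterministically per seed (NumPy `default_rng`
with fixed sub-seeds per component): a uniform-random genome with the
surrogate's boundary motif planted at recorded positions on random strands
(≥ 50 kb apart, ≥ 700 kb from contig ends); two SV cohorts; loops whose
left anchors sit 2–20 kb from a boundary with gaps of 100–750 kb (always
inside the 900 kb limit); genes, a configurable fraction of which have
promoters on left anchors and are always expressed; exon structures; CTCF
peaks at motif ± 200 bp; random histone-mark peaks; and a log-normal
expression table with a configurable zero fraction.

Default scale: 2 × 4 Mb chromosomes, 12 motifs per chromosome, 40 variants
per cohort with type mix DEL 0.55 / DUP 0.15 / INV 0.20 / CPX 0.10 and
log-uniform lengths of 50 bp – 50 kb, 30 loops, 60 genes. These sizes keep
the full suite and the acceptance run in tens of seconds on one CPU while
leaving every stage non-trivial. The cohort asymmetry is the study design
in miniature: 80% of "proband" variants are placed across a planted
boundary motif while "sibling" variants are uniform, so proband scores
stochastically dominate under the surrogate. An `exclusion_showcase`
preset adds one variant per exclusion code (an insertion call, a > 700 kb
deletion, a deletion between ⅔-window and 700 kb, a variant on a 10 kb
contig, and a variant inside an 80 kb N run).

What the fixtures do *not* emulate: real sequence composition, empirical SV
length spectra, loop-strength heterogeneity, cell-type specificity, or any
learned sequence grammar beyond the single boundary motif. Passing tests
demonstrate that the machinery — windowing, allele construction, alignment,
masking, weighting, merging, pairing, statistics — is correct, not that the
surrogate predicts real chromatin.

## Numerical choices and degenerate inputs

- Spearman ties take average ranks; masked/NaN entries are excluded
  pairwise; fewer than 3 comparable entries, or a constant map, yields a
  missing score with a reason.
- Percentiles use linear interpolation.
- The chi-squared test reports missing on a zero margin.
- Weighted scores over an all-masked track, and ROI-only scores in windows
  without unmasked ROI bins, raise a typed `ScoreUndefined` rather than
  returning a number.
- Edge-clamped windows are permitted but flagged; impossible ±1 bp
  augmentations fall back to the identity pair and are excluded from the
  average.
- Loop merging is capped at 100 rounds and asserts convergence (in practice
  it converges in ≤ 3).

## The acceptance script

`scripts/acceptance.py --seed S --out F` regenerates everything from the
seed and recomputes: predictor geometry identities from an actual
prediction; the 80-variant cohort run with its rank-sum p-value and mean
scores; CREint counts, pair counts and the fraction of variants whose
weighted score exceeds the unweighted; the 1 Mb enrichment chi-squared; the
criteria report (with synthetic experimental maps — reference predictions
plus symmetric Gaussian noise, σ = 0.1 — standing in for real Hi-C so the
prediction-quality criterion is exercised); and the tiled-scan peak
distance from a planted motif centre. Every reported number is computed at
run time; nothing is hard-coded.

## Known limitations

- The surrogate's insulation model is additive in the number of intervening
  boundaries; real maps saturate.
- Sub-bin misalignment after padding (≤ half a bin) injects a small score
  floor for length-changing variants near boundaries.
- The merge step's "shared anchor" relation is single-linkage within a
  pass, so long chains of anchors can merge into wide anchors on dense
  loop sets.
- BND/translocation algebra, multi-allelic records and phased alleles are
  out of scope; such calls load as UNSUPPORTED and are ledgered, not
  scored.
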