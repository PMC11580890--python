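"""Map alignment, global and per-bin disruption scores, ROI weighting,
augmentation averaging, tiled deletion scans."""

from __future__ import annotations

import numpy as np
import pytest

from svdisrupt.genome import DictGenome
from svdisrupt.geometry import PredictorGeometry
from svdisrupt.intervals import Interval
from svdisrupt.mutagenesis import (
    PredictionWindow,
    SequencePair,
    build_prediction_window,
    construct_allele_sequences,
)
from svdisrupt.pipeline import score_variant
from svdisrupt.predictor import ContactMap, SurrogatePredictor
from svdisrupt.records import SVRecord
from svdisrupt.scoring import (
    AlignedMapPair,
    AlignmentError,
    ScoreRecord,
    ScoreUndefined,
    WeightTrack,
    align_allele_maps,
    average_augmented,
    build_weight_track,
    disruption_track,
    score_global,
    tiled_deletion_scan,
    weighted_score,
)


# --- independent oracles ---------------------------------------------------


def rank_average_ties(x: np.ndarray) -> np.ndarray:
    """Average ranks, written independently of scipy."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = rank_average_ties(x), rank_average_ties(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def make_geometry(n_bins: int, crop: int = 1, bin_bp: int = 4) -> PredictorGeometry:
    return PredictorGeometry(
        input_span_bp=(n_bins + 2 * crop) * bin_bp,
        bin_bp=bin_bp,
        n_bins=n_bins,
        crop_bins_per_side=crop,
    )


def make_aligned(
    ref: np.ndarray,
    alt: np.ndarray,
    diagonal_offset: int = 2,
    joint_mask: np.ndarray | None = None,
) -> AlignedMapPair:
    n = ref.shape[0]
    g = make_geometry(n)
    mask = np.ones(n, dtype=bool)
    rm = ContactMap(g, ref, mask.copy(), diagonal_offset)
    am = ContactMap(g, alt, mask.copy(), diagonal_offset)
    jm = np.ones(n, dtype=bool) if joint_mask is None else joint_mask
    return AlignedMapPair(rm, am, jm, (0, 0))


def sym(rng: np.random.Generator, n: int) -> np.ndarray:
    m = rng.normal(size=(n, n))
    return (m + m.T) / 2


class TestAlignment:
    def test_inversion_masks_variant_bins_plus_guard_without_padding(self, toy_geometry):
        # toy output bins cover window offsets [16, 48); bins 2-3 = [24, 32)
        pair = SequencePair(
            ref_seq="A" * 64, alt_seq="A" * 64,
            variant_offset=24, ref_span_len=8, length_delta=0,
        )
        pred = SurrogatePredictor(toy_geometry)
        m = pred(pair.ref_seq)
        aligned = align_allele_maps(m, m.copy(), pair, toy_geometry)
        assert list(np.nonzero(~aligned.joint_mask)[0]) == [1, 2, 3, 4]
        assert aligned.ref_map.n_bins == aligned.alt_map.n_bins == 8

    def test_del_of_two_bins_inserts_two_masked_columns(self, full_geometry):
        pred = SurrogatePredictor(full_geometry)
        seq = "A" * full_geometry.input_span_bp
        m = pred(seq)
        pair = SequencePair(
            ref_seq=seq, alt_seq=seq,
            variant_offset=524_288, ref_span_len=4_096, length_delta=-4_096,
        )
        aligned = align_allele_maps(m, m.copy(), pair, full_geometry)
        # alternate map carries exactly b=2 inserted (masked) bins
        assert int((~aligned.alt_map.bin_mask).sum()) == 2
        assert int((~aligned.ref_map.bin_mask).sum()) == 0
        assert aligned.alt_map.values.shape == (448, 448)

    def test_sub_half_bin_delta_is_not_padded(self, full_geometry):
        pred = SurrogatePredictor(full_geometry)
        seq = "A" * full_geometry.input_span_bp
        m = pred(seq)
        pair = SequencePair(
            ref_seq=seq, alt_seq=seq,
            variant_offset=524_288, ref_span_len=1, length_delta=-1,
        )
        aligned = align_allele_maps(m, m.copy(), pair, full_geometry)
        assert aligned.alt_map.bin_mask.all()

    def test_identical_maps_with_small_mask_compare_equal(self, toy_geometry):
        pair = SequencePair("A" * 64, "A" * 64, 24, 4, 0)
        pred = SurrogatePredictor(toy_geometry)
        m = pred(pair.ref_seq)
        aligned = align_allele_maps(m, m.copy(), pair, toy_geometry)
        g = score_global(aligned)
        assert g.spearman_score == 0 and g.mse_score == 0

    def test_variant_covering_everything_is_an_error(self, toy_geometry):
        pair = SequencePair("A" * 64, "A" * 64, 0, 64, 0)
        pred = SurrogatePredictor(toy_geometry)
        m = pred(pair.ref_seq)
        with pytest.raises(AlignmentError, match="nothing left"):
            align_allele_maps(m, m.copy(), pair, toy_geometry)


class TestGlobalScores:
    def test_identical_maps_score_zero(self):
        rng = np.random.default_rng(0)
        m = sym(rng, 10)
        g = score_global(make_aligned(m, m.copy()))
        assert g.spearman_score == 0 and g.mse_score == 0

    def test_monotone_transform_preserves_ranks(self):
        rng = np.random.default_rng(1)
        m = sym(rng, 10)
        g = score_global(make_aligned(m, 2 * m + 1))
        assert g.spearman_score == pytest.approx(0, abs=1e-12)
        assert g.mse_score > 0

    def test_reversed_three_entry_map_scores_two(self):
        # 3 bins, diagonal_offset 1: comparable entries (0,1), (0,2), (1,2)
        ref = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        alt = np.array([[0, 3, 2], [3, 0, 1], [2, 1, 0]], dtype=float)
        g = make_geometry(3, crop=0)
        aligned = AlignedMapPair(
            ContactMap(g, ref, np.ones(3, bool), 1),
            ContactMap(g, alt, np.ones(3, bool), 1),
            np.ones(3, bool),
            (0, 0),
        )
        got = score_global(aligned)
        assert got.spearman_score == pytest.approx(2.0)
        assert got.mse_score == pytest.approx(8 / 3)

    def test_constant_map_reported_missing_not_zero(self):
        ref = np.zeros((6, 6))
        alt = sym(np.random.default_rng(2), 6)
        g = score_global(make_aligned(ref, alt))
        assert g.spearman_score is None and "constant" in g.reason
        assert g.mse_score is not None

    def test_matches_brute_force_rank_correlation_oracle(self):
        """100 random instances on <= 12-bin maps with random joint masks."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(6, 13))
            ref, alt = sym(rng, n), sym(rng, n)
            jm = rng.random(n) > 0.2
            aligned = make_aligned(ref, alt, joint_mask=jm)
            # oracle gathers entries with its own loop
            xs, ys = [], []
            for i in range(n):
                for j in range(i + 2, n):
                    if jm[i] and jm[j]:
                        xs.append(ref[i, j])
                        ys.append(alt[i, j])
            if len(xs) < 3:
                continue
            expect_rho = spearman_oracle(np.array(xs), np.array(ys))
            expect_mse = float(np.mean((np.array(xs) - np.array(ys)) ** 2))
            got = score_global(aligned)
            assert got.spearman_score == pytest.approx(1 - expect_rho, abs=1e-10)
            assert got.mse_score == pytest.approx(expect_mse, abs=1e-12)

    def test_mask_independence_scrambling_masked_bins_changes_nothing(self):
        rng = np.random.default_rng(8)
        n = 12
        ref, alt = sym(rng, n), sym(rng, n)
        jm = np.ones(n, bool)
        jm[[3, 7]] = False
        before = score_global(make_aligned(ref, alt, joint_mask=jm))
        ref2, alt2 = ref.copy(), alt.copy()
        for m2 in (ref2, alt2):
            m2[3, :] = rng.normal(size=n)
            m2[:, 3] = m2[3, :]
            m2[7, :] = rng.normal(size=n)
            m2[:, 7] = m2[7, :]
        after = score_global(make_aligned(ref2, alt2, joint_mask=jm))
        assert after.spearman_score == before.spearman_score
        assert after.mse_score == before.mse_score


class TestDisruptionTrack:
    def test_identical_maps_give_zero_track(self):
        m = sym(np.random.default_rng(3), 10)
        track = disruption_track(make_aligned(m, m.copy()), metric="mse")
        assert np.all(track.values[track.mask] == 0)

    def test_single_bin_perturbation_peaks_at_that_bin(self):
        rng = np.random.default_rng(4)
        ref = sym(rng, 8)
        alt = ref.copy()
        alt[5, :] += 3.0
        alt[:, 5] = alt[5, :]
        alt[5, 5] = ref[5, 5]
        track = disruption_track(make_aligned(ref, alt), metric="mse")
        assert np.nanargmax(track.values) == 5

    def test_track_length_is_bin_count(self, full_geometry, surrogate_full):
        seq = "A" * full_geometry.input_span_bp
        m = surrogate_full(seq)
        pair = SequencePair(seq, seq, 524_288, 100, 0)
        aligned = align_allele_maps(m, m.copy(), pair, full_geometry)
        assert len(disruption_track(aligned)) == 448

    def test_spearman_metric_track(self):
        rng = np.random.default_rng(5)
        ref = sym(rng, 10)
        track = disruption_track(make_aligned(ref, 3 * ref + 1), metric="spearman")
        assert np.allclose(track.values[track.mask], 0, atol=1e-12)


def make_window(chrom: str = "chrW", start: int = 0, geometry=None) -> PredictionWindow:
    g = geometry or PredictorGeometry()
    v = SVRecord("w", Interval(chrom, start + g.input_span_bp // 2 - 1,
                               start + g.input_span_bp // 2 + 1), "DEL")
    return PredictionWindow(chrom, start, start + g.input_span_bp, 0, v)


class TestWeighting:
    def test_empty_roi_list_gives_all_ones(self, full_geometry):
        wt = build_weight_track([], make_window(), full_geometry, 10)
        assert np.all(wt.values == 1)

    def test_roi_covering_one_bin_scales_exactly_that_bin(self, full_geometry):
        w = make_window()
        out_start = w.start + full_geometry.crop_bp
        roi = Interval("chrW", out_start + 100 * 2048, out_start + 101 * 2048)
        wt = build_weight_track([roi], w, full_geometry, 10)
        assert wt.values[100] == 10 and np.sum(wt.values > 1) == 1

    def test_one_bp_straddle_scales_both_bins(self, full_geometry):
        w = make_window()
        out_start = w.start + full_geometry.crop_bp
        edge = out_start + 101 * 2048
        roi = Interval("chrW", edge - 1, edge + 1)
        wt = build_weight_track([roi], w, full_geometry, 10)
        assert wt.values[100] == 10 and wt.values[101] == 10
        assert np.sum(wt.values > 1) == 2

    def _track(self, n=448):
        from svdisrupt.scoring import DisruptionTrack

        d = np.zeros(n)
        d[100] = d[101] = 0.4
        return DisruptionTrack(values=d, metric="mse", mask=np.ones(n, bool))

    def _weights(self, n=448, scale=10.0):
        v = np.ones(n)
        v[100:102] = scale
        return WeightTrack(values=v, scale=scale)

    def test_hand_derived_weighted_mean(self):
        track, weights = self._track(), self._weights()
        assert weighted_score(track, weights, "weighted") == pytest.approx(8 / 466)
        assert weighted_score(track, None, "weighted") == pytest.approx(0.8 / 448)
        assert weighted_score(track, weights, "roi_only") == pytest.approx(0.4)

    def test_uniform_track_is_invariant_to_weights(self):
        from svdisrupt.scoring import DisruptionTrack

        d = DisruptionTrack(np.full(448, 0.1), "mse", np.ones(448, bool))
        assert weighted_score(d, self._weights(), "weighted") == pytest.approx(0.1)

    def test_scale_one_and_full_coverage_reduce_to_unweighted(self):
        track = self._track()
        unw = weighted_score(track, None, "weighted")
        assert weighted_score(track, self._weights(scale=1.0 + 1e-12), "weighted") == pytest.approx(unw)
        full = WeightTrack(values=np.full(448, 10.0), scale=10.0)
        assert weighted_score(track, full, "weighted") == pytest.approx(unw)

    def test_direction_more_roi_disruption_raises_weighted_above_unweighted(self):
        from svdisrupt.scoring import DisruptionTrack

        rng = np.random.default_rng(6)
        base = rng.uniform(0.05, 0.15, 448)
        weights = self._weights()
        for bump, expect_up in ((+0.3, True), (-0.04, False)):
            d = base.copy()
            d[100:102] += bump
            track = DisruptionTrack(d, "mse", np.ones(448, bool))
            w = weighted_score(track, weights, "weighted")
            u = weighted_score(track, None, "weighted")
            assert (w > u) == expect_up

    def test_literal_unnormalized_form_available(self):
        track, weights = self._track(), self._weights()
        literal = weighted_score(track, weights, "weighted", normalize=False)
        assert literal == pytest.approx(8 / 448)

    def test_roi_only_without_roi_bins_is_undefined(self):
        track = self._track()
        w = WeightTrack(values=np.ones(448), scale=10.0)
        with pytest.raises(ScoreUndefined):
            weighted_score(track, w, "roi_only")


class TestAugmentedAverage:
    def _rec(self, s):
        return ScoreRecord("v", spearman_score=s, mse_score=s)

    def test_mean_of_four(self):
        out = average_augmented([self._rec(x) for x in (0.1, 0.2, 0.3, 0.4)])
        assert out.spearman_score == pytest.approx(0.25)
        assert out.augmentation == "averaged-of-4"

    def test_identical_records_average_to_same(self):
        out = average_augmented([self._rec(0.2)] * 4)
        assert out.spearman_score == pytest.approx(0.2)

    def test_three_available_tagged_accordingly(self):
        out = average_augmented([self._rec(x) for x in (0.1, 0.2, 0.3)])
        assert out.augmentation == "averaged-of-3"
        assert out.spearman_score == pytest.approx(0.2)


class TestIdentityNull:
    @pytest.mark.parametrize("svtype,alt", [
        ("DEL", None),
        ("DUP", None),
        ("INV", None),
        ("CPX", "AT" * 4),   # same length substitution
        ("CPX", "AT" * 2),   # shorter substitution
    ])
    def test_alt_equal_ref_scores_zero_for_every_sv_type(
        self, at_genome, full_geometry, surrogate_full, svtype, alt
    ):
        """On a strictly periodic genome, even-offset even-length edits of
        any type reproduce the reference, so every score must be zero."""
        v = SVRecord("v", Interval("chrA", 1_200_000, 1_200_008), svtype,
                     alt_sequence=alt)
        rec = score_variant(v, at_genome, surrogate_full, full_geometry, augment=False)
        assert rec.spearman_score == 0
        assert rec.mse_score == 0
        assert rec.unweighted_track_score == 0

    def test_augmented_identity_null_is_also_zero(
        self, at_genome, full_geometry, surrogate_full
    ):
        v = SVRecord("v", Interval("chrA", 1_200_000, 1_200_008), "DEL")
        rec = score_variant(v, at_genome, surrogate_full, full_geometry, augment=True)
        assert rec.spearman_score == 0 and rec.mse_score == 0
        assert rec.augmentation == "averaged-of-4"


class TestTiledScan:
    def test_profile_length_matches_region(self, motif_genome, full_geometry, surrogate_full):
        genome, pos = motif_genome
        profile = tiled_deletion_scan(
            Interval("chrM", pos - 210, pos - 190), genome, surrogate_full, full_geometry
        )
        assert len(profile) == 20

    def test_scan_cap_enforced(self, motif_genome, full_geometry, surrogate_full):
        genome, _ = motif_genome
        with pytest.raises(ValueError, match="cap"):
            tiled_deletion_scan(
                Interval("chrM", 0, 10_000), genome, surrogate_full, full_geometry,
                scan_cap=5_000,
            )
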