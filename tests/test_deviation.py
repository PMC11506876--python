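import numpy as np
import pytest
from scipy.stats import pearsonr

from redfas.deviation import (
    DeviationTrack,
    call_redfas,
    classify_redfas,
    deviation_track,
    gc_correct,
    nearest_rank_quantile,
    pairwise_peculiarity,
    pca_spectra,
    spectrum_deviation,
)
from redfas.genome_io import GenomicInterval, SequenceRecord
from redfas.spectra import Segment, SpectrumMatrix, segment_chromosome, word_to_index
from redfas.wordsets import WordSet


def make_track(d, gc=None, segment_size=10):
    d = np.asarray(d, dtype=float)
    segments = [
        Segment("c", i, i * segment_size, (i + 1) * segment_size, segment_size)
        for i in range(d.size)
    ]
    gc = np.full(d.size, 0.5) if gc is None else np.asarray(gc, dtype=float)
    return DeviationTrack(
        segments=segments, d=d, gc=gc, valid=np.isfinite(d)
    )


def random_matrix(rng, n_segments=20, k=2):
    rows = rng.dirichlet(np.ones(4**k), size=n_segments)
    segments = [Segment("c", i, i * 100, (i + 1) * 100, 99) for i in range(n_segments)]
    return SpectrumMatrix(segments=segments, rows=rows, k=k)


class TestSpectrumDeviation:
    def test_identity_is_zero(self, rng, word_sets):
        f = rng.dirichlet(np.ones(1024))
        assert spectrum_deviation(f, f) == 0.0
        assert spectrum_deviation(f, f, word_sets["AT-rich"]) == 0.0

    def test_disjoint_support_is_l1_maximum(self):
        a = np.zeros(16)
        b = np.zeros(16)
        a[0] = 1.0
        b[5] = 1.0
        assert spectrum_deviation(a, b) == pytest.approx(200.0)

    def test_single_word_set_tripled_frequency(self):
        ws = WordSet.from_patterns("one", ["AA"])
        ref = np.full(16, 1 / 16)
        local = ref.copy()
        i = word_to_index("AA")
        local[i] = 3 * ref[i]
        # |3f - f| / f = 200%
        assert spectrum_deviation(local, ref, ws) == pytest.approx(200.0)

    def test_matches_hand_computed_sum(self, rng):
        ws = WordSet.from_patterns("pair", ["AA", "CC"])
        for _ in range(20):
            local = rng.dirichlet(np.ones(16))
            ref = rng.dirichlet(np.ones(16))
            idx = [word_to_index("AA"), word_to_index("CC")]
            expected = 100 * sum(abs(local[i] - ref[i]) for i in idx) / sum(
                ref[i] for i in idx
            )
            assert spectrum_deviation(local, ref, ws) == pytest.approx(expected)
            # full-spectrum deviation is plain L1 x 100
            assert spectrum_deviation(local, ref) == pytest.approx(
                100 * np.abs(local - ref).sum()
            )

    def test_zero_reference_mass_flagged(self):
        ws = WordSet.from_patterns("one", ["AA"])
        ref = np.zeros(16)
        ref[5] = 1.0
        assert np.isnan(spectrum_deviation(ref, ref, ws))

    def test_mismatched_k_errors(self):
        with pytest.raises(ValueError):
            spectrum_deviation(np.ones(16) / 16, np.ones(64) / 64)

    def test_range_bounds(self, rng):
        for _ in range(50):
            local = rng.dirichlet(np.ones(64))
            ref = rng.dirichlet(np.ones(64))
            d = spectrum_deviation(local, ref)
            assert 0 <= d <= 200


class TestDeviationTrack:
    def test_identical_segments_zero(self):
        rows = np.tile(np.full(16, 1 / 16), (5, 1))
        segments = [Segment("c", i, i * 10, (i + 1) * 10, 9) for i in range(5)]
        m = SpectrumMatrix(segments=segments, rows=rows, k=2)
        t = deviation_track(m)
        np.testing.assert_allclose(t.d, 0.0, atol=1e-12)

    def test_poly_a_segment_deviates_more(self):
        seq = "ACGTTGCA" * 25 + "A" * 200 + "GCTAACGT" * 25
        m = segment_chromosome(SequenceRecord("c", seq), 200, 2)
        t = deviation_track(m)
        assert t.d[1] > t.d[0]
        assert t.d[1] > t.d[2]

    def test_composition_oracle(self, rng, word_sets):
        from redfas.spectra import reference_spectrum

        rows = rng.dirichlet(np.ones(1024), size=100)
        segments = [Segment("c", i, i * 10, (i + 1) * 10, 9) for i in range(100)]
        m = SpectrumMatrix(segments=segments, rows=rows, k=5)
        sets = list(word_sets.values())
        t = deviation_track(m, sets)
        ref = reference_spectrum(m)
        for i in range(100):
            assert t.d[i] == pytest.approx(spectrum_deviation(rows[i], ref))
            for ws in sets:
                assert t.d_by_set[ws.name][i] == pytest.approx(
                    spectrum_deviation(rows[i], ref, ws)
                )


class TestPairwisePeculiarity:
    def test_identical_segments_mean_one(self, rng):
        row = rng.dirichlet(np.ones(16))
        rows = np.tile(row, (5, 1))
        segments = [Segment("c", i, i * 10, (i + 1) * 10, 9) for i in range(5)]
        m = SpectrumMatrix(segments=segments, rows=rows, k=2)
        np.testing.assert_allclose(pairwise_peculiarity(m), 1.0)

    def test_matches_double_loop_oracle(self, rng):
        m = random_matrix(rng, n_segments=5)
        got = pairwise_peculiarity(m)
        for i in range(5):
            rs = [
                pearsonr(m.rows[i], m.rows[j]).statistic
                for j in range(5)
                if j != i
            ]
            assert got[i] == pytest.approx(np.mean(rs))

    def test_needs_three_segments(self, rng):
        m = random_matrix(rng, n_segments=2)
        with pytest.raises(ValueError):
            pairwise_peculiarity(m)

    def test_anticorrelated_with_deviation_on_planted_data(self):
        from redfas.deviation import deviation_track
        from redfas.spectra import segment_chromosome
        from redfas.synthetic import heterogeneous_chromosome

        record, truth = heterogeneous_chromosome(seed=42)
        m = segment_chromosome(record, truth.segment_size, k=5)
        t = deviation_track(m)
        pp = pairwise_peculiarity(m)
        v = t.valid
        r = pearsonr(pp[v], t.d[v]).statistic
        assert r <= -0.8


class TestGcCorrect:
    def test_independent_gc_leaves_track_unchanged(self, rng):
        d = rng.normal(20, 3, size=500)
        gc = rng.uniform(0.3, 0.5, size=500)
        t = gc_correct(make_track(d, gc))
        assert pearsonr(t.d, t.d_gc_corrected).statistic >= 0.99

    def test_exactly_linear_gc_gives_constant(self, rng):
        gc = rng.uniform(0.3, 0.5, size=100)
        d = 5 + 80 * gc
        t = gc_correct(make_track(d, gc))
        np.testing.assert_allclose(np.ptp(t.d_gc_corrected), 0.0, atol=1e-9)
        # mean preserved by re-centering
        assert t.d_gc_corrected.mean() == pytest.approx(d.mean())

    def test_mixed_case_decorrelates_from_gc(self, rng):
        gc = rng.uniform(0.3, 0.5, size=500)
        d = 10 + 50 * gc + rng.normal(0, 2, size=500)
        t = gc_correct(make_track(d, gc))
        assert abs(pearsonr(t.d_gc_corrected, gc).statistic) < 0.05

    def test_constant_gc_is_noop(self):
        d = np.arange(20, dtype=float)
        t = gc_correct(make_track(d, np.full(20, 0.4)))
        np.testing.assert_allclose(t.d_gc_corrected, d)

    def test_needs_ten_segments(self):
        with pytest.raises(ValueError):
            gc_correct(make_track(np.arange(5, dtype=float)))


class TestCallRedfas:
    def test_distinct_values_flag_exactly_five_percent(self):
        t = make_track(np.arange(100, dtype=float))
        regions = call_redfas(t, quantile=0.95)
        assert sum(r.n_segments for r in regions) == 5

    def test_all_equal_flags_nothing(self):
        t = make_track(np.full(50, 7.0))
        assert call_redfas(t, quantile=0.95) == []

    def test_planted_block_recovered(self, rng):
        d = rng.uniform(0, 1, size=190).tolist()
        block = (10 + rng.uniform(0, 1, size=10)).tolist()
        t = make_track(d[:100] + block + d[100:])
        (region,) = call_redfas(t, quantile=0.95)
        assert region.start == 100 * 10
        assert region.end == 110 * 10
        assert region.n_segments == 10

    def test_merge_gap_bridges_single_dip(self):
        d = np.zeros(100)
        d[40:44] = 10
        d[45:49] = 10  # one background-level segment splits the run
        t = make_track(d)
        assert len(call_redfas(t, quantile=0.9, merge_gap=0)) == 2
        merged = call_redfas(t, quantile=0.9, merge_gap=1)
        assert len(merged) == 1
        assert merged[0].n_segments == 9  # span includes the bridged gap

    def test_quantile_out_of_range_errors(self):
        t = make_track(np.arange(30, dtype=float))
        with pytest.raises(ValueError):
            call_redfas(t, quantile=1.0)

    def test_nearest_rank_definition(self):
        vals = np.arange(1, 101, dtype=float)
        assert nearest_rank_quantile(vals, 0.95) == 95.0
        assert nearest_rank_quantile(vals, 0.5) == 50.0


class TestClassify:
    def _regions(self):
        from redfas.deviation import ReDFASRegion

        return [
            ReDFASRegion("c", 4_900_000, 5_100_000, 50.0, 20),  # over centromere
            ReDFASRegion("c", 0, 200_000, 40.0, 20),  # chromosome start
            ReDFASRegion("c", 30_000_000, 30_500_000, 45.0, 50),  # mid-arm
        ]

    def test_three_way_classification(self):
        cen = GenomicInterval("c", 4_800_000, 5_200_000)
        labeled = classify_redfas(self._regions(), cen, chrom_length=60_000_000)
        assert [r.class_label for r in labeled] == [
            "centromeric", "subtelomeric", "intermediate",
        ]

    def test_centromeric_takes_precedence(self):
        cen = GenomicInterval("c", 0, 300_000)
        labeled = classify_redfas(self._regions()[1:2], cen, chrom_length=60_000_000)
        assert labeled[0].class_label == "centromeric"

    def test_missing_centromere_falls_back(self):
        labeled = classify_redfas(self._regions(), None, chrom_length=60_000_000)
        assert [r.class_label for r in labeled] == [
            "intermediate", "subtelomeric", "intermediate",
        ]


class TestPca:
    def test_rank_one_data(self, rng):
        base = rng.dirichlet(np.ones(16))
        direction = rng.normal(size=16)
        coeffs = rng.normal(size=20)
        rows = base + np.outer(coeffs, direction) * 1e-3
        segments = [Segment("c", i, i * 10, (i + 1) * 10, 9) for i in range(20)]
        m = SpectrumMatrix(segments=segments, rows=rows, k=2)
        res = pca_spectra(m, n_components=3)
        assert res.explained_variance[0] == pytest.approx(1.0, abs=1e-9)

    def test_components_orthonormal(self, rng):
        m = random_matrix(rng, n_segments=30, k=3)
        res = pca_spectra(m)
        np.testing.assert_allclose(
            res.components @ res.components.T, np.eye(3), atol=1e-9
        )
        assert np.all(np.diff(res.explained_variance) <= 1e-12)

    def test_scores_preserve_distances_up_to_truncation(self, rng):
        # eigendecomposition oracle: squared distances in score space
        # differ from centered-data distances by at most the discarded
        # variance contribution
        m = random_matrix(rng, n_segments=25, k=2)
        res = pca_spectra(m, n_components=3)
        centered = m.rows - m.rows.mean(axis=0)
        full = np.linalg.svd(centered, full_matrices=False)
        discarded = (full.S[3:] ** 2).sum()
        for i in range(0, 25, 5):
            for j in range(1, 25, 7):
                d_full = np.sum((centered[i] - centered[j]) ** 2)
                d_trunc = np.sum((res.scores[i] - res.scores[j]) ** 2)
                assert d_trunc <= d_full + 1e-9
                assert d_full - d_trunc <= 4 * discarded + 1e-9

    def test_deterministic_sign_convention(self, rng):
        m = random_matrix(rng, n_segments=30, k=3)
        a = pca_spectra(m)
        b = pca_spectra(m)
        np.testing.assert_allclose(a.components, b.components)
        for c in range(3):
            j = np.argmax(np.abs(a.components[c]))
            assert a.components[c, j] > 0

    def test_too_few_segments_errors(self, rng):
        m = random_matrix(rng, n_segments=3)
        with pytest.raises(ValueError):
            pca_spectra(m, n_components=3)
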