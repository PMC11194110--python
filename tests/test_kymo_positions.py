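"""Pixel calibration, AT content, binning, enrichment and wash survival."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from curtainkit.kymo_positions import (
    BinHistogram,
    PositionSet,
    at_content_track,
    bin_positions,
    classify_at_region,
    enrichment,
    map_pixels_to_bp,
    wash_survival_fraction,
)
from curtainkit.synthetic import simulate_binding_positions


class TestPixelCalibration:
    def test_endpoints_and_midpoint(self):
        assert map_pixels_to_bp(10.0, 10.0, 110.0, 48502) == 0.0
        assert map_pixels_to_bp(60.0, 10.0, 110.0, 48502) == pytest.approx(24251)
        assert map_pixels_to_bp(110.0, 10.0, 110.0, 48502) == 48502

    def test_out_of_span_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            map_pixels_to_bp(114.1, 10.0, 110.0, 48502, tolerance_px=2.0)

    def test_within_tolerance_clipped(self):
        assert map_pixels_to_bp(111.5, 10.0, 110.0, 48502) == 48502

    def test_degenerate_calibration(self):
        with pytest.raises(ValueError):
            map_pixels_to_bp(5.0, 10.0, 10.0, 48502)


class TestATContent:
    def test_all_at_sequence(self):
        np.testing.assert_allclose(at_content_track("A" * 50, 10), 1.0)

    def test_direct_count_full_window(self):
        # at the position whose centred window spans the whole 4-mer
        assert at_content_track("ATGC", 4)[1] == pytest.approx(0.5)

    def test_random_balanced_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 5000))
        track = at_content_track(seq, 500)
        assert track.mean() == pytest.approx(0.5, abs=0.05)

    @given(st.text(alphabet="ACGT", min_size=20, max_size=200))
    @settings(max_examples=30, deadline=None)
    def test_complement_invariance(self, seq):
        comp = seq.translate(str.maketrans("ACGT", "TGCA"))
        np.testing.assert_allclose(
            at_content_track(seq, 7), at_content_track(comp, 7)
        )

    def test_non_acgt_flagged(self):
        with pytest.warns(UserWarning, match="non-ACGT"):
            track = at_content_track("ANNNA", 5)
        assert track[2] == pytest.approx(2 / 5)

    @pytest.mark.parametrize("value, expected", [(0.5, "AT-rich"), (0.49, "GC-rich"),
                                                 (1.0, "AT-rich")])
    def test_region_classification_boundary(self, value, expected):
        assert classify_at_region(value) == expected


class TestBinning:
    def test_empty_set_all_zero(self, substrate_4x):
        h = bin_positions(PositionSet(np.array([])), substrate_4x)
        assert h.counts.sum() == 0 and h.counts.size == 40

    def test_one_position_per_bin_center(self, substrate_4x):
        centers = (substrate_4x.bin_edges[:-1] + substrate_4x.bin_edges[1:]) / 2
        h = bin_positions(PositionSet(centers), substrate_4x)
        np.testing.assert_array_equal(h.counts, np.ones(40, dtype=int))

    def test_default_substrate_has_two_cbs_bins(self, substrate_4x):
        assert substrate_4x.cbs_bin_mask().sum() == 2

    def test_counts_conserved(self, substrate_4x, rng):
        pos = rng.uniform(0, substrate_4x.length, 777)
        h = bin_positions(PositionSet(pos), substrate_4x)
        assert h.counts.sum() == 777

    def test_out_of_range_rejected(self, substrate_4x):
        with pytest.raises(ValueError, match="outside"):
            bin_positions(PositionSet(np.array([-5.0])), substrate_4x)


class TestEnrichment:
    def test_hand_example(self):
        counts = np.concatenate([[10, 10], np.ones(38)])
        mask = np.concatenate([[True, True], np.zeros(38, bool)])
        h = BinHistogram(np.linspace(0, 40, 41), counts, mask)
        assert enrichment(h).fold == pytest.approx(10.0)

    def test_uniform_positions_near_unity(self, substrate_4x, rng):
        # with only two CBS bins a single draw carries ~5% sampling sd;
        # the median over five seeded draws isolates the convergence check
        folds = []
        for _ in range(5):
            pos = rng.uniform(0, substrate_4x.length, 10_000)
            folds.append(enrichment(bin_positions(PositionSet(pos), substrate_4x)).fold)
        assert np.median(folds) == pytest.approx(1.0, abs=0.05)

    def test_zero_background_flagged_infinite(self):
        counts = np.concatenate([[5, 5], np.zeros(38)])
        mask = np.concatenate([[True, True], np.zeros(38, bool)])
        h = BinHistogram(np.linspace(0, 40, 41), counts, mask)
        with pytest.warns(UserWarning):
            res = enrichment(h)
        assert math.isinf(res.fold) and res.undefined

    @pytest.mark.parametrize("fold", [7.0, 16.0])
    def test_programmed_fold_recovered(self, substrate_4x, fold):
        folds = [
            enrichment(
                bin_positions(
                    simulate_binding_positions(seed=300 + i, n=500, fold=fold,
                                               substrate=substrate_4x),
                    substrate_4x,
                )
            ).fold
            for i in range(5)
        ]
        assert np.median(folds) == pytest.approx(fold, rel=0.15)

    def test_fold_zero_and_one(self, substrate_4x):
        ps = simulate_binding_positions(seed=1, n=400, fold=0.0, substrate=substrate_4x)
        h = bin_positions(ps, substrate_4x)
        assert h.counts[h.cbs_bins].sum() == 0
        ps = simulate_binding_positions(seed=2, n=20_000, fold=1.0, substrate=substrate_4x)
        res = enrichment(bin_positions(ps, substrate_4x))
        assert res.fold == pytest.approx(1.0, abs=0.1)


class TestWashSurvival:
    @pytest.mark.parametrize(
        "before, after, expected",
        [
            (range(10), range(10), 1.0),
            (range(10), [], 0.0),
            (range(100), range(37), 0.37),
            (range(10), range(5, 15), 0.5),  # ids outside 'before' ignored
        ],
    )
    def test_fractions(self, before, after, expected):
        assert wash_survival_fraction(before, after) == pytest.approx(expected)

    def test_empty_before_rejected(self):
        with pytest.raises(ValueError):
            wash_survival_fraction([], [1])
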