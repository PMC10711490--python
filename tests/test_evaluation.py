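"""Metric correctness against brute-force oracles; mask reshaping; eligibility."""

from __future__ import annotations

import numpy as np
import pytest

from mohsmap.datatypes import TumorMask
from mohsmap.evaluation import (
    GridMask,
    auroc,
    average_precision,
    best_dice,
    evaluate_image,
    folds_enrichment,
    image_eligible,
    reshape_mask_to_grid,
)
from mohsmap.saliency import GridSpec, ProbabilityMap
from oracles import auroc_oracle, average_precision_oracle, best_dice_oracle


def _random_instance(rng, n=30, tie_prob=0.3):
    scores = rng.random(n)
    if rng.random() < tie_prob:  # force tied scores sometimes
        scores = np.round(scores, 1)
    labels = rng.random(n) < rng.uniform(0.2, 0.8)
    if not labels.any():
        labels[rng.integers(n)] = True
    if labels.all():
        labels[rng.integers(n)] = False
    return scores, labels


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([0.9, 0.1], [1, 0]) == 1.0

    def test_all_positive_is_one(self):
        assert average_precision([0.3, 0.9, 0.5], [1, 1, 1]) == 1.0

    def test_matches_threshold_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(150):
            scores, labels = _random_instance(rng)
            assert abs(average_precision(scores, labels)
                       - average_precision_oracle(scores, labels)) < 1e-9

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            average_precision([0.1, 0.2], [0, 0])

    def test_duplication_invariance(self):
        rng = np.random.default_rng(1)
        scores, labels = _random_instance(rng)
        doubled = np.concatenate([scores, scores]), np.concatenate([labels, labels])
        assert np.isclose(average_precision(scores, labels),
                          average_precision(*doubled), atol=1e-12)


class TestAuroc:
    def test_separated_and_tied_extremes(self):
        assert auroc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0
        assert auroc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(150):
            scores, labels = _random_instance(rng)
            assert abs(auroc(scores, labels) - auroc_oracle(scores, labels)) < 1e-9

    def test_complement_symmetry(self):
        rng = np.random.default_rng(3)
        scores, labels = _random_instance(rng)
        assert np.isclose(auroc(scores, labels), auroc(-scores, ~labels), atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc([0.5, 0.6], [1, 1])


class TestBestDice:
    def test_exact_binary_predictor(self):
        labels = np.array([1, 0, 1, 0, 0], dtype=bool)
        dmax, thr = best_dice(labels.astype(float), labels)
        assert dmax == 1.0

    def test_all_zero_scores_closed_form(self):
        # predict-everything at t = 0: Dice = 2P / (2P + N)
        labels = np.array([1, 1, 0, 0, 0], dtype=bool)
        dmax, thr = best_dice(np.zeros(5), labels)
        assert dmax == pytest.approx(2 * 2 / (2 * 2 + 3))
        assert thr == 0.0

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(150):
            scores, labels = _random_instance(rng)
            dmax, _ = best_dice(scores, labels)
            assert abs(dmax - best_dice_oracle(scores, labels)) < 1e-9

    def test_smallest_achieving_threshold_returned(self):
        scores = np.array([0.2, 0.6, 0.6, 0.9])
        labels = np.array([0, 1, 1, 1], dtype=bool)
        dmax, thr = best_dice(scores, labels)
        assert dmax == 1.0
        assert thr == 0.6  # 0.9 also achieves 1.0 only if all positives kept; 0.6 is smallest

    def test_empty_threshold_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            best_dice([0.5], [1], threshold_grid=[])


class TestFoldsEnrichment:
    def test_arithmetic(self):
        assert folds_enrichment(0.5, 0.25) == 2.0
        assert folds_enrichment(1.0, 0.5) == 2.0

    def test_zero_positive_fraction_rejected(self):
        with pytest.raises(ValueError, match="zero positive"):
            folds_enrichment(0.5, 0.0)

    def test_random_scores_give_enrichment_near_one(self):
        rng = np.random.default_rng(5)
        n = 100_000
        scores = rng.random(n)
        labels = rng.random(n) < 0.3
        fep = folds_enrichment(average_precision(scores, labels), labels.mean())
        assert abs(fep - 1.0) < 0.05


class TestMaskReshaping:
    def test_all_ones(self):
        grid = GridSpec(tile_size=64, stride=32, image_height=128, image_width=128)
        gm = reshape_mask_to_grid(TumorMask(mask=np.ones((128, 128), bool)), grid)
        assert gm.labels.all()
        assert (gm.cell_tumor_fractions == 1.0).all()

    def test_half_plane_mask(self):
        grid = GridSpec(tile_size=64, stride=32, image_height=128, image_width=128)
        mask = np.zeros((128, 128), bool)
        mask[:, :64] = True
        gm = reshape_mask_to_grid(TumorMask(mask=mask), grid)
        assert gm.labels[:, :2].all() and not gm.labels[:, 2:].any()

    def test_cell_fractions_match_counting_oracle_with_truncation(self):
        rng = np.random.default_rng(6)
        h, w, stride = 150, 130, 48
        grid = GridSpec(tile_size=64, stride=stride, image_height=h, image_width=w)
        mask = rng.random((h, w)) < 0.4
        gm = reshape_mask_to_grid(TumorMask(mask=mask), grid)
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                block = mask[r * stride : min((r + 1) * stride, h),
                             c * stride : min((c + 1) * stride, w)]
                assert gm.cell_tumor_fractions[r, c] == block.mean()

    def test_dimension_mismatch_rejected(self):
        grid = GridSpec(tile_size=64, stride=32, image_height=128, image_width=128)
        with pytest.raises(ValueError, match="does not match"):
            reshape_mask_to_grid(TumorMask(mask=np.zeros((100, 128), bool)), grid)


class TestEligibility:
    def _grid_mask(self, labels):
        labels = np.asarray(labels, dtype=bool)
        grid = GridSpec(tile_size=1, stride=1,
                        image_height=labels.shape[0], image_width=labels.shape[1])
        return GridMask(grid=grid, labels=labels, cell_tumor_fractions=labels.astype(float))

    def test_too_little_nontumor(self):
        labels = np.ones((10, 10), bool)
        labels[0, :5] = False  # 5% negative
        assert not image_eligible(self._grid_mask(labels))

    def test_exactly_ten_percent_negative_is_eligible(self):
        labels = np.ones((10, 10), bool)
        labels[0, :] = False  # exactly 10% negative
        assert image_eligible(self._grid_mask(labels))

    def test_no_positive_cells_ineligible(self):
        assert not image_eligible(self._grid_mask(np.zeros((10, 10), bool)))


class TestEvaluateImage:
    def _perfect_setup(self, seed=0):
        rng = np.random.default_rng(seed)
        h = w = 160
        grid = GridSpec(tile_size=64, stride=32, image_height=h, image_width=w)
        mask = np.zeros((h, w), bool)
        r0, c0 = rng.integers(10, 60, 2)
        mask[r0 : r0 + 64, c0 : c0 + 64] = True
        tm = TumorMask(mask=mask)
        gm = reshape_mask_to_grid(tm, grid)
        pmap = ProbabilityMap(grid=grid, values=gm.labels.astype(float),
                              contributing_counts=np.ones_like(gm.labels, dtype=int))
        return pmap, tm

    def test_perfect_predictor_identities(self):
        pmap, tm = self._perfect_setup()
        res = evaluate_image(pmap, tm)
        assert res.auprc == 1.0 and res.auroc == 1.0 and res.dice_max == 1.0
        assert res.fep == 1.0 / res.positive_fraction

    def test_fep_times_positive_fraction_is_auprc(self):
        for seed in range(5):
            pmap, tm = self._perfect_setup(seed)
            noisy = ProbabilityMap(
                grid=pmap.grid,
                values=np.clip(pmap.values * 0.7 + 0.1, 0, 1),
                contributing_counts=pmap.contributing_counts,
            )
            res = evaluate_image(noisy, tm)
            assert abs(res.fep * res.positive_fraction - res.auprc) < 1e-12

    def test_uninformative_map_has_auroc_near_half(self):
        rng = np.random.default_rng(7)
        h = w = 640
        grid = GridSpec(tile_size=32, stride=8, image_height=h, image_width=w)
        mask = np.zeros((h, w), bool)
        mask[:, :256] = True
        pmap = ProbabilityMap(
            grid=grid,
            values=rng.random((grid.n_rows, grid.n_cols)),
            contributing_counts=np.ones((grid.n_rows, grid.n_cols), dtype=int),
        )
        res = evaluate_image(pmap, TumorMask(mask=mask))
        assert abs(res.auroc - 0.5) < 0.05

    def test_no_positive_cell_rejected(self):
        grid = GridSpec(tile_size=64, stride=32, image_height=128, image_width=128)
        pmap = ProbabilityMap(grid=grid, values=np.zeros((4, 4)),
                              contributing_counts=np.ones((4, 4), dtype=int))
        with pytest.raises(ValueError, match="no positive"):
            evaluate_image(pmap, TumorMask(mask=np.zeros((128, 128), bool)))
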