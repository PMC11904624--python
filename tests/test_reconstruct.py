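"""Quilting reconstruction: grid geometry, matching, blending, and the
end-to-end statistical contracts."""

import numpy as np
import pytest

from fibrosynth.distance_map import BinaryVolume, double_distance_map
from fibrosynth.patch_dataset import sample_patches
from fibrosynth.reconstruct import (
    Canvas,
    ReconstructionConfig,
    blend_patch,
    matching_error,
    placement_grid,
    reconstruct_volume,
    select_best_patch,
)


def config_100():
    return ReconstructionConfig(output_shape=(100, 100, 100),
                                patch_shape=(20, 20, 20), margin=6, seed=0)


class TestPlacementGrid:
    def test_grid_arithmetic(self):
        cfg = config_100()
        assert cfg.grid_spacing == (8, 8, 8)
        xs = sorted({c[0] for c in placement_grid(cfg)})
        assert xs[:4] == [6, 14, 22, 30]
        assert all(b - a == 8 for a, b in zip(xs, xs[1:]))

    def test_windows_cover_output_region(self):
        cfg = config_100()
        corners = placement_grid(cfg)
        for axis in range(3):
            covered = np.zeros(cfg.output_shape[axis], dtype=bool)
            for c in corners:
                lo = c[axis] - cfg.margin
                covered[lo:lo + cfg.patch_shape[axis]] = True
            assert covered.all()

    def test_degenerate_single_corner(self):
        cfg = ReconstructionConfig(output_shape=(30, 30, 30),
                                   patch_shape=(30, 30, 30), margin=0)
        assert placement_grid(cfg) == [(0, 0, 0)]

    def test_seeded_permutation_reproducible(self):
        cfg = config_100()
        assert placement_grid(cfg) == placement_grid(cfg)
        other = ReconstructionConfig(output_shape=(100,) * 3,
                                     patch_shape=(20,) * 3, margin=6, seed=1)
        assert placement_grid(other) != placement_grid(cfg)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            ReconstructionConfig(output_shape=(50,) * 3,
                                 patch_shape=(12,) * 3, margin=6)


class TestMatchingError:
    def test_identical_on_mask_is_zero(self):
        a = np.random.default_rng(0).random((4, 4, 4))
        assert matching_error(a, a.copy(), np.ones_like(a, bool)) == 0.0

    def test_hand_computed_value(self):
        sub = np.array([1.0, 2.0]).reshape(1, 1, 2)
        cand = np.array([1.5, 2.5]).reshape(1, 1, 2)
        assert matching_error(sub, cand, np.ones((1, 1, 2), bool)) == 0.5

    def test_empty_mask_is_no_constraint(self):
        a = np.zeros((3, 3, 3))
        assert matching_error(a, a, np.zeros((3, 3, 3), bool)) is None

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            matching_error(np.zeros((3, 3, 3)), np.zeros((3, 3, 2)),
                           np.zeros((3, 3, 3), bool))


class TestSelectBestPatch:
    def test_matches_brute_force_recomputation(self, small_dataset):
        cfg = ReconstructionConfig(output_shape=(48,) * 3,
                                   patch_shape=(16,) * 3, margin=4, seed=2)
        canvas = Canvas.for_config(cfg)
        rng = np.random.default_rng(3)
        canvas.values[:30] = rng.random(canvas.values[:30].shape) * 2
        canvas.occupancy[:30] = True
        corner = (28, 4, 4)
        sl = tuple(slice(c - 4, c - 4 + 16) for c in corner)
        idx, err = select_best_patch(canvas, corner, small_dataset, cfg, rng)
        errors = [
            matching_error(canvas.values[sl], p.astype(np.float64),
                           canvas.occupancy[sl])
            for p in small_dataset.patches
        ]
        assert idx == int(np.argmin(errors))
        assert err == pytest.approx(errors[idx])

    def test_exact_copy_scores_zero(self, small_dataset):
        cfg = ReconstructionConfig(output_shape=(48,) * 3,
                                   patch_shape=(16,) * 3, margin=4, seed=2)
        canvas = Canvas.for_config(cfg)
        corner = (4, 4, 4)
        sl = tuple(slice(0, 16) for _ in corner)
        canvas.values[sl] = small_dataset.patches[11]
        canvas.occupancy[sl] = True
        idx, err = select_best_patch(canvas, corner, small_dataset, cfg,
                                     np.random.default_rng(0))
        assert err == pytest.approx(0.0)
        np.testing.assert_array_equal(small_dataset.patches[idx],
                                      small_dataset.patches[11])

    def test_empty_canvas_uses_seeded_random_choice(self, small_dataset):
        cfg = ReconstructionConfig(output_shape=(48,) * 3,
                                   patch_shape=(16,) * 3, margin=4, seed=2)
        picks = set()
        for _ in range(3):
            canvas = Canvas.for_config(cfg)
            idx, err = select_best_patch(canvas, (4, 4, 4), small_dataset,
                                         cfg, np.random.default_rng(5))
            assert err is None
            picks.add(idx)
        assert len(picks) == 1  # reproducible under the same generator state


class TestBlendPatch:
    cfg = ReconstructionConfig(output_shape=(40,) * 3, patch_shape=(16,) * 3,
                               margin=4, seed=0)

    def test_unoccupied_window_takes_patch_exactly(self):
        canvas = Canvas.for_config(self.cfg)
        patch = np.random.default_rng(1).random((16, 16, 16))
        blend_patch(canvas, (4, 4, 4), patch, self.cfg)
        sl = (slice(0, 16),) * 3
        np.testing.assert_array_equal(canvas.values[sl], patch)
        assert canvas.occupancy[sl].all()

    def test_deep_interior_of_occupied_canvas_keeps_prior(self):
        canvas = Canvas.for_config(self.cfg)
        canvas.values[:] = 1.7
        canvas.occupancy[:] = True
        blend_patch(canvas, (20, 20, 20), np.zeros((16, 16, 16)), self.cfg)
        # the window centre is at maximal depth into the occupied region,
        # where the blending weight saturates at 1
        assert canvas.values[24, 24, 24] == pytest.approx(1.7)

    def test_half_occupied_window_ramps_monotonically(self):
        canvas = Canvas.for_config(self.cfg)
        canvas.values[:24] = 2.0
        canvas.occupancy[:24] = True
        blend_patch(canvas, (20, 4, 4), np.zeros((16, 16, 16)), self.cfg)
        line = canvas.values[16:32, 8, 8]
        assert line[-1] == 0.0  # unoccupied side: patch wins
        assert np.all(np.diff(line) <= 1e-12)  # prior grows into the interior


class TestReconstructVolume:
    def test_output_shape_and_determinism(self, small_dataset):
        cfg = ReconstructionConfig(output_shape=(48, 40, 36),
                                   patch_shape=(16,) * 3, margin=4, seed=9)
        a = reconstruct_volume(small_dataset, cfg)
        b = reconstruct_volume(small_dataset, cfg)
        assert a.shape == (48, 40, 36)
        assert np.array_equal(a.grid, b.grid)

    def test_striped_exemplar_porosity_preserved(self):
        z = np.arange(48)
        grid = np.broadcast_to((z // 4) % 2 == 0, (48, 48, 48)).copy()
        exemplar = BinaryVolume(grid)
        ds = sample_patches(double_distance_map(exemplar), 40, (12,) * 3,
                            seed=1)
        porosities = []
        for seed in range(10):
            cfg = ReconstructionConfig(output_shape=(36,) * 3,
                                       patch_shape=(12,) * 3, margin=3,
                                       seed=seed)
            porosities.append(reconstruct_volume(ds, cfg).porosity)
        assert abs(np.mean(porosities) - exemplar.porosity) < 0.05

    def test_matching_quality_metric_in_unit_interval(self, small_dataset):
        cfg = ReconstructionConfig(output_shape=(48,) * 3,
                                   patch_shape=(16,) * 3, margin=4, seed=4)
        _, report = reconstruct_volume(small_dataset, cfg, return_report=True)
        frac = report.fraction_below(0.2)
        assert 0.0 <= frac <= 1.0
        # every grid cell visited exactly once
        assert len(report.matching_errors) == len(placement_grid(cfg))

    def test_porosity_bias_follows_alpha_target(self, small_dataset):
        def mean_porosity(alpha):
            vals = []
            for seed in (0, 1):
                cfg = ReconstructionConfig(
                    output_shape=(48,) * 3, patch_shape=(16,) * 3, margin=4,
                    seed=seed, feature_target=(alpha, 0.5, 0.5))
                vals.append(reconstruct_volume(small_dataset, cfg).porosity)
            return np.mean(vals)

        assert mean_porosity(0.0) < mean_porosity(1.0)

    def test_patch_shape_mismatch_rejected(self, small_dataset):
        cfg = ReconstructionConfig(output_shape=(48,) * 3,
                                   patch_shape=(12,) * 3, margin=3)
        with pytest.raises(ValueError, match="patch shape"):
            reconstruct_volume(small_dataset, cfg)
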