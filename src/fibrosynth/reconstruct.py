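"""Volume reconstruction by randomized patch quilting.

A new volume is assembled on an oversized zero canvas.  Grid corners spaced
``delta = s - 2m`` apart (patch size ``s``, overlap margin ``m``) are
visited in a seeded random order; at each corner the patch window — the
stored patch footprint, which overlaps its neighbours by ``2m`` — is
compared against the already-written canvas content, the dataset patch with
the smallest mean absolute difference over the occupied voxels is chosen
(exhaustive scan), and it is blended in with weights that ramp from the
unoccupied frontier (new patch dominates) into the occupied interior
(existing content dominates).  Finally the canvas is cropped to the
requested shape, lightly Gaussian-smoothed and thresholded at 1 back to a
binary volume.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .distance_map import BinaryVolume
from .patch_dataset import PatchDataset, filter_by_feature_target

__all__ = [
    "ReconstructionConfig",
    "Canvas",
    "ReconstructionReport",
    "placement_grid",
    "matching_error",
    "select_best_patch",
    "blend_patch",
    "reconstruct_volume",
]


@dataclass(frozen=True)
class ReconstructionConfig:
    """Geometry and randomness of one reconstruction run.

    ``margin`` is the overlap half-width m (default 6 voxels); grid spacing
    is ``patch - 2 * margin`` per axis and must be positive.  ``sigma`` is
    the final Gaussian smoothing (default 0.5 voxels).  ``feature_target``,
    if set, filters the dataset to the 1/8 of patches nearest that
    (alpha, beta, gamma) point before synthesis.
    """

    output_shape: tuple[int, int, int]
    patch_shape: tuple[int, int, int]
    margin: int = 6
    sigma: float = 0.5
    seed: int = 0
    feature_target: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "output_shape",
                           tuple(int(s) for s in self.output_shape))
        object.__setattr__(self, "patch_shape",
                           tuple(int(s) for s in self.patch_shape))
        if self.margin < 0:
            raise ValueError("margin must be non-negative")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if any(d <= 0 for d in self.grid_spacing):
            raise ValueError(
                f"grid spacing {self.grid_spacing} must be positive "
                f"(patch {self.patch_shape}, margin {self.margin})"
            )

    @property
    def grid_spacing(self) -> tuple[int, int, int]:
        return tuple(s - 2 * self.margin for s in self.patch_shape)

    @property
    def canvas_shape(self) -> tuple[int, int, int]:
        return tuple(S + s for S, s in zip(self.output_shape, self.patch_shape))


@dataclass
class Canvas:
    """Oversized working volume plus an explicit occupancy mask.

    Occupancy is tracked separately from the values because a legitimate
    double-distance value can be exactly 0 (deep pore), which a
    "non-zero means written" test would misread as empty.
    """

    values: np.ndarray
    occupancy: np.ndarray

    @classmethod
    def for_config(cls, config: ReconstructionConfig) -> "Canvas":
        shape = config.canvas_shape
        return cls(np.zeros(shape, dtype=np.float64),
                   np.zeros(shape, dtype=bool))


@dataclass
class ReconstructionReport:
    """Per-placement diagnostics of one reconstruction."""

    seed: int
    matching_errors: list[float | None] = field(default_factory=list)

    def fraction_below(self, threshold: float = 0.2) -> float:
        """Fraction of constrained placements with matching error below
        ``threshold`` (the standard overlap-quality diagnostic)."""
        errs = [e for e in self.matching_errors if e is not None]
        if not errs:
            return 1.0
        return float(np.mean([e < threshold for e in errs]))


def placement_grid(config: ReconstructionConfig,
                   rng: np.random.Generator | None = None
                   ) -> list[tuple[int, int, int]]:
    """Grid corners ``m + n * delta`` per axis, in a seeded random order.

    Corners are generated while the patch window (which starts ``m`` before
    the corner) still begins inside the output region, which guarantees the
    windows tile the whole cropped volume with ``2m`` overlaps.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.margin
    axes = []
    for S, delta in zip(config.output_shape, config.grid_spacing):
        n_max = (S - 1) // delta  # corners with  corner - m  in [0, S)
        axes.append([m + n * delta for n in range(n_max + 1)])
    corners = list(itertools.product(*axes))
    order = rng.permutation(len(corners))
    return [corners[i] for i in order]


def _window_slices(corner, config: ReconstructionConfig) -> tuple[slice, ...]:
    m = config.margin
    return tuple(slice(c - m, c - m + s)
                 for c, s in zip(corner, config.patch_shape))


def matching_error(subsample: np.ndarray, candidate: np.ndarray,
                   mask: np.ndarray) -> float | None:
    """Mean absolute difference over masked voxels; ``None`` when the mask
    is empty (no constraint — the caller falls back to a random patch)."""
    if subsample.shape != candidate.shape or subsample.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: subsample {subsample.shape}, candidate "
            f"{candidate.shape}, mask {mask.shape}"
        )
    n = int(np.count_nonzero(mask))
    if n == 0:
        return None
    diff = np.abs(np.asarray(subsample, dtype=np.float64)
                  - np.asarray(candidate, dtype=np.float64))
    return float(diff[mask.astype(bool)].sum() / n)


def select_best_patch(canvas: Canvas, corner, dataset: PatchDataset,
                      config: ReconstructionConfig,
                      rng: np.random.Generator
                      ) -> tuple[int, float | None]:
    """Exhaustive argmin of the masked matching error over all patches.

    Ties resolve to the lowest index.  An empty overlap (first placements)
    yields a uniformly random index.  Returns ``(index, error)``.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    flat_patches = dataset.patches.reshape(len(dataset), -1).astype(np.float64)
    return _select_best_flat(canvas, corner, flat_patches, config, rng)


def _select_best_flat(canvas: Canvas, corner, flat_patches: np.ndarray,
                      config: ReconstructionConfig, rng: np.random.Generator
                      ) -> tuple[int, float | None]:
    sl = _window_slices(corner, config)
    window = canvas.values[sl]
    mask = canvas.occupancy[sl]
    n_masked = int(np.count_nonzero(mask))
    if n_masked == 0:
        return int(rng.integers(len(flat_patches))), None
    wflat = window.reshape(-1)
    mflat = mask.reshape(-1).astype(np.float64)
    errors = np.abs(flat_patches - wflat[None, :]) @ mflat / n_masked
    best = int(np.argmin(errors))  # argmin returns the lowest tied index
    return best, float(errors[best])


def blend_patch(canvas: Canvas, corner, patch: np.ndarray,
                config: ReconstructionConfig) -> None:
    """Blend ``patch`` into the canvas window with distance-ramped weights.

    The weight w of the *existing* content is the Euclidean distance of
    each occupied voxel into the occupied region (distance to the nearest
    unoccupied voxel, computed with context beyond the window so interior
    depth saturates correctly), normalized by its maximum over the window;
    w = 0 on unoccupied voxels.  The window becomes ``b*w + patch*(1-w)``
    and is marked occupied.
    """
    sl = _window_slices(corner, config)
    if canvas.values[sl].shape != patch.shape:
        raise ValueError("patch does not fit the placement window")
    occ = canvas.occupancy[sl]
    if not occ.any():
        canvas.values[sl] = patch
        canvas.occupancy[sl] = True
        return
    # Depth-into-occupied-region, with surrounding context so that a fully
    # occupied window still sees the true distance to the frontier.
    pad = max(patch.shape)
    ext = tuple(slice(max(s.start - pad, 0), min(s.stop + pad, dim))
                for s, dim in zip(sl, canvas.occupancy.shape))
    occ_ext = canvas.occupancy[ext]
    if occ_ext.all():
        # no frontier in reach: every window voxel is deep interior, the
        # existing content is kept unchanged
        canvas.occupancy[sl] = True
        return
    depth_ext = ndi.distance_transform_edt(occ_ext)
    inner = tuple(slice(s.start - e.start, s.start - e.start + (s.stop - s.start))
                  for s, e in zip(sl, ext))
    depth = depth_ext[inner]
    dmax = depth.max()
    w = depth / dmax if dmax > 0 else np.zeros_like(depth)
    canvas.values[sl] = canvas.values[sl] * w + np.asarray(patch, np.float64) * (1 - w)
    canvas.occupancy[sl] = True


def reconstruct_volume(dataset: PatchDataset, config: ReconstructionConfig,
                       *, return_report: bool = False):
    """Synthesize a binary volume from a patch dataset.

    Applies the feature filter if ``config.feature_target`` is set, visits
    every grid corner once in seeded random order (select best patch, blend),
    then crops to ``output_shape``, smooths with ``sigma`` and thresholds at
    1.  Fully deterministic for a fixed config + dataset + seed.
    """
    if tuple(dataset.patch_shape) != config.patch_shape:
        raise ValueError(
            f"dataset patch shape {dataset.patch_shape} does not match "
            f"config patch shape {config.patch_shape}"
        )
    if config.feature_target is not None:
        dataset = filter_by_feature_target(dataset, config.feature_target)

    rng = np.random.default_rng(config.seed)
    corners = placement_grid(config, rng)
    canvas = Canvas.for_config(config)
    report = ReconstructionReport(seed=config.seed)
    flat_patches = dataset.patches.reshape(len(dataset), -1).astype(np.float64)

    for corner in corners:
        idx, err = _select_best_flat(canvas, corner, flat_patches, config, rng)
        blend_patch(canvas, corner, dataset.patches[idx], config)
        report.matching_errors.append(err)

    S1, S2, S3 = config.output_shape
    cropped = canvas.values[:S1, :S2, :S3]
    if config.sigma > 0:
        cropped = ndi.gaussian_filter(cropped, sigma=config.sigma)
    volume = BinaryVolume((cropped - 1.0) > 0.0, voxel_size=dataset.voxel_size)
    if return_report:
        return volume, report
    return volume
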