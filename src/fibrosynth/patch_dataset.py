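"""Diversified patch datasets for exemplar-based synthesis.

From one exemplar double distance map, a 4-D dataset of cubic grayscale
patches is built in three steps:

1. seven geometric transformations of the whole map — the identity, small
   (+/-8 degree) rotations about each array axis, and grayscale morphology
   (opening / closing / erosion / dilation with a 3-voxel spherical element)
   composed with those rotations — plus a per-volume random intensity shift
   (+/-0.1) and scale (+/-10%);
2. N cubic patches sampled at uniform random corners from each transformed
   volume, giving exactly 7N patches;
3. per-patch morphology features (porosity, specific surface, maximum
   inscribed pore diameter), min-max normalized over the whole dataset to
   feature coordinates (alpha, beta, gamma) in the unit cube.

Conditioned synthesis keeps only the 1/8 of patches closest to a target
point in (alpha, beta, gamma) space; the centre (0.5, 0.5, 0.5) yields an
unbiased realization, while e.g. alpha* = 0 biases toward low porosity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import ball

from . import metrics
from .distance_map import DoubleDistanceMap

__all__ = [
    "TransformSpec",
    "PatchDataset",
    "apply_transform",
    "sample_patches",
    "compute_patch_features",
    "filter_by_feature_target",
]

_ROTATION_ANGLE = 8.0  # degrees; small enough to keep cropping losses minor
_CROP_GUARD = 2  # voxels shaved off the inscribed box against edge interpolation

# index -> (morphology op, rotation plane (array axes), angle sign)
# Rotation "about axis k" is an in-plane rotation of the two other axes.
_TRANSFORM_TABLE: dict[int, tuple[str | None, tuple[int, int] | None, float]] = {
    1: (None, None, 0.0),
    2: (None, (0, 1), +_ROTATION_ANGLE),
    3: (None, (0, 1), -_ROTATION_ANGLE),
    4: ("open", (0, 2), +_ROTATION_ANGLE),
    5: ("close", (0, 2), -_ROTATION_ANGLE),
    6: ("erosion", (1, 2), +_ROTATION_ANGLE),
    7: ("dilation", (1, 2), -_ROTATION_ANGLE),
}

_MORPH_FUNCS = {
    "open": ndi.grey_opening,
    "close": ndi.grey_closing,
    "erosion": ndi.grey_erosion,
    "dilation": ndi.grey_dilation,
}

_FEATURE_COLUMNS = ("porosity", "specific_surface_mm^-1", "max_pore_diameter_um")
_NORM_COLUMNS = ("alpha", "beta", "gamma")


@dataclass(frozen=True)
class TransformSpec:
    """One of the seven dataset-diversifying transformations."""

    index: int
    morphology: str | None
    rotation_plane: tuple[int, int] | None
    angle_deg: float
    shift: float = 0.0
    scale: float = 1.0

    @classmethod
    def from_index(cls, i: int, shift: float = 0.0, scale: float = 1.0
                   ) -> "TransformSpec":
        if i not in _TRANSFORM_TABLE:
            raise ValueError(f"transform index must be in 1..7, got {i}")
        morph, plane, angle = _TRANSFORM_TABLE[i]
        return cls(i, morph, plane, angle, shift, scale)


def _largest_inscribed_box(w: int, h: int, angle_deg: float) -> tuple[int, int]:
    """Largest centred axis-aligned rectangle inside a w-by-h rectangle
    rotated by ``angle_deg`` about its centre (classic closed form)."""
    a = abs(math.radians(angle_deg)) % math.pi
    if a > math.pi / 2:
        a = math.pi - a
    sin_a, cos_a = math.sin(a), math.cos(a)
    if sin_a == 0.0:
        return w, h
    short = min(w, h)
    if short <= 2.0 * sin_a * cos_a * max(w, h):
        x = 0.5 * short
        wr, hr = (x / sin_a, x / cos_a) if w <= h else (x / cos_a, x / sin_a)
    else:
        cos_2a = cos_a * cos_a - sin_a * sin_a
        wr = (w * cos_a - h * sin_a) / cos_2a
        hr = (h * cos_a - w * sin_a) / cos_2a
    return int(math.floor(wr)), int(math.floor(hr))


def _centred_crop(arr: np.ndarray, axis: int, size: int) -> np.ndarray:
    full = arr.shape[axis]
    start = (full - size) // 2
    sl = [slice(None)] * arr.ndim
    sl[axis] = slice(start, start + size)
    return arr[tuple(sl)]


def apply_transform(dmap: DoubleDistanceMap, i: int, *, shift: float = 0.0,
                    scale: float = 1.0) -> DoubleDistanceMap:
    """Apply transformation ``i`` in {1..7} to a double distance map.

    Morphology (grayscale, 3-voxel spherical element) is applied first,
    then the +/-8 degree rotation (trilinear interpolation), then the
    volume is cropped to the largest axis-aligned box of valid voxels and
    intensity-shifted/-scaled; values are clipped back to [0, 2].
    Transform 1 with ``shift=0, scale=1`` is the identity.
    """
    spec = TransformSpec.from_index(i, shift, scale)
    values = np.asarray(dmap.grid, dtype=np.float64)

    if spec.morphology is not None:
        values = _MORPH_FUNCS[spec.morphology](values, footprint=ball(1))

    if spec.rotation_plane is not None:
        values = ndi.rotate(values, spec.angle_deg, axes=spec.rotation_plane,
                            reshape=False, order=1, mode="constant", cval=0.0)
        ax0, ax1 = spec.rotation_plane
        w, h = values.shape[ax0], values.shape[ax1]
        wr, hr = _largest_inscribed_box(w, h, spec.angle_deg)
        wr = max(wr - 2 * _CROP_GUARD, 1)
        hr = max(hr - 2 * _CROP_GUARD, 1)
        values = _centred_crop(values, ax0, wr)
        values = _centred_crop(values, ax1, hr)

    if spec.scale != 1.0 or spec.shift != 0.0:
        # Scale acts on the distance values, i.e. the deviations about the
        # interface level 1, so rescaling never moves the phase boundary.
        values = (values - 1.0) * spec.scale + 1.0 + spec.shift
    values = np.clip(values, 0.0, 2.0)
    return DoubleDistanceMap(values, voxel_size=dmap.voxel_size)


def compute_patch_features(patch: np.ndarray, voxel_size: float
                           ) -> tuple[float, float, float]:
    """(porosity, specific surface 1/mm, max inscribed pore diameter um)
    of a grayscale patch, thresholded at 1 (sigma = 0).

    Total function: all-solid patches give (0, 0, 0); all-pore patches give
    porosity 1, specific surface 0, and the inscribed diameter of the block.
    """
    solid = np.asarray(patch) > 1.0
    return (
        metrics.porosity(solid),
        metrics.specific_surface(solid, voxel_size),
        metrics.max_pore_diameter(solid, voxel_size),
    )


@dataclass(frozen=True)
class PatchDataset:
    """Cubic grayscale patches plus their feature table.

    ``patches`` has shape (P, s1, s2, s3); ``features`` has one row per
    patch with provenance (transform index, sample corner), raw features
    and the normalized (alpha, beta, gamma) coordinates.  Normalization is
    min-max over the *unfiltered* dataset and is frozen: filtering keeps
    the original coordinates so targets always refer to the same frame.
    """

    patches: np.ndarray
    features: pd.DataFrame
    voxel_size: float

    def __post_init__(self) -> None:
        if self.patches.ndim != 4:
            raise ValueError("patches must be a 4-D array (P, s1, s2, s3)")
        if len(self.features) != len(self.patches):
            raise ValueError("feature table and patch array disagree in length")

    def __len__(self) -> int:
        return self.patches.shape[0]

    @property
    def patch_shape(self) -> tuple[int, int, int]:
        return self.patches.shape[1:]

    def to_csv(self, path) -> None:
        self.features.to_csv(path, index=False)


def _normalize_features(features: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale raw features to (alpha, beta, gamma) in [0, 1].

    A feature with zero range carries no information and maps to 0.5.
    """
    features = features.copy()
    for raw, norm in zip(_FEATURE_COLUMNS, _NORM_COLUMNS):
        col = features[raw].to_numpy(dtype=float)
        span = col.max() - col.min()
        features[norm] = 0.5 if span == 0 else (col - col.min()) / span
    return features


def sample_patches(dmap: DoubleDistanceMap, n_per_transform: int,
                   patch_shape: tuple[int, int, int], seed: int,
                   *, transforms: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7),
                   intensity_jitter: bool = True) -> PatchDataset:
    """Build the patch dataset: N patches from each of the transforms.

    For each transform, the random intensity shift and scale are drawn once
    for the whole transformed volume (disabled by ``intensity_jitter=False``),
    then ``n_per_transform`` corner positions are drawn uniformly over the
    valid range.  With the default seven transforms the dataset holds
    exactly ``7 * n_per_transform`` patches.  Deterministic for fixed seed.
    """
    if n_per_transform < 1:
        raise ValueError("n_per_transform must be >= 1")
    patch_shape = tuple(int(s) for s in patch_shape)
    rng = np.random.default_rng(seed)

    all_patches: list[np.ndarray] = []
    rows: list[tuple] = []
    s1, s2, s3 = patch_shape
    pid = 0
    for i in transforms:
        shift = rng.uniform(-0.1, 0.1) if intensity_jitter else 0.0
        scale = rng.uniform(0.9, 1.1) if intensity_jitter else 1.0
        tmap = apply_transform(dmap, i, shift=shift, scale=scale)
        tshape = tmap.shape
        if any(ts < ps for ts, ps in zip(tshape, patch_shape)):
            raise ValueError(
                f"patch shape {patch_shape} exceeds transformed volume "
                f"{tshape} for transform {i}"
            )
        xs = rng.integers(0, tshape[0] - s1 + 1, size=n_per_transform)
        ys = rng.integers(0, tshape[1] - s2 + 1, size=n_per_transform)
        zs = rng.integers(0, tshape[2] - s3 + 1, size=n_per_transform)
        grid = np.asarray(tmap.grid, dtype=np.float32)
        for x, y, z in zip(xs, ys, zs):
            patch = grid[x:x + s1, y:y + s2, z:z + s3]
            all_patches.append(patch)
            phi, ss, mpd = compute_patch_features(patch, dmap.voxel_size)
            rows.append((pid, i, int(x), int(y), int(z), phi, ss, mpd))
            pid += 1

    features = pd.DataFrame(
        rows, columns=["patch_id", "transform", "corner_x", "corner_y",
                       "corner_z", *_FEATURE_COLUMNS]
    )
    features = _normalize_features(features)
    return PatchDataset(np.stack(all_patches), features, dmap.voxel_size)


def filter_by_feature_target(dataset: PatchDataset,
                             target: tuple[float, float, float]) -> PatchDataset:
    """Keep the ceil(P/8) patches closest to ``target`` in (alpha, beta,
    gamma) space (Euclidean distance; ties broken by original order).

    The retained patches keep their original feature coordinates, so the
    selection sphere always lives in the unfiltered dataset's frame.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    target = np.asarray(target, dtype=float)
    if target.shape != (3,) or np.any(target < 0) or np.any(target > 1):
        raise ValueError("feature target must be three values in [0, 1]")
    coords = dataset.features[list(_NORM_COLUMNS)].to_numpy(dtype=float)
    d2 = ((coords - target) ** 2).sum(axis=1)
    k = math.ceil(len(dataset) / 8)
    keep = np.sort(np.argsort(d2, kind="stable")[:k])
    return replace(
        dataset,
        patches=dataset.patches[keep],
        features=dataset.features.iloc[keep].reset_index(drop=True),
    )
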