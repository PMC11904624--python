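"""Double distance maps: the grayscale representation used for synthesis.

A binary microstructure (solid = 1, pore = 0) cannot be interpolated or
rotated without destroying its phase boundary, so synthesis operates on a
*double distance map*

    I = d_hat(solid) - d_hat(pore) + 1,

where ``d_hat`` is the Euclidean distance transform of each phase (distance
of every in-phase voxel to the nearest voxel centre of the opposite phase),
normalized by its own maximum over the volume.  Values lie on a continuous
scale from 0 (deep pore) through 1 (the solid--pore interface) to 2 (deep
solid); thresholding at 1 recovers the binary volume exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "BinaryVolume",
    "DoubleDistanceMap",
    "DegeneratePhaseError",
    "double_distance_map",
    "threshold_to_binary",
]

#: Default voxel edge length in micrometres (typical desktop uCT resolution).
DEFAULT_VOXEL_SIZE_UM = 6.25


class DegeneratePhaseError(ValueError):
    """Raised when an operation needs both phases but the volume has one."""


@dataclass(frozen=True)
class BinaryVolume:
    """A 3D two-phase voxel image.

    Parameters
    ----------
    grid
        Boolean array; ``True`` marks solid voxels, ``False`` pore voxels.
    voxel_size
        Edge length of a voxel in micrometres.
    """

    grid: np.ndarray
    voxel_size: float = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        if g.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={g.ndim}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        object.__setattr__(self, "grid", g)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape

    @property
    def porosity(self) -> float:
        """Pore-phase volume fraction."""
        return float(1.0 - self.grid.mean())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryVolume):
            return NotImplemented
        return (
            self.voxel_size == other.voxel_size
            and self.grid.shape == other.grid.shape
            and bool(np.array_equal(self.grid, other.grid))
        )


@dataclass(frozen=True)
class DoubleDistanceMap:
    """Grayscale field on [0, 2] encoding normalized distance to the interface."""

    grid: np.ndarray
    voxel_size: float = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=np.float64)
        if g.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={g.ndim}")
        object.__setattr__(self, "grid", g)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape


def _distance_to_opposite_phase(in_phase: np.ndarray) -> np.ndarray:
    """Distance from each in-phase voxel centre to the nearest voxel centre
    of the opposite phase; 0 on out-of-phase voxels.

    ``distance_transform_edt`` measures distance to the nearest zero voxel,
    which is exactly the nearest opposite-phase voxel centre, so voxels
    adjacent to the interface get distance 1 (never 0).
    """
    return ndi.distance_transform_edt(in_phase)


def double_distance_map(volume: BinaryVolume) -> DoubleDistanceMap:
    """Compute ``I = d_hat(solid) - d_hat(pore) + 1`` on [0, 2].

    Each phase's distance field is normalized by its own maximum over the
    whole volume, which puts both terms on [0, 1] and the result on [0, 2].

    Raises
    ------
    DegeneratePhaseError
        If the volume contains only one phase (normalization undefined).
    """
    solid = volume.grid
    n_solid = int(solid.sum())
    if n_solid == 0 or n_solid == solid.size:
        raise DegeneratePhaseError(
            "degenerate phase: volume must contain both solid and pore voxels"
        )
    d_solid = _distance_to_opposite_phase(solid)
    d_pore = _distance_to_opposite_phase(~solid)
    d_solid /= d_solid.max()
    d_pore /= d_pore.max()
    return DoubleDistanceMap(d_solid - d_pore + 1.0, voxel_size=volume.voxel_size)


def threshold_to_binary(dmap: DoubleDistanceMap, sigma: float = 0.5) -> BinaryVolume:
    """Recover a binary volume: solid where ``(G_sigma(I) - 1) > 0``.

    A small Gaussian blur (``sigma`` in voxels, typically 0.5) removes minor
    discontinuities between quilted patches; with ``sigma=0`` this inverts
    :func:`double_distance_map` exactly, because every in-phase voxel sits
    strictly on its own side of 1.  Exact ties at 1 map to pore.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    values = np.asarray(dmap.grid, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("map contains non-finite values")
    if sigma > 0:
        values = ndi.gaussian_filter(values, sigma=sigma)
    return BinaryVolume((values - 1.0) > 0.0, voxel_size=dmap.voxel_size)
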