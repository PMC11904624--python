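"""Shared voxel-counting morphology metrics (porosity, specific surface,
inscribed pore size).  Used both for per-patch features and for whole-volume
summaries so the two report on identical scales."""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "porosity",
    "specific_surface",
    "max_pore_diameter",
    "count_interface_faces",
]


def porosity(solid: np.ndarray) -> float:
    """Pore-voxel fraction of a boolean solid mask."""
    return float(1.0 - np.asarray(solid, dtype=bool).mean())


def count_interface_faces(solid: np.ndarray) -> int:
    """Number of solid-pore face pairs (6-connectivity, interior faces only)."""
    s = np.asarray(solid, dtype=bool)
    n = 0
    for axis in range(s.ndim):
        a = np.moveaxis(s, axis, 0)
        n += int(np.count_nonzero(a[1:] != a[:-1]))
    return n


def specific_surface(solid: np.ndarray, voxel_size_um: float) -> float:
    """Solid-pore interface area per unit total volume, in 1/mm.

    The interface is measured by face counting: ``faces * a^2 / (n * a^3)``
    with ``a`` the voxel edge, which reduces to ``faces / (n * a_mm)``.
    """
    a_mm = voxel_size_um * 1e-3
    return count_interface_faces(solid) / (np.asarray(solid).size * a_mm)


def max_pore_diameter(solid: np.ndarray, voxel_size_um: float) -> float:
    """Diameter (um) of the largest sphere inscribed in the pore phase.

    Computed as twice the maximum of the unnormalized Euclidean distance of
    pore voxels to the nearest solid voxel centre.  All-solid inputs give 0;
    all-pore inputs give the inscribed diameter of the whole block (the
    shortest edge), since no interface constrains the sphere.
    """
    s = np.asarray(solid, dtype=bool)
    if s.all():
        return 0.0
    if not s.any():
        return float(min(s.shape)) * voxel_size_um
    dt = ndi.distance_transform_edt(~s)
    return float(2.0 * dt.max() * voxel_size_um)
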