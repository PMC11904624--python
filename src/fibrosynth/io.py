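"""Volume I/O: multi-page TIFF stacks with JSON sidecars.

Binary volumes are stored 8-bit (0 = pore, 255 = solid), grayscale maps as
32-bit float, one page per z-slice.  A ``<file>.json`` sidecar records the
voxel size (um) and volume kind; a missing sidecar falls back to the
default 6.25 um voxel with a logged warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import tifffile

from .distance_map import DEFAULT_VOXEL_SIZE_UM, BinaryVolume, DoubleDistanceMap

__all__ = ["read_volume", "write_volume", "sidecar_path", "sha256_of"]

log = logging.getLogger(__name__)


def sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_volume(volume: BinaryVolume | DoubleDistanceMap, path) -> Path:
    """Write a volume as a multi-page TIFF plus JSON sidecar.

    The array's third axis becomes the page (z) axis.  Binary volumes are
    written as uint8 0/255, maps as float32.  Returns the TIFF path.
    """
    path = Path(path)
    if isinstance(volume, BinaryVolume):
        pages = np.moveaxis(volume.grid, 2, 0).astype(np.uint8) * 255
        kind = "binary"
    elif isinstance(volume, DoubleDistanceMap):
        pages = np.moveaxis(volume.grid, 2, 0).astype(np.float32)
        kind = "map"
    else:
        raise TypeError(f"cannot write object of type {type(volume).__name__}")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, pages)
    sidecar = {
        "kind": kind,
        "voxel_size_um": volume.voxel_size,
        "shape": list(volume.shape),
    }
    sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path) -> BinaryVolume | DoubleDistanceMap:
    """Read a TIFF volume; the sidecar (or the dtype) decides the kind.

    Integer data becomes a :class:`BinaryVolume` (non-zero = solid), float
    data a :class:`DoubleDistanceMap`.  Raises on unreadable files or a
    sidecar/shape mismatch.
    """
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot read volume from {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got shape {pages.shape}")
    grid = np.moveaxis(pages, 0, 2)

    voxel_size = DEFAULT_VOXEL_SIZE_UM
    kind = None
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        voxel_size = float(meta.get("voxel_size_um", DEFAULT_VOXEL_SIZE_UM))
        kind = meta.get("kind")
        if "shape" in meta and tuple(meta["shape"]) != grid.shape:
            raise ValueError(
                f"{path}: sidecar shape {meta['shape']} does not match "
                f"stack shape {list(grid.shape)}"
            )
    else:
        log.warning("%s: no sidecar found, assuming voxel size %.2f um",
                    path, DEFAULT_VOXEL_SIZE_UM)

    if kind is None:
        kind = "map" if np.issubdtype(grid.dtype, np.floating) else "binary"
    if kind == "binary":
        return BinaryVolume(grid > 0, voxel_size=voxel_size)
    if kind == "map":
        return DoubleDistanceMap(grid.astype(np.float64), voxel_size=voxel_size)
    raise ValueError(f"{path}: unknown volume kind {kind!r} in sidecar")


def sha256_of(path) -> str:
    """Hex SHA-256 of a file's content (used for run manifests)."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
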