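"""Projection footprints and the global gap percentage.

The gap footprint is the axial shadow of the segmented gap volume: a pixel
belongs to it if any voxel in its z-column is a gap (the binary equivalent
of a minimum-intensity projection of a volume whose gaps are darkest). The
bonded (conditioned) footprint comes from a maximum-intensity projection of
the grey volume thresholded to separate the darker conditioned tooth area
from brighter cement-covered regions, restricted to the interface annulus.
The headline number is 100 x gap area / bonded area.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import annulus_mask
from .volio import Volume3D


@dataclasses.dataclass
class Footprint2D:
    """A 2D binary footprint in the (y, x) plane with physical pixel size."""

    mask: np.ndarray
    pixel_um: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError(f"footprint mask must be 2D, got {self.mask.ndim}D")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be > 0")

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_um**2


def _resolve_z_range(nz: int, z_range) -> tuple[int, int]:
    z0, z1 = (0, nz) if z_range is None else z_range
    z0, z1 = int(z0), int(z1)
    if not 0 <= z0 < z1 <= nz:
        raise ValueError(f"empty or invalid z range [{z0}, {z1}) for nz={nz}")
    return z0, z1


def gap_footprint(gap_mask: np.ndarray, voxel_um: float, z_range=None) -> Footprint2D:
    """Axial footprint of a binary gap volume over the half-open slice range."""
    gap_mask = np.asarray(gap_mask, dtype=bool)
    if gap_mask.ndim != 3:
        raise ValueError("gap_mask must be 3D")
    z0, z1 = _resolve_z_range(gap_mask.shape[0], z_range)
    return Footprint2D(gap_mask[z0:z1].any(axis=0), voxel_um)


def bonded_footprint(
    volume: Volume3D,
    split_threshold: float,
    center,
    annulus_um,
    z_range=None,
) -> Footprint2D:
    """Conditioned-area footprint from a maximum-intensity projection.

    Pixels whose projected maximum over the z range is <= ``split_threshold``
    (darker = conditioned tooth, brighter = cement-covered) and that lie in
    the interface annulus ``annulus_um=(r_in, r_out)`` around ``center``.
    """
    arr = volume.voxels
    z0, z1 = _resolve_z_range(arr.shape[0], z_range)
    vmin, vmax = float(arr.min()), float(arr.max())
    if not vmin <= split_threshold <= vmax:
        raise ValueError(
            f"split_threshold {split_threshold} outside data domain [{vmin:.4g}, {vmax:.4g}]"
        )
    mip = arr[z0:z1].max(axis=0)
    ann = annulus_mask(mip.shape, center, annulus_um[0], annulus_um[1], volume.voxel_um)
    return Footprint2D((mip <= split_threshold) & ann, volume.voxel_um)


def percent_gap(gap: Footprint2D, bonded: Footprint2D) -> float:
    """100 x area(gap within bonded) / area(bonded); NaN when bonded is empty.

    The gap footprint is intersected with the bonded annulus first, so stray
    pixels outside the interface never inflate the ratio. An undefined ratio
    (no bonded area) is returned as NaN rather than 0.
    """
    if gap.pixel_um != bonded.pixel_um:
        raise ValueError(
            f"pixel size mismatch: gap {gap.pixel_um} µm vs bonded {bonded.pixel_um} µm"
        )
    if gap.mask.shape != bonded.mask.shape:
        raise ValueError("footprint shapes differ")
    n_bonded = int(bonded.mask.sum())
    if n_bonded == 0:
        return float("nan")
    n_gap = int((gap.mask & bonded.mask).sum())
    return 100.0 * n_gap / n_bonded
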