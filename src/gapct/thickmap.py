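"""Local thickness of a binary structure (largest-inscribed-sphere definition).

The thickness at a structure voxel p is the diameter of the largest sphere
that lies entirely inside the structure and contains p. It is computed the
classical way: Euclidean distance transform -> distance ridge (centres whose
inscribed sphere is not contained in a neighbour's sphere) -> sphere
painting, taking at every voxel the largest diameter among covering spheres.

All sphere tests use exact squared integer distances, so the ridge-based
result is identical to painting every structure voxel's sphere. Sphere radii
follow the centre-to-nearest-background-voxel distance convention: an
n-voxel slab reads n for even n and n+1 for odd n, a one-voxel quantization
shared with the common distance-transform implementations of this
definition. The volume border does not bound the structure (spheres may
extend past it); border-limited voxels are flagged ``edge_affected``.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy import ndimage

__all__ = ["ThicknessMap", "local_thickness", "thickness_summary"]

_SUMMARY_FIELDS = ("n_voxels", "min_um", "p5_um", "median_um", "mean_um", "p95_um", "max_um")


@dataclasses.dataclass
class ThicknessMap:
    """Per-voxel local thickness in µm; zero outside the structure.

    ``edge_affected`` flags structure voxels whose assigned sphere crosses
    the volume border, where the field of view truncates the true structure
    and the value is a lower bound.
    """

    values: np.ndarray  # 3D float, µm
    voxel_um: float
    edge_affected: np.ndarray | None = None

    @property
    def structure(self) -> np.ndarray:
        return self.values > 0


def _bounding_slices(mask: np.ndarray, pad: int) -> tuple[slice, ...]:
    sl = []
    for ax in range(mask.ndim):
        other = tuple(i for i in range(mask.ndim) if i != ax)
        hit = np.flatnonzero(mask.any(axis=other))
        sl.append(slice(max(int(hit[0]) - pad, 0), min(int(hit[-1]) + pad + 1, mask.shape[ax])))
    return tuple(sl)


def _squared_radii(m: np.ndarray) -> np.ndarray:
    """Exact squared EDT radii (int64) on the cropped mask; 0 on background."""
    ft = ndimage.distance_transform_edt(m, return_distances=False, return_indices=True)
    zz, yy, xx = np.nonzero(m)
    r2 = np.zeros(m.shape, dtype=np.int64)
    r2[zz, yy, xx] = (
        (ft[0][zz, yy, xx].astype(np.int64) - zz) ** 2
        + (ft[1][zz, yy, xx].astype(np.int64) - yy) ** 2
        + (ft[2][zz, yy, xx].astype(np.int64) - xx) ** 2
    )
    return r2


def _distance_ridge(m: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Drop centres whose sphere is contained in a 26-neighbour's sphere.

    ``r_neighbour >= r + d`` guarantees containment by the triangle
    inequality, so pruned centres never change the painted result.
    """
    covered = np.zeros(m.shape, dtype=bool)
    for off in itertools.product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        d = float(np.sqrt(sum(o * o for o in off)))
        shifted = np.full(m.shape, -np.inf)
        src = tuple(slice(max(-o, 0), m.shape[i] - max(o, 0)) for i, o in enumerate(off))
        dst = tuple(slice(max(o, 0), m.shape[i] + min(o, 0)) for i, o in enumerate(off))
        shifted[dst] = r[src]
        covered |= shifted >= r + d - 1e-9
    return m & ~covered


def _paint_spheres(shape, centers_flat, centers_r2, pshape, pad) -> np.ndarray:
    """Max-diameter sphere painting on a padded flat array (exact, strict d^2 < r^2)."""
    out = np.zeros(int(np.prod(pshape)), dtype=np.int64)
    for rr2 in np.unique(centers_r2)[::-1]:  # descending: first write wins = max
        sel = centers_flat[centers_r2 == rr2]
        ir = int(np.floor(np.sqrt(max(rr2 - 1, 0))))
        ax = np.arange(-ir, ir + 1, dtype=np.int64)
        d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
        oz, oy, ox = np.nonzero(d2 < rr2)
        offs = ((oz - ir) * pshape[1] + (oy - ir)) * pshape[2] + (ox - ir)
        chunk = max(1, 4_000_000 // max(len(offs), 1))
        for i in range(0, len(sel), chunk):
            t = (sel[i : i + chunk, None] + offs[None, :]).ravel()
            t = t[out[t] == 0]
            out[t] = rr2
    return out.reshape(pshape)


def local_thickness(mask: np.ndarray, voxel_um: float = 1.0, quantize: bool = True) -> ThicknessMap:
    """Hildebrand–Rüegsegger local thickness map of a 3D binary mask.

    Values are reported in µm (``2 * radius * voxel_um``); with
    ``quantize=True`` (default) they are rounded to the achievable half-voxel
    resolution. An empty mask returns an all-zero map, not an error.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"mask must be 3D, got {mask.ndim}D")
    if mask.dtype != bool:
        mask = mask.astype(bool)
    if voxel_um <= 0:
        raise ValueError("voxel_um must be > 0")
    if not mask.any():
        return ThicknessMap(
            np.zeros(mask.shape, dtype=np.float64), voxel_um, np.zeros(mask.shape, bool)
        )
    if mask.all():
        raise ValueError("mask has no background voxels; local thickness is unbounded")

    # crop to the structure bounding box (pad 2): every structure voxel's
    # nearest background voxel lies within bbox+1, so distances are exact
    sl = _bounding_slices(mask, pad=2)
    m = mask[sl]
    r2 = _squared_radii(m)
    r = np.sqrt(r2.astype(float))
    centers = _distance_ridge(m, r)

    czyx = np.nonzero(centers)
    cr2 = r2[czyx]
    ir_max = int(np.floor(np.sqrt(max(int(cr2.max()) - 1, 0))))
    pad = ir_max + 1
    pshape = tuple(s + 2 * pad for s in m.shape)
    cflat = (
        ((czyx[0] + pad) * pshape[1] + (czyx[1] + pad)) * pshape[2] + (czyx[2] + pad)
    ).astype(np.int64)
    painted = _paint_spheres(m.shape, cflat, cr2, pshape, pad)
    out_r2 = painted[pad:-pad, pad:-pad, pad:-pad]

    tau_crop = 2.0 * np.sqrt(out_r2.astype(float))
    if quantize:
        tau_crop = np.round(tau_crop * 2.0) / 2.0
    tau_vox = np.zeros(mask.shape, dtype=np.float64)
    tau_vox[sl] = tau_crop
    values = tau_vox * voxel_um

    # voxels whose sphere radius exceeds the distance to the array border
    nz, ny, nx = mask.shape
    bz = np.minimum(np.arange(nz) + 1, nz - np.arange(nz))[:, None, None]
    by = np.minimum(np.arange(ny) + 1, ny - np.arange(ny))[None, :, None]
    bx = np.minimum(np.arange(nx) + 1, nx - np.arange(nx))[None, None, :]
    border = np.minimum(np.minimum(bz, by), bx)
    edge = mask & (border < tau_vox / 2.0)
    return ThicknessMap(values=values, voxel_um=voxel_um, edge_affected=edge)


def thickness_summary(tmap: ThicknessMap) -> dict:
    """Summary statistics (µm) over structure voxels; all-null for an empty map."""
    vals = tmap.values[tmap.structure]
    if vals.size == 0:
        out = {k: None for k in _SUMMARY_FIELDS}
        out["n_voxels"] = 0
        return out
    return {
        "n_voxels": int(vals.size),
        "min_um": float(vals.min()),
        "p5_um": float(np.percentile(vals, 5)),
        "median_um": float(np.median(vals)),
        "mean_um": float(vals.mean()),
        "p95_um": float(np.percentile(vals, 95)),
        "max_um": float(vals.max()),
    }
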