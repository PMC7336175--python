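"""Volume I/O: TIFF stacks with a structured-text (YAML) metadata sidecar.

Two on-disk dialects are supported, both common µCT exports:

* a single multipage TIFF (``volume.tif``) with sidecar ``volume.yaml``;
* a directory of single-slice TIFFs assembled in lexicographic filename
  order, with sidecar ``<dir>/volume.yaml``.

The sidecar records the physical voxel size (µm), the axis order and the
storage policy so that a round trip is lossless for masks, label maps and
32-bit float data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile
import yaml

AXIS_ORDER = "zyx"  # z = tooth/post long axis

_TIFF_SUFFIXES = {".tif", ".tiff"}


@dataclasses.dataclass
class Volume3D:
    """A 3D greyscale (or integer/boolean) voxel array with physical scale.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Grey values; floats are expected in [0, 1] for reconstructed data,
        but integer (label) and boolean (mask) payloads are also carried.
    voxel_um : float
        Isotropic voxel edge length in micrometres.
    meta : dict
        Free-form provenance (rescale policy, source path, ...).
    """

    voxels: np.ndarray
    voxel_um: float
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"Volume3D requires 3 dimensions, got {self.voxels.ndim}")
        if self.voxels.size == 0:
            raise ValueError("Volume3D must be non-empty")
        if not self.voxel_um > 0:
            raise ValueError(f"voxel_um must be > 0, got {self.voxel_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def _sidecar_path(path: Path) -> Path:
    if path.suffix.lower() in _TIFF_SUFFIXES:
        return path.with_suffix(".yaml")
    return path / "volume.yaml"


def _storage_kind(arr: np.ndarray) -> str:
    if arr.dtype == bool:
        return "binary"
    if np.issubdtype(arr.dtype, np.integer):
        return "label"
    return "grey"


def write_stack(volume: Volume3D, path, multipage: bool | None = None) -> Path:
    """Write a volume as TIFF plus a YAML sidecar; returns the sidecar path.

    Boolean masks are stored as uint8 {0, 1}, integers losslessly, floats as
    32-bit. ``path`` ending in .tif/.tiff selects a multipage file; any other
    path is treated as a directory of one TIFF per slice.
    """
    path = Path(path)
    if multipage is None:
        multipage = path.suffix.lower() in _TIFF_SUFFIXES
    arr = volume.voxels
    kind = _storage_kind(arr)
    if kind == "binary":
        stored = arr.astype(np.uint8)
    elif kind == "label":
        stored = arr
    else:
        stored = arr.astype(np.float32)

    if multipage:
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, stored, photometric="minisblack")
    else:
        path.mkdir(parents=True, exist_ok=True)
        ndigit = max(4, len(str(arr.shape[0] - 1)))
        for i, sl in enumerate(stored):
            tifffile.imwrite(path / f"s{i:0{ndigit}d}.tif", sl)

    sidecar = _sidecar_path(path)
    meta = {
        "voxel_um": float(volume.voxel_um),
        "axis_order": AXIS_ORDER,
        "kind": kind,
        "stored_dtype": str(stored.dtype),
        "shape": [int(s) for s in arr.shape],
        "rescale": volume.meta.get("rescale", "none"),
    }
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    return sidecar


def read_stack(path, voxel_um: float | None = None, rescale: bool = False) -> Volume3D:
    """Read a multipage TIFF or a directory of slice TIFFs into a Volume3D.

    The voxel size comes from the YAML sidecar when present, otherwise from
    ``voxel_um``; with neither, an error is raised. With ``rescale=True``
    integer data are divided by their dtype maximum to give floats in [0, 1]
    (recorded in ``meta['rescale']``).
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    meta = {}
    if sidecar.is_file():
        meta = yaml.safe_load(sidecar.read_text()) or {}

    if path.is_dir():
        slices = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES
        )
        if not slices:
            raise FileNotFoundError(f"no TIFF slices found in {path}")
        arrs = []
        for p in slices:
            try:
                arrs.append(tifffile.imread(p))
            except Exception as exc:  # noqa: BLE001 - re-raise naming the slice
                raise OSError(f"unreadable slice {p.name}: {exc}") from exc
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
        arr = np.stack(arrs, axis=0)
    else:
        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise OSError(f"unreadable file {path.name}: {exc}") from exc
        if arr.ndim == 2:
            arr = arr[None]

    vx = meta.get("voxel_um", voxel_um)
    if vx is None:
        raise ValueError(
            f"no voxel size: {sidecar.name} missing and voxel_um not provided"
        )

    out_meta = {"source": str(path), "rescale": "none"}
    if meta.get("kind") == "binary":
        arr = arr.astype(bool)
    elif rescale and np.issubdtype(arr.dtype, np.integer):
        maxval = np.iinfo(arr.dtype).max
        arr = arr.astype(np.float64) / maxval
        out_meta["rescale"] = f"v/{maxval}"
    return Volume3D(arr, float(vx), out_meta)
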