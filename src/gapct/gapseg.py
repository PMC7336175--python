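"""Interfacial gap segmentation: grey-range threshold, 3D connected components,
label selection and a QC overlay.

The route mirrors how voids are isolated from reconstructed tooth volumes in
practice: a grey range covering the gap/air mode of the histogram binarizes
the volume, connected-component labelling separates the candidate voids, and
irrelevant components (air surrounding the tooth, pores inside the resin
bulk) are discarded — either by explicit label ids / seed points, or
automatically by a radial region predicate around the restoration axis.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .geometry import radius_map_um
from .volio import Volume3D

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclasses.dataclass
class GreyRange:
    """Closed grey-value interval [lo, hi] selecting gap voxels."""

    lo: float
    hi: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"need lo <= hi, got [{self.lo}, {self.hi}]")


@dataclasses.dataclass
class LabelMap:
    """Dense 3D component labelling: 0 = background, labels 1..n_labels.

    Labels are assigned in raster-scan order of each component's first voxel
    so the result is deterministic and operator-independent.
    """

    labels: np.ndarray
    n_labels: int
    connectivity: int
    counts: np.ndarray  # counts[k] = voxel count of label k; counts[0] = background

    def __post_init__(self):
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")


def _as_array(volume) -> np.ndarray:
    return volume.voxels if isinstance(volume, Volume3D) else np.asarray(volume)


def threshold_range(volume, grey_range: GreyRange) -> np.ndarray:
    """Boolean mask of voxels with ``lo <= v <= hi`` (closed on both ends)."""
    arr = _as_array(volume)
    vmin, vmax = float(arr.min()), float(arr.max())
    if grey_range.hi < vmin or grey_range.lo > vmax:
        warnings.warn(
            f"grey range [{grey_range.lo}, {grey_range.hi}] lies outside the data "
            f"domain [{vmin:.4g}, {vmax:.4g}]; mask will be empty",
            stacklevel=2,
        )
    return (arr >= grey_range.lo) & (arr <= grey_range.hi)


def suggest_range(
    volume,
    bins: int = 256,
    smooth_sigma: float = 3.0,
    min_prominence: float = 0.01,
) -> GreyRange:
    """Propose a gap grey range [data minimum, first histogram valley].

    The histogram is smoothed with a Gaussian (sigma in bins) and the valley
    is the minimum between the two lowest-grey modes. This automates the
    usual manual reading of the volume histogram; it is advisory — pipelines
    record whether a suggested or manual range was used.

    Raises if fewer than two modes are found (unimodal data need a manual
    range).
    """
    arr = _as_array(volume).ravel()
    vmin, vmax = float(arr.min()), float(arr.max())
    if vmin == vmax:
        raise ValueError("constant volume: histogram is degenerate, supply a manual range")
    counts, edges = np.histogram(arr, bins=bins, range=(vmin, vmax))
    smoothed = ndimage.gaussian_filter1d(counts.astype(float), smooth_sigma, mode="nearest")

    from scipy.signal import find_peaks

    # zero-pad so modes in the first/last bin are still detected as peaks
    padded = np.r_[0.0, smoothed, 0.0]
    peaks, _ = find_peaks(padded, prominence=min_prominence * smoothed.max())
    peaks -= 1
    if len(peaks) < 2:
        raise ValueError(
            "histogram appears unimodal; choose the gap grey range manually"
        )
    lo_peak, hi_peak = sorted(peaks)[:2]
    between = smoothed[lo_peak : hi_peak + 1]
    minima = np.flatnonzero(between == between.min())
    valley_bin = lo_peak + int(minima[len(minima) // 2])  # middle of a flat valley
    centers = 0.5 * (edges[:-1] + edges[1:])
    return GreyRange(vmin, float(centers[valley_bin]))


def label_components(mask: np.ndarray, connectivity: int = 26) -> LabelMap:
    """3D connected-component labelling of a binary mask.

    Connectivity 6/18/26 selects face/edge/vertex adjacency. Components are
    renumbered in raster-scan order of their first voxel; per-label voxel
    counts are returned alongside.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask must be binary, found values {uniq[:8]}")
        mask = mask.astype(bool)
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    raw, n = ndimage.label(mask, structure=structure)
    if n > 0:
        # enforce raster-scan numbering regardless of the labeller's internals
        flat = raw.ravel()
        nz = np.flatnonzero(flat)
        order = flat[nz]
        first = np.full(n + 1, flat.size, dtype=np.int64)
        # first occurrence index of each label
        np.minimum.at(first, order, nz)
        remap = np.zeros(n + 1, dtype=raw.dtype)
        remap[1 + np.argsort(first[1:], kind="stable")] = np.arange(1, n + 1)
        raw = remap[raw]
    counts = np.bincount(raw.ravel(), minlength=n + 1)
    return LabelMap(labels=raw, n_labels=int(n), connectivity=connectivity, counts=counts)


def label_table(labelmap: LabelMap, center=None, voxel_um: float = 1.0):
    """Per-label summary: voxel count, centroid (z, y, x) and centroid radius (µm)."""
    import pandas as pd

    ids = np.arange(1, labelmap.n_labels + 1)
    cents = ndimage.center_of_mass(labelmap.labels > 0, labelmap.labels, ids) if len(ids) else []
    rows = []
    for lid, c in zip(ids, cents):
        row = {
            "label": int(lid),
            "voxels": int(labelmap.counts[lid]),
            "cz": c[0],
            "cy": c[1],
            "cx": c[2],
        }
        if center is not None:
            row["centroid_radius_um"] = float(
                np.hypot(c[1] - center[0], c[2] - center[1]) * voxel_um
            )
        rows.append(row)
    return pd.DataFrame(rows)


def select_labels(
    labelmap: LabelMap,
    keep=None,
    seeds=None,
    annulus_um=None,
    center=None,
    voxel_um: float = 1.0,
    predicate: str = "centroid",
    min_overlap: float = 0.5,
) -> np.ndarray:
    """Binary union of kept labels.

    Exactly one selection route must be given:

    * ``keep``: explicit label ids (the manual route);
    * ``seeds``: (z, y, x) points, keeping the components containing them;
    * ``annulus_um=(r_in, r_out)`` with ``center=(cy, cx)``: region predicate.
      ``predicate="centroid"`` keeps labels whose centroid radius lies in
      [r_in, r_out] (suits compact blobs); ``predicate="overlap"`` keeps
      labels with at least ``min_overlap`` of their voxels inside the
      annulus, which is robust for extended arc-shaped interfacial sheets
      whose centroid falls near the axis.
    """
    labels = labelmap.labels
    given = sum(x is not None for x in (keep, seeds, annulus_um))
    if given != 1:
        raise ValueError("give exactly one of keep=, seeds=, annulus_um=")

    if keep is not None:
        keep = np.atleast_1d(np.asarray(keep, dtype=labels.dtype))
        bad = keep[(keep < 1) | (keep > labelmap.n_labels)]
        if bad.size:
            raise ValueError(f"unknown label id(s): {bad.tolist()}")
        kept = set(int(k) for k in keep)
    elif seeds is not None:
        kept = set()
        for s in seeds:
            lid = int(labels[tuple(int(v) for v in s)])
            if lid == 0:
                raise ValueError(f"seed {tuple(s)} falls on background")
            kept.add(lid)
    else:
        if center is None:
            raise ValueError("annulus selection requires center=(cy, cx)")
        r_in, r_out = annulus_um
        if predicate not in ("centroid", "overlap"):
            raise ValueError(f"unknown predicate {predicate!r}")
        kept = set()
        ids = np.arange(1, labelmap.n_labels + 1)
        if predicate == "centroid":
            cents = ndimage.center_of_mass(labels > 0, labels, ids) if len(ids) else []
            for lid, c in zip(ids, cents):
                rad = np.hypot(c[1] - center[0], c[2] - center[1]) * voxel_um
                if r_in <= rad <= r_out:
                    kept.add(int(lid))
        else:
            r2d = radius_map_um(labels.shape[1:], center, voxel_um)
            inside2d = (r2d >= r_in) & (r2d < r_out)
            inside = np.broadcast_to(inside2d, labels.shape)
            in_counts = np.bincount(
                labels[inside].ravel(), minlength=labelmap.n_labels + 1
            )
            for lid in ids:
                if labelmap.counts[lid] and in_counts[lid] / labelmap.counts[lid] >= min_overlap:
                    kept.add(int(lid))

    if not kept:
        return np.zeros_like(labels, dtype=bool)
    lut = np.zeros(labelmap.n_labels + 1, dtype=bool)
    lut[list(kept)] = True
    return lut[labels]


def overlay_qc(volume, mask: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """RGB verification overlay: greyscale base with mask voxels tinted red.

    Returns a uint8 array of shape (nz, ny, nx, 3). An empty mask yields a
    plain greyscale RGB stack.
    """
    arr = _as_array(volume).astype(float)
    mask = np.asarray(mask, dtype=bool)
    if arr.shape != mask.shape:
        raise ValueError(f"shape mismatch: volume {arr.shape} vs mask {mask.shape}")
    lo, hi = float(arr.min()), float(arr.max())
    grey = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    rgb = np.repeat(grey[..., None], 3, axis=-1)
    rgb[mask, 0] = (1 - alpha) * grey[mask] + alpha  # red channel toward 1
    rgb[mask, 1] = (1 - alpha) * grey[mask]
    rgb[mask, 2] = (1 - alpha) * grey[mask]
    return np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8)
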