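"""Tracer binarization and hemisphere splitting.

The tracer (green) channel is binarized into a positive-voxel volume by
Otsu's between-class-variance criterion (with a manual-threshold override),
and the positive voxels are counted per hemisphere using a manually supplied
separation polyline extruded through the stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BinaryVolume",
    "HemisphereSplit",
    "otsu_threshold",
    "binarize_tracer",
    "split_hemispheres",
    "count_positive_voxels",
    "vertical_midline",
]


@dataclass
class BinaryVolume:
    """Boolean raster of tracer-positive voxels plus threshold provenance."""

    positive: np.ndarray
    mask: np.ndarray
    spacing_um: tuple[float, float, float]
    threshold: float
    method: str

    def __post_init__(self) -> None:
        if self.positive.shape != self.mask.shape:
            raise ValueError("positive and mask shapes differ")
        if bool(np.any(self.positive & ~self.mask)):
            raise ValueError("positive voxels outside the brain mask")


@dataclass
class HemisphereSplit:
    """Per-hemisphere positive-voxel counts relative to a separation surface."""

    ipsi: int
    contra: int
    on_surface: int
    ipsi_side: str  # "left" (smaller column) or "right"

    @property
    def total(self) -> int:
        return self.ipsi + self.contra + self.on_surface


def otsu_threshold(histogram) -> int:
    """Threshold maximizing between-class intensity variance.

    ``histogram`` is either an array of counts indexed by integer intensity,
    or a pair of arrays (values, counts). Classes are {v <= t} and {v > t};
    ties are broken toward the smallest t.
    """
    if isinstance(histogram, tuple):
        values, counts = (np.asarray(histogram[0], dtype=float),
                          np.asarray(histogram[1], dtype=float))
    else:
        counts = np.asarray(histogram, dtype=float)
        values = np.arange(counts.size, dtype=float)
    keep = counts > 0
    values, counts = values[keep], counts[keep]
    order = np.argsort(values)
    values, counts = values[order], counts[order]
    if values.size < 2:
        raise ValueError("degenerate histogram: fewer than two distinct "
                         "intensities with nonzero counts")
    total = counts.sum()
    # candidate thresholds: every distinct value except the largest
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    mu0 = np.cumsum(counts * values)[:-1] / w0
    mu1 = (np.sum(counts * values) - np.cumsum(counts * values)[:-1]) / w1
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    best = int(np.argmax(sigma_b))  # argmax returns the first (smallest t)
    t = values[best]
    return int(t) if float(t).is_integer() else float(t)


def binarize_tracer(volume, channel: str = "tracer",
                    threshold="auto") -> BinaryVolume:
    """Binarize one channel of a VolumeGrid into tracer-positive voxels.

    A voxel is positive iff its intensity is strictly above the threshold
    and it lies inside the brain mask. ``threshold="auto"`` computes Otsu's
    threshold on the masked intensity histogram.
    """
    if channel not in volume.channels:
        raise KeyError(f"channel {channel!r} not in volume")
    data = volume.channels[channel]
    if threshold == "auto":
        vals = np.clip(np.round(data[volume.mask]).astype(np.int64), 0, None)
        hist = np.bincount(vals.ravel())
        t = otsu_threshold(hist)
        method = "otsu"
    else:
        t = float(threshold)
        method = "manual"
    positive = (data > t) & volume.mask
    return BinaryVolume(positive=positive, mask=volume.mask,
                        spacing_um=volume.spacing_um, threshold=float(t),
                        method=method)


def vertical_midline(shape: tuple[int, int, int]) -> np.ndarray:
    """Separation polyline for a vertical midline between the two hemisphere
    column halves (column = cols/2 - 0.5, i.e. between the two centre
    columns for even widths)."""
    _, rows, cols = shape
    c = cols / 2.0 - 0.5
    return np.array([[0.0, c], [rows - 1.0, c]])


def _boundary_cols(polyline: np.ndarray, rows: int) -> np.ndarray:
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2:
        raise ValueError("polyline must be an (n, 2) array of (row, col)")
    order = np.argsort(poly[:, 0])
    pr, pc = poly[order, 0], poly[order, 1]
    if pr[0] > 0 or pr[-1] < rows - 1:
        raise ValueError("separation polyline does not span the full row "
                         "extent")
    return np.interp(np.arange(rows, dtype=float), pr, pc)


def split_hemispheres(binary: BinaryVolume,
                      separation,
                      ipsi_side: str = "left") -> HemisphereSplit:
    """Count positive voxels on each side of a separation surface.

    ``separation`` is an (n, 2) polyline of (row, col) vertices — drawn on a
    projection and extruded through all slices — or a dict mapping slice
    index to a per-slice polyline. A voxel whose column equals the
    interpolated boundary column at its row is counted as on-surface rather
    than assigned by tie-break, which keeps the conservation identity
    ipsi + contra + on_surface = total exact.
    """
    if ipsi_side not in ("left", "right"):
        raise ValueError("ipsi_side must be 'left' or 'right'")
    nsl, rows, _ = binary.positive.shape
    if isinstance(separation, dict):
        boundaries = {}
        for z in range(nsl):
            if z in separation:
                try:
                    boundaries[z] = _boundary_cols(separation[z], rows)
                except ValueError as exc:
                    raise ValueError(f"slice {z}: {exc}") from exc
            elif binary.positive[z].any():
                raise ValueError(
                    f"slice {z} has positive voxels but no separation "
                    "polyline")
    else:
        b = _boundary_cols(separation, rows)
        boundaries = {z: b for z in range(nsl)}

    zz, rr, cc = np.nonzero(binary.positive)
    left = right = on = 0
    for z, r, c in zip(zz, rr, cc):
        bc = boundaries[z][r]
        if c < bc:
            left += 1
        elif c > bc:
            right += 1
        else:
            on += 1
    if ipsi_side == "left":
        ipsi, contra = left, right
    else:
        ipsi, contra = right, left
    return HemisphereSplit(ipsi=ipsi, contra=contra, on_surface=on,
                           ipsi_side=ipsi_side)


def count_positive_voxels(binary: BinaryVolume) -> int:
    """Exact cardinality of the positive set."""
    return int(binary.positive.sum())


def read_separation_csv(path: str):
    """Read separation polylines from CSV (slice_index, vertex_row, vertex_col,
    ordered by appearance within each slice)."""
    df = pd.read_csv(path)
    out = {}
    for z, grp in df.groupby("slice_index", sort=True):
        out[int(z)] = grp[["vertex_row", "vertex_col"]].to_numpy(float)
    return out
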