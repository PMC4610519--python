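"""Foreground extraction from the synthesized image.

Three stages: (1) intensity clustering of the synthesized image — the
brightest cluster is the foreground candidate; (2) a boundary mask from the
modulus-magnitude difference (MMD) between current and reference frames;
(3) a morphological combination that closes the boundary, separates
small satellites (piglets), removes them, and keeps the single largest
connected region as the animal shape.

The intensity clustering is 1-D k-means solved *exactly* by weighted dynamic
programming over the sorted unique values (optimal clusters of sorted 1-D
data are contiguous intervals), so the result is deterministic and attains
the global within-cluster SSE optimum. Images with more than
``_MAX_UNIQUE`` distinct values are quantised to that many bins first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_closing, binary_erosion, binary_fill_holes
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

__all__ = [
    "DetectParams",
    "DetectionResult",
    "kmeans_1d",
    "foreground_by_kmeans",
    "boundary_by_mmd",
    "combine_and_extract",
]

_MAX_UNIQUE = 1024


@dataclass
class DetectParams:
    """k: number of intensity clusters (default 3: background, lit
    background, foreground); mmd_threshold: fixed boundary threshold or
    "otsu" to derive it from the MMD histogram; min_area_frac: components
    smaller than this fraction of the image are removed as clutter (the
    default 0.01 is sized to eliminate piglet-scale blobs and moved-straw
    patches while keeping any sow-scale region);
    se_diameter: diameter in pixels of the circular closing element (3 ->
    the 3×3 cross); min_contrast_ratio: if the brightest cluster centre is
    not at least this factor above the darkest, the frame has no genuine
    foreground contrast (the synthesized image separates foreground
    multiplicatively) and the mask is empty; trim_radius: final erosion in
    pixels compensating the outward bias of unioning the closed boundary
    band (0 disables; the pipeline default uses 2); kmeans_seed: retained
    for interface stability — the exact DP solver needs no randomness."""

    k: int = 3
    mmd_threshold: float | str = "otsu-log"
    min_area_frac: float = 0.01
    se_diameter: int = 3
    min_contrast_ratio: float = 1.5
    trim_radius: int = 0
    kmeans_seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.se_diameter % 2 != 1:
            raise ValueError("se_diameter must be odd")
        if isinstance(self.mmd_threshold, str) and self.mmd_threshold not in (
            "otsu", "otsu-log"
        ):
            raise ValueError("mmd_threshold must be a number, 'otsu' or 'otsu-log'")


@dataclass
class DetectionResult:
    """Final extracted shape with its ellipse summary features."""

    mask: np.ndarray
    area: int
    centroid: tuple[float, float] | None  # (row, col)
    orientation_deg: float | None  # x-axis to major axis, (-90, 90]
    n_components_raw: int


def kmeans_1d(
    values: np.ndarray, k: int, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Globally optimal 1-D k-means by dynamic programming.

    Parameters
    ----------
    values : 1-D array of sample values (need not be sorted or unique).
    k : number of clusters.
    weights : optional non-negative sample weights.

    Returns
    -------
    centers : array of cluster means, ascending.
    labels : cluster index per input value.

    Notes
    -----
    Optimal 1-D clusters are contiguous runs of the sorted unique values, so
    ``D[m][i] = min_j D[m-1][j-1] + sse(j..i)`` solves the problem exactly in
    ``O(k·U²)`` with prefix sums over the ``U`` unique values.
    """
    values = np.asarray(values, dtype=float).ravel()
    if weights is None:
        weights = np.ones_like(values)
    else:
        weights = np.asarray(weights, dtype=float).ravel()
    uniq, inv = np.unique(values, return_inverse=True)
    w = np.bincount(inv, weights=weights).astype(float)
    U = uniq.size
    if U < k:
        warnings.warn(
            f"only {U} distinct values for k={k}; degrading to k={U}"
        )
        k = U
    # prefix sums for weighted SSE of runs
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwv = np.concatenate([[0.0], np.cumsum(w * uniq)])
    cwv2 = np.concatenate([[0.0], np.cumsum(w * uniq * uniq)])

    def run_cost(j: np.ndarray, i: int) -> np.ndarray:
        s0 = cw[i + 1] - cw[j]
        s1 = cwv[i + 1] - cwv[j]
        s2 = cwv2[i + 1] - cwv2[j]
        return s2 - s1 * s1 / s0

    D = np.empty((k, U))
    split = np.zeros((k, U), dtype=int)
    zeros = np.zeros(1, dtype=int)
    D[0, :] = [run_cost(zeros, i)[0] for i in range(U)]
    for m in range(1, k):
        for i in range(U):
            # first m values must feed the earlier clusters
            j = np.arange(max(1, m), i + 1) if i >= m else np.array([i])
            cand = D[m - 1, j - 1] + run_cost(j, i)
            best = int(np.argmin(cand))
            D[m, i] = cand[best]
            split[m, i] = j[best]
    # backtrack interval starts
    starts = np.empty(k, dtype=int)
    i = U - 1
    for m in range(k - 1, -1, -1):
        starts[m] = split[m, i] if m > 0 else 0
        i = starts[m] - 1
    bounds = np.append(starts, U)
    uniq_labels = np.empty(U, dtype=int)
    centers = np.empty(k)
    for m in range(k):
        lo, hi = bounds[m], bounds[m + 1]
        uniq_labels[lo:hi] = m
        centers[m] = (cwv[hi] - cwv[lo]) / (cw[hi] - cw[lo])
    return centers, uniq_labels[inv]


def foreground_by_kmeans(
    synthesized: np.ndarray, params: DetectParams | None = None
) -> np.ndarray:
    """Foreground mask: pixels of the brightest of ``k`` intensity clusters.

    A frame whose brightest cluster is not meaningfully brighter than its
    darkest (see ``min_contrast_ratio``) carries no foreground and yields an
    empty mask — k-level quantisation of a contrast-free image is noise. A
    constant image degenerates to a single cluster and an all-true mask.
    """
    params = params or DetectParams()
    syn = np.asarray(synthesized, dtype=float)
    if not np.all(np.isfinite(syn)):
        raise ValueError("synthesized image must be finite")
    flat = syn.ravel()
    uniq = np.unique(flat)
    if uniq.size > _MAX_UNIQUE:
        lo, hi = uniq[0], uniq[-1]
        idx = np.minimum(
            ((flat - lo) / (hi - lo) * _MAX_UNIQUE).astype(int), _MAX_UNIQUE - 1
        )
        counts = np.bincount(idx, minlength=_MAX_UNIQUE).astype(float)
        sums = np.bincount(idx, weights=flat, minlength=_MAX_UNIQUE)
        occupied = counts > 0
        reps = sums[occupied] / counts[occupied]
        centers, rep_labels = kmeans_1d(reps, params.k, weights=counts[occupied])
        lut = np.zeros(_MAX_UNIQUE, dtype=int)
        lut[occupied] = rep_labels
        labels = lut[idx]
    else:
        centers, labels = kmeans_1d(flat, params.k)
    top = int(np.argmax(centers))
    if centers.size >= 2:
        lo = max(float(centers.min()), 1e-6)
        if float(centers.max()) < params.min_contrast_ratio * lo:
            return np.zeros(syn.shape, dtype=bool)
    return (labels == top).reshape(syn.shape)


def boundary_by_mmd(
    mmd: np.ndarray, params: DetectParams | None = None
) -> np.ndarray:
    """Boundary mask: pixels whose MMD strictly exceeds the threshold.

    ``mmd_threshold`` may be a fixed value, ``"otsu"`` (Otsu's threshold on
    the raw MMD histogram) or ``"otsu-log"`` — the default: a two-stage Otsu
    on the ``log1p`` histogram. The first stage separates changed from
    unchanged pixels; the second stage, applied within the changed class,
    separates strong object boundaries from moderate ambient change (moved
    bedding, globally rescaled texture after a lamp switch). MMD magnitudes
    are long-tailed, hence the log domain. A constant MMD field yields an
    empty mask.
    """
    params = params or DetectParams()
    mmd = np.asarray(mmd, dtype=float)
    if np.any(mmd < 0):
        raise ValueError("MMD values must be non-negative")
    th = params.mmd_threshold
    if isinstance(th, str):
        if np.ptp(mmd) == 0:
            return np.zeros(mmd.shape, dtype=bool)
        if th == "otsu":
            th = threshold_otsu(mmd)
        else:
            th = np.expm1(threshold_otsu(np.log1p(mmd)))
            changed = mmd[mmd > th]
            # refine within the changed class when it is large enough to
            # carry a histogram of its own
            if changed.size > max(256, mmd.size // 1000) and np.ptp(changed) > 0:
                th = np.expm1(threshold_otsu(np.log1p(changed)))
    return mmd > th


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_area`` pixels."""
    if min_area <= 1:
        return mask
    lab, n = label(mask, connectivity=2, return_num=True)
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return keep[lab]


def _shape_features(mask: np.ndarray):
    props = regionprops(mask.astype(np.uint8))
    if not props:
        return None, None
    p = props[0]
    centroid = tuple(float(c) for c in p.centroid)
    if p.area < 5:
        return centroid, None
    # regionprops measures counterclockwise from the row axis; convert to
    # the angle between the x-axis (columns) and the major axis, y up.
    deg = 90.0 + np.degrees(float(p.orientation))
    deg = ((deg + 90.0) % 180.0) - 90.0
    if deg == -90.0:
        deg = 90.0
    return centroid, deg


def combine_and_extract(
    fg: np.ndarray, bou: np.ndarray, params: DetectParams | None = None
) -> DetectionResult:
    """Combine cluster and boundary masks into the final animal shape.

    Steps: close the boundary mask with the circular structuring element;
    take the absolute difference with the cluster mask (separating animal
    body from satellite blobs) and drop small components; OR the result back
    with the closed boundary and drop small components again; keep the
    largest 8-connected component and fill its holes; optionally erode by
    ``trim_radius`` to undo the outward growth the boundary band adds.
    """
    params = params or DetectParams()
    fg = np.asarray(fg, dtype=bool)
    bou = np.asarray(bou, dtype=bool)
    if fg.shape != bou.shape:
        raise ValueError("masks must share a shape")
    min_area = int(np.ceil(params.min_area_frac * fg.size))
    se = disk((params.se_diameter - 1) // 2)
    closed = binary_closing(bou, structure=se)
    sub = fg ^ closed
    sub = _remove_small(sub, min_area)
    com = sub | closed
    com = _remove_small(com, min_area)
    lab, n = label(com, connectivity=2, return_num=True)
    if n == 0:
        return DetectionResult(
            np.zeros(fg.shape, dtype=bool), 0, None, None, 0
        )
    sizes = np.bincount(lab.ravel())[1:]
    keep = int(np.argmax(sizes)) + 1
    final = binary_fill_holes(lab == keep)
    if params.trim_radius > 0:
        trimmed = binary_erosion(final, structure=disk(params.trim_radius))
        if trimmed.any():
            # erosion may split thin necks; keep the dominant piece
            lab2, n2 = label(trimmed, connectivity=2, return_num=True)
            if n2 > 1:
                sizes2 = np.bincount(lab2.ravel())[1:]
                trimmed = lab2 == (int(np.argmax(sizes2)) + 1)
            final = trimmed
    centroid, orientation = _shape_features(final)
    return DetectionResult(
        final, int(final.sum()), centroid, orientation, int(n)
    )
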