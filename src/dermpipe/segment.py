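"""Grey-level clustering segmentation and lesion-mask extraction.

Segmentation is a deterministic k-means over the 256-bin grey-level
histogram rather than over pixels: each occurring grey level is assigned
to the nearest centroid by absolute intensity distance, and each
centroid is recomputed as the pixel-frequency-weighted mean intensity of
its member levels.  The cost per iteration is O(256 * B) regardless of
image size.  Lesions are darker than the surrounding skin, so the lesion
mask is the cluster with the lowest centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, DomainError

N_LEVELS = 256


@dataclass
class SegmentationResult:
    """Cluster centroids, per-level assignment, and per-pixel label map."""

    centroids: np.ndarray  # (B,) grey levels
    level_assignment: np.ndarray  # (256,) cluster index per grey level
    label_map: np.ndarray  # (H, W) cluster index per pixel
    iterations: int
    populated: np.ndarray  # (B,) bool, cluster has at least one pixel


def _quantize(image: np.ndarray) -> np.ndarray:
    return np.clip(np.round(np.asarray(image, dtype=np.float64)), 0, N_LEVELS - 1).astype(np.int64)


def cluster_intensities(
    image: np.ndarray,
    n_clusters: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> SegmentationResult:
    """Histogram k-means over grey levels.

    Centroids start evenly spaced at ``min + (k + 0.5) * range / B``
    over the image's occurring intensity range (a fixed 0-255 spread
    strands clusters empty when the image occupies a narrow band) and
    are updated as frequency-weighted means; assignment ties go to the
    lower cluster index and empty clusters keep their previous centroid.
    The loop stops when the largest centroid shift is <= tol.  Fully
    deterministic (no randomness involved).
    """
    if n_clusters <= 0:
        raise DomainError("n_clusters must be positive")
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise DomainError("image is empty")

    levels = _quantize(image)
    freq = np.bincount(levels.ravel(), minlength=N_LEVELS).astype(np.float64)
    grey = np.arange(N_LEVELS, dtype=np.float64)
    occurring = freq > 0

    lo, hi = grey[occurring].min(), grey[occurring].max()
    centroids = lo + (np.arange(n_clusters) + 0.5) * (hi - lo + 1) / n_clusters
    assignment = np.zeros(N_LEVELS, dtype=np.int64)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # argmin of |B_k - a_i|; np.argmin takes the first (lowest) index on ties
        dist = np.abs(centroids[:, None] - grey[None, :])
        assignment = np.argmin(dist, axis=0)
        new_centroids = centroids.copy()
        for k in range(n_clusters):
            member = occurring & (assignment == k)
            weight = freq[member].sum()
            if weight > 0:
                new_centroids[k] = (freq[member] * grey[member]).sum() / weight
        shift = np.max(np.abs(new_centroids - centroids))
        centroids = new_centroids
        if shift <= tol:
            break
    # final assignment against the converged centroids
    assignment = np.argmin(np.abs(centroids[:, None] - grey[None, :]), axis=0)

    populated = np.zeros(n_clusters, dtype=bool)
    for k in range(n_clusters):
        populated[k] = bool(freq[occurring & (assignment == k)].sum() > 0)

    return SegmentationResult(
        centroids=centroids,
        level_assignment=assignment,
        label_map=assignment[levels],
        iterations=iterations,
        populated=populated,
    )


def within_cluster_cost(image: np.ndarray, seg: SegmentationResult) -> float:
    """Frequency-weighted within-cluster squared deviation (the k-means objective)."""
    levels = _quantize(image)
    centroid_per_pixel = seg.centroids[seg.level_assignment[levels]]
    return float(np.sum((levels.astype(np.float64) - centroid_per_pixel) ** 2))


def lesion_mask(seg: SegmentationResult) -> np.ndarray:
    """Boolean mask of the populated cluster with the lowest centroid.

    Raises :class:`DegenerateInputError` when only a single cluster is
    populated (constant image): the darkest-cluster rule would then
    select the whole frame or nothing.
    """
    populated_idx = np.flatnonzero(seg.populated)
    if populated_idx.size < 2:
        raise DegenerateInputError("fewer than two populated clusters: lesion mask undefined")
    darkest = populated_idx[np.argmin(seg.centroids[populated_idx])]
    return seg.label_map == darkest


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero out pixels outside the mask; pixels inside are unchanged."""
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise DomainError("image and mask shapes differ")
    if image.ndim == 3:
        return image * mask[..., None]
    return image * mask
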