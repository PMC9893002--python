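"""Isolate a single tree from a raw capture: range cropping and
Statistical Outlier Removal (SOR).

SOR computes, for every point, the mean Euclidean distance ``d_i`` to its
``k`` nearest neighbors (the query point itself excluded) and removes the
point when ``d_i > mu + lambda * sigma``, where ``mu`` and ``sigma`` are
the mean and standard deviation of the ``d_i`` over the whole cloud.
``lambda`` is the standard-deviation multiplier ("scaling factor"):
smaller values remove more aggressively; useful values are typically in
[0, 1].  The best-performing setting on leafless orchard captures is
``k = 40, lambda = 0.2``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud

log = logging.getLogger(__name__)


@dataclass
class SorParams:
    k: int = 40
    lam: float = 0.2

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def crop_region(
    cloud: PointCloud,
    box: Optional[Tuple] = None,
    max_distance: Optional[float] = None,
) -> PointCloud:
    """Keep points inside an axis-aligned box and/or within a radial
    distance threshold from the origin.

    ``box`` is ``(xmin, ymin, zmin, xmax, ymax, zmax)``; points on the
    boundary are kept.  Order of surviving points is preserved and labels
    and colors are carried along.
    """
    if box is None and max_distance is None:
        raise ValueError("provide a box or a max distance")
    mask = np.ones(len(cloud), dtype=bool)
    if box is not None:
        lo = np.asarray(box[:3], float)
        hi = np.asarray(box[3:], float)
        if np.any(lo >= hi):
            raise ValueError("box must satisfy min < max on every axis")
        mask &= np.all((cloud.points >= lo) & (cloud.points <= hi), axis=1)
    if max_distance is not None:
        if max_distance <= 0:
            raise ValueError("max distance must be positive")
        mask &= np.linalg.norm(cloud.points, axis=1) < max_distance
    if not mask.any():
        log.warning("crop removed every point")
    return cloud.select(mask)


def mean_knn_distances(points: np.ndarray, k: int) -> np.ndarray:
    """Per-point mean distance to the k nearest neighbors (self excluded)."""
    points = np.asarray(points, float)
    if len(points) <= k:
        raise ValueError(f"cloud size {len(points)} must exceed k={k}")
    tree = cKDTree(points)
    d, _ = tree.query(points, k=k + 1)
    return d[:, 1:].mean(axis=1)


def remove_outliers(cloud: PointCloud, params: SorParams = SorParams()) -> Tuple[PointCloud, np.ndarray]:
    """Statistical Outlier Removal.

    Returns the inlier cloud (input order preserved) and the boolean mask
    of removed points.
    """
    d = mean_knn_distances(cloud.points, params.k)
    mu, sigma = d.mean(), d.std()
    removed = d > mu + params.lam * sigma
    log.info("SOR removed %d / %d points (k=%d, lambda=%.3g)",
             removed.sum(), len(cloud), params.k, params.lam)
    return cloud.select(~removed), removed
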