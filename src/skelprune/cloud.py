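"""Point cloud container.

All coordinates throughout the package are centimetres in a right-handed
frame with the z axis pointing up.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class PointCloud:
    """Unordered 3D points with optional per-point colors and integer labels.

    Parameters
    ----------
    points
        ``(n, 3)`` float array, centimetres.
    colors
        Optional ``(n, 3)`` uint8 RGB array.
    labels
        Optional ``(n,)`` integer array (branch ids, marker tags, ...).
    """

    points: np.ndarray
    colors: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
            if len(self.colors) != len(self.points):
                raise ValueError("colors length mismatch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
            if len(self.labels) != len(self.points):
                raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask_or_index) -> "PointCloud":
        """Subset the cloud, carrying colors and labels along."""
        idx = np.asarray(mask_or_index)
        return PointCloud(
            self.points[idx],
            None if self.colors is None else self.colors[idx],
            None if self.labels is None else self.labels[idx],
        )

    def concat(self, other: "PointCloud") -> "PointCloud":
        pts = np.vstack([self.points, other.points])

        def _merge(a, b, fill, dtype):
            if a is None and b is None:
                return None
            if a is None:
                a = np.full((len(self.points),) + b.shape[1:], fill, dtype=dtype)
            if b is None:
                b = np.full((len(other.points),) + a.shape[1:], fill, dtype=dtype)
            return np.concatenate([a, b])

        return PointCloud(
            pts,
            _merge(self.colors, other.colors, 128, np.uint8),
            _merge(self.labels, other.labels, -1, np.int64),
        )
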