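"""Masked 4-D voxel time-series container."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["VolumeSeries"]


@dataclass
class VolumeSeries:
    """A subject's 4-D scan: spatial grid x time, with a brain mask.

    ``data`` has shape (nx, ny, nz, n_scans); ``mask`` is a boolean volume of
    shape (nx, ny, nz).  Out-of-mask voxels never enter any statistic.
    """

    data: np.ndarray
    mask: np.ndarray
    tr: float
    subject_id: str = "sub-00"
    group: str = "none"
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4-D, got shape {self.data.shape}")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match spatial shape "
                f"{self.data.shape[:3]}"
            )
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("non-finite values inside the mask")

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def masked(self) -> np.ndarray:
        """In-mask time series as (n_voxels, n_scans)."""
        return self.data[self.mask]

    def with_masked(self, values: np.ndarray) -> "VolumeSeries":
        """New VolumeSeries with in-mask voxels replaced by ``values``."""
        out = np.zeros_like(self.data)
        out[self.mask] = values
        return replace(self, data=out)

    def unflatten(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-in-mask-voxel vector back into a 3-D volume."""
        vol = np.full(self.spatial_shape, fill)
        vol[self.mask] = values
        return vol
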