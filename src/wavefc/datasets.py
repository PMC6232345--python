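"""In-memory containers for masked BOLD-like time-series data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BoldDataset"]


@dataclass
class BoldDataset:
    """Per-subject masked voxel-by-time matrix with sampling metadata.

    ``data`` has shape ``(n_voxels, n_timepoints)``.  When a 3-D binary
    ``mask`` is attached, row ``i`` of ``data`` corresponds to the ``i``-th
    ``True`` voxel of the mask in C (row-major) flattening order; this
    ordering is fixed and shared by every array the pipeline derives.
    """

    data: np.ndarray
    tr_seconds: float
    mask: np.ndarray | None = None
    subject_id: str = "sub-0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (voxel x time) array")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if int(self.mask.sum()) != self.n_voxels:
                raise ValueError(
                    f"mask selects {int(self.mask.sum())} voxels but data has "
                    f"{self.n_voxels} rows"
                )

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def fs(self) -> float:
        """Sampling frequency in Hz (1 / TR)."""
        return 1.0 / self.tr_seconds

    def to_volume(self, fill: float = 0.0) -> np.ndarray:
        """Scatter the masked matrix back into a 4-D volume (x, y, z, t)."""
        if self.mask is None:
            raise ValueError("dataset carries no mask")
        vol = np.full(self.mask.shape + (self.n_timepoints,), fill, dtype=float)
        vol[self.mask] = self.data
        return vol

    @classmethod
    def from_volume(
        cls,
        volume: np.ndarray,
        mask: np.ndarray,
        tr_seconds: float,
        subject_id: str = "sub-0",
    ) -> "BoldDataset":
        volume = np.asarray(volume, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if volume.ndim != 4:
            raise ValueError("volume must be 4-D (x, y, z, t)")
        if volume.shape[:3] != mask.shape:
            raise ValueError("volume and mask shapes disagree")
        return cls(
            data=volume[mask], tr_seconds=tr_seconds, mask=mask, subject_id=subject_id
        )
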