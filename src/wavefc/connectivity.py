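"""Group-level per-packet functional connectivity.

Functional connectivity is defined as the Pearson correlation between the
real-valued wavelet packet coefficients of voxel pairs, computed on the
group matrix formed by concatenating one packet's coefficients voxel-by-
voxel across all subjects.  Distances are ``1 - r``; neighbor graphs keep,
per voxel, the top fraction (default 5%) most strongly correlating other
voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .wavelets import PacketAddress

__all__ = [
    "GroupPacketMatrix",
    "NeighborGraph",
    "concatenate_group",
    "correlation_distance",
    "top_fraction_neighbors",
    "ZeroVarianceWarning",
]


class ZeroVarianceWarning(UserWarning):
    """A voxel row had zero variance; its correlations are undefined."""


@dataclass
class GroupPacketMatrix:
    """Voxel x concatenated-coefficient matrix for one packet.

    Columns are ordered by subject, then coefficient index;
    ``subject_offsets[s]`` is the first column of subject ``s``'s block.
    Row order is the mask voxel order and is identical across packets.
    """

    data: np.ndarray
    subject_offsets: np.ndarray
    address: PacketAddress | None = None
    zscored: bool = True

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_offsets)


def _zscore_rows(block: np.ndarray) -> np.ndarray:
    mean = block.mean(axis=1, keepdims=True)
    std = block.std(axis=1, keepdims=True)
    safe = np.where(std == 0, 1.0, std)
    return (block - mean) / safe


def concatenate_group(
    per_subject_coefficients: list[np.ndarray],
    address: PacketAddress | None = None,
    zscore: bool = True,
) -> GroupPacketMatrix:
    """Concatenate one packet's coefficients across subjects.

    Each subject contributes a ``(n_voxels, n_coeffs)`` block; blocks are
    z-scored per voxel before concatenation (toggle with ``zscore``) so
    between-subject amplitude differences do not dominate the pooled
    correlations.
    """
    if not per_subject_coefficients:
        raise ValueError("no subjects given")
    blocks = [np.atleast_2d(np.asarray(b, dtype=float)) for b in per_subject_coefficients]
    n_voxels = blocks[0].shape[0]
    n_coeffs = blocks[0].shape[1]
    for s, b in enumerate(blocks):
        if b.shape[0] != n_voxels:
            raise ValueError(
                f"subject {s} has {b.shape[0]} voxels, expected {n_voxels}"
            )
        if b.shape[1] != n_coeffs:
            raise ValueError(
                f"subject {s} has {b.shape[1]} coefficients, expected {n_coeffs}"
            )
    if zscore:
        blocks = [_zscore_rows(b) for b in blocks]
    offsets = np.arange(len(blocks)) * n_coeffs
    return GroupPacketMatrix(
        data=np.concatenate(blocks, axis=1),
        subject_offsets=offsets,
        address=address,
        zscored=zscore,
    )


def correlation_distance(matrix) -> np.ndarray:
    """Pearson correlation distance ``1 - r`` between all voxel rows.

    Returns a symmetric matrix with zero diagonal and values in [0, 2].
    Zero-variance rows have undefined correlations; they are flagged with a
    :class:`ZeroVarianceWarning` and their distances set to NaN so callers
    can exclude them explicitly.
    """
    data = matrix.data if isinstance(matrix, GroupPacketMatrix) else np.asarray(matrix, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 columns")
    std = data.std(axis=1)
    bad = np.flatnonzero(std == 0)
    if bad.size:
        warnings.warn(
            f"{bad.size} zero-variance voxel row(s) {bad[:10].tolist()}...: "
            "correlation undefined, distances set to NaN",
            ZeroVarianceWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    dist = 1.0 - r
    np.clip(dist, 0.0, 2.0, out=dist)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    if bad.size:
        dist[bad, :] = np.nan
        dist[:, bad] = np.nan
    return dist


@dataclass
class NeighborGraph:
    """Per-voxel binary top-``fraction`` neighbor sets.

    ``indicator[i, j]`` is True when voxel ``j`` is among the ``k`` other
    voxels most correlated with voxel ``i`` (smallest ``1 - r``), with
    ``k = round(fraction * (n_voxels - 1))``; the voxel itself is excluded.
    """

    indicator: np.ndarray
    fraction: float
    k: int
    source: str = ""

    @property
    def n_voxels(self) -> int:
        return self.indicator.shape[0]


def top_fraction_neighbors(
    distance_matrix: np.ndarray,
    fraction: float = 0.05,
    source: str = "",
) -> NeighborGraph:
    """Binary nearest-neighbor graph keeping the closest ``fraction`` of voxels.

    Ties at the k-th smallest distance are broken toward the lower voxel
    index (stable sort), making the graph deterministic.
    """
    dist = np.asarray(distance_matrix, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    n = dist.shape[0]
    k = int(round(fraction * (n - 1)))
    if k == 0:
        raise ValueError(
            f"fraction {fraction} keeps zero neighbors at n={n}; "
            "increase fraction or voxel count"
        )
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN (excluded voxels?)")
    work = dist.copy()
    np.fill_diagonal(work, np.inf)
    order = np.argsort(work, axis=1, kind="stable")
    indicator = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    indicator[rows, order[:, :k].ravel()] = True
    return NeighborGraph(indicator=indicator, fraction=fraction, k=k, source=source)
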