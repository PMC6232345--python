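"""Voxelwise Jaccard comparison of subband neighbor graphs against a wideband reference.

For every voxel, the top-5% neighbor set computed from one wavelet packet
is compared, via the Jaccard distance

    JD(v, w) = #[(v_j != w_j) and (v_j != 0 or w_j != 0)] / #[(v_j != 0 or w_j != 0)],

to the corresponding neighbor set of a *wideband* signal — the inverse WPT
of a selected packet subset (all other coefficients zeroed).  The default
subset is the six analysis packets D6P1, D5P1, D4P1, D5P4, D5P5 and D4P3,
which tile roughly 12–194 mHz.  Graphs are built per subject; the map
reports each voxel's mean and standard deviation of JD across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import NeighborGraph, correlation_distance, top_fraction_neighbors
from .wavelets import (
    DEFAULT_MAX_DEPTH,
    DEFAULT_MODE,
    DEFAULT_WAVELET,
    PacketAddress,
    wpt_decompose,
    wpt_reconstruct,
)

__all__ = [
    "DEFAULT_WIDEBAND_PACKETS",
    "JaccardMap",
    "jaccard_distance",
    "jaccard_distance_rows",
    "build_wideband_reference",
    "voxelwise_jaccard_map",
]

#: six packets tiling ~12-194 mHz at fs = 1/0.645 Hz
DEFAULT_WIDEBAND_PACKETS = (
    PacketAddress(6, 1),
    PacketAddress(5, 1),
    PacketAddress(4, 1),
    PacketAddress(5, 4),
    PacketAddress(5, 5),
    PacketAddress(4, 3),
)


def jaccard_distance(v: np.ndarray, w: np.ndarray) -> float:
    """Jaccard distance between two binary indicator vectors.

    0 for identical non-empty sets, 1 for disjoint non-empty sets.  Raises
    when both vectors are all-zero (the distance is undefined).
    """
    v = np.asarray(v).astype(bool)
    w = np.asarray(w).astype(bool)
    if v.shape != w.shape:
        raise ValueError(f"length mismatch: {v.shape} vs {w.shape}")
    union = int((v | w).sum())
    if union == 0:
        raise ValueError("Jaccard distance undefined: both sets are empty")
    return float((v ^ w).sum() / union)


def jaccard_distance_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Jaccard distances between two binary matrices."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = (a | b).sum(axis=1)
    if (union == 0).any():
        raise ValueError("Jaccard distance undefined for all-empty row(s)")
    return (a ^ b).sum(axis=1) / union


@dataclass
class JaccardMap:
    """Per-voxel mean/std Jaccard distance across subjects."""

    mean: np.ndarray
    std: np.ndarray
    packet: str = ""
    reference: str = ""

    @property
    def n_voxels(self) -> int:
        return self.mean.shape[0]


def build_wideband_reference(
    per_subject_series: list[np.ndarray],
    selected_packets=DEFAULT_WIDEBAND_PACKETS,
    fraction: float = 0.05,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_MODE,
    max_depth: int = DEFAULT_MAX_DEPTH,
    fs: float = 1.0,
    per_subject_trees=None,
) -> list[NeighborGraph]:
    """Per-subject neighbor graphs of the wideband (packet-subset) signal.

    For each subject the voxel series are decomposed, all packets outside
    ``selected_packets`` are zeroed, the inverse WPT rebuilds the wideband
    series, and the top-``fraction`` correlation neighbor graph is taken.
    Pass ``per_subject_trees`` to reuse existing decompositions.
    """
    selected = [
        PacketAddress.parse(a) if isinstance(a, str) else a for a in selected_packets
    ]
    graphs = []
    desc = "wideband:" + "+".join(str(a) for a in selected)
    if per_subject_trees is None:
        per_subject_trees = [
            wpt_decompose(s, max_depth=max_depth, wavelet=wavelet, mode=mode, fs=fs)
            for s in per_subject_series
        ]
    for tree in per_subject_trees:
        wideband = wpt_reconstruct(tree, selected)
        dist = correlation_distance(wideband)
        graphs.append(top_fraction_neighbors(dist, fraction=fraction, source=desc))
    return graphs


def voxelwise_jaccard_map(
    packet_graphs_per_subject: list[NeighborGraph],
    reference_graphs_per_subject: list[NeighborGraph],
    packet: str = "",
    reference: str = "",
) -> JaccardMap:
    """Mean and std across subjects of per-voxel Jaccard distances.

    Subject ``s`` contributes, for each voxel ``i``, the Jaccard distance
    between voxel ``i``'s neighbor row in the packet graph and in the
    reference graph.
    """
    if len(packet_graphs_per_subject) != len(reference_graphs_per_subject):
        raise ValueError(
            f"subject count mismatch: {len(packet_graphs_per_subject)} packet "
            f"graphs vs {len(reference_graphs_per_subject)} reference graphs"
        )
    if not packet_graphs_per_subject:
        raise ValueError("need at least one subject")
    per_subject = []
    for pg, rg in zip(packet_graphs_per_subject, reference_graphs_per_subject):
        if pg.indicator.shape != rg.indicator.shape:
            raise ValueError("graphs do not share a voxel set")
        per_subject.append(jaccard_distance_rows(pg.indicator, rg.indicator))
    stack = np.stack(per_subject)
    return JaccardMap(
        mean=stack.mean(axis=0),
        std=stack.std(axis=0),
        packet=packet or (packet_graphs_per_subject[0].source or ""),
        reference=reference or (reference_graphs_per_subject[0].source or ""),
    )
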