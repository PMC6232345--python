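"""Reading and writing of pipeline artifacts.

Volumes travel as NIfTI (via nibabel), packet coefficient stores as HDF5
with a JSON sidecar, tabular results (partitions, VI matrices, Jaccard
maps, linkage tables) as CSV, and ground truth / manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .clustering import LinkageTree, Partition
from .datasets import BoldDataset
from .partition_compare import VIMatrix
from .synthetic import GroundTruth
from .voxel_compare import JaccardMap
from .wavelets import PacketAddress, PacketTree, packet_passband

__all__ = [
    "save_bold_nifti",
    "load_bold_nifti",
    "save_mask_nifti",
    "load_mask_nifti",
    "save_ground_truth",
    "load_ground_truth",
    "save_packet_store",
    "load_packet_store",
    "save_linkage_csv",
    "load_linkage_csv",
    "save_partition_csv",
    "load_partition_csv",
    "save_vi_matrix_csv",
    "load_vi_matrix_csv",
    "save_jaccard_map_csv",
    "save_neighbor_graph",
    "load_neighbor_graph",
]


def save_bold_nifti(dataset: BoldDataset, path) -> None:
    vol = dataset.to_volume()
    img = nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4))
    img.header["pixdim"][4] = dataset.tr_seconds
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def load_bold_nifti(path, mask: np.ndarray, tr_seconds: float | None = None,
                    subject_id: str = "sub-0") -> BoldDataset:
    img = nib.load(str(path))
    tr = tr_seconds if tr_seconds is not None else float(img.header["pixdim"][4])
    if tr <= 0:
        raise ValueError(f"no repetition time in header of {path}; pass tr_seconds")
    return BoldDataset.from_volume(
        np.asarray(img.dataobj, dtype=float), mask, tr, subject_id=subject_id
    )


def save_mask_nifti(mask: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine=np.eye(4)), str(path))


def load_mask_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_ground_truth(truth: GroundTruth, path, config_echo: dict | None = None) -> None:
    payload = {
        "partitions": [p.tolist() for p in truth.partitions],
        "passbands_hz": [list(b) for b in truth.passbands],
        "config": config_echo or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        partitions=[np.asarray(p) for p in payload["partitions"]],
        passbands=[tuple(b) for b in payload["passbands_hz"]],
        signals=[],
    )


def save_packet_store(tree: PacketTree, path, subject_id: str = "sub-0") -> None:
    """One HDF5 dataset per packet plus a JSON sidecar of band metadata."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs.update(
            {
                "source_length": tree.source_length,
                "max_depth": tree.max_depth,
                "fs": tree.fs,
                "wavelet": tree.wavelet,
                "mode": tree.mode,
                "subject_id": subject_id,
            }
        )
        for addr, coeffs in tree.nodes.items():
            f.create_dataset(str(addr), data=coeffs)
    sidecar = {
        "subject_id": subject_id,
        "fs": tree.fs,
        "wavelet": tree.wavelet,
        "mode": tree.mode,
        "max_depth": tree.max_depth,
        "packets": {
            str(a): {"depth": a.depth, "position": a.position,
                     "passband_hz": list(packet_passband(a, tree.fs))}
            for a in tree.nodes
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_packet_store(path) -> PacketTree:
    with h5py.File(str(path), "r") as f:
        nodes = {PacketAddress.parse(name): f[name][()] for name in f}
        return PacketTree(
            nodes=nodes,
            source_length=int(f.attrs["source_length"]),
            max_depth=int(f.attrs["max_depth"]),
            fs=float(f.attrs["fs"]),
            wavelet=str(f.attrs["wavelet"]),
            mode=str(f.attrs["mode"]),
        )


def save_linkage_csv(tree: LinkageTree, path) -> None:
    pd.DataFrame(
        tree.merges, columns=["left", "right", "height", "size"]
    ).to_csv(path, index=False)


def load_linkage_csv(path) -> LinkageTree:
    merges = pd.read_csv(path).to_numpy(dtype=float)
    return LinkageTree(merges=merges, n_leaves=merges.shape[0] + 1)


def save_partition_csv(partition: Partition, path) -> None:
    pd.DataFrame(
        {"voxel": np.arange(len(partition)), "label": partition.labels}
    ).to_csv(path, index=False)
    meta = {k: _jsonable(v) for k, v in partition.provenance.items()}
    Path(path).with_suffix(".json").write_text(json.dumps(meta))


def load_partition_csv(path) -> Partition:
    df = pd.read_csv(path)
    sidecar = Path(path).with_suffix(".json")
    prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Partition(labels=df["label"].to_numpy(), provenance=prov)


def save_vi_matrix_csv(vim: VIMatrix, path) -> None:
    pd.DataFrame(vim.values, index=vim.names, columns=vim.names).to_csv(path)


def load_vi_matrix_csv(path) -> VIMatrix:
    df = pd.read_csv(path, index_col=0)
    return VIMatrix(values=df.to_numpy(dtype=float), names=list(df.columns))


def save_jaccard_map_csv(jmap: JaccardMap, path) -> None:
    pd.DataFrame(
        {
            "voxel": np.arange(jmap.n_voxels),
            "mean_jd": jmap.mean,
            "std_jd": jmap.std,
        }
    ).to_csv(path, index=False)


def save_neighbor_graph(graph, path) -> None:
    from .connectivity import NeighborGraph  # local to avoid cycle at import

    assert isinstance(graph, NeighborGraph)
    with h5py.File(str(path), "w") as f:
        f.create_dataset("indicator", data=graph.indicator, compression="gzip")
        f.attrs.update({"fraction": graph.fraction, "k": graph.k, "source": graph.source})


def load_neighbor_graph(path):
    from .connectivity import NeighborGraph

    with h5py.File(str(path), "r") as f:
        return NeighborGraph(
            indicator=f["indicator"][()].astype(bool),
            fraction=float(f.attrs["fraction"]),
            k=int(f.attrs["k"]),
            source=str(f.attrs["source"]),
        )


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v
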