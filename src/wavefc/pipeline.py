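"""End-to-end orchestration: simulate -> decompose -> connectivity -> cluster -> compare -> voxelmap.

Every stage reads its inputs from the artifacts the previous stage wrote
under the output directory, so any stage can be re-run in isolation and
reproduces downstream outputs exactly.  A run manifest records the
effective parameters, derived seeds, output paths and content hashes;
stages whose parameter/input key is unchanged are skipped on re-runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as wio
from .clustering import GLOBAL, average_linkage, inconsistency, prune_by_inconsistency, prune_to_k
from .connectivity import concatenate_group, correlation_distance, top_fraction_neighbors
from .datasets import BoldDataset
from .partition_compare import cluster_spectra, vi_matrix
from .synthetic import (
    PlantedLayer,
    SimulationConfig,
    random_balanced_partition,
    synthesize_dataset,
)
from .voxel_compare import (
    DEFAULT_WIDEBAND_PACKETS,
    build_wideband_reference,
    voxelwise_jaccard_map,
)
from .wavelets import PacketAddress, wpt_decompose

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("wavefc.pipeline")

#: dense distance matrices above this voxel count are refused
DEFAULT_MAX_VOXELS = 20_000


@dataclass
class PipelineConfig:
    """Single configuration object driving all pipeline stages."""

    # simulation (used when input_niftis is empty)
    n_voxels: int = 200
    n_timepoints: int = 512
    tr_seconds: float = 0.645
    n_subjects: int = 2
    gamma: float = 0.75
    mask_fraction: float = 0.5
    layers: list[dict] = field(default_factory=list)  # {passband_hz, n_clusters, amplitude}
    # real-data ingestion alternative
    input_niftis: list[str] = field(default_factory=list)
    mask_nifti: str = ""
    # wavelet settings
    max_depth: int = 4
    wavelet: str = "db7"
    mode: str = "periodization"
    # connectivity settings
    fraction: float = 0.05
    zscore: bool = True
    max_voxels: int = DEFAULT_MAX_VOXELS
    # clustering settings
    cluster_method: str = "maxclust"  # or "inconsistency"
    k: int = 6
    g: object = GLOBAL
    threshold: float = 2.0
    # comparison settings
    packets: list[str] = field(default_factory=list)  # default: all at max_depth
    meta_modes: list[str] = field(default_factory=lambda: ["coarse-local", "fine-global"])
    designated: list[str] = field(default_factory=list)
    wideband_packets: list[str] = field(
        default_factory=lambda: [str(a) for a in DEFAULT_WIDEBAND_PACKETS]
    )
    map_packets: list[str] = field(default_factory=list)
    # global
    seed: int = 0
    output_dir: str = "wavefc-run"

    def packet_list(self) -> list[PacketAddress]:
        names = self.packets or [
            str(PacketAddress(self.max_depth, p)) for p in range(2**self.max_depth)
        ]
        return [PacketAddress.parse(n) for n in names]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["g"] = str(self.g)
        return d


def load_config(path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML (or JSON) file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig(**raw)
    if cfg.g not in (GLOBAL,) and not isinstance(cfg.g, int):
        cfg.g = GLOBAL if str(cfg.g).lower() == "global" else int(cfg.g)
    return cfg


def _key(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _stage_fresh(stage_dir: Path, key: str) -> bool:
    keyfile = stage_dir / ".key"
    return keyfile.exists() and keyfile.read_text() == key


def _finish_stage(stage_dir: Path, key: str) -> None:
    (stage_dir / ".key").write_text(key)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulation_config(cfg: PipelineConfig) -> SimulationConfig:
    layer_root = np.random.SeedSequence([cfg.seed, 1])
    layer_ss = layer_root.spawn(max(len(cfg.layers), 1))
    layers = [
        PlantedLayer(
            passband_hz=tuple(spec["passband_hz"]),
            labels=random_balanced_partition(
                cfg.n_voxels, int(spec.get("n_clusters", 6)), np.random.default_rng(ss)
            ),
            amplitude=float(spec.get("amplitude", 2.0)),
        )
        for spec, ss in zip(cfg.layers, layer_ss)
    ]
    return SimulationConfig(
        n_voxels=cfg.n_voxels,
        planted_layers=layers,
        n_timepoints=cfg.n_timepoints,
        tr_seconds=cfg.tr_seconds,
        n_subjects=cfg.n_subjects,
        gamma=cfg.gamma,
        mask_fraction=cfg.mask_fraction,
        seed=cfg.seed,
    )


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    stage = outdir / "simulate"
    sim = _simulation_config(cfg)
    key = _key({"stage": "simulate", "sim": {**cfg.to_dict(), "which": "sim"}})
    paths = [stage / f"sub-{s}_bold.nii.gz" for s in range(cfg.n_subjects)]
    if _stage_fresh(stage, key):
        log.info("simulate: cached")
        return paths
    stage.mkdir(parents=True, exist_ok=True)
    datasets, truth = synthesize_dataset(sim)
    for ds, p in zip(datasets, paths):
        wio.save_bold_nifti(ds, p)
    wio.save_mask_nifti(datasets[0].mask, stage / "mask.nii.gz")
    wio.save_ground_truth(truth, stage / "ground_truth.json",
                          config_echo={"seed": cfg.seed, "n_voxels": cfg.n_voxels})
    _finish_stage(stage, key)
    log.info("simulate: %d subjects, %d voxels", cfg.n_subjects, cfg.n_voxels)
    return paths


def _load_subjects(cfg: PipelineConfig, outdir: Path) -> list[BoldDataset]:
    if cfg.input_niftis:
        mask = wio.load_mask_nifti(cfg.mask_nifti)
        return [
            wio.load_bold_nifti(p, mask, tr_seconds=cfg.tr_seconds, subject_id=f"sub-{s}")
            for s, p in enumerate(cfg.input_niftis)
        ]
    stage = outdir / "simulate"
    mask = wio.load_mask_nifti(stage / "mask.nii.gz")
    return [
        wio.load_bold_nifti(stage / f"sub-{s}_bold.nii.gz", mask,
                            tr_seconds=cfg.tr_seconds, subject_id=f"sub-{s}")
        for s in range(cfg.n_subjects)
    ]


def stage_decompose(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    stage = outdir / "decompose"
    subjects = _load_subjects(cfg, outdir)
    if len(subjects[0].data) > cfg.max_voxels:
        raise ValueError(
            f"{len(subjects[0].data)} voxels exceeds max_voxels={cfg.max_voxels}"
        )
    key = _key({"stage": "decompose", "cfg": cfg.to_dict()})
    paths = [stage / f"sub-{s}_packets.h5" for s in range(len(subjects))]
    if _stage_fresh(stage, key):
        log.info("decompose: cached")
        return paths
    stage.mkdir(parents=True, exist_ok=True)
    for ds, p in zip(subjects, paths):
        tree = wpt_decompose(
            ds.data, max_depth=cfg.max_depth, wavelet=cfg.wavelet,
            mode=cfg.mode, fs=ds.fs,
        )
        wio.save_packet_store(tree, p, subject_id=ds.subject_id)
    _finish_stage(stage, key)
    log.info("decompose: depth %d, %d packets", cfg.max_depth, 2 ** (cfg.max_depth + 1) - 1)
    return paths


def stage_connectivity(cfg: PipelineConfig, outdir: Path) -> dict[str, Path]:
    stage = outdir / "connectivity"
    key = _key({"stage": "connectivity", "cfg": cfg.to_dict()})
    packets = cfg.packet_list()
    out = {str(a): stage / f"{a}_distance.npy" for a in packets}
    if _stage_fresh(stage, key):
        log.info("connectivity: cached")
        return out
    stage.mkdir(parents=True, exist_ok=True)
    trees = [
        wio.load_packet_store(outdir / "decompose" / f"sub-{s}_packets.h5")
        for s in range(cfg.n_subjects if not cfg.input_niftis else len(cfg.input_niftis))
    ]
    for addr in packets:
        group = concatenate_group(
            [t.node(addr) for t in trees], address=addr, zscore=cfg.zscore
        )
        dist = correlation_distance(group)
        np.save(out[str(addr)], dist)
        graph = top_fraction_neighbors(dist, fraction=cfg.fraction, source=str(addr))
        wio.save_neighbor_graph(graph, stage / f"{addr}_neighbors.h5")
    _finish_stage(stage, key)
    log.info("connectivity: %d packets", len(packets))
    return out


def stage_cluster(cfg: PipelineConfig, outdir: Path) -> dict[str, Path]:
    stage = outdir / "cluster"
    key = _key({"stage": "cluster", "cfg": cfg.to_dict()})
    packets = cfg.packet_list()
    out = {str(a): stage / f"{a}_partition.csv" for a in packets}
    if _stage_fresh(stage, key):
        log.info("cluster: cached")
        return out
    stage.mkdir(parents=True, exist_ok=True)
    for addr in packets:
        dist = np.load(outdir / "connectivity" / f"{addr}_distance.npy")
        tree = average_linkage(dist)
        wio.save_linkage_csv(tree, stage / f"{addr}_linkage.csv")
        if cfg.cluster_method == "maxclust":
            part = prune_to_k(tree, cfg.k)
        elif cfg.cluster_method == "inconsistency":
            table = inconsistency(tree, g=cfg.g)
            part = prune_by_inconsistency(tree, table, cfg.threshold)
        else:
            raise ValueError(f"unknown cluster_method {cfg.cluster_method!r}")
        part.provenance["packet"] = str(addr)
        wio.save_partition_csv(part, out[str(addr)])
    _finish_stage(stage, key)
    log.info("cluster: %d partitions (%s)", len(packets), cfg.cluster_method)
    return out


def stage_compare(cfg: PipelineConfig, outdir: Path) -> Path:
    stage = outdir / "compare"
    key = _key({"stage": "compare", "cfg": cfg.to_dict()})
    vi_path = stage / "vi_matrix.csv"
    if _stage_fresh(stage, key):
        log.info("compare: cached")
        return vi_path
    stage.mkdir(parents=True, exist_ok=True)
    packets = cfg.packet_list()
    parts = [
        wio.load_partition_csv(outdir / "cluster" / f"{a}_partition.csv")
        for a in packets
    ]
    vim = vi_matrix(parts, names=[str(a) for a in packets])
    wio.save_vi_matrix_csv(vim, vi_path)
    designated = (
        [str(PacketAddress.parse(d)) for d in cfg.designated] or None
    )
    desig_idx = (
        [i for i, a in enumerate(packets) if str(a) in designated]
        if designated
        else None
    )
    meta = {}
    for mode in cfg.meta_modes:
        part = cluster_spectra(vim, mode=mode, designated=desig_idx)
        meta[mode] = {
            "labels": {str(a): int(l) for a, l in zip(packets, part.labels)},
            "provenance": {k: wio._jsonable(v) for k, v in part.provenance.items()},
        }
    (stage / "meta_clusters.json").write_text(json.dumps(meta, indent=1))
    _finish_stage(stage, key)
    log.info("compare: VI matrix over %d packets", len(packets))
    return vi_path


def stage_voxelmap(cfg: PipelineConfig, outdir: Path) -> dict[str, Path]:
    stage = outdir / "voxelmap"
    key = _key({"stage": "voxelmap", "cfg": cfg.to_dict()})
    map_packets = [PacketAddress.parse(p) for p in (cfg.map_packets or cfg.wideband_packets)]
    out = {str(a): stage / f"{a}_jaccard.csv" for a in map_packets}
    if _stage_fresh(stage, key):
        log.info("voxelmap: cached")
        return out
    stage.mkdir(parents=True, exist_ok=True)
    subjects = _load_subjects(cfg, outdir)
    wideband = [PacketAddress.parse(p) for p in cfg.wideband_packets]
    refs = build_wideband_reference(
        [s.data for s in subjects], selected_packets=wideband,
        fraction=cfg.fraction, wavelet=cfg.wavelet, mode=cfg.mode,
        max_depth=cfg.max_depth, fs=subjects[0].fs,
    )
    trees = [
        wio.load_packet_store(outdir / "decompose" / f"sub-{s}_packets.h5")
        for s in range(len(subjects))
    ]
    for addr in map_packets:
        graphs = [
            top_fraction_neighbors(
                correlation_distance(t.node(addr)), fraction=cfg.fraction,
                source=str(addr),
            )
            for t in trees
        ]
        jmap = voxelwise_jaccard_map(graphs, refs, packet=str(addr))
        wio.save_jaccard_map_csv(jmap, out[str(addr)])
    _finish_stage(stage, key)
    log.info("voxelmap: %d packets vs wideband of %d", len(map_packets), len(wideband))
    return out


_STAGES = [
    ("simulate", stage_simulate),
    ("decompose", stage_decompose),
    ("connectivity", stage_connectivity),
    ("cluster", stage_cluster),
    ("compare", stage_compare),
    ("voxelmap", stage_voxelmap),
]


def run_pipeline(cfg: PipelineConfig, output_dir=None) -> dict:
    """Execute all stages and write ``manifest.json`` into the output directory."""
    outdir = Path(output_dir or cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    import pywt
    import scipy

    manifest: dict = {
        "config": cfg.to_dict(),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pywt": pywt.__version__,
        },
        "stages": {},
    }
    for name, fn in _STAGES:
        if name == "simulate" and cfg.input_niftis:
            continue
        t0 = time.perf_counter()
        try:
            fn(cfg, outdir)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        stage_dir = outdir / name
        outputs = sorted(
            str(p.relative_to(outdir))
            for p in stage_dir.rglob("*")
            if p.is_file() and p.name != ".key"
        )
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": outputs,
            "hashes": {
                o: _file_hash(outdir / o) for o in outputs if o.endswith(".csv")
            },
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
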