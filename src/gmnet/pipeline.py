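"""End-to-end orchestration: simulate -> networks -> metrics -> statistics.

Every stage communicates through standard file formats (NIfTI volumes, TSV
edge lists, CSV tables, JSON/YAML config), so stages are independently
re-runnable, and a fixed configuration reproduces all numeric outputs
bit-for-bit.  Per-subject and per-region seeds derive deterministically from
the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .local import (
    AtlasParcellation,
    filter_regions_min_nodes,
    regional_small_worldness,
)
from .metrics import small_worldness
from .network import (
    BinaryNetwork,
    GreyMatterVolume,
    ROTATIONS_24,
    ROTATIONS_48,
    binarize_fdr,
    build_similarity_matrix,
    estimate_null,
    extract_cube_nodes,
    reslice_to_2mm,
)
from .synthetic import SimulationConfig, generate_cohort

__all__ = [
    "RunConfig",
    "run_pipeline",
    "subject_seed",
    "read_gm_volume",
    "write_gm_volume",
    "read_atlas",
    "write_atlas",
    "read_cohort_csv",
    "write_table",
    "write_edge_list",
    "read_edge_list",
]

log = logging.getLogger("gmnet")

COHORT_COLUMNS = {
    "subject_id": str,
    "group": str,
    "age": float,
    "sex": str,
    "education": float,
    "gm_volume": float,
    "pas": float,
    "sas": float,
    "duration_illness": float,
    "cpz_dose": float,
}


@dataclass
class RunConfig:
    """Parameter home for a full pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    gm_voxel_threshold: float = 0.1
    min_gm_voxels_per_cube: int = 1
    use_reflections: bool = False  # 24 proper rotations vs all 48 symmetries
    n_perm: int = 100_000
    q: float = 0.05
    n_random: int = 20
    swap_attempts_factor: int = 10
    min_avg_nodes: float = 30.0
    levels: tuple[str, ...] = ("icn7", "regional")
    seed: int = 0
    write_volumes: bool = False

    @property
    def rotation_set(self) -> np.ndarray:
        return ROTATIONS_48 if self.use_reflections else ROTATIONS_24

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.as_dict()
        d["levels"] = list(self.levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        cfg = cls(simulation=SimulationConfig(**sim), **d)
        cfg.levels = tuple(cfg.levels)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def subject_seed(master_seed: int, subject_id: str, stage: str = "") -> int:
    """Deterministic per-subject (and per-stage) seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}|{subject_id}|{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_gm_volume(path, subject_id: str | None = None) -> GreyMatterVolume:
    """Read a NIfTI GM partial-volume map, reslicing to 2 mm if needed."""
    img = nib.load(str(path))
    voxels = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.min() < -1e-6 or data.max() > 1 + 1e-6:
        raise ValueError(f"{path}: GM values outside [0, 1]")
    vol = GreyMatterVolume(
        data=np.clip(data, 0, 1),
        voxel_size=voxels,
        subject_id=subject_id or Path(path).name.split(".")[0],
        affine=np.asarray(img.affine),
    )
    return reslice_to_2mm(vol)


def write_gm_volume(volume: GreyMatterVolume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    img.header.set_zooms(volume.voxel_size)
    nib.save(img, str(path))


def read_atlas(labels_path, table_path) -> AtlasParcellation:
    img = nib.load(str(labels_path))
    labels = np.asarray(img.get_fdata()).astype(np.int32)
    table = pd.read_csv(table_path)
    return AtlasParcellation(labels, table)


def write_atlas(atlas: AtlasParcellation, labels_path, table_path) -> None:
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine), str(labels_path))
    atlas.region_table.to_csv(table_path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort covariate table."""
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing cohort columns {sorted(missing)}")
    bad_groups = set(df["group"]) - {"patient", "control"}
    if bad_groups:
        raise ValueError(f"{path}: unknown group labels {sorted(bad_groups)}")
    if ((df["pas"] < 0) | (df["pas"] > 61)).any():
        raise ValueError(f"{path}: column 'pas' outside the 0-61 scale range")
    sas = df["sas"].dropna()
    if ((sas < 0) | (sas > 40)).any():
        raise ValueError(f"{path}: column 'sas' outside the 0-40 scale range")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_edge_list(net: BinaryNetwork, path) -> None:
    """Edge list TSV: two 0-based node indices per line, '# n=<n>' header."""
    with open(path, "w") as fh:
        fh.write(f"# n={net.n}\n")
        for i, j in net.edges:
            fh.write(f"{i}\t{j}\n")


def read_edge_list(path) -> BinaryNetwork:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# n="):
            raise ValueError(f"{path}: missing '# n=' header")
        n = int(header.split("=", 1)[1])
        edges = [tuple(map(int, line.split())) for line in fh if line.strip()]
    return BinaryNetwork(n, edges)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _global_network(volume: GreyMatterVolume, cfg: RunConfig, seed: int):
    nodes = extract_cube_nodes(
        volume, cfg.gm_voxel_threshold, cfg.min_gm_voxels_per_cube
    )
    if nodes.n_nodes < 2:
        raise ValueError("fewer than 2 cube nodes")
    sim = build_similarity_matrix(nodes, cfg.rotation_set)
    null = estimate_null(nodes, n_perm=cfg.n_perm, seed=seed, rotation_set=cfg.rotation_set)
    net = binarize_fdr(sim, null, q=cfg.q)
    return nodes, net


def process_subject(volume: GreyMatterVolume, cfg: RunConfig) -> dict:
    """Global-scale network and metrics for one subject."""
    seed = subject_seed(cfg.seed, volume.subject_id, "global")
    nodes, net = _global_network(volume, cfg, seed)
    row = {"subject_id": volume.subject_id, "n_nodes": nodes.n_nodes,
           "n_edges": net.n_edges}
    if net.n_edges == 0:
        return {**row, "sigma": np.nan, "status": "empty_network",
                "nodes": nodes, "network": net}
    m = small_worldness(
        net, n_random=cfg.n_random,
        swap_attempts_factor=cfg.swap_attempts_factor, seed=seed,
    )
    return {**row, "cc_raw": m.cc_raw, "L_raw": m.L_raw, "gamma": m.gamma,
            "lam": m.lam, "sigma": m.sigma,
            "component_fraction": m.component_fraction, "status": m.status,
            "nodes": nodes, "network": net}


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Simulate a cohort and run the full analysis, writing all artifacts.

    Writes per-subject node tables and edge lists, global and local metric
    CSVs, statistics tables, and a manifest (config echo, seeds, version,
    checksums).  Per-subject failures are quarantined with diagnostics and
    the run continues; the returned dict carries the in-memory tables.
    """
    outdir = Path(outdir)
    (outdir / "subjects").mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    cohort, volumes, atlas = generate_cohort(config.simulation)
    write_table(cohort.drop(columns=["regularity", "volume_seed"]),
                outdir / "cohort.csv")
    write_table(cohort, outdir / "cohort_latent.csv")
    write_atlas(atlas, outdir / "atlas_labels.nii.gz", outdir / "atlas_regions.csv")

    global_rows, regional_frames, failures = [], [], []
    for sid in volumes.subject_ids():
        try:
            vol = volumes[sid]
            if config.write_volumes:
                write_gm_volume(vol, outdir / "subjects" / f"{sid}_gm.nii.gz")
            res = process_subject(vol, config)
            nodes, net = res.pop("nodes"), res.pop("network")
            sdir = outdir / "subjects"
            write_edge_list(net, sdir / f"{sid}_edges.tsv")
            write_table(
                pd.DataFrame(
                    {"node_index": np.arange(nodes.n_nodes),
                     "x": nodes.origins[:, 0], "y": nodes.origins[:, 1],
                     "z": nodes.origins[:, 2]}
                ),
                sdir / f"{sid}_nodes.csv",
            )
            global_rows.append(res)
            for level in config.levels:
                reg = regional_small_worldness(
                    vol, atlas, level=level,
                    gm_voxel_threshold=config.gm_voxel_threshold,
                    min_gm_voxels_per_cube=config.min_gm_voxels_per_cube,
                    rotation_set=config.rotation_set,
                    n_perm=max(1000, config.n_perm // 10), q=config.q,
                    n_random=config.n_random,
                    swap_attempts_factor=config.swap_attempts_factor,
                    seed=subject_seed(config.seed, sid, level),
                )
                regional_frames.append(reg)
        except Exception as err:  # quarantine, keep going
            log.warning("subject %s failed: %s", sid, err)
            failures.append({"subject_id": sid, "error": str(err)})

    if not global_rows:
        raise RuntimeError("every subject failed; nothing to analyse")

    global_sigma = pd.DataFrame(global_rows)
    write_table(global_sigma, outdir / "global_metrics.csv")
    regional = pd.concat(regional_frames, ignore_index=True) if regional_frames else None
    if regional is not None:
        write_table(regional, outdir / "regional_metrics.csv")

    icn_sigma = regional_sigma = None
    retained = None
    if regional is not None:
        if "icn7" in config.levels:
            icn_sigma = regional[regional["level"] == "icn7"]
        if "regional" in config.levels:
            regional_sigma = regional[regional["level"] == "regional"]
            retained = filter_regions_min_nodes(
                regional_sigma[["subject_id", "region", "n_nodes"]],
                min_avg=config.min_avg_nodes,
            )

    from .stats import run_full_statistics

    stats_tables = run_full_statistics(
        cohort, global_sigma, icn_sigma, regional_sigma,
        retained_regions=retained, q=config.q,
    )
    for name, table in stats_tables.items():
        write_table(table, outdir / f"stats_{name}.csv")
    if failures:
        write_table(pd.DataFrame(failures), outdir / "failed_subjects.csv")

    manifest = {
        "gmnet_version": __version__,
        "config": config.as_dict(),
        "n_subjects_ok": len(global_rows),
        "n_subjects_failed": len(failures),
        "retained_regions": retained,
        "runtime_s": round(time.time() - t0, 2),
        "checksums": _checksums(outdir),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {"cohort": cohort, "global": global_sigma, "regional": regional,
            "retained_regions": retained, "stats": stats_tables,
            "manifest": manifest}


def _checksums(outdir: Path) -> dict:
    out = {}
    for p in sorted(outdir.rglob("*.csv")) + sorted(outdir.rglob("*.tsv")):
        out[str(p.relative_to(outdir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
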