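"""Local-scale (atlas-masked) network analysis.

The global whole-volume network construction is repeated on atlas-defined
subsets of the cube nodes: once at the level of 7 intrinsic connectivity
networks (ICNs; unions of atlas regions sharing a network grouping) and once
at the level of individual regions (an AAL-style parcellation).  Regions
whose average node count across the cohort falls below a minimum are omitted
from statistical analysis, since sigma estimated on very small networks is
unstable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import small_worldness
from .network import (
    CUBE_EDGE,
    GreyMatterVolume,
    NodeSet,
    ROTATIONS_24,
    binarize_fdr,
    build_similarity_matrix,
    estimate_null,
    extract_cube_nodes,
)

__all__ = [
    "ICN_NAMES",
    "AtlasParcellation",
    "assign_nodes_to_regions",
    "icn_node_sets",
    "filter_regions_min_nodes",
    "regional_small_worldness",
]

#: The 7 canonical intrinsic connectivity networks used for grouping regions.
ICN_NAMES = ("DMN", "CCN", "SVN", "DAN", "LN", "SMN", "VN")


@dataclass
class AtlasParcellation:
    """Integer label volume plus a region table.

    ``labels`` holds one region id per voxel (0 = background) on the same
    grid as the subject GM volume.  ``region_table`` maps each region id to a
    name and a network grouping: one of the 7 ICNs, or "none" for regions
    outside the cortical ICN scheme (subcortical / cerebellar).
    """

    labels: np.ndarray
    region_table: pd.DataFrame  # columns: region_id, name, grouping

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D volume")
        required = {"region_id", "name", "grouping"}
        if not required.issubset(self.region_table.columns):
            raise ValueError(f"region table must have columns {sorted(required)}")
        ids = self.region_table["region_id"].to_numpy()
        if len(ids) != len(set(ids)) or (ids <= 0).any():
            raise ValueError("region ids must be positive and unique")
        bad = set(self.region_table["grouping"]) - set(ICN_NAMES) - {"none"}
        if bad:
            raise ValueError(f"unknown network groupings: {sorted(bad)}")

    @property
    def region_ids(self) -> np.ndarray:
        return self.region_table["region_id"].to_numpy()

    def regions_in_grouping(self, grouping: str) -> np.ndarray:
        t = self.region_table
        return t.loc[t["grouping"] == grouping, "region_id"].to_numpy()


def assign_nodes_to_regions(
    nodes: NodeSet, atlas: AtlasParcellation
) -> dict[int, np.ndarray]:
    """Assign each cube node to the region holding most of its 27 voxels.

    Background (label 0) is excluded from the vote; an all-background cube is
    left unassigned.  Ties break toward the smallest region id.  Returns a
    mapping region_id -> array of node indices (into ``nodes``).
    """
    if len(nodes):
        needed = nodes.origins.max(axis=0) + CUBE_EDGE
        if any(s < need for s, need in zip(atlas.labels.shape, needed)):
            raise ValueError("atlas labels smaller than the node grid")
    assignments: dict[int, list[int]] = {}
    labels = atlas.labels
    for idx in range(nodes.n_nodes):
        x, y, z = nodes.origins[idx]
        block = labels[x : x + CUBE_EDGE, y : y + CUBE_EDGE, z : z + CUBE_EDGE]
        if block.shape != (CUBE_EDGE, CUBE_EDGE, CUBE_EDGE):
            raise ValueError("atlas labels do not cover the node grid")
        votes = np.bincount(block.ravel())
        votes[0] = 0  # background never wins
        if votes.sum() == 0:
            continue
        region = int(votes.argmax())  # argmax takes the smallest id on ties
        assignments.setdefault(region, []).append(idx)
    return {r: np.asarray(ix, dtype=np.int64) for r, ix in sorted(assignments.items())}


def icn_node_sets(
    nodes: NodeSet, atlas: AtlasParcellation
) -> dict[str, np.ndarray]:
    """Union the per-region node assignments into the 7 ICN groupings."""
    per_region = assign_nodes_to_regions(nodes, atlas)
    out: dict[str, np.ndarray] = {}
    for icn in ICN_NAMES:
        member_ids = atlas.regions_in_grouping(icn)
        idx = [per_region[r] for r in member_ids if r in per_region]
        out[icn] = (
            np.sort(np.concatenate(idx)) if idx else np.empty(0, dtype=np.int64)
        )
    return out


def filter_regions_min_nodes(
    counts: pd.DataFrame, min_avg: float = 30.0
) -> list:
    """Cohort-level region filter on average node count.

    ``counts`` has one row per (subject_id, region) with a ``n_nodes``
    column; a region is retained iff its mean node count across all subjects
    is at least ``min_avg`` (regions averaging fewer nodes are omitted).
    The retained set is shared by all subjects and both groups.
    """
    required = {"subject_id", "region", "n_nodes"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts must have columns {sorted(required)}")
    if counts["subject_id"].nunique() == 0:
        raise ValueError("empty cohort")
    n_subjects = counts["subject_id"].nunique()
    # subjects with no nodes in a region contribute 0 to that region's mean
    totals = counts.groupby("region")["n_nodes"].sum()
    means = totals / n_subjects
    return sorted(means.index[means >= min_avg].tolist())


def _region_metrics_row(
    subset: NodeSet,
    region,
    seed: int,
    rotation_set: np.ndarray,
    n_perm: int,
    q: float,
    n_random: int,
    swap_attempts_factor: int,
) -> dict:
    row = {"region": region, "n_nodes": subset.n_nodes}
    empty = dict(
        n_edges=0, sigma=np.nan, gamma=np.nan, lam=np.nan,
        cc_raw=np.nan, L_raw=np.nan, component_fraction=np.nan,
    )
    if subset.n_nodes < 2:
        return {**row, **empty, "status": "too_few_nodes"}
    sim = build_similarity_matrix(subset, rotation_set)
    null = estimate_null(subset, n_perm=n_perm, seed=seed, rotation_set=rotation_set)
    net = binarize_fdr(sim, null, q=q)
    if net.n_edges == 0 or net.n < 3:
        return {**row, **empty, "n_edges": net.n_edges, "status": "empty_network"}
    m = small_worldness(
        net, n_random=n_random, swap_attempts_factor=swap_attempts_factor, seed=seed
    )
    return {
        **row,
        "n_edges": m.n_edges,
        "sigma": m.sigma,
        "gamma": m.gamma,
        "lam": m.lam,
        "cc_raw": m.cc_raw,
        "L_raw": m.L_raw,
        "component_fraction": m.component_fraction,
        "status": m.status,
    }


def regional_small_worldness(
    volume: GreyMatterVolume,
    atlas: AtlasParcellation,
    level: str = "regional",
    gm_voxel_threshold: float = 0.1,
    min_gm_voxels_per_cube: int = 1,
    rotation_set: np.ndarray = ROTATIONS_24,
    n_perm: int = 10_000,
    q: float = 0.05,
    n_random: int = 20,
    swap_attempts_factor: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-region small-worldness with the identical global construction.

    For each region at the chosen level ("icn7": the 7 ICN unions;
    "regional": individual atlas regions) the full chain similarity matrix ->
    permutation null -> FDR binarization -> sigma is run on that region's
    node subset.  Null models are re-estimated within each region's node
    pool.  Regions failing preconditions yield rows with missing values and
    an explicit status, never silent zeros.
    """
    if level not in ("icn7", "regional"):
        raise ValueError("level must be 'icn7' or 'regional'")
    if volume.data.shape != atlas.labels.shape:
        raise ValueError("atlas and volume shapes differ")
    nodes = extract_cube_nodes(volume, gm_voxel_threshold, min_gm_voxels_per_cube)
    if level == "regional":
        groups = assign_nodes_to_regions(nodes, atlas)
        items = [(rid, groups.get(rid, np.empty(0, dtype=np.int64)))
                 for rid in atlas.region_ids]
    else:
        icn = icn_node_sets(nodes, atlas)
        items = list(icn.items())
    rows = []
    ss = np.random.SeedSequence(seed)
    for (region, idx), s in zip(items, ss.generate_state(max(len(items), 1)) % (2**31)):
        subset = nodes.subset(idx)
        rows.append(
            _region_metrics_row(
                subset, region, int(s), rotation_set, n_perm, q,
                n_random, swap_attempts_factor,
            )
        )
    out = pd.DataFrame(rows)
    out.insert(0, "subject_id", volume.subject_id)
    out.insert(1, "level", level)
    return out
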