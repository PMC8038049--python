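"""Single-subject grey-matter similarity network construction.

A segmented grey-matter (GM) partial-volume map on an isotropic 2 mm grid is
tiled into non-overlapping 3x3x3-voxel cubes.  Each cube that contains GM
becomes a graph node whose feature vector is its 27 raw voxel intensities.
Edges connect cube pairs whose intensity vectors are similar: the similarity
is the maximum Pearson correlation over all rigid rotations of one cube
relative to the other (so locally mirrored / rotated cortical folds still
match).  The similarity matrix is binarized by comparing each entry against a
permutation null distribution and keeping the entries that survive a
Benjamini-Hochberg false-discovery-rate (FDR) threshold of 5%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GreyMatterVolume",
    "CubeNode",
    "NodeSet",
    "SimilarityMatrix",
    "NullModel",
    "BinaryNetwork",
    "rotation_permutations",
    "ROTATIONS_24",
    "ROTATIONS_48",
    "reslice_to_2mm",
    "extract_cube_nodes",
    "cube_similarity",
    "build_similarity_matrix",
    "estimate_null",
    "binarize_fdr",
]

CUBE_EDGE = 3
CUBE_SIZE = CUBE_EDGE**3


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GreyMatterVolume:
    """A 3D grey-matter partial-volume field.

    Parameters
    ----------
    data : ndarray
        3D array of GM partial-volume estimates in ``[0, 1]``.
    voxel_size : tuple of float
        Voxel edge lengths in mm per axis.
    subject_id : str
        Identifier carried through to downstream tables.
    affine : ndarray, optional
        4x4 voxel-to-world affine.  Derived from ``voxel_size`` when absent.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    subject_id: str = "subject"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("GM volume must be a 3D array")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 1):
            raise ValueError("GM partial-volume values must lie in [0, 1]")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])

    @property
    def total_gm_volume_mm3(self) -> float:
        """Integral of the partial-volume field times the voxel volume."""
        return float(self.data.sum() * np.prod(self.voxel_size))


@dataclass(frozen=True)
class CubeNode:
    node_index: int
    origin: tuple[int, int, int]
    intensities: np.ndarray  # 27 values, x-fastest order


@dataclass
class NodeSet:
    """Ordered collection of cube nodes for one subject."""

    subject_id: str
    origins: np.ndarray  # (n, 3) int, lowest-index corner of each cube
    intensities: np.ndarray  # (n, 27) float, canonical x-fastest order

    def __post_init__(self) -> None:
        self.origins = np.asarray(self.origins, dtype=np.int64).reshape(-1, 3)
        self.intensities = np.asarray(self.intensities, dtype=np.float64).reshape(
            -1, CUBE_SIZE
        )
        if len(self.origins) != len(self.intensities):
            raise ValueError("origins and intensities disagree in length")
        if len(self.origins) != len({tuple(o) for o in self.origins}):
            raise ValueError("duplicate cube origins")

    @property
    def n_nodes(self) -> int:
        return len(self.origins)

    def __len__(self) -> int:
        return self.n_nodes

    def node(self, i: int) -> CubeNode:
        return CubeNode(i, tuple(self.origins[i]), self.intensities[i].copy())

    def subset(self, indices: np.ndarray) -> "NodeSet":
        indices = np.asarray(indices, dtype=np.int64)
        return NodeSet(self.subject_id, self.origins[indices], self.intensities[indices])


@dataclass
class SimilarityMatrix:
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if self.values.size and (self.values.min() < -1 - 1e-9 or self.values.max() > 1 + 1e-9):
            raise ValueError("similarities must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class NullModel:
    """Empirical null of rotation-maximized similarity under permuted cubes."""

    samples: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.samples = np.sort(np.asarray(self.samples, dtype=np.float64))
        if self.samples.size == 0:
            raise ValueError("null model has no samples")

    @property
    def n_perm(self) -> int:
        return self.samples.size

    def pvalues(self, values: np.ndarray) -> np.ndarray:
        """One-sided empirical p-values with add-one smoothing.

        p = (1 + #{null >= v}) / (n_perm + 1)
        """
        values = np.asarray(values, dtype=np.float64)
        n_ge = self.n_perm - np.searchsorted(self.samples, values, side="left")
        return (1.0 + n_ge) / (self.n_perm + 1.0)


class BinaryNetwork:
    """Undirected simple graph over cube nodes.

    Stored as a canonical edge array (``i < j``, lexicographically sorted),
    which keeps equality, hashing of outputs, and file round-trips exact.
    """

    def __init__(self, n: int, edges: np.ndarray | list) -> None:
        self.n = int(n)
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if edges.size:
            if edges.min() < 0 or edges.max() >= self.n:
                raise ValueError("edge endpoint out of range")
            lo = edges.min(axis=1)
            hi = edges.max(axis=1)
            if np.any(lo == hi):
                raise ValueError("self-loops are not allowed")
            edges = np.unique(np.column_stack([lo, hi]), axis=0)
        else:
            edges = edges.reshape(0, 2)
        self.edges = edges

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n, self.n), dtype=np.int8)
        if self.n_edges:
            a[self.edges[:, 0], self.edges[:, 1]] = 1
            a[self.edges[:, 1], self.edges[:, 0]] = 1
        return a

    def to_igraph(self):
        import igraph

        return igraph.Graph(n=self.n, edges=[tuple(e) for e in self.edges])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges))
        return g

    @classmethod
    def from_networkx(cls, g) -> "BinaryNetwork":
        mapping = {v: i for i, v in enumerate(sorted(g.nodes()))}
        edges = [(mapping[u], mapping[v]) for u, v in g.edges()]
        return cls(g.number_of_nodes(), edges)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinaryNetwork):
            return NotImplemented
        return self.n == other.n and np.array_equal(self.edges, other.edges)

    def __repr__(self) -> str:
        return f"BinaryNetwork(n={self.n}, n_edges={self.n_edges})"


# ---------------------------------------------------------------------------
# cube rotation group
# ---------------------------------------------------------------------------


def _index_cube() -> np.ndarray:
    # canonical x-fastest flattening: index = x + 3*y + 9*z
    idx = np.arange(CUBE_SIZE, dtype=np.int64)
    return idx.reshape(CUBE_EDGE, CUBE_EDGE, CUBE_EDGE, order="F")


def rotation_permutations(include_reflections: bool = False) -> np.ndarray:
    """Permutations of the 27 cube positions under rigid cube symmetries.

    Returns the 24 proper rotations of the cube (48 with reflections) as an
    array of index permutations acting on the canonical x-fastest flattening.
    """
    base = _index_cube()
    seen: dict[bytes, np.ndarray] = {}
    candidates = [base]
    if include_reflections:
        candidates.append(base[::-1, :, :])
    for start in candidates:
        # orient each of the 6 faces up, then 4 in-plane turns
        for cube in (
            start,
            np.rot90(start, 1, (0, 2)),
            np.rot90(start, 2, (0, 2)),
            np.rot90(start, 3, (0, 2)),
            np.rot90(start, 1, (0, 1)),
            np.rot90(start, 3, (0, 1)),
        ):
            for k in range(4):
                perm = np.rot90(cube, k, (1, 2)).reshape(-1, order="F")
                seen.setdefault(perm.tobytes(), perm)
    perms = np.array(list(seen.values()), dtype=np.int64)
    expected = 48 if include_reflections else 24
    if len(perms) != expected:  # pragma: no cover - structural sanity
        raise RuntimeError(f"expected {expected} cube symmetries, got {len(perms)}")
    return perms


ROTATIONS_24 = rotation_permutations(include_reflections=False)
ROTATIONS_48 = rotation_permutations(include_reflections=True)


def _standardize(vectors: np.ndarray) -> np.ndarray:
    """Center/scale rows so the dot product of two rows is their Pearson r.

    Zero-variance rows map to the zero vector, realising the convention that
    a correlation involving a constant cube is 0.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    centered = vectors - vectors.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    out = np.zeros_like(centered)
    np.divide(centered, norms, out=out, where=norms > 0)
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def reslice_to_2mm(volume: GreyMatterVolume, order: int = 1) -> GreyMatterVolume:
    """Reslice a GM volume to an isotropic 2 mm grid (trilinear by default).

    A volume already on a 2 mm isotropic grid is returned unchanged.
    """
    import nibabel as nib
    from nibabel.processing import resample_to_output

    if np.allclose(volume.voxel_size, 2.0):
        return volume
    img = nib.Nifti1Image(volume.data, volume.affine)
    res = resample_to_output(img, voxel_sizes=(2.0, 2.0, 2.0), order=order)
    data = np.clip(np.asarray(res.get_fdata(), dtype=np.float64), 0.0, 1.0)
    return GreyMatterVolume(
        data=data,
        voxel_size=(2.0, 2.0, 2.0),
        subject_id=volume.subject_id,
        affine=np.asarray(res.affine),
    )


def extract_cube_nodes(
    volume: GreyMatterVolume,
    gm_voxel_threshold: float = 0.1,
    min_gm_voxels_per_cube: int = 1,
) -> NodeSet:
    """Tile the volume into non-overlapping 3x3x3 cubes and keep GM cubes.

    The tiling is anchored at the array origin; trailing voxels that do not
    complete a cube are dropped.  A cube becomes a node iff at least
    ``min_gm_voxels_per_cube`` of its 27 voxels exceed ``gm_voxel_threshold``.
    """
    if not (0 <= gm_voxel_threshold < 1):
        raise ValueError("gm_voxel_threshold must lie in [0, 1)")
    if not (1 <= min_gm_voxels_per_cube <= CUBE_SIZE):
        raise ValueError("min_gm_voxels_per_cube must lie in [1, 27]")
    data = volume.data
    nx_, ny, nz = (s // CUBE_EDGE for s in data.shape)
    trimmed = data[: nx_ * CUBE_EDGE, : ny * CUBE_EDGE, : nz * CUBE_EDGE]
    # blocks[cx, cy, cz, ix, iy, iz]
    blocks = trimmed.reshape(nx_, CUBE_EDGE, ny, CUBE_EDGE, nz, CUBE_EDGE)
    blocks = blocks.transpose(0, 2, 4, 1, 3, 5)
    cube = blocks.reshape(nx_ * ny * nz, CUBE_EDGE, CUBE_EDGE, CUBE_EDGE)
    # canonical x-fastest flattening (index = x + 3y + 9z)
    flat = cube.transpose(0, 3, 2, 1).reshape(len(cube), CUBE_SIZE)
    keep = (flat > gm_voxel_threshold).sum(axis=1) >= min_gm_voxels_per_cube
    grid = np.stack(
        np.meshgrid(
            np.arange(nx_) * CUBE_EDGE,
            np.arange(ny) * CUBE_EDGE,
            np.arange(nz) * CUBE_EDGE,
            indexing="ij",
        ),
        axis=-1,
    ).reshape(-1, 3)
    return NodeSet(volume.subject_id, grid[keep], flat[keep])


def cube_similarity(
    a: np.ndarray, b: np.ndarray, rotation_set: np.ndarray = ROTATIONS_24
) -> float:
    """Rotation-maximized Pearson correlation between two 27-voxel cubes.

    Returns the maximum over all symmetries in ``rotation_set`` (applied to
    ``b``) of corr(a, rotated b); a zero-variance operand contributes 0.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size != CUBE_SIZE or b.size != CUBE_SIZE:
        raise ValueError("cube intensity vectors must have exactly 27 entries")
    za = _standardize(a[None, :])[0]
    zb = _standardize(b[None, :])[0]
    best = float((za * zb[rotation_set]).sum(axis=1).max())
    return float(np.clip(best, -1.0, 1.0))


def _rotation_max_matrix(z: np.ndarray, rotation_set: np.ndarray) -> np.ndarray:
    """All-pairs rotation-maximized correlation from standardized rows."""
    n = len(z)
    best = np.full((n, n), -np.inf)
    for perm in rotation_set:
        np.maximum(best, z @ z[:, perm].T, out=best)
    # zero-variance rows have z == 0 -> candidates all 0; -inf cannot occur
    return np.clip(best, -1.0, 1.0)


def build_similarity_matrix(
    nodes: NodeSet, rotation_set: np.ndarray = ROTATIONS_24
) -> SimilarityMatrix:
    """Evaluate rotation-maximized similarity for every unordered node pair."""
    if nodes.n_nodes < 2:
        raise ValueError("need at least 2 nodes to build a similarity matrix")
    z = _standardize(nodes.intensities)
    best = _rotation_max_matrix(z, rotation_set)
    # enforce exact symmetry (the 24/48 groups are closed under inverses, but
    # floating-point max ordering can differ by ulps across the diagonal)
    best = np.maximum(best, best.T)
    np.fill_diagonal(best, 1.0)
    return SimilarityMatrix(best)


def estimate_null(
    nodes: NodeSet,
    n_perm: int = 100_000,
    seed: int = 0,
    rotation_set: np.ndarray = ROTATIONS_24,
) -> NullModel:
    """Permutation null of the rotation-maximized similarity.

    Draws ``n_perm`` random node pairs with replacement, independently
    permutes the 27 voxel entries of each member, and records the
    rotation-maximized correlation of the permuted pair.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be at least 1000")
    if nodes.n_nodes < 2:
        raise ValueError("need at least 2 nodes to estimate a null")
    rng = np.random.default_rng(seed)
    n = nodes.n_nodes
    i = rng.integers(0, n, size=n_perm)
    j = rng.integers(0, n - 1, size=n_perm)
    j[j >= i] += 1  # distinct partner per draw
    z = _standardize(nodes.intensities)
    # permute entries of each drawn cube independently
    perm_a = np.argsort(rng.random((n_perm, CUBE_SIZE)), axis=1)
    perm_b = np.argsort(rng.random((n_perm, CUBE_SIZE)), axis=1)
    za = np.take_along_axis(z[i], perm_a, axis=1)
    zb = np.take_along_axis(z[j], perm_b, axis=1)
    best = np.full(n_perm, -np.inf)
    for perm in rotation_set:
        np.maximum(best, (za * zb[:, perm]).sum(axis=1), out=best)
    return NullModel(np.clip(best, -1.0, 1.0), seed=seed)


def binarize_fdr(
    sim: SimilarityMatrix, null: NullModel, q: float = 0.05
) -> BinaryNetwork:
    """Threshold a similarity matrix by a BH-FDR test against the null.

    Each upper-triangle entry receives a one-sided empirical p-value
    ``P(null >= value)`` (add-one smoothed); Benjamini-Hochberg at level ``q``
    over the whole edge family determines the surviving edges.
    """
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    iu, ju = np.triu_indices(sim.n, k=1)
    pvals = null.pvalues(sim.values[iu, ju])
    if pvals.size == 0:
        return BinaryNetwork(sim.n, [])
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return BinaryNetwork(sim.n, np.column_stack([iu[reject], ju[reject]]))
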