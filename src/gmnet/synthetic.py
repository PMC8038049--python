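"""Synthetic two-group cohorts for grey-matter network analysis.

The generator emulates the inputs a segmentation pipeline would hand to the
network analysis: per-subject grey-matter (GM) partial-volume maps on a 2 mm
grid, an atlas label volume aligned to that grid, and a covariate table
(group, age, sex, education, total GM volume, physical/social anhedonia
scales, and illness covariates for patients).

The scientific handle is a per-subject latent "regularity" in [0, 1] that
controls how coherently organised the covariance of cube intensities is.
Each atlas region carries a latent 27-voxel pattern mixed from basis factors
along a cohort-fixed small-world region graph.  High regularity concentrates
the covariance into crisp local neighbourhoods (sparse, clustered similarity
networks: high small-worldness sigma); low regularity spreads it into
widespread moderate correlations (dense, disorganised networks: sigma low).
Downstream sigma is a smooth monotone function of regularity without the
generator ever touching the network-construction code.

Anhedonia coupling: the social anhedonia scale (SAS) is generated as a
linear function of the subject's regularity plus noise — not of sigma itself
— so the sigma-SAS correlation is induced through the shared latent trait
rather than imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .local import ICN_NAMES, AtlasParcellation
from .network import CUBE_EDGE, CUBE_SIZE, BinaryNetwork, GreyMatterVolume

__all__ = [
    "SimulationConfig",
    "generate_toy_graph",
    "generate_gm_volume",
    "generate_atlas_labels",
    "generate_cohort",
    "CohortVolumes",
]

# Latent covariance design.  Atlas regions sit on a cohort-fixed small-world
# block graph (a ring with a little rewiring).  Each region's latent pattern
# is a normalised mix of its own basis factor and its graph neighbours'
# factors -- a generative construction, so the implied covariance is PSD by
# construction and correlation transitivity is respected.  Regularity
# interpolates two regimes:
#   * diffuse (regularity 0): wide neighbour mixing and low cube noise give
#     widespread moderate correlations -- a dense, disorganised similarity
#     graph whose small-worldness is low;
#   * concentrated (regularity 1): narrow mixing and higher cube noise give
#     crisp local neighbourhoods -- a sparse, clustered small-world graph
#     with high sigma.
# Both mixing width and cube noise vary smoothly, so sigma is a smooth
# monotone function of regularity.
_BLOCK_GRAPH_NEIGHBORS = 4  # ring neighbours in the block graph
_BLOCK_GRAPH_REWIRE = 0.15  # small-world rewiring of the block graph
_MIX_DIFFUSE, _MIX_CONCENTRATED = 0.70, 0.35  # neighbour mixing weight
_NOISE_DIFFUSE, _NOISE_CONCENTRATED = 0.30, 0.55  # per-cube pattern noise
# subjects share the cohort's basis factors; each subject perturbs them by
# this fraction (in sd units), mirroring how real cohorts share one
# anatomical covariance organisation with individual variation
_SUBJECT_FACTOR_SD = 0.25
_BASE_INTENSITY = 0.62  # mean GM partial volume inside the blob
_PATTERN_AMPLITUDE = 0.11
_VOXEL_NOISE = 0.02

# Calibration constant: the correlation between a subject's latent regularity
# and the measured sigma at the package's reduced test scale (the
# regularity -> sigma fidelity).  The SAS coupling divides the configured
# sigma-SAS target by it, so the induced correlation approaches the target as
# n grows (see docs/methods.md).  Measured once at the design point.
_SIGMA_FIDELITY = 0.81


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic two-group cohort.

    Defaults mirror the reference cohort: 121 patients / 160 controls,
    physical anhedonia (PAS, 0-61) means 21.5 / 12.4, social anhedonia
    (SAS, 0-40) means 16.4 / 8.9 with SAS observed in only 77 / 104
    subjects, and total GM volume 585.8 / 600.0 cm^3.
    """

    n_patients: int = 121
    n_controls: int = 160
    volume_shape: tuple[int, int, int] = (64, 76, 64)
    voxel_size_mm: float = 2.0
    regularity_patient: float = 0.30
    regularity_control: float = 0.55
    regularity_sd: float = 0.22
    gm_volume_means_sds: dict = field(
        default_factory=lambda: {"patient": (585.8, 60.5), "control": (600.0, 59.3)}
    )
    pas_params: dict = field(
        default_factory=lambda: {"patient": (21.5, 9.6), "control": (12.4, 7.5)}
    )
    sas_params: dict = field(
        default_factory=lambda: {"patient": (16.4, 6.9), "control": (8.9, 4.4)}
    )
    rho_sigma_sas_patient: float = 0.0
    rho_sigma_sas_control: float = 0.36
    sas_missing_fraction: dict = field(
        default_factory=lambda: {"patient": 44 / 121, "control": 56 / 160}
    )
    age_params: dict = field(
        default_factory=lambda: {"patient": (34.5, 8.8), "control": (33.4, 6.8)}
    )
    education_params: dict = field(
        default_factory=lambda: {"patient": (13.3, 2.2), "control": (16.2, 2.8)}
    )
    sex_female_fraction: dict = field(
        default_factory=lambda: {"patient": 55 / 123, "control": 73 / 160}
    )
    duration_params: tuple[float, float] = (9.7, 7.5)  # years, patients only
    dose_params: tuple[float, float] = (419.8, 337.3)  # CPZ-equivalent mg
    n_regions: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        if self.n_regions <= 1:
            raise ValueError("n_regions must be at least 2")
        self.volume_shape = tuple(int(s) for s in self.volume_shape)
        self.duration_params = tuple(self.duration_params)
        self.dose_params = tuple(self.dose_params)
        for attr in ("gm_volume_means_sds", "pas_params", "sas_params",
                     "age_params", "education_params"):
            d = getattr(self, attr)
            setattr(self, attr, {g: tuple(v) for g, v in d.items()})
        if len(self.volume_shape) != 3 or any(s < 12 for s in self.volume_shape):
            raise ValueError("volume_shape must be 3 integers, each >= 12")
        for name, value in [
            ("regularity_patient", self.regularity_patient),
            ("regularity_control", self.regularity_control),
        ]:
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for g, frac in self.sas_missing_fraction.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"sas_missing_fraction[{g}] must lie in [0, 1]")
        for rho in (self.rho_sigma_sas_patient, self.rho_sigma_sas_control):
            if not -1 < rho < 1:
                raise ValueError("target correlations must lie in (-1, 1)")

    def group_regularity(self, group: str) -> float:
        return self.regularity_patient if group == "patient" else self.regularity_control

    def as_dict(self) -> dict:
        d = asdict(self)
        d["volume_shape"] = list(self.volume_shape)
        d["duration_params"] = list(self.duration_params)
        d["dose_params"] = list(self.dose_params)
        for attr in ("gm_volume_means_sds", "pas_params", "sas_params",
                     "age_params", "education_params"):
            d[attr] = {g: list(v) for g, v in d[attr].items()}
        return d


# ---------------------------------------------------------------------------
# toy graphs (fixtures for the metrics layer)
# ---------------------------------------------------------------------------


def generate_toy_graph(kind: str, n: int, param=None, seed: int = 0) -> BinaryNetwork:
    """Deterministic toy graphs used to exercise the metrics layer.

    kind:
        "ring_lattice"  — param = neighbors per side (int)
        "erdos_renyi"   — param = edge probability
        "watts_strogatz"— param = (neighbors per side, rewiring probability)
        "complete", "star", "path" — param unused
    """
    if n < 3:
        raise ValueError("toy graphs need n >= 3")
    if kind == "ring_lattice":
        k = int(param)
        if not 1 <= k <= (n - 1) // 2:
            raise ValueError("neighbors per side must lie in [1, (n-1)//2]")
        g = nx.circulant_graph(n, range(1, k + 1))
    elif kind == "erdos_renyi":
        p = float(param)
        if not 0 <= p <= 1:
            raise ValueError("edge probability must lie in [0, 1]")
        g = nx.gnp_random_graph(n, p, seed=seed)
    elif kind == "watts_strogatz":
        k, p = param
        if not 0 <= float(p) <= 1:
            raise ValueError("rewiring probability must lie in [0, 1]")
        g = nx.watts_strogatz_graph(n, 2 * int(k), float(p), seed=seed)
    elif kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "star":
        g = nx.star_graph(n - 1)
    elif kind == "path":
        g = nx.path_graph(n)
    else:
        raise ValueError(f"unknown toy graph kind: {kind!r}")
    return BinaryNetwork.from_networkx(g)


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------


def generate_atlas_labels(
    volume_shape: tuple[int, int, int],
    n_regions: int,
    seed: int = 0,
    foreground: np.ndarray | None = None,
) -> AtlasParcellation:
    """Voronoi parcellation of the (foreground of the) grid into regions.

    Seed points are drawn inside the foreground (default: the whole volume),
    relaxed by a few Lloyd (k-means) iterations so regions end up roughly
    equal-sized, and every foreground voxel takes the label of its nearest
    center, giving contiguous convex-ish regions labeled 1..n_regions.
    Region r is mapped to ICN grouping ``ICN_NAMES[(r - 1) % 7]``, so every
    grouping receives at least one region whenever n_regions >= 7.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be at least 2")
    volume_shape = tuple(int(s) for s in volume_shape)
    if foreground is None:
        foreground = np.ones(volume_shape, dtype=bool)
    else:
        foreground = np.asarray(foreground, dtype=bool)
        if foreground.shape != volume_shape:
            raise ValueError("foreground mask shape mismatch")
    coords = np.argwhere(foreground).astype(np.float64)
    if len(coords) < n_regions:
        raise ValueError("n_regions exceeds the number of foreground voxels")
    rng = np.random.default_rng(seed)
    centers = coords[rng.choice(len(coords), size=n_regions, replace=False)]
    for _ in range(8):  # Lloyd relaxation for balanced cells
        d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        nearest = d2.argmin(axis=1)
        for k in range(n_regions):
            members = coords[nearest == k]
            if len(members):
                centers[k] = members.mean(axis=0)
    # nearest-center labels; ties resolve to the lowest region id (argmin)
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.zeros(volume_shape, dtype=np.int32)
    labels[tuple(coords.astype(np.int64).T)] = d2.argmin(axis=1) + 1
    table = pd.DataFrame(
        {
            "region_id": np.arange(1, n_regions + 1),
            "name": [f"region_{r:03d}" for r in range(1, n_regions + 1)],
            "grouping": [ICN_NAMES[(r - 1) % len(ICN_NAMES)] for r in range(1, n_regions + 1)],
        }
    )
    return AtlasParcellation(labels, table)


# ---------------------------------------------------------------------------
# GM volumes
# ---------------------------------------------------------------------------


def _ellipsoid_norm(shape: tuple[int, int, int]) -> np.ndarray:
    """Normalized ellipsoid radius (1.0 on the reference blob surface)."""
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    center = [(s - 1) / 2 for s in shape]
    radii = [0.47 * s for s in shape]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return np.sqrt(r2)


def _block_mixing(n_regions: int, regularity: float, cohort_seed: int) -> np.ndarray:
    """Row-normalised mixing matrix from basis factors to region patterns.

    Region k's pattern mixes its own factor with its neighbours' factors on
    the cohort's small-world block graph, with the mixing weight shrinking as
    regularity rises.  Being generative, the implied pattern covariance is
    positive semi-definite by construction.
    """
    K = n_regions
    k_ring = min(_BLOCK_GRAPH_NEIGHBORS, K - 1)
    bg = nx.watts_strogatz_graph(K, k_ring, _BLOCK_GRAPH_REWIRE, seed=cohort_seed)
    gmix = _MIX_DIFFUSE + (_MIX_CONCENTRATED - _MIX_DIFFUSE) * regularity
    M = np.eye(K)
    for k in range(K):
        for l in bg.neighbors(k):
            M[k, l] = gmix
    return M / np.sqrt((M**2).sum(axis=1, keepdims=True))


def _cube_noise(regularity: float) -> float:
    return _NOISE_DIFFUSE + (_NOISE_CONCENTRATED - _NOISE_DIFFUSE) * regularity


def _cohort_basis(n_regions: int, cohort_seed: int) -> np.ndarray:
    """K x 27 matrix with orthonormal rows, all orthogonal to the ones vector.

    Using an exact orthonormal basis for the cohort template removes the
    sampling noise a Gaussian draw would add to the realised region-pattern
    correlations (with 27-voxel patterns that noise is substantial), so the
    similarity topology is a stable function of the designed covariance.
    Orthogonality to the constant vector keeps the correlations exact after
    per-cube mean removal.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([cohort_seed, 0xA7145]).generate_state(1)[0]
    )
    g = rng.standard_normal((CUBE_SIZE, n_regions + 1))
    g[:, 0] = 1.0  # first column spans the constant vector
    q, _ = np.linalg.qr(g)
    return q[:, 1 : n_regions + 1].T


def _cube_region_of_center(
    origins: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    centers = origins + CUBE_EDGE // 2
    return labels[tuple(centers.T)]


def generate_gm_volume(
    config: SimulationConfig,
    subject_regularity: float,
    seed: int,
    target_gm_cm3: float | None = None,
    atlas: AtlasParcellation | None = None,
    subject_id: str = "subject",
) -> GreyMatterVolume:
    """One subject's GM partial-volume map with controllable covariance.

    The GM region is a cube-aligned ellipsoidal blob: the union of the
    3x3x3 tiling cubes whose centres fall inside the (rescaled) ellipsoid.
    Each GM cube's 27 voxels carry its atlas region's latent pattern plus
    idiosyncratic pattern noise and voxel noise, modulated by a smooth radial
    profile evaluated per cube (a per-cube scale/offset leaves within-cube
    correlations untouched).  The field is finally scaled so the total GM
    volume matches the drawn target within 5%.
    """
    shape = config.volume_shape
    if min(shape) // CUBE_EDGE < 1 or np.prod([s // CUBE_EDGE for s in shape]) < 30:
        raise ValueError("volume too small to fit at least 30 cubes")
    if not 0 <= subject_regularity <= 1:
        raise ValueError("subject_regularity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if atlas is None:
        atlas = generate_atlas_labels(shape, config.n_regions, seed=config.seed)

    r_norm = _ellipsoid_norm(shape)
    voxel_vol = config.voxel_size_mm**3
    capacity = float((r_norm <= 1.0).sum() * _BASE_INTENSITY * voxel_vol)
    if target_gm_cm3 is None:
        target_mm3 = capacity
    else:
        target_mm3 = float(target_gm_cm3) * 1000.0
        if not 0.05 * capacity <= target_mm3 <= 1.45 * capacity:
            raise ValueError(
                f"target GM volume {target_gm_cm3:.1f} cm^3 infeasible for "
                f"shape {shape} (capacity ~{capacity / 1000:.1f} cm^3)"
            )
    # shrink/grow the blob to put the target in easy multiplicative reach
    blob_scale = float(np.clip((target_mm3 / capacity) ** (1 / 3), 0.3, 1.0))

    # latent region patterns: cohort-stable covariance structure at the
    # subject's regularity.  The cohort template uses an orthonormal basis
    # (orthogonal to the constant vector), so the template's realised Gram
    # matrix EQUALS the designed covariance rather than a noisy draw of it;
    # each subject then adds a perturbation in the same covariance root.
    K = config.n_regions
    if K > CUBE_SIZE - 1:
        raise ValueError(f"n_regions must be at most {CUBE_SIZE - 1} (pattern rank)")
    mixing = _block_mixing(K, subject_regularity, cohort_seed=config.seed)
    basis = _cohort_basis(K, config.seed)  # K x 27, orthonormal rows
    eps = _SUBJECT_FACTOR_SD
    factors = np.sqrt(1.0 - eps**2) * np.sqrt(CUBE_SIZE) * basis
    factors = factors + eps * rng.standard_normal((K, CUBE_SIZE))
    h = mixing @ factors
    tau = _cube_noise(subject_regularity)

    # GM cubes: tiling cubes whose centre lies inside the rescaled blob
    nx_, ny, nz = (s // CUBE_EDGE for s in shape)
    grid = np.stack(
        np.meshgrid(
            np.arange(nx_) * CUBE_EDGE,
            np.arange(ny) * CUBE_EDGE,
            np.arange(nz) * CUBE_EDGE,
            indexing="ij",
        ),
        axis=-1,
    ).reshape(-1, 3)
    centers = grid + CUBE_EDGE // 2
    r_center = r_norm[tuple(centers.T)]
    gm_cubes = grid[r_center <= blob_scale]
    # gentle radial taper, constant within each cube
    taper = 1.0 - 0.15 * (r_center[r_center <= blob_scale] / blob_scale) ** 2

    data = np.zeros(shape, dtype=np.float64)
    regions = _cube_region_of_center(gm_cubes, atlas.labels)
    eps = rng.standard_normal((len(gm_cubes), CUBE_SIZE))
    vox_noise = rng.normal(0.0, _VOXEL_NOISE, size=(len(gm_cubes), CUBE_SIZE))
    for (x, y, z), region, noise, vn, scale in zip(
        gm_cubes, regions, eps, vox_noise, taper
    ):
        if region == 0:
            pattern = noise
        else:
            pattern = h[region - 1] + tau * noise
        pattern = (pattern - pattern.mean()) / max(pattern.std(), 1e-12)
        cube_vals = scale * _BASE_INTENSITY + _PATTERN_AMPLITUDE * pattern + vn
        data[x : x + CUBE_EDGE, y : y + CUBE_EDGE, z : z + CUBE_EDGE] = (
            cube_vals.reshape(CUBE_EDGE, CUBE_EDGE, CUBE_EDGE, order="F")
        )
    data = np.clip(data, 0.0, 1.0)

    # multiplicative rescale (with clipping) onto the volume target
    for _ in range(6):
        total = data.sum() * voxel_vol
        if abs(total - target_mm3) / target_mm3 <= 0.01:
            break
        data = np.clip(data * (target_mm3 / total), 0.0, 1.0)
    if abs(data.sum() * voxel_vol - target_mm3) / target_mm3 > 0.05:
        raise RuntimeError("could not match the GM volume target within 5%")

    voxel = (config.voxel_size_mm,) * 3
    return GreyMatterVolume(data=data, voxel_size=voxel, subject_id=subject_id)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


class CohortVolumes:
    """Lazy, deterministic per-subject volume store.

    Volumes are regenerated on demand from (config, per-subject seed), so a
    full cohort never has to sit in memory at once.
    """

    def __init__(self, config: SimulationConfig, table: pd.DataFrame, atlas: AtlasParcellation):
        self._config = config
        self._atlas = atlas
        self._table = table.set_index("subject_id")

    def __len__(self) -> int:
        return len(self._table)

    def subject_ids(self) -> list[str]:
        return list(self._table.index)

    def __getitem__(self, subject_id: str) -> GreyMatterVolume:
        row = self._table.loc[subject_id]
        return generate_gm_volume(
            self._config,
            subject_regularity=float(row["regularity"]),
            seed=int(row["volume_seed"]),
            target_gm_cm3=float(row["gm_volume"]),
            atlas=self._atlas,
            subject_id=subject_id,
        )


def _truncnorm(rng, mean, sd, lo, hi, size):
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, CohortVolumes, AtlasParcellation]:
    """Draw a full synthetic cohort: covariates, volumes, and the atlas.

    Returns the covariate table (one row per subject), a lazy volume store,
    and the shared atlas parcellation.  The designated groups' SAS scores are
    coupled to the subject's latent regularity so the realized correlation
    between constructed sigma and SAS approaches the configured target.
    """
    root = np.random.SeedSequence(config.seed)
    ss_cov, ss_atlas, ss_vol = root.spawn(3)
    rng = np.random.default_rng(ss_cov)
    # the atlas covers the reference ellipsoid (all subjects' blobs lie inside)
    foreground = _ellipsoid_norm(config.volume_shape) <= 1.0
    atlas = generate_atlas_labels(
        config.volume_shape,
        config.n_regions,
        seed=int(ss_atlas.generate_state(1)[0] % 2**31),
        foreground=foreground,
    )
    vol_seeds = ss_vol.generate_state(config.n_patients + config.n_controls) % (2**31)

    rows = []
    idx = 0
    for group, n in (("patient", config.n_patients), ("control", config.n_controls)):
        mu_rho = config.group_regularity(group)
        rho_subj = _truncnorm(rng, mu_rho, config.regularity_sd, 0.02, 0.98, n)
        z_rho = (rho_subj - mu_rho) / config.regularity_sd

        gm_mean, gm_sd = config.gm_volume_means_sds[group]
        gm = rng.normal(gm_mean, gm_sd, size=n)
        age_m, age_s = config.age_params[group]
        edu_m, edu_s = config.education_params[group]
        pas_m, pas_s = config.pas_params[group]
        sas_m, sas_s = config.sas_params[group]
        rho_target = (
            config.rho_sigma_sas_patient if group == "patient" else config.rho_sigma_sas_control
        )
        rho_couple = float(np.clip(rho_target / _SIGMA_FIDELITY, -0.97, 0.97))
        z_sas = rho_couple * z_rho + np.sqrt(1 - rho_couple**2) * rng.standard_normal(n)
        sas = np.clip(np.rint(sas_m + sas_s * z_sas), 0, 40)

        missing = np.zeros(n, dtype=bool)
        n_missing = int(round(config.sas_missing_fraction[group] * n))
        missing[rng.choice(n, size=n_missing, replace=False)] = True

        sex = np.where(
            rng.random(n) < config.sex_female_fraction[group], "female", "male"
        )
        for i in range(n):
            prefix = "p" if group == "patient" else "c"
            row = {
                "subject_id": f"{prefix}{i + 1:04d}",
                "group": group,
                "age": round(float(_truncnorm(rng, age_m, age_s, 18, 80, 1)[0]), 1),
                "sex": sex[i],
                "education": round(float(_truncnorm(rng, edu_m, edu_s, 6, 26, 1)[0]), 1),
                "gm_volume": round(float(gm[i]), 2),
                "pas": int(np.clip(np.rint(rng.normal(pas_m, pas_s)), 0, 61)),
                "sas": np.nan if missing[i] else int(sas[i]),
                "duration_illness": np.nan,
                "cpz_dose": np.nan,
                "regularity": float(rho_subj[i]),
                "volume_seed": int(vol_seeds[idx]),
            }
            if group == "patient":
                row["duration_illness"] = round(
                    float(_truncnorm(rng, *config.duration_params, 0.2, 45, 1)[0]), 1
                )
                row["cpz_dose"] = round(
                    float(_truncnorm(rng, *config.dose_params, 0, 2500, 1)[0]), 1
                )
            rows.append(row)
            idx += 1

    table = pd.DataFrame(rows)
    return table, CohortVolumes(config, table, atlas), atlas
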