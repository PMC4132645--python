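"""Synthetic lesion cohorts with controllable spatial stereotypy.

Real stroke lesions are not independent sprinklings of damage: they follow
the branching architecture of the arterial tree, so damage at one site
co-occurs with damage at others in a stereotyped way, and proximal
("upstream") tissue is hit with lower spatial variability than distal
tissue.  That hidden multivariate structure is precisely what biases
mass-univariate lesion-deficit mapping, so the generators here reproduce it
in a minimal, fully seeded form:

* :func:`make_territory_tree` carves one hemisphere of the grid into a
  rooted tree of contiguous territories (a vascular-tree-like architecture;
  a model, not an anatomical claim).
* :func:`sample_stereotyped_lesion` damages the union of territories on the
  path from the root to a randomly chosen endpoint node, then erodes voxels
  with a (optionally depth-graded) Bernoulli noise rate — giving proximal
  territories a higher damage probability and lower variability than distal
  ones.
* :func:`sample_independent_lesion` is the matched null: i.i.d. per-voxel
  Bernoulli damage, with no voxel-voxel correlation.
* :func:`make_two_region_toy` builds the canonical two-region fixture
  (extended critical region A whose damage always drags along the compact
  collateral region B) used to demonstrate mislocalization analytically.
* :func:`two_critical_area_cohort` builds the two-distant-critical-areas
  cohort used to contrast mass-univariate and multivariate inference.

All generators are pure functions of their arguments and seed, restrict
damage to the canonical hemisphere (first-axis index < dims[0]//2), and
enforce the minimum-lesion-volume floor by resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed, spawn_rng
from .grid import DEFAULT_MIN_LESION_MM3, LesionDataset, LesionMask, Parcellation, VoxelGrid

__all__ = [
    "TerritoryTree",
    "CohortSpec",
    "StereotypedParams",
    "default_grid",
    "hemisphere_mask",
    "make_territory_tree",
    "tree_from_topology",
    "sample_stereotyped_lesion",
    "sample_independent_lesion",
    "sample_blob_lesion",
    "make_synthetic_parcellation",
    "make_two_region_toy",
    "two_critical_area_cohort",
    "generate_cohort",
]


def default_grid(dims=(32, 32, 32), spacing=(2.0, 2.0, 2.0)) -> VoxelGrid:
    """The desk-scale analysis grid: 32^3 voxels at 2 mm isotropic."""
    return VoxelGrid(dims=dims, spacing=spacing)


def hemisphere_mask(grid: VoxelGrid) -> np.ndarray:
    """Boolean volume of the canonical hemisphere (first-axis half-space)."""
    mask = np.zeros(grid.dims, dtype=bool)
    mask[: grid.dims[0] // 2] = True
    return mask


class CohortGenerationError(RuntimeError):
    """A generator could not satisfy its constraints (e.g. volume floor)."""


# ---------------------------------------------------------------------------
# territory trees


@dataclass(frozen=True)
class TerritoryTree:
    """A rooted tree of disjoint, contiguous voxel territories.

    ``labels`` assigns every canonical-hemisphere voxel to exactly one node
    id (1..n); 0 marks voxels outside the hemisphere.  ``parent`` maps each
    node to its parent (the root maps to 0).
    """

    grid: VoxelGrid
    labels: np.ndarray
    parent: dict[int, int]
    root_id: int = 1

    def __post_init__(self):
        lab = np.asarray(self.labels).astype(np.int32)
        lab.setflags(write=False)
        object.__setattr__(self, "labels", lab)
        nodes = set(self.parent)
        for node, par in self.parent.items():
            if par != 0 and par not in nodes:
                raise ValueError(f"node {node} has unknown parent {par}")
        roots = [n for n, p in self.parent.items() if p == 0]
        if roots != [self.root_id]:
            raise ValueError(f"exactly one root expected, found {roots}")

    @property
    def nodes(self) -> list[int]:
        return sorted(self.parent)

    @property
    def leaves(self) -> list[int]:
        parents = set(self.parent.values())
        return [n for n in self.nodes if n not in parents]

    def depth(self, node: int) -> int:
        d = 0
        while self.parent[node] != 0:
            node = self.parent[node]
            d += 1
        return d

    def path_to_root(self, node: int) -> list[int]:
        """Nodes from the root down to ``node`` (inclusive)."""
        path = [node]
        while self.parent[path[-1]] != 0:
            path.append(self.parent[path[-1]])
        return path[::-1]

    def territory_voxels(self, node: int) -> np.ndarray:
        vox = np.argwhere(self.labels == node)
        if vox.size == 0:
            raise ValueError(f"territory {node} is empty")
        return vox

    def territory_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


def _voronoi_labels(grid: VoxelGrid, seed_points: np.ndarray) -> np.ndarray:
    """Assign each hemisphere voxel to its nearest seed (ties -> lower id)."""
    hemi = hemisphere_mask(grid)
    vox = np.argwhere(hemi).astype(float)
    # distances in mm so anisotropic grids behave sensibly
    sp = np.asarray(grid.spacing)
    d2 = ((vox[:, None, :] * sp - seed_points[None, :, :] * sp) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1) + 1  # argmin breaks ties toward lower id
    labels = np.zeros(grid.dims, dtype=np.int32)
    labels[hemi] = assign
    return labels


def tree_from_topology(
    grid: VoxelGrid,
    parent: dict[int, int],
    seed_fractions: dict[int, tuple[float, float, float]],
) -> TerritoryTree:
    """Build a territory tree from an explicit topology and seed placement.

    ``seed_fractions`` places each node's Voronoi seed at fractional
    coordinates of the hemisphere bounding box (each component in [0, 1]).
    """
    hemi_dims = (grid.dims[0] // 2, grid.dims[1], grid.dims[2])
    nodes = sorted(parent)
    pts = np.array(
        [[f * (d - 1) for f, d in zip(seed_fractions[n], hemi_dims)] for n in nodes]
    )
    labels = _voronoi_labels(grid, pts)
    root = [n for n, p in parent.items() if p == 0][0]
    return TerritoryTree(grid=grid, labels=labels, parent=dict(parent), root_id=root)


def make_territory_tree(grid: VoxelGrid, n_branches: int, seed: int) -> TerritoryTree:
    """Grow a seeded random territory tree over the canonical hemisphere.

    ``n_branches`` is the total number of territories (the root trunk plus
    branch territories).  Topology: each new node attaches to a uniformly
    chosen existing node; its Voronoi seed is drawn near its parent's seed,
    so territories on the same branch are spatially coherent.  Deterministic
    given ``(grid, n_branches, seed)``.
    """
    hemi = hemisphere_mask(grid)
    n_hemi = int(hemi.sum())
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    if n_branches > n_hemi:
        raise ValueError(
            f"grid too small: {n_branches} territories requested, "
            f"{n_hemi} hemisphere voxels available"
        )
    rng = spawn_rng(seed, "territory-tree")
    hemi_vox = np.argwhere(hemi)
    lo, hi = hemi_vox.min(axis=0), hemi_vox.max(axis=0)
    centre = (lo + hi) / 2.0

    parent: dict[int, int] = {1: 0}
    seeds = [centre]
    scale = (hi - lo + 1) / 4.0
    taken = {tuple(np.rint(centre).astype(int))}
    for node in range(2, n_branches + 1):
        parent[node] = int(rng.integers(1, node))
        for _ in range(200):
            cand = seeds[parent[node] - 1] + rng.normal(scale=scale, size=3)
            cand = np.clip(cand, lo, hi)
            key = tuple(np.rint(cand).astype(int))
            if key not in taken:
                break
        else:  # pragma: no cover - astronomically unlikely on sane grids
            free = [tuple(v) for v in hemi_vox if tuple(v) not in taken]
            cand = np.array(free[rng.integers(len(free))], dtype=float)
            key = tuple(np.rint(cand).astype(int))
        taken.add(key)
        seeds.append(cand)

    labels = _voronoi_labels(grid, np.array(seeds))
    # Voronoi cells of distinct sites are non-empty on a grid only if each
    # site's nearest voxel is its own; enforce by construction check.
    present = set(np.unique(labels[labels > 0]).tolist())
    missing = set(parent) - present
    if missing:
        raise CohortGenerationError(f"empty territories {sorted(missing)}; grid too small")
    return TerritoryTree(grid=grid, labels=labels, parent=parent)


# ---------------------------------------------------------------------------
# lesion samplers


@dataclass(frozen=True)
class StereotypedParams:
    """Parameters of the stereotyped (tree-structured) lesion sampler.

    noise
        Voxel-level Bernoulli erosion rate applied to damaged territories
        (default 0.1).
    noise_by_depth
        Optional per-depth erosion rates (index = node depth, last entry
        reused beyond); overrides ``noise`` and realises the lower spatial
        variability of proximal damage.
    leaves_only
        Restrict the random endpoint to leaf territories (default: any node,
        so a lesion may be the trunk alone).
    endpoint_weights
        Optional relative sampling weights per endpoint node id.
    endpoint
        Fix the endpoint node (diagnostics/tests).
    """

    noise: float = 0.1
    noise_by_depth: tuple[float, ...] | None = None
    leaves_only: bool = False
    endpoint_weights: dict[int, float] | None = None
    endpoint: int | None = None
    min_volume_mm3: float = DEFAULT_MIN_LESION_MM3
    max_retries: int = 100

    def noise_at_depth(self, depth: int) -> float:
        if self.noise_by_depth is not None:
            return self.noise_by_depth[min(depth, len(self.noise_by_depth) - 1)]
        return self.noise


def sample_stereotyped_lesion(
    tree: TerritoryTree,
    params: StereotypedParams = StereotypedParams(),
    seed: int = 0,
    subject_id: str = "",
) -> LesionMask:
    """Draw one stereotyped lesion: a root-to-endpoint path of territories.

    Damage covers every territory on the path from the trunk to a randomly
    chosen endpoint node, then each damaged voxel is spared independently at
    the (depth-graded) erosion rate.  Proximal territories are therefore
    damaged more often, and with less voxel-level variability, than distal
    ones.  Resamples until the volume floor is met.
    """
    rng = spawn_rng(seed, "stereotyped-lesion")
    candidates = tree.leaves if params.leaves_only else tree.nodes
    if params.endpoint is not None:
        if params.endpoint not in tree.nodes:
            raise ValueError(f"endpoint {params.endpoint} not in tree")
        candidates = [params.endpoint]
    weights = np.array(
        [
            (params.endpoint_weights or {}).get(n, 1.0)
            for n in candidates
        ],
        dtype=float,
    )
    weights = weights / weights.sum()
    min_vox = int(np.ceil(params.min_volume_mm3 / tree.grid.voxel_volume_mm3))
    for _ in range(params.max_retries):
        endpoint = int(rng.choice(candidates, p=weights))
        vox = np.zeros(tree.grid.dims, dtype=np.uint8)
        for node in tree.path_to_root(endpoint):
            noise = params.noise_at_depth(tree.depth(node))
            terr = tree.labels == node
            if noise > 0:
                keep = rng.random(int(terr.sum())) >= noise
                idx = np.argwhere(terr)[keep]
                vox[tuple(idx.T)] = 1
            else:
                vox[terr] = 1
        if int(vox.sum()) >= min_vox:
            return LesionMask(grid=tree.grid, voxels=vox, subject_id=subject_id)
    raise CohortGenerationError(
        f"could not satisfy the volume floor after {params.max_retries} draws"
    )


def sample_independent_lesion(
    grid: VoxelGrid,
    per_voxel_p: float,
    seed: int = 0,
    min_volume_mm3: float = DEFAULT_MIN_LESION_MM3,
    max_retries: int = 100,
    subject_id: str = "",
) -> LesionMask:
    """Draw one independent-damage null lesion: i.i.d. Bernoulli voxels."""
    if not 0 < per_voxel_p < 1:
        raise ValueError(f"per_voxel_p must be in (0, 1), got {per_voxel_p}")
    hemi = hemisphere_mask(grid)
    n_hemi = int(hemi.sum())
    min_vox = int(np.ceil(min_volume_mm3 / grid.voxel_volume_mm3))
    if per_voxel_p * n_hemi < 0.5 * min_vox:
        raise ValueError(
            f"per_voxel_p={per_voxel_p} incompatible with the volume floor "
            f"({min_vox} voxels) on this grid"
        )
    rng = spawn_rng(seed, "independent-lesion")
    for _ in range(max_retries):
        vox = np.zeros(grid.dims, dtype=np.uint8)
        vox[hemi] = rng.random(n_hemi) < per_voxel_p
        if int(vox.sum()) >= min_vox:
            return LesionMask(grid=grid, voxels=vox, subject_id=subject_id)
    raise CohortGenerationError(
        f"could not satisfy the volume floor after {max_retries} draws"
    )


def sample_blob_lesion(
    grid: VoxelGrid,
    radius_range_mm: tuple[float, float] = (6.0, 14.0),
    seed: int = 0,
    min_volume_mm3: float = DEFAULT_MIN_LESION_MM3,
    max_retries: int = 100,
    subject_id: str = "",
    centre_region: np.ndarray | None = None,
) -> LesionMask:
    """Draw one compact spherical lesion within the canonical hemisphere."""
    hemi = hemisphere_mask(grid)
    region = hemi if centre_region is None else (hemi & centre_region)
    centres = np.argwhere(region)
    if centres.size == 0:
        raise ValueError("empty centre region")
    rng = spawn_rng(seed, "blob-lesion")
    min_vox = int(np.ceil(min_volume_mm3 / grid.voxel_volume_mm3))
    coords = np.argwhere(hemi)
    world = coords * np.asarray(grid.spacing)
    for _ in range(max_retries):
        centre = centres[rng.integers(len(centres))]
        r = rng.uniform(*radius_range_mm)
        d2 = ((world - centre * np.asarray(grid.spacing)) ** 2).sum(axis=1)
        inside = coords[d2 <= r * r]
        if len(inside) >= min_vox:
            vox = np.zeros(grid.dims, dtype=np.uint8)
            vox[tuple(inside.T)] = 1
            return LesionMask(grid=grid, voxels=vox, subject_id=subject_id)
    raise CohortGenerationError(
        f"could not satisfy the volume floor after {max_retries} draws"
    )


# ---------------------------------------------------------------------------
# parcellations


def make_synthetic_parcellation(grid: VoxelGrid, n_areas: int, seed: int) -> Parcellation:
    """Seeded Voronoi parcellation of the hemisphere into contiguous areas."""
    if n_areas < 1:
        raise ValueError("n_areas must be >= 1")
    hemi_vox = np.argwhere(hemisphere_mask(grid))
    if n_areas > len(hemi_vox):
        raise ValueError(f"grid too small for {n_areas} areas")
    rng = spawn_rng(seed, "parcellation")
    pick = rng.choice(len(hemi_vox), size=n_areas, replace=False)
    labels = _voronoi_labels(grid, hemi_vox[pick].astype(float))
    return Parcellation(grid=grid, labels=labels)


# ---------------------------------------------------------------------------
# canonical fixtures


#: Area labels used by :func:`make_two_region_toy`.
TOY_AREA_A, TOY_AREA_B, TOY_AREA_C = 1, 2, 3


def make_two_region_toy(
    n_affected: int, n_unaffected: int, seed: int = 0
) -> tuple[LesionDataset, Parcellation]:
    """The canonical two-region mislocalization fixture.

    Region A is an extended 12-voxel strip whose damage defines the
    hypothetical deficit; region B is a compact 27-voxel block of pure
    collateral damage; region C lies elsewhere.  Every affected-type lesion
    covers a contiguous sub-segment of A *plus all of B* (B has zero spatial
    variability), so B is damaged in every affected-type lesion while each A
    voxel is damaged in strictly fewer.  Unaffected-type lesions are compact
    blocks wholly inside C.  Sub-segments are drawn from a balanced family
    (two long segments sparing one end each, two half-segments) so that
    every A voxel is both well covered and strictly less covered than B.
    """
    if n_affected < 2 or n_unaffected < 2:
        raise ValueError("both cohort arms need at least 2 subjects")
    grid = VoxelGrid(dims=(32, 12, 12), spacing=(2.0, 2.0, 2.0))
    rng = spawn_rng(seed, "two-region-toy")

    a_voxels = [(x, 6, 6) for x in range(2, 14)]  # 12-voxel strip
    b_block = (slice(16, 19), slice(5, 8), slice(5, 8))  # 27-voxel block

    labels = np.zeros(grid.dims, dtype=np.int32)
    for v in a_voxels:
        labels[v] = TOY_AREA_A
    labels[b_block] = TOY_AREA_B
    labels[21:32, :, :] = TOY_AREA_C
    parcellation = Parcellation(grid=grid, labels=labels)

    # segment family over A-strip positions 0..11 (half-open [start, stop))
    family = [(0, 6), (6, 12), (0, 11), (1, 12)]
    segments = [family[i % 4] for i in range(n_affected)]
    rng.shuffle(segments)

    masks = []
    for i, (s, e) in enumerate(segments):
        vox = np.zeros(grid.dims, dtype=np.uint8)
        for x in range(2 + s, 2 + e):
            vox[x, 6, 6] = 1
        vox[b_block] = 1
        masks.append(LesionMask(grid=grid, voxels=vox, subject_id=f"aff-{i:04d}"))
    for i in range(n_unaffected):
        x0 = int(rng.integers(21, 29))
        y0 = int(rng.integers(0, 10))
        z0 = int(rng.integers(0, 10))
        vox = np.zeros(grid.dims, dtype=np.uint8)
        vox[x0 : x0 + 3, y0 : y0 + 3, z0 : z0 + 3] = 1
        masks.append(LesionMask(grid=grid, voxels=vox, subject_id=f"unaff-{i:04d}"))
    return LesionDataset(grid=grid, masks=masks), parcellation


@dataclass(frozen=True)
class TwoCriticalAreaCohort:
    """The stereotyped two-distant-critical-areas fixture."""

    dataset: LesionDataset
    parcellation: Parcellation
    tree: TerritoryTree
    critical_areas: tuple[int, int]
    collateral_area: int


def two_critical_area_cohort(
    n_subjects: int = 300,
    seed: int = 0,
    grid: VoxelGrid | None = None,
    noise_by_depth: tuple[float, ...] = (0.05, 0.05, 0.2),
) -> TwoCriticalAreaCohort:
    """Build the cohort used to contrast univariate and multivariate mapping.

    The territory tree has a trunk, one intermediate territory M feeding
    three distal leaves (the two critical areas A1, A2 plus a non-critical
    sibling D), and three further leaves on other branches.  Lesions run
    from the trunk to a random leaf with depth-graded erosion, so M is
    damaged with low variability in *every* lesion reaching A1, A2 or D —
    the low-variance collateral core that drags the mass-univariate locus
    away from the true areas.  The parcellation is the territory map itself;
    the hypothetical ground truth is damage to >= 20% of A1 or A2.
    """
    grid = grid or default_grid()
    parent = {1: 0, 2: 1, 3: 2, 4: 2, 5: 2, 6: 1, 7: 1, 8: 1}
    # fractional hemisphere coordinates: trunk centre-bottom, M anterior,
    # its leaves fanned beyond it, other leaves posterior
    seed_fractions = {
        1: (0.50, 0.50, 0.30),  # trunk
        2: (0.50, 0.25, 0.60),  # M: shared collateral core
        3: (0.25, 0.08, 0.85),  # A1 (critical)
        4: (0.75, 0.08, 0.85),  # A2 (critical)
        5: (0.50, 0.02, 0.35),  # D: non-critical sibling under M
        6: (0.20, 0.75, 0.70),
        7: (0.80, 0.75, 0.70),
        8: (0.50, 0.92, 0.25),
    }
    tree = tree_from_topology(grid, parent, seed_fractions)
    params = StereotypedParams(noise_by_depth=noise_by_depth, leaves_only=True)
    masks = [
        sample_stereotyped_lesion(
            tree, params, seed=derive_seed(seed, "two-critical", i),
            subject_id=f"sub-{i:04d}",
        )
        for i in range(n_subjects)
    ]
    dataset = LesionDataset(grid=grid, masks=masks)
    parcellation = Parcellation(grid=grid, labels=np.asarray(tree.labels))
    return TwoCriticalAreaCohort(
        dataset=dataset,
        parcellation=parcellation,
        tree=tree,
        critical_areas=(3, 4),
        collateral_area=2,
    )


# ---------------------------------------------------------------------------
# cohort specification / dispatch


@dataclass(frozen=True)
class CohortSpec:
    """Declarative description of a synthetic cohort.

    ``generator`` is one of ``stereotyped``, ``independent``, ``blob`` or
    ``two-region-toy``; ``params`` holds the generator-specific knobs.
    """

    n_subjects: int
    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        known = {"stereotyped", "independent", "blob", "two-region-toy"}
        if self.generator not in known:
            raise ValueError(f"unknown generator {self.generator!r}; choose from {sorted(known)}")
        for key in ("noise", "per_voxel_p"):
            if key in self.params and not 0 <= float(self.params[key]) <= 1:
                raise ValueError(f"{key} must be in [0, 1], got {self.params[key]}")


def generate_cohort(
    spec: CohortSpec, grid: VoxelGrid | None = None
) -> tuple[LesionDataset, Parcellation | None]:
    """Materialize a :class:`CohortSpec` into a dataset (plus parcellation
    for the two-region toy, else ``None``)."""
    grid = grid or default_grid()
    p = dict(spec.params)
    if spec.generator == "two-region-toy":
        n_aff = int(p.pop("n_affected", spec.n_subjects // 2))
        n_unaff = spec.n_subjects - n_aff
        dataset, parcellation = make_two_region_toy(n_aff, n_unaff, seed=spec.seed)
        return dataset, parcellation

    masks = []
    if spec.generator == "stereotyped":
        tree = make_territory_tree(grid, int(p.pop("n_branches", 8)),
                                   seed=derive_seed(spec.seed, "tree"))
        sp_kwargs = {k: v for k, v in p.items()
                     if k in StereotypedParams.__dataclass_fields__}
        if sp_kwargs.get("noise_by_depth") is not None:
            sp_kwargs["noise_by_depth"] = tuple(sp_kwargs["noise_by_depth"])
        sp = StereotypedParams(**sp_kwargs)
        for i in range(spec.n_subjects):
            masks.append(sample_stereotyped_lesion(
                tree, sp, seed=derive_seed(spec.seed, "subject", i),
                subject_id=f"sub-{i:04d}"))
    elif spec.generator == "independent":
        pv = float(p.pop("per_voxel_p", 0.05))
        for i in range(spec.n_subjects):
            masks.append(sample_independent_lesion(
                grid, pv, seed=derive_seed(spec.seed, "subject", i),
                subject_id=f"sub-{i:04d}", **p))
    elif spec.generator == "blob":
        rr = tuple(p.pop("radius_range_mm", (6.0, 14.0)))
        for i in range(spec.n_subjects):
            masks.append(sample_blob_lesion(
                grid, rr, seed=derive_seed(spec.seed, "subject", i),
                subject_id=f"sub-{i:04d}", **p))
    return LesionDataset(grid=grid, masks=masks), None
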