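"""Synthetic clustered cell populations with voxelized compartments.

Emulates the statistical structure of adherent HER2+ cells imaged live on a
well bottom at confocal resolution: a Thomas cluster process for cell
positions (adherent cells cluster tightly, which drives cross-dose), flattened
half-ellipsoid cell bodies with ellipsoidal nuclei whose volumes follow a
log-normal distribution calibrated so the median matches a 10 µm
sphere-equivalent diameter, membrane/cytosol compartments derived by binary
erosion and distance-transform expansion, a three-phase antibody distribution
(membrane binding → endosomal internalization → perinuclear pooling),
saturation/kinetic binding-assay tables, and double-exponential
photobleaching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .nucleardata import WATER_DENSITY_KG_PER_UM3

#: in-plane / axial confocal voxel size, µm
DEFAULT_VOXEL_SIZE: tuple[float, float, float] = (0.101, 0.101, 0.159)


# ---------------------------------------------------------------------------
# layout and geometry containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WellLayout:
    """Lateral well-bottom extent and the voxel grid resolution."""

    width: float = 250.0
    height: float = 250.0
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel dimensions must be strictly positive")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("well dimensions must be positive")


@dataclass
class CellGeometry:
    """Voxelized masks of one cell on its own local grid.

    ``origin`` is the world coordinate (µm) of the center of voxel (0, 0, 0);
    masks are indexed [ix, iy, iz] with world x = origin[0] + ix * voxel[0].
    """

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    position: tuple[float, float]
    origin: tuple[float, float, float]
    voxel_size: tuple[float, float, float]
    cytosol_mask: np.ndarray | None = None
    membrane_mask: np.ndarray | None = None
    degenerate: bool = False

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def nucleus_volume(self) -> float:
        """Voxel-counted nucleus volume, µm³."""
        return float(self.nucleus_mask.sum()) * self.voxel_volume

    @property
    def nucleus_mass(self) -> float:
        """Water-equivalent nucleus mass, kg (1000 kg/m³)."""
        return self.nucleus_volume * WATER_DENSITY_KG_PER_UM3

    def voxel_centers(self, mask: np.ndarray) -> np.ndarray:
        """World coordinates (n, 3) of the centers of True voxels."""
        idx = np.argwhere(mask)
        return np.asarray(self.origin) + idx * np.asarray(self.voxel_size)


@dataclass
class Population:
    """A set of cells with per-cell selection-bias weights c_j."""

    cells: list[CellGeometry]
    bias_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bias_weights is None:
            self.bias_weights = np.ones(len(self.cells))
        self.bias_weights = np.asarray(self.bias_weights, dtype=float)
        if len(self.bias_weights) != len(self.cells):
            raise ValueError("one bias weight per cell required")
        if np.any(self.bias_weights < 0) or (
            len(self.cells) > 0 and self.bias_weights.sum() <= 0
        ):
            raise ValueError("bias weights must be nonnegative with positive sum")

    @property
    def positions(self) -> np.ndarray:
        return np.array([c.position for c in self.cells], dtype=float)


# ---------------------------------------------------------------------------
# cell positions: Thomas cluster process
# ---------------------------------------------------------------------------

def sample_cell_positions(
    layout: WellLayout,
    parent_intensity: float,
    mean_offspring: float,
    sigma: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample clustered cell positions from a Thomas process.

    Parents are a homogeneous Poisson process with intensity
    ``parent_intensity`` (per µm²); each parent spawns Poisson(``mean_offspring``)
    daughters displaced by an isotropic Gaussian with scale ``sigma`` (µm).
    Daughters falling outside the well are wrapped back in torus fashion so
    the realized intensity stays homogeneous.

    Returns an (n, 2) array of (x, y) positions in µm.
    """
    if parent_intensity < 0 or mean_offspring < 0:
        raise ValueError("intensities must be nonnegative")
    if sigma <= 0:
        raise ValueError("offspring spread sigma must be positive")
    rng = np.random.default_rng(rng)
    area = layout.width * layout.height
    n_parents = rng.poisson(parent_intensity * area)
    if n_parents == 0:
        return np.empty((0, 2))
    parents = rng.uniform([0, 0], [layout.width, layout.height], size=(n_parents, 2))
    counts = rng.poisson(mean_offspring, size=n_parents)
    centers = np.repeat(parents, counts, axis=0)
    pts = centers + rng.normal(0.0, sigma, size=centers.shape)
    pts[:, 0] %= layout.width
    pts[:, 1] %= layout.height
    return pts


# ---------------------------------------------------------------------------
# single-cell geometry
# ---------------------------------------------------------------------------

#: volume (µm³) of a sphere with 10 µm diameter — the calibration point for
#: the median nucleus volume
SPHERE_10UM_VOLUME: float = 4.0 / 3.0 * np.pi * 5.0**3


@dataclass(frozen=True)
class ShapeParams:
    """Parametric shape family: flattened half-ellipsoid cell, ellipsoidal nucleus."""

    cell_diameter_mean: float = 18.0     # lateral diameter, µm
    cell_diameter_cv: float = 0.15
    cell_height_ratio: float = 0.85      # height / lateral radius
    nucleus_volume_median: float = SPHERE_10UM_VOLUME  # µm³
    nucleus_volume_cv: float = 0.3       # log-scale dispersion
    nucleus_flattening: float = 0.6      # axial / lateral nucleus semi-axis


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center_vox: tuple[float, float, float],
    semi_axes_um: tuple[float, float, float],
    voxel: tuple[float, float, float],
    half: bool = False,
) -> np.ndarray:
    """Voxelize an (optionally lower-half-truncated) ellipsoid by center test."""
    ax = [(np.arange(n) - c) * v for n, c, v in zip(shape, center_vox, voxel)]
    x = ax[0][:, None, None] / semi_axes_um[0]
    y = ax[1][None, :, None] / semi_axes_um[1]
    z = ax[2][None, None, :] / semi_axes_um[2]
    mask = x * x + y * y + z * z <= 1.0
    if half:
        mask &= ax[2][None, None, :] >= -0.5 * voxel[2]
    return mask


def generate_cell_geometry(
    position: tuple[float, float],
    params: ShapeParams,
    layout: WellLayout,
    rng: np.random.Generator | int | None = None,
    with_compartments: bool = True,
    erosion_um: float = 0.2,
    expansion_um: float = 0.2,
) -> CellGeometry:
    """Generate one voxelized cell at ``position``.

    The cell body is the upper half of a flattened ellipsoid sitting on the
    well bottom (z = 0); the nucleus is a flattened ellipsoid whose volume is
    drawn log-normally with the configured median (default: the volume of a
    10 µm sphere).  If the drawn nucleus cannot fit inside the drawn cell
    body, the cell is scaled up to contain it, preserving the nucleus-volume
    distribution; an impossible configuration raises ``ValueError``.
    """
    rng = np.random.default_rng(rng)
    vx, vy, vz = layout.voxel_size

    # lateral cell radius, log-normal around the mean diameter
    sigma_c = np.sqrt(np.log1p(params.cell_diameter_cv**2))
    diam = params.cell_diameter_mean * np.exp(
        rng.normal(-0.5 * sigma_c**2, sigma_c)
    )
    a_cell = b_cell = diam / 2.0
    h_cell = params.cell_height_ratio * a_cell

    # nucleus volume: log-normal with exact median
    sigma_n = np.sqrt(np.log1p(params.nucleus_volume_cv**2))
    vol_n = params.nucleus_volume_median * np.exp(rng.normal(0.0, sigma_n))
    # V = 4/3 π a² c with c = flattening · a
    a_nuc = (3.0 * vol_n / (4.0 * np.pi * params.nucleus_flattening)) ** (1.0 / 3.0)
    c_nuc = params.nucleus_flattening * a_nuc

    # nucleus center height: rest the nucleus just above the well bottom
    z_nuc = c_nuc + vz

    # grow the cell if the nucleus does not fit (margin of one voxel)
    margin = max(vx, vy, vz)

    def fits(a_c: float, h_c: float) -> bool:
        if h_c <= z_nuc + c_nuc + margin:
            return False
        # containment at sampled heights: nucleus lateral half-width must stay
        # inside the cell's lateral half-width a_c * sqrt(1 - (z/h_c)^2)
        zs = z_nuc + c_nuc * np.linspace(-1.0, 1.0, 21)
        lat_nuc = a_nuc * np.sqrt(
            np.clip(1.0 - ((zs - z_nuc) / c_nuc) ** 2, 0.0, None)
        )
        lat_cell = a_c * np.sqrt(np.clip(1.0 - (zs / h_c) ** 2, 0.0, None))
        return bool(np.all(lat_cell >= lat_nuc + margin))

    # modest draws are accommodated by growing the cell (preserves the
    # nucleus-volume distribution); beyond a 4x linear scale the configured
    # shape family cannot plausibly host the nucleus
    scale = 1.0
    while not fits(a_cell * scale, h_cell * scale):
        scale *= 1.05
        if scale > 4.0:
            raise ValueError("nucleus larger than the admissible cell body")
    a_cell *= scale
    b_cell *= scale
    h_cell *= scale

    pad = expansion_um + margin
    nx = int(np.ceil(2 * (a_cell + pad) / vx)) + 1
    ny = int(np.ceil(2 * (b_cell + pad) / vy)) + 1
    nz = int(np.ceil((h_cell + pad) / vz)) + 2
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0

    cell_mask = _ellipsoid_mask(
        (nx, ny, nz), (cx, cy, 0.0), (a_cell, b_cell, h_cell),
        (vx, vy, vz), half=True,
    )
    nucleus_mask = _ellipsoid_mask(
        (nx, ny, nz), (cx, cy, z_nuc / vz), (a_nuc, a_nuc, c_nuc), (vx, vy, vz)
    )
    if not np.all(cell_mask[nucleus_mask]):
        # voxelization edge effects: clip the nucleus to the cell body
        nucleus_mask &= cell_mask

    origin = (position[0] - cx * vx, position[1] - cy * vy, 0.0)
    geom = CellGeometry(
        cell_mask=cell_mask,
        nucleus_mask=nucleus_mask,
        position=tuple(position),
        origin=origin,
        voxel_size=(vx, vy, vz),
    )
    if with_compartments:
        cyt, mem, degenerate = derive_compartments(
            cell_mask, (vx, vy, vz), erosion_um, expansion_um
        )
        geom.cytosol_mask, geom.membrane_mask = cyt, mem
        geom.degenerate = degenerate
    return geom


def sample_nucleus_volumes(
    n: int,
    params: ShapeParams = ShapeParams(),
    layout: WellLayout = WellLayout(),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Voxel-counted nucleus volumes (µm³) of ``n`` independently drawn cells.

    Uses the same random draws as :func:`generate_cell_geometry` but skips
    compartment derivation, which nucleus volumetry does not need.
    """
    rng = np.random.default_rng(rng)
    vols = np.empty(n)
    for i in range(n):
        g = generate_cell_geometry(
            (0.0, 0.0), params, layout, rng, with_compartments=False
        )
        vols[i] = g.nucleus_volume
    return vols


def sphere_equivalent_diameter(volume_um3) -> np.ndarray | float:
    """Diameter (µm) of the sphere with the given volume (µm³)."""
    return (6.0 * np.asarray(volume_um3, dtype=float) / np.pi) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# compartments: erosion + distance-transform expansion
# ---------------------------------------------------------------------------

def derive_compartments(
    cell_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    erosion_um: float = 0.2,
    expansion_um: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Split a cell mask into cytosol and membrane compartments.

    Cytosol: cell voxels deeper than ``erosion_um`` from the cell boundary
    (anisotropic Euclidean distance transform, so sub-voxel depths work at
    confocal resolution).  Membrane: the cell expanded outward by
    ``expansion_um`` minus the cytosol.  Returns (cytosol, membrane,
    degenerate_flag); the flag is set with a warning when erosion annihilates
    the mask.
    """
    if erosion_um < 0 or expansion_um < 0:
        raise ValueError("depths must be nonnegative")
    cell = np.asarray(cell_mask, dtype=bool)
    sampling = np.asarray(voxel_size, dtype=float)

    if erosion_um == 0:
        cytosol = cell.copy()
    else:
        inside = ndimage.distance_transform_edt(cell, sampling=sampling)
        cytosol = inside > erosion_um
    if expansion_um == 0:
        expanded = cell.copy()
    else:
        outside = ndimage.distance_transform_edt(~cell, sampling=sampling)
        expanded = cell | (outside <= expansion_um)
    membrane = expanded & ~cytosol
    if erosion_um > 0 and not membrane.any() and cell.any():
        # depths below the grid resolution: fall back to a one-voxel shell so
        # the membrane compartment never vanishes on coarse grids
        membrane = cell & ~ndimage.binary_erosion(cell)
        cytosol = cell & ~membrane

    degenerate = bool(cell.any() and not cytosol.any())
    if degenerate:
        warnings.warn(
            "erosion annihilated the cell mask; cell flagged degenerate",
            stacklevel=2,
        )
    return cytosol, membrane, degenerate


# ---------------------------------------------------------------------------
# antibody distribution over time
# ---------------------------------------------------------------------------

@dataclass
class AntibodyMap:
    """Per-compartment antibody intensity grids for one time frame.

    Grids share the cell's local voxel grid; each grid sums to the stated
    compartment count (antibodies).
    """

    membrane: np.ndarray
    cytosol: np.ndarray
    time_min: float
    origin: tuple[float, float, float]
    voxel_size: tuple[float, float, float]

    @property
    def counts(self) -> dict[str, float]:
        return {
            "membrane": float(self.membrane.sum()),
            "cytosol": float(self.cytosol.sum()),
        }


@dataclass
class EndosomeParams:
    count: int = 12
    radius_um: float = 0.5
    pooling_rate_um_per_min: float = 0.05


def simulate_antibody_distribution(
    geometry: CellGeometry,
    times_min: np.ndarray,
    membrane_counts: np.ndarray,
    internal_counts: np.ndarray,
    endosomes: EndosomeParams = EndosomeParams(),
    rng: np.random.Generator | int | None = None,
) -> list[AntibodyMap]:
    """Distribute compartment antibody counts over the cell's voxel grid.

    Membrane signal is uniform over membrane voxels.  Internalized signal is
    a set of Gaussian puncta (endosomes) seeded uniformly in the cytosol,
    whose centroids drift deterministically toward the nucleus surface at the
    pooling rate and merge pairwise when closer than one endosome radius —
    the perinuclear-pooling phase observed in live imaging.  Each frame's
    compartment sums equal the supplied counts exactly.
    """
    times_min = np.asarray(times_min, dtype=float)
    membrane_counts = np.asarray(membrane_counts, dtype=float)
    internal_counts = np.asarray(internal_counts, dtype=float)
    if np.any(membrane_counts < 0) or np.any(internal_counts < 0):
        raise ValueError("compartment counts must be nonnegative")
    if geometry.membrane_mask is None or geometry.cytosol_mask is None:
        raise ValueError("geometry needs derived compartments")
    rng = np.random.default_rng(rng)

    voxel = np.asarray(geometry.voxel_size)
    mem_idx = geometry.membrane_mask
    cyt_centers = geometry.voxel_centers(geometry.cytosol_mask)
    nuc_centers = geometry.voxel_centers(geometry.nucleus_mask)
    if len(cyt_centers) == 0:
        raise ValueError("empty cytosol compartment")
    nuc_centroid = nuc_centers.mean(axis=0) if len(nuc_centers) else cyt_centers.mean(axis=0)

    # distance to nucleus surface, sampled on the grid
    dist_out = ndimage.distance_transform_edt(
        ~geometry.nucleus_mask, sampling=voxel
    )

    def surface_distance(pts: np.ndarray) -> np.ndarray:
        idx = np.rint((pts - np.asarray(geometry.origin)) / voxel).astype(int)
        idx = np.clip(idx, 0, np.array(dist_out.shape) - 1)
        return dist_out[idx[:, 0], idx[:, 1], idx[:, 2]]

    # seed endosomes uniformly in the cytosol
    k = min(endosomes.count, len(cyt_centers))
    pos = cyt_centers[rng.choice(len(cyt_centers), size=k, replace=False)].astype(float)
    weights = np.ones(k)

    frames: list[AntibodyMap] = []
    prev_t = times_min[0]
    for t, m_count, i_count in zip(times_min, membrane_counts, internal_counts):
        dt = max(t - prev_t, 0.0)
        prev_t = t
        if dt > 0 and len(pos) > 0:
            # drift toward the nucleus centroid, capped at distance-to-surface
            d_surf = surface_distance(pos)
            vec = nuc_centroid - pos
            norm = np.linalg.norm(vec, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            step = np.minimum(endosomes.pooling_rate_um_per_min * dt, d_surf)
            pos = pos + vec / norm * step[:, None]
            # pairwise merge when closer than one radius
            pos, weights = _merge_puncta(pos, weights, endosomes.radius_um)

        mem_grid = np.zeros(geometry.cell_mask.shape, dtype=np.float32)
        if m_count > 0:
            n_mem = int(mem_idx.sum())
            if n_mem == 0:
                raise ValueError("membrane count supplied but membrane mask empty")
            mem_grid[mem_idx] = m_count / n_mem

        cyt_grid = np.zeros_like(mem_grid)
        if i_count > 0:
            dens = _rasterize_puncta(
                pos, weights, geometry, endosomes.radius_um
            )
            total = dens.sum()
            if total <= 0:
                raise ValueError("internalized count supplied but puncta empty")
            cyt_grid = (dens / total * i_count).astype(np.float32)

        frames.append(
            AntibodyMap(
                membrane=mem_grid,
                cytosol=cyt_grid,
                time_min=float(t),
                origin=geometry.origin,
                voxel_size=geometry.voxel_size,
            )
        )
    return frames


def _merge_puncta(
    pos: np.ndarray, weights: np.ndarray, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy pairwise merge of puncta closer than one radius."""
    merged = True
    while merged and len(pos) > 1:
        merged = False
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] < radius:
            w = weights[i] + weights[j]
            pos[i] = (weights[i] * pos[i] + weights[j] * pos[j]) / w
            weights[i] = w
            keep = np.ones(len(pos), dtype=bool)
            keep[j] = False
            pos, weights = pos[keep], weights[keep]
            merged = True
    return pos, weights


def _rasterize_puncta(
    pos: np.ndarray,
    weights: np.ndarray,
    geometry: CellGeometry,
    radius_um: float,
) -> np.ndarray:
    """Gaussian puncta rendered on the cell grid, clipped to the cytosol."""
    voxel = np.asarray(geometry.voxel_size)
    origin = np.asarray(geometry.origin)
    shape = geometry.cell_mask.shape
    grid = np.zeros(shape, dtype=float)
    sigma_vox = radius_um / voxel
    half = np.ceil(3 * sigma_vox).astype(int)
    for p, w in zip(pos, weights):
        c = (p - origin) / voxel
        lo = np.maximum(np.floor(c - half).astype(int), 0)
        hi = np.minimum(np.ceil(c + half).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        ax = [
            (np.arange(lo[d], hi[d]) - c[d]) / sigma_vox[d] for d in range(3)
        ]
        g = np.exp(
            -0.5
            * (
                ax[0][:, None, None] ** 2
                + ax[1][None, :, None] ** 2
                + ax[2][None, None, :] ** 2
            )
        )
        grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += w * g
    grid[~geometry.cytosol_mask] = 0.0
    if grid.sum() == 0 and len(pos) > 0:
        # all puncta rasterized outside the cytosol; fall back to nearest voxels
        cyt = geometry.voxel_centers(geometry.cytosol_mask)
        idx = np.argwhere(geometry.cytosol_mask)
        for p, w in zip(pos, weights):
            j = np.argmin(np.linalg.norm(cyt - p, axis=1))
            grid[tuple(idx[j])] += w
    return grid


# ---------------------------------------------------------------------------
# binding assay simulation
# ---------------------------------------------------------------------------

def simulate_binding_assay(
    pk_params,
    concentrations_nm: list[float],
    durations_min: list[float],
    replicates: int = 3,
    noise_cv: float = 0.05,
    doubling_time_h: float = 26.0,
    n_cells_seeded: float = 1e5,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate a saturation/kinetic binding assay from the forward PK model.

    Each (concentration, duration) condition is run through the
    pharmacokinetic model; per-cell membrane and internalized antibody counts
    get multiplicative log-normal noise with the given CV, replicated
    ``replicates`` times.  The cell number grows exponentially with the
    stated doubling time (default 26 h).

    Returns a tidy table with columns ``concentration_nM, time_min,
    replicate, compartment, antibodies_per_cell, n_cells``.
    """
    from .pk import simulate_pk  # local import to avoid a cycle

    if noise_cv < 0:
        raise ValueError("noise CV must be nonnegative")
    if len(concentrations_nm) == 0 or len(durations_min) == 0:
        raise ValueError("need at least one concentration and one duration")
    rng = np.random.default_rng(rng)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    rows = []
    t_grid = np.unique(np.concatenate([[0.0], np.asarray(durations_min, float)]))
    for c in concentrations_nm:
        p = pk_params.with_concentration(c)
        tc = simulate_pk(p, t_grid)
        for t in durations_min:
            i_t = int(np.searchsorted(t_grid, t))
            n_cells = n_cells_seeded * 2.0 ** (t / 60.0 / doubling_time_h)
            for compartment, value in (
                ("membrane", tc.membrane[i_t]),
                ("internalized", tc.internalized[i_t]),
            ):
                for r in range(replicates):
                    noisy = value
                    if sigma > 0:
                        noisy = value * np.exp(rng.normal(-0.5 * sigma**2, sigma))
                    rows.append(
                        (c, t, r, compartment, noisy, n_cells)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "concentration_nM",
            "time_min",
            "replicate",
            "compartment",
            "antibodies_per_cell",
            "n_cells",
        ],
    )


# ---------------------------------------------------------------------------
# photobleaching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhotobleachModel:
    """Normalized double-exponential bleach factor vs. laser passes.

    factor(n) = a·e^(−p1·n) + (1−a)·e^(−p2·n);  factor(0) = 1.
    """

    a: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("mixing fraction a must be in [0, 1]")
        if self.p1 < 0 or self.p2 < 0:
            raise ValueError("decay rates must be nonnegative")

    def factor(self, passes) -> np.ndarray:
        n = np.asarray(passes, dtype=float)
        if np.any(n < 0):
            raise ValueError("passes must be nonnegative")
        return self.a * np.exp(-self.p1 * n) + (1 - self.a) * np.exp(-self.p2 * n)


def apply_photobleaching(
    signal: np.ndarray, passes: np.ndarray, model: PhotobleachModel
) -> np.ndarray:
    """Attenuate per-frame signal by the bleach factor at each pass count."""
    return np.asarray(signal, dtype=float) * model.factor(passes)


def correct_photobleaching(
    signal: np.ndarray,
    passes: np.ndarray,
    model: PhotobleachModel,
    floor: float = 1e-3,
) -> np.ndarray:
    """Divide measured signal by the bleach factor; clip factors below ``floor``."""
    f = model.factor(passes)
    if np.any(f < floor):
        warnings.warn(
            "bleach factor below correction floor; correction clipped",
            stacklevel=2,
        )
        f = np.maximum(f, floor)
    return np.asarray(signal, dtype=float) / f


def fit_photobleach(
    passes: np.ndarray, bleached: np.ndarray
) -> PhotobleachModel:
    """Fit the double-exponential bleach model to a fixed-cell decay series.

    The series is normalized to its pass-0 value before fitting.
    """
    passes = np.asarray(passes, dtype=float)
    y = np.asarray(bleached, dtype=float)
    if passes.shape != y.shape or passes.size < 3:
        raise ValueError("need matching series with >= 3 points")
    y = y / y[np.argmin(passes)]

    def residuals(theta):
        a = 1.0 / (1.0 + np.exp(-theta[0]))  # logistic keeps a in (0, 1)
        p1, p2 = np.exp(theta[1]), np.exp(theta[2])
        return a * np.exp(-p1 * passes) + (1 - a) * np.exp(-p2 * passes) - y

    # data-driven starts: overall log-linear slope, and the tail slope as a
    # slow-component estimate
    pos = y > 0
    p_all = max(
        -np.polyfit(passes[pos], np.log(y[pos]), 1)[0], 1e-6
    )
    tail = passes >= np.quantile(passes, 0.5)
    tail &= pos
    p_slow = max(-np.polyfit(passes[tail], np.log(y[tail]), 1)[0], 1e-8)
    starts = [
        [0.0, np.log(p_all * 4), np.log(p_slow)],
        [1.5, np.log(p_all), np.log(p_slow)],
        [4.0, np.log(p_all), np.log(max(p_all / 10, 1e-8))],  # ~single exp
        [-1.5, np.log(p_all * 10), np.log(p_slow)],
    ]
    best = None
    with np.errstate(over="ignore", invalid="ignore"):
        for x0 in starts:
            res = optimize.least_squares(
                residuals, x0=x0, method="lm", max_nfev=5000
            )
            if best is None or res.cost < best.cost:
                best = res
    a = 1.0 / (1.0 + np.exp(-best.x[0]))
    p1, p2 = np.exp(best.x[1]), np.exp(best.x[2])
    if p1 < p2:  # canonical order: p1 is the fast component
        a, p1, p2 = 1 - a, p2, p1
    # the single-exponential boundary (a = 1) is outside the open logistic
    # parametrization; test it explicitly so the nested model never loses
    res_single = optimize.least_squares(
        lambda q: np.exp(-np.exp(q[0]) * passes) - y,
        x0=[np.log(p_all)],
        method="lm",
        max_nfev=2000,
    )
    if res_single.cost < best.cost:
        return PhotobleachModel(
            a=1.0, p1=float(np.exp(res_single.x[0])), p2=0.0
        )
    return PhotobleachModel(a=float(a), p1=float(p1), p2=float(p2))


# ---------------------------------------------------------------------------
# whole-population convenience
# ---------------------------------------------------------------------------

def generate_population(
    layout: WellLayout,
    n_cells: int | None = None,
    shape_params: ShapeParams = ShapeParams(),
    parent_intensity: float = 2e-4,
    mean_offspring: float = 8.0,
    cluster_sigma: float = 12.0,
    min_spacing_um: float = 9.0,
    rng: np.random.Generator | int | None = None,
    with_compartments: bool = True,
) -> Population:
    """Sample a clustered population and voxelize every cell.

    Positions come from the Thomas process; points closer than
    ``min_spacing_um`` to an accepted point are thinned so cell bodies do not
    fully overlap.  ``n_cells`` truncates (or errors on under-production)."""
    rng = np.random.default_rng(rng)
    pts = sample_cell_positions(
        layout, parent_intensity, mean_offspring, cluster_sigma, rng
    )
    kept: list[np.ndarray] = []
    for p in pts:
        if all(np.linalg.norm(p - q) >= min_spacing_um for q in kept):
            kept.append(p)
    if n_cells is not None:
        if len(kept) < n_cells:
            raise ValueError(
                f"cluster process produced {len(kept)} cells < requested {n_cells}; "
                "raise the intensities"
            )
        kept = kept[:n_cells]
    cells = [
        generate_cell_geometry(
            tuple(p), shape_params, layout, rng, with_compartments=with_compartments
        )
        for p in kept
    ]
    return Population(cells=cells)
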