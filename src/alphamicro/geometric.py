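"""Reference geometric model: identical concentric-sphere cells on a hex grid.

The classical idealization used by cellular S-value dosimetry (e.g.,
MIRDcell-style models): every cell is two concentric spheres (18 µm cell,
10 µm nucleus by default), placed on a hexagonal lattice whose pitch is
maximized for the given cell count and well so the cells are spread as far
apart as possible, with uniform activity in each compartment.  Running this
population through the same transport/microdosimetry/survival stack isolates
what realistic geometry, clustering and trafficking change relative to the
idealization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import (
    AntibodyMap,
    CellGeometry,
    Population,
    WellLayout,
    _ellipsoid_mask,
)


@dataclass(frozen=True)
class GeometricModelSpec:
    cell_diameter: float = 18.0   # µm
    nucleus_diameter: float = 10.0
    cell_count: int = 16
    well: WellLayout = WellLayout()

    def __post_init__(self) -> None:
        if self.nucleus_diameter >= self.cell_diameter:
            raise ValueError("nucleus must be smaller than the cell")
        if self.cell_count < 1:
            raise ValueError("need at least one cell")


def _hex_lattice(pitch: float, width: float, height: float) -> np.ndarray:
    """Hexagonal lattice points inside [0, width] × [0, height]."""
    row_h = pitch * np.sqrt(3.0) / 2.0
    pts = []
    j = 0
    y = 0.0
    while y <= height + 1e-9:
        x0 = 0.0 if j % 2 == 0 else pitch / 2.0
        x = x0
        while x <= width + 1e-9:
            pts.append((x, y))
            x += pitch
        j += 1
        y = j * row_h
    return np.asarray(pts) if pts else np.empty((0, 2))


def hexagonal_pitch(spec: GeometricModelSpec) -> float:
    """Largest lattice pitch that still fits ``cell_count`` cells in the well.

    Found by bisection on the lattice capacity; errors when even the minimum
    admissible pitch (one cell diameter, no overlap) cannot host the count.
    """
    margin = spec.cell_diameter / 2.0
    w = spec.well.width - 2 * margin
    h = spec.well.height - 2 * margin
    if w < 0 or h < 0:
        raise ValueError("well smaller than one cell")

    def capacity(p: float) -> int:
        return len(_hex_lattice(p, w, h))

    p_min = spec.cell_diameter
    if capacity(p_min) < spec.cell_count:
        raise ValueError(
            f"cannot place {spec.cell_count} cells at minimum spacing "
            f"{p_min:g} µm in a {spec.well.width:g}×{spec.well.height:g} µm well"
        )
    p_lo, p_hi = p_min, float(max(spec.well.width, spec.well.height))
    for _ in range(60):
        mid = 0.5 * (p_lo + p_hi)
        if capacity(mid) >= spec.cell_count:
            p_lo = mid
        else:
            p_hi = mid
    return p_lo


def build_hexagonal_population(
    spec: GeometricModelSpec, pitch: float | None = None
) -> Population:
    """Voxelize identical concentric-sphere cells on the maximal hex lattice.

    The membrane compartment is a one-voxel-thick shell at the outer radius;
    the cytosol is the cell interior minus nucleus and membrane.
    """
    if pitch is None:
        pitch = hexagonal_pitch(spec)
    margin = spec.cell_diameter / 2.0
    lattice = _hex_lattice(
        pitch, spec.well.width - 2 * margin, spec.well.height - 2 * margin
    ) + margin
    if len(lattice) < spec.cell_count:
        raise ValueError("pitch too large for requested cell count")
    # prefer central sites so truncation stays symmetric
    center = lattice.mean(axis=0)
    order = np.argsort(np.linalg.norm(lattice - center, axis=1), kind="stable")
    lattice = lattice[order[: spec.cell_count]]

    vx, vy, vz = spec.well.voxel_size
    r_cell = spec.cell_diameter / 2.0
    r_nuc = spec.nucleus_diameter / 2.0
    nx = int(np.ceil(2 * (r_cell + vx) / vx)) + 1
    ny = int(np.ceil(2 * (r_cell + vy) / vy)) + 1
    nz = int(np.ceil(2 * (r_cell + vz) / vz)) + 1
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0

    cell_mask = _ellipsoid_mask(
        (nx, ny, nz), (cx, cy, cz), (r_cell,) * 3, (vx, vy, vz)
    )
    nucleus_mask = _ellipsoid_mask(
        (nx, ny, nz), (cx, cy, cz), (r_nuc,) * 3, (vx, vy, vz)
    )
    inner = _ellipsoid_mask(
        (nx, ny, nz),
        (cx, cy, cz),
        (r_cell - vx, r_cell - vy, r_cell - vz),
        (vx, vy, vz),
    )
    membrane_mask = cell_mask & ~inner
    cytosol_mask = cell_mask & ~membrane_mask & ~nucleus_mask

    cells = []
    for x, y in lattice:
        origin = (x - cx * vx, y - cy * vy, 0.0)
        cells.append(
            CellGeometry(
                cell_mask=cell_mask,
                nucleus_mask=nucleus_mask,
                cytosol_mask=cytosol_mask,
                membrane_mask=membrane_mask,
                position=(float(x), float(y)),
                origin=origin,
                voxel_size=(vx, vy, vz),
            )
        )
    return Population(cells=cells)


def uniform_compartment_activity(
    population: Population,
    compartment: str,
    total_activity: float,
    time_min: float = 0.0,
) -> dict[int, AntibodyMap]:
    """Uniform activity in one compartment of every cell.

    ``total_activity`` (antibodies or decays) is split equally across cells
    and spread with equal per-voxel intensity over each cell's compartment.
    """
    if total_activity < 0:
        raise ValueError("activity must be nonnegative")
    per_cell = total_activity / len(population.cells)
    maps: dict[int, AntibodyMap] = {}
    for i, geom in enumerate(population.cells):
        if compartment == "membrane":
            mask = geom.membrane_mask
        elif compartment == "cytosol":
            mask = geom.cytosol_mask
        else:
            raise ValueError("compartment must be 'membrane' or 'cytosol'")
        if mask is None or not mask.any():
            raise ValueError(f"cell {i} has an empty {compartment} compartment")
        grid = np.zeros(geom.cell_mask.shape, dtype=np.float32)
        grid[mask] = per_cell / mask.sum()
        zero = np.zeros_like(grid)
        maps[i] = AntibodyMap(
            membrane=grid if compartment == "membrane" else zero,
            cytosol=grid if compartment == "cytosol" else zero,
            time_min=time_min,
            origin=geom.origin,
            voxel_size=geom.voxel_size,
        )
    return maps


def comparison_report(
    geometric_summary: dict[str, float], realistic_summary: dict[str, float]
) -> pd.DataFrame:
    """Side-by-side per-compartment mean-dose table (no direction asserted)."""
    comps = sorted(set(geometric_summary) | set(realistic_summary))
    return pd.DataFrame(
        {
            "compartment": comps,
            "geometric_mean_dose_Gy": [geometric_summary.get(c) for c in comps],
            "realistic_mean_dose_Gy": [realistic_summary.get(c) for c in comps],
        }
    )
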