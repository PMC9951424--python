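"""File I/O: NRRD activity maps, STL nucleus surfaces, TIFF masks, CSV tables.

NRRD files are written with ASCII encoding and the spatial metadata
(``space directions``, ``space origin``) that downstream transport codes use
to place voxels in world coordinates.  Nucleus surfaces are extracted by
marching cubes and written as non-binary (ASCII) STL.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import trimesh
from skimage import measure

from .population import AntibodyMap, CellGeometry

_NRRD_TYPES = {
    "float": np.float32,
    "double": np.float64,
    "int": np.int32,
    "uint8": np.uint8,
}


def write_nrrd(
    path: str | Path,
    array: np.ndarray,
    voxel_size: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> None:
    """Write a 3-D array as an ASCII-encoded NRRD with spatial metadata."""
    arr = np.asarray(array)
    if arr.ndim != 3:
        raise ValueError("NRRD writer expects a 3-D array")
    dtype = "double" if arr.dtype == np.float64 else "float"
    if np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool:
        arr = arr.astype(np.uint8)
        dtype = "uint8"
    vx, vy, vz = voxel_size
    header = [
        "NRRD0004",
        f"type: {dtype}",
        "dimension: 3",
        "space: left-posterior-superior",
        f"sizes: {arr.shape[0]} {arr.shape[1]} {arr.shape[2]}",
        f"space directions: ({vx},0,0) (0,{vy},0) (0,0,{vz})",
        "kinds: domain domain domain",
        "encoding: ascii",
        f"space origin: ({origin[0]},{origin[1]},{origin[2]})",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n\n")
        # NRRD stores the fastest axis first; C-order ravel matches axis 2 fastest
        flat = arr.ravel(order="C")
        for start in range(0, flat.size, 16):
            fh.write(" ".join(repr(v) for v in flat[start:start + 16].tolist()))
            fh.write("\n")


def read_nrrd(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ASCII NRRD written by :func:`write_nrrd`.

    Returns (array, header) with ``voxel_size`` and ``origin`` parsed into
    the header dict.
    """
    header: dict = {}
    values: list[str] = []
    with open(path) as fh:
        magic = fh.readline().strip()
        if not magic.startswith("NRRD"):
            raise ValueError("not an NRRD file")
        for line in fh:
            line = line.strip()
            if not line:
                break
            if ":" in line:
                key, val = line.split(":", 1)
                header[key.strip()] = val.strip()
        for line in fh:
            values.extend(line.split())
    if header.get("encoding") != "ascii":
        raise ValueError("only ascii-encoded NRRD is supported")
    shape = tuple(int(s) for s in header["sizes"].split())
    dtype = _NRRD_TYPES[header.get("type", "float")]
    arr = np.array(values, dtype=dtype).reshape(shape, order="C")
    dirs = header.get("space directions", "")
    triples = [
        [float(x) for x in t.strip("()").split(",")]
        for t in dirs.split(") (")
    ] if dirs else []
    if triples:
        header["voxel_size"] = tuple(triples[i][i] for i in range(3))
    if "space origin" in header:
        header["origin"] = tuple(
            float(x) for x in header["space origin"].strip("()").split(",")
        )
    return arr, header


def write_antibody_map(path_prefix: str | Path, amap: AntibodyMap) -> list[Path]:
    """Write one NRRD per compartment; returns the paths written."""
    prefix = Path(path_prefix)
    out = []
    for name, grid in (("membrane", amap.membrane), ("cytosol", amap.cytosol)):
        p = prefix.with_name(f"{prefix.name}_{name}.nrrd")
        write_nrrd(p, grid, amap.voxel_size, amap.origin)
        out.append(p)
    return out


def write_mask_tiff(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as a multi-page TIFF (one page per z-slice)."""
    pages = np.moveaxis(np.asarray(mask, dtype=np.uint8), 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")


def nucleus_mesh(geom: CellGeometry) -> trimesh.Trimesh:
    """Marching-cubes surface of the nucleus mask in world coordinates."""
    mask = np.pad(geom.nucleus_mask, 1)
    verts, faces, _, _ = measure.marching_cubes(
        mask.astype(np.float32), level=0.5, spacing=geom.voxel_size
    )
    verts = verts - np.asarray(geom.voxel_size) + np.asarray(geom.origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:  # marching-cubes winding is implementation-defined
        mesh.invert()
    return mesh


def write_nucleus_stl(path: str | Path, geom: CellGeometry) -> None:
    """Write the nucleus surface as non-binary (ASCII) STL."""
    mesh = nucleus_mesh(geom)
    with open(path, "wb") as fh:
        fh.write(trimesh.exchange.stl.export_stl_ascii(mesh).encode())
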