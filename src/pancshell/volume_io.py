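"""Image-volume, mesh and table I/O; owner of the unit and axis conventions.

All arrays are stored in ``(z, y, x)`` order with a per-axis physical
spacing in µm.  Every coordinate, length, area or volume that crosses the
public API is expressed in µm (µm², µm³); voxel indices never leak out.
Voxel centers sit at ``index * spacing`` (0-based), so the point (0,0,0) µm
is the center of voxel ``[0,0,0]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import trimesh

__all__ = [
    "VoxelGrid",
    "MultiChannelVolume",
    "SurfaceMesh",
    "read_volume",
    "write_volume",
    "export_mesh",
    "write_table",
]


@dataclass
class VoxelGrid:
    """One scalar 3D channel with anisotropic voxel spacing.

    Parameters
    ----------
    data:
        3D array in ``(z, y, x)`` order.
    spacing:
        ``(dz, dy, dx)`` voxel size in µm; all components positive.
    channel_name:
        Human-readable channel label (marker name).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VoxelGrid data must be 3D, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"VoxelGrid dimensions must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats (dz,dy,dx), got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size ``(Lz, Ly, Lx)`` in µm, counting whole voxels."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))  # type: ignore[return-value]

    def like(self, data: np.ndarray, channel_name: str | None = None) -> "VoxelGrid":
        """A new grid sharing this grid's geometry."""
        return VoxelGrid(data, self.spacing, channel_name if channel_name is not None else self.channel_name)

    def position_to_index(self, positions_xyz: np.ndarray) -> np.ndarray:
        """µm ``(x, y, z)`` positions -> nearest voxel ``(z, y, x)`` indices, clipped to bounds."""
        pos = np.atleast_2d(np.asarray(positions_xyz, dtype=float))
        zyx = pos[:, ::-1] / np.asarray(self.spacing)
        idx = np.rint(zyx).astype(int)
        return np.clip(idx, 0, np.asarray(self.shape) - 1)

    def sample_nearest(self, positions_xyz: np.ndarray) -> np.ndarray:
        """Value at the nearest voxel center for each µm (x,y,z) position."""
        idx = self.position_to_index(positions_xyz)
        return self.data[idx[:, 0], idx[:, 1], idx[:, 2]]

    def sample_linear(self, positions_xyz: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated value at µm (x,y,z) positions."""
        from scipy.ndimage import map_coordinates

        pos = np.atleast_2d(np.asarray(positions_xyz, dtype=float))
        coords = (pos[:, ::-1] / np.asarray(self.spacing)).T
        data = np.asarray(self.data, dtype=np.float64 if self.data.dtype.kind != "f" else self.data.dtype)
        return map_coordinates(data, coords, order=1, mode="nearest")


@dataclass
class MultiChannelVolume:
    """A named collection of congruent :class:`VoxelGrid` channels."""

    channels: dict[str, VoxelGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.channels.values())
        if not grids:
            return
        ref = grids[0]
        for g in grids[1:]:
            if g.shape != ref.shape or g.spacing != ref.spacing:
                raise ValueError(
                    "all channels must share shape and spacing; "
                    f"got {g.shape}/{g.spacing} vs {ref.shape}/{ref.spacing}"
                )

    @property
    def spacing(self) -> tuple[float, float, float]:
        return next(iter(self.channels.values())).spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> VoxelGrid:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels


@dataclass
class SurfaceMesh:
    """Triangle mesh in µm coordinates, vertices as ``(x, y, z)`` rows."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face indices exceed vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def area(self) -> float:
        """Total surface area in µm²."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.linalg.norm(np.cross(b - a, c - a), axis=1).sum() / 2.0)

    def enclosed_volume(self) -> float:
        """Signed volume magnitude via the divergence theorem, in µm³."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0))


# ---------------------------------------------------------------------------
# TIFF / OME-TIFF


def _spacing_from_ome(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    meta = tf.ome_metadata
    if not meta:
        return None
    # PhysicalSize attributes of the first Pixels element
    m = {}
    for axis in ("X", "Y", "Z"):
        hit = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', meta)
        if hit:
            m[axis] = float(hit.group(1))
    if {"X", "Y"} <= set(m):
        return (m.get("Z", m["Y"]), m["Y"], m["X"])
    return None


def read_volume(path, spacing: Sequence[float] | None = None) -> MultiChannelVolume:
    """Read a TIFF/OME-TIFF stack as a :class:`MultiChannelVolume`.

    The stack may be 3D ``(z,y,x)``, 4D ``(c,z,y,x)`` or ``(z,c,y,x)``
    (disambiguated by OME/ImageJ axis metadata when present; otherwise the
    smaller leading axis is taken as channels when <= 8).  Spacing is read
    from OME ``PhysicalSize*`` metadata; if absent, the ``spacing`` argument
    ``(dz, dy, dx)`` in µm is mandatory.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            axes = tf.series[0].axes if tf.series else ""
            meta_spacing = _spacing_from_ome(tf)
            names: list[str] | None = None
            if tf.ome_metadata:
                names = re.findall(r'<Channel[^>]*Name="([^"]+)"', tf.ome_metadata) or None
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"{path} is not a readable TIFF volume: {exc}") from exc

    if spacing is not None:
        use_spacing = tuple(float(s) for s in spacing)
    elif meta_spacing is not None:
        use_spacing = meta_spacing
    else:
        raise ValueError(
            f"{path}: no physical pixel size in metadata; pass spacing=(dz, dy, dx) in µm"
        )

    if data.ndim == 2:
        data = data[None]
    if data.ndim == 3:
        stacks = [data]
    elif data.ndim in (4, 5):
        data = data.reshape((-1,) + data.shape[-3:]) if data.ndim == 5 else data
        if axes[:2] in ("CZ", "SZ") or (axes and axes[0] == "C"):
            stacks = [data[i] for i in range(data.shape[0])]
        elif axes and "ZC" in axes.replace("S", "C"):
            stacks = [data[:, i] for i in range(data.shape[1])]
        elif data.shape[0] <= 8:
            stacks = [data[i] for i in range(data.shape[0])]
        else:
            stacks = [data[:, i] for i in range(data.shape[1])]
    else:
        raise ValueError(f"{path}: expected 2-5 dimensional stack, got ndim={data.ndim}")

    if names is None or len(names) != len(stacks):
        names = [f"ch{i}" for i in range(len(stacks))]
    channels = {n: VoxelGrid(s, use_spacing, n) for n, s in zip(names, stacks)}
    return MultiChannelVolume(channels)


def write_volume(volume: MultiChannelVolume, path) -> Path:
    """Write a multi-channel volume as OME-TIFF with µm pixel sizes.

    Round trip through :func:`read_volume` reproduces data bit-exactly and
    spacing to 6 decimals.
    """
    path = Path(path)
    dz, dy, dx = volume.spacing
    names = volume.channel_names
    stack = np.stack([volume[n].data for n in names], axis=0)  # (c, z, y, x)
    tifffile.imwrite(
        path,
        stack,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeY": dy,
            "PhysicalSizeZ": dz,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": names},
        },
    )
    return path


# ---------------------------------------------------------------------------
# Meshes and tables


def export_mesh(mesh: SurfaceMesh, path, fmt: str | None = None) -> Path:
    """Export a surface mesh as OBJ or PLY (ASCII), coordinates in µm."""
    if mesh.n_vertices == 0 or len(mesh.faces) == 0:
        raise ValueError("cannot export an empty mesh")
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("obj", "ply"):
        raise ValueError(f"unsupported mesh format {fmt!r}; use 'obj' or 'ply'")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(path, file_type=fmt, encoding="ascii") if fmt == "ply" else tm.export(path, file_type=fmt)
    return path


def load_mesh(path) -> SurfaceMesh:
    """Read back an OBJ/PLY mesh written by :func:`export_mesh`."""
    tm = trimesh.load_mesh(Path(path), process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def write_table(records: Iterable[Mapping] | pd.DataFrame, path, sort_by: str | None = None) -> Path:
    """Write records as UTF-8 CSV with header and deterministic row order.

    Rows are sorted by ``sort_by`` (default: an ``id``-like first column when
    present); numeric formatting uses the '.' decimal separator.
    """
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if len(df):
        key = sort_by
        if key is None:
            for cand in ("id", "spot_id", "segment_id", "label"):
                if cand in df.columns:
                    key = cand
                    break
        if key is not None:
            df = df.sort_values(key, kind="stable")
    df.to_csv(path, index=False, encoding="utf-8")
    return path
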