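"""Distance-shell neighborhood analysis around a reference surface.

The reference (typically the segmented epithelial bud) defines an
anisotropic Euclidean distance map over the surrounding tissue; cell
detections are binned into the first cell layer [0, 7.5) µm, a second layer
[7.5, 15) µm, and an excluded band beyond 15 µm.  Voxels inside the
reference are at distance 0 — cells engulfed between branches are in direct
contact with the epithelium, not "inside" it.  The same half-open layer
convention is used by the 2D section analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .volume_io import VoxelGrid

__all__ = [
    "FIRST_LAYER_UM",
    "MAX_DISTANCE_UM",
    "ShellRegion",
    "CompositionSummary",
    "distance_map",
    "record_distances",
    "layer_fractions",
    "cumulative_distribution",
    "shell_region",
    "composition_in_shell",
]

#: default first-cell-layer boundary: ~ one cell layer thick
FIRST_LAYER_UM = 7.5
#: default analysis band: ~ two cell layers around the reference
MAX_DISTANCE_UM = 15.0


@dataclass
class ShellRegion:
    """Voxels with ``inner <= d < outer`` µm from the reference, reference excluded."""

    inner: float
    outer: float
    mask: VoxelGrid
    volume: float  # µm³
    reference: str = ""


@dataclass
class CompositionSummary:
    """Cell-type composition inside a distance shell."""

    counts: dict[str, int]
    percentages: dict[str, float]
    total: int
    shell: tuple[float, float]

    def __post_init__(self) -> None:
        assert self.total == sum(self.counts.values())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(self.counts),
                "count": list(self.counts.values()),
                "percentage": [self.percentages[c] for c in self.counts],
            }
        )


def distance_map(reference: VoxelGrid) -> VoxelGrid:
    """Anisotropic Euclidean distance (µm) to the reference mask; 0 inside it."""
    mask = reference.data > 0
    if not mask.any():
        raise ValueError("distance_map: reference mask is empty")
    d = ndi.distance_transform_edt(~mask, sampling=reference.spacing)
    return VoxelGrid(d, reference.spacing, f"dist_to_{reference.channel_name or 'reference'}")


def _layer_of(distance: np.ndarray, first_layer: float, max_distance: float) -> np.ndarray:
    out = np.full(distance.shape, "excluded", dtype=object)
    out[distance < max_distance] = "second"
    out[distance < first_layer] = "first"
    return out


def record_distances(
    spots,
    dmap: VoxelGrid,
    max_distance: float = MAX_DISTANCE_UM,
    first_layer: float = FIRST_LAYER_UM,
) -> pd.DataFrame:
    """Per-spot distance records with layer tags.

    ``spots`` is a :class:`~pancshell.spots.SpotSet` or a DataFrame with
    ``id``, ``x``, ``y``, ``z`` (µm) and optional ``class`` columns.  The
    distance is the map value at the spot's nearest voxel center.  Spots
    beyond 15 µm are kept but tagged ``excluded`` so that distant-shell
    analyses can reuse them.
    """
    df = spots.df if hasattr(spots, "df") else spots
    if len(df) == 0:
        return pd.DataFrame(columns=["spot_id", "class", "distance", "layer"])
    pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    extent_xyz = np.asarray(dmap.extent)[::-1]
    hi = (np.asarray(dmap.shape)[::-1] - 0.5) * np.asarray(dmap.spacing)[::-1]
    outside = (pos < -0.5 * np.asarray(dmap.spacing)[::-1]).any(axis=1) | (pos > hi).any(axis=1)
    if outside.any():
        bad = df.loc[outside, "id"].tolist() if "id" in df else np.flatnonzero(outside).tolist()
        raise ValueError(f"spots outside the volume ({extent_xyz} µm): ids {bad}")
    dist = dmap.sample_nearest(pos)
    rec = pd.DataFrame(
        {
            "spot_id": df["id"].to_numpy() if "id" in df else np.arange(len(df)),
            "class": df["class"].to_numpy() if "class" in df else "unassigned",
            "distance": dist,
            "layer": _layer_of(dist, first_layer, max_distance),
        }
    )
    return rec


def layer_fractions(records: pd.DataFrame) -> dict[str, float]:
    """First/second layer percentages among non-excluded records; sums to 100."""
    eligible = records[records["layer"] != "excluded"]
    n = len(eligible)
    if n == 0:
        raise ValueError("layer_fractions: no records within the analysis band")
    first = float((eligible["layer"] == "first").sum())
    return {"first": 100.0 * first / n, "second": 100.0 * (n - first) / n}


def cumulative_distribution(
    records: pd.DataFrame,
    grid_step: float = 0.5,
    max_distance: float = MAX_DISTANCE_UM,
) -> pd.DataFrame:
    """Right-continuous cumulative frequency curve: % of the (non-excluded)
    population at distance <= d, on a uniform grid reaching 100% at
    ``max_distance``."""
    eligible = records.loc[records["layer"] != "excluded", "distance"].to_numpy()
    if len(eligible) == 0:
        raise ValueError("cumulative_distribution: no eligible records")
    grid = np.arange(0.0, max_distance + grid_step / 2, grid_step)
    pct = 100.0 * np.searchsorted(np.sort(eligible), grid, side="right") / len(eligible)
    return pd.DataFrame({"distance": grid, "cumulative_pct": pct})


def shell_region(
    dmap: VoxelGrid,
    inner: float,
    outer: float,
    reference: VoxelGrid | None = None,
    name: str = "",
) -> ShellRegion:
    """Voxel region at ``inner <= d < outer`` µm from the reference.

    The reference mask itself (d == 0 voxels inside it) is excluded; with
    ``inner == 0`` the shell starts at the first background voxel.
    """
    if not inner < outer:
        raise ValueError(f"shell bounds must satisfy inner < outer, got [{inner}, {outer})")
    d = dmap.data
    sel = (d >= inner) & (d < outer) & (d > 0)
    if reference is not None:
        sel &= ~(reference.data > 0)
    if not sel.any():
        raise ValueError(f"shell [{inner}, {outer}) µm is empty")
    vol = float(sel.sum()) * dmap.voxel_volume
    return ShellRegion(inner=inner, outer=outer, mask=dmap.like(sel, "shell"), volume=vol, reference=name)


def composition_in_shell(
    records: pd.DataFrame,
    shell: tuple[float, float] = (0.0, MAX_DISTANCE_UM),
    classes: tuple[str, ...] = ("epithelial", "endothelial", "mesenchymal"),
) -> CompositionSummary:
    """Cell-type counts/percentages among spots with ``inner <= d < outer``.

    Epithelial spots carry distance 0 by the inside-counts-as-contact
    convention, so they are always part of the 0-15 µm shell.
    """
    inner, outer = shell
    sel = (records["distance"] >= inner) & (records["distance"] < outer)
    sub = records.loc[sel & records["class"].isin(classes)]
    total = len(sub)
    if total == 0:
        raise ValueError(f"no spots of classes {classes} in shell [{inner}, {outer}) µm")
    counts = {c: int((sub["class"] == c).sum()) for c in classes}
    pct = {c: 100.0 * counts[c] / total for c in classes}
    return CompositionSummary(counts=counts, percentages=pct, total=total, shell=(inner, outer))
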