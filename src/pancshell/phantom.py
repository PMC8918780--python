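"""Seeded synthetic phantoms of the embryonic pancreatic microenvironment.

The generator emulates the tissue geometry the analysis modules are built
for: a branched epithelial bud (a trunk with side branches, oriented along
the optical z axis), a tubular vessel network wrapping the bud on offset
surfaces, endocrine cell clusters attached to the bud, and nuclei of four
classes (epithelial, endothelial, mesenchymal, endocrine) scattered with a
prescribed radial distance distribution.  Volumes are rendered with an
anisotropic Gaussian PSF and Poisson + Gaussian noise at light-sheet-like
voxel sizes, and every random draw is fixed by a single integer seed, so the
rendered image ships with exact ground truth (masks, spot positions and
classes, true distances, true tube radii, true cluster volumes).

Distance-structured nucleus placement is done by rejection sampling against
the anisotropic Euclidean distance map of the true epithelium mask; a
candidate is only accepted if its recorded true distance falls inside the
target shell, so shell-membership ground truth is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ._raster import paint_ball, paint_capsule, paint_polyline_tube
from .volume_io import MultiChannelVolume, VoxelGrid

__all__ = [
    "EpitheliumParams",
    "VesselParams",
    "NucleiParams",
    "ClusterParams",
    "RenderParams",
    "PhantomSpec",
    "PhantomTruth",
    "make_epithelium",
    "make_vessels",
    "make_clusters",
    "place_nuclei",
    "render_volume",
    "make_phantom",
    "make_sections",
    "PLACEMENT_SHELLS",
]

#: distance shells (µm) used for distance-structured nucleus placement,
#: matching the first-layer / second-layer / distant bands of the analysis.
PLACEMENT_SHELLS: tuple[tuple[float, float], ...] = ((0.0, 7.5), (7.5, 15.0), (15.0, 50.0))

CLASSES = ("epithelial", "endothelial", "mesenchymal", "endocrine")


@dataclass
class EpitheliumParams:
    """Branched epithelial bud: a trunk along z with tilted side branches."""

    n_branches: int = 4
    branch_length: float = 140.0  # µm
    branch_radius: float = 25.0  # µm
    trunk_length: float = 260.0  # µm
    trunk_radius: float = 40.0  # µm
    #: polar angle range of branches measured from the trunk (z) axis, degrees
    branch_angle_deg: tuple[float, float] = (25.0, 50.0)


@dataclass
class VesselParams:
    """Tubes wrapped on offset surfaces around the bud plus free-space tubes."""

    n_tubes: int = 6
    radii: tuple[float, ...] = (3.0, 4.0, 5.0, 6.0, 8.0, 10.0)  # µm, cycled over tubes
    tortuosity: float = 0.35  # direction jitter per ~4 µm step, dimensionless
    clearance: float = 3.0  # µm gap kept between tube surface and epithelium
    n_free_tubes: int = 2  # additional tubes not wrapping the bud
    path_length: float = 400.0  # µm of path per wrapped tube


@dataclass
class NucleiParams:
    counts: dict[str, int] = field(
        default_factory=lambda: {"epithelial": 600, "endothelial": 150, "mesenchymal": 350, "endocrine": 0}
    )
    nuclear_radius: float = 3.0  # µm
    #: per-class mixture weights over PLACEMENT_SHELLS; classes absent here
    #: fall back to their geometric default (endothelial -> vessel walls,
    #: mesenchymal -> uniform outside the bud within 50 µm).
    shell_weights: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    #: pairwise center separation >= factor x nuclear radius; the default of
    #: 2 radii ~ one cell diameter, the packing limit of adjacent cells
    min_separation_factor: float = 2.0
    #: epithelial/endocrine nuclear centers sit at least this depth (µm)
    #: inside their tissue mask (a nucleus cannot straddle the surface)
    interior_depth: float | None = None  # default: nuclear_radius
    #: non-epithelial centers keep at least this distance (µm) from the
    #: reference surface — a touching cell's center is ~a radius away
    contact_margin: float = 1.0


@dataclass
class ClusterParams:
    """Endocrine (glucagon+) clusters attached to the epithelial surface."""

    volumes: tuple[float, ...] = ()  # target sphere volumes, µm³


@dataclass
class RenderParams:
    """Image formation: blobs/masks -> anisotropic PSF -> Poisson + Gaussian noise.

    Defaults give a peak SNR (blob peak over background noise s.d.) of ~10.
    """

    psf_sigma: tuple[float, float, float] = (2.0, 1.0, 1.0)  # µm (z, y, x)
    amplitude: float = 100.0
    background: float = 5.0
    poisson_scale: float = 2.0  # photons per intensity unit; 0 disables shot noise
    gaussian_sd: float = 9.9  # read noise s.d., intensity units; 0 disables
    #: membrane markers (Ecad) light the mask boundary at full amplitude and
    #: the interior at this fraction (unresolved intracellular membranes)
    membrane_interior_fraction: float = 0.4


@dataclass
class PhantomSpec:
    volume_shape: tuple[int, int, int] = (150, 300, 300)  # voxels (z, y, x)
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)  # µm (dz, dy, dx)
    seed: int = 0
    epithelium: EpitheliumParams = field(default_factory=EpitheliumParams)
    vessels: VesselParams = field(default_factory=VesselParams)
    nuclei: NucleiParams = field(default_factory=NucleiParams)
    clusters: ClusterParams = field(default_factory=ClusterParams)
    render: RenderParams = field(default_factory=RenderParams)

    def __post_init__(self) -> None:
        for cls, w in self.nuclei.shell_weights.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown nucleus class {cls!r}")
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"shell weights for {cls!r} must sum to 1, got {w}")
        if any(c < 0 for c in self.nuclei.counts.values()):
            raise ValueError("nucleus counts must be >= 0")

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.volume_shape, self.spacing))  # type: ignore[return-value]

    def rng(self, stage: int) -> np.random.Generator:
        """Independent deterministic stream per generation stage."""
        return np.random.default_rng([int(self.seed), stage])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhantomTruth:
    """Generator-side ground truth mirroring the analysis outputs."""

    epithelium_mask: VoxelGrid
    vessel_mask: VoxelGrid
    vessel_segments: list[tuple[np.ndarray, float]]  # (polyline xyz µm, true radius µm)
    spots: pd.DataFrame  # columns: id, x, y, z, class, true_distance
    cluster_mask: VoxelGrid | None = None
    cluster_volumes: list[float] = field(default_factory=list)
    distance_map: VoxelGrid | None = None  # EDT of the true epithelium mask


# ---------------------------------------------------------------------------
# geometry


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def make_epithelium(spec: PhantomSpec) -> VoxelGrid:
    """Rasterize a random binary tree of capsules: trunk + tilted branches.

    Deterministic for a given seed; the result is a single connected
    component because every branch originates on the trunk axis.
    """
    ep = spec.epithelium
    if ep.branch_radius < max(spec.spacing) or ep.trunk_radius < max(spec.spacing):
        raise ValueError(
            f"branch/trunk radius must be >= one voxel ({max(spec.spacing)} µm) to be resolvable"
        )
    rng = spec.rng(1)
    Lz, Ly, Lx = spec.extent
    mask = np.zeros(spec.volume_shape, dtype=bool)

    base = np.array([Lx / 2, Ly / 2, max(0.05 * Lz, spec.spacing[0])])
    tilt = rng.uniform(-0.08, 0.08, size=2)
    axis = _unit(np.array([tilt[0], tilt[1], 1.0]))
    top = base + axis * ep.trunk_length
    paint_capsule(mask, spec.spacing, base, top, ep.trunk_radius)

    for _ in range(ep.n_branches):
        t = rng.uniform(0.35, 0.9)
        origin = base + axis * (t * ep.trunk_length)
        polar = np.deg2rad(rng.uniform(*ep.branch_angle_deg))
        azim = rng.uniform(0, 2 * np.pi)
        # direction tilted from the trunk axis by `polar`
        d = np.array([np.sin(polar) * np.cos(azim), np.sin(polar) * np.sin(azim), np.cos(polar)])
        paint_capsule(mask, spec.spacing, origin, origin + d * ep.branch_length, ep.branch_radius)

    if not mask.any():
        raise ValueError("epithelium fell entirely outside the volume")
    return VoxelGrid(mask, spec.spacing, "epithelium_mask")


def _edt_outside(mask: VoxelGrid) -> VoxelGrid:
    d = ndi.distance_transform_edt(~mask.data.astype(bool), sampling=mask.spacing)
    return VoxelGrid(d, mask.spacing, "distance")


def _grad_at(dmap: VoxelGrid, q: np.ndarray) -> np.ndarray:
    """Finite-difference unit gradient of the distance map at a µm (x,y,z) point."""
    h = max(dmap.spacing)
    g = np.zeros(3)
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = h
        g[ax] = (dmap.sample_linear(q + e)[0] - dmap.sample_linear(q - e)[0]) / (2 * h)
    return _unit(g)


def _clip_interior(q: np.ndarray, extent_xyz: np.ndarray, margin: float) -> np.ndarray:
    return np.clip(q, margin, extent_xyz - margin)


def _offset_path(
    rng: np.random.Generator,
    dmap: VoxelGrid,
    target_d: float,
    n_steps: int,
    step: float,
    tortuosity: float,
) -> np.ndarray | None:
    """Random smooth path hugging the iso-distance surface ``d == target_d``."""
    band = np.argwhere(np.abs(dmap.data - target_d) < max(dmap.spacing))
    if len(band) == 0:
        return None
    extent = np.asarray(dmap.extent)[::-1]  # (Lx, Ly, Lz)
    start_zyx = band[rng.integers(len(band))]
    p = start_zyx[::-1] * np.asarray(dmap.spacing)[::-1]
    direction = _unit(rng.normal(size=3))
    pts = [p.copy()]
    for _ in range(n_steps):
        direction = _unit(direction + tortuosity * rng.normal(size=3))
        q = p + step * direction
        q = _clip_interior(q, extent, 2 * max(dmap.spacing))
        for _ in range(3):  # Newton-style projection back onto the offset surface
            d = float(dmap.sample_linear(q)[0])
            if abs(d - target_d) < 0.25:
                break
            q = _clip_interior(q + (target_d - d) * _grad_at(dmap, q), extent, 2 * max(dmap.spacing))
        direction = _unit(q - p)
        p = q
        pts.append(p.copy())
    return np.asarray(pts)


def _free_path(rng: np.random.Generator, dmap: VoxelGrid, min_d: float, n_pts: int = 40) -> np.ndarray:
    """Straightish path through free space, pushed away from the epithelium."""
    extent = np.asarray(dmap.extent)[::-1]
    margin = 2 * max(dmap.spacing)
    a = rng.uniform(margin, extent - margin)
    b = rng.uniform(margin, extent - margin)
    ts = np.linspace(0.0, 1.0, n_pts)
    pts = a[None, :] + ts[:, None] * (b - a)[None, :]
    for i, q in enumerate(pts):
        d = float(dmap.sample_linear(q)[0])
        if d < min_d:
            q = _clip_interior(q + (min_d - d) * _grad_at(dmap, q), extent, margin)
            pts[i] = q
    return pts


def make_vessels(
    spec: PhantomSpec, epithelium: VoxelGrid, dmap: VoxelGrid | None = None
) -> tuple[VoxelGrid, list[tuple[np.ndarray, float]]]:
    """Paint the vessel network and return (mask, per-tube truth).

    Wrapped tubes follow random paths on offset surfaces around the bud (at
    distance ``radius + clearance`` from the epithelial surface, so tube and
    bud never overlap); free tubes cross the remaining space.  Per-tube
    centerline polylines and true radii are recorded.
    """
    vp = spec.vessels
    rng = spec.rng(2)
    if dmap is None:
        dmap = _edt_outside(epithelium)
    mask = np.zeros(spec.volume_shape, dtype=bool)
    segments: list[tuple[np.ndarray, float]] = []

    step = 4.0
    for i in range(vp.n_tubes):
        r = float(vp.radii[i % len(vp.radii)])
        target = r + vp.clearance
        path = _offset_path(rng, dmap, target, int(vp.path_length / step), step, vp.tortuosity)
        if path is None:
            raise ValueError(
                f"no room for a wrapped tube of radius {r} µm at offset {target} µm from the epithelium"
            )
        paint_polyline_tube(mask, spec.spacing, path, r)
        segments.append((path, r))
    for i in range(vp.n_free_tubes):
        r = float(vp.radii[(vp.n_tubes + i) % len(vp.radii)])
        path = _free_path(rng, dmap, r + vp.clearance)
        paint_polyline_tube(mask, spec.spacing, path, r)
        segments.append((path, r))

    overlap = mask & epithelium.data.astype(bool)
    if overlap.any():  # clearance should prevent this; enforce the invariant anyway
        mask &= ~epithelium.data.astype(bool)
    return VoxelGrid(mask, spec.spacing, "vessel_mask"), segments


def make_clusters(
    spec: PhantomSpec, epithelium: VoxelGrid, dmap: VoxelGrid | None = None
) -> tuple[VoxelGrid | None, list[float]]:
    """Spherical endocrine clusters attached to the epithelial surface.

    Returns an integer label mask (labels 1..k by generation order) and the
    realized per-cluster voxel volumes in µm³.
    """
    vols = spec.clusters.volumes
    if not vols:
        return None, []
    rng = spec.rng(3)
    if dmap is None:
        dmap = _edt_outside(epithelium)
    labels = np.zeros(spec.volume_shape, dtype=np.int32)
    placed: list[tuple[np.ndarray, float]] = []
    realized: list[float] = []
    voxel_volume = float(np.prod(spec.spacing))
    for k, v in enumerate(vols, start=1):
        r = (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
        # center sits ~r/2 outside the surface: cluster buds off the trunk
        band = np.argwhere(np.abs(dmap.data - r / 2) < max(spec.spacing))
        if len(band) == 0:
            raise ValueError(f"no room for cluster {k} (radius {r:.1f} µm)")
        extent_xyz = np.asarray(spec.extent)[::-1]
        ok = False
        for _ in range(500):
            c = band[rng.integers(len(band))][::-1] * np.asarray(spec.spacing)[::-1]
            if (c < r).any() or (c > extent_xyz - r).any():  # keep the ball unclipped
                continue
            if all(np.linalg.norm(c - pc) > r + pr + 2 for pc, pr in placed):
                ok = True
                break
        if not ok:
            raise ValueError(f"could not place cluster {k} without merging")
        sub = np.zeros(spec.volume_shape, dtype=bool)
        paint_ball(sub, spec.spacing, c, r)
        labels[sub & (labels == 0)] = k
        placed.append((c, r))
        realized.append(float((labels == k).sum()) * voxel_volume)
    return VoxelGrid(labels, spec.spacing, "cluster_mask"), realized


# ---------------------------------------------------------------------------
# nuclei


class _SeparationIndex:
    """Spatial hash enforcing a minimum pairwise distance between accepted points."""

    def __init__(self, min_sep: float):
        self.min_sep = float(min_sep)
        self.cell = max(self.min_sep, 1e-6)
        self._grid: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def ok(self, p: np.ndarray) -> bool:
        c = tuple((p // self.cell).astype(int))
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for q in self._grid.get((c[0] + dx, c[1] + dy, c[2] + dz), ()):
                        if np.linalg.norm(p - q) < self.min_sep:
                            return False
        return True

    def add(self, p: np.ndarray) -> None:
        self._grid.setdefault(tuple((p // self.cell).astype(int)), []).append(p)


def _shell_candidate_voxels(dmap: VoxelGrid, inner: float, outer: float, forbidden: np.ndarray) -> np.ndarray:
    d = dmap.data
    sel = (d > max(inner, 1e-9)) & (d < outer) & ~forbidden
    return np.argwhere(sel)


def place_nuclei(
    spec: PhantomSpec,
    epithelium: VoxelGrid,
    vessels: VoxelGrid | None = None,
    clusters: VoxelGrid | None = None,
    dmap: VoxelGrid | None = None,
) -> pd.DataFrame:
    """Place nuclei of all classes and record exact true distances.

    Placement rules:

    * epithelial — uniform inside the epithelium mask (true distance 0, the
      inside-counts-as-contact convention);
    * endothelial / mesenchymal — if the class has shell weights, rejection
      sampling against the epithelium distance map so the recorded true
      distance lands in the drawn shell; otherwise endothelial nuclei sit on
      vessel walls and mesenchymal nuclei are uniform outside the bud within
      the outermost shell;
    * endocrine — uniform inside the cluster mask.

    All nuclei respect a global minimum center separation of
    ``min_separation_factor × nuclear_radius``.  Raises if a class count
    cannot be met after bounded retries, reporting the achievable count.
    """
    np_params = spec.nuclei
    rng = spec.rng(4)
    if dmap is None:
        dmap = _edt_outside(epithelium)
    sp = np.asarray(spec.spacing)
    epi = epithelium.data.astype(bool)
    ves = vessels.data.astype(bool) if vessels is not None else np.zeros_like(epi)
    clu = clusters.data > 0 if clusters is not None else np.zeros_like(epi)

    min_sep = np_params.min_separation_factor * np_params.nuclear_radius
    index = _SeparationIndex(min_sep)
    rows: list[dict] = []
    next_id = 0

    def _accept(p_xyz: np.ndarray, cls: str, dist: float) -> None:
        nonlocal next_id
        index.add(p_xyz)
        rows.append(
            {"id": next_id, "x": p_xyz[0], "y": p_xyz[1], "z": p_xyz[2], "class": cls, "true_distance": dist}
        )
        next_id += 1

    def _jittered(vox_zyx: np.ndarray) -> np.ndarray:
        pos_zyx = (vox_zyx + rng.uniform(-0.5, 0.5, size=3)) * sp
        return pos_zyx[::-1]

    def _fill_from_voxels(cands: np.ndarray, n: int, cls: str, shell: tuple[float, float] | None, dist0: bool):
        placed = 0
        max_tries = max(400 * n, 2000)
        tries = 0
        while placed < n and tries < max_tries:
            tries += 1
            if len(cands) == 0:
                break
            p = _jittered(cands[rng.integers(len(cands))])
            if not index.ok(p):
                continue
            if dist0:
                dist = 0.0
            else:
                dist = float(dmap.sample_linear(p)[0])
                if shell is not None and not (max(shell[0], np_params.contact_margin) <= dist < shell[1]):
                    continue
                if dist <= np_params.contact_margin and shell is None:
                    continue
            _accept(p, cls, dist)
            placed += 1
        if placed < n:
            raise ValueError(
                f"could only place {placed}/{n} {cls} nuclei at separation {min_sep:.2f} µm"
            )

    depth = np_params.interior_depth if np_params.interior_depth is not None else np_params.nuclear_radius

    def _interior_voxels(mask: np.ndarray) -> np.ndarray:
        interior_edt = ndi.distance_transform_edt(mask, sampling=spec.spacing)
        cands = np.argwhere(interior_edt >= depth)
        return cands if len(cands) else np.argwhere(mask)  # thin tissue: fall back

    # epithelial: uniform inside the bud, centers >= one nuclear radius deep
    n_epi = np_params.counts.get("epithelial", 0)
    if n_epi:
        _fill_from_voxels(_interior_voxels(epi), n_epi, "epithelial", None, dist0=True)

    # endocrine: inside clusters
    n_endo = np_params.counts.get("endocrine", 0)
    if n_endo:
        if not clu.any():
            raise ValueError("endocrine nuclei requested but no cluster mask present")
        _fill_from_voxels(_interior_voxels(clu), n_endo, "endocrine", None, dist0=True)

    forbidden = epi | ves | clu
    margin = np_params.contact_margin
    shell_voxels = {
        s: _shell_candidate_voxels(dmap, max(s[0], margin), s[1], forbidden) for s in PLACEMENT_SHELLS
    }

    for cls in ("endothelial", "mesenchymal"):
        n = np_params.counts.get(cls, 0)
        if n == 0:
            continue
        weights = np_params.shell_weights.get(cls)
        if weights is not None:
            draws = rng.choice(len(PLACEMENT_SHELLS), size=n, p=np.asarray(weights, dtype=float))
            for si in range(len(PLACEMENT_SHELLS)):
                k = int((draws == si).sum())
                if k:
                    shell = PLACEMENT_SHELLS[si]
                    _fill_from_voxels(shell_voxels[shell], k, cls, shell, dist0=False)
        elif cls == "endothelial" and ves.any():
            wall = ves & ~ndi.binary_erosion(ves)
            _fill_from_voxels(np.argwhere(wall), n, cls, None, dist0=False)
        else:
            outer = PLACEMENT_SHELLS[-1][1]
            cands = _shell_candidate_voxels(dmap, margin, outer, forbidden)
            _fill_from_voxels(cands, n, cls, None, dist0=False)

    df = pd.DataFrame(rows, columns=["id", "x", "y", "z", "class", "true_distance"])
    return df


# ---------------------------------------------------------------------------
# rendering


def _erosion_ball(spacing) -> np.ndarray:
    """One-voxel-scale anisotropic structuring element (~max spacing in µm)."""
    r = float(max(spacing))
    sp = np.asarray(spacing, dtype=float)
    half = np.maximum((r / sp).astype(int), 1)
    zz, yy, xx = np.ogrid[-half[0] : half[0] + 1, -half[1] : half[1] + 1, -half[2] : half[2] + 1]
    return (zz * sp[0]) ** 2 + (yy * sp[1]) ** 2 + (xx * sp[2]) ** 2 <= r * r


def _blob_image(
    shape, spacing, positions_xyz: np.ndarray, sigma_um: np.ndarray, amplitude: float
) -> np.ndarray:
    """Sum of isotropic-in-µm Gaussian blobs with the stated peak amplitude."""
    img = np.zeros(shape, dtype=np.float32)
    if len(positions_xyz) == 0:
        return img
    sp = np.asarray(spacing)
    sigma_vox = np.asarray(sigma_um) / sp
    idx = np.rint(np.asarray(positions_xyz, dtype=float)[:, ::-1] / sp).astype(int)
    idx = np.clip(idx, 0, np.asarray(shape) - 1)
    np.add.at(img, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    img = ndi.gaussian_filter(img, sigma=sigma_vox, output=np.float32, truncate=3.5)
    peak = float(np.prod(1.0 / (np.sqrt(2 * np.pi) * sigma_vox)))
    return img * (amplitude / peak)


def render_volume(spec: PhantomSpec, truth: PhantomTruth) -> MultiChannelVolume:
    """Render the phantom truth into noisy multi-channel fluorescence data.

    Channels: ``ecad`` (blurred epithelium mask), ``erg`` (blobs at
    endothelial nuclei), ``vecad`` (blurred vessel mask), ``draq5`` (blobs at
    all nuclei), ``gfp`` (blobs at mesenchymal nuclei) and, when clusters are
    present, ``glucagon`` (blurred cluster mask).  Each channel is blurred by
    the anisotropic PSF then degraded with Poisson shot noise and additive
    Gaussian read noise; the noiseless signal depends only on the truth, the
    noise only on the seed.
    """
    rp = spec.render
    rng = spec.rng(5)
    sp = np.asarray(spec.spacing)
    psf_vox = np.asarray(rp.psf_sigma) / sp
    shape = spec.volume_shape
    blob_sigma = spec.nuclei.nuclear_radius / 1.5  # µm; FWHM ~ nuclear diameter
    # blobs rendered with PSF folded in (Gaussians add in quadrature)
    eff_sigma = np.sqrt(blob_sigma**2 + np.asarray(rp.psf_sigma) ** 2)

    spots = truth.spots
    pos = lambda sel: spots.loc[sel, ["x", "y", "z"]].to_numpy()  # noqa: E731

    channels: dict[str, np.ndarray] = {}
    epi = truth.epithelium_mask.data.astype(bool)
    interior = ndi.binary_erosion(epi, structure=_erosion_ball(sp))
    ecad_signal = epi.astype(np.float32) * rp.membrane_interior_fraction
    ecad_signal[epi & ~interior] = 1.0  # bright membranous rim
    channels["ecad"] = ndi.gaussian_filter(ecad_signal, psf_vox, output=np.float32) * rp.amplitude
    channels["vecad"] = (
        ndi.gaussian_filter(truth.vessel_mask.data.astype(np.float32), psf_vox, output=np.float32)
        * rp.amplitude
    )
    channels["erg"] = _blob_image(shape, sp, pos(spots["class"] == "endothelial"), eff_sigma, rp.amplitude)
    channels["draq5"] = _blob_image(shape, sp, pos(slice(None)), eff_sigma, rp.amplitude)
    channels["gfp"] = _blob_image(shape, sp, pos(spots["class"] == "mesenchymal"), eff_sigma, rp.amplitude)
    if truth.cluster_mask is not None:
        channels["glucagon"] = (
            ndi.gaussian_filter((truth.cluster_mask.data > 0).astype(np.float32), psf_vox, output=np.float32)
            * rp.amplitude
        )

    out = {}
    for name, signal in channels.items():
        img = signal + rp.background
        if rp.poisson_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * rp.poisson_scale).astype(np.float32) / rp.poisson_scale
        if rp.gaussian_sd > 0:
            img = img + rng.normal(0.0, rp.gaussian_sd, size=shape).astype(np.float32)
        out[name] = VoxelGrid(img.astype(np.float32), spec.spacing, name)
    return MultiChannelVolume(out)


def make_phantom(spec: PhantomSpec) -> tuple[MultiChannelVolume, PhantomTruth]:
    """Full generation: geometry, nuclei, truth and rendered volume."""
    epi = make_epithelium(spec)
    dmap = _edt_outside(epi)
    if spec.vessels.n_tubes + spec.vessels.n_free_tubes > 0:
        ves, segs = make_vessels(spec, epi, dmap=dmap)
    else:
        ves = VoxelGrid(np.zeros(spec.volume_shape, dtype=bool), spec.spacing, "vessel_mask")
        segs = []
    clu, cvols = make_clusters(spec, epi, dmap=dmap)
    spots = place_nuclei(spec, epi, ves, clu, dmap=dmap)
    truth = PhantomTruth(
        epithelium_mask=epi,
        vessel_mask=ves,
        vessel_segments=segs,
        spots=spots,
        cluster_mask=clu,
        cluster_volumes=cvols,
        distance_map=dmap,
    )
    volume = render_volume(spec, truth)
    return volume, truth


# ---------------------------------------------------------------------------
# 2D sections


def make_sections(
    spec: PhantomSpec,
    truth: PhantomTruth,
    spacing_between_sections: float = 30.0,
) -> tuple[list, pd.DataFrame]:
    """Cut the phantom into regularly spaced axial sections with 2D truth.

    Planes sit at ``z = k × spacing`` for ``k = 0 .. floor(Lz/Δ) − 1``.  A
    nucleus appears on its nearest plane (ties to the lower plane) when the
    plane passes within half a nuclear radius of its center — emulating
    physical sectioning, where a section only samples nuclei it intersects
    near their equator.  Per-section truth records in-plane positions,
    classes and the 2D distance to the sectioned epithelium profile.
    """
    from .sections2d import SectionImage

    dz = spec.spacing[0]
    if spacing_between_sections < dz:
        raise ValueError(f"section spacing {spacing_between_sections} µm is below the z step {dz} µm")
    Lz = spec.extent[0]
    n_sections = int(np.floor(Lz / spacing_between_sections))
    if n_sections == 0:
        raise ValueError("volume shallower than one section spacing")

    rp = spec.render
    rng = spec.rng(6)
    pix = np.array([spec.spacing[1], spec.spacing[2]])
    r = spec.nuclei.nuclear_radius
    blob_sigma = r / 1.5
    eff_sigma_yx = np.sqrt(blob_sigma**2 + np.asarray(rp.psf_sigma[1:]) ** 2)

    spots = truth.spots
    zq = spots["z"].to_numpy() / spacing_between_sections
    nearest = np.floor(zq + 0.5).astype(int)
    # tie at the exact midpoint between planes -> lower plane
    nearest = np.where(np.isclose(zq + 0.5, np.rint(zq + 0.5)) & (nearest > 0), nearest - 1, nearest)
    nearest = np.clip(nearest, 0, n_sections - 1)
    plane_z = nearest * spacing_between_sections
    captured = np.abs(spots["z"].to_numpy() - plane_z) <= r / 2

    sections: list[SectionImage] = []
    truth_rows: list[dict] = []
    shape2d = spec.volume_shape[1:]
    for k in range(n_sections):
        z_um = k * spacing_between_sections
        zi = min(int(round(z_um / dz)), spec.volume_shape[0] - 1)
        epi2d = truth.epithelium_mask.data[zi].astype(bool)
        d2d = ndi.distance_transform_edt(~epi2d, sampling=pix) if epi2d.any() else np.full(shape2d, np.inf)

        sel = captured & (nearest == k)
        sub = spots.loc[sel]
        pos_yx = sub[["y", "x"]].to_numpy()

        def blobs(mask_sel: np.ndarray) -> np.ndarray:
            img = np.zeros(shape2d, dtype=np.float32)
            pts = pos_yx[mask_sel]
            if len(pts):
                idx = np.clip(
                    np.rint(pts / np.asarray(pix)).astype(int), 0, np.asarray(shape2d) - 1
                )
                np.add.at(img, (idx[:, 0], idx[:, 1]), 1.0)
            sig = eff_sigma_yx / np.asarray(pix)
            img = ndi.gaussian_filter(img, sig, output=np.float32)
            peak = float(np.prod(1.0 / (np.sqrt(2 * np.pi) * sig)))
            return img * (rp.amplitude / peak)

        cls = sub["class"].to_numpy()
        ecad2d = epi2d.astype(np.float32) * rp.membrane_interior_fraction
        rim = epi2d & ~ndi.binary_erosion(epi2d, iterations=max(1, int(round(2.0 / pix.min()))))
        ecad2d[rim] = 1.0
        chans = {
            "nuclear": blobs(np.ones(len(sub), dtype=bool)),
            "ecad": ndi.gaussian_filter(ecad2d, np.asarray(rp.psf_sigma[1:]) / pix, output=np.float32)
            * rp.amplitude,
            "erg": blobs(cls == "endothelial"),
        }
        for name, img in chans.items():
            img = img + rp.background
            if rp.poisson_scale > 0:
                img = rng.poisson(np.clip(img, 0, None) * rp.poisson_scale).astype(np.float32) / rp.poisson_scale
            if rp.gaussian_sd > 0:
                img = img + rng.normal(0.0, rp.gaussian_sd, size=shape2d).astype(np.float32)
            chans[name] = img.astype(np.float32)

        sections.append(SectionImage(channels=chans, pixel_size=tuple(pix), z_position=z_um))

        iy = np.clip(np.rint(sub["y"].to_numpy() / pix[0]).astype(int), 0, shape2d[0] - 1)
        ix = np.clip(np.rint(sub["x"].to_numpy() / pix[1]).astype(int), 0, shape2d[1] - 1)
        inside = epi2d[iy, ix]
        dist2d = np.where(inside, 0.0, d2d[iy, ix])
        for (_, row), dv in zip(sub.iterrows(), dist2d):
            truth_rows.append(
                {
                    "section": k,
                    "z_plane": z_um,
                    "id": int(row["id"]),
                    "x": row["x"],
                    "y": row["y"],
                    "class": row["class"],
                    "distance_2d": float(dv) if np.isfinite(dv) else np.nan,
                }
            )

    truth2d = pd.DataFrame(
        truth_rows, columns=["section", "z_plane", "id", "x", "y", "class", "distance_2d"]
    )
    return sections, truth2d
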