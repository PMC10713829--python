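"""Trajectory-ensemble statistics: frame subsampling, replicate-averaged
RMSF, dihedral order parameters, two-stage single-linkage clustering, and
water-occupancy grids.

Frames are consumed as multi-model PDB ensembles with shared topology;
trajectory-format conversion is the caller's concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .structio.dihedrals import DihedralSeries
from .structio.model import AtomSelection, Ensemble, StructureModel
from .structio.superpose import FluctProfile, kabsch, per_atom_rmsf, rmsd

__all__ = [
    "FrameEnsemble", "OrderParameter", "ClusterAssignment", "OccupancyGrid",
    "subsample_frames", "subsample_indices", "averaged_rmsf", "dihedral_s2",
    "backbone_cluster", "sidechain_subcluster", "water_occupancy",
    "write_opendx",
]

WATER_RES_NAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC"})


@dataclass
class FrameEnsemble:
    """Shared-topology frames tagged with a replicate id each."""

    frames: Ensemble
    replicate_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames.shared_topology:
            self.frames = Ensemble(self.frames.models, shared_topology=True)
        if not self.replicate_ids:
            self.replicate_ids = ["rep1"] * len(self.frames)
        if len(self.replicate_ids) != len(self.frames):
            raise ValueError("replicate_ids must align with frames")

    def __len__(self) -> int:
        return len(self.frames)

    def replicate(self, rep_id: str) -> "FrameEnsemble":
        keep = [i for i, r in enumerate(self.replicate_ids) if r == rep_id]
        return FrameEnsemble(
            frames=Ensemble([self.frames[i] for i in keep],
                            shared_topology=True),
            replicate_ids=[rep_id] * len(keep),
        )

    @property
    def replicates(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.replicate_ids:
            seen.setdefault(r)
        return list(seen)


@dataclass
class OrderParameter:
    chain: str
    res_number: int
    res_name: str
    angle_name: str
    s2: float  # in [0, 1]
    n_frames: int
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.s2 <= 1.0 + 1e-9):
            raise ValueError(f"S2 out of range: {self.s2}")
        self.s2 = min(max(self.s2, 0.0), 1.0)


@dataclass
class ClusterAssignment:
    level: str  # 'backbone' | 'sidechain'
    cluster_id: int
    member_frames: list[int]  # global frame indices
    occupancy_pct: float  # relative to the grand frame total
    representative_frame: int  # medoid under the clustering metric
    parent_id: int | None = None


@dataclass
class OccupancyGrid:
    origin: np.ndarray  # Å, corner of voxel (0,0,0)
    spacing: float
    occupancy: np.ndarray  # (nx, ny, nz) fractions in [0, 1]
    within: float
    atom_radius: float

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nx, ny, nz = self.occupancy.shape
        cx = self.origin[0] + self.spacing * (np.arange(nx) + 0.5)
        cy = self.origin[1] + self.spacing * (np.arange(ny) + 0.5)
        cz = self.origin[2] + self.spacing * (np.arange(nz) + 0.5)
        return cx, cy, cz


def subsample_indices(n_total: int, n: int) -> np.ndarray:
    """Equally-spaced indices round(i*(N-1)/(n-1)), i = 0..n-1."""
    if n < 2:
        raise ValueError("need n >= 2")
    if n > n_total:
        raise ValueError(f"cannot take {n} frames from {n_total}")
    i = np.arange(n)
    return np.rint(i * (n_total - 1) / (n - 1)).astype(int)


def subsample_frames(frames: Ensemble | FrameEnsemble, n: int,
                     ) -> FrameEnsemble:
    """Deterministic equally-spaced subsampling; first and last frames kept.

    For a FrameEnsemble the subsampling is applied per replicate so frame
    counts per replicate stay equal.
    """
    if isinstance(frames, FrameEnsemble):
        parts = [frames.replicate(r) for r in frames.replicates]
        models, reps = [], []
        for part in parts:
            idx = subsample_indices(len(part), n)
            models.extend(part.frames[int(i)] for i in idx)
            reps.extend([part.replicate_ids[0]] * len(idx))
        return FrameEnsemble(frames=Ensemble(models, shared_topology=True),
                             replicate_ids=reps)
    idx = subsample_indices(len(frames), n)
    return FrameEnsemble(
        frames=Ensemble([frames[int(i)] for i in idx], shared_topology=True))


def averaged_rmsf(replicates: list[FrameEnsemble | Ensemble],
                  fit: AtomSelection, report: AtomSelection) -> FluctProfile:
    """Per-replicate RMSF, then the arithmetic mean across replicates."""
    if not replicates:
        raise ValueError("need >= 1 replicate")
    profiles = []
    for rep in replicates:
        ens = rep.frames if isinstance(rep, FrameEnsemble) else rep
        profiles.append(per_atom_rmsf(ens, fit, report))
    ref = profiles[0]
    for p in profiles[1:]:
        if p.atom_keys != ref.atom_keys:
            raise ValueError("replicate topologies differ over the report "
                             "selection")
    return FluctProfile(
        atom_keys=ref.atom_keys,
        rmsf=np.mean([p.rmsf for p in profiles], axis=0),
        residue_keys=ref.residue_keys,
        residue_rmsf=np.mean([p.residue_rmsf for p in profiles], axis=0),
        fit_selection=fit,
        report_selection=report,
    )


def dihedral_s2(series: DihedralSeries) -> OrderParameter:
    """Circular-resultant order parameter S2 = <cos>^2 + <sin>^2.

    1 for a rigid torsion, 0 for full cancellation.  NaN frames (angle
    undefined) are skipped and counted.
    """
    vals = series.values
    ok = np.isfinite(vals)
    used = vals[ok]
    if used.size < 2:
        raise ValueError("need >= 2 defined frames")
    rad = np.deg2rad(used)
    s2 = float(np.cos(rad).mean() ** 2 + np.sin(rad).mean() ** 2)
    return OrderParameter(
        chain=series.chain, res_number=series.res_number,
        res_name=series.res_name, angle_name=series.angle_name,
        s2=s2, n_frames=int(used.size), n_skipped=int((~ok).sum()),
    )


def _aligned_coords(fe: FrameEnsemble, sel: AtomSelection,
                    align_sel: AtomSelection | None) -> np.ndarray:
    """(T, m, 3) coordinates over ``sel``, optionally after superposing every
    frame on frame 0 over ``align_sel`` (the common-receptor-frame mode)."""
    ens = fe.frames
    ref = ens[0]
    isel = sel.indices(ref)
    if isel.size == 0:
        raise ValueError("empty clustering selection")
    coords = ens.coords()
    if align_sel is not None:
        ia = align_sel.indices(ref)
        ref_fit = coords[0, ia]
        out = np.empty((coords.shape[0], isel.size, 3))
        for t in range(coords.shape[0]):
            tr = kabsch(coords[t, ia], ref_fit)
            out[t] = tr.apply(coords[t, isel])
        return out
    return coords[:, isel, :]


def _pairwise_rmsd(coords: np.ndarray, self_fit: bool) -> np.ndarray:
    t = coords.shape[0]
    mat = np.zeros((t, t))
    if not self_fit:
        for i in range(t):
            d = coords[i + 1:] - coords[i]
            if d.size:
                mat[i, i + 1:] = np.sqrt((d ** 2).sum(axis=2).mean(axis=1))
        return mat + mat.T
    for i in range(t):
        for j in range(i + 1, t):
            tr = kabsch(coords[j], coords[i])
            d = tr.apply(coords[j]) - coords[i]
            mat[i, j] = mat[j, i] = np.sqrt((d ** 2).sum(axis=1).mean())
    return mat


def _single_linkage(dmat: np.ndarray, cutoff: float) -> np.ndarray:
    if dmat.shape[0] == 1:
        return np.array([1])
    link = linkage(squareform(dmat, checks=False), method="single")
    return fcluster(link, t=cutoff, criterion="distance")


def _assemble(labels: np.ndarray, frame_ids: list[int], dmat: np.ndarray,
              total_frames: int, level: str,
              parent_id: int | None) -> list[ClusterAssignment]:
    clusters = []
    for cid in sorted(set(labels)):
        local = np.flatnonzero(labels == cid)
        sub = dmat[np.ix_(local, local)]
        medoid = local[int(np.argmin(sub.sum(axis=0)))]
        clusters.append(ClusterAssignment(
            level=level,
            cluster_id=0,  # renumbered after occupancy sort
            member_frames=[frame_ids[int(i)] for i in local],
            occupancy_pct=100.0 * local.size / total_frames,
            representative_frame=frame_ids[int(medoid)],
            parent_id=parent_id,
        ))
    clusters.sort(key=lambda c: (-c.occupancy_pct, c.member_frames[0]))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = i
    return clusters


def backbone_cluster(fe: FrameEnsemble, cutoff: float = 0.5,
                     sel: AtomSelection | None = None,
                     align_sel: AtomSelection | None = None,
                     self_fit: bool = False) -> list[ClusterAssignment]:
    """Single-linkage clustering of frames at an RMSD merge threshold.

    Default metric is RMSD in a common receptor frame (frames superposed on
    frame 0 over ``align_sel`` when given); ``self_fit=True`` instead fits
    every pair on the clustering selection.  Clusters are reported by
    descending occupancy (percent of all frames).
    """
    sel = sel or AtomSelection(atom_class="backbone-no-O")
    coords = _aligned_coords(fe, sel, align_sel)
    dmat = _pairwise_rmsd(coords, self_fit)
    labels = _single_linkage(dmat, cutoff)
    return _assemble(labels, list(range(len(fe))), dmat, len(fe),
                     "backbone", None)


def sidechain_subcluster(parent: ClusterAssignment, fe: FrameEnsemble,
                         cutoff: float = 1.0,
                         sel: AtomSelection | None = None,
                         align_sel: AtomSelection | None = None,
                         self_fit: bool = False) -> list[ClusterAssignment]:
    """Second-stage clustering restricted to one backbone cluster's frames;
    occupancies remain relative to the grand frame total."""
    if not parent.member_frames:
        raise ValueError("empty parent cluster")
    sel = sel or AtomSelection(atom_class="all-heavy")
    coords = _aligned_coords(fe, sel, align_sel)
    sub = coords[parent.member_frames]
    dmat = _pairwise_rmsd(sub, self_fit)
    labels = _single_linkage(dmat, cutoff)
    return _assemble(labels, parent.member_frames, dmat, len(fe),
                     "sidechain", parent.cluster_id)


def water_occupancy(fe: FrameEnsemble, near: AtomSelection,
                    within: float = 5.0, spacing: float = 1.0,
                    atom_radius: float = 1.0) -> OccupancyGrid:
    """Fraction of frames in which a water oxygen occupies each voxel.

    Per frame, water oxygens within ``within`` Å of the ``near`` selection
    mark every voxel whose center lies within ``atom_radius``; the grid
    covers the selection envelope padded by within + atom_radius.  Frames
    are assumed aligned to a common receptor frame.
    """
    ens = fe.frames
    ref = ens[0]
    water = (np.isin(ref.res_names, list(WATER_RES_NAMES))
             & (ref.elements == "O"))
    if not water.any():
        raise ValueError("no water oxygen atoms present")
    inear = near.indices(ref)
    if inear.size == 0:
        raise ValueError("empty 'near' selection")

    coords = ens.coords()
    near_xyz = coords[:, inear, :].reshape(-1, 3)
    pad = within + atom_radius
    lo = near_xyz.min(axis=0) - pad
    hi = near_xyz.max(axis=0) + pad
    origin = np.floor(lo / spacing) * spacing
    dims = np.ceil((hi - origin) / spacing).astype(int)
    dims = np.maximum(dims, 1)
    occupancy = np.zeros(tuple(dims))

    iw = np.flatnonzero(water)
    for t in range(coords.shape[0]):
        tree = cKDTree(coords[t, inear, :])
        wxyz = coords[t, iw, :]
        dmin, _ = tree.query(wxyz, k=1)
        hits = wxyz[dmin <= within]
        if hits.size == 0:
            continue
        marked = np.zeros(tuple(dims), dtype=bool)
        for w in hits:
            ijk_lo = np.floor((w - atom_radius - origin) / spacing
                              - 0.5).astype(int)
            ijk_hi = np.ceil((w + atom_radius - origin) / spacing
                             - 0.5).astype(int)
            ijk_lo = np.maximum(ijk_lo, 0)
            ijk_hi = np.minimum(ijk_hi, dims - 1)
            if np.any(ijk_lo > ijk_hi):
                continue
            rng = [np.arange(ijk_lo[d], ijk_hi[d] + 1) for d in range(3)]
            gx, gy, gz = np.meshgrid(*rng, indexing="ij")
            centers = origin + spacing * (
                np.stack([gx, gy, gz], axis=-1) + 0.5)
            d2 = ((centers - w) ** 2).sum(axis=-1)
            inside = d2 <= atom_radius ** 2
            marked[gx[inside], gy[inside], gz[inside]] = True
        occupancy += marked
    occupancy /= coords.shape[0]
    return OccupancyGrid(origin=origin, spacing=spacing, occupancy=occupancy,
                         within=within, atom_radius=atom_radius)


def write_opendx(grid: OccupancyGrid, path: str | Path) -> None:
    """OpenDX scalar volumetric map (voxel-center positions)."""
    nx, ny, nz = grid.occupancy.shape
    ox, oy, oz = grid.origin + grid.spacing / 2.0
    s = grid.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.4f} {oy:.4f} {oz:.4f}",
        f"delta {s:.4f} 0 0",
        f"delta 0 {s:.4f} 0",
        f"delta 0 0 {s:.4f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} "
        "data follows",
    ]
    flat = grid.occupancy.ravel(order="C")
    for i in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.6f}" for v in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    Path(path).write_text("\n".join(lines) + "\n")
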