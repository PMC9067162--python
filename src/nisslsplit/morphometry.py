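"""Quantitative morphometry on channel masks: per-object tables, diameter
size classes, 3D density grids, region block statistics, normalized cortical
depth profiles, vessel skeleton graphs and plaque–vessel proximity.

Object "diameter" throughout is the 3D equivalent-sphere diameter
``(6 V / π)^(1/3)`` of the segmented component; the plaque size classes are
the half-open bins [0, 30), [30, 40), [40, ∞) µm.  Surface areas (for
sphericity) come from a marching-cubes iso-surface of the component, which
converges to the true area for digitized spheres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure
from skimage.morphology import skeletonize

from .channels import STRUCT_26
from .errors import RangeError, TopologyError, ValidationError
from .volume import RegionMask, Volume

#: plaque size-class edges in µm (closed-left bins)
DIAMETER_BIN_EDGES = (30.0, 40.0)
DIAMETER_BIN_LABELS = ("lt30", "30to40", "gt40")


def equivalent_diameter(volume_um3: float | np.ndarray) -> float | np.ndarray:
    """Diameter of the sphere with the same volume."""
    return (6.0 * np.asarray(volume_um3) / np.pi) ** (1.0 / 3.0)


def _surface_area_um2(comp_mask: np.ndarray, spacing: Sequence[float]) -> float:
    padded = np.pad(comp_mask.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    return float(measure.mesh_surface_area(verts, faces))


def plaque_morphometry(
    mask: np.ndarray, volume: Volume, score: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-plaque morphometry table from a plaque mask.

    One row per 26-connected component: centroid (µm), volume (voxel count ×
    voxel volume), equivalent diameter, mean core gray, sphericity
    ``π^(1/3) (6V)^(2/3) / A`` and the size-class bin.  ``score``, when
    given, supplies ``rim_contrast`` as the peak plaque score per component.
    """
    if mask.shape != volume.shape:
        raise ValidationError(f"mask shape {mask.shape} != volume shape {volume.shape}")
    cols = [
        "id", "centroid_z_um", "centroid_y_um", "centroid_x_um", "volume_um3",
        "equivalent_diameter_um", "mean_core_gray", "rim_contrast",
        "sphericity", "diameter_bin",
    ]
    labels, n = ndimage.label(np.asarray(mask, dtype=bool), structure=STRUCT_26)
    if n == 0:
        return pd.DataFrame(columns=cols)
    spacing = volume.spacing
    voxvol = volume.voxel_volume_um3
    index = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones(mask.shape, np.float32), labels, index)
    coms = ndimage.center_of_mass(np.ones(mask.shape, np.float32), labels, index)
    mean_gray = ndimage.mean(volume.voxels, labels, index)
    rim = (
        ndimage.maximum(score, labels, index)
        if score is not None
        else np.full(n, np.nan)
    )
    slices = ndimage.find_objects(labels)
    rows = []
    for i, lab in enumerate(index):
        vol = float(sizes[i]) * voxvol
        sl = slices[lab - 1]
        comp = labels[sl] == lab
        area = _surface_area_um2(comp, spacing)
        sph = float(np.pi ** (1.0 / 3.0) * (6.0 * vol) ** (2.0 / 3.0) / area)
        rows.append(
            {
                "id": int(lab),
                "centroid_z_um": coms[i][0] * spacing[0],
                "centroid_y_um": coms[i][1] * spacing[1],
                "centroid_x_um": coms[i][2] * spacing[2],
                "volume_um3": vol,
                "equivalent_diameter_um": float(equivalent_diameter(vol)),
                "mean_core_gray": float(mean_gray[i]),
                "rim_contrast": float(rim[i]),
                "sphericity": sph,
            }
        )
    df = pd.DataFrame(rows)
    df["diameter_bin"] = _bin_labels(df["equivalent_diameter_um"].to_numpy())
    return df.sort_values("id").reset_index(drop=True)[cols]


def _bin_labels(diam: np.ndarray) -> np.ndarray:
    idx = np.digitize(diam, DIAMETER_BIN_EDGES)  # closed-left: 30 → 30to40
    return np.asarray(DIAMETER_BIN_LABELS, dtype=object)[idx]


def bin_by_diameter(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign each plaque to its size class and return per-bin counts.

    Bins are [0, 30), [30, 40), [40, ∞) µm on the equivalent diameter; a
    boundary diameter of exactly 30 falls in the 30–40 class.
    """
    out = table.copy()
    if len(out):
        out["diameter_bin"] = _bin_labels(out["equivalent_diameter_um"].to_numpy())
    else:
        out["diameter_bin"] = pd.Series(dtype=object)
    counts = {lab: int((out["diameter_bin"] == lab).sum()) for lab in DIAMETER_BIN_LABELS}
    return out, counts


# ---------------------------------------------------------------------------
# density heatmap

@dataclass
class DensityGrid:
    """Plaque-density grid: centroid counts per cubic bin (optionally smoothed)."""

    counts: np.ndarray
    bin_edge_um: float
    origin_um: tuple[float, float, float]
    mode: str = "count"


def density_heatmap(
    centroids_um: np.ndarray,
    bin_edge_um: float = 100.0,
    extent_um: Sequence[float] | None = None,
    origin_um: Sequence[float] = (0.0, 0.0, 0.0),
    mode: str = "count",
    kernel_sigma_bins: float = 1.0,
) -> DensityGrid:
    """3D density heatmap of object centroids.

    Count mode increments exactly one bin per centroid (floor indexing; a
    centroid on the upper boundary is clamped into the last bin).  Kernel
    mode applies isotropic Gaussian smoothing afterwards, renormalised so
    total mass is preserved.
    """
    if bin_edge_um <= 0:
        raise ValidationError("bin_edge_um must be positive")
    if mode not in ("count", "kernel"):
        raise ValidationError(f"mode must be 'count' or 'kernel', got {mode!r}")
    cents = np.atleast_2d(np.asarray(centroids_um, dtype=np.float64))
    if cents.size == 0:
        cents = cents.reshape(0, 3)
    if cents.shape[1] != 3:
        raise ValidationError("centroids must be (n, 3) in µm")
    origin = np.asarray(origin_um, dtype=np.float64)
    if extent_um is None:
        hi = cents.max(axis=0) if len(cents) else origin + bin_edge_um
        extent_um = hi - origin + 1e-9
    extent = np.asarray(extent_um, dtype=np.float64)
    nbins = np.maximum(np.ceil(extent / bin_edge_um).astype(int), 1)
    rel = cents - origin
    outside = (rel < 0).any(axis=1) | (rel > nbins * bin_edge_um).any(axis=1)
    if outside.any():
        raise RangeError(
            f"centroids outside extent at rows {np.flatnonzero(outside).tolist()}"
        )
    grid = np.zeros(tuple(nbins), dtype=np.float64)
    if len(cents):
        idx = np.minimum((rel // bin_edge_um).astype(int), nbins - 1)
        np.add.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    if mode == "kernel":
        total = grid.sum()
        grid = ndimage.gaussian_filter(grid, sigma=kernel_sigma_bins, mode="constant")
        s = grid.sum()
        if total > 0 and s > 0:
            grid *= total / s
    return DensityGrid(grid, float(bin_edge_um), tuple(origin), mode)


# ---------------------------------------------------------------------------
# region block statistics

def region_stats(
    table: pd.DataFrame,
    regions: Sequence[RegionMask],
    spacing: Sequence[float],
) -> pd.DataFrame:
    """Per-region plaque count / total volume / average volume.

    Membership is by centroid-in-region; a centroid inside several masks is
    counted once, in the first region by argument order.  Zero-count regions
    report count 0 with a null (never NaN-propagating) average.
    """
    spacing = np.asarray(spacing, dtype=np.float64)
    assigned = np.zeros(len(table), dtype=bool)
    rows = []
    cents = table[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy() if len(table) else np.zeros((0, 3))
    vols = table["volume_um3"].to_numpy() if len(table) else np.zeros(0)
    for region in regions:
        shape = np.asarray(region.mask.shape)
        idx = np.floor(cents / spacing).astype(int)
        inside = (idx >= 0).all(axis=1) & (idx < shape).all(axis=1)
        member = np.zeros(len(table), dtype=bool)
        ii = np.flatnonzero(inside & ~assigned)
        if len(ii):
            member[ii] = region.mask[idx[ii, 0], idx[ii, 1], idx[ii, 2]]
        assigned |= member
        count = int(member.sum())
        total = float(vols[member].sum())
        rows.append(
            {
                "region": region.name,
                "count": count,
                "total_volume_um3": total,
                "average_volume_um3": total / count if count else pd.NA,
            }
        )
    df = pd.DataFrame(rows, columns=["region", "count", "total_volume_um3", "average_volume_um3"])
    df["average_volume_um3"] = df["average_volume_um3"].astype("Float64")
    return df


# ---------------------------------------------------------------------------
# cortical depth profile

@dataclass
class DepthProfile:
    """Counts of somata and plaques per normalized cortical-depth bin."""

    bin_edges: np.ndarray
    soma_counts: np.ndarray
    plaque_counts: np.ndarray
    slab_thickness_um: float | None = None
    slab_start_um: float | None = None


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    # border_value=1: a mask cut by the volume edge exposes no boundary there
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=1
    )
    return mask & ~eroded


def depth_profile(
    soma_centroids_um: np.ndarray,
    plaque_centroids_um: np.ndarray,
    cortex: RegionMask,
    pia: RegionMask,
    spacing: Sequence[float],
    n_bins: int = 10,
    slab_start_um: float | None = None,
    slab_thickness_um: float | None = None,
) -> DepthProfile:
    """Histogram centroids by normalized cortical depth.

    For each centroid inside the cortex mask (optionally restricted to a
    coronal slab on axis 0), the depth is the straight-line distance to the
    nearest pial-surface voxel; the normalized depth divides it by the local
    cortical size, ``d_pia / (d_pia + d_wm)`` with ``d_wm`` the distance to
    the white-matter-side boundary, so every profile spans [0, 1].
    """
    if not cortex.mask.any():
        raise ValidationError("cortex mask is empty")
    spacing = np.asarray(spacing, dtype=np.float64)
    pia_vox = pia.mask & cortex.mask
    boundary = _boundary_voxels(cortex.mask)
    near_pia = ndimage.binary_dilation(pia_vox, structure=STRUCT_26)
    wm_vox = boundary & ~near_pia
    if not pia_vox.any() or not wm_vox.any():
        raise TopologyError(
            "cortex mask must expose two distinct boundary sides (pia and white matter)"
        )
    d_pia = ndimage.distance_transform_edt(~pia_vox, sampling=spacing)
    d_wm = ndimage.distance_transform_edt(~wm_vox, sampling=spacing)
    edges = np.linspace(0.0, 1.0, n_bins + 1)

    def _count(cents: np.ndarray) -> np.ndarray:
        counts = np.zeros(n_bins, dtype=np.int64)
        cents = np.atleast_2d(np.asarray(cents, dtype=np.float64))
        if cents.size == 0:
            return counts
        idx = np.floor(cents / spacing).astype(int)
        shape = np.asarray(cortex.mask.shape)
        ok = (idx >= 0).all(axis=1) & (idx < shape).all(axis=1)
        for i in np.flatnonzero(ok):
            z, y, x = idx[i]
            if not cortex.mask[z, y, x]:
                continue
            if slab_start_um is not None and slab_thickness_um is not None:
                z_um = cents[i, 0]
                if not (slab_start_um <= z_um < slab_start_um + slab_thickness_um):
                    continue
            dp, dw = d_pia[z, y, x], d_wm[z, y, x]
            norm = dp / (dp + dw) if (dp + dw) > 0 else 0.0
            b = min(int(norm * n_bins), n_bins - 1)
            counts[b] += 1
        return counts

    return DepthProfile(
        bin_edges=edges,
        soma_counts=_count(soma_centroids_um),
        plaque_counts=_count(plaque_centroids_um),
        slab_thickness_um=slab_thickness_um,
        slab_start_um=slab_start_um,
    )


# ---------------------------------------------------------------------------
# vessel skeleton graph and proximity

@dataclass
class VesselGraph:
    """Medial-axis skeleton of the vessel mask with local radius per node."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def node_coords_um(self) -> np.ndarray:
        if self.n_nodes == 0:
            return np.zeros((0, 3))
        return np.array([self.graph.nodes[n]["coord_um"] for n in self.graph.nodes])

    def node_radii_um(self) -> np.ndarray:
        if self.n_nodes == 0:
            return np.zeros(0)
        return np.array([self.graph.nodes[n]["radius_um"] for n in self.graph.nodes])

    def branch_points(self) -> list:
        return [n for n in self.graph.nodes if self.graph.degree[n] >= 3]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "z_um": self.graph.nodes[n]["coord_um"][0],
                "y_um": self.graph.nodes[n]["coord_um"][1],
                "x_um": self.graph.nodes[n]["coord_um"][2],
                "radius_um": self.graph.nodes[n]["radius_um"],
                "degree": self.graph.degree[n],
            }
            for n in self.graph.nodes
        ]
        return pd.DataFrame(rows, columns=["z_um", "y_um", "x_um", "radius_um", "degree"])


def skeletonize_vessels(mask: np.ndarray, spacing: Sequence[float]) -> VesselGraph:
    """Medial-axis thinning of the vessel mask into a radius-annotated graph.

    Node radii are the Euclidean distance transform (µm) of the mask sampled
    at the skeleton voxel; edges follow 26-adjacency of skeleton voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    g = nx.Graph()
    if not mask.any():
        return VesselGraph(g)
    skel = skeletonize(mask)
    edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    coords = np.argwhere(skel)
    spacing = np.asarray(spacing, dtype=np.float64)
    voxset = {tuple(c) for c in coords}
    for c in coords:
        t = tuple(int(v) for v in c)
        g.add_node(t, coord_um=tuple(c * spacing), radius_um=float(edt[t]))
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0)  # half the neighbourhood, no duplicates
    ]
    for t in voxset:
        for off in offsets:
            nb = (t[0] + off[0], t[1] + off[1], t[2] + off[2])
            if nb in voxset:
                g.add_edge(t, nb)
    return VesselGraph(g)


def plaque_vessel_proximity(
    table: pd.DataFrame, graph: VesselGraph
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Nearest-skeleton-node distance and local vessel radius per plaque.

    Returns one row per plaque (distance µm, radius µm of the matched node,
    ``defined`` flag) plus summary quantiles of the matched radii, so a
    "distal-end" (small local radius) association can be tested downstream.
    An empty graph yields undefined-flagged rows, never an exception.
    """
    cols = ["plaque_id", "nearest_skeleton_um", "local_vessel_radius_um", "defined"]
    if graph.n_nodes == 0:
        df = pd.DataFrame(
            {
                "plaque_id": table["id"] if len(table) else pd.Series(dtype=int),
                "nearest_skeleton_um": np.nan,
                "local_vessel_radius_um": np.nan,
                "defined": False,
            },
            columns=cols,
        )
        return df, {}
    coords = graph.node_coords_um()
    radii = graph.node_radii_um()
    tree = cKDTree(coords)
    cents = table[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy()
    if len(cents) == 0:
        return pd.DataFrame(columns=cols), {}
    dist, idx = tree.query(cents)
    df = pd.DataFrame(
        {
            "plaque_id": table["id"].to_numpy(),
            "nearest_skeleton_um": dist,
            "local_vessel_radius_um": radii[idx],
            "defined": True,
        },
        columns=cols,
    )
    qs = np.quantile(radii[idx], [0.25, 0.5, 0.75]) if len(idx) else [np.nan] * 3
    summary = {
        "local_radius_q25_um": float(qs[0]),
        "local_radius_median_um": float(qs[1]),
        "local_radius_q75_um": float(qs[2]),
    }
    return df, summary


# ---------------------------------------------------------------------------
# mesh export

def export_mesh(
    mask: np.ndarray, spacing: Sequence[float], path: str | Path, fmt: str | None = None
) -> Path:
    """Export the iso-surface of a mask as a Wavefront OBJ (or PLY) mesh."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    padded = np.pad(np.asarray(mask, dtype=np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    verts -= np.asarray(spacing, dtype=verts.dtype)  # undo pad offset
    if fmt == "obj":
        lines = [f"v {v[0]:.6g} {v[1]:.6g} {v[2]:.6g}" for v in verts]
        lines += [f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}" for f in faces]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "ply":
        header = [
            "ply", "format ascii 1.0",
            f"element vertex {len(verts)}",
            "property float x", "property float y", "property float z",
            f"element face {len(faces)}",
            "property list uchar int vertex_indices", "end_header",
        ]
        body = [f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}" for v in verts]
        body += [f"3 {f[0]} {f[1]} {f[2]}" for f in faces]
        path.write_text("\n".join(header + body) + "\n")
    else:
        raise ValidationError(f"unsupported mesh format {fmt!r}; use obj or ply")
    return path
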