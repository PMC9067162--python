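"""Synthetic bright-field Nissl phantom with voxel- and object-level ground
truth, plus detection-evaluation metrics.

The generator emulates the contrast regime of serial-sectioning bright-field
Nissl data: blood vessels brightest, parenchyma in the middle band, somata,
plaque cores and nerve tracts darkest, and amyloid plaques rendered as a
dark core wrapped in a rim *paler* than the parenchyma (the "W" intensity
signature).  Structures are rendered at their clean gray offsets, ground
truth is recorded, and the stack is then corrupted with a per-slice
illumination gain ramp, horizontal stripe noise and Gaussian noise.

A single integer seed drives one pseudo-random stream; identical specs give
bit-identical volumes and truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import PlacementError, ValidationError
from .volume import DEFAULT_LEGEND, LabelVolume, Volume

LABEL = {v: k for k, v in DEFAULT_LEGEND.items()}


@dataclass
class PhantomSpec:
    """Generator parameters (defaults are the standard test-bed conditions).

    Gray offsets are relative to ``baseline`` and respect the bright-field
    Nissl ordering vessel > baseline > process band > soma/core; the plaque
    rim offset is positive (paler than parenchyma).
    """

    shape: tuple[int, int, int] = (256, 256, 256)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    baseline: float = 150.0
    noise_sd: float = 8.0
    illumination_ramp: float = 0.2      # per-slice gain ramps 1−r → 1+r
    stripe_amplitude: float = 10.0      # gray levels
    stripe_cycles: float = 8.0          # cycles per image, along rows
    # plaques: dark core + paler rim
    n_plaques: int = 40
    plaque_diameter_range_um: tuple[float, float] = (10.0, 50.0)
    plaque_diameters_um: Sequence[float] | None = None  # explicit override
    plaque_core_offset: float = -80.0
    plaque_rim_offset: float = 30.0
    plaque_rim_width_frac: float = 0.4  # rim shell spans r .. (1+frac)·r
    plaque_clearance_um: float = 8.0
    # somata
    n_somata: int = 300
    soma_diameter_range_um: tuple[float, float] = (6.0, 15.0)
    soma_small_max_um: float = 10.0
    soma_offset: float = -80.0
    soma_clearance_um: float = 3.0
    # vessels
    n_vessel_trees: int = 3
    vessel_root_radius_um: float = 8.0
    vessel_min_radius_um: float = 2.0
    vessel_taper: float = 0.01          # fractional radius loss per step
    vessel_tortuosity: float = 0.25     # direction jitter per step
    vessel_branch_prob: float = 0.02
    vessel_step_um: float = 1.5
    # tracts: massive dark cylinders along the sectioning axis
    n_tracts: int = 2
    tract_radius_um: float = 25.0
    tract_length_um: float = 140.0
    tract_offset: float = -80.0
    # nerve-process filaments: intermediate gray band
    n_filaments: int = 200
    filament_radius_um: float = 1.0
    filament_length_um: float = 80.0
    filament_offset: float = -25.0
    seed: int = 0
    max_tries: int = 500

    def __post_init__(self) -> None:
        for name in ("n_plaques", "n_somata", "n_vessel_trees", "n_tracts", "n_filaments"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.plaque_rim_offset <= 0:
            raise ValidationError("plaque rim must be paler than baseline (rim offset > 0)")
        if not (self.soma_offset < self.filament_offset < 0):
            raise ValidationError(
                "gray ordering violated: soma/core must be darker than the process band"
            )


@dataclass
class GroundTruth:
    """Clean per-structure labels plus object tables for parameter recovery."""

    label_volume: LabelVolume
    plaques: pd.DataFrame
    somata: pd.DataFrame
    vessels: pd.DataFrame       # one row per centerline node: tree, coords, radius
    tracts: pd.DataFrame
    filaments: pd.DataFrame     # one row per polyline node: filament, coords


def _ball_mask(shape_box: Sequence[int], center: Sequence[float],
               radii: Sequence[float], spacing: Sequence[float]) -> np.ndarray:
    grids = np.ogrid[: shape_box[0], : shape_box[1], : shape_box[2]]
    d2 = sum(
        (((g - c) * s) / r) ** 2
        for g, c, s, r in zip(grids, center, spacing, radii)
    )
    return d2 <= 1.0


class _Canvas:
    """Render target: gray canvas + truth labels + occupancy for clearances."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.gray = np.full(spec.shape, spec.baseline, dtype=np.float32)
        self.truth = np.zeros(spec.shape, dtype=np.int32)
        self.occupied = np.zeros(spec.shape, dtype=bool)
        self.spacing = np.asarray(spec.spacing, dtype=np.float64)
        self.shape = np.asarray(spec.shape)

    def box(self, center_vox: np.ndarray, radius_um: float) -> tuple[slice, ...]:
        r_vox = np.ceil(radius_um / self.spacing).astype(int)
        lo = np.maximum(center_vox - r_vox, 0)
        hi = np.minimum(center_vox + r_vox + 1, self.shape)
        return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))

    def is_free(self, center_vox: np.ndarray, radius_um: float) -> bool:
        sl = self.box(center_vox, radius_um)
        local_center = center_vox - np.array([s.start for s in sl])
        box_shape = [s.stop - s.start for s in sl]
        m = _ball_mask(box_shape, local_center, [radius_um] * 3, self.spacing)
        return not self.occupied[sl][m].any()

    def stamp_ball(
        self,
        center_vox: np.ndarray,
        radii_um: Sequence[float],
        value: float,
        label: int,
        occupy: bool = True,
        inner_um: Sequence[float] | None = None,
    ) -> int:
        sl = self.box(center_vox, max(radii_um))
        local_center = center_vox - np.array([s.start for s in sl])
        box_shape = [s.stop - s.start for s in sl]
        m = _ball_mask(box_shape, local_center, radii_um, self.spacing)
        if inner_um is not None:
            m &= ~_ball_mask(box_shape, local_center, inner_um, self.spacing)
        self.gray[sl][m] = value
        if label:
            self.truth[sl][m] = label
        if occupy:
            self.occupied[sl][m] = True
        return int(m.sum())


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _grow_vessel_tree(canvas: _Canvas, rng: np.random.Generator, tree_id: int) -> list[dict]:
    spec = canvas.spec
    extent = canvas.shape * canvas.spacing
    root = rng.uniform(0.15, 0.85, size=3) * extent
    stack = [(root, _random_unit(rng), spec.vessel_root_radius_um)]
    nodes: list[dict] = []
    guard = 0
    while stack and guard < 20000:
        pos, direction, radius = stack.pop()
        while radius >= spec.vessel_min_radius_um:
            guard += 1
            if guard >= 20000:
                break
            if ((pos < radius) | (pos > extent - radius)).any():
                break
            cvox = np.floor(pos / canvas.spacing).astype(int)
            canvas.stamp_ball(
                cvox, [radius] * 3, spec.baseline + 70.0, LABEL["vessel"]
            )
            nodes.append(
                {"tree": tree_id, "z_um": pos[0], "y_um": pos[1], "x_um": pos[2],
                 "radius_um": radius}
            )
            if rng.random() < spec.vessel_branch_prob and radius > 2 * spec.vessel_min_radius_um:
                child_dir = direction + spec.vessel_tortuosity * 3 * rng.normal(size=3)
                child_dir /= np.linalg.norm(child_dir)
                stack.append((pos.copy(), child_dir, radius * 0.7))
                radius *= 0.85
            direction = direction + spec.vessel_tortuosity * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = pos + direction * spec.vessel_step_um
            radius *= 1.0 - spec.vessel_taper
    return nodes


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Render the phantom and its ground truth, then corrupt the gray stack.

    Placement uses rejection sampling against an occupancy grid (object
    extent plus a clearance margin must be free); after ``max_tries``
    rejections a :class:`~nisslsplit.errors.PlacementError` names the
    offending structure class.  Rendering order: vessels, tracts, plaques,
    somata, filaments (filaments terminate early at collisions).
    """
    rng = np.random.default_rng(spec.seed)
    canvas = _Canvas(spec)
    extent = canvas.shape * canvas.spacing
    sp = canvas.spacing

    # --- tracts (placed first: largest objects) ----------------------------
    tract_rows = []
    for i in range(spec.n_tracts):
        r = spec.tract_radius_um
        length = min(spec.tract_length_um, extent[0] - 10)
        for attempt in range(spec.max_tries + 1):
            if attempt == spec.max_tries:
                raise PlacementError("could not place structure class 'tract'")
            z0 = rng.uniform(5, extent[0] - length - 5)
            cy = rng.uniform(r + 5, extent[1] - r - 5)
            cx = rng.uniform(r + 5, extent[2] - r - 5)
            za = max(int((z0 - 5) / sp[0]), 0)
            zb = min(int((z0 + length + 5) / sp[0]) + 1, canvas.shape[0])
            y0 = max(int((cy - r - 5) / sp[1]), 0)
            y1 = min(int((cy + r + 5) / sp[1]) + 1, canvas.shape[1])
            x0 = max(int((cx - r - 5) / sp[2]), 0)
            x1 = min(int((cx + r + 5) / sp[2]) + 1, canvas.shape[2])
            if canvas.occupied[za:zb, y0:y1, x0:x1].any():
                continue
            yy, xx = np.ogrid[: canvas.shape[1], : canvas.shape[2]]
            disk = ((yy * sp[1] - cy) ** 2 + (xx * sp[2] - cx) ** 2) <= r**2
            zs = slice(int(z0 / sp[0]), int((z0 + length) / sp[0]) + 1)
            region = np.zeros(canvas.shape, dtype=bool)
            region[zs, disk] = True
            canvas.gray[region] = spec.baseline + spec.tract_offset
            canvas.truth[region] = LABEL["tract"]
            canvas.occupied[region] = True
            tract_rows.append({"id": i + 1, "z0_um": z0, "z1_um": z0 + length,
                               "center_y_um": cy, "center_x_um": cx,
                               "radius_um": r, "axis": 0})
            break
    tracts = pd.DataFrame(tract_rows, columns=["id", "z0_um", "z1_um", "center_y_um",
                                               "center_x_um", "radius_um", "axis"])

    # --- vessels -----------------------------------------------------------
    vessel_rows: list[dict] = []
    for t in range(spec.n_vessel_trees):
        vessel_rows.extend(_grow_vessel_tree(canvas, rng, t))
    vessels = pd.DataFrame(vessel_rows, columns=["tree", "z_um", "y_um", "x_um", "radius_um"])

    # --- plaques -----------------------------------------------------------
    if spec.plaque_diameters_um is not None:
        diameters = np.asarray(list(spec.plaque_diameters_um), dtype=float)
    else:
        lo, hi = spec.plaque_diameter_range_um
        # stratified draw: every size class represented in a modest n
        edges = np.linspace(lo, hi, spec.n_plaques + 1)
        diameters = edges[:-1] + rng.uniform(0, 1, size=spec.n_plaques) * np.diff(edges)
        rng.shuffle(diameters)
    order = np.argsort(diameters)[::-1]  # place large plaques first
    plaque_rows: list[dict] = []
    for j in order:
        d = float(diameters[j])
        core_r = d / 2.0
        rim_r = core_r * (1.0 + spec.plaque_rim_width_frac)
        clear = rim_r + spec.plaque_clearance_um
        if np.any(extent - 2 * clear <= 0):
            raise PlacementError("could not place structure class 'plaque'")
        for attempt in range(spec.max_tries + 1):
            if attempt == spec.max_tries:
                raise PlacementError("could not place structure class 'plaque'")
            c_um = rng.uniform(clear, extent - clear)
            cvox = np.floor(c_um / sp).astype(int)
            if not canvas.is_free(cvox, clear):
                continue
            canvas.stamp_ball(cvox, [rim_r] * 3, spec.baseline + spec.plaque_rim_offset,
                              label=0, inner_um=[core_r] * 3)
            canvas.stamp_ball(cvox, [core_r] * 3, spec.baseline + spec.plaque_core_offset,
                              label=LABEL["plaque"])
            center = (cvox + 0.0) * sp  # voxel-grid-aligned center
            plaque_rows.append(
                {"id": int(j) + 1, "centroid_z_um": center[0], "centroid_y_um": center[1],
                 "centroid_x_um": center[2], "diameter_um": d}
            )
            break
    plaques = pd.DataFrame(
        plaque_rows,
        columns=["id", "centroid_z_um", "centroid_y_um", "centroid_x_um", "diameter_um"],
    ).sort_values("id").reset_index(drop=True)

    # --- somata ------------------------------------------------------------
    soma_rows: list[dict] = []
    for i in range(spec.n_somata):
        d = float(rng.uniform(*spec.soma_diameter_range_um))
        # volume-preserving anisotropy so the equivalent diameter stays d
        eps = rng.uniform(-0.15, 0.15, size=3)
        aniso = np.exp(eps - eps.mean())
        radii = (d / 2.0) * aniso
        clear = float(radii.max()) + spec.soma_clearance_um
        if np.any(extent - 2 * clear <= 0):
            raise PlacementError("could not place structure class 'soma'")
        for attempt in range(spec.max_tries + 1):
            if attempt == spec.max_tries:
                raise PlacementError("could not place structure class 'soma'")
            c_um = rng.uniform(clear, extent - clear)
            cvox = np.floor(c_um / sp).astype(int)
            if not canvas.is_free(cvox, clear):
                continue
            canvas.stamp_ball(cvox, radii, spec.baseline + spec.soma_offset,
                              label=LABEL["soma"])
            center = cvox * sp
            soma_rows.append(
                {"id": i + 1, "centroid_z_um": center[0], "centroid_y_um": center[1],
                 "centroid_x_um": center[2], "diameter_um": d,
                 "size_class": "small" if d <= spec.soma_small_max_um else "large"}
            )
            break
    somata = pd.DataFrame(
        soma_rows,
        columns=["id", "centroid_z_um", "centroid_y_um", "centroid_x_um",
                 "diameter_um", "size_class"],
    )

    # --- filaments ---------------------------------------------------------
    fil_rows: list[dict] = []
    n_steps = max(int(spec.filament_length_um / 2.0), 2)
    for i in range(spec.n_filaments):
        pos = rng.uniform(5, extent - 5)
        direction = _random_unit(rng)
        for _ in range(n_steps):
            if ((pos < 2) | (pos > extent - 2)).any():
                break
            cvox = np.floor(pos / sp).astype(int)
            if canvas.occupied[canvas.box(cvox, spec.filament_radius_um + 1)].any():
                break  # collision: filament ends at the obstacle
            canvas.stamp_ball(cvox, [spec.filament_radius_um] * 3,
                              spec.baseline + spec.filament_offset,
                              label=LABEL["process"], occupy=False)
            fil_rows.append({"filament": i + 1, "z_um": pos[0], "y_um": pos[1],
                             "x_um": pos[2]})
            direction = direction + 0.15 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = pos + direction * 2.0
    filaments = pd.DataFrame(fil_rows, columns=["filament", "z_um", "y_um", "x_um"])

    # --- corruption (after truth) ------------------------------------------
    nz = spec.shape[0]
    gray = canvas.gray
    if spec.illumination_ramp > 0 and nz > 1:
        gain = np.linspace(1 - spec.illumination_ramp, 1 + spec.illumination_ramp, nz)
        gray = gray * gain[:, None, None].astype(np.float32)
    if spec.stripe_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, size=nz)
        rows = np.arange(spec.shape[1])
        stripe = spec.stripe_amplitude * np.sin(
            2 * np.pi * spec.stripe_cycles * rows[None, :] / spec.shape[1]
            + phases[:, None]
        )
        gray = gray + stripe[:, :, None].astype(np.float32)
    if spec.noise_sd > 0:
        gray = gray + rng.normal(0, spec.noise_sd, size=spec.shape).astype(np.float32)
    voxels = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    vol = Volume(voxels, spec.spacing, provenance=f"phantom(seed={spec.seed})")
    truth = GroundTruth(
        label_volume=LabelVolume(canvas.truth, spec.spacing, dict(DEFAULT_LEGEND)),
        plaques=plaques,
        somata=somata,
        vessels=vessels,
        tracts=tracts,
        filaments=filaments,
    )
    return vol, truth


# ---------------------------------------------------------------------------
# detection evaluation

def evaluate_detection(
    predicted: pd.DataFrame, truth: pd.DataFrame, match_radius_um: float = 10.0
) -> dict[str, float]:
    """Greedy one-to-one matching of predicted vs true centroids.

    Pairs are matched in ascending centroid distance within
    ``match_radius_um``; precision = TP/(TP+FP), recall = TP/(TP+FN), F1 the
    harmonic mean, and the diameter MAE is taken over matched pairs (when
    both tables carry diameters).  Empty truth *and* empty prediction define
    all metrics as 1 by convention, flagged ``degenerate``.
    """
    if match_radius_um <= 0:
        raise ValidationError("match_radius_um must be positive")
    cent_cols = ["centroid_z_um", "centroid_y_um", "centroid_x_um"]
    p = predicted[cent_cols].to_numpy() if len(predicted) else np.zeros((0, 3))
    t = truth[cent_cols].to_numpy() if len(truth) else np.zeros((0, 3))
    if len(p) == 0 and len(t) == 0:
        return {"precision": 1.0, "recall": 1.0, "f1": 1.0,
                "diameter_mae_um": 0.0, "n_tp": 0, "n_fp": 0, "n_fn": 0,
                "degenerate": True}
    pairs = []
    for i in range(len(p)):
        d = np.linalg.norm(t - p[i], axis=1) if len(t) else np.zeros(0)
        for j in np.flatnonzero(d <= match_radius_um):
            pairs.append((d[j], i, int(j)))
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matches.append((i, j))
    tp = len(matches)
    fp = len(p) - tp
    fn = len(t) - tp
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    mae = np.nan
    pd_col = "equivalent_diameter_um" if "equivalent_diameter_um" in predicted else "diameter_um"
    if matches and pd_col in predicted and "diameter_um" in truth:
        diffs = [
            abs(float(predicted[pd_col].iloc[i]) - float(truth["diameter_um"].iloc[j]))
            for i, j in matches
        ]
        mae = float(np.mean(diffs))
    return {"precision": precision, "recall": recall, "f1": f1,
            "diameter_mae_um": mae, "n_tp": tp, "n_fp": fp, "n_fn": fn,
            "degenerate": False}
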