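"""Image-volume containers and TIFF I/O.

Axis convention (fixed package-wide): axis 0 is the sectioning depth (slice
index), axes 1 and 2 are row/column within a coronal slice.  Physical voxel
spacing is carried explicitly in micrometres and always comes from the caller
or config, never from TIFF tags — tag dialects are unreliable, so a
tag/config mismatch is logged as a warning and the config wins.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .errors import FormatError, RangeError, ValidationError

log = logging.getLogger(__name__)

#: canonical structure legend used by the fused label volume
DEFAULT_LEGEND: dict[int, str] = {
    0: "background",
    1: "vessel",
    2: "plaque",
    3: "soma",
    4: "tract",
    5: "process",
}

_BIT_MAX = {8: 255, 16: 65535}


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be three positive values, got {spacing!r}")
    return spacing


@dataclass
class Volume:
    """A 3D grayscale image grid with physical voxel spacing in µm.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Scalar grid, depth–row–column order, dtype uint8 or uint16.
    spacing : (float, float, float)
        Physical step per axis in µm, same axis order as ``voxels``.
    bit_depth : int, optional
        8 or 16; inferred from dtype when omitted.
    provenance : str
        Free-text lineage, appended to by processing stages.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    bit_depth: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValidationError(
                f"volume must be 3D with every axis length >= 1, got shape {self.voxels.shape}"
            )
        self.spacing = _check_spacing(self.spacing)
        if self.bit_depth is None:
            if self.voxels.dtype == np.uint8:
                self.bit_depth = 8
            elif self.voxels.dtype == np.uint16:
                self.bit_depth = 16
            else:
                raise ValidationError(
                    f"cannot infer bit depth from dtype {self.voxels.dtype}; pass bit_depth"
                )
        if self.bit_depth not in _BIT_MAX:
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        vmax = int(self.voxels.max()) if self.voxels.size else 0
        vmin = int(self.voxels.min()) if self.voxels.size else 0
        if vmin < 0 or vmax > _BIT_MAX[self.bit_depth]:
            raise ValidationError(
                f"voxel values [{vmin}, {vmax}] exceed declared {self.bit_depth}-bit range"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def max_value(self) -> int:
        """Maximum representable gray level for the declared bit depth."""
        return _BIT_MAX[self.bit_depth]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def with_voxels(self, voxels: np.ndarray, note: str = "") -> "Volume":
        """Return a copy carrying new voxel data and an appended provenance note."""
        prov = self.provenance if not note else (self.provenance + " | " + note).strip(" |")
        return Volume(voxels, self.spacing, self.bit_depth, prov)


@dataclass
class LabelVolume:
    """Integer structure labels aligned to a source :class:`Volume`.

    Label 0 is reserved for background; every nonzero label present in
    ``labels`` must appear in ``legend``.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    legend: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be an integer grid")
        self.spacing = _check_spacing(self.spacing)
        self.legend = {int(k): str(v) for k, v in dict(self.legend).items()}
        self.legend.setdefault(0, "background")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValidationError(f"labels {sorted(missing)} absent from legend")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of the structure called ``name`` in the legend."""
        ids = [k for k, v in self.legend.items() if v == name and k != 0]
        if not ids:
            raise ValidationError(f"structure {name!r} not in legend {self.legend}")
        return np.isin(self.labels, ids)


@dataclass
class RegionMask:
    """Named anatomical region as a boolean grid aligned to a Volume."""

    mask: np.ndarray
    name: str = "region"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValidationError("region mask must be 3D")


_NUM_RE = re.compile(r"(\d+)")


def _slice_files(directory: Path) -> list[Path]:
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".tif", ".tiff")
    )
    if not files:
        raise FormatError(f"no TIFF slices found in {directory}")
    # filename-order contract: if every stem carries a trailing integer, the
    # sequence must be gap-free — a missing slice silently shifts all depths
    nums = []
    for p in files:
        m = _NUM_RE.findall(p.stem)
        if not m:
            nums = None
            break
        nums.append(int(m[-1]))
    if nums is not None:
        expect = range(min(nums), min(nums) + len(nums))
        for p, n, e in zip(files, nums, expect):
            if n != e:
                raise FormatError(
                    f"slice index gap in {directory}: expected index {e}, found {p.name}"
                )
    return files


def read_volume(path: str | Path, spacing: Sequence[float]) -> Volume:
    """Read a multi-page TIFF or a directory of per-slice 2D TIFFs.

    Slices are ordered by page index (multi-page) or lexicographic filename
    order (directory); numerically indexed filenames must be gap-free.
    Voxel values are returned untouched.
    """
    spacing = _check_spacing(spacing)
    path = Path(path)
    if path.is_dir():
        files = _slice_files(path)
        slices = []
        shape0 = None
        for p in files:
            arr = tifffile.imread(p)
            if arr.ndim != 2:
                raise FormatError(f"{p.name}: expected a 2D slice, got shape {arr.shape}")
            if shape0 is None:
                shape0 = arr.shape
            elif arr.shape != shape0:
                raise FormatError(
                    f"{p.name}: slice shape {arr.shape} differs from first slice {shape0}"
                )
            slices.append(arr)
        voxels = np.stack(slices, axis=0)
    else:
        if not path.exists():
            raise FormatError(f"no such volume: {path}")
        voxels = tifffile.imread(path)
        if voxels.ndim == 2:
            voxels = voxels[None]
        if voxels.ndim != 3:
            raise FormatError(f"{path.name}: expected 2D/3D TIFF, got shape {voxels.shape}")
    if voxels.dtype not in (np.uint8, np.uint16):
        raise FormatError(
            f"{path.name}: unsupported dtype {voxels.dtype}; 8- or 16-bit grayscale required"
        )
    return Volume(voxels, spacing, provenance=f"read:{path.name}")


def _legend_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".legend.txt")


def write_volume(volume: Volume | LabelVolume, path: str | Path) -> Path:
    """Write a volume (or label volume + sidecar legend) as multi-page TIFF.

    Round trips bit-exactly with :func:`read_volume` / :func:`read_labels`.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if isinstance(volume, LabelVolume):
        vmax = int(volume.labels.max()) if volume.labels.size else 0
        if vmax > 65535:
            raise ValidationError("label ids exceed 16-bit TIFF range")
        tifffile.imwrite(path, volume.labels.astype(np.uint16), photometric="minisblack")
        lines = [f"{k}\t{v}" for k, v in sorted(volume.legend.items())]
        _legend_path(path).write_text("\n".join(lines) + "\n")
    else:
        tifffile.imwrite(path, volume.voxels, photometric="minisblack")
    return path


def read_labels(path: str | Path, spacing: Sequence[float]) -> LabelVolume:
    """Read a label volume written by :func:`write_volume` plus its legend."""
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    legend = {}
    lp = _legend_path(path)
    if lp.exists():
        for line in lp.read_text().splitlines():
            if line.strip():
                k, _, v = line.partition("\t")
                legend[int(k)] = v
    else:
        legend = {int(k): str(k) for k in np.unique(arr)}
    return LabelVolume(arr.astype(np.int32), _check_spacing(spacing), legend)


def um_to_voxel_origin(origin_um: Sequence[float], spacing: Sequence[float]) -> tuple[int, ...]:
    """µm → voxel index for origins: floor (deterministic, bias-free)."""
    return tuple(int(np.floor(o / s)) for o, s in zip(origin_um, spacing))


def um_to_voxel_extent(edge_um: Sequence[float], spacing: Sequence[float]) -> tuple[int, ...]:
    """µm → voxel count for extents: round-half-up, minimum 1 voxel."""
    return tuple(max(1, int(np.floor(e / s + 0.5))) for e, s in zip(edge_um, spacing))


def crop_block(volume: Volume, origin_um: Sequence[float], edge_um: Sequence[float]) -> Volume:
    """Crop an analysis block given in physical coordinates.

    A 0.5 × 0.5 × 0.5 mm quantification block at 1 µm isotropic sampling
    yields a 500³-voxel sub-volume.  Origins floor to the containing voxel,
    extents round half-up to the nearest voxel count.
    """
    origin = um_to_voxel_origin(origin_um, volume.spacing)
    extent = um_to_voxel_extent(edge_um, volume.spacing)
    for ax, (o, n, full) in enumerate(zip(origin, extent, volume.shape)):
        if o < 0 or o + n > full:
            raise RangeError(
                f"block exceeds volume bounds on axis {ax}: "
                f"voxels [{o}, {o + n}) vs extent {full}"
            )
    sl = tuple(slice(o, o + n) for o, n in zip(origin, extent))
    return volume.with_voxels(volume.voxels[sl].copy(), note=f"crop:{origin}+{extent}")
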