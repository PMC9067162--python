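"""Slice-wise image optimization: background correction, periodic-noise
(stripe) removal, and global contrast enhancement.

Bright-field serial-sectioning stacks drift in illumination between slices
and carry in-plane periodic artifacts; the gray-band channel splitting
downstream assumes one global intensity scale, so these steps run first and
in this fixed order (each can be switched off in the pipeline config):

1. :func:`correct_background` — divide out a smooth per-slice multiplicative
   background field, preserving the global median.
2. :func:`remove_periodic_noise` — notch narrow per-slice spectral peaks.
3. :func:`enhance_contrast` — global percentile stretch to the full bit range.

All three preserve shape, spacing and bit depth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .volume import Volume

log = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    """Diagnostics emitted by each preprocessing step."""

    step: str = ""
    per_slice_background: list[float] = field(default_factory=list)
    stripe_frequencies_removed: list[tuple[int, float]] = field(default_factory=list)
    rescale_bounds: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "per_slice_background": [float(b) for b in self.per_slice_background],
            "stripe_frequencies_removed": [
                [int(s), float(f)] for s, f in self.stripe_frequencies_removed
            ],
            "rescale_bounds": None
            if self.rescale_bounds is None
            else [float(self.rescale_bounds[0]), float(self.rescale_bounds[1])],
        }


def _background_field(slice_f: np.ndarray, w: int) -> np.ndarray:
    """Smooth estimate of the per-slice background mode.

    Block-wise medians (block = window/8) track the parenchyma level while
    rejecting structures occupying less than half a block, and are nearly
    noise-free, so the field carries no additive noise-envelope bias that
    would break the multiplicative correction.  A closing/opening on the
    coarse block grid removes residual dips/bumps from structures larger
    than a block (tracts, large plaques); Gaussian smoothing and bilinear
    upsampling give the final smooth field.
    """
    b = max(3, w // 8)
    ny, nx = slice_f.shape
    py, px = (-ny) % b, (-nx) % b
    padded = np.pad(slice_f, ((0, py), (0, px)), mode="edge")
    blocks = padded.reshape(padded.shape[0] // b, b, padded.shape[1] // b, b)
    coarse = np.median(blocks, axis=(1, 3))
    if min(coarse.shape) >= 3:
        coarse = ndimage.grey_closing(coarse, size=(3, 3), mode="nearest")
        coarse = ndimage.grey_opening(coarse, size=(3, 3), mode="nearest")
    coarse = ndimage.gaussian_filter(coarse, sigma=max(w / 4.0 / b, 0.5), mode="nearest")
    field = ndimage.zoom(coarse, b, order=1, mode="nearest", grid_mode=True)
    return field[:ny, :nx]


def correct_background(volume: Volume, window_um: float = 250.0) -> tuple[Volume, PreprocessReport]:
    """Divide out a smooth multiplicative background field per slice.

    ``window_um`` should exceed (≥ 5×) the largest genuine structure so the
    field tracks illumination, not anatomy; it must map to at least 3 voxels
    in-plane.  The corrected stack is rescaled so its global median equals
    the input's, then clipped to the bit range.
    """
    w = int(round(window_um / min(volume.spacing[1], volume.spacing[2])))
    if w < 3:
        raise ValidationError(
            f"background window {window_um} µm is {w} voxels; at least 3 required"
        )
    vox = volume.voxels.astype(np.float64)
    corrected = np.empty_like(vox)
    backgrounds = []
    for z in range(vox.shape[0]):
        fld = _background_field(vox[z], w)
        fld = np.maximum(fld, 1e-9)  # zero-variance / zero-valued slices: no div-by-zero
        corrected[z] = vox[z] / fld
        backgrounds.append(float(np.median(fld)))
    med_in = float(np.median(vox))
    med_corr = float(np.median(corrected))
    scale = med_in / med_corr if med_corr > 0 else 1.0
    out = np.clip(np.rint(corrected * scale), 0, volume.max_value).astype(volume.voxels.dtype)
    report = PreprocessReport(step="correct_background", per_slice_background=backgrounds)
    return volume.with_voxels(out, note=f"bgcorr(window={window_um}um)"), report


def _notch_slice(
    slice_f: np.ndarray, max_peaks: int, peak_factor: float, notch_radius: int, dc_guard: int
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    ny, nx = slice_f.shape
    F = np.fft.fft2(slice_f)
    mag = np.abs(np.fft.fftshift(F))
    cy, cx = ny // 2, nx // 2
    # "narrow" = large relative to the local spectral floor
    local = ndimage.median_filter(mag, size=9, mode="wrap")
    score = mag / np.maximum(local, 1e-12)
    yy, xx = np.ogrid[:ny, :nx]
    dc = (yy - cy) ** 2 + (xx - cx) ** 2 <= dc_guard**2
    score[dc] = 0.0
    removed: list[tuple[float, float]] = []
    Fs = np.fft.fftshift(F)
    for _ in range(max_peaks):
        idx = np.unravel_index(np.argmax(score), score.shape)
        if score[idx] < peak_factor:
            break
        py, px = idx
        fy, fx = py - cy, px - cx
        for sy, sx in ((py, px), (cy - fy, cx - fx)):  # conjugate pair
            y0, y1 = max(0, sy - notch_radius), min(ny, sy + notch_radius + 1)
            x0, x1 = max(0, sx - notch_radius), min(nx, sx + notch_radius + 1)
            Fs[y0:y1, x0:x1] = 0.0
            score[y0:y1, x0:x1] = 0.0
        removed.append((float(fy), float(fx)))
    if removed:
        out = np.fft.ifft2(np.fft.ifftshift(Fs)).real
    else:
        out = slice_f
    return out, removed


def remove_periodic_noise(
    volume: Volume,
    max_peaks: int = 4,
    peak_factor: float = 8.0,
    notch_radius: int = 1,
    dc_guard: int = 3,
) -> tuple[Volume, PreprocessReport]:
    """Notch-suppress up to ``max_peaks`` narrow spectral peaks per slice.

    A peak qualifies when its magnitude exceeds ``peak_factor`` times the
    local (9×9 median) spectral floor, outside a guard disk around the zero
    frequency.  Only the notched bins are modified, so energy elsewhere is
    untouched; stripe-free slices pass through unchanged.
    """
    if volume.shape[1] < 16 or volume.shape[2] < 16:
        raise ValidationError(
            f"slices must be at least 16×16 for spectral notching, got {volume.shape[1:]}"
        )
    if max_peaks == 0:
        return volume.with_voxels(volume.voxels.copy(), note="destripe(max_peaks=0)"), (
            PreprocessReport(step="remove_periodic_noise")
        )
    vox = volume.voxels.astype(np.float64)
    out = np.empty_like(vox)
    removed_all: list[tuple[int, float]] = []
    for z in range(vox.shape[0]):
        out[z], removed = _notch_slice(vox[z], max_peaks, peak_factor, notch_radius, dc_guard)
        for fy, fx in removed:
            removed_all.append((z, float(np.hypot(fy, fx))))
    out = np.clip(np.rint(out), 0, volume.max_value).astype(volume.voxels.dtype)
    report = PreprocessReport(
        step="remove_periodic_noise", stripe_frequencies_removed=removed_all
    )
    return volume.with_voxels(out, note=f"destripe(max_peaks={max_peaks})"), report


def enhance_contrast(
    volume: Volume, p_low: float = 0.05, p_high: float = 99.95
) -> tuple[Volume, PreprocessReport]:
    """Global percentile stretch: value at ``p_low`` → 0, at ``p_high`` → bit max.

    The mapping is linear between the bounds and clipped outside, hence
    monotone non-decreasing.  A degenerate histogram (equal bounds) yields a
    constant mid-gray volume with a warning, never NaN.
    """
    if not (0 <= p_low < p_high <= 100):
        raise ValidationError(f"need 0 <= p_low < p_high <= 100, got ({p_low}, {p_high})")
    lo, hi = np.percentile(volume.voxels, [p_low, p_high])
    vmax = volume.max_value
    if hi <= lo:
        warnings.warn(
            "degenerate percentile bounds; returning constant mid-gray", stacklevel=2
        )
        out = np.full_like(volume.voxels, (vmax + 1) // 2)
    else:
        stretched = (volume.voxels.astype(np.float64) - lo) * (vmax / (hi - lo))
        out = np.clip(np.rint(stretched), 0, vmax).astype(volume.voxels.dtype)
    report = PreprocessReport(
        step="enhance_contrast", rescale_bounds=(float(lo), float(hi))
    )
    return volume.with_voxels(out, note=f"stretch(p={p_low},{p_high})"), report
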