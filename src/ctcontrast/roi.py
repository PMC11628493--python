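"""Circular ROI patches: mask construction and gray-value statistics.

Patches are 2D discs in a single z-slice, mirroring the interactive
workflow in which an annotator picks a homogeneous section per organ. The
patch size is reported as the circle *circumference* (0.20 mm for organ and
background patches; 6.00 mm for the fallback region used on scans where the
organs are not distinguishable). Because stating a circle by circumference
is an unusual convention, the conversion to a radius is switchable:

* ``"circumference"`` (default): r = C / (2π)
* ``"diameter"``: r = C / 2  (in case the stated value is actually a diameter)

Statistics are the arithmetic mean and *population* standard deviation of
the voxels under the mask, matching the histogram readout of interactive
imaging software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .io_volumes import GrayVolume, PatchAnnotation

__all__ = [
    "PatchSample",
    "patch_radius_voxels",
    "circular_patch_mask",
    "sample_patch",
    "bilateral_mean",
    "background_mean",
    "fallback_region_sample",
]

INTERPRETATIONS = ("circumference", "diameter")


@dataclass(frozen=True)
class PatchSample:
    """Gray-value statistics of one sampled patch."""

    organ: str
    side: str
    mean_gray: float
    sd_gray: float
    n_voxels: int
    slice_index: int
    fallback: bool = False

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if self.sd_gray < 0:
            raise ValueError("sd_gray must be non-negative")


def patch_radius_voxels(
    circumference_mm: float, voxel_size_um: float, interpretation: str = "circumference"
) -> float:
    """Convert a stated patch size to a radius in voxel units."""
    if interpretation == "circumference":
        r_mm = circumference_mm / (2.0 * math.pi)
    elif interpretation == "diameter":
        r_mm = circumference_mm / 2.0
    else:
        raise ValueError(
            f"unknown interpretation {interpretation!r}; expected one of {INTERPRETATIONS}"
        )
    return r_mm * 1000.0 / voxel_size_um


def circular_patch_mask(
    ann: PatchAnnotation,
    voxel_size_um: float,
    shape: tuple[int, int],
    interpretation: str = "circumference",
) -> np.ndarray:
    """Boolean disc mask over a (height, width) slice.

    A voxel (y, x) belongs to the patch when (y-cy)² + (x-cx)² <= r², with
    the radius computed in physical units and converted by the voxel size.
    """
    r = patch_radius_voxels(ann.circumference_mm, voxel_size_um, interpretation)
    if r < 1.0:
        raise ValueError(
            f"patch radius {r:.3f} voxels < 1 for circumference "
            f"{ann.circumference_mm} mm at {voxel_size_um} μm voxels; use the "
            f"'diameter' interpretation or a finer voxel size"
        )
    cy, cx = ann.center_yx
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def sample_patch(
    vol: GrayVolume, ann: PatchAnnotation, interpretation: str = "circumference"
) -> PatchSample:
    """Mean and population SD of the voxels under the patch disc.

    The disc must lie entirely inside the slice: a patch clipped by the
    volume boundary would bias the mean and is rejected.
    """
    nz, ny, nx = vol.shape
    if not 0 <= ann.slice_index < nz:
        raise ValueError(
            f"slice_index {ann.slice_index} outside volume depth {nz}"
        )
    r = patch_radius_voxels(ann.circumference_mm, vol.voxel_size_um, interpretation)
    cy, cx = ann.center_yx
    if cy - r < 0 or cy + r > ny - 1 or cx - r < 0 or cx + r > nx - 1:
        raise ValueError(
            f"patch for {ann.organ!r} (r={r:.2f} vox at y={cy}, x={cx}) is "
            f"clipped by the {ny}x{nx} slice boundary"
        )
    mask = circular_patch_mask(ann, vol.voxel_size_um, (ny, nx), interpretation)
    vals = vol.voxels[ann.slice_index][mask].astype(np.float64)
    return PatchSample(
        organ=ann.organ,
        side=ann.side,
        mean_gray=float(vals.mean()),
        sd_gray=float(vals.std(ddof=0)),
        n_voxels=int(vals.size),
        slice_index=ann.slice_index,
    )


def bilateral_mean(left: PatchSample, right: PatchSample | None = None) -> float:
    """Average a left/right patch pair into one organ mean μ_organ.

    A midline organ, which has only one sample, passes through unchanged.
    """
    if right is None:
        return left.mean_gray
    if left.organ != right.organ:
        raise ValueError(
            f"cannot average patches of different organs: {left.organ!r} vs {right.organ!r}"
        )
    return 0.5 * (left.mean_gray + right.mean_gray)


def background_mean(samples: list[PatchSample]) -> float:
    """Average exactly two background patches into μ_background."""
    if len(samples) != 2:
        raise ValueError(f"expected exactly 2 background patches, got {len(samples)}")
    for s in samples:
        if s.side != "background":
            raise ValueError(f"patch for {s.organ!r} has side {s.side!r}, not 'background'")
    return 0.5 * (samples[0].mean_gray + samples[1].mean_gray)


def fallback_region_sample(
    vol: GrayVolume, ann: PatchAnnotation, interpretation: str = "circumference"
) -> PatchSample:
    """Sample the large (6.00 mm circumference) fallback disc.

    Used on poorly contrasted scans where individual organs cannot be
    distinguished: one big region is placed where the organs would be.
    The emitted record carries ``fallback=True``.
    """
    return replace(sample_patch(vol, ann, interpretation), fallback=True)
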