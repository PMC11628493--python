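"""Reading and writing of grayscale/label volumes and patch annotations.

Conventions used throughout the package:

* Volumes are 3D arrays in ``(z, y, x)`` order; the slice index runs along
  ``z``. Reconstructed micro-CT exports are 16-bit grayscale TIFF stacks
  (pixel values 0–65535), either one multi-page file or a directory of
  per-slice files ordered lexicographically by file name.
* Coordinates are 0-based voxel indices; patch centers may be fractional.
* Voxel size is isotropic and given in micrometres.
* Label volumes share the geometry of their paired gray volume, use 0 for
  background, and carry a sidecar table mapping each label to a CNS organ
  name and its brain region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "PROTOCOLS",
    "BRAIN_REGIONS",
    "SIDES",
    "VolumeFormatError",
    "ScanMeta",
    "GrayVolume",
    "LabelVolume",
    "PatchAnnotation",
    "read_gray_volume",
    "write_gray_volume",
    "read_label_volume",
    "write_label_volume",
    "read_annotations",
    "write_annotations",
]

#: The three fixation + staining protocols compared by the pipeline.
PROTOCOLS = ("FORMALIN_BLUGOL", "ETOH_BLUGOL", "ETOH_I2E")

#: Brain regions used to group CNS organs in morphometry tables.
BRAIN_REGIONS = (
    "visual receptors",
    "visual neuropils",
    "protocerebrum",
    "deutocerebrum",
    "tritocerebrum",
    "tract",
)

#: Allowed values for the ``side`` field of a patch annotation.
SIDES = ("left", "right", "midline", "background")

_ANNOTATION_COLUMNS = (
    "organ",
    "side",
    "slice_index",
    "center_y",
    "center_x",
    "circumference_mm",
)


class VolumeFormatError(ValueError):
    """An on-disk volume violates the 16-bit grayscale stack format."""


@dataclass(frozen=True)
class ScanMeta:
    """Identity of one scan: specimen, staining protocol and duration."""

    specimen_id: str
    protocol: str
    staining_time_h: float

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(
                f"unknown protocol {self.protocol!r}; expected one of {PROTOCOLS}"
            )
        if not math.isfinite(self.staining_time_h) or self.staining_time_h < 0:
            raise ValueError("staining_time_h must be a non-negative number")


@dataclass
class GrayVolume:
    """A 3D 16-bit grayscale image with isotropic voxel size (μm)."""

    voxels: np.ndarray
    voxel_size_um: float
    meta: ScanMeta

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x), got ndim={self.voxels.ndim}")
        if self.voxels.dtype != np.uint16:
            raise ValueError(f"voxels must be uint16, got {self.voxels.dtype}")
        if min(self.voxels.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        if not (math.isfinite(self.voxel_size_um) and self.voxel_size_um > 0):
            raise ValueError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class LabelVolume:
    """Integer organ labels on the same grid as a paired :class:`GrayVolume`.

    ``organ_table`` maps each nonzero label to ``(organ name, brain region)``;
    0 is reserved for background (air, shell, unsegmented tissue).
    """

    labels: np.ndarray
    voxel_size_um: float
    organ_table: Mapping[int, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D (z, y, x)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer-valued, got {self.labels.dtype}")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        if not (math.isfinite(self.voxel_size_um) and self.voxel_size_um > 0):
            raise ValueError("voxel_size_um must be positive")
        if 0 in self.organ_table:
            raise ValueError("label 0 is reserved for background")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.organ_table)
        if missing:
            raise ValueError(f"labels without an organ_table entry: {sorted(missing)}")
        for label, (organ, region) in self.organ_table.items():
            if region not in BRAIN_REGIONS:
                raise ValueError(
                    f"label {label} ({organ}): unknown brain region {region!r}"
                )

    @property
    def present_labels(self) -> list[int]:
        return sorted(set(np.unique(self.labels).tolist()) - {0})


@dataclass(frozen=True)
class PatchAnnotation:
    """Placement of one circular ROI patch in a single z-slice.

    ``circumference_mm`` follows the reporting convention of the ROI
    workflow: the patch size is stated as the circle circumference (0.20 mm
    for organ/background patches, 6.00 mm for the fallback region).
    """

    organ: str
    side: str
    slice_index: int
    center_yx: tuple[float, float]
    circumference_mm: float

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}; expected one of {SIDES}")
        if not (math.isfinite(self.circumference_mm) and self.circumference_mm > 0):
            raise ValueError("circumference_mm must be positive")
        if len(self.center_yx) != 2:
            raise ValueError("center_yx must be a (y, x) pair")


def _read_tiff_pages(path: Path) -> np.ndarray:
    """Read one TIFF file, validating every page is 2D uint16 grayscale."""
    with tifffile.TiffFile(path) as tf:
        pages = []
        shape = None
        for i, page in enumerate(tf.pages):
            arr = page.asarray()
            if arr.ndim != 2:
                raise VolumeFormatError(
                    f"{path} page {i}: expected single-channel grayscale, "
                    f"got shape {arr.shape}"
                )
            if arr.dtype != np.uint16:
                raise VolumeFormatError(
                    f"{path} page {i}: expected 16-bit data, got {arr.dtype}"
                )
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise VolumeFormatError(
                    f"{path} page {i}: shape {arr.shape} inconsistent with "
                    f"page 0 shape {shape}"
                )
            pages.append(arr)
    if not pages:
        raise VolumeFormatError(f"{path}: TIFF contains no pages")
    return np.stack(pages, axis=0)


def read_gray_volume(path: str | Path, voxel_size_um: float, meta: ScanMeta) -> GrayVolume:
    """Read a 16-bit grayscale stack from a multi-page TIFF or a directory.

    A directory is read as one slice per ``*.tif``/``*.tiff`` file, ordered
    lexicographically by file name (the usual scanner-export convention).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such volume: {p}")
    if p.is_dir():
        files = sorted(
            f for f in p.iterdir() if f.suffix.lower() in (".tif", ".tiff")
        )
        if not files:
            raise VolumeFormatError(f"{p}: directory contains no .tif files")
        slices = [_read_tiff_pages(f) for f in files]
        shape = slices[0].shape[1:]
        for f, s in zip(files, slices):
            if s.shape[1:] != shape:
                raise VolumeFormatError(
                    f"{f}: slice shape {s.shape[1:]} inconsistent with "
                    f"{files[0]} shape {shape}"
                )
        voxels = np.concatenate(slices, axis=0)
    else:
        voxels = _read_tiff_pages(p)
    return GrayVolume(voxels=voxels, voxel_size_um=voxel_size_um, meta=meta)


def write_gray_volume(vol: GrayVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page 16-bit grayscale TIFF (lossless)."""
    p = Path(path)
    tifffile.imwrite(p, vol.voxels, photometric="minisblack")
    return p


def write_label_volume(
    labels: LabelVolume, tiff_path: str | Path, table_path: str | Path
) -> tuple[Path, Path]:
    """Write labels as a 16-bit TIFF stack plus a CSV organ table sidecar."""
    if labels.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("labels exceed the 16-bit range of the TIFF container")
    tp = Path(tiff_path)
    tifffile.imwrite(tp, labels.labels.astype(np.uint16), photometric="minisblack")
    rows = [
        {"label": label, "organ": organ, "region": region}
        for label, (organ, region) in sorted(labels.organ_table.items())
    ]
    cp = Path(table_path)
    pd.DataFrame(rows, columns=["label", "organ", "region"]).to_csv(cp, index=False)
    return tp, cp


def read_label_volume(
    tiff_path: str | Path, table_path: str | Path, voxel_size_um: float
) -> LabelVolume:
    """Read a label stack and its CSV organ table written by :func:`write_label_volume`."""
    grid = _read_tiff_pages(Path(tiff_path))
    table = pd.read_csv(table_path)
    for col in ("label", "organ", "region"):
        if col not in table.columns:
            raise ValueError(f"{table_path}: missing column {col!r}")
    organ_table = {
        int(r.label): (str(r.organ), str(r.region)) for r in table.itertuples()
    }
    return LabelVolume(
        labels=grid.astype(np.int64), voxel_size_um=voxel_size_um, organ_table=organ_table
    )


def read_annotations(path: str | Path) -> list[PatchAnnotation]:
    """Parse a patch-annotation CSV into :class:`PatchAnnotation` records.

    Expected header: ``organ, side, slice_index, center_y, center_x,
    circumference_mm``. Rows violating the type invariants are rejected
    with an error naming the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation column(s) {missing}")
    anns: list[PatchAnnotation] = []
    for i, row in df.iterrows():
        try:
            ann = PatchAnnotation(
                organ=str(row["organ"]),
                side=str(row["side"]),
                slice_index=int(row["slice_index"]),
                center_yx=(float(row["center_y"]), float(row["center_x"])),
                circumference_mm=float(row["circumference_mm"]),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
        anns.append(ann)
    return anns


def write_annotations(anns: Sequence[PatchAnnotation], path: str | Path) -> Path:
    """Write annotations to CSV in the layout :func:`read_annotations` expects."""
    rows = [
        {
            "organ": a.organ,
            "side": a.side,
            "slice_index": a.slice_index,
            "center_y": a.center_yx[0],
            "center_x": a.center_yx[1],
            "circumference_mm": a.circumference_mm,
        }
        for a in anns
    ]
    p = Path(path)
    pd.DataFrame(rows, columns=list(_ANNOTATION_COLUMNS)).to_csv(p, index=False)
    return p
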