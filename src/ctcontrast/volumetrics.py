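"""Morphometry of segmented CNS label volumes.

Per-organ volume (voxel count × voxel volume), surface area, percentage of
total brain volume, and brain-region sums, in the layout of a standard
segmentation report: one row per organ, grouped by brain region, with the
region's percentage repeated on each member row.

Two surface estimators are exposed because interactive segmentation
software rarely documents its method:

* ``"mesh"`` (default): area of the triangulated 0.5-isosurface of the
  binary mask (marching cubes). Preferred — face counting overestimates
  curved surfaces by up to ~50% (the staircase effect).
* ``"voxel_faces"``: exposed-face count × (voxel edge)²; an upper bound for
  reasonably smooth solids, kept for comparison with tools that report it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import measure

from .io_volumes import LabelVolume

__all__ = [
    "OrganMorphometry",
    "organ_volume",
    "organ_surface",
    "percent_table",
    "label_morphometry",
    "morphometry_frame",
    "load_reference_morphometry",
]

SURFACE_METHODS = ("mesh", "voxel_faces")


@dataclass(frozen=True)
class OrganMorphometry:
    """One organ row of the morphometry table (percentages unrounded)."""

    organ: str
    region: str
    surface_mm2: float  # NaN when no surface was computed
    volume_mm3: float
    pct_of_total: float
    region_pct: float


def _organ_mask(labels: LabelVolume, label: int) -> np.ndarray:
    mask = labels.labels == label
    if not mask.any():
        raise ValueError(
            f"label {label} absent from volume; present labels: {labels.present_labels}"
        )
    return mask


def organ_volume(labels: LabelVolume, label: int) -> float:
    """Volume in mm³: voxel count × (voxel edge in mm)³."""
    mask = _organ_mask(labels, label)
    edge_mm = labels.voxel_size_um * 1e-3
    return float(int(mask.sum()) * edge_mm**3)


def organ_surface(labels: LabelVolume, label: int, method: str = "mesh") -> float:
    """Surface area in mm² of one organ's binary mask."""
    mask = _organ_mask(labels, label)
    edge_mm = labels.voxel_size_um * 1e-3
    if method == "mesh":
        # light Gaussian anti-aliasing of the binary mask before meshing:
        # a raw 0/1 isosurface inherits the voxel staircase and overestimates
        # smooth surfaces by ~8%; sigma below one voxel removes that bias
        # without eroding structure at the scales segmented here
        smoothed = gaussian_filter(np.pad(mask, 3).astype(np.float32), sigma=0.8)
        verts, faces, _, _ = measure.marching_cubes(
            smoothed, level=0.5, spacing=(edge_mm,) * 3
        )
        return float(measure.mesh_surface_area(verts, faces))
    if method == "voxel_faces":
        m = mask.astype(np.int64)
        shared = sum(
            int(np.sum(m.take(range(1, m.shape[ax]), axis=ax)
                       & m.take(range(0, m.shape[ax] - 1), axis=ax)))
            for ax in range(3)
        )
        exposed = 6 * int(m.sum()) - 2 * shared
        return float(exposed * edge_mm**2)
    raise ValueError(f"unknown surface method {method!r}; expected one of {SURFACE_METHODS}")


def percent_table(
    volumes: Mapping[str, float],
    regions: Mapping[str, str],
    surfaces: Mapping[str, float] | None = None,
) -> list[OrganMorphometry]:
    """Percent-of-total and region sums from per-organ volumes.

    ``pct_of_total`` = 100 · volume / Σ volumes; ``region_pct`` is the sum
    of the member organs' percentages, repeated on each member row. Rows
    keep the input organ order. Values are unrounded — round only at
    presentation (2 decimals by convention).
    """
    if not volumes:
        raise ValueError("need at least one organ volume")
    missing = [o for o in volumes if o not in regions]
    if missing:
        raise ValueError(f"organs without a region assignment: {missing}")
    total = float(sum(volumes.values()))
    if total <= 0:
        raise ValueError("total volume must be positive")
    pct = {o: 100.0 * v / total for o, v in volumes.items()}
    region_pct = {}
    for o in volumes:
        region_pct.setdefault(regions[o], 0.0)
        region_pct[regions[o]] += pct[o]
    return [
        OrganMorphometry(
            organ=o,
            region=regions[o],
            surface_mm2=float(surfaces[o]) if surfaces and o in surfaces else float("nan"),
            volume_mm3=float(volumes[o]),
            pct_of_total=pct[o],
            region_pct=region_pct[regions[o]],
        )
        for o in volumes
    ]


def label_morphometry(
    labels: LabelVolume, surface_method: str = "mesh"
) -> list[OrganMorphometry]:
    """Full morphometry of every labelled organ in a segmentation."""
    vols, surfs, regions = {}, {}, {}
    for label in labels.present_labels:
        organ, region = labels.organ_table[label]
        vols[organ] = organ_volume(labels, label)
        surfs[organ] = organ_surface(labels, label, method=surface_method)
        regions[organ] = region
    return percent_table(vols, regions, surfaces=surfs)


def morphometry_frame(rows: Sequence[OrganMorphometry], round_to: int | None = None) -> pd.DataFrame:
    """Tabulate morphometry rows; ``round_to`` rounds for presentation."""
    df = pd.DataFrame(
        [
            {
                "region": r.region,
                "organ": r.organ,
                "surface_mm2": r.surface_mm2,
                "volume_mm3": r.volume_mm3,
                "pct_of_total": r.pct_of_total,
                "region_pct": r.region_pct,
            }
            for r in rows
        ]
    )
    if round_to is not None:
        for col in ("surface_mm2", "volume_mm3", "pct_of_total", "region_pct"):
            df[col] = df[col].round(round_to)
    return df


def load_reference_morphometry() -> pd.DataFrame:
    """Published reference morphometry of a snapping-shrimp CNS.

    Surface and volume of the 14 segmented CNS organs of an adult
    *Alpheus richardsoni* (formalin-fixed, stained 48 h with B-Lugol 1.25%,
    scanned at 2.1 μm). Columns: region, organ, abbreviation, surface_mm2,
    volume_mm3. Used as a worked input for :func:`percent_table`.
    """
    ref = importlib.resources.files("ctcontrast") / "data" / "shrimp_cns_morphometry.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
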