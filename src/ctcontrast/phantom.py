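"""Synthetic stained-specimen phantoms for pipeline validation.

The generator emulates a reconstructed micro-CT scan of an iodine-stained
shrimp: a bright calcified shell (ellipsoidal annulus), 14 soft-tissue CNS
organs placed as disjoint ellipsoids (bilateral pairs mirrored about the
sagittal midplane, three midline organs), and an air background with a small
positive scatter floor. Organ mean intensity follows a single-peaked uptake
curve in staining time, scaled per protocol, so that the downstream
contrast-ratio pipeline can be validated against known ground truth.
Homogeneous water/air volumes stand in for the calibration phantoms used
for Hounsfield-unit standardization.

The uptake kinetics are a deliberate idealisation::

    mean(organ, protocol, t) = baseline + scale[protocol] * amplitude[organ] * f(t)
    f(t) = (t / t_peak) * exp(1 - t / t_peak)

``f`` rises strictly from f(0)=0 to f(t_peak)=1 and declines strictly
afterwards — the simplest smooth saturate-then-overstain shape with one
interpretable parameter, the peak staining time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np

from .io_volumes import (
    BRAIN_REGIONS,
    PROTOCOLS,
    GrayVolume,
    LabelVolume,
    PatchAnnotation,
    ScanMeta,
)

__all__ = [
    "ORGAN_REGIONS",
    "MIDLINE_ORGANS",
    "UptakeParams",
    "OrganGeometry",
    "PhantomLayout",
    "uptake_mean",
    "generate_phantom",
    "generate_calibration_phantom",
    "default_layout",
    "default_uptake_params",
    "default_annotations",
]

#: The 14 segmented CNS organs and their brain regions.
ORGAN_REGIONS: dict[str, str] = {
    "retinula": "visual receptors",
    "rhabdom": "visual receptors",
    "lamina": "visual neuropils",
    "external_medulla": "visual neuropils",
    "lobula": "visual neuropils",
    "hemiellipsoid_body_neuropil": "protocerebrum",
    "terminal_medulla_neuropil": "protocerebrum",
    "anterior_medial_protocerebral_neuropil": "protocerebrum",
    "posterior_medial_protocerebral_neuropil": "protocerebrum",
    "olfactory_lobe": "deutocerebrum",
    "lateral_antennular_neuropil": "deutocerebrum",
    "median_antennular_neuropil": "deutocerebrum",
    "antenna_ii_neuropil": "tritocerebrum",
    "olfactory_globular_tract": "tract",
}

#: Unpaired organs on the sagittal midline; all others occur as L/R pairs.
MIDLINE_ORGANS = frozenset(
    {
        "anterior_medial_protocerebral_neuropil",
        "posterior_medial_protocerebral_neuropil",
        "median_antennular_neuropil",
    }
)

# Peak gray-value increments above baseline per organ (protocol scale 1.0).
# Chosen to span the dynamic range seen between weakly and strongly staining
# neuropils so that organs remain mutually discriminable (R_inter > 0).
_DEFAULT_AMPLITUDE: dict[str, float] = {
    "retinula": 9000.0,
    "rhabdom": 8000.0,
    "lamina": 5200.0,
    "external_medulla": 5600.0,
    "lobula": 4800.0,
    "hemiellipsoid_body_neuropil": 12000.0,
    "terminal_medulla_neuropil": 10000.0,
    "anterior_medial_protocerebral_neuropil": 7000.0,
    "posterior_medial_protocerebral_neuropil": 6600.0,
    "olfactory_lobe": 11000.0,
    "lateral_antennular_neuropil": 6200.0,
    "median_antennular_neuropil": 4400.0,
    "antenna_ii_neuropil": 7600.0,
    "olfactory_globular_tract": 4000.0,
}


@dataclass(frozen=True)
class UptakeParams:
    """Parameters of the staining-uptake model and of image formation.

    All gray values are on the raw 16-bit scale. ``protocol_scale`` encodes
    the qualitative protocol ranking (buffered aqueous iodine after formalin
    fixation stains strongest; alcoholic iodine is far weaker); ``noise_sd``
    is per tissue class (air / soft_tissue / shell / water).
    """

    baseline_gray: float = 8000.0
    air_gray: float = 800.0
    shell_gray: float = 30000.0
    water_gray: float = 10000.0
    t_peak_h: float = 48.0
    amplitude: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AMPLITUDE)
    )
    protocol_scale: Mapping[str, float] = field(
        default_factory=lambda: {
            "FORMALIN_BLUGOL": 1.0,
            "ETOH_BLUGOL": 0.85,
            "ETOH_I2E": 0.25,
        }
    )
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "air": 50.0,
            "soft_tissue": 400.0,
            "shell": 800.0,
            "water": 50.0,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.air_gray <= 0:
            raise ValueError("air_gray must be > 0 (contrast-ratio denominator)")
        if self.t_peak_h <= 0:
            raise ValueError("t_peak_h must be positive")
        for organ, amp in self.amplitude.items():
            if amp <= 0:
                raise ValueError(f"amplitude for {organ!r} must be positive")
        if self.amplitude and self.baseline_gray + max(self.amplitude.values()) > 65535:
            raise ValueError("baseline_gray + max amplitude exceeds the 16-bit range")
        for proto, s in self.protocol_scale.items():
            if not 0 < s <= 1:
                raise ValueError(f"protocol_scale[{proto!r}] must lie in (0, 1]")
        for cls, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{cls!r}] must be non-negative")

    def with_seed(self, seed: int) -> "UptakeParams":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class OrganGeometry:
    """One organ's ellipsoid: center (left lobe for bilateral organs) and
    semi-axes in voxel units. The right lobe of a bilateral organ is the
    mirror image about the sagittal midplane x = (W-1)/2."""

    center_zyx: tuple[float, float, float]
    semi_axes_zyx: tuple[float, float, float]
    bilateral: bool


@dataclass(frozen=True)
class PhantomLayout:
    """Geometry of the synthetic specimen within the volume grid."""

    shape: tuple[int, int, int]
    voxel_size_um: float
    organs: tuple[tuple[str, OrganGeometry], ...]
    shell_inner_frac: float = 0.425
    shell_outer_frac: float = 0.47
    background_zyx: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 8:
            raise ValueError("shape must be a triple of integers >= 8")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if not 0 < self.shell_inner_frac < self.shell_outer_frac <= 0.5:
            raise ValueError("need 0 < shell_inner_frac < shell_outer_frac <= 0.5")

    def mirror_x(self, x: float) -> float:
        return (self.shape[2] - 1) - x

    def organ_lobes(self, organ: str) -> list[tuple[str, tuple[float, float, float]]]:
        """Centers of the organ's lobes as ``(side, (z, y, x))`` pairs."""
        geom = dict(self.organs)[organ]
        cz, cy, cx = geom.center_zyx
        if geom.bilateral:
            return [("left", (cz, cy, cx)), ("right", (cz, cy, self.mirror_x(cx)))]
        return [("midline", (cz, cy, cx))]


def uptake_mean(organ: str, protocol: str, t_h: float, params: UptakeParams) -> float:
    """Expected gray value of ``organ`` after ``t_h`` hours of staining."""
    if organ not in params.amplitude:
        raise KeyError(f"unknown organ {organ!r}")
    if protocol not in params.protocol_scale:
        raise KeyError(f"unknown protocol {protocol!r}")
    if t_h < 0:
        raise ValueError("staining time must be non-negative")
    u = t_h / params.t_peak_h
    f = u * math.exp(1.0 - u)
    return params.baseline_gray + params.protocol_scale[protocol] * params.amplitude[organ] * f


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    semi_axes: tuple[float, float, float],
) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    az, ay, ax = semi_axes
    return (
        ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    ) <= 1.0


# Tissue-class codes used internally when assembling the intensity field.
_AIR, _SOFT, _SHELL = 0, 1, 2


@lru_cache(maxsize=8)
def _build_grids(layout: PhantomLayout) -> tuple[np.ndarray, np.ndarray, dict[int, str]]:
    """Rasterise a layout once: (label grid, tissue-class grid, label->organ).

    Labels are 1..n_organs in layout order; both lobes of a bilateral organ
    share one label, matching the single-row-per-organ morphometry
    convention. Raises if any two structures overlap.
    """
    shape = layout.shape
    cz, cy, cx = ((d - 1) / 2.0 for d in shape)
    outer = tuple(layout.shell_outer_frac * (d - 1) for d in shape)
    inner = tuple(layout.shell_inner_frac * (d - 1) for d in shape)
    shell = _ellipsoid_mask(shape, (cz, cy, cx), outer) & ~_ellipsoid_mask(
        shape, (cz, cy, cx), inner
    )

    labels = np.zeros(shape, dtype=np.uint16)
    tissue = np.zeros(shape, dtype=np.uint8)
    tissue[shell] = _SHELL
    label_names: dict[int, str] = {}
    for i, (organ, geom) in enumerate(layout.organs, start=1):
        mask = np.zeros(shape, dtype=bool)
        for _side, center in layout.organ_lobes(organ):
            mask |= _ellipsoid_mask(shape, center, geom.semi_axes_zyx)
        if (mask & (tissue != _AIR)).any() or (mask & (labels != 0)).any():
            raise ValueError(f"layout overlap: organ {organ!r} intersects another structure")
        labels[mask] = i
        tissue[mask] = _SOFT
        label_names[i] = organ
    return labels, tissue, label_names


def generate_phantom(
    layout: PhantomLayout, meta: ScanMeta, params: UptakeParams
) -> tuple[GrayVolume, LabelVolume]:
    """Render one synthetic stained scan plus its ground-truth labels.

    Each voxel is drawn from a normal law centred on its structure's mean
    (organ uptake / shell / air scatter floor) with the tissue-class noise
    SD, then clipped to [0, 65535] and rounded to the 16-bit grid. The same
    seed and inputs always give bit-identical output.
    """
    labels, tissue, label_names = _build_grids(layout)

    means = np.full(layout.shape, params.air_gray, dtype=np.float64)
    means[tissue == _SHELL] = params.shell_gray
    for label, organ in label_names.items():
        m = uptake_mean(organ, meta.protocol, meta.staining_time_h, params)
        if not 0 <= m <= 65535:
            raise ValueError(
                f"mean gray {m:.1f} for organ {organ!r} falls outside the 16-bit range"
            )
        means[labels == label] = m

    sds = np.empty(layout.shape, dtype=np.float64)
    sds[tissue == _AIR] = params.noise_sd["air"]
    sds[tissue == _SOFT] = params.noise_sd["soft_tissue"]
    sds[tissue == _SHELL] = params.noise_sd["shell"]

    rng = np.random.default_rng(params.seed)
    raw = rng.normal(means, sds)
    voxels = np.clip(np.rint(raw), 0, 65535).astype(np.uint16)

    organ_table = {
        label: (organ, ORGAN_REGIONS.get(organ, "tract"))
        for label, organ in label_names.items()
    }
    gray = GrayVolume(voxels=voxels, voxel_size_um=layout.voxel_size_um, meta=meta)
    lab = LabelVolume(
        labels=labels.astype(np.int64),
        voxel_size_um=layout.voxel_size_um,
        organ_table=organ_table,
    )
    return gray, lab


def generate_calibration_phantom(
    kind: str, layout: PhantomLayout, params: UptakeParams
) -> GrayVolume:
    """Render a homogeneous water or air reference volume (seeded noise)."""
    if kind == "water":
        mean, sd = params.water_gray, params.noise_sd["water"]
    elif kind == "air":
        mean, sd = params.air_gray, params.noise_sd["air"]
    else:
        raise ValueError(f"unknown calibration phantom kind {kind!r}")
    rng = np.random.default_rng(params.seed)
    raw = rng.normal(mean, sd, size=layout.shape)
    voxels = np.clip(np.rint(raw), 0, 65535).astype(np.uint16)
    meta = ScanMeta(specimen_id=f"{kind}_phantom", protocol=PROTOCOLS[0], staining_time_h=0.0)
    return GrayVolume(voxels=voxels, voxel_size_um=layout.voxel_size_um, meta=meta)


def default_uptake_params(seed: int = 0) -> UptakeParams:
    """Default staining-model parameters (peak at 48 h)."""
    return UptakeParams(seed=seed)


def default_layout(
    shape: tuple[int, int, int] = (160, 160, 160), voxel_size_um: float = 10.0
) -> PhantomLayout:
    """Desk-scale specimen layout: 14 organs on a regular grid inside the shell.

    Organ positions and sizes scale with ``shape`` so the same anatomy can be
    rendered at reduced resolution for quick tests. The default 160-voxel
    cube at 10 μm (a 1.6 mm field of view) keeps full runs fast while leaving
    every 0.20 mm patch comfortably inside its organ.
    """
    nz, ny, nx = shape
    z_levels = [f * (nz - 1) for f in (0.28, 0.425, 0.57, 0.71)]
    y_levels = [f * (ny - 1) for f in (0.31, 0.5, 0.69)]
    slots = [(z, y) for z in z_levels for y in y_levels]  # 12 grid slots
    x_left = 0.34 * (nx - 1)
    x_mid = (nx - 1) / 2.0
    semi = max(3.0, round(0.045 * min(shape), 1))
    axes = (semi, semi, semi)

    bilateral = [o for o in ORGAN_REGIONS if o not in MIDLINE_ORGANS]
    midline = [o for o in ORGAN_REGIONS if o in MIDLINE_ORGANS]
    organs: list[tuple[str, OrganGeometry]] = []
    for organ, (z, y) in zip(bilateral, slots):
        organs.append(
            (organ, OrganGeometry(center_zyx=(z, y, x_left), semi_axes_zyx=axes, bilateral=True))
        )
    for organ, (z, y) in zip(midline, slots):
        organs.append(
            (organ, OrganGeometry(center_zyx=(z, y, x_mid), semi_axes_zyx=axes, bilateral=False))
        )
    # two background sampling points in interior air on the midline column
    background = (
        (slots[4][0], slots[4][1], x_mid),
        (slots[7][0], slots[7][1], x_mid),
    )
    return PhantomLayout(
        shape=tuple(int(d) for d in shape),
        voxel_size_um=float(voxel_size_um),
        organs=tuple(organs),
        background_zyx=background,
    )


def default_annotations(
    layout: PhantomLayout, circumference_mm: float = 0.20
) -> list[PatchAnnotation]:
    """Patch annotations at every organ-lobe center plus two background patches."""
    anns: list[PatchAnnotation] = []
    for organ, _geom in layout.organs:
        for side, (cz, cy, cx) in layout.organ_lobes(organ):
            anns.append(
                PatchAnnotation(
                    organ=organ,
                    side=side,
                    slice_index=int(round(cz)),
                    center_yx=(cy, cx),
                    circumference_mm=circumference_mm,
                )
            )
    for cz, cy, cx in layout.background_zyx:
        anns.append(
            PatchAnnotation(
                organ="background",
                side="background",
                slice_index=int(round(cz)),
                center_yx=(cy, cx),
                circumference_mm=circumference_mm,
            )
        )
    return anns
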