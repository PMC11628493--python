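"""End-to-end orchestration: simulate → sample → contrast → calibrate → stats → volumes.

A single :class:`RunConfig` (usually loaded from YAML) drives every stage;
all randomness derives from one seed, so identical config + seed gives
byte-identical outputs. Each stage writes plain CSV/JSON into the run
directory, and a manifest records the seed, a hash of the configuration
and every file produced. Stage failures abort with the stage name.

In simulate mode the phantom generator provides the scans; otherwise the
config lists existing volumes with their annotations and metadata, and the
same downstream stages apply.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contrast import ContrastRecord, build_record, peak_staining_time, records_to_frame
from .group_stats import dunn_bh, kruskal_wallis
from .hu_calibration import EPS_HU, fit_calibration, to_hu
from .io_volumes import (
    GrayVolume,
    ScanMeta,
    read_annotations,
    read_gray_volume,
    read_label_volume,
    write_annotations,
    write_gray_volume,
    write_label_volume,
)
from .phantom import (
    UptakeParams,
    default_annotations,
    default_layout,
    generate_calibration_phantom,
    generate_phantom,
)
from .roi import PatchSample, background_mean, bilateral_mean, sample_patch
from .volumetrics import label_morphometry, morphometry_frame

__all__ = [
    "RunConfig",
    "PhantomConfig",
    "ScanInput",
    "PipelineError",
    "load_config",
    "run_pipeline",
    "samples_to_frame",
    "frame_to_samples",
    "organ_means_from_samples",
    "phantom_contrast_series",
]

logger = logging.getLogger(__name__)

_SAMPLE_COLUMNS = [
    "specimen",
    "protocol",
    "time_h",
    "organ",
    "side",
    "mean_gray",
    "sd_gray",
    "n_voxels",
    "slice_index",
    "fallback",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PhantomConfig:
    """Simulation settings: grid, protocols, staining times, model overrides."""

    shape: tuple[int, int, int] = (160, 160, 160)
    voxel_size_um: float = 10.0
    protocols: tuple[str, ...] = ("FORMALIN_BLUGOL", "ETOH_BLUGOL", "ETOH_I2E")
    times_h: tuple[float, ...] = (0.0, 12.0, 24.0, 48.0, 72.0, 96.0)
    params: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class ScanInput:
    """One pre-existing scan: volume + annotations + identity."""

    volume: Path
    annotations: Path
    specimen_id: str
    protocol: str
    staining_time_h: float
    voxel_size_um: float


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    interpretation: str = "circumference"
    hu_convention: str = "air0"
    stats_time_h: float = 48.0
    surface_method: str = "mesh"
    calibrate: bool = True
    volumes: bool = True
    phantom: PhantomConfig | None = None
    scans: tuple[ScanInput, ...] = ()
    labels_tiff: Path | None = None
    organ_table_csv: Path | None = None
    labels_voxel_size_um: float | None = None

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        if d.get("scans"):
            d["scans"] = [
                {k: (str(v) if isinstance(v, Path) else v) for k, v in s.items()}
                for s in d["scans"]
            ]
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    phantom = None
    if "phantom" in raw and raw["phantom"] is not None:
        ph = dict(raw["phantom"])
        if "shape" in ph:
            ph["shape"] = tuple(int(d) for d in ph["shape"])
        if "protocols" in ph:
            ph["protocols"] = tuple(ph["protocols"])
        if "times_h" in ph:
            ph["times_h"] = tuple(float(t) for t in ph["times_h"])
        phantom = PhantomConfig(**ph)
    scans = tuple(
        ScanInput(
            volume=Path(s["volume"]),
            annotations=Path(s["annotations"]),
            specimen_id=str(s["specimen_id"]),
            protocol=str(s["protocol"]),
            staining_time_h=float(s["staining_time_h"]),
            voxel_size_um=float(s["voxel_size_um"]),
        )
        for s in raw.get("scans", [])
    )
    return RunConfig(
        out_dir=Path(raw["out_dir"]),
        seed=int(raw.get("seed", 0)),
        interpretation=raw.get("interpretation", "circumference"),
        hu_convention=raw.get("hu_convention", "air0"),
        stats_time_h=float(raw.get("stats_time_h", 48.0)),
        surface_method=raw.get("surface_method", "mesh"),
        calibrate=bool(raw.get("calibrate", True)),
        volumes=bool(raw.get("volumes", True)),
        phantom=phantom,
        scans=scans,
        labels_tiff=Path(raw["labels_tiff"]) if raw.get("labels_tiff") else None,
        organ_table_csv=Path(raw["organ_table_csv"]) if raw.get("organ_table_csv") else None,
        labels_voxel_size_um=(
            float(raw["labels_voxel_size_um"]) if raw.get("labels_voxel_size_um") else None
        ),
    )


def samples_to_frame(samples: Sequence[PatchSample], meta: ScanMeta) -> pd.DataFrame:
    rows = [
        {
            "specimen": meta.specimen_id,
            "protocol": meta.protocol,
            "time_h": meta.staining_time_h,
            "organ": s.organ,
            "side": s.side,
            "mean_gray": s.mean_gray,
            "sd_gray": s.sd_gray,
            "n_voxels": s.n_voxels,
            "slice_index": s.slice_index,
            "fallback": s.fallback,
        }
        for s in samples
    ]
    return pd.DataFrame(rows, columns=_SAMPLE_COLUMNS)


def frame_to_samples(df: pd.DataFrame) -> tuple[list[PatchSample], ScanMeta]:
    meta = ScanMeta(
        specimen_id=str(df["specimen"].iloc[0]),
        protocol=str(df["protocol"].iloc[0]),
        staining_time_h=float(df["time_h"].iloc[0]),
    )
    samples = [
        PatchSample(
            organ=str(r.organ),
            side=str(r.side),
            mean_gray=float(r.mean_gray),
            sd_gray=float(r.sd_gray),
            n_voxels=int(r.n_voxels),
            slice_index=int(r.slice_index),
            fallback=bool(r.fallback),
        )
        for r in df.itertuples()
    ]
    return samples, meta


def organ_means_from_samples(
    samples: Sequence[PatchSample],
) -> tuple[dict[str, float], float]:
    """Collapse patch samples to (organ → μ_organ, μ_background).

    Left/right pairs are averaged; midline organs pass through; the two
    background patches are averaged into μ_background.
    """
    background = [s for s in samples if s.side == "background"]
    mu_bg = background_mean(background)
    organ_means: dict[str, float] = {}
    organs = {s.organ for s in samples if s.side != "background"}
    for organ in sorted(organs):
        sides = {s.side: s for s in samples if s.organ == organ}
        if "left" in sides or "right" in sides:
            if not ("left" in sides and "right" in sides):
                raise ValueError(f"organ {organ!r}: bilateral organ needs both sides")
            organ_means[organ] = bilateral_mean(sides["left"], sides["right"])
        elif "midline" in sides:
            organ_means[organ] = bilateral_mean(sides["midline"])
        else:
            raise ValueError(f"organ {organ!r}: no usable patch side")
    return organ_means, mu_bg


def _scan_seed(base_seed: int, index: int) -> int:
    # per-scan substream, kept below 2**31 for portability
    return int(np.random.default_rng([base_seed, index]).integers(0, 2**31 - 1))


def phantom_contrast_series(
    protocol: str,
    times_h: Sequence[float],
    layout=None,
    params: UptakeParams | None = None,
    seed: int = 0,
    interpretation: str = "circumference",
) -> list[tuple[float, float]]:
    """Simulate one staining time course and measure the mean contrast ratio.

    Runs the full measurement chain in memory — render the phantom at each
    staining duration, sample every annotated patch, average bilateral
    pairs and the two background patches, form contrast ratios — and
    returns ``(time_h, mean_R)`` pairs ready for peak detection. Each scan
    uses an independent noise substream derived from ``seed``.
    """
    layout = default_layout() if layout is None else layout
    params = UptakeParams() if params is None else params
    anns = default_annotations(layout)
    series: list[tuple[float, float]] = []
    for i, t in enumerate(times_h):
        meta = ScanMeta(
            specimen_id=f"SIM_{protocol}", protocol=protocol, staining_time_h=float(t)
        )
        gray, _ = generate_phantom(layout, meta, params.with_seed(_scan_seed(seed, i)))
        samples = [sample_patch(gray, a, interpretation) for a in anns]
        organ_means, mu_bg = organ_means_from_samples(samples)
        series.append((float(t), build_record(organ_means, mu_bg, meta).mean_R))
    return series


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every configured stage; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": [],
        "stage_seconds": {},
    }
    cfg_dump = yaml.safe_dump(manifest["config"], sort_keys=True)
    manifest["config_sha256"] = hashlib.sha256(cfg_dump.encode()).hexdigest()

    def record(path: Path) -> Path:
        manifest["outputs"].append(str(path))
        return path

    scans: list[tuple[GrayVolume, Path]] = []  # (volume, annotations csv)
    label_volume = None
    params = None

    t0 = time.perf_counter()
    try:
        if config.phantom is not None:
            ph = config.phantom
            layout = default_layout(shape=ph.shape, voxel_size_um=ph.voxel_size_um)
            params = UptakeParams(**ph.params) if ph.params else UptakeParams()
            ann_path = record(write_annotations(default_annotations(layout), out / "annotations.csv"))
            idx = 0
            for protocol in ph.protocols:
                for t in ph.times_h:
                    meta = ScanMeta(
                        specimen_id=f"SIM_{protocol}", protocol=protocol, staining_time_h=t
                    )
                    p = params.with_seed(_scan_seed(config.seed, idx))
                    gray, labels = generate_phantom(layout, meta, p)
                    vol_path = out / f"sim_{protocol}_t{t:g}.tif"
                    record(write_gray_volume(gray, vol_path))
                    scans.append((gray, ann_path))
                    if label_volume is None:
                        label_volume = labels
                        tp, cp = write_label_volume(
                            labels, out / "labels.tif", out / "organ_table.csv"
                        )
                        record(tp), record(cp)
                    idx += 1
            truth = out / "phantom_truth.json"
            truth.write_text(
                json.dumps(
                    {
                        "t_peak_h": params.t_peak_h,
                        "protocol_scale": dict(params.protocol_scale),
                        "amplitude": dict(params.amplitude),
                        "baseline_gray": params.baseline_gray,
                        "air_gray": params.air_gray,
                        "water_gray": params.water_gray,
                    },
                    indent=2,
                )
            )
            record(truth)
        for s in config.scans:
            meta = ScanMeta(
                specimen_id=s.specimen_id,
                protocol=s.protocol,
                staining_time_h=s.staining_time_h,
            )
            scans.append((read_gray_volume(s.volume, s.voxel_size_um, meta), s.annotations))
        if not scans:
            raise ValueError("nothing to do: no phantom section and no scans listed")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("simulate", exc) from exc
    manifest["stage_seconds"]["simulate"] = round(time.perf_counter() - t0, 3)

    # ---- sample ----
    t0 = time.perf_counter()
    try:
        per_scan_samples: list[tuple[list[PatchSample], ScanMeta]] = []
        for i, (vol, ann_path) in enumerate(scans):
            anns = read_annotations(ann_path)
            samples = [sample_patch(vol, a, config.interpretation) for a in anns]
            per_scan_samples.append((samples, vol.meta))
            sp = out / f"samples_{i:03d}_{vol.meta.specimen_id}_t{vol.meta.staining_time_h:g}.csv"
            samples_to_frame(samples, vol.meta).to_csv(sp, index=False)
            record(sp)
    except Exception as exc:
        raise PipelineError("sample", exc) from exc
    manifest["stage_seconds"]["sample"] = round(time.perf_counter() - t0, 3)

    # ---- contrast ----
    t0 = time.perf_counter()
    try:
        records: list[ContrastRecord] = []
        for samples, meta in per_scan_samples:
            organ_means, mu_bg = organ_means_from_samples(samples)
            records.append(build_record(organ_means, mu_bg, meta))
        rec_path = out / "contrast_records.csv"
        records_to_frame(records).to_csv(rec_path, index=False)
        record(rec_path)
        peaks = {}
        for protocol in sorted({r.meta.protocol for r in records}):
            series = sorted(
                (r.meta.staining_time_h, r.mean_R)
                for r in records
                if r.meta.protocol == protocol
            )
            if len(series) >= 2:
                pk = peak_staining_time(series)
                peaks[protocol] = {
                    "peak_time_h": pk.time_h,
                    "peak_mean_R": pk.mean_R,
                    "no_decline": pk.no_decline,
                }
        peak_path = out / "peak_summary.json"
        peak_path.write_text(json.dumps(peaks, indent=2))
        record(peak_path)
        manifest["peak_summary"] = peaks
    except Exception as exc:
        raise PipelineError("contrast", exc) from exc
    manifest["stage_seconds"]["contrast"] = round(time.perf_counter() - t0, 3)

    # ---- calibrate (simulate mode only: needs a water phantom) ----
    t0 = time.perf_counter()
    if config.calibrate and config.phantom is not None and params is not None:
        try:
            layout = default_layout(
                shape=config.phantom.shape, voxel_size_um=config.phantom.voxel_size_um
            )
            water = generate_calibration_phantom(
                "water", layout, params.with_seed(_scan_seed(config.seed, 10_001))
            )
            air = generate_calibration_phantom(
                "air", layout, params.with_seed(_scan_seed(config.seed, 10_002))
            )
            water_mean = float(water.voxels.mean())
            air_mean = float(air.voxels.mean())
            model = fit_calibration(air_mean, water_mean, convention=config.hu_convention)
            cal_path = out / "calibration.json"
            cal_path.write_text(
                json.dumps(
                    {
                        "convention": model.convention,
                        "air_gray": model.air_gray,
                        "water_gray": model.water_gray,
                        "slope": model.slope,
                        "intercept": model.intercept,
                        "hu_at_water_mean": to_hu(water_mean, model),
                        "hu_at_air_mean": to_hu(air_mean, model),
                    },
                    indent=2,
                )
            )
            record(cal_path)
            # HU-standardized organ means at the comparison time point
            hu_rows = []
            for samples, meta in per_scan_samples:
                if meta.staining_time_h != config.stats_time_h:
                    continue
                organ_means, mu_bg = organ_means_from_samples(samples)
                bg_hu = to_hu(mu_bg, model)
                for organ, mu in organ_means.items():
                    organ_hu = to_hu(mu, model)
                    ratio = (
                        (organ_hu - bg_hu) / bg_hu if abs(bg_hu) > EPS_HU else float("nan")
                    )
                    hu_rows.append(
                        {
                            "specimen": meta.specimen_id,
                            "protocol": meta.protocol,
                            "time_h": meta.staining_time_h,
                            "organ": organ,
                            "organ_hu": organ_hu,
                            "background_hu": bg_hu,
                            "hu_R": ratio,
                        }
                    )
            hu_path = out / "hu_records.csv"
            pd.DataFrame(hu_rows).to_csv(hu_path, index=False)
            record(hu_path)
        except Exception as exc:
            raise PipelineError("calibrate", exc) from exc
    manifest["stage_seconds"]["calibrate"] = round(time.perf_counter() - t0, 3)

    # ---- stats ----
    t0 = time.perf_counter()
    try:
        groups: dict[str, list[float]] = {}
        for r in records:
            if r.meta.staining_time_h == config.stats_time_h:
                groups.setdefault(r.meta.protocol, []).extend(r.per_organ_R.values())
        if len(groups) >= 2:
            h, p = kruskal_wallis(groups)
            pairwise = dunn_bh(groups)
            stats_path = out / "pairwise_stats.csv"
            pd.DataFrame(
                [
                    {
                        "group_a": r.group_a,
                        "group_b": r.group_b,
                        "z": r.z,
                        "p_raw": r.p_raw,
                        "p_adjusted": r.p_adjusted,
                    }
                    for r in pairwise
                ]
            ).to_csv(stats_path, index=False)
            record(stats_path)
            summary = out / "stats_summary.txt"
            lines = [
                f"Kruskal-Wallis (per-organ R at t={config.stats_time_h:g} h): "
                f"H = {h:.4f}, p = {p:.4g}",
            ] + [
                f"{r.group_a} vs {r.group_b}: Z = {r.z:.3f}, p_raw = {r.p_raw:.4g}, "
                f"p_adjusted = {r.p_adjusted:.4g}"
                for r in pairwise
            ]
            summary.write_text("\n".join(lines) + "\n")
            record(summary)
            manifest["kruskal_wallis"] = {"H": h, "p": p}
    except Exception as exc:
        raise PipelineError("stats", exc) from exc
    manifest["stage_seconds"]["stats"] = round(time.perf_counter() - t0, 3)

    # ---- volumes ----
    t0 = time.perf_counter()
    try:
        if config.volumes:
            if label_volume is None and config.labels_tiff is not None:
                label_volume = read_label_volume(
                    config.labels_tiff,
                    config.organ_table_csv,
                    config.labels_voxel_size_um,
                )
            if label_volume is not None:
                rows = label_morphometry(label_volume, surface_method=config.surface_method)
                vol_path = out / "morphometry.csv"
                morphometry_frame(rows).to_csv(vol_path, index=False)
                record(vol_path)
    except Exception as exc:
        raise PipelineError("volumes", exc) from exc
    manifest["stage_seconds"]["volumes"] = round(time.perf_counter() - t0, 3)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
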