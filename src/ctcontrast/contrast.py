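"""Contrast-ratio statistics and staining-time optimisation.

Two dimensionless statistics quantify soft-tissue discriminability in a
stained scan, both computed from ROI mean gray values μ:

* per-organ contrast ratio            R = (μ_organ − μ_background) / μ_background
* inter-organ contrast ratio    R_inter = (max μ_organ − min μ_organ) / min μ_organ

R measures how well an organ separates from the (air) background; R_inter
measures how well organs separate from each other, irrespective of the
background. Both are invariant under rescaling of all gray values, so they
can be compared across scans acquired with different exposure settings.

Assembled over a staining time course, the organ-averaged R rises to a peak
(optimal staining) and declines afterwards (overstaining: all tissues
approach iodine saturation and contrast between them collapses). Peak
detection is a discrete argmax over the sampled durations — the protocol
comparison only ever considers the scanned time points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_volumes import ScanMeta

__all__ = [
    "EPS_GRAY",
    "ContrastRecord",
    "PeakResult",
    "contrast_ratio",
    "inter_organ_ratio",
    "build_record",
    "peak_staining_time",
    "records_to_frame",
]

#: Smallest |μ_background| considered non-degenerate, in gray units.
EPS_GRAY = 1.0


def contrast_ratio(mu_organ: float, mu_background: float, eps: float = EPS_GRAY) -> float:
    """Per-organ contrast ratio R = (μ_organ − μ_background) / μ_background."""
    if abs(mu_background) <= eps:
        raise ValueError(
            f"degenerate background mean {mu_background!r} (|μ| <= {eps}): "
            f"the contrast ratio is ill-conditioned"
        )
    return (mu_organ - mu_background) / mu_background


def inter_organ_ratio(mus: Mapping[str, float], eps: float = EPS_GRAY) -> float:
    """Inter-organ contrast ratio R_inter = (max μ − min μ) / min μ."""
    if not mus:
        raise ValueError("need at least one organ mean")
    lo = min(mus.values())
    hi = max(mus.values())
    if lo <= eps:
        raise ValueError(f"minimum organ mean {lo!r} <= {eps}: R_inter is ill-conditioned")
    return (hi - lo) / lo


@dataclass(frozen=True)
class ContrastRecord:
    """Per-scan contrast summary: R per organ, R_inter, and the organ-wise
    mean ± SD of R (the quantities plotted against staining time)."""

    meta: ScanMeta
    per_organ_R: Mapping[str, float]
    R_inter: float
    mean_R: float
    sd_R: float


def build_record(
    organ_means: Mapping[str, float], mu_background: float, meta: ScanMeta
) -> ContrastRecord:
    """Aggregate one scan's organ means into a :class:`ContrastRecord`.

    Organs absent from a scan are simply absent from the record; mean_R and
    sd_R (population SD) run over whatever organs were measured.
    """
    per_organ = {
        organ: contrast_ratio(mu, mu_background) for organ, mu in organ_means.items()
    }
    rs = np.array(list(per_organ.values()), dtype=float)
    return ContrastRecord(
        meta=meta,
        per_organ_R=per_organ,
        R_inter=inter_organ_ratio(organ_means),
        mean_R=float(rs.mean()),
        sd_R=float(rs.std(ddof=0)),
    )


@dataclass(frozen=True)
class PeakResult:
    """Outcome of peak-staining-time detection over a time course.

    ``no_decline`` is set when the maximum sits at the last sampled time,
    i.e. no post-peak decline was observed within the series.
    """

    time_h: float
    mean_R: float
    no_decline: bool


def peak_staining_time(series: Sequence[tuple[float, float]]) -> PeakResult:
    """Staining duration with the maximal organ-averaged contrast ratio.

    ``series`` is a list of ``(time_h, mean_R)`` pairs with strictly
    increasing times. Ties resolve to the earliest time (the shorter
    staining duration is always preferred at equal contrast).
    """
    if len(series) < 2:
        raise ValueError("need at least two time points")
    times = [t for t, _ in series]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")
    values = [v for _, v in series]
    if any(not math.isfinite(v) for v in values):
        raise ValueError("mean_R values must be finite")
    idx = int(np.argmax(values))  # argmax takes the first maximum: earliest tie
    return PeakResult(
        time_h=times[idx], mean_R=values[idx], no_decline=idx == len(series) - 1
    )


def records_to_frame(records: Sequence[ContrastRecord]) -> pd.DataFrame:
    """Long-format table of records: one row per (scan, organ).

    Columns: specimen, protocol, time_h, organ, R, R_inter, mean_R, sd_R;
    the scan-level quantities repeat on each organ row.
    """
    rows = []
    for rec in records:
        for organ, r in rec.per_organ_R.items():
            rows.append(
                {
                    "specimen": rec.meta.specimen_id,
                    "protocol": rec.meta.protocol,
                    "time_h": rec.meta.staining_time_h,
                    "organ": organ,
                    "R": r,
                    "R_inter": rec.R_inter,
                    "mean_R": rec.mean_R,
                    "sd_R": rec.sd_R,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["specimen", "protocol", "time_h", "organ", "R", "R_inter", "mean_R", "sd_R"],
    )
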