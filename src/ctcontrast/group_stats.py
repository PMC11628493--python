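"""Nonparametric group comparison: Kruskal–Wallis, Dunn, Benjamini–Hochberg.

The protocol comparison treats per-organ contrast ratios as replicates
within each fixation+staining protocol and asks whether the protocols
differ. The chain is implemented directly from the rank formulas (midranks
for ties throughout):

* Kruskal–Wallis omnibus test,
      H = 12/(N(N+1)) · Σ nᵢ (R̄ᵢ − (N+1)/2)²,
  divided by the tie-correction factor 1 − Σ(t³−t)/(N³−N), with the
  p-value from the χ² law on k−1 degrees of freedom;
* Dunn's pairwise post-hoc z statistics on the pooled mean ranks,
      z = (R̄ᵢ − R̄ⱼ) / sqrt[(N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/nᵢ + 1/nⱼ)],
  with two-sided normal p-values;
* Benjamini–Hochberg step-up adjustment of the pairwise p-values.

The χ² approximation is used regardless of sample size (conventional
software default); a warning is logged when any group has fewer than five
observations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairwiseResult",
    "midranks",
    "kruskal_wallis",
    "dunn_test",
    "benjamini_hochberg",
    "dunn_bh",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairwiseResult:
    """One Dunn pairwise comparison; ``p_adjusted`` is filled by BH."""

    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float | None = None


def midranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties assigned the average of their rank range."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size, dtype=float)
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0  # average of ranks i+1..j+1
        i = j + 1
    return ranks


def _validated_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for label, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {label!r} is empty")
        out[str(label)] = arr
    return out


def _pooled_ranks(groups: dict[str, np.ndarray]):
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = midranks(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in labels:
        n = groups[g].size
        mean_ranks[g] = float(ranks[start : start + n].mean())
        sizes[g] = n
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))  # Σ (t³ − t)
    return labels, mean_ranks, sizes, pooled.size, tie_term


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its χ²(k−1) p-value."""
    gs = _validated_groups(groups)
    labels, mean_ranks, sizes, n_total, tie_term = _pooled_ranks(gs)
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    if any(sizes[g] < 5 for g in labels):
        logger.warning(
            "Kruskal-Wallis chi-square approximation with a group of <5 "
            "observations; the p-value is approximate"
        )
    h = (12.0 / (n_total * (n_total + 1))) * sum(
        sizes[g] * (mean_ranks[g] - (n_total + 1) / 2.0) ** 2 for g in labels
    )
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction <= 0:
        raise ValueError("all values identical: the test statistic is undefined")
    h /= correction
    p = float(sps.chi2.sf(h, df=len(labels) - 1))
    return float(h), p


def dunn_test(groups: Mapping[str, Sequence[float]]) -> list[PairwiseResult]:
    """Dunn's z and two-sided raw p for every unordered group pair.

    Pairs are emitted in the iteration order of ``groups``; ``z`` is signed
    as mean_rank(a) − mean_rank(b).
    """
    gs = _validated_groups(groups)
    labels, mean_ranks, sizes, n_total, tie_term = _pooled_ranks(gs)
    sigma2 = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    if sigma2 <= 0:
        raise ValueError("all values tied: pairwise variance is degenerate")
    results = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(sigma2 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = float(2.0 * sps.norm.sf(abs(z)))
        results.append(PairwiseResult(group_a=a, group_b=b, z=float(z), p_raw=min(p, 1.0)))
    return results


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH step-up adjusted p-values, returned in the input order.

    adjusted p(i) = min over j with p(j) >= p(i) of min(1, m·p(j)/rank(j)).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out.tolist()


def dunn_bh(groups: Mapping[str, Sequence[float]]) -> list[PairwiseResult]:
    """Dunn pairwise tests with BH-adjusted p-values filled in."""
    results = dunn_test(groups)
    adjusted = benjamini_hochberg([r.p_raw for r in results])
    return [replace(r, p_adjusted=a) for r, a in zip(results, adjusted)]
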