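"""Mutation burden summaries: per-position frequency tracks, exact Poisson
intervals, region mutation probabilities, sliding-window hotspot scans and
log-link rate tests across age and strain."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genome import MtGenomeAnnotation
from .variants import ConditionTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencySummary:
    condition: tuple[str, str, str]
    mean_frequency: float       # mean of per-position frequencies
    pooled_frequency: float     # total alt depth / total depth
    ci_lower: float
    ci_upper: float


def site_frequencies(cond: ConditionTable) -> np.ma.MaskedArray:
    """Per-position frequency = summed alt depth at the position divided by
    the position's duplex depth; zero-depth positions are masked."""
    alt = np.zeros(cond.genome_length, dtype=np.float64)
    by_pos = cond.calls.groupby("position")["alt_depth"].sum()
    alt[by_pos.index.to_numpy() - 1] = by_pos.to_numpy()
    mask = cond.depth == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(mask, 0.0, alt / np.where(mask, 1, cond.depth))
    return np.ma.MaskedArray(freq, mask=mask)


def poisson_interval(count: float, exposure: float,
                     alpha: float = 0.05) -> tuple[float, float]:
    """Exact (chi-square quantile) Poisson interval for a rate, scaled by
    exposure.  Lower bound is 0 at count 0."""
    k = float(count)
    lower = 0.0 if k == 0 else stats.chi2.ppf(alpha / 2, 2 * k) / 2
    upper = stats.chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2
    return lower / exposure, upper / exposure


def mean_frequency_with_ci(cond: ConditionTable,
                           alpha: float = 0.05) -> FrequencySummary:
    freq = site_frequencies(cond)
    if freq.mask.all():
        raise ValueError("all positions masked")
    total_alt = float(cond.calls["alt_depth"].sum())
    total_depth = float(cond.depth.sum())
    lower, upper = poisson_interval(total_alt, total_depth, alpha)
    return FrequencySummary(condition=cond.condition,
                            mean_frequency=float(freq.mean()),
                            pooled_frequency=total_alt / total_depth,
                            ci_lower=lower, ci_upper=upper)


def region_mutation_probability(cond: ConditionTable, ann: MtGenomeAnnotation,
                                kind: str) -> float:
    """Mutation count in a region class divided by (region length x mean
    region duplex depth)."""
    positions = np.array([p for p in range(1, ann.length + 1)
                          if ann.classify_region(p) == kind], dtype=np.int64)
    if positions.size == 0:
        raise ValueError(f"no positions of kind {kind!r}")
    mean_depth = float(cond.depth[positions - 1].mean())
    if mean_depth == 0:
        raise ValueError(f"zero mean depth in region {kind!r}")
    in_region = cond.calls["position"].isin(positions)
    count = float(cond.calls.loc[in_region, "alt_depth"].sum())
    return count / (positions.size * mean_depth)


def homopolymer_region_frequency(cond: ConditionTable,
                                 span: tuple[int, int]) -> float:
    """Pooled frequency over a (possibly origin-wrapping) span: summed
    mutation counts divided by summed depth across positions."""
    start, end = span
    L = cond.genome_length
    if end >= start:
        positions = np.arange(start, end + 1)
    else:
        positions = np.concatenate([np.arange(start, L + 1),
                                    np.arange(1, end + 1)])
    depth_sum = float(cond.depth[positions - 1].sum())
    if depth_sum == 0:
        return 0.0
    in_span = cond.calls["position"].isin(positions)
    return float(cond.calls.loc[in_span, "alt_depth"].sum()) / depth_sum


def sliding_window_scan(cond: ConditionTable, width: int = 150,
                        step: int = 1) -> pd.DataFrame:
    """Mean per-position frequency in circular sliding windows.

    Returns a frame with 1-based window starts; ``end`` wraps modulo the
    genome length.  Masked (zero-depth) positions are excluded from each
    window's mean.
    """
    L = cond.genome_length
    if width > L:
        raise ValueError("window width exceeds genome length")
    freq = site_frequencies(cond)
    values = np.where(freq.mask, 0.0, freq.data)
    valid = (~freq.mask).astype(np.float64)
    # circular rolling sums via tiling
    kernel = np.ones(width)
    tiled_v = np.concatenate([values, values[:width - 1]])
    tiled_n = np.concatenate([valid, valid[:width - 1]])
    sums = np.convolve(tiled_v, kernel, mode="valid")[:L]
    ns = np.convolve(tiled_n, kernel, mode="valid")[:L]
    starts = np.arange(1, L + 1, step)
    with np.errstate(divide="ignore", invalid="ignore"):
        means = np.where(ns[starts - 1] > 0,
                         sums[starts - 1] / np.maximum(ns[starts - 1], 1), 0.0)
    ends = (starts + width - 2) % L + 1
    return pd.DataFrame({"start": starts, "end": ends,
                         "strain": cond.strain, "tissue": cond.tissue,
                         "mean_frequency": means})


def _rate_glm(counts: Sequence[float], exposures: Sequence[float],
              design: np.ndarray) -> sm.GLM:
    model = sm.GLM(np.asarray(counts, dtype=float), design,
                   family=sm.families.Poisson(),
                   offset=np.log(np.asarray(exposures, dtype=float)))
    return model.fit()


def age_rate_test(young: ConditionTable, aged: ConditionTable
                  ) -> tuple[float, float, tuple[float, float]]:
    """Log-link (Poisson) regression of mutation counts on age with log
    total depth as exposure offset.  Returns (rate ratio, Wald p,
    95% CI for the ratio); Bonferroni across conditions is the caller's
    responsibility."""
    if (young.strain, young.tissue) != (aged.strain, aged.tissue):
        raise ValueError("young/aged tables must share strain and tissue")
    counts = [float(young.calls["alt_depth"].sum()),
              float(aged.calls["alt_depth"].sum())]
    if counts[0] == 0 and counts[1] == 0:
        raise ValueError("zero counts in both age groups")
    exposures = [float(young.depth.sum()), float(aged.depth.sum())]
    design = np.array([[1.0, 0.0], [1.0, 1.0]])
    fit = _rate_glm(counts, exposures, design)
    ratio = float(np.exp(fit.params[1]))
    p = float(fit.pvalues[1])
    lo, hi = np.exp(fit.conf_int()[1])
    return ratio, p, (float(lo), float(hi))


def strain_rate_test(conditions: Sequence[ConditionTable],
                     baseline: str = "B6") -> pd.DataFrame:
    """Per-strain rate contrasts against the baseline strain from a single
    log-link regression with strain indicators."""
    strains = [c.strain for c in conditions]
    if baseline not in strains:
        raise ValueError(f"baseline strain {baseline!r} missing")
    others = sorted(set(strains) - {baseline})
    if not others:
        raise ValueError("need at least one non-baseline strain")
    design = np.zeros((len(conditions), 1 + len(others)))
    design[:, 0] = 1.0
    for i, cond in enumerate(conditions):
        if cond.strain != baseline:
            design[i, 1 + others.index(cond.strain)] = 1.0
    counts = [float(c.calls["alt_depth"].sum()) for c in conditions]
    exposures = [float(c.depth.sum()) for c in conditions]
    fit = _rate_glm(counts, exposures, design)
    rows = []
    for j, strain in enumerate(others):
        rows.append((strain, float(np.exp(fit.params[1 + j])),
                     float(fit.pvalues[1 + j])))
    return pd.DataFrame(rows, columns=["strain", "rate_ratio", "p"])


def percent_bp_mutated(cond: ConditionTable) -> float:
    """Percentage of genome positions carrying at least one retained
    mutation (depth normalization is expected upstream)."""
    n = cond.calls["position"].nunique()
    return 100.0 * n / cond.genome_length


def percent_bp_mutated_delta(young: ConditionTable,
                             aged: ConditionTable) -> float:
    return percent_bp_mutated(aged) - percent_bp_mutated(young)
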