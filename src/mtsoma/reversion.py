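"""NUMT-contamination estimation/correction and reversion-mutation tests.

Low-level leakage of reads from the chromosome-1 NUMT biases calls inside
the mt NUMT-homologous span toward the B6 allele.  Contamination is
estimated from junction read counts (chr1 reads / average masked mt
depth), validated against SNV-cluster estimates, and subtracted from
reversion allele counts.  Reversion enrichment and age-delta significance
use one-sided empirical p-values against the non-haplotype background
(rank-sum for many-site strains), Benjamini-Hochberg corrected within each
mt-haplotype group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Methods-quoted real-genome coordinates, configurable by callers.
DEFAULT_NUMT_MT_SPAN = (6394, 11042)
DEFAULT_NUMT_CHR1_SPAN = (24611535, 24616184)


@dataclass(frozen=True)
class NumtEstimate:
    junction_fractions: tuple[float, ...]
    adopted_fraction: float          # maximum junction estimate
    estimated_chr1_depth: float
    cluster_fractions: tuple[float, ...] = ()
    cluster_median: Optional[float] = None


@dataclass(frozen=True)
class ReversionResult:
    position: int
    reversion_allele: str
    young_frequency: float
    aged_frequency: float
    delta: float
    p: float
    adjusted_p: float
    significant: bool


def estimate_contamination(junction_chr1_reads: Sequence[float],
                           avg_mt_depth: float,
                           cluster_chr1_reads: Optional[Sequence[float]] = None
                           ) -> NumtEstimate:
    """Per-junction contamination fraction = chr1 reads / average duplex mt
    depth (computed with the NUMT span masked); the adopted fraction is the
    maximum across junctions.  Cluster counts, when given, provide the
    median used for validation."""
    if avg_mt_depth <= 0:
        raise ValueError("average mt depth must be positive")
    fractions = tuple(float(r) / avg_mt_depth for r in junction_chr1_reads)
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError("junction fraction outside [0, 1]")
    adopted = max(fractions) if fractions else 0.0
    cluster_fr: tuple[float, ...] = ()
    cluster_median = None
    if cluster_chr1_reads is not None:
        cluster_fr = tuple(float(r) / avg_mt_depth for r in cluster_chr1_reads)
        if cluster_fr:
            cluster_median = float(np.median(cluster_fr))
    return NumtEstimate(junction_fractions=fractions,
                        adopted_fraction=adopted,
                        estimated_chr1_depth=adopted * avg_mt_depth,
                        cluster_fractions=cluster_fr,
                        cluster_median=cluster_median)


def correct_reversion_counts(positions: np.ndarray, depths: np.ndarray,
                             reversion_counts: np.ndarray, est: NumtEstimate,
                             span: tuple[int, int] = DEFAULT_NUMT_MT_SPAN
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the estimated chr1 read depth from depths and reversion
    allele counts at haplotype sites inside the NUMT-homologous span
    (all chr1 reads are assumed to carry the B6 allele).  Counts clamp at
    zero; sites outside the span are unchanged."""
    positions = np.asarray(positions)
    depths = np.asarray(depths, dtype=np.float64).copy()
    counts = np.asarray(reversion_counts, dtype=np.float64).copy()
    in_span = (positions >= span[0]) & (positions <= span[1])
    chr1 = est.estimated_chr1_depth
    depths[in_span] = np.maximum(depths[in_span] - chr1, 0.0)
    counts[in_span] = np.maximum(counts[in_span] - chr1, 0.0)
    return depths, counts


def reversion_enrichment_test(hap_site_freqs: Mapping[int, float],
                              background_freqs: Sequence[float],
                              few_site_threshold: int = 10,
                              alpha: float = 0.001) -> pd.DataFrame:
    """Enrichment of haplotype-site mutation frequencies over background.

    Few-site strains (<= threshold sites): per-site one-sided empirical
    p = fraction of background sites with a higher frequency, BH-adjusted.
    Many-site strains: a single Wilcoxon rank-sum test of the two
    distributions (one-sided, haplotype > background).
    """
    bg = np.asarray(list(background_freqs), dtype=np.float64)
    if bg.size == 0:
        raise ValueError("empty background")
    sites = sorted(hap_site_freqs)
    if len(sites) <= few_site_threshold:
        pvals = [float(np.count_nonzero(bg > hap_site_freqs[s]) / bg.size)
                 for s in sites]
        reject, adj, _, _ = multipletests(pvals, method="fdr_bh", alpha=alpha)
        return pd.DataFrame({"position": sites, "test": "empirical",
                             "frequency": [hap_site_freqs[s] for s in sites],
                             "p": pvals, "adjusted_p": adj,
                             "significant": reject})
    u_stat, p = stats.mannwhitneyu([hap_site_freqs[s] for s in sites], bg,
                                   alternative="greater")
    return pd.DataFrame({"position": sites, "test": "rank-sum",
                         "frequency": [hap_site_freqs[s] for s in sites],
                         "p": float(p), "adjusted_p": float(p),
                         "significant": p < alpha})


def reversion_identity_test(allele_counts: Mapping[str, int],
                            b6_allele: str) -> tuple[float, float]:
    """Fraction of alternative reads matching the B6 base at a haplotype
    site, with an exact binomial test against the null that each of the
    three possible alternative bases is equally likely (p0 = 1/3)."""
    total = int(sum(allele_counts.values()))
    if total == 0:
        return 0.0, 1.0
    b6 = int(allele_counts.get(b6_allele, 0))
    res = stats.binomtest(b6, total, p=1 / 3, alternative="greater")
    return b6 / total, float(res.pvalue)


def reversion_age_delta_test(site_deltas: Mapping[int, float],
                             background_deltas: Sequence[float],
                             alpha: float = 0.02) -> pd.DataFrame:
    """Direction-conditional one-sided empirical p per haplotype site: the
    fraction of background deltas greater (for increasing sites) or less
    (for decreasing sites) than the site's delta; BH within the strain and
    flagged at adjusted p < alpha."""
    bg = np.asarray(list(background_deltas), dtype=np.float64)
    if bg.size == 0:
        raise ValueError("empty background deltas")
    if bg.size < 20:
        logger.warning("only %d background deltas; empirical p resolution "
                       "is coarse", bg.size)
    sites = sorted(site_deltas)
    pvals = []
    for s in sites:
        d = site_deltas[s]
        if d >= 0:
            tail = np.count_nonzero(bg > d)
        else:
            tail = np.count_nonzero(bg < d)
        pvals.append(float(tail / bg.size))
    reject, adj, _, _ = multipletests(pvals, method="fdr_bh", alpha=alpha)
    return pd.DataFrame({"position": sites,
                         "delta": [site_deltas[s] for s in sites],
                         "p": pvals, "adjusted_p": adj,
                         "significant": reject})


def read_junction_summary(path) -> pd.DataFrame:
    """Junction/cluster chr1 read-count TSV (columns: region, kind
    {junction, cluster}, chr1_reads)."""
    df = pd.read_csv(path, sep="\t")
    required = {"region", "kind", "chr1_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"junction summary missing columns {sorted(missing)}")
    return df
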