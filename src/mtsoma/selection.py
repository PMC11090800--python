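"""hN/hS selection statistics with a multinomial simulated null.

Observed hN (non-synonymous variants per non-synonymous site) and hS are
computed per protein gene; significance comes from an empirical null in
which the observed number of mutations is re-drawn with the observed
mutation-type proportions and placed uniformly over class-compatible
positions.  Empirical p-values are one-sided toward the observed
direction, doubled (capped at 1) and Benjamini-Hochberg corrected across
genes within a condition (or within each frequency bin for the binned
scan).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genome import MtGenomeAnnotation
from .spectra import CLASS_REF_PAIR, MUTATION_CLASSES, SNV_CLASSES, \
    classify_mutation
from .variants import ConditionTable

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

EFFECT_SYN = 0
EFFECT_NONSYN = 1   # includes nonsense (stop-gaining pooled with non-syn)
EFFECT_NONE = 2     # noncoding, or alt == ref


@dataclass(frozen=True)
class FrequencyBins:
    """Half-open [lo, hi) bins over mutation frequency."""

    edges: tuple[float, ...] = (0.0, 1e-5, 5e-5, 1e-3, 1.0)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        return [f"[{lo:g},{hi:g})" for lo, hi in
                zip(self.edges, self.edges[1:])]

    def assign(self, freq: np.ndarray) -> np.ndarray:
        """Bin index per frequency; -1 when outside all bins."""
        idx = np.searchsorted(self.edges, freq, side="right") - 1
        idx[(freq < self.edges[0]) | (freq >= self.edges[-1])] = -1
        # values exactly at the top edge fall out of the last half-open bin
        return idx


@dataclass(frozen=True)
class SelectionResult:
    gene: str
    hn: Optional[float]
    hs: Optional[float]
    ratio: Optional[float]
    p: Optional[float]
    adjusted_p: Optional[float]
    direction: str              # positive | negative | none
    bin_label: str = "aggregate"
    excluded: bool = False
    p_floor: Optional[float] = None  # "< 2/n_valid" resolution note


class EffectTable:
    """Vectorized per-position substitution classification.

    Arrays over the genome: reference base codes, effective gene index
    (region-priority aware) and a (position x alt base) effect code table.
    Built once per annotation; shared by the observed statistics and the
    null simulator so both routes use identical classifications.
    """

    def __init__(self, ann: MtGenomeAnnotation):
        self.ann = ann
        L = ann.length
        self.genes = [f.name for f in ann.protein_genes]
        self.base_code = np.array([_BASE_INDEX[b] for b in ann.sequence],
                                  dtype=np.int8)
        self.gene_index = np.full(L, -1, dtype=np.int16)
        self.effect = np.full((L, 4), EFFECT_NONE, dtype=np.int8)
        region = [ann.classify_region(p) for p in range(1, L + 1)]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for gi, feat in enumerate(ann.protein_genes):
            cds = ann.cds(feat.name)
            positions = list(feat.positions(L))
            span = len(positions)
            for plus_idx, pos in enumerate(positions):
                if region[pos - 1] != "protein" or self.gene_index[pos - 1] >= 0:
                    continue
                idx = span - 1 - plus_idx if feat.strand == "-" else plus_idx
                if idx >= len(cds):  # trailing partial codon (incomplete stop)
                    continue
                codon_i, off = divmod(idx, 3)
                codon = cds[3 * codon_i:3 * codon_i + 3]
                aa = ann.code[codon]
                self.gene_index[pos - 1] = gi
                ref = ann.base(pos)
                for alt in _BASES:
                    if alt == ref:
                        continue
                    alt_cds = alt if feat.strand == "+" else comp[alt]
                    mutated = codon[:off] + alt_cds + codon[off + 1:]
                    code = EFFECT_SYN if ann.code[mutated] == aa else EFFECT_NONSYN
                    self.effect[pos - 1, _BASE_INDEX[alt]] = code
        sites = [(g, *_site_counts(ann, g)) for g in self.genes]
        self.n_sites = np.array([s[1] for s in sites])
        self.s_sites = np.array([s[2] for s in sites])
        # positions compatible with each SNV class, and the implied alt base
        self.class_positions: dict[str, np.ndarray] = {}
        self.class_alts: dict[str, np.ndarray] = {}
        for cls in SNV_CLASSES:
            pair = CLASS_REF_PAIR[cls]
            mask = np.isin(self.base_code,
                           [_BASE_INDEX[pair[0]], _BASE_INDEX[pair[1]]])
            positions = np.flatnonzero(mask)
            canon_ref, canon_alt = cls.split("/")[0].split(">")
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            alts = np.where(self.base_code[positions] == _BASE_INDEX[canon_ref],
                            _BASE_INDEX[canon_alt],
                            _BASE_INDEX[comp[canon_alt]])
            self.class_positions[cls] = positions  # 0-based
            self.class_alts[cls] = alts.astype(np.int8)


def _site_counts(ann: MtGenomeAnnotation, gene: str) -> tuple[float, float]:
    from .genome import count_ns_sites
    return count_ns_sites(ann, gene)


# -- observed statistic ---------------------------------------------------

def _gene_ns_weights(calls: pd.DataFrame, table: EffectTable,
                     weighting: str) -> np.ndarray:
    """(n_genes x 2) weighted non-synonymous / synonymous counts; indels
    and noncoding calls contribute nothing."""
    out = np.zeros((len(table.genes), 2), dtype=np.float64)
    for row in calls.itertuples(index=False):
        if len(row.ref) != 1 or len(row.alt) != 1:
            continue
        i = row.position - 1
        eff = table.effect[i, _BASE_INDEX[row.alt]]
        if eff == EFFECT_NONE:
            continue
        g = table.gene_index[i]
        w = row.alt_depth if weighting == "alt_depth" else 1.0
        out[g, 1 - eff] += w  # column 0 = non-syn, column 1 = syn
    return out


def observed_hnhs(cond: ConditionTable, ann: MtGenomeAnnotation, gene: str,
                  weighting: str = "alt_depth",
                  table: Optional[EffectTable] = None
                  ) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(hN, hS, hN/hS) for one gene; components are None-flagged (excluded)
    when either weighted count is zero."""
    table = table or EffectTable(ann)
    gi = table.genes.index(gene)
    counts = _gene_ns_weights(cond.calls, table, weighting)
    hn = counts[gi, 0] / table.n_sites[gi]
    hs = counts[gi, 1] / table.s_sites[gi]
    if counts[gi, 0] == 0 or counts[gi, 1] == 0:
        return hn, hs, None
    return hn, hs, hn / hs


# -- null simulation ------------------------------------------------------

def estimate_class_proportions(calls: pd.DataFrame,
                               weighting: str = "alt_depth") -> pd.Series:
    """Observed proportion of each of the 8 strand-collapsed classes."""
    counts = pd.Series(0.0, index=list(MUTATION_CLASSES))
    for row in calls.itertuples(index=False):
        cls = classify_mutation(row.ref, row.alt)
        counts[cls] += row.alt_depth if weighting == "alt_depth" else 1.0
    total = counts.sum()
    if total == 0:
        raise ValueError("no calls to estimate proportions from")
    return counts / total


def simulate_null(ann: MtGenomeAnnotation, n_mut: int,
                  proportions: pd.Series, seed: int,
                  table: Optional[EffectTable] = None) -> pd.DataFrame:
    """One simulated call set: classes ~ multinomial(proportions), positions
    uniform over class-compatible sites, unit weight per mutation.
    Simulated indels are single-base A edits (they never enter hN/hS)."""
    table = table or EffectTable(ann)
    rng = np.random.default_rng(seed)
    probs = np.array([proportions.get(c, 0.0) for c in MUTATION_CLASSES])
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    counts = rng.multinomial(n_mut, probs)
    rows = []
    for cls, k in zip(MUTATION_CLASSES, counts):
        if k == 0:
            continue
        if cls in ("INS", "DEL"):
            pos = rng.integers(0, ann.length, size=k)
            for p in pos:
                ref = ann.base(int(p) + 1)
                alt = ref + "A" if cls == "INS" else ref
                ref = ref if cls == "INS" else ref + "A"
                rows.append((int(p) + 1, ref, alt, 1))
            continue
        compat = table.class_positions[cls]
        if compat.size == 0:
            raise ValueError(f"class {cls} has no compatible positions")
        idx = rng.integers(0, compat.size, size=k)
        for j in idx:
            p = int(compat[j])
            rows.append((p + 1, ann.base(p + 1),
                         _BASES[table.class_alts[cls][j]], 1))
    return pd.DataFrame(rows, columns=["position", "ref", "alt", "alt_depth"])


def _simulate_gene_ns(table: EffectTable, n_mut: int, probs: np.ndarray,
                      n_sim: int, rng: np.random.Generator,
                      chunk: int = 2_000_000) -> np.ndarray:
    """(n_sim x n_genes x 2) simulated non-syn / syn unit counts, produced
    with the same multinomial + uniform-compatible-position scheme as
    :func:`simulate_null` but vectorized across simulations."""
    G = len(table.genes)
    out = np.zeros((n_sim, G, 2), dtype=np.int32)
    counts = rng.multinomial(n_mut, probs, size=n_sim)  # n_sim x 8
    for ci, cls in enumerate(MUTATION_CLASSES):
        if cls in ("INS", "DEL"):
            continue  # indels never contribute to hN/hS
        per_sim = counts[:, ci]
        total = int(per_sim.sum())
        if total == 0:
            continue
        compat = table.class_positions[cls]
        if compat.size == 0:
            if np.any(per_sim > 0):
                raise ValueError(f"class {cls} has no compatible positions")
            continue
        sim_id = np.repeat(np.arange(n_sim), per_sim)
        for lo in range(0, total, chunk):
            hi = min(lo + chunk, total)
            idx = rng.integers(0, compat.size, size=hi - lo)
            pos = compat[idx]
            eff = table.effect[pos, table.class_alts[cls][idx]]
            keep = eff != EFFECT_NONE
            gi = table.gene_index[pos[keep]]
            flat = (sim_id[lo:hi][keep].astype(np.int64) * (G * 2)
                    + gi.astype(np.int64) * 2 + (1 - eff[keep]))
            out_flat = np.bincount(flat, minlength=n_sim * G * 2)
            out += out_flat.reshape(n_sim, G, 2).astype(np.int32)
    return out


def _empirical_p(observed: float, simulated: np.ndarray
                 ) -> tuple[float, Optional[float]]:
    """Two-sided empirical p: one-sided tail toward the observed direction
    (ties count as extreme), doubled and capped at 1.  Returns (p, floor)
    where floor is the p resolution when the tail count is zero."""
    n = simulated.size
    upper = np.count_nonzero(simulated >= observed)
    lower = np.count_nonzero(simulated <= observed)
    tail = min(upper, lower)
    p = min(1.0, 2.0 * tail / n)
    floor = 2.0 / n if tail == 0 else None
    return p, floor


def empirical_selection_test(cond: ConditionTable, ann: MtGenomeAnnotation,
                             n_sim: int = 10_000, seed: int = 0,
                             weighting: str = "alt_depth",
                             alpha: float = 0.01,
                             exclude_d_loop: bool = False,
                             high_frequency_cutoff: Optional[float] = 1e-3,
                             table: Optional[EffectTable] = None,
                             min_valid_sim: int = 100,
                             bin_label: str = "aggregate"
                             ) -> list[SelectionResult]:
    """Per-gene hN/hS with empirical p-values from ``n_sim`` simulations.

    In aggregate mode calls above the high-frequency cutoff are excluded;
    class proportions may optionally be estimated without D-loop calls.
    Genes whose observed ratio is undefined (zero hN or hS) are excluded.
    BH correction runs across the testable genes of this condition.
    """
    table = table or EffectTable(ann)
    calls = cond.calls
    if high_frequency_cutoff is not None:
        freq = cond.call_frequencies()
        calls = calls.loc[~(freq > high_frequency_cutoff)]
    prop_calls = calls
    if exclude_d_loop:
        d_loop = [p for p in range(1, ann.length + 1)
                  if ann.classify_region(p) == "D-loop"]
        prop_calls = calls.loc[~calls["position"].isin(d_loop)]
    if len(prop_calls) == 0:
        logger.info("no calls available for %s; nothing to test",
                    cond.condition)
        return [SelectionResult(g, None, None, None, None, None, "none",
                                bin_label, excluded=True)
                for g in table.genes]

    proportions = estimate_class_proportions(prop_calls, weighting=weighting)
    weights = prop_calls["alt_depth"] if weighting == "alt_depth" else \
        pd.Series(1.0, index=prop_calls.index)
    n_mut = int(round(weights.sum()))

    observed = _gene_ns_weights(calls, table, weighting)
    rng = np.random.default_rng(seed)
    probs = np.array([proportions.get(c, 0.0) for c in MUTATION_CLASSES])
    if n_sim * n_mut > 0 and 2.0 / n_sim > alpha:
        logger.warning("n_sim=%d gives p resolution %.3g coarser than "
                       "alpha=%.3g", n_sim, 2.0 / n_sim, alpha)
    sims = _simulate_gene_ns(table, n_mut, probs, n_sim, rng)

    results: list[SelectionResult] = []
    testable: list[int] = []
    pvals: list[float] = []
    for gi, gene in enumerate(table.genes):
        hn = observed[gi, 0] / table.n_sites[gi]
        hs = observed[gi, 1] / table.s_sites[gi]
        if observed[gi, 0] == 0 or observed[gi, 1] == 0:
            results.append(SelectionResult(gene, hn, hs, None, None, None,
                                           "none", bin_label, excluded=True))
            continue
        ratio = hn / hs
        sim_hn = sims[:, gi, 0] / table.n_sites[gi]
        sim_hs = sims[:, gi, 1] / table.s_sites[gi]
        valid = (sims[:, gi, 0] > 0) & (sims[:, gi, 1] > 0)
        n_valid = int(valid.sum())
        if n_valid < min_valid_sim:
            logger.warning("gene %s: only %d valid simulations", gene, n_valid)
            results.append(SelectionResult(gene, hn, hs, ratio, None, None,
                                           "none", bin_label, excluded=True))
            continue
        sim_ratio = sim_hn[valid] / sim_hs[valid]
        p, floor = _empirical_p(ratio, sim_ratio)
        results.append(SelectionResult(gene, hn, hs, ratio, p, None, "none",
                                       bin_label, p_floor=floor))
        testable.append(len(results) - 1)
        pvals.append(p)

    if pvals:
        _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
        for i, adj in zip(testable, adjusted):
            r = results[i]
            direction = "none"
            if adj < alpha and r.ratio is not None:
                if r.ratio > 1:
                    direction = "positive"
                elif r.ratio < 1:
                    direction = "negative"
            results[i] = SelectionResult(r.gene, r.hn, r.hs, r.ratio, r.p,
                                         float(adj), direction, r.bin_label,
                                         p_floor=r.p_floor)
    return results


def binned_selection_scan(cond: ConditionTable, ann: MtGenomeAnnotation,
                          bins: FrequencyBins = FrequencyBins(),
                          n_sim: int = 10_000, seed: int = 0,
                          weighting: str = "alt_depth", alpha: float = 0.01,
                          exclude_d_loop: bool = True,
                          table: Optional[EffectTable] = None
                          ) -> list[SelectionResult]:
    """Full empirical test within each frequency bin; calls above 1e-3 are
    retained (the top bin covers them), the D-loop is excluded, and BH is
    applied within each bin."""
    table = table or EffectTable(ann)
    freq = cond.call_frequencies()
    bin_idx = bins.assign(np.nan_to_num(freq, nan=-1.0))
    results: list[SelectionResult] = []
    for bi, label in enumerate(bins.labels):
        sub = cond.calls.loc[bin_idx == bi]
        if len(sub) == 0:
            logger.info("bin %s empty for %s; skipped", label, cond.condition)
            continue
        sub_cond = cond.with_calls(sub)
        results.extend(empirical_selection_test(
            sub_cond, ann, n_sim=n_sim, seed=seed + bi, weighting=weighting,
            alpha=alpha, exclude_d_loop=exclude_d_loop,
            high_frequency_cutoff=None, table=table, bin_label=label))
    return results


def ns_frequency_spectra(cond: ConditionTable, ann: MtGenomeAnnotation,
                         bins: FrequencyBins = FrequencyBins(),
                         weighting: str = "alt_depth",
                         table: Optional[EffectTable] = None) -> pd.DataFrame:
    """Unit-sum proportions of non-synonymous and synonymous (weighted)
    counts across frequency bins, protein-coding SNVs only."""
    table = table or EffectTable(ann)
    freq = cond.call_frequencies()
    bin_idx = bins.assign(np.nan_to_num(freq, nan=-1.0))
    totals = np.zeros((len(bins.labels), 2), dtype=np.float64)
    for (row, bi) in zip(cond.calls.itertuples(index=False), bin_idx):
        if bi < 0 or len(row.ref) != 1 or len(row.alt) != 1:
            continue
        eff = table.effect[row.position - 1, _BASE_INDEX[row.alt]]
        if eff == EFFECT_NONE:
            continue
        w = row.alt_depth if weighting == "alt_depth" else 1.0
        totals[bi, 1 - eff] += w
    sums = totals.sum(axis=0)
    if np.any(sums == 0):
        raise ValueError("zero non-synonymous or synonymous calls overall")
    props = totals / sums
    return pd.DataFrame({"bin": bins.labels,
                         "nonsynonymous": props[:, 0],
                         "synonymous": props[:, 1]})


def null_ns_spectrum(ann: MtGenomeAnnotation,
                     table: Optional[EffectTable] = None) -> pd.DataFrame:
    """Proportions of potential non-synonymous and synonymous changes each
    SNV class could produce, over all coding position x alt substitutions."""
    table = table or EffectTable(ann)
    counts = {cls: [0, 0] for cls in SNV_CLASSES}  # [nonsyn, syn]
    for pos in range(1, ann.length + 1):
        ref = ann.base(pos)
        for alt in _BASES:
            if alt == ref:
                continue
            eff = table.effect[pos - 1, _BASE_INDEX[alt]]
            if eff == EFFECT_NONE:
                continue
            cls = classify_mutation(ref, alt)
            counts[cls][0 if eff == EFFECT_NONSYN else 1] += 1
    total_n = sum(v[0] for v in counts.values())
    total_s = sum(v[1] for v in counts.values())
    rows = [(cls, counts[cls][0] / total_n if total_n else 0.0,
             counts[cls][1] / total_s if total_s else 0.0)
            for cls in SNV_CLASSES]
    return pd.DataFrame(rows, columns=["mutation_class",
                                       "nonsynonymous", "synonymous"])
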