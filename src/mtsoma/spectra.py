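"""Strand-collapsed mutational spectra.

Substitutions are pooled with their reverse complements into six classes
keyed by the purine-reference representation (G>A/C>T, ...), plus INS and
DEL; a converter to the pyrimidine-keyed (COSMIC-style) labels is provided
for interoperability.  Trinucleotide contexts are collapsed onto the
pyrimidine-centred facet (ACG represents both ACG and CGT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import MtGenomeAnnotation, complement, reverse_complement
from .variants import ConditionTable, SiteCall

logger = logging.getLogger(__name__)

SNV_CLASSES = ("G>A/C>T", "G>T/C>A", "G>C/C>G",
               "T>C/A>G", "T>A/A>T", "T>G/A>C")
MUTATION_CLASSES = SNV_CLASSES + ("INS", "DEL")

#: reference-base pair (plus-strand bases) compatible with each SNV class
CLASS_REF_PAIR = {
    "G>A/C>T": ("G", "C"), "G>T/C>A": ("G", "C"), "G>C/C>G": ("G", "C"),
    "T>C/A>G": ("T", "A"), "T>A/A>T": ("T", "A"), "T>G/A>C": ("T", "A"),
}

_PYRIMIDINE_KEY = {
    "G>A/C>T": "C>T", "G>T/C>A": "C>A", "G>C/C>G": "C>G",
    "T>C/A>G": "T>C", "T>A/A>T": "T>A", "T>G/A>C": "T>G",
}


class SpectrumError(ValueError):
    pass


def classify_mutation(ref: str, alt: str) -> str:
    """Strand-collapsed class of a (ref, alt) allele pair."""
    if len(ref) == 1 and len(alt) == 1:
        if ref == alt or ref not in "ACGT" or alt not in "ACGT":
            raise SpectrumError(f"bad SNV alleles {ref}>{alt}")
        if ref in "CA":  # collapse onto the purine/T-reference facet
            ref, alt = complement(ref), complement(alt)
        for cls in SNV_CLASSES:
            canonical = cls.split("/")[0]
            if canonical == f"{ref}>{alt}":
                return cls
        raise SpectrumError(f"unclassifiable SNV {ref}>{alt}")
    if len(alt) > len(ref):
        return "INS"
    if len(alt) < len(ref):
        return "DEL"
    raise SpectrumError(f"multi-nucleotide substitution {ref}>{alt} rejected")


def to_pyrimidine_key(cls: str) -> str:
    """COSMIC-style pyrimidine-reference label for an SNV class."""
    try:
        return _PYRIMIDINE_KEY[cls]
    except KeyError:
        raise SpectrumError(f"{cls!r} is not an SNV class") from None


@dataclass
class TrinucSpectrum:
    """Fractions over (class, pyrimidine-centred trinucleotide) cells."""

    fractions: pd.DataFrame  # columns: mutation_class, context, fraction
    total: int

    def fraction(self, cls: str, context: str) -> float:
        sel = self.fractions.loc[
            (self.fractions["mutation_class"] == cls)
            & (self.fractions["context"] == context), "fraction"]
        return float(sel.iloc[0]) if len(sel) else 0.0


def class_counts(calls_frame: pd.DataFrame,
                 weights: str = "alt_depth") -> pd.Series:
    """Weighted mutation count per strand-collapsed class.

    ``weights``: 'alt_depth' (duplex alt read weighting) or 'unit'
    (one per surviving (position, alt), the de novo convention).
    """
    counts = pd.Series(0.0, index=list(MUTATION_CLASSES))
    for row in calls_frame.itertuples(index=False):
        cls = classify_mutation(row.ref, row.alt)
        counts[cls] += row.alt_depth if weights == "alt_depth" else 1
    return counts


def class_frequencies(cond: ConditionTable, ann: MtGenomeAnnotation,
                      weights: str = "alt_depth") -> pd.DataFrame:
    """Per-class frequency: SNV classes are normalized by depth summed over
    positions whose reference base belongs to the class's base pair; INS
    and DEL by the total duplex depth."""
    seq = np.frombuffer(ann.sequence.encode(), dtype="S1")
    depth = cond.depth
    pair_depth = {}
    for pair in (("G", "C"), ("T", "A")):
        mask = (seq == pair[0].encode()) | (seq == pair[1].encode())
        pair_depth[pair] = int(depth[mask].sum())
    total_depth = int(depth.sum())

    counts = class_counts(cond.calls, weights=weights)
    rows = []
    for cls in MUTATION_CLASSES:
        if cls in ("INS", "DEL"):
            denom = total_depth
        else:
            denom = pair_depth[CLASS_REF_PAIR[cls]]
        if denom == 0:
            if counts[cls] > 0:
                raise SpectrumError(f"zero compatible depth for class {cls}")
            freq = 0.0
        else:
            freq = counts[cls] / denom
        rows.append((cls, counts[cls], denom, freq))
    return pd.DataFrame(rows, columns=["mutation_class", "count",
                                       "depth", "frequency"])


def trinucleotide_spectrum(de_novo_calls: Sequence[SiteCall],
                           ann: MtGenomeAnnotation) -> TrinucSpectrum:
    """Spectrum of de novo SNVs over strand-collapsed trinucleotide
    contexts; each call contributes unit weight."""
    cells: dict[tuple[str, str], int] = {}
    total = 0
    for c in de_novo_calls:
        if not c.is_snv:
            continue
        cls = classify_mutation(c.ref, c.alt)
        context = ann.context(c.position)
        if c.ref in "AG":  # purine reference: fold onto the pyrimidine facet
            context = reverse_complement(context)
        cells[(cls, context)] = cells.get((cls, context), 0) + 1
        total += 1
    rows = [(cls, ctx, n / total) for (cls, ctx), n in sorted(cells.items())]
    frame = pd.DataFrame(rows, columns=["mutation_class", "context", "fraction"])
    return TrinucSpectrum(fractions=frame, total=total)


def age_spectrum_test(young_counts: Mapping[str, float],
                      aged_counts: Mapping[str, float],
                      alpha: float = 0.01) -> pd.DataFrame:
    """Per-class 2x2 Fisher's exact test of class count vs all-other count
    across age, Benjamini-Hochberg corrected over the 8 classes."""
    y_total = sum(young_counts.get(c, 0) for c in MUTATION_CLASSES)
    a_total = sum(aged_counts.get(c, 0) for c in MUTATION_CLASSES)
    rows = []
    for cls in MUTATION_CLASSES:
        y = int(young_counts.get(cls, 0))
        a = int(aged_counts.get(cls, 0))
        table = [[a, a_total - a], [y, y_total - y]]
        odds, p = stats.fisher_exact(table)
        rows.append((cls, y, a, odds, p))
    df = pd.DataFrame(rows, columns=["mutation_class", "young", "aged",
                                     "odds_ratio", "p"])
    reject, adj, _, _ = multipletests(df["p"], method="fdr_bh", alpha=alpha)
    df["adjusted_p"] = adj
    df["significant"] = reject
    return df


def export_signature_matrix(conditions: Sequence[ConditionTable],
                            path=None, weights: str = "alt_depth",
                            high_frequency_cutoff: float = 1e-3
                            ) -> pd.DataFrame:
    """Conditions x 8 mutation-type count matrix for external signature
    extraction; high-frequency calls are excluded first."""
    from .variants import condition_filter_high_frequency

    rows = {}
    for cond in conditions:
        filtered = condition_filter_high_frequency(cond, high_frequency_cutoff)
        counts = class_counts(filtered.calls, weights=weights)
        key = "-".join(cond.condition)
        if counts.sum() == 0:
            logger.warning("condition %s has zero retained mutations", key)
        rows[key] = counts
    matrix = pd.DataFrame(rows).T
    matrix.index.name = "condition"
    if path is not None:
        matrix.to_csv(path, sep="\t")
    return matrix
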