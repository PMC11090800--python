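"""Synthetic duplex-sequencing-style datasets.

Generates annotated circular genomes, per-strain haplotype tables and
per-sample call tables with the statistical structure the downstream
analysis assumes: negative-binomial duplex depth, region- and
hotspot-scaled position-specific mutation rates, 8-class mutation-type
proportions with age fold-changes, frequency-dependent thinning of
non-synonymous calls, reversion enrichment at haplotype sites and
low-level NUMT read leakage.  A single master seed fixes every dataset
bit-exactly.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import Feature, MtGenomeAnnotation, reverse_complement
from .selection import EFFECT_NONSYN, EffectTable, _BASE_INDEX
from .spectra import CLASS_REF_PAIR, MUTATION_CLASSES
from .variants import HaplotypeTable, SampleMeta, SiteCall

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "AGA", "AGG"}

DEFAULT_TYPE_PROPORTIONS = {
    "G>A/C>T": 0.35, "G>T/C>A": 0.22, "G>C/C>G": 0.04,
    "T>C/A>G": 0.12, "T>A/A>T": 0.06, "T>G/A>C": 0.05,
    "INS": 0.06, "DEL": 0.10,
}

DEFAULT_REGION_RATES = {
    "protein": 1e-7, "tRNA": 1e-7, "rRNA": 1e-7,
    "D-loop": 6.4e-7, "OriL": 1e-7, "other-noncoding": 1.5e-7,
}


def stage_seed(master_seed: int, *labels) -> int:
    """Fan a master seed out to a stage/condition seed by stable hashing."""
    digest = hashlib.sha256(
        ("|".join(str(x) for x in (master_seed, *labels))).encode()).digest()
    return int.from_bytes(digest[:8], "little")


@dataclass
class SimConfig:
    genome_length: int = 8000
    n_proteins: int = 13
    n_trnas: int = 22
    n_rrnas: int = 2
    d_loop_length: int = 600
    oril_length: int = 30
    trna_length: int = 66
    rrna_length: int = 600
    region_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_RATES))
    type_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROPORTIONS))
    age_fold: Mapping[str, float] = field(default_factory=dict)
    #: extra multiplicative folds over (start, end) spans
    hotspots: Sequence[tuple[int, int, float]] = ()
    #: (freq_lo, freq_hi, s) spans: non-synonymous calls with frequency in
    #: [lo, hi) are dropped with probability s
    selection_thinning: Sequence[tuple[float, float, float]] = ()
    reversion_fold: float = 0.0     # 0 disables reversion calls
    reversion_age_slope: float = 0.0
    numt_fraction: float = 0.0
    numt_span: Optional[tuple[int, int]] = None
    depth_mean: float = 5000.0
    depth_dispersion: float = 20.0
    replicates: int = 3
    haplotype_counts: Mapping[str, int] = field(
        default_factory=lambda: {"B6": 0, "AKR": 1, "ALR": 3,
                                 "FVB": 2, "NZB": 91})
    #: fraction of mutation events drawn from the intermediate/high
    #: frequency mixture component (log-uniform target frequency)
    high_freq_weight: float = 0.03
    high_freq_range: tuple[float, float] = (2e-5, 2e-3)
    master_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.type_proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"type proportions sum to {total}, not 1")
        if any(r < 0 for r in self.region_rates.values()):
            raise ValueError("rates must be non-negative")
        if not 0 <= self.numt_fraction <= 0.05:
            raise ValueError("NUMT fraction outside [0, 0.05]")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "hotspots" in raw:
            raw["hotspots"] = [tuple(h) for h in raw["hotspots"]]
        if "selection_thinning" in raw:
            raw["selection_thinning"] = [tuple(s)
                                         for s in raw["selection_thinning"]]
        if "numt_span" in raw and raw["numt_span"] is not None:
            raw["numt_span"] = tuple(raw["numt_span"])
        if "high_freq_range" in raw:
            raw["high_freq_range"] = tuple(raw["high_freq_range"])
        return cls(**raw)


@dataclass
class SimSample:
    calls: list[SiteCall]
    meta: SampleMeta
    depth: np.ndarray


# -- genome ---------------------------------------------------------------

def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random internal non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in _STOPS:
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def simulate_genome(cfg: SimConfig
                    ) -> tuple[MtGenomeAnnotation, dict[str, HaplotypeTable]]:
    """Random circular genome with non-overlapping typed features plus
    per-strain haplotype tables with the configured site counts."""
    if cfg.genome_length < 2000:
        raise ValueError("genome length must be at least 2 kb")
    rng = np.random.default_rng(stage_seed(cfg.master_seed, "genome"))
    seq = list(rng.choice(list(_BASES), size=cfg.genome_length))
    features: list[Feature] = []
    cursor = 1

    def place(name: str, kind: str, length: int, strand: str = "+",
              cds: Optional[str] = None) -> None:
        nonlocal cursor
        end = cursor + length - 1
        if end > cfg.genome_length:
            raise ValueError("infeasible layout: features exceed genome")
        if cds is not None:
            segment = cds if strand == "+" else reverse_complement(cds)
            seq[cursor - 1:end] = list(segment)
        features.append(Feature(name=name, kind=kind, start=cursor, end=end,
                                strand=strand))
        cursor = end + 1 + int(rng.integers(2, 12))  # small spacer

    place("D-loop", "D-loop", cfg.d_loop_length)
    place("OriL", "OriL", cfg.oril_length)
    for i in range(cfg.n_rrnas):
        place(f"RNR{i + 1}", "rRNA", cfg.rrna_length)
    for i in range(cfg.n_trnas):
        place(f"TRN{i + 1}", "tRNA", cfg.trna_length)
    budget = cfg.genome_length - cursor - 14 * cfg.n_proteins
    if budget < cfg.n_proteins * 60:
        raise ValueError("infeasible layout: not enough room for proteins")
    per_gene = budget // cfg.n_proteins
    for i in range(cfg.n_proteins):
        n_codons = max(20, per_gene // 3)
        strand = "-" if (i + 1) % 7 == 0 else "+"
        place(f"GENE{i + 1}", "protein", n_codons * 3, strand=strand,
              cds=_random_cds(n_codons, rng))

    ann = MtGenomeAnnotation(sequence="".join(seq), features=features)

    haplotypes: dict[str, HaplotypeTable] = {}
    from .genome import classify_substitution
    for strain, n_sites in cfg.haplotype_counts.items():
        positions = rng.choice(np.arange(1, ann.length + 1), size=n_sites,
                               replace=False) if n_sites else np.array([], int)
        rows = []
        for pos in sorted(int(p) for p in positions):
            ref = ann.base(pos)
            alt = _BASES[(int(_BASE_INDEX[ref]) + int(rng.integers(1, 4))) % 4]
            effect = classify_substitution(ann, pos, alt).effect
            if effect == "nonsense":
                effect = "non-synonymous"
            rows.append((pos, ref, alt, effect))
        haplotypes[strain] = HaplotypeTable(
            strain=strain,
            records=pd.DataFrame(rows, columns=["position", "b6_allele",
                                                "conplastic_allele",
                                                "annotation"]))
    return ann, haplotypes


# -- condition simulation -------------------------------------------------

def _rate_matrix(cfg: SimConfig, ann: MtGenomeAnnotation,
                 table: EffectTable, aged: bool) -> np.ndarray:
    """(L x 8) per-read per-bp mutation rate by position and class."""
    L = ann.length
    base = np.empty(L)
    for pos in range(1, L + 1):
        base[pos - 1] = cfg.region_rates[ann.classify_region(pos)]
    for start, end, fold in cfg.hotspots:
        if end >= start:
            base[start - 1:end] *= fold
        else:  # wraps the origin
            base[start - 1:] *= fold
            base[:end] *= fold
    rates = np.zeros((L, len(MUTATION_CLASSES)))
    for ci, cls in enumerate(MUTATION_CLASSES):
        prop = cfg.type_proportions.get(cls, 0.0)
        fold = cfg.age_fold.get(cls, 1.0) if aged else 1.0
        col = base * prop * fold
        if cls in CLASS_REF_PAIR:
            pair = CLASS_REF_PAIR[cls]
            compat = np.isin(table.base_code,
                             [_BASE_INDEX[pair[0]], _BASE_INDEX[pair[1]]])
            # rescale so the class keeps its configured genome-wide share
            frac = compat.mean()
            col = np.where(compat, col / max(frac, 1e-12), 0.0)
        rates[:, ci] = col
    return rates


def _event_alt_depths(n: int, cfg: SimConfig, depth: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Alt read counts per mutation event: mostly singleton-scale
    (geometric), with a small log-uniform intermediate-frequency
    component."""
    low = rng.geometric(0.6, size=n)
    lo, hi = cfg.high_freq_range
    target = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    high = np.maximum(1, np.round(depth * target)).astype(np.int64)
    use_high = rng.random(n) < cfg.high_freq_weight
    out = np.where(use_high, high, low)
    return np.minimum(out, depth)


def _thinning_prob(cfg: SimConfig, freq: float) -> float:
    for lo, hi, s in cfg.selection_thinning:
        if lo <= freq < hi:
            return s
    return 0.0


def simulate_condition(cfg: SimConfig, ann: MtGenomeAnnotation, strain: str,
                       tissue: str, age: str,
                       haplotypes: Optional[Mapping[str, HaplotypeTable]] = None,
                       table: Optional[EffectTable] = None,
                       rates: Optional[np.ndarray] = None
                       ) -> list[SimSample]:
    """Replicate samples for one strain x tissue x age cell."""
    table = table or EffectTable(ann)
    aged = age == "aged"
    if rates is None:
        rates = _rate_matrix(cfg, ann, table, aged)
    hap = haplotypes.get(strain) if haplotypes else None
    hap_positions = hap.positions if hap else set()
    samples = []
    for rep in range(1, cfg.replicates + 1):
        rng = np.random.default_rng(
            stage_seed(cfg.master_seed, "condition", strain, tissue, age, rep))
        mean, disp = cfg.depth_mean, cfg.depth_dispersion
        depth = rng.negative_binomial(disp, disp / (disp + mean),
                                      size=ann.length).astype(np.int64)
        events = rng.poisson(depth[:, None] * rates)
        calls: dict[tuple[int, str, str], int] = {}
        pos_idx, cls_idx = np.nonzero(events)
        for i, ci in zip(pos_idx, cls_idx):
            position = int(i) + 1
            if position in hap_positions:
                continue  # haplotype sites carry only reversion calls
            d = int(depth[i])
            if d == 0:
                continue
            cls = MUTATION_CLASSES[ci]
            ref = ann.base(position)
            if cls == "INS":
                ref_out, alt_out = ref, ref + "A"
            elif cls == "DEL":
                ref_out, alt_out = ref + "A", ref
            else:
                canon_ref, canon_alt = cls.split("/")[0].split(">")
                alt = canon_alt if ref == canon_ref else \
                    reverse_complement(canon_alt)
                ref_out, alt_out = ref, alt
            n_events = int(events[i, ci])
            alt_depths = _event_alt_depths(n_events, cfg, depth[i], rng)
            is_nonsyn = (cls in CLASS_REF_PAIR and
                         table.effect[i, _BASE_INDEX[alt_out]] == EFFECT_NONSYN)
            total = 0
            for ad in alt_depths:
                if is_nonsyn and cfg.selection_thinning:
                    s = _thinning_prob(cfg, ad / d)
                    if s > 0 and rng.random() < s:
                        continue
                total += int(ad)
            if total > 0:
                key = (position, ref_out, alt_out)
                calls[key] = min(calls.get(key, 0) + total, d)

        if hap is not None and (cfg.reversion_fold > 0 or cfg.numt_fraction > 0):
            base_rate = cfg.region_rates["protein"]
            rate = base_rate * cfg.reversion_fold * \
                (1.0 + (cfg.reversion_age_slope if aged else 0.0))
            for row in hap.records.itertuples(index=False):
                i = int(row.position) - 1
                d = int(depth[i])
                if d == 0:
                    continue
                count = int(rng.poisson(d * rate)) if rate > 0 else 0
                if cfg.numt_span and cfg.numt_fraction > 0 and \
                        cfg.numt_span[0] <= row.position <= cfg.numt_span[1]:
                    count += int(rng.binomial(d, cfg.numt_fraction))
                if count > 0:
                    key = (int(row.position), str(row.conplastic_allele),
                           str(row.b6_allele))
                    calls[key] = min(count, d)

        sample_id = f"{strain}_{tissue}_{age}_r{rep}"
        site_calls = [SiteCall(p, r, a, ad, int(depth[p - 1]), sample_id)
                      for (p, r, a), ad in sorted(calls.items())]
        meta = SampleMeta(sample_id, strain, tissue, age, rep)
        samples.append(SimSample(calls=site_calls, meta=meta, depth=depth))
    return samples


def simulate_numt_summary(cfg: SimConfig, avg_mt_depth: float,
                          seed_label: str = "numt",
                          n_junctions: int = 2,
                          n_clusters: int = 6) -> pd.DataFrame:
    """Junction and SNV-cluster chr1 read counts implied by the configured
    contamination fraction."""
    rng = np.random.default_rng(stage_seed(cfg.master_seed, seed_label))
    n = int(round(avg_mt_depth))
    rows = []
    for j in range(n_junctions):
        rows.append((f"junction_{j + 1}", "junction",
                     int(rng.binomial(n, cfg.numt_fraction))))
    for c in range(n_clusters):
        rows.append((f"cluster_{c + 1}", "cluster",
                     int(rng.binomial(n, cfg.numt_fraction))))
    return pd.DataFrame(rows, columns=["region", "kind", "chr1_reads"])


# -- dataset emission -----------------------------------------------------

def write_dataset(cfg: SimConfig, out_dir: str | Path,
                  strains: Optional[Sequence[str]] = None,
                  tissues: Sequence[str] = ("brain", "heart", "liver"),
                  ages: Sequence[str] = ("young", "aged")) -> Path:
    """Emit a full synthetic dataset in the dialects the readers consume:
    genome FASTA + BED, haplotype TSVs, per-sample call and depth TSVs, a
    sample sheet and junction summaries."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann, haplotypes = simulate_genome(cfg)
    with open(out / "genome.fa", "w") as fh:
        fh.write(">chrM\n")
        for i in range(0, ann.length, 70):
            fh.write(ann.sequence[i:i + 70] + "\n")
    with open(out / "features.bed", "w") as fh:
        for f in ann.features:
            fh.write(f"chrM\t{f.start - 1}\t{f.end}\t{f.name}\t{f.kind}\t"
                     f"{f.strand}\n")
    hap_rows = []
    for strain, hap in haplotypes.items():
        df = hap.records.copy()
        df.insert(0, "strain", strain)
        hap_rows.append(df)
    pd.concat(hap_rows, ignore_index=True).to_csv(
        out / "haplotypes.tsv", sep="\t", index=False)

    table = EffectTable(ann)
    sheet_rows = []
    calls_dir = out / "calls"
    calls_dir.mkdir(exist_ok=True)
    for strain in (strains or list(cfg.haplotype_counts)):
        for tissue in tissues:
            for age in ages:
                samples = simulate_condition(cfg, ann, strain, tissue, age,
                                             haplotypes, table=table)
                depth_sum = np.zeros(ann.length)
                for s in samples:
                    from .variants import calls_to_frame, write_depth_track
                    calls_to_frame(s.calls).to_csv(
                        calls_dir / f"{s.meta.sample_id}.tsv", sep="\t",
                        index=False)
                    write_depth_track(
                        s.depth, calls_dir / f"{s.meta.sample_id}.depth.tsv")
                    sheet_rows.append((s.meta.sample_id, strain, tissue, age,
                                       s.meta.replicate))
                    depth_sum += s.depth
                if cfg.numt_fraction > 0:
                    simulate_numt_summary(
                        cfg, depth_sum.mean(),
                        seed_label=f"numt|{strain}|{tissue}|{age}").to_csv(
                        out / f"numt_{strain}_{tissue}_{age}.tsv", sep="\t",
                        index=False)
    pd.DataFrame(sheet_rows, columns=["sample_id", "strain", "tissue", "age",
                                      "replicate"]).to_csv(
        out / "samples.tsv", sep="\t", index=False)
    logger.info("synthetic dataset written to %s", out)
    return out
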