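"""Reading, validation, filtering and aggregation of duplex variant calls.

Call tables arrive as TSV (columns: position, ref, alt, alt_depth, depth,
sample_id) or VCF 4.2 with configurable depth field names.  Filters follow
the analysis conventions: a strict high-frequency cut at 1e-3, a de novo
proxy (alt depth < 100 and frequency < 0.01, scored once), and removal of
calls at conplastic haplotype sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

STRAINS = ("B6", "AKR", "ALR", "FVB", "NZB")
TISSUES = ("brain", "heart", "liver")
AGES = ("young", "aged")

CALL_COLUMNS = ["position", "ref", "alt", "alt_depth", "depth", "sample_id"]


class CallValidationError(ValueError):
    pass


@dataclass(frozen=True)
class SiteCall:
    position: int
    ref: str
    alt: str
    alt_depth: int
    depth: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.alt_depth <= self.depth:
            raise CallValidationError(
                f"position {self.position}: alt_depth {self.alt_depth} outside "
                f"(0, depth={self.depth}]")
        if self.ref == self.alt:
            raise CallValidationError(f"position {self.position}: ref == alt")
        if self.position < 1:
            raise CallValidationError(f"bad position {self.position}")

    @property
    def frequency(self) -> float:
        return self.alt_depth / self.depth

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    strain: str
    tissue: str
    age: str
    replicate: int = 1

    @property
    def condition(self) -> tuple[str, str, str]:
        return (self.strain, self.tissue, self.age)


@dataclass(frozen=True)
class HaplotypeTable:
    """Fixed differences of a conplastic strain from the B6 reference."""

    strain: str
    records: pd.DataFrame  # position, b6_allele, conplastic_allele, annotation

    def __post_init__(self) -> None:
        pos = self.records["position"]
        if pos.duplicated().any():
            raise CallValidationError(
                f"duplicate haplotype positions for {self.strain}")

    @property
    def positions(self) -> set[int]:
        return set(self.records["position"].astype(int))

    def b6_allele(self, position: int) -> str:
        row = self.records.loc[self.records["position"] == position]
        return str(row["b6_allele"].iloc[0])


@dataclass
class ConditionTable:
    """Calls and depth aggregated across replicates of one
    strain x tissue x age cell.  ``depth`` is a full-length per-position
    duplex depth track (index = position - 1); zero entries are masked."""

    strain: str
    tissue: str
    age: str
    depth: np.ndarray
    calls: pd.DataFrame  # position, ref, alt, alt_depth
    sample_ids: tuple[str, ...] = ()

    @property
    def condition(self) -> tuple[str, str, str]:
        return (self.strain, self.tissue, self.age)

    @property
    def genome_length(self) -> int:
        return len(self.depth)

    def call_depths(self) -> np.ndarray:
        """Condition depth at each call's position."""
        return self.depth[self.calls["position"].to_numpy(dtype=np.int64) - 1]

    def call_frequencies(self) -> np.ndarray:
        d = self.call_depths()
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(d > 0, self.calls["alt_depth"].to_numpy() / d, np.nan)

    def with_calls(self, calls: pd.DataFrame) -> "ConditionTable":
        return ConditionTable(self.strain, self.tissue, self.age,
                              self.depth, calls.reset_index(drop=True),
                              self.sample_ids)


# -- allele normalization -------------------------------------------------

def normalize_alleles(position: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimony-trim and left-anchor a VCF-style allele pair."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


# -- reading and writing --------------------------------------------------

def _detect_dialect(path: Path) -> str:
    if path.suffix.lower() == ".vcf":
        return "vcf"
    return "tsv"


def read_calls(path: str | Path, dialect: Optional[str] = None,
               depth_field: str = "DP", alt_depth_field: str = "AD",
               ) -> list[SiteCall]:
    """Read one sample's calls; indels are left-anchored and trimmed."""
    path = Path(path)
    dialect = dialect or _detect_dialect(path)
    calls: list[SiteCall] = []
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str,
                                                "sample_id": str})
        missing = set(CALL_COLUMNS) - set(df.columns)
        if missing:
            raise CallValidationError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                pos, ref, alt = normalize_alleles(int(row.position),
                                                  row.ref, row.alt)
                calls.append(SiteCall(pos, ref, alt, int(row.alt_depth),
                                      int(row.depth), str(row.sample_id)))
            except CallValidationError as exc:
                raise CallValidationError(f"{path} row {i}: {exc}") from exc
    elif dialect == "vcf":
        with pysam.VariantFile(str(path)) as vf:
            sample_id = path.stem
            for rec in vf:
                info = rec.info
                if depth_field not in info or alt_depth_field not in info:
                    raise CallValidationError(
                        f"{path} pos {rec.pos}: missing INFO field "
                        f"{depth_field}/{alt_depth_field}")
                depth = int(_scalar(info[depth_field]))
                alt_depth = int(_scalar(info[alt_depth_field]))
                for alt in rec.alts or ():
                    pos, ref, alt_n = normalize_alleles(rec.pos, rec.ref, alt)
                    calls.append(SiteCall(pos, ref, alt_n, alt_depth, depth,
                                          sample_id))
    else:
        raise CallValidationError(f"unknown dialect {dialect!r}")
    return calls


def _scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0]
    return value


def write_calls(calls: Sequence[SiteCall], path: str | Path,
                dialect: Optional[str] = None, contig: str = "chrM",
                contig_length: int = 16299) -> None:
    path = Path(path)
    dialect = dialect or _detect_dialect(path)
    if dialect == "tsv":
        calls_to_frame(calls).to_csv(path, sep="\t", index=False)
    elif dialect == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={contig},length={contig_length}>\n")
            fh.write('##INFO=<ID=DP,Number=1,Type=Integer,'
                     'Description="Total duplex depth">\n')
            fh.write('##INFO=<ID=AD,Number=1,Type=Integer,'
                     'Description="Alt duplex depth">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for c in sorted(calls, key=lambda c: (c.position, c.alt)):
                fh.write(f"{contig}\t{c.position}\t.\t{c.ref}\t{c.alt}\t.\t.\t"
                         f"DP={c.depth};AD={c.alt_depth}\n")
    else:
        raise CallValidationError(f"unknown dialect {dialect!r}")


def calls_to_frame(calls: Iterable[SiteCall]) -> pd.DataFrame:
    rows = [(c.position, c.ref, c.alt, c.alt_depth, c.depth, c.sample_id)
            for c in calls]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def read_sample_sheet(path: str | Path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    metas = {}
    for row in df.itertuples(index=False):
        meta = SampleMeta(row.sample_id, row.strain, row.tissue, row.age,
                          int(row.replicate))
        metas[meta.sample_id] = meta
    keys = [(m.strain, m.tissue, m.age, m.replicate) for m in metas.values()]
    if len(keys) != len(set(keys)):
        raise CallValidationError("duplicate (strain, tissue, age, replicate)")
    return metas


def read_haplotypes(path: str | Path, strain: str) -> HaplotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"b6_allele": str,
                                            "conplastic_allele": str})
    if "strain" in df.columns:
        df = df.loc[df["strain"] == strain].drop(columns=["strain"])
    return HaplotypeTable(strain=strain, records=df.reset_index(drop=True))


def read_depth_track(path: str | Path, genome_length: int) -> np.ndarray:
    """Per-position depth TSV (position, depth) -> dense array."""
    df = pd.read_csv(path, sep="\t")
    depth = np.zeros(genome_length, dtype=np.int64)
    depth[df["position"].to_numpy() - 1] = df["depth"].to_numpy()
    return depth


def write_depth_track(depth: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"position": np.arange(1, len(depth) + 1),
                  "depth": depth}).to_csv(path, sep="\t", index=False)


# -- filters --------------------------------------------------------------

def filter_haplotype_sites(calls: Sequence[SiteCall], hap: HaplotypeTable
                           ) -> tuple[list[SiteCall], list[SiteCall]]:
    """Split calls into (kept, removed-at-haplotype-sites)."""
    sites = hap.positions
    kept = [c for c in calls if c.position not in sites]
    removed = [c for c in calls if c.position in sites]
    return kept, removed


def filter_high_frequency(calls: Sequence[SiteCall],
                          threshold: float = 1e-3) -> list[SiteCall]:
    """Drop calls with frequency strictly greater than the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return [c for c in calls if c.frequency <= threshold]


def select_de_novo(calls: Sequence[SiteCall], max_alt_depth: int = 100,
                   max_frequency: float = 0.01) -> list[SiteCall]:
    """De novo proxy: alt depth < 100 and frequency < 0.01; each surviving
    (position, alt) is scored with unit weight downstream."""
    return [c for c in calls
            if c.alt_depth < max_alt_depth and c.frequency < max_frequency]


# -- aggregation ----------------------------------------------------------

def aggregate_condition(samples: Sequence[tuple[Sequence[SiteCall], SampleMeta]],
                        depths: Optional[Sequence[np.ndarray]] = None,
                        genome_length: Optional[int] = None) -> ConditionTable:
    """Sum calls and depth tracks across replicates of one condition.

    When per-sample dense depth tracks are not supplied, the condition
    depth is reconstructed from the calls' own per-position depths (only
    called positions are then unmasked).
    """
    if not samples:
        raise CallValidationError("empty sample list")
    conditions = {meta.condition for _, meta in samples}
    if len(conditions) > 1:
        raise CallValidationError(f"mixed conditions: {sorted(conditions)}")
    strain, tissue, age = conditions.pop()

    if depths is not None:
        if len(depths) != len(samples):
            raise CallValidationError("one depth track per sample required")
        depth = np.sum(np.stack(depths), axis=0).astype(np.int64)
    else:
        if genome_length is None:
            genome_length = max((c.position for calls, _ in samples
                                 for c in calls), default=0)
        depth = np.zeros(genome_length, dtype=np.int64)
        for calls, _ in samples:
            per_pos: dict[int, int] = {}
            for c in calls:
                per_pos[c.position] = max(per_pos.get(c.position, 0), c.depth)
            for p, d in per_pos.items():
                depth[p - 1] += d

    frames = [calls_to_frame(calls) for calls, _ in samples]
    merged = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=CALL_COLUMNS)
    agg = (merged.groupby(["position", "ref", "alt"], as_index=False)
           ["alt_depth"].sum()
           .sort_values(["position", "alt"]).reset_index(drop=True))
    return ConditionTable(strain=strain, tissue=tissue, age=age, depth=depth,
                          calls=agg,
                          sample_ids=tuple(m.sample_id for _, m in samples))


def condition_filter_high_frequency(cond: ConditionTable,
                                    threshold: float = 1e-3) -> ConditionTable:
    """High-frequency cut evaluated at condition-aggregate level."""
    freq = cond.call_frequencies()
    keep = ~(freq > threshold)
    return cond.with_calls(cond.calls.loc[keep])


def condition_filter_haplotype_sites(cond: ConditionTable, hap: HaplotypeTable
                                     ) -> tuple[ConditionTable, pd.DataFrame]:
    sites = hap.positions
    mask = cond.calls["position"].isin(sites)
    return cond.with_calls(cond.calls.loc[~mask]), \
        cond.calls.loc[mask].reset_index(drop=True)


def normalize_depth_across_conditions(tables: Sequence[ConditionTable],
                                      mode: str = "none",
                                      seed: int = 0) -> list[ConditionTable]:
    """Optionally rescale conditions to a common per-position depth.

    ``thin-to-min`` subsamples each condition's reads at every position to
    the minimum depth across conditions by multivariate hypergeometric
    thinning (expected frequency unchanged).  Positions with zero depth in
    any condition are masked in all.
    """
    if mode not in ("none", "thin-to-min"):
        raise ValueError(f"unknown mode {mode!r}")
    if not tables:
        return []
    lengths = {t.genome_length for t in tables}
    if len(lengths) != 1:
        raise CallValidationError("conditions disagree on genome length")
    depth_stack = np.stack([t.depth for t in tables])
    min_depth = depth_stack.min(axis=0)
    masked = min_depth == 0

    if mode == "none":
        out = []
        for t in tables:
            depth = t.depth.copy()
            depth[masked] = 0
            keep = ~t.calls["position"].isin(np.flatnonzero(masked) + 1)
            out.append(ConditionTable(t.strain, t.tissue, t.age, depth,
                                      t.calls.loc[keep].reset_index(drop=True),
                                      t.sample_ids))
        return out

    rng = np.random.default_rng(seed)
    out = []
    for t in tables:
        depth = min_depth.copy()
        depth[masked] = 0
        new_rows = []
        for pos, group in t.calls.groupby("position"):
            i = int(pos) - 1
            n = int(t.depth[i])
            m = int(min_depth[i])
            if m == 0 or n == 0:
                continue
            alts = group["alt_depth"].to_numpy()
            rest = n - int(alts.sum())
            if rest < 0:
                raise CallValidationError(
                    f"alt depths exceed depth at position {pos}")
            if m == n:
                thinned = alts
            else:
                colors = np.append(alts, rest)
                thinned = rng.multivariate_hypergeometric(colors, m)[:-1]
            for (row, k) in zip(group.itertuples(index=False), thinned):
                if k > 0:
                    new_rows.append((row.position, row.ref, row.alt, int(k)))
        calls = pd.DataFrame(new_rows,
                             columns=["position", "ref", "alt", "alt_depth"])
        out.append(ConditionTable(t.strain, t.tissue, t.age, depth, calls,
                                  t.sample_ids))
    return out
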