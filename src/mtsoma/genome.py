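"""Circular mitochondrial genome model.

Holds the reference sequence, typed feature annotation, the vertebrate
mitochondrial genetic code, and synonymous/non-synonymous site and
substitution classification.  All coordinates are 1-based inclusive
internally; BED input is converted on read.  Features may wrap the
origin (start > end) to model circularity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("protein", "tRNA", "rRNA", "D-loop", "OriL", "other-noncoding")

#: Overlap resolution priority: lower value wins.
REGION_PRIORITY = {"OriL": 0, "D-loop": 1, "tRNA": 2, "rRNA": 3, "protein": 4,
                   "other-noncoding": 5}

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial

#: codon -> single-letter amino acid, with "*" for stop codons.
VERTEBRATE_MITO_CODE: dict[str, str] = dict(_MITO_TABLE.forward_table)
for _stop in _MITO_TABLE.stop_codons:
    VERTEBRATE_MITO_CODE[_stop] = "*"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class Feature:
    """One annotated feature on the circular genome, 1-based inclusive."""

    name: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    #: protein features whose final codon is completed by polyadenylation;
    #: the partial codon is dropped from translation and site counting.
    incomplete_stop: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise AnnotationError(f"unknown feature kind {self.kind!r}")
        if self.start < 1:
            raise AnnotationError(f"feature {self.name}: start {self.start} < 1")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"feature {self.name}: bad strand {self.strand!r}")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def span_length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def positions(self, genome_length: int) -> Iterator[int]:
        """5'->3' on the plus strand; wraps through the origin if needed."""
        if self.wraps:
            yield from range(self.start, genome_length + 1)
            yield from range(1, self.end + 1)
        else:
            yield from range(self.start, self.end + 1)

    def contains(self, position: int, genome_length: int) -> bool:
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end


@dataclass(frozen=True)
class SiteClassification:
    position: int
    gene: Optional[str]
    codon_index: Optional[int]  # 1-based within the gene
    effect: str  # synonymous | non-synonymous | nonsense | noncoding


@dataclass
class MtGenomeAnnotation:
    sequence: str
    features: list[Feature] = field(default_factory=list)
    code: dict[str, str] = field(default_factory=lambda: dict(VERTEBRATE_MITO_CODE))

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise AnnotationError(f"non-ACGT symbols in sequence: {sorted(bad)}")
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise AnnotationError("feature names are not unique")
        for f in self.features:
            if f.start > self.length or f.end > self.length:
                raise AnnotationError(
                    f"feature {f.name} outside [1, {self.length}]")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference base at a 1-based position; indexing is modular."""
        return self.sequence[(position - 1) % self.length]

    def context(self, position: int, flank: int = 1) -> str:
        """Trinucleotide (or wider) context centred on position, circular."""
        return "".join(self.base(position + o) for o in range(-flank, flank + 1))

    # -- feature access ---------------------------------------------------

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r}")

    @property
    def protein_genes(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "protein"]

    def classify_region(self, position: int) -> str:
        """Region kind covering a position, resolved by fixed priority
        OriL > D-loop > tRNA > rRNA > protein; uncovered -> other-noncoding."""
        if not 1 <= position <= self.length:
            raise AnnotationError(f"position {position} outside [1, {self.length}]")
        best = "other-noncoding"
        for f in self.features:
            if f.contains(position, self.length):
                if REGION_PRIORITY[f.kind] < REGION_PRIORITY[best]:
                    best = f.kind
        return best

    def covering_gene(self, position: int) -> Optional[Feature]:
        """Protein feature effective at a position (None if a higher-priority
        feature kind covers it)."""
        if self.classify_region(position) != "protein":
            return None
        for f in self.features:
            if f.kind == "protein" and f.contains(position, self.length):
                return f
        return None

    # -- coding sequence --------------------------------------------------

    def cds(self, gene: str) -> str:
        """Strand-oriented coding sequence of a protein feature.  For
        incomplete-stop genes the trailing partial codon is dropped."""
        f = self.feature(gene)
        if f.kind != "protein":
            raise AnnotationError(f"{gene} is not a protein feature")
        raw = "".join(self.base(p) for p in f.positions(self.length))
        if f.strand == "-":
            raw = reverse_complement(raw)
        rem = len(raw) % 3
        if rem:
            if not f.incomplete_stop:
                raise AnnotationError(
                    f"{gene}: span {len(raw)} not divisible by 3 and not "
                    "flagged incomplete_stop")
            raw = raw[: len(raw) - rem]
        return raw

    def cds_index(self, gene: str, position: int) -> int:
        """0-based index of a genomic position within the gene's CDS
        (strand-oriented)."""
        f = self.feature(gene)
        plus_index = None
        for i, p in enumerate(f.positions(self.length)):
            if p == position:
                plus_index = i
                break
        if plus_index is None:
            raise AnnotationError(f"position {position} not in {gene}")
        if f.strand == "-":
            return f.span_length(self.length) - 1 - plus_index
        return plus_index

    def translate(self, cds: str, to_stop: bool = True) -> str:
        """Translate a CDS with the vertebrate mitochondrial code."""
        bad = set(cds) - set("ACGT")
        if bad:
            raise AnnotationError(f"non-ACGT symbols in CDS: {sorted(bad)}")
        aa = []
        for i in range(0, len(cds) - len(cds) % 3, 3):
            sym = self.code[cds[i:i + 3]]
            if sym == "*" and to_stop:
                break
            aa.append(sym)
        return "".join(aa)


# -- file loading ---------------------------------------------------------

def _parse_kind(token: str) -> str:
    tok = token.strip()
    aliases = {
        "protein": "protein", "protein_coding": "protein", "cds": "protein",
        "trna": "tRNA", "rrna": "rRNA", "d-loop": "D-loop", "dloop": "D-loop",
        "d_loop": "D-loop", "oril": "OriL",
        "other-noncoding": "other-noncoding", "noncoding": "other-noncoding",
    }
    key = tok.lower()
    if key not in aliases:
        raise AnnotationError(f"unknown feature kind {token!r}")
    return aliases[key]


def _read_bed(path: Path) -> list[Feature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise AnnotationError(f"BED line needs >=4 columns: {line!r}")
            _, start0, end0, name = parts[:4]
            # BED3+name convention: kind in column 5, or packed as "name|kind"
            if len(parts) > 4 and parts[4] not in (".", ""):
                kind = _parse_kind(parts[4])
            elif "|" in name:
                name, kind_tok = name.split("|", 1)
                kind = _parse_kind(kind_tok)
            else:
                raise AnnotationError(f"no kind for BED feature {name!r}")
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            feats.append(Feature(name=name, kind=kind,
                                 start=int(start0) + 1, end=int(end0),
                                 strand=strand))
    return feats


def _read_gff3(path: Path) -> list[Feature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise AnnotationError(f"GFF3 line needs 9 columns: {line!r}")
            _, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            attr = {}
            for kv in attrs.split(";"):
                kv = kv.strip()
                if kv and "=" in kv:
                    k, v = kv.split("=", 1)
                    attr[k] = v
            name = attr.get("Name") or attr.get("ID")
            if name is None:
                raise AnnotationError(f"GFF3 feature without Name/ID: {line!r}")
            kind = _parse_kind(attr.get("kind", ftype))
            incomplete = attr.get("incomplete_stop", "").lower() in ("1", "true")
            feats.append(Feature(name=name, kind=kind, start=int(start),
                                 end=int(end),
                                 strand=strand if strand in "+-" else "+",
                                 incomplete_stop=incomplete))
    return feats


def load_annotation(fasta_path: str | Path,
                    features_path: str | Path) -> MtGenomeAnnotation:
    """Load a single-record FASTA plus BED (0-based half-open) or GFF3
    (1-based inclusive) features; dialect chosen by file extension."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise AnnotationError(
            f"expected exactly one FASTA record, found {len(records)}")
    sequence = str(records[0].seq).upper()

    features_path = Path(features_path)
    if features_path.suffix.lower() == ".bed":
        feats = _read_bed(features_path)
    elif features_path.suffix.lower() in (".gff", ".gff3"):
        feats = _read_gff3(features_path)
    else:
        raise AnnotationError(
            f"cannot detect feature dialect from {features_path.name!r}")
    if not feats:
        logger.warning("feature file %s holds zero features", features_path)
    counts: dict[str, int] = {}
    for f in feats:
        counts[f.kind] = counts.get(f.kind, 0) + 1
    logger.info("loaded %d features: %s", len(feats), counts)
    return MtGenomeAnnotation(sequence=sequence, features=feats)


# -- classification operations -------------------------------------------

def translate_cds(ann: MtGenomeAnnotation, gene: str) -> str:
    """Translation of a protein gene up to (excluding) the first stop."""
    return ann.translate(ann.cds(gene), to_stop=True)


def count_ns_sites(ann: MtGenomeAnnotation, gene: str,
                   weights: Optional[dict[tuple[str, str], float]] = None
                   ) -> tuple[float, float]:
    """Non-synonymous and synonymous site counts for a protein gene.

    Every (codon, position, alt) point substitution is classified against
    the vertebrate mitochondrial code; each position contributes its
    fraction of non-synonymous / synonymous changes, so N + S equals the
    coding length in bp.  Stop-gaining and stop-losing changes count as
    non-synonymous.  ``weights`` optionally weights substitutions by
    (ref_base, alt_base) pair (hook for spectrum-aware counting); uniform
    by default.
    """
    cds = ann.cds(gene)
    n_sites = 0.0
    s_sites = 0.0
    for ci in range(0, len(cds), 3):
        codon = cds[ci:ci + 3]
        aa = ann.code[codon]
        for off in range(3):
            wn = ws = 0.0
            wtot = 0.0
            for alt in "ACGT":
                if alt == codon[off]:
                    continue
                w = 1.0 if weights is None else weights.get((codon[off], alt), 1.0)
                wtot += w
                mutated = codon[:off] + alt + codon[off + 1:]
                if ann.code[mutated] == aa:
                    ws += w
                else:
                    wn += w
            if wtot > 0:
                n_sites += wn / wtot
                s_sites += ws / wtot
    return n_sites, s_sites


def classify_substitution(ann: MtGenomeAnnotation, position: int,
                          alt: str) -> SiteClassification:
    """Effect of a single-base substitution at a genomic position."""
    if alt not in "ACGT" or len(alt) != 1:
        raise AnnotationError(f"bad alt allele {alt!r}")
    ref = ann.base(position)
    if alt == ref:
        raise AnnotationError(f"alt equals reference base {ref} at {position}")
    gene = ann.covering_gene(position)
    if gene is None:
        return SiteClassification(position, None, None, "noncoding")
    cds = ann.cds(gene.name)
    idx = ann.cds_index(gene.name, position)
    if idx >= len(cds):  # trailing partial codon of an incomplete-stop gene
        return SiteClassification(position, gene.name, None, "noncoding")
    codon_i = idx // 3
    off = idx % 3
    codon = cds[3 * codon_i:3 * codon_i + 3]
    alt_cds = alt if gene.strand == "+" else complement(alt)
    mutated = codon[:off] + alt_cds + codon[off + 1:]
    aa0, aa1 = ann.code[codon], ann.code[mutated]
    if aa0 == aa1:
        effect = "synonymous"
    elif aa1 == "*":
        effect = "nonsense"
    else:
        effect = "non-synonymous"
    return SiteClassification(position, gene.name, codon_i + 1, effect)


def frameshift_stop_scan(ann: MtGenomeAnnotation, gene: str, position: int,
                         insertion: Optional[str] = None,
                         deletion: Optional[str] = None
                         ) -> tuple[Optional[int], Optional[int]]:
    """First premature stop after applying a pure indel inside a gene.

    The indel is applied on the CDS in gene orientation: an insertion is
    placed immediately after the CDS base at ``position`` (VCF-anchored
    style); a deletion removes that many bases starting immediately after
    it.  Returns (1-based codon index of the first stop in the shifted
    frame, amino acids lost relative to the unmutated translation); both
    None when no stop exists before the sequence end.
    """
    if (insertion is None) == (deletion is None):
        raise AnnotationError("provide exactly one of insertion/deletion")
    cds = ann.cds(gene)
    f = ann.feature(gene)
    idx = ann.cds_index(gene, position)
    if insertion is not None:
        seq = insertion if f.strand == "+" else reverse_complement(insertion)
        mutated = cds[:idx + 1] + seq + cds[idx + 1:]
    else:
        seq = deletion if f.strand == "+" else reverse_complement(deletion)
        k = len(seq)
        if idx + 1 + k > len(cds):
            raise AnnotationError("deletion runs past the CDS end")
        mutated = cds[:idx + 1] + cds[idx + 1 + k:]
    if not mutated.startswith(cds[:3]) and idx < 3:
        raise AnnotationError("indel disrupts the start codon")
    stop_index = None
    for ci in range(0, len(mutated) - len(mutated) % 3, 3):
        if ann.code[mutated[ci:ci + 3]] == "*":
            stop_index = ci // 3 + 1
            break
    if stop_index is None:
        logger.warning("no stop codon found in shifted frame of %s", gene)
        return None, None
    wild_len = len(ann.translate(cds, to_stop=True))
    truncation = wild_len - (stop_index - 1)
    return stop_index, truncation
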