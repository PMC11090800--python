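import numpy as np
import pytest
from Bio.Seq import Seq

from mtsoma.genome import (AnnotationError, Feature, MtGenomeAnnotation,
                           VERTEBRATE_MITO_CODE, classify_substitution,
                           count_ns_sites, frameshift_stop_scan,
                           load_annotation, reverse_complement, translate_cds)

from conftest import make_single_gene_annotation, random_cds


# -- loading --------------------------------------------------------------

def write_fasta(path, seq, name="chrM"):
    path.write_text(f">{name}\n{seq}\n")


def test_load_bed_converts_to_one_based(tmp_path):
    seq = "ACGT" * 100
    write_fasta(tmp_path / "g.fa", seq)
    (tmp_path / "f.bed").write_text("chrM\t0\t9\tGENE1\tprotein\t+\n")
    ann = load_annotation(tmp_path / "g.fa", tmp_path / "f.bed")
    feat = ann.feature("GENE1")
    assert (feat.start, feat.end) == (1, 9)


def test_load_gff3_keeps_one_based(tmp_path):
    seq = "ACGT" * 2000
    write_fasta(tmp_path / "g.fa", seq)
    (tmp_path / "f.gff3").write_text(
        "chrM\tsrc\tgene\t3914\t4951\t.\t+\t.\tID=GENE1;kind=protein\n")
    ann = load_annotation(tmp_path / "g.fa", tmp_path / "f.gff3")
    feat = ann.feature("GENE1")
    assert (feat.start, feat.end) == (3914, 4951)


def test_load_empty_features_warns(tmp_path, caplog):
    write_fasta(tmp_path / "g.fa", "ACGT" * 10)
    (tmp_path / "f.bed").write_text("")
    with caplog.at_level("WARNING"):
        ann = load_annotation(tmp_path / "g.fa", tmp_path / "f.bed")
    assert ann.features == []
    assert any("zero features" in r.message for r in caplog.records)


def test_load_rejects_multiple_records(tmp_path):
    (tmp_path / "g.fa").write_text(">a\nACGT\n>b\nACGT\n")
    (tmp_path / "f.bed").write_text("")
    with pytest.raises(AnnotationError, match="one FASTA record"):
        load_annotation(tmp_path / "g.fa", tmp_path / "f.bed")


def test_feature_outside_genome_rejected():
    with pytest.raises(AnnotationError, match="outside"):
        MtGenomeAnnotation(sequence="ACGTACGT",
                           features=[Feature("X", "tRNA", 1, 99)])


def test_unknown_kind_rejected():
    with pytest.raises(AnnotationError, match="unknown feature kind"):
        Feature("X", "exon", 1, 5)


# -- region classification ------------------------------------------------

def test_classify_region_priority_and_default():
    ann = MtGenomeAnnotation(
        sequence="A" * 100,
        features=[Feature("g", "protein", 10, 39),
                  Feature("t", "tRNA", 30, 50),
                  Feature("o", "OriL", 45, 48)])
    assert ann.classify_region(15) == "protein"
    assert ann.classify_region(35) == "tRNA"      # tRNA beats protein
    assert ann.classify_region(46) == "OriL"      # OriL beats tRNA
    assert ann.classify_region(99) == "other-noncoding"
    with pytest.raises(AnnotationError):
        ann.classify_region(101)


def test_wrap_around_feature_contains_origin():
    ann = MtGenomeAnnotation(sequence="A" * 50,
                             features=[Feature("d", "D-loop", 45, 5)])
    assert ann.classify_region(48) == "D-loop"
    assert ann.classify_region(3) == "D-loop"
    assert ann.classify_region(20) == "other-noncoding"


# -- translation ----------------------------------------------------------

def test_translate_tga_is_trp():
    ann = make_single_gene_annotation("ATGTGATAA")
    assert translate_cds(ann, "GENE1") == "MW"


def test_translate_aga_is_stop():
    ann = make_single_gene_annotation("ATGAGAAAA")
    assert translate_cds(ann, "GENE1") == "M"


def test_minus_strand_translation_matches_plus_of_revcomp():
    cds = "ATGTGATGGTAA"
    minus = make_single_gene_annotation(cds, strand="-")
    plus = make_single_gene_annotation(cds, strand="+")
    assert translate_cds(minus, "GENE1") == translate_cds(plus, "GENE1")


def test_incomplete_stop_truncates_partial_codon():
    # 7-bp span: final partial codon dropped under the incomplete-stop flag
    seq = "ATGAAAG" + "CCC"
    ann = MtGenomeAnnotation(
        sequence=seq,
        features=[Feature("G", "protein", 1, 7, incomplete_stop=True)])
    assert ann.cds("G") == "ATGAAA"
    with pytest.raises(AnnotationError, match="divisible by 3"):
        MtGenomeAnnotation(
            sequence=seq,
            features=[Feature("G", "protein", 1, 7)]).cds("G")


# -- N/S site counting ----------------------------------------------------

def test_ggg_codon_sites():
    ann = make_single_gene_annotation("GGG")
    assert count_ns_sites(ann, "GENE1") == pytest.approx((2.0, 1.0))


def test_atg_codon_sites():
    # position 3: ATA is also Met in the vertebrate mito code
    ann = make_single_gene_annotation("ATG")
    n, s = count_ns_sites(ann, "GENE1")
    assert s == pytest.approx(1 / 3)
    assert n == pytest.approx(3 - 1 / 3)


def brute_force_ns_sites(cds: str) -> tuple[float, float]:
    """Independent oracle: enumerate all (codon, position, alt) triples and
    translate with biopython's vertebrate mitochondrial table."""
    n = s = 0.0
    for ci in range(0, len(cds), 3):
        codon = cds[ci:ci + 3]
        aa = str(Seq(codon).translate(table=2))
        for off in range(3):
            for alt in "ACGT":
                if alt == codon[off]:
                    continue
                mutated = codon[:off] + alt + codon[off + 1:]
                if str(Seq(mutated).translate(table=2)) == aa:
                    s += 1 / 3
                else:
                    n += 1 / 3
    return n, s


def test_ns_sites_match_brute_force_on_random_genes():
    rng = np.random.default_rng(11)
    for _ in range(50):
        cds = random_cds(rng, int(rng.integers(5, 40)))
        ann = make_single_gene_annotation(cds)
        n, s = count_ns_sites(ann, "GENE1")
        n0, s0 = brute_force_ns_sites(cds)
        assert n == pytest.approx(n0)
        assert s == pytest.approx(s0)
        assert n + s == pytest.approx(len(cds))  # coding length in bp


def test_ns_sites_sum_for_simulated_genes(sim_ann):
    for feat in sim_ann.protein_genes:
        n, s = count_ns_sites(sim_ann, feat.name)
        assert n + s == pytest.approx(feat.span_length(sim_ann.length))


# -- substitution classification ------------------------------------------

def test_third_position_gly_synonymous():
    ann = make_single_gene_annotation("ATGGGATAA")
    # GGA -> GGC at CDS position 6
    cls = classify_substitution(ann, 6, "C")
    assert cls.effect == "synonymous"
    assert cls.gene == "GENE1"
    assert cls.codon_index == 2


def test_tga_third_position_synonymous():
    ann = make_single_gene_annotation("ATGTGACCC")
    # TGA -> TGG, Trp -> Trp under the vertebrate mito code
    assert classify_substitution(ann, 6, "G").effect == "synonymous"


def test_d_loop_position_noncoding():
    ann = make_single_gene_annotation("ATGTAA", flank="ACGTACGT")
    assert classify_substitution(ann, 3, "A").effect == "noncoding"


def test_nonsense_reported_distinctly():
    ann = make_single_gene_annotation("ATGTGGTAA")
    # TGG -> TGA would be Trp; TGG -> TAG is a stop
    assert classify_substitution(ann, 5, "A").effect == "nonsense"


def test_alt_equal_ref_rejected():
    ann = make_single_gene_annotation("ATGTAA")
    with pytest.raises(AnnotationError):
        classify_substitution(ann, 1, "A")


def test_minus_strand_matches_complemented_plus():
    rng = np.random.default_rng(5)
    cds = random_cds(rng, 12)
    minus = make_single_gene_annotation(cds, strand="-")
    plus = make_single_gene_annotation(cds, strand="+")
    L = len(cds)
    for plus_pos in range(1, L + 1):
        minus_pos = L - plus_pos + 1
        ref_plus = plus.base(plus_pos)
        for alt in "ACGT":
            if alt == ref_plus:
                continue
            a = classify_substitution(plus, plus_pos, alt).effect
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            b = classify_substitution(minus, minus_pos, comp[alt]).effect
            assert a == b


# -- frameshift scanning --------------------------------------------------

def test_frameshift_deletion_example():
    # deleting the A after CDS position 3 shifts ATG AAA GGG TAA
    # to ATG AAG GGT AA: no stop before the sequence end
    ann = make_single_gene_annotation("ATGAAAGGGTAA")
    stop, trunc = frameshift_stop_scan(ann, "GENE1", 3, deletion="A")
    assert stop is None and trunc is None


def test_frameshift_insertion_creates_stop():
    # ATG GAA CCC TAA translates to MEP; inserting A after CDS position 3
    # shifts the frame to ATG AGA ..., and AGA is a stop in the vertebrate
    # mito code, so the premature stop sits at codon 2
    cds = "ATGGAACCCTAA"
    ann = make_single_gene_annotation(cds)
    stop, trunc = frameshift_stop_scan(ann, "GENE1", 3, insertion="A")
    assert stop == 2
    assert trunc == len("MEP") - (stop - 1) == 2
    # cross-check with a hand scan of the shifted frame
    shifted = cds[:3] + "A" + cds[3:]
    expect = next(i // 3 + 1 for i in range(0, len(shifted) - 2, 3)
                  if VERTEBRATE_MITO_CODE[shifted[i:i + 3]] == "*")
    assert stop == expect


def test_insertion_then_deletion_restores_wild_type():
    # apply an in-frame TTT insertion to the gene, then scan the mutated
    # annotation with the inverse deletion: the wild-type stop returns
    cds = "ATGAAAGGGCCCTAA"
    natural_stop = len("MKGP") + 1
    mutated = cds[:6] + "TTT" + cds[6:]
    ann_mut = make_single_gene_annotation(mutated)
    stop, trunc = frameshift_stop_scan(ann_mut, "GENE1", 6, deletion="TTT")
    assert stop == natural_stop
    # the mutated gene translates one codon longer than the restored frame
    assert trunc == 1


def test_minus_strand_frameshift():
    cds = "ATGGAACCCTAA"
    plus = make_single_gene_annotation(cds, strand="+")
    minus = make_single_gene_annotation(cds, strand="-")
    stop_p, _ = frameshift_stop_scan(plus, "GENE1", 3, insertion="A")
    # CDS position 3 of the minus-strand gene sits at genome position
    # len(cds) - 2, and the inserted base must be complemented
    stop_m, _ = frameshift_stop_scan(minus, "GENE1", len(cds) - 2,
                                     insertion="T")
    assert stop_p == 2
    assert stop_m == stop_p
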