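import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from mtsoma.genome import classify_substitution
from mtsoma.selection import (EFFECT_NONE, EFFECT_NONSYN, EFFECT_SYN,
                              EffectTable, FrequencyBins, _BASE_INDEX,
                              _empirical_p, _simulate_gene_ns,
                              empirical_selection_test, binned_selection_scan,
                              ns_frequency_spectra, null_ns_spectrum,
                              observed_hnhs, simulate_null)
from mtsoma.spectra import MUTATION_CLASSES, classify_mutation
from mtsoma.variants import ConditionTable

from conftest import make_single_gene_annotation

BASES = "ACGT"


def make_condition(depth, call_specs, strain="B6"):
    calls = pd.DataFrame(call_specs,
                         columns=["position", "ref", "alt", "alt_depth"])
    return ConditionTable(strain, "brain", "young",
                          np.asarray(depth, np.int64), calls)


# -- effect table agrees with the per-site classifier ---------------------

def test_effect_table_matches_classify_substitution(sim_ann):
    table = EffectTable(sim_ann)
    rng = np.random.default_rng(0)
    for pos in rng.integers(1, sim_ann.length + 1, size=400):
        pos = int(pos)
        ref = sim_ann.base(pos)
        for alt in BASES:
            if alt == ref:
                continue
            expected = classify_substitution(sim_ann, pos, alt).effect
            got = table.effect[pos - 1, _BASE_INDEX[alt]]
            if expected == "noncoding":
                assert got == EFFECT_NONE
            elif expected == "synonymous":
                assert got == EFFECT_SYN
            else:  # non-synonymous or nonsense both pool into hN
                assert got == EFFECT_NONSYN


# -- observed statistic ---------------------------------------------------

def test_observed_hnhs_arithmetic():
    # gene GGG GGG: positions 3 and 6 are synonymous sites for G>A
    ann = make_single_gene_annotation("GGGGGG")
    table = EffectTable(ann)
    cond = make_condition([1000] * 12,
                          [(1, "G", "A", 3), (2, "G", "A", 2),
                           (3, "G", "A", 5)])
    n_sites, s_sites = table.n_sites[0], table.s_sites[0]
    hn, hs, ratio = observed_hnhs(cond, ann, "GENE1", table=table)
    assert hn == pytest.approx(5 / n_sites)
    assert hs == pytest.approx(5 / s_sites)
    assert ratio == pytest.approx((5 / n_sites) / (5 / s_sites))


def test_observed_hnhs_zero_hs_excluded():
    ann = make_single_gene_annotation("GGGGGG")
    cond = make_condition([1000] * 12, [(1, "G", "A", 3)])
    hn, hs, ratio = observed_hnhs(cond, ann, "GENE1")
    assert hs == 0 and ratio is None


def test_unit_weighting_all_synonymous_gene():
    ann = make_single_gene_annotation("GGGGGG")
    cond = make_condition([1000] * 12,
                          [(3, "G", "A", 9), (6, "G", "A", 1),
                           (1, "G", "A", 1)])
    hn, hs, ratio = observed_hnhs(cond, ann, "GENE1", weighting="unit")
    assert ratio is not None and ratio < 1


# -- null simulation ------------------------------------------------------

def test_simulate_null_empty():
    ann = make_single_gene_annotation("GGGGGG")
    props = pd.Series({c: 1 / 8 for c in MUTATION_CLASSES})
    sim = simulate_null(ann, 0, props, seed=1)
    assert len(sim) == 0


def test_simulate_null_compatibility_contract():
    ann = make_single_gene_annotation("GGGCCCAAATTT")
    props = pd.Series({c: 0.0 for c in MUTATION_CLASSES})
    props["G>A/C>T"] = 1.0
    sim = simulate_null(ann, 200, props, seed=2)
    refs = {ann.base(int(p)) for p in sim["position"]}
    assert refs <= {"G", "C"}
    # the implied alt matches the class at each reference base
    for row in sim.itertuples(index=False):
        assert classify_mutation(row.ref, row.alt) == "G>A/C>T"


def test_simulate_null_deterministic():
    ann = make_single_gene_annotation("GGGCCCAAATTT")
    props = pd.Series({c: 1 / 8 for c in MUTATION_CLASSES})
    a = simulate_null(ann, 50, props, seed=7)
    b = simulate_null(ann, 50, props, seed=7)
    pd.testing.assert_frame_equal(a, b)


def test_multinomial_law_of_class_counts(sim_ann, effect_table):
    # over 1,000 draws of n_mut=1,000 the per-class totals obey the
    # multinomial mean within 3 SE
    props = np.array([0.3, 0.2, 0.1, 0.15, 0.1, 0.05, 0.04, 0.06])
    rng = np.random.default_rng(11)
    n_sim, n_mut = 1000, 1000
    counts = rng.multinomial(n_mut, props, size=n_sim)
    for ci in range(8):
        mean = counts[:, ci].mean()
        se = np.sqrt(n_mut * props[ci] * (1 - props[ci]) / n_sim)
        assert abs(mean - n_mut * props[ci]) < 3 * se


def test_simulated_gene_counts_match_binomial_enumeration():
    # two-codon gene GGG GGG with only G>A/C>T mutations: each of the six
    # coding positions is equally likely; positions 3 and 6 are synonymous
    # (p_syn = 1/3).  With n_mut draws the (nonsyn, syn) counts follow a
    # binomial law; compare the vectorized simulator against it.
    ann = make_single_gene_annotation("GGGGGG", pad="AAAAAA")
    table = EffectTable(ann)
    probs = np.zeros(8)
    probs[list(MUTATION_CLASSES).index("G>A/C>T")] = 1.0
    n_mut, n_sim = 4, 40_000
    rng = np.random.default_rng(3)
    sims = _simulate_gene_ns(table, n_mut, probs, n_sim, rng)
    nonsyn = sims[:, 0, 0]
    # compatible positions include the 6 gene Gs only (pad is A)
    p_nonsyn = 4 / 6
    from scipy import stats
    for k in range(n_mut + 1):
        expected = stats.binom.pmf(k, n_mut, p_nonsyn)
        observed = np.mean(nonsyn == k)
        se = np.sqrt(expected * (1 - expected) / n_sim)
        assert abs(observed - expected) < 4 * se


# -- empirical p behaviour ------------------------------------------------

def test_empirical_p_extreme_observation():
    sims = np.linspace(0.1, 0.9, 1000)
    p, floor = _empirical_p(2.0, sims)
    assert p == 0.0
    assert floor == pytest.approx(2 / 1000)


def test_empirical_p_at_median():
    sims = np.arange(1, 1002, dtype=float)
    p, floor = _empirical_p(501.0, sims)
    assert p == 1.0 and floor is None


def test_selection_test_median_observation_p_near_one(sim_ann, effect_table):
    # build observed calls directly from the null simulator, so the
    # observed ratio sits inside the simulated distribution
    props = pd.Series({c: 1 / 8 for c in MUTATION_CLASSES})
    sim = simulate_null(sim_ann, 400, props, seed=5, table=effect_table)
    cond = ConditionTable("B6", "brain", "young",
                          np.full(sim_ann.length, 10_000, np.int64), sim)
    results = empirical_selection_test(cond, sim_ann, n_sim=400, seed=6,
                                       weighting="unit", table=effect_table)
    tested = [r for r in results if not r.excluded]
    assert tested, "at least one gene should be testable"
    assert all(r.p is not None and r.p > 0.001 for r in tested)
    assert all(r.direction == "none" for r in tested)


# -- frequency bins -------------------------------------------------------

def test_bins_validate_and_assign():
    bins = FrequencyBins()
    idx = bins.assign(np.array([5e-6, 1e-5, 6e-5, 1e-3, 0.5, 1.0]))
    assert idx.tolist() == [0, 1, 2, 3, 3, -1]
    with pytest.raises(ValueError):
        FrequencyBins((0.1, 0.1))


def test_ns_frequency_spectra_unit_sum():
    ann = make_single_gene_annotation("GGGGGG", pad="AAAAAA")
    cond = make_condition([100_000] * 12,
                          [(1, "G", "A", 1),       # nonsyn, 1e-5 -> bin 1
                           (3, "G", "A", 30),      # syn, 3e-4 -> bin 2
                           (2, "G", "A", 2)])      # nonsyn, 2e-5 -> bin 1
    props = ns_frequency_spectra(cond, ann)
    assert props["nonsynonymous"].sum() == pytest.approx(1.0)
    assert props["synonymous"].sum() == pytest.approx(1.0)
    assert props.loc[2, "synonymous"] == pytest.approx(1.0)
    assert props.loc[1, "nonsynonymous"] == pytest.approx(1.0)


def test_ns_frequency_spectra_errors_without_both_classes():
    ann = make_single_gene_annotation("GGGGGG", pad="AAAAAA")
    cond = make_condition([1000] * 12, [(1, "G", "A", 1)])
    with pytest.raises(ValueError, match="zero"):
        ns_frequency_spectra(cond, ann)


# -- null N/S spectrum ----------------------------------------------------

def brute_force_null_spectrum(ann):
    """Independent oracle: classify every coding (position, alt) change by
    translating with biopython and collapsing classes by complement."""
    tallies = {}
    for gene in ann.protein_genes:
        cds = ann.cds(gene.name)
        positions = list(gene.positions(ann.length))
        for plus_idx, pos in enumerate(positions):
            if ann.classify_region(pos) != "protein":
                continue
            idx = plus_idx if gene.strand == "+" else \
                len(positions) - 1 - plus_idx
            codon_i, off = divmod(idx, 3)
            codon = cds[3 * codon_i:3 * codon_i + 3]
            ref = ann.base(pos)
            for alt in BASES:
                if alt == ref:
                    continue
                alt_cds = alt if gene.strand == "+" else \
                    {"A": "T", "C": "G", "G": "C", "T": "A"}[alt]
                mutated = codon[:off] + alt_cds + codon[off + 1:]
                syn = str(Seq(mutated).translate(table=2)) == \
                    str(Seq(codon).translate(table=2))
                cls = classify_mutation(ref, alt)
                key = (cls, "syn" if syn else "nonsyn")
                tallies[key] = tallies.get(key, 0) + 1
    return tallies


def test_null_ns_spectrum_matches_brute_force():
    ann = make_single_gene_annotation("ATGGGGCCCAAATTTTGA", pad="ACGTAC")
    spectrum = null_ns_spectrum(ann).set_index("mutation_class")
    oracle = brute_force_null_spectrum(ann)
    total_n = sum(v for (c, e), v in oracle.items() if e == "nonsyn")
    total_s = sum(v for (c, e), v in oracle.items() if e == "syn")
    for cls in spectrum.index:
        assert spectrum.loc[cls, "nonsynonymous"] == pytest.approx(
            oracle.get((cls, "nonsyn"), 0) / total_n)
        assert spectrum.loc[cls, "synonymous"] == pytest.approx(
            oracle.get((cls, "syn"), 0) / total_s)


def test_null_ns_spectrum_toy_gene_all_syn_third_position():
    ann = make_single_gene_annotation("GGGGGG", pad="AAAAAA")
    spectrum = null_ns_spectrum(ann)
    assert spectrum["nonsynonymous"].sum() == pytest.approx(1.0)
    assert spectrum["synonymous"].sum() == pytest.approx(1.0)


def test_null_ns_spectrum_on_simulated_genome(sim_ann, effect_table):
    spectrum = null_ns_spectrum(sim_ann, effect_table)
    assert spectrum["nonsynonymous"].sum() == pytest.approx(1.0)
    assert spectrum["synonymous"].sum() == pytest.approx(1.0)


# -- binned scan consistency ----------------------------------------------

def test_binned_scan_single_bin_matches_aggregate(sim_ann, effect_table):
    props = pd.Series({c: 1 / 8 for c in MUTATION_CLASSES})
    sim = simulate_null(sim_ann, 300, props, seed=8, table=effect_table)
    depth = np.full(sim_ann.length, 10_000, np.int64)
    cond = ConditionTable("B6", "brain", "young", depth, sim)
    # every unit-weight call has frequency 1e-4: all fall in [5e-5, 1e-3)
    bins = FrequencyBins((5e-5, 1e-3))
    binned = binned_selection_scan(cond, sim_ann, bins=bins, n_sim=300,
                                   seed=9, weighting="unit",
                                   exclude_d_loop=False, table=effect_table)
    aggregate = empirical_selection_test(cond, sim_ann, n_sim=300, seed=9,
                                         weighting="unit",
                                         high_frequency_cutoff=None,
                                         table=effect_table)
    for rb, ra in zip(binned, aggregate):
        assert rb.gene == ra.gene
        if ra.ratio is not None:
            assert rb.ratio == pytest.approx(ra.ratio)
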