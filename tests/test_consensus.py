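import numpy as np
import pytest

import strainkin as sk
from strainkin.consensus import (consensus_from_matrix, distance_matrix,
                                 extract_core, nj_tree, random_reference)

from conftest import build_small_pop


@pytest.fixture(scope="module")
def panel():
    """Three founder clades, each with a mutation-free clone and a selfed
    derivative, over a tiny two-chromosome reference."""
    pop = sk.simulate_founders(sk.make_layout(2, 20_000), 3,
                               snp_density=0.005, het_rate=0.3, seed=31)
    rng = np.random.default_rng(32)
    for i, f in enumerate(list(pop.strains)):
        pop.derive(sk.PedigreeRecord(f"{f}cl", "clone", (f,),
                                     n_mutations=0), rng)
        pop.derive(sk.PedigreeRecord(f"{f}sf", "self", (f,)), rng)
    matrix = sk.matrix_from_population(pop)
    reference = random_reference(pop.focal, 33, sites=matrix.sites)
    return pop, matrix, reference


# ---------------------------------------------------------------------------
# consensus patching
# ---------------------------------------------------------------------------

def test_no_variants_full_coverage_equals_reference(panel):
    _, _, reference = panel
    cons = sk.patch_consensus(reference, [])
    assert cons.sequences == reference


def test_het_call_becomes_iupac_code(panel):
    _, _, reference = panel
    cons = sk.patch_consensus(reference,
                              [("Scer_chrI", 10, ("A", "T")),
                               ("Scer_chrI", 11, ("C", "G")),
                               ("Scer_chrI", 12, ("T", "T"))])
    assert cons.sequences["Scer_chrI"][10] == "W"
    assert cons.sequences["Scer_chrI"][11] == "S"
    assert cons.sequences["Scer_chrI"][12] == "T"


def test_mask_wins_and_missing_becomes_n(panel):
    _, _, reference = panel
    cons = sk.patch_consensus(reference,
                              [("Scer_chrI", 5, None),
                               ("Scer_chrI", 100, ("A", "A"))],
                              mask={"Scer_chrI": [(90, 110)]})
    seq = cons.sequences["Scer_chrI"]
    assert seq[5] == "N"
    assert seq[90:110] == "N" * 20


def test_non_nucleotide_allele_rejected(panel):
    _, _, reference = panel
    with pytest.raises(ValueError):
        sk.patch_consensus(reference, [("Scer_chrI", 0, ("A", "X"))])
    with pytest.raises(KeyError):
        sk.patch_consensus(reference, [("nope", 0, ("A", "A"))])


def test_differences_from_reference_equal_variant_call_set(panel):
    """Set comparison: consensus-vs-reference mismatches are exactly the
    strain's het + hom-alt calls."""
    _, matrix, reference = panel
    strain = matrix.strains[0]
    cons = consensus_from_matrix(reference, matrix, strain)
    diffs = set()
    for contig, seq in cons.sequences.items():
        ref = reference[contig]
        diffs |= {(contig, i) for i, (a, b) in enumerate(zip(seq, ref))
                  if a != b}
    j = matrix.strain_index(strain)
    ref_codes = matrix.sites["ref"].map({"A": 0, "C": 1, "G": 2, "T": 3})
    g = matrix.geno[:, j]
    expect = {(c, p) for c, p, r, (a, b) in zip(
        matrix.sites["chrom"], matrix.sites["pos"], ref_codes, g)
        if not (a == b == r)}
    assert diffs == expect


# ---------------------------------------------------------------------------
# core alignment
# ---------------------------------------------------------------------------

def test_full_coverage_core_is_whole_reference(panel):
    _, matrix, reference = panel
    cons = [consensus_from_matrix(reference, matrix, s)
            for s in matrix.strains[:3]]
    core = extract_core(cons)
    assert core.length == sum(len(s) for s in reference.values())


def test_masked_strain_shrinks_core_by_union(panel):
    """Planted masks with a known union: core length equals reference
    length minus the union size (exact set algebra, boolean-array oracle)."""
    _, matrix, reference = panel
    masks = {
        matrix.strains[0]: {"Scer_chrI": [(0, 1_000), (5_000, 7_000)]},
        matrix.strains[1]: {"Scer_chrI": [(500, 1_500)],
                            "Scer_chrII": [(100, 200)]},
    }
    cons = [consensus_from_matrix(reference, matrix, s, masks.get(s))
            for s in matrix.strains[:4]]
    core = extract_core(cons)
    union = 0
    for contig in reference:
        covered = np.zeros(len(reference[contig]), dtype=bool)
        for m in masks.values():
            for s, e in m.get(contig, []):
                covered[s:e] = True
        union += int(covered.sum())
    ref_len = sum(len(s) for s in reference.values())
    assert core.length == ref_len - union
    # one strain masked over 10% of chrI -> core <= reference
    assert core.length <= ref_len


def test_core_monotone_nonincreasing_as_strains_added(panel):
    _, matrix, reference = panel
    rng = np.random.default_rng(1)
    cons = []
    lengths = []
    for k, s in enumerate(matrix.strains):
        start = int(rng.integers(0, 15_000))
        cons.append(consensus_from_matrix(
            reference, matrix, s,
            {"Scer_chrI": [(start, start + 2_000)]}))
        if k >= 1:
            lengths.append(extract_core(cons).length)
    assert all(a >= b for a, b in zip(lengths, lengths[1:]))


def test_variant_only_mode_drops_constant_columns(panel):
    _, matrix, reference = panel
    cons = [consensus_from_matrix(reference, matrix, s)
            for s in matrix.strains[:3]]
    core = extract_core(cons, variant_only=True)
    assert core.length < 2_000  # only polymorphic columns remain
    assert all((col != col[0]).any() for col in core.columns.T[:50])


def test_mismatched_references_rejected(panel):
    _, matrix, reference = panel
    a = consensus_from_matrix(reference, matrix, matrix.strains[0])
    other = {k: v[:-1] for k, v in reference.items()}
    b = sk.patch_consensus(other, [])
    b.strain = "odd"
    with pytest.raises(ValueError, match="reference"):
        extract_core([a, b])


# ---------------------------------------------------------------------------
# distances and the NJ tree
# ---------------------------------------------------------------------------

def test_ambiguity_scores_half_difference(panel):
    _, _, reference = panel
    a = sk.patch_consensus(reference, [("Scer_chrI", 0, ("A", "T"))])
    a.strain = "a"
    b = sk.patch_consensus(reference, [])
    b.strain = "b"
    c = sk.patch_consensus(reference, [("Scer_chrI", 0, ("C", "G"))])
    c.strain = "c"
    core = extract_core([a, b, c])
    dm = distance_matrix(core)
    n = core.length
    ref_base = reference["Scer_chrI"][0]
    # W vs the reference base (A or T inside W): half difference
    expected_ab = (0.5 if ref_base in "AT" else 1.0) / n
    assert dm["a", "b"] == pytest.approx(expected_ab)
    assert dm["a", "c"] == pytest.approx(1.0 / n)  # disjoint alleles


def test_mutation_free_clones_have_zero_distance(panel):
    pop, matrix, reference = panel
    cons = [consensus_from_matrix(reference, matrix, s)
            for s in ["F01", "F01cl", "F02"]]
    dm = distance_matrix(extract_core(cons))
    assert dm["F01", "F01cl"] == 0.0
    assert dm["F01", "F02"] > 0.0


def test_nj_recovers_planted_clades(panel):
    pop, matrix, reference = panel
    cons = [consensus_from_matrix(reference, matrix, s)
            for s in matrix.strains]
    tree = nj_tree(distance_matrix(extract_core(cons)))
    tips = {t.name for t in tree.tips()}
    clades = [{f, f + "cl", f + "sf"} for f in ["F01", "F02", "F03"]]
    splits = [frozenset(t.name for t in node.tips())
              for node in tree.non_tips(include_self=True)]
    for clade in clades:
        assert any(s == clade or s == frozenset(tips - clade)
                   for s in map(set, splits)), clade


def test_nj_invariant_to_input_order(panel):
    pop, matrix, reference = panel
    cons = [consensus_from_matrix(reference, matrix, s)
            for s in matrix.strains]
    t1 = nj_tree(distance_matrix(extract_core(cons)))
    t2 = nj_tree(distance_matrix(extract_core(cons[::-1])))
    assert str(t1) == str(t2)


def test_tree_needs_three_strains(panel):
    _, matrix, reference = panel
    cons = [consensus_from_matrix(reference, matrix, s)
            for s in matrix.strains[:2]]
    with pytest.raises(ValueError):
        nj_tree(distance_matrix(extract_core(cons)))
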