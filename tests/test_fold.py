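"""Folding engine: DP vs exhaustive enumeration, candidate criteria, catalogs."""

import random

import pytest

from jellyseq.fold import (
    DEFAULT_MODEL, EnergyModel, HairpinCandidate, criteria_check,
    dotbracket_to_pairs, extract_window, fold_exhaustive, fold_mfe,
    inventory_overlap, match_catalog, pairs_to_dotbracket, reverse_complement,
    structure_energy,
)
from jellyseq.synthio import make_hairpin


def test_fold_matches_exhaustive_enumeration(rng):
    """The DP minimum equals the minimum over every non-crossing structure."""
    for _ in range(80):
        n = rng.randint(5, 25)
        seq = "".join(rng.choice("ACGU") for _ in range(n))
        structure, mfe = fold_mfe(seq)
        _, mfe_ref = fold_exhaustive(seq)
        assert mfe == pytest.approx(mfe_ref, abs=1e-9), seq
        assert structure_energy(seq, dotbracket_to_pairs(structure)) == pytest.approx(mfe)


def test_unpairable_sequence_folds_open():
    structure, mfe = fold_mfe("AAAAAAAAAAAAAAAA")
    assert structure == "." * 16
    assert mfe == 0.0


def test_mfe_never_positive(rng):
    for _ in range(30):
        seq = "".join(rng.choice("ACGU") for _ in range(rng.randint(1, 40)))
        _, mfe = fold_mfe(seq)
        assert mfe <= 0.0


def test_extending_a_stem_never_raises_mfe():
    """Each added complementary stem pair can only stabilise the fold."""
    prev = 0.0
    for k in range(4, 12):
        arm = ("GC" * k)[:k]
        seq = arm + "AAAA" + reverse_complement(arm).replace("T", "U")
        _, mfe = fold_mfe(seq)
        assert mfe <= prev + 1e-9
        prev = mfe


def test_t_and_u_are_synonyms():
    s_dna = "GCGCGCAAAAGCGCGC"
    s_rna = s_dna.replace("T", "U")
    assert fold_mfe(s_dna) == fold_mfe(s_rna)


def test_invalid_alphabet_rejected():
    with pytest.raises(ValueError):
        fold_mfe("ACGTX")


def test_energy_model_validation():
    with pytest.raises(ValueError):
        EnergyModel(pair_stack_energies={"GC": 1.0})
    with pytest.raises(ValueError):
        EnergyModel(min_loop=2)


# --- window extraction ----------------------------------------------------

def test_window_centred_and_truncated():
    genome = "ACGT" * 2500
    w, span = extract_window(genome, 500, 22, window=100)
    assert len(w) == 100 and span == (39, 61)
    assert w[span[0]:span[1]] == genome[500:522]
    # near the contig start the window is truncated but the span stays valid
    w2, span2 = extract_window(genome, 10, 22, window=100)
    assert len(w2) == 100 and w2[span2[0]:span2[1]] == genome[10:32]


def test_minus_strand_window_is_reverse_complement():
    rng = random.Random(5)
    genome = "".join(rng.choice("ACGT") for _ in range(400))
    w_plus, span_plus = extract_window(genome, 200, 20, "+", window=80)
    w_minus, span_minus = extract_window(genome, 200, 20, "-", window=80)
    assert w_minus == reverse_complement(w_plus)
    assert w_minus[span_minus[0]:span_minus[1]] == reverse_complement(
        w_plus[span_plus[0]:span_plus[1]])


# --- candidate criteria ---------------------------------------------------

def test_planted_hairpin_passes_all_criteria():
    mature = "ACGGTTCAGCTAGGCATAGGCA"[:22]
    prec = make_hairpin(mature, stem_pairs=26, loop_len=8)
    assert len(prec) == 60 and prec.startswith(mature)
    structure, mfe = fold_mfe(prec)
    cand = criteria_check(HairpinCandidate(prec, structure, mfe, (0, 22), "intergenic"))
    assert cand.verdict and cand.arm == "5p" and cand.failed == []
    assert mfe < -20


def test_exonic_hairpin_fails_only_location():
    prec = make_hairpin("ACGGTTCAGCTAGGCATAGGCA", 26, 8)
    structure, mfe = fold_mfe(prec)
    cand = criteria_check(HairpinCandidate(prec, structure, mfe, (0, 22), "exon"))
    assert not cand.verdict and cand.failed == ["c"]


def test_weak_stem_fails_energy_criterion():
    """A 6-pair A:U stem folds at only -6 kcal/mol, above the -20 cutoff."""
    arm = "AUAUAU"
    seq = arm + "CCCC" + reverse_complement(arm)
    structure, mfe = fold_mfe(seq)
    cand = criteria_check(HairpinCandidate(seq, structure, mfe, (0, 6), "intergenic"))
    assert mfe > -20 and "b" in cand.failed and "c" not in cand.failed


def test_mature_straddling_loop_fails_arm_criterion():
    prec = make_hairpin("ACGGTTCAGCTAGGCATAGGCA", 26, 8)
    structure, mfe = fold_mfe(prec)
    # a span across the terminal loop cannot sit on a single arm
    cand = criteria_check(HairpinCandidate(prec, structure, mfe, (20, 42), "intergenic"))
    assert cand.arm == "none" and "a" in cand.failed


# --- catalog matching and inventories -------------------------------------

@pytest.mark.parametrize("query,max_mm,expected", [
    ("ACGGTTCAGCTAGGCATAGGCA", 0, "mir-x"),
    ("ACGGTTCAGCTAGGCATAGGCT", 0, "novel"),
    ("ACGGTTCAGCTAGGCATAGGCT", 1, "mir-x"),
    ("ACGGUUCAGCUAGGCAUAGGCA", 0, "mir-x"),  # RNA alphabet query
])
def test_match_catalog(query, max_mm, expected):
    catalog = {"mir-x": "ACGGTTCAGCTAGGCATAGGCA", "mir-y": "TTTTTTTTTTTTTTTTTTTTT"}
    assert match_catalog(query, catalog, max_mismatch=max_mm) == expected


def test_match_catalog_tie_breaks_lexicographically():
    seq = "ACGGTTCAGCTAGGCATAGGCA"
    assert match_catalog(seq, {"mir-b": seq, "mir-a": seq}) == "mir-a"


def test_inventory_overlap_counts():
    a = {f"m{i}" for i in range(69)}
    b = set(list(a)[:46]) | {"x1", "x2"}
    a_spec, b_spec, shared, counts = inventory_overlap(a, b)
    assert counts == {"a_total": 69, "b_total": 48, "a_specific": 23,
                      "b_specific": 2, "shared": 46}
    assert counts["a_total"] == counts["a_specific"] + counts["shared"]
    a_spec, b_spec, shared, counts = inventory_overlap({"m1"}, {"m1"})
    assert a_spec == [] and b_spec == [] and shared == ["m1"]


def test_dotbracket_roundtrip():
    s = "((..((...))..))..."
    assert pairs_to_dotbracket(len(s), dotbracket_to_pairs(s)) == s
    with pytest.raises(ValueError):
        dotbracket_to_pairs("((.)")
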