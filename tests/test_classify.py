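"""Tag collapsing, one-mismatch mapping vs brute force, annotation, overlaps."""

import pytest

from jellyseq.classify import (Tag, annotate_tags, category_summary,
                               collapse_tags, map_tags, overlap_summary)
from jellyseq.clean import percent
from jellyseq.synthio import Feature

from helpers import brute_map, revcomp


def test_collapse_drops_single_read_tags():
    tags = collapse_tags(["ACGTACGTACGTACGTAC"] * 3 + ["TTTTGGGGCCCCAAAAGG"], [])
    assert len(tags) == 1
    assert tags[0].sequence == "ACGTACGTACGTACGTAC" and tags[0].count_a == 3


def test_collapse_is_order_invariant():
    reads = ["ACGTACGTACGTACGTAC", "GGGGTTTTCCCCAAAAGG"] * 3
    t1 = collapse_tags(reads, [])
    t2 = collapse_tags(list(reversed(reads)), [])
    assert [(t.sequence, t.count_a) for t in t1] == [(t.sequence, t.count_a) for t in t2]


def test_collapse_merges_library_counts():
    tags = collapse_tags(["AACCGGTTAACCGGTTAA"], ["AACCGGTTAACCGGTTAA"] * 2)
    assert tags[0].count_a == 1 and tags[0].count_b == 2 and tags[0].total == 3


def test_tag_count_invariants():
    with pytest.raises(ValueError):
        Tag("ACGT", 0, 0)


# --- mapping ---------------------------------------------------------------

def test_exact_locus_found(small_genome):
    g = small_genome.sequence
    tag = Tag(g[1000:1022], 2, 0)
    map_tags([tag], g)
    assert (1000, "+", 0) in tag.loci
    assert all(mm == 0 for _, _, mm in tag.loci)


def test_two_mismatches_stay_unmapped(rng):
    genome = "".join(rng.choice("ACGT") for _ in range(3000))
    sub = list(genome[500:522])
    sub[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[sub[3]]
    sub[15] = {"A": "C", "C": "A", "G": "T", "T": "G"}[sub[15]]
    tag = Tag("".join(sub), 2, 0)
    map_tags([tag], genome)
    assert tag.loci == brute_map("".join(sub), genome)


def test_mapping_matches_brute_force_scan(rng):
    """Vectorised mapper equals the naive all-window Hamming scan, both strands."""
    genome = "".join(rng.choice("ACGT") for _ in range(2000))
    tags = []
    for _ in range(10):  # random tags (mostly unmapped or 1-mismatch)
        tags.append("".join(rng.choice("ACGT") for _ in range(rng.randint(18, 25))))
    for _ in range(10):  # planted: exact, 1-sub, and minus-strand copies
        pos = rng.randint(0, 1950)
        L = rng.randint(18, 24)
        s = genome[pos:pos + L]
        variant = list(s)
        if rng.random() < 0.5:
            i = rng.randrange(L)
            variant[i] = rng.choice("ACGT")
        s = "".join(variant)
        tags.append(revcomp(s) if rng.random() < 0.5 else s)
    objs = [Tag(s, 1, 1) for s in tags]
    map_tags(objs, genome)
    for t in objs:
        assert t.loci == brute_map(t.sequence, genome), t.sequence


def test_best_stratum_suppresses_one_mismatch_loci():
    core = "ACGTTGCAACGTTGCAACGT"
    variant = "ACGTTGCAACGTTGCAACGA"  # 1 sub from core
    genome = "CC" + core + "GGGGGGGGGG" + variant + "CC"
    t = Tag(core, 2, 0)
    map_tags([t], genome)
    assert all(mm == 0 for _, _, mm in t.loci)
    assert (2, "+", 0) in t.loci


def test_non_acgtn_tag_rejected(small_genome):
    with pytest.raises(ValueError, match="non-ACGTN"):
        map_tags([Tag("ACGU" * 5, 1, 0)], small_genome.sequence)


# --- annotation ------------------------------------------------------------

def _features():
    return [Feature("rRNA", 100, 200, "+", "r1"),
            Feature("gene", 300, 500, "+", "g1"),
            Feature("exon", 300, 500, "+", "g1")]


def test_annotation_precedence_mirna_first():
    catalog = {"mir-1": "ACGTTGCAACGTTGCAACGT"}
    t1 = Tag("ACGTTGCAACGTTGCAACGT", 5, 0, loci=[(150, "+", 0)])  # also in rRNA
    t2 = Tag("TTGCAACGTTGCAACGTTGC", 5, 0, loci=[(150, "+", 0)])
    t3 = Tag("GGCCAACGTTGCAACGTTGC", 5, 0, loci=[(400, "+", 0)])
    t4 = Tag("GGCCAACGTTGCAACGTCCC", 5, 0, loci=[])
    annotate_tags([t1, t2, t3, t4], _features(), catalog)
    assert [t.annotation for t in (t1, t2, t3, t4)] == [
        "miRNA", "rRNAetc", "unann", "unmapped"]


def test_category_summary_partitions_totals():
    catalog = {"mir-1": "ACGTTGCAACGTTGCAACGT"}
    tags = [Tag("ACGTTGCAACGTTGCAACGT", 5, 2, loci=[(400, "+", 0)]),
            Tag("TTGCAACGTTGCAACGTTGC", 3, 0, loci=[(150, "+", 0)]),
            Tag("GGCCAACGTTGCAACGTTGC", 0, 4, loci=[(400, "+", 0)])]
    annotate_tags(tags, _features(), catalog)
    df = category_summary(tags).set_index("category")
    assert df.loc["total", "total_a"] == 8 and df.loc["total", "total_b"] == 6
    classes = ["miRNA", "rRNAetc", "unann", "unmapped"]
    for col in ("unique_a", "unique_b", "total_a", "total_b"):
        assert df.loc[classes, col].sum() == df.loc["total", col]


def test_category_percentage_formatting():
    """Published unique-tag counts reproduce the printed percentage."""
    assert percent(503, 1_176_366) == 0.04
    assert percent(8_042, 10_318_386) == 0.08


# --- overlap summary --------------------------------------------------------

def test_overlap_disjoint_and_identical():
    ov = overlap_summary({"AAA": 3}, {"CCC": 4})
    assert ov.unique_shared == 0 and ov.reads_shared == 0
    assert ov.unique_a_specific == 1 and ov.reads_b_specific == 4
    same = {"AAA": 3, "CCC": 4}
    ov2 = overlap_summary(same, dict(same))
    assert ov2.unique_shared == ov2.unique_total == 2
    assert ov2.percentages["reads_shared"] == 100.0


def test_overlap_symmetry(rng):
    a = {f"s{i}": rng.randint(1, 50) for i in rng.sample(range(100), 40)}
    b = {f"s{i}": rng.randint(1, 50) for i in rng.sample(range(100), 40)}
    ab, ba = overlap_summary(a, b), overlap_summary(b, a)
    assert ab.unique_a_specific == ba.unique_b_specific
    assert ab.reads_a_specific == ba.reads_b_specific
    assert ab.unique_shared == ba.unique_shared
    assert ab.reads_total == ba.reads_total


def test_overlap_partition_invariant(small_genome, rng):
    a = {f"t{i}": rng.randint(1, 9) for i in range(30)}
    b = {f"t{i}": rng.randint(1, 9) for i in range(15, 45)}
    ov = overlap_summary(a, b)
    assert ov.unique_a_specific + ov.unique_b_specific + ov.unique_shared == ov.unique_total
    assert ov.reads_a_specific + ov.reads_b_specific + ov.reads_shared == ov.reads_total
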