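"""Synthetic-data generators: determinism, calibration, planted ground truth."""

import math
import random

import numpy as np
import pytest

from jellyseq.fold import fold_mfe, reverse_complement
from jellyseq.io import write_annotation_bed, write_fasta
from jellyseq.synthio import (
    DEFAULT_ADAPTER3, ExpressionTruth, GenomeConfig, LibraryProfile,
    make_genome, make_hairpin, plant_target_sites, simulate_counts,
    simulate_srna_library, transcript_sequence,
)


def test_genome_determinism_and_invariants(tmp_path):
    cfg = GenomeConfig(length=10_000, n_genes=3, n_hairpins=2)
    g1 = make_genome(cfg, seed=1)
    g2 = make_genome(cfg, seed=1)
    assert g1.sequence == g2.sequence and g1.features == g2.features
    # byte-identical artifacts
    for g, tag in ((g1, "a"), (g2, "b")):
        write_fasta(tmp_path / f"{tag}.fa", {g.name: g.sequence})
        write_annotation_bed(tmp_path / f"{tag}.bed", g)
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
    assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()
    # features stay in bounds; exons/introns nest inside their gene
    n = len(g1.sequence)
    for f in g1.features:
        assert 0 <= f.start < f.end <= n
    genes = {f.feature_id: f for f in g1.features if f.kind == "gene"}
    for f in g1.features:
        if f.kind in ("exon", "intron"):
            parent = genes[f.feature_id]
            assert parent.start <= f.start and f.end <= parent.end
    # both hairpins land wholly inside an intergenic feature
    inter = [f for f in g1.features if f.kind == "intergenic"]
    for h in g1.hairpins:
        lo, hi = h.locus, h.locus + len(h.precursor)
        assert any(f.start <= lo and hi <= f.end for f in inter)
        assert g1.sequence[lo:hi] == h.precursor
        assert h.precursor.startswith(h.mature_seq)


def test_genome_sizing_error():
    with pytest.raises(ValueError, match="cannot pack"):
        make_genome(GenomeConfig(length=1_000, n_genes=50, gene_length=100,
                                 exons_per_gene=1, n_rrna=0, n_hairpins=0), seed=0)


def test_make_hairpin_construction():
    mature = "ACGGTTCAGCTAGGCATAGGCA"
    prec = make_hairpin(mature, stem_pairs=26, loop_len=8)
    assert len(prec) == 60
    assert prec.startswith(mature)
    arm5 = prec[:26]
    assert prec[34:] == reverse_complement(arm5)
    with pytest.raises(ValueError, match="exceeds"):
        make_hairpin(mature, stem_pairs=50, loop_len=20)
    with pytest.raises(ValueError):
        make_hairpin("ACGT", stem_pairs=26, loop_len=8)


def test_all_a_mature_with_gc_clamp_still_stable():
    prec = make_hairpin("A" * 22, stem_pairs=26, loop_len=8, rng=random.Random(3))
    _, mfe = fold_mfe(prec)
    assert mfe < -20


def test_library_class_mix_within_binomial_bounds(small_genome):
    profile = LibraryProfile(n_reads=10_000, seed=4)
    _, truth = simulate_srna_library(small_genome, profile)
    assert len(truth) == 10_000
    counts = truth["label"].value_counts()
    for cls, p in profile.class_mix.items():
        expected = 10_000 * p
        sigma = math.sqrt(10_000 * p * (1 - p))
        assert abs(counts.get(cls, 0) - expected) <= 3 * sigma, cls


def test_library_determinism_and_seed_variation(small_genome):
    p = LibraryProfile(n_reads=2_000, seed=9)
    r1, t1 = simulate_srna_library(small_genome, p)
    r2, t2 = simulate_srna_library(small_genome, p)
    assert r1 == r2 and t1.equals(t2)
    r3, t3 = simulate_srna_library(small_genome, LibraryProfile(n_reads=2_000, seed=10))
    assert r3 != r1
    # marginal class proportions stay close across seeds
    f1 = t1["label"].value_counts(normalize=True)
    f3 = t3["label"].value_counts(normalize=True)
    for cls in set(f1.index) | set(f3.index):
        assert abs(f1.get(cls, 0) - f3.get(cls, 0)) < 0.05


def test_pure_mirna_library_reads_are_mature_plus_adapter(small_genome):
    mix = {c: 0.0 for c in LibraryProfile().class_mix}
    mix["mature_miRNA"] = 1.0
    _, truth = simulate_srna_library(small_genome, LibraryProfile(
        n_reads=200, class_mix=mix, seed=1))
    matures = {h.mature_seq for h in small_genome.hairpins}
    recs, _ = simulate_srna_library(small_genome, LibraryProfile(
        n_reads=200, class_mix=mix, seed=1))
    for _, seq, _ in recs:
        insert = seq[:-len(DEFAULT_ADAPTER3)]
        assert insert in matures and seq == insert + DEFAULT_ADAPTER3


def test_truth_table_conservation(small_genome):
    recs, truth = simulate_srna_library(small_genome, LibraryProfile(n_reads=500, seed=2))
    assert truth["read_id"].is_unique
    assert [r[0] for r in recs] == list(truth["read_id"])


def test_invalid_profile_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        LibraryProfile(class_mix={"mature_miRNA": 0.5})
    with pytest.raises(ValueError, match="length_range"):
        LibraryProfile(length_range=(5, 44))


# --- count simulation -----------------------------------------------------

def test_null_counts_centre_on_zero():
    n = 1_000
    truth = ExpressionTruth((1000,) * n, (1000.0,) * n, (0.0,) * n,
                            dispersion=0.0, seed=11)
    c1, c2, _ = simulate_counts(truth)
    ratios = np.log2(c1 / c2)
    assert abs(ratios.mean()) < 0.05


def test_planted_fold_change_recovered():
    truth = ExpressionTruth((1000,) * 200, (5000.0,) * 200, (2.0,) * 200,
                            dispersion=0.0, seed=12)
    c1, c2, _ = simulate_counts(truth)
    assert np.log2(c2 / c1).mean() == pytest.approx(2.0, abs=0.05)


def test_library_size_scaling_and_zero_baseline():
    truth = ExpressionTruth((1000,) * 500 + (1000,), (2000.0,) * 500 + (0.0,),
                            (0.0,) * 501, library_sizes=(1_000_000, 2_000_000),
                            dispersion=0.0, seed=13)
    c1, c2, _ = simulate_counts(truth)
    assert c1[-1] == 0 and c2[-1] == 0
    assert (c2[:-1].mean() / c1[:-1].mean()) == pytest.approx(2.0, rel=0.02)


def test_negative_dispersion_rejected():
    with pytest.raises(ValueError, match="dispersion"):
        ExpressionTruth((100,), (10.0,), (0.0,), dispersion=-1.0)


# --- target-site planting -------------------------------------------------

def test_perfect_sites_embedded_in_three_prime_region(small_genome):
    mirnas = {h.name: h.mature_seq for h in small_genome.hairpins}
    genes = sorted({f.feature_id for f in small_genome.features if f.kind == "gene"})
    g2, truth = plant_target_sites(small_genome, mirnas, genes[:2], "perfect", seed=1)
    assert len(truth) == 2
    for row in truth.itertuples():
        tx = transcript_sequence(g2, row.gene_id)
        assert tx[row.site_start:row.site_end] == reverse_complement(mirnas[row.mirna])


def test_empty_subset_leaves_genome_unchanged(small_genome):
    g2, truth = plant_target_sites(small_genome, {"m": "A" * 20}, [], "perfect")
    assert g2.sequence == small_genome.sequence and truth.empty
    g3, _ = plant_target_sites(small_genome, {"m": "A" * 20}, ["gene1"], "none")
    assert g3.sequence == small_genome.sequence


def test_unknown_gene_rejected(small_genome):
    with pytest.raises(ValueError, match="not in genome"):
        plant_target_sites(small_genome, {"m": "A" * 20}, ["nope"], "perfect")
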