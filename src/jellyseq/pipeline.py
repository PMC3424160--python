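"""End-to-end orchestration of the synthetic royal-jelly analysis demo.

``run_pipeline`` executes clean -> classify -> discover -> diffexp -> target on a
fully synthetic dataset, writing the summary tables each stage produces plus a
manifest recording the seed and a hash of the configuration.  Re-running with
the same configuration and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clean import QualityRule, chi2_length_test, clean_library, length_histogram
from .classify import (annotate_tags, category_summary, collapse_tags, map_tags,
                       overlap_summary)
from .diffexp import altered_mirna, dge_summary, dge_table
from .fold import (DEFAULT_MODEL, HairpinCandidate, criteria_check,
                   extract_window, fold_mfe, inventory_overlap, match_catalog)
from .io import (write_annotation_bed, write_annotation_gff3, write_fasta,
                 write_tag_fasta)
from .report import (render_cleaning_table, render_inventory_table,
                     render_length_table, render_overlap_table)
from .synthio import (ExpressionTruth, GenomeConfig, LibraryProfile,
                      make_genome, plant_target_sites, simulate_counts,
                      simulate_srna_library, transcript_sequence, write_fastq)
from .target import overlap_report, predict_targets

log = logging.getLogger("jellyseq")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and sizing of the full synthetic pipeline run."""

    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    library_reads: int = 20_000
    min_len: int = 18
    max_len: int = 44
    min_count: int = 2
    mfe_cutoff: float = -20.0
    min_copies: int = 10
    fold_change: float = 2.0
    fdr: float = 0.001
    lfc: float = 1.0
    n_count_genes: int = 1_000
    de_fraction: float = 0.05
    de_log2_fold: float = 3.0
    dispersion: float = 0.05
    target_energy_cutoff: float = -20.0
    max_candidates: int = 24
    # library B expresses hairpin 1 strongly and hairpin 2 weakly, so the
    # altered-miRNA rule has true positives in both directions
    mirna_weights_b: tuple = (("syn-mir-1", 6.0), ("syn-mir-2", 0.15))

    def validate(self):
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if not 10 <= self.min_len <= self.max_len <= 44:
            raise ValueError("length window must satisfy 10 <= min <= max <= 44")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if self.mfe_cutoff >= 0 or self.target_energy_cutoff >= 0:
            raise ValueError("energy cutoffs must be negative")
        if self.min_copies < 0 or self.lfc < 0:
            raise ValueError("min_copies and lfc must be non-negative")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on synthetic data; returns a dict of key results.

    Writes the stage tables (TSV), FASTA/FASTQ/annotation artifacts and a
    ``manifest.json`` into ``outdir``.  Raises with the stage name on failure.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "setup"
    t_start = time.perf_counter()
    try:
        # --- simulate ---------------------------------------------------
        stage = "simulate"
        rng = np.random.default_rng(config.seed)
        genome = make_genome(config.genome, seed=config.seed)
        catalog = {h.name: h.mature_seq for h in genome.hairpins}
        prof_a = LibraryProfile(n_reads=config.library_reads, seed=config.seed * 2 + 1)
        prof_b = LibraryProfile(n_reads=config.library_reads, seed=config.seed * 2 + 2,
                                mirna_weights=dict(config.mirna_weights_b))
        reads_a, truth_a = simulate_srna_library(genome, prof_a)
        reads_b, truth_b = simulate_srna_library(genome, prof_b)
        write_fasta(out / "genome.fa", {genome.name: genome.sequence})
        write_annotation_bed(out / "annotation.bed", genome)
        write_annotation_gff3(out / "annotation.gff3", genome)
        write_fasta(out / "catalog.fa", catalog)
        write_fastq(out / "lib_a.fastq", reads_a)
        write_fastq(out / "lib_b.fastq", reads_b)
        truth_a.to_csv(out / "truth_a.tsv", sep="\t", index=False)
        truth_b.to_csv(out / "truth_b.tsv", sep="\t", index=False)
        log.info("simulate: genome %d nt, 2 x %d reads", len(genome.sequence),
                 config.library_reads)

        # --- clean ------------------------------------------------------
        stage = "clean"
        rule = QualityRule(min_len=config.min_len, max_len=config.max_len)
        a3, a5 = prof_a.adapter3, prof_a.adapter5
        def as_phred(recs):
            return [(r, s, [ord(c) - 33 for c in q]) for r, s, q in recs]
        inserts_a, sum_a = clean_library(as_phred(reads_a), a3, a5, rule)
        inserts_b, sum_b = clean_library(as_phred(reads_b), a3, a5, rule)
        render_cleaning_table({"lib_a": sum_a, "lib_b": sum_b}).to_csv(
            out / "cleaning_summary.tsv", sep="\t", index=False)
        hist_a, hist_b = length_histogram(inserts_a), length_histogram(inserts_b)
        render_length_table({"lib_a": hist_a, "lib_b": hist_b}).to_csv(
            out / "length_distribution.tsv", sep="\t", index=False)
        x2, dof, pval = chi2_length_test(hist_a, hist_b)
        results["cleaning"] = {"lib_a": sum_a, "lib_b": sum_b}
        results["length_chi2"] = {"x2": x2, "df": dof, "p": pval}
        log.info("clean: %d/%d clean reads; length chi2=%.1f", sum_a.clean_reads,
                 sum_b.clean_reads, x2)

        # --- classify ---------------------------------------------------
        stage = "classify"
        tags = collapse_tags(inserts_a, inserts_b, min_count=config.min_count)
        map_tags(tags, genome.sequence)
        annotate_tags(tags, genome.features, catalog)
        write_tag_fasta(out / "tags.fa", tags)
        category_summary(tags).to_csv(out / "category_summary.tsv", sep="\t", index=False)
        ov = overlap_summary({t.sequence: t.count_a for t in tags if t.count_a},
                             {t.sequence: t.count_b for t in tags if t.count_b})
        render_overlap_table(ov, "lib_a", "lib_b").to_csv(
            out / "overlap_summary.tsv", sep="\t", index=False)
        results["tags"] = tags
        results["overlap"] = ov
        log.info("classify: %d tags, %d shared", ov.unique_total, ov.unique_shared)

        # --- discover ---------------------------------------------------
        stage = "discover"
        cand_tags = sorted(
            (t for t in tags if t.annotation in ("miRNA", "unann") and t.loci),
            key=lambda t: (-t.total, t.sequence))[:config.max_candidates]
        cand_rows = []
        for t in cand_tags:
            pos, strand, _mm = t.loci[0]
            wseq, span = extract_window(genome.sequence, pos, len(t.sequence), strand)
            structure, mfe = fold_mfe(wseq)
            loc = _location_class(genome.features, pos, len(t.sequence))
            cand = criteria_check(
                HairpinCandidate(wseq, structure, mfe, span, loc),
                mfe_cutoff=config.mfe_cutoff)
            name = match_catalog(t.sequence, catalog)
            cand_rows.append({
                "sequence": t.sequence, "position": pos, "strand": strand,
                "location": loc, "mfe": mfe, "structure": structure,
                "arm": cand.arm, "verdict": "pass" if cand.verdict else "fail",
                "failed_criteria": ",".join(cand.failed), "catalog_match": name,
            })
        cand_df = pd.DataFrame(cand_rows)
        cand_df.to_csv(out / "hairpin_candidates.tsv", sep="\t", index=False)
        known_a = {match_catalog(t.sequence, catalog) for t in tags
                   if t.annotation == "miRNA" and t.count_a > 0} - {"novel"}
        known_b = {match_catalog(t.sequence, catalog) for t in tags
                   if t.annotation == "miRNA" and t.count_b > 0} - {"novel"}
        a_spec, b_spec, shared, inv_counts = inventory_overlap(known_a, known_b)
        render_inventory_table(a_spec, b_spec, shared, "lib_a", "lib_b").to_csv(
            out / "mirna_inventory.tsv", sep="\t", index=False)
        results["candidates"] = cand_df
        results["inventory"] = inv_counts
        log.info("discover: %d candidates, %d pass",
                 len(cand_df), (cand_df["verdict"] == "pass").sum() if len(cand_df) else 0)

        # --- differential miRNA -----------------------------------------
        stage = "diffexp-mirna"
        n_a = sum(t.count_a for t in tags)
        n_b = sum(t.count_b for t in tags)
        mirna_rows = []
        for name in sorted(catalog):
            mature = catalog[name]
            ca = sum(t.count_a for t in tags if t.sequence == mature)
            cb = sum(t.count_b for t in tags if t.sequence == mature)
            cmp_ = altered_mirna(name, ca, cb, totals=(n_a, n_b),
                                 min_copies=config.min_copies,
                                 fold=config.fold_change)
            mirna_rows.append(vars(cmp_))
        mirna_df = pd.DataFrame(mirna_rows)
        mirna_df.to_csv(out / "mirna_differential.tsv", sep="\t", index=False)
        results["mirna_differential"] = mirna_df

        # --- differential gene expression --------------------------------
        stage = "diffexp-genes"
        n_genes = config.n_count_genes
        lengths = rng.integers(500, 4000, n_genes)
        baselines = np.exp(rng.normal(np.log(300), 1.0, n_genes))
        lfc = np.zeros(n_genes)
        n_de = int(round(config.de_fraction * n_genes))
        de_idx = rng.choice(n_genes, n_de, replace=False)
        lfc[de_idx] = rng.choice([-config.de_log2_fold, config.de_log2_fold], n_de)
        truth = ExpressionTruth(tuple(int(x) for x in lengths),
                                tuple(float(x) for x in baselines),
                                tuple(float(x) for x in lfc),
                                dispersion=config.dispersion,
                                seed=config.seed + 17)
        c1, c2, count_truth = simulate_counts(truth)
        count_truth.to_csv(out / "count_truth.tsv", sep="\t", index=False)
        dge = dge_table(c1, c2, lengths, truth.library_sizes[0], truth.library_sizes[1],
                        gene_ids=count_truth["gene_id"],
                        fdr_cutoff=config.fdr, lfc_cutoff=config.lfc)
        dge.to_csv(out / "dge_results.tsv", sep="\t", index=False, float_format="%.6g")
        summ = dge_summary(dge)
        pd.DataFrame([summ]).to_csv(out / "dge_summary.tsv", sep="\t", index=False)
        results["dge"] = dge
        results["dge_summary"] = summ
        log.info("diffexp: %d up, %d down of %d genes", summ["n_up"], summ["n_down"],
                 summ["n_genes"])

        # --- targets ------------------------------------------------------
        stage = "target"
        diff_names = sorted(mirna_df.loc[
            mirna_df["call"].isin(["up_in_A", "down_in_A"]), "name"])
        if not diff_names:
            diff_names = sorted(catalog)[:1]
        gene_ids = sorted({f.feature_id for f in genome.features if f.kind == "gene"})
        targeted_genes = gene_ids[: max(1, len(gene_ids) // 2)]
        genome_t, site_truth = plant_target_sites(
            genome, {n: catalog[n] for n in diff_names}, targeted_genes,
            site_type="perfect", seed=config.seed + 29)
        site_truth.to_csv(out / "target_truth.tsv", sep="\t", index=False)
        target_rows, target_map = [], {n: set() for n in diff_names}
        for gid in gene_ids:
            tx = transcript_sequence(genome_t, gid)
            for name in diff_names:
                site = predict_targets(name, catalog[name], gid, tx,
                                       energy_cutoff=config.target_energy_cutoff)
                if site:
                    target_map[name].add(gid)
                    target_rows.append(vars(site))
        pd.DataFrame(target_rows).to_csv(out / "target_sites.tsv", sep="\t", index=False)
        # DEG/target overlap over the genes that have transcripts in the genome
        deg_ids = set(dge.loc[dge["call"] != "ns", "gene_id"])
        ovr = overlap_report(deg_ids | set(targeted_genes), target_map)
        results["target_map"] = target_map
        results["target_overlap"] = ovr
        pd.DataFrame([{"n_deg": ovr.n_deg, "n_deg_targets": ovr.n_deg_targets,
                       "proportion_pct": ovr.proportion}]).to_csv(
            out / "target_overlap.tsv", sep="\t", index=False)

        # --- manifest -----------------------------------------------------
        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "tables": sorted(p.name for p in out.glob("*.tsv")),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        results["manifest"] = manifest
        log.info("pipeline finished in %.1f s", time.perf_counter() - t_start)
        return results
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e


def _location_class(features, pos: int, length: int) -> str:
    """Feature kind at a locus, with the gene hierarchy resolved to exon/intron."""
    hit = "intergenic"
    for f in features:
        if f.start <= pos and pos + length <= f.end:
            if f.kind in ("exon", "intron", "rRNA"):
                return f.kind
            if f.kind == "gene":
                hit = "exon"  # inside a gene but astride exon/intron boundary
            elif f.kind == "intergenic":
                hit = "intergenic"
    return hit
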