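"""File-format plumbing: FASTA/FASTQ, miRNA catalogs, BED-like and GFF3 annotation."""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthio import Feature, GenomeModel, Hairpin


def write_fasta(path, records):
    """Write ``{name: sequence}`` or an iterable of (name, seq) pairs as FASTA."""
    if hasattr(records, "items"):
        records = records.items()
    seqs = [SeqRecord(Seq(s), id=n, description="") for n, s in records]
    SeqIO.write(seqs, path, "fasta")


def read_fasta(path) -> dict:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(path, "fasta")}


def read_catalog(path) -> dict:
    """miRBase-style mature catalog ``>name`` -> sequence (T/U preserved)."""
    return read_fasta(path)


def iter_fastq(path):
    """Yield ``(read_id, seq, qual)``; raises naming the record index on bad input."""
    idx = 0
    try:
        for rec in SeqIO.parse(path, "fastq"):
            yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]
            idx += 1
    except ValueError as e:
        raise ValueError(f"malformed FASTQ record at index {idx}: {e}") from e


def write_tag_fasta(path, tags):
    """Clean tags as FASTA with per-library counts in the header."""
    with open(path, "w") as fh:
        for i, t in enumerate(tags):
            fh.write(f">tag{i} count_a={t.count_a} count_b={t.count_b}\n{t.sequence}\n")


def read_tag_fasta(path):
    from .classify import Tag
    tags = []
    for rec in SeqIO.parse(path, "fasta"):
        fields = dict(kv.split("=") for kv in rec.description.split()[1:])
        tags.append(Tag(str(rec.seq).upper(), int(fields.get("count_a", 0)),
                        int(fields.get("count_b", 0))))
    return tags


# --- annotation -----------------------------------------------------------

def write_annotation_bed(path, genome: GenomeModel):
    """BED-like TSV: chrom, start, end, kind, feature_id, strand (+ hairpin rows)."""
    with open(path, "w") as fh:
        for f in sorted(genome.features, key=lambda f: (f.start, f.end, f.kind)):
            fh.write(f"{genome.name}\t{f.start}\t{f.end}\t{f.kind}\t{f.feature_id}\t{f.strand}\n")
        for h in genome.hairpins:
            fh.write(f"{genome.name}\t{h.locus}\t{h.locus + len(h.precursor)}\t"
                     f"hairpin\t{h.name}\t+\n")


def read_annotation_bed(path):
    """Returns ``(features, hairpin_rows)``; hairpin rows are (name, start, end)."""
    features, hairpins = [], []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, kind, fid, strand = line.rstrip("\n").split("\t")
            if kind == "hairpin":
                hairpins.append((fid, int(start), int(end)))
            else:
                features.append(Feature(kind, int(start), int(end), strand, fid))
    return features, hairpins


def write_annotation_gff3(path, genome: GenomeModel):
    """GFF3 interchange writer (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {len(genome.sequence)}\n")
        for f in sorted(genome.features, key=lambda f: (f.start, f.end, f.kind)):
            ftype = {"gene": "gene", "exon": "exon", "intron": "intron",
                     "rRNA": "rRNA", "intergenic": "region"}[f.kind]
            attrs = f"ID={f.feature_id or ftype}"
            if f.kind in ("exon", "intron"):
                attrs += f";Parent={f.feature_id}"
            fh.write(f"{genome.name}\tjellyseq\t{ftype}\t{f.start + 1}\t{f.end}\t.\t"
                     f"{f.strand}\t.\t{attrs}\n")
        for h in genome.hairpins:
            fh.write(f"{genome.name}\tjellyseq\tpre_miRNA\t{h.locus + 1}\t"
                     f"{h.locus + len(h.precursor)}\t.\t+\t.\tID={h.name}\n")
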