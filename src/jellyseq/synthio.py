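"""Synthetic genomes, small-RNA libraries and count tables with known ground truth.

Every downstream stage of the pipeline (cleaning, tag classification, hairpin
discovery, differential expression, target prediction) is exercised on data from
this module: a small random genome carrying annotated genes/exons/introns/rRNAs
with planted miRNA hairpins, FASTQ small-RNA libraries whose reads are drawn from
configurable contaminant/insert classes, and overdispersed gene-count tables with
planted log2 fold changes.  Each generator emits a truth table naming the class or
effect it planted, and is byte-reproducible given its seed.

All genome-scale sequences use the DNA alphabet; the folding and duplex modules
treat T and U as synonyms.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fold import reverse_complement

__all__ = [
    "Feature", "Hairpin", "GenomeModel", "GenomeConfig", "LibraryProfile",
    "ExpressionTruth", "make_genome", "make_hairpin", "simulate_srna_library",
    "simulate_counts", "plant_target_sites", "transcript_sequence",
    "DEFAULT_ADAPTER3", "DEFAULT_ADAPTER5",
]

# arbitrary fixed 12-mers standing in for the sequencing adapters
DEFAULT_ADAPTER3 = "TCGTATGCCGTC"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCT"

READ_CLASSES = (
    "mature_miRNA", "rRNA_fragment", "degradation", "adapter3_null",
    "insert_null", "adapter5_contaminant", "too_short", "polyA", "low_quality",
)


@dataclass(frozen=True)
class Feature:
    kind: str          # gene | exon | intron | rRNA | intergenic
    start: int         # 0-based half-open
    end: int
    strand: str = "+"
    feature_id: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("empty feature")


@dataclass(frozen=True)
class Hairpin:
    name: str
    locus: int            # precursor start on the genome
    mature_start: int     # genome coordinate of the mature 5' end
    mature_len: int
    mature_seq: str
    precursor: str
    location_class: str   # feature kind the precursor sits in


@dataclass
class GenomeModel:
    sequence: str
    features: list
    hairpins: list
    name: str = "synchr1"

    def features_of(self, kind: str):
        return [f for f in self.features if f.kind == kind]


@dataclass(frozen=True)
class GenomeConfig:
    """Sizing of the synthetic genome; defaults give a ~20 kb toy chromosome."""

    length: int = 20_000
    n_genes: int = 6
    gene_length: int = 1_200
    exons_per_gene: int = 3
    intron_length: int = 150
    n_rrna: int = 2
    rrna_length: int = 400
    n_hairpins: int = 4
    hairpin_location: str = "intergenic"   # intergenic | intron | exon
    hairpin_stem_pairs: int = 26
    hairpin_loop_len: int = 8
    mature_len_range: tuple = (20, 22)
    min_intergenic: int = 120


def _random_seq(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def make_hairpin(mature: str, stem_pairs: int, loop_len: int,
                 rng: random.Random | None = None) -> str:
    """Build a hairpin precursor whose 5' arm starts with ``mature`` verbatim.

    The 5' arm is ``mature`` extended with GC-rich filler to ``stem_pairs``
    bases; the 3' arm is its reverse complement, so every stem position is a
    Watson-Crick pair.  The loop is non-self-complementary (poly-A/C).  Raises
    if the precursor would exceed the 100-nt discovery window.
    """
    if not (20 <= len(mature) <= 22):
        raise ValueError("mature length must be 20-22 nt")
    if stem_pairs < len(mature):
        raise ValueError("stem_pairs must be >= mature length")
    total = 2 * stem_pairs + loop_len
    if total > 100:
        raise ValueError(f"precursor of {total} nt exceeds the 100-nt window")
    rng = rng or random.Random(0)
    ext = _random_seq(rng, stem_pairs - len(mature), "GCGCAT")
    arm5 = mature.upper().replace("U", "T") + ext
    loop = "".join(rng.choice("AC") for _ in range(loop_len))
    return arm5 + loop + reverse_complement(arm5)


def make_genome(config: GenomeConfig, seed: int) -> GenomeModel:
    """Generate a genome with tiled features and planted hairpins.

    Genes (with alternating exons/introns), rRNAs and intergenic gaps tile the
    chromosome exactly; hairpin precursors overwrite sequence inside features of
    ``config.hairpin_location`` kind.  Deterministic given ``seed``.
    """
    rng = random.Random(seed)
    c = config
    exon_len = (c.gene_length - (c.exons_per_gene - 1) * c.intron_length) // c.exons_per_gene
    if exon_len <= 0:
        raise ValueError("gene_length too small for the requested exon/intron structure")

    blocks = [("gene", c.gene_length)] * c.n_genes + [("rRNA", c.rrna_length)] * c.n_rrna
    rng.shuffle(blocks)
    occupied = sum(n for _, n in blocks)
    n_gaps = len(blocks) + 1
    slack = c.length - occupied - n_gaps * c.min_intergenic
    if slack < 0:
        raise ValueError(
            f"cannot pack {occupied} nt of features plus {n_gaps} gaps of "
            f">= {c.min_intergenic} nt into a {c.length} nt genome")
    cuts = sorted(rng.randint(0, slack) for _ in range(n_gaps - 1))
    extras = [b - a for a, b in zip([0] + cuts, cuts + [slack])]
    gaps = [c.min_intergenic + e for e in extras]

    seq = list(_random_seq(rng, c.length))
    features: list[Feature] = []
    pos = 0
    gene_i = rrna_i = 0
    for gap, (kind, blen) in zip(gaps, blocks + [("end", 0)]):
        features.append(Feature("intergenic", pos, pos + gap, "+",
                                f"ig{len(features)}"))
        pos += gap
        if kind == "end":
            break
        if kind == "gene":
            gene_i += 1
            gid = f"gene{gene_i}"
            features.append(Feature("gene", pos, pos + blen, "+", gid))
            p = pos
            for e in range(c.exons_per_gene):
                features.append(Feature("exon", p, p + exon_len, "+", gid))
                p += exon_len
                if e < c.exons_per_gene - 1:
                    features.append(Feature("intron", p, p + c.intron_length, "+", gid))
                    p += c.intron_length
        else:
            rrna_i += 1
            features.append(Feature("rRNA", pos, pos + blen, "+", f"rrna{rrna_i}"))
        pos += blen
    assert pos == c.length

    # plant hairpins inside features of the requested kind
    hairpins: list[Hairpin] = []
    slots = [f for f in config_slots(features, c.hairpin_location)
             if f.end - f.start >= 2 * c.hairpin_stem_pairs + c.hairpin_loop_len + 4]
    if c.n_hairpins and not slots:
        raise ValueError(f"no {c.hairpin_location} feature large enough for hairpins")
    used: list[tuple] = []
    prec_len = 2 * c.hairpin_stem_pairs + c.hairpin_loop_len
    for h in range(c.n_hairpins):
        for _attempt in range(200):
            f = rng.choice(slots)
            start = rng.randint(f.start, f.end - prec_len)
            if all(start + prec_len <= a or start >= b for a, b in used):
                break
        else:
            raise ValueError("could not place hairpins without overlap")
        used.append((start, start + prec_len))
        mlen = rng.randint(*c.mature_len_range)
        mature = _random_seq(rng, mlen)
        prec = make_hairpin(mature, c.hairpin_stem_pairs, c.hairpin_loop_len, rng)
        seq[start:start + len(prec)] = prec
        hairpins.append(Hairpin(
            name=f"syn-mir-{h + 1}", locus=start, mature_start=start,
            mature_len=mlen, mature_seq=mature, precursor=prec,
            location_class=c.hairpin_location))
    return GenomeModel("".join(seq), features, hairpins)


def config_slots(features, kind):
    return [f for f in features if f.kind == kind]


# ---------------------------------------------------------------------------
# small-RNA library simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryProfile:
    """Read-class mixture and sizing of one small-RNA library.

    ``class_mix`` must sum to 1 over the nine read classes.  ``mirna_weights``
    optionally skews which planted hairpin each mature-miRNA read comes from
    (name -> weight), so two libraries can express the same hairpins at
    different levels.
    """

    n_reads: int = 20_000
    class_mix: dict = field(default_factory=lambda: {
        "mature_miRNA": 0.15,
        "rRNA_fragment": 0.30,
        "degradation": 0.435,
        "adapter3_null": 0.005,
        "insert_null": 0.002,
        "adapter5_contaminant": 0.002,
        "too_short": 0.10,
        "polyA": 0.002,
        "low_quality": 0.004,
    })
    length_range: tuple = (10, 44)
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    mirna_weights: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        unknown = set(self.class_mix) - set(READ_CLASSES)
        if unknown:
            raise ValueError(f"unknown read classes: {sorted(unknown)}")
        lo, hi = self.length_range
        if not (10 <= lo <= hi <= 44):
            raise ValueError("length_range must lie within [10, 44]")


def _region_fragment(rng, seq, regions, lo, hi, forbidden):
    """Random substring of one of ``regions`` with length in [lo, hi]."""
    for _ in range(100):
        f = rng.choice(regions)
        ln = rng.randint(lo, min(hi, f.end - f.start))
        start = rng.randint(f.start, f.end - ln)
        frag = seq[start:start + ln]
        if forbidden(frag):
            continue
        return frag
    raise RuntimeError("could not draw an unambiguous fragment")


def simulate_srna_library(genome: GenomeModel, profile: LibraryProfile):
    """Simulate one FASTQ library; returns ``(records, truth)``.

    ``records`` is a list of ``(read_id, sequence, quality)`` tuples (Phred+33);
    ``truth`` a DataFrame with one row per read giving the generating class and
    the true insert.  Reads are insert + 3' adapter on the forward strand; the
    contaminant classes reproduce the failure modes the cleaning stage counts.
    """
    rng = random.Random(profile.seed)
    a3, a5 = profile.adapter3, profile.adapter5
    lo, hi = max(profile.length_range[0], 10), profile.length_range[1]
    clean_lo = max(lo, 18)

    def ambiguous(frag):
        # would mis-classify: stray adapter hit or accidental poly-A
        return (a3 in frag or a5 in frag
                or frag.count("A") >= 0.9 * len(frag))

    exons = genome.features_of("exon") or genome.features_of("intergenic")
    rrnas = genome.features_of("rRNA")
    matures = [h.mature_seq for h in genome.hairpins]
    names = [h.name for h in genome.hairpins]
    if profile.mirna_weights:
        weights = [profile.mirna_weights.get(n, 1.0) for n in names]
    else:
        weights = [1.0] * len(names)

    classes = list(profile.class_mix)
    probs = [profile.class_mix[c] for c in classes]
    rows = []
    records = []
    for ridx in range(profile.n_reads):
        cls = rng.choices(classes, probs)[0]
        insert = ""
        source = ""
        if cls == "mature_miRNA":
            if not matures:
                raise ValueError("class_mix requests miRNA reads but genome has no hairpins")
            k = rng.choices(range(len(matures)), weights)[0]
            insert, source = matures[k], names[k]
            read = insert + a3
        elif cls == "rRNA_fragment":
            if not rrnas:
                raise ValueError("class_mix requests rRNA reads but genome has no rRNA")
            insert = _region_fragment(rng, genome.sequence, rrnas, clean_lo, hi, ambiguous)
            read = insert + a3
        elif cls == "degradation":
            insert = _region_fragment(rng, genome.sequence, exons, clean_lo, hi, ambiguous)
            read = insert + a3
        elif cls == "adapter3_null":
            # adapter-only read: 3' adapter with a null insert in front of it
            read = a3 + _random_seq(rng, 24)
        elif cls == "insert_null":
            # no adapter anywhere: the insert boundary is unrecoverable
            while True:
                read = _random_seq(rng, 36)
                if a3 not in read:
                    break
        elif cls == "adapter5_contaminant":
            insert = a5 + _random_seq(rng, rng.randint(0, 10))
            read = insert + a3
        elif cls == "too_short":
            while True:
                insert = _random_seq(rng, rng.randint(lo, 17))
                if not ambiguous(insert):
                    break
            read = insert + a3
        elif cls == "polyA":
            insert = "A" * rng.randint(clean_lo, 30)
            read = insert + a3
        elif cls == "low_quality":
            insert = _region_fragment(rng, genome.sequence, exons, clean_lo, hi, ambiguous)
            read = insert + a3
        qual = ("+" if cls == "low_quality" else "I") * len(read)
        rid = f"read{ridx}"
        records.append((rid, read, qual))
        rows.append((rid, cls, insert, source))
    truth = pd.DataFrame(rows, columns=["read_id", "label", "insert", "source"])
    return records, truth


def write_fastq(path, records):
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# gene-count simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionTruth:
    """Ground truth for a two-sample count simulation.

    Sample-2 means are the baseline scaled by ``2**log2_fold`` and by the
    library-size ratio ``N2/N1``; counts are negative-binomial with variance
    ``mu + dispersion * mu**2`` (Poisson when dispersion is 0).
    """

    gene_lengths: tuple
    baseline_means: tuple
    log2_fold: tuple
    library_sizes: tuple = (10_000_000, 10_000_000)
    dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if any(l <= 0 for l in self.gene_lengths):
            raise ValueError("gene lengths must be positive")
        if any(m < 0 for m in self.baseline_means):
            raise ValueError("baseline means must be non-negative")
        if any(n <= 0 for n in self.library_sizes):
            raise ValueError("library sizes must be positive")
        if not (len(self.gene_lengths) == len(self.baseline_means) == len(self.log2_fold)):
            raise ValueError("per-gene vectors must have equal length")


def simulate_counts(truth: ExpressionTruth):
    """Draw the two per-gene count vectors; returns ``(counts_1, counts_2, table)``."""
    rng = np.random.default_rng(truth.seed)
    mu1 = np.asarray(truth.baseline_means, dtype=float)
    n1, n2 = truth.library_sizes
    mu2 = mu1 * np.exp2(np.asarray(truth.log2_fold, dtype=float)) * (n2 / n1)

    def draw(mu):
        if truth.dispersion == 0:
            return rng.poisson(mu)
        lam = np.where(mu > 0,
                       rng.gamma(1.0 / truth.dispersion, truth.dispersion * np.maximum(mu, 1e-300)),
                       0.0)
        return rng.poisson(lam)

    c1, c2 = draw(mu1), draw(mu2)
    table = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(len(mu1))],
        "length": truth.gene_lengths,
        "baseline_mean": mu1,
        "log2_fold": truth.log2_fold,
        "count_1": c1,
        "count_2": c2,
    })
    return c1, c2, table


# ---------------------------------------------------------------------------
# target-site planting
# ---------------------------------------------------------------------------

def transcript_sequence(genome: GenomeModel, gene_id: str) -> str:
    exons = [f for f in genome.features if f.kind == "exon" and f.feature_id == gene_id]
    if not exons:
        raise ValueError(f"gene {gene_id!r} not in genome")
    return "".join(genome.sequence[f.start:f.end] for f in sorted(exons, key=lambda f: f.start))


def plant_target_sites(genome: GenomeModel, mirnas: dict, gene_subset,
                       site_type: str = "perfect", seed: int = 0):
    """Embed miRNA binding sites in the 3' regions of selected genes.

    For ``perfect`` the reverse complement of the full mature sequence is
    written near the 3' end of the gene's last exon; ``seed_only`` embeds only
    the complement of miRNA positions 2-8; ``none`` leaves the genome unchanged.
    Returns ``(new_genome, truth)`` where truth maps (gene, miRNA) to the site
    position in transcript coordinates.
    """
    if site_type not in ("perfect", "seed_only", "none"):
        raise ValueError(f"unknown site_type {site_type!r}")
    rng = random.Random(seed)
    seq = list(genome.sequence)
    rows = []
    gene_ids = {f.feature_id for f in genome.features if f.kind == "gene"}
    for gid in gene_subset:
        if gid not in gene_ids:
            raise ValueError(f"gene {gid!r} not in genome")
    if site_type != "none":
        names = sorted(mirnas)
        for gid in gene_subset:
            name = names[rng.randrange(len(names))]
            mature = mirnas[name].upper().replace("U", "T")
            site = reverse_complement(mature if site_type == "perfect" else mature[1:8])
            exons = sorted((f for f in genome.features
                            if f.kind == "exon" and f.feature_id == gid),
                           key=lambda f: f.start)
            last = exons[-1]
            start = last.end - len(site) - 5
            if start < last.start:
                raise ValueError(f"3' exon of {gid} too short for a site")
            seq[start:start + len(site)] = site
            # transcript coordinate of the site
            tpos = sum(f.end - f.start for f in exons[:-1]) + (start - last.start)
            rows.append((gid, name, tpos, tpos + len(site), site_type))
    truth = pd.DataFrame(rows, columns=["gene_id", "mirna", "site_start", "site_end", "site_type"])
    new_genome = GenomeModel("".join(seq), genome.features, genome.hairpins, genome.name)
    return new_genome, truth
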