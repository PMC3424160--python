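"""Unique-tag collapsing, genome mapping with at most one mismatch, and annotation.

Clean inserts from the two libraries are collapsed into unique *tags* carrying
per-library copy counts.  Tags are mapped to both strands of the genome allowing
0 or 1 substitutions (best stratum only: if a perfect locus exists, one-mismatch
loci are suppressed), then annotated with precedence miRNA > rRNAetc > unann.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clean import percent
from .fold import reverse_complement

__all__ = [
    "Tag", "OverlapSummary", "collapse_tags", "map_tags", "annotate_tags",
    "category_summary", "overlap_summary",
]


@dataclass
class Tag:
    sequence: str
    count_a: int = 0
    count_b: int = 0
    loci: list = field(default_factory=list)      # (position, strand, mismatches)
    annotation: str | None = None                 # miRNA | rRNAetc | unann | unmapped

    def __post_init__(self):
        if self.count_a < 0 or self.count_b < 0 or self.count_a + self.count_b == 0:
            raise ValueError("tag counts must be non-negative and not both zero")

    @property
    def total(self) -> int:
        return self.count_a + self.count_b


def collapse_tags(inserts_a, inserts_b, min_count: int = 2):
    """Collapse two libraries' clean inserts into unique tags.

    Tags whose combined copy number is below ``min_count`` (single-read
    sequences at the default) are discarded.  Output is sorted by sequence, so
    the result is independent of read order.
    """
    ca, cb = Counter(inserts_a), Counter(inserts_b)
    tags = []
    for seq in sorted(set(ca) | set(cb)):
        a, b = ca.get(seq, 0), cb.get(seq, 0)
        if a + b >= min_count:
            tags.append(Tag(seq, a, b))
    return tags


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def map_tags(tags, genome_seq: str, max_mismatch: int = 1, chunk: int = 64):
    """Map tags to both strands of ``genome_seq`` by exhaustive windowed comparison.

    Every window of the genome is compared against each tag (vectorised over
    positions); all loci in the best (fewest-mismatch) stratum with at most
    ``max_mismatch`` substitutions are recorded on each tag as
    ``(position, strand, mismatches)`` in forward-strand coordinates.
    Unmapped tags get ``annotation='unmapped'`` later.  Tags must be ACGT(N);
    N matches nothing.
    """
    genome = _encode(genome_seq.upper())
    n = len(genome)
    by_len: dict[int, list] = {}
    for t in tags:
        if set(t.sequence) - set("ACGTN"):
            raise ValueError(f"tag contains non-ACGTN characters: {t.sequence}")
        t.loci = []
        by_len.setdefault(len(t.sequence), []).append(t)

    for L, group in sorted(by_len.items()):
        if L > n:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(genome, L)  # (n-L+1, L)
        for start in range(0, len(group), chunk):
            block = group[start:start + chunk]
            fwd = np.stack([_encode(t.sequence) for t in block])
            rev = np.stack([_encode(reverse_complement(t.sequence)) for t in block])
            for arr, strand in ((fwd, "+"), (rev, "-")):
                mism = (windows[None, :, :] != arr[:, None, :]).sum(axis=2)
                for ti, t in enumerate(block):
                    hits = np.nonzero(mism[ti] <= max_mismatch)[0]
                    for pos in hits:
                        t.loci.append((int(pos), strand, int(mism[ti, pos])))
    for t in tags:
        if t.loci:
            best = min(mm for _, _, mm in t.loci)
            t.loci = sorted((p, s, mm) for p, s, mm in t.loci if mm == best)
    return tags


def _overlaps(pos: int, length: int, feat) -> bool:
    return pos < feat.end and feat.start < pos + length


def annotate_tags(tags, features, catalog: dict, contaminants=None):
    """Assign each tag a single class with precedence miRNA > rRNAetc > unann.

    miRNA: exact (T/U-insensitive) match to a catalog mature sequence.
    rRNAetc: a best locus overlaps an rRNA feature, or the sequence is in the
    configured contaminant set.  unmapped: no locus at all.
    """
    mature_set = {s.upper().replace("U", "T") for s in catalog.values()}
    contam = {s.upper().replace("U", "T") for s in (contaminants or ())}
    rrna = [f for f in features if f.kind == "rRNA"]
    for t in tags:
        seq = t.sequence.upper().replace("U", "T")
        if seq in mature_set:
            t.annotation = "miRNA"
        elif not t.loci:
            t.annotation = "unmapped"
        elif seq in contam or any(
                _overlaps(p, len(seq), f) for p, s, _ in t.loci for f in rrna):
            t.annotation = "rRNAetc"
        else:
            t.annotation = "unann"
    return tags


def category_summary(tags) -> pd.DataFrame:
    """Per-library unique/total counts and percentages for each annotation class."""
    classes = ("miRNA", "rRNAetc", "unann", "unmapped")
    rows = []
    tot = {
        "unique_a": sum(1 for t in tags if t.count_a > 0),
        "unique_b": sum(1 for t in tags if t.count_b > 0),
        "total_a": sum(t.count_a for t in tags),
        "total_b": sum(t.count_b for t in tags),
    }
    rows.append({"category": "total", **tot,
                 **{f"{k}_pct": percent(v, v) if v else 0.0 for k, v in tot.items()}})
    for cls in classes:
        sub = [t for t in tags if t.annotation == cls]
        row = {
            "category": cls,
            "unique_a": sum(1 for t in sub if t.count_a > 0),
            "unique_b": sum(1 for t in sub if t.count_b > 0),
            "total_a": sum(t.count_a for t in sub),
            "total_b": sum(t.count_b for t in sub),
        }
        for k in ("unique_a", "unique_b", "total_a", "total_b"):
            row[f"{k}_pct"] = percent(row[k], tot[k])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class OverlapSummary:
    """Shared vs library-specific tag accounting (unique- and read-level)."""

    unique_total: int
    unique_a_specific: int
    unique_b_specific: int
    unique_shared: int
    reads_total: int
    reads_a_specific: int
    reads_b_specific: int
    reads_shared: int

    def __post_init__(self):
        if self.unique_a_specific + self.unique_b_specific + self.unique_shared != self.unique_total:
            raise ValueError("unique counts do not partition the total")
        if self.reads_a_specific + self.reads_b_specific + self.reads_shared != self.reads_total:
            raise ValueError("read counts do not partition the total")

    @property
    def percentages(self) -> dict:
        return {
            "unique_a_specific": percent(self.unique_a_specific, self.unique_total),
            "unique_b_specific": percent(self.unique_b_specific, self.unique_total),
            "unique_shared": percent(self.unique_shared, self.unique_total),
            "reads_a_specific": percent(self.reads_a_specific, self.reads_total),
            "reads_b_specific": percent(self.reads_b_specific, self.reads_total),
            "reads_shared": percent(self.reads_shared, self.reads_total),
        }


def overlap_summary(counts_a: dict, counts_b: dict) -> OverlapSummary:
    """Shared/specific summary from two ``{sequence: copies}`` maps.

    A tag is shared iff it has copies in both libraries; read-level numbers sum
    the per-library copy counts.
    """
    seqs = set(counts_a) | set(counts_b)
    ua = ub = ush = ra = rb = rsh = 0
    for s in seqs:
        a, b = counts_a.get(s, 0), counts_b.get(s, 0)
        if a > 0 and b > 0:
            ush += 1
            rsh += a + b
        elif a > 0:
            ua += 1
            ra += a
        else:
            ub += 1
            rb += b
    return OverlapSummary(len(seqs), ua, ub, ush,
                          ra + rb + rsh, ra, rb, rsh)
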