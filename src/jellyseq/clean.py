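"""Raw small-RNA read cleaning: contaminant classification and length accounting.

Each high-quality read is assigned exactly one category, evaluated in a fixed
order that mirrors the columns of a sequencing-facility cleaning report:

    low_quality -> adapter3_null -> insert_null -> adapter5_contaminant
                -> too_short -> polyA -> clean

``low_quality`` reads are discarded before the report; the remaining categories
partition the high-quality reads exactly, and each is reported as a percentage
of high-quality reads (two decimals, half-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from scipy import stats

__all__ = [
    "QualityRule", "CleaningSummary", "LengthHistogram",
    "classify_read", "clean_library", "length_histogram", "chi2_length_test",
    "percent",
]

CATEGORIES = ("adapter3_null", "insert_null", "adapter5_contaminant",
              "too_short", "polyA", "clean")


def percent(part, total, decimals: int = 2) -> float:
    """100*part/total rounded half-up, 0.0 for an empty total."""
    if total == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(100 * part / total).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class QualityRule:
    """What counts as a low-quality read and a poly-A or short insert."""

    min_mean_phred: float = 20.0
    min_len: int = 18
    max_len: int = 44
    polya_fraction: float = 0.9


def classify_read(seq: str, qual, adapter3: str, adapter5: str,
                  rule: QualityRule = QualityRule()):
    """Classify one read; returns ``(category, insert)``.

    ``qual`` is a list of Phred scores (or ``None`` to skip the quality check).
    The insert is the sequence 5' of the first 3'-adapter occurrence.
    """
    if qual is not None:
        if len(qual) != len(seq):
            raise ValueError("sequence and quality lengths differ")
        if "N" in seq or (len(qual) and sum(qual) / len(qual) < rule.min_mean_phred):
            return "low_quality", ""
    if not seq:
        return "insert_null", ""
    idx = seq.find(adapter3)
    if idx == 0:
        # the read is 3' adapter from its first base: adapter with a null insert
        return "adapter3_null", ""
    if idx == -1:
        # no 3' adapter anywhere: the insert boundary cannot be recovered
        return "insert_null", ""
    insert = seq[:idx]
    if adapter5 in insert:
        return "adapter5_contaminant", insert
    if len(insert) < rule.min_len:
        return "too_short", insert
    if insert.count("A") >= rule.polya_fraction * len(insert):
        return "polyA", insert
    if len(insert) > rule.max_len:
        # adapter found only beyond the insert-size window: no usable insert
        return "insert_null", ""
    return "clean", insert


@dataclass
class CleaningSummary:
    """Cleaning report: category counts plus percentages of high-quality reads."""

    total_reads: int
    adapter3_null: int
    insert_null: int
    adapter5_contaminant: int
    too_short: int
    polyA: int
    clean_reads: int
    high_quality: int = field(init=False)

    def __post_init__(self):
        self.high_quality = (self.adapter3_null + self.insert_null
                             + self.adapter5_contaminant + self.too_short
                             + self.polyA + self.clean_reads)
        if self.high_quality > self.total_reads:
            raise ValueError("category counts exceed total reads")

    @property
    def low_quality(self) -> int:
        return self.total_reads - self.high_quality

    @property
    def percentages(self) -> dict:
        hq = self.high_quality
        return {
            "high_quality": percent(hq, hq) if hq else 0.0,
            "adapter3_null": percent(self.adapter3_null, hq),
            "insert_null": percent(self.insert_null, hq),
            "adapter5_contaminant": percent(self.adapter5_contaminant, hq),
            "too_short": percent(self.too_short, hq),
            "polyA": percent(self.polyA, hq),
            "clean_reads": percent(self.clean_reads, hq),
        }

    def as_row(self) -> dict:
        p = self.percentages
        row = {"total_reads": self.total_reads}
        for k in ("high_quality", "adapter3_null", "insert_null",
                  "adapter5_contaminant", "too_short", "polyA", "clean_reads"):
            row[k] = getattr(self, k)
            row[f"{k}_pct"] = p[k]
        return row


def clean_library(reads, adapter3: str, adapter5: str,
                  rule: QualityRule = QualityRule()):
    """Clean an iterable of ``(read_id, seq, qual)``; returns ``(inserts, summary)``.

    ``inserts`` is the list of clean trimmed insert sequences (with repeats,
    one per clean read), ready for tag collapsing.
    """
    counts = dict.fromkeys(("low_quality",) + CATEGORIES, 0)
    inserts = []
    total = 0
    for _rid, seq, qual in reads:
        total += 1
        cat, insert = classify_read(seq, qual, adapter3, adapter5, rule)
        counts[cat] += 1
        if cat == "clean":
            inserts.append(insert)
    summary = CleaningSummary(
        total_reads=total,
        adapter3_null=counts["adapter3_null"],
        insert_null=counts["insert_null"],
        adapter5_contaminant=counts["adapter5_contaminant"],
        too_short=counts["too_short"],
        polyA=counts["polyA"],
        clean_reads=counts["clean"],
    )
    return inserts, summary


@dataclass
class LengthHistogram:
    """Tag counts indexed by insert length 10..44 nt."""

    counts: dict
    total: int

    MIN, MAX = 10, 44

    @classmethod
    def from_lengths(cls, lengths):
        counts = {l: 0 for l in range(cls.MIN, cls.MAX + 1)}
        for l in lengths:
            if cls.MIN <= l <= cls.MAX:
                counts[l] += 1
        return cls(counts, sum(counts.values()))


def length_histogram(tags) -> LengthHistogram:
    """Histogram of insert lengths; ``tags`` are sequences or objects with ``.sequence``."""
    lengths = [len(getattr(t, "sequence", t)) for t in tags]
    return LengthHistogram.from_lengths(lengths)


def chi2_length_test(hist_a: LengthHistogram, hist_b: LengthHistogram):
    """Pearson chi-square contingency test of two length distributions.

    Bins with zero combined count are dropped; returns ``(X2, df, p)`` with
    ``df = (kept bins - 1)`` for the 2 x k table.
    """
    if hist_a.total == 0 or hist_b.total == 0:
        raise ValueError("cannot test an empty histogram")
    rows = [[], []]
    for l in sorted(hist_a.counts):
        a, b = hist_a.counts[l], hist_b.counts.get(l, 0)
        if a + b > 0:
            rows[0].append(a)
            rows[1].append(b)
    if len(rows[0]) < 2:
        raise ValueError("need at least 2 informative length bins")
    res = stats.chi2_contingency(rows, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
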