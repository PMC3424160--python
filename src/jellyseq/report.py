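"""Render stage outputs as the pipeline's summary tables (TSV-friendly DataFrames).

Every number in a rendered table is recomputed from the counts it summarises;
percentages use half-up rounding to two decimals (one decimal for the
target-overlap proportion), matching the conventions of the stage modules.
"""

from __future__ import annotations

import pandas as pd

from .clean import CleaningSummary, percent
from .classify import OverlapSummary

__all__ = [
    "render_cleaning_table", "render_overlap_table", "render_mapping_summary",
    "render_inventory_table", "render_length_table",
]


def render_cleaning_table(summaries: dict) -> pd.DataFrame:
    """One row per library: counts with percentages of high-quality reads."""
    rows = []
    for name, s in summaries.items():
        if not isinstance(s, CleaningSummary):
            raise TypeError("expected CleaningSummary values")
        rows.append({"library": name, **s.as_row()})
    return pd.DataFrame(rows)


def render_length_table(histograms: dict) -> pd.DataFrame:
    """Length-distribution frequencies (%) per library, lengths 10-44 nt."""
    out = {}
    for name, h in histograms.items():
        out[name] = {l: percent(c, h.total) for l, c in sorted(h.counts.items())}
    df = pd.DataFrame(out)
    df.index.name = "length_nt"
    return df.reset_index()


def render_overlap_table(ov: OverlapSummary, label_a: str = "A",
                         label_b: str = "B") -> pd.DataFrame:
    p = ov.percentages
    rows = [
        {"subset": "total", "unique": ov.unique_total, "unique_pct": 100.0,
         "reads": ov.reads_total, "reads_pct": 100.0},
        {"subset": f"{label_a} specific", "unique": ov.unique_a_specific,
         "unique_pct": p["unique_a_specific"], "reads": ov.reads_a_specific,
         "reads_pct": p["reads_a_specific"]},
        {"subset": f"{label_b} specific", "unique": ov.unique_b_specific,
         "unique_pct": p["unique_b_specific"], "reads": ov.reads_b_specific,
         "reads_pct": p["reads_b_specific"]},
        {"subset": f"shared {label_a}/{label_b}", "unique": ov.unique_shared,
         "unique_pct": p["unique_shared"], "reads": ov.reads_shared,
         "reads_pct": p["reads_shared"]},
    ]
    return pd.DataFrame(rows)


def render_mapping_summary(total_reads: int, sections: dict) -> pd.DataFrame:
    """Read-mapping accounting: each count as a percentage of total reads.

    ``sections`` maps a section name (e.g. ``"genome"``) to an ordered dict of
    ``label -> count``.
    """
    rows = [{"section": "", "label": "total_reads", "count": total_reads,
             "pct": percent(total_reads, total_reads)}]
    for section, counts in sections.items():
        for label, count in counts.items():
            rows.append({"section": section, "label": label, "count": count,
                         "pct": percent(count, total_reads)})
    return pd.DataFrame(rows)


def render_inventory_table(a_specific, b_specific, shared,
                           label_a: str = "A", label_b: str = "B") -> pd.DataFrame:
    rows = [{"subset": f"{label_a} specific", "n": len(a_specific),
             "names": ",".join(a_specific)},
            {"subset": f"{label_b} specific", "n": len(b_specific),
             "names": ",".join(b_specific)},
            {"subset": "shared", "n": len(shared), "names": ",".join(shared)}]
    return pd.DataFrame(rows)
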