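"""Differential expression for one-sample-per-condition count data.

Two decision rules are implemented:

* **altered miRNA** — a miRNA is evaluable only if it has at least ``min_copies``
  (default 10) copies in *both* libraries, and is called up/down on a plain
  two-fold copy-number difference.

* **digital gene expression** — per-gene RPKM normalisation,
  ``log2(RPKM_1/RPKM_2)``, an equal-expression probability from the
  Audic-Claverie conditional count model, Benjamini-Hochberg FDR, and a
  significance call requiring FDR < 0.001 and |log2 ratio| > 1.

The equal-expression probability uses the conditional count model for a pair of
library-size-offset Poisson counts: given the total ``n = x + y``, an equally
expressed gene has

    x | n  ~  Binomial(n, N1 / (N1 + N2))

whose pmf is, up to the constant factor N1/(N1+N2), the familiar digital-
expression form ``(N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1))``.  The
two-sided p-value is ``2 * min(P(X <= x), P(X >= x))`` capped at 1; this
conditional formulation is exactly symmetric under swapping the samples,
``p(x, y, N1, N2) = p(y, x, N2, N1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MirnaComparison", "altered_mirna", "rpkm", "log2_ratio", "p_equal",
    "bh_fdr", "dge_call", "dge_table", "dge_summary",
]


@dataclass
class MirnaComparison:
    name: str
    copies_a: int
    copies_b: int
    norm_a: float
    norm_b: float
    fold: float | None
    call: str  # up_in_A | down_in_A | equal | not_evaluable


def altered_mirna(name: str, copies_a: int, copies_b: int, totals=None,
                  min_copies: int = 10, fold: float = 2.0,
                  per_million: bool = False) -> MirnaComparison:
    """Apply the altered-miRNA decision rule to one miRNA's copy counts.

    Raw copy numbers drive the fold comparison by default; with
    ``per_million=True`` (requires ``totals=(N_a, N_b)``) copies are first
    normalised to copies per million.
    """
    if copies_a < 0 or copies_b < 0:
        raise ValueError("copy numbers must be non-negative")
    if totals:
        na, nb = totals
        norm_a, norm_b = 1e6 * copies_a / na, 1e6 * copies_b / nb
    else:
        norm_a, norm_b = float(copies_a), float(copies_b)
    if min(copies_a, copies_b) < min_copies:
        return MirnaComparison(name, copies_a, copies_b, norm_a, norm_b, None,
                               "not_evaluable")
    va, vb = (norm_a, norm_b) if per_million else (copies_a, copies_b)
    ratio = va / vb
    if va >= fold * vb:
        call = "up_in_A"
    elif vb >= fold * va:
        call = "down_in_A"
    else:
        call = "equal"
    return MirnaComparison(name, copies_a, copies_b, norm_a, norm_b, ratio, call)


def rpkm(count, gene_length_nt, library_total):
    """Reads per kilobase of transcript per million mapped reads."""
    if np.any(np.asarray(gene_length_nt) <= 0) or np.any(np.asarray(library_total) <= 0):
        raise ValueError("gene length and library total must be positive")
    return 1e9 * np.asarray(count, dtype=float) / (
        np.asarray(library_total, dtype=float) * np.asarray(gene_length_nt, dtype=float))


def log2_ratio(rpkm_a, rpkm_b):
    if np.any(np.asarray(rpkm_a) <= 0) or np.any(np.asarray(rpkm_b) <= 0):
        raise ValueError("log2 ratio requires positive RPKMs")
    return np.log2(np.asarray(rpkm_a, dtype=float) / np.asarray(rpkm_b, dtype=float))


def p_equal(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided equal-expression probability for counts ``(x, y)``.

    ``x`` is the count in the sample with library size ``n1``, ``y`` in the
    sample with library size ``n2``.  Evaluated through the binomial tails of
    the conditional model (computed in log space by scipy).
    """
    if x < 0 or y < 0 or x != int(x) or y != int(y):
        raise ValueError("counts must be non-negative integers")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    n, p = x + y, n1 / (n1 + n2)
    lower = stats.binom.cdf(x, n, p)
    upper = stats.binom.sf(x - 1, n, p)
    return float(min(1.0, 2.0 * min(lower, upper)))


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up q-values: ``q_(k) = min_{i>=k} p_(i) * n / i``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def dge_call(log2ratio: float, fdr: float, fdr_cutoff: float = 0.001,
             lfc_cutoff: float = 1.0) -> str:
    if fdr < fdr_cutoff and log2ratio > lfc_cutoff:
        return "up"
    if fdr < fdr_cutoff and log2ratio < -lfc_cutoff:
        return "down"
    return "ns"


def dge_table(counts_1, counts_2, lengths, n1, n2, gene_ids=None,
              fdr_cutoff: float = 0.001, lfc_cutoff: float = 1.0) -> pd.DataFrame:
    """Full digital-gene-expression table for two libraries.

    Genes with zero counts in both samples are excluded.  A gene with a zero in
    one sample gets its log2 ratio from a 0.5-count pseudo-offset (reporting
    only); the p-value always uses the raw integer counts.
    """
    c1 = np.asarray(counts_1, dtype=int)
    c2 = np.asarray(counts_2, dtype=int)
    lengths = np.asarray(lengths, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(len(c1))]
    gene_ids = np.asarray(gene_ids, dtype=object)
    keep = (c1 + c2) > 0
    c1, c2, lengths, gene_ids = c1[keep], c2[keep], lengths[keep], gene_ids[keep]

    r1 = rpkm(c1, lengths, n1)
    r2 = rpkm(c2, lengths, n2)
    zero = (c1 == 0) | (c2 == 0)
    lr = np.empty(len(c1))
    lr[~zero] = log2_ratio(r1[~zero], r2[~zero])
    if zero.any():
        lr[zero] = log2_ratio(rpkm(c1[zero] + 0.5, lengths[zero], n1),
                              rpkm(c2[zero] + 0.5, lengths[zero], n2))
    pvals = np.array([p_equal(int(x), int(y), n1, n2) for x, y in zip(c1, c2)])
    qvals = bh_fdr(pvals)
    calls = [dge_call(l, q, fdr_cutoff, lfc_cutoff) for l, q in zip(lr, qvals)]
    return pd.DataFrame({
        "gene_id": gene_ids, "length": lengths.astype(int),
        "count_1": c1, "count_2": c2,
        "rpkm_1": r1, "rpkm_2": r2,
        "log2_ratio": lr, "p_equal": pvals, "fdr": qvals, "call": calls,
    })


def dge_summary(table: pd.DataFrame) -> dict:
    """Up/down/ns counts; ``n_de`` is the total number of significant genes."""
    n_up = int((table["call"] == "up").sum())
    n_down = int((table["call"] == "down").sum())
    return {"n_genes": len(table), "n_up": n_up, "n_down": n_down,
            "n_ns": len(table) - n_up - n_down, "n_de": n_up + n_down}
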