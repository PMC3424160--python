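"""Independent reference implementations used as oracles by the test suite.

These deliberately avoid the package's own algorithms: tail probabilities by
direct log-space summation, BH by the step-up definition applied literally, and
read mapping by a naive all-window Hamming scan.
"""

import math

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_p_equal(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided equal-expression p-value by direct log-space summation of the
    conditional pmf p(k | n) over both tails."""
    n = x + y
    log_p = math.log(n1) - math.log(n1 + n2)
    log_q = math.log(n2) - math.log(n1 + n2)

    def log_pmf(k):
        return (math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
                + k * log_p + (n - k) * log_q)

    lower = sum(math.exp(log_pmf(k)) for k in range(0, x + 1))
    upper = sum(math.exp(log_pmf(k)) for k in range(x, n + 1))
    return min(1.0, 2.0 * min(lower, upper))


def brute_bh(pvals):
    """q_(k) = min_{i >= k} p_(i) * n / i, straight from the definition."""
    n = len(pvals)
    indexed = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    for rank_pos, i in enumerate(indexed):
        best = min(pvals[indexed[r]] * n / (r + 1) for r in range(rank_pos, n))
        q[i] = min(1.0, best)
    return q


def revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def brute_map(tag: str, genome: str, max_mismatch: int = 1):
    """All loci of ``tag`` on either strand with <= max_mismatch substitutions,
    reduced to the best (fewest-mismatch) stratum."""
    L = len(tag)
    hits = []
    for strand, query in (("+", tag), ("-", revcomp(tag))):
        for pos in range(len(genome) - L + 1):
            mm = sum(1 for a, b in zip(query, genome[pos:pos + L]) if a != b)
            if mm <= max_mismatch:
                hits.append((pos, strand, mm))
    if not hits:
        return []
    best = min(mm for _, _, mm in hits)
    return sorted(h for h in hits if h[2] == best)
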