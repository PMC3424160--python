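"""Minimum-free-energy RNA secondary structure prediction for miRNA hairpin discovery.

The folding engine predicts the lowest-energy non-crossing secondary structure of a
short (<= 100 nt) genomic window under a simplified nearest-neighbour energy model:
Watson-Crick and G:U wobble pairs gain energy only when stacked on an adjacent pair,
while hairpin loops, bulges and internal loops pay configurable penalties.  The model
is a reproducible desk-scale surrogate for a full thermodynamic folder: its parameters
are deliberately simple so that an exhaustive enumeration over all structures of a
short sequence (:func:`fold_exhaustive`) can verify the dynamic program exactly.

A mature-miRNA candidate hairpin must satisfy three criteria:

(a) the mature sequence sits entirely on one arm of the hairpin, with no long
    unpaired run (large internal loop or bulge) inside it;
(b) the fold is stable, with free energy below a cutoff (default -20 kcal/mol);
(c) the locus lies in an intergenic region or an intron.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "EnergyModel",
    "HairpinCandidate",
    "fold_mfe",
    "fold_exhaustive",
    "structure_energy",
    "pairs_to_dotbracket",
    "dotbracket_to_pairs",
    "extract_window",
    "criteria_check",
    "match_catalog",
    "inventory_overlap",
]

_COMPLEMENT = str.maketrans("ACGUT", "UGCAA")

#: canonical pairs: Watson-Crick plus G:U wobble (RNA alphabet, T == U)
_PAIRABLE = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}

INF = math.inf


def _normalize(seq: str) -> str:
    """Uppercase and map T->U; reject anything outside ACGU(T)."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving the DNA/RNA alphabet of the input."""
    if "U" in seq.upper():
        table = str.maketrans("ACGUacgu", "UGCAugca")
    else:
        table = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(table)[::-1]


@dataclass(frozen=True)
class EnergyModel:
    """Simplified nearest-neighbour energy parameters (kcal/mol).

    ``pair_stack_energies`` is keyed by the outer (closing) pair of a stacked
    helix step; penalties are charged per loop (hairpin) or per unpaired
    nucleotide (bulge/internal).  Multibranch loops are penalised at the
    internal-loop rate per unpaired nucleotide.  Interior loops and bulges
    larger than ``max_interior`` unpaired nucleotides are disallowed in the DP
    (the usual MAXLOOP convention); the bound cannot bind for sequences shorter
    than ~30 nt, keeping small-sequence folds exactly enumerable.
    """

    pair_stack_energies: dict = field(default_factory=lambda: {
        "GC": -3.0, "CG": -3.0,
        "AU": -2.0, "UA": -2.0,
        "GU": -1.0, "UG": -1.0,
    })
    hairpin_loop_penalty: float = 4.0
    bulge_penalty_per_nt: float = 3.0
    internal_loop_penalty_per_nt: float = 2.0
    min_loop: int = 3
    max_interior: int = 30

    def __post_init__(self):
        if any(e >= 0 for e in self.pair_stack_energies.values()):
            raise ValueError("stack energies must be negative")
        if (self.hairpin_loop_penalty < 0 or self.bulge_penalty_per_nt < 0
                or self.internal_loop_penalty_per_nt < 0):
            raise ValueError("loop penalties must be non-negative")
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3")

    def stack(self, outer_pair: str) -> float:
        return self.pair_stack_energies[outer_pair]


DEFAULT_MODEL = EnergyModel()


def _pairable(a: str, b: str) -> bool:
    return (a, b) in _PAIRABLE


def pairs_to_dotbracket(n: int, pairs) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i] = "("
        out[j] = ")"
    return "".join(out)


def dotbracket_to_pairs(structure: str):
    """Parse dot-bracket into a sorted list of (i, j) pairs."""
    stack, pairs = [], []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def structure_energy(seq: str, pairs, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Energy of an explicit structure (list of pairs) under the model.

    Decomposes the structure into loops: each pair closes a loop containing its
    directly nested child pairs.  No children -> hairpin penalty; one adjacent
    child -> stack energy keyed by the outer pair; one non-adjacent child ->
    bulge or internal-loop penalty per unpaired nt; two or more children
    (multibranch) -> internal-loop rate per unpaired nt in the loop.  Exterior
    unpaired bases are free.  This evaluator is the definition of the model;
    both the DP and the exhaustive reference minimise it.
    """
    s = _normalize(seq)
    pairs = sorted(pairs)
    energy = 0.0
    for idx, (i, j) in enumerate(pairs):
        # direct children: pairs nested in (i,j) but not inside a sibling
        children = []
        cursor = i
        for (k, l) in pairs[idx + 1:]:
            if k > j:
                break
            if k > cursor and l < j:
                children.append((k, l))
                cursor = l
        if not children:
            energy += model.hairpin_loop_penalty
        elif len(children) == 1:
            k, l = children[0]
            left, right = k - i - 1, j - l - 1
            if left == 0 and right == 0:
                energy += model.stack(s[i] + s[j])
            elif left == 0 or right == 0:
                energy += model.bulge_penalty_per_nt * (left + right)
            else:
                energy += model.internal_loop_penalty_per_nt * (left + right)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            energy += model.internal_loop_penalty_per_nt * unpaired
    return energy


def fold_mfe(seq: str, model: EnergyModel = DEFAULT_MODEL):
    """Predict the minimum-free-energy structure of ``seq``.

    Returns ``(structure, mfe)`` where ``structure`` is a dot-bracket string of
    the same length as ``seq`` and ``mfe`` is its energy in kcal/mol.  The empty
    structure has energy 0, so the MFE is never positive.

    Zuker-style dynamic program over the loop-decomposed energy:
    ``V[i][j]`` is the best energy of the region ``[i, j]`` given that ``(i, j)``
    pair; ``M[i][j]`` the best energy of a multibranch-interior region with at
    least one branch, each unpaired nucleotide charged at the internal-loop
    rate; ``W[j]`` the best energy of the prefix with free exterior bases.
    """
    s = _normalize(seq)
    n = len(s)
    if n == 0:
        return "", 0.0
    if n > 100:
        raise ValueError("fold_mfe is limited to sequences of <= 100 nt")

    min_loop = model.min_loop
    maxint = model.max_interior
    c_multi = model.internal_loop_penalty_per_nt
    c_bulge = model.bulge_penalty_per_nt
    hp = model.hairpin_loop_penalty
    stack_of = model.pair_stack_energies

    V = [[INF] * n for _ in range(n)]
    M = [[INF] * n for _ in range(n)]
    can_pair = [[_pairable(s[i], s[j]) for j in range(n)] for i in range(n)]

    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            # --- V: (i, j) paired ---
            if can_pair[i][j]:
                best = hp
                # single interior pair (stack / bulge / internal loop)
                Vrow = V
                for k in range(i + 1, min(i + 2 + maxint, j)):
                    left = k - i - 1
                    rem = maxint - left
                    lmin = max(k + min_loop + 1, j - 1 - rem)
                    row = Vrow[k]
                    for l in range(lmin, j):
                        v = row[l]
                        if v == INF:
                            continue
                        right = j - l - 1
                        if left == 0 and right == 0:
                            e = v + stack_of[s[i] + s[j]]
                        elif left == 0 or right == 0:
                            e = v + c_bulge * (left + right)
                        else:
                            e = v + c_multi * (left + right)
                        if e < best:
                            best = e
                # multibranch: >= 2 branches between i+1 and j-1
                Mi = M[i + 1] if i + 1 < n else None
                if Mi is not None:
                    for k in range(i + 2, j):
                        a = Mi[k - 1]
                        if a == INF:
                            continue
                        b = M[k][j - 1]
                        if b == INF:
                            continue
                        e = a + b
                        if e < best:
                            best = e
                V[i][j] = best

        # --- M: at least one branch in [i, j], unpaired cost c_multi ---
        for i in range(n - span):
            j = i + span
            best = INF
            if V[i][j] < best:
                best = V[i][j]
            a = M[i + 1][j] if i + 1 <= j else INF
            if a + c_multi < best:
                best = a + c_multi
            a = M[i][j - 1] if i <= j - 1 else INF
            if a + c_multi < best:
                best = a + c_multi
            row = M[i]
            for k in range(i + 1, j):
                a = row[k]
                if a == INF:
                    continue
                b = M[k + 1][j]
                if a + b < best:
                    best = a + b
            M[i][j] = best
        # spans shorter than a pairable region: M stays INF (handled above by bounds)

    # handle very short spans for M (no pair possible): remain INF, fine.

    W = [0.0] * (n + 1)  # W[j]: best energy of prefix s[0:j]
    for j in range(1, n + 1):
        best = W[j - 1]
        jj = j - 1
        for i in range(0, jj):
            v = V[i][jj]
            if v == INF:
                continue
            e = W[i] + v
            if e < best:
                best = e
        W[j] = best
    mfe = W[n]

    # --- traceback ---
    pairs = []
    EPS = 1e-9

    def trace_V(i, j):
        pairs.append((i, j))
        e = V[i][j]
        if abs(e - hp) < EPS:
            # could still be a coincidence; prefer hairpin only if nothing nested
            pass
        # try hairpin
        if abs(e - hp) < EPS:
            return
        for k in range(i + 1, min(i + 2 + maxint, j)):
            left = k - i - 1
            rem = maxint - left
            lmin = max(k + min_loop + 1, j - 1 - rem)
            for l in range(lmin, j):
                v = V[k][l]
                if v == INF:
                    continue
                right = j - l - 1
                if left == 0 and right == 0:
                    cand = v + stack_of[s[i] + s[j]]
                elif left == 0 or right == 0:
                    cand = v + c_bulge * (left + right)
                else:
                    cand = v + c_multi * (left + right)
                if abs(cand - e) < EPS:
                    trace_V(k, l)
                    return
        for k in range(i + 2, j):
            a, b = M[i + 1][k - 1], M[k][j - 1]
            if a != INF and b != INF and abs(a + b - e) < EPS:
                trace_M(i + 1, k - 1)
                trace_M(k, j - 1)
                return
        raise AssertionError("traceback failed in V")  # pragma: no cover

    def trace_M(i, j):
        e = M[i][j]
        if V[i][j] != INF and abs(V[i][j] - e) < EPS:
            trace_V(i, j)
            return
        if i + 1 <= j and M[i + 1][j] != INF and abs(M[i + 1][j] + c_multi - e) < EPS:
            trace_M(i + 1, j)
            return
        if i <= j - 1 and M[i][j - 1] != INF and abs(M[i][j - 1] + c_multi - e) < EPS:
            trace_M(i, j - 1)
            return
        for k in range(i + 1, j):
            a, b = M[i][k], M[k + 1][j]
            if a != INF and b != INF and abs(a + b - e) < EPS:
                trace_M(i, k)
                trace_M(k + 1, j)
                return
        raise AssertionError("traceback failed in M")  # pragma: no cover

    def trace_W(j):
        while j > 0:
            if abs(W[j] - W[j - 1]) < EPS and W[j] == W[j - 1]:
                j -= 1
                continue
            jj = j - 1
            found = False
            for i in range(0, jj):
                v = V[i][jj]
                if v != INF and abs(W[i] + v - W[j]) < EPS:
                    trace_V(i, jj)
                    j = i
                    found = True
                    break
            if not found:
                j -= 1
        return

    trace_W(n)
    structure = pairs_to_dotbracket(n, pairs)
    # internal consistency: the traced structure realises the DP minimum
    assert abs(structure_energy(s, pairs, model) - mfe) < 1e-6
    return structure, mfe


def _enumerate_structures(s: str, i: int, j: int, min_loop: int, memo):
    """All non-crossing pair sets on s[i..j] (inclusive), as tuples of pairs."""
    if j - i < min_loop + 1:
        return ((),)
    key = (i, j)
    if key in memo:
        return memo[key]
    out = list(_enumerate_structures(s, i + 1, j, min_loop, memo))
    for k in range(i + min_loop + 1, j + 1):
        if _pairable(s[i], s[k]):
            inner = _enumerate_structures(s, i + 1, k - 1, min_loop, memo)
            outer = _enumerate_structures(s, k + 1, j, min_loop, memo)
            for a in inner:
                base = ((i, k),) + a
                for b in outer:
                    out.append(base + b)
    memo[key] = tuple(out)
    return memo[key]


def fold_exhaustive(seq: str, model: EnergyModel = DEFAULT_MODEL):
    """Exhaustive reference fold: enumerate every non-crossing structure.

    Intended for short sequences (<= ~25 nt); the number of structures grows
    exponentially.  Returns ``(structure, mfe)`` for the best structure found
    (ties broken by enumeration order, empty structure first).
    """
    s = _normalize(seq)
    n = len(s)
    best_pairs, best_e = (), 0.0
    memo: dict = {}
    for pairs in _enumerate_structures(s, 0, n - 1, model.min_loop, memo):
        e = structure_energy(s, pairs, model)
        if e < best_e:
            best_pairs, best_e = pairs, e
    return pairs_to_dotbracket(n, sorted(best_pairs)), best_e


# ---------------------------------------------------------------------------
# hairpin candidate evaluation
# ---------------------------------------------------------------------------

@dataclass
class HairpinCandidate:
    """A folded genomic window evaluated as a miRNA precursor candidate."""

    window_seq: str
    structure: str
    mfe: float
    mature_span: tuple  # (start, end) half-open, window coordinates
    location_class: str  # intergenic | intron | exon | rRNA
    arm: str = "none"    # 5p | 3p | none
    verdict: bool = False
    failed: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.structure) != len(self.window_seq):
            raise ValueError("structure and window sequence lengths differ")
        a, b = self.mature_span
        if not (0 <= a < b <= len(self.window_seq)):
            raise ValueError("mature span outside window")


def extract_window(genome_seq: str, position: int, length: int, strand: str = "+",
                   window: int = 100):
    """Extract a genomic window centred on a mapped tag.

    ``position``/``length`` give the tag locus (0-based, forward-strand
    coordinates).  The window is truncated at contig ends.  For minus-strand
    loci the window is reverse complemented and the mature span translated
    accordingly.  Returns ``(window_seq, (mat_start, mat_end))`` in window
    coordinates (half-open).
    """
    n = len(genome_seq)
    if not (0 <= position and position + length <= n):
        raise ValueError("locus outside genome")
    pad = (window - length) // 2
    start = max(0, position - pad)
    end = min(n, start + window)
    start = max(0, end - window)  # re-extend left if right-truncated
    wseq = genome_seq[start:end]
    mat_start = position - start
    mat_end = mat_start + length
    if strand == "-":
        wseq = reverse_complement(wseq)
        mat_start, mat_end = len(wseq) - mat_end, len(wseq) - mat_start
    return wseq, (mat_start, mat_end)


def _max_unpaired_run(structure: str, span) -> int:
    run = best = 0
    for ch in structure[span[0]:span[1]]:
        if ch == ".":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def _terminal_loop(structure: str):
    """The hairpin loop closed by the deepest stem, as ``(loop_start, loop_end)``.

    A hairpin loop is the unpaired interior of an innermost pair; the terminal
    loop of the dominant stem is the one with the most enclosing pairs.
    Returns ``None`` for a structure without pairs.
    """
    pairs = dotbracket_to_pairs(structure)
    if not pairs:
        return None
    best = None
    for i, j in pairs:
        if any(i < k and l < j for k, l in pairs):
            continue  # not innermost
        depth = sum(1 for k, l in pairs if k <= i and j <= l)
        if best is None or depth > best[0]:
            best = (depth, i + 1, j)  # loop spans (i, j) exclusive -> half-open
    _, lo, hi = best
    return lo, hi


def _mature_arm(structure: str, span) -> str:
    """Which hairpin arm the mature span occupies: '5p', '3p' or 'none'.

    The mature sits on one arm iff it lies entirely 5' or 3' of the terminal
    loop of the dominant stem (no overlap with the loop itself).
    """
    loop = _terminal_loop(structure)
    if loop is None:
        return "none"
    lo, hi = loop
    a, b = span
    if b <= lo:
        return "5p"
    if a >= hi:
        return "3p"
    return "none"


def criteria_check(candidate: HairpinCandidate, mfe_cutoff: float = -20.0,
                   max_unpaired_run: int = 4) -> HairpinCandidate:
    """Apply the three miRNA-candidate criteria and record the verdict in place.

    (a) mature on one arm, no unpaired run longer than ``max_unpaired_run``
        inside the mature span; (b) ``mfe`` strictly below ``mfe_cutoff``;
    (c) location in an intergenic region or intron.
    """
    failed = []
    arm = _mature_arm(candidate.structure, candidate.mature_span)
    candidate.arm = arm
    if arm == "none" or _max_unpaired_run(candidate.structure, candidate.mature_span) > max_unpaired_run:
        failed.append("a")
    if not candidate.mfe < mfe_cutoff:
        failed.append("b")
    if candidate.location_class not in ("intergenic", "intron"):
        failed.append("c")
    candidate.failed = failed
    candidate.verdict = not failed
    return candidate


def match_catalog(mature_seq: str, catalog: dict, max_mismatch: int = 0) -> str:
    """Match a mature sequence against a ``{name: sequence}`` catalog.

    Returns the catalog name (ties broken lexicographically) or ``"novel"``.
    T/U are synonyms; comparison requires equal length and at most
    ``max_mismatch`` substitutions.
    """
    q = _normalize(mature_seq)
    hits = []
    for name, seq in catalog.items():
        t = _normalize(seq)
        if len(t) != len(q):
            continue
        mm = sum(1 for a, b in zip(q, t) if a != b)
        if mm <= max_mismatch:
            hits.append((mm, name))
    if not hits:
        return "novel"
    hits.sort()
    return hits[0][1]


def inventory_overlap(known_a, known_b):
    """Set arithmetic over two known-miRNA name inventories.

    Returns ``(a_specific, b_specific, shared)`` as sorted name sets plus a dict
    of counts, e.g. for reporting species-specific vs shared miRNAs.
    """
    a, b = set(known_a), set(known_b)
    shared = a & b
    a_spec, b_spec = a - b, b - a
    counts = {
        "a_total": len(a), "b_total": len(b),
        "a_specific": len(a_spec), "b_specific": len(b_spec),
        "shared": len(shared),
    }
    return sorted(a_spec), sorted(b_spec), sorted(shared), counts
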