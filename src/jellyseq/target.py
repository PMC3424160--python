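"""miRNA target prediction by intermolecular minimum-free-energy hybridisation.

A duplex is a chain of base pairs between the miRNA (5'->3') and a transcript
window (antiparallel, so window partners decrease as miRNA positions increase),
with no intramolecular pairing.  Under the shared simplified energy model,
adjacent pairs gain a stacking energy; skipped nucleotides between consecutive
pairs are charged at the bulge rate (one strand) or internal-loop rate (both
strands).  The empty duplex has energy 0, so a reported site energy is never
positive.

Each transcript is scanned in overlapping windows; the single lowest-energy
site is reported per (miRNA, transcript) pair, ties broken by leftmost
position — mirroring the "single predicted site of interaction with a minimum
free energy" convention of RNAhybrid-style tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .clean import percent
from .fold import DEFAULT_MODEL, EnergyModel, _normalize, _pairable

__all__ = [
    "DuplexSite", "OverlapReport", "duplex_energy", "duplex_mfe",
    "duplex_exhaustive", "predict_targets", "overlap_report",
]

INF = math.inf


@dataclass
class DuplexSite:
    mirna_name: str
    transcript_id: str
    site_start: int      # transcript coordinates, half-open
    site_end: int
    energy: float
    pairing: str         # "mirna_struct&window_struct" dot-bracket
    rank: int = 1

    def __post_init__(self):
        if self.energy > 0:
            raise ValueError("a reported duplex site cannot have positive energy")


def duplex_energy(mirna: str, window: str, pairs,
                  model: EnergyModel = DEFAULT_MODEL) -> float:
    """Energy of an explicit duplex (list of (i, j) pairs, original coordinates).

    Validates monotonicity (i strictly increasing, j strictly decreasing) and
    complementarity.  This evaluator defines the duplex model; the DP and the
    exhaustive reference both minimise it.
    """
    m = _normalize(mirna)
    w = _normalize(window)
    pairs = sorted(pairs)
    energy = 0.0
    prev = None
    for i, j in pairs:
        if not (0 <= i < len(m) and 0 <= j < len(w)):
            raise ValueError("pair outside sequences")
        if not _pairable(m[i], w[j]):
            raise ValueError(f"non-complementary pair ({i}, {j})")
        if prev is not None:
            pi, pj = prev
            if i <= pi or j >= pj:
                raise ValueError("duplex pairs must be monotone (antiparallel)")
            di, dj = i - pi - 1, pj - j - 1
            if di == 0 and dj == 0:
                energy += model.stack(m[pi] + w[pj])
            elif di == 0 or dj == 0:
                energy += model.bulge_penalty_per_nt * (di + dj)
            else:
                energy += model.internal_loop_penalty_per_nt * (di + dj)
        prev = (i, j)
    return energy


def duplex_mfe(mirna: str, window: str, model: EnergyModel = DEFAULT_MODEL):
    """Minimum-energy intermolecular duplex; returns ``(energy, pairing, pairs)``.

    ``pairing`` is a dot-bracket string ``mirna&window``; ``pairs`` the list of
    (miRNA position, window position) base pairs of the optimal duplex (empty
    when no duplex beats the empty one).  Dynamic program is O(|miRNA|*|window|)
    with four states (last-pair, miRNA-bulge, window-bulge, internal loop).
    """
    m = _normalize(mirna)
    w = _normalize(window)
    if not (1 <= len(m) <= 30):
        raise ValueError("miRNA length out of range")
    M, W = len(m), len(w)
    if W == 0:
        return 0.0, "&" + "", []
    wr = w[::-1]  # reversed window: both strands now 5'->3' index-ascending
    cb = model.bulge_penalty_per_nt
    ci = model.internal_loop_penalty_per_nt

    A = [[INF] * W for _ in range(M)]   # last pair at (i, k)
    Bm = [[INF] * W for _ in range(M)]  # miRNA-side gap after a pair at window k
    Bw = [[INF] * W for _ in range(M)]  # window-side gap after a pair at miRNA i
    C = [[INF] * W for _ in range(M)]   # gap on both sides (internal loop)

    def get(arr, i, k):
        return arr[i][k] if i >= 0 and k >= 0 else INF

    for i in range(M):
        for k in range(W):
            if _pairable(m[i], wr[k]):
                prev = get(A, i - 1, k - 1)
                best = 0.0
                if prev < INF:
                    cand = prev + model.stack(m[i - 1] + wr[k - 1])
                    if cand < best:
                        best = cand
                for arr in (Bm, Bw, C):
                    cand = get(arr, i - 1, k - 1)
                    if cand < best:
                        best = cand
                A[i][k] = best
            Bm[i][k] = min(get(A, i - 1, k) + cb, get(Bm, i - 1, k) + cb)
            Bw[i][k] = min(get(A, i, k - 1) + cb, get(Bw, i, k - 1) + cb)
            C[i][k] = min(get(A, i - 1, k - 1) + 2 * ci,
                          get(C, i - 1, k) + ci, get(C, i, k - 1) + ci)

    best_e, best_ik = 0.0, None
    for i in range(M):
        for k in range(W):
            if A[i][k] < best_e:
                best_e, best_ik = A[i][k], (i, k)

    pairs_rev = []
    eps = 1e-9
    i, k = best_ik if best_ik else (None, None)
    while i is not None:
        pairs_rev.append((i, k))
        e = A[i][k]
        if abs(e) < eps:
            break  # duplex can start here
        stack_prev = get(A, i - 1, k - 1)
        if stack_prev < INF and abs(stack_prev + model.stack(m[i - 1] + wr[k - 1]) - e) < eps:
            i, k = i - 1, k - 1
            continue
        nxt = None
        for arr, kind in ((Bm, "m"), (Bw, "w"), (C, "c")):
            if abs(get(arr, i - 1, k - 1) - e) < eps:
                gi, gk = i - 1, k - 1
                # walk back through the gap state to the pair that opened it
                while True:
                    ge = arr[gi][gk]
                    if kind == "m" and abs(get(A, gi - 1, gk) + cb - ge) < eps:
                        nxt = (gi - 1, gk)
                        break
                    if kind == "w" and abs(get(A, gi, gk - 1) + cb - ge) < eps:
                        nxt = (gi, gk - 1)
                        break
                    if kind == "c" and abs(get(A, gi - 1, gk - 1) + 2 * ci - ge) < eps:
                        nxt = (gi - 1, gk - 1)
                        break
                    if kind == "m":
                        gi -= 1
                    elif kind == "w":
                        gk -= 1
                    elif abs(get(C, gi - 1, gk) + ci - ge) < eps:
                        gi -= 1
                    else:
                        gk -= 1
                break
        if nxt is None:  # pragma: no cover
            raise AssertionError("duplex traceback failed")
        i, k = nxt

    pairs = sorted((i, W - 1 - k) for i, k in pairs_rev)
    mstruct = "".join("(" if any(i == p for p, _ in pairs) else "." for i in range(M))
    wstruct = "".join(")" if any(j == q for _, q in pairs) else "." for j in range(W))
    return best_e, mstruct + "&" + wstruct, pairs


def _chains(m, w, start_i, max_j, memo):
    key = (start_i, max_j)
    if key in memo:
        return memo[key]
    out = [()]
    for i in range(start_i, len(m)):
        for j in range(max_j):
            if _pairable(m[i], w[j]):
                for rest in _chains(m, w, i + 1, j, memo):
                    out.append(((i, j),) + rest)
    memo[key] = out
    return out


def duplex_exhaustive(mirna: str, window: str,
                      model: EnergyModel = DEFAULT_MODEL) -> float:
    """Exhaustive reference: minimum energy over every monotone pairing chain.

    Exponential; intended for |miRNA| <= ~12 and |window| <= ~15.
    """
    m = _normalize(mirna)
    w = _normalize(window)
    best = 0.0
    for chain in _chains(m, w, 0, len(w), {}):
        e = duplex_energy(m, w, chain, model)
        if e < best:
            best = e
    return best


def _seed_paired(pairs, seed_span=(1, 8)) -> bool:
    """Contiguous duplex over miRNA positions 2-8 (0-based 1..7)."""
    lo, hi = seed_span
    need = {i: None for i in range(lo, hi)}
    for i, j in pairs:
        if lo <= i < hi:
            need[i] = j
    if any(v is None for v in need.values()):
        return False
    js = [need[i] for i in range(lo, hi)]
    return all(a - b == 1 for a, b in zip(js, js[1:]))


def predict_targets(mirna_name: str, mirna_seq: str, transcript_id: str,
                    transcript_seq: str, model: EnergyModel = DEFAULT_MODEL,
                    energy_cutoff: float = -20.0, seed_required: bool = False,
                    window: int = 60, step: int = 30):
    """Best hybridisation site of one miRNA on one transcript, or ``None``.

    The transcript is scanned in windows of ``window`` nt advancing by ``step``;
    the single lowest-energy duplex strictly below ``energy_cutoff`` is
    returned (ties: leftmost site).  ``seed_required`` additionally demands
    contiguous pairing of miRNA positions 2-8.
    """
    t = transcript_seq.upper()
    best = None
    starts = list(range(0, max(1, len(t) - window + step), step))
    for ws in starts:
        sub = t[ws:ws + window]
        if len(sub) < 8:
            continue
        e, pairing, pairs = duplex_mfe(mirna_seq, sub, model)
        if not pairs or not e < energy_cutoff:
            continue
        if seed_required and not _seed_paired(pairs):
            continue
        lo = ws + min(j for _, j in pairs)
        hi = ws + max(j for _, j in pairs) + 1
        key = (e, lo)
        if best is None or key < (best.energy, best.site_start):
            best = DuplexSite(mirna_name, transcript_id, lo, hi, e, pairing)
    return best


@dataclass
class OverlapReport:
    """How many differentially expressed genes are predicted miRNA targets."""

    n_deg: int
    n_deg_targets: int

    def __post_init__(self):
        if not 0 <= self.n_deg_targets <= max(self.n_deg, 0):
            raise ValueError("target count outside [0, n_deg]")

    @property
    def proportion(self) -> float:
        return percent(self.n_deg_targets, self.n_deg, decimals=1)


def overlap_report(deg_ids, target_map: dict) -> OverlapReport:
    """``target_map`` maps each miRNA name to an iterable of targeted gene ids."""
    targeted = set()
    for genes in target_map.values():
        targeted.update(genes)
    degs = set(deg_ids)
    return OverlapReport(len(degs), len(degs & targeted))
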