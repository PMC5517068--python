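"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's optimised code paths (k-mer
prefilters, cached overlap machinery): they enumerate candidate solutions
directly so the implementation can be checked against them bit-exactly.
"""

from __future__ import annotations

import math

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _enc(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def pair_qualifies(a: str, b: str, min_identity: float, min_overlap: float) -> bool:
    """Does any gapless overlap of a vs b (either strand, any shift)
    reach the identity and overlap thresholds?  All shifts enumerated."""
    la, lb = len(a), len(b)
    short = min(la, lb)
    minov = math.ceil(min_overlap * short - 1e-9)
    eb = _enc(b)
    for astr in (a, rc(a)):
        ea = _enc(astr)
        # alignment convention: position x of b pairs with x + d of a
        for d in range(-(lb - 1), la):
            x0 = max(0, -d)
            x1 = min(lb, la - d)
            ov = x1 - x0
            if ov < minov:
                continue
            matches = int(np.count_nonzero(ea[x0 + d : x1 + d] == eb[x0:x1]))
            if matches / ov >= min_identity:
                return True
    return False


def brute_force_edges(
    seqs: list[str], min_identity: float, min_overlap: float
) -> set[tuple[int, int]]:
    edges = set()
    for i in range(len(seqs)):
        for j in range(i):
            if pair_qualifies(seqs[i], seqs[j], min_identity, min_overlap):
                edges.add((j, i))
    return edges


def brute_force_min_rotation(seq: str) -> str:
    candidates = []
    for s in (seq, rc(seq)):
        for i in range(len(s)):
            candidates.append(s[i:] + s[:i])
    return min(candidates)


def brute_force_microsatellites(
    seq: str, min_copies: int
) -> list[tuple[str, int, int]]:
    """All maximal perfect tandem tracts with primitive 1-6 bp motifs,
    reported as (canonical motif, full copies, start)."""
    out = []
    L = len(seq)
    for u in range(1, 7):
        x = 0
        while x + u < L:
            if seq[x] != seq[x + u]:
                x += 1
                continue
            start = x
            while x + u < L and seq[x] == seq[x + u]:
                x += 1
            tract_len = (x - start) + u
            motif = seq[start : start + u]
            primitive = all(
                not (u % d == 0 and motif == motif[:d] * (u // d))
                for d in range(1, u)
            )
            if primitive and tract_len // u >= min_copies:
                out.append(
                    (brute_force_min_rotation(motif), tract_len // u, start)
                )
    out.sort(key=lambda t: (t[2], len(t[0])))
    return out


def smith_waterman_score(
    a: str, b: str, match: int = 1, mismatch: int = -2,
    gap_open: int = -4, gap_extend: int = -2,
) -> float:
    """Plain affine-gap Smith-Waterman best local score."""
    n, m = len(a), len(b)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in a (left moves)
    F = np.full((n + 1, m + 1), neg)  # gap in b (up moves)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def chi2_closed_form(table) -> float:
    (a, b), (c, d) = table
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
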