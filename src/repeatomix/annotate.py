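"""Cluster annotation: contigs, tandem periodicity, repeat classification
and consensus monomer inference.

Clusters coming out of :mod:`repeatomix.clustering` are anonymous read
communities.  This module turns them into interpretable repeat calls:

* a greedy overlap-layout assembly builds representative contigs;
* a self-dotplot (exact word matches) detects tandem periodicity, with an
  autocorrelation fallback for periods shorter than the word size;
* clusters are classified into the six repeat categories (LTR, non-LTR,
  DNA_TE, satDNA, rDNA, unclassified) by library matching and periodicity;
* a phase-aligned majority-vote consensus recovers the canonical monomer of
  a satellite family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .clustering import Cluster
from .syndata import ReadSet, reverse_complement

REPEAT_CATEGORIES = ("LTR", "non-LTR", "DNA_TE", "satDNA", "rDNA", "unclassified")


class InsufficientSpanError(ValueError):
    """No contig spans two full periods; the monomer cannot be phased."""


@dataclass
class Contig:
    sequence: str
    cluster_id: int
    depth: float  # mean read depth

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ConsensusMonomer:
    """Canonical repeat unit of a satellite family.

    ``sequence`` is stored as the lexicographically minimal rotation over
    both strands so the same family inferred from different samples compares
    byte-identical.
    """

    sequence: str
    unit_length: int
    at_content: float
    support: int

    def __post_init__(self) -> None:
        if self.unit_length != len(self.sequence):
            raise ValueError("unit_length must equal len(sequence)")


@dataclass
class RepeatClassCall:
    category: str
    subfamily: str = ""
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.category not in REPEAT_CATEGORIES:
            raise ValueError(f"category must be one of {REPEAT_CATEGORIES}")


@dataclass
class LibraryEntry:
    """One labelled reference repeat (RepeatMasker-style ``name#CAT/Sub``)."""

    name: str
    category: str
    subfamily: str
    sequence: str


# ---------------------------------------------------------------------------
# greedy overlap assembly


_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i

_diag_cache: dict[int, np.ndarray] = {}


def _diag_index(m: int) -> np.ndarray:
    got = _diag_cache.get(m)
    if got is None:
        got = np.arange(m)[None, :] - np.arange(m)[:, None] + (m - 1)
        _diag_cache[m] = got
    return got


def _best_suffix_prefix(a: str, b: str, min_ov: int, max_mismatch_rate: float) -> int:
    """Longest near-exact overlap of a suffix of ``a`` with a prefix of ``b``.

    All candidate overlaps are diagonals of one suffix-vs-prefix comparison
    matrix, evaluated in a single vectorised pass.
    """
    m = min(len(a), len(b))
    if m < min_ov:
        return 0
    ea = np.frombuffer(a[-m:].encode(), dtype=np.uint8)
    eb = np.frombuffer(b[:m].encode(), dtype=np.uint8)
    eq = ea[:, None] == eb[None, :]
    # overlap ov is the diagonal col-row == ov-m shifted to bin ov-1
    diag = _diag_index(m)
    matches = np.bincount(diag[eq], minlength=2 * m - 1)
    ovs = np.arange(min_ov, m + 1)
    good = ovs - matches[ovs - 1] <= np.floor(max_mismatch_rate * ovs)
    hits = np.nonzero(good)[0]
    return int(ovs[hits[-1]]) if hits.size else 0


def assemble_cluster_contigs(
    cluster: Cluster,
    reads: ReadSet,
    min_overlap_bp: int = 40,
    max_mismatch_rate: float = 0.08,
    max_reads: Optional[int] = 60,
) -> list[Contig]:
    """Greedy overlap-layout assembly of the cluster's reads.

    The pair with the longest exact-or-near-exact suffix/prefix overlap
    (either orientation) at least ``min_overlap_bp`` long is merged
    repeatedly; ties break lexicographically by sequence, so the result is
    deterministic.  For large clusters only ``max_reads`` evenly spaced
    reads are assembled — a representative contig, not a full assembly, is
    what downstream periodicity and classification need.
    """
    if not cluster.read_ids:
        raise ValueError("cluster has no reads")
    id_to_seq = dict(zip(reads.ids, reads.sequences))
    seqs = sorted(id_to_seq[r] for r in cluster.read_ids if r in id_to_seq)
    if not seqs:
        raise ValueError("cluster reads not found in the provided ReadSet")
    if max_reads is not None and len(seqs) > max_reads:
        step = len(seqs) / max_reads
        seqs = [seqs[int(i * step)] for i in range(max_reads)]

    pool: dict[int, tuple[str, int]] = {i: (s, 1) for i, s in enumerate(seqs)}
    next_idx = len(seqs)
    cache: dict[tuple[int, int, bool], int] = {}

    def _score(i: int, j: int) -> None:
        a = pool[i][0]
        b = pool[j][0]
        for b_rc in (False, True):
            bb = reverse_complement(b) if b_rc else b
            ov = _best_suffix_prefix(a, bb, min_overlap_bp, max_mismatch_rate)
            if ov:
                cache[(i, j, b_rc)] = ov

    ids = list(pool)
    for i in ids:
        for j in ids:
            if i != j:
                _score(i, j)

    while cache:
        # longest overlap wins; ties break lexicographically by sequences
        (i, j, b_rc), ov = max(
            cache.items(),
            key=lambda kv: (kv[1], pool[kv[0][0]][0], pool[kv[0][1]][0]),
        )
        a, na = pool[i]
        b, nb = pool[j]
        bb = reverse_complement(b) if b_rc else b
        merged = a + bb[ov:]
        del pool[i], pool[j]
        cache = {k: v for k, v in cache.items()
                 if i not in k[:2] and j not in k[:2]}
        pool[next_idx] = (merged, na + nb)
        for other in list(pool):
            if other != next_idx:
                _score(next_idx, other)
                _score(other, next_idx)
        next_idx += 1
    contigs = list(pool.values())

    read_len = max((len(s) for s in seqs), default=0)
    out = [
        Contig(sequence=s, cluster_id=cluster.cluster_id,
               depth=n * read_len / max(1, len(s)))
        for s, n in contigs
    ]
    out.sort(key=lambda c: (-c.depth, -len(c.sequence), c.sequence))
    return out


# ---------------------------------------------------------------------------
# tandem periodicity


def _autocorrelation_period(
    seq: str, max_lag: int, min_match: float = 0.60
) -> Optional[int]:
    """Smallest lag (2..max_lag) whose self-match fraction is both high and
    within 5% of the best, i.e. the base period rather than a multiple."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    scores = {}
    for lag in range(2, max_lag + 1):
        if arr.size - lag < 10:
            break
        scores[lag] = float(np.mean(arr[lag:] == arr[:-lag]))
    if not scores:
        return None
    best = max(scores.values())
    if best < min_match:
        return None
    for lag in sorted(scores):
        if scores[lag] >= best - 0.05:
            return lag
    return None


def _window_consensus_identity(seq: str, period: int) -> float:
    """Mean leave-one-out identity of length-``period`` windows vs the
    majority consensus of the *other* windows.

    Plain window-vs-consensus identity is biased upward for small window
    counts (two windows always agree with their own consensus), which would
    make a long multiple of the true unit look better than the unit itself;
    the leave-one-out form is count-unbiased.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n_win = arr.size // period
    if n_win < 2:
        return 0.0
    w = arr[: n_win * period].reshape(n_win, period)
    # base index matrix (non-ACGT bases never match)
    bidx = _BASE_CODE[w]
    counts = np.stack([(bidx == b).sum(axis=0) for b in range(4)])  # (4, p)
    matches = 0
    for b in range(4):
        adj = counts.copy()
        adj[b] -= 1
        winner = np.argmax(adj, axis=0)  # ties resolve in A<C<G<T order
        matches += int(np.count_nonzero((bidx == b) & (winner == b)[None, :]))
    return matches / (n_win * period)


def refine_period(seq: str, period: int, tolerance: float = 0.01) -> int:
    """Refine a modal dotplot spacing to the true repeat unit.

    Candidate periods are the divisors of ``period`` (the modal spacing of a
    simple repeat is often a multiple of the unit) plus its low-order
    multiples 2p and 3p (the unit of a higher-order repeat can be a multiple
    of the strongest spacing).  Candidates are scored by mean
    window-vs-consensus identity; the smallest within ``tolerance`` of the
    best wins, so a HOR is not reported as its subrepeat and a simple repeat
    is not reported as a multiple of itself.
    """
    candidates = {d for d in range(2, period + 1) if period % d == 0}
    candidates.update(m * period for m in (1, 2, 3))
    candidates = sorted(p for p in candidates if 2 * p <= len(seq))
    if not candidates:
        return period
    scores = {p: _window_consensus_identity(seq, p) for p in candidates}
    best = max(scores.values())
    for p in candidates:
        if scores[p] >= best - tolerance:
            return p
    return period


def tandem_periodicity(
    contig: Contig | str,
    word: int = 10,
    min_diagonals: int = 3,
) -> tuple[bool, Optional[int]]:
    """Self-dotplot periodicity detection.

    Exact matches of length ``word`` define dotplot diagonals; the contig is
    called tandem when at least ``min_diagonals`` equally spaced off-main
    diagonals (spacings s, 2s, 3s, ...) are supported.  The modal spacing,
    refined against its low-order multiples, is the period.  For periods
    shorter than the word size a nucleotide autocorrelation fallback is
    used.
    """
    seq = contig.sequence if isinstance(contig, Contig) else contig
    if len(seq) < 2 * word:
        raise ValueError("contig shorter than two words")

    occurrences: dict[str, list[int]] = {}
    for i in range(len(seq) - word + 1):
        occurrences.setdefault(seq[i : i + word], []).append(i)

    spacing_support: dict[int, int] = {}
    for poss in occurrences.values():
        if len(poss) < 2:
            continue
        poss = poss[:30]  # cap quadratic blowup on simple repeats
        for x in range(len(poss)):
            for y in range(x + 1, len(poss)):
                s = poss[y] - poss[x]
                if s > 0:
                    spacing_support[s] = spacing_support.get(s, 0) + 1

    if spacing_support:
        s_star = max(spacing_support, key=lambda s: (spacing_support[s], -s))
        floor = max(2, spacing_support[s_star] // 10)
        # equally spaced diagonals at s*, 2s*, 3s*, ...; ones beyond the
        # contig end cannot exist, so only reachable multiples are demanded
        reachable = sum(
            1 for m in range(1, min_diagonals + 1) if m * s_star <= len(seq) - word
        )
        supported = sum(
            1
            for m in range(1, min_diagonals + 1)
            if spacing_support.get(m * s_star, 0) >= floor
        )
        if supported >= min(min_diagonals, reachable) and supported >= 2:
            return True, refine_period(seq, s_star)

    period = _autocorrelation_period(seq, max_lag=word - 1)
    if period is not None:
        return True, period
    return False, None


# ---------------------------------------------------------------------------
# classification


def _library_hit(
    query: str, entry: LibraryEntry
) -> tuple[float, float]:
    """(identity, cover-of-query) of the best infix alignment of the shorter
    sequence within the longer one, either strand.

    When the library entry is shorter than the contig, coverage counts the
    non-overlapping best-score hit locations so a tandem contig of a
    library unit is recognised as fully covered.
    """
    import edlib

    if len(query) <= len(entry.sequence):
        short, long_ = query, entry.sequence
    else:
        short, long_ = entry.sequence, query
    best = 0.0
    n_hits = 1
    for t in (long_, reverse_complement(long_)):
        res = edlib.align(short, t, mode="HW", task="locations")
        ed = res["editDistance"]
        if ed < 0:
            continue
        ident = 1.0 - ed / len(short)
        if ident > best:
            best = ident
            locs = sorted(res["locations"] or [])
            n_hits = 0
            prev_end = -1
            for s, e in locs:
                if s is None:
                    s = 0
                if s > prev_end:
                    n_hits += 1
                    prev_end = e
            n_hits = max(1, n_hits)
    if len(query) <= len(entry.sequence):
        cover = 1.0
    else:
        cover = min(1.0, n_hits * len(entry.sequence) / len(query))
    return best, cover


def classify_cluster(
    cluster: Cluster,
    library: Sequence[LibraryEntry] = (),
    word: int = 10,
    min_diagonals: int = 3,
    library_min_identity: float = 0.75,
    library_min_cover: float = 0.50,
) -> RepeatClassCall:
    """Assign one of the six repeat categories to a cluster.

    Priority: (1) rDNA (or mitochondrial) by library hit on the
    majority-depth contig; (2) satDNA by tandem periodicity; (3) TE category
    by the best qualifying library hit; (4) unclassified.  An empty library
    restricts calls to rules (2) and (4).
    """
    if not cluster.contigs:
        raise ValueError("cluster has no contigs; run assemble_cluster_contigs first")
    rep = max(cluster.contigs, key=lambda c: (c.depth, len(c.sequence)))

    hits = []
    for entry in library:
        ident, cover = _library_hit(rep.sequence, entry)
        if ident >= library_min_identity and cover >= library_min_cover:
            hits.append((ident * cover, entry, ident))
    hits.sort(key=lambda h: -h[0])

    for _, entry, ident in hits:
        if entry.category.lower() in ("rdna", "mito", "mitochondrial"):
            if entry.category.lower() != "rdna":
                cluster.is_mito = True
                return RepeatClassCall(
                    "unclassified", entry.subfamily,
                    f"mitochondrial hit {entry.name} id={ident:.2f}",
                )
            return RepeatClassCall(
                "rDNA", entry.subfamily, f"library hit {entry.name} id={ident:.2f}"
            )

    # periodicity is checked on the few deepest/longest contigs: the
    # majority-depth contig of a fragmented satellite cluster can be too
    # short to show the repeat unit
    candidates = sorted(
        cluster.contigs, key=lambda c: (-c.depth, -len(c.sequence), c.sequence)
    )[:3]
    for contig in candidates:
        if len(contig.sequence) < 2 * word:
            continue
        is_tandem, period = tandem_periodicity(contig, word, min_diagonals)
        if is_tandem:
            return RepeatClassCall("satDNA", "", f"tandem period {period} bp")

    for _, entry, ident in hits:
        if entry.category in ("LTR", "non-LTR", "DNA_TE"):
            return RepeatClassCall(
                entry.category, entry.subfamily,
                f"library hit {entry.name} id={ident:.2f}",
            )

    return RepeatClassCall("unclassified", "", "no periodicity, no library hit")


# ---------------------------------------------------------------------------
# consensus monomer


def canonical_rotation(seq: str) -> str:
    """Lexicographically minimal rotation over both strands."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    n = len(seq)
    best = None
    for s in (seq, reverse_complement(seq)):
        doubled = s + s
        for i in range(n):
            cand = doubled[i : i + n]
            if best is None or cand < best:
                best = cand
    return best


def at_content(seq: str) -> float:
    """A+T percentage of a sequence."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    return 100.0 * (seq.count("A") + seq.count("T")) / len(seq)


def _rotations_matrix(arr: np.ndarray) -> np.ndarray:
    n = arr.size
    doubled = np.concatenate([arr, arr])
    return np.lib.stride_tricks.sliding_window_view(doubled, n)[:n]


_TIE_ORDER = np.frombuffer(b"ACGT", dtype=np.uint8)


def infer_monomer(contigs: Sequence[Contig | str], period: int) -> ConsensusMonomer:
    """Phase-aligned majority-vote consensus of a satellite monomer.

    Length-``period`` windows of every contig are phased (rotation and
    strand) against the windows of the first sufficiently long contig, then
    a per-column majority vote is taken; ties break by fixed base order
    A < C < G < T (no IUPAC ambiguity is emitted).  The result is stored in
    canonical rotation.  Contigs shorter than two periods contribute
    nothing; if none spans two periods an :class:`InsufficientSpanError` is
    raised.
    """
    if period < 1:
        raise ValueError("period must be >= 1")
    seqs = [c.sequence if isinstance(c, Contig) else c for c in contigs]
    usable = [s for s in seqs if len(s) >= 2 * period]
    if not usable:
        raise InsufficientSpanError(
            f"no contig spans two periods ({2 * period} bp)"
        )

    windows: list[np.ndarray] = []
    ref: Optional[np.ndarray] = None
    for s in usable:
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        n_win = arr.size // period
        w_fwd = arr[: n_win * period].reshape(n_win, period)
        if ref is None:
            ref = w_fwd[0]
            windows.extend(w_fwd)
            continue
        rc = np.frombuffer(reverse_complement(s).encode(), dtype=np.uint8)
        w_rc = rc[: n_win * period].reshape(n_win, period)
        best_score, best_windows = -1.0, None
        for w in (w_fwd, w_rc):
            rots = _rotations_matrix(w[0])
            scores = np.mean(rots == ref[None, :], axis=1)
            r = int(np.argmax(scores))
            if scores[r] > best_score:
                best_score = float(scores[r])
                best_windows = np.roll(w, -r, axis=1)
        windows.extend(best_windows)

    mat = np.stack(windows)
    cons = np.empty(period, dtype=np.uint8)
    for c in range(period):
        col = mat[:, c]
        counts = np.array([(col == b).sum() for b in _TIE_ORDER])
        cons[c] = _TIE_ORDER[int(np.argmax(counts))]  # argmax ties -> A<C<G<T
    consensus = cons.tobytes().decode()
    canon = canonical_rotation(consensus)
    return ConsensusMonomer(
        sequence=canon,
        unit_length=period,
        at_content=at_content(canon),
        support=mat.shape[0],
    )
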