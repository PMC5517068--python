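"""Graph-based clustering of unassembled reads into repeat families.

The core quantification of the pipeline: reads are compared all-vs-all, an
edge joins two reads whose best gapless overlap (over all shifts and both
strands) reaches an identity and an overlap-length threshold, and connected
communities of the resulting graph are repeat clusters.  A cluster's genome
proportion is simply its read percentage of all analyzed reads.

Pair comparison is accelerated by a shared-k-mer diagonal prefilter that is
provably lossless for the gapless criterion: a qualifying diagonal of length
``ov`` with at most ``m = floor((1-min_identity)*ov)`` mismatches must, by
pigeonhole, contain an exact match run of length at least
``ceil((ov-m)/(m+1))`` and at least ``(ov-m) - (m+1)(k-1)`` shared k-mers on
that diagonal.  Candidate diagonals failing that count bound provably cannot
qualify and are skipped without alignment.

Two equivalent paths are provided: :func:`build_similarity_graph` +
:func:`cluster_graph` materialise the full edge list (used for moderate read
counts and for oracle tests), while :func:`cluster_reads` computes identical
connected components with a union-find shortcut that skips verification of
already-connected pairs, which is what makes genome-scale runs tractable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .syndata import ReadSet, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_OVERLAP = 0.55


@dataclass
class SampleSpec:
    """One sequenced individual: its reads and haploid genome size."""

    sample_id: str
    lineage_label: str
    genome_size: int  # bp per haploid genome
    reads: Optional[ReadSet] = None

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")


@dataclass
class ReadGraph:
    """Undirected read-similarity graph.

    Edges are stored as parallel arrays; ``identity`` is the match fraction
    of the best qualifying diagonal and ``overlap`` the aligned fraction of
    the shorter read.
    """

    read_ids: list[str]
    edge_a: np.ndarray
    edge_b: np.ndarray
    identity: np.ndarray
    overlap: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.read_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_a)

    def edge_set(self) -> set[tuple[int, int]]:
        return {
            (min(a, b), max(a, b))
            for a, b in zip(self.edge_a.tolist(), self.edge_b.tolist())
        }

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for a, b, ident, ov in zip(
            self.edge_a.tolist(), self.edge_b.tolist(),
            self.identity.tolist(), self.overlap.tolist(),
        ):
            g.add_edge(a, b, identity=ident, overlap=ov)
        return g


@dataclass
class Cluster:
    """A connected community of reads; one repeat family candidate."""

    cluster_id: int
    read_ids: list[str]
    genome_proportion: float  # % of analyzed reads
    n_analyzed: int
    contigs: list = field(default_factory=list)
    classification: str = "unclassified"
    subfamily: str = ""
    is_mito: bool = False

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


# ---------------------------------------------------------------------------
# read sampling and mitochondrial filtering


def sample_reads(reads: ReadSet, target_count: int, seed: int) -> ReadSet:
    """Uniform subsample without replacement, deterministic under ``seed``."""
    n = len(reads)
    if target_count >= n:
        if target_count > n:
            logger.info("target_count %d >= read count %d; returning all reads",
                        target_count, n)
        return reads
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=target_count, replace=False))
    return reads.subset(idx.tolist())


def filter_mitochondrial(
    reads: ReadSet,
    mito_reference: Optional[str],
    min_identity: float = 0.90,
    min_cover: float = 0.80,
) -> tuple[ReadSet, int]:
    """Drop reads aligning to the mitochondrial reference.

    A read is removed when its best semi-global (infix) alignment against
    either strand of the reference reaches ``min_identity`` over the read.
    The infix alignment covers the whole read, so ``min_cover`` is satisfied
    by construction for reads shorter than the reference; the parameter is
    kept for interface stability.
    """
    if mito_reference is None or not mito_reference:
        return reads, 0
    import edlib

    targets = (mito_reference, reverse_complement(mito_reference))
    keep: list[int] = []
    removed = 0
    for i, seq in enumerate(reads.sequences):
        max_ed = int(len(seq) * (1.0 - min_identity))
        hit = False
        for t in targets:
            res = edlib.align(seq, t, mode="HW", task="distance", k=max_ed)
            if res["editDistance"] != -1:
                hit = True
                break
        if hit:
            removed += 1
        else:
            keep.append(i)
    return reads.subset(keep), removed


# ---------------------------------------------------------------------------
# k-mer machinery


_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def _encode_read(seq: str) -> np.ndarray:
    return _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _revcomp_enc(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    valid = out < 4
    out[valid] = 3 - out[valid]
    return out


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, positions) of all valid (N-free) k-mers of an encoded read."""
    L = arr.size
    if L < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    n = L - k + 1
    code = np.zeros(n, dtype=np.int64)
    for t in range(k):
        code = code * 4 + np.minimum(arr[t : t + n], 3)
    bad = (arr >= 4).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    pos = np.nonzero(valid)[0]
    return code[valid], pos


def lossless_kmer_size(min_identity: float, min_overlap_bp: int, max_len: int) -> int:
    """Largest k such that every qualifying diagonal shares a k-mer."""
    best = max_len
    for ov in range(min_overlap_bp, max_len + 1):
        m = math.floor((1.0 - min_identity) * ov + 1e-9)
        best = min(best, math.ceil((ov - m) / (m + 1)))
    return max(2, best)


def _count_threshold(ov: np.ndarray, k: int, min_identity: float) -> np.ndarray:
    """Minimum shared-k-mer count on any qualifying diagonal of length ov."""
    m = np.floor((1.0 - min_identity) * ov + 1e-9).astype(np.int64)
    return np.maximum(1, (ov - m) - (m + 1) * (k - 1))


class _PairEngine:
    """Shared candidate-generation machinery for both clustering paths."""

    def __init__(
        self,
        sequences: Sequence[str],
        min_identity: float,
        min_overlap: float,
        kmer_prefilter: int = 0,
    ):
        self.min_identity = float(min_identity)
        self.min_overlap = float(min_overlap)
        self.n = len(sequences)
        self.enc = [_encode_read(s) for s in sequences]
        self.enc_rc = [_revcomp_enc(a) for a in self.enc]
        self.lens = np.array([a.size for a in self.enc], dtype=np.int64)
        min_len = int(self.lens.min()) if self.n else 0
        max_len = int(self.lens.max()) if self.n else 0
        self.max_len = max_len
        minov = max(1, math.ceil(self.min_overlap * min_len))
        k_safe = lossless_kmer_size(self.min_identity, minov, max_len)
        if kmer_prefilter and kmer_prefilter <= k_safe:
            self.k = kmer_prefilter
        else:
            if kmer_prefilter > k_safe:
                logger.info(
                    "kmer_prefilter=%d is not lossless at these thresholds; using %d",
                    kmer_prefilter, k_safe,
                )
            self.k = k_safe

        # global forward-strand k-mer index, sorted by code
        codes, rids, poss = [], [], []
        for i, arr in enumerate(self.enc):
            c, p = _kmer_codes(arr, self.k)
            codes.append(c)
            rids.append(np.full(c.size, i, dtype=np.int64))
            poss.append(p)
        if codes:
            km = np.concatenate(codes)
            order = np.argsort(km, kind="stable")
            self.km = km[order]
            self.rid = np.concatenate(rids)[order]
            self.pos = np.concatenate(poss)[order]
        else:
            self.km = np.empty(0, dtype=np.int64)
            self.rid = np.empty(0, dtype=np.int64)
            self.pos = np.empty(0, dtype=np.int64)

    def candidates(self, i: int):
        """All (j < i, strand, diag, count) candidate diagonals for read i.

        ``strand`` 0 compares read i forward vs j, 1 compares the reverse
        complement of i vs j.  ``diag`` d means position x of j aligns with
        position x + d of (the chosen strand of) i.  Only diagonals whose
        overlap can reach the thresholds and whose shared-k-mer count meets
        the pigeonhole bound are returned.
        """
        Li = int(self.lens[i])
        shift = self.max_len  # diag offset to keep keys non-negative
        all_keys = []
        for strand, arr in ((0, self.enc[i]), (1, self.enc_rc[i])):
            q, qp = _kmer_codes(arr, self.k)
            if q.size == 0:
                continue
            lo = np.searchsorted(self.km, q, side="left")
            hi = np.searchsorted(self.km, q, side="right")
            counts = hi - lo
            total = int(counts.sum())
            if total == 0:
                continue
            csum = np.concatenate(([0], np.cumsum(counts[:-1])))
            idx = np.arange(total) + np.repeat(lo - csum, counts)
            j = self.rid[idx]
            jpos = self.pos[idx]
            qpos = np.repeat(qp, counts)
            mask = j < i
            if not mask.any():
                continue
            j = j[mask]
            d = qpos[mask] - jpos[mask]
            key = (j * 2 + strand) * (2 * self.max_len + 1) + (d + shift)
            all_keys.append(key)
        if not all_keys:
            return (np.empty(0, np.int64),) * 4
        keys = np.concatenate(all_keys)
        ukeys, kcounts = np.unique(keys, return_counts=True)
        d = ukeys % (2 * self.max_len + 1) - shift
        rest = ukeys // (2 * self.max_len + 1)
        strand = rest % 2
        j = rest // 2
        Lj = self.lens[j]
        ov = np.minimum(Lj, Li - d) - np.maximum(0, -d)
        minov = np.ceil(self.min_overlap * np.minimum(Li, Lj) - 1e-9).astype(np.int64)
        ok = (ov >= minov) & (kcounts >= _count_threshold(ov, self.k, self.min_identity))
        return j[ok], strand[ok], d[ok], kcounts[ok]

    def verify(self, i: int, j: int, strand: int, d: int):
        """Gapless alignment on one diagonal; returns (identity, overlap_frac)
        if it qualifies, else None."""
        ai = self.enc[i] if strand == 0 else self.enc_rc[i]
        aj = self.enc[j]
        x0 = max(0, -d)
        x1 = min(aj.size, ai.size - d)
        ov = x1 - x0
        if ov <= 0:
            return None
        a = ai[x0 + d : x1 + d]
        b = aj[x0:x1]
        matches = int(np.count_nonzero((a == b) & (a < 4)))
        ident = matches / ov
        short = min(ai.size, aj.size)
        if ident >= self.min_identity and ov >= math.ceil(self.min_overlap * short - 1e-9):
            return ident, ov / short
        return None


# ---------------------------------------------------------------------------
# graph construction and clustering


def build_similarity_graph(
    reads: ReadSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    kmer_prefilter: int = 0,
) -> ReadGraph:
    """Full all-vs-all similarity graph.

    An edge (a, b) is present iff some gapless overlap of a vs b (either
    strand, any shift) has identity >= ``min_identity`` over at least
    ``min_overlap`` of the shorter read.  The stored identity/overlap are
    those of the best qualifying diagonal (highest identity, ties to the
    longer overlap).  ``kmer_prefilter`` sets the prefilter k-mer size; 0
    chooses the largest provably lossless value for the thresholds.
    """
    if len(reads) == 0:
        raise ValueError("reads must be non-empty")
    eng = _PairEngine(reads.sequences, min_identity, min_overlap, kmer_prefilter)
    ea, eb, eid, eov = [], [], [], []
    for i in range(eng.n):
        j, strand, d, _ = eng.candidates(i)
        if j.size == 0:
            continue
        best: dict[int, tuple[float, float]] = {}
        for jj, ss, dd in zip(j.tolist(), strand.tolist(), d.tolist()):
            res = eng.verify(i, jj, ss, dd)
            if res is None:
                continue
            cur = best.get(jj)
            if cur is None or res > cur:
                best[jj] = res
        for jj, (ident, ovf) in best.items():
            ea.append(jj)
            eb.append(i)
            eid.append(ident)
            eov.append(ovf)
    return ReadGraph(
        read_ids=list(reads.ids),
        edge_a=np.array(ea, dtype=np.int64),
        edge_b=np.array(eb, dtype=np.int64),
        identity=np.array(eid, dtype=float),
        overlap=np.array(eov, dtype=float),
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def _components_to_clusters(
    labels: Sequence[int],
    read_ids: Sequence[str],
    min_cluster_size: Optional[int],
) -> list[Cluster]:
    n = len(read_ids)
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(lab, []).append(idx)
    members = [g for g in groups.values() if len(g) > 1]  # singletons: non-repetitive
    if min_cluster_size is None:
        min_cluster_size = max(5, math.ceil(1e-4 * n))
    kept = [g for g in members if len(g) >= min_cluster_size]
    folded = sum(len(g) for g in members) - sum(len(g) for g in kept)
    if folded:
        logger.info(
            "folded %d reads in sub-floor clusters (<%d reads) into the "
            "below-detection tail", folded, min_cluster_size,
        )
    kept.sort(key=lambda g: (-len(g), g[0]))
    return [
        Cluster(
            cluster_id=rank + 1,
            read_ids=[read_ids[x] for x in g],
            genome_proportion=100.0 * len(g) / n,
            n_analyzed=n,
        )
        for rank, g in enumerate(kept)
    ]


def cluster_graph(
    graph: ReadGraph,
    min_cluster_size: Optional[int] = None,
    split_low_density: bool = False,
    density_threshold: float = 0.10,
) -> list[Cluster]:
    """Extract clusters from a similarity graph.

    Connected components are the communities; components whose internal edge
    density falls below ``density_threshold`` can optionally be split by
    greedy modularity agglomeration (off by default).  Singleton components
    are non-repetitive and excluded; components below ``min_cluster_size``
    (default max(5 reads, 0.01% of analyzed reads) — see the methods note on
    the chance-overlap detection floor) are folded into the below-detection
    tail.  Clusters are numbered from 1 by decreasing size.
    """
    n = graph.n_nodes
    uf = _UnionFind(n)
    for a, b in zip(graph.edge_a.tolist(), graph.edge_b.tolist()):
        uf.union(a, b)
    labels = [uf.find(i) for i in range(n)]

    if split_low_density and graph.n_edges:
        import networkx as nx

        g = graph.to_networkx()
        comp_nodes: dict[int, list[int]] = {}
        for i, lab in enumerate(labels):
            comp_nodes.setdefault(lab, []).append(i)
        next_label = n
        for lab, nodes in comp_nodes.items():
            m = len(nodes)
            if m < 4:
                continue
            sub = g.subgraph(nodes)
            density = 2 * sub.number_of_edges() / (m * (m - 1))
            if density >= density_threshold:
                continue
            comms = nx.algorithms.community.greedy_modularity_communities(sub)
            if len(comms) > 1:
                for comm in comms:
                    for node in comm:
                        labels[node] = next_label
                    next_label += 1
    return _components_to_clusters(labels, graph.read_ids, min_cluster_size)


def cluster_reads(
    reads: ReadSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    kmer_prefilter: int = 0,
    min_cluster_size: Optional[int] = None,
) -> list[Cluster]:
    """Cluster reads without materialising the full edge list.

    Produces the same connected components as
    ``cluster_graph(build_similarity_graph(reads, ...))``: the candidate
    stream is identical and a pair is only skipped when its reads are
    already in one component, which cannot change the final partition.
    """
    if len(reads) == 0:
        raise ValueError("reads must be non-empty")
    eng = _PairEngine(reads.sequences, min_identity, min_overlap, kmer_prefilter)
    uf = _UnionFind(eng.n)
    for i in range(eng.n):
        j, strand, d, counts = eng.candidates(i)
        if j.size == 0:
            continue
        order = np.lexsort((-counts, j))
        j = j[order]
        strand = strand[order]
        d = d[order]
        ri = uf.find(i)
        prev_j = -1
        done = False
        for jj, ss, dd in zip(j.tolist(), strand.tolist(), d.tolist()):
            if jj == prev_j and done:
                continue
            if jj != prev_j:
                prev_j = jj
                done = False
            if uf.find(jj) == ri:
                done = True
                continue
            if eng.verify(i, jj, ss, dd) is not None:
                uf.union(i, jj)
                ri = uf.find(i)
                done = True
    labels = [uf.find(i) for i in range(eng.n)]
    return _components_to_clusters(labels, reads.ids, min_cluster_size)


def repeatome_fraction(clusters: Sequence[Cluster]) -> float:
    """Summed genome proportion (%) of all non-mitochondrial clusters."""
    total = sum(c.genome_proportion for c in clusters if not c.is_mito)
    return min(100.0, total)
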