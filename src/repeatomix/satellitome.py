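"""Satellite DNA family analysis: nomenclature, structure and probes.

Satellite clusters become named families (``AbbrSatNN-L``: species
abbreviation, zero-padded rank by decreasing abundance in a designated
reference sample, and unit length), and their consensus monomers are
dissected the way a satellitome study does: higher-order repeat (HOR)
decomposition, shared regions between families, variant repeat units,
internal microsatellites, p-distance divergence, and FISH probe design
(oligos for short monomers, a primer pair for monomers over 85 bp).

All rotation-aware comparisons use the doubled-sequence trick: a monomer is
circular, so any rotation of it appears as a substring of the unit
concatenated with itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotate import ConsensusMonomer, canonical_rotation
from .syndata import ReadSet, reverse_complement

logger = logging.getLogger(__name__)


class UndefinedDistanceError(ValueError):
    """p-distance has no retained sites after pairwise deletion."""


@dataclass
class HORStructure:
    """Decomposition of a monomer into diverged subrepeats."""

    n_subrepeats: int
    subrepeat_bounds: list[tuple[int, int]]  # 0-based half-open on the consensus
    ancestral_unit_estimate: int

    def __post_init__(self) -> None:
        if self.n_subrepeats < 2:
            raise ValueError("a HOR needs at least 2 subrepeats")
        prev = 0
        for s, e in self.subrepeat_bounds:
            if s != prev or e <= s:
                raise ValueError("subrepeat bounds must tile the consensus")
            prev = e


@dataclass
class SharedRegion:
    family_a: str
    family_b: str
    length: int
    identity: float  # %
    coords_a: tuple[int, int]
    coords_b: tuple[int, int]


@dataclass
class SatFamily:
    """One satellite family, possibly quantified in several samples."""

    consensus: ConsensusMonomer
    abundance: dict[str, float] = field(default_factory=dict)  # sample -> % genome
    mbp: dict[str, float] = field(default_factory=dict)  # sample -> Mbp haploid
    name: str = ""
    rank: int = 0
    location_annotation: str = ""
    hor: Optional[HORStructure] = None
    combined_only: set[str] = field(default_factory=set)  # detected via combined run
    probe_oligo_override: bool = False
    notes: str = ""

    @property
    def unit_length(self) -> int:
        return self.consensus.unit_length


@dataclass
class ProbeDesign:
    family: str
    mode: str  # "oligo" or "primer_pair"
    sequences: list[str]
    positions: list[tuple[int, int]]  # 0-based half-open on the consensus
    tm: list[float]
    conservation: list[float]
    note: str = ""


# ---------------------------------------------------------------------------
# nomenclature and cross-sample merging


def _rotation_identity(a: str, b: str) -> float:
    """Best rotation-aware identity of the shorter unit within the longer."""
    import edlib

    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    doubled = long_ + long_
    best = 0.0
    for t in (doubled, reverse_complement(doubled)):
        res = edlib.align(short, t, mode="HW", task="distance")
        if res["editDistance"] >= 0:
            best = max(best, 1.0 - res["editDistance"] / len(short))
    return best


def same_family(
    a: ConsensusMonomer,
    b: ConsensusMonomer,
    min_identity: float = 0.80,
    max_length_ratio: float = 1.25,
) -> bool:
    """Two samples' consensi describe the same family iff they align at
    >=80% identity over the (rotation-aware) shorter unit and their unit
    lengths are compatible."""
    la, lb = a.unit_length, b.unit_length
    if max(la, lb) > max_length_ratio * min(la, lb):
        return False
    return _rotation_identity(a.sequence, b.sequence) >= min_identity


def merge_families(
    families: Sequence[SatFamily], min_identity: float = 0.80
) -> list[SatFamily]:
    """Merge per-sample families that describe the same satellite.

    The merged family keeps the consensus from the sample where it is most
    abundant; abundance/Mbp maps and combined-run flags are unioned.
    """
    merged: list[SatFamily] = []
    for fam in families:
        target = None
        for m in merged:
            if same_family(fam.consensus, m.consensus, min_identity):
                target = m
                break
        if target is None:
            merged.append(
                SatFamily(
                    consensus=fam.consensus,
                    abundance=dict(fam.abundance),
                    mbp=dict(fam.mbp),
                    location_annotation=fam.location_annotation,
                    hor=fam.hor,
                    combined_only=set(fam.combined_only),
                    probe_oligo_override=fam.probe_oligo_override,
                    notes=fam.notes,
                )
            )
            continue
        if max(fam.abundance.values(), default=0.0) > max(
            target.abundance.values(), default=0.0
        ):
            target.consensus = fam.consensus
        target.abundance.update(
            {k: v for k, v in fam.abundance.items()
             if v > target.abundance.get(k, 0.0)}
        )
        target.mbp.update(
            {k: v for k, v in fam.mbp.items() if v > target.mbp.get(k, 0.0)}
        )
        target.combined_only |= fam.combined_only
    return merged


def name_families(
    families: Sequence[SatFamily], abbrev: str, reference_sample: str
) -> list[SatFamily]:
    """Assign ``AbbrSatNN-L`` names by decreasing abundance in the reference
    sample (families absent there count as 0); ties break lexicographically
    by canonical consensus.  Families must already be merged: duplicate
    canonical consensi are an error."""
    seqs = [f.consensus.sequence for f in families]
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate canonical consensi; merge families first")
    ordered = sorted(
        families,
        key=lambda f: (-f.abundance.get(reference_sample, 0.0), f.consensus.sequence),
    )
    for rank, fam in enumerate(ordered, start=1):
        fam.rank = rank
        fam.name = f"{abbrev}Sat{rank:02d}-{fam.unit_length}"
    return list(ordered)


# ---------------------------------------------------------------------------
# higher-order repeat decomposition


def _block_identity(a: str, b: str) -> float:
    import edlib

    if not a or not b:
        return 0.0
    ed = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - ed / max(len(a), len(b))


def _mean_pairwise_identity(blocks: Sequence[str]) -> float:
    ids = [
        _block_identity(blocks[i], blocks[j])
        for i in range(len(blocks))
        for j in range(i + 1, len(blocks))
    ]
    return float(np.mean(ids)) if ids else 0.0


def _refine_bounds(
    seq: str, bounds: list[int], min_subrepeat: int, radius: int = 4
) -> list[int]:
    """Coordinate-ascent refinement of interior block boundaries."""
    bounds = list(bounds)
    improved = True
    while improved:
        improved = False
        for bi in range(1, len(bounds) - 1):
            best_pos = bounds[bi]
            blocks = [seq[bounds[x] : bounds[x + 1]] for x in range(len(bounds) - 1)]
            best_score = _mean_pairwise_identity(blocks)
            for pos in range(bounds[bi] - radius, bounds[bi] + radius + 1):
                if pos == bounds[bi]:
                    continue
                if pos - bounds[bi - 1] < min_subrepeat:
                    continue
                if bounds[bi + 1] - pos < min_subrepeat:
                    continue
                trial = bounds[:bi] + [pos] + bounds[bi + 1 :]
                blocks = [seq[trial[x] : trial[x + 1]] for x in range(len(trial) - 1)]
                score = _mean_pairwise_identity(blocks)
                if score > best_score:
                    best_score, best_pos = score, pos
            if best_pos != bounds[bi]:
                bounds[bi] = best_pos
                improved = True
    return bounds


def detect_hor(
    consensus: ConsensusMonomer | str,
    min_subrepeat: int = 10,
    min_identity: float = 70.0,
) -> Optional[HORStructure]:
    """Decompose a monomer into k >= 2 contiguous subrepeats.

    For each candidate k (largest first), the monomer is split into
    near-equal blocks whose boundaries are refined by coordinate ascent on
    the all-pairs mean identity (edit-distance identity, so length drift
    between subrepeats is tolerated).  The largest k whose refined
    decomposition reaches ``min_identity`` (%) wins; ``None`` when no
    decomposition qualifies.
    """
    seq = consensus.sequence if isinstance(consensus, ConsensusMonomer) else consensus
    L = len(seq)
    if L < 2 * min_subrepeat:
        raise ValueError("unit shorter than two minimal subrepeats")
    for k in range(L // min_subrepeat, 1, -1):
        base = L / k
        bounds = [round(i * base) for i in range(k + 1)]
        bounds[0], bounds[-1] = 0, L
        bounds = _refine_bounds(seq, bounds, min_subrepeat)
        blocks = [seq[bounds[i] : bounds[i + 1]] for i in range(k)]
        score = 100.0 * _mean_pairwise_identity(blocks)
        if score >= min_identity:
            return HORStructure(
                n_subrepeats=k,
                subrepeat_bounds=[(bounds[i], bounds[i + 1]) for i in range(k)],
                ancestral_unit_estimate=round(L / k),
            )
    return None


# ---------------------------------------------------------------------------
# inter-family shared regions


def find_shared_region(
    a: ConsensusMonomer,
    b: ConsensusMonomer,
    min_length: int = 20,
    min_identity: float = 80.0,
    name_a: str = "a",
    name_b: str = "b",
) -> Optional[SharedRegion]:
    """Best local alignment between two monomers, rotation- and strand-aware.

    Both consensi are doubled (circular units) and the best local alignment
    of doubled-a against either strand of doubled-b is taken; it is reported
    when the aligned span reaches ``min_length`` columns at ``min_identity``
    percent matches.  Reported length and coordinates are capped at one unit.
    """
    from Bio import Align

    sa = a.sequence + a.sequence
    # mismatch -2 caps the identity of any positive-scoring region at >2/3
    # and makes chaining through noise unprofitable, so the reported region
    # stays a compact high-identity block rather than a diluted chain
    aligner = Align.PairwiseAligner(
        mode="local", match_score=1, mismatch_score=-2,
        open_gap_score=-4, extend_gap_score=-2,
    )
    best = None
    for strand, sb in enumerate((b.sequence + b.sequence,
                                 reverse_complement(b.sequence + b.sequence))):
        alns = aligner.align(sa, sb)
        if len(alns) == 0:
            continue
        aln = alns[0]
        if best is None or aln.score > best[0].score:
            best = (aln, strand)
    if best is None:
        return None
    aln, strand = best
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return None
    identity = 100.0 * counts.identities / columns
    length = min(columns, a.unit_length, b.unit_length)
    if columns < min_length or identity < min_identity:
        return None
    (a0, a1) = (int(aln.coordinates[0][0]), int(aln.coordinates[0][-1]))
    (b0, b1) = (int(aln.coordinates[1][0]), int(aln.coordinates[1][-1]))
    if strand == 1:  # map back to forward coordinates of the doubled b
        b0, b1 = 2 * b.unit_length - b1, 2 * b.unit_length - b0
    ca = (a0 % a.unit_length, a0 % a.unit_length + min(a1 - a0, a.unit_length))
    cb = (b0 % b.unit_length, b0 % b.unit_length + min(b1 - b0, b.unit_length))
    return SharedRegion(
        family_a=name_a, family_b=name_b,
        length=length, identity=identity, coords_a=ca, coords_b=cb,
    )


# ---------------------------------------------------------------------------
# variant repeat units and internal microsatellites


def _is_primitive(motif: str) -> bool:
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[: d] * (n // d):
            return False
    return True


def _periodic_tracts(seq: str, unit: int, min_copies: int) -> list[tuple[int, int]]:
    """Maximal intervals [i, j) of ``seq`` with exact period ``unit`` and at
    least ``min_copies`` full copies; tract starts are leftmost."""
    L = len(seq)
    if L < 2 * unit:
        return []
    eq = [seq[x] == seq[x + unit] for x in range(L - unit)]
    tracts = []
    x = 0
    while x < len(eq):
        if not eq[x]:
            x += 1
            continue
        start = x
        while x < len(eq) and eq[x]:
            x += 1
        tract_len = (x - start) + unit
        if tract_len // unit >= min_copies:
            tracts.append((start, start + tract_len))
    return tracts


def detect_internal_microsatellite(
    consensus: ConsensusMonomer | str, min_copies: int = 5
) -> list[tuple[str, int, int]]:
    """Perfect internal microsatellite tracts of a monomer.

    Returns ``(motif_canonical, copies, position)`` for every maximal
    perfect tandem tract with a primitive motif of 1-6 bp repeated at least
    ``min_copies`` times; ``copies`` counts full units and ``position`` is
    the 0-based tract start.
    """
    seq = consensus.sequence if isinstance(consensus, ConsensusMonomer) else consensus
    out = []
    for unit in range(1, 7):
        for start, end in _periodic_tracts(seq, unit, min_copies):
            motif = seq[start : start + unit]
            if not _is_primitive(motif):
                continue
            out.append((canonical_rotation(motif), (end - start) // unit, start))
    out.sort(key=lambda t: (t[2], len(t[0])))
    return out


def _motif_similarity(variant: str, base: str) -> float:
    """Best phase/strand match fraction of ``variant`` against the periodic
    extension of ``base``."""
    best = 0
    for b in (base, reverse_complement(base)):
        ext = b * (len(variant) // len(b) + 2)
        for phase in range(len(b)):
            win = ext[phase : phase + len(variant)]
            m = sum(x == y for x, y in zip(variant, win))
            best = max(best, m)
    return best / len(variant)


def find_variant_units(
    cluster_reads: ReadSet | Sequence[str],
    base_motif: str,
    min_copies: int = 3,
    min_support: int = 2,
    max_unit: int = 24,
) -> list[tuple[str, int]]:
    """Variant repeat units derived from a simple satellite.

    Scans reads for maximal tandem tracts (primitive unit 2..``max_unit``,
    >= ``min_copies`` copies) whose unit is *not* a rotation of
    ``base_motif`` on either strand but shares at least half its bases with
    a phase of the base motif's periodic extension.  Distinct canonical
    variant units with at least ``min_support`` supporting reads are
    returned, most supported first.
    """
    if len(base_motif) < 2:
        raise ValueError("base_motif must be at least 2 bp")
    seqs = (
        cluster_reads.sequences
        if isinstance(cluster_reads, ReadSet)
        else list(cluster_reads)
    )
    base_canon = canonical_rotation(base_motif)
    support: dict[str, set[int]] = {}
    for ridx, seq in enumerate(seqs):
        for unit in range(2, max_unit + 1):
            for start, end in _periodic_tracts(seq, unit, min_copies):
                motif = seq[start : start + unit]
                if not _is_primitive(motif):
                    continue
                canon = canonical_rotation(motif)
                if canon == base_canon:
                    continue
                if _motif_similarity(motif, base_motif) >= 0.5:
                    support.setdefault(canon, set()).add(ridx)
    out = [(m, len(r)) for m, r in support.items() if len(r) >= min_support]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


# ---------------------------------------------------------------------------
# p-distance


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites with pairwise deletion.

    Sequences must be pre-aligned to equal length; columns where either
    sequence has a gap (``-``) or ``N`` are excluded.  Raises
    :class:`UndefinedDistanceError` when no sites remain.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    skip = {"-", "N", "n"}
    retained = diffs = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in skip or y in skip:
            continue
        retained += 1
        if x != y:
            diffs += 1
    if retained == 0:
        raise UndefinedDistanceError("no retained sites after pairwise deletion")
    return diffs / retained


# ---------------------------------------------------------------------------
# FISH probe design


def estimate_tm(seq: str) -> float:
    """Quick hybridization Tm: Wallace rule below 14 bp, GC formula above."""
    n = len(seq)
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if n < 14:
        return 2.0 * at + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / n


def _column_conservation(copies: Sequence[str]) -> np.ndarray:
    mat = np.array([np.frombuffer(c.encode(), dtype=np.uint8) for c in copies])
    out = np.empty(mat.shape[1])
    for c in range(mat.shape[1]):
        _, counts = np.unique(mat[:, c], return_counts=True)
        out[c] = counts.max() / mat.shape[0]
    return out


def _best_window(cons_score: np.ndarray, lengths: Sequence[int],
                 lo: int, hi: int) -> tuple[int, int, float]:
    """Highest-mean-conservation window with start in [lo, hi); ties break to
    the longest then leftmost window."""
    best = (-1.0, 0, 0)
    for w in lengths:
        if hi - lo < w:
            continue
        sums = np.convolve(cons_score[lo:hi], np.ones(w), mode="valid") / w
        i = int(np.argmax(sums))
        score = float(sums[i])
        if (score, w) > (best[0], best[2] - best[1]):
            best = (score, lo + i, lo + i + w)
    return best[1], best[2], best[0]


def design_probe(family: SatFamily, copies: Sequence[str]) -> ProbeDesign:
    """Design a FISH probe for a satellite family.

    Monomers longer than 85 bp get a PCR primer pair (two 18-25 bp windows
    of maximal per-column conservation, one per strand, amplicon at least
    half the monomer) for probe cloning; shorter monomers (or families with
    the oligo override set) get one or two directly labelled oligos
    (18-40 bp) on the most conserved windows.  Conservation is the mean
    per-column majority-base frequency across the aligned ``copies``.
    Monomers under 18 bp are handled by concatenating at least three
    canonical units into one oligo.
    """
    L = family.unit_length
    cons_seq = family.consensus.sequence
    if copies:
        if any(len(c) != L for c in copies):
            raise ValueError("copies must be aligned to the consensus length")
        score = _column_conservation(copies)
    else:
        score = np.ones(L)

    if L < 18:
        n_units = max(3, math.ceil(18 / L))
        oligo = cons_seq * n_units
        logger.info(
            "monomer %d bp < 18 bp: oligo built from %d concatenated units",
            L, n_units,
        )
        return ProbeDesign(
            family=family.name or "unnamed", mode="oligo",
            sequences=[oligo], positions=[(0, L)],
            tm=[estimate_tm(oligo)], conservation=[float(score.mean())],
            note=f"{n_units} concatenated canonical units",
        )

    if L > 85 and not family.probe_oligo_override:
        f0, f1, fs = _best_window(score, range(18, 26), 0, L // 2)
        r0, r1, rs = _best_window(score, range(18, 26), L // 2, L)
        fwd = cons_seq[f0:f1]
        rev = reverse_complement(cons_seq[r0:r1])
        return ProbeDesign(
            family=family.name or "unnamed", mode="primer_pair",
            sequences=[fwd, rev], positions=[(f0, f1), (r0, r1)],
            tm=[estimate_tm(fwd), estimate_tm(rev)],
            conservation=[fs, rs],
            note=f"amplicon {r1 - f0} bp",
        )

    w_hi = min(40, L)
    if L > 60:
        o0, o1, s1 = _best_window(score, range(18, w_hi + 1), 0, L // 2)
        p0, p1, s2 = _best_window(score, range(18, w_hi + 1), L // 2, L)
        seqs = [cons_seq[o0:o1], cons_seq[p0:p1]]
        return ProbeDesign(
            family=family.name or "unnamed", mode="oligo",
            sequences=seqs, positions=[(o0, o1), (p0, p1)],
            tm=[estimate_tm(s) for s in seqs], conservation=[s1, s2],
        )
    o0, o1, s1 = _best_window(score, range(18, w_hi + 1), 0, L)
    oligo = cons_seq[o0:o1]
    return ProbeDesign(
        family=family.name or "unnamed", mode="oligo",
        sequences=[oligo], positions=[(o0, o1)],
        tm=[estimate_tm(oligo)], conservation=[s1],
    )
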