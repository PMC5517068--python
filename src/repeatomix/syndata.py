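"""Synthetic repeat-rich genomes with known ground truth.

This module generates the study conditions for the rest of the package: a
haploid genome assembled from tandem satellite arrays, dispersed transposon-
like elements, a ribosomal tandem unit and an i.i.d. unique-sequence
background, plus Illumina-like reads sampled from it.  Every placement and
mutation is driven by a :class:`numpy.random.Generator` seeded from the spec,
so an identical (spec, seed) pair reproduces a byte-identical genome and read
set.

The substitution model is per-site uniform substitution to one of the three
alternative bases; no indels are introduced by default so monomer lengths
stay interpretable.  Satellite arrays are placed as a single contiguous block
per family (satellites are locally tandem); dispersed elements are scattered
uniformly without overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

DNA_ALPHABET = frozenset("ACGT")
READ_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: repeat categories used throughout the package
CATEGORIES = ("LTR", "non-LTR", "DNA_TE", "satDNA", "rDNA", "unclassified")


class InfeasibleSpecError(ValueError):
    """Raised when the requested repeat content cannot fit in the genome."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{what} must be non-empty")
    if not set(seq) <= DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise ValueError(f"{what} contains non-ACGT characters: {bad}")


@dataclass
class SatFamilySpec:
    """Recipe for one satellite DNA family.

    Parameters
    ----------
    label:
        Free-text family label used in the ground-truth manifest.
    monomer:
        Repeat unit, 4-1000 bp over {A,C,G,T}.
    target_proportion:
        Fraction of the genome this family should occupy, in [0, 1).
    divergence:
        Per-site substitution probability applied independently to each
        monomer copy, in [0, 0.3].  Satellite families in insect genomes are
        homogenised by concerted evolution; 0.05 is a realistic default for a
        young, FISH-detectable family and is the package default elsewhere.
    hor_subunits:
        Optional subunit sequences whose concatenation equals ``monomer``,
        for families built as higher-order repeats.
    microsat_insert:
        Optional ``(motif, min_copies, max_copies)``; each emitted monomer
        copy carries a perfect tract of ``motif`` repeated a uniform number
        of times in ``[min_copies, max_copies]``, making the realized unit
        length variable (as in satellites with internal microsatellites).
    """

    label: str
    monomer: str
    target_proportion: float
    divergence: float = 0.05
    hor_subunits: Optional[Sequence[str]] = None
    microsat_insert: Optional[tuple[str, int, int]] = None

    def __post_init__(self) -> None:
        _check_dna(self.monomer, f"monomer of family {self.label!r}")
        if not 0 <= self.target_proportion < 1:
            raise ValueError("target_proportion must be in [0, 1)")
        if not 0 <= self.divergence <= 0.3:
            raise ValueError("divergence must be in [0, 0.3]")
        if self.hor_subunits is not None:
            if "".join(self.hor_subunits) != self.monomer:
                raise ValueError(
                    "hor_subunits must concatenate to the monomer"
                )
        if self.microsat_insert is not None:
            motif, lo, hi = self.microsat_insert
            _check_dna(motif, "microsat motif")
            if not 1 <= lo <= hi:
                raise ValueError("microsat copy bounds must satisfy 1 <= min <= max")

    @property
    def expected_copy_length(self) -> float:
        """Mean emitted length of one monomer copy."""
        n = len(self.monomer)
        if self.microsat_insert is not None:
            motif, lo, hi = self.microsat_insert
            n += len(motif) * (lo + hi) / 2.0
        return n


@dataclass
class DispersedElementSpec:
    """A transposon-like element scattered through the genome."""

    label: str
    sequence: str
    copy_count: int
    divergence: float = 0.03
    category: str = "unclassified"  # one of LTR / non-LTR / DNA_TE / unclassified

    def __post_init__(self) -> None:
        _check_dna(self.sequence, f"element {self.label!r}")
        if self.copy_count < 0:
            raise ValueError("copy_count must be >= 0")
        if self.category not in ("LTR", "non-LTR", "DNA_TE", "unclassified"):
            raise ValueError(f"unknown dispersed category {self.category!r}")


@dataclass
class SyntheticGenomeSpec:
    """Full generative recipe for one haploid genome."""

    genome_length: int
    sat_families: Sequence[SatFamilySpec] = ()
    dispersed_elements: Sequence[DispersedElementSpec] = ()
    rdna_unit: Optional[tuple[str, int]] = None
    mito_sequence: Optional[str] = None
    mito_contamination: float = 0.0
    at_bias_background: float = 0.60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        total = sum(f.target_proportion for f in self.sat_families)
        if total >= 1:
            raise ValueError("sum of satellite target_proportions must be < 1")
        if self.mito_sequence is not None:
            _check_dna(self.mito_sequence, "mito_sequence")
        if not 0 <= self.mito_contamination < 1:
            raise ValueError("mito_contamination must be in [0, 1)")
        if not 0 < self.at_bias_background < 1:
            raise ValueError("at_bias_background must be in (0, 1)")


@dataclass
class GroundTruth:
    """Planted truth for one synthetic genome.

    Coordinates are 0-based half-open.  ``category_bp`` plus
    ``background_bp`` always sum to ``genome_length`` exactly.
    """

    genome_length: int
    family_proportion_pct: dict[str, float]
    family_intervals: dict[str, list[tuple[int, int]]]
    category_bp: dict[str, int]
    background_bp: int

    @property
    def repeat_bp(self) -> int:
        return sum(self.category_bp.values())

    @property
    def repeat_fraction_pct(self) -> float:
        return 100.0 * self.repeat_bp / self.genome_length

    def to_dict(self) -> dict:
        return {
            "genome_length": self.genome_length,
            "family_proportion_pct": dict(self.family_proportion_pct),
            "family_intervals": {
                k: [list(iv) for iv in v] for k, v in self.family_intervals.items()
            },
            "category_bp": dict(self.category_bp),
            "background_bp": self.background_bp,
        }


@dataclass
class ReadSet:
    """A set of (optionally paired) reads from one sample."""

    ids: list[str]
    sequences: list[str]
    mates: list[Optional[str]] = field(default_factory=list)
    read_length: int = 0
    declared_coverage: float = 0.0
    source_sample: str = ""

    def __post_init__(self) -> None:
        if not self.mates:
            self.mates = [None] * len(self.ids)
        if not (len(self.ids) == len(self.sequences) == len(self.mates)):
            raise ValueError("ids, sequences and mates must have equal length")
        for seq in self.sequences:
            if not set(seq) <= READ_ALPHABET:
                raise ValueError("read sequences must be over {A,C,G,T,N}")
        by_id = dict(zip(self.ids, self.mates))
        for rid, mate in by_id.items():
            if mate is not None and by_id.get(mate) != rid:
                raise ValueError(f"mate of {rid!r} does not reference back")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, indices: Sequence[int]) -> "ReadSet":
        idx = list(indices)
        kept = {self.ids[i] for i in idx}
        return ReadSet(
            ids=[self.ids[i] for i in idx],
            sequences=[self.sequences[i] for i in idx],
            mates=[self.mates[i] if self.mates[i] in kept else None for i in idx],
            read_length=self.read_length,
            declared_coverage=self.declared_coverage,
            source_sample=self.source_sample,
        )


# ---------------------------------------------------------------------------
# sequence generation


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def mutate_sequence(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``divergence``.

    A substituted site is replaced by one of the three alternative bases with
    equal probability (Jukes-Cantor-like, no back-substitution to self).
    """
    if divergence <= 0:
        return seq
    arr = _encode(seq).copy()
    hit = rng.random(arr.size) < divergence
    n_hit = int(hit.sum())
    if n_hit:
        idx = _BASE_INDEX[arr[hit]]
        # shift by 1..3 positions in base order => uniform over the 3 others
        shift = rng.integers(1, 4, size=n_hit)
        arr[hit] = _BASES[(idx + shift) % 4]
    return _decode(arr)


def random_dna(length: int, rng: np.random.Generator, at_fraction: float = 0.5) -> str:
    """I.i.d. random DNA with the given A+T fraction."""
    p = np.array(
        [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    )
    arr = _BASES[rng.choice(4, size=length, p=p)]
    return _decode(arr)


def build_tandem_array(
    spec: SatFamilySpec, copies: int, seed: int | np.random.Generator
) -> str:
    """Concatenate ``copies`` independently mutated copies of the monomer.

    Each copy is substituted per-site at rate ``spec.divergence``; if
    ``spec.microsat_insert`` is set, a perfect microsatellite tract of a
    uniformly drawn copy number is inserted at the monomer midpoint of every
    copy (the tract itself is kept perfect so the emitted unit length varies
    while the tract stays recognisable).
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts: list[str] = []
    mid = len(spec.monomer) // 2
    for _ in range(copies):
        copy = mutate_sequence(spec.monomer, spec.divergence, rng)
        if spec.microsat_insert is not None:
            motif, lo, hi = spec.microsat_insert
            tract = motif * int(rng.integers(lo, hi + 1))
            copy = copy[:mid] + tract + copy[mid:]
        parts.append(copy)
    return "".join(parts)


def build_genome(spec: SyntheticGenomeSpec) -> tuple[str, GroundTruth]:
    """Realize a genome from its spec.

    Satellite arrays (one block per family), rDNA (one tandem block) and
    dispersed element copies are shuffled into a random order and separated
    by unique-background gaps whose lengths are drawn multinomially, so no
    two repeat pieces overlap and the realized genome length equals
    ``spec.genome_length`` exactly.  Realized (integer-rounded) proportions,
    coordinates and per-category bp are returned as :class:`GroundTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    G = spec.genome_length

    pieces: list[tuple[str, str, str]] = []  # (label, category, sequence)
    for fam in spec.sat_families:
        copies = max(1, round(fam.target_proportion * G / fam.expected_copy_length))
        pieces.append((fam.label, "satDNA", build_tandem_array(fam, copies, rng)))
    if spec.rdna_unit is not None:
        unit, n = spec.rdna_unit
        _check_dna(unit, "rdna unit")
        pieces.append(("rDNA", "rDNA", unit * n))
    for elem in spec.dispersed_elements:
        for _ in range(elem.copy_count):
            pieces.append(
                (elem.label, elem.category, mutate_sequence(elem.sequence, elem.divergence, rng))
            )

    total_repeat = sum(len(s) for _, _, s in pieces)
    if total_repeat >= G:
        raise InfeasibleSpecError(
            f"planted repeats ({total_repeat} bp) do not fit in genome ({G} bp)"
        )
    background = G - total_repeat

    order = rng.permutation(len(pieces))
    n_gaps = len(pieces) + 1
    gaps = rng.multinomial(background, np.full(n_gaps, 1.0 / n_gaps))

    chunks: list[str] = []
    intervals: dict[str, list[tuple[int, int]]] = {}
    category_bp: dict[str, int] = {c: 0 for c in CATEGORIES}
    pos = 0
    for k, idx in enumerate(order):
        gap = int(gaps[k])
        if gap:
            chunks.append(random_dna(gap, rng, spec.at_bias_background))
            pos += gap
        label, category, seqpiece = pieces[idx]
        chunks.append(seqpiece)
        intervals.setdefault(label, []).append((pos, pos + len(seqpiece)))
        category_bp[category] += len(seqpiece)
        pos += len(seqpiece)
    last = int(gaps[-1])
    if last:
        chunks.append(random_dna(last, rng, spec.at_bias_background))
        pos += last
    assert pos == G

    genome = "".join(chunks)
    fam_pct = {
        label: 100.0 * sum(e - s for s, e in ivs) / G for label, ivs in intervals.items()
    }
    truth = GroundTruth(
        genome_length=G,
        family_proportion_pct=fam_pct,
        family_intervals={k: sorted(v) for k, v in intervals.items()},
        category_bp=category_bp,
        background_bp=background,
    )
    return genome, truth


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    genome: str,
    coverage: float,
    read_length: int,
    insert_mean: Optional[int] = None,
    seed: int | np.random.Generator = 0,
    error_rate: float = 0.0,
    source_sample: str = "",
) -> ReadSet:
    """Sample uniform random reads from both strands of ``genome``.

    The read count is ``round(coverage * len(genome) / read_length)``; for
    paired mode (``insert_mean`` set) that count is split into pairs with a
    fixed insert size.  ``error_rate`` applies uniform substitutions to the
    emitted reads (default 0; the clustering identity threshold absorbs
    planted divergence instead).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    G = len(genome)
    if read_length > G:
        raise ValueError("read_length exceeds genome length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_reads = round(coverage * G / read_length)

    ids: list[str] = []
    seqs: list[str] = []
    mates: list[Optional[str]] = []

    if insert_mean is None:
        starts = rng.integers(0, G - read_length + 1, size=n_reads)
        flip = rng.random(n_reads) < 0.5
        for i in range(n_reads):
            s = int(starts[i])
            frag = genome[s : s + read_length]
            if flip[i]:
                frag = reverse_complement(frag)
            if error_rate > 0:
                frag = mutate_sequence(frag, error_rate, rng)
            ids.append(f"{source_sample or 'read'}_{i}")
            seqs.append(frag)
            mates.append(None)
    else:
        insert = max(insert_mean, 2 * read_length)
        n_pairs = max(1, n_reads // 2)
        starts = rng.integers(0, G - insert + 1, size=n_pairs)
        flip = rng.random(n_pairs) < 0.5
        for i in range(n_pairs):
            s = int(starts[i])
            frag = genome[s : s + insert]
            if flip[i]:
                frag = reverse_complement(frag)
            r1 = frag[:read_length]
            r2 = reverse_complement(frag[-read_length:])
            if error_rate > 0:
                r1 = mutate_sequence(r1, error_rate, rng)
                r2 = mutate_sequence(r2, error_rate, rng)
            stem = f"{source_sample or 'read'}_{i}"
            ids += [stem + "/1", stem + "/2"]
            seqs += [r1, r2]
            mates += [stem + "/2", stem + "/1"]

    return ReadSet(
        ids=ids,
        sequences=seqs,
        mates=mates,
        read_length=read_length,
        declared_coverage=coverage,
        source_sample=source_sample,
    )


def simulate_sample(
    spec: SyntheticGenomeSpec,
    coverage: float,
    read_length: int = 100,
    insert_mean: Optional[int] = None,
    seed: Optional[int] = None,
    error_rate: float = 0.0,
    sample_id: str = "sample",
) -> tuple[ReadSet, GroundTruth]:
    """Build the genome and simulate its read set in one step.

    If the spec carries a mitochondrial sequence with a nonzero contamination
    fraction, that fraction of additional reads is drawn from the (circular)
    mitochondrial genome and appended, emulating organellar contamination of
    a whole-body DNA extraction.
    """
    genome, truth = build_genome(spec)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    reads = simulate_reads(
        genome,
        coverage,
        read_length,
        insert_mean=insert_mean,
        seed=rng,
        error_rate=error_rate,
        source_sample=sample_id,
    )
    if spec.mito_sequence and spec.mito_contamination > 0:
        n_mito = round(len(reads) * spec.mito_contamination / (1 - spec.mito_contamination))
        circ = spec.mito_sequence + spec.mito_sequence[: read_length - 1]
        starts = rng.integers(0, len(spec.mito_sequence), size=n_mito)
        flip = rng.random(n_mito) < 0.5
        for i in range(n_mito):
            frag = circ[int(starts[i]) : int(starts[i]) + read_length]
            if flip[i]:
                frag = reverse_complement(frag)
            reads.ids.append(f"{sample_id}_mito_{i}")
            reads.sequences.append(frag)
            reads.mates.append(None)
    return reads, truth
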