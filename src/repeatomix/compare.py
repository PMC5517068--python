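"""Cross-sample repeatome accounting and statistics.

Converts cluster read-percentages into absolute Mbp per haploid genome,
builds per-category genome profiles, compares two lineages category by
category with 2x2 chi-square tests, pools samples for a combined clustering
run (which detects shared families below the per-sample detection floor),
and reports shared/exclusive family partitions and per-family fold changes.

The chi-square table for a category is ``[[category Mbp, rest-of-genome
Mbp]]`` per sample, treating Mbp as counts; the statistic therefore scales
with the chosen unit, which is why the unit is config-exposed and a
sensitivity note accompanies the report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .clustering import Cluster, SampleSpec, cluster_reads, repeatome_fraction, sample_reads
from .satellitome import SatFamily
from .syndata import ReadSet

logger = logging.getLogger(__name__)

PROFILE_CATEGORIES = ("LTR", "non-LTR", "DNA_TE", "satDNA", "rDNA", "unclassified")


class DegenerateTableError(ValueError):
    """A 2x2 chi-square table has a zero marginal."""


def proportion_to_mbp(percent: float, genome_size: int) -> float:
    """Convert a genome percentage to Mbp per haploid genome."""
    if not 0 <= percent <= 100:
        raise ValueError("percent must be in [0, 100]")
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return percent / 100.0 * genome_size / 1e6


@dataclass
class GenomeProfile:
    """Per-category accounting for one sample (%, Mbp per haploid genome)."""

    sample_id: str
    genome_size: int
    categories: dict[str, tuple[float, float]]  # cat -> (pct, mbp)
    non_repetitive: tuple[float, float]

    def __post_init__(self) -> None:
        total = sum(p for p, _ in self.categories.values()) + self.non_repetitive[0]
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"profile percentages sum to {total}, not 100")

    @property
    def genome_mbp(self) -> float:
        return self.genome_size / 1e6

    def category_mbp(self, category: str) -> float:
        if category == "non_repetitive":
            return self.non_repetitive[1]
        return self.categories[category][1]

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "genome_size": self.genome_size,
            "categories": {k: list(v) for k, v in self.categories.items()},
            "non_repetitive": list(self.non_repetitive),
        }


def category_totals(clusters: Sequence[Cluster], sample: SampleSpec) -> GenomeProfile:
    """Sum cluster proportions per repeat category into a genome profile.

    Unclassified clusters accrue to "unclassified" (never dropped);
    mitochondrial clusters are excluded from the repeat categories.  The
    non-repetitive remainder is 100 minus the repeatome fraction, so the
    accounting identity holds exactly before any rounding.
    """
    pct: dict[str, float] = {c: 0.0 for c in PROFILE_CATEGORIES}
    for cl in clusters:
        if cl.is_mito:
            continue
        cat = cl.classification if cl.classification in pct else "unclassified"
        pct[cat] += cl.genome_proportion
    non_rep = 100.0 - sum(pct.values())
    return GenomeProfile(
        sample_id=sample.sample_id,
        genome_size=sample.genome_size,
        categories={
            c: (p, proportion_to_mbp(p, sample.genome_size)) for c, p in pct.items()
        },
        non_repetitive=(non_rep, proportion_to_mbp(non_rep, sample.genome_size)),
    )


def chi_square_2x2(table: Sequence[Sequence[float]], correction: bool = False):
    """Closed-form 2x2 chi-square test of independence.

    ``chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``, df = 1.  Yates
    correction is off by default.  Raises on a zero marginal.
    """
    (a, b), (c, d) = table
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m <= 0 for m in margins):
        raise DegenerateTableError(f"degenerate 2x2 table {table}")
    num = abs(a * d - b * c)
    if correction:
        num = max(0.0, num - n / 2.0)
    stat = n * num * num / math.prod(margins)
    p = float(stats.chi2.sf(stat, df=1))
    return stat, 1, p


def chi_square_category(
    profile_a: GenomeProfile,
    profile_b: GenomeProfile,
    category: str,
    correction: bool = False,
):
    """2x2 chi-square of one category's Mbp vs rest-of-genome Mbp between
    two samples; returns ``(statistic, df, p)``."""
    rows = []
    for prof in (profile_a, profile_b):
        cat_mbp = prof.category_mbp(category)
        rows.append([cat_mbp, prof.genome_mbp - cat_mbp])
    return chi_square_2x2(rows, correction=correction)


@dataclass
class ComparisonReport:
    sample_a: str
    sample_b: str
    alpha: float
    per_category: dict[str, tuple[float, int, float, bool]]  # stat, df, p, significant
    shared_families: list[str] = field(default_factory=list)
    exclusive_families: dict[str, list[str]] = field(default_factory=dict)
    fold_changes: dict[str, float] = field(default_factory=dict)  # family -> a/b
    unit_note: str = (
        "chi-square statistics computed on the Mbp scale; the statistic "
        "scales linearly with the chosen unit"
    )

    def to_dict(self) -> dict:
        return {
            "sample_a": self.sample_a,
            "sample_b": self.sample_b,
            "alpha": self.alpha,
            "per_category": {k: list(v) for k, v in self.per_category.items()},
            "shared_families": self.shared_families,
            "exclusive_families": self.exclusive_families,
            "fold_changes": {
                k: ("inf" if math.isinf(v) else v) for k, v in self.fold_changes.items()
            },
            "unit_note": self.unit_note,
        }


def compare_profiles(
    profile_a: GenomeProfile,
    profile_b: GenomeProfile,
    families: Sequence[SatFamily] = (),
    alpha: float = 0.001,
) -> ComparisonReport:
    """Category-wise chi-square comparison of two genome profiles, plus
    family sharing and fold changes when a merged family list is given."""
    per_cat = {}
    for cat in list(PROFILE_CATEGORIES) + ["non_repetitive"]:
        try:
            stat, df, p = chi_square_category(profile_a, profile_b, cat)
        except DegenerateTableError:
            continue
        per_cat[cat] = (stat, df, p, p < alpha)
    report = ComparisonReport(
        sample_a=profile_a.sample_id,
        sample_b=profile_b.sample_id,
        alpha=alpha,
        per_category=per_cat,
    )
    if families:
        part = shared_exclusive(families, [profile_a.sample_id, profile_b.sample_id])
        report.shared_families = part.shared
        report.exclusive_families = part.exclusive
        for fam in families:
            if fam.mbp.get(profile_b.sample_id, 0.0) >= 0:
                report.fold_changes[fam.name or fam.consensus.sequence[:12]] = (
                    fold_change(fam, profile_a.sample_id, profile_b.sample_id)
                )
    return report


# ---------------------------------------------------------------------------
# combined (pooled) clustering


@dataclass
class CombinedResult:
    """Joint clusters over pooled samples with per-sample read composition."""

    clusters: list[Cluster]
    composition: dict[int, dict[str, int]]  # cluster_id -> sample -> n reads
    reads_per_sample: int
    min_reads_detect: int

    def detected_in(self, cluster_id: int, sample_id: str) -> bool:
        return self.composition.get(cluster_id, {}).get(sample_id, 0) >= self.min_reads_detect


def combined_analysis(
    samples: Sequence[SampleSpec],
    seed: int,
    reads_per_sample: Optional[int] = None,
    min_identity: float = 0.90,
    min_overlap: float = 0.55,
    min_reads_detect: int = 10,
    min_cluster_size: Optional[int] = None,
) -> CombinedResult:
    """Pool equal-sized read subsamples from every sample and cluster jointly.

    Shared families of very unequal abundance surface here even when the
    rarer sample's separate run cannot detect them: its few reads join the
    abundant sample's cluster.  A family counts as detected in sample S when
    its joint cluster holds at least ``min_reads_detect`` reads from S.
    """
    if len(samples) < 2:
        raise ValueError("combined analysis needs at least 2 samples")
    if reads_per_sample is None:
        reads_per_sample = min(len(s.reads) for s in samples)
    rng = np.random.default_rng(seed)

    ids: list[str] = []
    seqs: list[str] = []
    origin: dict[str, str] = {}
    for s in samples:
        sub = sample_reads(s.reads, reads_per_sample, int(rng.integers(1 << 31)))
        for rid, seq in zip(sub.ids, sub.sequences):
            tag = f"{s.sample_id}::{rid}"
            ids.append(tag)
            seqs.append(seq)
            origin[tag] = s.sample_id
    pooled = ReadSet(ids=ids, sequences=seqs, source_sample="combined")

    clusters = cluster_reads(
        pooled, min_identity=min_identity, min_overlap=min_overlap,
        min_cluster_size=min_cluster_size,
    )
    composition: dict[int, dict[str, int]] = {}
    for cl in clusters:
        counts: dict[str, int] = {}
        for rid in cl.read_ids:
            counts[origin[rid]] = counts.get(origin[rid], 0) + 1
        composition[cl.cluster_id] = counts
    return CombinedResult(
        clusters=clusters,
        composition=composition,
        reads_per_sample=reads_per_sample,
        min_reads_detect=min_reads_detect,
    )


# ---------------------------------------------------------------------------
# family sharing and fold change


@dataclass
class FamilyPartition:
    shared: list[str]
    exclusive: dict[str, list[str]]
    below_floor: dict[str, list[str]]  # sample -> families present only via combined run


def shared_exclusive(
    families: Sequence[SatFamily],
    samples: Sequence[str],
    floor: float = 0.1,
) -> FamilyPartition:
    """Partition families into shared vs per-sample exclusive.

    A family is present in sample S when its abundance there is positive or
    its combined-run flag for S is set; combined-run-only detections are
    additionally listed as present below the ``floor`` (%) abundance limit.
    """
    shared: list[str] = []
    exclusive: dict[str, list[str]] = {s: [] for s in samples}
    below: dict[str, list[str]] = {s: [] for s in samples}
    for fam in families:
        name = fam.name or fam.consensus.sequence[:12]
        present = []
        for s in samples:
            if fam.abundance.get(s, 0.0) > 0:
                present.append(s)
            elif s in fam.combined_only:
                present.append(s)
                below[s].append(name)
        if len(present) >= 2:
            shared.append(name)
        elif len(present) == 1:
            exclusive[present[0]].append(name)
    return FamilyPartition(shared=shared, exclusive=exclusive, below_floor=below)


def plot_profiles(profiles: Sequence[GenomeProfile], path: str) -> None:
    """Stacked-bar chart of per-category Mbp per haploid genome, one bar per
    sample (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.8 + 1.2 * len(profiles), 4.5))
    xs = np.arange(len(profiles))
    bottom = np.zeros(len(profiles))
    for cat in list(PROFILE_CATEGORIES) + ["non_repetitive"]:
        vals = np.array([
            p.non_repetitive[1] if cat == "non_repetitive" else p.categories[cat][1]
            for p in profiles
        ])
        ax.bar(xs, vals, bottom=bottom, label=cat)
        bottom += vals
    ax.set_xticks(xs)
    ax.set_xticklabels([p.sample_id for p in profiles])
    ax.set_ylabel("Mbp per haploid genome")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def fold_change(family: SatFamily, sample_a: str, sample_b: str) -> float:
    """Mbp ratio ``sample_a / sample_b`` for one family; ``inf`` (flagged in
    reports) when the denominator is zero."""
    num = family.mbp.get(sample_a, 0.0)
    den = family.mbp.get(sample_b, 0.0)
    if den == 0:
        logger.warning(
            "fold change of %s: zero Mbp in %s; reporting infinite",
            family.name or "family", sample_b,
        )
        return math.inf
    return num / den
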