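"""Mbp accounting, chi-square comparison, combined run, fold changes."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from repeatomix.annotate import ConsensusMonomer, at_content, canonical_rotation
from repeatomix.clustering import Cluster, SampleSpec
from repeatomix.compare import (
    DegenerateTableError,
    GenomeProfile,
    category_totals,
    chi_square_2x2,
    chi_square_category,
    combined_analysis,
    fold_change,
    proportion_to_mbp,
    shared_exclusive,
)
from repeatomix.satellitome import SatFamily
from repeatomix.syndata import (
    SatFamilySpec,
    SyntheticGenomeSpec,
    build_genome,
    random_dna,
    simulate_reads,
)
from tests._oracles import chi2_closed_form


def test_proportion_to_mbp_examples():
    assert proportion_to_mbp(50.0, 1_000_000) == pytest.approx(0.5)
    assert proportion_to_mbp(0.0, 123) == 0.0
    # the dominant-family abundance over the larger haploid genome
    assert proportion_to_mbp(11.77, 1_936_000_000) == pytest.approx(227.87, abs=0.005)


def _sample(sid="s", genome=1_000_000_000):
    return SampleSpec(sid, "lineage", genome)


def test_no_clusters_is_all_non_repetitive():
    prof = category_totals([], _sample())
    assert prof.non_repetitive[0] == pytest.approx(100.0)
    assert all(p == 0 for p, _ in prof.categories.values())


def test_two_satdna_clusters_sum_to_five_percent_fifty_mbp():
    clusters = [
        Cluster(1, ["a"] * 30, 3.0, 1000, classification="satDNA"),
        Cluster(2, ["b"] * 20, 2.0, 1000, classification="satDNA"),
    ]
    prof = category_totals(clusters, _sample(genome=1_000_000_000))
    assert prof.categories["satDNA"] == (pytest.approx(5.0), pytest.approx(50.0))


def test_unclassified_clusters_are_never_dropped():
    clusters = [Cluster(1, ["a"] * 10, 1.0, 1000, classification="weird")]
    prof = category_totals(clusters, _sample())
    assert prof.categories["unclassified"][0] == pytest.approx(1.0)


def test_accounting_identity_exact():
    clusters = [
        Cluster(1, ["a"] * 7, 0.7, 1000, classification="satDNA"),
        Cluster(2, ["b"] * 3, 0.3, 1000, classification="LTR"),
    ]
    prof = category_totals(clusters, _sample(genome=1_936_000_000))
    total_mbp = sum(m for _, m in prof.categories.values()) + prof.non_repetitive[1]
    assert total_mbp == pytest.approx(prof.genome_mbp, abs=1e-9)
    for pct, mbp in list(prof.categories.values()) + [prof.non_repetitive]:
        assert mbp == pytest.approx(pct / 100 * prof.genome_size / 1e6, abs=1e-12)


# ---------------------------------------------------------------------------
# chi-square


def test_identical_profiles_give_zero_statistic():
    stat, df, p = chi_square_2x2([[10, 90], [10, 90]])
    assert stat == 0.0 and df == 1 and p == pytest.approx(1.0)


def test_chi_square_matches_closed_form_and_scipy_to_ten_digits():
    tables = [
        [[10, 90], [20, 80]],
        [[630.78, 1305.22], [376.05, 1110.95]],
        [[5, 5], [4, 6]],
        [[1000, 1], [1, 1000]],
    ]
    for t in tables:
        stat, _, p = chi_square_2x2(t)
        assert stat == pytest.approx(chi2_closed_form(t), rel=1e-10)
        ref = chi2_contingency(np.array(t), correction=False)
        assert stat == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


def test_satdna_mbp_comparison_is_significant_below_point_one_percent():
    stat, df, p = chi_square_2x2([[630.78, 1305.22], [376.05, 1110.95]])
    assert df == 1
    assert p < 0.001


def test_degenerate_table_raises():
    with pytest.raises(DegenerateTableError):
        chi_square_2x2([[0, 0], [5, 5]])


def _profile(sid, genome, sat_pct):
    non_rep = 100.0 - sat_pct
    cats = {c: (0.0, 0.0) for c in
            ("LTR", "non-LTR", "DNA_TE", "rDNA", "unclassified")}
    cats["satDNA"] = (sat_pct, proportion_to_mbp(sat_pct, genome))
    return GenomeProfile(sid, genome, cats,
                         (non_rep, proportion_to_mbp(non_rep, genome)))


def test_chi_square_category_uses_mbp_table():
    pa = _profile("a", 1_936_000_000, 32.58)  # ~630.78 Mbp
    pb = _profile("b", 1_487_000_000, 25.29)  # ~376.05 Mbp
    stat, df, p = chi_square_category(pa, pb, "satDNA")
    expected = chi2_closed_form(
        [[pa.category_mbp("satDNA"), pa.genome_mbp - pa.category_mbp("satDNA")],
         [pb.category_mbp("satDNA"), pb.genome_mbp - pb.category_mbp("satDNA")]]
    )
    assert stat == pytest.approx(expected, rel=1e-12)
    assert p < 0.001


# ---------------------------------------------------------------------------
# combined analysis


def _two_sample_setup(pct_a, pct_b, seed=0):
    monomer = random_dna(33, np.random.default_rng(555), 0.65)
    samples = []
    truths = {}
    for sid, pct, sd in (("A", pct_a, seed + 1), ("B", pct_b, seed + 2)):
        fams = []
        if pct > 0:
            fams.append(SatFamilySpec(label="shared", monomer=monomer,
                                      target_proportion=pct / 100,
                                      divergence=0.05))
        spec = SyntheticGenomeSpec(genome_length=400_000, sat_families=fams,
                                   seed=sd)
        genome, truth = build_genome(spec)
        reads = simulate_reads(genome, 0.5, 100, seed=sd + 10,
                               source_sample=sid)
        samples.append(SampleSpec(sid, sid, 400_000, reads))
        truths[sid] = (genome, truth)
    return samples, truths


def _array_read_ids(sample, genome, truth):
    from tests._oracles import rc

    (a, b), = truth.family_intervals["shared"]
    region = genome[max(0, a - 99) : b + 99]
    return {
        rid
        for rid, seq in zip(sample.reads.ids, sample.reads.sequences)
        if seq in region or rc(seq) in region
    }


def test_combined_run_detects_family_below_separate_floor():
    """A family at 5% in sample A and ~0.15% in sample B is invisible in
    B's separate run but its reads join the joint cluster."""
    from repeatomix.clustering import cluster_reads

    samples, truths = _two_sample_setup(5.0, 0.15)
    array_b = _array_read_ids(samples[1], *truths["B"])
    separate_b = cluster_reads(samples[1].reads)
    # no separate-run cluster is dominated by the family's few reads
    for c in separate_b:
        assert len(array_b & set(c.read_ids)) < 5

    result = combined_analysis(samples, seed=3, min_reads_detect=2)
    top = result.clusters[0]
    comp = result.composition[top.cluster_id]
    assert comp.get("A", 0) > 50
    assert comp.get("B", 0) >= 2
    assert result.detected_in(top.cluster_id, "B")


def test_combined_detection_monotone_in_abundance():
    for pct_b in (0.15, 0.5):
        samples, _ = _two_sample_setup(5.0, pct_b)
        result = combined_analysis(samples, seed=3, min_reads_detect=2)
        assert result.detected_in(result.clusters[0].cluster_id, "B"), pct_b


def test_disjoint_samples_give_single_origin_clusters():
    monomer_a = random_dna(40, np.random.default_rng(71), 0.65)
    monomer_b = random_dna(52, np.random.default_rng(72), 0.65)
    samples = []
    for sid, mon, sd in (("A", monomer_a, 1), ("B", monomer_b, 2)):
        fam = SatFamilySpec(label="own", monomer=mon, target_proportion=0.05,
                            divergence=0.05)
        spec = SyntheticGenomeSpec(genome_length=300_000, sat_families=[fam],
                                   seed=sd)
        genome, _ = build_genome(spec)
        reads = simulate_reads(genome, 0.5, 100, seed=sd + 30,
                               source_sample=sid)
        samples.append(SampleSpec(sid, sid, 300_000, reads))
    result = combined_analysis(samples, seed=9)
    for cl in result.clusters:
        comp = result.composition[cl.cluster_id]
        assert max(comp.values()) / cl.n_reads >= 0.99


# ---------------------------------------------------------------------------
# shared/exclusive and fold change


def _named_family(name, abundance, mbp=None, combined_only=()):
    cons = ConsensusMonomer("ACGTACGTAC", 10, 40.0, 1)
    fam = SatFamily(consensus=cons, abundance=abundance, mbp=mbp or {},
                    name=name, combined_only=set(combined_only))
    return fam


def test_shared_exclusive_partition():
    fams = [
        _named_family("F1", {"A": 2.0, "B": 0.0}),
        _named_family("F2", {"A": 0.0, "B": 1.0}, combined_only={"A"}),
        _named_family("F3", {"A": 1.0, "B": 1.0}),
    ]
    part = shared_exclusive(fams, ["A", "B"])
    assert part.shared == ["F2", "F3"]
    assert part.exclusive == {"A": ["F1"], "B": []}
    assert part.below_floor["A"] == ["F2"]


def test_all_shared_leaves_exclusives_empty():
    fams = [_named_family(f"F{i}", {"A": 1.0, "B": 2.0}) for i in range(3)]
    part = shared_exclusive(fams, ["A", "B"])
    assert part.exclusive == {"A": [], "B": []}


def test_fold_change_examples():
    fam = _named_family("TinfSat01-33", {}, mbp={"andean": 228.78,
                                                 "non_andean": 37.76})
    assert fold_change(fam, "andean", "non_andean") == pytest.approx(6.06, abs=0.005)
    fam_eq = _named_family("X", {}, mbp={"a": 3.0, "b": 3.0})
    assert fold_change(fam_eq, "a", "b") == 1.0
    fam_zero = _named_family("Y", {}, mbp={"a": 3.0, "b": 0.0})
    assert math.isinf(fold_change(fam_zero, "a", "b"))
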