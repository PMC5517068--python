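"""Read-similarity graph and cluster quantification."""

import numpy as np
import pytest

from repeatomix.clustering import (
    Cluster,
    ReadGraph,
    build_similarity_graph,
    cluster_graph,
    cluster_reads,
    filter_mitochondrial,
    repeatome_fraction,
    sample_reads,
)
from repeatomix.syndata import (
    ReadSet,
    SatFamilySpec,
    SyntheticGenomeSpec,
    build_genome,
    build_tandem_array,
    random_dna,
    reverse_complement,
    simulate_reads,
)
from tests._oracles import brute_force_edges, rc


def _readset(seqs):
    return ReadSet(ids=[f"r{i}" for i in range(len(seqs))], sequences=list(seqs))


# ---------------------------------------------------------------------------
# sampling and mito filtering


def test_sample_reads_identity_when_target_covers_all():
    reads = _readset([random_dna(100, np.random.default_rng(i)) for i in range(20)])
    assert sample_reads(reads, 20, seed=0) is reads
    assert sample_reads(reads, 50, seed=0) is reads


def test_sample_reads_deterministic():
    reads = _readset([random_dna(100, np.random.default_rng(i)) for i in range(200)])
    a = sample_reads(reads, 50, seed=7)
    b = sample_reads(reads, 50, seed=7)
    assert a.ids == b.ids
    assert len(a) == 50


def test_sampled_array_fraction_matches_population():
    """Subsampling preserves the fraction of reads from a planted array
    within a hypergeometric-style tolerance."""
    rng = np.random.default_rng(0)
    array_reads = [random_dna(100, rng, 0.7) for _ in range(300)]
    bg_reads = [random_dna(100, rng, 0.5) for _ in range(700)]
    reads = _readset(array_reads + bg_reads)
    marked = set(reads.ids[:300])
    sub = sample_reads(reads, 400, seed=3)
    frac = sum(1 for r in sub.ids if r in marked) / 400
    se = np.sqrt(0.3 * 0.7 / 400)
    assert abs(frac - 0.3) < 4 * se


def test_mito_filter_removes_verbatim_and_keeps_background():
    rng = np.random.default_rng(5)
    mito = random_dna(15_000, rng, 0.68)
    mito_read = mito[2000:2100]
    mito_rc = reverse_complement(mito[8000:8100])
    bg = [random_dna(100, rng, 0.5) for _ in range(1000)]
    reads = _readset([mito_read, mito_rc] + bg)
    kept, removed = filter_mitochondrial(reads, mito)
    assert removed >= 2
    assert "r0" not in kept.ids and "r1" not in kept.ids
    false_removed = removed - 2
    assert false_removed / 1000 < 0.01


def test_mito_filter_without_reference_is_identity():
    reads = _readset([random_dna(100, np.random.default_rng(1))])
    kept, removed = filter_mitochondrial(reads, None)
    assert kept is reads and removed == 0


# ---------------------------------------------------------------------------
# similarity graph


def test_identical_reads_edge_full_identity():
    seq = random_dna(100, np.random.default_rng(2))
    g = build_similarity_graph(_readset([seq, seq]))
    assert g.n_edges == 1
    assert g.identity[0] == 1.0 and g.overlap[0] == 1.0


def test_reverse_complement_pair_has_edge():
    seq = random_dna(100, np.random.default_rng(3))
    g = build_similarity_graph(_readset([seq, reverse_complement(seq)]))
    assert g.edge_set() == {(0, 1)}


def _mixed_reads(n_random=150, n_array=50, seed=0):
    rng = np.random.default_rng(seed)
    fam = SatFamilySpec(label="f", monomer=random_dna(33, rng, 0.65),
                        target_proportion=0.1, divergence=0.05)
    arr = build_tandem_array(fam, 200, seed=int(rng.integers(1 << 30)))
    array_reads = simulate_reads(arr, n_array * 100 / len(arr), 100,
                                 seed=int(rng.integers(1 << 30)))
    seqs = [random_dna(100, rng, 0.5) for _ in range(n_random)]
    seqs += array_reads.sequences[:n_array]
    return seqs


def test_graph_equals_brute_force_all_pairs():
    """Prefiltered graph is bit-identical to exhaustive all-shift alignment
    on a mix of random reads and tandem-array reads."""
    seqs = _mixed_reads()
    g = build_similarity_graph(_readset(seqs))
    expected = brute_force_edges(seqs, 0.90, 0.55)
    assert g.edge_set() == expected
    assert len(expected) > 100  # the array reads really do form a community


def test_raising_min_identity_never_adds_edges():
    seqs = _mixed_reads(n_random=50, n_array=40, seed=4)
    reads = _readset(seqs)
    loose = build_similarity_graph(reads, min_identity=0.85).edge_set()
    tight = build_similarity_graph(reads, min_identity=0.95).edge_set()
    assert tight <= loose


def test_graph_determinism():
    seqs = _mixed_reads(n_random=40, n_array=30, seed=8)
    g1 = build_similarity_graph(_readset(seqs))
    g2 = build_similarity_graph(_readset(seqs))
    assert g1.edge_set() == g2.edge_set()
    assert np.array_equal(g1.identity, g2.identity)


# ---------------------------------------------------------------------------
# clustering


def _clique_graph(n_nodes, cliques):
    ea, eb = [], []
    for members in cliques:
        for i in members:
            for j in members:
                if i < j:
                    ea.append(i)
                    eb.append(j)
    m = len(ea)
    return ReadGraph(
        read_ids=[f"r{i}" for i in range(n_nodes)],
        edge_a=np.array(ea), edge_b=np.array(eb),
        identity=np.ones(m), overlap=np.ones(m),
    )


def test_two_cliques_give_two_ranked_clusters():
    g = _clique_graph(1000, [range(0, 30), range(100, 120)])
    clusters = cluster_graph(g)
    assert [c.n_reads for c in clusters] == [30, 20]
    assert [c.cluster_id for c in clusters] == [1, 2]
    assert clusters[0].genome_proportion == pytest.approx(3.0)
    assert clusters[1].genome_proportion == pytest.approx(2.0)


def test_empty_edge_set_gives_no_clusters():
    g = _clique_graph(500, [])
    clusters = cluster_graph(g)
    assert clusters == []
    assert repeatome_fraction(clusters) == 0.0


def test_proportion_conservation_is_exact():
    g = _clique_graph(1000, [range(0, 30), range(100, 120), range(200, 210)])
    clusters = cluster_graph(g)
    in_clusters = sum(c.n_reads for c in clusters)
    singleton_prop = 100.0 * (1000 - in_clusters) / 1000
    total = sum(c.genome_proportion for c in clusters) + singleton_prop
    assert total == pytest.approx(100.0, abs=1e-12)


def test_repeatome_fraction_arithmetic_and_mito_exclusion():
    clusters = [
        Cluster(1, [f"r{i}" for i in range(440)], 44.0, 1000),
        Cluster(2, [f"m{i}" for i in range(100)], 10.0, 1000, is_mito=True),
    ]
    assert repeatome_fraction(clusters) == pytest.approx(44.0)


def _three_family_sample(seed=0):
    rng = np.random.default_rng(seed)
    fams = [
        SatFamilySpec(label=f"fam{L}", monomer=random_dna(L, rng, 0.65),
                      target_proportion=p, divergence=0.05)
        for L, p in ((33, 0.08), (79, 0.05), (51, 0.03))
    ]
    return SyntheticGenomeSpec(genome_length=600_000, sat_families=fams,
                               seed=int(rng.integers(1 << 30)))


def test_planted_three_families_recovered_within_one_point():
    spec = _three_family_sample(seed=5)
    genome, truth = build_genome(spec)
    reads = simulate_reads(genome, 0.5, 100, seed=6)
    clusters = cluster_reads(reads)
    planted = sorted(truth.family_proportion_pct.values(), reverse=True)
    recovered = [c.genome_proportion for c in clusters[:3]]
    for want, got in zip(planted, recovered):
        assert abs(want - got) <= 1.0, (planted, recovered)


def test_fast_path_matches_graph_path_partition():
    """cluster_reads (union-find shortcut) yields exactly the partition of
    the materialised graph."""
    spec = _three_family_sample(seed=11)
    genome, _ = build_genome(spec)
    reads = simulate_reads(genome, 0.3, 100, seed=12)
    reads = sample_reads(reads, 1200, seed=13)
    fast = cluster_reads(reads)
    slow = cluster_graph(build_similarity_graph(reads))
    fast_sets = sorted(frozenset(c.read_ids) for c in fast)
    slow_sets = sorted(frozenset(c.read_ids) for c in slow)
    assert fast_sets == slow_sets
    assert [c.genome_proportion for c in fast] == [c.genome_proportion for c in slow]


def test_low_density_component_split_by_modularity():
    # two 12-cliques joined by a single bridge edge: density is low and the
    # split recovers the cliques
    cliques = [list(range(0, 12)), list(range(12, 24))]
    g = _clique_graph(200, cliques)
    g.edge_a = np.append(g.edge_a, 11)
    g.edge_b = np.append(g.edge_b, 12)
    g.identity = np.append(g.identity, 0.9)
    g.overlap = np.append(g.overlap, 0.6)
    merged = cluster_graph(g, split_low_density=False)
    assert merged[0].n_reads == 24
    split = cluster_graph(g, split_low_density=True, density_threshold=0.8)
    assert sorted(c.n_reads for c in split) == [12, 12]
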