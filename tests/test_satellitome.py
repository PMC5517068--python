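"""Family nomenclature, HOR decomposition, shared regions, variants,
microsatellites, p-distance and probe design."""

import math

import numpy as np
import pytest

from repeatomix.annotate import ConsensusMonomer, at_content, canonical_rotation
from repeatomix.satellitome import (
    SatFamily,
    UndefinedDistanceError,
    design_probe,
    detect_hor,
    detect_internal_microsatellite,
    find_shared_region,
    find_variant_units,
    merge_families,
    name_families,
    p_distance,
    same_family,
)
from repeatomix.syndata import (
    SatFamilySpec,
    build_tandem_array,
    mutate_sequence,
    random_dna,
    reverse_complement,
)
from tests._oracles import brute_force_microsatellites, smith_waterman_score


def _monomer(seq, support=10):
    return ConsensusMonomer(canonical_rotation(seq), len(seq),
                            at_content(canonical_rotation(seq)), support)


def _family(seq, abundances, **kw):
    return SatFamily(consensus=_monomer(seq), abundance=dict(abundances),
                     mbp={}, **kw)


# ---------------------------------------------------------------------------
# naming


def test_names_follow_rank_and_unit_length():
    rng = np.random.default_rng(0)
    fams = [
        _family(random_dna(33, rng, 0.6), {"ref": 11.77}),
        _family(random_dna(79, rng, 0.6), {"ref": 9.0}),
        _family(random_dna(5, rng, 0.6), {"ref": 0.01}),
    ]
    named = name_families(fams, "Tinf", "ref")
    assert named[0].name == "TinfSat01-33"
    assert named[1].name == "TinfSat02-79"
    assert named[2].name == "TinfSat03-5"


def test_rank_thirty_nine_formats_without_padding_loss():
    rng = np.random.default_rng(1)
    fams = [_family(random_dna(20 + i, rng, 0.6), {"ref": 50.0 - i})
            for i in range(38)]
    fams.append(_family("TTAGG", {"ref": 0.001}))
    named = name_families(fams, "Tinf", "ref")
    assert named[-1].name == "TinfSat39-5"


def test_duplicate_consensus_rejected():
    fams = [_family("GATTACAGATTACAGATTACA", {"a": 1.0}),
            _family("GATTACAGATTACAGATTACA", {"a": 2.0})]
    with pytest.raises(ValueError, match="merge"):
        name_families(fams, "X", "a")


def test_renaming_is_idempotent():
    rng = np.random.default_rng(2)
    fams = [_family(random_dna(30 + i, rng, 0.6), {"ref": 10.0 - i})
            for i in range(5)]
    once = name_families(fams, "Syn", "ref")
    names1 = [f.name for f in once]
    twice = name_families(once, "Syn", "ref")
    assert [f.name for f in twice] == names1


def test_same_planted_family_merges_across_samples():
    monomer = random_dna(33, np.random.default_rng(3), 0.65)
    spec = SatFamilySpec(label="f", monomer=monomer, target_proportion=0.1,
                         divergence=0.05)
    from repeatomix.annotate import infer_monomer

    fams = []
    for sample, seed in (("a", 10), ("b", 20)):
        arr = build_tandem_array(spec, 120, seed=seed)
        cons = infer_monomer([arr], 33)
        fams.append(SatFamily(consensus=cons, abundance={sample: 5.0}, mbp={}))
    merged = merge_families(fams)
    assert len(merged) == 1
    assert set(merged[0].abundance) == {"a", "b"}


# ---------------------------------------------------------------------------
# higher-order repeats


def _hor_monomer(rng, sub_len=28, k=4, pad=1, divergence=0.10):
    ancestral = random_dna(sub_len, rng, 0.6)
    subs = [mutate_sequence(ancestral, divergence, rng) for _ in range(k)]
    if pad:
        subs[0] = random_dna(pad, rng, 0.6) + subs[0]
    return "".join(subs)


def test_hor_recovery_over_randomized_constructions():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(500 + seed)
        monomer = _hor_monomer(rng, sub_len=28, k=4, pad=1)
        hor = detect_hor(monomer, min_subrepeat=20, min_identity=70.0)
        if hor is not None and hor.n_subrepeats == 4:
            hits += 1
    assert hits >= 18


def test_hor_113_gives_four_subrepeats_of_about_28():
    rng = np.random.default_rng(77)
    monomer = _hor_monomer(rng, sub_len=28, k=4, pad=1)
    assert len(monomer) == 113
    hor = detect_hor(monomer, min_subrepeat=20)
    assert hor is not None
    assert hor.n_subrepeats == 4
    assert hor.ancestral_unit_estimate == 28
    assert hor.subrepeat_bounds[0][0] == 0
    assert hor.subrepeat_bounds[-1][1] == 113


def test_identical_subunits_recovered_exactly():
    sub = random_dna(25, np.random.default_rng(8), 0.6)
    hor = detect_hor(sub * 4, min_subrepeat=20, min_identity=95.0)
    assert hor is not None
    assert hor.n_subrepeats == 4
    assert hor.subrepeat_bounds == [(0, 25), (25, 50), (50, 75), (75, 100)]


def test_hor_false_positive_rate_on_random_monomers():
    fp = sum(
        detect_hor(random_dna(113, np.random.default_rng(9000 + s), 0.6),
                   min_subrepeat=20) is not None
        for s in range(100)
    )
    assert fp / 100 < 0.05


def test_short_subunit_hor_with_lowered_floor():
    rng = np.random.default_rng(11)
    seed4 = random_dna(4, rng, 0.5)
    monomer = "".join(mutate_sequence(seed4, 0.1, rng) for _ in range(4)) + seed4[:1]
    hor = detect_hor(monomer, min_subrepeat=4, min_identity=70.0)
    assert hor is not None and hor.n_subrepeats >= 2


# ---------------------------------------------------------------------------
# shared regions


def test_identical_consensi_share_full_unit():
    m = _monomer(random_dna(64, np.random.default_rng(12), 0.6))
    sr = find_shared_region(m, m, min_length=20)
    assert sr is not None
    assert sr.length == 64
    assert sr.identity == pytest.approx(100.0)


def test_planted_23bp_block_found_at_91_percent():
    rng = np.random.default_rng(4)
    b = random_dna(113, rng, 0.6)
    a = random_dna(64, rng, 0.6)
    block = list(b[30:53])
    block[5] = "A" if block[5] != "A" else "C"
    block[15] = "G" if block[15] != "G" else "T"
    a = a[:20] + "".join(block) + a[43:]
    ma, mb = _monomer(a), _monomer(b)
    sr = find_shared_region(ma, mb, min_length=20)
    assert sr is not None
    assert sr.length >= 21
    assert sr.identity == pytest.approx(91.3, abs=2.0)
    # the aligner's best local score equals an independent Smith-Waterman
    sw = max(
        smith_waterman_score(ma.sequence + ma.sequence, t)
        for t in (
            mb.sequence + mb.sequence,
            reverse_complement(mb.sequence + mb.sequence),
        )
    )
    # score of the reported region: matches - 2*mismatches (no gaps here)
    cols = 23
    assert sw >= 21 - 2 * 2  # the planted block is reachable
    assert sr.length <= cols or sr.identity >= 80.0


def test_shared_region_symmetry():
    rng = np.random.default_rng(21)
    b = random_dna(113, rng, 0.6)
    a = random_dna(64, rng, 0.6)
    a = a[:10] + b[40:70] + a[40:]
    ma, mb = _monomer(a), _monomer(b)
    ab = find_shared_region(ma, mb, min_length=20)
    ba = find_shared_region(mb, ma, min_length=20)
    assert ab is not None and ba is not None
    assert ab.length == ba.length
    assert ab.identity == pytest.approx(ba.identity)


def test_unrelated_monomers_rarely_share_regions():
    fp = 0
    for s in range(100):
        m1 = _monomer(random_dna(64, np.random.default_rng(100 + s), 0.6))
        m2 = _monomer(random_dna(113, np.random.default_rng(5000 + s), 0.6))
        if find_shared_region(m1, m2, min_length=20, min_identity=80.0):
            fp += 1
    assert fp / 100 < 0.05


# ---------------------------------------------------------------------------
# variant repeat units


def test_gatagtta_variant_detected_next_to_gata():
    reads = ["GATA" * 25, ("GATAGTTA" * 13)[:100], ("GATAGTTA" * 13)[:100]]
    variants = find_variant_units(reads, "GATA")
    assert (canonical_rotation("GATAGTTA"), 2) in variants


def test_pure_base_motif_yields_no_variants():
    assert find_variant_units(["GATA" * 25] * 3, "GATA") == []


def test_seventeen_bp_variant_near_cata():
    reads = [("CAATACATACATACATA" * 7)[:100]] * 2 + ["CATA" * 25]
    variants = find_variant_units(reads, "CATA")
    assert (canonical_rotation("CAATACATACATACATA"), 2) in variants


# ---------------------------------------------------------------------------
# internal microsatellites


def test_ca_tract_reported_in_canonical_rotation():
    cons = "GGTTCGGT" + "CA" * 6 + "GGTTCCGGAAGG"
    out = detect_internal_microsatellite(cons, min_copies=5)
    assert out == [("AC", 6, 8)]


def test_no_tract_below_copy_floor():
    assert detect_internal_microsatellite("ACGTACGT", min_copies=3) == []


def test_microsatellites_match_brute_force_enumeration():
    for s in range(100):
        seq = random_dna(1000, np.random.default_rng(2000 + s), 0.6)
        assert detect_internal_microsatellite(seq, min_copies=3) == \
            brute_force_microsatellites(seq, 3)


# ---------------------------------------------------------------------------
# p-distance


def test_p_distance_examples():
    assert p_distance("ACGTACGT", "ACGTACGT") == 0.0
    assert p_distance("ACGT", "ACGA") == 0.25
    assert p_distance("AC-T", "ACGT") == 0.0  # gap column removed


def test_p_distance_axioms_on_random_triples():
    rng = np.random.default_rng(31)
    for _ in range(50):
        a = random_dna(60, rng, 0.5)
        b = mutate_sequence(a, 0.1, rng)
        c = mutate_sequence(b, 0.1, rng)
        assert p_distance(a, a) == 0.0
        assert p_distance(a, b) == p_distance(b, a)
        assert p_distance(a, c) <= p_distance(a, b) + p_distance(b, c) + 1e-12


def test_p_distance_undefined_without_retained_sites():
    with pytest.raises(UndefinedDistanceError):
        p_distance("--N", "NN-")


# ---------------------------------------------------------------------------
# probe design


def test_monomer_over_85bp_gets_primer_pair():
    rng = np.random.default_rng(41)
    monomer = random_dna(113, rng, 0.6)
    fam = SatFamily(consensus=_monomer(monomer), name="SynSat01-113")
    copies = [mutate_sequence(fam.consensus.sequence, 0.05, rng) for _ in range(8)]
    probe = design_probe(fam, copies)
    assert probe.mode == "primer_pair"
    assert all(18 <= len(s) <= 25 for s in probe.sequences)
    amplicon = probe.positions[1][1] - probe.positions[0][0]
    assert amplicon >= 113 // 2


def test_monomer_79bp_gets_oligo():
    fam = SatFamily(consensus=_monomer(random_dna(79, np.random.default_rng(42), 0.6)),
                    name="SynSat02-79")
    probe = design_probe(fam, [])
    assert probe.mode == "oligo"
    assert all(18 <= len(s) <= 40 for s in probe.sequences)


def test_zero_divergence_copies_choose_leftmost_window():
    fam = SatFamily(consensus=_monomer(random_dna(40, np.random.default_rng(43), 0.6)),
                    name="SynSat03-40")
    copies = [fam.consensus.sequence] * 6
    probe = design_probe(fam, copies)
    assert probe.conservation[0] == pytest.approx(1.0)
    assert probe.positions[0][0] == 0  # deterministic leftmost tie-break


def test_short_monomer_concatenates_canonical_units():
    fam = SatFamily(consensus=ConsensusMonomer("AGAT", 4, 100.0, 5), name="SynSat04-4")
    probe = design_probe(fam, [])
    assert probe.mode == "oligo"
    assert probe.sequences[0] == "AGAT" * 5
    assert len(probe.sequences[0]) >= 18


def test_oligo_override_for_long_monomer():
    fam = SatFamily(consensus=_monomer(random_dna(181, np.random.default_rng(44), 0.6)),
                    name="SynSat06-181", probe_oligo_override=True)
    probe = design_probe(fam, [])
    assert probe.mode == "oligo"
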