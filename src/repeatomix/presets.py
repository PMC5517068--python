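"""Ready-made synthetic genome specs emulating a two-lineage triatomine study.

The presets model two evolutionary lineages of a repeat-rich insect genome
that share one library of satellite DNA families (the "library hypothesis")
amplified to very different abundances in each lineage.  The category mix
follows the published repeatome composition of *Triatoma infestans*: an
Andean-like genome with ~44% repeats dominated by satDNA (~33%) and a
non-Andean-like genome with ~34% repeats (~25% satDNA), both with a 5-7%
transposon fraction split across LTR, non-LTR and DNA-transposon classes,
an rDNA tandem block, mitochondrial read contamination, and unique
background.

All library sequences are generated from a fixed internal seed so the two
lineages (and the bundled classification library) agree on family sequences
regardless of the user-facing simulation seed.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .syndata import (
    DispersedElementSpec,
    SatFamilySpec,
    SyntheticGenomeSpec,
    mutate_sequence,
    random_dna,
)

_LIBRARY_SEED = 104729  # fixed: the shared family library is part of the design


def _library_rng() -> np.random.Generator:
    return np.random.default_rng(_LIBRARY_SEED)


def _make_hor_monomer(rng: np.random.Generator, subunit_len: int, k: int, pad: int,
                      subunit_divergence: float = 0.10) -> tuple[str, list[str]]:
    """Build a monomer as k diverged copies of one ancestral subunit."""
    ancestral = random_dna(subunit_len, rng, at_fraction=0.62)
    subs = [mutate_sequence(ancestral, subunit_divergence, rng) for _ in range(k)]
    if pad:
        subs[0] = random_dna(pad, rng, at_fraction=0.62) + subs[0]
    return "".join(subs), subs


def satellite_library() -> dict[str, dict]:
    """The shared satellite family library (label -> template fields).

    Unit lengths span 4-1000 bp and A+T contents sit in the 55-81% range
    typical of insect satDNA.  The 4-bp families are the GATA and CATA
    simple-sequence satellites; the 1000-bp family carries an internal
    (CA)6-20 microsatellite; the 113-bp family is a higher-order repeat of
    four ~28-bp subrepeats.
    """
    rng = _library_rng()
    lib: dict[str, dict] = {}

    lib["sat33"] = {"monomer": random_dna(33, rng, 0.70)}
    lib["sat79"] = {"monomer": random_dna(79, rng, 0.65)}
    lib["sat4gata"] = {"monomer": "GATA"}
    monomer1000 = random_dna(1000, rng, 0.60)
    lib["sat1000"] = {"monomer": monomer1000, "microsat_insert": ("CA", 6, 20)}
    lib["sat4cata"] = {"monomer": "CATA"}
    lib["sat181"] = {"monomer": random_dna(181, rng, 0.66)}
    lib["sat10"] = {"monomer": random_dna(10, rng, 0.70)}
    lib["sat239"] = {"monomer": random_dna(239, rng, 0.58)}
    hor_monomer, hor_subs = _make_hor_monomer(rng, subunit_len=28, k=4, pad=1)
    lib["sat113hor"] = {"monomer": hor_monomer, "hor_subunits": hor_subs}
    lib["sat53"] = {"monomer": random_dna(53, rng, 0.72)}
    lib["sat85"] = {"monomer": random_dna(85, rng, 0.64)}
    lib["sat21"] = {"monomer": random_dna(21, rng, 0.76)}
    lib["sat5telo"] = {"monomer": "TTAGG"}  # insect telomeric repeat
    lib["sat64"] = {"monomer": random_dna(64, rng, 0.68)}
    return lib


# per-lineage genome proportions (%) for the shared families; the dominant
# family swaps between lineages and the Andean-like genome carries roughly
# twice the satDNA of the non-Andean-like one.
_ANDEAN_SAT_PCT = {
    "sat33": 11.77, "sat79": 9.03, "sat4gata": 4.59, "sat1000": 4.28,
    "sat4cata": 1.42, "sat181": 0.24, "sat10": 0.13, "sat239": 0.08,
    "sat113hor": 0.07, "sat53": 0.05, "sat85": 0.03, "sat21": 1.31,
}
_NON_ANDEAN_SAT_PCT = {
    "sat33": 3.55, "sat79": 10.03, "sat4gata": 4.46, "sat1000": 2.72,
    "sat4cata": 0.95, "sat181": 0.10, "sat10": 0.01, "sat239": 0.07,
    "sat113hor": 0.23, "sat53": 0.03, "sat85": 0.03, "sat21": 2.82,
    "sat5telo": 0.02, "sat64": 0.04,
}

# dispersed/TE composition (% of genome) per lineage
_ANDEAN_TE_PCT = {"non-LTR": 3.0, "DNA_TE": 1.0, "LTR": 1.0, "unclassified": 5.0}
_NON_ANDEAN_TE_PCT = {"non-LTR": 3.0, "DNA_TE": 3.0, "LTR": 1.0, "unclassified": 1.0}
_RDNA_PCT = 1.0
_MITO_CONTAMINATION = 0.02


def _te_elements() -> dict[str, list[tuple[str, str]]]:
    """Per-category element sequences (label, sequence) from the fixed library."""
    rng = np.random.default_rng(_LIBRARY_SEED + 1)
    return {
        "non-LTR": [
            ("LOA_like", random_dna(4000, rng, 0.60)),
            ("jockey_like", random_dna(3000, rng, 0.60)),
        ],
        "DNA_TE": [
            ("mariner_like", random_dna(1300, rng, 0.62)),
            ("helitron_like", random_dna(2000, rng, 0.60)),
        ],
        "LTR": [("gypsy_like", random_dna(5000, rng, 0.58))],
        "unclassified": [
            ("unk_repeat_1", random_dna(2000, rng, 0.60)),
            ("unk_repeat_2", random_dna(1500, rng, 0.60)),
        ],
    }


def _rdna_unit() -> str:
    rng = np.random.default_rng(_LIBRARY_SEED + 2)
    return random_dna(5000, rng, 0.48)


def mito_reference() -> str:
    """A fixed 15 kb mitochondrial-like reference sequence."""
    rng = np.random.default_rng(_LIBRARY_SEED + 3)
    return random_dna(15000, rng, 0.68)


def reference_library() -> list[tuple[str, str, str]]:
    """Classification library entries ``(name, category_tag, sequence)``.

    The tag follows the RepeatMasker-style header dialect
    ``>name#CATEGORY/Subfamily`` used by :mod:`repeatomix.annotate`.
    """
    entries = []
    for cat, elems in _te_elements().items():
        if cat == "unclassified":
            continue  # unclassified elements are, by construction, not in the library
        for label, seq in elems:
            sub = label.split("_")[0]
            entries.append((label, f"{cat}/{sub}", seq))
    entries.append(("rdna_unit", "rDNA/45S", _rdna_unit()))
    return entries


def _lineage_spec(
    genome_length: int,
    seed: int,
    sat_pct: dict[str, float],
    te_pct: dict[str, float],
    divergence: float,
    te_divergence: float,
    with_mito: bool,
) -> SyntheticGenomeSpec:
    lib = satellite_library()
    fams = []
    for label, pct in sat_pct.items():
        tpl = lib[label]
        fams.append(
            SatFamilySpec(
                label=label,
                monomer=tpl["monomer"],
                target_proportion=pct / 100.0,
                divergence=divergence,
                hor_subunits=tpl.get("hor_subunits"),
                microsat_insert=tpl.get("microsat_insert"),
            )
        )
    elements = []
    te_lib = _te_elements()
    for cat, total_pct in te_pct.items():
        elems = te_lib[cat]
        for label, seq in elems:
            frac = total_pct / 100.0 / len(elems)
            copies = max(1, round(frac * genome_length / len(seq)))
            elements.append(
                DispersedElementSpec(
                    label=label, sequence=seq, copy_count=copies,
                    divergence=te_divergence, category=cat,
                )
            )
    rdna = _rdna_unit()
    rdna_copies = max(2, round(_RDNA_PCT / 100.0 * genome_length / len(rdna)))
    return SyntheticGenomeSpec(
        genome_length=genome_length,
        sat_families=fams,
        dispersed_elements=elements,
        rdna_unit=(rdna, rdna_copies),
        mito_sequence=mito_reference() if with_mito else None,
        mito_contamination=_MITO_CONTAMINATION if with_mito else 0.0,
        at_bias_background=0.60,
        seed=seed,
    )


def andean_like_spec(
    genome_length: int = 2_000_000, seed: int = 0, divergence: float = 0.05,
    with_mito: bool = False,
) -> SyntheticGenomeSpec:
    """Andean-like genome: ~44% repeats, satDNA-dominated (~33%)."""
    return _lineage_spec(
        genome_length, seed, _ANDEAN_SAT_PCT, _ANDEAN_TE_PCT,
        divergence, 0.03, with_mito,
    )


def non_andean_like_spec(
    genome_length: int = 2_000_000, seed: int = 1, divergence: float = 0.05,
    with_mito: bool = False,
) -> SyntheticGenomeSpec:
    """Non-Andean-like genome: ~34% repeats, ~25% satDNA."""
    return _lineage_spec(
        genome_length, seed, _NON_ANDEAN_SAT_PCT, _NON_ANDEAN_TE_PCT,
        divergence, 0.03, with_mito,
    )


def single_family_spec(
    monomer_length: int,
    proportion_pct: float,
    genome_length: int = 2_000_000,
    seed: int = 0,
    divergence: float = 0.05,
    monomer: Optional[str] = None,
) -> SyntheticGenomeSpec:
    """One satellite family in unique background, for recovery experiments."""
    if monomer is None:
        rng = np.random.default_rng(_LIBRARY_SEED + monomer_length)
        monomer = random_dna(monomer_length, rng, 0.65)
    fam = SatFamilySpec(
        label=f"sat{monomer_length}",
        monomer=monomer,
        target_proportion=proportion_pct / 100.0,
        divergence=divergence,
    )
    return SyntheticGenomeSpec(
        genome_length=genome_length, sat_families=[fam], seed=seed,
    )
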