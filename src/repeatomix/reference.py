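"""Published reference quantification of the *Triatoma infestans* satellitome.

The Chagas-disease vector *T. infestans* comprises an Andean and a
non-Andean lineage whose haploid genomes differ by ~30% in size
(1.936 vs 1.487 Gbp), a difference driven almost entirely by satellite DNA.
This module bundles the published per-family Mbp quantification of the 11
FISH-mapped satDNA families together with the headline genome-level
numbers, as the worked reference dataset for the package's accounting and
statistics (Mbp conversion, fold changes, chi-square lineage comparison).

Location codes: A = autosomes, E = euchromatin, H = heterochromatin,
X = euchromatic X, X* = heterochromatic X (Andean), Y = Y chromosome.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: haploid genome sizes (bp)
GENOME_SIZE = {"andean": 1_936_000_000, "non_andean": 1_487_000_000}

#: total sequenced bp per sample and the samples' lineages
SEQUENCED_BP = {"uruguay": 2.4e9, "argentina": 1.9e9, "bolivia": 4.4e9}
SAMPLE_LINEAGE = {"uruguay": "non_andean", "argentina": "non_andean",
                  "bolivia": "andean"}

#: repeatome and satDNA fractions (% of genome) per lineage
REPEATOME_PCT = {"andean": 44.0, "non_andean": 34.0}
SATDNA_PCT = {"andean": 33.0, "non_andean": 25.0}

#: total satDNA per haploid genome (Mbp), all 42 families
SATDNA_TOTAL_MBP = {"andean": 630.78, "non_andean": 376.05}

#: non-repetitive fraction per haploid genome (Mbp)
NON_REPETITIVE_MBP = {"andean": 1081.92, "non_andean": 980.31}

#: diploid total of the three heterochromatin-associated families
#: (ranks 1-3), as published
HETEROCHROMATIN_TRIO_DIPLOID_MBP = {"andean": 984.95, "non_andean": 507.35}

#: dominant-family genome percentages per lineage
DOMINANT_FAMILY_PCT = {
    "andean": ("TinfSat01-33", 11.77),
    "non_andean": ("TinfSat02-79", 10.03),
}

#: family counts: characterized, found in both lineages
N_FAMILIES = 42
N_SHARED_FAMILIES = 34


def load_family_table() -> pd.DataFrame:
    """The 11 FISH-mapped families: Mbp per haploid genome per lineage and
    chromosomal location code, indexed by family name."""
    with resources.files("repeatomix.data").joinpath(
        "tinf_satdna_families.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df.set_index("family")


def sample_coverage(sample: str) -> float:
    """Sequencing depth of one sample: sequenced bp over the haploid genome
    size of its lineage."""
    return SEQUENCED_BP[sample] / GENOME_SIZE[SAMPLE_LINEAGE[sample]]
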