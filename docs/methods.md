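# Methods

`repeatomix` implements a comparative repeatome/satellitome workflow for
unassembled short reads: graph-based read clustering quantifies repeat
families as read percentages, cluster annotation identifies satellite DNA
and classifies transposons, and cross-sample accounting converts
abundances to Mbp per haploid genome and tests lineage differences. A
synthetic-genome generator with a full ground-truth manifest provides the
controlled conditions under which every stage is validated.

## Read clustering

### Similarity criterion

Two reads are similar when some **gapless overlap** (a diagonal of the
comparison matrix, over all shifts and both strands) aligns them at
identity ≥ `min_identity` over at least `min_overlap` of the shorter read.
Defaults are 0.90 and 0.55, the established defaults of graph-based repeat
clustering from low-coverage reads.

A gapless criterion (rather than a gapped local alignment) is a deliberate
design choice: the package's substitution-only mutation model makes
qualifying alignments gap-free by construction, the criterion is exactly
reproducible by a brute-force all-shift oracle (which the test suite
checks bit-exactly), and it admits a provably lossless k-mer prefilter.
For data with real indel variation the identity threshold absorbs small
indels only partially; this is a documented limitation, not a silent
approximation.

### Lossless prefilter

For a qualifying diagonal of overlap `ov` with at most
`m = floor((1-min_identity)*ov)` mismatches, pigeonhole guarantees an
exact match run of length `>= ceil((ov-m)/(m+1))` and at least
`(ov-m) - (m+1)(k-1)` shared k-mers *on that diagonal*. The prefilter
k-mer size is the largest k for which the run bound holds over every
admissible overlap (k = 8 at the default thresholds for 100-bp reads), and
candidate diagonals below the count bound are discarded without alignment.
Neither step can remove a qualifying pair.

### Components and the fast path

Clusters are connected components (a density-triggered greedy-modularity
split is available but off by default). `build_similarity_graph`
materialises the full edge list; `cluster_reads` computes the identical
partition with union-find, skipping verification of pairs already in one
component — a pure optimisation of connectivity, property-tested equal to
the graph path.

### Detection floor

Clusters are read communities; a community is only reported when it has at
least `max(5, 0.01% of analyzed reads)` members. The floor exists because
at the default clustering coverage (≤ 0.5×) unique-background reads
overlap **genomically** by chance: with read length R = 100 and join
window 2·(R − min_overlap·R) ≈ 90 bp, the probability that a background
read chains to a neighbour is `1 - exp(-rho*90)` ≈ 0.20 at 0.5×
(`rho` = reads per bp), so roughly 10% of background reads fall in chance
components of size ≥ 3 — but well under 1% in components of size ≥ 5.
Sub-floor communities and singletons are accounted as *below detection*
(with the non-repetitive fraction), never as repeats. Real pipelines at
higher read counts use the same 0.01% logic; the absolute 5-read leg
matters only for small analyzed sets.

## Annotation

* **Assembly.** A greedy overlap-layout step merges the cluster's reads at
  the longest exact-or-near-exact (≤ 8% mismatch) suffix/prefix overlap
  ≥ 40 bp, either orientation, with deterministic lexicographic
  tie-breaks. Only a representative subsample (60 evenly spaced reads) is
  assembled: downstream needs a representative contig, not a complete
  assembly.
* **Tandem periodicity.** Exact word matches (word 10) define self-dotplot
  diagonals; a contig is tandem when the spacings s, 2s, 3s of the modal
  spacing are supported (diagonals beyond the contig end are not demanded).
  For periods shorter than the word size a nucleotide autocorrelation
  fallback (lags 2–9, match fraction ≥ 0.60) covers simple repeats such as
  (GATA)n. The modal spacing is then refined: its divisors and low-order
  multiples are scored by **leave-one-out** window-vs-consensus identity
  and the smallest candidate within 0.01 of the best wins. The
  leave-one-out form matters: plain window-vs-consensus identity is biased
  upward when few windows exist, which would systematically report 2× the
  true unit on short contigs, and would let a higher-order repeat pass as
  its subrepeat.
* **Classification.** Priority: (1) rDNA or mitochondrial library hit,
  (2) satDNA by periodicity of the deepest contigs, (3) transposon
  category by best library hit (identity ≥ 0.75 over ≥ 0.5 coverage;
  coverage counts non-overlapping hit locations so tandem contigs of a
  library unit are fully covered), (4) unclassified. Library matching is
  local (edlib infix) against a user FASTA with RepeatMasker-style
  `name#CATEGORY/Subfamily` headers; no remote searches are ever made.
* **Consensus monomers.** Length-p windows are phased (rotation × strand)
  against a reference contig and majority-voted per column; ties break by
  fixed base order A<C<G<T and no IUPAC codes are emitted. Consensi are
  stored in canonical rotation (lexicographic minimum over both strands of
  all rotations) so the same family inferred in different samples is
  byte-identical. Monomer inference requires one contig spanning two
  periods and raises otherwise.

## Satellitome analyses

* **Nomenclature** follows `AbbrSatNN-L`: abbreviation, zero-padded rank
  by decreasing abundance in a designated reference sample, unit length.
  Cross-sample merging precedes naming; two consensi are the same family
  at ≥ 80% rotation-aware identity over the shorter unit.
* **HOR decomposition** searches k = L/min_subrepeat … 2 near-equal
  contiguous splits, refines boundaries by coordinate ascent on all-pairs
  mean edit identity, and accepts the largest k reaching 70% — with the
  ancestral unit estimated as round(L/k). False-positive rate on random
  113-mers is under 5% at defaults.
* **Shared regions** between families use the doubled-sequence trick on
  both monomers and a local alignment scored 1/−2 with gaps −4/−2; the
  harsh mismatch cost keeps the reported region a compact high-identity
  block instead of a noise-diluted chain. Reported length and coordinates
  are capped at one unit.
* **Variant units and microsatellites** are maximal perfect periodic
  tracts with primitive motifs; variants must share ≥ half their bases
  with a phase of the base motif's periodic extension without being a
  rotation of it. Both are checked against brute-force enumeration.
* **p-distance** uses pairwise deletion of gap/N columns and raises when
  no sites remain.
* **Probe design** follows the monomer-length rule: > 85 bp gives a PCR
  primer pair (two 18–25 bp maximal-conservation windows, one per strand,
  amplicon ≥ half the monomer); ≤ 85 bp (or a per-family oligo override,
  for cases like a 181-bp family probed directly) gives one or two 18–40 bp
  oligos; < 18 bp concatenates ≥ 3 canonical units. Conservation is mean
  per-column majority-base frequency — monotone equivalent to entropy for
  this ranking. Tm is Wallace rule below 14 bp, GC formula above.

## Cross-sample statistics

Genome proportion `p` (% of analyzed reads) converts to absolute abundance
as `Mbp = p/100 · G/10^6` with G the haploid genome size. Per-category
accounting sums cluster proportions; the non-repetitive remainder closes
the identity to 100% exactly before any rounding.

The lineage comparison is a 2×2 chi-square of independence per category,
`[[category Mbp, rest-of-genome Mbp]]` for each sample, closed form
`N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))`, df = 1, Yates correction off,
α = 0.001. Treating Mbp as counts makes the statistic scale with the
chosen unit — the unit and α are config-exposed and every report carries a
sensitivity note. A zero marginal raises a degenerate-table error.

The combined run pools equal-sized subsamples of all samples and clusters
jointly: a family far below one sample's separate detection floor is still
detected when ≥ 10 of its reads (configurable) join the other sample's
cluster. Families present only via the combined run are flagged as below
the abundance floor (0.1% default) in shared/exclusive partitions.
Fold changes are Mbp ratios; zero denominators are reported as flagged
infinities.

## Synthetic genomes and reads

The generator emulates a two-lineage repeat-rich insect genome:

* satellite families with unit lengths 4–1000 bp and A+T 55–81%, placed
  as one contiguous array per family (satellites are locally tandem);
  per-copy divergence defaults to 5% — the data give no within-family
  divergence estimate, so this is a configurable stand-in for a young,
  homogenised family;
* one family built as a higher-order repeat (four ~28-bp subrepeats) and
  one carrying an internal perfect (CA)6–20 microsatellite whose copy
  number varies per monomer copy;
* dispersed LTR/non-LTR/DNA-transposon-like elements at ~5–7% of the
  genome, copy divergence 3% (young elements; pairwise read identity
  (1−d)² + d²/3 must clear the 0.90 clustering threshold for a family to
  cohere, which bounds realistic d below ~5%);
* an rDNA tandem block, optional mitochondrial read contamination (2%),
  and i.i.d. unique background with configurable A+T bias (0.60);
* uniform single- or paired-end reads, count = round(coverage·G/R), both
  strands, sequencing-error rate 0 by default (thresholds absorb planted
  divergence).

Mutation is per-site substitution to one of the three alternatives with
equal probability; **no indels** by default, keeping unit lengths exact.
Placement interleaves shuffled repeat pieces with multinomially split
background gaps, so pieces never overlap and the realized genome length is
exact; the ground truth records realized (integer-rounded) proportions and
0-based half-open coordinates, and category bp + background bp equals the
genome length exactly.

What the generator does **not** model — and what passing tests therefore
do not demonstrate about real data: indel and length variation within
satellite arrays, nested/fragmented transposon insertions, GC-dependent
coverage bias, sequencing error profiles, PCR duplicates, and between-array
divergence structure (each family is one array). Recovery results on real
libraries will degrade with divergence above ~8% pairwise and with heavy
indel content.

The Andean-like preset plants 44% repeats (satDNA 33% across 12 families
led by a 33-bp family at 11.77%, transposon classes 5%, rDNA 1%,
undetermined 5%); the non-Andean-like preset plants 34% (satDNA 25% led by
a 79-bp family at 10.03%). Family sequences come from a fixed internal
seed so both lineages share one library regardless of the simulation seed.

## Problem sizes and determinism

Validation runs use 2 Mbp genomes at 0.5× (10,000 reads) for
dominant-family recovery and a 5 Mbp Andean-like genome at 0.5×
(25,000 reads) for repeatome-fraction recovery; the test suite uses
0.15–3 Mbp genomes. These sizes put per-family read counts far above the
detection floor while keeping runs reproducible on one CPU in minutes.
All randomness flows from named seeds (spawned per stage from one master
seed recorded in the run manifest); identical config + seed reproduces
byte-identical FASTA/FASTQ/TSV outputs, which the manifest's checksums
make checkable.

## Known limitations

* Monomers longer than the assembled contig span (e.g. 1000 bp units at
  very low coverage) may be detected as repeat clusters but not
  satellite-classified without a library entry; their abundance is still
  counted (as unclassified).
* The HOR search assumes near-equal subrepeat lengths; strongly unequal
  decompositions are found only through boundary refinement.
* The chi-square on Mbp "counts" is the field's printed-table convention,
  not a read-count test; its absolute statistic has no sampling
  interpretation and should be read comparatively.
* Combined-run family flags depend on consensus matching between the joint
  cluster and per-sample families; families whose joint cluster yields no
  monomer are not flagged.
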