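"""End-to-end orchestration: per-sample clustering, annotation, satellite
family building, combined run and cross-sample comparison.

The workflow mirrors how a comparative satellitome study is run: each
sample is clustered separately (after mitochondrial read removal), clusters
are annotated and satellite consensus monomers inferred, families are
merged across samples and named by abundance rank in a designated reference
sample, a combined pooled run recovers shared families below the per-sample
detection floor, and category profiles of the samples are compared by
chi-square.  Every stage draws its randomness from seeds spawned off the
single master seed recorded in the manifest, so identical config + seed
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .annotate import (
    LibraryEntry,
    assemble_cluster_contigs,
    classify_cluster,
    infer_monomer,
    tandem_periodicity,
    InsufficientSpanError,
)
from .clustering import (
    Cluster,
    SampleSpec,
    cluster_reads,
    filter_mitochondrial,
    repeatome_fraction,
    sample_reads,
)
from .compare import category_totals, combined_analysis, compare_profiles, proportion_to_mbp
from .io import (
    clusters_table,
    export_table1,
    membership_table,
    read_repeat_library,
    read_sequences,
    write_fasta,
)
from .satellitome import SatFamily, detect_hor, merge_families, name_families, same_family
from .syndata import ReadSet

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class SampleConfig:
    sample_id: str
    lineage: str
    genome_size: int
    reads: Optional[ReadSet] = None
    read_paths: list[str] = field(default_factory=list)

    def load_reads(self) -> ReadSet:
        if self.reads is not None:
            return self.reads
        if not self.read_paths:
            raise ValueError(f"sample {self.sample_id}: no reads configured")
        parts = [read_sequences(p) for p in self.read_paths]
        merged = parts[0]
        for extra in parts[1:]:
            merged.ids += extra.ids
            merged.sequences += extra.sequences
            merged.mates += [None] * len(extra.ids)
        return merged


@dataclass
class RunConfig:
    """Validated configuration for one end-to-end run."""

    samples: list[SampleConfig]
    out_dir: str
    seed: int = 0
    sample_target: Optional[int] = None
    min_identity: float = 0.90
    min_overlap: float = 0.55
    word_size: int = 10
    min_diagonals: int = 3
    hor_min_identity: float = 70.0
    hor_min_subrepeat: int = 10
    abundance_floor_pct: float = 0.1
    library_min_identity: float = 0.75
    library_min_cover: float = 0.50
    min_cluster_size: Optional[int] = None
    max_annotated_clusters: int = 30
    mito_sequence: Optional[str] = None
    mito_fasta: Optional[str] = None
    library_fasta: Optional[str] = None
    library: list[LibraryEntry] = field(default_factory=list)
    reference_sample: Optional[str] = None
    abbrev: str = "Syn"
    combined: bool = True
    combined_min_reads: int = 10
    alpha: float = 0.001

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("at least one sample is required")
        for name, lo, hi in (
            ("min_identity", 0.5, 1.0),
            ("min_overlap", 0.1, 1.0),
            ("library_min_identity", 0.0, 1.0),
            ("library_min_cover", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.reference_sample is None:
            self.reference_sample = self.samples[0].sample_id

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = [SampleConfig(**s) for s in raw.pop("samples")]
        return cls(samples=samples, **raw)

    def effective_dict(self) -> dict:
        d = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("samples", "library", "mito_sequence")
        }
        d["samples"] = [
            {"sample_id": s.sample_id, "lineage": s.lineage,
             "genome_size": s.genome_size, "read_paths": s.read_paths}
            for s in self.samples
        ]
        return d


@dataclass
class RunManifest:
    version: str
    config_hash: str
    master_seed: int
    stage_seeds: dict[str, int]
    checksums: dict[str, str]
    started: float
    finished: float
    effective_config: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class SampleResult:
    sample: SampleSpec
    clusters: list[Cluster]
    n_analyzed: int
    n_mito_removed: int
    families: list[SatFamily]
    profile: object = None


def _annotate_sample(
    clusters: list[Cluster],
    reads: ReadSet,
    cfg: RunConfig,
    sample_id: str,
    genome_size: int,
) -> list[SatFamily]:
    """Assemble, classify and (for satellites) infer monomers for the top
    clusters of one sample; returns the per-sample satellite families."""
    families: list[SatFamily] = []
    for cl in clusters[: cfg.max_annotated_clusters]:
        cl.contigs = assemble_cluster_contigs(cl, reads)
        call = classify_cluster(
            cl,
            cfg.library,
            word=cfg.word_size,
            min_diagonals=cfg.min_diagonals,
            library_min_identity=cfg.library_min_identity,
            library_min_cover=cfg.library_min_cover,
        )
        cl.classification = call.category
        cl.subfamily = call.subfamily
        if call.category != "satDNA":
            continue
        period = None
        for rep in sorted(cl.contigs,
                          key=lambda c: (-c.depth, -len(c.sequence), c.sequence))[:3]:
            if len(rep.sequence) < 2 * cfg.word_size:
                continue
            is_tandem, period = tandem_periodicity(rep, cfg.word_size,
                                                   cfg.min_diagonals)
            if is_tandem and period is not None:
                break
            period = None
        if period is None:
            continue
        try:
            cons = infer_monomer([c.sequence for c in cl.contigs], period)
        except InsufficientSpanError:
            logger.info("cluster %d of %s: no contig spans two periods (%d bp)",
                        cl.cluster_id, sample_id, period)
            continue
        fam = SatFamily(
            consensus=cons,
            abundance={sample_id: cl.genome_proportion},
            mbp={sample_id: proportion_to_mbp(cl.genome_proportion, genome_size)},
        )
        if cons.unit_length >= 2 * cfg.hor_min_subrepeat:
            fam.hor = detect_hor(
                cons, min_subrepeat=cfg.hor_min_subrepeat,
                min_identity=cfg.hor_min_identity,
            )
        families.append(fam)
    return merge_families(families)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full workflow and write all artifacts to ``out_dir``.

    Any stage failure raises :class:`PipelineStageError` naming the stage;
    artifacts written before the failure are left in place.
    """
    started = time.time()
    os.makedirs(config.out_dir, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (1 << 31))
        for name, s in zip(
            ("subsample", "combined"), ss.spawn(2)
        )
    }
    checksums: dict[str, str] = {}

    def _emit(name: str, writer) -> None:
        path = os.path.join(config.out_dir, name)
        writer(path)
        checksums[name] = _sha256(path)

    stage = "configure"
    try:
        if config.library_fasta and not config.library:
            config.library = read_repeat_library(config.library_fasta)
        mito = config.mito_sequence
        if config.mito_fasta and mito is None:
            mito = "".join(read_sequences(config.mito_fasta).sequences)

        results: list[SampleResult] = []
        for si, sc in enumerate(config.samples):
            stage = f"load[{sc.sample_id}]"
            reads = sc.load_reads()
            stage = f"subsample[{sc.sample_id}]"
            if config.sample_target is not None:
                reads = sample_reads(reads, config.sample_target,
                                     stage_seeds["subsample"] + si)
            stage = f"mito_filter[{sc.sample_id}]"
            reads, n_removed = filter_mitochondrial(reads, mito)
            stage = f"cluster[{sc.sample_id}]"
            clusters = cluster_reads(
                reads,
                min_identity=config.min_identity,
                min_overlap=config.min_overlap,
                min_cluster_size=config.min_cluster_size,
            )
            stage = f"annotate[{sc.sample_id}]"
            fams = _annotate_sample(clusters, reads, config, sc.sample_id,
                                    sc.genome_size)
            spec = SampleSpec(sc.sample_id, sc.lineage, sc.genome_size, reads)
            results.append(
                SampleResult(
                    sample=spec, clusters=clusters, n_analyzed=len(reads),
                    n_mito_removed=n_removed, families=fams,
                )
            )
            _emit(f"clusters_{sc.sample_id}.tsv",
                  lambda p, c=clusters: clusters_table(c).to_csv(p, sep="\t", index=False))
            _emit(f"membership_{sc.sample_id}.tsv",
                  lambda p, c=clusters: membership_table(c).to_csv(p, sep="\t", index=False))

        stage = "merge_families"
        all_fams = merge_families(
            [f for r in results for f in r.families]
        )
        named = name_families(all_fams, config.abbrev, config.reference_sample)

        stage = "combined"
        if config.combined and len(results) >= 2:
            combined = combined_analysis(
                [r.sample for r in results],
                seed=stage_seeds["combined"],
                min_identity=config.min_identity,
                min_overlap=config.min_overlap,
                min_reads_detect=config.combined_min_reads,
            )
            pooled_reads = ReadSet(
                ids=[f"{r.sample.sample_id}::{rid}" for r in results
                     for rid in r.sample.reads.ids],
                sequences=[s for r in results for s in r.sample.reads.sequences],
            )
            for cl in combined.clusters[: config.max_annotated_clusters]:
                cl.contigs = assemble_cluster_contigs(cl, pooled_reads)
                rep = max(cl.contigs, key=lambda c: (c.depth, len(c.sequence)))
                if len(rep.sequence) < 2 * config.word_size:
                    continue
                is_tandem, period = tandem_periodicity(
                    rep, config.word_size, config.min_diagonals
                )
                if not is_tandem or period is None:
                    continue
                try:
                    cons = infer_monomer([c.sequence for c in cl.contigs], period)
                except InsufficientSpanError:
                    continue
                for fam in named:
                    if same_family(fam.consensus, cons):
                        for r in results:
                            sid = r.sample.sample_id
                            if (
                                fam.abundance.get(sid, 0.0) == 0
                                and combined.detected_in(cl.cluster_id, sid)
                            ):
                                fam.combined_only.add(sid)
                        break

        stage = "profiles"
        for r in results:
            r.profile = category_totals(r.clusters, r.sample)
        sample_ids = [r.sample.sample_id for r in results]

        stage = "compare"
        report = None
        if len(results) >= 2:
            report = compare_profiles(
                results[0].profile, results[1].profile, named, alpha=config.alpha
            )

        stage = "emit"
        _emit("families.tsv",
              lambda p: export_table1(named, sample_ids, p))
        _emit("consensus.fasta",
              lambda p: write_fasta(
                  [(f.name, f.consensus.sequence) for f in named], p))
        _emit("profiles.json",
              lambda p: open(p, "w").write(json.dumps(
                  {r.sample.sample_id: r.profile.to_dict() for r in results},
                  indent=2)))
        if report is not None:
            _emit("comparison.json",
                  lambda p: open(p, "w").write(json.dumps(report.to_dict(), indent=2)))
        summary = {
            "n_samples": len(results),
            "per_sample": {
                r.sample.sample_id: {
                    "n_analyzed": r.n_analyzed,
                    "n_mito_removed": r.n_mito_removed,
                    "n_clusters": len(r.clusters),
                    "repeatome_pct": repeatome_fraction(r.clusters),
                }
                for r in results
            },
            "n_families": len(named),
        }
        _emit("summary.json",
              lambda p: open(p, "w").write(json.dumps(summary, indent=2)))
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError(stage, exc) from exc

    cfg_dict = config.effective_dict()
    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        master_seed=config.seed,
        stage_seeds=stage_seeds,
        checksums=checksums,
        started=started,
        finished=time.time(),
        effective_config=cfg_dict,
    )
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        fh.write(manifest.to_json())
    logger.info("effective config: %s", json.dumps(cfg_dict, sort_keys=True))
    return manifest
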