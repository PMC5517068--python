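"""File formats: FASTA/FASTQ read sets, repeat libraries, result tables.

Sequence parsing goes through Bio.SeqIO; repeat libraries use the
RepeatMasker-style header dialect ``>name#CATEGORY/Subfamily``.  Tables are
written as TSV through pandas so they round-trip losslessly.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .annotate import LibraryEntry
from .satellitome import SatFamily
from .syndata import ReadSet


class ParseError(ValueError):
    pass


def _guess_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".fq", ".fastq"):
        return "fastq"
    if ext in (".fa", ".fasta", ".fna"):
        return "fasta"
    raise ParseError(f"cannot guess sequence format from {path!r}")


def read_sequences(
    path: str, format: Optional[str] = None, paired: bool = False
) -> ReadSet:
    """Read a FASTA/FASTQ file into a :class:`ReadSet`.

    Sequences are upper-cased; reads containing N are retained.  With
    ``paired`` set, mates are resolved by the ``/1`` ``/2`` id suffix
    convention.
    """
    fmt = format or _guess_format(path)
    ids: list[str] = []
    seqs: list[str] = []
    try:
        for rec in SeqIO.parse(path, fmt):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
    except ValueError as exc:
        raise ParseError(f"malformed {fmt} in {path}: {exc}") from exc
    if not ids:
        raise ParseError(f"no records parsed from {path}")

    mates: list[Optional[str]] = [None] * len(ids)
    if paired:
        index = {rid: i for i, rid in enumerate(ids)}
        for i, rid in enumerate(ids):
            if rid.endswith("/1") or rid.endswith("/2"):
                other = rid[:-1] + ("2" if rid.endswith("/1") else "1")
                if other in index:
                    mates[i] = other
    read_length = max((len(s) for s in seqs), default=0)
    return ReadSet(ids=ids, sequences=seqs, mates=mates, read_length=read_length)


def write_fasta(records: Sequence[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_reads(reads: ReadSet, path: str, format: Optional[str] = None,
                quality: int = 40) -> None:
    """Write a read set as FASTA or FASTQ (constant quality)."""
    fmt = format or _guess_format(path)
    if fmt == "fasta":
        write_fasta(list(zip(reads.ids, reads.sequences)), path)
        return
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for rid, seq in zip(reads.ids, reads.sequences):
            fh.write(f"@{rid}\n{seq}\n+\n{qchar * len(seq)}\n")


def read_repeat_library(path: str) -> list[LibraryEntry]:
    """Parse a labelled repeat library FASTA (``>name#CATEGORY/Subfamily``)."""
    entries = []
    for rec in SeqIO.parse(path, "fasta"):
        name, _, tag = rec.id.partition("#")
        category, _, subfamily = tag.partition("/")
        entries.append(
            LibraryEntry(
                name=name,
                category=category or "unclassified",
                subfamily=subfamily,
                sequence=str(rec.seq).upper(),
            )
        )
    return entries


def write_repeat_library(entries: Sequence[LibraryEntry | tuple], path: str) -> None:
    records = []
    for e in entries:
        if isinstance(e, LibraryEntry):
            tag = f"{e.category}/{e.subfamily}" if e.subfamily else e.category
            records.append((f"{e.name}#{tag}", e.sequence))
        else:
            name, tag, seq = e
            records.append((f"{name}#{tag}", seq))
    write_fasta(records, path)


def clusters_table(clusters) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "n_reads": c.n_reads,
                "proportion_pct": c.genome_proportion,
                "classification": c.classification,
                "subfamily": c.subfamily,
                "is_mito": c.is_mito,
            }
            for c in clusters
        ]
    )


def membership_table(clusters) -> pd.DataFrame:
    rows = []
    for c in clusters:
        rows.extend({"read_id": r, "cluster_id": c.cluster_id} for r in c.read_ids)
    return pd.DataFrame(rows)


def export_table1(
    families: Sequence[SatFamily],
    samples: Sequence[str],
    path: Optional[str] = None,
) -> pd.DataFrame:
    """Family quantification table: per-sample Mbp plus location code, with
    a TOTAL row holding the exact column sums."""
    rows = []
    for fam in sorted(families, key=lambda f: f.rank or 1 << 30):
        row = {"family": fam.name or fam.consensus.sequence[:12]}
        for s in samples:
            row[f"{s}_mbp"] = fam.mbp.get(s, 0.0)
        row["location"] = fam.location_annotation
        rows.append(row)
    total = {"family": "TOTAL", "location": ""}
    for s in samples:
        total[f"{s}_mbp"] = sum(r[f"{s}_mbp"] for r in rows)
    rows.append(total)
    df = pd.DataFrame(rows)
    if path:
        df.to_csv(path, sep="\t", index=False)
    return df


def read_table1(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
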