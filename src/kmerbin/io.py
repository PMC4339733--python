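"""Reading shotgun reads from FASTA/FASTQ (plain or gzip)."""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .kmers import ReadSet

_FASTQ_SUFFIXES = {".fastq", ".fq"}


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _format_of(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    core = suffixes[-2] if suffixes and suffixes[-1] == ".gz" and len(suffixes) > 1 else (
        suffixes[-1] if suffixes else ""
    )
    return "fastq" if core in _FASTQ_SUFFIXES else "fasta"


def _parse(path: Path) -> tuple[list[str], list[str]]:
    ids: list[str] = []
    seqs: list[str] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, _format_of(path)):
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"empty sequence for read {rec.id!r} in {path}")
            ids.append(rec.id)
            seqs.append(seq)
    if not ids:
        raise ValueError(f"no reads parsed from {path}")
    return ids, seqs


def load_reads(
    paths: list[str | Path],
    read_type: str = "single",
    interleaved: bool = False,
) -> ReadSet:
    """Load a read set from one or two FASTA/FASTQ files.

    Paired-end input is either two synchronized mate files (mate order
    preserved) or one interleaved file; in both cases mates end up
    adjacent (2i, 2i+1) in the returned ReadSet.
    """
    paths = [Path(p) for p in paths]
    if read_type not in ("single", "paired"):
        raise ValueError("read_type must be 'single' or 'paired'")
    if read_type == "single":
        if len(paths) != 1:
            raise ValueError("single-end input takes exactly one file")
        ids, seqs = _parse(paths[0])
        return ReadSet(ids=ids, seqs=seqs, read_type="single")

    if len(paths) == 2:
        ids1, seqs1 = _parse(paths[0])
        ids2, seqs2 = _parse(paths[1])
        if len(ids1) != len(ids2):
            raise ValueError(
                f"mate-count mismatch: {len(ids1)} reads in {paths[0]} vs "
                f"{len(ids2)} in {paths[1]}"
            )
        ids, seqs = [], []
        for i1, s1, i2, s2 in zip(ids1, seqs1, ids2, seqs2):
            if i1 == i2:  # disambiguate identical mate names
                i1, i2 = f"{i1}/1", f"{i2}/2"
            ids.extend([i1, i2])
            seqs.extend([s1, s2])
    elif len(paths) == 1 and interleaved:
        ids, seqs = _parse(paths[0])
        if len(ids) % 2:
            raise ValueError("interleaved paired file has an odd number of reads")
    else:
        raise ValueError("paired-end input takes two files, or one with interleaved=True")
    return ReadSet.from_sequences(seqs, ids=ids, paired=True)
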