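"""File helpers: FASTA/FASTQ round-trips and deterministic gzip output."""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def open_text(path: str | Path, mode: str = "rt"):
    """Open plain or gzipped text transparently.

    Writes with a fixed gzip mtime of 0 so that identical content yields
    byte-identical files (required by the simulator's determinism contract).
    """
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            raw = gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
            return _io.TextIOWrapper(raw, encoding="ascii", newline="\n")
        return gzip.open(path, "rt")
    return open(path, mode)


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open_text(path, "wt") as fh:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
            fh,
            "fasta",
        )


def read_fasta(path: str | Path) -> dict[str, str]:
    with open_text(path, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    """Write (id, sequence, quality-string) triples as FASTQ."""
    with open_text(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with open_text(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield rec.id, str(rec.seq).upper(), qual
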