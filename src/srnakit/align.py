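"""Best-stratum ungapped alignment and the length-dependent mismatch filter.

A read is placed at every genomic offset (both strands) whose Hamming
distance equals the minimum achievable distance, provided that minimum
is at most `max_mismatches` (default 3). Candidate positions come from
a pigeonhole seed table: a read is split into four contiguous segments,
so any placement with <= 3 mismatches matches at least one segment
exactly; seeds are the k-prefixes of the segments with k = len(read)//4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import revcomp
from .preprocess import CollapsedRead

VALID_CHARS = set("ACGTN")


@dataclass(frozen=True, order=True)
class Alignment:
    chrom: str
    start: int  # 0-based
    strand: str
    sequence: str
    count: int
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)

    @property
    def pos5(self) -> int:
        """Genomic position of the read's 5' nucleotide."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class StratumPolicy:
    max_mismatches: int = 3


@dataclass(frozen=True)
class LengthMismatchRule:
    """Maximum mismatches allowed per read-length bin.

    Default bins: 16-17 nt -> 0, 18-19 -> 1, 20-24 -> 2, >= 25 -> 3.
    """

    bins: tuple = ((16, 17, 0), (18, 19, 1), (20, 24, 2), (25, None, 3))

    def max_mismatches(self, length: int) -> int:
        if length < self.bins[0][0]:
            raise ValueError(f"read length {length} below filter domain "
                             f"(should have been removed upstream)")
        for lo, hi, mm in self.bins:
            if length >= lo and (hi is None or length <= hi):
                return mm
        raise AssertionError("bins do not partition lengths")

    def accepts(self, length: int, mismatches: int) -> bool:
        return mismatches <= self.max_mismatches(length)


class GenomeIndex:
    """Seed lookup tables over the forward genome, built lazily per k."""

    def __init__(self, chroms: dict[str, str]):
        self.chrom_names = sorted(chroms)
        self.seqs = {c: chroms[c].upper() for c in self.chrom_names}
        self.arrays = {
            c: np.frombuffer(self.seqs[c].encode("ascii"), dtype=np.uint8)
            for c in self.chrom_names
        }
        self._kmer_tables: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _table(self, k: int) -> dict[str, list[tuple[str, int]]]:
        table = self._kmer_tables.get(k)
        if table is None:
            table = {}
            for chrom in self.chrom_names:
                seq = self.seqs[chrom]
                for pos in range(len(seq) - k + 1):
                    table.setdefault(seq[pos:pos + k], []).append((chrom, pos))
            self._kmer_tables[k] = table
        return table

    def seed_hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._table(len(kmer)).get(kmer, [])


def align_read(sequence: str, index: GenomeIndex,
               policy: StratumPolicy = StratumPolicy()) -> list[Alignment]:
    """All minimal-mismatch placements of `sequence`, both strands.

    Returns an empty list when no placement has <= policy.max_mismatches
    mismatches. Output is sorted by (chrom, start, strand).
    """
    seq = sequence.upper()
    if set(seq) - VALID_CHARS:
        raise ValueError(f"sequence contains non-ACGTN symbols: {sequence!r}")
    L = len(seq)
    k = L // 4
    if k < 1:
        raise ValueError("sequence too short to align")
    hits: list[tuple[int, str, int, str]] = []  # (mm, chrom, start, strand)
    best_mm = policy.max_mismatches
    boundaries = [0, k, 2 * k, 3 * k]
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        qarr = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
        candidates: dict[str, set[int]] = {}
        for b in boundaries:
            kmer = query[b:b + k]
            if "N" in kmer:
                continue
            for chrom, pos in index.seed_hits(kmer):
                start = pos - b
                if 0 <= start <= len(index.seqs[chrom]) - L:
                    candidates.setdefault(chrom, set()).add(start)
        for chrom, starts in candidates.items():
            arr = index.arrays[chrom]
            starts_arr = np.fromiter(starts, dtype=np.int64)
            windows = arr[starts_arr[:, None] + np.arange(L)]
            mms = (windows != qarr).sum(axis=1)
            for start, mm in zip(starts_arr, mms):
                if mm <= best_mm:
                    hits.append((int(mm), chrom, int(start), strand))
    if not hits:
        return []
    stratum = min(h[0] for h in hits)
    placements = sorted((chrom, start, strand, mm)
                        for mm, chrom, start, strand in hits if mm == stratum)
    return [Alignment(chrom, start, strand, seq, 1, mm)
            for chrom, start, strand, mm in placements]


@dataclass
class MappingSummary:
    total_reads: int = 0  # distinct collapsed sequences
    total_count: int = 0
    mapped_reads: int = 0
    mapped_count: int = 0
    filtered_out: int = 0  # sequences whose whole stratum failed the filter

    @property
    def mapped_fraction(self) -> float:
        return self.mapped_count / self.total_count if self.total_count else 0.0


@dataclass
class ReadAlignments:
    """Surviving stratum alignments for one collapsed read."""

    sequence: str
    count: int
    alignments: list[Alignment] = field(default_factory=list)

    @property
    def n_best(self) -> int:
        return len(self.alignments)


def align_library(collapsed: list[CollapsedRead], index: GenomeIndex,
                  policy: StratumPolicy = StratumPolicy(),
                  rule: LengthMismatchRule | None = LengthMismatchRule(),
                  cache: dict | None = None):
    """Align a collapsed library and apply the length/mismatch filter.

    The stratum is computed first; the filter is then applied to the
    stratum members (a read whose whole stratum fails counts as
    unmapped). Returns (list[ReadAlignments] for mapped reads, summary).
    A shared `cache` dict may be passed to reuse alignments of sequences
    seen in other libraries.
    """
    summary = MappingSummary()
    out: list[ReadAlignments] = []
    for rec in collapsed:
        summary.total_reads += 1
        summary.total_count += rec.count
        if cache is not None and rec.sequence in cache:
            placements = cache[rec.sequence]
        else:
            placements = align_read(rec.sequence, index, policy)
            if cache is not None:
                cache[rec.sequence] = placements
        if rule is not None and placements:
            kept = [a for a in placements
                    if rule.accepts(len(rec.sequence), a.mismatches)]
            if not kept and placements:
                summary.filtered_out += 1
            placements = kept
        if placements:
            summary.mapped_reads += 1
            summary.mapped_count += rec.count
            out.append(ReadAlignments(
                rec.sequence, rec.count,
                [Alignment(a.chrom, a.start, a.strand, a.sequence, rec.count,
                           a.mismatches) for a in placements]))
    return out, summary


def write_alignments_tsv(path: str | Path, aligned: list[ReadAlignments]) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\tchrom\tstart0\tstrand\tmm\tn_best\n")
        for ra in aligned:
            for a in ra.alignments:
                fh.write(f"{ra.sequence}\t{ra.count}\t{a.chrom}\t{a.start}\t"
                         f"{a.strand}\t{a.mismatches}\t{ra.n_best}\n")


def read_alignments_tsv(path: str | Path) -> list[ReadAlignments]:
    by_seq: dict[str, ReadAlignments] = {}
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("sequence")
        for line in fh:
            seq, count, chrom, start, strand, mm, _n = line.rstrip("\n").split("\t")
            ra = by_seq.setdefault(seq, ReadAlignments(seq, int(count)))
            ra.alignments.append(
                Alignment(chrom, int(start), strand, seq, int(count), int(mm)))
    return list(by_seq.values())


def write_sam(path: str | Path, aligned: list[ReadAlignments],
              index: GenomeIndex) -> None:
    """SAM output (1-based, NM tag); sequences on '-' are reverse-complemented."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom in index.chrom_names:
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(index.seqs[chrom])}\n")
        for i, ra in enumerate(aligned, start=1):
            name = f"seq{i}_x{ra.count}"
            for a in ra.alignments:
                flag = 0 if a.strand == "+" else 16
                seq = ra.sequence if a.strand == "+" else revcomp(ra.sequence)
                fh.write(f"{name}\t{flag}\t{a.chrom}\t{a.start + 1}\t255\t"
                         f"{len(ra.sequence)}M\t*\t0\t0\t{seq}\t*\t"
                         f"NM:i:{a.mismatches}\n")
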