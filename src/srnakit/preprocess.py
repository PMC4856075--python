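"""Adapter trimming, barcode demultiplexing, length filtering, collapsing.

Adapter-match contract: an adapter match may contain substitutions and
indels; a candidate matching `k` adapter bases is accepted when its
error count is at most floor(error_rate * k). Among acceptable
candidates the best is the one with fewest errors, then the most adapter
bases matched, then the leftmost position. `N` never matches anything.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .io import open_text

_INF = 10 ** 9


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError("empty read sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality length does not match sequence length")


@dataclass(frozen=True)
class TrimSpec:
    adapter_5p: str = ""
    adapter_3p: str = "GATCGTTCGGACTGTAGATC"
    error_rate: float = 0.25
    min_length: int = 16
    min_overlap: int = 3

    def __post_init__(self):
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass(frozen=True)
class TrimmedRead:
    read: RawRead | None  # None when trimming consumed the whole read
    trimmed_5p: bool
    trimmed_3p: bool
    reason: str | None = None

    @property
    def untrimmed(self) -> bool:
        return not (self.trimmed_5p or self.trimmed_3p)


@dataclass(frozen=True)
class CollapsedRead:
    sequence: str
    count: int
    library: str

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")


def _mismatch(a: str, b: str) -> int:
    return 1 if (a != b or a == "N" or b == "N") else 0


def _semiglobal_candidates(seq: str, adapter: str):
    """Edit-distance DP of `adapter` against `seq` with a free start in seq.

    Yields candidates (errors, matched_adapter_len, start, end) where
    [start, end) is the matched span in `seq`. Includes full-adapter
    matches ending anywhere and adapter-prefix matches ending at the end
    of `seq` (adapter running off the 3' end).
    """
    n, m = len(seq), len(adapter)
    # dp rows over adapter index; free start: row 0 cost is 0 at every j
    prev = [0] * (n + 1)
    prev_start = list(range(n + 1))
    rows = [(prev, prev_start)]
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        cur_start = [0] * (n + 1)
        for j in range(1, n + 1):
            diag = prev[j - 1] + _mismatch(seq[j - 1], adapter[i - 1])
            up = prev[j] + 1  # deletion in read (adapter base unmatched)
            left = cur[j - 1] + 1  # insertion in read
            best = min(diag, up, left)
            cur[j] = best
            if best == diag:
                cur_start[j] = prev_start[j - 1]
            elif best == up:
                cur_start[j] = prev_start[j]
            else:
                cur_start[j] = cur_start[j - 1]
        prev, prev_start = cur, cur_start
        rows.append((cur, cur_start))
    full, full_start = rows[m]
    for j in range(n + 1):
        yield full[j], m, full_start[j], j
    for i in range(1, m):
        row, row_start = rows[i]
        yield row[n], i, row_start[n], n


def _best_match(seq: str, adapter: str, error_rate: float, min_overlap: int):
    """Best acceptable adapter match in `seq`, or None.

    Score = adapter bases matched minus errors (so a long match with a
    few errors beats a short perfect one); ties resolve to fewer errors,
    then leftmost.
    """
    best = None
    for errors, matched, start, end in _semiglobal_candidates(seq, adapter):
        if matched < min_overlap or errors > int(error_rate * matched):
            continue
        key = (errors - matched, errors, start)
        if best is None or key < best[0]:
            best = (key, start, end)
    if best is None:
        return None
    return best[1], best[2]


def trim_read(read: RawRead, spec: TrimSpec) -> TrimmedRead:
    """Trim 5' and 3' adapters from one read.

    The 5' adapter (with anything before it) is removed when it matches
    near the read start; matching is done on the reversed sequences so
    that a partial adapter overhanging the read's 5' end is found. The
    3' adapter and everything after it is removed at the best match.
    """
    seq = read.sequence
    qual = read.quality
    trimmed5 = trimmed3 = False

    if spec.adapter_5p:
        hit = _best_match(seq[::-1], spec.adapter_5p[::-1],
                          spec.error_rate, spec.min_overlap)
        if hit is not None:
            start_r, _end_r = hit
            cut = len(seq) - start_r  # adapter match ends here in forward coords
            seq = seq[cut:]
            qual = qual[cut:] if qual else None
            trimmed5 = True

    if spec.adapter_3p and seq:
        hit = _best_match(seq, spec.adapter_3p, spec.error_rate, spec.min_overlap)
        if hit is not None:
            start, _end = hit
            seq = seq[:start]
            qual = qual[:start] if qual else None
            trimmed3 = True

    if not seq:
        return TrimmedRead(None, trimmed5, trimmed3, reason="empty_after_trimming")
    return TrimmedRead(RawRead(read.id, seq, qual), trimmed5, trimmed3)


@dataclass
class PreprocessSummary:
    input_reads: int = 0
    untrimmed: int = 0
    discarded_empty: int = 0
    undetermined: int = 0
    discarded_short: int = 0
    assigned: dict = field(default_factory=dict)  # library -> surviving reads

    def to_rows(self) -> list[tuple[str, int]]:
        rows = [("input_reads", self.input_reads),
                ("untrimmed", self.untrimmed),
                ("discarded_empty", self.discarded_empty),
                ("undetermined", self.undetermined),
                ("discarded_short", self.discarded_short)]
        rows += [(f"assigned:{lib}", n) for lib, n in sorted(self.assigned.items())]
        return rows


def trim_reads(reads: Iterable[RawRead], spec: TrimSpec,
               summary: PreprocessSummary | None = None,
               discard_untrimmed: bool = False) -> Iterator[RawRead]:
    """Trim a stream of reads; empty results are discarded with a count.

    Fast path: an exact full-adapter occurrence is always an optimal
    match (0 errors, maximal length), so the DP only runs when the
    adapters are not found verbatim.
    """
    for read in reads:
        if summary is not None:
            summary.input_reads += 1
        seq = read.sequence
        if spec.adapter_3p and not spec.adapter_5p:
            pos = seq.find(spec.adapter_3p)
            if pos >= 0:
                if pos == 0:
                    if summary is not None:
                        summary.discarded_empty += 1
                    continue
                yield RawRead(read.id, seq[:pos],
                              read.quality[:pos] if read.quality else None)
                continue
        result = trim_read(read, spec)
        if result.read is None:
            if summary is not None:
                summary.discarded_empty += 1
            continue
        if result.untrimmed:
            if summary is not None:
                summary.untrimmed += 1
            if discard_untrimmed:
                continue
        yield result.read


def demultiplex(reads: Iterable[RawRead], barcode_map: dict[str, str]):
    """Assign reads to libraries by exact barcode prefix.

    Returns (per_library, undetermined). Barcodes are stripped on
    assignment.
    """
    codes = list(barcode_map.values())
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate barcodes in map")
    if len({len(c) for c in codes}) > 1:
        raise ValueError("barcodes must be equal length")
    if any("N" in c for c in codes):
        raise ValueError("barcodes may not contain N")
    blen = len(codes[0])
    lookup = {code: lib for lib, code in barcode_map.items()}
    per_library: dict[str, list[RawRead]] = {lib: [] for lib in barcode_map}
    undetermined: list[RawRead] = []
    for read in reads:
        prefix = read.sequence[:blen]
        lib = lookup.get(prefix) if "N" not in prefix else None
        if lib is None:
            undetermined.append(read)
        else:
            per_library[lib].append(
                RawRead(read.id, read.sequence[blen:] or "N",
                        read.quality[blen:] if read.quality else None))
    return per_library, undetermined


def length_filter(reads: Iterable[RawRead], min_length: int = 16):
    """Split reads into (survivors, discarded) by minimum length."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    keep, drop = [], []
    for read in reads:
        (keep if len(read.sequence) >= min_length else drop).append(read)
    return keep, drop


def collapse(reads: Iterable[RawRead], library: str) -> list[CollapsedRead]:
    """Combine identical sequences; descending count then lexicographic."""
    counts = Counter(r.sequence for r in reads)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [CollapsedRead(seq, n, library) for seq, n in ordered]


def write_collapsed_fasta(path: str | Path, collapsed: list[CollapsedRead]) -> None:
    with open_text(path, "wt") as fh:
        for rank, rec in enumerate(collapsed, start=1):
            fh.write(f">seq{rank}_x{rec.count}\n{rec.sequence}\n")


def read_collapsed_fasta(path: str | Path, library: str) -> list[CollapsedRead]:
    out = []
    with open_text(path, "rt") as fh:
        header = None
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                header = line[1:]
            elif line:
                count = int(header.rsplit("_x", 1)[1])
                out.append(CollapsedRead(line, count, library))
    return out


def preprocess_libraries(reads: Iterable[RawRead], spec: TrimSpec,
                         barcode_map: dict[str, str],
                         discard_untrimmed: bool = False):
    """Full preprocessing: trim -> demultiplex -> length filter -> collapse.

    Returns (collapsed_per_library, summary). The summary satisfies
    input_reads == discarded_empty + undetermined + discarded_short +
    sum(assigned) (untrimmed reads are retained by default and counted
    separately).
    """
    summary = PreprocessSummary()
    trimmed = trim_reads(reads, spec, summary, discard_untrimmed=discard_untrimmed)
    per_library, undetermined = demultiplex(trimmed, barcode_map)
    summary.undetermined = len(undetermined)
    collapsed: dict[str, list[CollapsedRead]] = {}
    for lib, lib_reads in per_library.items():
        keep, drop = length_filter(lib_reads, spec.min_length)
        summary.discarded_short += len(drop)
        summary.assigned[lib] = len(keep)
        collapsed[lib] = collapse(keep, lib)
    return collapsed, summary
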