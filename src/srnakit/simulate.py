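"""Synthetic small-RNA experiment generator.

Builds a toy annotated genome (miRNA hairpins with guide/passenger arms,
21-nt U-starting piRNA loci, tRNA/rRNA loci, transposons, genes with
5'UTR/exon/3'UTR sub-features, pathway gene lists) and simulates
barcoded, 3'-adapter-ligated small-RNA libraries in two replicate groups
with known per-read origins and spiked between-group fold changes.

Everything is driven by explicit integer seeds; identical specs produce
byte-identical output files.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, Feature, MatureMirna, PATHWAYS
from .io import revcomp, write_fasta, write_fastq

# hairpin geometry (offsets within a 60 nt miRNA locus, sense orientation)
HAIRPIN_LEN = 60
GUIDE_OFFSET = 8  # 5' end of the 22 nt guide arm
PASSENGER_OFFSET = 34  # 5' end of the 22 nt passenger arm
ARM_LEN = 22

FEATURE_GEOMETRY = {
    "miRNA": HAIRPIN_LEN,
    "piRNA_gene": 21,
    "tRNA": 70,
    "rRNA": 120,
    "transposable_element": 400,
    "gene": 600,  # 80 UTR5 + 180 exon + 60 intron + 180 exon + 100 UTR3
}

READ_CLASSES = (
    "mirna",
    "pirna",
    "trna",
    "rrna",
    "transposon",
    "endo_sirna",
    "gene_sense",
    "unannotated",
)

DEFAULT_CLASS_PROPORTIONS = {
    "mirna": 0.40,
    "endo_sirna": 0.25,
    "pirna": 0.10,
    "trna": 0.06,
    "rrna": 0.06,
    "transposon": 0.06,
    "gene_sense": 0.05,
    "unannotated": 0.02,
}

DEFAULT_LENGTH_DISTS = {
    "mirna": {21: 0.2, 22: 0.6, 23: 0.2},
    "pirna": {21: 1.0},
    "endo_sirna": {21: 0.15, 22: 0.70, 23: 0.15},
    "trna": {18: 0.3, 19: 0.4, 20: 0.3},
    "rrna": {19: 0.3, 20: 0.4, 21: 0.3},
    "transposon": {22: 0.5, 23: 0.3, 24: 0.2},
    "gene_sense": {20: 0.4, 21: 0.3, 22: 0.3},
    "unannotated": {20: 0.5, 22: 0.5},
}

DEFAULT_ADAPTER_3P = "GATCGTTCGGACTGTAGATC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PlacementError(ValueError):
    """Raised when a requested feature cannot be placed on the genome."""


@dataclass(frozen=True)
class GenomeSpec:
    n_chromosomes: int = 2
    chrom_length: int = 26000
    n_mirna: int = 30
    n_pirna: int = 30
    n_trna: int = 10
    n_rrna: int = 5
    n_transposon: int = 10
    n_gene: int = 40
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chromosomes", "chrom_length", "n_mirna", "n_pirna",
                     "n_trna", "n_rrna", "n_transposon", "n_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_chromosomes == 0 and self._n_features() > 0:
            raise PlacementError("no chromosomes to place features on")

    def _n_features(self) -> int:
        return (self.n_mirna + self.n_pirna + self.n_trna + self.n_rrna
                + self.n_transposon + self.n_gene)


@dataclass(frozen=True)
class LibrarySpec:
    n_libraries_per_group: int = 3
    reads_per_library: int = 10000
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    insert_length_distributions: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_LENGTH_DISTS.items()})
    adapter_3p: str = DEFAULT_ADAPTER_3P
    adapter_5p_leader: str = ""
    barcode_map: dict | None = None  # library id -> barcode; autogenerated if None
    barcode_length: int = 4
    error_rate: float = 0.0
    spike_table: dict = field(default_factory=dict)  # feature id -> fold change (mut/wt)
    mirna_offset_range: tuple[int, int] = (-2, 2)
    passenger_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        for cls in self.class_proportions:
            if cls not in READ_CLASSES:
                raise ValueError(f"unknown read class {cls!r}")
        for feat, fc in self.spike_table.items():
            if fc <= 0:
                raise ValueError(f"fold change for {feat} must be > 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.barcode_map is not None:
            _check_barcodes(self.barcode_map)

    def library_names(self) -> list[str]:
        n = self.n_libraries_per_group
        return [f"wt_{i + 1}" for i in range(n)] + [f"mut_{i + 1}" for i in range(n)]

    def groups(self) -> dict[str, str]:
        return {lib: lib.split("_")[0] for lib in self.library_names()}


def _check_barcodes(barcode_map: dict) -> None:
    codes = list(barcode_map.values())
    if len(set(codes)) != len(codes):
        raise ValueError("barcodes must be unique")
    if len({len(c) for c in codes}) > 1:
        raise ValueError("barcodes must be equal length")


def generate_barcodes(n: int, length: int = 4, min_hamming: int = 2) -> list[str]:
    """Deterministic greedy barcode design with pairwise Hamming >= min_hamming."""
    chosen: list[str] = []
    for combo in itertools.product("ACGT", repeat=length):
        cand = "".join(combo)
        if all(sum(a != b for a, b in zip(cand, c)) >= min_hamming for c in chosen):
            chosen.append(cand)
            if len(chosen) == n:
                return chosen
    raise ValueError(f"cannot design {n} barcodes of length {length}")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def oriented_substring(seq: str, pos5: int, length: int, strand: str) -> str:
    """Sequence of `length` nt read 5'->3' from genomic 5'-end position `pos5`."""
    if strand == "+":
        return seq[pos5:pos5 + length]
    return revcomp(seq[pos5 - length + 1:pos5 + 1])


def build_genome(spec: GenomeSpec):
    """Generate genome sequences and annotations.

    Returns (chromosomes: dict[str, str], AnnotationSet). Features are
    placed left to right with random 40-80 nt gaps, spilling onto the
    next chromosome when full; a PlacementError names the first feature
    that does not fit.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chrI_{i + 1}" for i in range(spec.n_chromosomes)]
    seqs = {c: _random_sequence(rng, spec.chrom_length) for c in chrom_names}

    requests: list[tuple[str, str]] = []
    requests += [("miRNA", f"mir-{i + 1:04d}") for i in range(spec.n_mirna)]
    requests += [("piRNA_gene", f"pir-{i + 1:04d}") for i in range(spec.n_pirna)]
    requests += [("tRNA", f"trn-{i + 1:04d}") for i in range(spec.n_trna)]
    requests += [("rRNA", f"rrn-{i + 1:04d}") for i in range(spec.n_rrna)]
    requests += [("transposable_element", f"tpn-{i + 1:04d}") for i in range(spec.n_transposon)]
    requests += [("gene", f"gene-{i + 1:04d}") for i in range(spec.n_gene)]

    features: list[Feature] = []
    matures: list[MatureMirna] = []
    chrom_idx, cursor = 0, 0
    for ftype, fid in requests:
        length = FEATURE_GEOMETRY[ftype]
        gap = int(rng.integers(40, 81))
        while chrom_idx < len(chrom_names) and cursor + gap + length > spec.chrom_length:
            chrom_idx += 1
            cursor = 0
        if chrom_idx >= len(chrom_names):
            raise PlacementError(f"cannot place feature {fid}: genome too small")
        chrom = chrom_names[chrom_idx]
        start = cursor + gap
        end = start + length
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        cursor = end
        features.append(Feature(chrom, start, end, strand, ftype, fid))

        if ftype == "miRNA":
            if strand == "+":
                g5, p5 = start + GUIDE_OFFSET, start + PASSENGER_OFFSET
            else:
                g5 = end - 1 - GUIDE_OFFSET
                p5 = end - 1 - PASSENGER_OFFSET
            matures.append(MatureMirna(fid, "g", chrom, g5, strand))
            matures.append(MatureMirna(fid, "p", chrom, p5, strand))
        elif ftype == "piRNA_gene":
            # force the sense 5' nucleotide to U (T on the template strand)
            if strand == "+":
                seqs[chrom][start] = ord("T")
            else:
                seqs[chrom][end - 1] = ord("A")
        elif ftype == "gene":
            if strand == "+":
                parts = [("five_prime_UTR", start, start + 80),
                         ("exon", start + 80, start + 260),
                         ("exon", start + 320, start + 500),
                         ("three_prime_UTR", start + 500, start + 600)]
            else:
                parts = [("three_prime_UTR", start, start + 100),
                         ("exon", start + 100, start + 280),
                         ("exon", start + 340, start + 520),
                         ("five_prime_UTR", start + 520, start + 600)]
            for i, (sub, s, e) in enumerate(parts):
                features.append(Feature(chrom, s, e, strand, sub,
                                        f"{fid}.{sub}.{i + 1}", parent=fid))

    # pathway membership: 80% of genes cycle through the four lists
    pathways = {}
    gene_ids = [fid for ftype, fid in requests if ftype == "gene"]
    for i, gid in enumerate(gene_ids):
        if i < int(0.8 * len(gene_ids)):
            pathways[gid] = PATHWAYS[i % len(PATHWAYS)]

    chroms = {c: s.tobytes().decode("ascii") for c, s in seqs.items()}
    ann = AnnotationSet(
        chrom_sizes={c: spec.chrom_length for c in chrom_names},
        features=features,
        mature_mirnas=matures,
        pathways=pathways,
    )
    return chroms, ann


def intergenic_gaps(ann: AnnotationSet, min_length: int = 35) -> list[tuple[str, int, int]]:
    """Intervals not covered by any feature, at least min_length long."""
    gaps = []
    for chrom, size in sorted(ann.chrom_sizes.items()):
        spans = sorted((f.start, f.end) for f in ann.features if f.chrom == chrom)
        cursor = 0
        for s, e in spans:
            if s - cursor >= min_length:
                gaps.append((chrom, cursor, s))
            cursor = max(cursor, e)
        if size - cursor >= min_length:
            gaps.append((chrom, cursor, size))
    return gaps


@dataclass(frozen=True)
class _Cell:
    """One sampling unit: a (class, feature) combination with base weight."""
    rclass: str
    feature_id: str
    weight: float


def _build_cells(ann: AnnotationSet, lib_spec: LibrarySpec,
                 rng: np.random.Generator) -> list[_Cell]:
    cells: list[_Cell] = []

    def lognorm():
        return float(rng.lognormal(0.0, 0.5))

    for m in sorted(ann.mature_mirnas):
        w = lognorm()
        if m.arm == "p":
            w *= lib_spec.passenger_fraction
        cells.append(_Cell("mirna", m.arm_id, w))
    for f in ann.by_type("piRNA_gene"):
        cells.append(_Cell("pirna", f.id, lognorm()))
    for f in ann.by_type("tRNA"):
        cells.append(_Cell("trna", f.id, lognorm()))
    for f in ann.by_type("rRNA"):
        cells.append(_Cell("rrna", f.id, lognorm()))
    for f in ann.by_type("transposable_element"):
        cells.append(_Cell("transposon", f.id, lognorm()))
    for f in ann.genes():
        cells.append(_Cell("endo_sirna", f.id, lognorm()))
    for f in ann.genes():
        cells.append(_Cell("gene_sense", f.id, lognorm()))
    cells.append(_Cell("unannotated", "", 1.0))
    return cells


def _cell_probs(cells: list[_Cell], lib_spec: LibrarySpec,
                spiked: bool) -> np.ndarray:
    """Class proportions x within-class weights, optionally spiked, normalized."""
    by_class: dict[str, float] = {}
    for c in cells:
        by_class[c.rclass] = by_class.get(c.rclass, 0.0) + c.weight
    p = np.empty(len(cells))
    for i, c in enumerate(cells):
        prop = lib_spec.class_proportions.get(c.rclass, 0.0)
        p[i] = prop * c.weight / by_class[c.rclass] if by_class[c.rclass] > 0 else 0.0
        if spiked and c.feature_id in lib_spec.spike_table:
            p[i] *= lib_spec.spike_table[c.feature_id]
    return p / p.sum()


def simulate_libraries(chroms: dict[str, str], ann: AnnotationSet,
                       lib_spec: LibrarySpec):
    """Simulate all libraries.

    Returns (reads, truth, barcode_map) where reads maps library id to a
    list of (read_id, sequence, quality) triples and truth is a pandas
    DataFrame of per-read origin records.
    """
    if not lib_spec.adapter_3p:
        raise ValueError("3' adapter must be non-empty")
    for feat in lib_spec.spike_table:
        known = {m.arm_id for m in ann.mature_mirnas} | {f.id for f in ann.features}
        if feat not in known:
            raise ValueError(f"spike_table references unknown feature {feat}")

    lib_names = lib_spec.library_names()
    if lib_spec.barcode_map is None:
        codes = generate_barcodes(len(lib_names), lib_spec.barcode_length)
        barcode_map = dict(zip(lib_names, codes))
    else:
        barcode_map = dict(lib_spec.barcode_map)
        if set(barcode_map) != set(lib_names):
            raise ValueError("barcode_map must cover exactly the library names")
    if any(not b for b in barcode_map.values()):
        raise ValueError("barcodes must be non-empty")

    cell_rng = np.random.default_rng([lib_spec.seed, 0xC0FFEE])
    cells = _build_cells(ann, lib_spec, cell_rng)

    matures = {m.arm_id: m for m in ann.mature_mirnas}
    feats = {f.id: f for f in ann.features}
    subregions: dict[str, list[Feature]] = {}
    for f in ann.features:
        if f.parent and f.type in ("five_prime_UTR", "exon", "three_prime_UTR"):
            subregions.setdefault(f.parent, []).append(f)
    for subs in subregions.values():
        subs.sort()
    gaps = intergenic_gaps(ann)
    if lib_spec.class_proportions.get("unannotated", 0) > 0 and not gaps:
        raise ValueError("no intergenic gaps available for unannotated reads")

    reads: dict[str, list[tuple[str, str, str]]] = {}
    truth_rows: list[tuple] = []
    for lib_index, lib in enumerate(lib_names):
        rng = np.random.default_rng([lib_spec.seed, 1, lib_index])
        group = lib_spec.groups()[lib]
        if lib_spec.reads_per_library == 0:
            warnings.warn(f"library {lib}: zero reads requested, emitting empty library")
            reads[lib] = []
            continue
        probs = _cell_probs(cells, lib_spec, spiked=(group == "mut"))
        counts = rng.multinomial(lib_spec.reads_per_library, probs)
        lib_reads: list[tuple[str, str, str]] = []
        serial = 0
        for cell, n in zip(cells, counts):
            for _ in range(int(n)):
                origin = _draw_insert(cell, chroms, feats, matures, subregions,
                                      gaps, lib_spec, rng)
                insert, feature_id, chrom, start, strand, offset5 = origin
                serial += 1
                read_id = f"{lib}:{serial}"
                seq = (lib_spec.adapter_5p_leader + barcode_map[lib]
                       + insert + lib_spec.adapter_3p)
                seq = _apply_errors(seq, lib_spec.error_rate, rng)
                lib_reads.append((read_id, seq, "I" * len(seq)))
                truth_rows.append((lib, read_id, cell.rclass, feature_id,
                                   chrom, start, strand, offset5, insert))
        reads[lib] = lib_reads

    truth = pd.DataFrame(
        truth_rows,
        columns=["library", "read_id", "rclass", "feature_id", "chrom",
                 "start", "strand", "offset5", "insert"],
    )
    return reads, truth, barcode_map


def _choose_length(dist: dict[int, float], rng: np.random.Generator) -> int:
    lengths = sorted(dist)
    p = np.array([dist[l] for l in lengths], dtype=float)
    return int(rng.choice(lengths, p=p / p.sum()))


def _draw_insert(cell: _Cell, chroms, feats, matures, subregions, gaps,
                 lib_spec: LibrarySpec, rng: np.random.Generator):
    """Draw one insert for a sampling cell.

    Returns (insert, feature_id, chrom, genomic start of insert, strand,
    miRNA 5' offset or None).
    """
    dist = lib_spec.insert_length_distributions[cell.rclass]
    if cell.rclass == "mirna":
        m = matures[cell.feature_id]
        lo, hi = lib_spec.mirna_offset_range
        offset = int(rng.integers(lo, hi + 1))
        length = _choose_length(dist, rng)
        pos5 = m.pos5 + offset if m.strand == "+" else m.pos5 - offset
        insert = oriented_substring(chroms[m.chrom], pos5, length, m.strand)
        start = pos5 if m.strand == "+" else pos5 - length + 1
        return insert, cell.feature_id, m.chrom, start, m.strand, offset
    if cell.rclass == "pirna":
        f = feats[cell.feature_id]
        pos5 = f.start if f.strand == "+" else f.end - 1
        insert = oriented_substring(chroms[f.chrom], pos5, 21, f.strand)
        return insert, f.id, f.chrom, f.start, f.strand, None
    if cell.rclass in ("trna", "rrna", "transposon"):
        f = feats[cell.feature_id]
        length = _choose_length(dist, rng)
        start = f.start + int(rng.integers(0, f.length - length + 1))
        if cell.rclass == "transposon":
            strand = f.strand if rng.integers(0, 2) == 0 else ("-" if f.strand == "+" else "+")
        else:
            strand = f.strand
        pos5 = start if strand == "+" else start + length - 1
        insert = oriented_substring(chroms[f.chrom], pos5, length, strand)
        return insert, f.id, f.chrom, start, strand, None
    if cell.rclass in ("endo_sirna", "gene_sense"):
        gene = feats[cell.feature_id]
        subs = subregions.get(gene.id, [])
        if not subs:
            raise ValueError(f"gene {gene.id} has no sub-features")
        length = _choose_length(dist, rng)
        usable = [s for s in subs if s.length >= length]
        weights = np.array([s.length - length + 1 for s in usable], dtype=float)
        sub = usable[int(rng.choice(len(usable), p=weights / weights.sum()))]
        start = sub.start + int(rng.integers(0, sub.length - length + 1))
        if cell.rclass == "endo_sirna":
            strand = "-" if gene.strand == "+" else "+"
        else:
            strand = gene.strand
        pos5 = start if strand == "+" else start + length - 1
        insert = oriented_substring(chroms[sub.chrom], pos5, length, strand)
        return insert, gene.id, sub.chrom, start, strand, None
    # unannotated: uniform position over intergenic gaps
    length = _choose_length(dist, rng)
    usable = [g for g in gaps if g[2] - g[1] >= length]
    weights = np.array([g[2] - g[1] - length + 1 for g in usable], dtype=float)
    chrom, gs, ge = usable[int(rng.choice(len(usable), p=weights / weights.sum()))]
    start = gs + int(rng.integers(0, ge - gs - length + 1))
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    pos5 = start if strand == "+" else start + length - 1
    insert = oriented_substring(chroms[chrom], pos5, length, strand)
    return insert, "", chrom, start, strand, None


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if not hit.any():
        return seq
    for i in np.nonzero(hit)[0]:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


# ----------------------------------------------------------------------
# serialization of a full simulated experiment


def write_experiment(outdir: str | Path, chroms: dict[str, str],
                     ann: AnnotationSet, reads, truth: pd.DataFrame,
                     barcode_map: dict[str, str], gzip_fastq: bool = True) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "genome.fa", sorted(chroms.items()))
    ann.write_gff3(outdir / "annotations.gff3")
    ann.write_mature_tsv(outdir / "mature_mirnas.tsv")
    ann.write_pathways(outdir / "pathways")
    with open(outdir / "barcodes.tsv", "w") as fh:
        fh.write("library\tbarcode\n")
        for lib in sorted(barcode_map):
            fh.write(f"{lib}\t{barcode_map[lib]}\n")
    ext = ".fastq.gz" if gzip_fastq else ".fastq"
    for lib, recs in reads.items():
        write_fastq(outdir / f"{lib}{ext}", recs)
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    # declare conventions that are simulator choices, not inferences
    (outdir / "metadata.txt").write_text(
        "barcode_placement=5prime_of_insert\n"
        "barcode_design=greedy_hamming_ge_2\n"
        "quality=constant_I\n"
    )


def read_barcode_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    out = dict(zip(df["library"], df["barcode"]))
    _check_barcodes(out)
    return out
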