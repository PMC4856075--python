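"""Genomic feature model with GFF3 / TSV serialization.

Coordinates are 0-based half-open in memory; GFF3 files are written and
read 1-based inclusive per the format standard.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

#: feature classes written to the GFF3 ``type`` column
FEATURE_TYPES = (
    "miRNA",
    "piRNA_gene",
    "tRNA",
    "rRNA",
    "transposable_element",
    "gene",
    "five_prime_UTR",
    "exon",
    "three_prime_UTR",
)

GENE_SUBREGIONS = ("five_prime_UTR", "exon", "three_prime_UTR")

PATHWAYS = ("CSR-1", "WAGO", "ALG-3/4", "ERGO-1")


def pathway_filename(pathway: str) -> str:
    return pathway.replace("/", "-") + ".txt"


@dataclass(frozen=True, order=True)
class Feature:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str
    type: str
    id: str
    parent: str | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.id}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval for {self.id}: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class MatureMirna:
    """Annotated mature-arm 5' anchor of a miRNA hairpin."""

    mirna_id: str
    arm: str  # 'g' (guide) or 'p' (passenger)
    chrom: str
    pos5: int  # 0-based genomic position of the mature 5' nucleotide
    strand: str

    @property
    def arm_id(self) -> str:
        return f"{self.mirna_id}.{self.arm}"


@dataclass
class AnnotationSet:
    chrom_sizes: dict[str, int]
    features: list[Feature] = field(default_factory=list)
    mature_mirnas: list[MatureMirna] = field(default_factory=list)
    pathways: dict[str, str] = field(default_factory=dict)  # gene id -> pathway

    def __post_init__(self):
        self.features = sorted(self.features)
        self.mature_mirnas = sorted(self.mature_mirnas)
        self.validate()

    def validate(self) -> None:
        for f in self.features:
            size = self.chrom_sizes.get(f.chrom)
            if size is None or f.end > size:
                raise ValueError(f"feature {f.id} outside chromosome bounds")
        hairpins = {f.id: f for f in self.features if f.type == "miRNA"}
        for m in self.mature_mirnas:
            h = hairpins.get(m.mirna_id)
            if h is None or not (h.start <= m.pos5 < h.end) or h.strand != m.strand:
                raise ValueError(f"mature arm {m.arm_id} not inside its hairpin")
        gene_ids = {f.id for f in self.features if f.type == "gene"}
        for g in self.pathways:
            if g not in gene_ids:
                raise ValueError(f"pathway membership references unknown gene {g}")

    def by_type(self, type_: str) -> list[Feature]:
        return [f for f in self.features if f.type == type_]

    def genes(self) -> list[Feature]:
        return self.by_type("gene")

    def gene_subregions(self, gene_id: str) -> list[Feature]:
        return [f for f in self.features if f.parent == gene_id and f.type in GENE_SUBREGIONS]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AnnotationSet)
            and self.chrom_sizes == other.chrom_sizes
            and self.features == other.features
            and self.mature_mirnas == other.mature_mirnas
            and self.pathways == other.pathways
        )

    # --- GFF3 ---------------------------------------------------------

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom in sorted(self.chrom_sizes):
                fh.write(f"##sequence-region {chrom} 1 {self.chrom_sizes[chrom]}\n")
            for f in self.features:
                attrs = f"ID={f.id}"
                if f.parent:
                    attrs += f";Parent={f.parent}"
                fh.write(
                    f"{f.chrom}\tsrnakit\t{f.type}\t{f.start + 1}\t{f.end}\t.\t"
                    f"{f.strand}\t.\t{attrs}\n"
                )

    @classmethod
    def read_gff3(
        cls,
        path: str | Path,
        mature_mirnas: list[MatureMirna] | None = None,
        pathways: dict[str, str] | None = None,
    ) -> "AnnotationSet":
        chrom_sizes: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, chrom, _start, end = line.split()
                    chrom_sizes[chrom] = int(end)
        db = gffutils.create_db(
            str(path), ":memory:", keep_order=True, merge_strategy="error"
        )
        feats = []
        for rec in db.all_features():
            parents = rec.attributes.get("Parent")
            feats.append(
                Feature(
                    chrom=rec.seqid,
                    start=rec.start - 1,
                    end=rec.end,
                    strand=rec.strand,
                    type=rec.featuretype,
                    id=rec.id,
                    parent=parents[0] if parents else None,
                )
            )
        return cls(
            chrom_sizes=chrom_sizes,
            features=feats,
            mature_mirnas=mature_mirnas or [],
            pathways=pathways or {},
        )

    # --- mature-miRNA TSV --------------------------------------------

    def write_mature_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["mirna_id", "arm", "chrom", "mature_5p_position", "strand"])
            for m in self.mature_mirnas:
                w.writerow([m.mirna_id, m.arm, m.chrom, m.pos5, m.strand])

    @staticmethod
    def read_mature_tsv(path: str | Path) -> list[MatureMirna]:
        out = []
        with open(path) as fh:
            r = csv.DictReader(fh, delimiter="\t")
            for row in r:
                out.append(
                    MatureMirna(
                        mirna_id=row["mirna_id"],
                        arm=row["arm"],
                        chrom=row["chrom"],
                        pos5=int(row["mature_5p_position"]),
                        strand=row["strand"],
                    )
                )
        return sorted(out)

    # --- pathway lists (one gene per line, one file per pathway) ------

    def write_pathways(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for pw in PATHWAYS:
            genes = sorted(g for g, p in self.pathways.items() if p == pw)
            (directory / pathway_filename(pw)).write_text(
                "".join(g + "\n" for g in genes)
            )

    @staticmethod
    def read_pathways(directory: str | Path) -> dict[str, str]:
        membership: dict[str, str] = {}
        dupes = []
        for pw in PATHWAYS:
            p = Path(directory) / pathway_filename(pw)
            if not p.exists():
                continue
            for line in p.read_text().splitlines():
                gene = line.strip()
                if not gene:
                    continue
                if gene in membership:
                    dupes.append(gene)
                membership[gene] = pw
        if dupes:
            raise ValueError(f"genes in more than one pathway list: {sorted(set(dupes))}")
        return membership
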