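"""Assignment of filtered alignments to small-RNA classes and count tables.

Rules:
  * miRNA: a read is assigned to a mature arm when it is on the arm's
    strand and its 5' end falls within +/- `window` nt (default 5) of the
    annotated mature 5' end; ties go to the nearest anchor, then guide
    over passenger.
  * other features: reported when the alignment interval is fully
    contained in the feature interval; orientation recorded as sense or
    antisense by strand comparison.
  * endo-siRNA: antisense containment in a gene's 5'UTR / exon / 3'UTR.
  * multi-mappers contribute weight count/n to each surviving alignment
    (fractional mode, default) or full count (mode "all").
  * one summary label per read by precedence: miRNA > rRNA > tRNA >
    piRNA(sense) > transposon > endo-siRNA > gene-sense > unannotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import Alignment, ReadAlignments
from .annotations import AnnotationSet, GENE_SUBREGIONS, MatureMirna, PATHWAYS

CLASS_LABELS = (
    "mirna",
    "rrna",
    "trna",
    "pirna",
    "transposon",
    "endo_sirna",
    "gene_sense",
    "unannotated",
)

_PRECEDENCE = {label: i for i, label in enumerate(CLASS_LABELS)}


class _FeatureIndex:
    """Vectorized containment lookup over one chromosome's features."""

    def __init__(self, feats):
        self.feats = feats
        self.starts = np.array([f.start for f in feats], dtype=np.int64)
        self.ends = np.array([f.end for f in feats], dtype=np.int64)

    def containing(self, start: int, end: int):
        if len(self.feats) == 0:
            return []
        mask = (self.starts <= start) & (self.ends >= end)
        return [self.feats[i] for i in np.nonzero(mask)[0]]


class Classifier:
    def __init__(self, ann: AnnotationSet, window: int = 5,
                 count_mode: str = "fractional"):
        if count_mode not in ("fractional", "all"):
            raise ValueError("count_mode must be 'fractional' or 'all'")
        self.ann = ann
        self.window = window
        self.count_mode = count_mode
        by_chrom: dict[str, list] = {}
        for f in ann.features:
            by_chrom.setdefault(f.chrom, []).append(f)
        self._index = {c: _FeatureIndex(fs) for c, fs in by_chrom.items()}
        self._mature_by_chrom: dict[str, list[MatureMirna]] = {}
        for m in ann.mature_mirnas:
            self._mature_by_chrom.setdefault(m.chrom, []).append(m)
        self._gene_strand = {f.id: f.strand for f in ann.genes()}

    # --- single-alignment assignments --------------------------------

    def assign_mirna(self, aln: Alignment) -> str | None:
        """Mature-arm id for an alignment, or None.

        Sense-only: the read must be on the arm's strand. Ties across
        overlapping arms resolve to the nearest 5' anchor, then guide
        over passenger, then arm id.
        """
        cands = []
        for m in self._mature_by_chrom.get(aln.chrom, []):
            if m.strand != aln.strand:
                continue
            dist = abs(aln.pos5 - m.pos5)
            if dist <= self.window:
                cands.append((dist, 0 if m.arm == "g" else 1, m.arm_id))
        if not cands:
            return None
        return min(cands)[2]

    def assign_features(self, aln: Alignment):
        """(feature, orientation) for every feature fully containing the alignment."""
        idx = self._index.get(aln.chrom)
        if idx is None:
            return []
        return [(f, "sense" if f.strand == aln.strand else "antisense")
                for f in idx.containing(aln.start, aln.end)]

    # --- per-read classification -------------------------------------

    def classify_read(self, ra: ReadAlignments) -> str:
        """Single summary label for a read, over all surviving alignments."""
        best = _PRECEDENCE["unannotated"]
        for aln in ra.alignments:
            if self.assign_mirna(aln) is not None:
                return "mirna"
            for feat, orient in self.assign_features(aln):
                label = None
                if feat.type == "rRNA":
                    label = "rrna"
                elif feat.type == "tRNA":
                    label = "trna"
                elif feat.type == "piRNA_gene" and orient == "sense":
                    label = "pirna"
                elif feat.type == "transposable_element":
                    label = "transposon"
                elif feat.type in GENE_SUBREGIONS or feat.type == "gene":
                    label = "endo_sirna" if orient == "antisense" else "gene_sense"
                if label is not None:
                    best = min(best, _PRECEDENCE[label])
        return CLASS_LABELS[best]


@dataclass
class LibraryClassification:
    library: str
    class_totals: dict = field(default_factory=dict)  # label -> weighted count
    mirna_counts: dict = field(default_factory=dict)  # arm id -> weight
    gene_antisense: dict = field(default_factory=dict)  # gene -> weight
    gene_antisense_by_subregion: dict = field(default_factory=dict)
    pirna_counts: dict = field(default_factory=dict)  # locus -> sense weight
    mapped_count: float = 0.0


def classify_library(aligned: list[ReadAlignments], classifier: Classifier,
                     library: str) -> LibraryClassification:
    """Classify every read of a library and accumulate all count layers."""
    res = LibraryClassification(library)
    res.class_totals = {label: 0.0 for label in CLASS_LABELS}
    for ra in aligned:
        res.mapped_count += ra.count
        res.class_totals[classifier.classify_read(ra)] += ra.count
        weight = ra.count / ra.n_best if classifier.count_mode == "fractional" else ra.count
        for aln in ra.alignments:
            arm = classifier.assign_mirna(aln)
            if arm is not None:
                res.mirna_counts[arm] = res.mirna_counts.get(arm, 0.0) + weight
            hit_genes = set()
            for feat, orient in classifier.assign_features(aln):
                if feat.type == "piRNA_gene" and orient == "sense":
                    res.pirna_counts[feat.id] = res.pirna_counts.get(feat.id, 0.0) + weight
                elif (feat.type in GENE_SUBREGIONS and orient == "antisense"
                      and feat.parent and feat.parent not in hit_genes):
                    hit_genes.add(feat.parent)
                    res.gene_antisense[feat.parent] = (
                        res.gene_antisense.get(feat.parent, 0.0) + weight)
                    key = (feat.parent, feat.type)
                    res.gene_antisense_by_subregion[key] = (
                        res.gene_antisense_by_subregion.get(key, 0.0) + weight)
    return res


def class_distribution(results: list[LibraryClassification]) -> pd.DataFrame:
    """Per-library weighted class counts (read-distribution summary)."""
    data = {r.library: [r.class_totals.get(label, 0.0) for label in CLASS_LABELS]
            for r in results}
    return pd.DataFrame(data, index=list(CLASS_LABELS))


def build_count_matrix(results: list[LibraryClassification], ann: AnnotationSet,
                       level: str, groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Features x libraries count table, zero-filled, deterministic order.

    level: 'mirna_arm', 'gene' (antisense / endo-siRNA counts), or
    'pirna_locus'. Column group labels are stored in DataFrame.attrs.
    """
    libs = [r.library for r in results]
    if len(set(libs)) != len(libs):
        raise ValueError("duplicate library ids")
    if level == "mirna_arm":
        rows = [m.arm_id for m in ann.mature_mirnas]
        getter = lambda r: r.mirna_counts
    elif level == "gene":
        rows = [f.id for f in ann.genes()]
        getter = lambda r: r.gene_antisense
    elif level == "pirna_locus":
        rows = [f.id for f in ann.by_type("piRNA_gene")]
        getter = lambda r: r.pirna_counts
    else:
        raise ValueError(f"unknown level {level!r}")
    rows = sorted(rows)
    table = pd.DataFrame(0.0, index=rows, columns=libs)
    for r in results:
        for feat, w in getter(r).items():
            if feat in table.index:
                table.loc[feat, r.library] += w
    table.index.name = "feature"
    if groups:
        table.attrs["groups"] = {lib: groups[lib] for lib in libs}
    return table


def partition_pathways(gene_table: pd.DataFrame,
                       membership: dict[str, str]) -> dict[str, pd.DataFrame]:
    """Split a per-gene table into one table per pathway plus 'unassigned'."""
    seen: dict[str, str] = {}
    for gene, pw in membership.items():
        if gene in seen:
            raise ValueError(f"gene {gene} assigned to multiple pathways")
        seen[gene] = pw
    out = {}
    for pw in PATHWAYS:
        genes = [g for g in gene_table.index if membership.get(g) == pw]
        sub = gene_table.loc[genes].copy()
        sub.attrs = dict(gene_table.attrs)
        out[pw] = sub
    rest = [g for g in gene_table.index if g not in membership]
    sub = gene_table.loc[rest].copy()
    sub.attrs = dict(gene_table.attrs)
    out["unassigned"] = sub
    return out


# --- TSV round-trips with a group-label header line -------------------


def write_count_table(path: str | Path, table: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        groups = table.attrs.get("groups")
        if groups:
            fh.write("#groups\t" + "\t".join(groups[c] for c in table.columns) + "\n")
        table.to_csv(fh, sep="\t")


def read_count_table(path: str | Path) -> pd.DataFrame:
    groups_row = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#groups"):
            groups_row = first.rstrip("\n").split("\t")[1:]
        else:
            fh.seek(0)
        table = pd.read_csv(fh, sep="\t", index_col=0)
    if groups_row:
        table.attrs["groups"] = dict(zip(table.columns, groups_row))
    return table
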