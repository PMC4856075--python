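import numpy as np
import pandas as pd
import pytest

from srnakit import align as al
from srnakit import classify as cl
from srnakit import preprocess as pp
from srnakit import simulate as sim
from srnakit.align import Alignment, ReadAlignments
from srnakit.annotations import AnnotationSet, Feature, MatureMirna
from srnakit.io import revcomp


@pytest.fixture(scope="module")
def classifier(small_genome_module):
    _, ann = small_genome_module
    return cl.Classifier(ann)


@pytest.fixture(scope="module")
def small_genome_module():
    from .conftest import SMALL_GENOME
    return sim.build_genome(SMALL_GENOME)


def _aln(chrom, start, length, strand, seq="A"):
    return Alignment(chrom, start, strand, seq * length, 1, 0)


class TestAssignMirna:
    @pytest.mark.parametrize("offset,assigned", [
        (0, True), (-5, True), (5, True), (-6, False), (6, False),
    ])
    def test_window_boundaries(self, classifier, small_genome_module,
                               offset, assigned):
        _, ann = small_genome_module
        m = ann.mature_mirnas[0]
        start = (m.pos5 + offset) if m.strand == "+" else (m.pos5 - offset) - 21
        got = classifier.assign_mirna(_aln(m.chrom, start, 22, m.strand))
        if assigned:
            assert got == m.arm_id
        else:
            assert got is None

    def test_antisense_not_assigned(self, classifier, small_genome_module):
        _, ann = small_genome_module
        m = ann.mature_mirnas[0]
        other = "-" if m.strand == "+" else "+"
        start = m.pos5 if m.strand == "+" else m.pos5 - 21
        assert classifier.assign_mirna(_aln(m.chrom, start, 22, other)) is None

    def test_tie_prefers_nearest_then_guide(self):
        ann = AnnotationSet(
            chrom_sizes={"c": 1000},
            features=[Feature("c", 100, 160, "+", "miRNA", "mir-x")],
            mature_mirnas=[MatureMirna("mir-x", "g", "c", 110, "+"),
                           MatureMirna("mir-x", "p", "c", 114, "+")],
        )
        clf = cl.Classifier(ann)
        # 5' end at 111: distance 1 to guide, 3 to passenger
        assert clf.assign_mirna(_aln("c", 111, 22, "+")) == "mir-x.g"
        # equidistant at 112: guide wins
        assert clf.assign_mirna(_aln("c", 112, 22, "+")) == "mir-x.g"
        # nearer to passenger
        assert clf.assign_mirna(_aln("c", 114, 22, "+")) == "mir-x.p"


class TestAssignFeatures:
    def test_containment_and_orientation(self, classifier, small_genome_module):
        _, ann = small_genome_module
        trna = ann.by_type("tRNA")[0]
        anti = "-" if trna.strand == "+" else "+"
        hits = classifier.assign_features(_aln(trna.chrom, trna.start + 5, 20, anti))
        assert (trna, "antisense") in hits

    def test_straddling_not_reported(self, classifier, small_genome_module):
        _, ann = small_genome_module
        trna = ann.by_type("tRNA")[0]
        hits = classifier.assign_features(
            _aln(trna.chrom, trna.end - 10, 20, trna.strand))
        assert trna not in [f for f, _ in hits]

    def test_nested_features_both_reported(self, classifier, small_genome_module):
        _, ann = small_genome_module
        gene = ann.genes()[0]
        exon = [f for f in ann.gene_subregions(gene.id) if f.type == "exon"][0]
        hits = classifier.assign_features(
            _aln(exon.chrom, exon.start + 10, 20, exon.strand))
        got = {f.id for f, _ in hits}
        assert gene.id in got and exon.id in got


class TestClassifyRead:
    def test_mirna_precedence_over_host(self, small_genome_module):
        _, ann = small_genome_module
        m = ann.mature_mirnas[0]
        start = m.pos5 if m.strand == "+" else m.pos5 - 21
        clf = cl.Classifier(ann)
        ra = ReadAlignments("A" * 22, 1, [_aln(m.chrom, start, 22, m.strand)])
        assert clf.classify_read(ra) == "mirna"

    def test_gene_antisense_is_endo_sirna(self, classifier, small_genome_module):
        _, ann = small_genome_module
        gene = ann.genes()[0]
        exon = [f for f in ann.gene_subregions(gene.id) if f.type == "exon"][0]
        anti = "-" if exon.strand == "+" else "+"
        ra = ReadAlignments("A" * 22, 1, [_aln(exon.chrom, exon.start + 4, 22, anti)])
        assert classifier.classify_read(ra) == "endo_sirna"

    def test_gene_sense_is_other(self, classifier, small_genome_module):
        _, ann = small_genome_module
        gene = ann.genes()[0]
        exon = [f for f in ann.gene_subregions(gene.id) if f.type == "exon"][0]
        ra = ReadAlignments("A" * 22, 1,
                            [_aln(exon.chrom, exon.start + 4, 22, exon.strand)])
        assert classifier.classify_read(ra) == "gene_sense"

    def test_intergenic_is_unannotated(self, classifier, small_genome_module):
        _, ann = small_genome_module
        gap = sim.intergenic_gaps(ann)[0]
        ra = ReadAlignments("A" * 20, 1, [_aln(gap[0], gap[1], 20, "+")])
        assert classifier.classify_read(ra) == "unannotated"

    def test_antisense_pirna_falls_through(self, small_genome_module):
        _, ann = small_genome_module
        f = ann.by_type("piRNA_gene")[0]
        anti = "-" if f.strand == "+" else "+"
        clf = cl.Classifier(ann)
        ra = ReadAlignments("A" * 21, 1, [_aln(f.chrom, f.start, 21, anti)])
        assert clf.classify_read(ra) != "pirna"


class TestWindowSharpness:
    def test_uniform_offsets_minus8_to_8(self, small_genome_module):
        chroms, ann = small_genome_module
        clf = cl.Classifier(ann)
        for m in ann.mature_mirnas:
            if m.arm != "g":
                continue
            for offset in range(-8, 9):
                pos5 = m.pos5 + offset if m.strand == "+" else m.pos5 - offset
                start = pos5 if m.strand == "+" else pos5 - 21
                seq = sim.oriented_substring(chroms[m.chrom], pos5, 22, m.strand)
                got = clf.assign_mirna(Alignment(m.chrom, start, m.strand, seq, 1, 0))
                if -5 <= offset <= 5:
                    assert got is not None, (m.arm_id, offset)
                else:
                    assert got is None, (m.arm_id, offset)


class TestCounting:
    def _classify_all(self, small_experiment, count_mode="fractional"):
        chroms, ann, spec, reads, truth, bmap = small_experiment
        index = al.GenomeIndex(chroms)
        clf = cl.Classifier(ann, count_mode=count_mode)
        results = []
        cache = {}
        for lib in spec.library_names():
            stream = (pp.RawRead(i, s, q) for i, s, q in reads[lib])
            collapsed, _ = pp.preprocess_libraries(
                stream, pp.TrimSpec(adapter_3p=spec.adapter_3p), bmap)
            aligned, _ = al.align_library(collapsed[lib], index, cache=cache)
            results.append(cl.classify_library(aligned, clf, lib))
        return ann, spec, truth, results

    def test_class_distribution_matches_truth(self, small_experiment):
        ann, spec, truth, results = self._classify_all(small_experiment)
        dist = cl.class_distribution(results)
        for res in results:
            expected = truth[truth.library == res.library].rclass.value_counts()
            for label in cl.CLASS_LABELS:
                assert dist.loc[label, res.library] == expected.get(label, 0)

    def test_partition_invariant(self, small_experiment):
        _, spec, _, results = self._classify_all(small_experiment)
        for res in results:
            assert sum(res.class_totals.values()) == pytest.approx(res.mapped_count)

    def test_mirna_counts_match_truth(self, small_experiment):
        ann, spec, truth, results = self._classify_all(small_experiment)
        table = cl.build_count_matrix(results, ann, "mirna_arm")
        for res in results:
            expected = truth[(truth.library == res.library)
                             & (truth.rclass == "mirna")].feature_id.value_counts()
            for arm in table.index:
                assert table.loc[arm, res.library] == expected.get(arm, 0)

    def test_gene_antisense_counts_match_truth(self, small_experiment):
        ann, spec, truth, results = self._classify_all(small_experiment)
        table = cl.build_count_matrix(results, ann, "gene")
        for res in results:
            expected = truth[(truth.library == res.library)
                             & (truth.rclass == "endo_sirna")].feature_id.value_counts()
            for gene in table.index:
                assert table.loc[gene, res.library] == expected.get(gene, 0)

    def test_count_matrix_shape_and_zero_rows(self, small_experiment):
        ann, spec, _, results = self._classify_all(small_experiment)
        table = cl.build_count_matrix(results, ann, "mirna_arm",
                                      groups=spec.groups())
        assert table.shape == (2 * len(ann.by_type("miRNA")), 6)
        assert table.attrs["groups"]["wt_1"] == "wt"
        # a zero row stays present
        empty = pd.DataFrame(
            0.0, index=table.index, columns=table.columns)
        assert set(table.index) == set(empty.index)

    def test_pirna_counts_match_truth(self, small_experiment):
        ann, spec, truth, results = self._classify_all(small_experiment)
        table = cl.build_count_matrix(results, ann, "pirna_locus")
        for res in results:
            expected = truth[(truth.library == res.library)
                             & (truth.rclass == "pirna")].feature_id.value_counts()
            for locus in table.index:
                assert table.loc[locus, res.library] == expected.get(locus, 0)


class TestPathways:
    def test_partition_conservation(self, small_genome_module):
        _, ann = small_genome_module
        genes = [g.id for g in ann.genes()]
        table = pd.DataFrame({"lib1": np.arange(len(genes), dtype=float)},
                             index=genes)
        parts = cl.partition_pathways(table, ann.pathways)
        assert sum(len(p) for p in parts.values()) == len(genes)
        total = sum(p["lib1"].sum() for p in parts.values())
        assert total == pytest.approx(table["lib1"].sum())

    def test_gene_appears_only_in_its_pathway(self, small_genome_module):
        _, ann = small_genome_module
        genes = [g.id for g in ann.genes()]
        table = pd.DataFrame({"lib1": [7.0] * len(genes)}, index=genes)
        parts = cl.partition_pathways(table, ann.pathways)
        some_gene, pw = next(iter(ann.pathways.items()))
        assert some_gene in parts[pw].index
        for other, part in parts.items():
            if other != pw:
                assert some_gene not in part.index

    def test_empty_pathway_table(self):
        table = pd.DataFrame({"lib1": [1.0, 2.0]}, index=["g1", "g2"])
        parts = cl.partition_pathways(table, {"g1": "CSR-1"})
        assert len(parts["WAGO"]) == 0
        assert list(parts["unassigned"].index) == ["g2"]

    def test_duplicate_membership_file_rejected(self, tmp_path, small_genome_module):
        _, ann = small_genome_module
        ann.write_pathways(tmp_path / "pw")
        gene = next(iter(ann.pathways))
        other = [p for p in ("CSR-1", "WAGO") if p != ann.pathways[gene]][0]
        with open(tmp_path / "pw" / f"{other}.txt", "a") as fh:
            fh.write(gene + "\n")
        with pytest.raises(ValueError, match="more than one pathway"):
            AnnotationSet.read_pathways(tmp_path / "pw")


class TestCountTableIO:
    def test_round_trip_with_groups(self, tmp_path):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]},
                             index=["f1", "f2"])
        table.index.name = "feature"
        table.attrs["groups"] = {"a": "wt", "b": "mut"}
        p = tmp_path / "t.tsv"
        cl.write_count_table(p, table)
        again = cl.read_count_table(p)
        pd.testing.assert_frame_equal(table, again)
        assert again.attrs["groups"] == {"a": "wt", "b": "mut"}

    def test_multimapper_fractional_weight(self, small_genome_module):
        _, ann = small_genome_module
        m = ann.mature_mirnas[0]
        start = m.pos5 if m.strand == "+" else m.pos5 - 21
        clf = cl.Classifier(ann)
        gap = sim.intergenic_gaps(ann)[0]
        ra = ReadAlignments("A" * 22, 6, [
            _aln(m.chrom, start, 22, m.strand),
            _aln(gap[0], gap[1], 22, "+"),
        ])
        res = cl.classify_library([ra], clf, "lib")
        assert res.mirna_counts[m.arm_id] == pytest.approx(3.0)  # 6 / 2
        res_all = cl.classify_library(
            [ra], cl.Classifier(ann, count_mode="all"), "lib")
        assert res_all.mirna_counts[m.arm_id] == pytest.approx(6.0)
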