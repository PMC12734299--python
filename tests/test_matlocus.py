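"""Mating-type locus classification, coverage test and breeding calls."""

import itertools

import pytest

from anispec.matlocus import (AnnotationError, GeneAnnotation, GeneCoverage,
                              MatArchitecture, attempt_edge_reassembly,
                              classify_architecture, coverage_ratio_test,
                              infer_breeding_system, read_annotations_gff3,
                              read_annotations_tsv, read_coverage_tsv)
from anispec.simulate import (ARCHITECTURE_LABELS, CoverageSimParams,
                              build_mat_fixture, simulate_gene_coverage,
                              write_annotations_gff3, write_annotations_tsv,
                              write_coverage_tsv)

# printed reads/kbp values for the three strains with unlinked idiomorphs
PSN1167 = GeneCoverage({"APN2": 184, "SLA2": 195, "mat1-1-1": 196,
                        "mat1-1-2": 208, "mat1-1-3": 224, "mat1-2-1": 206})
PSN850 = GeneCoverage({"APN2": 202, "SLA2": 226, "mat1-1-1": 246,
                       "mat1-1-2": 242, "mat1-1-3": 217, "mat1-2-1": 238})
CBS365_69 = GeneCoverage({"APN2": 1241, "SLA2": 1090, "mat1-1-1": 1289,
                          "mat1-1-2": 1289, "mat1-1-3": 1216,
                          "mat1-2-1": 1019})


def _ann(gene, contig, start, end, strand="+", pseudo=False):
    return GeneAnnotation(gene, contig, start, end, strand, pseudo)


class TestClassifyArchitecture:
    @pytest.mark.parametrize("label", ARCHITECTURE_LABELS)
    @pytest.mark.parametrize("seed", range(5))
    def test_fixture_recovery(self, label, seed):
        genome, anns = build_mat_fixture(label, seed=seed)
        arch = classify_architecture(anns, genome.contig_lengths)
        expected = {
            "fused": "fused", "split_edge_reassemblable": "fused",
            "split_unlinked": "split_unlinked",
            "single_mat1-1": "single_idiomorph",
            "single_mat1-2": "single_idiomorph"}[label]
        assert arch.architecture == expected
        assert arch.edge_reassembled == (label == "split_edge_reassemblable")

    def test_duplicated_gene_incomplete_with_warning(self):
        anns = [_ann("APN2", "c1", 100, 3700),
                _ann("mat1-1-1", "c1", 4000, 5100),
                _ann("mat1-1-1", "c2", 100, 1200),
                _ann("mat1-2-1", "c1", 6000, 6800),
                _ann("SLA2", "c1", 7000, 10300)]
        arch = classify_architecture(anns, {"c1": 12_000, "c2": 5_000})
        assert arch.architecture == "incomplete"
        assert any("duplicated gene mat1-1-1" in e for e in arch.evidence)

    def test_missing_flank_incomplete(self):
        anns = [_ann("mat1-1-1", "c1", 100, 1200),
                _ann("mat1-2-1", "c1", 2000, 2800)]
        arch = classify_architecture(anns, {"c1": 5_000})
        assert arch.architecture == "incomplete"

    def test_mat_gene_outside_flanks_not_fused(self):
        anns = [_ann("APN2", "c1", 5000, 8600),
                _ann("mat1-1-1", "c1", 9000, 10_100),
                _ann("mat1-2-1", "c1", 1000, 1800),  # outside APN2..SLA2
                _ann("SLA2", "c1", 11_000, 14_300)]
        arch = classify_architecture(anns, {"c1": 20_000})
        assert arch.architecture != "fused"

    def test_missing_contig_length_rejected(self):
        anns = [_ann("APN2", "c1", 100, 3700)]
        with pytest.raises(AnnotationError):
            classify_architecture(anns, {})

    def test_no_annotations_rejected(self):
        with pytest.raises(AnnotationError):
            classify_architecture([], {"c1": 1000})


class TestEdgeReassembly:
    def test_reassemblable_fixture_fires(self):
        genome, anns = build_mat_fixture("split_edge_reassemblable", seed=3)
        arch = attempt_edge_reassembly(anns, genome.contig_lengths, 2000)
        assert arch is not None and arch.edge_reassembled
        assert arch.architecture == "fused"

    def test_mid_contig_orphan_unchanged(self):
        genome, anns = build_mat_fixture("split_unlinked", seed=3)
        assert attempt_edge_reassembly(anns, genome.contig_lengths, 2000) is None
        arch = classify_architecture(anns, genome.contig_lengths)
        assert arch.architecture == "split_unlinked"

    def test_edge_distance_zero_never_fires(self):
        for seed in range(5):
            genome, anns = build_mat_fixture("split_edge_reassemblable",
                                             seed=seed)
            assert attempt_edge_reassembly(
                anns, genome.contig_lengths, 0) is None


class TestCoverageRatioTest:
    @pytest.mark.parametrize("cov", [PSN1167, PSN850, CBS365_69],
                             ids=["PSN1167", "PSN850", "CBS365.69"])
    def test_printed_values_equal_coverage(self, cov):
        ratio, pvalue, verdict = coverage_ratio_test(cov)
        assert verdict == "equal_coverage"
        assert ratio < 1.5

    def test_psn1167_ratio_below_one(self):
        ratio, _, _ = coverage_ratio_test(PSN1167)
        assert ratio < 1.0  # mat genes actually a touch deeper than flanks

    def test_balanced_heterokaryon_elevated(self):
        cov = GeneCoverage({"APN2": 205, "SLA2": 197, "mat1-1-1": 95,
                            "mat1-1-2": 104, "mat1-1-3": 99, "mat1-2-1": 101})
        ratio, pvalue, verdict = coverage_ratio_test(cov)
        assert verdict == "elevated_flank"
        assert ratio == pytest.approx(2.0, abs=0.2)
        assert pvalue < 0.001

    def test_pseudogene_excluded_from_mean(self):
        cov = GeneCoverage({"APN2": 200, "SLA2": 200, "mat1-1-1": 100,
                            "mat1-1-2": 100, "mat1-1-3": 5, "mat1-2-1": 100})
        with_ps, _, _ = coverage_ratio_test(cov)
        without_ps, _, _ = coverage_ratio_test(
            cov, exclude_pseudogenes=["mat1-1-3"])
        assert with_ps > without_ps
        assert without_ps == pytest.approx(2.0)

    def test_zero_mat_coverage_undetermined(self):
        cov = GeneCoverage({"APN2": 200, "SLA2": 200, "mat1-2-1": 0})
        assert coverage_ratio_test(cov)[2] == "undetermined"

    def test_missing_genes_undetermined(self):
        assert coverage_ratio_test(GeneCoverage({"APN2": 200}))[2] == \
            "undetermined"


class TestBreedingSystem:
    def _arch(self, cls, idio=("mat1-1", "mat1-2"), edge=False):
        return MatArchitecture(cls, frozenset(idio), edge_reassembled=edge)

    def test_truth_table_total_and_unique(self):
        archs = [self._arch("fused"), self._arch("split_unlinked"),
                 self._arch("single_idiomorph", ("mat1-1",)),
                 self._arch("incomplete", ())]
        verdicts = ["equal_coverage", "elevated_flank", "undetermined", None]
        fertility = [True, False, None]
        for arch, cov, fert in itertools.product(archs, verdicts, fertility):
            call = infer_breeding_system(arch, cov, fert)
            assert call.call in {"homothallic", "heterothallic_likely",
                                 "single_mating_type_unresolved",
                                 "undetermined"}

    def test_fused_always_homothallic(self):
        for fert in (True, False, None):
            call = infer_breeding_system(self._arch("fused"), None, fert)
            assert call.call == "homothallic"

    def test_unlinked_equal_coverage_homothallic(self):
        # the PSN1167 pattern: unlinked idiomorphs, equal per-gene depth
        call = infer_breeding_system(self._arch("split_unlinked"),
                                     "equal_coverage", True)
        assert call.call == "homothallic"

    def test_unlinked_elevated_flank_heterothallic(self):
        call = infer_breeding_system(self._arch("split_unlinked"),
                                     "elevated_flank", None)
        assert call.call == "heterothallic_likely"

    def test_unlinked_no_coverage_undetermined(self):
        call = infer_breeding_system(self._arch("split_unlinked"), None, None)
        assert call.call == "undetermined"

    def test_single_idiomorph_sterile_heterothallic(self):
        # sterile single-mat strain: probable heterothallic that lost one type
        call = infer_breeding_system(
            self._arch("single_idiomorph", ("mat1-2",)), None, False)
        assert call.call == "heterothallic_likely"

    def test_single_idiomorph_fertile_unresolved(self):
        # fruiting despite a single idiomorph leaves the system open
        call = infer_breeding_system(
            self._arch("single_idiomorph", ("mat1-1",)), None, True)
        assert call.call == "single_mating_type_unresolved"

    def test_incomplete_undetermined(self):
        call = infer_breeding_system(self._arch("incomplete", ()), None, None)
        assert call.call == "undetermined"


class TestIO:
    def test_tsv_roundtrip(self, tmp_path):
        _, anns = build_mat_fixture("fused", seed=6)
        path = tmp_path / "genes.tsv"
        write_annotations_tsv(anns, path)
        back = read_annotations_tsv(path)
        assert [(a.gene, a.contig, a.start, a.end, a.strand) for a in back] == \
            [(a.gene, a.contig, a.start, a.end, a.strand) for a in anns]

    def test_gff3_roundtrip(self, tmp_path):
        _, anns = build_mat_fixture("fused", seed=6,
                                    pseudogenize_mat113=True)
        path = tmp_path / "genes.gff3"
        write_annotations_gff3(anns, path)
        back = read_annotations_gff3(path)
        key = lambda a: (a.contig, a.start)
        assert [(a.gene, a.start, a.end, a.strand, a.pseudogene)
                for a in sorted(back, key=key)] == \
            [(a.gene, a.start, a.end, a.strand, a.pseudogene)
             for a in sorted(anns, key=key)]

    def test_coverage_tsv_roundtrip(self, tmp_path):
        cov = simulate_gene_coverage(CoverageSimParams(seed=1), "homokaryon")
        path = tmp_path / "cov.tsv"
        write_coverage_tsv(cov, path)
        back = read_coverage_tsv(path)
        for g in cov:
            assert back[g] == pytest.approx(cov[g], abs=1e-3)
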