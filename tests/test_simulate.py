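"""Simulator tests: determinism, conservation, divergence recovery."""

import numpy as np
import pytest

from anispec.genome import GenomeSequence
from anispec.simulate import (ARCHITECTURE_LABELS, CoverageSimParams,
                              ParameterError, SimulationParams,
                              build_mat_fixture, divergence_for_identity,
                              evolve_pair, expected_gene_depth,
                              expected_pairwise_identity, generate_ancestor,
                              insert_rdna_cassette, random_cassette,
                              simulate_gene_coverage, simulate_pair)
from anispec.matlocus import (MAT11_GENES, MAT12_GENES, classify_architecture)


class TestGenerateAncestor:
    def test_gc_and_length(self):
        g = generate_ancestor(10_000, 0.5, 1, seed=7)
        assert len(g) == 10_000 and len(g.contigs) == 1
        seq = g.contigs[0][1]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.45 <= gc <= 0.55  # ~10 sd of the binomial bound

    def test_biased_gc(self):
        g = generate_ancestor(50_000, 0.62, 1, seed=3)
        seq = g.contigs[0][1]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.62) < 0.01

    def test_deterministic(self):
        a = generate_ancestor(10_000, 0.5, 2, seed=7)
        b = generate_ancestor(10_000, 0.5, 2, seed=7)
        assert a.contigs == b.contigs

    def test_contig_split_conserves_length(self):
        g = generate_ancestor(10_000, 0.5, 3, seed=7)
        assert len(g) == 10_000 and len(g.contigs) == 3

    @pytest.mark.parametrize("args", [(0, 0.5, 1), (10_000, 0.5, 0),
                                      (1500, 0.5, 2), (10_000, 1.5, 1)])
    def test_bad_params(self, args):
        with pytest.raises(ParameterError):
            generate_ancestor(*args, seed=1)


class TestEvolvePair:
    def test_zero_divergence_identity(self):
        anc = generate_ancestor(20_000, 0.5, 1, seed=1)
        params = SimulationParams(length_bp=20_000, background_divergence=0.0,
                                  seed=2)
        a, b, truth = evolve_pair(anc, params)
        assert a.contigs[0][1] == anc.contigs[0][1] == b.contigs[0][1]
        assert truth.realized_background_identity == 100.0

    def test_realized_divergence_column_count(self):
        # direct column-count oracle on the known positional alignment
        d0 = 0.05
        a, b, truth = simulate_pair(SimulationParams(
            length_bp=1_000_000, background_divergence=d0, seed=11))
        sa = np.frombuffer(a.contigs[0][1].encode(), dtype=np.uint8)
        sb = np.frombuffer(b.contigs[0][1].encode(), dtype=np.uint8)
        realized = 100.0 * float(np.mean(sa == sb))
        expected = expected_pairwise_identity(d0)
        assert abs(realized - expected) < 0.5
        assert abs(truth.realized_background_identity - realized) < 1e-9

    @pytest.mark.parametrize("d0", [0.01, 0.05, 0.10])
    def test_identity_recovery_over_replicates(self, d0):
        # mean realized identity over replicates matches the analytic
        # double-hit-corrected expectation to 0.2 percentage points
        reps = [simulate_pair(SimulationParams(
            length_bp=1_000_000, background_divergence=d0, seed=s))[2]
            for s in range(20)]
        mean_realized = np.mean([t.realized_background_identity for t in reps])
        assert abs(mean_realized - expected_pairwise_identity(d0)) < 0.2

    def test_specific_intervals_cover_fraction(self):
        params = SimulationParams(length_bp=500_000,
                                  background_divergence=0.002,
                                  specific_fraction=0.08, seed=5)
        a, b, truth = simulate_pair(params)
        covered = sum(e - s for _, s, e in truth.specific_intervals_A)
        assert abs(covered / 500_000 - 0.08) < 0.005
        # intervals non-overlapping and inside contigs
        lens = a.contig_lengths
        ivs = sorted(truth.specific_intervals_A, key=lambda x: (x[0], x[1]))
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            assert c1 != c2 or e1 <= s2
        for c, s, e in ivs:
            assert 0 <= s < e <= lens[c]

    def test_divergent_blocks_realized_identity(self):
        d_blk = divergence_for_identity(87.5)
        params = SimulationParams(length_bp=400_000,
                                  background_divergence=0.002,
                                  divergent_block_fraction=0.04,
                                  divergent_block_divergence=d_blk, seed=9)
        _, _, truth = simulate_pair(params)
        assert truth.expected_block_identity == pytest.approx(87.5)
        assert abs(truth.realized_block_identity - 87.5) < 1.0
        covered = sum(e - s for _, s, e in truth.block_intervals)
        assert abs(covered / 400_000 - 0.04) < 0.005

    def test_deterministic_byte_identical(self):
        params = SimulationParams(length_bp=50_000,
                                  background_divergence=0.01,
                                  specific_fraction=0.05, seed=21)
        r1 = simulate_pair(params)
        r2 = simulate_pair(params)
        assert r1[0].contigs == r2[0].contigs
        assert r1[1].contigs == r2[1].contigs
        assert r1[2] == r2[2]

    def test_indel_length_conservation(self):
        params = SimulationParams(length_bp=100_000,
                                  background_divergence=0.01,
                                  indel_rate=2e-4, mean_indel_len=4.0, seed=13)
        a, b, truth = simulate_pair(params)
        assert len(a) == 100_000 + truth.indel_net_A
        assert len(b) == 100_000 + truth.indel_net_B
        assert truth.indel_net_A != 0 or truth.indel_net_B != 0

    @pytest.mark.parametrize("kwargs", [
        dict(background_divergence=1.5),
        dict(divergent_block_fraction=0.3, specific_fraction=0.3),
        dict(divergent_block_fraction=0.04, divergent_block_divergence=0.001,
             background_divergence=0.01),
        dict(length_bp=5000),
        dict(mean_indel_len=0.0),
    ])
    def test_invalid_params(self, kwargs):
        base = dict(length_bp=20_000, seed=1)
        base.update(kwargs)
        with pytest.raises(ParameterError):
            SimulationParams(**base)


class TestAnalyticIdentity:
    def test_inverse_roundtrip(self):
        for ident in (99.8, 99.2, 95.0, 90.0, 85.0):
            d = divergence_for_identity(ident)
            assert expected_pairwise_identity(d) == pytest.approx(ident)

    def test_double_hit_correction_direction(self):
        # realized identity exceeds the naive 1 - d expectation
        assert expected_pairwise_identity(0.10) > 90.0


class TestCassette:
    def test_length_conservation(self):
        g = generate_ancestor(10_000, 0.5, 1, seed=2)
        cass = random_cassette(1200, seed=3)
        g2, iv = insert_rdna_cassette(g, cass, "contig_1", 5000, "+")
        assert len(g2.sequence("contig_1")) == 11_200
        assert iv == ("contig_1", 5000, 6200, "+")
        assert g2.sequence("contig_1")[5000:6200] == cass

    def test_prefix_insertion(self):
        g = generate_ancestor(10_000, 0.5, 1, seed=2)
        cass = random_cassette(800, seed=4)
        g2, _ = insert_rdna_cassette(g, cass, "contig_1", 0, "+")
        assert g2.sequence("contig_1").startswith(cass)

    def test_out_of_range_position(self):
        g = generate_ancestor(10_000, 0.5, 1, seed=2)
        with pytest.raises(ParameterError):
            insert_rdna_cassette(g, random_cassette(800, seed=1),
                                 "contig_1", 10_001, "+")

    def test_short_cassette_rejected(self):
        g = generate_ancestor(10_000, 0.5, 1, seed=2)
        with pytest.raises(ParameterError):
            insert_rdna_cassette(g, "ACGT" * 50, "contig_1", 0, "+")


class TestMatFixture:
    @pytest.mark.parametrize("label", ARCHITECTURE_LABELS)
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fixture_soundness(self, label, seed):
        genome, anns = build_mat_fixture(label, seed=seed)
        arch = classify_architecture(anns, genome.contig_lengths)
        if label == "fused":
            assert arch.architecture == "fused" and not arch.edge_reassembled
        elif label == "split_edge_reassemblable":
            assert arch.architecture == "fused" and arch.edge_reassembled
        elif label == "split_unlinked":
            assert arch.architecture == "split_unlinked"
        elif label == "single_mat1-1":
            assert arch.architecture == "single_idiomorph"
            assert arch.idiomorph_present == frozenset({"mat1-1"})
        else:
            assert arch.architecture == "single_idiomorph"
            assert arch.idiomorph_present == frozenset({"mat1-2"})

    def test_pseudogene_flag(self):
        _, anns = build_mat_fixture("fused", pseudogenize_mat113=True, seed=4)
        flags = {a.gene: a.pseudogene for a in anns}
        assert flags["mat1-1-3"] is True
        assert not any(v for g, v in flags.items() if g != "mat1-1-3")

    def test_unknown_architecture(self):
        with pytest.raises(ParameterError):
            build_mat_fixture("circular", seed=0)


class TestCoverageSim:
    def test_expectations_arithmetic(self):
        p = CoverageSimParams(mean_depth=200.0, nuclear_ratio=0.5, seed=0)
        assert expected_gene_depth("APN2", p, "heterokaryon") == 200.0
        assert expected_gene_depth("mat1-1-1", p, "heterokaryon") == 100.0
        assert expected_gene_depth("mat1-2-1", p, "heterokaryon") == 100.0
        assert expected_gene_depth("mat1-1-1", p, "homokaryon") == 200.0
        p95 = CoverageSimParams(mean_depth=200.0, nuclear_ratio=0.95, seed=0)
        assert expected_gene_depth("mat1-2-1", p95, "heterokaryon") == \
            pytest.approx(10.0)

    @pytest.mark.parametrize("karyotype,mat_expect", [
        ("homokaryon", 200.0), ("heterokaryon", 100.0)])
    def test_simulated_means(self, karyotype, mat_expect):
        depths = {g: [] for g in ("APN2", "mat1-1-1", "mat1-2-1")}
        for s in range(200):
            cov = simulate_gene_coverage(
                CoverageSimParams(mean_depth=200.0, nuclear_ratio=0.5, seed=s),
                karyotype)
            for g in depths:
                depths[g].append(cov[g])
        assert np.mean(depths["APN2"]) == pytest.approx(200.0, abs=3.0)
        assert np.mean(depths["mat1-1-1"]) == pytest.approx(mat_expect, abs=3.0)
        assert np.mean(depths["mat1-2-1"]) == pytest.approx(mat_expect, abs=3.0)

    def test_bad_ratio(self):
        with pytest.raises(ParameterError):
            CoverageSimParams(nuclear_ratio=1.2)
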