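"""Reference geometry, repair models, and read simulation."""

import edlib
import numpy as np
import pytest

from ssa_spectra import (
    ErrorModel,
    LibraryDesign,
    RepairModel,
    draw_depths,
    make_reference_pair,
    merge_pair,
    read_fastq,
    revcomp,
    simulate_colony_reads,
    simulate_duplex_genotype,
    simulate_library,
    write_fastq,
)
from ssa_spectra.genotype_calling import DuplexGenotype
from ssa_spectra.synthetic_data import generate_barcodes
from ssa_spectra.variant_tracing import mm2_raw_discordance, trace_reads


class TestReferencePair:
    def test_run_geometry(self, pair, vmap):
        run = vmap.run_site
        assert pair.f_seq[run.run_start : run.run_start + 12] == "T" * 12
        # the F run is exactly 12 T's: bounded by non-T on both sides
        assert pair.f_seq[run.run_start - 1] != "T"
        assert pair.f_seq[run.run_start + 12] != "T"
        # A run is exactly 10, preceded by the MM1 A allele
        a_run_start = run.run_start + 1
        assert pair.a_seq[a_run_start : a_run_start + 10] == "T" * 10
        assert pair.a_seq[run.run_start] == vmap.sites[0].a_allele
        assert pair.a_seq[a_run_start + 10] != "T"
        assert len(pair.f_seq) - len(pair.a_seq) == 1

    def test_exactly_seven_differences_indel_aware(self, pair):
        aln = edlib.align(pair.f_seq, pair.a_seq, task="path")
        assert aln["editDistance"] == 7

    def test_anchors_unique_in_both_amplicons(self, pair, vmap):
        for site in vmap.sites:
            for anchor in (site.left_anchor, site.right_anchor):
                assert pair.f_amplicon().count(anchor) == 1
                assert pair.a_amplicon().count(anchor) == 1
                assert anchor not in pair.left_flank
                assert anchor not in pair.right_flank

    def test_deterministic_given_seed(self):
        p1, _ = make_reference_pair(seed=7)
        p2, _ = make_reference_pair(seed=7)
        p3, _ = make_reference_pair(seed=8)
        assert p1.f_seq == p2.f_seq and p1.left_flank == p2.left_flank
        assert p3.f_seq != p1.f_seq

    def test_site_positions(self, vmap):
        positions = [s.f_pos for s in vmap.sites]
        assert positions == [17, 17, 29, 55, 82, 108, 135]


class TestRepairModel:
    def test_degenerate_probabilities(self, vmap):
        rng = np.random.default_rng(0)
        g = simulate_duplex_genotype(RepairModel.pure("F"), rng)
        assert g.top == g.bottom == "F" * 7
        g = simulate_duplex_genotype(RepairModel.pure("A"), rng)
        assert g.top == g.bottom == "A" * 7
        g = simulate_duplex_genotype(RepairModel(0, 0, 1, 0), rng)
        assert (g.top, g.bottom) == ("F" * 7, "A" * 7)

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            RepairModel(0.5, 0.5, 0.5, -0.5)
        with pytest.raises(ValueError):
            RepairModel(1, 0, 0, 0, site_f_bias=(0.5,) * 6)
        with pytest.raises(ValueError):
            # end-gradient tracts need a non-increasing bias vector
            RepairModel(0, 0, 0, 1, site_f_bias=(0.5, 0.9, 0.5, 0.5, 0.5, 0.5, 0.5))

    def test_mixed_independent_site_bias_monte_carlo(self):
        bias = (0.9, 0.9, 0.8, 0.7, 0.65, 0.6, 0.55)
        model = RepairModel(0, 0, 0, 1, site_f_bias=bias, rho=0.0,
                            tract_mode="independent")
        rng = np.random.default_rng(42)
        n = 10_000
        counts = np.zeros(7)
        for _ in range(n):
            g = simulate_duplex_genotype(model, rng)
            counts += np.frombuffer(g.bottom.encode(), np.uint8) == ord("F")
        frac = counts / n
        se = np.sqrt(np.array(bias) * (1 - np.array(bias)) / n)
        assert np.all(np.abs(frac - bias) <= 3 * se)

    def test_end_gradient_is_single_switch_tract(self):
        model = RepairModel(0, 0, 0, 1)  # default non-increasing bias
        rng = np.random.default_rng(3)
        for _ in range(500):
            g = simulate_duplex_genotype(model, rng)
            # corrected (F) sites on the bottom strand form a left prefix
            assert "AF" not in g.bottom

    def test_rho_one_flat_bias_is_all_or_none(self):
        model = RepairModel(0, 0, 0, 1, site_f_bias=(0.5,) * 7, rho=1.0,
                            tract_mode="independent")
        rng = np.random.default_rng(4)
        bottoms = {simulate_duplex_genotype(model, rng).bottom for _ in range(300)}
        assert bottoms == {"F" * 7, "A" * 7}


class TestLibraryDesign:
    def test_default_design(self):
        design = LibraryDesign.default(seed=1)
        pairs = design.colony_pairs()
        assert len(pairs) == 96 and len(set(pairs)) == 96
        assert len(design.forward_barcodes) == 8
        assert len(design.reverse_barcodes) == 12

    def test_close_barcodes_rejected(self):
        rng = np.random.default_rng(0)
        barcodes = generate_barcodes(rng, 20)
        near = barcodes[0][:7] + ("A" if barcodes[0][7] != "A" else "C")
        with pytest.raises(ValueError, match="Hamming"):
            LibraryDesign(
                forward_barcodes=(barcodes[0], near) + tuple(barcodes[2:8]),
                reverse_barcodes=tuple(barcodes[8:20]),
            )

    def test_depth_distribution_band(self):
        # 3-SE band around the target mean 186 (sd 112, n=96)
        design = LibraryDesign.default(seed=1)
        depths = draw_depths(design, np.random.default_rng(5), 96)
        assert 150 <= depths.mean() <= 222
        assert depths.min() >= design.depth_min


class TestReadSimulation:
    def test_zero_error_reads_reconstruct_amplicon(self, pair, vmap, small_design):
        genotype = DuplexGenotype("F" * 7, "F" * 7)
        r1, r2, _ = simulate_colony_reads(
            genotype, pair, vmap, ErrorModel(), small_design, 0,
            np.random.default_rng(0), depth=50,
        )
        fbc, rbc = small_design.pair_for(0)
        template = fbc + pair.f_amplicon() + revcomp(rbc)
        for a, b in zip(r1, r2):
            merged = merge_pair(a, b)
            assert merged.sequence == template

    def test_slippage_rate_binomial(self, pair, vmap, small_design):
        err = ErrorModel(sub_rate=0.0, homopolymer_indel_rate=0.05)
        genotype = DuplexGenotype("F" * 7, "F" * 7)
        n = 10_000
        r1, _, _ = simulate_colony_reads(
            genotype, pair, vmap, err, small_design, 0,
            np.random.default_rng(1), depth=n,
        )
        # R1 alone spans the whole variant region; trace it directly
        calls = trace_reads([rec.sequence for rec in r1], vmap)
        frac = mm2_raw_discordance(calls, vmap)
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) <= 3 * se

    def test_strand_mixture_tracks_drawn_proportion(self, pair, vmap, small_design):
        genotype = DuplexGenotype("F" * 7, "A" * 7)
        n = 2000
        r1, _, info = simulate_colony_reads(
            genotype, pair, vmap, ErrorModel(), small_design, 3,
            np.random.default_rng(2), depth=n,
        )
        calls = trace_reads([rec.sequence for rec in r1], vmap)
        f_frac = sum(1 for c in calls if c.calls == "F" * 7) / n
        se = np.sqrt(info.strand_proportion * (1 - info.strand_proportion) / n)
        assert abs(f_frac - info.strand_proportion) <= 3 * se

    def test_overlong_amplicon_raises(self, pair, vmap):
        design = LibraryDesign.default(
            seed=2, n_colonies=12, depth_mean=40.0, depth_sd=15.0, read_len=100
        )
        with pytest.raises(ValueError, match="overlap"):
            simulate_colony_reads(
                DuplexGenotype("F" * 7, "F" * 7), pair, vmap, ErrorModel(),
                design, 0, np.random.default_rng(0), depth=1,
            )


class TestLibrarySimulation:
    def test_library_truth_and_barcodes(self, pair, vmap, no_error):
        design = LibraryDesign.default(seed=2, n_colonies=96,
                                       depth_mean=12.0, depth_sd=4.0, depth_min=3)
        sim = simulate_library(RepairModel.wild_type_tailed(), pair, vmap,
                               no_error, design, seed=9)
        assert len(sim.truth) == 96
        observed_pairs = {
            (a.sequence[:8], b.sequence[:8]) for a, b in zip(sim.r1, sim.r2)
        }
        assert observed_pairs == set(design.colony_pairs())
        assert (sim.truth["depth"] >= design.depth_min).all()
        assert len(sim.r1) == sim.truth["depth"].sum()

    def test_explicit_genotypes_and_model_lists(self, pair, vmap, no_error,
                                                small_design):
        genotypes = [DuplexGenotype("F" * 7, "A" * 7)] * small_design.n_colonies
        sim = simulate_library(genotypes, pair, vmap, no_error, small_design, seed=3)
        assert set(sim.truth["top"]) == {"F" * 7}
        with pytest.raises(ValueError, match="per colony"):
            simulate_library(genotypes[:-1], pair, vmap, no_error, small_design)

    def test_fastq_roundtrip(self, pair, vmap, no_error, small_design, tmp_path):
        sim = simulate_library(RepairModel.pure("F"), pair, vmap, no_error,
                               small_design, seed=4)
        path = tmp_path / "r1.fastq"
        write_fastq(sim.r1, path)
        back = read_fastq(path)
        assert [(r.id, r.sequence, r.quality) for r in back] == [
            (r.id, r.sequence, r.quality) for r in sim.r1
        ]
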