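"""Pair merging, L/Q filtering, and dual-barcode demultiplexing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssa_spectra import (
    ErrorModel,
    FastqRecord,
    LibraryDesign,
    MergedRead,
    MergeReject,
    RepairModel,
    demultiplex,
    filter_read,
    merge_pair,
    process_library,
    revcomp,
    simulate_library,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=40)


def _record(seq: str, rid: str = "r", q: int = 38) -> FastqRecord:
    return FastqRecord(rid, seq, chr(q + 33) * len(seq))


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestMergePair:
    def test_constructed_overlap_length(self):
        rng = np.random.default_rng(0)
        amplicon = _rand_dna(rng, 160)
        r1 = _record(amplicon[:100], "a/1")
        r2 = _record(revcomp(amplicon[60:]), "a/2")
        merged = merge_pair(r1, r2)
        assert isinstance(merged, MergedRead)
        assert merged.overlap_len == 40
        assert len(merged.sequence) == 100 + 100 - 40
        assert merged.sequence == amplicon

    def test_identical_fully_overlapping_mates(self):
        rng = np.random.default_rng(1)
        seq = _rand_dna(rng, 80)
        merged = merge_pair(_record(seq), _record(revcomp(seq)))
        assert isinstance(merged, MergedRead)
        assert merged.sequence == seq
        assert merged.overlap_len == 80

    def test_no_overlap_rejected(self):
        rng = np.random.default_rng(2)
        r1 = _record(_rand_dna(rng, 60))
        r2 = _record(_rand_dna(rng, 60))
        rejected = merge_pair(r1, r2)
        assert isinstance(rejected, MergeReject)
        assert rejected.reason == "no_overlap"

    def test_ambiguous_overlap_rejected(self):
        rng = np.random.default_rng(3)
        motif = _rand_dna(rng, 30)
        r1 = _record(_rand_dna(rng, 20) + motif + motif)
        r2 = _record(revcomp(motif + motif + _rand_dna(rng, 20)))
        rejected = merge_pair(r1, r2)
        assert isinstance(rejected, MergeReject)
        assert rejected.reason == "ambiguous"

    def test_consensus_takes_higher_quality_base(self):
        rng = np.random.default_rng(4)
        amplicon = _rand_dna(rng, 90)
        r1_seq = list(amplicon[:60])
        r1_seq[45] = "A" if amplicon[45] != "A" else "C"  # error in r1
        r1 = FastqRecord("x/1", "".join(r1_seq), chr(20 + 33) * 60)
        r2 = FastqRecord("x/2", revcomp(amplicon[30:]), chr(40 + 33) * 60)
        assert isinstance(merge_pair(r1, r2), MergeReject)  # strict mode
        merged = merge_pair(r1, r2, max_mismatch=1)
        assert merged.sequence == amplicon
        assert merged.quality[45] == 40

    @given(st.integers(0, 2**31 - 1))
    def test_merge_symmetry(self, seed):
        """Swapping mate roles yields the reverse-complementary merge."""
        rng = np.random.default_rng(seed)
        amp_len = int(rng.integers(90, 131))
        read_len = int(rng.integers((amp_len + 31) // 2 + 1, min(amp_len, 90)))
        amplicon = _rand_dna(rng, amp_len)
        r1 = _record(amplicon[:read_len], "s/1")
        r2 = _record(revcomp(amplicon[-read_len:]), "s/2")
        fwd = merge_pair(r1, r2)
        swapped = merge_pair(r2, r1)
        assert type(fwd) is type(swapped)
        if isinstance(fwd, MergedRead):
            assert fwd.sequence == amplicon
            assert revcomp(swapped.sequence) == fwd.sequence


class TestFilterRead:
    @pytest.mark.parametrize(
        "length,mean_q,kept",
        [
            (250, 40.0, False),  # L must strictly exceed 250
            (300, 35.0, False),  # Q must strictly exceed 35
            (300, 36.0, True),
            (251, 35.1, True),
        ],
    )
    def test_strict_boundaries(self, length, mean_q, kept):
        q = np.full(length, int(round(mean_q)))
        read = MergedRead("A" * length, q, mean_q, "a", "b", 40)
        assert filter_read(read) is kept


def _merged_from(seq: str) -> MergedRead:
    q = np.full(len(seq), 38)
    return MergedRead(seq, q, 38.0, "m/1", "m/2", 40)


class TestDemultiplex:
    def test_exact_match_assignment_and_trimming(self, pair):
        design = LibraryDesign.default(seed=2, n_colonies=12,
                                       depth_mean=40.0, depth_sd=15.0)
        fbc, rbc = design.pair_for(7)
        read = _merged_from(fbc + pair.f_amplicon() + revcomp(rbc))
        colonies, unassigned = demultiplex([read], design)
        assert unassigned == 0
        assert [len(c.reads) for c in colonies.values()] == [0] * 7 + [1] + [0] * 4
        assert colonies[7].reads[0].sequence == pair.f_amplicon()

    def test_single_mismatch_unassigned_by_default(self, pair):
        design = LibraryDesign.default(seed=2, n_colonies=12,
                                       depth_mean=40.0, depth_sd=15.0)
        fbc, rbc = design.pair_for(7)
        bad = ("A" if fbc[0] != "A" else "C") + fbc[1:]
        read = _merged_from(bad + pair.f_amplicon() + revcomp(rbc))
        colonies, unassigned = demultiplex([read], design)
        assert unassigned == 1
        colonies, unassigned = demultiplex([read], design, max_barcode_mismatch=1)
        assert unassigned == 0
        assert len(colonies[7].reads) == 1

    def test_duplicate_barcode_pair_raises(self):
        class BadDesign:
            forward_barcodes = ("AAAAAAAA",)
            reverse_barcodes = ("CCCCCCCC",)

            def colony_pairs(self):
                return [("AAAAAAAA", "CCCCCCCC")] * 2

        with pytest.raises(ValueError, match="duplicate"):
            demultiplex([], BadDesign())


class TestProcessLibrary:
    def test_error_free_library_fully_recovered(self, pair, vmap, small_design):
        sim = simulate_library(
            RepairModel.wild_type_tailed(), pair, vmap, ErrorModel(),
            small_design, seed=6,
        )
        colonies, counts = process_library(sim.r1, sim.r2, small_design)
        assert counts.conserved()
        assert counts.rejected_merge == counts.rejected_filter == 0
        assert counts.unassigned == 0
        # every read lands on its truth-table colony
        per_colony = {cid: len(c.reads) for cid, c in colonies.items()}
        expected = dict(zip(sim.truth["colony_id"], sim.truth["depth"]))
        assert per_colony == expected

    def test_conservation_with_errors(self, pair, vmap, small_design):
        err = ErrorModel(sub_rate=0.01, homopolymer_indel_rate=0.1)
        sim = simulate_library(
            RepairModel.wild_type_tailed(), pair, vmap, err, small_design, seed=7,
        )
        _, counts = process_library(sim.r1, sim.r2, small_design, max_mismatch=1)
        assert counts.conserved()
        assert counts.total_pairs == len(sim.r1)
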