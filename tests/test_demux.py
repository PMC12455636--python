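"""Barcode matching, pool assignment, length filter and orientation."""

import numpy as np
import pytest

from oracles import brute_force_infix_distance
from sortscreen import demux, simulate
from sortscreen.demux import (
    demultiplex,
    length_filter,
    match_barcode,
    orient_reads,
)
from sortscreen.simulate import ErrorModel, ReadRecord, revcomp, simulate_reads


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestMatchBarcode:
    def test_exact_at_read_start(self):
        read = "ACGTACGTAAAACCCCGGGGTTTT" + "T" * 100
        hit = match_barcode(read, "ACGTACGT", end="head", max_dist=2)
        assert hit.edit_distance == 0
        assert hit.start == 0
        assert read[hit.start : hit.stop] == "ACGTACGT"

    def test_one_substitution(self):
        barcode = "ACGTACGTACGT"
        read = "TT" + "ACGTACCTACGT" + "G" * 80  # one substitution inside
        hit = match_barcode(read, barcode, end="head", max_dist=2)
        assert hit is not None
        assert hit.edit_distance == 1

    def test_unrelated_read_yields_none(self):
        rng = np.random.default_rng(123)
        read = _random_dna(rng, 2000)
        barcode = _random_dna(np.random.default_rng(456), 24)
        assert match_barcode(read, barcode, end="head", max_dist=2) is None
        assert match_barcode(read, barcode, end="tail", max_dist=2) is None

    def test_tail_window_respected(self):
        barcode = "ACGTACGTACGTACGTACGTACGT"
        read = "T" * 300 + barcode
        assert match_barcode(read, barcode, end="tail", max_dist=0) is not None
        # same barcode buried mid-read is invisible from the tail window
        read2 = barcode + "T" * 300
        assert match_barcode(read2, barcode, end="tail", max_dist=0, window=150) is None

    def test_window_clipped_to_short_read(self):
        hit = match_barcode("ACGT", "ACGT", end="head", max_dist=0, window=500)
        assert hit is not None and hit.edit_distance == 0

    @pytest.mark.parametrize("case_seed", range(40))
    def test_agrees_with_brute_force_oracle(self, case_seed):
        """Error-tolerant matcher equals an all-substrings edit-distance DP."""
        rng = np.random.default_rng(1000 + case_seed)
        read = _random_dna(rng, int(rng.integers(40, 200)))
        bc_len = int(rng.integers(6, 13))
        if rng.random() < 0.6:
            # embed a mutated copy so interesting distances occur
            bc = _random_dna(rng, bc_len)
            copy = list(bc)
            for _ in range(int(rng.integers(0, 3))):
                copy[int(rng.integers(len(copy)))] = str(rng.choice(list("ACGT")))
            pos = int(rng.integers(0, len(read) - bc_len))
            read = read[:pos] + "".join(copy) + read[pos + bc_len :]
        else:
            bc = _random_dna(rng, bc_len)
        oracle_dist, _ = brute_force_infix_distance(bc, read)
        hit = match_barcode(read, bc, end="head", max_dist=len(bc), window=len(read))
        assert hit is not None
        assert hit.edit_distance == oracle_dist


class TestDemultiplex:
    def test_noise_free_reads_recover_truth_pools(self, elp2_designs, barcodes):
        lib = barcodes[(barcodes["role"] == "rev") | (barcodes["pool"] == "ELP2")]
        pools = {g: {d.genotype_key: 5 for d in elp2_designs[:4]}
                 for g in ("low", "medium", "high")}
        reads = simulate_reads(pools, elp2_designs, lib, ErrorModel(0, 0, 0),
                               30, seed=6, orf_pool="ELP2")
        assignments = demultiplex(reads, barcodes)
        truth = {r.read_id: (r.orf_pool, r.gate, r.strand) for r in reads}
        for a in assignments:
            assert a.status == "assigned"
            assert (a.orf_pool, a.gate_pool, a.strand) == truth[a.read_id]

    def test_missing_reverse_barcode_is_no_rev(self, barcodes):
        rng = np.random.default_rng(0)
        fwd = barcodes[barcodes["role"] == "fwd"].iloc[0]["sequence"]
        read = ReadRecord("r1", fwd + _random_dna(rng, 2400), "")
        (a,) = demultiplex([read], barcodes)
        assert a.status == "no_rev"

    def test_missing_forward_barcode_is_no_fwd(self, barcodes):
        rng = np.random.default_rng(1)
        rev = barcodes[barcodes["role"] == "rev"].iloc[0]["sequence"]
        read = ReadRecord("r1", _random_dna(rng, 2400) + rev, "")
        (a,) = demultiplex([read], barcodes)
        assert a.status == "no_fwd"

    def test_two_forward_barcodes_is_ambiguous(self, barcodes):
        rng = np.random.default_rng(2)
        fwd = barcodes[barcodes["role"] == "fwd"]
        rev = barcodes[barcodes["role"] == "rev"].iloc[0]["sequence"]
        read = ReadRecord(
            "r1",
            fwd.iloc[0]["sequence"] + fwd.iloc[1]["sequence"] + _random_dna(rng, 2300) + rev,
            "",
        )
        (a,) = demultiplex([read], barcodes)
        assert a.status == "ambiguous"

    def test_noisy_assignment_purity_and_recall(self, elp2_designs, barcodes):
        """At the default error model, purity >= 99% and recall >= 90%."""
        lib = barcodes[(barcodes["role"] == "rev") | (barcodes["pool"] == "ELP2")]
        pools = {g: {d.genotype_key: 5 for d in elp2_designs}
                 for g in ("low", "medium", "high")}
        reads = simulate_reads(pools, elp2_designs, lib, ErrorModel(),
                               200, seed=8, orf_pool="ELP2")
        assignments = demultiplex(reads, barcodes)
        truth = {r.read_id: (r.orf_pool, r.gate) for r in reads}
        assigned = [a for a in assignments if a.status == "assigned"]
        correct = sum((a.orf_pool, a.gate_pool) == truth[a.read_id] for a in assigned)
        assert correct / len(assigned) >= 0.99
        assert len(assigned) / len(reads) >= 0.90

    def test_empty_manifest_rejected(self, barcodes):
        with pytest.raises(ValueError):
            demultiplex([], barcodes[barcodes["role"] == "fwd"])


class TestLengthFilter:
    @pytest.mark.parametrize("length,expected", [(1999, "too_short"), (2000, "assigned")])
    def test_at_least_2kb_boundary(self, length, expected):
        read = ReadRecord("r1", "A" * length, "")
        a = demux.PoolAssignment("r1", "assigned", "ELP2", "high", 0, 0, length, "+")
        (out,) = length_filter([a], [read], min_len=2000)
        assert out.status == expected

    def test_zero_threshold_keeps_all(self):
        read = ReadRecord("r1", "A" * 5, "")
        a = demux.PoolAssignment("r1", "assigned", "ELP2", "high", 0, 0, 5, "+")
        (out,) = length_filter([a], [read], min_len=0)
        assert out.status == "assigned"

    def test_demoted_read_keeps_pool_labels(self):
        read = ReadRecord("r1", "A" * 10, "")
        a = demux.PoolAssignment("r1", "assigned", "ELP2", "high", 0, 0, 10, "+")
        (out,) = length_filter([a], [read], min_len=2000)
        assert out.status == "too_short" and out.orf_pool == "ELP2"


class TestOrientReads:
    def _assigned(self, read):
        return [demux.PoolAssignment(read.read_id, "assigned", "ELP2", "high",
                                     0, 0, len(read.sequence), "+")]

    def test_minus_strand_read_is_flipped(self, elp2_designs, barcodes, registry):
        lib = barcodes[(barcodes["role"] == "rev") | (barcodes["pool"] == "ELP2")]
        pools = {"high": {d.genotype_key: 5 for d in elp2_designs[:3]}}
        reads = simulate_reads(pools, elp2_designs, lib, ErrorModel(0, 0, 0),
                               40, seed=3, orf_pool="ELP2")
        assignments = demultiplex(reads, barcodes)
        marker = registry["CBM"].sequence
        oriented, out = orient_reads(reads, assignments, marker)
        for r in reads:
            seq = oriented[r.read_id]
            # marker must now sit in the 3' half, whatever the original strand
            pos = seq.find(marker)
            assert pos > len(seq) / 2
            if r.strand == "-":
                assert seq == revcomp(r.sequence)
            else:
                assert seq == r.sequence

    def test_read_without_marker_is_no_marker(self, registry):
        rng = np.random.default_rng(7)
        read = ReadRecord("r1", _random_dna(rng, 2500), "")
        oriented, (a,) = orient_reads([read], self._assigned(read),
                                      registry["CBM"].sequence)
        assert a.status == "no_marker"
        assert "r1" not in oriented

    def test_chimeric_reads_all_flagged(self, elp2_designs, barcodes, registry):
        lib = barcodes[(barcodes["role"] == "rev") | (barcodes["pool"] == "ELP2")]
        pools = {"high": {d.genotype_key: 5 for d in elp2_designs[:3]}}
        reads = simulate_reads(pools, elp2_designs, lib,
                               ErrorModel(0, 0, 0, chimera_prob=1.0),
                               30, seed=4, orf_pool="ELP2")
        assert all(r.chimeric for r in reads)
        assignments = demultiplex(reads, barcodes)
        oriented, out = orient_reads(reads, assignments, registry["CBM"].sequence)
        flagged = [a for a in out if a.status == "chimeric"]
        assert len(flagged) == sum(a.status != "no_rev" and a.status != "no_fwd"
                                   for a in assignments)
        assert not oriented

    def test_short_marker_rejected(self):
        read = ReadRecord("r1", "A" * 100, "")
        with pytest.raises(ValueError, match="30"):
            orient_reads([read], self._assigned(read), "ACGT")
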