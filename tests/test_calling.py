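"""Part annotation, GFF3 round-trip and genotype calling."""

import numpy as np
import pytest

from oracles import affine_sw_score, brute_force_infix_distance
from sortscreen import calling, parts
from sortscreen.calling import (
    PartHit,
    annotate_read,
    call_genotype,
    emit_gff,
    read_gff,
)
from sortscreen.parts import Part, PartRegistry
from sortscreen.simulate import ErrorModel, revcomp, simulate_reads


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _hit(part_id, role, start, stop, **kw):
    defaults = dict(strand="+", identity=1.0, coverage=1.0, score=2.0 * (stop - start))
    defaults.update(kw)
    return PartHit(part_id, role, start, stop, **defaults)


class TestAnnotateRead:
    def test_noise_free_construct_fully_annotated(self, registry, slot_parts):
        design = parts.assemble(slot_parts)
        hits = annotate_read(design.assembled_sequence, registry)
        ids = [h.part_id for h in hits]
        assert ids == ["pYTK010", "MF", "ELP2", "CBM", "cassette_display"]
        assert all(h.identity == 1.0 for h in hits)
        assert [h.start for h in hits] == sorted(h.start for h in hits)

    def test_noisy_read_recovers_same_parts(self, registry, elp2_designs, barcodes):
        lib = barcodes[(barcodes["role"] == "rev") | (barcodes["pool"] == "ELP2")]
        pools = {"high": {d.genotype_key: 1 for d in elp2_designs}}
        reads = simulate_reads(pools, elp2_designs, lib, ErrorModel(),
                               40, seed=12, orf_pool="ELP2")
        for r in reads:
            seq = r.sequence if r.strand == "+" else revcomp(r.sequence)
            hits = annotate_read(seq, registry)
            slot_ids = {h.role: h.part_id for h in hits}
            assert slot_ids["promoter"] == r.genotype_key[0]
            assert slot_ids["sp_flag"] == r.genotype_key[1]
            assert slot_ids["cds"] == r.genotype_key[2]
            assert slot_ids["fusion_4a"] == "CBM"

    def test_random_dna_yields_no_hits(self, registry):
        rng = np.random.default_rng(99)
        assert annotate_read(_random_dna(rng, 2500), registry) == []

    def test_elp_cross_hits_resolved_to_longer_repeat(self, registry):
        """An ELP4 read contains a perfect ELP2 sub-hit; the longer (higher
        scoring) repeat wins the slot."""
        reg_parts = [registry["pYTK010"], registry["MF"], registry["ELP4"],
                     registry["CBM"], registry["cassette_display"]]
        design = parts.assemble(reg_parts)
        hits = annotate_read(design.assembled_sequence, registry)
        cds_hits = [h for h in hits if h.role == "cds"]
        assert [h.part_id for h in cds_hits] == ["ELP4"]

    def test_clipped_promoter_rescued_at_reduced_coverage(self, registry, slot_parts):
        design = parts.assemble(slot_parts)
        promoter = slot_parts[0]
        clip = int(len(promoter) * 0.4)  # keep 60% of the promoter
        read = design.assembled_sequence[clip:]
        hits = annotate_read(read, registry)
        prom_hits = [h for h in hits if h.role == "promoter"]
        assert len(prom_hits) == 1
        hit = prom_hits[0]
        assert hit.part_id == "pYTK010" and hit.clipped_5p
        assert 0.5 <= hit.coverage < 0.8

    def test_empty_registry_rejected(self):
        with pytest.raises(ValueError):
            annotate_read("ACGT" * 100, PartRegistry([]))

    def test_scores_match_quadratic_alignment_oracle(self):
        """Accepted-hit scores on small reads equal (exact/SW paths) or are
        bounded by (fast path) an independent affine-gap DP optimum."""
        rng = np.random.default_rng(77)
        for trial in range(12):
            body = _random_dna(rng, 60)
            part = Part("pX", "cds", "TTCT" + body + "GGAT", "TTCT", "GGAT")
            reg = PartRegistry([part])
            read = list(_random_dna(rng, 40) + part.sequence + _random_dna(rng, 40))
            n_mut = int(rng.integers(0, 6))
            for _ in range(n_mut):  # substitutions within the embedded part
                pos = 40 + int(rng.integers(4, 60))
                read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
            read = "".join(read)
            hits = annotate_read(read, reg, min_identity=0.8, min_coverage=0.8)
            assert len(hits) == 1
            optimum = affine_sw_score(read, part.sequence)
            if n_mut == 0:
                assert hits[0].score == optimum
            else:
                assert hits[0].score <= optimum
                assert hits[0].score >= optimum - 5 * n_mut

    def test_placement_agrees_with_infix_distance_oracle(self):
        """The located window matches a brute-force all-substrings DP."""
        rng = np.random.default_rng(88)
        body = _random_dna(rng, 50)
        part = Part("pX", "cds", "TTCT" + body + "GGAT", "TTCT", "GGAT")
        reg = PartRegistry([part])
        mutated = part.sequence[:20] + part.sequence[21:]  # one deletion
        read = _random_dna(rng, 30) + mutated + _random_dna(rng, 30)
        (hit,) = annotate_read(read, reg, min_identity=0.9, min_coverage=0.9)
        dist, start = brute_force_infix_distance(part.sequence, read)
        assert dist == 1
        assert abs(hit.start - start) <= 1  # equivalent placements at one indel


class TestCallGenotype:
    def test_full_ordered_hits(self):
        hits = [
            _hit("pYTK010", "promoter", 24, 500),
            _hit("MF", "sp_flag", 496, 650),
            _hit("ELP2", "cds", 646, 1250),
            _hit("CBM", "fusion_4a", 1246, 1600),
        ]
        call = call_genotype(hits, "r1")
        assert call.call_status == "full"
        assert call.genotype_key == ("pYTK010", "MF", "ELP2")

    def test_missing_cds_is_truncated_no_cds(self):
        hits = [
            _hit("pYTK010", "promoter", 24, 500),
            _hit("MF", "sp_flag", 496, 650),
            _hit("CBM", "fusion_4a", 646, 1000),
        ]
        call = call_genotype(hits, "r1")
        assert call.call_status == "truncated_no_cds"
        assert call.promoter_id == "pYTK010" and call.cds_id is None

    def test_promoter_downstream_of_sp_is_ambiguous(self):
        hits = sorted(
            [_hit("MF", "sp_flag", 24, 180), _hit("pYTK010", "promoter", 200, 676),
             _hit("ELP2", "cds", 680, 1290), _hit("CBM", "fusion_4a", 1290, 1640)],
            key=lambda h: h.start,
        )
        assert call_genotype(hits, "r1").call_status == "ambiguous"

    def test_two_promoters_ambiguous(self):
        hits = [
            _hit("pYTK010", "promoter", 24, 500),
            _hit("pYTK011", "promoter", 510, 990),
            _hit("MF", "sp_flag", 1000, 1150),
            _hit("ELP2", "cds", 1150, 1750),
            _hit("CBM", "fusion_4a", 1750, 2100),
        ]
        assert call_genotype(hits, "r1").call_status == "ambiguous"

    def test_junction_overlap_tolerated(self):
        """Adjacent hits share the 4-nt fusion junction; still a full call."""
        hits = [
            _hit("pYTK010", "promoter", 24, 500),
            _hit("MF", "sp_flag", 496, 650),  # 4-nt overlap with promoter
            _hit("ELP2", "cds", 646, 1250),
            _hit("CBM", "fusion_4a", 1246, 1600),
        ]
        assert call_genotype(hits, "r1").call_status == "full"

    def test_fewer_slots_partial_and_none_uncallable(self):
        partial = call_genotype([_hit("pYTK010", "promoter", 24, 500)], "r1")
        assert partial.call_status == "partial"
        assert call_genotype([], "r2").call_status == "uncallable"

    def test_truncated_reads_never_called_full(self, registry, elp2_designs, barcodes):
        """CDS-less (false-high) templates are caught: promoter + sp + 4a
        present but no CDS, so the call is truncated_no_cds, never full."""
        lib = barcodes[(barcodes["role"] == "rev") | (barcodes["pool"] == "ELP2")]
        pools = {"high": {d.genotype_key: 1 for d in elp2_designs[:10]}}
        reads = simulate_reads(pools, elp2_designs, lib,
                               ErrorModel(truncation_prob=1.0),
                               40, seed=31, orf_pool="ELP2")
        assert all(r.truncated for r in reads)
        for r in reads:
            seq = r.sequence if r.strand == "+" else revcomp(r.sequence)
            hits = calling.annotate_read(seq, registry)
            call = calling.call_genotype(hits, r.read_id)
            assert call.call_status != "full"
            if call.call_status == "truncated_no_cds":
                assert call.promoter_id == r.genotype_key[0]

    def test_orientation_invariance(self, registry, slot_parts):
        """Orient-then-call equals calling the pre-oriented read."""
        design = parts.assemble(slot_parts)
        fwd = design.assembled_sequence
        hits_fwd = annotate_read(fwd, registry)
        # a minus-strand read, flipped back before annotation
        hits_flipped = annotate_read(revcomp(revcomp(fwd)), registry)
        assert call_genotype(hits_fwd, "r") == call_genotype(hits_flipped, "r")


class TestGff:
    def test_coordinates_are_one_based_inclusive(self, tmp_path):
        out = tmp_path / "x.gff3"
        emit_gff({"read1": [_hit("pYTK010", "promoter", 0, 500)]}, out)
        line = [l for l in out.read_text().splitlines() if not l.startswith("#")][0]
        cols = line.split("\t")
        assert (cols[0], cols[3], cols[4]) == ("read1", "1", "500")

    def test_empty_hit_set_writes_valid_header_only(self, tmp_path):
        out = tmp_path / "x.gff3"
        emit_gff({}, out)
        assert out.read_text().strip() == "##gff-version 3"
        assert read_gff(out) == {}

    def test_roundtrip_identical_multiset(self, registry, elp2_designs, barcodes, tmp_path):
        lib = barcodes[(barcodes["role"] == "rev") | (barcodes["pool"] == "ELP2")]
        pools = {"high": {d.genotype_key: 1 for d in elp2_designs[:20]}}
        reads = simulate_reads(pools, elp2_designs, lib, ErrorModel(),
                               100, seed=21, orf_pool="ELP2")
        oriented = {r.read_id: (r.sequence if r.strand == "+" else revcomp(r.sequence))
                    for r in reads}
        hits, _ = calling.call_reads(oriented, registry)
        out = tmp_path / "x.gff3"
        emit_gff(hits, out)
        back = read_gff(out)
        flat = lambda d: sorted(
            (rid, h.part_id, h.start, h.stop, round(h.identity, 6), round(h.coverage, 6))
            for rid, hs in d.items() for h in hs
        )
        assert flat(back) == flat(hits)
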