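"""Scaffold annotation, classification, circular reconstruction, and the
feature metrics / in-silico validations."""

import numpy as np
import pytest

from minicircles import (
    CircularSequence,
    Scaffold,
    annotate_features,
    circularize,
    classify,
    digest_insilico,
    estimate_copy_number,
    inverse_pcr,
    merge_partial,
    orf_scan,
    record_from_lengths,
    segment_scaffold,
)
from minicircles._util import at_fraction, revcomp, round_half_up, wrap_substring


def make_scaffold(seq, sid="s1"):
    return Scaffold(id=sid, seq=seq, supporting_reads=[], mean_depth=1.0)


class TestSegmentAndClassify:
    def test_two_junction_hybrid_layout(self, small_refs, small_index, pcfg):
        refs, _ = small_refs
        v = refs.virus.seq
        host = refs.get("chr2").seq
        seq = v[:500] + host[40_000:40_800] + v[2500:2845]
        ann = segment_scaffold(make_scaffold(seq), refs, pcfg, small_index)
        kinds = [refs.is_virus(b.ref_id) for b in ann.blocks]
        assert kinds == [True, False, True]
        assert ann.n_terminal_junctions == 2
        assert classify(ann) == "hybrid"

    def test_virus_only_scaffold(self, small_refs, small_index, pcfg):
        refs, _ = small_refs
        ann = segment_scaffold(
            make_scaffold(refs.virus.seq[200:1400]), refs, pcfg, small_index
        )
        assert len(ann.blocks) == 1 and ann.n_terminal_junctions == 0
        assert classify(ann) == "defective"

    def test_single_junction_broken_assembly(self, small_refs, small_index, pcfg):
        refs, _ = small_refs
        seq = refs.virus.seq[:300] + refs.get("chr1").seq[30_000:30_600]
        ann = segment_scaffold(make_scaffold(seq), refs, pcfg, small_index)
        assert ann.n_terminal_junctions == 1
        assert classify(ann) == "hybrid"

    def test_full_genome_not_defective(self, small_refs, small_index, pcfg):
        refs, _ = small_refs
        ann = segment_scaffold(
            make_scaffold(refs.virus.seq + refs.virus.seq[:60]), refs, pcfg, small_index
        )
        assert classify(ann) == "unclassified"

    def test_host_only_and_empty(self, small_refs, small_index, pcfg):
        refs, _ = small_refs
        ann = segment_scaffold(
            make_scaffold(refs.get("chr1").seq[1000:1600]), refs, pcfg, small_index
        )
        assert classify(ann) == "host_only"
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), 400))
        ann2 = segment_scaffold(make_scaffold(junk), refs, pcfg, small_index)
        assert classify(ann2) == "unclassified"


class TestCircularize:
    def _planted_circle(self, refs):
        v = refs.virus.seq
        host = refs.get("chr2").seq
        return v[:220] + host[50_000:50_800] + v[2528:2845]  # 1337 nt

    def test_end_overlap_collapse_exact_length(self, small_refs, small_index, pcfg):
        refs, _ = small_refs
        circle = self._planted_circle(refs)
        rotated = circle[400:] + circle[:400]
        scaffold_seq = rotated + rotated[:40]  # 40 nt terminal duplication
        ann = segment_scaffold(make_scaffold(scaffold_seq), refs, pcfg, small_index)
        cand = circularize(ann, refs, pcfg)
        assert cand.closure == "end_overlap"
        assert len(cand.circle.seq) == 1337
        assert cand.circle.seq == circle  # canonical rotation: origin first
        assert cand.anchored_at == 0

    def test_junction_pair_reconstruction_without_overlap(
        self, small_refs, small_index, pcfg
    ):
        refs, _ = small_refs
        circle = self._planted_circle(refs)
        # linear scaffold spanning both junctions but not closing the circle
        seq = circle[: len(circle) - 50]
        ann = segment_scaffold(make_scaffold(seq), refs, pcfg, small_index)
        assert ann.n_terminal_junctions == 2
        cand = circularize(ann, refs, pcfg)
        assert cand.closure == "junction_pair"
        assert cand.viral_arc_from_reference

    def test_linear_candidate_raises(self, small_refs, small_index, pcfg):
        refs, _ = small_refs
        seq = refs.virus.seq[:300] + refs.get("chr1").seq[30_000:30_500]
        ann = segment_scaffold(make_scaffold(seq), refs, pcfg, small_index)
        with pytest.raises(ValueError):
            circularize(ann, refs, pcfg)


class TestMergePartial:
    def test_two_halves_of_one_circle_merge(self, small_refs, small_index, pcfg):
        refs, _ = small_refs
        v = refs.virus.seq
        host = refs.get("chr1").seq
        circle = v[:200] + host[25_000:25_800] + v[2600:2845]
        half1 = circle[:700]  # contains the first junction
        half2 = circle[600:]  # overlaps 100 nt, contains the second junction
        a1 = segment_scaffold(make_scaffold(half1, "h1"), refs, pcfg, small_index)
        a2 = segment_scaffold(make_scaffold(half2, "h2"), refs, pcfg, small_index)
        assert a1.n_terminal_junctions == a2.n_terminal_junctions == 1
        merged, leftovers, ambiguous = merge_partial([a1, a2], pcfg)
        assert not ambiguous and len(merged) == 1 and leftovers == []
        assert merged[0][1] == circle

    def test_halves_of_different_circles_do_not_merge(
        self, small_refs, small_index, pcfg
    ):
        refs, _ = small_refs
        v = refs.virus.seq
        h1 = refs.get("chr1").seq
        h2 = refs.get("chr2").seq
        a1 = segment_scaffold(
            make_scaffold(v[:200] + h1[25_000:25_600], "x1"), refs, pcfg, small_index
        )
        a2 = segment_scaffold(
            make_scaffold(h2[45_000:45_600] + v[2600:2845], "x2"), refs, pcfg, small_index
        )
        merged, leftovers, ambiguous = merge_partial([a1, a2], pcfg)
        assert merged == [] and len(leftovers) == 2

    def test_empty_input(self, pcfg):
        assert merge_partial([], pcfg) == ([], [], False)


class TestFeatureArithmetic:
    def test_printed_row_reproduction(self):
        r = record_from_lengths("MC#1", viral_length=580, host_length=735)
        assert r.total_length == 1315
        assert round_half_up(r.viral_percent, 1) == 44.1
        r2 = record_from_lengths("scf#33", viral_length=763, host_length=478)
        assert r2.total_length == 1241
        assert round_half_up(r2.viral_percent, 2) == 61.48

    def test_at_percent_trivial(self):
        r = record_from_lengths("x", 2, 2, viral_seq="AT", host_seq="ATAT")
        assert r.at_host == 100.0

    def test_full_record_from_planted_circle(self, small_refs, small_index, pcfg):
        refs, _ = small_refs
        v = refs.virus.seq
        host = refs.get("chr2").seq
        circle = v[:220] + host[50_000:50_800] + v[2528:2845]
        ann = segment_scaffold(make_scaffold(circle, "c"), refs, pcfg, small_index)
        rec = annotate_features(
            CircularSequence("c", circle), ann, refs, pcfg
        )
        assert rec.total_length == 1337
        assert rec.viral_length + rec.host_length == rec.total_length
        assert rec.viral_coord_string.startswith("1-")
        assert rec.host_locus[0] == "chr2"
        lo, hi = rec.host_locus[1]
        assert lo <= 50_001 + 5 and hi >= 50_795
        expect_at = 100 * at_fraction(host[50_000:50_800])
        assert abs(rec.at_host - expect_at) < 1.5


class TestOrfScan:
    def _orf_seq(self, n_codons=100):
        rng = np.random.default_rng(3)
        codons = ["ATG"]
        safe = [c for c in
                ("GCT GCC GCA GCG TGT TGC GAT GAC GAA GAG TTT TTC GGT GGC "
                 "CAT CAC ATT ATC AAA AAG CTG CTC ATG AAT AAC CCT CCG CAA "
                 "CAG CGT CGC TCT TCC ACT ACC GTT GTC TGG TAT TAC").split()]
        codons += list(rng.choice(safe, n_codons - 1))
        return "".join(codons) + "TAA"

    def test_explicit_orf_found(self):
        seq = self._orf_seq(100)
        orfs = orf_scan(seq, circular=False, min_codons=100)
        assert len([o for o in orfs if o["strand"] == "+"]) == 1
        assert orfs[0]["n_codons"] == 100

    def test_at_rich_sequence_is_orf_free(self):
        """Under an AT-rich null composition, 900-nt sequences essentially
        never contain a 100-codon ORF (stop codons are AT-rich too)."""
        empty = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            p = [0.35, 0.15, 0.15, 0.35]
            seq = "".join(rng.choice(list("ACGT"), 900, p=p))
            if not orf_scan(seq, circular=False, min_codons=100):
                empty += 1
        assert empty >= 95

    def test_wraparound_orf_needs_circular_flag(self):
        seq = self._orf_seq(100)
        cut = len(seq) // 2
        rotated = seq[cut:] + seq[:cut]
        assert orf_scan(rotated, circular=True, min_codons=100)
        plus_linear = [o for o in orf_scan(rotated, circular=False, min_codons=100)]
        assert not plus_linear


class TestDigest:
    def test_single_site_returns_genome_length(self, small_refs):
        refs, _ = small_refs
        frags = digest_insilico(refs.virus, "GAATTC")
        assert frags == [2845]

    def test_two_sites_fragment_arithmetic(self):
        rng = np.random.default_rng(4)
        clean = "".join(rng.choice(list("ACGT"), 1500)).replace("GAATTC", "GAATTA")
        circ_seq = (clean[:100] + "GAATTC" + clean[106:500] + "GAATTC" + clean[506:])[:1500]
        frags = digest_insilico(CircularSequence("c", circ_seq), "GAATTC")
        assert frags is not None
        assert sum(frags) == 1500
        assert 400 in frags and 1100 in frags

    def test_uncut_marker(self):
        circ = CircularSequence("c", "ACGTAC" * 100)
        assert digest_insilico(circ, "GAATTC") is None

    def test_fragment_sum_invariant(self, small_refs):
        refs, _ = small_refs
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(500, 3000))
            seq = "".join(rng.choice(list("ACGT"), n))
            frags = digest_insilico(CircularSequence("x", seq), "GAAT")
            if frags is not None:
                assert sum(frags) == n


class TestInversePcr:
    def _circle(self, small_refs):
        refs, _ = small_refs
        v = refs.virus.seq
        host = refs.get("chr1").seq
        return CircularSequence("c", v[:220] + host[45_000:45_800] + v[2528:2845])

    def test_outward_primers_amplify_across_both_junctions(self, small_refs):
        circ = self._circle(small_refs)
        seq = circ.seq
        # primers inside the host block (positions 220..1020), outward facing
        fwd = seq[700:720]  # walks right, across the downstream junction
        rev = revcomp(seq[500:520])  # binds plus strand at 500..520
        res = inverse_pcr(circ, fwd, rev)
        assert len(res["products"]) == 1 and not res["ambiguous"]
        prod = res["products"][0]
        gap = 700 - 520  # inter-primer gap skipped by the product
        assert prod["length"] == len(seq) - gap
        assert prod["seq"] == wrap_substring(seq, 700, prod["length"])

    def test_inverted_primers_on_linear_template_fail(self, small_refs):
        circ = self._circle(small_refs)
        linear = CircularSequence("l", circ.seq, is_circular=False)
        fwd = circ.seq[700:720]
        rev = revcomp(circ.seq[500:520])
        res = inverse_pcr(linear, fwd, rev)
        assert res["products"] == []

    def test_absent_primer_no_product(self, small_refs):
        circ = self._circle(small_refs)
        res = inverse_pcr(circ, "ACGTACGTACGTACGTACG", revcomp(circ.seq[500:520]))
        assert res["products"] == []


class TestCopyNumber:
    def test_identity_and_zero_cases(self, small_refs, small_index, pcfg):
        from minicircles import ReadPair, map_all

        refs, _ = small_refs
        chrom = refs.get("chr1").seq
        pairs = [
            ReadPair(
                f"p{i}", chrom[5000 + 40 * i : 5076 + 40 * i], [35] * 76,
                revcomp(chrom[5300 + 40 * i : 5376 + 40 * i]), [35] * 76,
            )
            for i in range(30)
        ]
        store = map_all(small_index, pairs, pcfg)
        region = ("chr1", 5100, 5900)
        assert estimate_copy_number(store, region, region) == 1.0
        assert estimate_copy_number(store, ("chr1", 20_000, 20_400), region) == 0.0
        assert estimate_copy_number(store, region, ("chr1", 20_000, 20_400)) is None

    def test_region_size_validated(self, small_refs, small_index, pcfg):
        from minicircles import map_all

        store = map_all(small_index, [], pcfg)
        with pytest.raises(ValueError):
            estimate_copy_number(store, ("chr1", 0, 100), ("chr1", 0, 1000))
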