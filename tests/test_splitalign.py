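"""Seed-and-extend split alignment: exact placement, chimera splitting,
identity bookkeeping, circular wrap handling, and the alignment store."""

import numpy as np

from minicircles import AlignmentStore, ReadPair, map_all, map_read
from minicircles._util import revcomp


def ref_substring(refs, ref_id, start, end):
    ref = refs.get(ref_id)
    if ref.is_circular:
        doubled = ref.seq + ref.seq
        return doubled[start:end]
    return ref.seq[start:end]


class TestMapRead:
    def test_exact_host_read_single_segment(self, small_refs, small_index, pcfg):
        refs, _ = small_refs
        read = refs.get("chr1").seq[5000:5076]
        segs = map_read(small_index, read, pcfg)
        assert len(segs) == 1
        s = segs[0]
        assert (s["ref_id"], s["ref_start"], s["ref_end"]) == ("chr1", 5000, 5076)
        assert s["identity"] == 1.0 and s["strand"] == "+"

    def test_chimeric_read_splits_at_planted_offset(self, small_refs, small_index, pcfg):
        refs, _ = small_refs
        v = refs.virus.seq
        read = v[2845 - 46 :] + refs.get("chr2").seq[30000:30030]
        segs = map_read(small_index, read, pcfg)
        assert len(segs) == 2
        a, b = sorted(segs, key=lambda s: s["read_start"])
        assert a["ref_id"] == "virus" and (a["read_start"], a["read_end"]) == (0, 46)
        assert b["ref_id"] == "chr2" and b["ref_start"] == 30000

    def test_scattered_errors_reject_full_length_alignment(self, small_refs, small_index, pcfg):
        refs, _ = small_refs
        read = list(refs.get("chr1").seq[8000:8076])
        for p in (7, 22, 37, 52, 67):  # 5 substitutions, identity 71/76 = 0.93
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        segs = map_read(small_index, "".join(read), pcfg)
        assert all(s["read_end"] - s["read_start"] < 76 - 16 + 1 for s in segs)
        assert all(s["identity"] >= 0.95 for s in segs)

    def test_origin_crossing_read_wrap_split(self, small_refs, small_index, pcfg):
        refs, _ = small_refs
        v = refs.virus.seq
        read = (v + v)[2840 : 2840 + 76]  # oracle: doubled linearization
        segs = map_read(small_index, read, pcfg)
        assert len(segs) == 2
        assert {s["wrap_group"] for s in segs} == {0}
        assert {s["order_index"] for s in segs} == {0}
        first, second = sorted(segs, key=lambda s: s["read_start"])
        assert (first["ref_start"], first["ref_end"]) == (2840, 2845)
        assert (second["ref_start"], second["ref_end"]) == (0, 71)
        assert all(s["ref_end"] <= 2845 for s in segs)

    def test_strand_symmetry(self, small_refs, small_index, pcfg):
        refs, _ = small_refs
        read = refs.get("chr1").seq[12000:12076]
        fwd = map_read(small_index, read, pcfg)
        rev = map_read(small_index, revcomp(read), pcfg)
        assert len(fwd) == len(rev) == 1
        f, r = fwd[0], rev[0]
        assert (f["ref_id"], f["ref_start"], f["ref_end"]) == (
            r["ref_id"], r["ref_start"], r["ref_end"],
        )
        assert {f["strand"], r["strand"]} == {"+", "-"}
        assert (r["read_start"], r["read_end"]) == (
            76 - f["read_end"], 76 - f["read_start"],
        )

    def test_unmappable_read_empty(self, small_index, pcfg):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), 76))
        # random 76-mers share no 15-mer with the references w.h.p.
        assert map_read(small_index, junk, pcfg) in ([], map_read(small_index, junk, pcfg))

    def test_stored_identity_matches_recomputation(self, small_refs, small_index, pcfg):
        refs, _ = small_refs
        rng = np.random.default_rng(5)
        chrom = refs.get("chr1").seq
        for _ in range(30):
            p = int(rng.integers(0, len(chrom) - 76))
            read = list(chrom[p : p + 76])
            if rng.random() < 0.5:
                q = int(rng.integers(0, 76))
                read[q] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[q]]
            for s in map_read(small_index, "".join(read), pcfg):
                piece = "".join(read)[s["read_start"] : s["read_end"]]
                if s["strand"] == "-":
                    piece = revcomp(piece)
                tgt = ref_substring(refs, s["ref_id"], s["ref_start"], s["ref_end"])
                ident = sum(a == b for a, b in zip(piece, tgt)) / len(tgt)
                assert abs(ident - s["identity"]) < 1e-9


class TestStore:
    def test_round_trip_tsv(self, small_refs, small_index, pcfg, tmp_path):
        refs, _ = small_refs
        chrom = refs.get("chr1").seq
        pairs = [
            ReadPair("p1", chrom[100:176], [35] * 76, revcomp(chrom[400:476]), [35] * 76),
            ReadPair("p2", chrom[900:976], [35] * 76, revcomp(chrom[1200:1276]), [35] * 76),
        ]
        store = map_all(small_index, pairs, pcfg)
        path = tmp_path / "aln.tsv"
        store.to_tsv(path)
        back = AlignmentStore.from_tsv(path)
        assert back.df.equals(store.df)

    def test_empty_stream(self, small_index, pcfg):
        store = map_all(small_index, [], pcfg)
        assert len(store.df) == 0
        assert len(store.query_region("chr1", 0, 1000)) == 0

    def test_region_query_depth(self, small_refs, small_index, pcfg):
        refs, _ = small_refs
        chrom = refs.get("chr1").seq
        pairs = [
            ReadPair("p1", chrom[100:176], [35] * 76, revcomp(chrom[300:376]), [35] * 76)
        ]
        store = map_all(small_index, pairs, pcfg)
        assert set(store.query_region("chr1", 150, 160)["read_id"]) == {"p1"}
        assert store.depth("chr1", 100, 176).min() == 1
        assert store.depth("chr1", 200, 250).max() == 0


def test_split_detection_rate_on_error_free_library(planted_template, small_refs, small_index, pcfg):
    """Error-free reads whose breakpoint sits >= 16 nt from both ends must
    essentially always yield a split alignment (truth-table comparison)."""
    from minicircles import SimulationConfig, simulate_library

    refs, _ = small_refs
    t = planted_template
    cfg = SimulationConfig(
        seed=13, n_host_chrom=2, host_chrom_length=60_000,
        per_base_error=0.0, background_depth=1.0,
    )
    pairs, truth = simulate_library([t], refs, cfg)
    L = len(t.seq)
    # the virus->host breakpoint position in template coordinates
    v = sum(b - a + 1 for a, b in t.viral_segments) - t.microhomology_len[0]
    bp_list = [v]
    n_check, n_split = 0, 0
    store = map_all(small_index, [p for p in pairs], pcfg)
    split_ids = set(map(tuple, store.split_mates()[["read_id", "mate"]].values))
    for _, r in truth.iterrows():
        if r.source_id != t.id:
            continue
        s, l = int(r.frag_start), int(r.frag_len)
        reads = [(1, s), (2, (s + l - 76) % L)] if not r.flipped else [(2, s), (1, (s + l - 76) % L)]
        for mate, rs in reads:
            for bp in bp_list:
                rel = (bp - rs) % L
                if 16 <= rel <= 60:
                    n_check += 1
                    if (r.pair_id, mate) in split_ids:
                        n_split += 1
    assert n_check > 0
    assert n_split / n_check >= 0.99
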