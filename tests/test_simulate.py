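"""Generator contracts: genome landmarks, template geometry, library noise
model, and determinism."""

import gzip

import numpy as np
import pytest

from minicircles import (
    CircularSequence,
    SimulationConfig,
    make_defective,
    make_host_genome,
    make_minicircle,
    make_virus_genome,
    simulate_library,
)
from minicircles._util import at_fraction, revcomp, wrap_substring
from minicircles.seqio import write_fastq_pairs


def wrap_count(seq: str, motif: str) -> int:
    doubled = seq + seq[: len(motif) - 1]
    return sum(
        1 for i in range(len(seq)) if doubled[i : i + len(motif)] == motif
    )


class TestVirusGenome:
    def test_default_genome_landmarks(self):
        cfg = SimulationConfig(seed=5)
        v = make_virus_genome(cfg)
        assert len(v) == 2845 and v.is_circular
        assert v.seq.startswith("TAATATTAC")
        assert wrap_count(v.seq, "TAATATTAC") == 1
        assert wrap_count(v.seq, "GAATTC") == 1

    def test_tiny_genome_with_motif_at_position_one(self):
        cfg = SimulationConfig(
            seed=1, virus_length=30, intergenic_span=(28, 3), ecori_pos=15
        )
        v = make_virus_genome(cfg)
        assert len(v) == 30
        assert v.seq.startswith("TAATATTAC")

    def test_determinism_and_seed_sensitivity(self):
        a = make_virus_genome(SimulationConfig(seed=7))
        b = make_virus_genome(SimulationConfig(seed=7))
        c = make_virus_genome(SimulationConfig(seed=8))
        assert a.seq == b.seq
        assert sum(x != y for x, y in zip(a.seq, c.seq)) > 0

    def test_motif_longer_than_genome_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, virus_length=8, intergenic_span=(8, 1), ecori_pos=1)


class TestHostGenome:
    def test_chromosome_count_and_length(self):
        cfg = SimulationConfig(seed=2, n_host_chrom=2, host_chrom_length=50_000)
        refs, windows = make_host_genome(cfg)
        assert len(refs.hosts) == 2
        assert all(len(h) == 50_000 for h in refs.hosts)
        assert not refs.hosts[0].is_circular and refs.virus.is_circular

    def test_at_windows_match_target(self):
        cfg = SimulationConfig(
            seed=3, n_host_chrom=2, host_chrom_length=50_000, host_at_fraction=0.71
        )
        refs, windows = make_host_genome(cfg)
        for cid, lo, hi in windows:
            at = 100 * at_fraction(refs.get(cid).seq[lo:hi])
            assert 69.0 <= at <= 73.0

    def test_same_seed_reproduces(self):
        cfg = SimulationConfig(seed=4, n_host_chrom=1, host_chrom_length=40_000)
        r1, w1 = make_host_genome(cfg)
        r2, w2 = make_host_genome(cfg)
        assert [h.seq for h in r1.hosts] == [h.seq for h in r2.hosts]
        assert w1 == w2


class TestMinicircleTemplates:
    def test_explicit_geometry_with_homology_adjustment(self, small_refs, small_sim_cfg):
        """Viral arms 1-172 + 2435-2845 (583 nt of maximal intervals) with a
        735-nt host fragment: 1318 nt before homology adjustment, 1315 with a
        3-nt junction homology (interval-arithmetic oracle)."""
        refs, windows = small_refs
        cid, lo, hi = windows[1]
        frag = (cid, (lo + 101, lo + 100 + 735), "+")
        plain = make_minicircle(
            refs.virus, refs, small_sim_cfg,
            template_id="plain",
            viral_segments=[(1, 172), (2435, 2845)],
            host_fragment=frag,
        )
        assert len(plain.seq) == 172 + 411 + 735 == 1318
        adjusted = make_minicircle(
            refs.virus, refs, small_sim_cfg,
            template_id="adj",
            viral_segments=[(1, 172), (2435, 2845)],
            host_fragment=frag,
            microhomology=(3, 0),
        )
        assert len(adjusted.seq) == 1315

    def test_sampled_templates_respect_bounds(self):
        # local genome: sampling imprints junction homology into host windows
        cfg = SimulationConfig(seed=42, n_host_chrom=2, host_chrom_length=60_000)
        small_sim_cfg = cfg
        refs, windows = make_host_genome(cfg)
        rng = np.random.default_rng(1)
        for i in range(60):
            t = make_minicircle(
                refs.virus, refs, small_sim_cfg, rng,
                template_id=f"t{i}", window=windows[i % len(windows)],
            )
            total = len(t.seq)
            assert 1241 <= total <= 1572
            _, (h1, h2m), _ = t.host_locus
            host_phys = (h2m - h1 + 1) - t.microhomology_len[1]
            assert 735 <= host_phys <= 1058
            # composition: length = sum(segments) - sum(homology)
            seg = sum(b - a + 1 for a, b in t.viral_segments) + (h2m - h1 + 1)
            assert total == seg - sum(t.microhomology_len)
            # the full origin motif is inside the first viral segment
            a, b = t.viral_segments[0]
            assert a == 1 and b >= len(small_sim_cfg.origin_motif)

    def test_template_sequence_matches_references(self):
        cfg = SimulationConfig(seed=42, n_host_chrom=2, host_chrom_length=60_000)
        small_sim_cfg = cfg
        refs, windows = make_host_genome(cfg)
        rng = np.random.default_rng(9)
        t = make_minicircle(
            refs.virus, refs, small_sim_cfg, rng, template_id="x",
            window=windows[2],
        )
        v = refs.virus.seq
        a_max = t.viral_segments[0][1]
        b = t.viral_segments[1][0]
        mh1, mh2 = t.microhomology_len
        arc = wrap_substring(v, b - 1, (len(v) - b + 1) + (a_max - mh1))
        assert t.seq.startswith(v[b - 1 :])
        assert t.seq[: len(arc)] == arc

    def test_defective_lengths_and_origin_rule(self, small_refs):
        refs, _ = small_refs
        d = make_defective(refs.virus, [(1, 500), (2000, 2845)])
        assert len(d.seq) == 500 + 846 == 1346
        assert d.host_locus is None and d.klass == "defective"
        full = make_defective(refs.virus, [(1, 2845)])
        assert len(full.seq) == 2845 and full.junctions == []
        with pytest.raises(ValueError):
            make_defective(refs.virus, [(100, 600), (2000, 2845)])


class TestLibrary:
    def _one_template_cfg(self, seed=21, err=0.002, bg=0.0):
        return SimulationConfig(
            seed=seed, n_host_chrom=1, host_chrom_length=30_000,
            per_base_error=err, background_depth=bg,
        )

    def _template(self, cfg, copy_number=15.0):
        refs, windows = make_host_genome(cfg)
        rng = np.random.default_rng(3)
        t = make_minicircle(
            refs.virus, refs, cfg, rng, template_id="tpl",
            copy_number=copy_number, window=windows[0],
        )
        return refs, t

    def test_depth_and_wraparound_coverage(self):
        cfg = self._one_template_cfg(bg=1.0)
        refs, t = self._template(cfg, copy_number=30.0)
        pairs, truth = simulate_library([t], refs, cfg)
        sub = truth[truth.source_id == "tpl"]
        L = len(t.seq)
        cov = np.zeros(L)
        for _, r in sub.iterrows():
            s, l = int(r.frag_start), int(r.frag_len)
            for i in list(range(0, 76)) + list(range(l - 76, l)):
                cov[(s + i) % L] += 1
        expected = cfg.background_depth * 30.0
        assert abs(cov.mean() - expected) / expected < 0.15
        # wrap-around: fragments cross the circle origin, no forbidden zone
        assert ((sub.frag_start + sub.frag_len) > L).any()
        assert cov.min() > 0

    def test_error_free_reads_match_template_exactly(self):
        cfg = self._one_template_cfg(err=0.0, bg=1.0)
        refs, t = self._template(cfg)
        pairs, truth = simulate_library([t], refs, cfg)
        for p, (_, r) in zip(pairs, truth.iterrows()):
            if r.source_id != "tpl":
                continue
            frag = wrap_substring(t.seq, int(r.frag_start), int(r.frag_len))
            s1, s2 = (p.seq2, p.seq1) if r.flipped else (p.seq1, p.seq2)
            assert s1 == frag[:76] or len(frag) < 76
            assert s2 == revcomp(frag)[:76] or len(frag) < 76

    def test_fixed_seed_fastq_byte_identical(self, tmp_path):
        cfg = self._one_template_cfg(bg=1.0)
        refs, t = self._template(cfg)
        for tag in ("a", "b"):
            pairs, _ = simulate_library([t], refs, cfg)
            write_fastq_pairs(tmp_path / f"r{tag}", pairs)
        for mate in (1, 2):
            b1 = gzip.open(tmp_path / f"ra_{mate}.fastq.gz").read()
            b2 = gzip.open(tmp_path / f"rb_{mate}.fastq.gz").read()
            assert b1 == b2

    def test_empty_inputs_warn_not_raise(self):
        cfg = self._one_template_cfg(bg=0.0)
        refs, _ = make_host_genome(cfg)
        with pytest.warns(UserWarning):
            pairs, truth = simulate_library([], refs, cfg)
        assert pairs == []
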