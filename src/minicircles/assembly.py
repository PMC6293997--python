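"""Read recovery around selected junctions and targeted consensus assembly.

Recovery follows the detection design: every read with an alignment inside
the recovery window around either side of a selected junction is pulled out
together with its mate, aligned or not.

Assembly is a greedy overlap walk: starting from a seed read, the contig is
extended by the read giving the longest consistent suffix-prefix overlap,
with a per-step majority vote over all overlapping candidates deciding the
next base whenever reads disagree (the vote is what keeps a walk on its own
molecule where several circular molecules share identical viral sequence).
The final sequence is a per-column majority consensus over all placed reads.
Everything is deterministic under a fixed input order.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np

from ._util import revcomp
from .config import PipelineConfig
from .records import Junction, ReadPair, ReferenceSet, Scaffold

_ANCHOR_K = 20  # prefix anchor length for overlap candidate lookup


def junction_windows(
    j: Junction, refs: ReferenceSet, cfg: PipelineConfig
) -> list[tuple[str, int, int]]:
    """Recovery windows (ref, start, end) around both sides of a junction;
    clipped at linear reference ends, wrap-aware (split in two) on the
    circular virus."""
    half = cfg.recovery_window // 2 if cfg.recovery_mode == "centered" else cfg.recovery_window
    out = []
    for side in (j.side_a, j.side_b):
        ref = refs.get(side.ref_id)
        n = len(ref.seq)
        lo, hi = side.pos - half, side.pos + half
        if ref.is_circular:
            if hi - lo >= n:
                out.append((side.ref_id, 0, n))
            else:
                lo %= n
                hi %= n
                if lo < hi:
                    out.append((side.ref_id, lo, hi))
                else:
                    out.append((side.ref_id, lo, n))
                    out.append((side.ref_id, 0, hi))
        else:
            out.append((side.ref_id, max(0, lo), min(n, hi)))
    return out


def recover_reads(
    store,
    junctions: list[Junction],
    pairs: list[ReadPair],
    refs: ReferenceSet,
    cfg: PipelineConfig,
) -> list[ReadPair]:
    """All pairs with a mate aligned inside any junction window (the other
    mate rides along), deduplicated, in input order."""
    wanted: set[str] = set()
    for j in junctions:
        for ref, lo, hi in junction_windows(j, refs, cfg):
            sub = store.query_region(ref, lo, hi)
            wanted.update(sub["read_id"])
    return [p for p in pairs if p.id in wanted]


# ------------------------------------------------------------- grouping ----

_GROUP_TOL = 4000  # host-side clustering distance for junctions of one locus


def group_junctions(
    junctions: list[Junction], refs: ReferenceSet
) -> list[list[Junction]]:
    """Group selected junctions into per-locus assembly targets: virus-host
    junctions sharing a host locus (both breakpoints of one circular molecule
    land within a few kb) form one group; each virus-virus junction is its
    own group.  Hybrid groups come first, sorted by host locus."""
    hybrid = [j for j in junctions if j.jtype == "virus-host"]
    vv = [j for j in junctions if j.jtype == "virus-virus"]

    def host_side(j: Junction):
        return j.side_b if j.side_b.ref_id != refs.virus_id else j.side_a

    hybrid.sort(key=lambda j: (host_side(j).ref_id, host_side(j).pos))
    groups: list[list[Junction]] = []
    for j in hybrid:
        h = host_side(j)
        if groups:
            h0 = host_side(groups[-1][-1])
            if h.ref_id == h0.ref_id and abs(h.pos - h0.pos) <= _GROUP_TOL:
                groups[-1].append(j)
                continue
        groups.append([j])
    for j in sorted(vv, key=lambda j: (j.side_a.pos, j.side_b.pos)):
        groups.append([j])
    return groups


def recover_group_reads(
    store,
    group: list[Junction],
    pairs_by_id: dict[str, ReadPair],
    refs: ReferenceSet,
    cfg: PipelineConfig,
) -> list[ReadPair]:
    """Reads for one assembly target.  For hybrid groups only the host-side
    windows are used (the virus-side window covers the whole small viral
    genome and would drag in every viral read of every molecule); mates
    reach the viral arms.  Virus-virus groups use both sides."""
    wanted: set[str] = set()
    for j in group:
        if j.jtype == "virus-host":
            sides = [s for s in (j.side_a, j.side_b) if s.ref_id != refs.virus_id]
        else:
            sides = [j.side_a, j.side_b]
        for side in sides:
            sub = Junction(side_a=side, side_b=side, support=j.support)
            for ref, lo, hi in junction_windows(sub, refs, cfg):
                wanted.update(store.query_region(ref, lo, hi)["read_id"])
    return [pairs_by_id[i] for i in sorted(wanted) if i in pairs_by_id]


# ------------------------------------------------------------- assembly ----


def _flatten(reads: list[ReadPair], min_len: int) -> list[tuple[str, str]]:
    out = []
    for p in reads:
        for mate, seq in ((1, p.seq1), (2, p.seq2)):
            if len(seq) >= min_len:
                out.append((f"{p.id}/{mate}", seq))
    return out


class _ReadSet:
    """Deduplicated oriented read universe with prefix-anchor lookup."""

    def __init__(self, reads: list[tuple[str, str]]):
        bykey: dict[str, list[str]] = defaultdict(list)
        for rid, seq in sorted(reads):
            bykey[seq.upper()].append(rid)
        self.seqs = sorted(bykey)  # deterministic key order
        self.ids = {s: bykey[s] for s in self.seqs}
        self.mult = {s: len(bykey[s]) for s in self.seqs}
        self.prefix: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for s in self.seqs:
            if len(s) >= _ANCHOR_K:
                self.prefix[s[:_ANCHOR_K]].append((s, +1))
                rc = revcomp(s)
                self.prefix[rc[:_ANCHOR_K]].append((s, -1))

    def oriented(self, key: str, orient: int) -> str:
        return key if orient > 0 else revcomp(key)


def _mismatches(a: str, b: str, limit: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


def _extend_right(
    contig: str,
    rs: _ReadSet,
    used: set[str],
    placements: list[tuple[str, int, int]],
    cfg: PipelineConfig,
    read_len: int,
) -> str:
    placed = {(k, o, off) for k, o, off in placements}
    # the scan window must exceed read length + the largest possible step,
    # or reads can be jumped over without ever being consumed
    window = read_len + _ANCHOR_K + (read_len - cfg.min_overlap) + 8
    while True:
        tail_from = max(0, len(contig) - window)
        tail = contig[tail_from:]
        cands = []  # (key, orient, offset, overlap, ext)
        for jpos in range(len(tail) - _ANCHOR_K + 1):
            for key, orient in rs.prefix.get(tail[jpos : jpos + _ANCHOR_K], ()):
                off = tail_from + jpos
                ovl = len(contig) - off
                seq = rs.oriented(key, orient)
                if ovl < cfg.min_overlap:
                    continue
                if ovl >= len(seq):
                    # read fully inside the contig: consume it
                    lim = max(1, len(seq) // 32)
                    if _mismatches(contig[off : off + len(seq)], seq, lim) <= lim:
                        used.add(key)
                        if (key, orient, off) not in placed:
                            placed.add((key, orient, off))
                            placements.append((key, orient, off))
                    continue
                ext = len(seq) - ovl
                lim = max(1, ovl // 32)
                if _mismatches(contig[off:], seq[:ovl], lim) > lim:
                    continue
                cands.append((key, orient, off, ovl, ext))
        if not cands:
            return contig
        # place (for consensus) every consistent overlapping read
        fresh = []
        for key, orient, off, ovl, ext in cands:
            if (key, orient, off) not in placed:
                placed.add((key, orient, off))
                placements.append((key, orient, off))
            if key not in used:
                fresh.append((key, orient, off, ovl, ext))
        if not fresh:
            return contig
        votes = Counter()
        for key, orient, off, ovl, ext in fresh:
            votes[rs.oriented(key, orient)[ovl]] += rs.mult[key]
        winner = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        agree = [
            c
            for c in fresh
            if rs.oriented(c[0], c[1])[c[3]] == winner
        ]
        if not agree:
            return contig
        key, orient, off, ovl, ext = sorted(
            agree, key=lambda c: (-c[4], c[0], c[1])
        )[0]
        contig = contig + rs.oriented(key, orient)[ovl:]
        used.add(key)


def _recruit(
    contig: str,
    rs: _ReadSet,
    used: set[str],
    placements: list[tuple[str, int, int]],
) -> None:
    """Sweep the whole contig, consuming and placing every read it fully
    contains (consensus support + prevents re-seeding from leftovers)."""
    placed = {(k, o, off) for k, o, off in placements}
    for jpos in range(len(contig) - _ANCHOR_K + 1):
        for key, orient in rs.prefix.get(contig[jpos : jpos + _ANCHOR_K], ()):
            seq = rs.oriented(key, orient)
            if jpos + len(seq) > len(contig):
                continue
            lim = max(1, len(seq) // 32)
            if _mismatches(contig[jpos : jpos + len(seq)], seq, lim) <= lim:
                used.add(key)
                if (key, orient, jpos) not in placed:
                    placed.add((key, orient, jpos))
                    placements.append((key, orient, jpos))


def _consensus(
    contig_len: int, rs: _ReadSet, placements: list[tuple[str, int, int]]
) -> tuple[str, float]:
    idx = {b: i for i, b in enumerate("ACGTN")}
    counts = np.zeros((5, contig_len), dtype=np.int32)
    total = 0
    for key, orient, off in placements:
        seq = rs.oriented(key, orient)
        w = rs.mult[key]
        for i, b in enumerate(seq):
            p = off + i
            if 0 <= p < contig_len:
                counts[idx.get(b, 4), p] += w
                total += w
    best = counts.argmax(axis=0)
    bases = np.array(list("ACGTN"))[best]
    covered = counts.sum(axis=0) > 0
    return "".join(bases[covered]), total / max(1, covered.sum())


def assemble(reads: list[ReadPair], cfg: PipelineConfig) -> list[Scaffold]:
    """Greedy overlap-consensus assembly of a recovered read set."""
    flat = _flatten(reads, cfg.min_overlap)
    if not flat:
        return []
    read_len = max(len(s) for _, s in flat)
    rs = _ReadSet(flat)
    used: set[str] = set()
    scaffolds: list[Scaffold] = []
    n_scaf = 0
    # deterministic seed order: first occurrence id of each distinct sequence
    seed_order = sorted(rs.seqs, key=lambda s: rs.ids[s][0])
    for seed in seed_order:
        if seed in used:
            continue
        used.add(seed)
        placements: list[tuple[str, int, int]] = [(seed, +1, 0)]
        contig = seed
        contig = _extend_right(contig, rs, used, placements, cfg, read_len)
        # extend left by walking the reverse complement
        flipped = [
            (k, -o, len(contig) - (off + len(k)))
            for k, o, off in placements
        ]
        contig_rc = revcomp(contig)
        contig_rc = _extend_right(contig_rc, rs, used, flipped, cfg, read_len)
        contig = revcomp(contig_rc)
        placements = [
            (k, -o, len(contig) - (off + len(k)))
            for k, o, off in flipped
        ]
        if len(contig) < 2 * read_len:
            continue
        _recruit(contig, rs, used, placements)
        seq, depth = _consensus(len(contig), rs, placements)
        n_scaf += 1
        support = sorted(
            rid
            for key, _, _ in placements
            for rid in rs.ids.get(key, ())
        )
        scaffolds.append(
            Scaffold(
                id=f"scaffold{n_scaf}",
                seq=seq,
                supporting_reads=sorted(set(support)),
                mean_depth=float(depth),
            )
        )
    return scaffolds


def assemble_groups(
    store,
    groups: list[list[Junction]],
    pairs_by_id: dict[str, ReadPair],
    refs: ReferenceSet,
    cfg: PipelineConfig,
) -> list[tuple[list[Junction], list[Scaffold]]]:
    """Per-locus targeted assembly.  Hybrid-locus groups are assembled first;
    later (virus-virus) groups skip reads already consumed by an earlier
    scaffold, so molecules sharing viral sequence do not cross-contaminate."""
    consumed: set[str] = set()
    out = []
    counter = 0
    for group in groups:
        reads = [
            p
            for p in recover_group_reads(store, group, pairs_by_id, refs, cfg)
            if p.id not in consumed
        ]
        scaffolds = assemble(reads, cfg)
        for sc in scaffolds:
            counter += 1
            sc.id = f"scaffold{counter}"
            for rid in sc.supporting_reads:
                consumed.add(rid.rsplit("/", 1)[0])
        out.append((group, scaffolds))
    return out
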