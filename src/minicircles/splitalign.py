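"""Desk-scale seed-and-extend split-read alignment.

Reads are aligned to the combined host + virus reference with exact k-mer
seeds extended along the seed diagonal (the library simulates substitution
errors only, so gapless extension is exact for its data; see the methods
note).  A read is reported as a split (chimeric) alignment when no single
segment at the identity threshold explains nearly the whole read, exposing
virus/host breakpoints.

The circular viral genome is indexed doubled so seeds and alignments can
cross the origin on a single diagonal; reported coordinates are always
canonical (< genome length), origin-crossing hits being split into two
wrap-linked segments.
"""

from __future__ import annotations

from bisect import bisect_right

import numpy as np
import pandas as pd

from ._util import encode_kmers, revcomp
from .config import PipelineConfig
from .records import AlignedSegment, ReadPair, ReferenceSet

_MAX_KMER_HITS = 100  # repeat guard
_MAX_DIAGONALS = 50


class SeedIndex:
    """Exact k-mer lookup over all references (forward strand; queries search
    both read orientations)."""

    def __init__(self, refs: ReferenceSet, cfg: PipelineConfig):
        self.k = cfg.seed_k
        self.refs = refs
        ids = [r.id for r in refs]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate reference ids")
        parts, meta, offset = [], [], 0
        for ref in refs:
            if self.k > len(ref.seq):
                raise ValueError(f"seed_k longer than reference {ref.id}")
            # circular references are doubled so any origin-crossing run up
            # to the full genome stays on a single seed diagonal
            ext = ref.seq + ref.seq if ref.is_circular else ref.seq
            parts.append(ext)
            meta.append((ref.id, offset, len(ext), len(ref.seq), ref.is_circular))
            offset += len(ext)
        self.cat = "".join(parts)
        self.meta = meta
        self._starts = [m[1] for m in meta]
        kmers = []
        positions = []
        for _, off, ext_len, _, _ in meta:
            km = encode_kmers(self.cat[off : off + ext_len], self.k)
            kmers.append(km)
            positions.append(np.arange(off, off + len(km), dtype=np.int64))
        km = np.concatenate(kmers) if kmers else np.empty(0, np.int64)
        pos = np.concatenate(positions) if positions else np.empty(0, np.int64)
        keep = km >= 0
        km, pos = km[keep], pos[keep]
        order = np.argsort(km, kind="stable")
        self._km_sorted = km[order]
        self._pos_sorted = pos[order]

    def lookup(self, kmer: int) -> np.ndarray:
        lo = np.searchsorted(self._km_sorted, kmer, side="left")
        hi = np.searchsorted(self._km_sorted, kmer, side="right")
        return self._pos_sorted[lo:hi]

    def locate(self, gpos: int) -> tuple[str, int, int, bool]:
        """Map a global position to (ref_id, local_pos, true_len, circular)."""
        i = bisect_right(self._starts, gpos) - 1
        ref_id, off, _, true_len, circ = self.meta[i]
        return ref_id, gpos - off, true_len, circ

    def ref_bounds(self, gpos: int) -> tuple[int, int]:
        i = bisect_right(self._starts, gpos) - 1
        _, off, ext_len, _, _ = self.meta[i]
        return off, off + ext_len


def _best_subsegment(
    match: np.ndarray, min_len: int, min_identity: float
) -> tuple[int, int, int] | None:
    """Best-scoring contiguous interval of the 0/1 match profile, score =
    matches - mismatches, subject to length >= min_len and identity >=
    min_identity.  Ties prefer the shorter, then leftmost interval, so a
    chance match beyond a mismatch never extends a segment past a true
    breakpoint.  Returns (start, end, matches) or None."""
    n = len(match)
    if n < min_len:
        return None
    cum = np.concatenate([[0], np.cumsum(match)])
    best = None  # (score, length, start, end, matches)
    for s in range(0, n - min_len + 1):
        if s > 0 and match[s - 1]:  # optimal segments start right after a mismatch
            continue
        e_range = np.arange(s + min_len, n + 1)
        m = cum[e_range] - cum[s]
        length = e_range - s
        score = 2 * m - length
        valid = (match[e_range - 1] == 1) & (m >= min_identity * length)
        if not valid.any():
            continue
        sc = np.where(valid, score, -(10**9))
        # argmax score; among ties the smallest e (shortest interval)
        i_best = int(np.argmax(sc))
        cand = (int(sc[i_best]), int(length[i_best]), s, int(e_range[i_best]), int(m[i_best]))
        if (
            best is None
            or cand[0] > best[0]
            or (cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2]))
        ):
            best = cand
    if best is None:
        return None
    return best[2], best[3], best[4]


class _Candidate:
    __slots__ = ("read_start", "read_end", "gstart", "strand", "matches", "cum")

    def __init__(self, read_start, read_end, gstart, strand, matches, cum):
        self.read_start = read_start
        self.read_end = read_end
        self.gstart = gstart  # global ref pos aligned to read_start (strand frame)
        self.strand = strand
        self.matches = matches
        self.cum = cum  # cumulative matches over [read_start, read_end)


def map_read(index: SeedIndex, seq: str, cfg: PipelineConfig) -> list[AlignedSegment]:
    segs = _map_read_inner(index, seq, cfg)
    return _finalize(index, segs, len(seq))


def _map_read_inner(index, seq, cfg) -> list[_Candidate]:
    L = len(seq)
    k = index.k
    if L < max(cfg.min_mate_len, k):
        return []
    seq = seq.upper()
    strands = {"+": seq, "-": revcomp(seq)}

    # fast path: full-length exact match
    exact: list[tuple[str, int, int, str]] = []  # (ref, local, gpos, strand)
    for strand, s in strands.items():
        km = encode_kmers(s[:k], k)
        if len(km) and km[0] >= 0:
            for g in index.lookup(int(km[0])):
                g = int(g)
                lo, hi = index.ref_bounds(g)
                if g + L <= hi and index.cat[g : g + L] == s:
                    ref_id, local, _, _ = index.locate(g)
                    exact.append((ref_id, local, g, strand))
    if exact:
        exact.sort()
        ref_id, local, g, strand = exact[0]
        match = np.ones(L, dtype=np.int8)
        cum = np.concatenate([[0], np.cumsum(match)])
        return [_Candidate(0, L, g, strand, L, cum)]

    candidates: list[_Candidate] = []
    for strand, s in strands.items():
        km = encode_kmers(s, k)
        diag_hits: dict[int, tuple[int, int]] = {}  # d -> (count, witness hit)
        for i in range(len(km)):
            v = km[i]
            if v < 0:
                continue
            hits = index.lookup(int(v))
            if len(hits) > _MAX_KMER_HITS:
                continue
            for g in hits:
                d = int(g) - i
                c, rep = diag_hits.get(d, (0, int(g)))
                diag_hits[d] = (c + 1, rep)
        diags = sorted(diag_hits, key=lambda d: (-diag_hits[d][0], d))[:_MAX_DIAGONALS]
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        for d in diags:
            # bounds from a witness hit: the diagonal offset itself can fall
            # before the reference start near reference boundaries
            lo, hi = index.ref_bounds(diag_hits[d][1])
            rlo = max(0, lo - d)
            rhi = min(L, hi - d)
            if rhi - rlo < cfg.min_split_segment:
                continue
            ref_arr = np.frombuffer(
                index.cat[d + rlo : d + rhi].encode(), dtype=np.uint8
            )
            match = (arr[rlo:rhi] == ref_arr).astype(np.int8)
            best = _best_subsegment(match, cfg.min_split_segment, cfg.min_identity)
            if best is None:
                continue
            s0, e0, m = best
            cum = np.concatenate([[0], np.cumsum(match[s0:e0])])
            candidates.append(
                _Candidate(rlo + s0, rlo + e0, d + rlo + s0, strand, m, cum)
            )

    if not candidates:
        return []

    # convert '-' strand candidates into original-read frame for chaining
    def read_iv(c: _Candidate) -> tuple[int, int]:
        if c.strand == "+":
            return c.read_start, c.read_end
        return L - c.read_end, L - c.read_start

    def seg_score(c: _Candidate) -> int:
        return 2 * c.matches - (c.read_end - c.read_start)

    # deterministic order: by original-read start, then global pos
    candidates.sort(key=lambda c: (read_iv(c)[0], c.gstart, c.strand))
    best_single = max(candidates, key=lambda c: (seg_score(c), -c.gstart))
    if best_single.read_end - best_single.read_start >= L - cfg.min_split_segment + 1:
        return [best_single]

    # chain DP over original-read coordinates; read-interval overlaps
    # (homology tracts and chance extensions) are resolved afterwards by
    # picking the best split point
    n = len(candidates)
    MAX_OVL = 16
    score = [seg_score(c) for c in candidates]
    parent = [-1] * n
    for j in range(n):
        sj, ej = read_iv(candidates[j])
        for i in range(j):
            si, ei = read_iv(candidates[i])
            ovl = ei - sj
            if ovl > MAX_OVL or ei >= ej or si >= sj:
                continue
            cand = score[i] + seg_score(candidates[j]) - max(0, ovl)
            if cand > score[j]:
                score[j] = cand
                parent[j] = i
    j_best = max(range(n), key=lambda j: (score[j], -read_iv(candidates[j])[0]))
    chain = []
    j = j_best
    while j != -1:
        chain.append(candidates[j])
        j = parent[j]
    chain.reverse()
    if len(chain) == 1:
        return [best_single]
    if score[j_best] <= seg_score(best_single):
        return [best_single]

    # resolve overlapping adjacent segments at the split point that
    # maximizes total matched bases (ties -> leftmost split), so raw
    # breakpoints stay inside the true homology tract
    def strand_iv(c: _Candidate, os0: int, oe0: int) -> tuple[int, int]:
        if c.strand == "+":
            s, e = os0, oe0
        else:
            s, e = L - oe0, L - os0
        return max(s, c.read_start), min(e, c.read_end)

    def matches_in(c: _Candidate, os0: int, oe0: int) -> int:
        s, e = strand_iv(c, os0, oe0)
        if e <= s:
            return 0
        return int(c.cum[e - c.read_start] - c.cum[s - c.read_start])

    def trim_to(c: _Candidate, os0: int, oe0: int) -> _Candidate | None:
        s, e = strand_iv(c, os0, oe0)
        if e - s < cfg.min_split_segment:
            return None
        rs = c.read_start
        m = int(c.cum[e - rs] - c.cum[s - rs])
        if m < cfg.min_identity * (e - s):
            return None
        return _Candidate(
            s, e, c.gstart + (s - rs), c.strand, m, c.cum[s - rs : e - rs + 1] - c.cum[s - rs]
        )

    out = [chain[0]]
    for c in chain[1:]:
        prev = out[-1]
        ps, pe = read_iv(prev)
        cs, ce = read_iv(c)
        if pe <= cs:
            out.append(c)
            continue
        best_rb, best_sc = None, -1
        for rb in range(cs, pe + 1):
            sc = matches_in(prev, ps, rb) + matches_in(c, rb, ce)
            if sc > best_sc:
                best_sc, best_rb = sc, rb
        new_prev = trim_to(prev, ps, best_rb)
        new_c = trim_to(c, best_rb, ce)
        if new_prev is None or new_c is None:
            return [best_single]
        out[-1] = new_prev
        out.append(new_c)
    return out


def _finalize(index: SeedIndex, cands: list[_Candidate], L: int) -> list[dict]:
    """Turn candidates into plain segment dicts in original-read coordinates,
    splitting origin-crossing viral hits into canonical wrap-linked halves."""
    out = []
    wrap_counter = 0
    for order, c in enumerate(cands):
        ref_id, local, true_len, circ = index.locate(c.gstart)
        if circ:
            local %= true_len
        span = c.read_end - c.read_start
        if c.strand == "+":
            r0, r1 = c.read_start, c.read_end
        else:
            r0, r1 = L - c.read_end, L - c.read_start
        pieces = []
        if circ and local + span > true_len:
            cut = true_len - local  # strand-frame offset where the wrap happens
            pieces = [(0, cut, local), (cut, span, 0)]
            wg = wrap_counter
            wrap_counter += 1
        else:
            pieces = [(0, span, local)]
            wg = -1
        for off0, off1, ref0 in pieces:
            plen = off1 - off0
            m = int(c.cum[off1] - c.cum[off0])
            if c.strand == "+":
                rs, re = r0 + off0, r0 + off1
            else:
                rs, re = r1 - off1, r1 - off0
            out.append(
                dict(
                    read_start=rs,
                    read_end=re,
                    ref_id=ref_id,
                    ref_start=ref0 % max(true_len, 1),
                    ref_end=ref0 % max(true_len, 1) + plen,
                    strand=c.strand,
                    identity=m / plen,
                    order_index=order,
                    wrap_group=wg,
                )
            )
    return out


# ----------------------------------------------------------------- store ---


_STORE_COLS = [
    "read_id",
    "mate",
    "ref",
    "start",
    "end",
    "strand",
    "read_start",
    "read_end",
    "identity",
    "order_index",
    "wrap_group",
    "n_segments",
]


class AlignmentStore:
    """All aligned segments of a library, queryable by reference interval and
    by split status; mate linkage preserved through the shared pair id."""

    def __init__(self, df: pd.DataFrame):
        if df.empty:
            df = pd.DataFrame(columns=_STORE_COLS)
        self.df = df.reset_index(drop=True)
        self._by_ref = {}
        for ref, sub in self.df.groupby("ref"):
            sub = sub.sort_values("start", kind="stable")
            self._by_ref[ref] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub.index.to_numpy(),
            )

    # -- queries -----------------------------------------------------------
    def split_mates(self) -> pd.DataFrame:
        """Rows of mates aligning in >= 2 segments."""
        return self.df[self.df["n_segments"] >= 2]

    def query_region(self, ref: str, start: int, end: int) -> pd.DataFrame:
        if ref not in self._by_ref:
            return self.df.iloc[0:0]
        starts, ends, idx = self._by_ref[ref]
        sel = idx[(starts < end) & (ends > start)]
        return self.df.loc[sel]

    def depth(self, ref: str, start: int, end: int) -> np.ndarray:
        cov = np.zeros(end - start, dtype=np.int32)
        sub = self.query_region(ref, start, end)
        for s, e in zip(sub["start"], sub["end"]):
            cov[max(0, s - start) : max(0, min(e, end) - start)] += 1
        return cov

    # -- round trip --------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AlignmentStore":
        return cls(pd.read_csv(path, sep="\t", dtype={"ref": str, "read_id": str, "strand": str}))


def map_all(index: SeedIndex, pairs: list[ReadPair], cfg: PipelineConfig) -> AlignmentStore:
    rows = []
    for pair in pairs:
        for mate, seq in ((1, pair.seq1), (2, pair.seq2)):
            if len(seq) < cfg.min_mate_len:
                continue
            segs = map_read(index, seq, cfg)
            # count mate-level segments ignoring wrap splitting
            n_chain = len({s["order_index"] for s in segs})
            for s in segs:
                rows.append(
                    (
                        pair.id,
                        mate,
                        s["ref_id"],
                        s["ref_start"],
                        s["ref_end"],
                        s["strand"],
                        s["read_start"],
                        s["read_end"],
                        s["identity"],
                        s["order_index"],
                        s["wrap_group"],
                        n_chain,
                    )
                )
    df = pd.DataFrame(rows, columns=_STORE_COLS)
    return AlignmentStore(df)


def segments_of(store: AlignmentStore, read_id: str, mate: int) -> list[AlignedSegment]:
    sub = store.df[(store.df["read_id"] == read_id) & (store.df["mate"] == mate)]
    out = []
    for _, r in sub.sort_values(["order_index", "read_start"]).iterrows():
        out.append(
            AlignedSegment(
                read_id=r["read_id"],
                mate=int(r["mate"]),
                read_start=int(r["read_start"]),
                read_end=int(r["read_end"]),
                ref_id=r["ref"],
                ref_start=int(r["start"]),
                ref_end=int(r["end"]),
                strand=r["strand"],
                identity=float(r["identity"]),
                order_index=int(r["order_index"]),
                wrap_group=int(r["wrap_group"]),
            )
        )
    return out
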