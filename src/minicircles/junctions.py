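"""Breakpoint junction calling from split alignments.

Every mate aligning in two or more chained segments contributes one raw
breakpoint event per adjacent segment pair.  Events are clustered within a
small positional tolerance, junction microhomology (the identical flank
shared by both sides, within which the true breakpoint cannot be localized)
is measured on the reference sequences, and the breakpoint is reported at
the canonical leftmost position of the homology span.  The selection filter
keeps junctions with sufficient distinct-read support that involve the viral
genome.
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

from .config import PipelineConfig
from .records import CircularSequence, Junction, JunctionSide, ReferenceSet

_MAX_HOMOLOGY = 50

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _base(seqs: dict[str, CircularSequence], ref: str, pos: int) -> str | None:
    s = seqs[ref]
    n = len(s.seq)
    if s.is_circular:
        return s.seq[pos % n]
    if 0 <= pos < n:
        return s.seq[pos]
    return None


def canonicalize_breakpoint(
    seqs: dict[str, CircularSequence],
    side_a: tuple[str, int, str],
    side_b: tuple[str, int, str],
    virus_id: str | None = None,
) -> tuple[tuple[str, int, str], tuple[str, int, str], int]:
    """Shift a breakpoint to its canonical position and measure microhomology.

    ``side_a`` is the upstream side of the event (the molecule ends there),
    ``side_b`` the downstream side; each is (ref_id, 0-based pos, 'left'|
    'right') where 'right' retains ref[..pos] and 'left' retains ref[pos..].
    Returns the two sides ordered virus-first (else lexicographically) at the
    shift that minimizes the leading side's coordinate, plus the homology
    span length.
    """
    ra, pa, da = side_a
    rb, pb, db = side_b

    def up_beyond(i: int) -> str | None:  # i >= 1, past the breakpoint on A
        if da == "right":
            return _base(seqs, ra, pa + i)
        b = _base(seqs, ra, pa - i)
        return _COMP[b] if b else None

    def up_retained(i: int) -> str | None:  # i >= 0, last retained bases of A
        if da == "right":
            return _base(seqs, ra, pa - i)
        b = _base(seqs, ra, pa + i)
        return _COMP[b] if b else None

    def down_retained(i: int) -> str | None:  # i >= 0, first retained of B
        if db == "left":
            return _base(seqs, rb, pb + i)
        b = _base(seqs, rb, pb - i)
        return _COMP[b] if b else None

    def down_before(i: int) -> str | None:  # i >= 1, before the breakpoint on B
        if db == "left":
            return _base(seqs, rb, pb - i)
        b = _base(seqs, rb, pb + i)
        return _COMP[b] if b else None

    r = 0
    while r < _MAX_HOMOLOGY:
        x, y = up_beyond(r + 1), down_retained(r)
        if x is None or y is None or x != y:
            break
        r += 1
    l = 0
    while l < _MAX_HOMOLOGY:
        x, y = up_retained(l), down_before(l + 1)
        if x is None or y is None or x != y:
            break
        l += 1

    def at_shift(delta: int):
        qa = pa + delta if da == "right" else pa - delta
        qb = pb + delta if db == "left" else pb - delta
        na, nb = len(seqs[ra].seq), len(seqs[rb].seq)
        if seqs[ra].is_circular:
            qa %= na
        if seqs[rb].is_circular:
            qb %= nb
        return (ra, qa, da), (rb, qb, db)

    def ordered(pair):
        a, b = pair
        if virus_id is not None:
            if a[0] == virus_id and b[0] != virus_id:
                return a, b
            if b[0] == virus_id and a[0] != virus_id:
                return b, a
        return (a, b) if (a[0], a[1], a[2]) <= (b[0], b[1], b[2]) else (b, a)

    best = None
    for delta in range(-l, r + 1):
        cand = ordered(at_shift(delta))
        key = (cand[0][1], cand[1][1], cand[0], cand[1])
        if best is None or key < best[0]:
            best = (key, cand)
    (first, second) = best[1]
    return first, second, l + r


def _circdist(seqs, ref: str, p: int, q: int) -> int:
    s = seqs[ref]
    d = abs(p - q)
    if s.is_circular:
        d = min(d, len(s.seq) - d)
    return d


def call_junctions(
    store, refs: ReferenceSet, cfg: PipelineConfig
) -> list[Junction]:
    """Cluster raw split-read breakpoint events into junction calls."""
    seqs = {r.id: r for r in refs}
    virus_id = refs.virus_id
    events = []  # (sideA, sideB, mh, read_key)
    split = store.split_mates()
    for (read_id, mate), sub in split.groupby(["read_id", "mate"], sort=True):
        segs = sub.sort_values(["read_start", "order_index"]).to_dict("records")
        for s1, s2 in zip(segs, segs[1:]):
            if s1["wrap_group"] >= 0 and s1["wrap_group"] == s2["wrap_group"]:
                continue  # the two halves of one origin-crossing alignment
            if s1["strand"] == "+":
                up = (s1["ref"], int(s1["end"]) - 1, "right")
            else:
                up = (s1["ref"], int(s1["start"]), "left")
            if s2["strand"] == "+":
                down = (s2["ref"], int(s2["start"]), "left")
            else:
                down = (s2["ref"], int(s2["end"]) - 1, "right")
            ca, cb, mh = canonicalize_breakpoint(seqs, up, down, virus_id)
            events.append((ca, cb, mh, (read_id, mate)))

    clusters: dict[tuple, list] = {}
    for ca, cb, mh, rk in events:
        key = (ca[0], ca[2], cb[0], cb[2])
        placed = False
        for clu in clusters.setdefault(key, []):
            ra, rb = clu["rep"]
            if (
                _circdist(seqs, ca[0], ca[1], ra) <= cfg.junction_cluster_tol
                and _circdist(seqs, cb[0], cb[1], rb) <= cfg.junction_cluster_tol
            ):
                clu["votes"][(ca[1], cb[1], mh)] += 1
                clu["reads"].add(rk)
                placed = True
                break
        if not placed:
            clusters[key].append(
                {"rep": (ca[1], cb[1]), "votes": Counter({(ca[1], cb[1], mh): 1}), "reads": {rk}}
            )

    out = []
    for key in sorted(clusters):
        ra_id, da, rb_id, db = key
        for clu in clusters[key]:
            (pa, pb, mh), _ = sorted(
                clu["votes"].items(), key=lambda kv: (-kv[1], kv[0])
            )[0]
            jtype_parts = tuple(
                "virus" if r == virus_id else "host" for r in (ra_id, rb_id)
            )
            jtype = "-".join(sorted(jtype_parts, reverse=True))
            out.append(
                Junction(
                    side_a=JunctionSide(ra_id, pa, da),
                    side_b=JunctionSide(rb_id, pb, db),
                    support=len(clu["reads"]),
                    microhomology=mh,
                    jtype=jtype,
                )
            )
    out.sort(key=lambda j: (j.side_a.ref_id, j.side_a.pos, j.side_b.ref_id, j.side_b.pos))
    return out


def filter_junctions(junctions: list[Junction], cfg: PipelineConfig) -> list[Junction]:
    """Keep junctions with enough distinct-read support that involve the
    viral genome; host-host junctions are always removed."""
    return [
        j
        for j in junctions
        if j.support >= cfg.min_junction_support and j.jtype in ("virus-host", "virus-virus")
    ]


# ------------------------------------------------------------------ I/O ----


def junctions_to_frame(junctions: list[Junction]) -> pd.DataFrame:
    rows = [
        {
            "refA": j.side_a.ref_id,
            "posA": j.side_a.pos,
            "orientA": j.side_a.side,
            "refB": j.side_b.ref_id,
            "posB": j.side_b.pos,
            "orientB": j.side_b.side,
            "support": j.support,
            "microhomology": j.microhomology,
            "jtype": j.jtype,
        }
        for j in junctions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "refA",
            "posA",
            "orientA",
            "refB",
            "posB",
            "orientB",
            "support",
            "microhomology",
            "jtype",
        ],
    )


def junctions_from_frame(df: pd.DataFrame) -> list[Junction]:
    return [
        Junction(
            side_a=JunctionSide(r["refA"], int(r["posA"]), r["orientA"]),
            side_b=JunctionSide(r["refB"], int(r["posB"]), r["orientB"]),
            support=int(r["support"]),
            microhomology=int(r["microhomology"]),
            jtype=r["jtype"],
        )
        for _, r in df.iterrows()
    ]


def junctions_to_bed(junctions: list[Junction], path) -> None:
    with open(path, "w") as fh:
        for i, j in enumerate(junctions):
            for side in (j.side_a, j.side_b):
                fh.write(
                    f"{side.ref_id}\t{side.pos}\t{side.pos + 1}\t"
                    f"junction_{i + 1}_{side.side}\t{j.support}\t.\n"
                )
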