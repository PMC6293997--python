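"""Synthetic genomes, planted minicircle templates, and paired-end reads.

The generator emulates the sequencing design of a geminivirus infection
experiment: a circular ~2.8 kb single-stranded DNA viral genome whose
replication origin (the conserved TAATATTAC nonanucleotide at the stem-loop)
sits at position 1 and which carries a single EcoRI site; a multi-chromosome
host genome with AT-rich intergenic windows from which circularized fragments
are captured; hybrid minicircle templates (viral origin-containing arc +
host fragment), virus-only defective circles, and a full-length helper
genome at virus-like abundance.  Reads are 2 x 76 nt pairs from ~350 nt
inserts with substitution errors only.

Junction microhomology is planted one-directionally: the segment upstream in
the molecule can be extended ``mh`` bases into the downstream segment, so
recorded maximal segment intervals double-count each homology tract and
``len(seq) == sum(segments) - sum(mh)``.  Truth breakpoints are stored in
the same leftmost canonical form the junction caller emits.

Every function is a pure function of (config, seed); named sub-streams keep
stages independently reproducible.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd

from ._util import revcomp, wrap_substring
from .config import SimulationConfig
from .records import CircularSequence, MinicircleTemplate, ReadPair, ReferenceSet

VIRUS_ID = "virus"

_STREAMS = {"virus": 11, "host": 23, "templates": 37, "library": 51, "errors": 67}


def _rng(cfg: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), _STREAMS[stream]])


def _random_seq(rng: np.random.Generator, n: int, at: float) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _exact_at_seq(rng: np.random.Generator, n: int, at: float) -> str:
    """Sequence whose A+T count is exactly round(n * at)."""
    n_at = int(round(n * at))
    bases = np.empty(n, dtype="<U1")
    at_pos = rng.permutation(n)[:n_at]
    mask = np.zeros(n, dtype=bool)
    mask[at_pos] = True
    bases[mask] = rng.choice(list("AT"), size=n_at)
    bases[~mask] = rng.choice(list("CG"), size=n - n_at)
    return "".join(bases)


def _wrap_occurrences(seq: str, motif: str) -> list[int]:
    """0-based start positions of ``motif`` on the circular ``seq``."""
    n, m = len(seq), len(motif)
    doubled = seq + seq[: m - 1]
    out, i = [], doubled.find(motif)
    while i != -1:
        if i < n:
            out.append(i)
        i = doubled.find(motif, i + 1)
    return out


def make_virus_genome(cfg: SimulationConfig) -> CircularSequence:
    """Circular viral genome with the origin motif exactly once at position 1
    and exactly one EcoRI site."""
    motif = cfg.origin_motif.upper()
    if len(motif) > cfg.virus_length:
        raise ValueError("origin motif longer than the viral genome")
    site = "GAATTC"
    e0 = cfg.ecori_pos - 1
    if e0 + len(site) > cfg.virus_length:
        raise ValueError("EcoRI site would run past the genome end")
    if e0 < len(motif) and cfg.virus_length > len(motif) + len(site):
        raise ValueError("ecori_pos overlaps the origin motif")

    rng = _rng(cfg, "virus")
    seq = list(_random_seq(rng, cfg.virus_length, cfg.virus_at))
    seq[: len(motif)] = motif
    seq[e0 : e0 + len(site)] = site
    # scrub accidental extra occurrences of either landmark (wrap-aware)
    for _ in range(100):
        s = "".join(seq)
        extra = [p for p in _wrap_occurrences(s, site) if p != e0]
        extra += [p for p in _wrap_occurrences(s, motif) if p != 0]
        if not extra:
            break
        for p in extra:
            mid = (p + len(site) // 2) % cfg.virus_length
            if mid < len(motif) or e0 <= mid < e0 + len(site):
                mid = (p + len(site) - 1) % cfg.virus_length
            old = seq[mid]
            choices = [b for b in "ACGT" if b != old]
            seq[mid] = choices[int(rng.integers(0, 3))]
    else:
        raise RuntimeError("could not scrub duplicate landmarks")
    return CircularSequence(VIRUS_ID, "".join(seq), is_circular=True)


def make_host_genome(
    cfg: SimulationConfig, virus: CircularSequence | None = None
) -> tuple[ReferenceSet, list[tuple[str, int, int]]]:
    """Linear host chromosomes with cataloged AT-rich intergenic windows.

    Returns the full reference set (virus included) and the window catalog as
    (chrom_id, start, end) 0-based half-open intervals.
    """
    if virus is None:
        virus = make_virus_genome(cfg)
    rng = _rng(cfg, "host")
    hosts, windows = [], []
    w = cfg.at_window_length
    for c in range(cfg.n_host_chrom):
        cid = f"chr{c + 1}"
        L = cfg.host_chrom_length
        seq = list(_random_seq(rng, L, cfg.host_background_at))
        nw = cfg.n_at_windows_per_chrom
        margin = min(15_000, max(0, (L - nw * w) // 4))
        usable = L - 2 * margin
        slot = usable // nw
        if slot < w:
            raise ValueError("chromosome too short for the requested AT windows")
        for j in range(nw):
            lo = margin + j * slot
            start = lo + int(rng.integers(0, slot - w + 1))
            target = cfg.host_at_fraction + float(rng.uniform(-0.01, 0.01))
            seq[start : start + w] = _exact_at_seq(rng, w, target)
            windows.append((cid, start, start + w))
        hosts.append(CircularSequence(cid, "".join(seq), is_circular=False))
    return ReferenceSet(virus=virus, hosts=hosts), windows


def sample_copy_number(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _plant(host: CircularSequence, pos0: int, bases: str) -> None:
    s = host.seq
    host.seq = s[:pos0] + bases + s[pos0 + len(bases) :]


def make_minicircle(
    virus: CircularSequence,
    host: ReferenceSet,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    *,
    template_id: str = "mc",
    viral_segments: list[tuple[int, int]] | None = None,
    host_fragment: tuple[str, tuple[int, int], str] | None = None,
    microhomology: tuple[int, int] | None = None,
    copy_number: float = 15.0,
    window: tuple[str, int, int] | None = None,
) -> MinicircleTemplate:
    """Build one hybrid minicircle template.

    Fully explicit mode: pass ``viral_segments`` (1-based inclusive, maximal
    intervals) and ``host_fragment``; the sequence is concatenated as given
    (microhomology defaults to 0).  Sampling mode: pass ``rng`` and a host
    ``window``; geometry is drawn from the configured bounds and junction
    homology of 0..microhomology_max nt is imprinted into the host window.
    """
    vlen = len(virus)
    ig_hi, ig_lo = cfg.intergenic_span  # wrap interval (hi..vlen, 1..lo)

    if viral_segments is not None:
        if host_fragment is None:
            raise ValueError("explicit mode needs both viral_segments and host_fragment")
        mh = list(microhomology) if microhomology else [0, 0]
        ref_id, (h1, h2), strand = host_fragment
        hseq = host.get(ref_id).seq[h1 - 1 : h2]
        if strand == "-":
            hseq = revcomp(hseq)
        vseq = "".join(virus.seq[a - 1 : b] for a, b in viral_segments)
        # trim each homology tract once (it is double-counted in the intervals)
        seq = vseq[: len(vseq) - mh[0]] + hseq[: len(hseq) - mh[1]]
        total = len(seq)
    else:
        if rng is None or window is None:
            raise ValueError("sampling mode needs rng and a host window")
        mh = [int(rng.integers(0, cfg.microhomology_max + 1)) for _ in range(2)]
        lo_t, hi_t = cfg.minicircle_total_bounds
        lo_h, hi_h = cfg.host_fragment_bounds
        for _ in range(100):
            # physical host length; keep the maximal interval in bounds too
            host_len = int(rng.integers(lo_h, min(hi_h - mh[1], hi_h) + 1))
            v_lo = max(lo_t - host_len, ig_lo + (vlen - ig_hi + 1) + 2)
            v_hi = hi_t - host_len
            if v_lo <= v_hi:
                break
        else:
            raise ValueError("host fragment bounds incompatible with total bounds")
        viral_len = int(rng.integers(v_lo, v_hi + 1))  # physical nt
        a_hi = min(330, viral_len - (vlen - ig_hi + 1))
        a = int(rng.integers(ig_lo, a_hi + 1))  # upstream arm 1..a (physical)
        b = vlen - (viral_len - a) + 1  # downstream arm b..vlen
        assert ig_lo <= a and b <= ig_hi, (a, b, viral_len)

        cid, wstart, wend = window
        chrom = host.get(cid)
        need = host_len + mh[1]
        h1 = wstart + 1 + int(rng.integers(0, wend - wstart - need + 1))
        h2 = h1 + host_len - 1  # physical host interval, 1-based inclusive
        # imprint homology: upstream segment extends into the downstream one
        if mh[0]:
            _plant(chrom, h1 - 1, virus.seq[a : a + mh[0]])
        if mh[1]:
            _plant(chrom, h2, virus.seq[b - 1 : b - 1 + mh[1]])
        viral_segments = [(1, a + mh[0]), (b, vlen)]
        host_fragment = (cid, (h1, h2 + mh[1]), "+")  # maximal host interval
        seq = (
            wrap_substring(virus.seq, b - 1, (vlen - b + 1) + a)
            + chrom.seq[h1 - 1 : h2]
        )
        total = len(seq)
        assert lo_t <= total <= hi_t

    # origin coverage check: some viral segment must contain the full motif
    m = len(cfg.origin_motif)
    if not any(s <= 1 and e >= m for s, e in viral_segments):
        raise ValueError("no viral segment covers the replication origin")

    tpl = MinicircleTemplate(
        id=template_id,
        viral_segments=list(viral_segments),
        host_locus=host_fragment,
        seq=seq,
        copy_number=copy_number,
        microhomology_len=mh,
    )
    _fill_truth_junctions(tpl, virus, host)
    return tpl


def _fill_truth_junctions(
    tpl: MinicircleTemplate, virus: CircularSequence, refs: ReferenceSet | None
) -> None:
    """Record canonical (leftmost) breakpoints for the template's junctions."""
    from .junctions import canonicalize_breakpoint  # convention, shared on purpose

    tpl.junctions = []
    if tpl.host_locus is None:
        # defective: junction between non-contiguous retained viral intervals
        segs = tpl.viral_segments
        vlen = len(virus)
        for i in range(len(segs)):
            a_end = segs[i][1]
            b_start = segs[(i + 1) % len(segs)][0]
            if (a_end % vlen) + 1 == b_start:
                continue  # contiguous on the circle
            side_a = (VIRUS_ID, a_end - 1, "right")
            side_b = (VIRUS_ID, b_start - 1, "left")
            ca, cb, mh = canonicalize_breakpoint({VIRUS_ID: virus}, side_a, side_b, virus_id=VIRUS_ID)
            tpl.junctions.append((ca, cb, mh))
        return
    assert refs is not None
    ref_id, (h1, h2), _ = tpl.host_locus
    seqs = {VIRUS_ID: virus, ref_id: refs.get(ref_id)}
    a_max = tpl.viral_segments[0][1]
    b_min = tpl.viral_segments[-1][0]
    mh1, mh2 = (tpl.microhomology_len + [0, 0])[:2]
    # physical breakpoints: viral arm ends at a_max - mh1; host ends at h2 - mh2
    j1 = ((VIRUS_ID, a_max - mh1 - 1, "right"), (ref_id, h1 - 1, "left"))
    j2 = ((ref_id, h2 - mh2 - 1, "right"), (VIRUS_ID, b_min - 1, "left"))
    for side_a, side_b in (j1, j2):
        ca, cb, mh = canonicalize_breakpoint(seqs, side_a, side_b, virus_id=VIRUS_ID)
        tpl.junctions.append((ca, cb, mh))


def make_defective(
    virus: CircularSequence,
    retained: list[tuple[int, int]],
    *,
    template_id: str = "def",
    copy_number: float = 15.0,
    origin_len: int = 9,
) -> MinicircleTemplate:
    """Virus-only circle from retained intervals (1-based inclusive)."""
    vlen = len(virus)
    for a, b in retained:
        if not 1 <= a <= b <= vlen:
            raise ValueError(f"interval {a}-{b} outside the viral genome")
    if not any(a <= 1 and b >= origin_len for a, b in retained):
        raise ValueError("no retained interval covers the replication origin")
    seq = "".join(virus.seq[a - 1 : b] for a, b in retained)
    tpl = MinicircleTemplate(
        id=template_id,
        viral_segments=list(retained),
        host_locus=None,
        seq=seq,
        copy_number=copy_number,
        microhomology_len=[0] * len(retained),
    )
    _fill_truth_junctions(tpl, virus, None)
    return tpl


# ---------------------------------------------------------------- library ---


def _apply_errors(seq: str, rng: np.random.Generator, e: float) -> str:
    if e <= 0:
        return seq
    n = len(seq)
    k = rng.binomial(n, e)
    if k == 0:
        return seq
    pos = rng.choice(n, size=k, replace=False)
    s = list(seq)
    for p in pos:
        alts = [b for b in "ACGT" if b != s[p]]
        s[p] = alts[int(rng.integers(0, 3))]
    return "".join(s)


def simulate_library(
    templates: list[MinicircleTemplate],
    refs: ReferenceSet,
    cfg: SimulationConfig,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Draw paired-end reads from circular templates (wrap-around fragments)
    and from the references as linear/circular background.

    Per-template expected read depth is ``background_depth * copy_number``.
    Returns the pairs plus a per-pair truth table.
    """
    R = cfg.read_length
    rng = _rng(cfg, "library")
    erng = _rng(cfg, "errors")

    sources: list[tuple[str, str, str, bool, float]] = []
    # (source_id, class, sequence, circular, depth)
    for t in sorted(templates, key=lambda t: t.id):
        depth = cfg.background_depth * t.copy_number
        klass = getattr(t, "role", None) or t.klass
        sources.append((t.id, klass, t.seq, True, depth))
    if cfg.background_depth > 0:
        for ref in refs:
            sources.append(
                (ref.id, "background", ref.seq, ref.is_circular, cfg.background_depth)
            )
    if not sources:
        warnings.warn("no templates and no background: empty library")
        return [], pd.DataFrame()

    pairs: list[ReadPair] = []
    truth_rows = []
    idx = 0
    for source_id, klass, seq, circular, depth in sources:
        L = len(seq)
        n_frags = int(round(L * depth / (2 * R)))
        if n_frags == 0:
            continue
        inserts = np.clip(
            np.round(rng.normal(cfg.insert_mean, cfg.insert_sd, n_frags)),
            40,
            L,
        ).astype(int)
        if circular:
            starts = rng.integers(0, L, n_frags)
        else:
            starts = np.array(
                [rng.integers(0, max(1, L - ins + 1)) for ins in inserts]
            )
        flips = rng.integers(0, 2, n_frags).astype(bool)
        for start, ins, flip in zip(starts, inserts, flips):
            frag = (
                wrap_substring(seq, int(start), int(ins))
                if circular
                else seq[int(start) : int(start) + int(ins)]
            )
            fwd, rev = frag, revcomp(frag)
            if len(frag) < R:  # adapter read-through on short fragments
                pad = cfg.adapter_seq + "G" * R
                fwd = (frag + pad)[:R]
                rev = (revcomp(frag) + pad)[:R]
            else:
                fwd, rev = frag[:R], rev[:R]
            s1, s2 = (rev, fwd) if flip else (fwd, rev)
            s1 = _apply_errors(s1, erng, cfg.per_base_error)
            s2 = _apply_errors(s2, erng, cfg.per_base_error)
            pid = f"sim{idx:07d}"
            idx += 1
            q = [cfg.base_quality] * R
            pairs.append(ReadPair(pid, s1, list(q[: len(s1)]), s2, list(q[: len(s2)])))
            truth_rows.append(
                {
                    "pair_id": pid,
                    "source_id": source_id,
                    "source_class": klass,
                    "frag_start": int(start),
                    "frag_len": int(ins),
                    "flipped": bool(flip),
                }
            )
    return pairs, pd.DataFrame(truth_rows)


def templates_table(templates: list[MinicircleTemplate]) -> pd.DataFrame:
    rows = []
    for t in templates:
        host = t.host_locus
        rows.append(
            {
                "template_id": t.id,
                "class": getattr(t, "role", None) or t.klass,
                "length": len(t.seq),
                "copy_number": t.copy_number,
                "viral_segments": ";".join(f"{a}-{b}" for a, b in t.viral_segments),
                "host_ref": host[0] if host else "",
                "host_start": host[1][0] if host else -1,
                "host_end": host[1][1] if host else -1,
                "host_strand": host[2] if host else "",
                "microhomology": ";".join(map(str, t.microhomology_len)),
                "junctions": json.dumps(t.junctions),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------- scenario ---


def default_scenario(
    cfg: SimulationConfig,
    *,
    n_hybrids: int = 8,
    n_defectives: int = 2,
    helper_copy_number: float = 100.0,
    hybrid_cn_bounds: tuple[float, float] = (25.0, 100.0),
    defective_cn: float = 25.0,
):
    """The default study design: n hybrids on distinct AT-rich host windows,
    n virus-only defectives, and a full-length helper genome at virus-like
    abundance.  Hybrid copy numbers are drawn log-uniform from
    ``hybrid_cn_bounds``; the lower bound guarantees the planted per-junction
    split-read support stays comfortably above the selection threshold.
    """
    refs, windows = make_host_genome(cfg)
    virus = refs.virus
    rng = _rng(cfg, "templates")
    if n_hybrids > len(windows):
        raise ValueError("not enough AT windows for the requested hybrids")
    picked = rng.choice(len(windows), size=n_hybrids, replace=False)
    templates: list[MinicircleTemplate] = []
    for i, wi in enumerate(picked):
        cn = sample_copy_number(rng, hybrid_cn_bounds)
        templates.append(
            make_minicircle(
                virus,
                refs,
                cfg,
                rng,
                template_id=f"hyb{i + 1}",
                copy_number=cn,
                window=windows[int(wi)],
            )
        )
    vlen = len(virus)
    for i in range(n_defectives):
        a = int(rng.integers(380, 700))
        b = int(rng.integers(1700, 2200))
        templates.append(
            make_defective(
                virus,
                [(1, a), (b, vlen)],
                template_id=f"def{i + 1}",
                copy_number=defective_cn,
            )
        )
    if helper_copy_number > 0:
        helper = make_defective(
            virus, [(1, vlen)], template_id="helper", copy_number=helper_copy_number
        )
        helper.role = "helper"
        templates.append(helper)
    pairs, pair_truth = simulate_library(templates, refs, cfg)
    return refs, windows, templates, pairs, pair_truth
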