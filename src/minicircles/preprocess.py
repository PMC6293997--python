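"""Read quality trimming and pair-length filtering.

The trimming rule: after removing any 3' adapter occurrence, bases are cut
inward from each read end until the first window of ``trim_window`` bases
whose mean quality reaches ``trim_min_q``; windows truncated by the read end
use the mean of the remaining bases.  Pairs in which either trimmed mate is
shorter than ``min_mate_len`` are discarded.  An alternative single-pass
mode (``trim_mode='sliding_cut'``) cuts the read at the first bad window
scanning 5'->3', mirroring the classic sliding-window trimmer.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import PipelineConfig
from .records import ReadPair


def _find_adapter(seq: str, adapter: str, min_suffix: int = 8) -> int:
    """Position where a 3' adapter begins, or -1.  Full occurrences anywhere
    count; at the very 3' end a prefix of the adapter >= min_suffix does."""
    if not adapter:
        return -1
    p = seq.find(adapter)
    if p != -1:
        return p
    for k in range(min(len(adapter) - 1, len(seq)), min_suffix - 1, -1):
        if seq.endswith(adapter[:k]):
            return len(seq) - k
    return -1


def _window_mean(qual: list[int], i: int, w: int, direction: int) -> float:
    """Mean quality of the w-window starting at i going inward; truncated
    windows fall back to the remaining bases."""
    if direction > 0:
        chunk = qual[i : i + w]
    else:
        chunk = qual[max(0, i - w + 1) : i + 1]
    return sum(chunk) / len(chunk)


def sliding_window_trim(
    seq: str, qual: list[int], cfg: PipelineConfig
) -> tuple[str, list[int]]:
    """Trim one read; returns the (possibly empty) retained sequence and
    qualities."""
    if len(seq) != len(qual):
        raise ValueError("sequence/quality length mismatch")
    a = _find_adapter(seq.upper(), cfg.adapter_seq.upper())
    if a != -1:
        seq, qual = seq[:a], qual[:a]
    n = len(seq)
    if n == 0:
        return "", []
    w, t = cfg.trim_window, cfg.trim_min_q

    if cfg.trim_mode == "sliding_cut":
        # classic single-pass: cut at the first bad window scanning 5'->3'
        for i in range(n - w + 1):
            if sum(qual[i : i + w]) / w < t:
                return seq[:i], qual[:i]
        return seq, qual

    # iterate window scan + terminal strip to a fixpoint: the scan finds the
    # first inward window passing the mean threshold, the strip removes
    # terminal bases individually below it (a straddling window can shelter
    # 1-3 low-quality bases), and stripping can expose a new failing window
    start, end = 0, n
    while True:
        new_start = None
        for i in range(start, end):
            win = qual[i : min(i + w, end)]
            if sum(win) / len(win) >= t:
                new_start = i
                break
        if new_start is None:
            return "", []
        new_end = None
        for i in range(end - 1, new_start - 1, -1):
            win = qual[max(new_start, i - w + 1) : i + 1]
            if sum(win) / len(win) >= t:
                new_end = i + 1
                break
        if new_end is None or new_end <= new_start:
            return "", []
        while new_start < new_end and qual[new_start] < t:
            new_start += 1
        while new_end > new_start and qual[new_end - 1] < t:
            new_end -= 1
        if new_end <= new_start:
            return "", []
        if (new_start, new_end) == (start, end):
            break
        start, end = new_start, new_end
    return seq[start:end], qual[start:end]


@dataclass
class TrimReport:
    pairs_in: int
    pairs_out: int

    @property
    def surviving_fraction(self) -> float:
        return self.pairs_out / self.pairs_in if self.pairs_in else 0.0


def trim_pair(pair: ReadPair, cfg: PipelineConfig) -> ReadPair:
    s1, q1 = sliding_window_trim(pair.seq1, pair.qual1, cfg)
    s2, q2 = sliding_window_trim(pair.seq2, pair.qual2, cfg)
    return ReadPair(pair.id, s1, q1, s2, q2, truth=pair.truth)


def filter_pairs(
    pairs: list[ReadPair], cfg: PipelineConfig
) -> tuple[list[ReadPair], TrimReport]:
    """Keep pairs whose mates are both >= min_mate_len, preserving order."""
    out = [
        p
        for p in pairs
        if len(p.seq1) >= cfg.min_mate_len and len(p.seq2) >= cfg.min_mate_len
    ]
    return out, TrimReport(pairs_in=len(pairs), pairs_out=len(out))


def trim_and_filter(
    pairs: list[ReadPair], cfg: PipelineConfig
) -> tuple[list[ReadPair], TrimReport]:
    trimmed = [trim_pair(p, cfg) for p in pairs]
    return filter_pairs(trimmed, cfg)
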