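"""Domain records used throughout the pipeline.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open on the forward strand of the
named reference.  User-facing viral coordinates (coordinate strings in the
feature table, junction reports) are 1-based inclusive, matching the
convention that places the rolling-circle replication origin at position 1
of the viral genome.  Conversion happens only in the formatting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import at_fraction

_ALPHABET = set("ACGTN")


@dataclass
class CircularSequence:
    """A named nucleotide sequence, flagged linear or circular."""

    id: str
    seq: str
    is_circular: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        if not set(self.seq.upper()) <= _ALPHABET:
            bad = sorted(set(self.seq.upper()) - _ALPHABET)
            raise ValueError(f"{self.id}: illegal characters {bad}")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceSet:
    """The combined alignment target: exactly one circular viral genome plus
    any number of linear host chromosomes."""

    virus: CircularSequence
    hosts: list[CircularSequence]

    def __post_init__(self) -> None:
        if not self.virus.is_circular:
            raise ValueError("virus reference must be circular")
        for h in self.hosts:
            if h.is_circular:
                raise ValueError(f"host reference {h.id} must be linear")
        ids = [self.virus.id] + [h.id for h in self.hosts]
        if len(ids) != len(set(ids)):
            raise ValueError("reference ids must be unique")

    @property
    def virus_id(self) -> str:
        return self.virus.id

    def __iter__(self):
        yield self.virus
        yield from self.hosts

    def get(self, ref_id: str) -> CircularSequence:
        for s in self:
            if s.id == ref_id:
                return s
        raise KeyError(ref_id)

    def length(self, ref_id: str) -> int:
        return len(self.get(ref_id))

    def is_virus(self, ref_id: str) -> bool:
        return ref_id == self.virus.id


@dataclass
class MinicircleTemplate:
    """A planted circular molecule: ordered viral segments (1-based inclusive
    intervals on the viral genome, maximal through junction homology tracts)
    plus an optional host fragment.

    ``len(seq) == sum(segment lengths) - sum(microhomology_len)`` because each
    homology tract is counted once per flanking segment.
    """

    id: str
    viral_segments: list[tuple[int, int]]
    host_locus: tuple[str, tuple[int, int], str] | None  # (ref_id, 1-based incl, strand)
    seq: str
    copy_number: float
    microhomology_len: list[int] = field(default_factory=list)
    # canonical (leftmost) junction breakpoints, filled by the generator:
    # list of ((ref_a, pos_a, side_a), (ref_b, pos_b, side_b), realized_mh)
    junctions: list[tuple] = field(default_factory=list)
    role: str | None = None  # overrides klass in truth tables (e.g. "helper")

    @property
    def is_hybrid(self) -> bool:
        return self.host_locus is not None

    @property
    def klass(self) -> str:
        return "hybrid" if self.is_hybrid else "defective"

    def __post_init__(self) -> None:
        if self.copy_number <= 0:
            raise ValueError("copy_number must be positive")
        seg_total = sum(b - a + 1 for a, b in self.viral_segments)
        if self.host_locus is not None:
            a, b = self.host_locus[1]
            seg_total += b - a + 1
        expect = seg_total - sum(self.microhomology_len)
        if len(self.seq) != expect:
            raise ValueError(
                f"{self.id}: sequence length {len(self.seq)} != "
                f"segments {seg_total} - microhomology {sum(self.microhomology_len)}"
            )


@dataclass
class ReadPair:
    """One simulated or sequenced fragment, as two mates with Phred qualities."""

    id: str
    seq1: str
    qual1: list[int]
    seq2: str
    qual2: list[int]
    truth: dict | None = None  # template/ref id, fragment coordinates, strand

    def __post_init__(self) -> None:
        for seq, qual in ((self.seq1, self.qual1), (self.seq2, self.qual2)):
            if len(seq) != len(qual):
                raise ValueError(f"{self.id}: sequence/quality length mismatch")
            if qual and not (0 <= min(qual) and max(qual) <= 60):
                raise ValueError(f"{self.id}: qualities outside [0, 60]")


@dataclass
class AlignedSegment:
    """One gapless local alignment of part of a read to a reference."""

    read_id: str
    mate: int  # 1 or 2
    read_start: int  # 0-based half-open interval on the original read
    read_end: int
    ref_id: str
    ref_start: int  # 0-based half-open, forward strand
    ref_end: int
    strand: str  # '+' or '-'
    identity: float
    order_index: int = 0
    wrap_group: int = -1  # >=0 links the two halves of one origin-crossing hit

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity outside [0, 1]")
        if self.read_end <= self.read_start or self.ref_end <= self.ref_start:
            raise ValueError("empty alignment interval")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start


@dataclass(frozen=True)
class JunctionSide:
    """One side of a breakpoint.  ``side`` says which part of the reference is
    retained in the molecule: 'right' keeps ``ref[..pos]`` (breakpoint after
    pos), 'left' keeps ``ref[pos..]`` (breakpoint before pos).  ``pos`` is
    0-based."""

    ref_id: str
    pos: int
    side: str  # 'left' | 'right'


@dataclass
class Junction:
    """A clustered breakpoint call joining two reference positions."""

    side_a: JunctionSide
    side_b: JunctionSide
    support: int
    microhomology: int = 0
    jtype: str = "unknown"  # virus-host | virus-virus | host-host

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass
class Scaffold:
    """A consensus sequence assembled from recovered reads."""

    id: str
    seq: str
    supporting_reads: list[str]
    mean_depth: float
    circular_closure: bool = False  # walk returned to its start


@dataclass
class Block:
    """One reference-matching block of a scaffold annotation."""

    scaf_start: int  # 0-based half-open on the scaffold
    scaf_end: int
    ref_id: str
    ref_start: int  # 0-based half-open, forward strand
    ref_end: int
    strand: str
    identity: float


@dataclass
class SegmentAnnotation:
    scaffold_id: str
    seq: str
    blocks: list[Block]
    n_terminal_junctions: int = 0
    virus_id: str = ""
    virus_len: int = 0


@dataclass
class MinicircleRecord:
    """One row of the minicircle feature table."""

    id: str
    total_length: int
    viral_length: int
    host_length: int
    viral_percent: float  # full precision; round for printing
    viral_coord_string: str  # 1-based inclusive, " ... "-joined
    at_viral: float  # percent
    at_host: float  # percent
    host_locus: tuple[str, tuple[int, int]] | None  # (ref, 1-based inclusive)
    orf_free_host: bool
    copy_number_rel: float | None = None

    def __post_init__(self) -> None:
        if self.viral_length + self.host_length != self.total_length:
            raise ValueError(
                f"{self.id}: viral {self.viral_length} + host {self.host_length} "
                f"!= total {self.total_length}"
            )
        for v in (self.at_viral, self.at_host):
            if not (0.0 <= v <= 100.0):
                raise ValueError("AT percentage outside [0, 100]")


def record_from_lengths(
    id: str,
    viral_length: int,
    host_length: int,
    viral_seq: str = "",
    host_seq: str = "",
    viral_coord_string: str = "",
    host_locus=None,
    orf_free_host: bool = True,
    copy_number_rel: float | None = None,
) -> MinicircleRecord:
    """Build a feature-table row from segment lengths (and optionally
    sequences, for the AT percentages).  Total length and viral percent are
    derived, never supplied."""
    total = viral_length + host_length
    return MinicircleRecord(
        id=id,
        total_length=total,
        viral_length=viral_length,
        host_length=host_length,
        viral_percent=100.0 * viral_length / total,
        viral_coord_string=viral_coord_string,
        at_viral=100.0 * at_fraction(viral_seq),
        at_host=100.0 * at_fraction(host_seq),
        host_locus=host_locus,
        orf_free_host=orf_free_host,
        copy_number_rel=copy_number_rel,
    )
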