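"""File I/O: FASTA, (gzipped) FASTQ and tabular artifacts.

FASTA parsing/writing goes through Biopython.  FASTQ records are written as
plain 4-line Phred+33 records (gzip-compressed when the path ends in .gz);
mates go to ``_1``/``_2`` files.
"""

from __future__ import annotations

import gzip
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import CircularSequence, ReadPair, ReferenceSet


def write_fasta(path, seqs: list[CircularSequence]) -> None:
    records = [
        SeqRecord(
            Seq(s.seq),
            id=s.id,
            description="circular" if s.is_circular else "linear",
        )
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, circular: bool = False) -> list[CircularSequence]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        is_circ = circular or "circular" in (rec.description or "")
        out.append(CircularSequence(rec.id, str(rec.seq), is_circular=is_circ))
    return out


def write_reference_set(virus_path, host_path, refs: ReferenceSet) -> None:
    write_fasta(virus_path, [refs.virus])
    write_fasta(host_path, refs.hosts)


def read_reference_set(virus_path, host_path) -> ReferenceSet:
    virus = read_fasta(virus_path, circular=True)
    if len(virus) != 1:
        raise ValueError("virus reference file must contain exactly one sequence")
    hosts = [
        CircularSequence(h.id, h.seq, is_circular=False)
        for h in read_fasta(host_path)
    ]
    return ReferenceSet(virus=virus[0], hosts=hosts)


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # fixed mtime keeps identical runs byte-identical
            import io

            raw = gzip.GzipFile(path, "wb", mtime=0)
            return io.TextIOWrapper(raw)
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _qual_str(qual: list[int]) -> str:
    return "".join(chr(q + 33) for q in qual)


def write_fastq_pairs(prefix, pairs: list[ReadPair], gz: bool = True) -> tuple[Path, Path]:
    """Write mates to ``<prefix>_1.fastq[.gz]`` / ``<prefix>_2.fastq[.gz]``."""
    ext = ".fastq.gz" if gz else ".fastq"
    p1 = Path(f"{prefix}_1{ext}")
    p2 = Path(f"{prefix}_2{ext}")
    with _open_text(p1, "w") as f1, _open_text(p2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{_qual_str(p.qual1)}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{_qual_str(p.qual2)}\n")
    return p1, p2


def _read_fastq(path) -> list[tuple[str, str, list[int]]]:
    out = []
    with _open_text(path, "r") as fh:
        while True:
            header = fh.readline().rstrip()
            if not header:
                break
            seq = fh.readline().rstrip()
            fh.readline()
            qual = fh.readline().rstrip()
            name = header[1:].split()[0]
            out.append((name, seq, [ord(c) - 33 for c in qual]))
    return out


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    r1 = _read_fastq(path1)
    r2 = _read_fastq(path2)
    if len(r1) != len(r2):
        raise ValueError("mate files have different record counts")
    pairs = []
    for (n1, s1, q1), (n2, s2, q2) in zip(r1, r2):
        base1 = n1.rsplit("/", 1)[0]
        base2 = n2.rsplit("/", 1)[0]
        if base1 != base2:
            raise ValueError(f"mate pairing broken: {n1} vs {n2}")
        pairs.append(ReadPair(base1, s1, q1, s2, q2))
    return pairs
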