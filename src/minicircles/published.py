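"""Published feature table of BCTIV minicircles characterized in beet.

These are the printed characteristics of hybrid minicircles cloned after
rolling-circle amplification (field and experimental infections) or
assembled from sequencing reads, used as reference inputs for arithmetic
cross-checks: total length, viral-derived length with the printed
percentage, host-derived length, viral coordinate string (1-based, origin
at the stem-loop), per-segment AT percentages and the best host locus.

``host_incomplete`` marks rows whose host-derived match was flagged
incomplete/discontinuous in the original characterization; their printed
percentages are not arithmetically reproducible from the printed lengths
and are excluded from exact percentage checks.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PublishedRow:
    id: str
    section: str  # field_rca | experimental_rca | experimental_ngs
    total: int
    viral: int
    viral_pct_printed: float
    host: int
    coords: str
    at_viral: float
    at_host: float
    locus: str
    host_incomplete: bool = False


TABLE: list[PublishedRow] = [
    PublishedRow("MC#1", "field_rca", 1315, 580, 44.1, 735,
                 "1-172 ... 2435-2845", 61.4, 69.8, "chr6:9915362-9916096"),
    PublishedRow("MC#2", "field_rca", 1294, 416, 32.0, 878,
                 "1-166 ... 2596-2845", 61.3, 71.2, "chr7:36583873-36584676", True),
    PublishedRow("MC#3", "field_rca", 1502, 444, 29.3, 1058,
                 "1-157 ... 2223-2299 ... 2637-2845", 59.0, 71.2,
                 "chr3:un.sca001:135440-136484"),
    PublishedRow("MC#4", "experimental_rca", 1337, 459, 34.33, 878,
                 "1-135 ... 1184-1234 ... 2570-2845", 62.3, 73.6,
                 "chr6:57105781-57106674", True),
    PublishedRow("MC#5", "experimental_rca", 1504, 532, 35.4, 972,
                 "1-267 ... 2581-2845", 62.0, 70.6,
                 "chr3.sca001:1755016-1755723", True),
    PublishedRow("MC#6", "experimental_rca", 1572, 574, 36.5, 998,
                 "1-188 ... 2460-2845", 61.5, 68.2,
                 "chr5.sca008:17697504-17698497"),
    PublishedRow("MC#7", "experimental_rca", 1484, 664, 44.7, 820,
                 "1-327 ... 2509-2845", 61.1, 71.2,
                 "chr1.sca002:10250861-10250043"),
    PublishedRow("scf#1", "experimental_ngs", 1407, 396, 28.0, 1011,
                 "1-110 ... 2560-2845", 60.36, 71.97,
                 "chr4:23770925-23771936", True),
    PublishedRow("scf#2", "experimental_ngs", 1315, 332, 25.24, 983,
                 "1-177 ... 2560-2845", 60.25, 73.25,
                 "chr8:1269745-1270665", True),
    PublishedRow("scf#4", "experimental_ngs", 1336, 458, 34.28, 878,
                 "1-135 ... 1184-1234 ... 2570-2845", 62.3, 73.6,
                 "chr6:57105781-57106674", True),
    PublishedRow("scf#5", "experimental_ngs", 1552, 715, 46.1, 837,
                 "1-196 ... 2327-2845", 59.31, 71.45,
                 "chr8:33213612-33212757", True),
    PublishedRow("scf#7", "experimental_ngs", 1393, 621, 44.6, 772,
                 "1-329 ... 2554-2845", 61.20, 73.06,
                 "chr6:470978-471718", True),
    PublishedRow("scf#33", "experimental_ngs", 1241, 763, 61.48, 478,
                 "1-108 ... 2188-2845", 56.49, 73.44,
                 "0118.sca003:8222639-23116"),
    PublishedRow("scf#56/59", "experimental_ngs", 1429, 453, 31.7, 976,
                 "1-102 ... 2495-2845", 59.83, 68.04,
                 "chr3:21716285-21716210", True),
]

#: rows whose printed percentage equals the value recomputed from the
#: printed lengths at the printed precision (half-up rounding)
ARITHMETIC_CONSISTENT = [
    "MC#1", "MC#4", "MC#5", "MC#6", "MC#7",
    "scf#4", "scf#5", "scf#7", "scf#33", "scf#56/59",
]


def load_published_sequence(name: str):
    """Load a published minicircle sequence from the package's
    ``data/published`` directory (FASTA, one record).

    These sequences are distributed in public repositories, not bundled
    here; place ``<name>.fasta`` under ``data/published/`` to enable the
    sequence-level checks (e.g. the AT content of MC#1's beet-derived
    segment)."""
    from pathlib import Path

    from .seqio import read_fasta

    path = Path(__file__).parent / "data" / "published" / f"{name}.fasta"
    if not path.exists():
        raise FileNotFoundError(
            f"published sequence {name!r} not available at {path}; "
            "download the record and place it there to run sequence-level checks"
        )
    return read_fasta(path, circular=True)[0]


def rows(section: str | None = None) -> list[PublishedRow]:
    if section is None:
        return list(TABLE)
    return [r for r in TABLE if r.section == section]


def experimental_rows() -> list[PublishedRow]:
    return [r for r in TABLE if r.section in ("experimental_rca", "experimental_ngs")]
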