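"""Configuration objects.

``PipelineConfig`` gathers every numeric knob of the detection pipeline:
quality-trimming window and threshold, minimum surviving mate length,
alignment identity threshold, minimum junction read support, and the size of
the locus recovered around each selected junction.  ``SimulationConfig``
gathers the sequencing-design parameters the synthetic library emulates
(2 x 76 nt paired-end reads, ~350 nt inserts, a 2845 nt circular viral
genome with a single origin and a single EcoRI site, AT-rich host capture
windows, minicircle size bounds).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

ILLUMINA_ADAPTER = "AGATCGGAAGAGC"


@dataclass
class PipelineConfig:
    # quality trimming / pair filter
    trim_window: int = 4
    trim_min_q: int = 15
    min_mate_len: int = 16
    trim_mode: str = "both_ends"  # or "sliding_cut" (cut 5'->3' at first bad window)
    adapter_seq: str = ILLUMINA_ADAPTER
    # alignment
    min_identity: float = 0.95
    seed_k: int = 15
    min_split_segment: int = 16
    # junction calling
    min_junction_support: int = 10
    junction_cluster_tol: int = 5
    # recovery + assembly
    recovery_window: int = 10_000
    recovery_mode: str = "centered"  # or "flank": full window on each side
    min_overlap: int = 31
    # annotation
    orf_min_codons: int = 100
    ecori_site: str = "GAATTC"

    def __post_init__(self) -> None:
        positive = (
            "trim_window trim_min_q min_mate_len seed_k min_split_segment "
            "min_junction_support recovery_window min_overlap orf_min_codons"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.junction_cluster_tol < 0:
            raise ValueError("junction_cluster_tol must be >= 0")
        if not 0.5 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0.5, 1]")
        if self.min_split_segment < self.seed_k:
            raise ValueError("min_split_segment must be >= seed_k")
        if self.trim_mode not in ("both_ends", "sliding_cut"):
            raise ValueError("trim_mode must be 'both_ends' or 'sliding_cut'")
        if self.recovery_mode not in ("centered", "flank"):
            raise ValueError("recovery_mode must be 'centered' or 'flank'")


@dataclass
class SimulationConfig:
    seed: int = 1
    # viral genome
    virus_length: int = 2845
    origin_motif: str = "TAATATTAC"  # conserved nonanucleotide, placed at position 1
    intergenic_span: tuple[int, int] = (2640, 100)  # wrap interval, 1-based incl.
    virus_at: float = 0.59
    ecori_pos: int = 1000  # 1-based position of the single GAATTC site
    # host genome
    n_host_chrom: int = 5
    host_chrom_length: int = 200_000
    host_at_fraction: float = 0.71  # AT inside capture-prone intergenic windows
    host_background_at: float = 0.62
    at_window_length: int = 2_000
    n_at_windows_per_chrom: int = 6
    # templates
    minicircle_total_bounds: tuple[int, int] = (1241, 1572)
    host_fragment_bounds: tuple[int, int] = (735, 1058)
    microhomology_max: int = 3  # per-junction homology drawn uniform [0, max]
    copy_number_bounds: tuple[float, float] = (10.0, 500.0)  # log-uniform sampler
    # library
    read_length: int = 76
    insert_mean: float = 350.0
    insert_sd: float = 35.0
    per_base_error: float = 0.002
    base_quality: int = 35
    adapter_seq: str = ILLUMINA_ADAPTER
    background_depth: float = 2.0
    template_depth: float = 30.0

    def __post_init__(self) -> None:
        for name in (
            "virus_length n_host_chrom host_chrom_length at_window_length "
            "n_at_windows_per_chrom read_length"
        ).split():
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("minicircle_total_bounds", "host_fragment_bounds"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be an ordered positive interval")
        if not 0.0 <= self.per_base_error <= 0.2:
            raise ValueError("per_base_error must be in [0, 0.2]")
        for name in ("host_at_fraction", "host_background_at", "virus_at"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        span = self._intergenic_len()
        if self.virus_length < len(self.origin_motif) + span:
            raise ValueError("virus too short for origin motif + intergenic span")
        if not 1 <= self.ecori_pos <= self.virus_length:
            raise ValueError("ecori_pos outside the viral genome")

    def _intergenic_len(self) -> int:
        a, b = self.intergenic_span
        if a <= b:
            return b - a + 1
        return (self.virus_length - a + 1) + b


def _to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _from_dict(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in data.items():
        if k not in fields:
            raise ValueError(f"unknown {cls.__name__} key: {k}")
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def save_config(path, pipeline: PipelineConfig | None = None, simulation: SimulationConfig | None = None) -> None:
    doc = {}
    if pipeline is not None:
        doc["pipeline"] = _to_dict(pipeline)
    if simulation is not None:
        doc["simulation"] = _to_dict(simulation)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_config(path) -> tuple[PipelineConfig, SimulationConfig]:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    pipe = _from_dict(PipelineConfig, doc.get("pipeline", {}))
    sim = _from_dict(SimulationConfig, doc.get("simulation", {}))
    return pipe, sim
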