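"""End-to-end pipeline: simulate -> trim -> align -> junctions -> recover ->
assemble -> annotate, with a reproducible run manifest.

Every stage writes its artifact under the run directory; the manifest
records the config snapshot, seed, per-stage counts and a checksum of every
file consumed or produced, so identical (config, seed) runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate as ann_mod
from . import assembly, junctions as junc_mod, preprocess, seqio, simulate
from .config import PipelineConfig, SimulationConfig, save_config
from .records import CircularSequence, ReferenceSet
from .splitalign import SeedIndex, map_all


@dataclass
class RunManifest:
    seed: int
    config: dict
    counts: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    hybrids: list = field(default_factory=list)
    failed_stage: str | None = None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _checksum(manifest: RunManifest, *paths) -> None:
    for p in paths:
        manifest.checksums[Path(p).name] = _sha(p)


def _dedup_key(record) -> tuple:
    if record.host_locus is None:
        return ("virus-only", record.viral_coord_string)
    ref, (lo, hi) = record.host_locus
    return (ref, lo // 2000)


def _pick_control_region(refs: ReferenceSet, selected, cfg) -> tuple[str, int, int]:
    """First 5 kb host window at least one recovery window away from every
    selected junction: the single-copy normalization control."""
    half = cfg.recovery_window
    best = None  # fallback: maximize distance to the nearest junction
    for chrom in refs.hosts:
        n = len(chrom.seq)
        margin = min(20_000, max(0, n // 10))
        # wide windows keep the depth normalizer's sampling noise small
        span = min(20_000, max(2_000, (n - 2 * margin) // 3))
        pos = margin
        while pos + span <= n - margin:
            dist = min(
                (
                    0
                    if pos <= side.pos <= pos + span
                    else min(abs(side.pos - pos), abs(side.pos - (pos + span)))
                    for j in selected
                    for side in (j.side_a, j.side_b)
                    if side.ref_id == chrom.id
                ),
                default=n,
            )
            if dist >= half:
                return (chrom.id, pos, pos + span)
            if best is None or dist > best[0]:
                best = (dist, chrom.id, pos, span)
            pos += 5_000
    if best is None:
        raise RuntimeError("no control region found")
    return (best[1], best[2], best[2] + best[3])


def run_pipeline(
    workdir,
    pipe_cfg: PipelineConfig | None = None,
    sim_cfg: SimulationConfig | None = None,
    *,
    do_simulate: bool = True,
    virus_path=None,
    host_path=None,
    reads_prefix=None,
    scenario_kwargs: dict | None = None,
    write_fastq: bool = True,
) -> RunManifest:
    """Run all stages.  With ``do_simulate`` the default scenario is
    generated; otherwise references and reads are loaded from the given
    paths.  Returns the populated manifest (also written to
    ``manifest.json``)."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    pipe_cfg = pipe_cfg or PipelineConfig()
    sim_cfg = sim_cfg or SimulationConfig()
    manifest = RunManifest(
        seed=sim_cfg.seed,
        config={
            "pipeline": dataclasses.asdict(pipe_cfg),
            "simulation": dataclasses.asdict(sim_cfg),
        },
    )
    save_config(workdir / "config.yaml", pipe_cfg, sim_cfg)
    _checksum(manifest, workdir / "config.yaml")

    stage = "input"
    try:
        truth_templates = None
        if do_simulate:
            stage = "simulate"
            refs, windows, templates, pairs, pair_truth = simulate.default_scenario(
                sim_cfg, **(scenario_kwargs or {})
            )
            seqio.write_reference_set(
                workdir / "virus.fasta", workdir / "host.fasta", refs
            )
            truth_templates = simulate.templates_table(templates)
            truth_templates.to_csv(workdir / "truth_templates.tsv", sep="\t", index=False)
            pair_truth.to_csv(workdir / "truth_pairs.tsv", sep="\t", index=False)
            if write_fastq:
                seqio.write_fastq_pairs(workdir / "reads", pairs)
                _checksum(
                    manifest,
                    workdir / "reads_1.fastq.gz",
                    workdir / "reads_2.fastq.gz",
                )
            _checksum(
                manifest,
                workdir / "virus.fasta",
                workdir / "host.fasta",
                workdir / "truth_templates.tsv",
            )
        else:
            if virus_path is None or host_path is None or reads_prefix is None:
                raise ValueError("non-simulated runs need virus, host and reads paths")
            for p in (virus_path, host_path):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
            refs = seqio.read_reference_set(virus_path, host_path)
            pairs = seqio.read_fastq_pairs(
                f"{reads_prefix}_1.fastq.gz", f"{reads_prefix}_2.fastq.gz"
            )
        manifest.counts["pairs_in"] = len(pairs)

        stage = "trim"
        trimmed, report = preprocess.trim_and_filter(pairs, pipe_cfg)
        manifest.counts["pairs_surviving"] = report.pairs_out
        manifest.counts["surviving_fraction"] = round(report.surviving_fraction, 4)

        stage = "align"
        index = SeedIndex(refs, pipe_cfg)
        store = map_all(index, trimmed, pipe_cfg)
        store.to_tsv(workdir / "alignments.tsv")
        _checksum(manifest, workdir / "alignments.tsv")
        manifest.counts["aligned_segments"] = len(store.df)

        stage = "junctions"
        called = junc_mod.call_junctions(store, refs, pipe_cfg)
        selected = junc_mod.filter_junctions(called, pipe_cfg)
        junc_mod.junctions_to_frame(called).to_csv(
            workdir / "junctions_all.tsv", sep="\t", index=False
        )
        junc_mod.junctions_to_frame(selected).to_csv(
            workdir / "junctions_selected.tsv", sep="\t", index=False
        )
        junc_mod.junctions_to_bed(selected, workdir / "junctions_selected.bed")
        _checksum(
            manifest,
            workdir / "junctions_all.tsv",
            workdir / "junctions_selected.tsv",
        )
        manifest.counts["junctions_called"] = len(called)
        manifest.counts["junctions_selected"] = len(selected)

        stage = "recover_assemble"
        pairs_by_id = {p.id: p for p in trimmed}
        recovered = assembly.recover_reads(store, selected, trimmed, refs, pipe_cfg)
        manifest.counts["pairs_recovered"] = len(recovered)
        groups = assembly.group_junctions(selected, refs)
        grouped = assembly.assemble_groups(store, groups, pairs_by_id, refs, pipe_cfg)
        scaffolds = [sc for _, scs in grouped for sc in scs]
        seqio.write_fasta(
            workdir / "scaffolds.fasta",
            [CircularSequence(s.id, s.seq, is_circular=False) for s in scaffolds],
        )
        _checksum(manifest, workdir / "scaffolds.fasta")
        manifest.counts["scaffolds"] = len(scaffolds)

        stage = "annotate"
        anns = [ann_mod.segment_scaffold(s, refs, pipe_cfg, index) for s in scaffolds]
        classified = [(a, ann_mod.classify(a)) for a in anns]
        # try to merge complementary single-junction hybrid fragments
        singles = [a for a, c in classified if c == "hybrid" and a.n_terminal_junctions == 1]
        merged_seqs, leftovers, _ = ann_mod.merge_partial(singles, pipe_cfg)
        merged_anns = []
        for mid, seq in merged_seqs:
            sc = CircularSequence(mid, seq, is_circular=False)
            merged_anns.append(ann_mod.segment_scaffold(sc, refs, pipe_cfg, index))
        candidates = (
            [
                (a, c)
                for a, c in classified
                if not (c == "hybrid" and a.n_terminal_junctions == 1)
            ]
            + [(a, ann_mod.classify(a)) for a in merged_anns]
            + [(a, "hybrid") for a in leftovers]  # may still close via end overlap
        )

        control = _pick_control_region(refs, selected, pipe_cfg)
        records = []
        n_defective = 0
        seen = set()
        for a, c in candidates:
            if c == "hybrid":
                try:
                    cand = ann_mod.circularize(a, refs, pipe_cfg, junctions=selected)
                except ValueError:
                    continue  # incomplete hybrid evidence
                circle_ann = ann_mod.segment_scaffold(cand.circle, refs, pipe_cfg, index)
                if ann_mod.classify(circle_ann) != "hybrid":
                    continue
                rec = ann_mod.annotate_features(cand.circle, circle_ann, refs, pipe_cfg)
                key = _dedup_key(rec)
                if key in seen:
                    continue
                seen.add(key)
                cn = None
                if rec.host_locus is not None:
                    ref_id, (lo, hi) = rec.host_locus
                    if hi - lo + 1 >= 200:
                        cn = ann_mod.estimate_copy_number(
                            store, (ref_id, lo - 1, hi), control
                        )
                rec.copy_number_rel = cn
                records.append(rec)
            elif c == "defective":
                n_defective += 1
        records.sort(
            key=lambda r: (r.host_locus[0], r.host_locus[1][0]) if r.host_locus else ("", 0)
        )
        manifest.counts["hybrid_circles"] = len(records)
        manifest.counts["defective_scaffolds"] = n_defective
        manifest.counts["virus_virus_junctions"] = sum(
            1 for j in selected if j.jtype == "virus-virus"
        )

        rows = []
        for i, r in enumerate(records, 1):
            rows.append(
                {
                    "id": f"circle{i}",
                    "total_length": r.total_length,
                    "viral_length": r.viral_length,
                    "viral_percent": round(r.viral_percent, 2),
                    "host_length": r.host_length,
                    "viral_coords": r.viral_coord_string,
                    "at_viral": round(r.at_viral, 1),
                    "at_host": round(r.at_host, 1),
                    "host_locus": (
                        f"{r.host_locus[0]}:{r.host_locus[1][0]}-{r.host_locus[1][1]}"
                        if r.host_locus
                        else ""
                    ),
                    "orf_free_host": r.orf_free_host,
                    "copy_number_rel": (
                        round(r.copy_number_rel, 2) if r.copy_number_rel else "nd"
                    ),
                }
            )
        table = pd.DataFrame(
            rows,
            columns=[
                "id",
                "total_length",
                "viral_length",
                "viral_percent",
                "host_length",
                "viral_coords",
                "at_viral",
                "at_host",
                "host_locus",
                "orf_free_host",
                "copy_number_rel",
            ],
        )
        table.to_csv(workdir / "minicircles.tsv", sep="\t", index=False)
        _checksum(manifest, workdir / "minicircles.tsv")
        manifest.hybrids = rows
    except Exception:
        manifest.failed_stage = stage
        manifest.to_json(workdir / "manifest.json")
        raise
    manifest.to_json(workdir / "manifest.json")
    return manifest


# --------------------------------------------------------- truth compare ---


def compare_to_truth(workdir, tol_extra: int = 2) -> dict:
    """Per-template evaluation of a simulated run against its truth table.

    A planted hybrid is detected when a reported circle shares its host
    locus; its junction coordinates must match within +/- (microhomology +
    ``tol_extra``) and its length exactly.  Planted defectives are detected
    through their virus-virus junctions and must not surface as hybrids.
    """
    workdir = Path(workdir)
    truth = pd.read_csv(workdir / "truth_templates.tsv", sep="\t")
    if truth.empty:
        raise ValueError("empty truth table")
    manifest = json.loads((workdir / "manifest.json").read_text())
    circles = manifest["hybrids"]
    selected = pd.read_csv(workdir / "junctions_selected.tsv", sep="\t")

    per_template = []
    matched_circles = set()
    for _, t in truth.iterrows():
        if t["class"] == "helper":
            continue
        entry = {"template_id": t["template_id"], "class": t["class"]}
        t_junc = json.loads(t["junctions"])
        if t["class"] == "hybrid":
            hit = None
            for c in circles:
                if not c["host_locus"]:
                    continue
                ref, iv = c["host_locus"].split(":")
                lo, hi = map(int, iv.split("-"))
                if ref == t["host_ref"] and lo <= t["host_end"] and hi >= t["host_start"]:
                    hit = c
                    break
            entry["detected"] = hit is not None
            if hit:
                matched_circles.add(hit["id"])
                entry["length_error"] = abs(hit["total_length"] - int(t["length"]))
                errs = []
                for (ra, pa, _), (rb, pb, _), mh in t_junc:
                    best = None
                    for _, j in selected.iterrows():
                        if {j["refA"], j["refB"]} != {ra, rb}:
                            continue
                        pairs = (
                            (abs(j["posA"] - pa), abs(j["posB"] - pb))
                            if j["refA"] == ra
                            else (abs(j["posA"] - pb), abs(j["posB"] - pa))
                        )
                        err = max(pairs)
                        if best is None or err < best:
                            best = err
                    errs.append(best if best is not None else 10**9)
                entry["max_junction_error"] = max(errs)
                entry["junction_tol"] = max(mh for *_, mh in t_junc) + tol_extra
        else:  # defective
            found = False
            for (ra, pa, _), (rb, pb, _), mh in t_junc:
                for _, j in selected.iterrows():
                    if (
                        j["jtype"] == "virus-virus"
                        and abs(j["posA"] - pa) <= mh + tol_extra
                        and abs(j["posB"] - pb) <= mh + tol_extra
                    ):
                        found = True
            entry["detected"] = found
        per_template.append(entry)

    hybrids = [e for e in per_template if e["class"] == "hybrid"]
    defectives = [e for e in per_template if e["class"] == "defective"]
    n_det = sum(e["detected"] for e in hybrids)
    false_circles = [c for c in circles if c["id"] not in matched_circles]
    return {
        "per_template": per_template,
        "sensitivity": n_det / len(hybrids) if hybrids else float("nan"),
        "precision": (
            len(matched_circles) / len(circles) if circles else float("nan")
        ),
        "false_hybrids": len(false_circles),
        "defectives_detected": sum(e["detected"] for e in defectives),
        "defectives_total": len(defectives),
        "max_length_error": max(
            (e.get("length_error", 0) for e in hybrids if e["detected"]), default=None
        ),
        "max_junction_error": max(
            (e.get("max_junction_error", 0) for e in hybrids if e["detected"]),
            default=None,
        ),
    }
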