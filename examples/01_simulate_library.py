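"""Simulate a geminivirus infection sequencing experiment.

Builds a synthetic circular viral genome (origin at position 1, one EcoRI
site), a small host genome with AT-rich capture windows, plants two hybrid
minicircles plus one virus-only defective and a helper genome, and draws
2 x 76 nt read pairs.  Prints what was planted and how many reads cover it.
"""

from minicircles import SimulationConfig, default_scenario

cfg = SimulationConfig(seed=4, n_host_chrom=2, host_chrom_length=60_000)
refs, windows, templates, pairs, truth = default_scenario(
    cfg, n_hybrids=2, n_defectives=1, helper_copy_number=50.0
)

print(f"virus: {len(refs.virus)} nt, origin {refs.virus.seq[:9]}")
print(f"host: {len(refs.hosts)} chromosomes x {len(refs.hosts[0])} nt, "
      f"{len(windows)} AT-rich windows")
for t in templates:
    host = (
        f"{t.host_locus[0]}:{t.host_locus[1][0]}-{t.host_locus[1][1]}"
        if t.host_locus else "none"
    )
    print(
        f"  {t.id:7s} {t.role or t.klass:9s} {len(t.seq):5d} nt, "
        f"viral {t.viral_segments}, host {host}, copy number {t.copy_number:.1f}"
    )
print(f"{len(pairs)} read pairs drawn; per-pair truth table has {len(truth)} rows")
# Each planted molecule is covered at background_depth x copy_number; the
# truth table ties every read pair back to its source molecule.
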