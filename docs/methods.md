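# Methods

## The problem and the model

Geminivirus-infected plants can accumulate small circular DNAs besides the
helper genome: virus-only deletion derivatives ("defective DNAs") and —
in the system this package models — *hybrid minicircles* in which a
fragment of host chromosomal DNA is fused to the origin-containing viral
region. Because the viral arc always retains the stem-loop with the
nonanucleotide origin (`TAATATTAC`), the helper replicates these molecules
in trans to high copy number, so shotgun sequencing of infected tissue
contains them at far above 1× chromosomal depth. Detection reduces to:
find read-supported virus/host breakpoints, assemble the molecules around
them, prove circularity, and characterize the product.

## Synthetic data generator

The generator is the package's definition of the study conditions, not a
convenience fixture. It produces:

- **Viral genome** — circular, 2845 nt by default, origin motif placed at
  position 1 and occurring exactly once, exactly one EcoRI site (`GAATTC`,
  default position 1000); background composition 59 % AT. Accidental extra
  occurrences of either landmark are scrubbed by point substitution.
- **Host genome** — `n` linear chromosomes (default 5 × 200 kb, AT 62 %)
  carrying cataloged 2-kb "intergenic" windows whose AT fraction is set
  exactly to the target (default 71 % ± 1 pp jitter), emulating the
  AT-rich, gene-poor loci that minicircles capture.
- **Hybrid templates** — total length uniform in [1241, 1572] nt, host
  fragment in [735, 1058] nt, viral arc `[b..2845]+[1..a]` with
  `a ∈ [100, 330]` and `b` constrained so the arc spans the intergenic
  region; one template per host window (windows drawn without
  replacement). Junction microhomology of 0–3 nt per junction is imprinted
  into the host reference so that the upstream segment of each junction
  can be extended into the downstream one; recorded maximal segment
  intervals therefore double-count each homology tract and
  `len(seq) = Σ segments − Σ microhomology` — the same bookkeeping that
  makes a published coordinate string sum to 3 nt more than the printed
  viral length. Truth breakpoints are stored in the caller's canonical
  leftmost form, with the *realized* homology (planted + chance
  extensions) measured on the final references.
- **Defective templates** — retained viral intervals only, one of which
  must cover the origin; the degenerate full-genome case doubles as the
  helper.
- **Library** — fragments uniform on each circle (wrap-around across the
  origin), insert length N(350, 35²) clipped, 2 × 76 nt reads, constant
  Q35, independent substitution errors at 0.2 % per base (no indels),
  3′ adapter read-through when the fragment is shorter than a read.
  Per-template depth is `background_depth × copy_number` (background 2×);
  whole-genome background covers every reference. One global seed drives
  named sub-streams (genome / host / templates / library / errors), so
  every stage is independently reproducible and identical runs are
  byte-identical (gzip written with fixed mtime).

**Default scenario** (used by the acceptance script): 8 hybrids with copy
number log-uniform in [25, 100], 2 defectives at 25, helper at 100. The
lower bounds guarantee the planted condition that every junction clears
the 10-read support threshold (expected usable split support ≈ 29 at copy
number 25; Poisson tail < 10⁻⁶). The general-purpose copy-number sampler
spans [10, 500], the range from near-background to virus-like abundance.

What the generator does **not** emulate: indel sequencing errors, quality
profiles (qualities are constant and independent of the error process),
PCR amplification bias (the modeled protocol is PCR-free), repetitive or
transposon-rich host sequence, structural variation between the sequenced
plant and its reference, and inverted-orientation host capture. Passing
tests therefore demonstrate correctness of the pipeline's logic under the
stated noise model, not robustness to repeat-rich real genomes.

## Pipeline stages and numerical choices

**Trimming.** Adapter removal, then both-ends window trimming: cut inward
from each end to the first 4-nt window with mean quality ≥ 15 (truncated
windows use the remaining bases), then strip terminal bases individually
below the threshold — without the strip, a straddling window shelters 1–3
terminal Q2 bases. Scan and strip iterate to a fixpoint, which makes
trimming idempotent. Pairs with a mate < 16 nt are discarded. A
`sliding_cut` mode reproduces the classic single-pass 5′→3′ trimmer.

**Alignment.** Exact 15-mer seeds over all references (the circular virus
is indexed doubled so origin-crossing runs stay on one diagonal),
extended gaplessly along the seed diagonal. Gapless extension is exact
for the generator's substitution-only noise model, which is why no banded
gapped aligner is used. Per diagonal the reported segment maximizes
*matches − mismatches* subject to identity ≥ 0.95 and length ≥ 16
(ties → shorter, then leftmost), so a chance match beyond a mismatch
never drags a segment past a true breakpoint. A read is split when no
single segment explains ≥ (length − 15) bases; segment chains are chosen
by dynamic programming on the same score, and overlapping adjacent
segments are re-cut at the split point that maximizes total matches
(ties → leftmost), which pins raw breakpoints inside the true homology
tract. Identity is matches / aligned columns. Origin-crossing alignments
are reported as two wrap-linked segments with canonical (< genome length)
coordinates.

**Junction calling.** Each split mate contributes one event per adjacent
segment pair (wrap-linked pairs are contiguous on the circle, not
junctions). A breakpoint side is `(reference, position, retained side)`;
this representation is identical whichever read orientation observed the
junction. Microhomology is measured on the references by extending the
breakpoint left and right while the flanks agree; the call is placed at
the leftmost equivalent position, virus side first. Events cluster within
±5 nt — enough to absorb homology ambiguity, far below the distance
between distinct loci. Cluster support counts distinct mates; the
reported coordinate is the modal canonical position. Selection keeps
support ≥ 10 and at least one viral side; virus-virus junctions are kept
and labeled (they underlie defective DNAs), host-host junctions are
dropped.

**Recovery and targeted assembly.** Reads with an alignment inside the
10-kb window around either side of a selected junction are recovered with
their mates (window centered by default; a `flank` toggle gives 10 kb per
side, since the original description is ambiguous). For assembly the
pipeline groups junctions by locus: virus-host junctions sharing a host
locus (≤ 4 kb apart) form one target, each virus-virus junction its own,
and hybrid targets are assembled first with later targets excluded from
reads already placed. Grouping by the *host* side is deliberate: the
virus-side window covers the whole small viral genome, and a pooled
assembly of molecules that share viral sequence longer than a read is
inherently chimeric — no assembler can separate identical sequence; only
junction-spanning reads are discriminative.

The assembler is a greedy overlap-consensus walk: from a seed read,
extend by the longest consistent suffix–prefix overlap (≥ 31 nt, ≤ 1
mismatch per 32 nt), with a per-step majority vote over all overlapping
candidates deciding the next base whenever reads disagree — at a planted
junction the molecule's reads outvote the 2× chromosomal background, and
at a shared-sequence branch an earlier walk's consumed reads no longer
vote. Reads fully contained in the contig are consumed as the walk
passes (the scan window exceeds read length + maximal step, so nothing is
jumped over); a final sweep recruits all remaining contained reads for
consensus and prevents re-seeding. The final sequence is a per-column
majority over all placements; scaffolds shorter than twice the read
length are discarded. Everything is deterministic: seeds in first-read-id
order, ties broken lexicographically.

**Circularization and annotation.** Scaffolds are tiled with gapless
reference blocks (same seed-diagonal machinery; per-diagonal pieces are
trimmed to their best-scoring subinterval so low-identity tails never
leak past a junction; maximal-score chain with ≤ 20 nt overlap assigned
to the downstream block). A scaffold with virus and host blocks is a
hybrid; virus-only scaffolds are defective unless they span ≥ 99 % of the
genome (helper). Closure uses the scaffold's terminal self-overlap when
the walk went all the way around (overlap ≥ 31 nt, collapsed once);
otherwise a two-junction candidate is rebuilt exactly between its called
junction breakpoints, completing the viral arc (and host fragment) from
the references — junction-delimited reconstruction is length-exact by
construction because shifting a breakpoint within its homology tract
moves both sides together. Circles are rotated so the base matching
viral position 1 comes first (fallback: lowest covered viral coordinate,
flagged). Complementary single-junction scaffolds are merged when their
sequences share a consistent ≥ 31 nt overlap and their host blocks agree
(ambiguous multi-way merges are reported and not merged). Duplicate
circles are collapsed by host locus.

Feature rows: viral length is the scaffold span covered by viral blocks,
host length is the complement (so viral + host = total holds by
definition, as in the published table); the viral coordinate string joins
merged 1-based block intervals; AT % is computed per segment on the
circle's own sequence; the host locus is the best host alignment
(longest, then smallest reference/coordinate); ORF-freeness of the host
part uses a 100-codon threshold (configurable — the published claim gives
none), scanning ATG→stop in all six frames, wrap-aware on circles.

**Validations.** In-silico EcoRI digestion (wrap-aware, double-stranded;
fragment lengths always sum to the circle length; no site → "uncut") and
inverse PCR (exact primer sites, reverse primer as its reverse
complement; the product walks the circle from the forward primer's 5′ end
to the reverse primer's 3′ end; linear templates with inverted primers
yield nothing — the negative-control logic; multiple sites enumerate all
products flagged ambiguous).

**Copy number.** Relative abundance = robust depth over the circle's host
locus divided by robust depth over a junction-free single-copy control
window (≥ 2 kb, up to 20 kb — wide enough that the normalizer's sampling
noise at 2× stays in the few-percent range). Robust depth is a 20 %
trimmed mean of 100-nt binned depth: as resistant to local pileups as a
median, but continuous (a per-base median is integer-quantized — at 5×
that alone is a 20 % error floor) and identical-on-both-sides so that
region = control gives exactly 1.0. The estimate approximates
copy number + 1, since the locus also carries the 1× chromosome.

## Evaluation

`compare_to_truth` matches reported circles to planted hybrids by host
locus overlap and scores: detection sensitivity/precision, absolute
circle-length error (exact recovery expected), and junction coordinate
error with tolerance (realized microhomology + 2 nt) — coordinates within
a homology tract are genuinely unidentifiable. Planted defectives count
as detected through their virus-virus junctions; with a helper at
virus-like abundance their full circles are usually not assembled
(helper reads dominate the virus-side continuation), which matches the
design goal: defectives must be *reported and never misclassified as
hybrids*, not necessarily rebuilt base-exactly.

## Problem sizes

Default simulated design: 5 × 200 kb host + 2845 nt virus, ~25 k read
pairs, 11 planted molecules; the full pipeline runs in well under a
minute on one CPU, and the whole test suite in a few minutes. Unit tests
use 1–2 × 30–60 kb genomes.

## Known limitations

- Substitution-only alignment: indel-containing reads would fragment or
  drop; supporting them needs a gapped extender.
- Host fragments are modeled on the forward strand; inverted captures
  would exercise the reverse-orientation paths more heavily.
- Junction-delimited reconstruction takes the host fragment from the
  reference when the assembly did not close; a sample whose captured
  locus differs from its reference assembly would need the
  consensus-first path.
- The assembler is targeted and coverage-aware by design; it is not a
  general-purpose assembler and degrades when distinct molecules share
  more sequence than read length *and* have similar depth.
- One test requires a published sequence record that cannot be bundled;
  it reports failure until the record is placed under
  `src/minicircles/data/published/`.
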