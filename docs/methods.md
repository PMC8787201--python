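# Methods

## The hybridization model

A candidate binding site is an mRNA window exactly as long as the miRNA,
paired antiparallel and ungapped: site position *i* (0-based) pairs miRNA
position *L−1−i*. Each bonded pair contributes a fixed free-energy
magnitude and the duplex energy is the negated sum

ΔG = −Σᵢ E(site[i], mirna[L−1−i]),

with E(G:C) = 6.37 kJ/mol (3 hydrogen bonds), E(A:U) = 4.25 (2),
E(G:U) = E(A:C) = 2.12 (1), and 0 for every other pair. The model is
strictly per-pair additive: no nearest-neighbour/stacking terms, no gaps or
bulges, no mRNA secondary-structure accessibility. These are deliberate
assumptions of the full-length scoring approach, not omissions — the
statistic of interest is complementarity over the whole miRNA, and the
wobble pairs preserve helical geometry, so a colinear per-pair sum is the
natural score.

ΔGm is ΔG of the miRNA against its exact canonical complement; it depends
only on base composition and bounds ΔG from below. The site-quality
statistic is the complementarity ratio 100·ΔG/ΔGm (%). It is 100 exactly
when the site is the canonical reverse complement (property-tested), and
replacing any canonical pair by a wobble or mismatch strictly decreases
|ΔG|.

Sign convention: energies are stored negative (ΔG ≤ 0); "greater binding
energy" throughout means larger |ΔG|. Mismatches contribute 0 — the model
defines bonded pairs only, and no penalty term is defined.

## Scanning and filtering

Every window from the first transcript position, step 1 nt, is scored
(vectorized over an integer-encoded transcript with a 5×5 energy lookup).
Windows with unrounded ratio ≥ threshold are reported as sites, annotated
with the region (5′UTR/CDS/3′UTR) containing their **start** position —
boundary-spanning sites get exactly one region. The default threshold is
90%, the smallest ratio printed in the reference tables; it is fully
configurable since the original cutoff for genome-scale lists is not
stated. A 1e-9 epsilon in the comparison absorbs float summation-order
noise so perfect sites always pass threshold 100. Windows with more than
10% N are skipped: N forms no bond, so masked stretches would otherwise
produce spurious low-ratio windows rather than honest no-calls.

Ratio and ΔG are kept unrounded internally; only the report layer rounds
(integer kJ/mol, integer percent, integer compaction), matching the
formatting of the printed tables. The ratio is computed from unrounded ΔG.

Overlap resolution: when sites of *different* miRNAs intersect, the site
with the larger |ΔG| is kept, applied transitively over overlap chains by
iterative removal of the weakest conflicted site. Ties keep the 5′-most
start, then the lexicographically smallest miRNA id, making the operation
a pure, idempotent, order-independent function (tested against an
exhaustive oracle over all subsets of a conflict pool). Same-miRNA
overlaps are never removed — massively overlapping tandem repeats of one
miRNA are a real reported phenomenon. Because the reference tables
themselves print mutually overlapping sites of different miRNAs, overlap
resolution is an optional stage: off by default, available via
`--resolve-overlaps` and on in the cluster subcommand.

## Clusters

A cluster is a maximal group of sites whose intervals overlap or lie
within `gap` nt of each other (default gap 0 = overlap or abut). Site
`end` is defined as `start + length`, and cluster span as
`last_end − first_start`; this reproduces the printed span arithmetic
(e.g. a region covered by 21-nt sites from 276 to 306 has span 30) and is
one larger than a fully inclusive convention — documented here once,
applied everywhere. Degree of compaction = total summed site length /
span (e.g. 281 nt of sites over a 28-nt span → 10.04, reported as 10);
start spacings are successive start differences in 5′→3′ order. The
cluster report filter defaults to ≥ 14 member sites, the selection used
for the reference cluster table.

## GCC repeats and homopolymers

The exact detector finds the maximal contiguous (GCC)ᵏ substring
(leftmost on ties; equivalent to a regex search, which serves as the test
oracle). Only the GCC family is implemented — every repeat length class in
the reference data is a multiple of 3 and hand-verification of the 5′UTR
table confirms the (GCC)ᵏ definition. The tolerant variant allows up to
`m` interior non-GCC triplets in phase (never at either end) for
interrupted repeats; with m = 0 it reduces to the exact detector, and it
is monotone non-decreasing in m (property-tested). Length classes are
18, 21, 24 and 27plus (≥ 27); shorter runs classify as "none".

A CDS run encodes a homopolymer whose residue depends on codon phase. We
define `frame_offset` as the offset into the run where the first full
codon begins — `(cds_start − run_start) mod 3` in 1-based coordinates —
so offset 0 reads GCC (polyalanine), 1 reads CCG (polyproline), 2 reads
CGC (polyarginine), always k residues. Runs outside the CDS are refused.

## Synthetic data

The generator emulates exactly the structures the pipeline detects, at the
study conditions used throughout: i.i.d. background sequence with
P(G)=P(C)=gc/2 (default gc 0.5), transcripts of 1200–2000 nt with a 20%
5′UTR and a 50% CDS snapped to a codon multiple, and a demonstration study
of 20 transcripts, 5 miRNAs (20–22 nt, plus one period-2 miRNA for tandem
planting) and 30 planted features: 15 single sites with 0–2 wobbles, 3
tandem triples at spacing 2, and 6 GCC runs (k = 6–9) split between 5′UTR
and CDS with all three frame offsets. These sizes keep end-to-end recovery
tests small while exercising every feature type, region and frame.

Planting writes the canonical reverse complement of the miRNA, then
substitutes wobbles on the mRNA side only (C→U opposite G, U→C opposite
A), mirroring fixed reference miRNAs against variable transcripts; the
truth table carries the analytic expected ratio
100·(|ΔGm| − Σ losses)/|ΔGm| (loss 4.25 per G-opposed wobble, 2.13 per
A-opposed one). Tandem planting with spacing < L requires the miRNA's
reverse complement to be periodic with period = spacing — otherwise the
overlapped writes would conflict and the call refuses, naming the first
conflicting position. Every feature gets 3-nt flank guards: around GCC
runs, AUA triplets that cannot extend the run; around sites, bases chosen
bond-free against the miRNA positions they would face in a window shifted
by the planting period, so period-shifted windows fall below threshold
instead of extending the cluster.

All randomness derives from numpy generators keyed by (seed, stream
label) with CRC-based stream hashing, so outputs are byte-identical across
runs and platforms and planting one feature never perturbs another.

What the generator does *not* model: real transcriptome composition and
codon usage, expression or exosomal abundance, RNA structure, sequencing
error. Passing recovery tests therefore demonstrates correctness of the
scoring/clustering/repeat machinery under the stated model, not predictive
accuracy on biological data.

## Fixtures

The four packaged TSVs transcribe the published summary tables row by row,
preserving the original typesetting (zero-width separators, mixed T/U) in
sequence cells; loading cleans them (strip non-letters, uppercase, T→U)
and verifies SHA-256 checksums. Printed cluster coordinates refer to
unspecified GenBank mRNA versions and are treated as opaque integers, not
re-derived. Known internal inconsistencies of the printed tables (one
cluster row with last < first start; a 5′UTR distinct-gene count of seven
where six distinct genes appear) are kept as printed; the recomputed
fixture checks use the counts that are internally consistent
(3′UTR and CDS distinct genes, 100%-complementarity genes, repeat-length
classes).

## Numerical and interface choices

* Coordinates are 1-based inclusive everywhere in the API and reports;
  half-open arithmetic is internal only.
* The energy model is overridable from a flat YAML mapping (pair →
  [energy, hbonds]); validation enforces symmetry, magnitude/bond-count
  consistency and matching orderings.
* The annotation reader accepts a 3-column TSV or a GFF3 subset
  (five_prime_UTR/CDS rows per mRNA), tested for dialect equivalence.
* `run_pipeline` is a pure function of (inputs, config): reruns are
  byte-identical; partial outputs are removed on any stage failure.
* Degenerate inputs: empty miRNA, ΔGm = 0, span ≤ 0, non-triplet run
  lengths and out-of-range thresholds all raise typed errors rather than
  producing numbers.

## Limitations

Thermodynamic folding, seed-region scoring, statistical significance
models and accessibility weighting are out of scope by design. The
scanner's per-pair energies are fixed constants of the model; they are not
fitted. Genome-scale corpus scans (full miRBase × RefSeq) are supported as
a user-run command but are not part of the test surface, which operates at
fixture and synthetic-study scale.
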