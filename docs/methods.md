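# Methods

This note records the models, conventions, numerical choices and
limitations behind the `threecs` toolkit.

## Oligonucleotide design

A 3Cs mutagenic oligo is `arm5 + insert + arm3`. The arms anneal the oligo
to circular ssDNA template, so they must match the template exactly: the 5′
arm is a suffix of the U6-promoter tail, the 3′ arm a prefix of the gRNA
scaffold head. Arm selection takes the *shortest* arm satisfying both a
length floor (default 15 nt) and a melting-temperature floor (default
50 °C); shorter oligos are cheaper to synthesize and the constraints are
monotone in arm length, so the greedy minimum is optimal and unique.

Melting temperature defaults to the Wallace rule, 2·(A+T) + 4·(G+C) °C. It
is deterministic, dependency-free and adequate for threshold checks at
15–18 nt arm lengths; a nearest-neighbor alternative (SantaLucia 1997
parameters via Biopython, 50 mM Na⁺) is available through
`melting_temperature(..., method="nearest_neighbor")` for users who prefer
a thermodynamic model. Annealing temperature is not modelled; the 45 °C
screening threshold sometimes quoted for 18-nt arms is simply a different
threshold value passed to the same machinery.

The template placeholder between U6 tail and scaffold head carries a
restriction site (I-SceI `TAGGGATAACAGGGTAAT` for gRNA vectors, Bsu36I
`CCTNAGG` for the pLKO.1-style shRNA vector) whose digestion destroys
unreacted template. Two design rules follow: the placeholder *must*
contain the site (validated on `TemplateContext` construction, either
orientation), and a finished oligo must *not* contain it on either strand
(checked by a naive IUPAC-aware scan of the assembled sequence and its
reverse complement). For degenerate site patterns such as Bsu36I the scan
is conservative: a window counts as an occurrence if every position's base
sets intersect.

### Randomized oligo series

A block of four consecutive Ns begins at (1-based) oligo position 30; each
additional randomized position extends the block alternately left and
right. The direction of the first extension is not dictated by the
construction itself, so it is a parameter (`extend_order`, default
`left_first`, giving blocks 30–33, 29–33, 29–34, 28–34, 28–35, 27–35 for
n = 4…9). Every concrete occurrence of the clean-up site in the backbone
must overlap the randomized block — that is what lets correctly
synthesized products escape the clean-up digest — and the design errors
out otherwise. Oligo positions are reported 1-based to match how
synthesis orders are written; all genomic coordinates elsewhere are
0-based half-open.

### shRNA oligos

The hairpin cassette is `target + loop + reverse_complement(target)` with a
mandatory 6-nt loop and a 19–22-nt target. A palindromic target makes
sense and antisense identical and triggers a warning (the hairpin would be
abnormally stable). Clean-up-site occurrences wholly inside the cassette
are tolerated (they are the user's intent); any occurrence touching the
arms is an error.

## Degenerate libraries and target scanning

Diversity is the exact arbitrary-precision product of per-position IUPAC
degeneracies, cross-checked in tests against exhaustive enumeration for
every pattern with diversity ≤ 4⁸.

Screening scale: `cells = ⌈D · coverage / MOI⌉` with MOI in particles per
cell, so MOI 0.2 means five cells per particle. Note the formula divides
by MOI: lowering the MOI *raises* the cell number.

The target scanner is a vectorized brute-force scan. A genome base
mismatches a pattern position iff it lies outside that position's
IUPAC expansion set — for a concrete guide this reduces to Hamming
distance. The PAM (default NGG) is matched exactly, with no mismatch
budget, immediately 3′ of the protospacer on the site's strand. Genome
`N` bases lie outside every expansion set, so masked regions accumulate
mismatches and (for spans wider than the budget) yield no sites.
Minus-strand sites are found by scanning the forward strand for
`revcomp(PAM) + revcomp(pattern)`; reported coordinates always refer to
the forward strand and span the protospacer only. Overlapping sites are
all reported; output order is (start, strand) per contig, deterministic.
Off-target *scoring* (CFD/MIT), bulges and PAM mismatches are out of
scope.

## Read counting

Trimming locates the leftmost occurrence of the adapter (a prefix of the
3′ homology); failing that, the longest adapter prefix of at least
`min_overlap` (default 3) nt flush with the read's 3′ end. Everything from
the adapter onward is removed, then only the last `keep_last` nt are kept
(20 by default, 17 for 17-mer libraries), which makes the stage robust to
variable upstream vector sequence. Reads with any non-ACGT base in the
kept window are rejected as ambiguous. Adapter matching is exact — the
last-`k` rule absorbs adapter-edge effects, and exact matching keeps the
stage deterministic; reads with no adapter evidence are rejected
(`allow_untrimmed` exists but defaults off, to avoid frame-shifted
protospacers). Base qualities are carried but never interpreted.

Assignment is exact matching with precedence library member → wildtype
placeholder → degenerate pattern (novel members counted under their own
sequence) → unassigned. Counts are order-independent and the class totals
plus rejections always sum to the input read count. Normalized counts
divide the assigned classes (library + pattern-novel) by their per-sample
total, so they sum to 1; the wildtype rate is reported against
wildtype + assigned reads.

## Distribution statistics

* **CV** = 100 · s/x̄ with the sample (n−1) standard deviation; a
  population-SD switch exists. Scale-invariant, so raw and normalized
  counts agree.
* **Lorenz/AUC**: members ranked by *descending* abundance; points
  (i/n, cumulative fraction), (0,0) prepended; trapezoid AUC. Uniform
  counts give exactly 0.5 and concentration approaches 1 − 1/(2n). The
  descending convention (curve above the diagonal) is used because library
  uniformity is then "AUC close to 0.5 from above", the reading used
  throughout this field's QC figures; a Gini-style ascending curve would
  mirror it below the diagonal.
* **Uniformity**: Pearson chi-squared against the uniform expectation,
  upper-tail p at n−1 df (the standard one-sided goodness-of-fit reading).
  Not scale-invariant — run it on raw counts; a warning fires when
  expected counts drop below 5.
* **Positional profiles**: count-weighted L×4 base-frequency matrix, rows
  summing to 1. The IUPAC consensus takes, per position, the code whose
  expansion equals the set of bases at frequency ≥ `min_freq`
  (default 0.10 — between the sequencing-noise floor and the smallest
  legitimate allowed-base frequency of 0.25 for an equimolar N); if
  nothing clears the threshold the argmax base is used.
* **C-content ranking**: members ranked by descending count with
  lexicographic tie-breaking for determinism; the mean C fraction over the
  top ⌈f·n⌉ members is the synthesis-bias diagnostic.

## Cytosine-bias correction

The model is fit on the same counts it corrects (no held-out set): the
observed positional frequencies are compared to the 25% expectation, and
each read is scored by *summing* its positional weights. The count of each
guide is multiplied by its score, divided by the total assigned count, and
renormalized to sum to 1 — the intermediate division only changes a global
constant, so the normalized output is unambiguous.

The direction of the weights deserves a note. Read literally,
"normalizing observed to expected" could mean observed/expected, but
multiplying counts by that score would *amplify* overrepresented bases.
The default here is `expected / observed` (down-weighting overrepresented
bases), which is the direction that flattens a C-biased library — it
lowers the Lorenz AUC and moves positional C frequencies toward 0.25, the
documented purpose of the procedure. The literal direction remains
available via `direction=up_weight_overrepresented` for comparison. A
base never observed at a position receives weight 0 with a warning (it
cannot occur in any counted read). Correction is not claimed to be
idempotent; the tested guarantees are conservation (output sums to 1),
identity under an exactly uniform frequency matrix, and strict reduction
of AUC and of positional C deviation (equivalently KL divergence from
uniform) on C-biased simulations across seeds. Dinucleotide or
coupled-position bias models are out of scope.

## Screen arithmetic

Gene aggregation sums guide counts per gene and normalizes by the sample
total; because both operations are linear, aggregate-then-normalize equals
normalize-then-aggregate (tested). Unannotated guides are excluded from
gene totals and tracked separately. Log2 fold changes use normalized
values with a depth-scaled pseudocount (default 0.5 / sample total; 0 for
exact ratios), making the statistic antisymmetric under sample swap.
Replicate correlation reports Pearson r, r², and Spearman ρ (average
ranks for ties) on normalized values over the shared member set.
Enrichment filtering uses a strict inequality ("more than k-fold" excludes
exactly k-fold); members with zero control counts are included but
flagged, since their ratio is undefined rather than small. Dedicated
hit-calling statistics (RRA-style rank aggregation, p-values, FDR) are
deliberately not reimplemented here.

## Simulator

The simulator emulates amplicon sequencing of a pooled library: an
abundance vector (uniform; log-normal with σ for realistic skew; or
C-biased with weight ∝ exp(β·#C), reproducing the synthesis-bias
phenomenon parametrically), an optional wildtype-placeholder fraction, and
reads laid out as `5′ vector context + protospacer + 3′ adapter`,
left-truncated to the read length so the protospacer and adapter evidence
always fit. Reads are drawn multinomially; the truth table is exact.
Everything is a deterministic function of the seed. There is no
sequencing-error model by default (the counting pipeline matches exactly,
so errors would only exercise the rejection path); a real instrument's
quality profiles, PCR duplicates and paired-end structure are not
modelled. Passing tests on simulator output therefore demonstrate the
pipeline's arithmetic and bookkeeping, not robustness to instrument
artifacts.

Synthetic genomes are i.i.d. at a specified GC content with planted
protospacer+PAM sites at recorded coordinates; planted sites never
overlap. Real genomes' repeat structure and composition heterogeneity are
not emulated — scanner correctness is instead established by equality with
an independent sliding-window oracle at 0–2 mismatches on both strands.

## Problem sizes and determinism

The test suite and worked examples run at desk scale by choice: simulated
libraries of 10²–5×10³ members and 10⁴–10⁶ reads, genomes of 10³–10⁵ bp.
These sizes are where the statistical assertions (3-binomial-SD recovery
bounds, occupancy-model uniqueness, correction monotonicity across ≥5
seeds) are already sharp. Genome-scale site counts (hundreds of millions
of SpCas9 sites in a mammalian genome) and published screen hit lists
depend on external genome builds, figure-only pattern strings and
third-party hit-calling tools, and are documented inputs rather than test
targets. All randomness flows through explicit seeds; identical spec +
seed reproduces byte-identical tables and reports.
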