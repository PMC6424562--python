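# threecs

Design and NGS quality control of covalently-closed-circular-synthesized
(3Cs) CRISPR/Cas gRNA libraries.

3Cs library generation inserts gRNA-encoding oligonucleotides into circular
single-stranded template DNA by Kunkel-style mutagenesis — no PCR, no
cloning — which uncouples a library's sequence *diversity* from its
sequence *distribution*. This package implements the computational side of
that workflow for people who build and validate such libraries:

* **Oligo design** — mutagenic oligos for single gRNAs, equimolar pools,
  partially randomized (IUPAC) libraries and shRNA hairpins, with homology
  arms selected against the template's U6-promoter tail and scaffold head
  (minimum length 15 nt, Wallace T<sub>m</sub> ≥ 50 °C by default) and a
  guarantee that the template clean-up restriction site (I-SceI
  `TAGGGATAACAGGGTAAT`, or Bsu36I `CCTNAGG` for shRNA vectors) never occurs
  in a finished oligo.
* **Diversity and screening scale** — exact diversity of degenerate
  libraries (`∏ per-position degeneracy`, e.g. 4<sup>20</sup> ≈ 1.1 × 10<sup>12</sup>
  for a fully randomized 20-mer), cells required for a screen
  (`⌈D · coverage / MOI⌉`), and genome-coverage fractions.
* **Target-site scanning** — brute-force enumeration of protospacer + PAM
  matches on both genome strands with up to *k* protospacer mismatches
  (PAM matched exactly), for concrete or degenerate guide patterns.
* **Read QC** — FASTQ → count table: adapter trimming by a prefix of the 3′
  homology, last-*k* protospacer extraction (20 nt, or 17 for 17-mer
  libraries), ambiguous-read exclusion, exact assignment to library /
  degenerate pattern / wildtype placeholder.
* **Distribution statistics** — coefficient of variation (CV = s/x̄, as a
  percentage), Lorenz curves and their AUC (descending-rank convention:
  uniform = 0.5), chi-squared uniformity tests, positional nucleotide
  frequency matrices, IUPAC consensus recovery, and C-content-vs-abundance
  profiles.
* **Cytosine-bias correction** — randomized oligo pools carry a cytosine
  excess from incomplete phosphoramidite mixing; the correction weights
  every position/base by `expected(0.25) / observed`, scores each guide by
  the sum of its positional weights, rescales counts by the score and
  renormalizes, flattening the abundance distribution.
* **Screen arithmetic** — gene-level aggregation (sum guide counts per
  gene, normalize per sample), log2 fold changes, replicate correlation
  (Pearson R², Spearman ρ), strict fold-change enrichment filtering and
  replicate intersection.
* **Simulator** — deterministic synthetic reads (uniform, log-normal or
  C-biased abundances; wildtype contamination; vector-context read layout)
  and genomes with planted target sites, so the whole pipeline is testable
  without downloads.

## Worked example

```python
from threecs import (TemplateContext, design_grna_oligo, cells_required,
                     SimSpec, DegeneratePattern, simulate_reads,
                     CountTable, qc_report, correct_counts)
from threecs.readqc import CLASS_PATTERN_NOVEL

# 1. Design a 3Cs oligo for a GFP-targeting guide.
ctx = TemplateContext(
    u6_tail="CTTGTGGAAAGGACGAAACACCG",
    scaffold_head="GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCG",
    placeholder="GTAGGGATAACAGGGTAATC",          # carries the I-SceI site
)
oligo = design_grna_oligo("GACCAGGATGGGCACCACCC", ctx)
print(oligo.arm5, len(oligo.arm5), oligo.arm5_tm)
# GAAAGGACGAAACACCG 17 52.0        <- shortest arm with Tm >= 50 degC
print(oligo.arm3, len(oligo.arm3), oligo.arm3_tm)
# GTTTTAGAGCTAGAAATAG 19 50.0

# 2. How many cells does a 363-guide screen need at 1000x coverage, MOI 0.2?
print(cells_required(363, coverage=1000, moi=0.2))
# 1815000

# 3. Simulate a C-biased randomized library, QC it, correct it.
spec = SimSpec(library=DegeneratePattern("N" * 10), n_reads=100_000,
               n_pattern_members=1500, abundance_model="c_biased",
               beta=0.4, seed=1)
counts = simulate_reads(spec).truth
table = CountTable.from_counts(counts, CLASS_PATTERN_NOVEL)
report, _ = qc_report(counts)
print(f"CV {report.cv_percent:.1f}%  AUC {report.auc:.3f}  "
      f"top-5% C {report.top_c_content:.1f}%")
# CV 67.0%  AUC 0.660  top-5% C 54.9%
corrected = correct_counts(table)["sample"]
print(f"corrected AUC {qc_report(corrected)[0].auc:.3f}")
# corrected AUC 0.647
```

The arm lengths show the design rule at work (arms grow past 15 nt until
the Wallace T<sub>m</sub> threshold is met); the QC numbers show the C-bias
phenomenon (the most abundant guides are C-rich, AUC above the uniform 0.5)
and its partial removal by the positional-frequency correction.

The same operations are available from the shell:

```sh
threecs simulate --library NNNNNNNNNN --abundance c_biased --beta 0.4 \
        --n-reads 100000 --seed 1 --out sim/
threecs count --fastq sim/reads.fastq.gz --pattern NNNNNNNNNN \
        --adapter GTTTTAGAGCTAGAAATAGCAAG --keep-last 10 --out counts/
threecs qc counts/counts.tsv --report report.json
threecs correct counts/counts.tsv --out corrected.tsv
threecs scan genome.fasta --pattern GACCAGGATGGGCACCACCC --pam NGG --max-mm 2
```

## Layout

`src/threecs/` — `seqcore` (alphabets, IUPAC, T<sub>m</sub>, FASTA/FASTQ),
`oligo_design`, `degenerate` (diversity, scanning, scale), `readqc`,
`libstats`, `bias_correction`, `screen`, `simulate`, `cli`.
`docs/methods.md` describes the models, conventions and limitations.
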