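# Methods

## Problem setting

Reciprocal F1 hybrid mouse ESC lines (JB1 = JF1 mother x B6 father; BJ1 = the
reciprocal cross) carry two haplotypes separated by roughly one SNP per 250 bp.
ChIP-seq reads from such a hybrid can be assigned to the parental haplotype
they came from wherever they overlap a distinguishing SNP, turning an ordinary
binding profile into an allele-specific one. Comparing the two reciprocal
lines separates two causes of mono-allelic binding: *parental-origin* binding
follows the inherited parent (maternal or paternal allele in both crosses, the
signature of imprinting control regions), while *strain-specific* binding
follows the genotype (the same B6 or JF1 haplotype in both crosses, the
signature of a SNP disrupting a binding site). The package implements this
analysis for ZFP57/KAP1-type binding together with the motif-architecture
analysis that explains strain-specific loci: hexamer variant scanning
(TGCCGC, GGCCGC), SNP-driven motif disruption calls, and clusters of closely
spaced motifs.

## Read assignment

Alignment is replaced by *placement-level* comparison: each read comes with
its genomic placement (from a SAM file or the simulator), and its mismatch
count against each haplotype is the Hamming distance at that placement
(minus-strand reads are reverse-complemented first). On SNV-only haplotype
pairs this reproduces the decision an ungapped 0/3-mismatch aligner would
make, without an aligner dependency, and is exactly testable.

* **Informative read (IR):** footprint overlaps >= 1 SNP.
* **Stringent contract (x):** the sequenced base at every overlapped SNP must
  vote for one haplotype, and the read must match that haplotype with zero
  mismatches. Conflicted or error-carrying reads are *ambiguous* and are
  excluded from both IR and ASR, so IR = ASR_B6 + ASR_JF1 identically.
* **Control contract (j):** the same pool is re-evaluated allowing up to three
  mismatches. By default (`control_semantics="alignment"`) an informative read
  is counted for **every** haplotype it matches within the bound — a clean
  informative read matches both (its SNP mismatch is within 3), so per-peak
  control percentages j concentrate near 50 and their spread reflects residual
  asymmetric mappability (reads stacked on >= 4 SNPs, or errors pushing one
  side over the bound), i.e. mapping bias rather than biology. The alternative
  `control_semantics="vote"` gives a single call per read under the 3-mismatch
  bound; it is retained for comparison but makes j track x, which defeats the
  calibration below.

Duplicates are removed positionally — one representative per
(chromosome, start, strand) — and reads overlapping indel intervals can be
excluded; the haplotype model itself is SNV-only.

## Calibration, score and classification

Per peak and line, x = ASR_B6/(ASR_B6+ASR_JF1) x 100 (stringent) and j is the
same from control counts. Peaks on sex chromosomes are removed (the hybrid
lines are male), and a peak is analysed only when IR >= 5 **and** IR_C >= 5 in
**both** lines (inclusive bound).

The per-line calibration takes the mean j_bar and sample standard deviation
sigma (n-1 denominator; the spec of the original procedure does not fix the
estimator, and the sample SD gives the conservative, wider range) of the j
distribution over all informative autosomal peaks, and defines the
bi-allelicity range Y = j_bar +/- 3 sigma (membership inclusive). The Y-rule
classifies a peak bi-allelic when x is inside Y in both lines, mono-allelic
when outside in both, and discordant otherwise.

The combined two-line allelic score is

    S = ( |j_bar_JB1 - x_JB1| + |j_bar_BJ1 - x_BJ1| ) / 2,

with operating points S <= 26 (bi-allelic), S >= 27 (mono-allelic; values in
the open gap are labelled indeterminate) and S > 42.5 (strong bias). Both
classifications — Y-range and S-threshold — are computed and reported side by
side, never merged. The pipeline's confusion table and recovery statistics use
the S-threshold rule: on clean data the control distribution collapses
(sigma -> 0) and Y degenerates to the point {j_bar}, so the Y-rule cannot
separate sampling noise from true bias there, whereas S measures the deviation
magnitude directly. On real data with genuine mapping noise the two rules are
designed to coincide; the package reports both precisely so that a user can
see when they do not.

Mono-allelic peaks are categorized by the side of j_bar (not of 50 — so
mapping bias cannot flip a category) that x falls on in each line:
below/below = JF1-specific, above/above = B6-specific, below in JB1 and above
in BJ1 = maternal (JF1 is the JB1 mother, B6 the BJ1 mother), the mirror =
paternal.

## Motif architecture

Scanning is exact-match, strand-aware and overlap-preserving: a hit at a
position is reported for the forward strand when the substring equals the
motif, and for the reverse strand when it equals the motif's reverse
complement; N never matches. Opposite-strand overlapping occurrences are
distinct motifs (the Commd1-type architecture of two overlapping GGCCGC in
inverted orientation requires this).

Pair distance is the intervening gap (start2 - end1 - 1, negative for
overlap); "less than 38 bp apart" is strict on this gap. A start-to-start
convention is available behind `convention="start"` since the published
phrasing does not pin the convention down. Clusters are single-linkage chains
of >= 2 hits with consecutive separations below the threshold; for
equal-length hexamer hits this equals the transitive closure of the pairwise
relation (asserted against a union-find oracle in tests).

A SNP disrupts a motif when, comparing the +/-5 bp windows around it on the
two haplotypes, exactly one allele carries a motif occurrence (any variant,
either strand) covering the SNP. The affected motif position is reported in
motif coordinates (reverse-complemented for minus-strand hits). With the
variant-aware motif set, a SNP toggling TGCCGC <-> GGCCGC is *not* a
disruption — both alleles remain binding-permissive — which is how
variant-aware scanning explains otherwise unexplained strain-specific loci.

Cluster enrichment compares densities expressed as bp of sequence per cluster:
fold = (bp/cluster genome-wide) / (bp/cluster inside peaks), reported both raw
and rounded half-up. Genome-wide density uses non-N scanned length; region
density uses summed peak widths.

Peak motif content is evaluated on the B6/reference haplotype by default; the
analysis functions accept any `HaplotypeGenome`, so an allele-aware pass over
the alternate haplotype is a second function call.

## Synthetic data generator

The generator emulates the study conditions so every stage is testable with
known truth; it does **not** model fragment-size/shift effects, GC bias,
input-chromatin tracks or aligner artifacts, so passing tests demonstrate the
correctness of the contracts above on SNV-only data, not robustness to those
real-data effects.

* Reference chromosomes are uniform A/C/G/T (default 2 x 50 kb; tests and the
  acceptance runs use 5 x 41 kb with 40 peaks per category).
* Non-overlapping 300 bp peaks receive 1-4 planted motifs (80% TGCCGC / 20%
  GGCCGC, random strand), with consecutive gaps drawn short (< 38 bp, p=0.6)
  or long, so cluster statistics have signal.
* Strain-specific peaks carry one SNP at the first motif's CpG cytosine whose
  non-permissive allele destroys the motif (for a JF1-specific peak the
  reference holds the broken hexamer and the JF1 allele restores it).
* Background SNPs fall at 1/250 bp outside motif footprints. Every peak is
  additionally guaranteed one SNP inside its read-coverable core
  ([start + L - 1, end - L + 1] for read length L): a SNP closer than one read
  length to a peak edge can be covered by almost no in-peak read start, which
  would starve that peak of informative reads at any sequencing depth.
* Reads: 50 bp single-end, start uniform over valid in-peak placements,
  strand-symmetric, haplotype drawn from the category- and line-dependent B6
  fraction (mono-allelic fraction 0.95 by default), per-base substitution
  errors at 0.001, plus 5% exact duplicate copies. Coverage defaults are free
  parameters of the generator (the emulated study does not publish per-peak
  coverage); 250 reads/peak/line yields 30+ informative reads per peak and
  line after positional dedup at these settings.
* One seed drives everything through a fixed stream order (reference,
  planting, reads per line) via `numpy` `SeedSequence` children, so outputs
  are bit-identical across runs.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive internally; BED conversion happens only at
  I/O. Closed-interval overlap (>= 1 bp) is used for read-peak and
  consensus-peak intersection, and a read is attributed to a peak on any
  overlap.
* `percent_b6` returns None on a zero denominator (uninformative marker);
  peaks reaching scoring cannot trigger it after the IR filters, and defensive
  drops are preferred to imputation before calibration.
* Calibration requires >= 2 informative peaks (sigma undefined below that);
  with fewer, the pipeline reports every peak uninformative and exits cleanly
  rather than failing.
* Ties: Y-membership is inclusive at both bounds; S thresholds are inclusive
  as published (<= 26, >= 27) with the open interval labelled indeterminate;
  strong bias is strictly > 42.5; the enrichment report value rounds half-up.
* The exact-diagonal verification of truth recovery is run error-free at 600
  reads/peak/line. At that informative depth (~70-170 informative reads/peak)
  the binomial sampling noise of a 50% fraction sits many standard deviations
  inside the S <= 26 region, so any off-diagonal entry indicates an
  implementation defect rather than sampling variance; at materially lower
  informative coverage a borderline cohort-level outlier is expected roughly
  once per hundred cohorts and says nothing about the method.

## Known limitations

* The haplotype model is SNV-only; indel-containing loci are handled by
  exclusion, not realignment.
* Base qualities are ignored (the mismatch contracts are count-based, as in
  `-v`-style alignment).
* The control-alignment calibration assumes reads rarely stack > 3 SNPs; in
  SNP-dense regions (> 1/17 bp over a read) control counts would lose the
  both-haplotype symmetry.
* Motif scanning is exact-match by design — the binding model is a small set
  of discrete hexamer variants, not a PWM; near-miss variants score zero.
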