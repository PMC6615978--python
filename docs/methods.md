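# Methods

## Model and procedure

chromplex treats sex-chromosome complement inference as a copy-number problem
on windowed sequencing depth, and gametolog mismapping as a reference-design
problem solved by hard masking.

**Depth model.** A chromosome present in `k` copies in a genome sequenced to
diploid depth `D` is expected at window depth `kD/2`. Depth in a window
`[s, e)` is approximated as the total query length of primary alignments
whose leftmost aligned position falls in the window, divided by `e − s`.
Assigning each read to exactly one window (by start position) conserves
reads — the per-window counts sum to the chromosome's primary-alignment
count — and the approximation equals exact per-base depth whenever reads are
fully contained in their window, converging to it as windows grow.
Secondary, supplementary and unmapped records are always excluded;
duplicate-flagged reads are included unless excluded explicitly, since flags
vary by upstream pipeline.

**Statistical comparison of a chromosome pair.** Three tests run on the
threshold-passing window depths of chromosomes a and b:

* percentile bootstrap (default `n_boot` 10,000, α 0.05) of each mean window
  depth, checked for CI overlap;
* permutation test of |d̄_a − d̄_b| with label shuffling (default `n_perm`
  10,000) and the +1 correction, p = (#{stat ≥ observed} + 1)/(n_perm + 1),
  so p is never exactly 0; an exact mode enumerates all C(n, n_a) label
  assignments for small inputs;
* two-sample Kolmogorov–Smirnov test, D = sup |ECDF_a − ECDF_b| computed over
  all observed points, with the asymptotic two-sample p-value.

All randomness flows from a single seeded NumPy generator per call, so equal
seeds give bit-identical CIs and p-values. Only the bootstrap drives the
complement call; the permutation and KS results are reported as evidence.

**Decision rule.** With `r_X` and `r_Y` the ratios of mean sex-chromosome
window depth to mean autosome window depth (bootstrap CIs obtained by
resampling numerator and denominator windows independently): Y is *absent*
when the CI upper bound of `r_Y` < 0.10, *present* when the lower bound
> 0.25, otherwise indeterminate; X is *diploid-like* when the `r_X` CI
overlaps [0.8, 1.2] and *haploid-like* when it lies inside (0.3, 0.7).
"XX" requires Y absent plus diploid-like X, "XY" requires Y present plus
haploid-like X; all other combinations are reported indeterminate and are
never remapped silently. These thresholds are engineering defaults, exposed
in configuration: the gap between 0.10 and 0.25 absorbs residual mismapped
coverage on a truly absent Y (the mechanism that leaves depth ≈ 0.02–0.05·A
on Y in homogametic samples), while a real Y at uniform coverage sits near
0.5. When no Y window passes filters — typical for XX samples whose only Y
"coverage" is MAPQ-0 homology noise — the unfiltered Y windows are used with
a warning, which keeps the evidence honest rather than substituting zeros.

**Quick multi-sample classification.** With many samples, the per-sample
Y read count normalized by an autosome splits into two clusters; the split
is placed at the largest gap in the sorted ratios. Low cluster → XX, high →
XY. All-identical ratios give indeterminate calls with a warning. For a
single sample the fixed thresholds above apply.

**Window filtering.** A window passes iff mean MAPQ ≥ `min_mapq` (default
30; strict preset 55, the level needed to remove partial-homology XTR-like
windows) AND its depth lies within [0.25·μ, 4·μ] of the chromosome's mean
window depth μ. Comparisons are inclusive; empty windows always fail. The
default window size is 5 kb; desk-scale analyses here use 1 kb so the toy
chromosomes still contribute ≥ 100 windows each.

**Variant metrics.** Sites are filtered by site QUAL ≥ 30, MQ annotation
≥ 30 (a missing MQ passes with a warning, since not all callers emit it),
GQ ≥ 30 (a missing GQ fails, conservatively), and depth ≥ 8 (depth has no
canonical published value; 8 is the documented default). Read balance is
alt/(ref+alt) from the AD field; multi-allelic records are reduced to the
highest-depth alt allele. The "heterozygous view" histogram keeps balances
strictly inside (0.05, 1.0). Region-unique variant counting uses the
identity key (chrom, pos, ref, alt) and reports counts plus per-Mb rates
(count/(length/1e6)); raw rates are retained and display rounding (1 decimal,
0 decimals above 1000/Mb) is a formatting concern only.

**Masking.** Hard masks are uppercase 'N', lengths conserved, BED
coordinates 0-based half-open, output FASTA fixed at 60 columns with a .fai
emitted, record order preserved. Soft-masking is deliberately not offered —
the point of the hard mask is that no read can align to the masked copy,
while identical sequence dictionaries keep downstream files interoperable.

**Strip/remap/merge.** A read pair is exported when either mate's primary
alignment touches a target chromosome ("pair rescue"), which keeps FASTQs
valid for paired remapping; this also exports unmapped mates of mapped
target-chromosome reads. Mates are restored to sequenced orientation and
emitted in matched order per read group (files per read group preserve
library structure); orphans go to a singles file. Merging partitions by
chromosome: non-target records are copied verbatim from the original BAM and
target-chromosome records come only from the remapped BAM, carrying the `XR`
provenance tag. This partition (rather than per-read replacement) is what
makes the counting invariant exact — total = original non-target + remapped
on-target — and avoids double-counting rescued mates that remap back to
their original non-target position.

## Built-in aligner and caller

The **toy aligner** used for desk-scale remapping is seed-and-verify: exact
20-mer seeds at the read's start, middle, and end are looked up in a
reference k-mer index (k-mers containing N are never indexed, which is how
masked regions become unmappable), candidates are verified by full-length
Hamming distance (budget 10% of read length), the unique best hit gets MAPQ
60, tied best hits get MAPQ 0 at the lowest coordinate, and reads exceeding
the budget are dropped. It handles substitution errors but not indels, which
matches the simulator.

The **pileup caller** calls any site with ≥ 1 non-reference read. QUAL is
the phred-scaled binomial tail probability of the alt count under a 1%
error model; genotype is the maximum-likelihood choice among alt-fraction
models {0.01, 0.5, 0.99} and GQ is the phred ratio of best to second-best
likelihood (capped at 99); best-model-hom-ref candidates are dropped. Site
MQ is the mean MAPQ of overlapping reads. Both components are first-class
implementations with their own tests; external tools can replace them via
command templates at any scale.

## The simulator

The synthetic genome has one autosome (120 kb), an X (120 kb) and a Y
(110 kb); PAR1/PAR2 (5 kb each) are copied byte-identically from X to Y and
an XTR block (10 kb) is copied at 98% identity. Lengths were chosen so every
chromosome contributes ≥ 100 windows at 1-kb windows while a full simulation
stays around a second; the Y is deliberately not scaled to its true relative
size, which would starve it of windows at desk scale. Base composition is
uniform ACGT; no indels (depth and balance signals do not require them).

Reads (default 100 bp, paired, fragment ≈ 300 ± 20 bp, per-base error
0.001, two read groups) are drawn uniformly per chromosome copy, so expected
depth ratios are 1.0 (XX) and 0.5 (XY) against the autosome at the default
20× diploid depth. The mapping-quality model encodes the reference the reads
were notionally mapped against: with both sex chromosomes present,
PAR-contained fragments get MAPQ 0 and a fair-coin placement on X or Y at
the homologous offset, XTR fragments keep their position with MAPQ drawn
uniformly from 30–54 (below the strict 55 threshold, above the default 30 —
partial homology depresses but does not erase MAPQ); with the Y (or its
PARs) masked, the affected fragments map uniquely at MAPQ 60 on the X.
Truth tables record every read's origin, placement, MAPQ, and feature.

Simulated variants place heterozygous sites only on chromosomes with ≥ 2
copies (alt count ~ Binomial(depth, 0.5)) and hom-alt sites everywhere
(~ Binomial(depth, 1 − error)); site depth is Poisson with mean scaled by
copy number. The same truth table can be planted into simulated reads so the
pileup caller recovers the sites from the BAM.

**What the simulator does not model** — and hence what passing tests do not
show about real data: indels and structural variation, GC and context
coverage bias, duplicate reads, base-quality miscalibration, ampliconic
(palindromic, multi-copy) Y sequence and the anomalous intermediate
read-balance peak real Y chromosomes can show, genuine aligner behavior on
divergent paralogs, and contamination or mosaicism. Real-data thresholds —
particularly the Y-presence bounds — should be sanity-checked per cohort and
sequencing strategy, since relative X/Y depth varies across capture designs.

## Numerical and design choices

* Read length in the depth heuristic is the query length; a CIGAR-aware
  aligned span is available as an option. The two differ only for clipped or
  gapped alignments, which the simulator does not produce.
* Bootstrap CIs use the percentile method; no bias correction. With ≥ 100
  windows the difference from BCa is immaterial for ratios this far from the
  decision boundaries.
* Permutation and exact-enumeration tail comparisons use a 1e-12 tolerance
  when testing "≥ observed" so floating-point ties count as ties.
* The KS p-value uses the asymptotic Kolmogorov series (100 terms); the D
  statistic, which drives nothing in the default decision, is exact.
* Empty windows report mean MAPQ 0 with an explicit empty flag and always
  fail filtering, so no-data regions cannot pass silently.
* Zero denominators in normalization produce NaN ("undefined") rather than
  an error; a zero-read Y in an XX sample is a result, not a failure.
* VCF positions are 1-based throughout; BED and window coordinates are
  0-based half-open; conversion happens once at module boundaries.
* Contigs not named in any mask list appear unmasked in both reference
  versions (mito/unplaced contigs are left to the user's mask BEDs).
* Indeterminate complements skip remapping with an explicit report entry;
  ambiguity is surfaced, never resolved by default.

## Problem sizes used in tests and the acceptance script

Unit and integration tests run on 60/60/50-kb genomes at 10–20×; the
complement-recovery check uses the default 120/120/110-kb genome at 20× with
1-kb windows (≥ 110 windows per chromosome), 20 XX + 20 XY replicates,
n_boot 2,000 and n_perm 1,000; bootstrap coverage is measured over 200
replicates of n = 500 at n_boot 2,000 (the implementation's coverage was
additionally verified at 95.0% over 3,000 replicates during development).
These sizes keep a full test run around half a minute and the acceptance
script around one minute on a single CPU.
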