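# Methods

## Scope and data model

All genomic arithmetic is done on 0-based half-open intervals; 1-based
conventions (CX cytosine reports, GFF3) are converted at the I/O boundary
only. Chromosome names match exactly; an optional alias map handles
`Chr1`/`1`-style mismatches explicitly rather than silently. Readers retain
zero-coverage cytosines — coverage filtering is an analysis parameter, not a
parsing rule — and drop non-CG/CHG/CHH context lines (CN/CHN at chromosome
ends) with a logged count.

The developmental axis is an ordered stage list. The methylome axis defaults
to the five embryo stages GL/H/T/BT/MG; the sRNA axis has its own eight
stages (public embryo sRNA datasets are staged differently) and the two are
never force-aligned.

## Windowed methylation levels

Windows are non-overlapping, on a grid anchored at coordinate 0, identical
across stages; the trailing partial window of a chromosome is kept if it
passes filters. A window is emitted iff it contains enough cytosines of the
requested context, *each* with depth at or above the read minimum — the
per-cytosine reading of the depth filter is the stricter of the two possible
interpretations and matches the per-cytosine phrasing of the underlying
protocol. Window level is read-weighted (Σmeth/Σtotal), the WGBS community
default; the per-TE statistic deliberately differs (below). Both strands
pool into one window. The chromosome-scale map uses 5 kb windows with a
*strict* ">10 cytosines" filter; boundary cases (exactly 10) are excluded
and tested.

## Spreading blocks

The spreading statistic uses 10 bp windows (≥1 site, depth ≥5). Thresholding
is strict ("above 5/10/15%" excludes equality) and merging is strict
("closer than 40 bp" excludes a gap of exactly 40). Gaps are measured
end-to-start in half-open coordinates, so adjacent windows (gap 0) always
merge. The window grid and coverage eligibility are stage-independent, but
cutoff-passing and merging are evaluated per stage — otherwise per-stage
length growth could not exist. Block length summaries report mean,
*population* SD and count per stage, pooled genome-wide.

The cross-stage consensus is computed at base resolution: a base counts as
supported in a stage if any qualifying window of that stage covers it;
bases supported in ≥3 of 5 stages are assembled into consensus blocks with
the same <40 bp rule. Stage-to-stage comparisons of per-locus values use
Welch's unequal-variance t-test (two-sided); the choice of test is an
assumption, cross-checked in tests against an independent statistics
implementation.

## sRNA clusters and overlap

Cluster merging is *inclusive* at ≤75 bp ("within 75 bp"), intentionally
different from the strict 40 bp block rule; both thresholds are parameters.
The 5-of-8 consensus is base-resolution by default, with a whole-cluster
mode (`resolution="cluster"`) for the alternative reading in which entire
candidate regions are kept when hit by clusters in enough stages. Block/
cluster overlap is ≥1 bp (bedtools-intersect semantics); the two groups
always partition the input blocks.

## TE classification

Assignment is ≥1 bp overlap per class, with multiple same-class DMRs
counting once (class membership is a set property). The result is a strict
partition: cCMT2 / cRdDM / eRdDM / multi-class / unassigned; only the three
exclusive classes enter summaries. Positional distributions bin interval
*midpoints* (robust to the large length differences between classes;
start-anchored binning is available), with half-open bins so a midpoint on a
boundary falls right.

## Context frequencies and the expectation model

CG and CHG are counted on the forward strand only; both are palindromic at
the site level, so one strand determines the other. CHH is asymmetric and
counted on both strands (a reverse-strand CHH appears on the forward strand
as D-D-G, D = A/G/T). Frequencies divide counts by sequence length in bp
(not by the number of k-mer start positions), so the CHH frequency of both
strands can in principle exceed 1. Cytosines within the last one or two
bases of a sequence have no complete context and contribute nothing.

The expectation under base probabilities is E[CG] = p(C)p(G),
E[CHG] = p(C)p(H)p(G) with p(H) = 1 − p(G), and
E[CHH] = p(C)p(H)² + p(D)²p(G) with p(D) = 1 − p(C). The second CHH term is
the reverse strand; when composition is strand-symmetric (p(C) = p(G)) it
equals the forward term, recovering the familiar "×2 double strands" form,
and at uniform composition the values are 0.0625 / 0.046875 / 0.28125. The
two-term form is used because it is what double-strand counting actually
converges to for arbitrary composition (verified by simulation in the test
suite); the ×2 shortcut is exact only in the symmetric case. Note one
subtlety the tests pin down: per-strand CHG counts are *not* reverse-
complement invariant — a CCG is CHG on its strand while its opposite-strand
cytosine sits in CG context — so only the exact relation
n_CHG(s) − n_CHG(rc(s)) = #CCG(s) − #CCG(rc(s)) holds.

Frequency tables print half-up at table precision (0.0625 → 0.063);
`printed_frequency` exists because Python's built-in banker's rounding
would print 0.062. Group cells pool TEs length-weighted (Σcounts/Σlength)
by default — consistent with "counts divided by length" applied at group
level — with an unweighted per-TE-mean mode available. Enrichment flags
compare each (class, superfamily) cell against the all-TE cell of the same
superfamily with a 1e-12 equality tolerance.

## Metaprofiles and per-TE levels

Feature metaprofiles scale each body to a fixed bin count (default 60) with
fixed-width flank bins (default 1,500 bp / 30 bins — the typical plant
metaplot convention; the parameters are explicit because no single standard
exists). Bin levels are read-weighted over all sites of all features;
minus-strand features are reversed so profiles read 5'→3'. TEs are treated
as unstranded unless strand is annotated. Per-TE methylation is the
*unweighted mean of per-site fractions* over covered sites (depth ≥5) — a
deliberate contrast with window levels: it is invariant to depth rescaling
and matches how per-element levels are conventionally reported. TEs with no
covered site are flagged undefined and excluded from length-vs-level
scatters.

## Synthetic data generator

The generator emulates the study conditions end to end, with one seed fixing
every stream (per-step child seeds derive from it):

* **Genome**: 2 chromosomes × 400 kb, uniform base composition, central
  pericentromere spanning 40% of each chromosome. Small by design — large
  enough for ≥500 blocks and ~300 TEs, small enough that the full pipeline
  runs in seconds.
* **TEs**: cCMT2 long (lognormal, median 3.5 kb, clipped to disjoint slots)
  and pericentromeric; cRdDM (median 600 bp) and eRdDM (median 350 bp)
  short and arm-placed; superfamily composition differs by class
  (Gypsy-heavy cCMT2, Helitron/SINE-leaning RdDM classes). Each assigned TE
  embeds one 150 bp same-class DMR; 10% of TEs get no DMR (truth:
  unassigned). Slot placement keeps TEs — hence DMRs of different classes —
  disjoint, so classification truth is exactly recoverable.
* **CHH blocks**: 300 per chromosome in disjoint slots, initial length
  200 bp, extending 60 bp per stage (split over both ends) with level
  0.30 + 0.08·stage; background CHH 0.02. Slots guarantee inter-block gaps
  exceed the 40 bp merge rule at full extension, so recovered block counts
  equal the truth. Because extents are nested across stages, the 3-of-5
  consensus equals the middle-stage extent by construction.
* **CG/CHG**: CG constant (0.90 in TEs, 0.20 background); CHG inside TEs
  follows a schedule dipping at the middle (torpedo) stage
  (0.62, 0.60, 0.52, 0.58, 0.61), background 0.02.
* **Reads**: depth Poisson(40) per site and stage (echoing the >40×
  coverage standard for methylome analysis), methylated reads binomial at
  the true level. Methylated CHH sites sit on the genome's actual CHH
  positions, so context counts and methylation calls share one consistent
  sequence.
* **sRNA clusters**: a fraction *f* (default 0.5) of blocks receives a
  co-located 24-nt cluster extending 40 bp per sRNA stage over eight
  stages; 30 independent 200 bp clusters per chromosome are re-sampled each
  stage (transient expression), so the 5-of-8 consensus almost surely
  retains only co-expanding clusters and the recovered overlap fraction
  estimates *f* cleanly.

What the generator does *not* model — and hence what passing tests do not
show about real data: TE sequence structure (no terminal repeats or
insertion-age signal), bisulfite conversion error, replicate variation,
mappability gaps, chromatin-state covariates, or any correlation between
block placement and TE class. Parameter-recovery results demonstrate the
*estimators* are correct under the assumed generative structure, not that
real embryos follow that structure.

## Numerical and degenerate-input choices

* Empty inputs return empty tables (merging, stats) except where the
  operation is undefined (metaprofile of zero features, test with n < 2),
  which raise.
* Stage/class summaries omit empty groups with a warning rather than emit
  NaN rows; overlap group stats report n = 0 rows so the two-group table is
  always complete.
* Welch p-values come from scipy; identical samples give p = 1.
* All SDs in length summaries are population (ddof = 0) SDs.
* TSV outputs are written with `%.6g` float formatting and a commented
  parameter header; the run manifest stores paths relative to the output
  directory and no timestamps, making reruns byte-comparable.

## Problem sizes

The default simulation (2 × 400 kb, ~600 blocks, ~300 TEs, 5 + 8 stages,
depth 40) is the package's reference configuration for parameter-recovery
checks; the I/O-heavy determinism and CLI checks use a 2 × 120 kb variant.
Randomized oracle-equivalence suites run 100 instances per operation with
tens of intervals each — sizes at which the brute-force oracles are exact
and fast.

## Known limitations

* `support_intervals` materializes breakpoint events per chromosome; for
  genome-scale inputs with tens of millions of intervals a streaming sweep
  would be preferable.
* GFF3 attribute parsing handles the flat `key=value;` form used by TE
  annotations; it does not resolve multi-level Parent hierarchies.
* The whole-cluster consensus mode keeps entire merged candidate regions;
  mixed interpretations (fractional overlap thresholds) are not offered.
* Metaprofile flank bins are clipped at position 0 implicitly (no sites
  exist below it) but are not truncated at chromosome ends without a
  chromosome-size table; terminal features can therefore bin a few bases of
  nonexistent flank as empty bins.
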