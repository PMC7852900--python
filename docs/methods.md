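# Methods

This note documents the models behind `triocnv`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was open.

## Signal model and simulator

A SNP-array genotyping experiment is summarised per marker by the Log R
Ratio (LRR, total intensity relative to diploid) and the B Allele
Frequency (BAF, relative B-allele intensity).  The simulator works in
allele-copy space: every sample carries per-marker copy counts of the A
and B alleles, built from Hardy–Weinberg parental haplotypes
(`P(B) = pfb`, drawn uniformly on (0.1, 0.9) per marker) and recorded
Mendelian transmission.  CNVs are implanted as coherent haplotype
segments: a deletion removes one parental contribution across the span,
a duplication adds one extra copy drawn from the origin parent's homologs
(either homolog by default, modelling interchromosomal NAHR; a flag
restricts it to the transmitted homolog), and an inherited event is
implanted in the parent first and then transmitted.  A mosaic gain in a
cell fraction *f* adds *f* fractional copies, which moves the
heterozygous BAF bands to `1/(2+f)` and `(1+f)/(2+f)`.

Rendered LRR is the canonical state mean for the total copy number —
CN0 −3.5, CN1 −0.66, CN2 0, CN3 +0.40, CN4 +0.68, linearly interpolated
for fractional totals — plus a per-sample sinusoidal wave (one period per
chromosome window, random phase) and Gaussian noise.  BAF is the allele
ratio `b/(a+b)` plus truncated Gaussian band noise, clipped to [0, 1];
copy-number-0 markers and a small outlier fraction emit uniform BAF.

Default noise (LRR SD 0.10, BAF SD 0.03, outlier rate 0.002, wave
amplitude 0.01) is calibrated so that QC-passing samples resemble a clean
genotyping batch (median LRR SD ≈ 0.10, median calls per sample ≈ 0–10).
Default study conditions reproduce the published 12,252-trio screen:
per-region offspring event rates are the published per-region counts over
12,252; the de novo fraction is 20/59; the maternal share is 24/39 among
inherited and 10/19 among de novo events; one in seven de novo
duplications is mosaic with fraction drawn uniformly on (0.3, 0.7); and
untransmitted parental carriers are implanted at 19 (maternal) and 29
(paternal) per 12,252, allocated across regions proportionally to the
offspring rates because per-region parental counts are not published.

The simulated genome is compact: only the 13 reference regions plus
configurable flanks carry markers, with a density boost inside regions
(array designs enrich clinically relevant loci).  The generator does not
emulate: GC-driven wave structure derived from sequence, array cluster
artefacts, genotyping batch effects beyond a configurable call-count
threshold, sex chromosomes, or relatedness beyond the trio.  Passing
tests therefore demonstrate correctness of the algorithms under a
faithful band-and-noise model of array signals, not robustness to every
real-array artefact.

## Caller

The 6-state HMM (CN0, CN1, CN2, CN2-LOH, CN3, CN4) emits, per marker, a
Gaussian LRR term (per-state SDs 1.0/0.22/0.18/0.18/0.22/0.26 — CN0 wide
because homozygous-deletion intensity is erratic) and a BAF band mixture:
for a state with *c* copies the B-dosage bands sit at `b/c` with
Binomial(*c*, pfb) weights; CN2-LOH uses only the homozygous bands; CN0
is uniform.  Band densities are normals (SD 0.04) truncated to [0, 1] —
the truncation absorbs the clipping mass at 0 and 1 — mixed with a 1%
uniform outlier component that makes single aberrant markers cheap to
ignore.  Transitions leave a state over a gap of *d* bp with probability
`ε(1 − e^{−d/D})`, ε = 1e-4, D = 100 kb, split evenly over the five other
states: a two-parameter distance-aware model.  The neutral prior is
0.995.

Decoding is exact Viterbi (verified against exhaustive path enumeration
on small instances), with ties broken toward CN2 so ambiguous evidence
never creates a call.  The implementation exploits the uniform
off-diagonal structure: the best predecessor of any state is either the
state itself or the globally best state, making each step O(samples ×
states); with the shared-band emission cache the caller decodes thousands
of samples in seconds.  Maximal non-CN2 runs become calls; CN2-LOH runs
are decoded (they absorb runs of homozygous markers that would otherwise
tempt deletion states) but dropped from output, since the analysis
concerns deletions and duplications only.  Same-copy-number neighbours
merge while `gap/span ≤ 0.20`, iterated to a fixpoint.  An optional
breakpoint refinement extends a call while flanking markers' emission
log-odds favour the call state over CN2 (margin 0 by default); it mirrors
the manual practice of extending a call whose flanking signal continues
the CNV, and is off in the batch pipeline.

Trio-aware joint decoding is deliberately not implemented; samples are
decoded independently and family information enters through the
classification rules.  This is a documented simplification — it loses a
little power on borderline parental calls but keeps the decoding stage
single-sample and testable.

## QC

Four per-sample metrics gate the cohort: LRR SD; BAF drift, made concrete
as the fraction of BAF values in (0.2, 0.25) ∪ (0.75, 0.8) (the reference
tooling leaves the definition internal; this operationalization reproduces
the gate's semantics — off-band mass between the canonical bands); the
wave factor, the signed amplitude of a least-squares one-period sinusoid
per chromosome window (marker-count-weighted across windows); and the
post-merge, pre-frequency-filter call count.  LRR SD and BAF drift are
noise metrics, so markers inside the sample's own called CNVs are excluded
from them: a genuine duplication's BAF bands at 1/3 and 2/3 shed tail mass
into the drift windows, and on the compact simulated genome — where one
multi-megabase event can cover several percent of all markers, unlike on
a genome-wide array — counting that signal as drift would preferentially
eject carriers at the trio gate and bias prevalence downward.  QC runs
after calling (the call-count metric already requires this), so the
exclusion uses the sample's merged call spans.  Thresholds: LRR SD < 0.3,
drift < 0.001, |WF| < 0.05, calls < 100 (130 for the denser-array batch
profile).  A trio passes only when all three members pass all four
criteria; the gate is monotone in every threshold.

## Filters and classification

Calls cluster across the cohort by ≥ 50% reciprocal overlap and sign
(union-find); a cluster whose carrier frequency among parents — parents
only, offspring never contribute — exceeds 1% is removed cohort-wide.
Any 1-bp overlap with a blacklist interval removes a call (the packaged
blacklist for the simulated genome is synthetic, constructed in the
region flanks; it is not real centromere/telomere annotation).  Calls
must span ≥ 100 kb and ≥ 10 markers.  A call is assigned to every
reference region it covers by ≥ 50% of the region's length; CN0/CN1 pool
as deletions and CN3/CN4 as duplications.

Inheritance: a same-class parental call at ≥ 50% reciprocal overlap makes
the event inherited from that parent; neither parent means de novo; both
parents (never observed in practice) is flagged `ambiguous_both` and
excluded from per-parent tallies rather than guessed.

Mosaic screening applies to duplications with ≥ 10 heterozygous-band
markers (BAF in (0.2, 0.8)).  The lower heterozygous band centre `b` is
the median BAF in (0.30, 0.5] — the window starts at 0.30, not 0.2,
because `1/(2+f)` always lies in [1/3, 1/2) while a mosaic gain adds a
second band at `f/(2+f) < 1/3` whose tail would otherwise bias the
estimate — and the fraction estimate is `f = 1/b − 2`, clipped to [0, 1].
Events with `0 < f < 0.9` are reported mosaic; the 0.9 cutoff is a
stated operationalization of a visual judgement, and the estimator
inverts implanted fractions within ±0.05 at BAF SD ≤ 0.03 with ~50
heterozygous markers.

## Parent of origin

Evidence is read from signals, as in the source workflow: parental
genotypes from the nearest of the 0/½/1 BAF bands, child allele counts
from the nearest of {0, 1} (CN1) or {0, ⅓, ⅔, 1} (CN3), all within a
tolerance of 0.08; out-of-tolerance markers are discarded.  Deletion
markers vote for the parent who could not have transmitted the retained
allele (their homolog is the deleted one).  Duplication markers test the
child's three-allele multiset against "a 2-allele multiset from the
mother's homolog pair plus one paternal allele" and the symmetric
hypothesis; only-one-fits votes for that parent, both-fit is
uninformative, neither-fits is inconsistent and serves as a genotyping
error proxy (an inconsistent rate above 10% triggers a warning).  The
2-allele multiset is drawn with replacement from the parent's two
homologs by default (interchromosomal NAHR); a strict mode requires two
copies of one homolog.  Aggregation needs ≥ 3 informative markers and
≥ 80% concordance, otherwise the event is unresolved — with few
informative markers the outcome is unresolved by design, matching the one
published de novo duplication whose origin could not be assigned.
CN4 events are reported unresolved with a warning; the two-band mixture
model does not cover isodicentric configurations.

## Statistics

Prevalence is `NCNVs/Ntrios` over QC-passing trios.  Confidence intervals
use the Wilson score interval (well-behaved at zero counts: 0/12,252
yields an upper bound of 0.0003), implemented in closed form and
cross-checked against `statsmodels` in the tests.  Deletion/duplication
contrasts use the pooled two-proportion Z-test; transmission uses the
classic 1-df TDT chi-square `(T − NT)²/(T + NT)` (an exact binomial
option exists but is not the default, because the chi-square form
reproduces the published p-values of 0.03 and 0.33).  Report tables round
prevalence per 10,000 to 2 decimals and Z to 2, matching the print style,
while full precision is kept internally.  No multiple-testing correction
is applied, as none was applied in the source analysis.

The published counts ship as a package fixture and run through the same
table builders, so the full-cohort statistics are reproduced without
access to the controlled genotype data.  The fixture follows the
cumulative table where the Discussion disagrees with it (de novo
deletions vs duplications: 13 vs 7, p = 0.18).

## Problem sizes used in verification

The test suite verifies the caller on 100 replicates of a 1 Mb, 50-marker
event at LRR SD 0.15 (≥ 95% recovered within two markers); decoding
exactness on 200 random ≤ 8-marker instances against exhaustive
enumeration; parent-of-origin on simulated de novo cohorts (≥ 99% correct
with ≥ 20 informative markers); and end-to-end behaviour on fifty
2,000-trio cohorts at the published event rates on a compact map
(30 kb flank spacing, 2× in-region boost, 250 kb flanks), checking that
the estimated prevalence covers the true rate within its 95% Wilson
interval in ≥ 90% of runs and that inheritance classification matches
truth ≥ 99%.  These sizes are the package's verification conditions; the
generator scales to denser maps and larger cohorts through
`CohortConfig`.

## Known limitations

* Independent (non-joint) trio decoding, as noted above.
* The parental-carrier model conditions transmission on the event list
  rather than simulating meiosis with recombination; markers outside CNV
  spans transmit independently, which is adequate for every statistic the
  pipeline computes but not for haplotype-scale analyses.
* The blacklist fixture is synthetic; runs on real data must supply a
  real exclusion track.
* Nested or partially overlapping events on one haplotype are rejected by
  the implanting machinery rather than modelled.
* The 15q13.3 nested CHRNA7/OTUD7A interval and isodicentric 15q
  configurations are out of scope.
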