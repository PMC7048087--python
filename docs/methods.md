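# Methods

`ctdnakit` implements a multi-assay workflow for detecting circulating
tumor DNA (ctDNA) in body fluids of patients with low-shedding tumors,
renal cell carcinoma (RCC) being the motivating case. ctDNA levels in
RCC are routinely below 1% tumor fraction and often below 0.1%, so the
package combines untargeted genome-wide assays (cheap, shallow) with a
patient-specific targeted assay (expensive, deep) and a fragmentomics
triage model that decides who should receive the latter. Every assay is
exercised against a fragment-level cfDNA simulator so the whole chain is
testable without sequencing data.

## The simulator

The atomic unit is a cfDNA fragment: a genomic interval with a length,
a source label (tumor or normal), and — when it covers a targeted locus
— an observed allele. A sample is defined by a `SimulationConfig`:
tumor fraction *tf*, fragment count, somatic copy-number (SCNA)
segments, a fragment-length mixture, target loci with tissue mutant
allele fractions (mAF), background error rates, a UMI family-size
distribution, a GC-bias strength, and a mandatory seed.

**Copy-number dilution.** A segment carried at total copy number *c* by
the tumor has expected relative coverage `(2(1−tf) + c·tf)/2` against
the diploid background. The simulator realizes this by sampling each
fragment's source (tumor with probability proportional to *tf* weighted
by the genome-average relative copy), then sampling tumor positions with
density proportional to local copy number. The law is exact by
construction and is verified against raw chromosome count ratios.

**Fragment lengths.** Two truncated log-normal components on [20, 700]
bp, parameterized by their modes: 167 bp for normal cfDNA (the
mono-nucleosomal peak) and, by default, 145 bp for tumor cfDNA with a
slightly wider spread (σ = 0.10 vs 0.12 on the log scale). The
magnitude of the tumor shift in RCC is not an established constant, so
it is an explicit parameter rather than an assertion; 145 bp puts
roughly 60% of tumor fragments inside the 90–150 bp selection window
versus ~8% of normal fragments, which reproduces the qualitative
enrichment that in-silico size selection exploits. Below 150 bp both
components are modulated by a multiplicative 10-bp comb
`1 + A·cos(2πL/10)` (default A = 0.15) emulating the nucleosomal
degradation periodicity that the fragmentomics features measure.

**GC bias.** Fragment acceptance probability is linear in the local GC
fraction: `clip(1 + 2·strength·(gc − 0.5), 0.2, 1)`. This is the
simplest bias the correction step must be able to undo; it is not a
model of library chemistry. Control cohorts draw a per-sample
multiplicative jitter (uniform 0.8–1.2) on the strength so that
inter-control variability exists for the threshold-setting steps.

**Genome.** Desk-scale synthetic genomes replace a real assembly: by
default two 50-Mb chromosomes for copy-number work and eight 20-Mb
chromosomes (16 arms) for arm-level aneuploidy scoring. GC tracks are
smooth (Gaussian-kernel-filtered noise mapped into [0.3, 0.7]),
mappability is 1 with a ~1% tail of poor windows, and ~1% of each
chromosome is blacklisted as two contiguous runs (mimicking
pericentromeric repeat regions — scattered single-window blacklists
would contaminate every coarse bin). All bin sizes are configurable, so
the genome scale changes problem size, not algorithm behavior.

**Targeted reads.** Per locus, Poisson-many template molecules; each is
a true mutant with probability `tf × tissue mAF`, otherwise it carries
the alternate base at the trinucleotide-class background error rate
(and one of the two remaining bases at twice that rate). Each molecule
founds a UMI family with configurable size distribution, and each read
in a family is independently corrupted at a per-read sequencing error
rate, so consensus logic sees realistic disagreement.

**What the simulator does not model** — and hence what passing tests do
not demonstrate about real data: read-level base sequences and
alignment artifacts, sequencing-instrument error profiles, chimeric and
duplicated fragments, real GC/mappability structure, germline
variation, and biological fragmentation differences beyond the
two-component length mixture. The simulator establishes that the
*statistics* are implemented correctly and calibrated under their own
assumptions, not that those assumptions hold in plasma.

## Copy-number deviation (tMAD)

Fragments are allocated to equal-width bins by midpoint (symmetric and
strand-free; a midpoint exactly on an edge belongs to the bin starting
there). Counts are corrected for GC by decile-median scaling (each
bin's count divided by the median of its GC-decile, rescaled by the
overall median) and divided by mappability; bins with mappability
< 0.5, blacklisted bins, and truncated chromosome-tail bins are
excluded — this exclusion is the "trimming". Decile medians were chosen
over loess for having no tuning knobs and a testable contract (residual
|correlation(corrected, gc)| < 0.05 on simulator output).

Normalization mode `control` scales case and reference to equal totals
over shared usable bins and takes `log2(case/ref)`; the reference is
the cohort median profile by default (`reference="single"` uses one
control). Mode `self` (for sample types without matched controls, e.g.
urine cell pellets) centers on the sample's own mean. Mean scaling
implies a known property: a genome with unbalanced aberrations shifts
the neutral baseline by `−log2(mean relative coverage)`; dilution-law
tests therefore use balanced loss+gain architectures where the shift is
zero, and real-data users should expect tMAD (a deviation score), not
absolute log-ratios, from heavily aneuploid genomes.

Segmentation is recursive binary change-point search minimizing
within-segment squared error; a split is accepted when its SSE gain
exceeds `penalty · σ̂² · ln(n)`, with σ̂ estimated robustly from
successive bin differences (MAD of diffs). The penalty constant (4.0)
is calibrated so that a flat σ = 0.05 profile returns one segment per
chromosome in ≥ 95% of seeds while a log2(0.8) step spanning a third of
a chromosome is recovered with breakpoints within 3 bins. Minimum
segment length is 3 bins; chromosomes are segmented independently.

tMAD is the median of |segmented log2R| over usable bins, deviation
measured from zero (the copy-neutral state), not from the sample
median. Per-bin segmented values and bin-weighted segment means give
identical medians when segments are bin-weighted; we use per-bin
values. Detection: score strictly greater than the maximum tMAD of the
healthy cohort. Under exchangeability this threshold yields a held-out
null false-detection rate of 1/(n_controls + 1), which the acceptance
suite verifies with 46-control cohorts.

Protocol defaults mirror the assay definitions: 10 million reads and
30 kb bins unselected; after 90–150 bp size selection, 2 million reads
and 500 kb bins, with samples below 2 million post-selection fragments
ineligible. Downsampling targets and the eligibility floor are
parameters so that desk-scale studies (hundreds of thousands of
fragments) exercise the identical code path; the test suite states the
sizes it uses.

## Aneuploidy z-scores

Arm-level read fractions emulate the selective-amplification screen:
amplicon choice is wet-lab chemistry, so uniform fragment sampling
stands in and arm fractions are the sufficient statistic. Per arm,
`z = (f_case − mean_controls) / sd_controls` (unbiased sd). Genome-wide
aggregation: `S = Σ z²` standardized against the leave-one-out control
distribution of S — direction-agnostic, so simultaneous gains and
losses both add evidence. Detection at genome-wide z ≥ 3 (inclusive).
A minimum of 100,000 fragments is recommended (warning below).

At tf = 0.10 with the canonical RCC karyotype (3p−, 3q+, 8p−, 8q+ on
the synthetic genome) detection is essentially complete, while tf =
0.05 detects ~40% — matching the assay family's stated sensitivity
boundary of 3–10% tumor fraction depending on the number and amplitude
of SCNA. A 2-arm karyotype at tf = 0.10 sits at roughly 60–70%
detection; sensitivity claims in the tests therefore use the multi-arm
karyotype, which is also the biologically motivated one.

## Tumor-fraction estimation

A deliberately simplified, deterministic replacement for an HMM-based
caller: over a grid t ∈ {0, 0.01, …, 0.95}, each segment takes the
integer copy state c ∈ {0..4} minimizing
`(obs − log2((2(1−t)+c·t)/2))² + λ·|c − 2|`, and the bin-weighted total
is minimized over t, ties toward smaller t. The λ term (10⁻⁴ per bin
per copy step) resolves a genuine non-identifiability: a homozygous
loss at t/2 reproduces a one-copy loss at t exactly (and c = 4 at t/2
mimics c = 3 at t), so without a preference for near-diploid states the
estimator would halve every tumor fraction. λ is small enough never to
override a real signal (a true c = 0 segment beats c = 1 by ~n·t²/2 in
SSE) but large enough to dominate noise-level ties. The flip side is an
upper working range: above tf ≈ 0.5 the aliasing direction reverses and
estimates may fold down; the recovery suite covers tf ≤ 0.4. Subclones
and ploidy shifts are out of scope.

Detection applies the 0.03 tumor-fraction floor. Samples with fewer
than 2 million post-selection reads additionally require the
frequent-SCNA rescue rule: at least one inferred non-neutral segment
overlapping a configured frequent arm event (> 50% of the arm, matching
direction). The default set — 3p loss, 8p loss, 3q gain, 8q gain — is
the RCC-typical list; arm names accept both "3p" and "chr3p" spellings.

## Variant post-filters

All rules read as stated, with boundary conventions fixed and recorded:
callable regions require germline depth strictly > 20×; population-AF
exclusion is strictly > 0.02 (unannotated = 0); normal-adjacent
exclusion removes AF > 0 in *any* NAT sample (absence of NATs is
flagged, not silently passed); the FFPE artifact filter removes C>A
calls preceded by C or T and G>T calls preceded by G or A (the
reverse-complement image), contexts on the reference strand, applied
only to FFPE-derived call sets, and raises if a relevant call lacks
context; replicate concordance keeps the intersection of duplicate
runs with the mean AF; panel polishing removes synonymous calls and
popAF > 0.01. Filters are pure functions returning (retained, removed)
and log into a `FilterReport` whose stages conserve counts.

## Targeted detection (INVAR-lite)

UMI families need ≥ 2 members and a base reaching ≥ 90% of members
(inclusive — a 9:1 family passes) to yield a consensus molecule;
consensus depth d and mutant count m per locus form the pileup.
Background error rates are pooled per trinucleotide-substitution class
from control consensus data; classes under 10,000 consensus bases fall
back to the global pooled rate, and zero-error classes are floored at
half a count (0.5/depth) because a literal zero would make any later
mutant observation infinitely significant.

Per-locus significance is the one-sided binomial tail
P(X ≥ m | d, e_class). Aggregation is a profile-likelihood ratio: the
sample-level allele fraction f is profiled over {0} ∪ logspace(10⁻⁶,
10⁻¹, 61) (ties toward smaller f), and the score is
`Σ w_i · log[Binom(m_i; d_i, e_i + f̂) / Binom(m_i; d_i, e_i)]` with
weights w_i proportional to tissue mAF normalized to mean 1. This uses
exactly the signal channels the assay describes — sequence context via
e_class and tumor mAF via the weights; fragment-length weighting is
not modeled (size selection can be applied upstream as a prefilter).
Loci with d = 0 contribute nothing.

The detection threshold is set on negative-control scores built by
scoring samples against other patients' mutation lists (non-matched
controls): the smallest value achieving the target specificity
(default 0.99; 1.0 = the cohort maximum). Detection requires score
strictly above threshold and no technical failure. Informative reads
IR = Σ d_i; IR < 20,000 is a technical failure (boundary exact: 19,999
fails, 20,000 passes) and fewer than 100 loci triggers a warning. gmAF
is `max(0, (Σm_i − Σd_i·e_i)/Σd_i)` — the background-subtracted,
depth-weighted mean allele fraction; at f = 10⁻³ over 100 loci × ~1000
consensus molecules it recovers f within binomial noise (~10%
relative).

## Fragmentomics and triage

Ten features in fixed order: tMAD, the 10-bp oscillation amplitude,
and proportions/ratios of fragment-length windows (P(20–150),
P(160–180), P(20–150)/P(160–180), P(100–150), P(100–150)/P(163–169),
P(180–220), P(250–320), P(20–150)/P(180–220)). All ranges are
inclusive at both ends (the prose "between 90 and 150 bp" is read
inclusively; fixed once so results are bit-stable). Zero-denominator
ratios are set to a capped sentinel (10⁶) with a provenance flag rather
than dropping the sample, keeping feature matrices rectangular.

`amplitude_10bp` is defined constructively: the histogram restricted
to [76, 150] bp is detrended by an 11-bp centered moving average (the
fraction of a period-10 comb that survives the filter is analytically
known and compensated), and the discrete Fourier magnitude at 1/10
bp⁻¹ is reported, clipped to [0, 1]. A flat density modulated by
`1 + A·cos(2πL/10)` reads A to within a few percent (the analytic test
case); any smooth comb-free density reads ≈ 0. The 76–150 bp window
and the exact functional are parameters, since only monotone
equivalence matters to the classifier.

The triage model is a seeded random forest (500 trees, default feature
subsampling, ≥ 20 training samples per class) over the ten features;
probability of cancer is the fraction of trees voting cancer, and a
sample is triaged to the targeted assay when probability is strictly
greater than 0.5. The shipped trainer runs on synthetic cohorts: it is
sample-triage plumbing, not a clinical classifier, and no performance
claim transfers to real cfDNA.

## Heterogeneity representation

The multi-region matrix holds mAF for samples (tumor regions plus
fluids) × mutations; a fluid entry of 0 means covered with no mutant
reads, while an uncovered locus is missing (NaN) and excluded from that
fluid's statistics. Region count per mutation uses tumor regions only.
Mutations (columns) are clustered by Euclidean distance with complete
linkage — the linkage was an open choice; complete linkage gives
compact AF clusters and is configurable — and rows are never
reordered.

A region is *represented* in a fluid if at least one of its called
mutations is fluid-detected (default rule: fluid AF > 0; a detection
set from the targeted detector can be supplied instead). Because
truncal mutations make every region trivially representable, the
private-mutations-only fraction is reported alongside the overall one;
the headline 90%/100% plasma/urine figures refer to the private-only
reading. The region-count trend groups fluid mAF by the number of
regions carrying each mutation and rank-sum tests every group against
the count-1 group (two-sided, unpaired — the "Wilcoxon" of the source
analysis is read as the rank-based two-sample test since no pairing
exists across mutation groups); groups under 3 mutations are skipped
with a note.

## Cohort statistics

Detection combination is a logical OR over the in-scope
(fluid, assay) records; technical failures leave both numerator and
denominator. Fisher's exact test is two-sided by the "sum of
hypergeometric probabilities ≤ observed" rule (this convention — not
tail-doubling — reproduces the reference p-value 9.4 × 10⁻³ for the
triage association table [[11, 1], [4, 7]]); scipy provides the
implementation and a brute-force enumeration is the test oracle.
Mann-Whitney U is exact for combined n ≤ 12 without ties, otherwise
normal-approximated with tie correction. Cohort reports always carry
explicit numerators and denominators; Spearman correlation of paired
plasma/urine gmAF is computed where both fluids exist.

## Reference experiments and problem sizes

`ctdnakit.benchmarks` packages the calibration studies the test suite
asserts and the acceptance script reports. Problem sizes are package
choices balancing statistical resolution against desk-scale runtime:
the tMAD null study uses 3 × (46 controls + 70 held-out nulls) at
40,000 fragments and 500 kb bins; the dilution/recovery study uses the
stated 2 × 10⁶ fragments (30 kb bins, 8 controls, 20 seeds per tumor
fraction); size-selection enrichment uses 20 seeds at 400,000
fragments; the targeted calibration uses 12 patients × 40 loci at
~500× consensus depth with 19 non-matched controls per panel and 100
fresh nulls; aneuploidy calibration uses 46 controls and 200 null
resimulations at 100,000 fragments. Genome structures are fixed seeds
(they play the role of a reference assembly); all sampling randomness
derives from the experiment seed.

## Known limitations

- The simulator's realism limits are listed above; calibration results
  are statements about the method under its own assumptions.
- Mean-scaling normalization biases absolute log-ratios on heavily
  aneuploid genomes (baseline shift); tMAD detection is unaffected but
  tumor-fraction estimates from unbalanced architectures inherit a
  small bias.
- The tumor-fraction estimator is single-clone, integer-copy (0–4),
  and reliable for tf ≲ 0.5.
- The aggregate-likelihood detector omits fragment-length weighting
  and patient-specific outlier suppression present in full
  implementations of this assay family.
- The triage random forest is trained on synthetic cohorts only.
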