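# ctdnakit

Multi-assay detection of circulating tumor DNA (ctDNA) in plasma and
urine, built for the hardest case: tumors that shed very little DNA,
such as renal cell carcinoma. The package implements, as one tested
Python library, the assays such a study chains together:

- **tMAD** — genome-wide copy-number deviation from shallow WGS:
  binned fragment counts → GC/mappability correction → control
  normalization → segmentation → trimmed median absolute deviation of
  segmented log2R from 0, with detection above the maximum score of a
  healthy control cohort (`ctdnakit.cna`);
- **in-silico size selection** — re-analysis after keeping 90–150 bp
  fragments, which enriches the shorter tumor-derived cfDNA
  (`ctdnakit.fragmentomics`);
- **aneuploidy z-scores** — chromosome-arm read fractions standardized
  against healthy controls, aggregated genome-wide (Σz² standardized
  leave-one-out), detection at z ≥ 3 (`ctdnakit.aneuploidy`);
- **tumor-fraction estimation** — grid fit of segment log2 ratios to
  `log2((2(1−t)+c·t)/2)` over integer copy states, 0.03 detection
  floor, frequent-SCNA rescue rule for low-read size-selected samples
  (`ctdnakit.tumor_fraction`);
- **INVAR-lite** — patient-specific targeted detection: UMI consensus
  collapsing (family ≥ 2, 90% majority), trinucleotide-class
  background error rates, per-locus binomial tails, tissue-mAF-weighted
  profile-likelihood aggregation across loci, non-matched-control ROC
  threshold, background-subtracted depth-weighted gmAF, and the
  20,000-informative-reads technical gate (`ctdnakit.invar`);
- **variant post-filters** — callable-depth, population-AF,
  normal-adjacent, FFPE [C/T]C>A / [G/A]G>T context artifact,
  duplicate-replicate concordance and panel polishing filters
  (`ctdnakit.filters`);
- **fragmentomics triage** — the ten fragment-length features and a
  seeded random-forest model with a strict 50% triage threshold
  (`ctdnakit.fragmentomics`);
- **heterogeneity representation** — multi-region mutation × sample
  mAF matrices, Euclidean clustering of mutations, fraction of tumor
  regions represented in a fluid, and the region-count mAF trend test
  (`ctdnakit.heterogeneity`);
- **cohort statistics** — detection combination across assays/fluids
  and the exact association tests (`ctdnakit.pipeline`).

Everything runs against a fragment-level cfDNA simulator
(`ctdnakit.simulate`): seeded samples with SCNA dilution, bimodal
fragment lengths with 10-bp periodicity, GC bias, control cohorts,
targeted UMI read sets over a context-dependent error model, and
multi-region tumor mutation matrices. The simulator is first-class,
tested code — it defines the conditions under which every calibration
claim is verified.

## Worked example

`examples/` holds one short script per capability. For instance,
size-selection enrichment (`examples/02_size_selection.py`) simulates
a tumor sample at 10% tumor fraction with arm-scale copy-number
changes and prints:

```
tumor fragment share : 0.090 -> 0.306 after 90-150 bp selection
tMAD unselected      : 0.0591
tMAD size-selected   : 0.1780
enrichment factor    : 3.01x
```

Keeping only 90–150 bp fragments triples the tumor share of the
library, and the copy-number deviation score rises accordingly — the
enrichment factor above 1 is what rescues samples whose unselected
signal sits below the healthy-cohort threshold. The targeted example
(`examples/03_targeted_invar.py`) detects a 1%-tumor-fraction sample
with an aggregate likelihood score orders of magnitude above its
non-matched-control threshold and reports its gmAF; the heterogeneity
example shows a single plasma sample representing all ten simulated
tumor regions through private mutations.

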