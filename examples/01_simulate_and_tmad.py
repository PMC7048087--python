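"""Simulate a cfDNA cohort and score copy-number deviation (tMAD).

Builds a 2x50 Mb genome, simulates six healthy plasma controls and one
renal-tumor-like sample (multi-arm losses/gains at tumor fraction 0.2),
and runs the tMAD assay: 500 kb bins, GC correction, control-cohort
normalization, segmentation, and the cohort-maximum detection rule.
"""

import ctdnakit as ck
from ctdnakit import cna

genome = ck.build_genome_model(2, 50_000_000, 1000, seed=7)
b1 = genome.arm_boundaries["chr1"]
b2 = genome.arm_boundaries["chr2"]
scna = (
    ck.SCNASegment("chr1", 0, b1, 1),          # one-copy loss, chr1p
    ck.SCNASegment("chr1", b1, 50_000_000, 3),  # one-copy gain, chr1q
    ck.SCNASegment("chr2", 0, b2, 1),          # one-copy loss, chr2p
)

template = ck.SimulationConfig(seed=0, n_fragments=400_000, gc_bias_strength=0.3)
controls = ck.simulate_control_cohort(6, template, genome, seed=40)

case = ck.simulate_sample(
    ck.SimulationConfig(
        seed=1, tumor_fraction=0.2, n_fragments=400_000,
        scna_segments=scna, gc_bias_strength=0.3,
    ),
    genome,
)

result = cna.run_tmad_assay(
    case, controls, genome, bin_bp=500_000, downsample_n=300_000
)
print(f"tMAD score      : {result.tmad_score:.4f}")
print(f"cohort threshold: {result.threshold:.4f} (max of {len(result.control_scores)} controls)")
print(f"SCNA detected   : {result.detected}")
# The score is the median |log2 ratio| of segmented bins: ~0 for a flat
# (healthy) profile, rising with tumor fraction and SCNA extent.  A
# sample is called ctDNA-positive when it strictly exceeds the largest
# score seen in the healthy cohort.
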