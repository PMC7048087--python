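"""Reference experiments: end-to-end calibration and recovery studies.

Each function runs one seeded study against the simulator at desk
scale and returns plain numbers: the tMAD null false-detection rate
under the cohort-maximum threshold, the copy-number dilution law and
tumor-fraction recovery, size-selection enrichment, the targeted
detector's specificity and gmAF recovery, aneuploidy z-score
calibration, and multi-region fluid representation.  The test suite
asserts tolerances on these numbers; the acceptance script reports
them.

Genome structures are fixed (they play the role of the reference
assembly); all sampling randomness derives from the ``seed`` argument.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import aneuploidy as an
from . import cna
from . import fragmentomics as fx
from . import heterogeneity as het
from . import invar
from .genome import build_genome_model
from .pipeline import fisher_2x2
from .simulate import (
    SCNASegment,
    SimulationConfig,
    TargetLocus,
    simulate_control_cohort,
    simulate_multiregion_tumor,
    simulate_sample,
    simulate_targeted_reads,
)
from .tumor_fraction import estimate_tumor_fraction

__all__ = [
    "fisher_triage_pvalue",
    "tmad_null_false_detection",
    "dilution_and_tf_recovery",
    "size_selection_enrichment",
    "invar_calibration",
    "aneuploidy_calibration",
    "heterogeneity_representation",
]


def _cna_genome():
    return build_genome_model(2, 50_000_000, 1000, seed=7)


def _arm_genome():
    return build_genome_model(8, 20_000_000, 10_000, seed=3)


# ---------------------------------------------------------------------------


def fisher_triage_pvalue() -> dict:
    """Fisher's exact test on the triage-vs-detection table.

    12 triage-positive patients with 11 detected (91.7%) against 11
    triage-negative with 4 detected (36.4%) is the unique integer 2x2
    table consistent with those rounded proportions; the two-sided
    exact p-value is computed from scratch.
    """
    table = [[11, 1], [4, 7]]
    p, odds = fisher_2x2(table)
    return {"p_value": p, "odds_ratio": odds, "table": table}


def tmad_null_false_detection(
    seed: int,
    n_cohorts: int = 3,
    n_controls: int = 46,
    n_cases_per_cohort: int = 70,
    n_fragments: int = 40_000,
) -> dict:
    """Held-out null false-detection rate of the cohort-max threshold.

    For each replicate cohort, 46 healthy controls set the threshold
    (max tMAD) and fresh null samples from the same generator are
    scored against it.  Under exchangeability the expected rate is
    1/(n_controls + 1).
    """
    genome = _cna_genome()
    tmpl = SimulationConfig(seed=0, n_fragments=n_fragments, gc_bias_strength=0.3)
    detections, total = 0, 0
    for c in range(n_cohorts):
        cohort = simulate_control_cohort(
            n_controls + n_cases_per_cohort, tmpl, genome, seed=seed + 10_000 * c
        )
        prep = cna.prepare_controls(
            cohort[:n_controls],
            genome,
            bin_bp=500_000,
            downsample_n=n_fragments,
            seed=seed + 10_000 * c + 999,
        )
        for i, case in enumerate(cohort[n_controls:]):
            res = cna.score_sample(case, prep, seed=seed + 10_000 * c + i)
            detections += bool(res.detected)
            total += 1
    return {
        "false_detection_rate": detections / total,
        "expected_rate": 1.0 / (n_controls + 1),
        "n_replicates": total,
    }


def _balanced_scna():
    # 10-Mb one-copy loss + 10-Mb one-copy gain: no net coverage shift
    return (
        SCNASegment("chr1", 0, 10_000_000, 1),
        SCNASegment("chr2", 0, 10_000_000, 3),
    )


def dilution_and_tf_recovery(
    seed: int,
    tfs=(0.05, 0.1, 0.2, 0.4),
    n_seeds: int = 20,
    n_fragments: int = 2_000_000,
    n_controls: int = 8,
) -> dict:
    """Segment dilution law and grid tumor-fraction recovery.

    A one-copy loss at tf = 0.4 must land its segment mean log2R at
    log2(0.8); across tfs, the estimator must recover tf within 0.02.
    """
    genome = _cna_genome()
    scna = _balanced_scna()
    tmpl = SimulationConfig(seed=0, n_fragments=n_fragments, gc_bias_strength=0.5)
    controls = simulate_control_cohort(n_controls, tmpl, genome, seed=seed + 77)
    prep = cna.prepare_controls(
        controls, genome, bin_bp=30_000, downsample_n=n_fragments, seed=seed + 78
    )

    def loss_segment_mean(result):
        best, overlap = None, 0
        for s in result.segments:
            if s.chrom != "chr1":
                continue
            o = max(0, min(s.end, 10_000_000) - s.start)
            if o > overlap:
                best, overlap = s, o
        return best.mean_log2r

    cfg = SimulationConfig(
        seed=seed + 79, tumor_fraction=0.4, n_fragments=n_fragments,
        scna_segments=scna, gc_bias_strength=0.5,
    )
    res = cna.score_sample(
        simulate_sample(cfg, genome), prep, seed=seed + 80, keep_profile=True
    )
    loss_log2r = loss_segment_mean(res)

    hits, total, errors = 0, 0, []
    for tf in tfs:
        for k in range(n_seeds):
            cfg = SimulationConfig(
                seed=seed + 100 + int(tf * 1000) * 37 + k,
                tumor_fraction=tf,
                n_fragments=n_fragments,
                scna_segments=scna,
                gc_bias_strength=0.5,
            )
            r = cna.score_sample(
                simulate_sample(cfg, genome), prep, seed=seed + 81, keep_profile=True
            )
            est = estimate_tumor_fraction(r.segments)
            errors.append(abs(est.tf_hat - tf))
            hits += abs(est.tf_hat - tf) <= 0.02
            total += 1
    return {
        "loss_segment_log2r": loss_log2r,
        "expected_log2r": float(np.log2(0.8)),
        "log2r_error": abs(loss_log2r - np.log2(0.8)),
        "tf_recovery_within_002": hits / total,
        "tf_mean_abs_error": float(np.mean(errors)),
        "n_runs": total,
    }


def size_selection_enrichment(
    seed: int,
    n_seeds: int = 20,
    tf: float = 0.1,
    n_fragments: int = 400_000,
    n_controls: int = 6,
) -> dict:
    """Size-selected vs unselected tMAD at tf = 0.1.

    Tumor fragments mode 145 bp vs normal 167 bp; the in-silico 90-150
    bp selection should raise tMAD (enrichment factor > 1).
    """
    genome = _cna_genome()
    b1 = genome.arm_boundaries["chr1"]
    b2 = genome.arm_boundaries["chr2"]
    scna = (
        SCNASegment("chr1", 0, b1, 1),
        SCNASegment("chr1", b1, 50_000_000, 3),
        SCNASegment("chr2", 0, b2, 1),
    )
    tmpl = SimulationConfig(seed=0, n_fragments=n_fragments, gc_bias_strength=0.3)
    controls = simulate_control_cohort(n_controls, tmpl, genome, seed=seed + 40)
    prep_un = cna.prepare_controls(
        controls, genome, bin_bp=500_000, downsample_n=300_000, seed=seed + 1
    )
    prep_ss = cna.prepare_controls(
        [fx.size_select(c) for c in controls],
        genome, bin_bp=500_000, downsample_n=50_000, seed=seed + 2,
    )
    enrichments = []
    for s in range(n_seeds):
        cfg = SimulationConfig(
            seed=seed + 300 + s, tumor_fraction=tf, n_fragments=n_fragments,
            scna_segments=scna, gc_bias_strength=0.3,
        )
        df = simulate_sample(cfg, genome)
        un = cna.score_sample(df, prep_un, seed=seed + 5)
        ss = fx.size_selected_tmad(
            df, prep_ss, unselected_tmad=un.tmad_score,
            downsample_n=50_000, min_fragments=30_000, seed=seed + 6,
        )
        enrichments.append(ss.enrichment)
    enrichments = np.array(enrichments)
    return {
        "fraction_enrichment_gt1": float((enrichments > 1).mean()),
        "median_enrichment": float(np.median(enrichments)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------


_CONTEXT_POOL = [
    ("ACA", "C", "T"), ("CCG", "C", "A"), ("TCT", "C", "G"), ("GCC", "C", "T"),
    ("AGA", "G", "A"), ("TGC", "G", "T"), ("CGT", "G", "C"), ("GGA", "G", "A"),
]


def _make_panel(rng, n_loci):
    loci = []
    for i in range(n_loci):
        ctx, ref, alt = _CONTEXT_POOL[int(rng.integers(len(_CONTEXT_POOL)))]
        loci.append(
            TargetLocus(
                "chr1", 1000 + i * 500, ref, alt, ctx,
                tissue_maf=float(rng.uniform(0.1, 0.6)),
            )
        )
    return tuple(loci)


def invar_calibration(
    seed: int,
    n_patients: int = 12,
    n_loci: int = 40,
    depth: float = 600,
    n_controls_per_panel: int = 19,
    n_fresh: int = 100,
    case_tf: float = 0.01,
) -> dict:
    """Targeted detector calibration: non-matched-control threshold,
    specificity on fresh controls, matched-case sensitivity, and gmAF
    recovery at a sample-level allele fraction of 1e-3."""
    rng = np.random.default_rng(seed)
    panels = [_make_panel(rng, n_loci) for _ in range(n_patients)]
    base = SimulationConfig(seed=0, default_error_rate=1e-4, read_error_rate=1e-3)
    null_cfg = dataclasses.replace(base, tumor_fraction=0.0)

    # background error model from dedicated null sequencing runs
    bg_piles = []
    for i, panel in enumerate(panels):
        for j in range(2):
            reads = simulate_targeted_reads(
                null_cfg, panel, depth, seed=seed + 100 + 10 * i + j
            )
            bg_piles.extend(invar.collapse_umi(reads, panel))
    bg = invar.estimate_background(bg_piles, min_class_depth=10_000)

    def score_null(panel, s):
        reads = simulate_targeted_reads(null_cfg, panel, depth, seed=s)
        piles = invar.collapse_umi(reads, panel)
        return invar.aggregate_likelihood(piles, bg)[0]

    control_scores = [
        score_null(panels[i], seed + 1000 + 10 * i + j)
        for i in range(n_patients)
        for j in range(n_controls_per_panel)
    ]
    threshold = invar.roc_threshold(control_scores, target_specificity=1.0)

    fresh_detected = 0
    for k in range(n_fresh):
        s = score_null(panels[k % n_patients], seed + 50_000 + k)
        fresh_detected += s > threshold
    specificity = 1.0 - fresh_detected / n_fresh

    case_cfg = dataclasses.replace(base, tumor_fraction=case_tf)
    case_detected = 0
    for i, panel in enumerate(panels):
        reads = simulate_targeted_reads(case_cfg, panel, depth, seed=seed + 90_000 + i)
        piles = invar.collapse_umi(reads, panel)
        score, _ = invar.aggregate_likelihood(piles, bg)
        case_detected += score > threshold

    # gmAF recovery: 100 loci x ~1000 consensus depth at f = 1e-3
    gm_loci = tuple(
        TargetLocus("chr1", 1000 + i * 500, "C", "T", "ACA", tissue_maf=1.0)
        for i in range(100)
    )
    gm_cfg = dataclasses.replace(
        base,
        tumor_fraction=1e-3,
        umi_family_size_distribution=((3, 1.0),),
    )
    reads = simulate_targeted_reads(gm_cfg, gm_loci, 1050, seed=seed + 123_456)
    piles = invar.collapse_umi(reads, gm_loci)
    gm_bg = invar.estimate_background(
        invar.collapse_umi(
            simulate_targeted_reads(
                dataclasses.replace(gm_cfg, tumor_fraction=0.0),
                gm_loci, 1050, seed=seed + 123_457,
            ),
            gm_loci,
        )
    )
    gmaf = invar.compute_gmaf(piles, gm_bg)
    return {
        "threshold": threshold,
        "specificity_fresh_controls": specificity,
        "n_fresh_controls": n_fresh,
        "case_detection_rate": case_detected / n_patients,
        "gmaf": gmaf,
        "gmaf_true": 1e-3,
        "gmaf_relative_error": abs(gmaf - 1e-3) / 1e-3,
    }


def aneuploidy_calibration(
    seed: int,
    n_controls: int = 46,
    n_null: int = 200,
    n_fragments: int = 100_000,
) -> dict:
    """Leave-one-out z calibration and the genome-wide false-positive
    rate of the >= 3 rule under the null, plus detection of the
    multi-arm renal karyotype at tf = 0.1."""
    genome = _arm_genome()
    tmpl = SimulationConfig(seed=0, n_fragments=n_fragments, gc_bias_strength=0.2)
    cohort = simulate_control_cohort(n_controls, tmpl, genome, seed=seed + 50)
    counts = [an.arm_read_counts(c, genome) for c in cohort]
    loo = an._loo_zscore_matrix(counts)

    fp = 0
    for s in range(n_null):
        cfg = SimulationConfig(
            seed=seed + 9000 + s, n_fragments=n_fragments, gc_bias_strength=0.2
        )
        case = an.arm_read_counts(simulate_sample(cfg, genome), genome)
        fp += an.run_aneuploidy_assay(case, counts, loo_matrix=loo).detected

    b3 = genome.arm_boundaries["chr3"]
    b8 = genome.arm_boundaries["chr8"]
    scna = (
        SCNASegment("chr3", 0, b3, 1),
        SCNASegment("chr3", b3, 20_000_000, 3),
        SCNASegment("chr8", 0, b8, 1),
        SCNASegment("chr8", b8, 20_000_000, 3),
    )
    det = 0
    for s in range(10):
        cfg = SimulationConfig(
            seed=seed + 700 + s, tumor_fraction=0.1, n_fragments=n_fragments,
            scna_segments=scna, gc_bias_strength=0.2,
        )
        case = an.arm_read_counts(simulate_sample(cfg, genome), genome)
        det += an.run_aneuploidy_assay(case, counts, loo_matrix=loo).detected
    return {
        "loo_z_mean": float(np.nanmean(loo)),
        "loo_z_sd": float(np.nanstd(loo)),
        "null_fpr": fp / n_null,
        "n_null": n_null,
        "rcc_karyotype_detection_at_tf10pct": det / 10,
    }


def heterogeneity_representation(seed: int, n_null: int = 200) -> dict:
    """Fluid representation of multi-region heterogeneity.

    Urine detects every mutation (100% of regions represented); plasma
    misses the private mutations of exactly one region (90%).  Also
    measures the type-I error of the region-count mAF trend test under
    the null.
    """
    matrix, _ = simulate_multiregion_tumor(
        10, 3, 5, 3, seed=seed, fluid_tfs={"plasma": 0.1, "urine": 0.1}
    )
    urine = het.fluid_representation(matrix, "urine")
    missed_region = matrix.tumor_regions[4]
    rc = matrix.region_count
    missed = {
        m for m in matrix.calls_of_region(missed_region) if rc[m] == 1
    }
    detected = set(matrix.af.columns) - missed
    plasma = het.fluid_representation(matrix, "plasma", detected=detected)

    rng = np.random.default_rng(seed + 1)
    rejections = 0
    for _ in range(n_null):
        regions = [f"T{i}" for i in range(1, 4)]
        region_calls = {r: {} for r in regions}
        fluid = {}
        mid = 0
        for count in (1, 2):
            for _ in range(30):
                name = f"m{mid}"
                mid += 1
                for r in regions[:count]:
                    region_calls[r][name] = 0.3
                fluid[name] = float(rng.random() * 0.05)
        m = het.build_matrix(region_calls, {"plasma": fluid})
        out = het.af_by_region_count_trend(m, "plasma")
        rejections += out["tests_vs_count1"][2]["p_value"] < 0.05
    return {
        "urine_regions_represented_pct": 100.0 * urine["fraction_represented_private_only"],
        "plasma_regions_represented_pct": 100.0
        * plasma["fraction_represented_private_only"],
        "trend_null_type1_rate": rejections / n_null,
        "n_null": n_null,
    }
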