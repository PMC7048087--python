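"""Chromosome-arm aneuploidy z-scores (mFAST-SeqS style).

Per-arm fragment fractions of a case are standardized against a healthy
control cohort; arm z-scores are aggregated genome-wide as the sum of
squared arm z's, itself standardized against the leave-one-out control
distribution.  A genome-wide z-score >= 3 flags aneuploid ctDNA.

The wet-lab LINE-1 amplicon selection is emulated as uniform fragment
sampling: arm fractions are the sufficient statistic the scores use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel

__all__ = [
    "ArmCounts",
    "AneuploidyScores",
    "arm_read_counts",
    "arm_zscores",
    "genomewide_zscore",
    "run_aneuploidy_assay",
]

MIN_FRAGMENTS = 100_000
DETECTION_Z = 3.0


def is_detected(genomewide_z: float) -> bool:
    """Detection rule: genome-wide z-score of at least 3 (inclusive)."""
    return genomewide_z >= DETECTION_Z


@dataclass
class ArmCounts:
    arms: list[str]
    counts: np.ndarray
    fractions: np.ndarray  # over included arms, sums to 1
    excluded_arms: tuple[str, ...] = ()


@dataclass
class AneuploidyScores:
    arms: list[str]
    arm_z: np.ndarray
    genomewide_z: float
    n_controls: int
    detected: bool  # genomewide_z >= 3 (inclusive)


def arm_read_counts(
    fragments: pd.DataFrame,
    genome: GenomeModel,
    excluded_arms: tuple[str, ...] = (),
) -> ArmCounts:
    """Partition fragments by the chromosome arm of their midpoint."""
    if len(fragments) < MIN_FRAGMENTS:
        warnings.warn(
            f"only {len(fragments)} fragments; below the {MIN_FRAGMENTS} recommended minimum"
        )
    arms = genome.arms()
    names = [a[0] for a in arms if a[0] not in excluded_arms]
    counts = np.zeros(len(names), dtype=np.int64)
    mids = (fragments["start"].to_numpy() + fragments["end"].to_numpy()) // 2
    pos = 0
    for arm_name, chrom, start, end in arms:
        if arm_name in excluded_arms:
            continue
        mask = (fragments["chrom"] == chrom).to_numpy() & (mids >= start) & (mids < end)
        counts[pos] = int(mask.sum())
        pos += 1
    total = counts.sum()
    fractions = counts / total if total > 0 else np.zeros_like(counts, dtype=float)
    return ArmCounts(arms=names, counts=counts, fractions=fractions, excluded_arms=excluded_arms)


def arm_zscores(case: ArmCounts, controls: list[ArmCounts]) -> np.ndarray:
    """z per arm: (case fraction - control mean) / control sd (ddof=1).

    Arms with zero control variance are excluded (NaN) with a warning.
    """
    if len(controls) < 3:
        raise ValueError("need at least 3 controls")
    for c in controls:
        if c.arms != case.arms:
            raise ValueError("mismatched arm sets between case and controls")
    mat = np.vstack([c.fractions for c in controls])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    z = np.full(len(case.arms), np.nan)
    ok = sd > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} arms with zero control variance excluded")
    z[ok] = (case.fractions[ok] - mean[ok]) / sd[ok]
    return z


def _loo_zscore_matrix(controls: list[ArmCounts]) -> np.ndarray:
    """Leave-one-out arm z of every control against the rest."""
    out = []
    for j in range(len(controls)):
        rest = controls[:j] + controls[j + 1 :]
        out.append(arm_zscores(controls[j], rest))
    return np.vstack(out)


def genomewide_zscore(arm_z: np.ndarray, controls_arm_z: np.ndarray) -> float:
    """Genome-wide aggregation: S = sum of squared arm z-scores,
    standardized against the leave-one-out control S distribution."""
    s_case = float(np.nansum(arm_z**2))
    s_ctrl = np.nansum(controls_arm_z**2, axis=1)
    sd = s_ctrl.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate control variance in genome-wide aggregation")
    return (s_case - s_ctrl.mean()) / sd


def run_aneuploidy_assay(
    case_counts: ArmCounts,
    control_counts: list[ArmCounts],
    loo_matrix: np.ndarray | None = None,
) -> AneuploidyScores:
    """Arm z-scores plus genome-wide z with the >= 3 detection rule.

    ``loo_matrix`` (the leave-one-out control z matrix) can be passed to
    amortize its computation across many cases.
    """
    z = arm_zscores(case_counts, control_counts)
    if loo_matrix is None:
        loo_matrix = _loo_zscore_matrix(control_counts)
    gw = genomewide_zscore(z, loo_matrix)
    return AneuploidyScores(
        arms=case_counts.arms,
        arm_z=z,
        genomewide_z=gw,
        n_controls=len(control_counts),
        detected=is_detected(gw),
    )
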