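"""Simplified tumor-fraction estimation from a segmented profile.

Grid search over tumor fraction t and integer copy states: a segment
carried at total copy c in the tumor, at fraction t, has expected
log2 ratio ``log2((2*(1-t) + c*t) / 2)``.  For each candidate t every
segment takes the copy state (0..4) minimizing its squared deviation
(plus a small complexity penalty that prefers near-diploid states among
equivalent fits — without it the model is not identifiable, since e.g.
a homozygous loss at t/2 reproduces a one-copy loss at t exactly).
The bin-weighted total objective is minimized over t; ties break toward
smaller t.

Detection follows the 0.03 lower limit: estimates below it are called
ctDNA-negative.  Low-read size-selected samples (< 2 million fragments)
are additionally required to show a copy-number alteration frequent in
renal cell carcinoma (default: 3p loss, 8p loss, 3q gain, 8q gain) to
count as positive — the frequent-SCNA rescue rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cna import Segment
from .genome import GenomeModel

__all__ = [
    "TFEstimate",
    "DEFAULT_FREQUENT_SCNA",
    "estimate_tumor_fraction",
    "frequent_scna_rescue",
]

TF_DETECTION_FLOOR = 0.03
LOW_READ_THRESHOLD = 2_000_000
COPY_STATES = np.arange(0, 5)
COMPLEXITY_LAMBDA = 1e-4  # per-bin penalty per copy-state step away from 2

# Arm-level gains/losses frequent in renal cell carcinoma.
DEFAULT_FREQUENT_SCNA: tuple[tuple[str, str], ...] = (
    ("3p", "loss"),
    ("8p", "loss"),
    ("3q", "gain"),
    ("8q", "gain"),
)


@dataclass
class TFEstimate:
    tf_hat: float
    copy_states: list[int]  # per input segment
    fit_score: float
    detected: bool
    rescue_rule_applied: bool = False
    segments: list[Segment] | None = None


def _expected_log2r(t: float, copies: np.ndarray) -> np.ndarray:
    return np.log2((2.0 * (1.0 - t) + copies * t) / 2.0)


def estimate_tumor_fraction(
    segments: list[Segment],
    grid: np.ndarray | None = None,
) -> TFEstimate:
    """Fit tumor fraction to bin-weighted segment means by grid search.

    The default grid is t in {0.00, 0.01, ..., 0.95}.  An all-neutral
    profile lands on t = 0 by the smaller-t tie-break.
    """
    if not segments:
        raise ValueError("no segments to fit")
    if grid is None:
        grid = np.round(np.arange(0.0, 0.951, 0.01), 2)
    obs = np.array([s.mean_log2r for s in segments])
    weights = np.array([s.n_bins for s in segments], dtype=float)

    best_t, best_score, best_states = 0.0, np.inf, None
    for t in grid:
        exp = _expected_log2r(t, COPY_STATES)  # per copy state
        sq = (obs[:, None] - exp[None, :]) ** 2 + COMPLEXITY_LAMBDA * np.abs(
            COPY_STATES - 2
        )[None, :]
        state_idx = np.argmin(sq, axis=1)
        score = float(np.sum(weights * sq[np.arange(len(obs)), state_idx]))
        if score < best_score - 1e-12:  # strict improvement: ties keep smaller t
            best_score = score
            best_t = float(t)
            best_states = COPY_STATES[state_idx].tolist()
    return TFEstimate(
        tf_hat=best_t,
        copy_states=best_states,
        fit_score=best_score,
        detected=best_t >= TF_DETECTION_FLOOR,
        segments=list(segments),
    )


def frequent_scna_rescue(
    estimate: TFEstimate,
    genome: GenomeModel,
    reads_available: int,
    frequent_set: tuple[tuple[str, str], ...] = DEFAULT_FREQUENT_SCNA,
    min_overlap: float = 0.5,
) -> TFEstimate:
    """Apply the low-read frequent-SCNA detection gate.

    For samples with at least ``LOW_READ_THRESHOLD`` reads the rule is
    not consulted and the estimate is returned unchanged.  Below it, a
    sample counts as detected only if (besides clearing the 0.03 floor)
    at least one inferred non-neutral segment overlaps a frequent
    (arm, direction) by more than ``min_overlap`` of the arm length,
    with the segment's direction matching (copies < 2 for a loss,
    > 2 for a gain).
    """
    if reads_available >= LOW_READ_THRESHOLD:
        return estimate
    if estimate.segments is None:
        raise ValueError("estimate lacks segment coordinates for the rescue rule")
    # accept both "3p" and "chr3p" spellings for arm names
    arms: dict[str, tuple[str, int, int]] = {}
    for name, chrom, s, e in genome.arms():
        arms[name] = (chrom, s, e)
        if name.startswith("chr"):
            arms[name[3:]] = (chrom, s, e)
    matched = False
    for seg, copies in zip(estimate.segments, estimate.copy_states):
        if copies == 2:
            continue
        direction = "loss" if copies < 2 else "gain"
        for arm_name, want in frequent_set:
            if want != direction or arm_name not in arms:
                continue
            chrom, a_start, a_end = arms[arm_name]
            if seg.chrom != chrom:
                continue
            overlap = min(seg.end, a_end) - max(seg.start, a_start)
            if overlap > min_overlap * (a_end - a_start):
                matched = True
    detected = estimate.detected and matched
    return TFEstimate(
        tf_hat=estimate.tf_hat,
        copy_states=estimate.copy_states,
        fit_score=estimate.fit_score,
        detected=detected,
        rescue_rule_applied=True,
        segments=estimate.segments,
    )
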