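"""Patient-specific targeted ctDNA detection (INVAR-lite).

UMI read families are collapsed to consensus molecules (minimum family
size 2, >= 90% base majority), background error rates are pooled per
trinucleotide-substitution class from control data, and evidence is
aggregated across the patient's mutated loci as a profile-likelihood
ratio weighted by tissue mutant allele fraction.  A detection threshold
is set on negative-control scores (samples scored against non-matched
patients' mutation lists); samples with fewer than 20,000 informative
reads (consensus molecules over patient loci) are technical failures.

The global mutant allele fraction (gmAF) is the background-subtracted,
depth-weighted mean allele fraction across the patient-specific loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import TargetLocus

__all__ = [
    "LocusPileup",
    "BackgroundErrorModel",
    "InvarResult",
    "collapse_umi",
    "estimate_background",
    "locus_significance",
    "aggregate_likelihood",
    "roc_threshold",
    "compute_gmaf",
    "informative_reads",
    "run_invar",
]

MIN_FAMILY_SIZE = 2
MAJORITY_FRACTION = 0.9  # inclusive
IR_TECHNICAL_FLOOR = 20_000
MIN_LOCI_WARN = 100

# profile-likelihood grid for the sample-level allele fraction
F_GRID = np.concatenate(([0.0], np.logspace(-6, -1, 61)))


@dataclass
class LocusPileup:
    """Consensus depth and mutant count at one patient-specific locus."""

    locus: TargetLocus
    depth: int  # consensus molecules covering the locus
    mutant: int  # consensus molecules showing the alt base
    p_value: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.mutant <= self.depth:
            raise ValueError("need 0 <= mutant <= depth")


@dataclass
class BackgroundErrorModel:
    """Per trinucleotide-substitution-class background error rates."""

    rates: dict[str, float]
    counts: dict[str, tuple[int, int]]  # class -> (mutant, depth) pooled
    global_rate: float
    fallback_classes: tuple[str, ...] = ()

    def rate_for(self, error_class: str) -> float:
        return self.rates.get(error_class, self.global_rate)


@dataclass
class InvarResult:
    score: float
    threshold: float | None
    detected: bool | None
    gmaf: float
    ir_total: int
    technical_fail: bool
    f_hat: float
    pileups: list[LocusPileup] = field(default_factory=list)


# ---------------------------------------------------------------------------
# UMI consensus
# ---------------------------------------------------------------------------


def collapse_umi(
    raw_reads: pd.DataFrame, loci: list[TargetLocus] | tuple[TargetLocus, ...]
) -> list[LocusPileup]:
    """Collapse raw reads into consensus molecules per locus.

    Families (grouped by locus and UMI) of fewer than 2 reads are
    dropped; a family yields a consensus base only when a single base
    reaches at least 90% of its members, else it is discarded.
    Consensus depth is the number of surviving families; the mutant
    count is the number whose consensus equals the locus alt base.
    """
    pileups = []
    if len(raw_reads):
        grouped = raw_reads.groupby(["locus_id", "umi", "base"]).size()
        fam_totals = grouped.groupby(level=["locus_id", "umi"]).sum()
        fam_top = grouped.groupby(level=["locus_id", "umi"]).max()
        top_base = grouped.groupby(level=["locus_id", "umi"]).idxmax().str[2]
        keep = (fam_totals >= MIN_FAMILY_SIZE) & (
            fam_top / fam_totals >= MAJORITY_FRACTION
        )
        consensus = top_base[keep]
        per_locus = consensus.groupby(level="locus_id")
        depth_by_locus = per_locus.size()
        mutant_by_locus = {}
        for li, bases in per_locus:
            alt = loci[int(li)].alt
            mutant_by_locus[li] = int((bases == alt).sum())
    else:
        depth_by_locus, mutant_by_locus = pd.Series(dtype=int), {}
    for li, locus in enumerate(loci):
        d = int(depth_by_locus.get(li, 0))
        m = int(mutant_by_locus.get(li, 0))
        pileups.append(LocusPileup(locus=locus, depth=d, mutant=m))
    return pileups


# ---------------------------------------------------------------------------
# background error model
# ---------------------------------------------------------------------------


def estimate_background(
    control_pileups: list[LocusPileup], min_class_depth: int = 10_000
) -> BackgroundErrorModel:
    """Pool control consensus counts per trinucleotide-substitution class.

    ``e_class = pooled mutant / pooled depth``; classes with fewer than
    ``min_class_depth`` pooled consensus bases fall back to the global
    pooled rate and are flagged.  A class (or global pool) with zero
    observed errors is floored at half a count (0.5/depth) — a rate of
    exactly 0 would make any later mutant observation infinitely
    significant, which finite control data cannot support.
    """
    per_class: dict[str, list[int]] = {}
    tot_m = tot_d = 0
    for p in control_pileups:
        cls = p.locus.error_class
        m, d = per_class.get(cls, [0, 0])
        per_class[cls] = [m + p.mutant, d + p.depth]
        tot_m += p.mutant
        tot_d += p.depth
    if tot_d == 0:
        raise ValueError("zero consensus depth in control pileups")
    global_rate = tot_m / tot_d if tot_m > 0 else 0.5 / tot_d
    rates, counts, fallback = {}, {}, []
    for cls, (m, d) in per_class.items():
        counts[cls] = (m, d)
        if d >= min_class_depth:
            rates[cls] = m / d if m > 0 else 0.5 / d
        else:
            fallback.append(cls)
    return BackgroundErrorModel(
        rates=rates,
        counts=counts,
        global_rate=global_rate,
        fallback_classes=tuple(sorted(fallback)),
    )


# ---------------------------------------------------------------------------
# per-locus and aggregate statistics
# ---------------------------------------------------------------------------


def locus_significance(pileup: LocusPileup, error_model: BackgroundErrorModel) -> float:
    """One-sided binomial tail P(X >= m | n=d, p=e_class)."""
    e = error_model.rate_for(pileup.locus.error_class)
    if e >= 1:
        raise ValueError("error rate must be < 1")
    if pileup.depth < 1:
        raise ValueError("locus has no consensus depth")
    if pileup.mutant == 0:
        return 1.0
    if e == 0:
        return 0.0
    return float(stats.binom.sf(pileup.mutant - 1, pileup.depth, e))


def aggregate_likelihood(
    pileups: list[LocusPileup],
    error_model: BackgroundErrorModel,
    f_grid: np.ndarray = F_GRID,
) -> tuple[float, float]:
    """Aggregate evidence across loci as a weighted log likelihood ratio.

    The sample-level allele fraction f is profiled over ``f_grid``
    (ties toward smaller f); the score is
    ``sum_i w_i * log[ Binom(m_i; d_i, e_i + f_hat) / Binom(m_i; d_i, e_i) ]``
    with weights w_i proportional to the tissue mAF (normalized to mean
    1).  Loci with zero depth contribute nothing.

    Returns ``(score, f_hat)``.
    """
    live = [p for p in pileups if p.depth > 0]
    if not live:
        raise ValueError("no locus with consensus depth > 0")
    d = np.array([p.depth for p in live])
    m = np.array([p.mutant for p in live])
    e = np.array([error_model.rate_for(p.locus.error_class) for p in live])
    w = np.array([p.locus.tissue_maf for p in live], dtype=float)
    w = w / w.mean() if w.mean() > 0 else np.ones_like(w)

    p_mat = np.clip(e[None, :] + f_grid[:, None], 1e-300, 1 - 1e-12)
    ll = stats.binom.logpmf(m[None, :], d[None, :], p_mat) @ w
    best = int(np.argmax(ll))  # argmax takes the first (smallest f) on ties
    f_hat = float(f_grid[best])
    null = float(stats.binom.logpmf(m, d, np.clip(e, 1e-300, 1 - 1e-12)) @ w)
    score = float(ll[best] - null)
    return score, f_hat


def roc_threshold(
    control_scores, target_specificity: float = 0.99
) -> float:
    """Smallest threshold achieving >= target specificity on negative
    controls (non-matched mutation-list scores); detection is strictly
    above the threshold."""
    scores = np.sort(np.asarray(list(control_scores), dtype=float))
    if scores.size == 0:
        raise ValueError("no control scores")
    if not 0 < target_specificity <= 1:
        raise ValueError("target_specificity must lie in (0, 1]")
    k = int(np.ceil(target_specificity * scores.size)) - 1
    return float(scores[k])


def compute_gmaf(
    pileups: list[LocusPileup], error_model: BackgroundErrorModel
) -> float:
    """Background-subtracted depth-weighted mean allele fraction:
    ``max(0, (sum m_i - sum d_i * e_i) / sum d_i)``."""
    d = np.array([p.depth for p in pileups])
    if d.sum() == 0:
        raise ValueError("zero total consensus depth")
    m = np.array([p.mutant for p in pileups])
    e = np.array([error_model.rate_for(p.locus.error_class) for p in pileups])
    return float(max(0.0, (m.sum() - (d * e).sum()) / d.sum()))


def informative_reads(pileups: list[LocusPileup]) -> tuple[int, bool]:
    """Total informative reads (sum of consensus depths) and the
    technical-failure flag (IR strictly below 20,000)."""
    ir = int(sum(p.depth for p in pileups))
    if len(pileups) < MIN_LOCI_WARN:
        warnings.warn(
            f"only {len(pileups)} patient-specific loci (< {MIN_LOCI_WARN}); "
            "expect few informative reads"
        )
    return ir, ir < IR_TECHNICAL_FLOOR


def run_invar(
    pileups: list[LocusPileup],
    error_model: BackgroundErrorModel,
    threshold: float | None = None,
) -> InvarResult:
    """Score a sample end to end: aggregate likelihood, gmAF, IR gate,
    per-locus significance, and (when a threshold is given) detection."""
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        ir, fail = informative_reads(pileups)
    score, f_hat = aggregate_likelihood(pileups, error_model)
    gmaf = compute_gmaf(pileups, error_model)
    for p in pileups:
        if p.depth > 0:
            p.p_value = locus_significance(p, error_model)
    detected = None
    if threshold is not None:
        detected = (not fail) and score > threshold
    return InvarResult(
        score=score,
        threshold=threshold,
        detected=detected,
        gmaf=gmaf,
        ir_total=ir,
        technical_fail=fail,
        f_hat=f_hat,
        pileups=pileups,
    )
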