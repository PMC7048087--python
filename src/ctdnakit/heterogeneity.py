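"""Multi-region tumor heterogeneity and its representation in fluids.

Builds a mutations-by-samples allele-fraction matrix from multi-region
tumor calls plus plasma/urine pileups, clusters mutations (columns) by
Euclidean distance, measures what fraction of tumor regions is
represented by at least one fluid-detected mutation, and tests whether
fluid mAF rises with the number of tumor regions carrying a mutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu

__all__ = [
    "MultiRegionMatrix",
    "build_matrix",
    "cluster_mutations",
    "fluid_representation",
    "af_by_region_count_trend",
]


@dataclass
class MultiRegionMatrix:
    """Samples (tumor regions + fluids) x mutations allele fractions.

    Missing fluid entries (locus uncovered in that fluid) are NaN and
    tracked; a fluid entry of 0.0 means covered with no mutant reads.
    ``region_count`` counts, per mutation, the tumor regions in which
    it was called (fluids excluded).
    """

    af: pd.DataFrame  # rows = samples, columns = mutation ids
    tumor_regions: list[str]
    fluids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.af.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
            raise ValueError("allele fractions must lie in [0, 1]")

    @property
    def region_count(self) -> pd.Series:
        sub = self.af.loc[self.tumor_regions]
        return (sub > 0).sum(axis=0)

    def calls_of_region(self, region: str) -> list[str]:
        row = self.af.loc[region]
        return list(row.index[row > 0])


def build_matrix(
    region_calls: dict[str, dict[str, float]],
    fluid_pileups: dict[str, dict[str, float | None]] | None = None,
) -> MultiRegionMatrix:
    """Assemble the complete rectangular matrix from per-region calls
    (mutation id -> AF) and per-fluid measured AFs at the union loci
    (None marks an uncovered locus, stored as NaN)."""
    fluid_pileups = fluid_pileups or {}
    mutations: list[str] = []
    for calls in region_calls.values():
        for mid in calls:
            if mid not in mutations:
                mutations.append(mid)
    rows = {}
    for region, calls in region_calls.items():
        rows[region] = [calls.get(m, 0.0) for m in mutations]
    for fluid, pile in fluid_pileups.items():
        rows[fluid] = [np.nan if pile.get(m, 0.0) is None else pile.get(m, 0.0) for m in mutations]
    af = pd.DataFrame.from_dict(rows, orient="index", columns=mutations)
    return MultiRegionMatrix(
        af=af, tumor_regions=list(region_calls), fluids=list(fluid_pileups)
    )


def cluster_mutations(
    matrix: MultiRegionMatrix, method: str = "complete"
) -> tuple[list[str], np.ndarray]:
    """Hierarchical clustering of mutations (columns) by Euclidean
    distance; rows are left in their given order.  Returns the leaf
    column ordering and the scipy linkage matrix."""
    if matrix.af.shape[1] < 2:
        raise ValueError("need at least 2 mutations to cluster")
    X = matrix.af.to_numpy(dtype=float).T  # mutations x samples
    X = np.nan_to_num(X, nan=0.0)
    link = hierarchy.linkage(pdist(X, metric="euclidean"), method=method)
    order = hierarchy.leaves_list(link)
    return [matrix.af.columns[i] for i in order], link


def fluid_representation(
    matrix: MultiRegionMatrix,
    fluid_row: str,
    detected: set[str] | None = None,
    detect_rule=None,
) -> dict:
    """Fraction of tumor regions represented in a fluid.

    A region is represented iff at least one of its called mutations is
    detected in the fluid.  Detection defaults to fluid AF > 0 at the
    locus; pass an explicit ``detected`` set of mutation ids (e.g. from
    the targeted detector's per-locus significance), or a callable
    ``detect_rule(mutation_id, fluid_af) -> bool``.

    Returns overall and private-mutations-only representation plus the
    per-region breakdown.
    """
    if fluid_row not in matrix.af.index:
        raise KeyError(f"no fluid row {fluid_row!r}")
    fluid = matrix.af.loc[fluid_row]

    def is_detected(mid: str) -> bool:
        af = fluid[mid]
        if detected is not None:
            return mid in detected
        if detect_rule is not None:
            return bool(detect_rule(mid, af))
        return bool(np.isfinite(af) and af > 0)

    rc = matrix.region_count
    per_region, per_region_private = {}, {}
    for region in matrix.tumor_regions:
        calls = matrix.calls_of_region(region)
        if not calls:
            warnings.warn(f"region {region} has no called mutations; excluded")
            continue
        per_region[region] = any(is_detected(m) for m in calls)
        private = [m for m in calls if rc[m] == 1]
        if private:
            per_region_private[region] = any(is_detected(m) for m in private)
    frac = sum(per_region.values()) / len(per_region) if per_region else float("nan")
    frac_private = (
        sum(per_region_private.values()) / len(per_region_private)
        if per_region_private
        else float("nan")
    )
    return {
        "fraction_represented": frac,
        "fraction_represented_private_only": frac_private,
        "per_region": per_region,
        "per_region_private": per_region_private,
    }


def af_by_region_count_trend(
    matrix: MultiRegionMatrix, fluid_row: str, min_group: int = 3
) -> dict:
    """Fluid mAF grouped by mutation region-count, with each group
    rank-sum tested (two-sided) against the region-count = 1 group.

    Groups smaller than ``min_group`` are skipped with a note.
    Returns group medians, test statistics and p-values.
    """
    fluid = matrix.af.loc[fluid_row]
    rc = matrix.region_count
    groups = {}
    for count in sorted(rc.unique()):
        vals = fluid[rc[rc == count].index].dropna().to_numpy()
        groups[int(count)] = vals
    notes = []
    usable = {c: v for c, v in groups.items() if len(v) >= min_group}
    skipped = sorted(set(groups) - set(usable))
    if skipped:
        notes.append(f"groups skipped (fewer than {min_group} mutations): {skipped}")
    tests = {}
    if 1 in usable and len(usable) >= 2:
        base = usable[1]
        for count, vals in usable.items():
            if count == 1:
                continue
            stat, p = mannwhitneyu(vals, base, alternative="two-sided")
            tests[count] = {"statistic": float(stat), "p_value": float(p)}
    else:
        notes.append("no region_count=1 baseline group or only one group; no tests run")
    medians = {c: float(np.median(v)) for c, v in usable.items()}
    return {"medians": medians, "tests_vs_count1": tests, "notes": notes, "groups": groups}
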