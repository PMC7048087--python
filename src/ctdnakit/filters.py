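"""Somatic SNV post-filters.

Rule set applied downstream of a somatic caller: callable-region gating
(germline depth strictly > 20x), population allele frequency exclusion
(> 0.02 strict), normal-adjacent tissue exclusion (AF > 0 in any NAT),
the FFPE C:G>A:T sequence-context artifact filter ([C/T]C>A on the
reference strand and its reverse-complement image [G/A]G>T), duplicate
replicate concordance (a variant is real only if called in both
replicates; reported AF is the replicate mean), and panel annotation
filters (synonymous variants and popAF > 1% polymorphisms removed).

Call sets are pandas DataFrames with columns as documented per filter;
every filter returns ``(retained, removed)`` and can log into a
:class:`FilterReport` (input = removed + retained at every stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "callable_mask",
    "filter_callable",
    "filter_population_af",
    "filter_normal_adjacent",
    "ffpe_context_filter",
    "replicate_concordance",
    "panel_annotation_filters",
]


@dataclass
class FilterReport:
    """Per-filter accounting: input, removed, retained counts."""

    stages: list[dict] = field(default_factory=list)

    def log(self, name: str, n_in: int, n_removed: int) -> None:
        self.stages.append(
            {"filter": name, "input": n_in, "removed": n_removed, "retained": n_in - n_removed}
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def _split(calls: pd.DataFrame, remove: pd.Series, name: str, report: FilterReport | None):
    removed = calls.loc[remove].reset_index(drop=True)
    retained = calls.loc[~remove].reset_index(drop=True)
    if report is not None:
        report.log(name, len(calls), int(remove.sum()))
    return retained, removed


def callable_mask(germline_depths: pd.DataFrame, min_depth: int = 20) -> pd.DataFrame:
    """Intervals of the germline depth track strictly above ``min_depth``.

    ``germline_depths`` has columns chrom/start/end/depth (0-based
    half-open windows); adjacent qualifying windows are merged.
    """
    keep = germline_depths.loc[germline_depths["depth"] > min_depth]
    if keep.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    rows = []
    for chrom, grp in keep.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def filter_callable(
    calls: pd.DataFrame, mask: pd.DataFrame, report: FilterReport | None = None
):
    """Drop calls outside the callable mask (1-based ``pos`` column)."""
    inside = np.zeros(len(calls), dtype=bool)
    for _, iv in mask.iterrows():
        inside |= (
            (calls["chrom"] == iv["chrom"])
            & (calls["pos"] - 1 >= iv["start"])
            & (calls["pos"] - 1 < iv["end"])
        ).to_numpy()
    return _split(calls, pd.Series(~inside, index=calls.index), "callable_region", report)


def filter_population_af(
    calls: pd.DataFrame, threshold: float = 0.02, report: FilterReport | None = None
):
    """Remove likely SNPs: population AF strictly above ``threshold``.
    Unannotated (NaN) popAF counts as 0."""
    popaf = calls.get("popaf", pd.Series(0.0, index=calls.index)).fillna(0.0)
    return _split(calls, popaf > threshold, "population_af", report)


def filter_normal_adjacent(
    calls: pd.DataFrame,
    nat_afs: pd.DataFrame | None,
    report: FilterReport | None = None,
):
    """Remove calls with AF > 0 in ANY normal-adjacent tissue sample.

    ``nat_afs`` columns are NAT sample names aligned row-wise with
    ``calls``; when no NAT is available the set is returned unchanged
    with a ``nat_unscreened`` flag column.
    """
    if nat_afs is None or nat_afs.shape[1] == 0:
        out = calls.copy()
        out["nat_unscreened"] = True
        if report is not None:
            report.log("normal_adjacent", len(calls), 0)
        return out, calls.iloc[0:0]
    remove = (nat_afs.to_numpy() > 0).any(axis=1)
    return _split(calls, pd.Series(remove, index=calls.index), "normal_adjacent", report)


def ffpe_context_filter(
    calls: pd.DataFrame, sample_is_ffpe: bool, report: FilterReport | None = None
):
    """FFPE C:G>A:T artifact filter.

    In FFPE-derived call sets, removes C>A calls whose preceding base is
    C or T and G>T calls whose preceding base is G or A (the reverse-
    complement image).  All other calls — and every call from a
    non-FFPE sample — pass through.  Contexts are read on the reference
    strand from the 3-base ``context`` column.
    """
    if not sample_is_ffpe:
        if report is not None:
            report.log("ffpe_context", len(calls), 0)
        return calls.reset_index(drop=True), calls.iloc[0:0]
    is_ca = (calls["ref"] == "C") & (calls["alt"] == "A")
    is_gt = (calls["ref"] == "G") & (calls["alt"] == "T")
    ctx = calls["context"]
    if ((is_ca | is_gt) & (ctx.isna() | (ctx.str.len() != 3))).any():
        raise ValueError("C>A/G>T call without trinucleotide context in FFPE sample")
    preceding = ctx.str[0]
    remove = (is_ca & preceding.isin(["C", "T"])) | (is_gt & preceding.isin(["G", "A"]))
    return _split(calls, remove, "ffpe_context", report)


_KEY = ["chrom", "pos", "ref", "alt"]


def replicate_concordance(
    calls_rep1: pd.DataFrame,
    calls_rep2: pd.DataFrame,
    report: FilterReport | None = None,
) -> pd.DataFrame:
    """Keep only variants identified in both duplicate replicates;
    the reported AF is the mean of the replicate AFs."""
    merged = calls_rep1.merge(
        calls_rep2[_KEY + (["af"] if "af" in calls_rep2 else [])],
        on=_KEY,
        how="inner",
        suffixes=("", "_rep2"),
    )
    if "af" in merged and "af_rep2" in merged:
        merged["af"] = (merged["af"] + merged["af_rep2"]) / 2.0
        merged = merged.drop(columns=["af_rep2"])
    if report is not None:
        report.log("replicate_concordance", len(calls_rep1), len(calls_rep1) - len(merged))
    return merged.reset_index(drop=True)


def panel_annotation_filters(
    calls: pd.DataFrame, popaf_threshold: float = 0.01, report: FilterReport | None = None
):
    """Panel polishing: drop synonymous variants and popAF > 1%
    polymorphisms (strict inequality)."""
    popaf = calls.get("popaf", pd.Series(0.0, index=calls.index)).fillna(0.0)
    synonymous = calls.get("synonymous", pd.Series(False, index=calls.index)).fillna(False)
    remove = synonymous.astype(bool) | (popaf > popaf_threshold)
    return _split(calls, remove, "panel_annotation", report)
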