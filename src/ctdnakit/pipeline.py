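"""Cohort orchestration and association statistics.

Combines per-sample detection calls across assays and fluids (logical
OR, technical failures excluded from numerators and denominators), and
computes the cohort association statistics: Fisher's exact test (the
two-sided "probability <= observed" convention), the Mann-Whitney U
test (exact for small samples), and Spearman correlation of paired
fluid allele fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResultRecord",
    "combine_detection",
    "fisher_2x2",
    "mannwhitney_u",
    "cohort_report",
]


@dataclass
class ResultRecord:
    """One (sample, fluid, assay) detection outcome."""

    sample_id: str
    fluid: str
    assay: str
    statistic: float | None
    threshold: float | None
    detected: bool | None
    technical_fail: bool = False
    ancillary: dict | None = None


def combine_detection(records: list[ResultRecord], scope=None) -> bool | None:
    """Logical OR of detection over the records in scope.

    ``scope`` is an optional predicate on the record (e.g. restrict to
    one fluid).  Technical-failure records are excluded; if every
    in-scope record is a technical failure the result is undefined
    (None) and the patient should be excluded from rates.
    """
    in_scope = [r for r in records if scope is None or scope(r)]
    if not in_scope:
        raise ValueError("no records in scope")
    usable = [r for r in in_scope if not r.technical_fail and r.detected is not None]
    if not usable:
        return None
    return any(r.detected for r in usable)


def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Two-sided by the sum of hypergeometric probabilities not exceeding
    the observed table's.  Degenerate margins give p = 1 by convention.
    Returns ``(p_value, odds_ratio)``.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if t.sum(axis=0).min() == 0 and t.sum(axis=1).min() == 0 and t.sum() == 0:
        return 1.0, float("nan")
    res = stats.fisher_exact(t, alternative="two-sided")
    return float(res.pvalue), float(res.statistic)


def mannwhitney_u(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction.

    Exact enumeration when the combined sample size is at most 12 and
    there are no ties; normal approximation otherwise.
    Returns ``(U statistic, p_value)``.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cohort_report(table: pd.DataFrame) -> dict:
    """Cohort summary from a long-format results table.

    ``table`` has one row per (patient, fluid, assay) with columns
    ``patient fluid assay detected technical_fail`` and optionally
    ``gmaf``, plus per-patient covariate columns (``tumor_size_cm``,
    ``thrombus`` ...) repeated on each row.

    Reports detection rates (explicit numerator/denominator; technical
    failures excluded from both), per-assay and any-assay/any-fluid
    rates, the tumor-size Mann-Whitney test, the thrombus Fisher test,
    and Spearman correlation of plasma vs urine gmAF where both exist.
    """
    required = {"patient", "fluid", "assay", "detected", "technical_fail"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must carry columns {sorted(required)}")
    report: dict = {"rates": {}, "associations": {}}

    def rate(sub: pd.DataFrame) -> dict:
        ok = sub.loc[~sub["technical_fail"]]
        num = int(ok["detected"].sum())
        den = int(len(ok))
        return {"detected": num, "eligible": den, "rate": num / den if den else float("nan")}

    for (fluid, assay), sub in table.groupby(["fluid", "assay"]):
        report["rates"][f"{fluid}:{assay}"] = rate(sub)

    per_patient = {}
    for patient, sub in table.groupby("patient"):
        records = [
            ResultRecord(
                sample_id=str(patient),
                fluid=r["fluid"],
                assay=r["assay"],
                statistic=None,
                threshold=None,
                detected=bool(r["detected"]),
                technical_fail=bool(r["technical_fail"]),
            )
            for _, r in sub.iterrows()
        ]
        per_patient[patient] = combine_detection(records)
    usable = {p: d for p, d in per_patient.items() if d is not None}
    excluded = sorted(set(per_patient) - set(usable))
    report["rates"]["any_assay_any_fluid"] = {
        "detected": int(sum(usable.values())),
        "eligible": len(usable),
        "rate": sum(usable.values()) / len(usable) if usable else float("nan"),
        "patients_excluded_all_technical_fail": excluded,
    }

    covs = table.drop_duplicates("patient").set_index("patient")
    if "tumor_size_cm" in covs:
        det = [covs.loc[p, "tumor_size_cm"] for p, d in usable.items() if d]
        und = [covs.loc[p, "tumor_size_cm"] for p, d in usable.items() if not d]
        if det and und:
            u, p = mannwhitney_u(det, und)
            report["associations"]["tumor_size_mannwhitney"] = {"U": u, "p_value": p}
    if "thrombus" in covs:
        tab = np.zeros((2, 2), dtype=int)
        for patient, d in usable.items():
            thr = bool(covs.loc[patient, "thrombus"])
            tab[0 if d else 1, 0 if thr else 1] += 1
        p, orr = fisher_2x2(tab)
        report["associations"]["thrombus_fisher"] = {
            "table": tab.tolist(),
            "p_value": p,
            "odds_ratio": orr,
        }
    if "gmaf" in table.columns:
        g = table.pivot_table(index="patient", columns="fluid", values="gmaf")
        if {"plasma", "urine"}.issubset(g.columns):
            both = g[["plasma", "urine"]].dropna()
            if len(both) >= 3:
                rho, p = stats.spearmanr(both["plasma"], both["urine"])
                report["associations"]["plasma_urine_gmaf_spearman"] = {
                    "rho": float(rho),
                    "p_value": float(p),
                    "n": int(len(both)),
                }
    return report
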