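"""Fragment-length analytics and random-forest triage.

In-silico size selection (90-150 bp) enriches tumor-derived cfDNA;
the ten fragmentation features summarize a sample's length histogram
(plus its tMAD) and feed a random-forest model that triages samples for
the expensive targeted assay at a 50% probability threshold.

All length ranges are inclusive at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cna import (
    PreparedControls,
    TMADResult,
    prepare_controls,
    score_sample,
)
from .genome import GenomeModel
from .lengths import LENGTH_MAX, LENGTH_MIN

__all__ = [
    "LengthHistogram",
    "FragmentomicsFeatures",
    "TriageModel",
    "TriageResult",
    "size_select",
    "size_selected_tmad",
    "proportion_in_range",
    "amplitude_10bp",
    "compute_features",
    "train_triage_model",
    "predict_triage",
    "FEATURE_NAMES",
]

RATIO_SENTINEL = 1e6
_EPS = 1e-12

FEATURE_NAMES = [
    "t_mad",
    "amplitude_10bp",
    "p_20_150",
    "p_160_180",
    "ratio_20_150_over_160_180",
    "p_100_150",
    "ratio_100_150_over_163_169",
    "p_180_220",
    "p_250_320",
    "ratio_20_150_over_180_220",
]


@dataclass
class LengthHistogram:
    """Counts per 1-bp fragment length over [20, 700]."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        if len(self.counts) != LENGTH_MAX - LENGTH_MIN + 1:
            raise ValueError("histogram must cover lengths 20..700")
        if (self.counts < 0).any():
            raise ValueError("histogram counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_fragments(cls, fragments: pd.DataFrame) -> "LengthHistogram":
        lengths = np.clip(fragments["length"].to_numpy(), LENGTH_MIN, LENGTH_MAX)
        return cls(np.bincount(lengths - LENGTH_MIN, minlength=LENGTH_MAX - LENGTH_MIN + 1))


def size_select(fragments: pd.DataFrame, lo: int = 90, hi: int = 150) -> pd.DataFrame:
    """Keep fragments with lo <= length <= hi (inclusive both ends)."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    keep = (fragments["length"] >= lo) & (fragments["length"] <= hi)
    return fragments.loc[keep].reset_index(drop=True)


def proportion_in_range(hist: LengthHistogram, lo: int, hi: int) -> float:
    """count(lo..hi) / total, inclusive bounds."""
    if hist.total == 0:
        raise ValueError("empty histogram")
    lengths = np.arange(LENGTH_MIN, LENGTH_MAX + 1)
    sel = (lengths >= lo) & (lengths <= hi)
    return float(hist.counts[sel].sum() / hist.total)


def amplitude_10bp(hist: LengthHistogram, lo: int = 76, hi: int = 150) -> float:
    """Amplitude of the 10-bp periodicity of the length density.

    The histogram restricted to [76, 150] is detrended by an 11-bp
    centered moving average (which removes the smooth nucleosomal trend
    while attenuating a period-10 comb by a fixed, analytically known
    factor that is compensated for), then the discrete Fourier
    magnitude at frequency 1/10 bp^-1 is read off: ~0 for any smooth
    comb-free density, ~A for a density modulated by
    ``1 + A*cos(2*pi*L/10)``.  Clipped to [0, 1].
    """
    lengths = np.arange(LENGTH_MIN, LENGTH_MAX + 1)
    sel = (lengths >= lo) & (lengths <= hi)
    h = hist.counts[sel].astype(float)
    if h.sum() == 0:
        raise ValueError("no fragments in the periodicity window")
    k = 11
    padded = np.pad(h, k // 2, mode="reflect")
    trend = np.convolve(padded, np.ones(k) / k, mode="valid")
    trend = np.where(trend > 0, trend, 1.0)
    y = h / trend - 1.0
    ls = lengths[sel]
    coef = np.sum(y * np.exp(-2j * np.pi * ls / 10.0))
    # the 11-point mean passes a fraction r of a period-10 comb;
    # detrending therefore scales the comb by (1 - r) — undo it
    r = np.sin(k * np.pi / 10.0) / (k * np.sin(np.pi / 10.0))
    amp = 2.0 * np.abs(coef) / len(ls) / (1.0 - r)
    return float(np.clip(amp, 0.0, 1.0))


def _ratio(num: float, den: float) -> tuple[float, bool]:
    if den <= 0:
        return min(num / _EPS, RATIO_SENTINEL), True
    return num / den, False


@dataclass
class FragmentomicsFeatures:
    """The ten fragmentation features, in canonical order."""

    t_mad: float
    amplitude_10bp: float
    p_20_150: float
    p_160_180: float
    ratio_20_150_over_160_180: float
    p_100_150: float
    ratio_100_150_over_163_169: float
    p_180_220: float
    p_250_320: float
    ratio_20_150_over_180_220: float
    sentinel_flags: tuple[str, ...] = ()

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


def compute_features(
    fragments: pd.DataFrame, tmad_result: TMADResult | float
) -> FragmentomicsFeatures:
    """All ten features from a fragment table plus the unselected tMAD."""
    if len(fragments) < 1000:
        raise ValueError("need at least 1000 fragments for stable features")
    hist = LengthHistogram.from_fragments(fragments)
    tmad = tmad_result.tmad_score if isinstance(tmad_result, TMADResult) else float(tmad_result)

    p = lambda lo, hi: proportion_in_range(hist, lo, hi)  # noqa: E731
    p20_150, p160_180 = p(20, 150), p(160, 180)
    p100_150, p163_169 = p(100, 150), p(163, 169)
    p180_220, p250_320 = p(180, 220), p(250, 320)
    flags = []
    r1, f1 = _ratio(p20_150, p160_180)
    r2, f2 = _ratio(p100_150, p163_169)
    r3, f3 = _ratio(p20_150, p180_220)
    for flagged, name in (
        (f1, "ratio_20_150_over_160_180"),
        (f2, "ratio_100_150_over_163_169"),
        (f3, "ratio_20_150_over_180_220"),
    ):
        if flagged:
            flags.append(name)
    return FragmentomicsFeatures(
        t_mad=tmad,
        amplitude_10bp=amplitude_10bp(hist),
        p_20_150=p20_150,
        p_160_180=p160_180,
        ratio_20_150_over_160_180=r1,
        p_100_150=p100_150,
        ratio_100_150_over_163_169=r2,
        p_180_220=p180_220,
        p_250_320=p250_320,
        ratio_20_150_over_180_220=r3,
        sentinel_flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# size-selected tMAD re-analysis
# ---------------------------------------------------------------------------


@dataclass
class SizeSelectedTMAD:
    result: TMADResult
    eligible: bool
    n_selected: int
    enrichment: float | None  # size-selected tMAD / unselected tMAD


def size_selected_tmad(
    fragments: pd.DataFrame,
    controls: list[pd.DataFrame] | PreparedControls,
    genome: GenomeModel | None = None,
    unselected_tmad: float | None = None,
    lo: int = 90,
    hi: int = 150,
    bin_bp: int = 500_000,
    downsample_n: int = 2_000_000,
    min_fragments: int = 2_000_000,
    seed: int = 0,
) -> SizeSelectedTMAD:
    """tMAD re-analysis after in-silico size selection.

    Pipeline: select fragments in [lo, hi], require at least
    ``min_fragments`` (else the sample is ineligible and carries no
    score), downsample to ``downsample_n``, bin at 500 kb and score
    against an identically size-selected, downsampled control cohort.
    The enrichment factor is the size-selected tMAD divided by the
    unselected tMAD when both are defined.

    ``controls`` may be raw control fragment tables (which will be
    size-selected here) or an already-prepared size-selected cohort.
    """
    selected = size_select(fragments, lo, hi)
    n_sel = len(selected)
    if n_sel < min_fragments:
        res = TMADResult(
            tmad_score=None,
            threshold=None,
            detected=None,
            bin_bp=bin_bp,
            reads_used=n_sel,
            normalization_mode="control",
            eligible=False,
        )
        return SizeSelectedTMAD(result=res, eligible=False, n_selected=n_sel, enrichment=None)
    if isinstance(controls, PreparedControls):
        prepared = controls
    else:
        if genome is None:
            raise ValueError("genome required when controls are raw fragment tables")
        prepared = prepare_controls(
            [size_select(c, lo, hi) for c in controls],
            genome,
            bin_bp=bin_bp,
            downsample_n=downsample_n,
            seed=seed,
        )
    res = score_sample(selected, prepared, seed=seed + 1)
    enrichment = None
    if unselected_tmad is not None and unselected_tmad > 0:
        enrichment = res.tmad_score / unselected_tmad
    return SizeSelectedTMAD(result=res, eligible=True, n_selected=n_sel, enrichment=enrichment)


# ---------------------------------------------------------------------------
# random-forest triage
# ---------------------------------------------------------------------------


@dataclass
class TriageModel:
    classifier: RandomForestClassifier
    seed: int
    feature_names: tuple[str, ...] = tuple(FEATURE_NAMES)
    version: str = "1"


@dataclass
class TriageResult:
    probability_cancer: float
    triaged_positive: bool  # strictly > 0.5


def train_triage_model(
    feature_table: pd.DataFrame,
    labels,
    seed: int,
    n_estimators: int = 500,
    min_per_class: int = 20,
) -> TriageModel:
    """Train the triage random forest on a labeled feature table.

    ``feature_table`` must contain the ten canonical feature columns;
    ``labels`` are binary (1 = cancer).  Requires at least
    ``min_per_class`` samples per class.
    """
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < min_per_class:
        raise ValueError(f"need >= {min_per_class} samples per class")
    X = feature_table[FEATURE_NAMES].to_numpy()
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(X, y)
    return TriageModel(classifier=clf, seed=seed)


def predict_triage(model: TriageModel, features: FragmentomicsFeatures) -> TriageResult:
    """Probability of cancer (fraction of trees voting cancer) and the
    50%-threshold triage flag (strictly greater than 0.5)."""
    prob = float(model.classifier.predict_proba(features.to_array()[None, :])[0, 1])
    return TriageResult(probability_cancer=prob, triaged_positive=prob > 0.5)
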