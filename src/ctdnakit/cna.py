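"""Shallow-WGS copy-number deviation scoring (tMAD).

Pipeline: allocate fragments to equal-width genomic bins by midpoint,
correct bin counts for GC content (decile-median) and mappability,
normalize against a healthy-control reference (or the sample's own
mean), segment the log2-ratio track with binary change-point search,
and summarize SCNA burden as the trimmed median absolute deviation of
the segmented bins from log2R = 0 (tMAD).  "Trimmed" means blacklisted
and low-mappability bins are excluded before the median.

Detection uses the cohort-maximum rule: a sample is SCNA-positive iff
its tMAD strictly exceeds the largest tMAD observed in the healthy
control cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel

__all__ = [
    "BinTrack",
    "BinCounts",
    "NormalizedProfile",
    "Segment",
    "TMADResult",
    "PreparedControls",
    "build_bin_track",
    "count_fragments_in_bins",
    "correct_gc_mappability",
    "normalize",
    "segment_profile",
    "compute_tmad",
    "detection_threshold_from_controls",
    "downsample_fragments",
    "prepare_controls",
    "run_tmad_assay",
]

MIN_MAPPABILITY = 0.5
DEFAULT_SEGMENT_PENALTY = 4.0


@dataclass
class BinTrack:
    """Equal-width non-overlapping bins tiling the genome."""

    bin_bp: int
    chrom: np.ndarray  # per-bin chromosome name
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray
    mappability: np.ndarray
    blacklisted: np.ndarray  # bool
    short: np.ndarray  # bool: truncated final bin of a chromosome

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def base_excluded(self) -> np.ndarray:
        """Bins excluded a priori: blacklist, short tail, low mappability."""
        return self.blacklisted | self.short | (self.mappability < MIN_MAPPABILITY)


@dataclass
class BinCounts:
    track: BinTrack
    counts: np.ndarray
    total_fragments: int
    n_rejected: int = 0


@dataclass
class NormalizedProfile:
    track: BinTrack
    log2r: np.ndarray  # NaN on excluded bins
    excluded: np.ndarray
    mode: str  # "control" or "self"


@dataclass
class Segment:
    chrom: str
    start: int  # bp, from first member bin
    end: int  # bp, from last member bin
    bin_indices: np.ndarray  # indices into the profile's bin arrays
    mean_log2r: float

    @property
    def n_bins(self) -> int:
        return len(self.bin_indices)


@dataclass
class TMADResult:
    tmad_score: float | None
    threshold: float | None
    detected: bool | None
    bin_bp: int
    reads_used: int
    normalization_mode: str
    eligible: bool = True
    control_scores: list[float] = field(default_factory=list)
    profile: NormalizedProfile | None = None
    segments: list[Segment] | None = None


# ---------------------------------------------------------------------------
# binning and correction
# ---------------------------------------------------------------------------


def build_bin_track(genome: GenomeModel, bin_bp: int) -> BinTrack:
    """Tile the genome with bins of ``bin_bp``, aggregating the genome's
    GC/mappability windows and blacklist into per-bin values."""
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    chroms, starts, ends, gcs, maps, blk, short = [], [], [], [], [], [], []
    wbp = genome.window_bp
    bl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in genome.blacklist:
        bl_by_chrom.setdefault(c, []).append((s, e))
    for name, size in genome.chromosomes:
        gc_win = genome.gc[name]
        map_win = genome.mappability[name]
        for s in range(0, size, bin_bp):
            e = min(s + bin_bp, size)
            w0, w1 = s // wbp, max(s // wbp + 1, min(e, size) // wbp)
            chroms.append(name)
            starts.append(s)
            ends.append(e)
            gcs.append(float(gc_win[w0:w1].mean()))
            maps.append(float(map_win[w0:w1].mean()))
            bl_bp = sum(
                max(0, min(be, e) - max(bs, s)) for bs, be in bl_by_chrom.get(name, ())
            )
            blk.append(bl_bp > 0.5 * (e - s))
            short.append(e - s < bin_bp)
    return BinTrack(
        bin_bp=bin_bp,
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        gc=np.array(gcs),
        mappability=np.array(maps),
        blacklisted=np.array(blk, dtype=bool),
        short=np.array(short, dtype=bool),
    )


def count_fragments_in_bins(fragments: pd.DataFrame, track: BinTrack) -> BinCounts:
    """Assign each fragment to the bin containing its midpoint.

    Midpoint exactly on a bin edge belongs to the bin starting there
    (half-open convention).  Fragments on contigs absent from the track
    are dropped and counted in ``n_rejected``.
    """
    counts = np.zeros(track.n_bins, dtype=np.int64)
    offsets: dict[str, tuple[int, int]] = {}
    for name in pd.unique(track.chrom):
        idx = np.flatnonzero(track.chrom == name)
        offsets[name] = (int(idx[0]), int(idx[-1]))
    rejected = 0
    mids = ((fragments["start"].to_numpy() + fragments["end"].to_numpy()) // 2).astype(
        np.int64
    )
    known = np.zeros(len(fragments), dtype=bool)
    for name, (first, last) in offsets.items():
        mask = (fragments["chrom"] == name).to_numpy()
        known |= mask
        if not mask.any():
            continue
        b = first + mids[mask] // track.bin_bp
        ok = b <= last
        rejected += int((~ok).sum())
        counts += np.bincount(b[ok], minlength=track.n_bins)
    rejected += int((~known).sum())
    return BinCounts(
        track=track,
        counts=counts,
        total_fragments=len(fragments),
        n_rejected=rejected,
    )


def correct_gc_mappability(
    bin_counts: BinCounts, n_deciles: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """GC decile-median correction followed by mappability division.

    Each bin's count is divided by the median count of bins in the same
    GC decile and rescaled by the overall median, then divided by the
    bin's mappability.  Bins with mappability below 0.5, blacklisted
    bins and short tail bins are excluded (NaN).

    Returns ``(corrected_values, excluded_mask)``.
    """
    track = bin_counts.track
    raw = bin_counts.counts.astype(float)
    excluded = track.base_excluded.copy()
    ok = ~excluded
    if ok.sum() < n_deciles:
        raise ValueError("too few usable bins for GC correction")
    gc_ok = track.gc[ok]
    edges = np.quantile(gc_ok, np.linspace(0, 1, n_deciles + 1)[1:-1])
    decile = np.searchsorted(edges, track.gc, side="right")
    overall_med = np.median(raw[ok])
    corrected = np.full(track.n_bins, np.nan)
    for d in range(n_deciles):
        sel = ok & (decile == d)
        if not sel.any():
            continue
        med = np.median(raw[sel])
        if med == 0:
            warnings.warn(f"GC decile {d} has zero median count; using overall median")
            med = overall_med if overall_med > 0 else 1.0
        corrected[sel] = raw[sel] / med * overall_med
    corrected[ok] = corrected[ok] / track.mappability[ok]
    return corrected, excluded


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize(
    corrected_case: np.ndarray,
    track: BinTrack,
    excluded: np.ndarray,
    reference: np.ndarray | None = None,
    mode: str = "control",
) -> NormalizedProfile:
    """Per-bin log2 ratio of the case against a reference.

    mode="control": both case and reference are scaled to equal totals
    over shared usable bins, then ``log2(case/ref)``; reference bins at
    0 are excluded with a warning.  mode="self": ``log2(case / mean)``,
    mean-centered so the profile averages to 0.
    """
    excluded = excluded.copy()
    log2r = np.full(track.n_bins, np.nan)
    if mode == "control":
        if reference is None:
            raise ValueError("mode='control' requires a reference profile")
        excluded |= ~np.isfinite(reference)
        zero_ref = (~excluded) & (reference == 0)
        if zero_ref.any():
            warnings.warn(f"{int(zero_ref.sum())} reference bins at 0 excluded")
            excluded |= zero_ref
        ok = ~excluded & np.isfinite(corrected_case)
        case = corrected_case / np.nanmean(corrected_case[ok])
        ref = reference / np.nanmean(reference[ok])
        with np.errstate(divide="ignore", invalid="ignore"):
            log2r[ok] = np.log2(case[ok] / ref[ok])
        excluded |= ~np.isfinite(log2r) & ~excluded
        log2r[excluded] = np.nan
    elif mode == "self":
        ok = ~excluded & np.isfinite(corrected_case) & (corrected_case > 0)
        excluded = ~ok
        vals = corrected_case[ok]
        log2r[ok] = np.log2(vals / vals.mean())
        log2r[ok] -= log2r[ok].mean()
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return NormalizedProfile(track=track, log2r=log2r, excluded=excluded, mode=mode)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _best_split(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int, min_size: int):
    """Best single change-point of y[i:j] by within-segment SSE.

    Returns (gain, k) where k is the split index (segment boundary) and
    gain is the SSE reduction relative to no split.
    """
    n = j - i
    if n < 2 * min_size:
        return 0.0, -1
    total = prefix[j] - prefix[i]
    total2 = prefix2[j] - prefix2[i]
    sse0 = total2 - total**2 / n
    ks = np.arange(i + min_size, j - min_size + 1)
    left_n = ks - i
    right_n = j - ks
    left_sum = prefix[ks] - prefix[i]
    right_sum = total - left_sum
    sse_split = (
        (prefix2[ks] - prefix2[i]) - left_sum**2 / left_n
        + (total2 - (prefix2[ks] - prefix2[i])) - right_sum**2 / right_n
    )
    best = int(np.argmin(sse_split))
    return float(sse0 - sse_split[best]), int(ks[best])


def _binary_segment(y: np.ndarray, threshold: float, min_size: int) -> list[tuple[int, int]]:
    prefix = np.concatenate(([0.0], np.cumsum(y)))
    prefix2 = np.concatenate(([0.0], np.cumsum(y**2)))
    # guard against float rounding producing spurious tiny "gains"
    eps = 1e-9 * max(1.0, float(prefix2[-1]))
    out: list[tuple[int, int]] = []
    stack = [(0, len(y))]
    while stack:
        i, j = stack.pop()
        gain, k = _best_split(prefix, prefix2, i, j, min_size)
        if k >= 0 and gain > threshold + eps:
            stack.append((k, j))
            stack.append((i, k))
        else:
            out.append((i, j))
    return sorted(out)


def _noise_sigma2(y: np.ndarray) -> float:
    """Robust noise variance from successive differences."""
    if len(y) < 3:
        return float(np.var(y)) if len(y) else 0.0
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    sigma = mad / 0.6745 / np.sqrt(2.0)
    return float(sigma**2)


def segment_profile(
    profile: NormalizedProfile,
    penalty: float = DEFAULT_SEGMENT_PENALTY,
    min_size: int = 3,
) -> list[Segment]:
    """Piecewise-constant fit via recursive binary change-point search.

    A split is accepted when its SSE reduction exceeds
    ``penalty * sigma^2 * ln(n)`` (a BIC-style criterion), with the
    noise variance estimated robustly from successive bin differences.
    Chromosomes are segmented independently on their non-excluded bins.
    """
    ok = ~profile.excluded & np.isfinite(profile.log2r)
    n_ok = int(ok.sum())
    if n_ok == 0:
        raise ValueError("no usable bins to segment")
    if n_ok < 10:
        warnings.warn("fewer than 10 usable bins; returning a single segment")
    sigma2 = _noise_sigma2(profile.log2r[ok])
    threshold = penalty * sigma2 * np.log(max(n_ok, 2))
    segments: list[Segment] = []
    track = profile.track
    for name in pd.unique(track.chrom):
        idx = np.flatnonzero((track.chrom == name) & ok)
        if idx.size == 0:
            continue
        y = profile.log2r[idx]
        if idx.size < 2 * min_size or idx.size < 10:
            pieces = [(0, idx.size)]
        else:
            pieces = _binary_segment(y, threshold, min_size)
        for a, b in pieces:
            member = idx[a:b]
            segments.append(
                Segment(
                    chrom=name,
                    start=int(track.start[member[0]]),
                    end=int(track.end[member[-1]]),
                    bin_indices=member,
                    mean_log2r=float(y[a:b].mean()),
                )
            )
    return segments


def segmented_values(profile: NormalizedProfile, segments: list[Segment]) -> np.ndarray:
    """Per-bin segmented value (its segment's mean); NaN on excluded bins."""
    vals = np.full(profile.track.n_bins, np.nan)
    for seg in segments:
        vals[seg.bin_indices] = seg.mean_log2r
    return vals


# ---------------------------------------------------------------------------
# tMAD statistic and detection
# ---------------------------------------------------------------------------


def compute_tmad(profile: NormalizedProfile, segments: list[Segment]) -> float:
    """Median absolute deviation of segmented bins from log2R = 0.

    The deviation is measured from zero (the copy-neutral state), not
    from the sample median; trimming is the exclusion of blacklisted /
    low-mappability bins already applied upstream.
    """
    vals = segmented_values(profile, segments)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no segmented bins to summarize")
    return float(np.median(np.abs(vals)))


def detection_threshold_from_controls(control_tmads) -> float:
    """Maximum tMAD over the healthy cohort; detection is strictly above."""
    scores = list(control_tmads)
    if len(scores) < 2:
        raise ValueError("need at least 2 control scores")
    return float(max(scores))


def downsample_fragments(
    fragments: pd.DataFrame, target_n: int, seed: int
) -> pd.DataFrame:
    """Seeded simple random sample (without replacement) of exactly
    ``target_n`` fragments; identity with a warning when fewer exist."""
    n = len(fragments)
    if target_n >= n:
        if target_n > n:
            warnings.warn(f"requested {target_n} fragments but only {n} available")
        return fragments
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=target_n, replace=False))
    return fragments.iloc[idx].reset_index(drop=True)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class PreparedControls:
    """A processed healthy cohort: reference profile and tMAD threshold."""

    track: BinTrack
    reference: np.ndarray
    excluded: np.ndarray
    control_tmads: list[float]
    threshold: float
    downsample_n: int
    mode: str


def _process_sample(fragments, track, downsample_n, seed):
    frags = downsample_fragments(fragments, downsample_n, seed=seed)
    counts = count_fragments_in_bins(frags, track)
    corrected, excluded = correct_gc_mappability(counts)
    return corrected, excluded, len(frags)


def prepare_controls(
    control_fragments: list[pd.DataFrame],
    genome: GenomeModel,
    bin_bp: int = 30_000,
    downsample_n: int = 10_000_000,
    mode: str = "control",
    reference: str = "median",
    penalty: float = DEFAULT_SEGMENT_PENALTY,
    seed: int = 0,
) -> PreparedControls:
    """Process a healthy cohort once: corrected profiles, the cohort
    reference (median profile by default, or the first sample with
    ``reference="single"``), each control's tMAD, and the max threshold.
    """
    if len(control_fragments) < 2:
        raise ValueError("need at least 2 controls")
    track = build_bin_track(genome, bin_bp)
    profiles, excl_any = [], track.base_excluded.copy()
    for i, frags in enumerate(control_fragments):
        corr, excl, _ = _process_sample(frags, track, downsample_n, seed=seed + i)
        scale = np.nanmean(corr[~excl])
        profiles.append(corr / scale)
        excl_any |= excl
    stack = np.vstack(profiles)
    ref = np.full(stack.shape[1], np.nan)
    if reference == "median":
        ok = ~excl_any
        ref[ok] = np.nanmedian(stack[:, ok], axis=0)
    elif reference == "single":
        ref = profiles[0].copy()
        ref[excl_any] = np.nan
    else:
        raise ValueError("reference must be 'median' or 'single'")
    tmads = []
    for corr in profiles:
        prof = normalize(corr, track, excl_any.copy(), reference=ref, mode=mode) \
            if mode == "control" else normalize(corr, track, excl_any.copy(), mode="self")
        segs = segment_profile(prof, penalty=penalty)
        tmads.append(compute_tmad(prof, segs))
    return PreparedControls(
        track=track,
        reference=ref,
        excluded=excl_any,
        control_tmads=tmads,
        threshold=detection_threshold_from_controls(tmads),
        downsample_n=downsample_n,
        mode=mode,
    )


def score_sample(
    fragments: pd.DataFrame,
    prepared: PreparedControls,
    penalty: float = DEFAULT_SEGMENT_PENALTY,
    seed: int = 0,
    keep_profile: bool = False,
) -> TMADResult:
    """Score one case against a prepared control cohort."""
    track = prepared.track
    corr, excl, used = _process_sample(fragments, track, prepared.downsample_n, seed)
    excl = excl | prepared.excluded
    if prepared.mode == "control":
        prof = normalize(corr, track, excl, reference=prepared.reference, mode="control")
    else:
        prof = normalize(corr, track, excl, mode="self")
    segs = segment_profile(prof, penalty=penalty)
    score = compute_tmad(prof, segs)
    return TMADResult(
        tmad_score=score,
        threshold=prepared.threshold,
        detected=score > prepared.threshold,
        bin_bp=track.bin_bp,
        reads_used=used,
        normalization_mode=prepared.mode,
        control_scores=list(prepared.control_tmads),
        profile=prof if keep_profile else None,
        segments=segs if keep_profile else None,
    )


def run_tmad_assay(
    fragments: pd.DataFrame,
    controls: list[pd.DataFrame],
    genome: GenomeModel,
    bin_bp: int = 30_000,
    downsample_n: int = 10_000_000,
    mode: str = "control",
    reference: str = "median",
    penalty: float = DEFAULT_SEGMENT_PENALTY,
    seed: int = 0,
    keep_profile: bool = False,
) -> TMADResult:
    """One-shot tMAD assay: process the cohort, then score the case.

    Defaults mirror the unselected plasma protocol: 10 million reads,
    30 kb bins, control-cohort normalization.
    """
    prepared = prepare_controls(
        controls,
        genome,
        bin_bp=bin_bp,
        downsample_n=downsample_n,
        mode=mode,
        reference=reference,
        penalty=penalty,
        seed=seed,
    )
    return score_sample(
        fragments, prepared, penalty=penalty, seed=seed + len(controls),
        keep_profile=keep_profile,
    )
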