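"""Fragment-level cfDNA simulator.

Generates the datasets every downstream assay consumes: whole-genome
fragment tables with copy-number dilution, GC bias and a bimodal
tumor/normal length mixture; healthy control cohorts; targeted UMI read
sets at patient-specific loci with a trinucleotide-context background
error model; and multi-region tumor mutation matrices with truncal,
shared and private clones.

The dilution model is the standard ctDNA mixture: a genomic segment
carried at ``c`` total copies by the tumor, in a sample of tumor
fraction ``tf``, has expected relative coverage ``(2*(1-tf) + c*tf)/2``
against the diploid background.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .lengths import FragmentLengthModel

__all__ = [
    "SCNASegment",
    "TargetLocus",
    "SimulationConfig",
    "FRAGMENT_COLUMNS",
    "simulate_sample",
    "simulate_control_cohort",
    "simulate_targeted_reads",
    "simulate_multiregion_tumor",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "length", "source", "umi", "locus_alleles"]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SCNASegment:
    """A somatic copy-number segment carried by the tumor.

    ``tumor_total_copies`` is the total copy number in tumor cells
    (diploid background = 2); the interval is 0-based half-open.
    """

    chrom: str
    start: int
    end: int
    tumor_total_copies: int

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError("segment interval must be non-empty with start >= 0")
        if self.tumor_total_copies < 0:
            raise ValueError("tumor_total_copies must be >= 0")


@dataclass(frozen=True)
class TargetLocus:
    """A patient-specific SNV targeted by the deep assay."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    context: str  # trinucleotide, middle base == ref
    tissue_maf: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref must differ from alt")
        if len(self.context) != 3 or self.context[1] != self.ref:
            raise ValueError("context must be 3 bases with middle == ref")
        if not 0.0 <= self.tissue_maf <= 1.0:
            raise ValueError("tissue_maf must lie in [0, 1]")

    @property
    def error_class(self) -> str:
        return f"{self.context}>{self.alt}"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulated sample.  ``seed`` is mandatory."""

    seed: int
    tumor_fraction: float = 0.0
    n_fragments: int = 100_000
    scna_segments: tuple[SCNASegment, ...] = ()
    length_model: FragmentLengthModel = field(default_factory=FragmentLengthModel)
    target_loci: tuple[TargetLocus, ...] = ()
    background_error_rates: tuple[tuple[str, float], ...] = ()
    default_error_rate: float = 1e-4
    umi_family_size_distribution: tuple[tuple[int, float], ...] = (
        (1, 0.15),
        (2, 0.30),
        (3, 0.25),
        (4, 0.20),
        (5, 0.10),
    )
    read_error_rate: float = 1e-3
    gc_bias_strength: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be positive")
        if not 0.0 <= self.gc_bias_strength <= 1.0:
            raise ValueError("gc_bias_strength must lie in [0, 1]")
        for _, rate in self.background_error_rates:
            if not 0.0 <= rate < 1.0:
                raise ValueError("error rates must lie in [0, 1)")
        if not 0.0 <= self.default_error_rate < 1.0:
            raise ValueError("default_error_rate must lie in [0, 1)")
        probs = [p for _, p in self.umi_family_size_distribution]
        if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
            raise ValueError("umi_family_size_distribution must be a distribution")

    def error_rate_for(self, error_class: str) -> float:
        for cls, rate in self.background_error_rates:
            if cls == error_class:
                return rate
        return self.default_error_rate


# ---------------------------------------------------------------------------
# whole-genome fragment sampling
# ---------------------------------------------------------------------------


def _region_table(config: SimulationConfig, genome: GenomeModel):
    """Flatten the genome into (chrom_idx, start, end, copies) regions."""
    sizes = dict(genome.chromosomes)
    for seg in config.scna_segments:
        if seg.chrom not in sizes or seg.end > sizes[seg.chrom]:
            raise ValueError(f"SCNA segment {seg} outside the genome")
    rows = []
    for ci, (name, size) in enumerate(genome.chromosomes):
        cuts = {0, size}
        for seg in config.scna_segments:
            if seg.chrom == name:
                cuts.update((seg.start, seg.end))
        edges = sorted(cuts)
        for a, b in zip(edges[:-1], edges[1:]):
            copies = 2
            for seg in config.scna_segments:
                if seg.chrom == name and seg.start <= a and b <= seg.end:
                    copies = seg.tumor_total_copies
            rows.append((ci, a, b, copies))
    tab = np.array(rows, dtype=float)
    return tab  # columns: chrom_idx, start, end, copies


def _sample_midpoints(
    n: int,
    region_tab: np.ndarray,
    weights: np.ndarray,
    genome: GenomeModel,
    gc_bias_strength: float,
    rng: np.random.Generator,
):
    """Sample n (chrom_idx, midpoint) pairs with region weights and GC thinning."""
    cum = np.cumsum(weights)
    total = cum[-1]
    if total <= 0:
        raise ValueError("no genomic mass to sample from")
    gc_tracks = [genome.gc[name] for name, _ in genome.chromosomes]
    wbp = genome.window_bp
    chroms_out: list[np.ndarray] = []
    mids_out: list[np.ndarray] = []
    got = 0
    while got < n:
        m = max(int((n - got) * 1.3) + 64, 64)
        ridx = np.searchsorted(cum, rng.random(m) * total, side="right")
        starts = region_tab[ridx, 1]
        lens = region_tab[ridx, 2] - starts
        mids = (starts + rng.random(m) * lens).astype(np.int64)
        cidx = region_tab[ridx, 0].astype(np.int64)
        if gc_bias_strength > 0:
            gc = np.empty(m)
            for ci in np.unique(cidx):
                mask = cidx == ci
                gc[mask] = gc_tracks[ci][mids[mask] // wbp]
            accept = np.clip(1.0 + 2.0 * gc_bias_strength * (gc - 0.5), 0.2, 1.0)
            keep = rng.random(m) < accept
            cidx, mids = cidx[keep], mids[keep]
        chroms_out.append(cidx)
        mids_out.append(mids)
        got += len(mids)
    cidx = np.concatenate(chroms_out)[:n]
    mids = np.concatenate(mids_out)[:n]
    return cidx, mids


def simulate_sample(config: SimulationConfig, genome: GenomeModel) -> pd.DataFrame:
    """Simulate one cfDNA sample as a fragment table.

    Returns a DataFrame with columns ``chrom start end length source umi
    locus_alleles`` sorted by genomic position.  Exactly
    ``config.n_fragments`` rows are emitted.  Tumor-origin probability
    per fragment is ``tf``-weighted by local segment copy number; tumor
    and normal fragments draw lengths from their respective mixture
    components; start positions are thinned against the GC track.
    """
    if not genome.chromosomes:
        raise ValueError("empty genome")
    rng = np.random.default_rng(config.seed)
    tf = config.tumor_fraction
    region_tab = _region_table(config, genome)
    seg_len = region_tab[:, 2] - region_tab[:, 1]
    g_total = seg_len.sum()
    mean_copy = float((seg_len * region_tab[:, 3] / 2.0).sum() / g_total)

    p_tumor = tf * mean_copy / (tf * mean_copy + (1 - tf)) if tf > 0 else 0.0
    n_tumor = int(rng.binomial(config.n_fragments, p_tumor)) if p_tumor > 0 else 0
    n_normal = config.n_fragments - n_tumor

    parts = []
    for source_code, source, count, weights in (
        (0, "normal", n_normal, seg_len.copy()),
        (1, "tumor", n_tumor, seg_len * region_tab[:, 3] / 2.0),
    ):
        if count == 0:
            continue
        cidx, mids = _sample_midpoints(
            count, region_tab, weights, genome, config.gc_bias_strength, rng
        )
        lens = config.length_model.sample(source, count, rng)
        sizes = np.array([s for _, s in genome.chromosomes], dtype=np.int64)
        starts = np.clip(mids - lens // 2, 0, sizes[cidx] - lens)
        parts.append((cidx, starts, starts + lens, lens, source_code))

    cidx = np.concatenate([p[0] for p in parts])
    starts = np.concatenate([p[1] for p in parts])
    ends = np.concatenate([p[2] for p in parts])
    lens = np.concatenate([p[3] for p in parts])
    src_codes = np.concatenate(
        [np.full(len(p[0]), p[4], dtype=np.int8) for p in parts]
    )

    order = np.lexsort((starts, cidx))
    cidx, starts, ends, lens, src_codes = (
        cidx[order],
        starts[order],
        ends[order],
        lens[order],
        src_codes[order],
    )

    locus_alleles = _assign_locus_alleles(
        config, genome, cidx, starts, ends, src_codes, rng
    )
    n = len(cidx)
    return pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(cidx.astype(np.int16), genome.names),
            "start": starts.astype(np.int64),
            "end": ends.astype(np.int64),
            "length": lens.astype(np.int64),
            "source": pd.Categorical.from_codes(src_codes, ["normal", "tumor"]),
            "umi": pd.Categorical.from_codes(np.zeros(n, dtype=np.int8), [""]),
            "locus_alleles": locus_alleles,
        }
    )


def _assign_locus_alleles(config, genome, cidx, starts, ends, src_codes, rng):
    """Per-fragment allele at each covered target locus.

    A tumor-origin fragment carries the alt allele with probability
    equal to the locus tissue mAF; otherwise the fragment shows the alt
    base with the context-class background error rate, one of the two
    remaining bases with twice that rate, and the ref base otherwise.
    Encoded as ``"i:B"`` entries (locus index, base) joined by ``;``.
    """
    if not config.target_loci:
        return pd.Categorical.from_codes(np.zeros(len(cidx), dtype=np.int8), [""])
    alleles = np.full(len(cidx), "", dtype=object)
    name_to_idx = {name: i for i, name in enumerate(genome.names)}
    for li, locus in enumerate(config.target_loci):
        ci = name_to_idx[locus.chrom]
        cover = (cidx == ci) & (starts <= locus.pos) & (ends > locus.pos)
        idx = np.flatnonzero(cover)
        if idx.size == 0:
            continue
        e = config.error_rate_for(locus.error_class)
        is_tumor = src_codes[idx] == 1
        mutant = is_tumor & (rng.random(idx.size) < locus.tissue_maf)
        u = rng.random(idx.size)
        others = [b for b in "ACGT" if b not in (locus.ref, locus.alt)]
        base = np.full(idx.size, locus.ref, dtype=object)
        base[u < e] = locus.alt  # context-class substitution error
        err2 = (u >= e) & (u < 3 * e)
        base[err2] = rng.choice(np.array(others, dtype=object), size=int(err2.sum()))
        base[mutant] = locus.alt
        for j, b in zip(idx, base):
            prev = alleles[j]
            entry = f"{li}:{b}"
            alleles[j] = entry if not prev else f"{prev};{entry}"
    return alleles


def simulate_control_cohort(
    n_controls: int,
    config_template: SimulationConfig,
    genome: GenomeModel,
    seed: int,
) -> list[pd.DataFrame]:
    """Simulate a healthy control cohort (tumor fraction 0).

    Per-sample seeds are derived from the master ``seed`` by sample
    index offset (``seed + 1 + i``); inter-control variability is
    injected as a multiplicative jitter (uniform 0.8-1.2) on the GC
    bias strength.
    """
    if n_controls < 2:
        raise ValueError("a control cohort needs n_controls >= 2")
    master = np.random.default_rng(seed)
    jitter = master.uniform(0.8, 1.2, n_controls)
    out = []
    for i in range(n_controls):
        cfg = dataclasses.replace(
            config_template,
            tumor_fraction=0.0,
            scna_segments=(),
            seed=seed + 1 + i,
            gc_bias_strength=min(1.0, config_template.gc_bias_strength * jitter[i]),
        )
        out.append(simulate_sample(cfg, genome))
    return out


# ---------------------------------------------------------------------------
# targeted UMI reads
# ---------------------------------------------------------------------------


def simulate_targeted_reads(
    config: SimulationConfig,
    loci: tuple[TargetLocus, ...] | list[TargetLocus],
    mean_depth: float,
    seed: int,
) -> pd.DataFrame:
    """Simulate raw targeted reads with UMI families at patient loci.

    Per locus, ``Poisson(mean_depth)`` template molecules are drawn.
    A molecule is a true mutant with probability ``tf * tissue_maf``;
    non-mutant molecules carry the alt base with the context-class
    background rate (and another base at twice that rate).  Each
    molecule founds a UMI family with size from the configured family
    size distribution, and every read in the family is subject to the
    per-read sequencing error rate.

    Returns a DataFrame with columns ``locus_id umi base``.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not loci:
        raise ValueError("loci must be non-empty")
    rng = np.random.default_rng(seed)
    fam_sizes = np.array([s for s, _ in config.umi_family_size_distribution])
    fam_probs = np.array([p for _, p in config.umi_family_size_distribution])
    tf = config.tumor_fraction

    frames = []
    for li, locus in enumerate(loci):
        n_mol = int(rng.poisson(mean_depth))
        if n_mol == 0:
            continue
        e = config.error_rate_for(locus.error_class)
        others = [b for b in "ACGT" if b not in (locus.ref, locus.alt)]
        true_base = np.full(n_mol, locus.ref, dtype=object)
        u = rng.random(n_mol)
        true_base[u < e] = locus.alt
        err2 = (u >= e) & (u < 3 * e)
        true_base[err2] = rng.choice(np.array(others, dtype=object), size=int(err2.sum()))
        mutant = rng.random(n_mol) < tf * locus.tissue_maf
        true_base[mutant] = locus.alt

        sizes = rng.choice(fam_sizes, size=n_mol, p=fam_probs)
        reads = np.repeat(true_base, sizes)
        umis = np.repeat(
            np.array([f"{li}-{j}" for j in range(n_mol)], dtype=object), sizes
        )
        if config.read_error_rate > 0:
            flip = rng.random(len(reads)) < config.read_error_rate
            if flip.any():
                shift = rng.integers(1, 4, size=int(flip.sum()))
                orig = reads[flip]
                base_idx = np.searchsorted(_BASES, orig.astype(str))
                reads[flip] = _BASES[(base_idx + shift) % 4]
        frames.append(
            pd.DataFrame({"locus_id": np.full(len(reads), li), "umi": umis, "base": reads})
        )
    if not frames:
        return pd.DataFrame({"locus_id": [], "umi": [], "base": []})
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# multi-region tumor
# ---------------------------------------------------------------------------


def simulate_multiregion_tumor(
    n_regions: int,
    n_truncal: int,
    n_shared: int,
    n_private_per_region: int,
    af_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    fluid_tfs: dict[str, float] | None = None,
    mixing_weights: np.ndarray | None = None,
):
    """Simulate a mutations-by-regions allele-fraction matrix.

    Truncal mutations are present in every tumor region, shared ones in
    a random proper subset (>= 2 regions), private ones in exactly one.
    Each fluid row carries AF ``tf_fluid *`` (mixing-weighted mean of
    the regional AFs), i.e. perfect plasma/urine shedding diluted by the
    fluid's tumor fraction.

    Returns ``(MultiRegionMatrix, mixing_weights)``.
    """
    from .heterogeneity import MultiRegionMatrix

    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if min(n_truncal, n_shared, n_private_per_region) < 0:
        raise ValueError("mutation counts must be >= 0")
    rng = np.random.default_rng(seed)
    ranges = {
        "truncal": (0.20, 0.50),
        "shared": (0.10, 0.30),
        "private": (0.05, 0.20),
    }
    if af_ranges:
        ranges.update(af_ranges)
    if fluid_tfs is None:
        fluid_tfs = {"plasma": 0.1, "urine": 0.1}
    weights = (
        np.full(n_regions, 1.0 / n_regions)
        if mixing_weights is None
        else np.asarray(mixing_weights, dtype=float) / np.sum(mixing_weights)
    )

    regions = [f"T{i + 1}" for i in range(n_regions)]
    cols, data = [], []

    def add(name: str, present: np.ndarray, lo: float, hi: float) -> None:
        af = np.zeros(n_regions)
        af[present] = rng.uniform(lo, hi, int(present.sum()))
        cols.append(name)
        data.append(af)

    for k in range(n_truncal):
        add(f"truncal_{k}", np.ones(n_regions, bool), *ranges["truncal"])
    for k in range(n_shared):
        size = int(rng.integers(2, n_regions)) if n_regions > 2 else 2
        members = rng.choice(n_regions, size=size, replace=False)
        present = np.zeros(n_regions, bool)
        present[members] = True
        add(f"shared_{k}", present, *ranges["shared"])
    for r in range(n_regions):
        for k in range(n_private_per_region):
            present = np.zeros(n_regions, bool)
            present[r] = True
            add(f"private_{regions[r]}_{k}", present, *ranges["private"])

    region_af = np.array(data).T  # regions x mutations
    rows = {region: region_af[i] for i, region in enumerate(regions)}
    for fluid, tf in fluid_tfs.items():
        rows[fluid] = tf * (weights @ region_af)
    af = pd.DataFrame(rows, index=cols).T
    matrix = MultiRegionMatrix(af=af, tumor_regions=regions, fluids=list(fluid_tfs))
    return matrix, weights
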