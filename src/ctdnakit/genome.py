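"""Synthetic reference genome model.

A :class:`GenomeModel` is a desk-scale stand-in for a real reference
assembly: an ordered set of chromosomes with centromere (arm boundary)
positions, smooth per-window GC and mappability tracks, and a small
blacklist of excluded intervals.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeModel", "build_genome_model"]


@dataclass
class GenomeModel:
    """Chromosome sizes plus per-window GC/mappability tracks.

    Attributes
    ----------
    chromosomes : list of (name, length_bp)
        Ordered chromosomes.
    arm_boundaries : dict
        Per-chromosome centromere position (bp), strictly inside the
        chromosome; splits it into a p (left) and q (right) arm.
    window_bp : int
        Width of the GC/mappability windows; windows tile each
        chromosome exactly.
    gc : dict of str -> ndarray
        Per-window GC fraction in [0.3, 0.7].
    mappability : dict of str -> ndarray
        Per-window mappability in [0, 1].
    blacklist : list of (chrom, start, end)
        Excluded intervals (multiples of ``window_bp`` as generated).
    """

    chromosomes: list[tuple[str, int]]
    arm_boundaries: dict[str, int]
    window_bp: int
    gc: dict[str, np.ndarray]
    mappability: dict[str, np.ndarray]
    blacklist: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = dict(self.chromosomes)
        for name, size in self.chromosomes:
            if size <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            if size % self.window_bp:
                raise ValueError(
                    f"window_bp={self.window_bp} does not divide {name} length {size}"
                )
            bound = self.arm_boundaries[name]
            if not 0 < bound < size:
                raise ValueError(f"arm boundary of {name} not inside chromosome")
            n_win = size // self.window_bp
            if len(self.gc[name]) != n_win or len(self.mappability[name]) != n_win:
                raise ValueError(f"gc/mappability tracks of {name} do not tile it")
        for chrom, start, end in self.blacklist:
            if chrom not in sizes or start < 0 or end > sizes[chrom] or end <= start:
                raise ValueError(f"blacklist interval {(chrom, start, end)} out of bounds")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(s for _, s in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def arms(self) -> list[tuple[str, str, int, int]]:
        """All (arm_name, chrom, start, end) tuples, p then q per chromosome."""
        out = []
        for name, size in self.chromosomes:
            b = self.arm_boundaries[name]
            out.append((f"{name}p", name, 0, b))
            out.append((f"{name}q", name, b, size))
        return out

    def gc_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        return self.gc[chrom][np.asarray(positions) // self.window_bp]

    # -- serialization -------------------------------------------------
    def to_json(self, path: str) -> None:
        obj = {
            "chromosomes": self.chromosomes,
            "arm_boundaries": self.arm_boundaries,
            "window_bp": self.window_bp,
            "gc": {k: v.tolist() for k, v in self.gc.items()},
            "mappability": {k: v.tolist() for k, v in self.mappability.items()},
            "blacklist": self.blacklist,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path: str) -> "GenomeModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            chromosomes=[tuple(c) for c in obj["chromosomes"]],
            arm_boundaries=obj["arm_boundaries"],
            window_bp=obj["window_bp"],
            gc={k: np.asarray(v) for k, v in obj["gc"].items()},
            mappability={k: np.asarray(v) for k, v in obj["mappability"].items()},
            blacklist=[tuple(b) for b in obj["blacklist"]],
        )


def _smooth_track(rng: np.random.Generator, n: int, kernel: int = 25) -> np.ndarray:
    """Autocorrelated standard-normal-ish track of length n."""
    raw = rng.standard_normal(n + 2 * kernel)
    k = np.exp(-0.5 * ((np.arange(-kernel, kernel + 1)) / (kernel / 3.0)) ** 2)
    k /= k.sum()
    sm = np.convolve(raw, k, mode="same")[kernel:-kernel]
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def build_genome_model(
    n_chroms: int,
    chrom_length_bp: int,
    window_bp: int = 1000,
    seed: int = 0,
    blacklist_fraction: float = 0.01,
) -> GenomeModel:
    """Build a seeded synthetic genome.

    GC is sampled as a smooth (autocorrelated) track mapped into
    [0.3, 0.7]; mappability is 1.0 for most windows with a small tail of
    poorly mappable windows; ~``blacklist_fraction`` of windows are
    blacklisted.  Arm boundaries land between 40% and 60% of each
    chromosome.  Deterministic for a given seed.
    """
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    chrom_length_bp = int(chrom_length_bp)
    window_bp = int(window_bp)
    if chrom_length_bp <= 0 or window_bp <= 0:
        raise ValueError("sizes must be positive")
    if chrom_length_bp % window_bp:
        raise ValueError("window_bp must divide chrom_length_bp")

    rng = np.random.default_rng(seed)
    n_win = chrom_length_bp // window_bp
    chroms, bounds, gc, mapp, blacklist = [], {}, {}, {}, []
    for i in range(n_chroms):
        name = f"chr{i + 1}"
        chroms.append((name, chrom_length_bp))
        frac = rng.uniform(0.4, 0.6)
        bounds[name] = int(round(frac * n_win)) * window_bp
        z = _smooth_track(rng, n_win)
        gc[name] = np.clip(0.5 + 0.08 * z, 0.3, 0.7)
        m = np.ones(n_win)
        low = rng.random(n_win) < 0.01
        m[low] = rng.uniform(0.1, 0.9, low.sum())
        mapp[name] = m
        # blacklist ~blacklist_fraction of the chromosome as two
        # contiguous runs (mimicking pericentromeric/repeat regions)
        n_runs = 2
        run_len = max(1, int(round(blacklist_fraction * n_win / n_runs)))
        for _ in range(n_runs):
            w0 = int(rng.integers(0, n_win - run_len + 1))
            blacklist.append((name, w0 * window_bp, (w0 + run_len) * window_bp))
    return GenomeModel(chroms, bounds, window_bp, gc, mapp, blacklist)
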