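"""cfDNA fragment-length mixture model.

Plasma cfDNA fragment lengths peak at the mono-nucleosomal ~167 bp;
tumor-derived fragments are shifted shorter, and below ~150 bp the
density carries a 10-bp periodicity from nucleosomal DNA degradation.
The model is a two-component truncated log-normal mixture on the
integer lengths [20, 700], each component optionally modulated by a
multiplicative 10-bp comb ``1 + A*cos(2*pi*L/10)`` below 150 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["FragmentLengthModel", "LENGTH_MIN", "LENGTH_MAX"]

LENGTH_MIN = 20
LENGTH_MAX = 700
_COMB_CUTOFF = 150


def _lognormal_comb_pmf(mode: float, sigma: float, comb_amplitude: float) -> np.ndarray:
    lengths = np.arange(LENGTH_MIN, LENGTH_MAX + 1, dtype=float)
    # log-normal parameterized by its mode: mu = ln(mode) + sigma^2
    mu = np.log(mode) + sigma**2
    dens = np.exp(-0.5 * ((np.log(lengths) - mu) / sigma) ** 2) / lengths
    comb = np.ones_like(lengths)
    below = lengths < _COMB_CUTOFF
    comb[below] = 1.0 + comb_amplitude * np.cos(2 * np.pi * lengths[below] / 10.0)
    dens = dens * comb
    return dens / dens.sum()


@dataclass(frozen=True)
class FragmentLengthModel:
    """Two-component length mixture (normal cfDNA vs tumor cfDNA).

    Parameters
    ----------
    normal_mode, tumor_mode : float
        Modal fragment length (bp) of each component.  Default 167 bp
        for the normal (mono-nucleosomal) component; the tumor shift is
        a free parameter, default 145 bp.
    normal_sigma, tumor_sigma : float
        Log-scale spread of each log-normal component.
    periodicity_amplitude : float
        Amplitude A of the 10-bp comb applied below 150 bp.
    """

    normal_mode: float = 167.0
    normal_sigma: float = 0.10
    tumor_mode: float = 145.0
    tumor_sigma: float = 0.12
    periodicity_amplitude: float = 0.15

    def __post_init__(self) -> None:
        if not (LENGTH_MIN < self.tumor_mode and LENGTH_MIN < self.normal_mode):
            raise ValueError("component modes must exceed the minimum length")
        if not -1.0 < self.periodicity_amplitude < 1.0:
            raise ValueError("periodicity_amplitude must lie in (-1, 1)")

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(LENGTH_MIN, LENGTH_MAX + 1)

    def pmf(self, component: str) -> np.ndarray:
        """Normalized pmf over integer lengths [20, 700] for one component."""
        if component == "normal":
            return _cached_pmf(self.normal_mode, self.normal_sigma, self.periodicity_amplitude)
        if component == "tumor":
            return _cached_pmf(self.tumor_mode, self.tumor_sigma, self.periodicity_amplitude)
        raise ValueError(f"unknown component {component!r}")

    def probability_in_range(self, component: str, lo: int, hi: int) -> float:
        """P(lo <= L <= hi) for one component (inclusive bounds)."""
        p = self.pmf(component)
        lengths = self.lengths
        return float(p[(lengths >= lo) & (lengths <= hi)].sum())

    def sample(self, component: str, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.lengths, size=n, p=self.pmf(component))


@lru_cache(maxsize=64)
def _cached_pmf(mode: float, sigma: float, amp: float) -> np.ndarray:
    arr = _lognormal_comb_pmf(mode, sigma, amp)
    arr.setflags(write=False)
    return arr
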