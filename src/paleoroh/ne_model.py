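"""Effective population size from the ROH length spectrum.

Under a constant-size coalescent, the two homologs of a diploid individual
coalesce t generations ago with density (1/(2Ne))·exp(−t/(2Ne)).  Given t,
IBD tract ends occur at rate 2t per Morgan, so a chromosome of genetic
length G carries segments of length l with expected density

    (G − l)·(2t)²·exp(−2tl)   (interior segments, two recombination ends)
  +       2·(2t)·exp(−2tl)    (chromosome-edge segments, one end)

Integrating out t against the coalescent density gives the closed-form
intensity per diploid genome

    λ(l) = Σ_c, l ≤ G_c  (1/(2Ne)) · [ 8(G_c − l)/α³ + 4/α² ],
    α = 1/(2Ne) + 2l.

Observed segment lengths across individuals are modelled as an
inhomogeneous Poisson process with this intensity; Ne is estimated by
maximising the Poisson likelihood, with a 95% profile-likelihood CI.
Individuals flagged for close-kin inbreeding are excluded before fitting,
since their long ROH reflect recent pedigree loops, not population size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, minimize_scalar

from .io_formats import DEFAULT_AUTOSOME_LENGTHS_CM
from .roh_hmm import ROHProfile, flag_close_kin_inbreeding

__all__ = [
    "DEFAULT_AUTOSOME_LENGTHS_M",
    "ConstantNeModel",
    "NeEstimate",
    "roh_intensity",
    "expected_bin_length",
    "total_intensity",
    "fit_ne",
    "sample_roh_lengths",
]

#: Genetic lengths of the 22 autosomes in Morgans (35.4 M total).
DEFAULT_AUTOSOME_LENGTHS_M = DEFAULT_AUTOSOME_LENGTHS_CM / 100.0

_CI_DROP = 1.92
_NE_BOUNDS = (10.0, 1e6)


@dataclass(frozen=True)
class ConstantNeModel:
    """Constant diploid effective size over a fixed autosomal map."""

    ne: float
    chrom_lengths_m: tuple = tuple(DEFAULT_AUTOSOME_LENGTHS_M)
    l_min: float = 0.04  # Morgans

    def __post_init__(self):
        if self.ne <= 0:
            raise ValueError("Ne must be positive")
        if self.l_min <= 0 or self.l_min >= max(self.chrom_lengths_m):
            raise ValueError("l_min must lie in (0, max chromosome length)")


def roh_intensity(
    l,
    ne: float,
    chrom_lengths_m: Sequence[float] = DEFAULT_AUTOSOME_LENGTHS_M,
):
    """Expected ROH segments per diploid genome per Morgan at length l.

    ``l`` is in Morgans; scalar or array.  Chromosomes shorter than l do not
    contribute.
    """
    l_arr = np.atleast_1d(np.asarray(l, dtype=float))
    if (l_arr <= 0).any():
        raise ValueError("segment length must be positive")
    beta = 1.0 / (2.0 * ne)
    alpha = beta + 2.0 * l_arr
    lam = np.zeros_like(l_arr)
    for g in np.asarray(chrom_lengths_m, dtype=float):
        mask = l_arr <= g
        lam[mask] += beta * (
            8.0 * (g - l_arr[mask]) / alpha[mask] ** 3 + 4.0 / alpha[mask] ** 2
        )
    return lam if np.ndim(l) else float(lam[0])


def expected_bin_length(
    ne: float,
    bin_cm: tuple[float, float] = (4.0, 8.0),
    chrom_lengths_m: Sequence[float] = DEFAULT_AUTOSOME_LENGTHS_M,
) -> float:
    """Expected total ROH length (cM) per diploid genome in a length bin."""
    lo, hi = bin_cm[0] / 100.0, bin_cm[1] / 100.0
    if hi < lo:
        raise ValueError("inverted length bin")
    if hi == lo:
        return 0.0
    val, _ = quad(
        lambda l: l * roh_intensity(l, ne, chrom_lengths_m), lo, hi, limit=200
    )
    return val * 100.0  # Morgans -> cM


def total_intensity(
    ne: float,
    l_min: float = 0.04,
    chrom_lengths_m: Sequence[float] = DEFAULT_AUTOSOME_LENGTHS_M,
) -> float:
    """Expected number of ROH segments longer than l_min per diploid genome."""
    total = 0.0
    for g in np.asarray(chrom_lengths_m, dtype=float):
        if g <= l_min:
            continue
        val, _ = quad(lambda l: roh_intensity(l, ne, [g]), l_min, g, limit=200)
        total += val
    return total


@dataclass
class NeEstimate:
    ne_hat: float
    ci_low: float
    ci_high: float
    n_segments_used: int
    n_individuals: int
    at_bound: bool = False

    def __post_init__(self):
        if not (self.ci_low <= self.ne_hat <= self.ci_high):
            raise ValueError("CI does not bracket ne_hat")


def _poisson_loglik(
    ne: float, lengths_m: np.ndarray, n_individuals: int,
    l_min: float, chrom_lengths_m,
) -> float:
    lam = roh_intensity(lengths_m, ne, chrom_lengths_m)
    if np.any(lam <= 0):
        return -np.inf
    return float(
        np.sum(np.log(lam))
        - n_individuals * total_intensity(ne, l_min, chrom_lengths_m)
    )


def fit_ne(
    profiles: Sequence[ROHProfile],
    chrom_lengths_m: Sequence[float] = DEFAULT_AUTOSOME_LENGTHS_M,
    l_min: float = 0.04,
    exclude_kin: bool = True,
    max_length_cM: float | None = None,
) -> NeEstimate:
    """Maximum-likelihood Ne from pooled ROH length spectra.

    Individuals flagged for close-kin inbreeding are removed first (unless
    ``exclude_kin`` is False).  ``max_length_cM`` optionally drops very long
    segments from the fit.  Zero usable segments yields an estimate pinned
    at the upper search bound with ``at_bound`` set.
    """
    kept = [
        p for p in profiles
        if not (exclude_kin and flag_close_kin_inbreeding(p))
    ]
    lengths = [
        s.length_cM / 100.0
        for p in kept
        for s in p.segments
        if s.length_cM / 100.0 >= l_min
        and (max_length_cM is None or s.length_cM <= max_length_cM)
    ]
    n_ind = len(kept)
    lengths_m = np.asarray(lengths, dtype=float)
    if n_ind == 0 or lengths_m.size == 0:
        hi = _NE_BOUNDS[1]
        return NeEstimate(hi, _NE_BOUNDS[0], hi, 0, n_ind, at_bound=True)

    lo_x, hi_x = np.log10(_NE_BOUNDS)

    def nll(x: float) -> float:
        return -_poisson_loglik(10 ** x, lengths_m, n_ind, l_min, chrom_lengths_m)

    res = minimize_scalar(nll, bounds=(lo_x, hi_x), method="bounded",
                          options={"xatol": 1e-4})
    x_hat = float(res.x)
    ll_max = -float(res.fun)
    target = ll_max - _CI_DROP

    def drop(x):
        return -nll(x) - target

    ci_lo_x = lo_x
    if drop(lo_x) < 0:
        ci_lo_x = brentq(drop, lo_x, x_hat, xtol=1e-5)
    ci_hi_x = hi_x
    if drop(hi_x) < 0:
        ci_hi_x = brentq(drop, x_hat, hi_x, xtol=1e-5)

    return NeEstimate(
        ne_hat=10 ** x_hat, ci_low=10 ** ci_lo_x, ci_high=10 ** ci_hi_x,
        n_segments_used=int(lengths_m.size), n_individuals=n_ind,
        at_bound=not (lo_x + 1e-3 < x_hat < hi_x - 1e-3),
    )


def sample_roh_lengths(
    ne: float,
    rng: np.random.Generator,
    chrom_lengths_m: Sequence[float] = DEFAULT_AUTOSOME_LENGTHS_M,
    l_min: float = 0.04,
    grid_points: int = 2048,
) -> list[tuple[int, float]]:
    """Draw one diploid genome's ROH segments from the Poisson model.

    Returns (chromosome index, length in Morgans) pairs.  Per chromosome the
    segment count is Poisson with mean ∫λ and lengths follow the normalised
    intensity, sampled by inverse-CDF interpolation on a log-spaced grid.
    """
    out: list[tuple[int, float]] = []
    for ci, g in enumerate(np.asarray(chrom_lengths_m, dtype=float)):
        if g <= l_min:
            continue
        grid = np.geomspace(l_min, g, grid_points)
        pdf = roh_intensity(grid, ne, [g])
        cdf = np.concatenate(([0.0], np.cumsum(np.diff(grid) * 0.5 * (pdf[1:] + pdf[:-1]))))
        lam_c = cdf[-1]
        n = rng.poisson(lam_c)
        if n == 0:
            continue
        u = rng.uniform(0.0, lam_c, size=n)
        lengths = np.interp(u, cdf, grid)
        out.extend((ci, float(x)) for x in lengths)
    return out
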