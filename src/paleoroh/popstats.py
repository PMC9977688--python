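"""Pairwise mismatch rates, relatedness, heterozygosity and ML allele
frequencies for low-coverage pseudo-genotype data.

The relatedness coefficient is r = 2·(1 − PMR/b), where b is the
population baseline mismatch rate.  Two calibration identities pin the
scale: an unrelated pair has PMR = b (r = 0) and an individual compared
with itself has PMR = b/2 (r = 1).  The baseline is the group's mean
*expected* heterozygosity 2f(1−f); note that random-read pseudo-diploid
calls observe a het only when the two sampled reads hit different
chromosomes, so their raw het rate is half the expected heterozygosity and
is doubled when forming the baseline.

Group allele frequencies at phenotype-informative SNPs are estimated by
maximum likelihood directly from read counts, marginalising the latent
diploid genotype of each individual under a Hardy–Weinberg prior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import gammaln, xlog1py, xlogy

from .io_formats import MISSING

__all__ = [
    "PairwiseStats",
    "DiversityStats",
    "AlleleFrequencyEstimate",
    "pmr",
    "relatedness",
    "degree_label",
    "heterozygosity",
    "group_baseline",
    "ml_allele_frequency",
]

_CI_DROP = 1.92

#: Relatedness-degree cut-points (conventional midpoints between expected
#: r of 1, 1/2, 1/4 and 0); configurable via `degree_label`.
DEFAULT_DEGREE_CUTS = (0.75, 0.35, 0.10)


@dataclass
class PairwiseStats:
    id_a: str
    id_b: str
    pmr: float
    n_overlap: int
    r: float | None = None
    baseline_b: float | None = None
    degree: str | None = None


@dataclass
class DiversityStats:
    individual_id: str
    h: float  # fraction of pseudo-diploid calls that are het
    n_sites: int

    def __post_init__(self):
        if not (0.0 <= self.h <= 1.0):
            raise ValueError("heterozygosity outside [0, 1]")


@dataclass
class AlleleFrequencyEstimate:
    snp_id: str
    f_hat: float
    ci_low: float
    ci_high: float
    n_individuals: int
    total_reads: int

    def __post_init__(self):
        if not (0.0 <= self.ci_low <= self.f_hat <= self.ci_high <= 1.0):
            raise ValueError("CI must lie in [0,1] and contain f_hat")


def pmr(row_a: np.ndarray, row_b: np.ndarray, id_a: str = "A", id_b: str = "B") -> PairwiseStats:
    """Pairwise mismatch rate over sites covered in both pseudo-haploid rows."""
    a = np.asarray(row_a)
    b = np.asarray(row_b)
    if a.shape != b.shape:
        raise ValueError("rows cover different site universes")
    overlap = (a != MISSING) & (b != MISSING)
    n = int(overlap.sum())
    if n == 0:
        raise ValueError(f"no overlapping covered sites for {id_a}/{id_b}")
    mism = int((a[overlap] != b[overlap]).sum())
    return PairwiseStats(id_a, id_b, mism / n, n)


def relatedness(pmr_value: float, baseline_b: float) -> float:
    """Relatedness coefficient r = 2·(1 − PMR/b)."""
    if baseline_b <= 0:
        raise ValueError("baseline must be positive")
    return 2.0 * (1.0 - pmr_value / baseline_b)


def degree_label(r: float, cuts: tuple[float, float, float] = DEFAULT_DEGREE_CUTS) -> str:
    ident, first, second = cuts
    if r > ident:
        return "identical/twin"
    if r > first:
        return "first degree"
    if r > second:
        return "second degree"
    return "unrelated"


def heterozygosity(row: np.ndarray, individual_id: str = "") -> DiversityStats:
    """Fraction of non-missing pseudo-diploid calls that are heterozygous."""
    g = np.asarray(row)
    called = g != MISSING
    n = int(called.sum())
    if n == 0:
        raise ValueError("no called sites")
    h = int((g[called] == 1).sum()) / n
    return DiversityStats(individual_id, h, n)


def group_baseline(het_values: Sequence[float], method: str = "expected_het",
                   pmr_values: Sequence[float] | None = None) -> float:
    """Population baseline mismatch rate b.

    ``expected_het`` doubles the mean pseudo-diploid het rate (random-read
    diploid calls see only half of 2f(1−f)); ``median_pmr`` instead takes
    the median PMR among (presumed unrelated) pairs.
    """
    if method == "expected_het":
        if not len(het_values):
            raise ValueError("no heterozygosity values")
        return 2.0 * float(np.mean(het_values))
    if method == "median_pmr":
        if pmr_values is None or not len(pmr_values):
            raise ValueError("median_pmr baseline needs pairwise PMR values")
        return float(np.median(pmr_values))
    raise ValueError(f"unknown baseline method {method!r}")


def _af_loglik(f: float, n_reads: np.ndarray, n_alt: np.ndarray,
               logcomb: np.ndarray, eps: float) -> float:
    p_g = np.array([eps, 0.5, 1.0 - eps])
    hw = np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
    # xlogy handles the 0*log(0) corners of error-free genotypes
    lw = (xlogy(n_alt[:, None], p_g[None, :])
          + xlog1py((n_reads - n_alt)[:, None], -p_g[None, :]))
    like = np.exp(lw + logcomb[:, None]) @ hw
    return float(np.sum(np.log(np.maximum(like, 1e-300))))


def ml_allele_frequency(
    n_reads: Sequence[int],
    n_alt: Sequence[int],
    eps: float = 0.001,
    snp_id: str = "",
    grid_step: float = 1e-3,
) -> AlleleFrequencyEstimate:
    """ML derived-allele frequency from per-individual read counts at a SNP.

    L(f) = Π_i Σ_g HW(g; f) · Binomial(n_alt,i | n_i, (g/2)(1−ε)+(1−g/2)ε).
    The maximiser is located on a coarse grid then refined; the 95% CI is
    the profile-likelihood interval (1.92 log-unit drop) truncated to [0,1].
    """
    n_reads = np.asarray(n_reads, dtype=float)
    n_alt = np.asarray(n_alt, dtype=float)
    if n_reads.shape != n_alt.shape:
        raise ValueError("n_reads and n_alt must align")
    keep = n_reads > 0
    n_reads, n_alt = n_reads[keep], n_alt[keep]
    if n_reads.size == 0:
        raise ValueError("no individuals with reads")
    if not (0 <= eps < 0.5):
        raise ValueError("eps must be in [0, 0.5)")
    logcomb = gammaln(n_reads + 1) - gammaln(n_alt + 1) - gammaln(n_reads - n_alt + 1)

    def ll(f):
        return _af_loglik(f, n_reads, n_alt, logcomb, eps)

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    vals = np.array([ll(f) for f in grid])
    i_best = int(np.argmax(vals))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(lambda f: -ll(f), bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        f_hat = float(res.x)
        ll_max = -float(res.fun)
    else:
        f_hat, ll_max = float(grid[i_best]), float(vals[i_best])
    for edge in (0.0, 1.0):
        if ll(edge) >= ll_max:
            f_hat, ll_max = edge, ll(edge)

    target = ll_max - _CI_DROP

    def drop(f):
        return ll(f) - target

    ci_low = 0.0
    if f_hat > 0 and drop(0.0) < 0:
        ci_low = float(brentq(drop, 0.0, f_hat, xtol=1e-6))
    ci_high = 1.0
    if f_hat < 1 and drop(1.0) < 0:
        ci_high = float(brentq(drop, f_hat, 1.0, xtol=1e-6))

    return AlleleFrequencyEstimate(
        snp_id=snp_id, f_hat=f_hat, ci_low=ci_low, ci_high=ci_high,
        n_individuals=int(n_reads.size), total_reads=int(n_reads.sum()),
    )
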