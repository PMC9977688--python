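"""Synthetic data generator emulating SNP-capture ancient-DNA studies.

Stands in for the raw study data: a phased reference panel with linkage
disequilibrium, inbred target individuals carrying planted or model-drawn
runs of homozygosity, and per-site read counts with sequencing error,
terminal deamination damage and a modern contaminant fraction.  Every
simulated dataset ships with its :class:`TruthRecord` so estimators can be
checked against known ground truth.

LD is produced by a founder-mosaic process: a handful of founder haplotypes
are drawn site-wise from a frequency spectrum, and the remaining panel
haplotypes are recombinant mosaics of the founders with template switches
along the genetic map.  Haplotype correlation therefore decays with map
distance, which is what the copying model needs to be identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import LibraryPileup, LibraryProtocol, SNPSite
from .ne_model import sample_roh_lengths
from .roh_hmm import ReferencePanel

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_panel",
    "simulate_individual",
    "simulate_reads",
]

_NUCS = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the generator; the seed is mandatory.

    Defaults mirror a desk-scale version of a 1240k-capture experiment: a
    50 cM chromosome arm carrying 20,000 panel SNPs, a 100-haplotype
    reference panel, 1x mean coverage, sequencing error 1e-3 and no damage
    or contamination unless asked for.
    """

    seed: int
    n_sites: int = 20_000
    n_haplotypes: int = 100
    n_founders: int | None = None  # default: min(20, n_haplotypes)
    freq_beta_a: float = 1.0
    freq_beta_b: float = 1.0
    mosaic_switch_per_cM: float = 1.0
    chrom_length_cM: float = 50.0
    coverage: float = 1.0
    seq_error: float = 0.001
    damage_rate: float = 0.0
    contamination: float = 0.0

    def __post_init__(self):
        if self.n_haplotypes < 2:
            raise ValueError("panel needs at least 2 haplotypes")
        if self.n_founders is not None and not (
            2 <= self.n_founders <= self.n_haplotypes
        ):
            raise ValueError("n_founders must be in [2, n_haplotypes]")
        for name in ("seq_error", "damage_rate", "contamination"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")
        if self.coverage < 0 or self.chrom_length_cM <= 0 or self.n_sites < 1:
            raise ValueError("invalid coverage / map length / site count")
        if self.mosaic_switch_per_cM < 0:
            raise ValueError("mosaic switch rate must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth accompanying a simulated dataset."""

    roh_intervals_cM: list[tuple[float, float]] = field(default_factory=list)
    contamination: float = 0.0
    ne: float | None = None
    genotypes: np.ndarray | None = None  # (2, S) haplotype alleles


def _mosaic(
    founders: np.ndarray, pos_cm: np.ndarray, switch_per_cm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant mosaic of the founder haplotypes along the map."""
    n_f, S = founders.shape
    template = np.empty(S, dtype=np.int64)
    cur = rng.integers(n_f)
    if switch_per_cm <= 0:
        return founders[cur].copy()
    pos = pos_cm[0]
    start = 0
    while True:
        pos += rng.exponential(1.0 / switch_per_cm)
        nxt = int(np.searchsorted(pos_cm, pos))
        template[start:nxt] = cur
        if nxt >= S:
            break
        start = nxt
        cur = rng.integers(n_f)
    return founders[template, np.arange(S)]


def simulate_panel(config: SimulationConfig) -> ReferencePanel:
    """Reference panel with founder-mosaic LD over one chromosome.

    Site positions are uniform on the map; ref/alt allele pairs are random
    distinct nucleotides (so transitions and transversions both occur and
    the protocol filters have something to bite on).  Panel frequencies are
    recomputed as column means of the final haplotype matrix.
    """
    rng = np.random.default_rng(config.seed)
    S, K = config.n_sites, config.n_haplotypes
    pos_cm = np.sort(rng.uniform(0.0, config.chrom_length_cM, size=S))
    f0 = 0.1 + 0.8 * rng.beta(config.freq_beta_a, config.freq_beta_b, size=S)

    ref_idx = rng.integers(0, 4, size=S)
    alt_off = rng.integers(1, 4, size=S)
    alt_idx = (ref_idx + alt_off) % 4

    n_founders = config.n_founders or min(20, K)
    founders = (rng.random((n_founders, S)) < f0).astype(np.int8)
    haps = np.empty((K, S), dtype=np.int8)
    haps[:n_founders] = founders
    for k in range(n_founders, K):
        haps[k] = _mosaic(founders, pos_cm, config.mosaic_switch_per_cM, rng)

    freqs = haps.mean(axis=0)
    sites = [
        SNPSite(
            chrom="1",
            pos_bp=int(round(p * 1e6)) + 1,
            pos_cM=float(p),
            ref_allele=str(_NUCS[r]),
            alt_allele=str(_NUCS[a]),
            snp_id=f"snp{i}",
        )
        for i, (p, r, a) in enumerate(zip(pos_cm, ref_idx, alt_idx))
    ]
    return ReferencePanel(haps, freqs, sites)


def simulate_individual(
    panel: ReferencePanel,
    roh_spec: Sequence[tuple[float, float]] | None,
    seed: int,
    ne: float | None = None,
    switch_per_cM: float = 1.0,
) -> tuple[np.ndarray, TruthRecord]:
    """Diploid genotypes as two panel mosaics, homozygous inside ROH.

    ``roh_spec`` gives explicit (start_cM, end_cM) intervals; alternatively
    pass ``ne`` to draw segment lengths from the constant-size ROH model and
    place them uniformly without overlap.  Inside each interval the second
    haplotype is a verbatim copy of the first; outside, the two haplotypes
    are independent mosaics.
    """
    rng = np.random.default_rng(seed)
    pos_cm = panel.pos_cM
    length = float(pos_cm[-1] - pos_cm[0])

    if roh_spec is None and ne is not None:
        drawn = sample_roh_lengths(ne, rng, chrom_lengths_m=[length / 100.0])
        intervals: list[tuple[float, float]] = []
        for _, l_m in drawn:
            l_cm = l_m * 100.0
            for _attempt in range(100):
                start = pos_cm[0] + rng.uniform(0.0, length - l_cm)
                cand = (start, start + l_cm)
                if all(cand[1] <= a or cand[0] >= b for a, b in intervals):
                    intervals.append(cand)
                    break
        intervals.sort()
    else:
        intervals = sorted(tuple(map(float, iv)) for iv in (roh_spec or []))
        for (a0, b0), (a1, b1) in zip(intervals, intervals[1:]):
            if a1 < b0:
                raise ValueError("planted ROH intervals overlap")
        for a, b in intervals:
            if a < pos_cm[0] - 1e-9 or b > pos_cm[-1] + 1e-9:
                raise ValueError("planted ROH interval outside chromosome bounds")

    hap1 = _mosaic(panel.haplotypes, pos_cm, switch_per_cM, rng)
    hap2 = _mosaic(panel.haplotypes, pos_cm, switch_per_cM, rng)
    for a, b in intervals:
        mask = (pos_cm >= a) & (pos_cm <= b)
        hap2[mask] = hap1[mask]
    geno = np.vstack([hap1, hap2])
    truth = TruthRecord(
        roh_intervals_cM=list(intervals),
        ne=ne,
        genotypes=geno,
    )
    return geno, truth


def simulate_reads(
    genotypes: np.ndarray,
    config: SimulationConfig,
    panel: ReferencePanel,
    library_id: str = "sim",
    protocol: LibraryProtocol | None = None,
) -> tuple[LibraryPileup, TruthRecord]:
    """Per-site stranded read counts with error, damage and contamination.

    Read depth is Poisson(coverage).  Each read derives from the endogenous
    genome with probability 1−c (allele from a random chromosome) and from
    a contaminant genome drawn from the panel frequencies otherwise; the
    allele is flipped with probability ε.  At C/T SNPs forward reads
    carrying the C allele additionally flip C→T with the damage rate δ, and
    symmetrically G→A on reverse reads at G/A SNPs.
    """
    rng = np.random.default_rng(config.seed + 1)
    geno = np.asarray(genotypes, dtype=np.int8)
    S = geno.shape[1]
    if S != panel.n_sites:
        raise ValueError("genotype length != panel site count")

    depth = rng.poisson(config.coverage, size=S)
    total = int(depth.sum())
    site_idx = np.repeat(np.arange(S), depth)

    chrom_pick = rng.integers(0, 2, size=total)
    endo = geno[chrom_pick, site_idx]
    is_contam = rng.random(total) < config.contamination
    contam = (rng.random(total) < panel.frequencies[site_idx]).astype(np.int8)
    allele = np.where(is_contam, contam, endo)
    flip = rng.random(total) < config.seq_error
    allele = np.where(flip, 1 - allele, allele)
    is_rev = rng.random(total) < 0.5

    if config.damage_rate > 0:
        is_ct = np.array([s.is_ct for s in panel.sites])[site_idx]
        is_ga = np.array([s.is_ga for s in panel.sites])[site_idx]
        ref_is_c = np.array(
            [s.ref_allele.upper() == "C" for s in panel.sites]
        )[site_idx]
        ref_is_g = np.array(
            [s.ref_allele.upper() == "G" for s in panel.sites]
        )[site_idx]
        carries_c = is_ct & ((allele == 0) == ref_is_c)
        carries_g = is_ga & ((allele == 0) == ref_is_g)
        dmg = rng.random(total) < config.damage_rate
        hit = dmg & ((carries_c & ~is_rev) | (carries_g & is_rev))
        allele = np.where(hit, 1 - allele, allele)

    key = site_idx * 4 + allele.astype(np.int64) * 2 + is_rev.astype(np.int64)
    counts = np.bincount(key, minlength=S * 4).reshape(S, 4)

    pileup = LibraryPileup(
        library_id=library_id,
        n_ref_fwd=counts[:, 0].astype(np.int32),
        n_ref_rev=counts[:, 1].astype(np.int32),
        n_alt_fwd=counts[:, 2].astype(np.int32),
        n_alt_rev=counts[:, 3].astype(np.int32),
        protocol=protocol or LibraryProtocol.from_name("ds_halfUDG"),
        meta={"quality_threshold": 30, "simulated": True},
    )
    truth = TruthRecord(contamination=config.contamination, genotypes=geno)
    return pileup, truth
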