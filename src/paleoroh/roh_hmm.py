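"""Runs-of-homozygosity detection with a Li–Stephens haplotype-copying HMM.

Within an ROH the two homologous chromosomes are identical, so the genome is
locally haploid and can be modelled as a mosaic copy of reference-panel
haplotypes.  The HMM therefore has one *background* (outbred, diploid)
macro-state plus K *copying* states, one per panel haplotype:

* background emissions marginalise a Hardy–Weinberg diploid genotype at the
  panel allele frequency f_s, with per-read error ε (mixture of binomials —
  the latent genotype is shared by all reads at a site);
* copying-state emissions are Binomial(n_alt | n, q) with
  q = a'(1−ε) + (1−a')ε, where a' is the copied allele h_k(s) flipped with
  miscopy probability θ (folded into a per-read allele probability);
* transitions between consecutive covered sites at map distance d cM:
  background↔ROH with probability 1 − exp(−rate·d), and within-ROH template
  jumps with probability 1 − exp(−ρ·d) landing uniformly on the K templates.

Posterior decoding (forward–backward) yields per-site ROH probabilities;
segments are maximal runs with P(ROH) above a threshold, nearby runs are
merged, and short segments are discarded.  Lengths are genetic (cM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.special import gammaln

from .io_formats import MISSING, GenotypeTable, LibraryPileup, SNPSite

__all__ = [
    "ReferencePanel",
    "CopyingParams",
    "ROHSegment",
    "ROHProfile",
    "ROH_BINS_CM",
    "forward_loglik",
    "posterior_roh",
    "infer_roh",
    "check_roh_eligibility",
    "summarize_roh",
    "flag_close_kin_inbreeding",
]

#: Length bins (cM, half-open [a, b)) used for ROH summaries.
ROH_BINS_CM = ((4.0, 8.0), (8.0, 12.0), (12.0, 20.0), (20.0, np.inf))


@dataclass
class ReferencePanel:
    """Phased haplotype matrix over panel sites plus allele frequencies.

    ``haplotypes`` is (K, S) with alleles in {0, 1}; ``frequencies`` holds
    the alt-allele frequency f_s per site in the panel's source population.
    """

    haplotypes: np.ndarray
    frequencies: np.ndarray
    sites: list[SNPSite]

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D (K x S)")
        if self.haplotypes.shape[0] < 2:
            raise ValueError("reference panel needs K >= 2 haplotypes")
        if self.haplotypes.shape[1] != len(self.sites):
            raise ValueError("haplotype matrix width != number of sites")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")
        if ((self.frequencies < 0) | (self.frequencies > 1)).any():
            raise ValueError("allele frequencies outside [0, 1]")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def pos_cM(self) -> np.ndarray:
        return np.array([s.pos_cM for s in self.sites])


@dataclass(frozen=True)
class CopyingParams:
    """Rates and error probabilities of the copying model.

    jump_rate (ρ): expected template switches per cM within ROH.
    roh_enter / roh_exit: background↔ROH transition intensities per cM.
    miscopy (θ): per-site probability the endogenous allele differs from the
    copied template.  seq_error (ε): per-read allele flip probability.
    """

    jump_rate: float = 1.0
    roh_enter: float = 0.005
    roh_exit: float = 0.01
    miscopy: float = 0.001
    seq_error: float = 0.01

    def __post_init__(self):
        if self.jump_rate <= 0 or self.roh_enter <= 0 or self.roh_exit <= 0:
            raise ValueError("rates must be positive")
        if not (0 <= self.miscopy < 0.5):
            raise ValueError("miscopy must be in [0, 0.5)")
        if not (0 <= self.seq_error < 0.5):
            raise ValueError("seq_error must be in [0, 0.5)")


@dataclass(frozen=True)
class ROHSegment:
    chrom: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    start_cM: float
    end_cM: float
    mean_posterior: float

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM


@dataclass
class ROHProfile:
    """Detected ROH segments of one individual plus binned totals."""

    individual_id: str
    segments: list[ROHSegment] = field(default_factory=list)
    n_covered_sites: int = 0

    def bin_totals(self) -> dict[str, float]:
        totals = {}
        for lo, hi in ROH_BINS_CM:
            label = f"[{lo:g},{hi:g})" if np.isfinite(hi) else f"[{lo:g},inf)"
            totals[label] = sum(
                s.length_cM for s in self.segments if lo <= s.length_cM < hi
            )
        return totals

    def total_cM(self) -> float:
        return sum(s.length_cM for s in self.segments)


# ---------------------------------------------------------------------------
# observation handling
# ---------------------------------------------------------------------------

def _as_counts(observations) -> tuple[np.ndarray, np.ndarray]:
    """Normalise observations to per-site (n_reads, n_alt) arrays.

    Accepts a :class:`LibraryPileup` (read-count mode, binomial emissions) or
    a 1-D pseudo-haploid call vector in {-1, 0, 1} (single-Bernoulli mode).
    """
    if isinstance(observations, LibraryPileup):
        return observations.depth.astype(np.int64), observations.n_alt.astype(np.int64)
    obs = np.asarray(observations)
    if obs.ndim == 1 and np.isin(obs, (MISSING, 0, 1)).all():
        n = (obs != MISSING).astype(np.int64)
        na = (obs == 1).astype(np.int64)
        return n, na
    raise TypeError("observations must be a LibraryPileup or a {-1,0,1} call vector")


def _emissions(
    n: np.ndarray,
    n_alt: np.ndarray,
    panel: ReferencePanel,
    params: CopyingParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site emission likelihoods at covered sites.

    Returns (emit_bg (S,), emit_copy (S, K)) including the shared binomial
    coefficient, so values are genuine probabilities of the observed counts.
    """
    eps = params.seq_error
    theta = params.miscopy
    f = panel.frequencies
    H = panel.haplotypes  # (K, S)

    logcomb = gammaln(n + 1) - gammaln(n_alt + 1) - gammaln(n - n_alt + 1)
    comb = np.exp(logcomb)

    def binom(q):
        q = np.clip(q, 0.0, 1.0)
        return comb * q ** n_alt * (1.0 - q) ** (n - n_alt)

    # background: HW genotype shared across reads -> mixture of binomials
    p_g = (eps, 0.5, 1.0 - eps)
    hw = ((1 - f) ** 2, 2 * f * (1 - f), f ** 2)
    emit_bg = sum(w * binom(np.full_like(f, p)) for w, p in zip(hw, p_g))

    # copying: miscopy folded into per-read allele probability
    a_eff = H * (1 - theta) + (1 - H) * theta  # (K, S)
    q = a_eff * (1 - eps) + (1 - a_eff) * eps
    emit_copy = comb[None, :] * q ** n_alt[None, :] * (1 - q) ** (n - n_alt)[None, :]
    return emit_bg, emit_copy.T.copy()  # (S,), (S, K)


# ---------------------------------------------------------------------------
# numba kernels (scaled forward / forward-backward)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forward_kernel(emit_bg, emit_copy, p_enter, p_exit, p_jump, pi_roh):
    S, K = emit_copy.shape
    alpha_bg = (1.0 - pi_roh) * emit_bg[0]
    alpha = np.empty(K)
    for k in range(K):
        alpha[k] = pi_roh / K * emit_copy[0, k]
    norm = alpha_bg + alpha.sum()
    if norm <= 0.0:
        return -np.inf
    loglik = np.log(norm)
    alpha_bg /= norm
    alpha /= norm
    for t in range(1, S):
        pe, px, pj = p_enter[t - 1], p_exit[t - 1], p_jump[t - 1]
        s_copy = alpha.sum()
        new_bg = ((1.0 - pe) * alpha_bg + px * s_copy) * emit_bg[t]
        from_bg = pe / K * alpha_bg
        pooled = (1.0 - px) * pj / K * s_copy
        new = np.empty(K)
        for k in range(K):
            new[k] = (from_bg + (1.0 - px) * (1.0 - pj) * alpha[k] + pooled) \
                * emit_copy[t, k]
        norm = new_bg + new.sum()
        if norm <= 0.0:
            return -np.inf
        loglik += np.log(norm)
        alpha_bg = new_bg / norm
        alpha = new / norm
    return loglik


@njit(cache=True)
def _forward_backward_kernel(emit_bg, emit_copy, p_enter, p_exit, p_jump, pi_roh):
    S, K = emit_copy.shape
    alphas_bg = np.empty(S)
    alphas = np.empty((S, K))
    norms = np.empty(S)

    alphas_bg[0] = (1.0 - pi_roh) * emit_bg[0]
    for k in range(K):
        alphas[0, k] = pi_roh / K * emit_copy[0, k]
    norms[0] = alphas_bg[0] + alphas[0].sum()
    if norms[0] <= 0.0:
        return -np.inf, np.full(S, np.nan)
    alphas_bg[0] /= norms[0]
    alphas[0] /= norms[0]
    loglik = np.log(norms[0])

    for t in range(1, S):
        pe, px, pj = p_enter[t - 1], p_exit[t - 1], p_jump[t - 1]
        s_copy = alphas[t - 1].sum()
        alphas_bg[t] = ((1.0 - pe) * alphas_bg[t - 1] + px * s_copy) * emit_bg[t]
        from_bg = pe / K * alphas_bg[t - 1]
        pooled = (1.0 - px) * pj / K * s_copy
        for k in range(K):
            alphas[t, k] = (from_bg + (1.0 - px) * (1.0 - pj) * alphas[t - 1, k]
                            + pooled) * emit_copy[t, k]
        norms[t] = alphas_bg[t] + alphas[t].sum()
        if norms[t] <= 0.0:
            return -np.inf, np.full(S, np.nan)
        alphas_bg[t] /= norms[t]
        alphas[t] /= norms[t]
        loglik += np.log(norms[t])

    post_bg = np.empty(S)
    beta_bg = 1.0
    beta = np.ones(K)
    denom = alphas_bg[S - 1] * beta_bg + (alphas[S - 1] * beta).sum()
    post_bg[S - 1] = alphas_bg[S - 1] * beta_bg / denom
    for t in range(S - 2, -1, -1):
        pe, px, pj = p_enter[t], p_exit[t], p_jump[t]
        v_bg = emit_bg[t + 1] * beta_bg
        v = np.empty(K)
        for k in range(K):
            v[k] = emit_copy[t + 1, k] * beta[k]
        s_v = v.sum()
        new_beta_bg = (1.0 - pe) * v_bg + pe / K * s_v
        pooled = (1.0 - px) * pj / K * s_v
        new_beta = np.empty(K)
        for k in range(K):
            new_beta[k] = px * v_bg + (1.0 - px) * (1.0 - pj) * v[k] + pooled
        # rescale with the forward norms to keep magnitudes bounded
        beta_bg = new_beta_bg / norms[t + 1]
        beta = new_beta / norms[t + 1]
        denom = alphas_bg[t] * beta_bg + (alphas[t] * beta).sum()
        post_bg[t] = alphas_bg[t] * beta_bg / denom
    return loglik, post_bg


def _transition_probs(pos_cm: np.ndarray, params: CopyingParams):
    d = np.diff(pos_cm)
    p_enter = 1.0 - np.exp(-params.roh_enter * d)
    p_exit = 1.0 - np.exp(-params.roh_exit * d)
    p_jump = 1.0 - np.exp(-params.jump_rate * d)
    return p_enter, p_exit, p_jump


def _prepare(observations, panel: ReferencePanel, params: CopyingParams):
    n, n_alt = _as_counts(observations)
    if n.shape[0] != panel.n_sites:
        raise ValueError("observation length != panel site count")
    pos_cm = panel.pos_cM
    if np.any(np.diff(pos_cm) < 0):
        raise ValueError("panel sites not sorted by pos_cM")
    cov = np.flatnonzero(n > 0)
    if cov.size == 0:
        raise ValueError("no covered sites")
    sub = ReferencePanel(
        panel.haplotypes[:, cov], panel.frequencies[cov],
        [panel.sites[i] for i in cov],
    )
    emit_bg, emit_copy = _emissions(n[cov], n_alt[cov], sub, params)
    p_enter, p_exit, p_jump = _transition_probs(pos_cm[cov], params)
    pi_roh = params.roh_enter / (params.roh_enter + params.roh_exit)
    return cov, emit_bg, emit_copy, p_enter, p_exit, p_jump, pi_roh


def forward_loglik(observations, panel: ReferencePanel, params: CopyingParams) -> float:
    """Log-likelihood of the observations under the copying HMM."""
    cov, e_bg, e_c, pe, px, pj, pi = _prepare(observations, panel, params)
    return float(_forward_kernel(e_bg, e_c, pe, px, pj, pi))


def posterior_roh(
    observations, panel: ReferencePanel, params: CopyingParams
) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior P(ROH) at covered sites.

    Returns (covered site indices, posterior ROH probability, log-likelihood).
    """
    cov, e_bg, e_c, pe, px, pj, pi = _prepare(observations, panel, params)
    loglik, post_bg = _forward_backward_kernel(e_bg, e_c, pe, px, pj, pi)
    return cov, 1.0 - post_bg, float(loglik)


def infer_roh(
    observations,
    panel: ReferencePanel,
    params: CopyingParams | None = None,
    min_cM: float = 4.0,
    posterior_threshold: float = 0.5,
    merge_gap_cM: float = 0.5,
    individual_id: str = "",
) -> ROHProfile:
    """Call ROH segments by posterior decoding.

    Maximal runs of covered sites with P(ROH) > ``posterior_threshold`` are
    taken as candidate segments; runs separated by a genetic gap smaller
    than ``merge_gap_cM`` are merged; segments with length <= ``min_cM`` are
    discarded.  Interval ends are the first/last member sites (closed,
    1-based) and length is end_cM − start_cM.
    """
    params = params or CopyingParams()
    cov, post, _ = posterior_roh(observations, panel, params)
    pos_cm = panel.pos_cM
    in_roh = post > posterior_threshold

    runs: list[list[int]] = []  # [first, last] positions into `cov`
    start = None
    for i, flag in enumerate(in_roh):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(in_roh) - 1])

    # merge runs separated by small genetic gaps (same chromosome only)
    merged: list[list[int]] = []
    for run in runs:
        if merged:
            prev = merged[-1]
            gap = pos_cm[cov[run[0]]] - pos_cm[cov[prev[1]]]
            same_chrom = (
                panel.sites[cov[run[0]]].chrom == panel.sites[cov[prev[1]]].chrom
            )
            if same_chrom and gap < merge_gap_cM:
                prev[1] = run[1]
                continue
        merged.append(run)

    segments = []
    for a, b in merged:
        i0, i1 = int(cov[a]), int(cov[b])
        s0, s1 = panel.sites[i0], panel.sites[i1]
        if s0.chrom != s1.chrom:
            continue  # a run may not span chromosomes
        length = s1.pos_cM - s0.pos_cM
        if length <= min_cM:
            continue
        segments.append(
            ROHSegment(
                chrom=s0.chrom, start_idx=i0, end_idx=i1,
                start_bp=s0.pos_bp, end_bp=s1.pos_bp,
                start_cM=s0.pos_cM, end_cM=s1.pos_cM,
                mean_posterior=float(np.mean(post[a:b + 1])),
            )
        )
    return ROHProfile(
        individual_id=individual_id, segments=segments, n_covered_sites=int(cov.size)
    )


def check_roh_eligibility(
    table: GenotypeTable, individual: str, min_sites: int = 400_000
) -> bool:
    """True iff the individual has strictly more than ``min_sites`` covered."""
    idx = table.individuals.index(individual)
    return int(table.covered_counts()[idx]) > min_sites


def summarize_roh(profile: ROHProfile) -> dict:
    """Per-bin total lengths plus the genome-wide sum (cM)."""
    out = profile.bin_totals()
    out["total"] = profile.total_cM()
    return out


def flag_close_kin_inbreeding(profile: ROHProfile) -> bool:
    """True iff >= 50 cM of the genome lies in ROH segments longer than 20 cM.

    Such individuals descend from close-kin unions and are excluded from
    population-level effective-size fits.
    """
    long_total = sum(s.length_cM for s in profile.segments if s.length_cM > 20.0)
    return long_total >= 50.0


# ---------------------------------------------------------------------------
# text interchange
# ---------------------------------------------------------------------------

def write_panel_tsv(panel: ReferencePanel, out_prefix) -> None:
    """Write a panel as ``<prefix>.sites.tsv`` + ``<prefix>.haps.tsv``.

    The sites file carries snp_id, chrom, pos_bp, pos_cM, ref, alt and the
    panel alt-allele frequency; the haplotype file holds one 0/1 string row
    per haplotype.
    """
    from pathlib import Path

    out_prefix = Path(str(out_prefix))
    with open(f"{out_prefix}.sites.tsv", "w") as fh:
        fh.write("snp_id\tchrom\tpos_bp\tpos_cM\tref\talt\tfreq\n")
        for s, f in zip(panel.sites, panel.frequencies):
            fh.write(
                f"{s.snp_id}\t{s.chrom}\t{s.pos_bp}\t{s.pos_cM:.6f}"
                f"\t{s.ref_allele}\t{s.alt_allele}\t{f:.6f}\n"
            )
    with open(f"{out_prefix}.haps.tsv", "w") as fh:
        for row in panel.haplotypes:
            fh.write("".join(map(str, row)) + "\n")


def read_panel_tsv(prefix) -> ReferencePanel:
    """Read a panel written by :func:`write_panel_tsv`."""
    import pandas as pd

    df = pd.read_csv(f"{prefix}.sites.tsv", sep="\t", dtype={"chrom": str})
    sites = [
        SNPSite(str(r.chrom), int(r.pos_bp), float(r.pos_cM),
                str(r.ref), str(r.alt), str(r.snp_id))
        for r in df.itertuples(index=False)
    ]
    haps = np.array(
        [[int(ch) for ch in line.strip()]
         for line in open(f"{prefix}.haps.tsv") if line.strip()],
        dtype=np.int8,
    )
    return ReferencePanel(haps, df["freq"].to_numpy(), sites)


def write_roh_tsv(profile: ROHProfile, path) -> None:
    """BED-like per-segment TSV (closed 1-based intervals, cM lengths)."""
    with open(path, "w") as fh:
        fh.write(
            "#individual\tchrom\tstart_bp\tend_bp\tstart_cM\tend_cM"
            "\tlength_cM\tmean_posterior\n"
        )
        fh.write(f"#n_covered_sites={profile.n_covered_sites}\n")
        for s in profile.segments:
            fh.write(
                f"{profile.individual_id}\t{s.chrom}\t{s.start_bp}\t{s.end_bp}"
                f"\t{s.start_cM:.4f}\t{s.end_cM:.4f}\t{s.length_cM:.4f}"
                f"\t{s.mean_posterior:.4f}\n"
            )


def read_roh_tsv(path) -> ROHProfile:
    """Read a profile written by :func:`write_roh_tsv`."""
    profile = ROHProfile(individual_id="")
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#n_covered_sites="):
                profile.n_covered_sites = int(line.split("=", 1)[1])
                continue
            if not line or line.startswith("#"):
                continue
            ind, chrom, sbp, ebp, scm, ecm, _len, post = line.split("\t")
            profile.individual_id = ind
            profile.segments.append(
                ROHSegment(
                    chrom=chrom, start_idx=-1, end_idx=-1,
                    start_bp=int(sbp), end_bp=int(ebp),
                    start_cM=float(scm), end_cM=float(ecm),
                    mean_posterior=float(post),
                )
            )
    return profile
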