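"""Independent brute-force oracles used across the test suite.

These enumerate every hidden-state path explicitly (feasible for <= 6 sites
and <= 3 haplotypes) and must stay independent of the forward-algorithm
implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import binom as binom_dist


def _binom_pmf(k, n, p):
    p = min(max(p, 0.0), 1.0)
    return float(binom_dist.pmf(k, n, p))


def _bg_emission(n, n_alt, f, eps):
    hw = [(1 - f) ** 2, 2 * f * (1 - f), f ** 2]
    probs = [eps, 0.5, 1 - eps]
    return sum(w * _binom_pmf(n_alt, n, p) for w, p in zip(hw, probs))


def _copy_emission(n, n_alt, allele, eps, theta):
    a_eff = allele * (1 - theta) + (1 - allele) * theta
    q = a_eff * (1 - eps) + (1 - a_eff) * eps
    return _binom_pmf(n_alt, n, q)


def enumerate_roh_loglik(n, n_alt, haps, freqs, pos_cm, params) -> float:
    """Exhaustive-path log-likelihood of the background+copying HMM.

    States: 0 = background, 1..K = copy-from-haplotype.  Only covered sites
    (n > 0) participate, matching the model's contract.
    """
    cov = [i for i in range(len(n)) if n[i] > 0]
    K = haps.shape[0]
    pi_roh = params.roh_enter / (params.roh_enter + params.roh_exit)
    init = [1 - pi_roh] + [pi_roh / K] * K

    emis = []
    for i in cov:
        row = [_bg_emission(n[i], n_alt[i], freqs[i], params.seq_error)]
        for k in range(K):
            row.append(_copy_emission(n[i], n_alt[i], haps[k, i],
                                      params.seq_error, params.miscopy))
        emis.append(row)

    trans = []
    for a, b in zip(cov, cov[1:]):
        d = pos_cm[b] - pos_cm[a]
        pe = 1 - math.exp(-params.roh_enter * d)
        px = 1 - math.exp(-params.roh_exit * d)
        pj = 1 - math.exp(-params.jump_rate * d)
        T = np.zeros((K + 1, K + 1))
        T[0, 0] = 1 - pe
        T[0, 1:] = pe / K
        T[1:, 0] = px
        for k in range(1, K + 1):
            for j in range(1, K + 1):
                T[k, j] = (1 - px) * (pj / K + (1 - pj) * (k == j))
        trans.append(T)

    total = 0.0
    for path in itertools.product(range(K + 1), repeat=len(cov)):
        p = init[path[0]] * emis[0][path[0]]
        for t in range(1, len(cov)):
            p *= trans[t - 1][path[t - 1], path[t]] * emis[t][path[t]]
        total += p
    return math.log(total) if total > 0 else -math.inf


def enumerate_copying_loglik(c, n, n_alt, haps, freqs, pos_cm, params) -> float:
    """Exhaustive-path log-likelihood of the within-ROH contamination model."""
    cov = [i for i in range(len(n)) if n[i] > 0]
    K = haps.shape[0]
    eps, theta = params.seq_error, params.miscopy

    emis = []
    for i in cov:
        row = []
        for k in range(K):
            a_eff = haps[k, i] * (1 - theta) + (1 - haps[k, i]) * theta
            p_endo = a_eff * (1 - eps) + (1 - a_eff) * eps
            p_cont = freqs[i] * (1 - eps) + (1 - freqs[i]) * eps
            q = (1 - c) * p_endo + c * p_cont
            row.append(_binom_pmf(n_alt[i], n[i], q))
        emis.append(row)

    jumps = []
    for a, b in zip(cov, cov[1:]):
        d = pos_cm[b] - pos_cm[a]
        jumps.append(1 - math.exp(-params.jump_rate * d))

    total = 0.0
    for path in itertools.product(range(K), repeat=len(cov)):
        p = (1.0 / K) * emis[0][path[0]]
        for t in range(1, len(cov)):
            pj = jumps[t - 1]
            p *= (pj / K + (1 - pj) * (path[t - 1] == path[t])) * emis[t][path[t]]
        total += p
    return math.log(total) if total > 0 else -math.inf


def as_pileup(n, n_alt, panel=None):
    """Wrap (n, n_alt) per-site counts as an all-forward LibraryPileup."""
    from paleoroh import LibraryPileup, LibraryProtocol

    n = np.asarray(n, dtype=np.int32)
    n_alt = np.asarray(n_alt, dtype=np.int32)
    zero = np.zeros_like(n)
    return LibraryPileup("t", (n - n_alt).astype(np.int32), zero,
                         n_alt.astype(np.int32), zero,
                         protocol=LibraryProtocol.from_name("ds_halfUDG"))


def segment(length_cm, chrom="1", start=0.0):
    from paleoroh import ROHSegment

    return ROHSegment(chrom, 0, 1, 1, 2, start, start + length_cm, 0.9)


def profile_from_truth(truth_intervals, individual_id="truth"):
    """Build an ROHProfile directly from planted truth intervals."""
    from paleoroh import ROHProfile, ROHSegment

    segments = [
        ROHSegment(
            chrom="1", start_idx=-1, end_idx=-1,
            start_bp=int(a * 1e6) + 1, end_bp=int(b * 1e6) + 1,
            start_cM=float(a), end_cM=float(b), mean_posterior=1.0,
        )
        for a, b in truth_intervals
    ]
    return ROHProfile(individual_id=individual_id, segments=segments)
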