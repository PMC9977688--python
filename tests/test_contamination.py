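"""Within-ROH contamination likelihood, ML estimation and QC labels."""

import math

import numpy as np
import pytest

from paleoroh import (
    CopyingParams,
    QCThresholds,
    SimulationConfig,
    classify_contamination,
    contamination_loglik,
    estimate_contamination,
    simulate_individual,
    simulate_panel,
    simulate_reads,
)

from conftest import tiny_panel
from helpers import as_pileup, enumerate_copying_loglik, profile_from_truth


def whole_chrom_profile(panel):
    return profile_from_truth([(panel.pos_cM[0], panel.pos_cM[-1])])


def simulate_roh_reads(seed, c, n_sites=6000, K=40, length_cm=50.0,
                       coverage=1.0, eps=0.001):
    cfg = SimulationConfig(seed=seed, n_sites=n_sites, n_haplotypes=K,
                           chrom_length_cM=length_cm, coverage=coverage,
                           seq_error=eps, contamination=c)
    panel = simulate_panel(cfg)
    geno, _ = simulate_individual(
        panel, [(panel.pos_cM[0], panel.pos_cM[-1])], seed=seed + 7919)
    pileup, _ = simulate_reads(geno, cfg, panel)
    return panel, pileup


class TestLoglik:
    def test_closed_form_single_site(self):
        """Copied allele 0, contaminant frequency 1, no error: L = c."""
        haps = np.zeros((2, 1), dtype=np.int8)
        panel = tiny_panel(haps, [1.0], freqs=[1.0])
        params = CopyingParams(miscopy=0.0, seq_error=0.0)
        prof = profile_from_truth([(0.5, 1.5)])
        pu = as_pileup([1], [1], panel)
        for c in (0.05, 0.2, 0.4):
            ll = contamination_loglik(c, prof, pu, panel, params)
            assert ll == pytest.approx(math.log(c), abs=1e-12)

    def test_impossible_observation_is_minus_inf(self):
        """c=0, no error, read contradicts the only haplotype: probability 0."""
        haps = np.zeros((2, 1), dtype=np.int8)
        panel = tiny_panel(haps, [1.0], freqs=[0.0])
        params = CopyingParams(miscopy=0.0, seq_error=0.0)
        prof = profile_from_truth([(0.5, 1.5)])
        pu = as_pileup([1], [1], panel)
        assert contamination_loglik(0.0, prof, pu, panel, params) == -math.inf

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        """Forward marginalisation equals brute-force path sums to 1e-9."""
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 4))
        S = int(rng.integers(3, 6))
        haps = rng.integers(0, 2, size=(K, S)).astype(np.int8)
        pos = np.sort(rng.uniform(0, 8, size=S))
        freqs = rng.uniform(0.05, 0.95, size=S)
        panel = tiny_panel(haps, pos, freqs)
        n = rng.integers(1, 4, size=S)
        n_alt = rng.binomial(n, 0.4)
        params = CopyingParams(jump_rate=rng.uniform(0.3, 2.0),
                               miscopy=rng.uniform(0, 0.05),
                               seq_error=rng.uniform(0.001, 0.1))
        prof = profile_from_truth([(pos[0] - 0.1, pos[-1] + 0.1)])
        c = 0.15
        got = contamination_loglik(c, prof, as_pileup(n, n_alt, panel),
                                   panel, params)
        want = enumerate_copying_loglik(c, n, n_alt, haps, freqs, pos, params)
        assert got == pytest.approx(want, abs=1e-9)

    def test_domain_errors(self):
        haps = np.zeros((2, 1), dtype=np.int8)
        panel = tiny_panel(haps, [1.0], freqs=[0.5])
        prof = profile_from_truth([(0.5, 1.5)])
        pu = as_pileup([1], [0], panel)
        with pytest.raises(ValueError, match=r"\[0, 0.5\]"):
            contamination_loglik(0.6, prof, pu, panel)
        with pytest.raises(ValueError, match="no read"):
            contamination_loglik(0.1, prof, as_pileup([0], [0], panel), panel)

    def test_continuity_in_c(self):
        """With eps > 0 the log-likelihood is finite and smooth on [0, 0.5]."""
        panel, pileup = simulate_roh_reads(71, 0.1, n_sites=800, K=10,
                                           length_cm=20.0)
        prof = whole_chrom_profile(panel)
        params = CopyingParams(seq_error=0.001)
        grid = np.linspace(0, 0.5, 26)
        vals = [contamination_loglik(c, prof, pileup, panel, params)
                for c in grid]
        assert np.all(np.isfinite(vals))
        # continuity at a representative interior point: increments shrink
        # proportionally with the step size
        ll = lambda c: contamination_loglik(c, prof, pileup, panel, params)
        d_coarse = abs(ll(0.1 + 1e-2) - ll(0.1))
        d_fine = abs(ll(0.1 + 1e-4) - ll(0.1))
        assert d_fine < max(d_coarse / 10.0, 1e-6)


class TestEstimate:
    def test_clean_library_estimated_near_zero(self):
        """c=0 truth: c_hat <= 0.02 and the CI covers 0 (each of 20 seeds)."""
        params = CopyingParams(seq_error=0.001)
        hats = []
        for seed in range(20):
            panel, pileup = simulate_roh_reads(100 + seed, 0.0)
            est = estimate_contamination(whole_chrom_profile(panel), pileup,
                                         panel, params)
            hats.append(est.c_hat)
            assert est.ci_low <= 0.005
        assert np.median(hats) <= 0.02

    def test_substantial_contamination_recovered(self):
        """c=0.10 truth recovered within +-0.03 in >=90% of 20 seeds."""
        params = CopyingParams(seq_error=0.001)
        hits = 0
        for seed in range(20):
            panel, pileup = simulate_roh_reads(200 + seed, 0.10)
            est = estimate_contamination(whole_chrom_profile(panel), pileup,
                                         panel, params)
            hits += abs(est.c_hat - 0.10) <= 0.03
        assert hits >= 18

    def test_recovery_curve_monotone_and_calibrated(self):
        """Median c_hat over seeds is monotone in truth and within +-0.03."""
        params = CopyingParams(seq_error=0.001)
        truths = [0.0, 0.02, 0.05, 0.10, 0.20]
        medians = []
        for c in truths:
            hats = []
            for seed in range(10):
                panel, pileup = simulate_roh_reads(
                    int(1000 * c) * 100 + seed + 300, c,
                    n_sites=5000, K=30, length_cm=40.0)
                est = estimate_contamination(whole_chrom_profile(panel),
                                             pileup, panel, params)
                hats.append(est.c_hat)
            medians.append(float(np.median(hats)))
        assert all(b >= a - 1e-6 for a, b in zip(medians, medians[1:]))
        for c, m in zip(truths, medians):
            assert abs(m - c) <= 0.03

    def test_more_roh_shrinks_ci(self):
        """Median CI width at 50 cM of ROH is below that at 10 cM."""
        params = CopyingParams(seq_error=0.001)
        widths = {}
        for length in (10.0, 50.0):
            ws = []
            for seed in range(8):
                panel, pileup = simulate_roh_reads(
                    500 + seed, 0.05, n_sites=int(120 * length), K=30,
                    length_cm=length)
                est = estimate_contamination(whole_chrom_profile(panel),
                                             pileup, panel, params)
                ws.append(est.ci_high - est.ci_low)
            widths[length] = np.median(ws)
        assert widths[50.0] < widths[10.0]

    def test_optimizer_agrees_with_grid(self):
        """argmax matches an exhaustive 0.001-step grid within one step."""
        panel, pileup = simulate_roh_reads(42, 0.08, n_sites=1500, K=12,
                                           length_cm=25.0)
        params = CopyingParams(seq_error=0.001)
        prof = whole_chrom_profile(panel)
        est = estimate_contamination(prof, pileup, panel, params)
        grid = np.arange(0.0, 0.5001, 0.001)
        vals = [contamination_loglik(c, prof, pileup, panel, params,
                                     trim_cM=0.5) for c in grid]
        c_grid = grid[int(np.argmax(vals))]
        assert abs(est.c_hat - c_grid) <= 0.001

    def test_flat_likelihood_flagged_unidentifiable(self):
        """Contaminant frequencies equal to the copied haplotype: flat in c."""
        rng = np.random.default_rng(9)
        S = 400
        hap = rng.integers(0, 2, size=S).astype(np.int8)
        haps = np.vstack([hap, hap])
        pos = np.sort(rng.uniform(0, 30, size=S))
        panel = tiny_panel(haps, pos, freqs=hap.astype(float))
        params = CopyingParams(miscopy=0.0, seq_error=0.01)
        n = np.ones(S, dtype=int)
        n_alt = np.where(rng.random(S) < 0.01, 1 - hap, hap).astype(int)
        prof = profile_from_truth([(pos[0], pos[-1])])
        est = estimate_contamination(prof, as_pileup(n, n_alt, panel),
                                     panel, params)
        assert est.unidentifiable and est.low_confidence

    def test_short_roh_low_confidence(self):
        panel, pileup = simulate_roh_reads(77, 0.05, n_sites=600, K=10,
                                           length_cm=8.0)
        est = estimate_contamination(whole_chrom_profile(panel), pileup,
                                     panel, CopyingParams(seq_error=0.001))
        assert est.total_cM_used < 10.0 and est.low_confidence

    def test_no_segments_error(self):
        panel, pileup = simulate_roh_reads(1, 0.0, n_sites=300, K=6,
                                           length_cm=5.0)
        with pytest.raises(ValueError, match="no segments"):
            estimate_contamination(profile_from_truth([]), pileup, panel)


class TestClassification:
    @pytest.mark.parametrize("c,label", [
        (0.12, "substantial"),
        (0.07, "marginal"),
        (0.01, "clean"),
        (0.05, "marginal"),
        (0.10, "marginal"),
        (0.101, "substantial"),
    ])
    def test_thresholds(self, c, label):
        got, action = classify_contamination({"nuclear": c})
        assert got == label
        if label == "substantial":
            assert action == "use damage-filtered reads"
        if label == "clean":
            assert action == "none"

    def test_any_estimate_dominates(self):
        label, _ = classify_contamination({"mt": 0.2, "nuclear": 0.01})
        assert label == "substantial"

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            QCThresholds(substantial=0.05, marginal_low=0.10)
        with pytest.raises(ValueError):
            classify_contamination({})
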