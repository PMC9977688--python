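"""Haplotype-copying HMM: likelihood correctness and ROH calling."""

import numpy as np
import pytest

from paleoroh import (
    CopyingParams,
    ROHProfile,
    ROHSegment,
    GenotypeTable,
    MISSING,
    SimulationConfig,
    check_roh_eligibility,
    flag_close_kin_inbreeding,
    forward_loglik,
    infer_roh,
    posterior_roh,
    simulate_individual,
    simulate_panel,
    simulate_reads,
    summarize_roh,
)

from conftest import tiny_panel
from helpers import as_pileup, enumerate_roh_loglik, segment


def random_instance(rng, n_sites=5, K=3):
    haps = rng.integers(0, 2, size=(K, n_sites)).astype(np.int8)
    pos = np.sort(rng.uniform(0, 10, size=n_sites))
    freqs = rng.uniform(0.05, 0.95, size=n_sites)
    panel = tiny_panel(haps, pos, freqs)
    n = rng.integers(0, 4, size=n_sites)
    if n.sum() == 0:
        n[0] = 1
    n_alt = rng.binomial(n, 0.4)
    params = CopyingParams(
        jump_rate=rng.uniform(0.2, 3.0),
        roh_enter=rng.uniform(0.002, 0.05),
        roh_exit=rng.uniform(0.002, 0.05),
        miscopy=rng.uniform(0.0, 0.05),
        seq_error=rng.uniform(0.001, 0.1),
    )
    return panel, n, n_alt, params


class TestForwardLoglik:
    def test_perfect_match_zero_loglik(self):
        """Identical haplotypes, matching reads, no error: all emissions are 1."""
        haps = np.zeros((2, 6), dtype=np.int8)
        panel = tiny_panel(haps, np.linspace(0, 5, 6), freqs=np.zeros(6))
        params = CopyingParams(miscopy=0.0, seq_error=0.0)
        pu = as_pileup(np.ones(6, int), np.zeros(6, int), panel)
        assert forward_loglik(pu, panel, params) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed):
        """Forward algorithm equals brute-force path enumeration to 1e-9."""
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 4))
        S = int(rng.integers(3, 7))
        panel, n, n_alt, params = random_instance(rng, n_sites=S, K=K)
        got = forward_loglik(as_pileup(n, n_alt, panel), panel, params)
        want = enumerate_roh_loglik(n, n_alt, panel.haplotypes,
                                    panel.frequencies, panel.pos_cM, params)
        assert got == pytest.approx(want, abs=1e-9)

    def test_pseudohaploid_observation_mode(self):
        """A {-1,0,1} call vector behaves as single-read counts."""
        rng = np.random.default_rng(3)
        panel, n, n_alt, params = random_instance(rng)
        calls = np.full(panel.n_sites, MISSING, dtype=np.int8)
        calls[n > 0] = (n_alt[n > 0] > 0).astype(np.int8)
        n1 = (calls != MISSING).astype(int)
        na1 = (calls == 1).astype(int)
        got = forward_loglik(calls, panel, params)
        want = enumerate_roh_loglik(n1, na1, panel.haplotypes,
                                    panel.frequencies, panel.pos_cM, params)
        assert got == pytest.approx(want, abs=1e-9)

    def test_forward_and_forward_backward_agree(self):
        rng = np.random.default_rng(11)
        panel, n, n_alt, params = random_instance(rng, n_sites=6, K=3)
        pu = as_pileup(n, n_alt, panel)
        ll_f = forward_loglik(pu, panel, params)
        _, post, ll_fb = posterior_roh(pu, panel, params)
        assert ll_f == pytest.approx(ll_fb, abs=1e-9)
        assert np.all(post >= -1e-12) and np.all(post <= 1 + 1e-12)

    def test_zero_covered_sites_error(self):
        rng = np.random.default_rng(1)
        panel, _, _, params = random_instance(rng)
        with pytest.raises(ValueError, match="covered"):
            forward_loglik(as_pileup(np.zeros(5, int), np.zeros(5, int), panel),
                           panel, params)

    def test_unsorted_sites_error(self):
        rng = np.random.default_rng(2)
        panel, n, n_alt, params = random_instance(rng)
        panel.sites[0], panel.sites[1] = panel.sites[1], panel.sites[0]
        with pytest.raises(ValueError, match="sorted"):
            forward_loglik(as_pileup(n, n_alt, panel), panel, params)


class TestInferRoh:
    def test_doubled_haplotype_detected_as_single_segment(self):
        """A verbatim doubled panel haplotype at 5x is one near-full segment."""
        cfg = SimulationConfig(seed=21, n_sites=6000, n_haplotypes=40,
                               chrom_length_cM=50.0, coverage=5.0,
                               seq_error=0.001)
        panel = simulate_panel(cfg)
        geno = np.vstack([panel.haplotypes[0], panel.haplotypes[0]])
        pileup, _ = simulate_reads(geno, cfg, panel)
        prof = infer_roh(pileup, panel)
        assert len(prof.segments) == 1
        chrom_len = panel.pos_cM[-1] - panel.pos_cM[0]
        assert prof.segments[0].length_cM >= 0.98 * chrom_len

    def test_outbred_individual_rarely_triggers_calls(self):
        """Two independent mosaics on 30 cM at 1x: >=95% of seeds yield 0 ROH."""
        false_pos = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=1000 + seed, n_sites=2000,
                                   n_haplotypes=16, chrom_length_cM=30.0,
                                   coverage=1.0, seq_error=0.001)
            panel = simulate_panel(cfg)
            geno, _ = simulate_individual(panel, [], seed=2000 + seed)
            pileup, _ = simulate_reads(geno, cfg, panel)
            if infer_roh(pileup, panel).segments:
                false_pos += 1
        assert false_pos <= 0.05 * n_seeds

    def test_short_planted_roh_below_threshold_absent(self):
        """A planted 3 cM tract is never reported with the 4 cM minimum."""
        cfg = SimulationConfig(seed=5, n_sites=4000, n_haplotypes=30,
                               chrom_length_cM=40.0, coverage=5.0,
                               seq_error=0.001)
        panel = simulate_panel(cfg)
        geno, _ = simulate_individual(panel, [(20.0, 23.0)], seed=6)
        pileup, _ = simulate_reads(geno, cfg, panel)
        prof = infer_roh(pileup, panel)
        for seg in prof.segments:
            # anything called must not be the short planted tract
            assert seg.length_cM > 4.0

    def test_recovery_monotone_in_coverage_and_length(self):
        """Planted-ROH recovery improves with coverage and segment length."""
        lengths = [5.0, 10.0, 20.0]
        coverages = [0.1, 0.5, 2.0]
        recovery = {}
        for cov in coverages:
            for length in lengths:
                overlaps = []
                for seed in range(3):
                    cfg = SimulationConfig(seed=300 + seed, n_sites=3000,
                                           n_haplotypes=24,
                                           chrom_length_cM=40.0, coverage=cov,
                                           seq_error=0.001)
                    panel = simulate_panel(cfg)
                    lo = 10.0
                    geno, _ = simulate_individual(panel, [(lo, lo + length)],
                                                  seed=400 + seed)
                    pileup, _ = simulate_reads(geno, cfg, panel)
                    prof = infer_roh(pileup, panel)
                    got = 0.0
                    for seg in prof.segments:
                        got += max(0.0, min(seg.end_cM, lo + length)
                                   - max(seg.start_cM, lo))
                    overlaps.append(got / length)
                recovery[(cov, length)] = np.mean(overlaps)
        tol = 0.02  # small Monte-Carlo slack
        for length in lengths:
            assert recovery[(0.1, length)] <= recovery[(0.5, length)] + tol
            assert recovery[(0.5, length)] <= recovery[(2.0, length)] + tol
        for cov in coverages:
            assert recovery[(cov, 5.0)] <= recovery[(cov, 10.0)] + tol
            assert recovery[(cov, 10.0)] <= recovery[(cov, 20.0)] + tol


class TestEligibility:
    def _table(self, covered):
        data = np.full((1, 450_000), MISSING, dtype=np.int8)
        data[0, :covered] = 0
        return GenotypeTable(data, ["I0"], "pseudo_haploid")

    def test_boundary_is_strict(self):
        """Exactly 400,000 covered sites is ineligible; one more qualifies."""
        assert not check_roh_eligibility(self._table(400_000), "I0")
        assert check_roh_eligibility(self._table(400_001), "I0")
        assert not check_roh_eligibility(self._table(0), "I0")


class TestSummaries:
    def test_bin_totals(self):
        prof = ROHProfile("x", [segment(l) for l in (5.0, 7.0, 15.0, 25.0)])
        out = summarize_roh(prof)
        assert out["[4,8)"] == pytest.approx(12.0)
        assert out["[8,12)"] == pytest.approx(0.0)
        assert out["[12,20)"] == pytest.approx(15.0)
        assert out["[20,inf)"] == pytest.approx(25.0)
        assert out["total"] == pytest.approx(52.0)

    def test_empty_profile_zero(self):
        out = summarize_roh(ROHProfile("x", []))
        assert all(v == 0.0 for v in out.values())

    def test_eight_cm_goes_to_second_bin(self):
        out = summarize_roh(ROHProfile("x", [segment(8.0)]))
        assert out["[8,12)"] == pytest.approx(8.0)
        assert out["[4,8)"] == 0.0


class TestCloseKinFlag:
    def test_two_long_segments_flagged(self):
        assert flag_close_kin_inbreeding(
            ROHProfile("x", [segment(30.0), segment(25.0, start=40.0)])
        )

    def test_many_segments_below_20cm_not_flagged(self):
        prof = ROHProfile("x", [segment(19.0, start=20.0 * i) for i in range(10)])
        assert not flag_close_kin_inbreeding(prof)

    def test_single_50cm_segment_flagged(self):
        assert flag_close_kin_inbreeding(ROHProfile("x", [segment(50.0)]))
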