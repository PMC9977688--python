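# paleoroh

Authentication and population-diversity toolkit for SNP-capture ancient-DNA
data. It targets the standard low-coverage aDNA workflow built around the
1240k capture panel: per-library read pileups go in; authenticated
pseudo-haploid genotypes, runs of homozygosity (ROH), contamination
estimates, effective population sizes and diversity statistics come out.
Everything is testable end-to-end against the in-package synthetic-data
generator, which ships ground truth with every dataset.

## What it computes

**Genotype calling** (`paleoroh.calling`). Random-haploid calls (one read
per site) and random-diploid calls (two reads without replacement), with
the protocol-specific eligibility rules of aDNA libraries: transversions
only for non-UDG double-stranded libraries, strand-aware read exclusion at
C/T and G/A SNPs for single-stranded libraries. Plus random-allele library
merging, the 6,000-SNP minimum-coverage filter and Y/autosome
coverage-ratio sex assignment (male > 0.2 > female).

**ROH detection** (`paleoroh.roh_hmm`). A Li–Stephens haplotype-copying
hidden Markov model with one outbred *background* state and K *copying*
states, one per reference-panel haplotype. Inside an ROH the genome is
locally haploid and is modelled as a mosaic copy of panel haplotypes; read
counts enter through binomial emissions with sequencing error ε and
miscopy θ. Posterior decoding yields segments longer than 4 cM; an
individual qualifies with > 400,000 covered panel SNPs.

**Contamination inside ROH** (`paleoroh.contamination`). Within a called
ROH every endogenous read copies a single panel haplotype, so each read is
alt with probability

    q_k(s) = (1 − c)·[a'(1−ε) + (1−a')ε] + c·[f_s(1−ε) + (1−f_s)ε],

where a' is the copied allele (miscopy-adjusted) and f_s the modern
contaminant allele frequency. The copying path is marginalised by the
forward algorithm and c is the ML point on [0, 0.5] with a 95%
profile-likelihood CI. This works for male *and* female libraries, unlike
X-chromosome estimators. Libraries are classified clean / marginal
(5–10%) / substantial (> 10%).

**Effective population size** (`paleoroh.ne_model`). Under a constant-size
coalescent the expected density of ROH of genetic length l per diploid
genome is, summed over autosomes with map length G_c ≥ l,

    λ(l) = Σ_c (1/(2Ne)) · [ 8(G_c − l)/α³ + 4/α² ],   α = 1/(2Ne) + 2l.

Observed segment lengths are an inhomogeneous Poisson process with this
intensity; Ne is the ML point with a profile-likelihood CI. Individuals
with ≥ 50 cM in ROH > 20 cM (close-kin inbreeding) are excluded by default.

**Diversity statistics** (`paleoroh.popstats`). Pairwise mismatch rate
(PMR), relatedness r = 2(1 − PMR/b) with the population baseline b taken
from pseudo-diploid heterozygosity, and ML derived-allele frequencies with
95% CIs marginalising the latent diploid genotype of each low-coverage
individual.

**Simulation** (`paleoroh.simulate`). Reference panels with LD
(founder-mosaic process), inbred individuals with planted or
model-drawn ROH, and reads with sequencing error, terminal deamination
damage and a contaminant fraction — each with a truth record.

## Worked example

```python
import numpy as np
from paleoroh import (CopyingParams, SimulationConfig, estimate_contamination,
                      infer_roh, simulate_individual, simulate_panel,
                      simulate_reads)

cfg = SimulationConfig(seed=7, n_sites=20_000, n_haplotypes=100,
                       chrom_length_cM=50.0, coverage=1.0,
                       seq_error=0.001, contamination=0.10)
panel = simulate_panel(cfg)
geno, truth = simulate_individual(
    panel, [(panel.pos_cM[0], panel.pos_cM[-1])], seed=8)   # fully inbred
pileup, _ = simulate_reads(geno, cfg, panel)

profile = infer_roh(pileup, panel, individual_id="sim")
print(len(profile.segments), round(profile.total_cM(), 1))
# 1 50.0

est = estimate_contamination(profile, pileup, panel,
                             CopyingParams(seq_error=0.001))
print(round(est.c_hat, 3), (round(est.ci_low, 3), round(est.ci_high, 3)))
# 0.088 (0.081, 0.095)
```

A 50 cM chromosome simulated as a single ROH at 1x coverage with a 10%
modern contaminant: the HMM calls one segment spanning the chromosome, and
the within-ROH estimator recovers the contamination fraction (here 8.8%
with a tight CI; the median across seeds sits at the simulated 10%).

The same pipeline is available from the shell:

```
paleoroh simulate --seed 7 --contamination 0.1 --roh 0-50 --out run/
paleoroh roh --pileup run/pileup.tsv --panel run/panel \
             --min-eligible-snps 1000 --out run/
paleoroh contam --pileup run/pileup.tsv --panel run/panel \
                --roh run/roh.tsv --seq-error 0.001 --out run/
```

## Scope

Read mapping, duplicate removal, PMD scoring, mtDNA assembly and
haplogroup calling, PCA/f-statistics and other downstream population
analyses are out of scope; this package covers the genotype-calling,
authentication and ROH-based inference layer between them.
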