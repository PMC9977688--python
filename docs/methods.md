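# Methods

This note documents the models implemented in `paleoroh`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Haplotype-copying model for ROH

The hidden state at covered site s is either *background* (outbred,
locally diploid) or *copy-from-k* for one of the K reference-panel
haplotypes. Emissions for a site with n reads, a of them alt:

* **background** — the latent diploid genotype g ∈ {0,1,2} is shared by
  all reads at the site, so the emission is a mixture of binomials over
  the Hardy–Weinberg prior at the panel frequency f_s:
  Σ_g HW(g; f_s) · Binom(a | n, p_g) with p_g = (g/2)(1−ε) + (1−g/2)ε.
* **copying** — the copied allele h_k(s) is flipped with the miscopy
  probability θ, folded into a per-read allele probability
  a' = h_k(1−θ) + (1−h_k)θ, giving Binom(a | n, a'(1−ε) + (1−a')ε).

The asymmetry is deliberate: in the background state the genotype is a
shared latent variable (a heterozygote explains balanced read counts far
better than any single per-read probability), while miscopy and error act
independently per read along a haploid copy.

Transitions between consecutive covered sites at map distance d cM use
exponential waiting times: background↔ROH with probability
1 − exp(−rate·d), and within-ROH template jumps with probability
1 − exp(−ρ·d), landing uniformly on the K templates. The initial
distribution is the stationary law of the two-macro-state chain.

Defaults (all exposed on `CopyingParams`): ρ = 1 per cM, enter = 0.005 per
cM, exit = 0.01 per cM, θ = 0.001, ε = 0.01. These were fixed a priori as
round, literature-typical magnitudes for low-coverage aDNA: a copying
mosaic on the cM scale, macro-states persistent over tens of cM (prior
ROH fraction 1/3, appropriate for small inbred forager populations), and
a calling error rate dominated by residual damage. The behavioural
contract — not the constants — is what the test suite pins down. When
read data with a known, lower sequencing error are analysed (e.g. the
simulation studies at ε = 0.001), ε should be set to that known value; it
is an input of the method, not a fitted quantity.

Decoding: forward–backward posteriors, ROH = maximal runs with
P(ROH) > 0.5, runs separated by < 0.5 cM merged, segments ≤ 4 cM
discarded. The 0.5 posterior threshold is the symmetric decoding rule and
the 0.5 cM merge absorbs isolated miscalls; both are configurable.
Segment coordinates are closed [first site, last site] (1-based) and
lengths are genetic: pos_cM(last) − pos_cM(first).

Likelihood kernels are computed in scaled linear space with per-site
renormalisation (numba-compiled); exact −inf is returned for genuinely
impossible observations (ε = 0 contradictions). Forward likelihoods are
verified against exhaustive path enumeration on ≤ 6-site instances.

## Contamination inside ROH

A two-pass design: ROH are called assuming c = 0, segments are trimmed
0.5 cM at each edge (boundary uncertainty), and c is then estimated from
the reads inside the trimmed segments. Small contamination biases ROH
boundaries negligibly — contaminant reads look like isolated mismatches,
which the persistent macro-state absorbs — and the detection and
estimation steps stay separately testable.

Within a segment there is no background state (the segment is
conditioned homozygous); the copying path is marginalised by the forward
algorithm and each read is a (1−c)/c mixture of the copied-haplotype and
contaminant allele probabilities (formula in the README). Segment
likelihoods add. The ML point is found by bounded scalar search on
c ∈ [0, 0.5] (tolerance 1e-4) and the 95% CI by the 1.92 log-unit
profile-likelihood drop. Beyond c = 0.5 the endogenous/contaminant labels
are unidentifiable, hence the search bound.

The contaminant allele-frequency vector defaults to the panel's f_s (a
modern contaminant resembling the panel population); a separate vector
can be supplied. When the contaminant matches the copied haplotype the
likelihood is flat in c; the estimator reports this honestly via the
`unidentifiable` flag (CI spanning the whole search interval) rather than
returning an arbitrary interior point. Estimates backed by < 10 cM of
trimmed ROH carry a `low_confidence` flag.

Estimation is per library, matching library-level QC; classification
uses > 10% (substantial) and 5–10% inclusive (marginal) on any available
estimate (mtDNA estimates enter as externally supplied numbers).

## Effective population size from the ROH length spectrum

Within a diploid individual the two homologs coalesce t generations ago
with density (1/(2Ne))·exp(−t/(2Ne)); given t, segment ends arrive at
rate 2t per Morgan, giving the closed-form intensity λ(l) in the README
(interior two-ended segments plus chromosome-edge segments; upper
integration limit truncated at each chromosome's length). The closed form
is verified against numerical time-quadrature to 0.1%.

Segment lengths pooled over individuals form an inhomogeneous Poisson
process; the log-likelihood is Σ log λ(l_i) − n_ind · ∫_{l_min} λ, with
l_min = 0.04 M (the 4 cM calling floor). Ne is maximised on a log scale
over [10, 1e6] and the CI is again the 1.92-drop profile interval. The
likelihood is checked to be unimodal in log Ne on simulated data.

The default genome is 22 autosomes with sex-averaged genetic lengths
rescaled to a 35.4 Morgan total (overridable). The close-kin filter
(≥ 50 cM in ROH > 20 cM) is applied before fitting by default because in
real data very long ROH reflect recent pedigree loops, which the
constant-size model does not describe. In simulation round-trips the
filter must be disabled: at small Ne the constant-size model itself
produces such genomes legitimately, and filtering them would bias the
refit upward. The recovery tests and the acceptance script therefore fit
with `exclude_kin=False`.

## Pairwise statistics and allele frequencies

PMR is the mismatch fraction over jointly covered pseudo-haploid sites.
The relatedness coefficient r = 2(1 − PMR/b) needs a baseline b equal to
the unrelated-pair mismatch level, i.e. the mean *expected*
heterozygosity 2f(1−f). Random-read pseudo-diploid calls observe a het
only when the two sampled reads hit different chromosomes, so their raw
het rate is half that; `group_baseline` doubles the mean pseudo-diploid
het rate accordingly. This satisfies both calibration identities
(unrelated pairs r ≈ 0, self-comparisons r ≈ 1), which is verified by
simulation. A median-PMR-of-unrelated-pairs baseline is available as a
config alternative. Degree labels use conventional midpoints
(0.75 / 0.35 / 0.10), configurable.

ML allele frequencies marginalise each individual's latent diploid
genotype under a Hardy–Weinberg prior at frequency f, with per-read error
ε (default 0.001). The maximiser is located on a 1e-3 grid and refined by
bounded search; the 95% CI is the 1.92-drop profile interval truncated to
[0, 1]. For a single alt read at ε = 0 the likelihood is L(f) = f, so the
lower CI bound is exp(−1.92) ≈ 0.147 — the profile-likelihood interval,
which is narrower than an exact (Clopper–Pearson-style) interval at such
extreme data.

## Genotype calling conventions

Pseudo-diploid draws are *without* replacement, requiring ≥ 2 eligible
reads: a single molecule must not be duplicated into two chromosomes.
Transversion-only filtering for ds_nonUDG libraries is site-level (on the
SNP's ref/alt pair). A Y/Auto ratio exactly at 0.2 is left unassigned —
both decision inequalities are strict. Library merging picks uniformly
per site among non-missing calls, unweighted by coverage. All random
calling takes an explicit seed and is exactly reproducible.

EIGENSTRAT geno digits are treated as alt-allele dosages ({0,2,9} for
pseudo-haploid data, stored internally as 0/1/missing alt indicators with
one conversion point); the .snp genetic-position column is read and
written in Morgans, the dialect of real 1240k-ecosystem files. A .snp
file whose genetic positions are all zero gets them backfilled from a
genome map (default: constant 1 cM/Mb), with a flag recorded.

## The synthetic-data generator

The generator emulates the statistical structure the estimators rely on:

* **panels with LD** — founder haplotypes drawn site-wise from a
  frequency spectrum (default ~Uniform(0.1, 0.9) via a scaled Beta),
  remaining haplotypes as founder mosaics switching templates at 1 per
  cM. Correlation decays with map distance, which makes the copying model
  identifiable.
* **individuals** — two independent panel mosaics, with the second
  haplotype copying the first inside planted ROH; alternatively ROH
  lengths drawn from the constant-size model at a given Ne (inverse-CDF
  sampling of λ, Poisson segment counts per chromosome).
* **reads** — Poisson depth; per read: contaminant with probability c
  (allele from f_s), else a random endogenous chromosome; error flip ε;
  C→T on forward / G→A on reverse strands with the damage rate δ at the
  damage-eligible SNP classes, to exercise the protocol filters.

Default study conditions: 20,000 sites on a 50 cM chromosome, K = 100
panel haplotypes, 1x coverage, ε = 0.001 — a desk-scale single-arm
version of a 1240k-capture experiment.

What it does **not** emulate: read-position-dependent damage profiles
(damage is a per-read flip, since the callers consume counts, not reads),
reference bias, mapping artefacts, panel/target population mismatch, and
contaminants with LD (the contaminant is drawn site-independently from
f_s, exactly matching the estimator's assumption). Passing recovery tests
therefore demonstrate internal consistency of the estimators under their
own assumptions, not robustness to every real-data violation of them.

## Problem sizes used in tests and the acceptance script

The acceptance script refits Ne on 10 cohorts of 10 diploid genomes
(whole 35.4 M autosomal complement) and estimates contamination on 20
replicates per contaminant fraction at the default study conditions
above. Module-level property suites use smaller panels (2,000–6,000
sites, 16–40 haplotypes, 25–50 cM) — these sizes keep each simulation
below a second while leaving the statistical checks well-powered (a 5,000
site × 1x design pins a contamination fraction to about ±1 point).

## Known limitations

* ROH calling and hapROH-style tools are not asserted to be numerically
  equivalent; the model here is a documented reconstruction validated by
  simulation recovery and exhaustive-enumeration checks.
* The contamination estimator assumes the within-ROH state; heavily
  contaminated libraries (> 30–40%) blur ROH detection itself, and the
  two-pass design has only been validated to c = 0.2.
* Constant-size Ne only; recent bottlenecks or growth bias the single
  number in the usual ways.
* X-chromosome ROH, between-individual IBD and phasing are out of scope.
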