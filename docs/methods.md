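# Methods

## Count model

For sample `i`, genomic site `j`, allele `k ∈ {A, C, G, T, DEL}` and read
orientation `s ∈ {forward, reverse}`, the allele count `X` out of coverage
`n` is modeled as beta-binomial,

    X ~ BetaBin(n, μ, ρ),   α = μ(1−ρ)/ρ,   β = (1−μ)(1−ρ)/ρ,

with mean rate μ and intraclass-correlation dispersion ρ shared across
samples (no sample index) and strands. ρ → 0 recovers the binomial; the
implementation evaluates the binomial limit directly below ρ = 1e-10,
where the log-beta route loses precision (the α, β parameters grow like
1/ρ and log-gamma cancellation error exceeds the pmf itself). Above that
threshold the pmf is computed through `scipy.stats.betabinom`. Means of
0 or 1 are treated as the degenerate point masses.

Counts come from a strand-aware pileup: a read base contributes to
exactly one allele slot; bases below the base-quality threshold
(default 25), bases called N, and reads below the mapping-quality
threshold (default 30) are removed from both counts and coverage, so
error rates are always relative to quality-passing reads and coverage
equals the allele-count sum. A deletion (CIGAR `D`) spanning a site
counts toward the DEL allele; reference skips (`N`) contribute nothing —
panel data is DNA and skips indicate artifacts. Insertions are not
tallied. Coordinates are 0-based half-open internally; every file
interface (count table, VCF, catalogues) is 1-based.

## Aggregate controls and point estimates

Instead of a matched normal, each hypothesis uses the cohort itself: the
reference set J(i) contains every other sample whose combined-strand VAF
at (site, allele) is strictly below a threshold (default 0.1; samples
without coverage count as VAF 0 and stay in). Aggregate control counts
are the element-wise sums over J(i). The null pools the target with its
controls at one rate per strand,

    μ̂_s = (X_s + x_s + c) / (N_s + n_s + 2c),

with pseudocount c = 0.5 (Jeffreys-like). The pseudocount keeps μ̂
strictly inside (0, 1); a zero error-rate estimate would make the Bayes
factor degenerate at the first variant read. A config switch
(`pool_target=False`) gives strict leave-one-out rates for sensitivity
analysis. The M1 plug-in is ν̂_s = x_s/n_s (0 at zero coverage);
`nu_mode="excess"` optionally subtracts μ̂ first, for the reading that an
observed VAF is the sum of the true allele frequency and the error rate.

## Dispersion

ρ is estimated per (site, allele) from the reference samples' combined
VAFs ν_i and coverages n_i by the method of moments: with μ̄ the
coverage-weighted mean VAF, s² the sample variance of ν_i and
m = mean(1/n_i),

    ρ̂ = (s² − μ̄(1−μ̄) m) / (μ̄(1−μ̄)(1 − m)),

clamped to [ρ_min, ρ_max] = [1e-4, 0.1]. For equal coverages this is the
classical intraclass-correlation estimator and is consistent (recovery is
tested by simulation; the estimator, not a closed form, is the contract).
Degenerate inputs — fewer than two covered samples, μ̄ on the boundary,
zero variance — return ρ_min. A fixed ρ can be configured instead
(`rho_fixed`), which the benchmark uses for its fixed-dispersion runs.

## Model selection and priors

M0 states the sample's rate equals the pooled error rate on the forward
OR the reverse strand; M1 that both strands exceed it. The OR makes
single-strand artifacts null by construction. With L_s(θ) the
beta-binomial likelihood of strand s, the plug-in Bayes factor is

    BF = [L_f(μ̂_f)L_r(ν̂_r) + L_f(ν̂_f)L_r(μ̂_r) − L_f(μ̂_f)L_r(μ̂_r)]
         / [L_f(ν̂_f)L_r(ν̂_r)],

an inclusion–exclusion over the two ways of being null, floored at 0.
The subtracted term is usually negligible when both ν̂ differ from the
error rates; a config switch (`numerator="additive"`) keeps the plain
two-term sum. All products are assembled in log space; a strand with
zero coverage contributes factor 1, so a hypothesis with an uncovered
strand (or no coverage at all) has BF = 1 — no evidence either way, a
deliberate conservative property of the OR null at region flanks. If
both numerator and denominator underflow, BF = 1. The strand-agnostic
variant (`strand_mode="agnostic"`) pools strands into a single
comparison L(μ̂)/L(ν̂) and trades specificity for power where coverage is
one-sided.

Priors: a hotspot catalogue (gene, site, alt, observation count) yields
per-gene histograms h_jk = count_jk / Σ counts, and
π_jk = P(gene mutated) · h_jk, clipped inside (0, 1); sites off the
catalogue get a constant π0 = 1e-4 (configurable and logged — with the
default posterior cutoff 0.5 this makes the effective BF cutoff
π0/(1−π0) ≈ 1e-4). The gene probability defaults to a uniform 0.05 per
gene, with per-gene overrides by TSV. The posterior is
P(M0|D) = BF(1−π)/(BF(1−π)+π); calls are made at P(M0|D) ≤ 0.5, the
natural Bayes cutoff. A local exclusion list (chrom, pos, alt) drops
known polymorphisms after calling, keeping the core caller
database-free. Reference alleles are never tested.

## Synthetic cohorts

The generator emulates a targeted panel: per-(sample, site) coverages
either fixed (deterministic strand split) or lognormal with median 128×
and log-sd σ = 1.02, split binomially between strands. The lognormal is
calibrated to a deeply sequenced normal control summarized by median
128×, 5th percentile 13×, 95th percentile 372×; a two-parameter
lognormal cannot match both tail quantiles (they imply σ = 1.39 and
0.65 respectively), so σ is their log-space least-squares compromise.
Background error reads are beta-binomial per strand with site-specific
rates (constant 1e-3 by default; a mixture option makes a fraction of
site-strands high-error, emulating recurrent artifacts). Implanted
variants add binomial(coverage, VAF) reads on both strands on top of the
background — signal plus noise — capped at coverage; optional germline
polymorphisms implant VAF ≈ 0.5 in a chosen fraction of samples. A
Dirichlet mode draws the whole per-site VAF vector across samples from a
symmetric Dirichlet instead of fixed implants; both paths share the read
sampler. Every draw flows from one `numpy` Generator seeded by the
mandatory config seed; benchmark cells derive independent child seeds by
hashing (seed, cell, replicate), so each cell is reproducible on its own.

What the generator does **not** emulate: the heterogeneous per-site
error-rate spectrum of a real capture panel (under the constant-rate
default every site is equally clean), mapping and alignment artifacts,
batch effects, and correlated errors between samples sharing a library
preparation. Consequences: power and AUC measured on the default clean
background are systematically *higher* at low VAF than on real panels,
where high-error sites mask faint variants — passing benchmark numbers
here demonstrate correctness of the machinery under its stated model,
not field performance. Specificity numbers likewise reflect an idealized
null.

## Benchmarks

Power: for each (VAF, coverage) cell the benchmark simulates cohorts of
500 samples (default) with one implanted carrier per site, scores the
implanted hypotheses through the full caller (reference sets, aggregate
controls, μ̂, ρ fixed or estimated, BF) and reports the fraction below a
Bayes-factor cutoff — default the cutoff equivalent to the configured
posterior cutoff, 0.05/0.95 in the headline runs (posterior odds 1 under
a uniform prior of 0.05) — with exact binomial confidence intervals. AUC:
implants at half the sites, one matched null hypothesis per remaining
site, rank-based AUC of −BF with mid-rank ties (unscorable hypotheses
count as BF = 1). Problem sizes in the shipped runs — 1000 implanted
sites per power cell, 2000 hypotheses per AUC point, 100 cohorts for
dispersion recovery — keep Monte-Carlo error near or below one
percentage point while the whole suite stays a few-minute run.

## Numerical and design notes

- Beta-binomial parameterization fixed as α = μ(1−ρ)/ρ (standard
  intraclass form); only mean/dispersion semantics are inherent to the
  model.
- VCF output is plain deterministic text with full-precision float
  `repr`, so BF/posterior fields round-trip exactly (binary VCF FORMAT
  floats are 32-bit and would not); output is parsed back with pysam in
  tests. Single-base deletions are anchored one base upstream
  (two-base REF, one-base ALT) per VCF convention.
- Ties and degenerate inputs: empty reference set → hypothesis skipped
  and logged; empty aggregate (all-zero controls) is handled by the
  pseudocount; VAF of an uncovered sample is 0 by definition.
- Calls are per allele: multiple alternative alleles at one site are
  independent tests.
- Known limitations: no matched-normal mode, no insertions, no
  base-quality weighting (hard thresholds only), no joint multi-sample
  genotyping, single-base deletions only.
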