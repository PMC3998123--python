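# shearwater

Calling clonal and subclonal single-nucleotide variants (and single-base
deletions) in large targeted-resequencing cohorts.

## The problem

Deep targeted sequencing of cancer genes across hundreds of samples can
reveal mutations carried by only a small fraction of cells — but at variant
allele frequencies (VAF) of a few percent, true variants are easily drowned
out by sequencing and library artifacts, which recur at specific sites and
often on one read orientation only. With a large cohort, however, every
sample's error profile can be measured precisely at each site from all the
*other* samples. This package implements that idea:

- **Strand-specific beta-binomial error model.** The count `X_ijk` of
  nucleotide `k` at site `j` in sample `i` (per read orientation) is modeled
  as beta-binomial with site-specific mean error rate μ and dispersion ρ
  (intraclass correlation; ρ = 0 reduces to binomial). Error rates are
  estimated from a leave-one-out **aggregate control**: the pooled counts of
  all other samples with VAF below a threshold (default 10%) at that site.
- **Bayes-factor test.** The null model M0 says the sample's rate equals the
  pooled error rate on the forward **or** the reverse strand — so purely
  single-strand signals stay null — while M1 requires elevated rates on both
  strands. With plug-in point estimates (method of moments) the Bayes factor
  is

  ```
  BF = [ L_f(μ_f) L_r(ν_r) + L_f(ν_f) L_r(μ_r) − L_f(μ_f) L_r(μ_r) ]
       / [ L_f(ν_f) L_r(ν_r) ]
  ```

  where `L_s(θ)` is the beta-binomial likelihood of strand `s` at rate θ,
  μ the pooled error rates and ν = x/n the sample VAFs. Small BF favors a
  variant.
- **Hotspot priors.** A somatic-mutation catalogue is converted into a
  per-site, per-allele prior π = P(gene mutated) × (relative frequency of
  that mutation in the gene), with a small default π0 elsewhere. Bayes'
  formula combines BF and π into the posterior null probability
  `P(M0|D) = BF(1−π) / (BF(1−π) + π)`; variants are called below a cutoff
  (default 0.5).
- **Dispersion estimation.** ρ is estimated per site and allele by the
  beta-binomial method-of-moments (intraclass-correlation) estimator from
  the reference samples' VAFs, clamped to [1e-4, 0.1], or fixed by config.
- **Simulation benchmark.** A synthetic-cohort generator (fixed or
  lognormal coverage profiles, strand-specific error rates, beta-binomial
  background, implanted variants, optional germline polymorphisms and
  Dirichlet VAF draws) plus power and ROC-AUC evaluation over (VAF,
  coverage) grids.

## Worked example

`examples/call_simulated_cohort.py` simulates 50 samples over 20 sites at
200× per strand with a 1e-3 error rate, implants five variants at VAF 10%,
and runs the caller:

```
implanted 5 variants, called 5:
sample   site alt    VAF        BF   P(M0|D)
S0038       0   T  0.090  1.35e-05  1.19e-01
S0032       4   G  0.125  9.71e-13  9.71e-09
S0029       6   T  0.080  2.05e-08  2.05e-04
S0008       9   C  0.105  2.31e-06  2.25e-02
S0045      12   T  0.100  1.23e-09  1.23e-05
missed implants: 0; false calls: 0
```

Every implanted variant is recovered with a Bayes factor far below 1 (the
data are orders of magnitude more probable under "variant on both strands"
than under the pooled error model) and no clean hypothesis is called. The
posterior uses the default prior π0 = 1e-4, so e.g. BF = 1.35e-5 becomes
P(M0|D) = 0.119. The other examples print a power grid
(`power_benchmark.py` — power rises from 8% at VAF 2%/100× to 100% at VAF
10%/250×) and the effect of a hotspot prior (`hotspot_prior.py` — a
catalogued hotspot tolerates a ~500× larger Bayes factor than an
uncatalogued site at the same posterior cutoff).

## Command line

```bash
shearwater count --bam-list bams.tsv --bed targets.bed -o counts.tsv
shearwater call --counts counts.tsv --ref genome.fa \
    --hotspots hotspots.tsv --gene-prob 0.05 -o calls.vcf
shearwater prior-build --hotspots hotspots.tsv -o prior.tsv
shearwater simulate --config sim.yaml --seed 11 -o sim_counts.tsv
shearwater benchmark --vaf-grid 0.05,0.1 --coverage-grid 100,250 \
    --seed 11 -o bench.tsv
```

Count tables are TSV (`sample chrom pos strand A C G T DEL coverage`,
1-based positions); calls are written as VCF 4.2 with per-sample
`BF:PM0:VF:FD:RD:FC:RC` fields and the prior in `INFO/PI`. All thresholds
(posterior cutoff, π0, VAF threshold, ρ bounds or fixed ρ, strand mode,
numerator mode, pseudocount) are exposed as flags and YAML config keys.

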