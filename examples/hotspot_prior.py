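"""How a mutation-hotspot prior shifts the calling threshold.

A catalogue of observed somatic mutations in a gene is turned into a
per-site, per-allele prior: the relative frequency of each mutation,
scaled by the probability that the gene is mutated at all.  For the same
Bayes factor, a hotspot needs much weaker evidence to be called than an
uncatalogued site with the default prior pi0.
"""

from shearwater import (
    bf_cutoff_for_posterior,
    build_mutation_histogram,
    build_prior_track,
    posterior_null,
)

# (site, alt allele, times observed) for one gene, e.g. a splicing factor
catalogue = [
    (("chr2", 198266833), "C", 97),   # recurrent hotspot
    (("chr2", 198266834), "T", 2),
    (("chr2", 198267490), "A", 1),
]
hist = build_mutation_histogram(catalogue)
prior = build_prior_track({"SF3B1": hist}, gene_probs=0.05, pi0=1e-4)

print("site           alt     prior pi   BF needed for P(M0|D) <= 0.5")
for (chrom, pos), alt, _ in catalogue:
    pi = prior.get(chrom, pos, alt)
    print(f"{chrom}:{pos}  {alt}   {pi:9.2e}   {bf_cutoff_for_posterior(0.5, pi):9.2e}")
pi0 = prior.pi0
print(f"elsewhere       .   {pi0:9.2e}   {bf_cutoff_for_posterior(0.5, pi0):9.2e}")

bf = 1e-3  # moderate evidence
print(f"\nwith BF = {bf:g}: posterior at the hotspot = "
      f"{posterior_null(bf, prior.get('chr2', 198266833, 'C')):.4f}, "
      f"at a default site = {posterior_null(bf, pi0):.4f}")
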