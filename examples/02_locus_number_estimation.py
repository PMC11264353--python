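"""Estimate how many loci a gene family has from allelism-free counts.

A diploid individual carries at most 2L distinct variants of an L-locus
family, so half the distinct-variant count per individual estimates L.
Three aggregations are shown (the single most variant-rich individual, the
mean, the median), plus the proportion-based variant that uses the smallest
within-individual read proportion (a single allele copy out of 2L draws
about 1/(2L) of the reads).
"""
from shannonhet import PopulationProfile, VariantProfile, estimate_loci

population = PopulationProfile(
    [
        VariantProfile("a", {f"v{k}": 1 for k in range(7)}),  # 7 variants
        VariantProfile("b", {"v0": 2, "v1": 1, "v2": 1}),     # 3 variants
        VariantProfile("c", {"v0": 3, "v3": 1}),              # 2 variants
    ]
)

for method in ("one_individual", "mean", "median"):
    est = estimate_loci(population, method)
    print(f"{method:15s} raw={est.raw:5.2f}  rounded L={est.rounded}")

est = estimate_loci(population, "one_individual", proportion_based=True)
print(f"proportion-based one_individual: raw={est.raw:5.2f} rounded L={est.rounded}")
print()
print(
    "Raw estimates are halves of per-individual variant richness; they are\n"
    "rounded half-up with a floor of one locus. The one-individual method\n"
    "is a lower bound on L and reaches it when some individual is\n"
    "heterozygous at every locus with all-distinct variants."
)
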