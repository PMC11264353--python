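"""Compute the Shannon heterozygosity statistic on a toy variant table.

Four individuals were sequenced for a two-locus gene family. We only know
which variants each individual carries and in what read proportions — not
which locus each variant belongs to — so classical F_IS is unavailable and
we use the Shannon analogue ¹H_IS instead.
"""
from shannonhet import (
    PopulationProfile,
    VariantProfile,
    his_from_profiles,
)

# read counts per individual; rows of a wide TSV would look the same
population = PopulationProfile(
    [
        VariantProfile("ind1", {"v1": 12, "v2": 11}),       # two variants
        VariantProfile("ind2", {"v1": 25}),                 # apparently fixed
        VariantProfile("ind3", {"v1": 9, "v3": 10}),
        VariantProfile("ind4", {"v1": 24, "v2": 2}),
    ]
)

result = his_from_profiles(population, loci=2)

print(f"mean individual Shannon information H_I (bar): {result.h_bar:.4f} nats")
print(f"population Shannon information H_S:            {result.h_s:.4f} nats")
print(f"evenness EV = H_S / ln V:                      {result.evenness:.4f}")
print(f"1H_IS with L = {result.loci} loci:                      {result.his:+.4f}")
print()
print(
    "A positive value means individuals hold less variant diversity than\n"
    "the population offers - a heterozygote deficit, as produced by\n"
    "inbreeding, positive assortative mating or selection against\n"
    "heterozygotes. Negative values would indicate heterozygote excess."
)
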