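"""Validate ¹H_IS against F_IS on a small simulated sweep.

Forward-time simulations generate populations with known heterozygote
excess or deficit (random mating, closed family groups, heterozygote
selection). Each replicate yields a classical multiple F_IS (computed with
full allelism) paired with ¹H_IS (computed after the locus labels are
discarded). Agreement is summarized by regressing F_IS on ¹H_IS.
"""
import numpy as np

from shannonhet import ScenarioConfig, assess_sweep, run_sweep

grid = [
    ScenarioConfig(mating="random", selection="none", loci=5,
                   distribution="even", generations=10, pop_size=40),
    ScenarioConfig(mating="inbred_small_family", selection="none", loci=5,
                   distribution="even", generations=10, pop_size=40),
    ScenarioConfig(mating="random", selection="strong_het", loci=5,
                   distribution="even", generations=10, pop_size=40),
]

pairs = run_sweep(grid, replicates=30, seed=12)
usable = pairs[pairs.flag == "ok"]
print(f"{len(usable)} usable replicates of {len(pairs)}")
for (mating, selection), group in usable.groupby(["mating", "selection"]):
    print(
        f"  {mating:20s} {selection:10s} "
        f"mean F_IS {group.fis.mean():+.3f}  mean 1H_IS {group.his.mean():+.3f}"
    )

summary = assess_sweep(pairs, "all", np.random.default_rng(0), binned=False)["all"]
print(
    f"\nOLS of F_IS on 1H_IS: slope={summary.slope:.3f} "
    f"R^2={summary.r_squared:.3f} RMSE={summary.rmse:.3f} (n={summary.n_points})"
)
print(
    "\nClosed family groups push both statistics up (heterozygote deficit)\n"
    "relative to random mating; a positive slope with substantial R^2 means\n"
    "the allelism-free statistic recovers the classical F_IS signal."
)
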