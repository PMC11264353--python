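# Methods

## The statistic

For one individual with variant read (or allele-copy) proportions p_i over
the v variants it carries, the Shannon information is H_I¹ = −Σ p_i ln p_i;
H̄_I¹ averages this over individuals. Population proportions P_i give
H_S¹ = −Σ P_i ln P_i over the V variants present, and the genetic evenness
EV = H_S¹ / ln V ∈ (0, 1] is 1 when all variants are equally frequent.
With L loci in the family,

    ¹H′_IS = −( H̄_I¹ (L+1) / H_S¹ − L ),      ¹H_IS = ¹H′_IS · EV.

The rationale: under heterozygote excess individuals hold nearly all of the
population's variant diversity (H̄_I¹/H_S¹ → 1 and the bracket → −1); under
deficit they hold little. The (L+1)/…−L weighting compensates the ceiling
that 2L allele copies put on H_I¹ — a diploid individual sampling 2L copies
from an even pool of V variants has E[H_I¹] ≈ H_S¹ − (V−1)/(4L) (the usual
plug-in entropy bias), which the weighting absorbs so that panmictic
populations score near 0. The evenness factor corrects the residual
sensitivity to skewed variant pools. Values slightly above +1 can occur
stochastically; the reporting layer can clamp them to +1 (flagged), and the
assessment pipeline does so by default.

Degenerate inputs surface as typed errors rather than NaN: a population
carrying a single variant (total fixation) has H_S¹ = 0 and no defined
statistic; V < 2 leaves evenness undefined. When each locus is fixed for a
different variant, every individual looks maximally and identically
diverse: ¹H_IS = −EV = −1 even though no heterozygosity exists. Such data
are detectable through zero between-individual variance of H_I¹ and are
excluded by the replicate filter (below); partially fixed families are the
statistic's known blind spot and bias it negative.

Natural logarithms are used throughout; 0·ln 0 = 0. Population proportions
default to the mean of per-individual proportion vectors (robust to
unequal read depth); pooled raw counts are available as an option and
coincide for equal-depth data.

## Classical reference statistics

For allelism-aware genotypes, He = 1 − Σ P̃_i² (sample allele proportions),
Ho is the observed heterozygote fraction, and F_IS = (He − Ho)/He per
locus; multiple F_IS averages the per-locus values over loci that are
polymorphic in the sample (monomorphic loci carry no information and are
skipped; a fully monomorphic table raises). No small-sample correction is
applied.

## Locus-number estimation

A diploid individual carries at most 2L distinct variants, so per-individual
variant richness estimates 2L. Aggregations: `one_individual` (maximum over
individuals), `mean`, `median`; raw estimates are rounded half-up with a
floor of 1 (the only rounding consistent with all published raw/rounded
pairs). The default basis is the distinct-variant count. A proportion-based
basis — per individual, 2L ≈ 1/(smallest within-individual variant
proportion), since a single allele copy draws ≈ 1/(2L) of the reads — is
available via `proportion_based=True`; it recovers the true L in simulated
allele-copy data whenever some individual carries a singleton copy, which
the count basis cannot once variants are shared across loci (richness caps
at the variant-pool size). The simulation sweep therefore uses the
proportion-based one-individual estimator; for real read data, where
stochastic depth makes the extremes noisy, the median or mean of either
basis is the safer choice.

## Forward-time simulator

Diploid, constant population size N ∈ {40, 400}, non-overlapping
generations (10/30/50), L ∈ {3, 5, 10} unlinked loci, no mutation. Ten
variant types are shared across loci — the same variant can occur at any
locus, which is what makes allelism unrecoverable after conversion.
Genotypes are stored as an (N, L, 2) integer array; each generation every
offspring draws two distinct parents from its mating pool with probability
proportional to the selection weight and inherits one allele per locus from
each, independently per locus.

*Selection* assigns each locus a pass probability — (p_hom, p_het) =
(0.60, 0.50) mild homozygote advantage, (0.20, 0.60) mild heterozygote
advantage, (0.00, 1.00) strong heterozygote advantage — multiplied across
loci into a parent-acceptance weight. Selection acts only on parent
choice; offspring are never culled, so each censused generation is a
random union of gametes from the weighted pool. A consequence worth
stating plainly: censused genotype frequencies stay near Hardy–Weinberg,
and the mild schemes shift mean F_IS only marginally; the strong scheme
produces a clear heterozygote excess because the qualifying parent pool
(heterozygous at every locus) is small. A replicate in which fewer than
two acceptable parents remain is restarted afresh up to three times, then
flagged failed and carried with its flag.

*Mating* is either whole-population random mating or closed family groups
(`inbred_small_family`): the population is partitioned once into persistent
groups of `family_size` (default 8) whose offspring replace their own
group. Random union without selfing in a group of n has effective size
≈ n + 1/2, so inbreeding accumulates at ΔF ≈ 1/17 per generation and the
expected F_IS after t generations is 1 − (1 − 1/17)^t: ≈ 0.45 at t = 10 and
≥ 0.8 by t = 30, matching the cluster structure the method is validated
against. Size 8 divides both default population sizes.

*Initial frequencies*: `even` gives every variant frequency 0.1 at every
locus. `uneven` draws an integer weight per variant per locus from a
unit-rate Poisson distribution (redrawing a locus while all weights are
zero) and normalizes: strongly unequal proportions whose mean is still
1/10, with some variants absent per locus. The rate is a design choice;
much sparser draws (e.g. rate 0.1) leave most loci fixed from the start,
which floods the data with the partial-fixation pattern the statistic is
known to misread and makes the locus count unestimable — under that regime
the uneven arm of the validation collapses rather than, as observed on
real-data-scale simulations, performing comparably to the even arm.

Randomness: one `numpy` Generator per (scenario, replicate), spawned as
`SeedSequence(master_seed, spawn_key=(scenario_index, replicate))`, so
sweeps are reproducible and order-independent.

## Validation pipeline

Each replicate yields multiple F_IS from the true allelism and ¹H_IS from
the converted (locus-label-free) profiles with the one-individual locus
estimate. Replicates are dropped when the population carries one variant
(no variation) or when the between-individual variance of H_I¹ is ≤ 1e-12
(exact zero up to floating point — the locus-specific-fixation signature);
the tolerance is configurable. ¹H_IS is clamped at +1.

F_IS values are binned at width 0.1 over [−1.05, +1.05), half-open on the
right; from every nonempty bin the size of the smallest nonempty bin is
drawn without replacement (the one balanced design needing no discard
rule), and F_IS is regressed on ¹H_IS by OLS (statsmodels; slope p-value
from the classical t-test). RMSE = sqrt(Σ(¹H_IS − F_IS)²/n). Because
extreme bins hold few replicates, a single balanced subsample is small and
its R² noisy; `assess_sweep(n_draws=...)` averages the summary over
independent draws and is used for reported values. Unbinned summaries over
the full filtered set are also available (`binned=False`) and are the
stabler basis for comparing subgroups; RMSE is defined over all values
used, so the unbinned RMSE is the primary accuracy number.

Problem sizes: the package's own validation runs the full 180-scenario
grid at 100 replicates per scenario (18,000 simulations, a few minutes
vectorized on one CPU); the test suite uses 50 replicates. Typical results
at these sizes: combined binned R² ≈ 0.71–0.80 with slope well above 0 and
p < 0.001; unbinned R² rising with the number of loci (≈ 0.54 / 0.60 /
0.69 for 3/5/10 loci) and unbinned RMSE falling (≈ 0.30 → 0.23); even- and
uneven-distribution arms performing comparably, with the uneven arm ahead
on some sweeps and behind on others (the difference is within
sweep-to-sweep noise).

## What the synthetic data do and do not show

The simulator provides exact allele-copy profiles: read proportions equal
allele-copy proportions, every carried variant is observed, and depth is
uniform. Real amplicon data add depth stochasticity (emulated by
`sample_reads`' multinomial model, at a common per-individual depth),
sequencing artefacts (the per-individual 10% proportion filter is provided
for cleaning but is not part of the simulation pipeline), amplification
bias, and chimeras — none of which are modelled. Passing validation
therefore shows the statistic tracks F_IS given faithful variant
proportions; it does not certify robustness to platform-specific noise,
nor does it resolve which biological mechanism (assortative mating,
selection, Wahlund effect) produced a given excess or deficit.

## Known limitations

- Partial locus-specific fixation biases ¹H_IS negative and is not
  detectable from allelism-free data; only the complete case (zero H_I¹
  variance) is filtered.
- The statistic's magnitude depends on the locus-number estimate;
  overestimating L inflates positive values (visible in the published
  one-individual rows).
- Multi-allelic variants are assumed; biallelic SNP families would need
  different machinery.
- No confidence intervals or permutation tests are provided for ¹H_IS.
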