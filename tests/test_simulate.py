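"""Forward-time simulator: configs, reproduction mechanics, sanity checks."""
import numpy as np
import pytest

from shannonhet import (
    Distribution,
    InvalidInputError,
    ScenarioConfig,
    SELECTION_SCHEMES,
    estimate_loci,
    evolve,
    full_grid,
    genotypes_to_profiles,
    his_from_profiles,
    init_population,
    initial_frequencies,
    multiple_fis,
    parent_acceptance_prob,
    run_sweep,
)
from shannonhet.simulate import (
    _evolve_alleles,
    _fis_int,
    _his_summary,
    _profile_matrix,
    _to_table,
)


class TestScenarioConfig:
    def test_inbred_with_selection_rejected(self):
        with pytest.raises(InvalidInputError):
            ScenarioConfig(mating="inbred_small_family", selection="strong_het")

    def test_family_size_must_divide_population(self):
        with pytest.raises(InvalidInputError):
            ScenarioConfig(
                mating="inbred_small_family", pop_size=42, family_size=8
            )

    def test_selection_scheme_probabilities(self):
        assert SELECTION_SCHEMES["mild_hom"].p_hom == 0.60
        assert SELECTION_SCHEMES["mild_hom"].p_het == 0.50
        assert SELECTION_SCHEMES["mild_het"].p_hom == 0.20
        assert SELECTION_SCHEMES["mild_het"].p_het == 0.60
        assert SELECTION_SCHEMES["strong_het"].p_hom == 0.00
        assert SELECTION_SCHEMES["strong_het"].p_het == 1.00

    def test_full_grid_has_180_scenarios(self):
        grid = full_grid()
        assert len(grid) == 180
        # 2 mating-only + 3 selection schemes
        schemes = {(c.mating.value, c.selection) for c in grid}
        assert len(schemes) == 5


class TestInitialFrequencies:
    def test_even(self):
        f = initial_frequencies("even", 10, np.random.default_rng(0), n_loci=3)
        assert f.shape == (3, 10)
        assert np.allclose(f, 0.1)

    def test_uneven_normalized_and_reproducible(self):
        f1 = initial_frequencies("uneven", 10, np.random.default_rng(5), n_loci=4)
        f2 = initial_frequencies("uneven", 10, np.random.default_rng(5), n_loci=4)
        assert np.allclose(f1.sum(axis=1), 1.0)
        assert (f1 >= 0).all()
        assert np.array_equal(f1, f2)
        # every locus has at least one variant
        assert (f1.max(axis=1) > 0).all()


class TestInitPopulation:
    def test_shape_and_determinism(self):
        cfg = ScenarioConfig(loci=3, pop_size=40, seed=1)
        t1 = init_population(cfg, np.random.default_rng(3))
        t2 = init_population(cfg, np.random.default_rng(3))
        assert t1.n_individuals == 40 and t1.n_loci == 3
        assert (t1.alleles == t2.alleles).all()

    def test_even_sampling_frequencies(self):
        cfg = ScenarioConfig(loci=2, pop_size=400, variants_per_locus=10)
        table = init_population(cfg, np.random.default_rng(11))
        for locus in table.loci:
            props = table.allele_proportions(locus)
            se = np.sqrt(0.1 * 0.9 / 800)
            for p in props.values():
                assert abs(p - 0.1) < 3 * se + 1e-9


class TestParentAcceptance:
    def test_strong_het_all_heterozygous(self):
        geno = [("A", "B"), ("C", "D"), ("A", "C")]
        assert parent_acceptance_prob(geno, SELECTION_SCHEMES["strong_het"]) == 1.0

    def test_strong_het_any_homozygous(self):
        geno = [("A", "B"), ("C", "C"), ("A", "C")]
        assert parent_acceptance_prob(geno, SELECTION_SCHEMES["strong_het"]) == 0.0

    def test_mild_hom_product(self):
        geno = [("A", "A"), ("B", "B"), ("A", "B")]
        assert parent_acceptance_prob(
            geno, SELECTION_SCHEMES["mild_hom"]
        ) == pytest.approx(0.6 * 0.6 * 0.5)


class TestEvolve:
    def test_allele_copy_conservation_and_no_mutation(self):
        cfg = ScenarioConfig(
            loci=4, pop_size=20, generations=5, distribution="uneven", seed=3
        )
        rng = np.random.default_rng(3)
        start = sorted(
            np.unique(init_population(cfg, np.random.default_rng(3)).alleles)
        )
        rep = evolve(cfg, np.random.default_rng(3))
        table = rep.final_genotypes
        assert table.alleles.shape == (20, 4, 2)
        # no variant IDs outside the founding set (no mutation)
        assert set(np.unique(table.alleles)) <= set(start)
        for prof in genotypes_to_profiles(table):
            assert prof.total == 2 * cfg.loci

    def test_deterministic_given_seed(self):
        cfg = ScenarioConfig(loci=3, pop_size=16, generations=4, seed=9)
        a = evolve(cfg).final_genotypes.alleles
        b = evolve(cfg).final_genotypes.alleles
        assert (a == b).all()

    def test_neutral_random_mating_fis_near_zero(self):
        """Hardy-Weinberg null: neutral random mating, N=400."""
        values = []
        cfg = ScenarioConfig(
            loci=5, pop_size=400, generations=10, distribution="even"
        )
        for r in range(100):
            rng = np.random.default_rng(np.random.SeedSequence(0, spawn_key=(r,)))
            alleles, _ = _evolve_alleles(cfg, rng)
            values.append(_fis_int(alleles))
        assert abs(float(np.mean(values))) < 0.02

    def test_neutral_drift_heterozygosity_decline(self):
        """E[He_t] ~ He_0 (1 - 1/(2N))^t under neutral drift."""
        n, t, reps = 40, 15, 200
        cfg = ScenarioConfig(
            loci=2, pop_size=n, generations=t, distribution="even"
        )
        he = []
        for r in range(reps):
            rng = np.random.default_rng(np.random.SeedSequence(1, spawn_key=(r,)))
            alleles, _ = _evolve_alleles(cfg, rng)
            for j in range(cfg.loci):
                counts = np.bincount(alleles[:, j, :].ravel(), minlength=10)
                p = counts / counts.sum()
                he.append(1 - (p**2).sum())
        expected = 0.9 * (1 - 1 / (2 * n)) ** t
        observed = float(np.mean(he))
        se = float(np.std(he) / np.sqrt(len(he)))
        assert abs(observed - expected) < max(4 * se, 0.02)

    def test_inbred_small_family_fis_cluster(self):
        """Persistent mating groups of 8 accumulate F_IS ~ 0.45 by
        generation 10 (the line-inbreeding expectation 1 - (1 - 1/17)^10)."""
        cfg = ScenarioConfig(
            mating="inbred_small_family", loci=5, pop_size=40, generations=10
        )
        values = []
        for r in range(100):
            rng = np.random.default_rng(np.random.SeedSequence(2, spawn_key=(r,)))
            alleles, _ = _evolve_alleles(cfg, rng)
            f = _fis_int(alleles)
            if np.isfinite(f):
                values.append(f)
        assert 0.3 < float(np.mean(values)) < 0.6

    def test_strong_het_failure_flagged(self):
        # two individuals cannot both stay fully heterozygous forever at
        # high loci counts with a fixed-from-start locus
        cfg = ScenarioConfig(
            selection="strong_het", loci=10, pop_size=10, generations=30,
            distribution="uneven",
        )
        reps = [evolve(cfg, np.random.default_rng(s)) for s in range(6)]
        assert any(r.failed for r in reps)
        for r in reps:
            if r.failed:
                assert r.final_genotypes is None


class TestFastPathsMatchPublicApi:
    @pytest.mark.parametrize("seed", range(4))
    def test_summary_matches_profiles(self, seed):
        cfg = ScenarioConfig(
            loci=4, pop_size=24, generations=6,
            distribution="uneven" if seed % 2 else "even",
        )
        alleles, _ = _evolve_alleles(cfg, np.random.default_rng(seed))
        table = _to_table(cfg, alleles)
        pop = genotypes_to_profiles(table)
        summary = _his_summary(_profile_matrix(alleles, cfg.variants_per_locus))
        if summary["n_variants"] >= 2:
            est = estimate_loci(pop, "one_individual", proportion_based=True)
            assert summary["loci_est"] == est.rounded
            res = his_from_profiles(pop, est.rounded)
            assert summary["his"] == pytest.approx(res.his_raw, abs=1e-10)
            assert summary["h_bar"] == pytest.approx(res.h_bar, abs=1e-10)
            assert summary["h_s"] == pytest.approx(res.h_s, abs=1e-10)
        fis = _fis_int(alleles)
        if np.isfinite(fis):
            assert fis == pytest.approx(multiple_fis(table), abs=1e-10)


class TestRunSweep:
    def test_one_scenario_one_replicate(self):
        grid = [ScenarioConfig(loci=3, pop_size=16, generations=3)]
        out = run_sweep(grid, replicates=1, seed=5)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["flag"] in {"ok", "failed", "no_population_variation",
                               "zero_hi_variance"}

    def test_same_seed_reproducible(self):
        grid = [ScenarioConfig(loci=3, pop_size=16, generations=3)]
        a = run_sweep(grid, replicates=4, seed=7)
        b = run_sweep(grid, replicates=4, seed=7)
        assert a.equals(b)

    def test_selection_direction_strong_het(self):
        """Strong heterozygote selection restricts the parent pool to
        all-heterozygous individuals, producing heterozygote excess."""
        grid = [
            ScenarioConfig(selection=s, loci=5, pop_size=40, generations=10)
            for s in ("none", "strong_het")
        ]
        out = run_sweep(grid, replicates=60, seed=11)
        ok = out[out.flag == "ok"]
        means = ok.groupby("selection")["fis"].mean()
        assert means["strong_het"] < means["none"]
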