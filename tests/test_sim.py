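import dataclasses

import numpy as np
import pytest

from admixscan.genome import GenomeMap, MarkerGrid, validate_haploid
from admixscan.sim import (
    BEEFMASTER,
    BRANGUS_SG,
    CrossingScheme,
    FoundingStep,
    SelectionSpec,
    SimCohort,
    cross,
    emit_window_calls,
    expected_tract_count,
    founder,
    iid_cohort,
    meiosis,
    next_generation,
    run_scheme,
    simulate_design,
)

from conftest import AB


def _f1(gmap, rng):
    return cross(founder("Angus", gmap, AB), founder("Brahman", gmap, AB), gmap, rng, "F1")


class TestFounder:
    def test_brahman_founder_58_tracts(self, bovine_map):
        g = founder("Brahman", bovine_map, AB)
        assert g.n_tracts() == 58
        assert g.global_fraction("Brahman") == 1.0

    def test_angus_founder_no_brahman(self, bovine_map):
        g = founder("Angus", bovine_map, AB)
        assert g.global_fraction("Brahman") == 0.0

    def test_one_chromosome_two_tracts(self, one_chrom_map):
        assert founder("Angus", one_chrom_map, AB).n_tracts() == 2

    def test_unknown_label(self, one_chrom_map):
        with pytest.raises(ValueError):
            founder("Hereford", one_chrom_map, AB)


class TestMeiosis:
    def test_zero_rate_copies_one_homolog(self, toy_map, rng):
        cold = GenomeMap(toy_map.chromosomes, recomb_rate_per_mb=0.0)
        f1 = _f1(toy_map, rng)
        gamete = meiosis(f1, cold, rng)
        for chrom in cold.names:
            matches = [
                np.array_equal(gamete.ends[chrom], hap.ends[chrom])
                and np.array_equal(gamete.codes[chrom], hap.codes[chrom])
                for hap in (f1.hap1, f1.hap2)
            ]
            assert any(matches)

    def test_purebred_crossovers_invisible(self, bovine_map, rng):
        hot = GenomeMap(bovine_map.chromosomes, recomb_rate_per_mb=0.05)
        g = founder("Brahman", bovine_map, AB)
        gamete = meiosis(g, hot, rng)
        assert gamete.n_tracts() == 29
        assert all(len(c) == 1 for c in gamete.codes.values())

    def test_f1_tract_count_matches_closed_form(self, bovine_map, rng):
        # every crossover in an F1 meiosis switches ancestry, so
        # E[tracts per gamete] = sum_c (1 + lambda_c) = 58 at lambda = 1
        f1 = _f1(bovine_map, rng)
        n = 2000
        counts = [meiosis(f1, bovine_map, rng, lam=1.0).n_tracts() for _ in range(n)]
        assert np.mean(counts) == pytest.approx(58.0, abs=0.5)

    def test_bit_reproducible_with_seed(self, bovine_map):
        f1 = _f1(bovine_map, np.random.default_rng(0))
        g1 = meiosis(f1, bovine_map, np.random.default_rng(42))
        g2 = meiosis(f1, bovine_map, np.random.default_rng(42))
        for chrom in bovine_map.names:
            assert np.array_equal(g1.ends[chrom], g2.ends[chrom])
            assert np.array_equal(g1.codes[chrom], g2.codes[chrom])


class TestCross:
    def test_same_breed_purebred_offspring(self, toy_map, rng):
        a = founder("Angus", toy_map, AB)
        child = cross(a, a, toy_map, rng)
        assert child.global_fraction("Angus") == 1.0

    def test_f1_every_locus_heterozygous(self, toy_map, rng):
        f1 = _f1(toy_map, rng)
        assert f1.global_fraction("Brahman") == 0.5

    def test_backcross_quarter_brahman(self, bovine_map, rng):
        # (F1 x taurine purebred) offspring average 1/4 indicine
        angus = founder("Angus", bovine_map, AB)
        f1 = _f1(bovine_map, rng)
        fracs = [
            cross(angus, f1, bovine_map, rng).global_fraction("Brahman")
            for _ in range(300)
        ]
        se = np.std(fracs) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.25) < 4 * se + 1e-9


class TestNextGeneration:
    def _gen1(self, gmap, rng, n=40):
        sch = dataclasses.replace(BRANGUS_SG, n=n, generations_random_mating=0)
        return run_scheme(sch, gmap, rng)

    def test_neutral_mean_fraction_conserved(self, bovine_map, rng):
        cohort = self._gen1(bovine_map, rng, n=60)
        for _ in range(2):
            cohort = next_generation(cohort, 60, rng)
        fracs = [g.global_fraction("Brahman") for g in cohort.genomes]
        se = np.std(fracs) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.375) < 4 * se + 0.01

    def test_pair_equal_odd_count_rejected(self, toy_map, rng):
        cohort = self._gen1(toy_map, rng, n=40)
        with pytest.raises(ValueError, match="even"):
            next_generation(cohort, 41, rng)

    def test_resample_mode_runs(self, toy_map, rng):
        cohort = self._gen1(toy_map, rng, n=20)
        nxt = next_generation(cohort, 30, rng, mating_mode="resample")
        assert len(nxt) == 30
        assert nxt.generation == cohort.generation + 1

    def test_selection_matches_wright_fisher_oracle(self, rng):
        # one chromosome, zero recombination: the tract simulator reduces
        # exactly to a 1-locus viability model, so compare it against an
        # independent allele-based Wright-Fisher simulation
        gmap = GenomeMap((("1", 1_000_000),), recomb_rate_per_mb=0.0)
        s, n, gens, reps = 0.5, 40, 4, 25
        sel = SelectionSpec.single("1", 500_000, "Brahman", s)

        def tract_run(seed):
            r = np.random.default_rng(seed)
            f1 = _f1(gmap, r)
            cohort = SimCohort([cross(f1, f1, gmap, r, str(i)) for i in range(n)],
                               1, AB, gmap=gmap)
            for _ in range(gens):
                cohort = next_generation(cohort, n, r, "resample", sel)
            return np.mean([g.global_fraction("Brahman") for g in cohort.genomes])

        def wf_run(seed):
            r = np.random.default_rng(seed)
            pop = r.integers(0, 2, size=(n, 2))  # F2-like: allele ~ Bernoulli(1/2)
            for _ in range(gens):
                new = np.empty_like(pop)
                for i in range(n):
                    while True:
                        a = r.integers(n)
                        b = (a + 1 + r.integers(n - 1)) % n
                        child = (pop[a, r.integers(2)], pop[b, r.integers(2)])
                        if r.random() < (1 + s) ** sum(child) / (1 + s) ** 2:
                            new[i] = child
                            break
                pop = new
            return pop.mean()

        sim = np.mean([tract_run(1000 + i) for i in range(reps)])
        oracle = np.mean([wf_run(2000 + i) for i in range(4 * reps)])
        assert sim > 0.55  # selection must push the favored ancestry up
        assert abs(sim - oracle) < 0.06

    def test_zero_selection_matches_neutral_expectation(self, toy_map, rng):
        cohort = self._gen1(toy_map, rng, n=40)
        sel = SelectionSpec.single("1", 1_000_000, "Brahman", 0.0)
        nxt = next_generation(cohort, 40, rng, selection=sel)
        fracs = [g.global_fraction("Brahman") for g in nxt.genomes]
        assert abs(np.mean(fracs) - 0.375) < 0.12


class TestRunScheme:
    def test_brangus_generation1_expectation(self, bovine_map, rng):
        sch = dataclasses.replace(BRANGUS_SG, n=200, generations_random_mating=0)
        cohort = run_scheme(sch, bovine_map, rng, keep_intermediate=True)
        assert cohort.generation == 1
        mean = cohort.mean_fraction("Brahman")
        assert mean == pytest.approx(0.375, abs=0.02)
        bc1 = cohort.intermediates["BC1"]
        assert bc1.mean_fraction("Brahman") == pytest.approx(0.25, abs=0.02)

    def test_beefmaster_generation1_expectation(self, bovine_map, rng):
        sch = dataclasses.replace(BEEFMASTER, n=200, generations_random_mating=0)
        cohort = run_scheme(sch, bovine_map, rng)
        # per-individual fraction has SD ~0.04 at generation 1, SE ~0.003
        assert cohort.mean_fraction("Brahman") == pytest.approx(0.5, abs=0.012)

    def test_tract_counts_grow_across_generations(self, bovine_map, rng):
        sch = dataclasses.replace(BRANGUS_SG, n=60, generations_random_mating=6)
        cohort = run_scheme(sch, bovine_map, rng, keep_intermediate=True)
        means = [
            np.mean([g.n_tracts() for g in cohort.intermediates[f"gen{i}"].genomes])
            for i in range(2, 8)
        ]
        assert means[-1] > means[0]
        assert np.polyfit(range(len(means)), means, 1)[0] > 0

    def test_seeded_runs_bit_reproducible(self, toy_map):
        sch = dataclasses.replace(BRANGUS_SG, n=20, generations_random_mating=2)
        c1 = run_scheme(sch, toy_map, np.random.default_rng(5))
        c2 = run_scheme(sch, toy_map, np.random.default_rng(5))
        for g1, g2 in zip(c1.genomes, c2.genomes):
            for chrom in toy_map.names:
                assert np.array_equal(g1.hap1.ends[chrom], g2.hap1.ends[chrom])
                assert np.array_equal(g1.hap2.codes[chrom], g2.hap2.codes[chrom])

    def test_undefined_population_rejected(self):
        with pytest.raises(ValueError, match="undefined population"):
            CrossingScheme("bad", ("A", "B"), (FoundingStep("F1", "A", "C"),))


class TestIidCohort:
    def test_valid_and_unbiased(self, bovine_map, rng):
        sch = dataclasses.replace(BRANGUS_SG, n=100, generations_random_mating=8)
        cohort = iid_cohort(sch, 100, bovine_map, rng)
        assert cohort.generation == 9
        for g in cohort.genomes[:5]:
            assert validate_haploid(g.hap1, bovine_map) == []
            assert validate_haploid(g.hap2, bovine_map) == []
        fracs = [g.global_fraction("Brahman") for g in cohort.genomes]
        se = np.std(fracs) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.375) < 4 * se + 1e-9

    def test_seeded_reproducibility(self, toy_map):
        sch = dataclasses.replace(BEEFMASTER, n=10, generations_random_mating=3)
        c1 = iid_cohort(sch, 10, toy_map, np.random.default_rng(9))
        c2 = iid_cohort(sch, 10, toy_map, np.random.default_rng(9))
        for g1, g2 in zip(c1.genomes, c2.genomes):
            for chrom in toy_map.names:
                assert np.array_equal(g1.hap1.ends[chrom], g2.hap1.ends[chrom])


class TestExpectedTractCount:
    @pytest.mark.parametrize(
        "design,c,expected",
        [
            ("purebred", 0.7, 58.0),
            ("F1", 1.3, 58.0),
            ("BC1", 1.0, 87.0),
            ("F2", 1.0, 116.0),
            ("BC1", 2.0, 29 + 29 * 3.0),
        ],
    )
    def test_closed_form(self, design, c, expected):
        assert expected_tract_count(design, c) == pytest.approx(expected)

    def test_monte_carlo_agreement_small(self, bovine_map, rng):
        genomes = simulate_design("BC1", 400, bovine_map, rng, crossovers_per_chrom=1.0)
        mean = np.mean([g.n_tracts() for g in genomes])
        assert mean == pytest.approx(87.0, abs=1.5)


class TestEmitWindowCalls:
    def test_purebred_cohort_constant_calls(self, toy_map, toy_grid, rng):
        genomes = [founder("Brahman", toy_map, AB, f"s{i}") for i in range(3)]
        cohort = SimCohort(genomes, 0, AB, gmap=toy_map)
        calls = emit_window_calls(cohort, toy_grid, window_snps=10)
        assert (calls.calls == AB.index("Brahman")).all()

    def test_f1_cohort_one_call_each(self, toy_map, toy_grid, rng):
        genomes = [_f1(toy_map, rng) for _ in range(3)]
        for i, g in enumerate(genomes):
            g.id = f"s{i}"
        cohort = SimCohort(genomes, 0, AB, gmap=toy_map)
        calls = emit_window_calls(cohort, toy_grid, window_snps=10)
        for i in range(3):
            pair = calls.calls[:, 2 * i : 2 * i + 2]
            assert (np.sort(pair, axis=1) == [0, 1]).all()

    def test_breakpoint_inside_window_majority_rule(self, one_chrom_map):
        from admixscan.genome import AncestryTract, DiploidGenome, HaploidGenome

        # breakpoint at 530 kb: window 500-600 kb has 10 markers at
        # 505,...,595 kb; 3 markers are Angus, 7 Brahman -> Brahman call
        hap = HaploidGenome.from_tracts(
            AB,
            [AncestryTract("1", 0, 530_000, "Angus"),
             AncestryTract("1", 530_000, 1_000_000, "Brahman")],
        )
        other = HaploidGenome.from_tracts(AB, [AncestryTract("1", 0, 1_000_000, "Angus")])
        g = DiploidGenome("s0", hap, other)
        grid = MarkerGrid({"1": np.arange(5_000, 1_000_000, 10_000, dtype=np.int64)})
        cohort = SimCohort([g], 0, AB, gmap=one_chrom_map)
        calls = emit_window_calls(cohort, grid, window_snps=10)
        hap0 = calls.calls[:, 0]
        # windows span 100 kb each; breakpoint falls in window 5
        assert (hap0[:5] == 0).all()
        assert hap0[5] == 1  # majority of markers past the breakpoint
        assert (hap0[6:] == 1).all()
        assert (calls.calls[:, 1] == 0).all()

    def test_windows_tile_chromosome(self, toy_map, toy_grid, rng):
        genomes = [founder("Angus", toy_map, AB, "s0")]
        cohort = SimCohort(genomes, 0, AB, gmap=toy_map)
        calls = emit_window_calls(cohort, toy_grid, window_snps=7)
        for chrom, length in toy_map.chromosomes:
            block = calls.windows[calls.windows["chrom"] == chrom]
            assert block["start"].iloc[0] == 0
            assert block["end"].iloc[-1] == length
            assert (block["start"].to_numpy()[1:] == block["end"].to_numpy()[:-1]).all()
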