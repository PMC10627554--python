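import numpy as np
import pytest

import msprime

from headwater import _kernels, coalsim
from headwater.demography import (
    DemographicEvent,
    ParameterDraw,
    ParameterPrior,
    PopulationSpec,
    ScenarioModel,
    compile_demography,
)

from conftest import single_pop_demography


def _batch_stats(dem, n_reps, seed):
    sample_pops = np.repeat(np.arange(dem.sample_copies.shape[0]),
                            dem.sample_copies)
    return _kernels.tmrca_and_length_batch(
        sample_pops, dem.init_sizes, dem.event_times, dem.event_kinds,
        dem.event_pop_a, dem.event_pop_b, dem.event_sizes, n_reps, seed,
    )


def two_pop_split(n1, n2, ne, t_split, ne_anc=None):
    model = ScenarioModel(
        scenario_id=7,
        populations=[PopulationSpec("A", n1, "N"),
                     PopulationSpec("B", n2, "N")],
        events=[DemographicEvent("merge", "t", "B", "A")]
        + ([DemographicEvent("size_change", "t", "A",
                             new_size_param="Nanc")] if ne_anc else []),
        priors=[ParameterPrior("N", "uniform", ne, ne),
                ParameterPrior("t", "uniform", max(t_split, 1e-6),
                               max(t_split, 1e-6)),
                ParameterPrior("Nanc", "uniform", ne_anc or ne,
                               ne_anc or ne)],
    )
    vals = {"N": ne, "t": max(t_split, 1e-6), "Nanc": ne_anc or ne}
    return compile_demography(model, ParameterDraw(7, vals))


class TestClosedForms:
    def test_pair_tmrca_mean_is_two_ne(self):
        # E[T2] = 2N generations for a diploid population of size N
        dem = single_pop_demography(1, 1000.0)
        tm = _batch_stats(dem, 20_000, 11)[:, 0]
        assert abs(tm.mean() - 2000.0) < 3 * tm.std() / np.sqrt(tm.size)

    def test_ten_copy_tmrca_mean(self):
        # E[TMRCA] = 4N (1 - 1/n) for n gene copies
        dem = single_pop_demography(5, 1000.0)   # 10 gene copies
        tm = _batch_stats(dem, 20_000, 13)[:, 0]
        expect = 4 * 1000.0 * (1 - 1 / 10)
        assert abs(tm.mean() - expect) < 3 * tm.std() / np.sqrt(tm.size)

    def test_zero_age_split_equals_panmixia(self):
        split = _batch_stats(two_pop_split(3, 3, 800.0, 1e-9), 8_000, 17)
        panmictic = _batch_stats(single_pop_demography(6, 800.0), 8_000, 19)
        for col in (0, 1):
            a, b = split[:, col], panmictic[:, col]
            se = np.hypot(a.std() / np.sqrt(a.size), b.std() / np.sqrt(b.size))
            assert abs(a.mean() - b.mean()) < 4 * se


class TestMsprimeCrossCheck:
    """Independent-oracle agreement on mean TMRCA and total length."""

    @pytest.mark.parametrize(
        "config",
        ["single", "split", "bottleneck"],
    )
    def test_agreement(self, config):
        n_reps = 4000
        if config == "single":
            dem = single_pop_demography(4, 2000.0)
            msdem = msprime.Demography()
            msdem.add_population(name="pop", initial_size=2000)
            samples = {"pop": 4}
        elif config == "split":
            dem = two_pop_split(3, 2, 1500.0, 6000.0, ne_anc=500.0)
            msdem = msprime.Demography()
            msdem.add_population(name="A", initial_size=1500)
            msdem.add_population(name="B", initial_size=1500)
            msdem.add_population(name="anc", initial_size=500)
            msdem.add_population_split(6000.0, derived=["A", "B"],
                                       ancestral="anc")
            samples = {"A": 3, "B": 2}
        else:
            # size change 200 -> 5000 further back in time
            model = ScenarioModel(
                scenario_id=8,
                populations=[PopulationSpec("pop", 4, "N")],
                events=[DemographicEvent("size_change", "t", "pop",
                                         new_size_param="Nold")],
                priors=[ParameterPrior("N", "uniform", 200, 200),
                        ParameterPrior("t", "uniform", 400, 400),
                        ParameterPrior("Nold", "uniform", 5000, 5000)],
            )
            dem = compile_demography(
                model, ParameterDraw(8, {"N": 200, "t": 400, "Nold": 5000}))
            msdem = msprime.Demography()
            msdem.add_population(name="pop", initial_size=200)
            msdem.add_population_parameters_change(400, initial_size=5000)
            samples = {"pop": 4}
        ours = _batch_stats(dem, n_reps, 23)
        ts_reps = msprime.sim_ancestry(
            samples=samples, demography=msdem, num_replicates=n_reps,
            ploidy=2, random_seed=29,
        )
        theirs = np.array([
            (t.first().time(t.first().root), t.first().total_branch_length)
            for t in ts_reps
        ])
        for col in (0, 1):
            a, b = ours[:, col], theirs[:, col]
            se = np.hypot(a.std() / np.sqrt(n_reps), b.std() / np.sqrt(n_reps))
            assert abs(a.mean() - b.mean()) < 4 * se


class TestMutationPlacement:
    def test_every_locus_polymorphic_pooled(self, scenario3, scenario3_draw):
        matrix = coalsim.simulate_snp_dataset(scenario3, scenario3_draw,
                                              100_000, seed=31)
        pooled = matrix.genotypes.sum(axis=1)
        assert pooled.min() >= 1
        assert pooled.max() <= 2 * matrix.n_individuals - 1

    def test_placement_probability_proportional_to_branch_length(self):
        # balanced 4-tip tree: cherries (0,1) and (2,3) at t=1, root at t=2;
        # each tip branch has length 1 and each internal branch length 1,
        # so P(both copies of individual 0 derived) = 1/6
        g = coalsim.Genealogy(
            node_time=np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 2.0]),
            parent=np.array([4, 4, 5, 5, 6, 6, -1]),
            left=np.array([-1, -1, -1, -1, 0, 2, 4]),
            right=np.array([-1, -1, -1, -1, 1, 3, 5]),
            root=6,
            sample_pops=np.array([0, 0, 0, 0]),
            pop_names=("pop",),
        )
        assert g.total_branch_length == 6.0
        rng = np.random.default_rng(37)
        cols = np.array(
            [coalsim.place_single_mutation(g, rng) for _ in range(6000)]
        )
        se = np.sqrt((1 / 6) * (5 / 6) / 6000)
        assert abs((cols[:, 0] == 2).mean() - 1 / 6) < 4 * se
        assert abs((cols[:, 1] == 2).mean() - 1 / 6) < 4 * se
        # a single tip is hit with probability 1/6 as well
        assert abs(((cols[:, 0] == 1).mean()) - 2 / 6) < 4 * np.sqrt(
            (2 / 6) * (4 / 6) / 6000
        )

    def test_unfolded_sfs_shape_is_one_over_i(self):
        # panmictic n=4 gene copies: P(derived count = i) proportional to 1/i
        dem = single_pop_demography(2, 500.0)
        matrix = coalsim.simulate_snp_dataset(dem, n_loci=30_000, seed=41)
        counts = matrix.genotypes.sum(axis=1)
        freq = np.array([(counts == i).sum() for i in (1, 2, 3)], float)
        expect = np.array([1.0, 1 / 2, 1 / 3])
        expect = expect / expect.sum() * counts.size
        # chi-square against the Watterson shape
        chi2 = ((freq - expect) ** 2 / expect).sum()
        from scipy.stats import chi2 as chi2_dist
        assert chi2 < chi2_dist(2).ppf(0.999)


class TestDatasets:
    def test_dataset_shape_and_popmap(self, scenario3, scenario3_draw):
        matrix = coalsim.simulate_snp_dataset(scenario3, scenario3_draw,
                                              50, seed=43)
        assert matrix.genotypes.shape == (50, 33)
        sizes = {p: matrix.populations.count(p)
                 for p in matrix.population_names}
        assert sizes == {"Paraguacu": 6, "Jequirica": 5, "Almas": 4,
                         "Contas": 9, "Almada": 9}

    def test_fixed_seed_reproducible(self, scenario3, scenario3_draw):
        a = coalsim.simulate_snp_dataset(scenario3, scenario3_draw, 40,
                                         seed=47)
        b = coalsim.simulate_snp_dataset(scenario3, scenario3_draw, 40,
                                         seed=47)
        c = coalsim.simulate_snp_dataset(scenario3, scenario3_draw, 40,
                                         seed=48)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert not np.array_equal(a.genotypes, c.genotypes)

    def test_zero_loci_rejected(self, scenario3, scenario3_draw):
        with pytest.raises(ValueError):
            coalsim.simulate_snp_dataset(scenario3, scenario3_draw, 0, 1)

    def test_python_and_kernel_paths_agree(self):
        dem = two_pop_split(2, 2, 1000.0, 3000.0)
        py = [coalsim.simulate_genealogy(dem, seed=s).tmrca
              for s in range(300)]
        kern = _batch_stats(dem, 3000, 53)[:, 0]
        se = np.hypot(np.std(py) / np.sqrt(len(py)),
                      kern.std() / np.sqrt(kern.size))
        assert abs(np.mean(py) - kern.mean()) < 4 * se


class TestExpectedSfs:
    def test_sums_to_one_and_corners_masked(self):
        dem = two_pop_split(3, 3, 1000.0, 2000.0)
        sfs = coalsim.expected_joint_sfs(dem, n_sims=2000, seed=59)
        assert np.isclose(sfs.normalized().sum(), 1.0)
        assert sfs.mask[0, 0] and sfs.mask[-1, -1]

    def test_symmetric_for_equal_samples_and_zero_split(self):
        dem = two_pop_split(3, 3, 1000.0, 1e-9)
        sfs = coalsim.expected_joint_sfs(dem, n_sims=40_000, seed=61)
        p = sfs.normalized()
        asym = np.abs(p - p.T)[~sfs.mask & ~sfs.mask.T]
        assert asym.max() < 0.01

    def test_zero_split_marginal_is_watterson(self):
        dem = two_pop_split(2, 2, 800.0, 1e-9)
        sfs = coalsim.expected_joint_sfs(dem, n_sims=40_000, seed=67)
        p = sfs.normalized()
        pooled = np.zeros(9)
        for i in range(5):
            for j in range(5):
                if not sfs.mask[i, j]:
                    pooled[i + j] += p[i, j]
        expect = np.array([1 / k for k in range(1, 8)])
        expect /= expect.sum()
        assert np.abs(pooled[1:8] - expect).max() < 0.01

    def test_deep_split_concentrates_on_fixed_differences(self):
        dem = two_pop_split(3, 3, 1000.0, 2e6)
        sfs = coalsim.expected_joint_sfs(dem, n_sims=5000, seed=71)
        p = sfs.normalized()
        assert p[6, 0] + p[0, 6] > 0.9

    def test_requires_two_populations(self, scenario3, scenario3_draw):
        with pytest.raises(ValueError):
            coalsim.expected_joint_sfs(scenario3, scenario3_draw,
                                       n_sims=10, seed=1)
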