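"""Parameter grids, sweeps, sub-group tuning and the uncertainty sweep."""

import numpy as np
import pandas as pd
import pytest

from eigas import (
    GapModel,
    crossval_tune,
    generate_synthetic_family,
    parameter_grid,
    robustness_curve,
    roc_points,
    score_all,
    sweep,
)
from eigas.spectral import fingerprint_chain


class TestParameterGrid:
    def test_default_grid_has_2000_triples(self):
        grid = parameter_grid()
        assert len(grid) == 2000
        assert len(grid.kappas) == 20
        assert grid.kappas[0] == 4.0 and grid.kappas[-1] == 23.0
        assert grid.rho_opens == tuple(round(0.1 * k, 1) for k in range(10))

    def test_single_value_ranges(self):
        grid = parameter_grid(kappas=[19.0], rho_opens=[0.5], rho_continues=[0.3])
        assert len(grid) == 1
        assert list(grid.triples()) == [(19.0, 0.5, 0.3)]

    def test_empty_or_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            parameter_grid(kappas=[])
        with pytest.raises(ValueError):
            parameter_grid(kappas=[-1.0])


SMALL_GRID = dict(kappas=[7.0, 19.0], rho_opens=[0.3, 0.5], rho_continues=[0.3])


class TestSweep:
    def test_record_count_equals_grid_size(self, benchmark_chains, benchmark_families):
        grid = parameter_grid(**SMALL_GRID)
        table = sweep(benchmark_chains, benchmark_families, grid)
        assert len(table) == len(grid)

    def test_well_separated_families_reach_perfect_auroc(
        self, benchmark_chains, benchmark_families
    ):
        """Frozen benchmark: for cutoffs of 7 Å and above (and non-zero gap
        opening) the two families separate perfectly."""
        grid = parameter_grid(
            kappas=[7.0, 12.0, 19.0, 23.0], rho_opens=[0.1, 0.5, 0.9], rho_continues=[0.3]
        )
        table = sweep(benchmark_chains, benchmark_families, grid)
        assert np.all(table["auroc"] == 1.0)

    def test_sweep_is_deterministic(self, benchmark_chains, benchmark_families):
        grid = parameter_grid(**SMALL_GRID)
        a = sweep(benchmark_chains, benchmark_families, grid)
        b = sweep(benchmark_chains, benchmark_families, grid)
        pd.testing.assert_frame_equal(a, b)

    def test_caching_never_changes_scores(self, benchmark_chains, benchmark_families):
        kappa, gaps = 9.0, GapModel(0.5, 0.3)
        fps = [fingerprint_chain(c, kappa) for c in benchmark_chains]
        cached = score_all(
            benchmark_chains,
            benchmark_families,
            kappa,
            gaps,
            fingerprints=fps,
            similarity_cache={},
        )
        plain = score_all(benchmark_chains, benchmark_families, kappa, gaps)
        pd.testing.assert_frame_equal(cached.scores, plain.scores)

    def test_single_family_rejected(self, benchmark_chains):
        families = {c.chain_id: "same" for c in benchmark_chains}
        with pytest.raises(ValueError):
            sweep(benchmark_chains, families, parameter_grid(**SMALL_GRID))


@pytest.fixture(scope="module")
def six_family_chains():
    chains = []
    for k, (t_seed, m_seed) in enumerate(
        [(11, 101), (22, 202), (33, 303), (44, 404), (55, 505), (66, 606)]
    ):
        chains.extend(
            generate_synthetic_family(
                n_members=3, length=30, template_seed=t_seed, jitter_sd=0.3, member_seed=m_seed
            )
        )
    return chains


class TestCrossvalTune:
    def test_partition_contract_and_disjoint_validation(self, six_family_chains):
        families = {c.chain_id: c.family_id for c in six_family_chains}
        grid = parameter_grid(kappas=[10.0], rho_opens=[0.5], rho_continues=[0.3])
        results = crossval_tune(six_family_chains, families, grid, n_subgroups=3, seed=5)
        assert len(results) == 3
        seen = []
        for r in results:
            assert len(r.tuning_families) == 2
            seen.extend(r.tuning_families)
        assert sorted(seen) == sorted({families[c.chain_id] for c in six_family_chains})

    def test_same_seed_same_partition(self, six_family_chains):
        families = {c.chain_id: c.family_id for c in six_family_chains}
        grid = parameter_grid(kappas=[10.0], rho_opens=[0.5], rho_continues=[0.3])
        a = crossval_tune(six_family_chains, families, grid, seed=5)
        b = crossval_tune(six_family_chains, families, grid, seed=5)
        assert [r.tuning_families for r in a] == [r.tuning_families for r in b]

    def test_winning_triple_is_argmax_of_tuning_auroc(self, six_family_chains):
        """A grid containing one clearly superior triple (kappa large enough
        to separate the fixture) must be selected for every sub-group."""
        families = {c.chain_id: c.family_id for c in six_family_chains}
        grid = parameter_grid(kappas=[4.0, 12.0], rho_opens=[0.5], rho_continues=[0.3])
        results = crossval_tune(six_family_chains, families, grid, seed=5)
        for r in results:
            assert r.best_kappa == 12.0
            assert r.tuning_auroc == 1.0

    def test_indivisible_family_count_rejected(self, six_family_chains):
        families = {c.chain_id: c.family_id for c in six_family_chains}
        grid = parameter_grid(kappas=[10.0], rho_opens=[0.5], rho_continues=[0.3])
        with pytest.raises(ValueError):
            crossval_tune(six_family_chains, families, grid, n_subgroups=4)


class TestRobustnessCurve:
    def test_s_zero_equals_unperturbed_run(self, benchmark_chains, benchmark_families):
        triple = (19.0, 0.5, 0.3)
        table = robustness_curve(
            benchmark_chains, benchmark_families, triple, [0.0], master_seed=3
        )
        direct = roc_points(
            score_all(benchmark_chains, benchmark_families, 19.0, GapModel(0.5, 0.3))
        )
        assert table.loc[0, "mean_auroc"] == direct.auroc
        assert table.loc[0, "ci_low"] == table.loc[0, "ci_high"] == direct.auroc

    def test_three_samples_satisfy_trimmed_interval_contract(
        self, benchmark_chains, benchmark_families
    ):
        table = robustness_curve(
            benchmark_chains,
            benchmark_families,
            (19.0, 0.5, 0.3),
            [5.0],
            n_samples=3,
            master_seed=3,
        )
        row = table.iloc[0]
        assert row["ci_low"] == row["ci_high"]  # min and max dropped from 3
        assert row["n_samples"] == 3

    def test_repeat_run_is_bit_identical(self, benchmark_chains, benchmark_families):
        kw = dict(n_samples=4, master_seed=9)
        a = robustness_curve(
            benchmark_chains, benchmark_families, (19.0, 0.5, 0.3), [1.0], **kw
        )
        b = robustness_curve(
            benchmark_chains, benchmark_families, (19.0, 0.5, 0.3), [1.0], **kw
        )
        pd.testing.assert_frame_equal(a, b)

    def test_heavy_perturbation_degrades_auroc(self, benchmark_chains, benchmark_families):
        table = robustness_curve(
            benchmark_chains,
            benchmark_families,
            (19.0, 0.5, 0.3),
            [0.0, 50.0],
            n_samples=10,
            master_seed=7,
        )
        assert table.loc[1, "mean_auroc"] <= table.loc[0, "mean_auroc"]
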