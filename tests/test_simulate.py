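"""Simulator primitives, scenario construction, determinism, I/O round trip."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from epiconserve import io as eio
from epiconserve.simulate import (
    SimConfig,
    apply_shock,
    cross_population_pwd,
    evolve,
    generate_scenario,
    init_population,
    measure_beta,
    neutral_divergence_expectation,
    replicate_pair_divergence,
    step_generation,
    write_scenario,
)

SMALL = SimConfig(n_cells=20, n_genes=10, cpgs_per_gene=3, generations=20,
                  clonal_checkpoints=(5, 20), recovery_times=(2, 5, 9, 14),
                  burn_in=10, seed=11)


class TestPrimitives:
    def test_clonal_identity_at_start(self):
        rng = np.random.default_rng(0)
        pop = init_population(SMALL, rng)
        assert (pop.states == pop.states[0]).all()
        assert cross_population_pwd(pop, pop.copy()).max() == 0.0

    def test_essential_sites_start_at_optimum(self):
        pop = init_population(SMALL, np.random.default_rng(0))
        ess = SMALL.essential_sites()
        assert (pop.states[:, ess] == SMALL.optimum_state).all()

    def test_founder_deterministic_across_runs(self):
        a = init_population(SMALL, np.random.default_rng(5))
        b = init_population(SMALL, np.random.default_rng(5))
        assert (a.states == b.states).all()

    def test_zero_error_rate_freezes_population(self):
        cfg = dataclasses.replace(SMALL, error_rate=0.0)
        pop = init_population(cfg, np.random.default_rng(0))
        out = evolve(pop.copy(), cfg, np.random.default_rng(1), 30)
        assert (out.states == pop.states[0]).all()

    def test_population_size_constant(self):
        rng = np.random.default_rng(0)
        pop = init_population(SMALL, rng)
        nxt = step_generation(pop, SMALL, rng)
        assert nxt.states.shape == pop.states.shape
        assert set(np.unique(nxt.states)) <= {0, 1}

    def test_strong_selection_pins_essential_sites(self):
        cfg = dataclasses.replace(SMALL, selection=50.0, generations=150)
        seqs = np.random.SeedSequence(3).spawn(3)
        founder = init_population(cfg, np.random.default_rng(seqs[0]))
        a = evolve(founder.copy(), cfg, np.random.default_rng(seqs[1]), 150)
        b = evolve(founder.copy(), cfg, np.random.default_rng(seqs[2]), 150)
        div = cross_population_pwd(a, b)
        ess = cfg.essential_sites()
        non = np.setdiff1d(np.arange(cfg.n_sites), ess)
        assert div[ess].mean() < div[non].mean()


class TestShock:
    def _methylated_pop(self):
        states = np.ones((50, 30), dtype=np.uint8)
        from epiconserve.simulate import CellPopulation
        return CellPopulation(states)

    def test_zero_shock_is_identity(self):
        pop = self._methylated_pop()
        cfg = dataclasses.replace(SMALL, shock_prob=0.0)
        out = apply_shock(pop, cfg, np.random.default_rng(0))
        assert (out.states == pop.states).all()

    def test_full_shock_demethylates_everything(self):
        pop = self._methylated_pop()
        cfg = dataclasses.replace(SMALL, shock_prob=1.0)
        out = apply_shock(pop, cfg, np.random.default_rng(0))
        assert out.states.sum() == 0

    def test_half_shock_binomial(self):
        pop = self._methylated_pop()
        cfg = dataclasses.replace(SMALL, shock_prob=0.5)
        out = apply_shock(pop, cfg, np.random.default_rng(0))
        n = pop.states.size
        frac = out.states.sum() / n
        sd = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) < 3 * sd

    def test_unmethylated_sites_untouched(self):
        from epiconserve.simulate import CellPopulation
        pop = CellPopulation(np.zeros((10, 10), dtype=np.uint8))
        out = apply_shock(pop, dataclasses.replace(SMALL, shock_prob=1.0),
                          np.random.default_rng(0))
        assert (out.states == 0).all()


class TestMeasurement:
    def test_noiseless_clonal_beta(self):
        cfg = dataclasses.replace(SMALL, measurement_noise_sd=0.0)
        pop = init_population(cfg, np.random.default_rng(0))
        beta = measure_beta(pop, cfg, np.random.default_rng(1), "s")
        founder = pop.states[0].astype(float)
        assert beta.to_numpy() == pytest.approx(founder)

    def test_half_methylated_site(self):
        from epiconserve.simulate import CellPopulation
        states = np.zeros((10, SMALL.n_sites), dtype=np.uint8)
        states[:5] = 1
        cfg = dataclasses.replace(SMALL, measurement_noise_sd=0.0)
        beta = measure_beta(CellPopulation(states), cfg, np.random.default_rng(0), "s")
        assert (beta == 0.5).all()

    def test_noise_stays_in_unit_interval(self):
        cfg = dataclasses.replace(SMALL, measurement_noise_sd=0.3)
        pop = init_population(cfg, np.random.default_rng(0))
        beta = measure_beta(pop, cfg, np.random.default_rng(1), "s")
        assert (beta >= 0).all() and (beta <= 1).all()


class TestNeutralDrift:
    def test_short_horizon_matches_markov_closed_form(self):
        cfg = SimConfig(n_cells=300, n_genes=40, cpgs_per_gene=5,
                        selection=0.0, measurement_noise_sd=0.0,
                        error_rate=0.01, seed=2)
        div = replicate_pair_divergence(cfg, [10, 40])
        for t, d in div.items():
            expected = neutral_divergence_expectation(cfg.error_rate, t)
            sem = d.std(ddof=1) / np.sqrt(d.size)
            assert abs(d.mean() - expected) < 3 * sem


class TestScenarios:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            generate_scenario("nope", SMALL)

    def test_clonal_drift_zero_generations_zero_pwd(self):
        cfg = dataclasses.replace(SMALL, measurement_noise_sd=0.0,
                                  clonal_checkpoints=(0,))
        data = generate_scenario("clonal_drift", cfg)
        from epiconserve.pwd import grouped_gene_pwd
        tbl = grouped_gene_pwd(data.beta, data.annotation, data.sheet)
        assert (tbl["gene_pwd"] == 0.0).all()

    def test_gene_effect_matches_ground_truth(self):
        from epiconserve.essentiality import call_essential
        data = generate_scenario("clonal_drift", SMALL)
        calls = call_essential(data.gene_effect)
        truth = data.ground_truth["essential"].reindex(calls.index)
        assert (calls["essential"].to_numpy() == truth.to_numpy()).all()

    def test_crypt_design_shape(self):
        data = generate_scenario("crypts", SMALL)
        counts = data.sheet.groupby("group")["sample_id"].count()
        assert len(counts) == SMALL.n_individuals
        assert (counts == SMALL.units_per_individual).all()

    def test_determinism_bit_identical(self):
        a = generate_scenario("aza_recovery", SMALL)
        b = generate_scenario("aza_recovery", SMALL)
        pd.testing.assert_frame_equal(a.beta, b.beta)
        pd.testing.assert_frame_equal(a.sheet, b.sheet)
        pd.testing.assert_frame_equal(a.gene_effect, b.gene_effect)

    def test_different_seed_different_data(self):
        a = generate_scenario("clonal_drift", SMALL)
        b = generate_scenario("clonal_drift", dataclasses.replace(SMALL, seed=12))
        assert not a.beta.equals(b.beta)

    def test_round_trip_through_readers(self, tmp_path):
        cfg = SimConfig.drug_panel(seed=4, n_lines=4, line_generations=(5, 20))
        data = generate_scenario("drug_panel", cfg)
        write_scenario(data, tmp_path)
        beta = eio.read_beta_matrix(tmp_path / "beta_matrix.tsv")
        pd.testing.assert_frame_equal(beta, data.beta, check_names=False)
        sheet = eio.read_sample_sheet(tmp_path / "sample_sheet.csv")
        assert list(sheet["sample_id"]) == list(data.sheet["sample_id"])
        ann = eio.read_cpg_annotation(tmp_path / "annotation.tsv")
        pd.testing.assert_frame_equal(ann, data.annotation)
        effect = eio.read_gene_effect(tmp_path / "gene_effect.csv")
        pd.testing.assert_frame_equal(effect, data.gene_effect, check_names=False)
        drug = eio.read_drug_response(tmp_path / "drug_response.csv")
        assert len(drug) == len(data.drug_response)
        assert (tmp_path / "manifest.json").exists()

    def test_drug_panel_row_multiplicity(self):
        cfg = SimConfig.drug_panel(seed=4, n_lines=5, n_target_genes=3,
                                   line_generations=(5, 20))
        data = generate_scenario("drug_panel", cfg)
        # one drug per target plus one dual-target drug = 3 + 2 rows of pairs
        pairs = data.drug_response.groupby(["drug", "target"]).ngroups
        assert pairs == cfg.n_target_genes + 2
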