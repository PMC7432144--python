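import numpy as np
import pytest

from hazelnet.datagen import (
    DEFAULT_BLENDS,
    INPUT_COLUMNS,
    RESPONSE_COLUMNS,
    Blend,
    ConfigurationError,
    DesignConfig,
    ResponseSurface,
    SurfaceParams,
    generate_design,
    simulate_responses,
    true_optimum,
    true_response,
)


class TestDesign:
    def test_default_design_has_720_rows(self):
        # 10 blends x 3 conc x 3 reps x (5 harvests after day 13 + 3 after day 17)
        assert len(generate_design()) == 720

    def test_harvest_schedule_for_late_addition(self):
        cfg = DesignConfig(adding_days=(17.0,))
        assert cfg.harvest_days(17.0) == [19.0, 21.0, 23.0]

    def test_blend_concentrations(self):
        cfg = DesignConfig(blend_levels=(Blend(0.75, 0.25),), conc_levels=(10.0,))
        design = generate_design(cfg)
        assert set(design.ce_conc) == {7.5}
        assert set(design.cf_conc) == {2.5}

    def test_control_blends_carry_no_elicitor(self):
        cfg = DesignConfig(blend_levels=(Blend(0.75, 0.25, control=True),))
        design = generate_design(cfg)
        assert (design.ce_conc == 0).all() and (design.cf_conc == 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_row_count_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        cfg = DesignConfig(
            blend_levels=tuple(DEFAULT_BLENDS[: rng.integers(1, 10)]),
            conc_levels=tuple(rng.uniform(1, 10, rng.integers(1, 4))),
            adding_days=tuple(sorted(rng.choice([11, 13, 15, 17], rng.integers(1, 3), replace=False).astype(float))),
            harvest_interval_days=int(rng.integers(1, 4)),
            n_replicates=int(rng.integers(1, 4)),
        )
        expected = (
            len(cfg.blend_levels) * len(cfg.conc_levels) * cfg.n_replicates
            * sum(len(cfg.harvest_days(a)) for a in cfg.adding_days)
        )
        assert len(generate_design(cfg)) == expected

    def test_harvest_days_bounded_by_design(self):
        design = generate_design()
        assert (design.harvest_day > design.adding_day).all()
        assert (design.harvest_day <= 23).all()

    def test_empty_levels_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_design(DesignConfig(conc_levels=()))

    def test_final_day_before_addition_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_design(DesignConfig(adding_days=(13.0, 24.0)))

    def test_blend_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            Blend(0.7, 0.2)


class TestSimulation:
    def test_zero_noise_satisfies_yield_identity(self, default_design):
        params = SurfaceParams(noise_fraction=0.0)
        table = simulate_responses(default_design, params)
        np.testing.assert_allclose(
            table.total, table.intra * table.dw + table.extra, rtol=1e-12
        )
        np.testing.assert_allclose(
            table.portion, 100 * table.extra / table.total, rtol=1e-12
        )

    def test_same_seed_reproduces_table(self, default_design):
        a = simulate_responses(default_design, SurfaceParams(seed=7))
        b = simulate_responses(default_design, SurfaceParams(seed=7))
        assert a.equals(b)

    def test_different_seeds_differ(self, default_design):
        a = simulate_responses(default_design, SurfaceParams(seed=7))
        b = simulate_responses(default_design, SurfaceParams(seed=8))
        assert not a.dw.equals(b.dw)

    def test_noise_identity_residual_centred_at_zero(self, default_table):
        resid = default_table.total - (
            default_table.intra * default_table.dw + default_table.extra
        )
        assert abs(resid.mean()) < 3 * resid.std() / np.sqrt(len(resid))

    def test_control_means_track_true_baseline(self, default_design):
        params = SurfaceParams(seed=3)
        controls = None
        for seed in (3, 11):
            table = simulate_responses(default_design, params.replace(seed=seed))
            mask = (table.ce_conc == 0) & (table.cf_conc == 0)
            controls = table[mask]
            truth = true_response(
                params, "dw",
                controls.ce_conc.to_numpy(), controls.cf_conc.to_numpy(),
                controls.adding_day.to_numpy(), controls.harvest_day.to_numpy(),
            )
            resid = controls.dw.to_numpy() - truth
            sd = params.noise_fraction * float(
                np.std(true_response(
                    params, "dw",
                    table.ce_conc.to_numpy(), table.cf_conc.to_numpy(),
                    table.adding_day.to_numpy(), table.harvest_day.to_numpy(),
                ))
            )
            assert abs(resid.mean()) < 3 * sd / np.sqrt(len(resid))

    def test_responses_non_negative(self, default_table):
        assert (default_table[RESPONSE_COLUMNS] >= 0).all().all()

    def test_block_offsets_shift_replicates(self, default_design):
        params = SurfaceParams(seed=5, noise_fraction=0.0, block_sd=0.5)
        table = simulate_responses(default_design, params)
        rep_means = table.groupby("replicate").dw.mean()
        assert rep_means.std() > 0


class TestTrueOptimum:
    def test_gaussian_bump_centre_recovered(self):
        surfaces = {
            "dw": ResponseSurface(baseline=10.0, harvest_rate=5.0, harvest_clock="culture"),
            "intra": ResponseSurface(
                baseline=1.0, ce_amp=5.0, ce_opt=4.0, ce_width=2.0,
                cf_amp=5.0, cf_opt=5.0, cf_width=2.0, harvest_rate=5.0,
            ),
            "extra": ResponseSurface(baseline=1.0, harvest_rate=5.0),
        }
        params = SurfaceParams(surfaces=surfaces)
        opt = true_optimum(params, response="intra")
        assert abs(opt.inputs["ce_conc"] - 4.0) <= opt.grid_step["ce_conc"]
        assert abs(opt.inputs["cf_conc"] - 5.0) <= opt.grid_step["cf_conc"]

    def test_monotone_harvest_optimum_at_upper_bound(self):
        opt = true_optimum(SurfaceParams(), response="dw")
        assert opt.inputs["harvest_day"] == 23.0

    def test_grid_refinement_moves_at_most_one_coarse_step(self):
        params = SurfaceParams()
        coarse = true_optimum(params, response="total")
        fine = true_optimum(
            params, response="total",
            grid_step={k: v / 2 for k, v in coarse.grid_step.items()},
        )
        for key in coarse.inputs:
            assert abs(fine.inputs[key] - coarse.inputs[key]) <= coarse.grid_step[key] + 1e-9
        assert fine.value >= coarse.value - 1e-9

    def test_unknown_response_rejected(self):
        with pytest.raises(KeyError):
            true_optimum(SurfaceParams(), response="ash_content")
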