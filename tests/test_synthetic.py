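"""Ground-truth and determinism properties of the simulator."""

import numpy as np
import pytest
from scipy import stats

from ulvaphen.synthetic import (
    MetaboliteConfig,
    NoiseConfig,
    PanelConfig,
    SimConfig,
    simulate_disc_stack,
    simulate_metabolite_matrix,
    simulate_strain_panel,
)


class TestDiscStack:
    def test_no_growth_no_noise_frames_identical(self, quiet_config):
        cfg = SimConfig(
            **{
                **quiet_config.__dict__,
                "sgr_day_mean": 0.0,
                "sgr_day_sd": 0.0,
                "sgr_night_mean": 0.0,
                "sgr_night_sd": 0.0,
                "disc_sgr_sd": 0.0,
                "days": 1,
            }
        )
        stack, gt = simulate_disc_stack(cfg)
        first = np.asarray(stack.frames[0])
        for f in stack.frames[1:]:
            assert np.array_equal(first, f)
        assert np.allclose(gt.area_at("tank1_well00", [0.0, 500.0, 1440.0]), gt.discs["initial_area_mm2"].iloc[0])

    def test_area_doubling_per_night_is_100_ln2(self, quiet_config):
        cfg = SimConfig(
            **{
                **quiet_config.__dict__,
                "sgr_day_mean": 0.0,
                "sgr_day_sd": 0.0,
                "sgr_night_mean": 100.0 * np.log(2.0),
                "sgr_night_sd": 0.0,
                "disc_sgr_sd": 0.0,
                "days": 1,
            }
        )
        _, gt = simulate_disc_stack(cfg)
        assert np.allclose(gt.discs["sgr_night_pct"], 100.0 * np.log(2.0))
        a0 = gt.area_at("tank1_well00", 0.0)
        a24 = gt.area_at("tank1_well00", 1440.0)
        assert a24 == pytest.approx(2.0 * a0, rel=1e-12)

    def test_analytic_area_law_matches_hand_formula(self, tiny_config):
        _, gt = simulate_disc_stack(tiny_config)
        row = gt.discs.iloc[3]
        t = 1440.0 + 300.0  # 5 h into day 2
        expected = row["initial_area_mm2"] * np.exp(
            (row["sgr_day_pct"] / 100.0) * (1.0 + 300.0 / 720.0) + (row["sgr_night_pct"] / 100.0) * 1.0
        )
        assert gt.area_at(row["disc_id"], t) == pytest.approx(expected, rel=1e-12)

    def test_same_seed_bit_identical(self, tiny_config):
        s1, g1 = simulate_disc_stack(tiny_config)
        s2, g2 = simulate_disc_stack(tiny_config)
        assert np.array_equal(np.asarray(s1.frames), np.asarray(s2.frames))
        assert g1.discs.equals(g2.discs)

    def test_escape_flagged_not_raised(self, quiet_config):
        cfg = SimConfig(
            **{
                **quiet_config.__dict__,
                "sgr_night_mean": 80.0,
                "sgr_night_sd": 0.0,
                "days": 3,
            }
        )
        stack, gt = simulate_disc_stack(cfg)
        assert stack.metadata["escaped_discs"]
        assert gt.discs["escaped"].any()

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_strains": 0},
            {"days": -1},
            {"calibration_mm_per_px": 0.0},
            {"light_hours": 10.0},  # 10 + 12 != 24
            {"sgr_day_sd": -1.0},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad)


class TestStrainPanel:
    def test_null_nitrate_coupling_uncorrelated(self):
        cfg = SimConfig(
            seed=5,
            n_strains=2000,
            panel=PanelConfig(nitrate_rgr_coupling=0.0),
        )
        panel, gt = simulate_strain_panel(cfg)
        rho, _ = stats.spearmanr(panel["nitrate_eon"], gt.strains["rgr"])
        assert abs(rho) < 0.06

    def test_positive_coupling_detected(self):
        cfg = SimConfig(seed=5, n_strains=200)
        panel, gt = simulate_strain_panel(cfg)
        rho, p = stats.spearmanr(panel["nitrate_eon"], gt.strains["rgr"])
        assert rho > 0.2 and p < 0.01

    def test_nitrate_consumed_fraction_recovered(self):
        cfg = SimConfig(seed=7, n_strains=1500, panel=PanelConfig(nitrate_consumed_frac=0.8))
        panel, _ = simulate_strain_panel(cfg)
        frac = (panel["nitrate_eon"] - panel["nitrate_eod"]) / panel["nitrate_eon"]
        assert frac.mean() == pytest.approx(0.8, abs=0.02)

    def test_starch_fifty_times_sucrose(self):
        cfg = SimConfig(
            seed=9,
            n_strains=1500,
            panel=PanelConfig(sucrose_eod_mean=10.0, starch_sucrose_ratio=50.0),
        )
        panel, _ = simulate_strain_panel(cfg)
        assert panel["starch_eod"].mean() == pytest.approx(500.0, rel=0.05)
        assert panel["sucrose_eod"].mean() == pytest.approx(10.0, rel=0.05)

    def test_determinism(self, tiny_config):
        p1, g1 = simulate_strain_panel(tiny_config)
        p2, g2 = simulate_strain_panel(tiny_config)
        assert p1.equals(p2) and g1.strains.equals(g2.strains)


class TestMetaboliteMatrix:
    def test_shape_and_catalogue(self, tiny_config):
        rgr = np.linspace(0.1, 0.3, tiny_config.n_strains)
        matrix, gt = simulate_metabolite_matrix(tiny_config, rgr)
        assert matrix["metabolite"].nunique() == 47
        assert set(matrix["timepoint"]) == {"EOD", "EON"}
        assert len(matrix) == 47 * 2 * tiny_config.n_strains
        assert len(gt.night_consumed) == 17

    def test_unknown_planted_name_rejected(self, tiny_config):
        cfg = SimConfig(
            **{
                **tiny_config.__dict__,
                "metabolites": MetaboliteConfig(planted_eod={"unobtainium": 1}),
            }
        )
        with pytest.raises(ValueError, match="catalogue"):
            simulate_metabolite_matrix(cfg, np.linspace(0.1, 0.3, cfg.n_strains))

    def test_rgr_length_checked(self, tiny_config):
        with pytest.raises(ValueError):
            simulate_metabolite_matrix(tiny_config, np.ones(3))

    def test_determinism(self, tiny_config):
        rgr = np.linspace(0.1, 0.3, tiny_config.n_strains)
        m1, _ = simulate_metabolite_matrix(tiny_config, rgr)
        m2, _ = simulate_metabolite_matrix(tiny_config, rgr)
        assert m1.equals(m2)

    def test_noiseless_fold_change_exact(self):
        cfg = SimConfig(
            seed=3,
            n_strains=16,
            metabolites=MetaboliteConfig(abundance_sigma=0.0, night_fold=4.0),
        )
        matrix, gt = simulate_metabolite_matrix(cfg, np.linspace(0.1, 0.3, 16))
        wide = matrix.pivot_table(index="strain_id", columns=["metabolite", "timepoint"], values="value")
        for met in gt.night_consumed:
            ratio = wide[met]["EOD"].mean() / wide[met]["EON"].mean()
            assert ratio == pytest.approx(4.0, rel=1e-12)
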