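import numpy as np
import pandas as pd
import pytest

from gamediv.contributions import evolutionary_distinctiveness, total_branch_length
from gamediv.prices import standardize_by_species, validate_panel
from gamediv.simulate import (
    SimConfig,
    calibrated_sigma,
    default_study_configs,
    simulate_cpi,
    simulate_prices,
    simulate_study,
    simulate_traits,
    simulate_tree,
    simulate_trend_panel,
    split_sexes,
    to_nominal,
    trend_curve,
    write_study,
)


class TestSimulateTree:
    def test_two_species_cherry_is_ultrametric(self):
        tree = simulate_tree(2, 10.0, 0)
        assert tree.n_tips == 2
        lengths = [tree.lengths[i] for i in tree.tip_label]
        assert lengths == pytest.approx([10.0, 10.0])

    def test_same_seed_same_newick(self):
        assert simulate_tree(15, 20.0, 42).to_newick() == simulate_tree(15, 20.0, 42).to_newick()

    def test_different_seed_different_topology(self):
        assert simulate_tree(15, 20.0, 1).to_newick() != simulate_tree(15, 20.0, 2).to_newick()

    @pytest.mark.parametrize("seed", range(10))
    def test_root_to_tip_depth_equals_target(self, seed):
        tree = simulate_tree(20, 30.0, seed)
        depths = {0: 0.0}
        for i in tree.preorder():
            if i != 0:
                depths[i] = depths[tree.parents[i]] + tree.lengths[i]
        tip_depths = [depths[i] for i in tree.tip_label]
        assert np.allclose(tip_depths, 30.0, atol=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_conservation_feeds(self, seed):
        tree = simulate_tree(50, 25.0, 1000 + seed)
        total = total_branch_length(tree)
        assert abs(evolutionary_distinctiveness(tree).sum() - total) < 1e-9 * total


class TestSimulateTraits:
    def test_same_seed_same_table(self):
        tree = simulate_tree(10, 10.0, 3)
        a = simulate_traits(tree, 3, 2, 5).data
        b = simulate_traits(tree, 3, 2, 5).data
        pd.testing.assert_frame_equal(a, b)

    def test_bm_variance_grows_with_depth(self):
        shallow, deep = [], []
        for seed in range(25):
            t1 = simulate_tree(15, 1.0, seed)
            t2 = simulate_tree(15, 100.0, seed)
            shallow.append(simulate_traits(t1, 1, 0, seed).data["num1"].var())
            deep.append(simulate_traits(t2, 1, 0, seed).data["num1"].var())
        assert np.mean(deep) > 10 * np.mean(shallow)

    def test_missingness_keeps_table_valid(self):
        tree = simulate_tree(12, 10.0, 9)
        table = simulate_traits(tree, 2, 2, 9, missing_rate=0.3)
        assert not table.data.isna().all(axis=1).any()
        for col in table.numeric_columns():
            assert table.data[col].notna().sum() >= 2


class TestSimulateCPI:
    def test_zero_inflation_constant_index(self):
        cpi = simulate_cpi(2000, 5, (0.0, 0.0), 1)
        assert cpi.index.nunique() == 1

    def test_fixed_rate_ratio(self):
        cpi = simulate_cpi(2000, 5, (0.05, 0.05), 1)
        ratios = cpi.index.values[1:] / cpi.index.values[:-1]
        assert np.allclose(ratios, 1.05)

    def test_drawn_rates_recovered_from_index(self):
        rng = np.random.default_rng(4)
        cpi = simulate_cpi(1991, 22, (0.03, 0.09), rng)
        inferred = cpi.annual_inflation()
        assert ((inferred >= 0.03 - 1e-9) & (inferred <= 0.09 + 1e-9)).all()


class TestSimulatePrices:
    def setup_method(self):
        self.cfg = SimConfig(n_species=8, n_priced=8, seed=0)
        self.devs = pd.Series(
            np.linspace(-0.02, 0.02, 8), index=[f"sp{i:03d}" for i in range(1, 9)]
        )

    def test_prices_positive_and_panel_valid(self):
        panel = simulate_prices(self.devs, self.devs, self.cfg, 5)
        assert (panel["price"] > 0).all()
        validate_panel(panel)

    def test_deterministic_under_seed(self):
        a = simulate_prices(self.devs, self.devs, self.cfg, 5)
        b = simulate_prices(self.devs, self.devs, self.cfg, 5)
        pd.testing.assert_frame_equal(a, b)

    def test_noiseless_shared_trend_standardizes_identically(self):
        """With no contribution effect and vanishing noise, every species'
        standardized series collapses onto the same shared trend."""
        cfg = SimConfig(
            n_species=8, n_priced=8, gamma_phylo=0.0, gamma_func=0.0,
            ar1_phi=0.0, sigma_resid=1e-9, seed=0,
        )
        panel = simulate_prices(self.devs * 0, self.devs * 0, cfg, 11)
        scaled, _ = standardize_by_species(panel)
        wide = scaled.pivot(index="year", columns="species", values="scaled_price")
        ref = wide.iloc[:, 0]
        for col in wide.columns[1:]:
            assert np.allclose(wide[col], ref, atol=1e-5)

    def test_nominal_roundtrip(self):
        cpi = simulate_cpi(self.cfg.start_year, self.cfg.n_years, (0.03, 0.09), 2)
        panel = simulate_prices(self.devs, self.devs, self.cfg, 5)
        ref = self.cfg.start_year + self.cfg.n_years - 1
        nominal = to_nominal(panel, cpi, ref)
        back = nominal.copy()
        back["price"] = [
            p * cpi.ratio(ref, int(y)) for p, y in zip(back["price"], back["year"])
        ]
        assert np.allclose(back["price"], panel["price"], rtol=1e-12)

    def test_sex_split_mean_preserves_price(self):
        panel = simulate_prices(self.devs, self.devs, self.cfg, 5)
        split = split_sexes(panel, rate=0.5, gap=0.2, seed_or_rng=3)
        merged = split[["price_male", "price_female"]].mean(axis=1)
        combined = split["price"].where(split["price"].notna(), merged)
        assert np.allclose(combined, panel["price"], rtol=1e-12)


class TestCalibration:
    def test_default_trend_plus_noise_has_unit_variance(self):
        cfg = SimConfig(seed=0)
        t = np.arange(cfg.n_years, dtype=float)
        var_f = np.var(trend_curve(t, cfg.beta_time, cfg.beta_time2))
        stat_var = calibrated_sigma(cfg) ** 2 / (1 - cfg.ar1_phi**2)
        assert var_f + stat_var == pytest.approx(1.0, abs=1e-9)

    def test_explicit_sigma_passes_through(self):
        cfg = SimConfig(sigma_resid=0.5, seed=0)
        assert calibrated_sigma(cfg) == 0.5


class TestTrendPanel:
    def test_null_trend_fits_near_zero(self, study_devs):
        from gamediv.models import fit_trend_model
        from .conftest import attach_contributions

        cfg = SimConfig(beta_time=0.0, beta_time2=0.0, ar1_phi=0.0, seed=0)
        slopes = []
        for seed in range(10):
            panel = attach_contributions(
                simulate_trend_panel(study_devs["ED"], study_devs["FD"], cfg,
                                     300 + seed),
                study_devs,
            )
            fit = fit_trend_model(panel, "overall", 2, reml=True)
            slopes.append(fit.params["time"])
        assert abs(np.median(slopes)) < 0.02


class TestStudyBundle:
    def test_bundle_round_trips_through_files(self, tmp_path):
        study = simulate_study(7, default_study_configs(7))
        manifest = write_study(study, tmp_path)
        assert (tmp_path / "prices.csv").exists()
        assert set(manifest["groups"]) == {"ungulate", "carnivore"}
        prices = pd.read_csv(tmp_path / "prices.csv")
        assert set(prices["group"]) == {"ungulate", "carnivore"}
        # study scale: 37 priced ungulates, 6 priced carnivores
        ung = prices[prices["group"] == "ungulate"]
        car = prices[prices["group"] == "carnivore"]
        assert ung["species"].nunique() == 37
        assert car["species"].nunique() == 6
        assert study.assemblages["ungulate"].tree.n_tips == 41
        assert study.assemblages["carnivore"].tree.n_tips == 13

    def test_study_deterministic(self, tmp_path):
        a = simulate_study(3)
        b = simulate_study(3)
        pd.testing.assert_frame_equal(a.assemblages["ungulate"].prices_nominal,
                                      b.assemblages["ungulate"].prices_nominal)
        assert a.assemblages["carnivore"].tree.to_newick() == \
            b.assemblages["carnivore"].tree.to_newick()
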