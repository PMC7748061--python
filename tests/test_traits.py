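"""Trait model: effect sampling/scaling, TBVs, residual calibration."""

import numpy as np
import pytest

from wheatsim import genome, traits
from wheatsim.traits import AYT, BVP, PYT


class TestSampleEffects:
    def test_sample_correlation_matches_target(self):
        rng = np.random.default_rng(0)
        C = traits.genetic_correlation_matrix(0.9, 0.1)
        eff = traits.sample_qtl_effects(1039, C, rng)
        got = np.corrcoef(eff.T)
        se = 3.0 / np.sqrt(1039)
        assert abs(got[PYT, AYT] - 0.9) < 3 * se * (1 - 0.81)  # Fisher-ish
        assert abs(got[BVP, PYT] - 0.1) < 3 * se

    def test_zero_correlation(self):
        rng = np.random.default_rng(1)
        eff = traits.sample_qtl_effects(1039, np.eye(3), rng)
        got = np.corrcoef(eff.T)
        assert abs(got[0, 1]) < 3 / np.sqrt(1039)

    def test_determinism(self):
        e1 = traits.sample_qtl_effects(50, np.eye(3),
                                       np.random.default_rng(5))
        e2 = traits.sample_qtl_effects(50, np.eye(3),
                                       np.random.default_rng(5))
        np.testing.assert_array_equal(e1, e2)

    def test_non_psd_rejected(self):
        bad = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(traits.InvalidCovarianceError):
            traits.sample_qtl_effects(10, bad, np.random.default_rng(0))


class TestScaling:
    def test_empirical_scaling_exact_unit_variance(self, toy_layout, toy_base):
        rng = np.random.default_rng(2)
        raw = traits.sample_qtl_effects(toy_layout.n_qtl, np.eye(3), rng)
        eff, p = traits.scale_qtl_effects(raw, toy_base, toy_layout.qtl_idx)
        D = toy_base.sum(axis=1)[:, toy_layout.qtl_idx]
        tbv = (D - 2 * p) @ eff
        np.testing.assert_allclose(tbv.var(axis=0, ddof=1), 1.0, rtol=1e-10)

    def test_zero_target_zeroes_effects(self, toy_layout, toy_base):
        raw = np.ones((toy_layout.n_qtl, 3))
        eff, _ = traits.scale_qtl_effects(raw, toy_base, toy_layout.qtl_idx,
                                          target_variance=0.0)
        assert not eff.any()

    def test_covariance_scaling_delivers_exact_correlations(self, toy_layout,
                                                            toy_base):
        """Full-covariance calibration: base TBV covariance equals the
        scenario correlation matrix exactly, despite LD among QTL."""
        rng = np.random.default_rng(11)
        C = traits.genetic_correlation_matrix(0.7, 0.1)
        raw = traits.sample_qtl_effects(toy_layout.n_qtl, C, rng)
        eff, p = traits.scale_qtl_effects(raw, toy_base, toy_layout.qtl_idx,
                                          mode="empirical_cov",
                                          target_correlation=C)
        D = toy_base.sum(axis=1)[:, toy_layout.qtl_idx]
        tbv = (D - 2 * p) @ eff
        np.testing.assert_allclose(np.cov(tbv.T, ddof=1), C, atol=1e-10)

    def test_analytic_two_qtl_hand_oracle(self):
        # base of 4 inbred lines; QTL frequencies p = (0.5, 0.25);
        # raw effects a' = (1, 2): denominator per trait is
        # sqrt(sum 2p(1-p)a'^2) = sqrt(2*.5*.5*1 + 2*.25*.75*4) = sqrt(2.0)
        base = np.zeros((4, 2, 2), dtype=np.int8)
        base[:2, :, 0] = 1          # locus 0: freq 0.5
        base[0, :, 1] = 1           # locus 1: freq 0.25
        raw = np.array([[1.0], [2.0]])
        raw3 = np.tile(raw, (1, 3))
        eff, p = traits.scale_qtl_effects(raw3, base, np.array([0, 1]),
                                          mode="analytic")
        np.testing.assert_allclose(p, [0.5, 0.25])
        np.testing.assert_allclose(eff[:, 0], raw[:, 0] / np.sqrt(2.0))


class TestTBV:
    def test_two_qtl_hand_sum(self):
        model = traits.TraitModel(
            qtl_idx=np.array([1, 3]),
            effects=np.array([[1.0, 0.0, 2.0], [0.5, 0.0, -1.0]]),
            qtl_base_freq=np.array([0.5, 0.25]),
            G0=np.eye(3), sigma_e2={})
        haps = np.zeros((1, 2, 5), dtype=np.int8)
        haps[0, :, 1] = 1   # dosage 2 at first QTL
        haps[0, 0, 3] = 1   # dosage 1 at second QTL
        tbv = traits.true_breeding_values(haps, model)
        # trait 0: (2-1)*1 + (1-0.5)*0.5 = 1.25 ; trait 2: (2-1)*2 + 0.5*(-1)
        np.testing.assert_allclose(tbv[0], [1.25, 0.0, 1.5])

    def test_base_population_centered(self, toy_layout, toy_base, toy_model):
        tbv = toy_model.tbv(toy_base)
        assert np.allclose(tbv.mean(axis=0), 0.0, atol=1e-10)


class TestResidualCalibration:
    def test_analytic_direct_substitution(self):
        # 2*1*1*1*(1-0.5)/0.5 - 0 = 2.0
        assert traits.calibrate_residual_variance(
            0.5, 1, H=1.0, mode="analytic") == pytest.approx(2.0)

    def test_analytic_h_term_vanishes_at_full_homozygosity(self):
        a = traits.calibrate_residual_variance(0.3, 10, H=1.0,
                                               mode="analytic")
        assert a == pytest.approx(2 * 10 * 0.7 / 0.3)

    def test_analytic_infeasible(self):
        with pytest.raises(traits.InfeasibleHeritabilityError):
            traits.calibrate_residual_variance(0.9, 1, H=0.0,
                                               mode="analytic")

    @pytest.mark.parametrize("h2,n_plants", [(0.2, 50), (0.3, 1500)])
    def test_empirical_bisection_hits_target(self, h2, n_plants):
        """Realized plot heritability within +-0.005 of target."""
        rng = np.random.default_rng(3)
        se2 = traits.calibrate_residual_variance(h2, n_plants, mode="empirical",
                                                 rng=rng)
        # independent check on fresh plots
        g = rng.normal(0, 1, 200_000)
        y = g + rng.normal(0, np.sqrt(se2 / n_plants), g.size)
        realized = g.var(ddof=1) / y.var(ddof=1)
        assert abs(realized - h2) < 0.005

    def test_invalid_heritability(self):
        with pytest.raises(traits.InfeasibleHeritabilityError):
            traits.calibrate_residual_variance(1.2, 10)


class TestPhenotypes:
    def test_zero_residual_plot_equals_mean_tbv(self, toy_model, rng):
        model = traits.TraitModel(
            qtl_idx=toy_model.qtl_idx, effects=toy_model.effects,
            qtl_base_freq=toy_model.qtl_base_freq, G0=toy_model.G0,
            sigma_e2={"AYT": 0.0})
        v = traits.simulate_plot_phenotype(np.array([1.0]), "AYT", 100,
                                           model, rng)
        assert v == pytest.approx(1.0)

    def test_plot_noise_variance_scales_with_plants(self, toy_model):
        """var(plot | TBV) = sigma_e2 / N_p for a clonal plot."""
        rng = np.random.default_rng(4)
        model = traits.TraitModel(
            qtl_idx=toy_model.qtl_idx, effects=toy_model.effects,
            qtl_base_freq=toy_model.qtl_base_freq, G0=toy_model.G0,
            sigma_e2={"PYT": 8.0})
        vals = traits.plot_values_batch(np.zeros(20000), "PYT", 4, model, rng)
        assert vals.var() == pytest.approx(2.0, rel=0.06)

    def test_plant_phenotype_heritability(self, toy_model):
        """Squared correlation of BVP phenotype with TBV is ~ 0.1."""
        rng = np.random.default_rng(5)
        g = rng.normal(0, 1, 20000)
        model = traits.TraitModel(
            qtl_idx=toy_model.qtl_idx, effects=toy_model.effects,
            qtl_base_freq=toy_model.qtl_base_freq, G0=toy_model.G0,
            sigma_e2={"BVP": 9.0})
        y = traits.simulate_plant_phenotype(g, model, rng)
        assert np.corrcoef(y, g)[0, 1] ** 2 == pytest.approx(0.1, abs=0.01)

    def test_empty_plot_rejected(self, toy_model, rng):
        with pytest.raises(ValueError):
            traits.simulate_plot_phenotype(np.array([]), "AYT", 10,
                                           toy_model, rng)

    def test_phenotype_unbiased(self, toy_model):
        """E[y | g] = g: regression of plot value on TBV has slope ~ 1."""
        rng = np.random.default_rng(6)
        g = rng.normal(0, 1, 20000)
        y = traits.plot_values_batch(g, "AYT", 1500, toy_model, rng)
        slope = np.cov(y, g)[0, 1] / g.var()
        assert slope == pytest.approx(1.0, abs=0.02)


def test_bvp_residual_is_nine(toy_model):
    # h2 = 0.1 at the plant level with unit genetic variance
    assert toy_model.sigma_e2["BVP"] == pytest.approx(9.0)
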