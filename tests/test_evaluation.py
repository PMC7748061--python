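"""GRM construction, multi-trait GBLUP (both solvers), accuracy."""

import numpy as np
import pytest

from wheatsim import evaluation
from wheatsim.traits import AYT, BVP, PYT


def _records(li, ti, y, rv):
    return (np.asarray(li), np.asarray(ti), np.asarray(y, dtype=float),
            np.asarray(rv, dtype=float))


class TestGRM:
    def test_inbred_self_relationship_at_half_frequency(self):
        # dosage in {0, 2}, reference p = 0.5: Zc = +-1, so the diagonal is
        # m / (m * 2 * 0.5 * 0.5) = 2 exactly
        rng = np.random.default_rng(0)
        d = 2 * (rng.random((1, 40)) < 0.5).astype(float)
        grm = evaluation.build_grm(d, np.full(40, 0.5), blend=0.0)
        assert grm.entries[0, 0] == pytest.approx(2.0)

    def test_identical_lines_share_relationship(self):
        rng = np.random.default_rng(1)
        d = 2 * (rng.random((1, 60)) < 0.5).astype(float)
        D = np.vstack([d, d])
        grm = evaluation.build_grm(D, np.full(60, 0.5), blend=0.0)
        assert grm.entries[0, 1] == pytest.approx(grm.entries[0, 0])

    def test_average_inbred_diagonal_brute_force(self):
        """Mean diagonal ~ 1 + F with F ~ 1 for inbreds (20-line toy)."""
        rng = np.random.default_rng(2)
        p = rng.uniform(0.2, 0.8, 500)
        d = 2 * (rng.random((20, 500)) < p).astype(float)
        grm = evaluation.build_grm(d, p, blend=0.0)
        # independent brute-force computation
        Zc = d - 2 * p
        G = Zc @ Zc.T / np.sum(2 * p * (1 - p))
        np.testing.assert_allclose(grm.entries, G)
        assert grm.entries.diagonal().mean() == pytest.approx(2.0, rel=0.1)

    def test_monomorphic_markers_excluded(self):
        d = np.array([[0.0, 2.0, 1.0], [2.0, 2.0, 1.0]])
        p = np.array([0.5, 1.0, 0.5])
        grm = evaluation.build_grm(d, p)
        assert grm.n_markers_excluded == 1

    def test_blending_makes_positive_definite(self):
        d = np.zeros((5, 10))  # degenerate genotypes
        grm = evaluation.build_grm(d, np.full(10, 0.5), blend=0.01)
        assert np.all(np.linalg.eigvalsh(grm.entries) > 0)


class TestGBLUP:
    def test_scalar_shrinkage_closed_form(self):
        """With G = I and one record per line, GEBV_i = h2 (y_i - mu)."""
        rng = np.random.default_rng(3)
        n = 12
        y = rng.normal(2.0, 1.0, n)
        g0 = np.eye(3)
        rv = 3.0
        rec = _records(np.arange(n), np.full(n, AYT), y, np.full(n, rv))
        for method in ("mme", "gls"):
            res = evaluation.solve_multitrait_gblup(rec, np.eye(n), g0,
                                                    method=method)
            h2 = 1.0 / (1.0 + rv)
            mu = res.means[AYT]
            np.testing.assert_allclose(res.scores[:, AYT], h2 * (y - mu),
                                       atol=1e-8)

    def test_mme_and_gls_agree_multitrait(self):
        """Both solvers give identical GEBVs on a 3-trait missing-pattern toy."""
        rng = np.random.default_rng(4)
        n = 8
        A = rng.normal(size=(n, n + 2))
        G = A @ A.T / (n + 2) + 0.05 * np.eye(n)
        G0 = np.array([[1.0, 0.1, 0.1], [0.1, 1.0, 0.9], [0.1, 0.9, 1.0]])
        li = np.array([0, 1, 2, 3, 4, 0, 1, 5])
        ti = np.array([PYT, PYT, PYT, AYT, AYT, AYT, BVP, PYT])
        y = rng.normal(size=8)
        rv = np.array([4.0, 4.0, 4.0, 0.26, 0.26, 0.26, 9.0, 4.0])
        r1 = evaluation.solve_multitrait_gblup(_records(li, ti, y, rv), G, G0,
                                               method="mme")
        r2 = evaluation.solve_multitrait_gblup(_records(li, ti, y, rv), G, G0,
                                               method="gls")
        np.testing.assert_allclose(r1.scores, r2.scores, atol=1e-8)
        np.testing.assert_allclose(r1.means, r2.means, atol=1e-8)

    def test_unrelated_candidate_gets_zero(self):
        n = 5
        G = np.eye(n)
        rec = _records([0, 1, 2], [AYT] * 3, [1.0, 2.0, 3.0], [1.0] * 3)
        res = evaluation.solve_multitrait_gblup(rec, G, np.eye(3))
        assert res.scores[4, AYT] == pytest.approx(0.0, abs=1e-10)

    def test_cross_trait_information_flow_sign(self):
        """A line phenotyped only for PYT gets an AYT GEBV of matching sign."""
        G0 = np.array([[1.0, 0.1, 0.1], [0.1, 1.0, 0.9], [0.1, 0.9, 1.0]])
        rec = _records([0, 1], [PYT, PYT], [1.0, -1.0], [0.5, 0.5])
        res = evaluation.solve_multitrait_gblup(rec, np.eye(2), G0,
                                                method="mme")
        assert res.scores[0, AYT] > 0 > res.scores[1, AYT]

    def test_mean_shift_invariance(self):
        """Adding a constant to all records of a trait leaves GEBVs unchanged."""
        rng = np.random.default_rng(5)
        n = 6
        y = rng.normal(size=n)
        rec1 = _records(np.arange(n), [AYT] * n, y, [1.0] * n)
        rec2 = _records(np.arange(n), [AYT] * n, y + 100.0, [1.0] * n)
        r1 = evaluation.solve_multitrait_gblup(rec1, np.eye(n), np.eye(3))
        r2 = evaluation.solve_multitrait_gblup(rec2, np.eye(n), np.eye(3))
        np.testing.assert_allclose(r1.scores, r2.scores, atol=1e-8)

    def test_diagonal_g0_decouples_traits(self):
        rng = np.random.default_rng(6)
        n = 6
        yP = rng.normal(size=n)
        yA = rng.normal(size=n)
        both = _records(list(range(n)) * 2, [PYT] * n + [AYT] * n,
                        np.concatenate([yP, yA]), [2.0] * (2 * n))
        only_p = _records(range(n), [PYT] * n, yP, [2.0] * n)
        rb = evaluation.solve_multitrait_gblup(both, np.eye(n), np.eye(3))
        rp = evaluation.solve_multitrait_gblup(only_p, np.eye(n), np.eye(3))
        np.testing.assert_allclose(rb.scores[:, PYT], rp.scores[:, PYT],
                                   atol=1e-8)

    def test_unknown_line_rejected(self):
        rec = _records([5], [AYT], [1.0], [1.0])
        with pytest.raises(evaluation.IndexingError):
            evaluation.solve_multitrait_gblup(rec, np.eye(3), np.eye(3))


class TestPhenotypeCriterion:
    def test_single_and_multi_plot_means(self):
        rec = _records([0, 1, 1, 1], [AYT] * 4, [1.0, 2.0, 4.0, 6.0],
                       [1.0] * 4)
        res = evaluation.phenotype_criterion(rec, np.array([0, 1]), "AYT")
        np.testing.assert_allclose(res.criterion("AYT"), [1.0, 4.0])

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        li = np.repeat(np.arange(5), 9)
        y = rng.normal(size=45)
        perm = rng.permutation(45)
        r1 = evaluation.phenotype_criterion(
            _records(li, [AYT] * 45, y, [1.0] * 45), np.arange(5), "AYT")
        r2 = evaluation.phenotype_criterion(
            _records(li[perm], [AYT] * 45, y[perm], [1.0] * 45),
            np.arange(5), "AYT")
        np.testing.assert_allclose(r1.criterion("AYT"), r2.criterion("AYT"))

    def test_missing_candidate_raises(self):
        rec = _records([0], [AYT], [1.0], [1.0])
        with pytest.raises(evaluation.MissingDataError):
            evaluation.phenotype_criterion(rec, np.array([0, 3]), "AYT")


class TestAccuracy:
    def test_perfect_and_inverted(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        assert evaluation.selection_accuracy(g, g) == pytest.approx(1.0)
        assert evaluation.selection_accuracy(-g, g) == pytest.approx(-1.0)

    def test_noise_ratio_closed_form(self):
        """corr(g + e, g) ~ sqrt(var_g / (var_g + var_e))."""
        rng = np.random.default_rng(8)
        g = rng.normal(0, 1, 40000)
        crit = g + rng.normal(0, np.sqrt(3.0), g.size)
        expect = np.sqrt(1.0 / 4.0)
        got = evaluation.selection_accuracy(crit, g)
        assert got == pytest.approx(expect, abs=3 / np.sqrt(40000) * 2)

    def test_degenerate_inputs_signal_missing(self):
        assert np.isnan(evaluation.selection_accuracy([1.0, 1.0, 1.0],
                                                      [1.0, 2.0, 3.0]))
        assert np.isnan(evaluation.selection_accuracy([1.0, 2.0],
                                                      [1.0, 2.0]))
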