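"""Breeding-scheme engine: crossing block, parent pool, program structure."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wheatsim import scheme
from conftest import mini_config


class TestCrossingBlock:
    @pytest.mark.parametrize("n,expect", [(60, 1770), (2, 1)])
    def test_possible_crosses(self, n, expect):
        assert scheme.count_possible_crosses(n) == expect

    def test_possible_crosses_matches_enumeration(self):
        pairs = list(itertools.combinations(range(10), 2))
        assert scheme.count_possible_crosses(10) == len(pairs) == 45

    def test_invalid_parent_count(self):
        with pytest.raises(ValueError):
            scheme.count_possible_crosses(1)

    def test_default_block_respects_cap(self, rng):
        pairs = scheme.make_crosses(60, 100, 6, rng)
        assert pairs.shape == (100, 2)
        assert len({tuple(p) for p in pairs}) == 100
        usage = np.bincount(pairs.ravel(), minlength=60)
        assert usage.max() <= 6

    def test_two_parents_single_cross(self, rng):
        pairs = scheme.make_crosses(2, 1, 1, rng)
        np.testing.assert_array_equal(pairs, [[0, 1]])

    def test_cap_one_yields_perfect_matchings(self):
        # 4 parents, cap 1, 2 crosses: result must be one of the 3 perfect
        # matchings, and more than one must be reachable across seeds
        matchings = set()
        for seed in range(30):
            pairs = scheme.make_crosses(4, 2, 1, np.random.default_rng(seed))
            flat = pairs.ravel()
            assert sorted(flat) == [0, 1, 2, 3]  # every parent used once
            matchings.add(frozenset(map(tuple, pairs)))
        assert len(matchings) > 1

    def test_infeasible_cap_rejected(self, rng):
        with pytest.raises(ValueError):
            scheme.make_crosses(4, 3, 1, rng)


class TestDrawParents:
    def _pool(self, n_stored=80, year_stored=9):
        rng = np.random.default_rng(0)
        pool = scheme.ParentPool(
            base_haps=np.zeros((480, 2, 4), dtype=np.int8),
            base_tbv=rng.normal(size=(480, 3)))
        pool.add(year_stored, np.ones((n_stored, 2, 4), dtype=np.int8),
                 rng.normal(size=(n_stored, 3)),
                 np.arange(1000, 1000 + n_stored),
                 rng.normal(size=n_stored))
        return pool

    def test_early_years_draw_from_base(self):
        pool = self._pool()
        _, _, ids = scheme.draw_parents(pool, 60, 3,
                                        np.random.default_rng(1))
        assert np.all(ids < 0)  # base lines carry negative ids

    def test_post_burn_in_draw_from_stored(self):
        pool = self._pool()
        _, _, ids = scheme.draw_parents(pool, 60, 10,
                                        np.random.default_rng(1))
        assert np.all(ids >= 1000)

    def test_pool_of_exactly_n_returns_whole_pool(self):
        pool = self._pool(n_stored=60)
        _, _, ids = scheme.draw_parents(pool, 60, 10,
                                        np.random.default_rng(2))
        assert set(ids) == set(range(1000, 1060))

    def test_draw_uniformity(self):
        """Each stored line appears with ~uniform frequency over many draws."""
        pool = self._pool(n_stored=80)
        counts = np.zeros(80)
        rng = np.random.default_rng(3)
        n_draws = 2000
        for _ in range(n_draws):
            _, _, ids = scheme.draw_parents(pool, 10, 10, rng)
            counts[ids - 1000] += 1
        expect = n_draws * 10 / 80
        chi2 = np.sum((counts - expect) ** 2 / expect)
        # chi-square with 79 dof: mean 79, sd ~12.6
        assert chi2 < 79 + 5 * 12.6

    def test_truncation_selects_top_criterion(self):
        pool = self._pool(n_stored=80)
        _, tbv, ids = scheme.draw_parents(pool, 10, 10,
                                          np.random.default_rng(4),
                                          selection="truncation")
        crit = pool.entries[0]["criterion"]
        top = np.argsort(-crit)[:10]
        assert set(ids) == set(1000 + top)

    def test_exhaustion(self):
        pool = self._pool(n_stored=10)
        with pytest.raises(scheme.PoolExhaustionError):
            scheme.draw_parents(pool, 60, 10, np.random.default_rng(5))


class TestProgramStructure:
    def test_first_year_creates_one_f1_cohort(self):
        cfg = mini_config()
        state = scheme.initialize_state(cfg, 3)
        scheme.advance_year(state, cfg, state._program_rng)
        assert list(state.cohorts) == [1]
        c = state.cohorts[1]
        assert c.stage == "F1" and c.n == cfg.n_crosses

    def test_steady_state_has_all_generations(self, mini_ps_output):
        df = mini_ps_output.stage_stats
        year10 = df[df.year == 10]
        assert sorted(year10.stage) == [f"F{g}" for g in range(1, 9)]

    def test_funnel_cardinalities_exact(self, mini_ps_output):
        """Stage sizes follow the configured funnel exactly, every cycle."""
        cfg = mini_ps_output.config
        expect = {
            "F1": cfg.n_crosses,
            "F2": cfg.n_crosses * cfg.f2_seeds_per_f1,
            "F3": cfg.n_crosses * cfg.f2_select_per_family,
            "F4": cfg.f3_families_kept * cfg.f4_plants_per_family,
            "F5": cfg.f3_families_kept * cfg.f4_select_per_family,
            "F6": cfg.f5_kept,
            "F7": cfg.f6_kept,
            "F8": cfg.f7_kept,
        }
        df = mini_ps_output.stage_stats
        steady = df[df.year >= 9]
        for stage, n in expect.items():
            assert (steady[steady.stage == stage].n == n).all(), stage

    def test_determinism(self):
        cfg = mini_config()
        a = scheme.run_program(cfg, seed=5).stage_stats
        b = scheme.run_program(cfg, seed=5).stage_stats
        pd.testing.assert_frame_equal(a, b)

    def test_burn_in_bit_equivalence_ps_gs(self, mini_ps_output,
                                           mini_gs_output):
        """With a shared seed, PS and GS are identical through the burn-in."""
        a = mini_ps_output.stage_stats
        b = mini_gs_output.stage_stats
        cols = [c for c in a.columns if c != "strategy"]
        pd.testing.assert_frame_equal(
            a[a.year <= 8][cols].reset_index(drop=True),
            b[b.year <= 8][cols].reset_index(drop=True))

    def test_strategies_diverge_after_burn_in(self, mini_ps_output,
                                              mini_gs_output):
        a = mini_ps_output.stage_stats
        b = mini_gs_output.stage_stats
        post_a = a[(a.year > 10)].mean_AYT.to_numpy()
        post_b = b[(b.year > 10)].mean_AYT.to_numpy()
        assert not np.allclose(post_a, post_b)

    def test_reference_grows_by_750_equivalent(self, mini_gs_output):
        """The genomic reference grows by one F4 cohort per GS year."""
        df = mini_gs_output.stage_stats
        cfg = mini_gs_output.config
        cohort = cfg.f3_families_kept * cfg.f4_select_per_family
        ref = df.groupby("year").reference_size.max()
        # year 9 is the first GS year: one genotyped F4 cohort by year end,
        # growing by one cohort per year thereafter
        for y in range(9, cfg.years + 1):
            assert ref[y] == (y - 8) * cohort

    def test_gain_monotone_trend(self, mini_ps_output):
        """Mean F8 TBV regressed on year has positive slope."""
        df = mini_ps_output.stage_stats
        f8 = df[df.stage == "F8"]
        x = f8.year.to_numpy(dtype=float)
        y = f8.mean_AYT.to_numpy()
        slope = np.polyfit(x, y, 1)[0]
        assert slope > 0

    def test_parent_pool_traceability(self, mini_ps_output):
        """F1 variance stays near half the parental variance (inbred parents,
        zero Mendelian sampling at the F1)."""
        df = mini_ps_output.stage_stats
        f1 = df[(df.stage == "F1") & (df.year <= 7)]  # base-population parents
        assert f1.var_AYT.mean() == pytest.approx(0.5, abs=0.2)


class TestConfigValidation:
    def test_funnel_inconsistency_rejected(self):
        with pytest.raises(scheme.FunnelError):
            mini_config(f2_select_per_family=10).validate()

    def test_bad_strategy_rejected(self):
        with pytest.raises(ValueError):
            mini_config(strategy="XX").validate()

    def test_scaled_gs_config(self):
        cfg = scheme.scaled_gs_config(corr_pyt_ayt=0.5)
        assert cfg.strategy == "GS"
        assert cfg.marker_thin_step == 4
        assert cfg.reference_window == 3
        assert cfg.corr_pyt_ayt == 0.5
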