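import numpy as np
import pytest

from wheatsim import genome, scheme, traits


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_layout():
    """Two 100 cM chromosomes, 40 loci, 8 QTL."""
    return genome.build_genome_layout(40, 8, 2, 100.0,
                                      np.random.default_rng(7))


@pytest.fixture(scope="session")
def toy_pool(toy_layout):
    return genome.simulate_founder_pool(toy_layout, 60,
                                        rng=np.random.default_rng(8))


@pytest.fixture(scope="session")
def toy_base(toy_pool):
    return genome.sample_base_population(toy_pool, 40,
                                         np.random.default_rng(9))


@pytest.fixture(scope="session")
def toy_model(toy_layout, toy_base):
    return traits.build_trait_model(toy_layout, toy_base, 0.5,
                                    np.random.default_rng(10))


def mini_config(**kwargs):
    """A reduced breeding program for structural tests.

    The funnel shape (within-family selection, family selection, three
    yield-trial stages, rolling parent pool) matches the full program, only
    the counts are shrunk so a 12-year run takes ~a second.
    """
    defaults = dict(
        years=12, burn_in_years=8,
        n_loci=210, n_qtl=30, n_chromosomes=7, map_length_cM=120.0,
        n_founders=60, n_base=40,
        n_parents=8, n_crosses=12, max_crosses_per_parent=6,
        f2_seeds_per_f1=6, f2_select_per_family=2,
        f3_families_kept=9, f3_plots_per_family=3,
        f4_plants_per_family=6, f4_select_per_family=4,
        f5_kept=18, f6_kept=6, f7_kept=2,
        pyt_plot_plants=10, ayt_plot_plants=50, ayt_replicates=9,
        reference_window=2,
    )
    defaults.update(kwargs)
    return scheme.SchemeConfig(**defaults)


@pytest.fixture(scope="session")
def mini_ps_output():
    return scheme.run_program(mini_config(strategy="PS"), seed=77)


@pytest.fixture(scope="session")
def mini_gs_output():
    return scheme.run_program(mini_config(strategy="GS"), seed=77)
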