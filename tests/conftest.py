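import copy

import pytest

from mitonuc.haplocall import HaplogroupTree
from mitonuc.pipeline import demo_config
from mitonuc.popsim import SimConfig, simulate_cohort
from mitonuc.variant_io import load_default_haplogroup_tree


@pytest.fixture(scope="session")
def hg_tree() -> HaplogroupTree:
    return load_default_haplogroup_tree()


@pytest.fixture(scope="session")
def chain_tree() -> HaplogroupTree:
    """5-node chain reference -> H1 -> H2 -> H3 -> H4, one variant per edge."""
    return HaplogroupTree(
        root="reference",
        parent={"H1": "reference", "H2": "H1", "H3": "H2", "H4": "H3"},
        edge_variants={
            "reference": frozenset(),
            "H1": frozenset({(100, "T")}),
            "H2": frozenset({(200, "T")}),
            "H3": frozenset({(300, "T")}),
            "H4": frozenset({(400, "T")}),
        },
        macro_map={n: "H" for n in ("reference", "H1", "H2", "H3", "H4")},
        origin_map={n: "Europe" for n in ("reference", "H1", "H2", "H3", "H4")},
    )


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """3 populations in 2 continental groups, cheap enough for unit tests."""
    return SimConfig(
        pops=["AFR1", "EUR1", "EUR2"],
        group_of_pop={"AFR1": "Africa", "EUR1": "Europe", "EUR2": "Europe"},
        samples_per_pop=10,
        n_nuclear_sites=200,
        fst=0.1,
        mt_freqs={
            "AFR1": {"L0": 0.5, "L1": 0.5},
            "EUR1": {"H": 1.0},
            "EUR2": {"U": 0.5, "T": 0.5},
        },
        private_mut_rate=0.0,
        cross_mt_rate=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config, hg_tree):
    return simulate_cohort(small_config, hg_tree)


@pytest.fixture(scope="session")
def demo_sim_config() -> SimConfig:
    """The bundled 6-pop demo simulation block (copy; safe to mutate)."""
    return copy.deepcopy(demo_config("unused", seed=0).simulate)
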