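import numpy as np
import pytest

from gpcrsel.phylogeny import Tree
from gpcrsel.synthetic_data import (
    SimulationConfig,
    make_subgroup_fixture,
    simulate_codon_alignment,
)


@pytest.fixture(scope="session")
def strong_negative_fixture(tmp_path_factory):
    """Synthetic subgroup under strong negative selection at the key columns."""
    outdir = tmp_path_factory.mktemp("fixture_neg")
    return make_subgroup_fixture(
        category="small", selection_regime="strong-negative", seed=2, outdir=outdir
    )


@pytest.fixture(scope="session")
def positive_fixture(tmp_path_factory):
    """Synthetic MRGX-like subgroup with planted positive selection."""
    outdir = tmp_path_factory.mktemp("fixture_pos")
    return make_subgroup_fixture(
        category="peptide", selection_regime="positive-at-key", seed=1, outdir=outdir
    )


@pytest.fixture(scope="session")
def small_m0_alignment():
    """Five-taxon alignment simulated under a single-ratio model."""
    config = SimulationConfig(
        n_taxa=5,
        n_codons=200,
        site_classes=[(1.0, 0.3)],
        seed=42,
        tree_height=0.4,
    )
    alignment, true_omega, tree = simulate_codon_alignment(config)
    return alignment, true_omega, tree


@pytest.fixture(scope="session")
def quartet_tree():
    return Tree.from_newick("((t1:0.2,t2:0.3):0.1,(t3:0.25,t4:0.15):0.12);")


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
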