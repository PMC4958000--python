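import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from phylorigins.alignment import Alignment
from phylorigins.synthetic import SynthConfig, generate_dataset, simulate_yule_tree


@pytest.fixture
def toy_alignment():
    """4x6 alignment with per-column non-gap counts (4, 4, 1, 4, 2, 4)."""
    return Alignment.from_records(
        [
            ("a", "ACGTAC"),
            ("b", "AC-TAC"),
            ("c", "AC-T-C"),
            ("d", "AC-T-C"),
        ]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """60-taxon synthetic pool with 3 planted endosymbiont origins."""
    config = SynthConfig(n_taxa=60, k_origins=3, seed=1)
    aln, labels, truth = generate_dataset(config)
    return aln, labels, truth


def random_labeled_tree(rng, n_min=4, n_max=30, p_endo=0.5):
    """Random Yule tree plus random binary leaf labels."""
    n = int(rng.integers(n_min, n_max + 1))
    tree = simulate_yule_tree(n, 1.0, int(rng.integers(0, 2**31 - 1)))
    labels = {
        leaf.taxon.label: bool(rng.random() < p_endo)
        for leaf in tree.leaf_node_iter()
    }
    return tree, labels
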