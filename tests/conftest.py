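import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ovorate import simulate as sim
from ovorate.trees import PhyloTree, star_tree


@pytest.fixture(scope="session")
def five_taxon_tree() -> PhyloTree:
    return sim.melanogaster_tree()


@pytest.fixture(scope="session")
def five_star() -> PhyloTree:
    return star_tree(["A", "B", "C", "D", "E"], 0.15)


@pytest.fixture(scope="session")
def small_alignment(five_taxon_tree):
    return sim.simulate_codon_alignment(
        five_taxon_tree, kappa=2.0, omega=0.3, n_codons=200, seed=42
    )


def random_resolved_tree(rng: np.random.Generator, tips: list[str]) -> PhyloTree:
    """Random rooted binary tree with uniform(0.05, 1) branch lengths."""
    nodes = [f"{t}:{rng.uniform(0.05, 1.0):.4f}" for t in tips]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        if len(nodes) == 0:
            nodes.append(f"({a},{b})")
        else:
            nodes.append(f"({a},{b}):{rng.uniform(0.05, 1.0):.4f}")
    return PhyloTree.from_newick(nodes[0] + ";")
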