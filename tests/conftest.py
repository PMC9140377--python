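import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from numtclock.phylo import Node, Phylogeny  # noqa: E402


def _random_binary_tree(
    rng: np.random.Generator,
    n_leaves: int,
    min_len: float = 0.02,
    max_len: float = 0.3,
) -> Phylogeny:
    """Random rooted binary tree with strictly positive branch lengths."""
    nodes = [Node(f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.uniform(min_len, max_len))
        b.length = float(rng.uniform(min_len, max_len))
        nodes.append(Node(children=[a, b]))
    return Phylogeny(nodes[0])


def _path_matrix(t: Phylogeny) -> tuple[np.ndarray, list[str]]:
    labels = sorted(t.leaf_names())
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = t.path_length(labels[i], labels[j])
    return D, labels


@pytest.fixture
def tree_factory():
    return _random_binary_tree


@pytest.fixture
def path_matrix():
    return _path_matrix
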