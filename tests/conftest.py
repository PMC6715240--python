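import pytest

from gmlayout import ModuleAssignment, Network, example_network_24


@pytest.fixture
def example24():
    """The fixed 24-node demonstration network and its predefined module."""
    return example_network_24()


@pytest.fixture
def path_abc():
    """Path graph a-b-c, all in one module."""
    net = Network(["a", "b", "c"], [("a", "b"), ("b", "c")])
    assign = ModuleAssignment({"a": "M", "b": "M", "c": "M"})
    return net, assign


@pytest.fixture
def two_cliques_bridge():
    """Two 4-cliques joined by a single bridge edge."""
    left = ["a1", "a2", "a3", "a4"]
    right = ["b1", "b2", "b3", "b4"]
    edges = [(u, v) for i, u in enumerate(left) for v in left[i + 1:]]
    edges += [(u, v) for i, u in enumerate(right) for v in right[i + 1:]]
    edges.append(("a4", "b1"))
    return Network(left + right, edges)
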