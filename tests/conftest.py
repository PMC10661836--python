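import pytest

from keynet import ScoredEdge, ScoredNetwork


def net_from_edges(edges, name="test", nodes=(), default_cs=900):
    """Build a ScoredNetwork from (a, b) or (a, b, cs) tuples."""
    net = ScoredNetwork(name, nodes=nodes)
    for e in edges:
        a, b, *rest = e
        cs = rest[0] if rest else default_cs
        net.add_edge(ScoredEdge(a, b, cs))
    return net


def complete_graph(n, name="complete", default_cs=900):
    names = [f"N{i}" for i in range(n)]
    return net_from_edges(
        [(names[i], names[j]) for i in range(n) for j in range(i + 1, n)],
        name=name, default_cs=default_cs,
    )


def star_graph(n_leaves, name="star"):
    return net_from_edges([("HUB", f"L{i}") for i in range(n_leaves)], name=name)


@pytest.fixture
def path3():
    """Path A-B-C."""
    return net_from_edges([("A", "B"), ("B", "C")], name="path3")


@pytest.fixture
def fixture_lists():
    from keynet import make_fixture_lists

    return make_fixture_lists(seed=13)
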