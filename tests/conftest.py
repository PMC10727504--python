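import numpy as np
import pytest

from mscintro.network import ParamSet, tree_from_newick, add_introgression_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def three_species_tree():
    net = tree_from_newick("((A,B)ab,C)r;")
    params = ParamSet(
        tau={"ab": 0.01, "r": 0.03},
        theta={k: 0.01 for k in ["A", "B", "C", "ab", "r"]},
    )
    return net, params


@pytest.fixture
def four_species_tree():
    net = tree_from_newick("(((A,B)n1,C)n2,D)r;")
    params = ParamSet(
        tau={"n1": 0.01, "n2": 0.03, "r": 0.05},
        theta={k: 0.01 for k in ["A", "B", "C", "D", "n1", "n2", "r"]},
    )
    return net, params


@pytest.fixture
def one_pair_network():
    """Two-species tree with one bidirectional introgression pair."""
    net = add_introgression_pair(tree_from_newick("(A,B)ab;"), "A", "B", "hA", "hB")
    params = ParamSet(
        tau={"ab": 0.02, "hA": 0.008, "hB": 0.008},
        theta={k: 0.01 for k in ["A", "B", "ab"]},
        phi={"hA": 0.3, "hB": 0.6},
    )
    return net, params


def random_network(rng, n_tips, n_pairs):
    """Random rooted binary tree with random valid introgression pairs
    and a consistent ParamSet (used by roundtrip/property tests)."""
    from mscintro.network import SpeciesNetwork, Node

    tips = [f"t{i}" for i in range(n_tips)]
    clades = [(t,) for t in tips]
    nodes = {t: Node(t, "tip") for t in tips}
    counter = 0
    while len(clades) > 1:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        counter += 1
        name = f"v{counter}"
        a = clades[i]
        b = clades[j]
        ca = a[0] if len(a) == 1 else a[1]
        cb = b[0] if len(b) == 1 else b[1]
        nodes[name] = Node(name, "divergence", children=[ca, cb])
        nodes[ca].parents = [name]
        nodes[cb].parents = [name]
        merged = (a[0] + b[0], name)
        clades = [c for k, c in enumerate(clades) if k not in (i, j)] + [merged]
    root = clades[0][1]
    net = SpeciesNetwork(nodes, root)

    # ages bottom-up (parent strictly older), then add pairs
    params = ParamSet()

    def assign(name):
        node = net.nodes[name]
        if node.kind == "tip":
            return 0.0
        child_max = max(assign(c) for c in net.structural_children(name))
        age = child_max + 0.005 * (0.5 + rng.random())
        params.tau[name] = age
        return age

    assign(root)

    for k in range(n_pairs):
        cands = [
            n
            for n, node in net.nodes.items()
            if n != net.root and node.kind != "hybrid"
        ]
        for _ in range(50):
            a, b = rng.choice(len(cands), size=2, replace=False)
            na, nb = cands[int(a)], cands[int(b)]
            from mscintro.network import node_age

            lo = max(node_age(net, params, na), node_age(net, params, nb))
            hi = min(
                params.tau.get(net.main_parent(na), 0.0) or 0.0,
                params.tau.get(net.main_parent(nb), 0.0) or 0.0,
            )
            if hi > lo * 1.0 + 1e-9 and hi - lo > 1e-6:
                net = add_introgression_pair(net, na, nb, f"h{k}a", f"h{k}b")
                t = lo + (hi - lo) * (0.2 + 0.6 * rng.random())
                params.tau[f"h{k}a"] = params.tau[f"h{k}b"] = t
                params.phi[f"h{k}a"] = float(rng.random())
                params.phi[f"h{k}b"] = float(rng.random())
                break
    for key in net.theta_keys("linked"):
        params.theta[key] = 0.005 + 0.01 * rng.random()
    return net, params
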