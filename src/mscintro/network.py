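"""Species trees and introgression networks.

The species phylogeny is a rooted binary tree whose internal nodes are
speciation (divergence) events.  Introgression is modelled as *pulse*
events: a pair of hybridization nodes, one on each of two contemporaneous
branches, sharing a single event time tau_h, with a directed arrow in each
direction.  Tracing a lineage backwards in time, when it reaches the
hybridization node on its branch it follows the *donor* branch with
probability phi and its own ancestral branch with probability 1 - phi.
This tree-plus-pulse-edges class (MSC-I) is the only network class
implemented; general level-k networks are out of scope.

Populations are the edges of the network.  Every node (including the
root) owns the population directly above it; a hybridization node splits
an ordinary branch into a lower and an upper population.  Under the
``linked`` theta model the populations above and below a hybridization
node share one effective-population-size parameter theta = 4*N*mu, so the
number of free theta parameters equals (#tips + #divergence nodes).

All times (tau) are in expected substitutions per site.

Extended-Newick dialect
-----------------------
A hybridization node labelled ``x`` with hybrid id ``#H1`` appears twice:

* once *in place* on its branch, with its real subtree as first child and
  the partner node's reference leaf as second child:  ``(subtree, y#H2)x#H1``
* once as a bare reference leaf ``x#H1`` inside the partner's in-place node.

``phi`` may be attached in a bracket comment after the in-place
occurrence, e.g. ``(A, y#H2)x#H1[&phi=0.1]``; phi is the probability that
a lineage below ``x`` traces back to the donor branch (the partner's
upper population).  Plain Newick (no ``#H`` labels) is accepted for trees.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "SpeciesNetwork",
    "Node",
    "ParamSet",
    "NetworkParseError",
    "parse_network",
    "write_network",
    "count_free_parameters",
    "validate",
]


class NetworkParseError(ValueError):
    """Raised when an (extended-)Newick string cannot be parsed."""


@dataclass
class Node:
    """One node of a species network.

    kind is 'tip', 'divergence' or 'hybrid'.  ``parents`` holds one name
    for tips/divergence nodes (empty for the root) and two for hybrid
    nodes: ``parents[0]`` is the ancestral (same-branch) parent and
    ``parents[1]`` the donor parent, which is always the partner
    hybridization node of the pair.
    """

    name: str
    kind: str
    children: list[str] = field(default_factory=list)
    parents: list[str] = field(default_factory=list)


class SpeciesNetwork:
    """Rooted species tree plus zero or more bidirectional introgression pairs."""

    def __init__(self, nodes: dict[str, Node], root: str):
        self.nodes = nodes
        self.root = root
        self._check_structure()

    # -- basic accessors -------------------------------------------------
    @property
    def tips(self) -> list[str]:
        return [n.name for n in self.nodes.values() if n.kind == "tip"]

    @property
    def divergence_nodes(self) -> list[str]:
        return [n.name for n in self.nodes.values() if n.kind == "divergence"]

    @property
    def hybrid_nodes(self) -> list[str]:
        return [n.name for n in self.nodes.values() if n.kind == "hybrid"]

    @property
    def hybrid_pairs(self) -> list[tuple[str, str]]:
        """Introgression pairs as (name_a, name_b) with name_a < name_b."""
        pairs = set()
        for h in self.hybrid_nodes:
            partner = self.nodes[h].parents[1]
            pairs.add(tuple(sorted((h, partner))))
        return sorted(pairs)

    def partner(self, hybrid: str) -> str:
        return self.nodes[hybrid].parents[1]

    def main_parent(self, name: str) -> str | None:
        node = self.nodes[name]
        return node.parents[0] if node.parents else None

    def main_child(self, hybrid: str) -> str:
        """The same-branch child below a hybridization node."""
        return self.nodes[hybrid].children[0]

    def base_branch(self, name: str) -> str:
        """Lowest non-hybrid node of the branch ``name`` sits on.

        Used as the theta key under the linked theta model: all
        populations along one original branch share the theta of the
        branch's bottom (tip or divergence) node.
        """
        node = self.nodes[name]
        while node.kind == "hybrid":
            node = self.nodes[node.children[0]]
        return node.name

    def theta_keys(self, theta_model: str = "linked") -> list[str]:
        if theta_model == "linked":
            return sorted(self.tips) + sorted(self.divergence_nodes)
        if theta_model == "independent":
            return sorted(self.nodes)
        raise ValueError(f"unknown theta_model {theta_model!r}")

    def tip_set(self, name: str, _cache: dict | None = None) -> frozenset[str]:
        """Species reachable (toward the tips) from ``name`` via main-child edges."""
        node = self.nodes[name]
        if node.kind == "tip":
            return frozenset([name])
        out: set[str] = set()
        for c in node.children:
            if self.nodes[c].kind == "hybrid" and self.nodes[c].parents[1] == name:
                continue  # donor reference, not a structural child
            out |= self.tip_set(c)
        return frozenset(out)

    def structural_children(self, name: str) -> list[str]:
        """Children excluding donor references (partner hybrids)."""
        return [
            c
            for c in self.nodes[name].children
            if not (self.nodes[c].kind == "hybrid" and self.nodes[c].parents[1] == name)
        ]

    # -- validation ------------------------------------------------------
    def _check_structure(self) -> None:
        if not self.tips:
            raise NetworkParseError("network has no tips")
        if len(set(self.tips)) != len(self.tips):
            raise NetworkParseError("duplicate tip labels")
        for node in self.nodes.values():
            if node.name == self.root:
                if node.parents:
                    raise NetworkParseError("root must have no parent")
            elif node.kind == "hybrid":
                if len(node.parents) != 2:
                    raise NetworkParseError(
                        f"hybrid node {node.name} must have two parents"
                    )
                partner = node.parents[1]
                if (
                    self.nodes[partner].kind != "hybrid"
                    or self.nodes[partner].parents[1] != node.name
                ):
                    raise NetworkParseError(
                        f"hybrid node {node.name} is not part of a mutual pair"
                    )
            else:
                if len(node.parents) != 1:
                    raise NetworkParseError(
                        f"node {node.name} must have exactly one parent"
                    )
        # acyclicity of the root->tips digraph over structural edges
        seen: set[str] = set()
        stack: set[str] = set()

        def visit(name: str) -> None:
            if name in stack:
                raise NetworkParseError("cycle detected in network")
            if name in seen:
                return
            stack.add(name)
            for c in self.structural_children(name):
                visit(c)
            stack.discard(name)
            seen.add(name)

        visit(self.root)
        if seen != set(self.nodes):
            raise NetworkParseError("nodes unreachable from root")

    # -- equality / display ----------------------------------------------
    def _signature(self):
        items = []
        for name in sorted(self.nodes):
            n = self.nodes[name]
            items.append((name, n.kind, tuple(sorted(n.children)), tuple(n.parents)))
        return (self.root, tuple(items))

    def __eq__(self, other) -> bool:
        return isinstance(other, SpeciesNetwork) and self._signature() == other._signature()

    def __hash__(self):
        return hash(self._signature())

    def __repr__(self) -> str:
        return (
            f"SpeciesNetwork({len(self.tips)} tips, "
            f"{len(self.divergence_nodes)} divergence nodes, "
            f"{len(self.hybrid_pairs)} introgression pairs)"
        )


@dataclass
class ParamSet:
    """Parameters of an MSC / MSC-I / MSC-M model.

    tau
        node name -> age (expected substitutions/site).  Keys: every
        divergence node, and every hybridization node (both members of a
        pair carry the same, shared value).  Tips are implicitly at 0.
    theta
        theta key -> 4*N*mu.  Under linked theta the keys are tips and
        divergence nodes; populations above hybridization nodes resolve
        to the theta of their base branch.
    phi
        hybrid node name -> probability that a lineage below that node
        traces back into the donor branch.
    mig
        "i->j" -> M_ij = expected migrants per generation from population
        i to population j, forward in time (MSC-M only).
    """

    tau: dict[str, float] = field(default_factory=dict)
    theta: dict[str, float] = field(default_factory=dict)
    phi: dict[str, float] = field(default_factory=dict)
    mig: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "ParamSet":
        return ParamSet(dict(self.tau), dict(self.theta), dict(self.phi), dict(self.mig))

    def to_json(self) -> str:
        return json.dumps(
            {"tau": self.tau, "theta": self.theta, "phi": self.phi, "mig": self.mig},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ParamSet":
        d = json.loads(text)
        return cls(
            tau=dict(d.get("tau", {})),
            theta=dict(d.get("theta", {})),
            phi=dict(d.get("phi", {})),
            mig=dict(d.get("mig", {})),
        )

    def resolve_theta(self, net: SpeciesNetwork, name: str) -> float:
        """Theta of the population above ``name`` (linked-model aware)."""
        if name in self.theta:
            return self.theta[name]
        return self.theta[net.base_branch(name)]


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""\s*(
        \(|\)|,|;|:|
        \[&[^\]]*\]|
        [^\s(),:;\[\]]+
    )""",
    re.VERBOSE,
)


def _tokenize(text: str) -> list[str]:
    pos = 0
    tokens = []
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise NetworkParseError(f"unexpected character at {text[pos:pos + 10]!r}")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


@dataclass
class _RawNode:
    label: str
    hybrid_id: str | None
    children: list["_RawNode"]
    phi: float | None = None
    length: float | None = None


def _parse_clade(tokens: list[str], idx: int, counter: list[int]) -> tuple[_RawNode, int]:
    children: list[_RawNode] = []
    if idx < len(tokens) and tokens[idx] == "(":
        idx += 1
        while True:
            child, idx = _parse_clade(tokens, idx, counter)
            children.append(child)
            if idx >= len(tokens):
                raise NetworkParseError("unexpected end of input inside '('")
            if tokens[idx] == ",":
                idx += 1
                continue
            if tokens[idx] == ")":
                idx += 1
                break
            raise NetworkParseError(f"expected ',' or ')', got {tokens[idx]!r}")
    label = ""
    if idx < len(tokens) and tokens[idx] not in "(),:;" and not tokens[idx].startswith("[&"):
        label = tokens[idx]
        idx += 1
    phi = None
    if idx < len(tokens) and tokens[idx].startswith("[&"):
        body = tokens[idx][2:-1]
        for part in body.split(","):
            if "=" in part:
                key, val = part.split("=", 1)
                if key.strip() == "phi":
                    phi = float(val)
        idx += 1
    length = None
    if idx < len(tokens) and tokens[idx] == ":":
        idx += 1
        if idx >= len(tokens):
            raise NetworkParseError("branch length expected after ':'")
        try:
            length = float(tokens[idx])
        except ValueError as exc:
            raise NetworkParseError(f"bad branch length {tokens[idx]!r}") from exc
        idx += 1
    hybrid_id = None
    if "#" in label:
        label, _, hid = label.partition("#")
        hybrid_id = hid
        if not hybrid_id.startswith("H"):
            raise NetworkParseError(f"hybrid id must start with 'H': #{hybrid_id}")
    if not label and not children:
        raise NetworkParseError("empty node with no label")
    if not label:
        counter[0] += 1
        label = f"_i{counter[0]}"
    return _RawNode(label, hybrid_id, children, phi, length), idx


def parse_network(text: str) -> SpeciesNetwork:
    """Parse a plain or extended Newick string into a :class:`SpeciesNetwork`.

    Returns only the topology and hybrid-edge structure; phi annotations,
    if present, are available via :func:`parse_network_with_phi`.
    """
    net, _phi = parse_network_with_phi(text)
    return net


def parse_network_with_phi(text: str) -> tuple[SpeciesNetwork, dict[str, float]]:
    tokens = _tokenize(text.strip())
    if not tokens or tokens[-1] != ";":
        raise NetworkParseError("input must end with ';'")
    counter = [0]
    raw, idx = _parse_clade(tokens, 0, counter)
    if idx != len(tokens) - 1:
        raise NetworkParseError(f"trailing tokens near {tokens[idx]!r}")

    # collect occurrences of each hybrid id
    occurrences: dict[str, list[_RawNode]] = {}

    def collect(r: _RawNode) -> None:
        if r.hybrid_id is not None:
            occurrences.setdefault(r.hybrid_id, []).append(r)
        for c in r.children:
            collect(c)

    collect(raw)
    for hid, occ in occurrences.items():
        with_children = [o for o in occ if o.children]
        bare = [o for o in occ if not o.children]
        if len(occ) != 2 or len(with_children) != 1 or len(bare) != 1:
            raise NetworkParseError(
                f"hybrid id #{hid} must occur exactly twice "
                "(once in place, once as a reference leaf)"
            )
        if with_children[0].label != bare[0].label:
            raise NetworkParseError(
                f"hybrid id #{hid} used with two labels: "
                f"{with_children[0].label!r} vs {bare[0].label!r}"
            )

    nodes: dict[str, Node] = {}
    phi: dict[str, float] = {}

    def build(r: _RawNode, parent: str | None) -> str:
        if r.hybrid_id is not None and not r.children:
            # reference leaf: its *parent in the text* is the donor parent
            # of the hybrid node; recorded when the in-place copy is built.
            return r.label
        if r.label in nodes:
            raise NetworkParseError(f"duplicate node label {r.label!r}")
        if r.hybrid_id is not None:
            real = [c for c in r.children if not (c.hybrid_id and not c.children)]
            refs = [c for c in r.children if c.hybrid_id and not c.children]
            if len(real) != 1 or len(refs) != 1:
                raise NetworkParseError(
                    f"in-place hybrid node {r.label!r} must have exactly one "
                    "subtree child and one partner reference"
                )
            node = Node(r.label, "hybrid")
            nodes[r.label] = node
            if parent is None:
                raise NetworkParseError("root cannot be a hybridization node")
            node.parents = [parent, refs[0].label]  # donor parent = partner
            if r.phi is not None:
                phi[r.label] = r.phi
            child_name = build(real[0], r.label)
            node.children = [child_name, refs[0].label]
            return r.label
        kind = "tip" if not r.children else "divergence"
        node = Node(r.label, kind)
        nodes[r.label] = node
        if parent is not None:
            node.parents = [parent]
        node.children = [build(c, r.label) for c in r.children]
        return r.label

    root = build(raw, None)
    net = SpeciesNetwork(nodes, root)
    # every hybrid's recorded donor parent must be its partner (mutual pair)
    for h in net.hybrid_nodes:
        p = net.nodes[h].parents[1]
        if net.nodes[p].parents[1] != h:
            raise NetworkParseError(f"hybrid nodes {h} and {p} are not mutual partners")
    return net, phi


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_network(
    net: SpeciesNetwork,
    phi: Mapping[str, float] | None = None,
) -> str:
    """Render a network in the extended-Newick dialect described above."""
    hybrid_ids = {name: f"H{i + 1}" for i, name in enumerate(sorted(net.hybrid_nodes))}

    def render(name: str) -> str:
        node = net.nodes[name]
        if node.kind == "tip":
            return name
        if node.kind == "hybrid":
            partner = net.partner(name)
            inner = render(node.children[0])
            ann = ""
            if phi is not None and name in phi:
                ann = f"[&phi={phi[name]:g}]"
            return f"({inner},{partner}#{hybrid_ids[partner]}){name}#{hybrid_ids[name]}{ann}"
        parts = ",".join(render(c) for c in net.structural_children(name))
        label = "" if name.startswith("_i") else name
        return f"({parts}){label}"

    return render(net.root) + ";"


# ---------------------------------------------------------------------------
# Parameter counting and validation
# ---------------------------------------------------------------------------

def count_free_parameters(net: SpeciesNetwork, theta_model: str = "linked") -> dict[str, int]:
    """Count free parameters of the MSC-I model on ``net``.

    Conventions: each bidirectional introgression pair contributes one
    shared event time and two introgression probabilities; under linked
    theta, hybridization nodes add no theta parameters, so
    n_theta = #tips + #divergence nodes.
    """
    if theta_model not in ("linked", "independent"):
        raise ValueError(f"unknown theta_model {theta_model!r}")
    n_pairs = len(net.hybrid_pairs)
    n_phi = 2 * n_pairs
    n_tau = len(net.divergence_nodes) + n_pairs
    n_theta = len(net.tips) + len(net.divergence_nodes)
    if theta_model == "independent":
        n_theta += 2 * n_pairs
    return {
        "n_phi": n_phi,
        "n_tau": n_tau,
        "n_theta": n_theta,
        "total": n_phi + n_tau + n_theta,
    }


def node_age(net: SpeciesNetwork, params: ParamSet, name: str) -> float:
    if net.nodes[name].kind == "tip":
        return 0.0
    return params.tau[name]


def validate(
    net: SpeciesNetwork,
    params: ParamSet,
    theta_model: str = "linked",
) -> list[str]:
    """Check all ParamSet invariants; return human-readable violations."""
    v: list[str] = []
    for name in net.divergence_nodes + net.hybrid_nodes:
        if name not in params.tau:
            v.append(f"missing tau for node {name}")
    if v:
        return v
    for name, node in net.nodes.items():
        t = node_age(net, params, name)
        if t < 0:
            v.append(f"negative age at node {name}")
        for p in node.parents[:1]:
            tp = node_age(net, params, p)
            if tp < t:
                v.append(f"child {name} (age {t:g}) older than parent {p} (age {tp:g})")
    for a, b in net.hybrid_pairs:
        ta, tb = params.tau[a], params.tau[b]
        if not math.isclose(ta, tb, rel_tol=0, abs_tol=1e-12):
            v.append(f"introgression pair ({a},{b}) times differ: {ta:g} vs {tb:g}")
        for h in (a, b):
            lo = node_age(net, params, net.main_child(h))
            hi = node_age(net, params, net.main_parent(h))
            if not (lo < params.tau[h] < hi):
                v.append(
                    f"introgression time of {h} ({params.tau[h]:g}) not strictly "
                    f"between child age {lo:g} and parent age {hi:g}"
                )
    for key in net.theta_keys(theta_model):
        if key not in params.theta:
            v.append(f"missing theta for population {key}")
        elif params.theta[key] <= 0:
            v.append(f"theta for population {key} must be > 0")
    for h in net.hybrid_nodes:
        if h not in params.phi:
            v.append(f"missing phi for hybrid node {h}")
        elif not (0.0 <= params.phi[h] <= 1.0):
            v.append(f"phi for {h} outside [0,1]: {params.phi[h]:g}")
    for key, m in params.mig.items():
        if m < 0:
            v.append(f"migration rate {key} must be >= 0")
    return v


# ---------------------------------------------------------------------------
# Convenience constructors
# ---------------------------------------------------------------------------

def tree_from_newick(text: str) -> SpeciesNetwork:
    """Parse a plain Newick tree (rejects hybrid labels)."""
    net = parse_network(text)
    if net.hybrid_nodes:
        raise NetworkParseError("plain tree expected, found hybridization nodes")
    return net


def add_introgression_pair(
    net: SpeciesNetwork,
    branch_a: str,
    branch_b: str,
    name_a: str | None = None,
    name_b: str | None = None,
) -> SpeciesNetwork:
    """Return a new network with a bidirectional pair between the branches
    above nodes ``branch_a`` and ``branch_b``."""
    if branch_a == branch_b:
        raise ValueError("introgression pair needs two distinct branches")
    nodes = {
        name: Node(n.name, n.kind, list(n.children), list(n.parents))
        for name, n in net.nodes.items()
    }
    name_a = name_a or f"h_{branch_a}"
    name_b = name_b or f"h_{branch_b}"
    for nm in (name_a, name_b):
        if nm in nodes:
            raise ValueError(f"node name {nm} already in use")
    for child, hname, partner in ((branch_a, name_a, name_b), (branch_b, name_b, name_a)):
        parent = nodes[child].parents[0] if nodes[child].parents else None
        if parent is None:
            raise ValueError(f"cannot place a hybridization node above the root ({child})")
        nodes[hname] = Node(hname, "hybrid", [child, partner], [parent, partner])
        pc = nodes[parent].children
        pc[pc.index(child)] = hname
        nodes[child].parents[0] = hname
    return SpeciesNetwork(nodes, net.root)
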