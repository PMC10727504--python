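"""Compiled population-structure view of a species network.

Both the coalescent simulator and the gene-tree density functions walk
populations through time; this module flattens a (network, parameters)
pair into indexed arrays and a sorted event list so that walk is cheap.

Population i is the edge above node ``names[i]``; it is alive on
[t_lo[i], t_hi[i]) with t_hi = +inf for the root population.  Events are
either speciations (lineages in the child populations join the parent
population) or introgression pulses (lineages below each hybridization
node of a pair independently choose the donor or the ancestral
population).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ParamSet, SpeciesNetwork, node_age

__all__ = ["PopModel", "compile_model"]


@dataclass
class _Event:
    time: float
    kind: str  # "div" | "hyb"
    # div: sources -> target
    sources: tuple[int, ...] = ()
    target: int = -1
    # hyb: (src, main, donor, hybrid label, phi) per side
    sides: tuple = ()


@dataclass
class PopModel:
    names: list[str]
    index: dict[str, int]
    theta: np.ndarray
    t_lo: np.ndarray
    t_hi: np.ndarray
    events: list[_Event]
    tip_pop: dict[str, int]
    root_pop: int
    # backward migration rates: mig_rate[j][i] = rate at which one lineage
    # in pop j jumps to pop i (= 4 M_ij / theta_j), entries only where > 0
    mig_rate: dict[int, dict[int, float]]

    def alive(self, pop: int, t: float) -> bool:
        return self.t_lo[pop] <= t < self.t_hi[pop]


def compile_model(
    net: SpeciesNetwork,
    params: ParamSet,
    theta_model: str = "linked",
) -> PopModel:
    names = sorted(net.nodes)
    index = {n: i for i, n in enumerate(names)}
    theta = np.empty(len(names))
    t_lo = np.empty(len(names))
    t_hi = np.empty(len(names))
    for n, i in index.items():
        if theta_model == "linked":
            theta[i] = params.resolve_theta(net, n)
        else:
            theta[i] = params.theta[n]
        t_lo[i] = node_age(net, params, n)
        parent = net.main_parent(n)
        t_hi[i] = np.inf if parent is None else node_age(net, params, parent)

    events: list[_Event] = []
    for d in net.divergence_nodes:
        srcs = tuple(index[c] for c in net.structural_children(d))
        events.append(_Event(params.tau[d], "div", sources=srcs, target=index[d]))
    for a, b in net.hybrid_pairs:
        sides = (
            (index[net.main_child(a)], index[a], index[b], a, params.phi.get(a, 0.0)),
            (index[net.main_child(b)], index[b], index[a], b, params.phi.get(b, 0.0)),
        )
        events.append(_Event(params.tau[a], "hyb", sides=sides))
    events.sort(key=lambda e: (e.time, e.kind))

    mig_rate: dict[int, dict[int, float]] = {}
    for key, m in params.mig.items():
        if m <= 0:
            continue
        src, _, dst = key.partition("->")
        if dst == "":
            raise ValueError(f"migration key {key!r} must be 'i->j'")
        i, j = index[src.strip()], index[dst.strip()]
        # forward migrants i -> j at rate M; backward, a lineage in j
        # jumps to i at rate 4 M / theta_j per unit of mutational time
        mig_rate.setdefault(j, {})[i] = 4.0 * m / theta[j]

    return PopModel(
        names=names,
        index=index,
        theta=theta,
        t_lo=t_lo,
        t_hi=t_hi,
        events=events,
        tip_pop={t: index[t] for t in net.tips},
        root_pop=index[net.root],
        mig_rate=mig_rate,
    )
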