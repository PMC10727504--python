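"""Sequence likelihoods, coalescent gene-tree densities, and priors.

The sequence likelihood is the standard pruning algorithm under the
equal-rates (JC69) substitution model, with IUPAC ambiguity codes and
missing symbols handled as partial likelihood 1 over the compatible base
set.  Gene-tree densities follow the multispecies coalescent: within a
population of size theta each pair of lineages coalesces at rate
2/theta, and an interval of length dt with k lineages present
contributes exp(-k(k-1) dt / theta).  Under MSC-I, each recorded
crossing of a hybridization node contributes log(phi) for the donor path
and log(1-phi) for the ancestral path.

Priors follow the blockwise analysis defaults: a gamma prior on the root
age, a flat (uniform-Dirichlet) prior on the other divergence times
given the root age, gamma priors on population sizes and migration
rates, and U(0,1) on introgression probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alignment import IUPAC_SETS, LocusAlignment
from .genetree import GeneTree
from .network import ParamSet, SpeciesNetwork
from .popmodel import PopModel, compile_model

__all__ = [
    "GammaPrior",
    "PriorSpec",
    "make_gamma_prior",
    "jc69_transition",
    "locus_loglik",
    "msc_logdensity",
    "msci_logdensity",
    "prior_logdensity",
]

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

class GammaPrior:
    """Gamma distribution in (shape, rate) parameterization; mean = shape/rate."""

    def __init__(self, shape: float, rate: float):
        if shape <= 0 or rate <= 0:
            raise ValueError("shape and rate must be > 0")
        self.shape = float(shape)
        self.rate = float(rate)
        self._dist = stats.gamma(a=shape, scale=1.0 / rate)
        self._lognorm = shape * math.log(rate) - math.lgamma(shape)

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return float("-inf")
        return self._lognorm + (self.shape - 1.0) * math.log(x) - self.rate * x

    def pdf(self, x):
        return self._dist.pdf(x)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape, 1.0 / self.rate, size=size)

    def __repr__(self) -> str:
        return f"GammaPrior({self.shape:g}, {self.rate:g})"


def make_gamma_prior(shape: float, rate: float) -> GammaPrior:
    return GammaPrior(shape, rate)


@dataclass
class PriorSpec:
    """Default priors of the blockwise analyses: tau0 ~ G(7,200) (mean
    0.035), theta ~ G(4,200) (mean 0.02), M ~ G(2,10) (mean 0.2),
    phi ~ U(0,1)."""

    root_tau: GammaPrior = field(default_factory=lambda: GammaPrior(7, 200))
    theta: GammaPrior = field(default_factory=lambda: GammaPrior(4, 200))
    mig: GammaPrior = field(default_factory=lambda: GammaPrior(2, 10))


# ---------------------------------------------------------------------------
# JC69
# ---------------------------------------------------------------------------

def jc69_transition(t: float) -> np.ndarray:
    """4x4 transition-probability table of the equal-rates model at time t."""
    if t < 0:
        raise ValueError("negative time")
    same = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
    diff = (1.0 - same) / 3.0
    p = np.full((4, 4), diff)
    np.fill_diagonal(p, same)
    return p


_CODE_INDEX = {c: i for i, c in enumerate(IUPAC_SETS)}
_CODE_PARTIALS = np.zeros((len(IUPAC_SETS), 4))
for _c, _i in _CODE_INDEX.items():
    for _j, _b in enumerate("ACGT"):
        if _b in IUPAC_SETS[_c]:
            _CODE_PARTIALS[_i, _j] = 1.0


def locus_loglik(tree: GeneTree, aln: LocusAlignment) -> float:
    """Pruning log-likelihood of an alignment on a gene tree (JC69).

    Alignment labels must be a subset of the tree's tip labels;
    ambiguity/missing symbols contribute partial likelihood 1 over their
    compatible base set (missing tips are fully ambiguous).
    """
    if aln.n_sites == 0 or aln.n_seqs == 0:
        raise ValueError("empty alignment")
    tip_index = {lab: i for i, lab in enumerate(tree.labels)}
    for lab in aln.labels:
        if lab not in tip_index:
            raise ValueError(f"alignment label {lab!r} not among tree tips")

    codes = np.full((tree.n_tips, aln.n_sites), _CODE_INDEX["N"], dtype=np.int64)
    for lab, seq in zip(aln.labels, aln.seqs):
        row = tip_index[lab]
        try:
            codes[row] = [_CODE_INDEX[c] for c in seq.upper()]
        except KeyError as exc:
            raise ValueError(f"unknown symbol in sequence {lab!r}: {exc}") from exc

    patterns, counts = np.unique(codes.T, axis=0, return_counts=True)
    npat = patterns.shape[0]

    partial = np.empty((tree.n_nodes, npat, 4))
    for i in range(tree.n_tips):
        partial[i] = _CODE_PARTIALS[patterns[:, i]]
    logscale = np.zeros(npat)
    ch = tree.children()
    for node in tree.postorder():
        if node < tree.n_tips:
            continue
        acc = np.ones((npat, 4))
        for c in ch[node]:
            p = jc69_transition(tree.branch_length(c))
            acc *= partial[c] @ p.T
        mx = acc.max(axis=1)
        mx[mx == 0.0] = 1.0
        logscale += np.log(mx)
        partial[node] = acc / mx[:, None]
    site_lik = 0.25 * partial[tree.root].sum(axis=1)
    return float(np.dot(counts, np.log(site_lik) + logscale))


# ---------------------------------------------------------------------------
# Coalescent densities
# ---------------------------------------------------------------------------

@dataclass
class CoalStats:
    """Sufficient statistics of a gene tree given the species model:
    per-population coalescence counts and waiting-time sums, and
    per-hybrid-node donor/ancestral crossing counts.  The log-density is
    sum_p [c_p log(2/theta_p) - s_p/theta_p]
    + sum_h [d_h log(phi_h) + a_h log(1-phi_h)]."""

    coal_count: dict[int, int]
    wait_sum: dict[int, float]  # sum over intervals of k(k-1)*dt in pop p
    donor: dict[str, int]
    ancestral: dict[str, int]
    crossings: list = field(default_factory=list)  # (lineage, hybrid, indicator)
    feasible: bool = True

    def logdensity(self, theta: np.ndarray, phi: dict[str, float]) -> float:
        if not self.feasible:
            return NEG_INF
        out = 0.0
        for p, c in self.coal_count.items():
            out += c * math.log(2.0 / theta[p])
        for p, s in self.wait_sum.items():
            out -= s / theta[p]
        for h, d in self.donor.items():
            f = phi.get(h, 0.0)
            if d:
                if f <= 0.0:
                    return NEG_INF
                out += d * math.log(f)
        for h, a in self.ancestral.items():
            f = phi.get(h, 0.0)
            if a:
                if f >= 1.0:
                    return NEG_INF
                out += a * math.log1p(-f)
        return out


def coalescent_stats(tree: GeneTree, model: PopModel) -> CoalStats:
    """Sweep a gene tree through the population structure.

    Raises ValueError if a lineage crossing a hybridization node has no
    recorded path indicator.  Infeasible configurations (coalescence of
    lineages in different populations) yield ``feasible=False``.
    """
    stats_ = CoalStats({}, {}, {}, {})
    ch = tree.children()
    order = sorted(range(tree.n_tips, tree.n_nodes), key=lambda i: tree.ages[i])
    lineage_pop: dict[int, int] = {}
    for i in range(tree.n_tips):
        lineage_pop[i] = model.tip_pop[tree.species[i]]

    # merged timeline: coalescences first at exact ties with events
    timeline: list[tuple[float, int, object]] = [
        (tree.ages[i], 0, i) for i in order
    ] + [(e.time, 1, e) for e in model.events]
    timeline.sort(key=lambda x: (x[0], x[1]))

    t = 0.0
    for when, kind, item in timeline:
        dt = when - t
        if dt > 0:
            counts: dict[int, int] = {}
            for p in lineage_pop.values():
                counts[p] = counts.get(p, 0) + 1
            for p, k in counts.items():
                if k > 1:
                    stats_.wait_sum[p] = stats_.wait_sum.get(p, 0.0) + k * (k - 1) * dt
        t = when
        if kind == 0:  # coalescence
            node = item
            a, b = ch[node]
            pa, pb = lineage_pop[a], lineage_pop[b]
            if pa != pb:
                stats_.feasible = False
                return stats_
            stats_.coal_count[pa] = stats_.coal_count.get(pa, 0) + 1
            del lineage_pop[a], lineage_pop[b]
            lineage_pop[node] = pa
        else:
            ev = item
            if ev.kind == "div":
                for lin, p in list(lineage_pop.items()):
                    if p in ev.sources:
                        lineage_pop[lin] = ev.target
            else:
                moves: dict[int, int] = {}
                for src, main, donor, label, _phi in ev.sides:
                    for lin, p in lineage_pop.items():
                        if p == src:
                            ind = tree.indicators.get((lin, label))
                            if ind is None:
                                raise ValueError(
                                    f"lineage {lin} crosses hybridization node "
                                    f"{label} without a path indicator"
                                )
                            stats_.crossings.append((lin, label, ind))
                            if ind:
                                stats_.donor[label] = stats_.donor.get(label, 0) + 1
                                moves[lin] = donor
                            else:
                                stats_.ancestral[label] = (
                                    stats_.ancestral.get(label, 0) + 1
                                )
                                moves[lin] = main
                lineage_pop.update(moves)
    return stats_


def msc_logdensity(
    tree: GeneTree,
    net: SpeciesNetwork,
    params: ParamSet,
    theta_model: str = "linked",
    model: PopModel | None = None,
) -> float:
    """MSC log-density of a gene tree on a species *tree* (no introgression)."""
    if net.hybrid_nodes:
        raise ValueError("msc_logdensity requires a network without introgression")
    if model is None:
        model = compile_model(net, params, theta_model)
    return coalescent_stats(tree, model).logdensity(model.theta, params.phi)


def msci_logdensity(
    tree: GeneTree,
    net: SpeciesNetwork,
    params: ParamSet,
    theta_model: str = "linked",
    model: PopModel | None = None,
) -> float:
    """MSC-I log-density of a gene tree with hybrid-path indicators."""
    if model is None:
        model = compile_model(net, params, theta_model)
    return coalescent_stats(tree, model).logdensity(model.theta, params.phi)


# ---------------------------------------------------------------------------
# Prior density of a parameter set
# ---------------------------------------------------------------------------

def _subtree_sizes(net: SpeciesNetwork, node: str, sizes: dict[str, int]) -> int:
    n = 1
    for c in net.structural_children(node):
        if net.nodes[c].kind == "divergence":
            n += _subtree_sizes(net, c, sizes)
        elif net.nodes[c].kind == "hybrid":
            # skip through hybridization nodes to the divergence below
            cc = c
            while net.nodes[cc].kind == "hybrid":
                cc = net.main_child(cc)
            if net.nodes[cc].kind == "divergence":
                n += _subtree_sizes(net, cc, sizes)
    sizes[node] = n
    return n


def dirichlet_age_lognorm(net: SpeciesNetwork, tau0: float) -> float:
    """Log normalizing constant of the flat prior on non-root divergence
    times given the root age.

    The density is flat over the polytope {parent older than child,
    ages in (0, tau0)} and normalized so it integrates to 1; the volume
    of that polytope is tau0^m * L / m!, with m non-root divergence
    nodes and L the number of ancestor-compatible orderings (linear
    extensions of the forest poset; L = m! / prod subtree sizes)."""
    sizes: dict[str, int] = {}
    for c in net.structural_children(net.root):
        cc = c
        while net.nodes[cc].kind == "hybrid":
            cc = net.main_child(cc)
        if net.nodes[cc].kind == "divergence":
            _subtree_sizes(net, cc, sizes)
    m = len(sizes)
    if m == 0:
        return 0.0
    # volume = tau0^m / prod(sizes)
    log_volume = m * math.log(tau0) - sum(math.log(s) for s in sizes.values())
    return -log_volume


def prior_logdensity(
    params: ParamSet,
    priors: PriorSpec,
    net: SpeciesNetwork,
    theta_model: str = "linked",
) -> float:
    """Joint prior log-density of a parameter set on a network.

    Gamma on the root age and every theta and M; flat (normalized)
    uniform-Dirichlet on non-root divergence times given the root age;
    each introgression-pair time uniform over its feasible interval given
    the divergence times; U(0,1) on each phi (out-of-range phi gives
    -inf, not an exception).
    """
    from .network import node_age  # local import to avoid cycle at module load

    if net.nodes[net.root].kind == "tip":
        # single-population model: no divergence times
        out = 0.0
    else:
        tau0 = params.tau[net.root]
        if tau0 <= 0:
            return NEG_INF
        out = priors.root_tau.logpdf(tau0)
        for d in net.divergence_nodes:
            if d == net.root:
                continue
            td = params.tau[d]
            if not (0 < td < tau0):
                return NEG_INF
            p = net.main_parent(d)
            while net.nodes[p].kind == "hybrid":
                p = net.main_parent(p)
            if params.tau[p] < td:
                return NEG_INF
        out += dirichlet_age_lognorm(net, tau0)
    seen_pairs = set()
    for a, b in net.hybrid_pairs:
        if (a, b) in seen_pairs:
            continue
        seen_pairs.add((a, b))
        th = params.tau[a]
        intervals = []
        for h in (a, b):
            lo = node_age(net, params, net.main_child(h))
            hi = node_age(net, params, net.main_parent(h))
            intervals.append((lo, hi))
        lo = max(iv[0] for iv in intervals)
        hi = min(iv[1] for iv in intervals)
        if not (lo < th < hi):
            return NEG_INF
        out -= math.log(hi - lo)
    for key in net.theta_keys(theta_model):
        th = params.theta[key]
        if th <= 0:
            return NEG_INF
        out += priors.theta.logpdf(th)
    for h in net.hybrid_nodes:
        f = params.phi.get(h, 0.0)
        if not (0.0 <= f <= 1.0):
            return NEG_INF
    for _, m in params.mig.items():
        if m < 0:
            return NEG_INF
        out += priors.mig.logpdf(m)
    return float(out)
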