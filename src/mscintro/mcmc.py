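"""Bayesian MCMC under the MSC and MSC-I models.

The sampler targets the joint posterior of model parameters (tau, theta,
phi) and per-locus gene trees given multilocus sequence data.  The
sequence likelihood factorizes over loci and depends only on the gene
trees (pruning, JC69); the coalescent density couples gene trees to the
species model.  Moves:

* sliding-window updates of divergence/introgression times (reflected at
  their feasible bounds),
* multiplier updates of population sizes using cached per-population
  coalescent sufficient statistics (O(1) per proposal),
* exact Beta Gibbs updates of introgression probabilities given the
  donor/ancestral crossing counts,
* gene-tree node-age sliding windows and subtree-prune-regraft moves
  restricted to attachment points that exist at the proposed age,
* flips of hybrid-path indicators,
* a whole-model scaling ("mixing") move multiplying every time and theta
  by a common factor,
* for species-tree search with <= 5 taxa, Gibbs jumps over the full set
  of enumerated ranked histories (labelled topologies with an assignment
  of the shared, rank-indexed node ages), conditional on the current
  gene trees.

Hybrid-path indicators are kept for *every* (lineage, hybridization
node) key, active or not; inactive ones carry probability 1/2 each, so
the state dimension never changes and reversibility of age/SPR moves is
immediate.  Marginalizing the inactive indicators recovers the intended
posterior exactly; the bookkeeping appears in the acceptance ratios as
a factor 2 per newly active crossing.

Marginal likelihoods are estimated by thermodynamic integration over
power posteriors at Gauss-Legendre points, and Bayes-factor series can
be smoothed with local quadratic (loess-style) regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import coal_sweep, event_arrays, prune_jc69
from .alignment import IUPAC_SETS, LocusAlignment
from .genetree import GeneTree
from .likelihood import PriorSpec, prior_logdensity
from .network import Node, ParamSet, SpeciesNetwork
from .popmodel import compile_model

__all__ = [
    "ChainSettings",
    "BlockPosterior",
    "run_mcmc",
    "infer_block_species_tree",
    "assess_convergence",
    "marginal_loglik_ti",
    "log_bayes_factor",
    "smooth_bayes_factors",
    "species_of_label",
    "canonical_topology",
]

NEG_INF = float("-inf")
LOG2 = math.log(2.0)


@dataclass
class ChainSettings:
    """MCMC run settings.  The blockwise analyses of the study used
    2e6 iterations, 1e5 burn-in, sampling every 200, 10 runs; desk-scale
    defaults here are much smaller."""

    n_iterations: int = 2000
    burn_in: int = 500
    sample_every: int = 5
    n_runs: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_iterations, self.sample_every, self.n_runs) <= 0 or self.burn_in < 0:
            raise ValueError("all chain settings must be positive")
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn-in must be smaller than n_iterations")


@dataclass
class BlockPosterior:
    """Posterior over species-tree topologies for one block of loci."""

    block_id: object
    table: dict[str, float]
    map_tree: str
    map_prob: float
    run_tables: list[dict[str, float]] = field(default_factory=list)
    kept_runs: list[int] = field(default_factory=list)


def species_of_label(label: str) -> str:
    """Species name from a sequence label: 'sp^k' (haploid sample k) or
    'sp-j' (diploid individual j) both map to 'sp'."""
    for sep in ("^", "-"):
        if sep in label:
            return label.split(sep)[0]
    return label


_CODE_INDEX = {c: i for i, c in enumerate(IUPAC_SETS)}
_CODE_PARTIALS = np.zeros((len(IUPAC_SETS), 4))
for _c, _i in _CODE_INDEX.items():
    for _j, _b in enumerate("ACGT"):
        if _b in IUPAC_SETS[_c]:
            _CODE_PARTIALS[_i, _j] = 1.0


def _encode_alignment(aln: LocusAlignment) -> tuple[np.ndarray, np.ndarray]:
    """(tip_partials [ntips, npat, 4] in alignment label order, counts)."""
    codes = np.empty((aln.n_seqs, aln.n_sites), dtype=np.int64)
    for i, seq in enumerate(aln.seqs):
        codes[i] = [_CODE_INDEX[c] for c in seq.upper()]
    patterns, counts = np.unique(codes.T, axis=0, return_counts=True)
    tp = _CODE_PARTIALS[patterns.T]  # (ntips, npat, 4)
    return np.ascontiguousarray(tp), counts.astype(float)


# ---------------------------------------------------------------------------
# ranked histories (species-tree search)
# ---------------------------------------------------------------------------

def enumerate_ranked_histories(taxa: list[str]) -> list[list[tuple[frozenset, frozenset]]]:
    """All sequences of pairwise clade merges on the taxon set.

    Each history is a list of (clade_a, clade_b) merges from the first
    (most recent) to the last (root); histories are in bijection with
    ranked labelled rooted trees.
    """
    taxa = sorted(taxa)
    out: list[list[tuple[frozenset, frozenset]]] = []

    def rec(clades: list[frozenset], acc):
        if len(clades) == 1:
            out.append(list(acc))
            return
        for i in range(len(clades)):
            for j in range(i + 1, len(clades)):
                merged = clades[i] | clades[j]
                rest = [c for k, c in enumerate(clades) if k not in (i, j)]
                rec(rest + [merged], acc + [(clades[i], clades[j])])

    rec([frozenset([t]) for t in taxa], [])
    return out


def history_to_network(history) -> SpeciesNetwork:
    """Build a species tree whose internal nodes are named s1..sm in
    merge (rank) order; sm is the root."""
    nodes: dict[str, Node] = {}
    name_of: dict[frozenset, str] = {}
    for a, b in history:
        for c in (a, b):
            if len(c) == 1:
                (tip,) = c
                if tip not in nodes:
                    nodes[tip] = Node(tip, "tip")
                name_of[c] = tip
    for j, (a, b) in enumerate(history, start=1):
        name = f"s{j}"
        ca, cb = name_of[a], name_of[b]
        nodes[name] = Node(name, "divergence", children=[ca, cb])
        nodes[ca].parents = [name]
        nodes[cb].parents = [name]
        name_of[a | b] = name
    root = f"s{len(history)}"
    return SpeciesNetwork(nodes, root)


def canonical_topology(net: SpeciesNetwork) -> str:
    """Canonical rooted-Newick form (sorted child subtrees, internal
    labels dropped) used as the topology identity for tabulation."""

    def render(name: str) -> str:
        node = net.nodes[name]
        if node.kind == "tip":
            return name
        parts = sorted(render(c) for c in net.structural_children(name))
        return "(" + ",".join(parts) + ")"

    return render(net.root) + ";"


def _log_extension_weight(net: SpeciesNetwork) -> float:
    """Topology-dependent part of the flat uniform-Dirichlet age prior
    (dirichlet_age_lognorm at tau0 = 1, i.e. sum of log subtree sizes)."""
    from .likelihood import dirichlet_age_lognorm

    return dirichlet_age_lognorm(net, 1.0)


# ---------------------------------------------------------------------------
# chain
# ---------------------------------------------------------------------------

def _init_gene_tree_arrays(
    net: SpeciesNetwork,
    params: ParamSet,
    labels: list[str],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """A feasible starting genealogy (parent, ages): coalesce within
    species just above age 0, then join clades just above each
    speciation time, following the species tree's main structure."""
    from .network import node_age

    species = [species_of_label(l) for l in labels]
    n_tips = len(labels)
    parent = np.full(2 * n_tips - 1, -1, dtype=np.int64)
    ages = np.zeros(2 * n_tips - 1)
    nxt = [n_tips]
    eps = 1e-9

    def join(members: list[int], t: float) -> int:
        t = max([t] + [float(ages[m]) for m in members])
        while len(members) > 1:
            node = nxt[0]
            nxt[0] += 1
            a = members.pop()
            b = members.pop()
            parent[a] = node
            parent[b] = node
            t += eps * (1.0 + rng.random())
            ages[node] = t
            members.append(node)
        return members[0]

    def build(name: str) -> list[int]:
        node = net.nodes[name]
        if node.kind == "tip":
            members = [i for i, sp in enumerate(species) if sp == name]
            if len(members) > 1:
                return [join(members, 0.0)]
            return members
        if node.kind == "hybrid":
            return build(net.main_child(name))
        members: list[int] = []
        for c in net.structural_children(name):
            members.extend(build(c))
        if len(members) > 1:
            return [join(members, node_age(net, params, name))]
        return members

    build(net.root)
    return parent, ages


class _Chain:
    """One MCMC chain over (params, gene trees[, topology]).

    Gene trees are flat (parent, ages, indicator) arrays.  Coalescent
    sufficient statistics are kept as stacked per-locus matrices
    (coalescence counts and waiting sums per population, donor/ancestral
    crossing counts per hybridization node), so theta and phi updates
    and the per-locus density vector are single matrix operations.
    """

    def __init__(
        self,
        loci: list[LocusAlignment],
        net: SpeciesNetwork,
        priors: PriorSpec,
        rng: np.random.Generator,
        theta_model: str = "linked",
        estimate_topology: bool = False,
        beta: float = 1.0,
        init_params: ParamSet | None = None,
    ):
        self.rng = rng
        self.priors = priors
        self.theta_model = theta_model
        self.beta = beta
        self.estimate_topology = estimate_topology
        self.loci = loci
        self.encoded = [_encode_alignment(a) for a in loci]
        self.labels = [list(a.labels) for a in loci]

        if estimate_topology:
            if net.hybrid_nodes:
                raise ValueError("topology search supports plain species trees only")
            taxa = sorted(net.tips)
            if len(taxa) > 5:
                raise ValueError(
                    "exhaustive ranked-history search supports at most 5 taxa"
                )
            if len(taxa) < 2:
                raise ValueError("need at least 2 taxa")
            self.histories = enumerate_ranked_histories(taxa)
            self.cand_nets = [history_to_network(h) for h in self.histories]
            self.cand_ext = [_log_extension_weight(n) for n in self.cand_nets]
            start = canonical_topology(net)
            self.cand_index = [
                k for k, n in enumerate(self.cand_nets)
                if canonical_topology(n) == start
            ][0]
            net = self.cand_nets[self.cand_index]
        self.net = net
        self.hyb_labels = sorted(net.hybrid_nodes)
        self.H = len(self.hyb_labels)

        self.params = init_params.copy() if init_params else self._default_params()
        self._compile()
        self.P = len(self.model.names)

        # per-locus gene-tree state
        L = len(loci)
        self.tree_parent: list[np.ndarray] = []
        self.tree_ages: list[np.ndarray] = []
        self.tree_ind: list[np.ndarray] = []
        self.tip_pop: list[np.ndarray] = []
        for labs in self.labels:
            parent, ages = _init_gene_tree_arrays(self.net, self.params, labs, rng)
            self.tree_parent.append(parent)
            self.tree_ages.append(ages)
            self.tree_ind.append(
                np.zeros((len(parent), max(self.H, 1)), dtype=np.int64)
            )
            self.tip_pop.append(
                np.array(
                    [self.model.index[species_of_label(l)] for l in labs],
                    dtype=np.int64,
                )
            )

        self.CC = np.zeros((L, self.P))
        self.WS = np.zeros((L, self.P))
        self.DN = np.zeros((L, max(self.H, 1)))
        self.AN = np.zeros((L, max(self.H, 1)))
        self.NC = np.zeros(L)
        self.cross: list[np.ndarray] = [None] * L
        for i in range(L):
            row = self._sweep_row(i)
            if row is None:
                raise RuntimeError("infeasible initial gene tree")
            self._set_row(i, row)
        self.dens = self._dens_all()
        self.logliks = np.array(
            [
                self._prune(i, self.tree_parent[i], self.tree_ages[i])
                for i in range(L)
            ]
        )
        self.logprior = prior_logdensity(self.params, priors, self.net, theta_model)

        self.steps = {"tau": 0.01, "theta": 0.5, "age": 0.005, "spr": 0.01, "mix": 0.2}
        self._acc = {k: [0, 0] for k in self.steps}
        self.mix_every = 10
        self.topo_every = 10

    # -- model compilation ----------------------------------------------
    def _compile(self) -> None:
        self.model = compile_model(self.net, self.params, self.theta_model)
        ev = event_arrays(self.model)
        # re-key hybrid indices to the stable sorted order
        remap = {ev[6].index(h): k for k, h in enumerate(self.hyb_labels)} if ev[6] else {}
        ev_d = np.array(
            [remap.get(int(x), -1) if x >= 0 else -1 for x in ev[5]], dtype=np.int64
        )
        self.ev = (ev[0], ev[1], ev[2], ev[3], ev[4], ev_d)
        self.phi_arr = np.array(
            [self.params.phi.get(h, 0.0) for h in self.hyb_labels]
        )
        self._pop_theta_key = [
            self.net.base_branch(n) if self.theta_model == "linked" else n
            for n in self.model.names
        ]

    def _sweep_row(self, i: int, parent=None, ages=None, ind=None):
        """Sweep one locus; returns (cc, ws, dn, an, crossings) or None
        if the genealogy is infeasible under the current species model."""
        parent = self.tree_parent[i] if parent is None else parent
        ages = self.tree_ages[i] if ages is None else ages
        ind = self.tree_ind[i] if ind is None else ind
        feasible, cc, ws, dn, an, crossings = coal_sweep(
            parent,
            ages,
            len(self.labels[i]),
            self.tip_pop[i],
            ind,
            self.P if hasattr(self, "P") else len(self.model.names),
            max(self.H, 1),
            *self.ev,
        )
        if not feasible:
            return None
        return cc, ws, dn, an, crossings

    def _set_row(self, i: int, row) -> None:
        cc, ws, dn, an, crossings = row
        self.CC[i] = cc
        self.WS[i] = ws
        self.DN[i] = dn
        self.AN[i] = an
        self.NC[i] = len(crossings)
        self.cross[i] = crossings

    def _dens_all(self) -> np.ndarray:
        """Per-locus log-densities with phi integrated out: the
        phi^d (1-phi)^a factors are collected globally into the
        Beta-function term of :meth:`_lbeta_total` (collapsed Gibbs),
        which decouples the introgression probabilities from the
        per-lineage path indicators and greatly improves mixing."""
        a = np.log(2.0 / self.model.theta)
        b = 1.0 / self.model.theta
        return self.CC @ a - self.WS @ b + self.NC * LOG2

    def _row_dens(self, row) -> float:
        cc, ws, dn, an, crossings = row
        a = np.log(2.0 / self.model.theta)
        b = 1.0 / self.model.theta
        return float(cc @ a - ws @ b + len(crossings) * LOG2)

    def _counts(self) -> tuple[np.ndarray, np.ndarray]:
        return self.DN.sum(axis=0), self.AN.sum(axis=0)

    @staticmethod
    def _lbeta_total(D: np.ndarray, A: np.ndarray) -> float:
        """log integral of prod_h phi^D (1-phi)^A under U(0,1) priors."""
        out = 0.0
        for d, a in zip(D, A):
            out += math.lgamma(d + 1) + math.lgamma(a + 1) - math.lgamma(d + a + 2)
        return out

    def _count_delta(self, i: int, new_row) -> float:
        """Change in the collapsed-phi Beta term when locus i's
        donor/ancestral counts are replaced by those of new_row."""
        if not self.H:
            return 0.0
        D, A = self._counts()
        Dn = D - self.DN[i] + new_row[2]
        An = A - self.AN[i] + new_row[3]
        return self._lbeta_total(Dn, An) - self._lbeta_total(D, A)

    def _prune(self, i: int, parent, ages) -> float:
        tp, counts = self.encoded[i]
        return prune_jc69(parent, ages, len(self.labels[i]), tp, counts)

    # -- initial parameters ---------------------------------------------
    def _default_params(self) -> ParamSet:
        p = ParamSet()
        taus: dict[str, float] = {}
        tau0 = self.priors.root_tau.mean
        divs = self.net.divergence_nodes
        if self.estimate_topology:
            m = len(divs)
            for j in range(1, m + 1):
                taus[f"s{j}"] = tau0 * j / m
        else:
            depth: dict[str, int] = {}

            def assign_depth(name: str, d: int):
                depth[name] = d
                for c in self.net.structural_children(name):
                    cc = c
                    while self.net.nodes[cc].kind == "hybrid":
                        cc = self.net.main_child(cc)
                    if self.net.nodes[cc].kind == "divergence":
                        assign_depth(cc, d + 1)

            assign_depth(self.net.root, 0)
            maxd = max(depth.values()) + 1
            for d in divs:
                taus[d] = tau0 * (1.0 - depth[d] / maxd)
        from .network import node_age as _na

        pending = list(self.net.hybrid_pairs)
        while pending:
            progressed = False
            for a, b in list(pending):
                tmp = ParamSet(tau=dict(taus))
                try:
                    lo = max(_na(self.net, tmp, self.net.main_child(h)) for h in (a, b))
                    hi = min(_na(self.net, tmp, self.net.main_parent(h)) for h in (a, b))
                except KeyError:
                    continue
                taus[a] = taus[b] = 0.5 * (lo + hi)
                pending.remove((a, b))
                progressed = True
            if not progressed:
                raise RuntimeError("could not place hybridization times")
        p.tau = taus
        p.theta = {
            k: self.priors.theta.mean for k in self.net.theta_keys(self.theta_model)
        }
        p.phi = {h: 0.5 for h in self.net.hybrid_nodes}
        return p

    # -- tau moves -------------------------------------------------------
    def _tau_variables(self) -> list[tuple[str, ...]]:
        out = [(d,) for d in self.net.divergence_nodes]
        out += [tuple(pair) for pair in self.net.hybrid_pairs]
        return out

    def _tau_bounds(self, names: tuple[str, ...]) -> tuple[float, float]:
        from .network import node_age

        lo, hi = 0.0, np.inf
        for name in names:
            for c in self.net.structural_children(name):
                lo = max(lo, node_age(self.net, self.params, c))
            p = self.net.main_parent(name)
            if p is not None:
                hi = min(hi, node_age(self.net, self.params, p))
        if self.estimate_topology and len(names) == 1:
            j = int(names[0][1:])
            x = self.params.tau
            if j > 1:
                lo = max(lo, x[f"s{j - 1}"])
            if f"s{j + 1}" in x:
                hi = min(hi, x[f"s{j + 1}"])
        return lo, hi

    @staticmethod
    def _reflect(x: float, lo: float, hi: float) -> float:
        if not math.isfinite(hi):
            if x < lo:
                x = 2 * lo - x
            return x
        width = hi - lo
        if width <= 0:
            return lo
        y = (x - lo) % (2 * width)
        return lo + (width - abs(y - width))

    def _move_tau(self, names: tuple[str, ...]) -> None:
        old = self.params.tau[names[0]]
        lo, hi = self._tau_bounds(names)
        prop = self._reflect(old + self.steps["tau"] * (self.rng.random() - 0.5), lo, hi)
        if prop <= lo or (math.isfinite(hi) and prop >= hi) or prop <= 0:
            self._record("tau", False)
            return
        old_taus = {n: self.params.tau[n] for n in names}
        for n in names:
            self.params.tau[n] = prop
        new_prior = prior_logdensity(self.params, self.priors, self.net, self.theta_model)
        if new_prior == NEG_INF:
            for n, v in old_taus.items():
                self.params.tau[n] = v
            self._record("tau", False)
            return
        old_model, old_ev = self.model, self.ev
        self._compile()
        rows = []
        for i in range(len(self.loci)):
            row = self._sweep_row(i)
            if row is None:
                rows = None
                break
            rows.append(row)
        if rows is None:
            for n, v in old_taus.items():
                self.params.tau[n] = v
            self.model, self.ev = old_model, old_ev
            self._record("tau", False)
            return
        new_dens = np.array([self._row_dens(r) for r in rows])
        delta = new_dens.sum() - self.dens.sum() + new_prior - self.logprior
        if self.H:
            D, A = self._counts()
            Dn = np.sum([r[2] for r in rows], axis=0)
            An = np.sum([r[3] for r in rows], axis=0)
            delta += self._lbeta_total(Dn, An) - self._lbeta_total(D, A)
        if delta > 0 or math.log(self.rng.random() + 1e-300) < delta:
            for i, r in enumerate(rows):
                self._set_row(i, r)
            self.dens = new_dens
            self.logprior = new_prior
            self._record("tau", True)
        else:
            for n, v in old_taus.items():
                self.params.tau[n] = v
            self.model, self.ev = old_model, old_ev
            self._record("tau", False)

    # -- theta moves -----------------------------------------------------
    def _theta_pops(self, key: str) -> np.ndarray:
        return np.array(
            [i for i, k in enumerate(self._pop_theta_key) if k == key], dtype=np.int64
        )

    def _move_theta(self, key: str) -> None:
        old = self.params.theta[key]
        eps = self.steps["theta"] * (self.rng.random() - 0.5)
        new = old * math.exp(eps)
        pops = self._theta_pops(key)
        c_loc = self.CC[:, pops].sum(axis=1)
        s_loc = self.WS[:, pops].sum(axis=1)
        per_locus = c_loc * (math.log(old) - math.log(new)) - s_loc * (
            1.0 / new - 1.0 / old
        )
        dprior = self.priors.theta.logpdf(new) - self.priors.theta.logpdf(old)
        delta = per_locus.sum() + dprior + eps  # eps = log multiplier Jacobian
        if delta > 0 or math.log(self.rng.random() + 1e-300) < delta:
            self.params.theta[key] = new
            self.model.theta[pops] = new
            self.dens += per_locus
            self.logprior += dprior
            self._record("theta", True)
        else:
            self._record("theta", False)

    # -- phi draws (collapsed) -------------------------------------------
    def _move_phi(self, h: str) -> None:
        """phi is integrated out of the chain's target; its exact
        conditional given the crossing counts is Beta(d+1, a+1), drawn
        here so the recorded samples form the phi posterior."""
        k = self.hyb_labels.index(h)
        d = self.DN[:, k].sum()
        a = self.AN[:, k].sum()
        new = float(self.rng.beta(d + 1, a + 1))
        self.params.phi[h] = new
        self.phi_arr[k] = new

    # -- indicator flips -------------------------------------------------
    def _move_indicator(self, i: int) -> None:
        crossings = self.cross[i]
        if crossings is None or len(crossings) == 0:
            return
        row = crossings[int(self.rng.integers(len(crossings)))]
        lin, h = int(row[0]), int(row[1])
        ind = self.tree_ind[i]
        ind[lin, h] = 1 - ind[lin, h]
        new_row = self._sweep_row(i)
        if new_row is None or len(new_row[4]) == 0:
            ind[lin, h] = 1 - ind[lin, h]
            return
        new_d = self._row_dens(new_row)
        delta = (
            new_d
            - self.dens[i]
            + self._count_delta(i, new_row)
            + math.log(len(crossings) / len(new_row[4]))
        )
        if delta > 0 or math.log(self.rng.random() + 1e-300) < delta:
            self._set_row(i, new_row)
            self.dens[i] = new_d
        else:
            ind[lin, h] = 1 - ind[lin, h]

    # -- gene tree moves -------------------------------------------------
    def _accept_tree(self, i, parent, ages, row, new_d, new_l) -> None:
        self.tree_parent[i] = parent
        self.tree_ages[i] = ages
        self._set_row(i, row)
        self.dens[i] = new_d
        self.logliks[i] = new_l

    def _move_gene_age(self, i: int) -> None:
        parent = self.tree_parent[i]
        ages = self.tree_ages[i]
        n_tips = len(self.labels[i])
        n = len(parent)
        node = int(self.rng.integers(n_tips, n))
        lo = 0.0
        for k in range(n):
            if parent[k] == node and ages[k] > lo:
                lo = float(ages[k])
        p = parent[node]
        hi = float(ages[p]) if p >= 0 else np.inf
        prop = self._reflect(
            float(ages[node]) + self.steps["age"] * (self.rng.random() - 0.5), lo, hi
        )
        if prop <= lo or (math.isfinite(hi) and prop >= hi):
            self._record("age", False)
            return
        new_ages = ages.copy()
        new_ages[node] = prop
        row = self._sweep_row(i, parent, new_ages)
        if row is None:
            self._record("age", False)
            return
        new_d = self._row_dens(row)
        new_l = self._prune(i, parent, new_ages)
        delta = (
            self.beta * (new_l - self.logliks[i])
            + new_d
            - self.dens[i]
            + self._count_delta(i, row)
        )
        if delta > 0 or math.log(self.rng.random() + 1e-300) < delta:
            self._accept_tree(i, parent, new_ages, row, new_d, new_l)
            self._record("age", True)
        else:
            self._record("age", False)

    def _move_spr(self, i: int) -> None:
        parent = self.tree_parent[i]
        ages = self.tree_ages[i]
        n_tips = len(self.labels[i])
        n = len(parent)
        if n_tips < 3:
            return
        cands = np.flatnonzero(parent >= 0)
        c = int(cands[self.rng.integers(len(cands))])
        p = int(parent[c])
        g = int(parent[p])
        s = -1
        for k in range(n):
            if parent[k] == p and k != c:
                s = k
        # moving subtree = descendants of c
        in_sub = np.zeros(n, dtype=bool)
        in_sub[c] = True
        changed = True
        while changed:
            changed = False
            for k in range(n):
                if not in_sub[k] and parent[k] >= 0 and in_sub[parent[k]]:
                    in_sub[k] = True
                    changed = True

        new_parent = parent.copy()
        new_ages = ages.copy()
        new_parent[s] = g  # g may be -1: s becomes root
        new_parent[p] = -1

        old_age = float(ages[p])
        prop_age = old_age + self.steps["spr"] * (self.rng.random() - 0.5)
        if prop_age <= ages[c]:
            prop_age = 2 * float(ages[c]) - prop_age
        if prop_age <= ages[c]:
            self._record("spr", False)
            return

        def spanning(age: float) -> list[int]:
            out = []
            for x in range(n):
                if x == p or in_sub[x]:
                    continue
                px = new_parent[x]
                if px < 0:
                    if age > new_ages[x]:
                        out.append(-1)  # above the root
                elif new_ages[x] < age <= new_ages[px]:
                    out.append(x)
            return out

        fwd = spanning(prop_age)
        if not fwd:
            self._record("spr", False)
            return
        rev = spanning(old_age)
        target = fwd[int(self.rng.integers(len(fwd)))]
        if target == -1:
            for x in range(n):
                if new_parent[x] < 0 and x != p:
                    new_parent[x] = p
            new_parent[p] = -1
        else:
            new_parent[p] = new_parent[target]
            new_parent[target] = p
        new_ages[p] = prop_age
        row = self._sweep_row(i, new_parent, new_ages)
        if row is None:
            self._record("spr", False)
            return
        new_d = self._row_dens(row)
        new_l = self._prune(i, new_parent, new_ages)
        delta = (
            self.beta * (new_l - self.logliks[i])
            + new_d
            - self.dens[i]
            + self._count_delta(i, row)
            + math.log(len(fwd) / max(len(rev), 1))
        )
        if delta > 0 or math.log(self.rng.random() + 1e-300) < delta:
            self._accept_tree(i, new_parent, new_ages, row, new_d, new_l)
            self._record("spr", True)
        else:
            self._record("spr", False)

    def _swapset(self, i: int, lin: int, h: int) -> tuple | None:
        """The direction-confusion pair of a crossing: flip (lin, h)
        together with (sibling-of-lin, partner-of-h).  A lineage that
        introgressed and then coalesced with some partner is typically
        indistinguishable from that partner having introgressed the
        other way; this flip-set hops between the two explanations."""
        parent = self.tree_parent[i]
        p = parent[lin]
        if p < 0:
            return None
        sib = -1
        for k in range(len(parent)):
            if parent[k] == p and k != lin:
                sib = k
        label = self.hyb_labels[h]
        partner = self.net.partner(label)
        hp = self.hyb_labels.index(partner)
        return (lin, h, sib, hp)

    def _move_direction_swap(self, i: int) -> None:
        crossings = self.cross[i]
        if crossings is None or len(crossings) == 0:
            return
        row = crossings[int(self.rng.integers(len(crossings)))]
        lin, h = int(row[0]), int(row[1])
        fs = self._swapset(i, lin, h)
        if fs is None:
            return
        lin, h, sib, hp = fs
        target = {(lin, h), (sib, hp)}

        def multiplicity(cross_rows) -> int:
            m = 0
            for r in cross_rows:
                s = self._swapset(i, int(r[0]), int(r[1]))
                if s is not None and {(s[0], s[1]), (s[2], s[3])} == target:
                    m += 1
            return m

        m_f = multiplicity(crossings)
        ind = self.tree_ind[i]
        ind[lin, h] = 1 - ind[lin, h]
        ind[sib, hp] = 1 - ind[sib, hp]
        new_row = self._sweep_row(i)
        if new_row is None or len(new_row[4]) == 0:
            ind[lin, h] = 1 - ind[lin, h]
            ind[sib, hp] = 1 - ind[sib, hp]
            return
        new_d = self._row_dens(new_row)
        m_r = multiplicity(new_row[4])
        if m_r == 0:
            ind[lin, h] = 1 - ind[lin, h]
            ind[sib, hp] = 1 - ind[sib, hp]
            return
        delta = (
            new_d
            - self.dens[i]
            + self._count_delta(i, new_row)
            + math.log((m_r / len(new_row[4])) / (m_f / len(crossings)))
        )
        if delta > 0 or math.log(self.rng.random() + 1e-300) < delta:
            self._set_row(i, new_row)
            self.dens[i] = new_d
        else:
            ind[lin, h] = 1 - ind[lin, h]
            ind[sib, hp] = 1 - ind[sib, hp]

    def _move_path_switch(self, i: int) -> None:
        """Joint move: flip one hybrid-path indicator and re-graft the
        lineage's parent at a proposed age above the pulse time.

        A bare indicator flip is nearly always infeasible (the lineage's
        existing coalescence sits in a population the other path never
        visits), so donor/ancestral transitions need the coordinated
        re-attachment.  Keeping the proposed parent age above the event
        time preserves the crossing, which keeps the move reversible.
        """
        crossings = self.cross[i]
        if crossings is None or len(crossings) == 0:
            return
        parent = self.tree_parent[i]
        ages = self.tree_ages[i]
        n = len(parent)
        row = crossings[int(self.rng.integers(len(crossings)))]
        lin, h = int(row[0]), int(row[1])
        p = int(parent[lin])
        if p < 0:
            return
        tau_h = self.params.tau[self.hyb_labels[h]]
        g = int(parent[p])
        s = -1
        for k in range(n):
            if parent[k] == p and k != lin:
                s = k
        in_sub = np.zeros(n, dtype=bool)
        in_sub[lin] = True
        changed = True
        while changed:
            changed = False
            for k in range(n):
                if not in_sub[k] and parent[k] >= 0 and in_sub[parent[k]]:
                    in_sub[k] = True
                    changed = True
        new_parent = parent.copy()
        new_ages = ages.copy()
        new_parent[s] = g
        new_parent[p] = -1
        lo = max(tau_h, float(ages[lin]))
        old_age = float(ages[p])
        prop_age = self._reflect(
            old_age + self.steps["spr"] * (self.rng.random() - 0.5), lo, np.inf
        )
        if prop_age <= lo:
            return

        def spanning(age: float) -> list[int]:
            out = []
            for x in range(n):
                if x == p or in_sub[x]:
                    continue
                px = new_parent[x]
                if px < 0:
                    if age > new_ages[x]:
                        out.append(-1)
                elif new_ages[x] < age <= new_ages[px]:
                    out.append(x)
            return out

        fwd = spanning(prop_age)
        if not fwd:
            return
        rev = spanning(old_age)
        target = fwd[int(self.rng.integers(len(fwd)))]
        if target == -1:
            for x in range(n):
                if new_parent[x] < 0 and x != p:
                    new_parent[x] = p
            new_parent[p] = -1
        else:
            new_parent[p] = new_parent[target]
            new_parent[target] = p
        new_ages[p] = prop_age

        ind = self.tree_ind[i]
        ind[lin, h] = 1 - ind[lin, h]
        new_row = self._sweep_row(i, new_parent, new_ages)
        if new_row is None or len(new_row[4]) == 0:
            ind[lin, h] = 1 - ind[lin, h]
            return
        new_d = self._row_dens(new_row)
        new_l = self._prune(i, new_parent, new_ages)
        delta = (
            self.beta * (new_l - self.logliks[i])
            + new_d
            - self.dens[i]
            + self._count_delta(i, new_row)
            + math.log(len(fwd) / max(len(rev), 1))
            + math.log(len(crossings) / len(new_row[4]))
        )
        if delta > 0 or math.log(self.rng.random() + 1e-300) < delta:
            self._accept_tree(i, new_parent, new_ages, new_row, new_d, new_l)
        else:
            ind[lin, h] = 1 - ind[lin, h]

    # -- mixing move -----------------------------------------------------
    def _n_scale_vars(self) -> int:
        n = len(self.net.divergence_nodes) + len(self.net.hybrid_pairs)
        n += len(self.params.theta)
        n += sum(len(p) - len(l) for p, l in zip(self.tree_parent, self.labels))
        return n

    def _move_mix(self) -> None:
        eps = self.steps["mix"] * (self.rng.random() - 0.5)
        c = math.exp(eps)
        old_params = self.params.copy()
        for k in self.params.tau:
            self.params.tau[k] *= c
        for k in self.params.theta:
            self.params.theta[k] *= c
        new_prior = prior_logdensity(self.params, self.priors, self.net, self.theta_model)
        if new_prior == NEG_INF:
            self.params = old_params
            self._record("mix", False)
            return
        new_ages = [a * c for a in self.tree_ages]
        new_logliks = np.array(
            [
                prune_jc69(
                    self.tree_parent[i],
                    new_ages[i],
                    len(self.labels[i]),
                    *self.encoded[i],
                )
                for i in range(len(self.loci))
            ]
        )
        coal_per_locus = np.array(
            [len(p) - len(l) for p, l in zip(self.tree_parent, self.labels)],
            dtype=float,
        )
        delta = (
            self.beta * (new_logliks.sum() - self.logliks.sum())
            - coal_per_locus.sum() * eps
            + new_prior
            - self.logprior
            + self._n_scale_vars() * eps
        )
        if delta > 0 or math.log(self.rng.random() + 1e-300) < delta:
            self.tree_ages = new_ages
            self.logliks = new_logliks
            self._compile()
            # statistics scale exactly: waiting sums by c, counts unchanged
            self.WS *= c
            self.dens -= coal_per_locus * eps
            self.logprior = new_prior
            self._record("mix", True)
        else:
            self.params = old_params
            self._record("mix", False)

    # -- topology Gibbs --------------------------------------------------
    def _move_topology(self) -> None:
        m = len(self.net.divergence_nodes)
        x = [self.params.tau[f"s{j}"] for j in range(1, m + 1)]
        weights = np.full(len(self.cand_nets), NEG_INF)
        theta_snapshot = dict(self.params.theta)
        log2theta = None
        for k, cnet in enumerate(self.cand_nets):
            params_k = ParamSet(
                tau={f"s{j}": x[j - 1] for j in range(1, m + 1)},
                theta=theta_snapshot,
            )
            model_k = compile_model(cnet, params_k, self.theta_model)
            evk = event_arrays(model_k)
            ev = (evk[0], evk[1], evk[2], evk[3], evk[4], evk[5])
            a = np.log(2.0 / model_k.theta)
            b = 1.0 / model_k.theta
            tot = self.cand_ext[k]
            ok = True
            for i in range(len(self.loci)):
                feasible, cc, ws, dn, an, crossings = coal_sweep(
                    self.tree_parent[i],
                    self.tree_ages[i],
                    len(self.labels[i]),
                    self.tip_pop[i],
                    self.tree_ind[i],
                    len(model_k.names),
                    1,
                    *ev,
                )
                if not feasible:
                    ok = False
                    break
                tot += float(cc @ a - ws @ b)
            if ok:
                weights[k] = tot
        mx = weights.max()
        if not math.isfinite(mx):
            return
        w = np.exp(weights - mx)
        w /= w.sum()
        choice = int(self.rng.choice(len(w), p=w))
        if choice != self.cand_index:
            self.cand_index = choice
            self.net = self.cand_nets[choice]
            self._compile()
            for i in range(len(self.loci)):
                self._set_row(i, self._sweep_row(i))
            self.dens = self._dens_all()
            self.logprior = prior_logdensity(
                self.params, self.priors, self.net, self.theta_model
            )

    # -- bookkeeping -----------------------------------------------------
    def _record(self, kind: str, accepted: bool) -> None:
        a = self._acc[kind]
        a[0] += int(accepted)
        a[1] += 1

    def _tune(self) -> None:
        for kind, (acc, tot) in self._acc.items():
            if tot >= 20:
                rate = acc / tot
                self.steps[kind] *= math.exp(1.2 * (rate - 0.3))
                self.steps[kind] = min(max(self.steps[kind], 1e-7), 10.0)
                self._acc[kind] = [0, 0]

    def gene_trees(self) -> list[GeneTree]:
        """Current per-locus genealogies as GeneTree objects."""
        out = []
        for i, labs in enumerate(self.labels):
            indicators = {}
            for row in self.cross[i]:
                indicators[(int(row[0]), self.hyb_labels[int(row[1])])] = int(row[2])
            out.append(
                GeneTree(
                    labs,
                    [species_of_label(l) for l in labs],
                    self.tree_parent[i],
                    self.tree_ages[i],
                    indicators,
                )
            )
        return out

    # -- main loop -------------------------------------------------------
    def run(self, settings: ChainSettings) -> dict:
        n_iter, burn = settings.n_iterations, settings.burn_in
        samples: dict[str, list] = {"loglik": [], "logdens": [], "topology": []}
        for k in self.params.tau:
            samples[f"tau:{k}"] = []
        for k in self.params.theta:
            samples[f"theta:{k}"] = []
        for k in self.params.phi:
            samples[f"phi:{k}"] = []
        tau_vars = self._tau_variables()
        for it in range(n_iter):
            for i in range(len(self.loci)):
                self._move_gene_age(i)
                if self.rng.random() < 0.5:
                    self._move_spr(i)
                if self.H and self.rng.random() < 0.5:
                    self._move_indicator(i)
                if self.H and self.rng.random() < 0.5:
                    self._move_path_switch(i)
                if self.H and self.rng.random() < 0.5:
                    self._move_direction_swap(i)
            for names in tau_vars:
                self._move_tau(names)
            for key in list(self.params.theta):
                self._move_theta(key)
            for h in self.hyb_labels:
                self._move_phi(h)
            if (it + 1) % self.mix_every == 0:
                self._move_mix()
            if self.estimate_topology and (it + 1) % self.topo_every == 0:
                self._move_topology()
            if it < burn:
                if (it + 1) % 25 == 0:
                    self._tune()
                continue
            if (it - burn) % settings.sample_every == 0:
                for k, v in self.params.tau.items():
                    samples[f"tau:{k}"].append(v)
                for k, v in self.params.theta.items():
                    samples[f"theta:{k}"].append(v)
                for k, v in self.params.phi.items():
                    samples[f"phi:{k}"].append(v)
                samples["loglik"].append(float(self.logliks.sum()))
                samples["logdens"].append(float(self.dens.sum()))
                if self.estimate_topology:
                    samples["topology"].append(canonical_topology(self.net))
        out = {k: (np.asarray(v) if k != "topology" else v) for k, v in samples.items()}
        out["acceptance"] = {
            k: (a / t if t else float("nan")) for k, (a, t) in self._acc.items()
        }
        out["final_params"] = self.params.copy()
        return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def run_mcmc(
    dataset: list[LocusAlignment],
    net: SpeciesNetwork,
    priors: PriorSpec,
    settings: ChainSettings,
    estimate_topology: bool = False,
    theta_model: str = "linked",
    beta: float = 1.0,
    init_params: ParamSet | None = None,
) -> dict:
    """Run one MCMC chain; returns a dict of posterior sample arrays
    keyed 'tau:<node>', 'theta:<pop>', 'phi:<hybrid>', plus 'loglik',
    'logdens', 'topology' (topology mode) and 'acceptance'.  Fixed seed
    gives an identical sample stream."""
    rng = np.random.default_rng(settings.seed)
    chain = _Chain(
        dataset,
        net,
        priors,
        rng,
        theta_model=theta_model,
        estimate_topology=estimate_topology,
        beta=beta,
        init_params=init_params,
    )
    return chain.run(settings)


def _upgma_history(
    loci: list[LocusAlignment], taxa: list[str]
) -> list[tuple[frozenset, frozenset]]:
    """Starting ranked history from average pairwise sequence distances."""
    idx = {t: i for i, t in enumerate(taxa)}
    dsum = np.zeros((len(taxa), len(taxa)))
    dn = np.zeros((len(taxa), len(taxa)))
    for aln in loci:
        sps = [species_of_label(l) for l in aln.labels]
        arr = np.array([list(s) for s in aln.seqs])
        for i in range(len(sps)):
            for j in range(i + 1, len(sps)):
                a, b = idx[sps[i]], idx[sps[j]]
                if a == b:
                    continue
                ok = (arr[i] != "N") & (arr[j] != "N") & (arr[i] != "-") & (arr[j] != "-")
                if ok.sum() == 0:
                    continue
                dsum[a, b] += (arr[i][ok] != arr[j][ok]).mean()
                dn[a, b] += 1
    d = np.where(dn + dn.T > 0, (dsum + dsum.T) / np.maximum(dn + dn.T, 1), 0.75)
    np.fill_diagonal(d, np.inf)
    clusters: list[tuple[frozenset, list[int]]] = [
        (frozenset([t]), [i]) for i, t in enumerate(taxa)
    ]
    merges = []
    while len(clusters) > 1:
        best = (np.inf, 0, 1)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dij = np.mean([d[a, b] for a in clusters[i][1] for b in clusters[j][1]])
                if dij < best[0]:
                    best = (dij, i, j)
        _, i, j = best
        a, b = clusters[i], clusters[j]
        merges.append((a[0], b[0]))
        merged = (a[0] | b[0], a[1] + b[1])
        clusters = [cl for k, cl in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def infer_block_species_tree(
    block: list[LocusAlignment],
    priors: PriorSpec,
    settings: ChainSettings,
    block_id=0,
    tv_threshold: float = 0.1,
) -> BlockPosterior:
    """Posterior over rooted species-tree topologies for one block of loci.

    Runs ``settings.n_runs`` independent chains (exhaustive ranked-history
    jumps; <= 5 taxa), discards nonconvergent runs by total-variation
    distance of their topology posteriors from the coordinate-wise
    median, and merges the kept runs with equal weight.
    """
    taxa = sorted({species_of_label(l) for a in block for l in a.labels})
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    history = _upgma_history(block, taxa)
    start = history_to_network(history)
    run_tables = []
    for r in range(settings.n_runs):
        s = ChainSettings(
            settings.n_iterations,
            settings.burn_in,
            settings.sample_every,
            1,
            settings.seed + 1000 * r,
        )
        res = run_mcmc(block, start, priors, s, estimate_topology=True)
        table: dict[str, float] = {}
        for t in res["topology"]:
            table[t] = table.get(t, 0.0) + 1.0
        tot = sum(table.values())
        run_tables.append({k: v / tot for k, v in table.items()})
    kept = assess_convergence(run_tables, tv_threshold)
    merged: dict[str, float] = {}
    for r in kept:
        for k, v in run_tables[r].items():
            merged[k] = merged.get(k, 0.0) + v / len(kept)
    map_tree = max(merged, key=lambda k: (merged[k], k))
    return BlockPosterior(
        block_id=block_id,
        table=merged,
        map_tree=map_tree,
        map_prob=merged[map_tree],
        run_tables=run_tables,
        kept_runs=kept,
    )


def assess_convergence(
    run_tables: list[dict[str, float]], tv_threshold: float = 0.1
) -> list[int]:
    """Indices of runs whose topology posterior is within ``tv_threshold``
    total-variation distance (inclusive) of the coordinate-wise median
    posterior; the closest run is always kept."""
    if len(run_tables) < 2:
        return list(range(len(run_tables)))
    keys = sorted({k for t in run_tables for k in t})
    mat = np.array([[t.get(k, 0.0) for k in keys] for t in run_tables])
    med = np.median(mat, axis=0)
    tv = 0.5 * np.abs(mat - med).sum(axis=1)
    kept = [i for i, v in enumerate(tv) if v <= tv_threshold]
    if not kept:
        kept = [int(np.argmin(tv))]
    return kept


def marginal_loglik_ti(
    dataset: list[LocusAlignment],
    net: SpeciesNetwork,
    priors: PriorSpec,
    settings: ChainSettings,
    n_points: int = 32,
    theta_model: str = "linked",
) -> float:
    """Log marginal likelihood by thermodynamic integration.

    Power-posterior chains are run at Gauss-Legendre beta points on
    (0,1) (warm-started from small to large beta) and the mean
    log-likelihood is integrated over beta.  With no data the model
    integrates to 1 and the result is 0.
    """
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    if not dataset:
        return 0.0
    nodes, weights = np.polynomial.legendre.leggauss(n_points)
    betas = 0.5 * (nodes + 1.0)
    weights = 0.5 * weights
    order = np.argsort(betas)
    means = np.empty(n_points)
    init_params = None
    for rank, k in enumerate(order):
        s = ChainSettings(
            settings.n_iterations,
            settings.burn_in if rank == 0 else max(settings.burn_in // 4, 1),
            settings.sample_every,
            1,
            settings.seed + 17 * int(k),
        )
        res = run_mcmc(
            dataset,
            net,
            priors,
            s,
            theta_model=theta_model,
            beta=float(betas[k]),
            init_params=init_params,
        )
        means[k] = res["loglik"].mean()
        init_params = res["final_params"]
    return float(np.dot(weights, means))


def log_bayes_factor(logml_a: float, logml_b: float) -> float:
    """Log Bayes factor of model A over model B: logML_A - logML_B."""
    return logml_a - logml_b


def smooth_bayes_factors(positions, log_bf, span: float = 0.4) -> np.ndarray:
    """Loess-style smoothing of a log-Bayes-factor series: local
    quadratic polynomials with tricube weights over the nearest
    span-fraction of points, evaluated at each input position."""
    x = np.asarray(positions, dtype=float)
    y = np.asarray(log_bf, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    q = max(int(math.ceil(span * n)), 3)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-12)
        X = np.vstack([np.ones(q), x[idx] - x[i], (x[idx] - x[i]) ** 2]).T
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * W[:, None], y[idx] * W, rcond=None)
        out[i] = coef[0]
    return out
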