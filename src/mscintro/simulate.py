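"""Coalescent simulation under MSC, MSC-I and MSC-M, with JC69 mutation.

Gene trees are simulated backwards in time through the population
structure of a species network.  Within a population of size theta,
k lineages coalesce at total rate k(k-1)/theta (2/theta per pair).  At a
hybridization node each lineage independently follows the donor branch
with probability phi.  Under MSC-M a lineage in population j jumps
backwards to population i at rate 4*M_ij/theta_j, where M_ij is the
expected number of migrants moving i -> j forward in time per generation.

Sequences evolve by the equal-rates (JC69) model on the same
substitutions-per-site time scale: along a branch of length t,
P(no change) = 1/4 + (3/4) exp(-4 t / 3).  Loci are unlinked (free
recombination between loci; complete linkage within a locus).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import IUPAC_PAIR, LocusAlignment, write_fasta
from .genetree import GeneTree
from .network import ParamSet, SpeciesNetwork, validate, write_network
from .popmodel import PopModel, compile_model

__all__ = [
    "sim_gene_tree",
    "sim_alignment_jc69",
    "sim_diploid_collapse",
    "sim_block_dataset",
]

BASES = np.array(list("ACGT"))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sim_gene_tree(
    net: SpeciesNetwork,
    params: ParamSet,
    samples_per_species: Mapping[str, int],
    rng_seed,
    theta_model: str = "linked",
    model: PopModel | None = None,
) -> GeneTree:
    """Simulate one gene tree for the given numbers of sampled sequences.

    ``samples_per_species`` maps species (tip) names to haploid sample
    counts; species absent from the map contribute no samples.  Sequence
    labels are ``species^k`` with k starting at 1.
    """
    rng = _as_rng(rng_seed)
    if model is None:
        problems = validate(net, params, theta_model)
        if problems:
            raise ValueError("invalid model: " + "; ".join(problems))
        model = compile_model(net, params, theta_model)
    n_tips = sum(int(v) for v in samples_per_species.values())
    if n_tips < 2:
        raise ValueError("need at least 2 sampled sequences in total")

    labels: list[str] = []
    species: list[str] = []
    lineage_pop: dict[int, int] = {}
    for sp in sorted(samples_per_species):
        k = int(samples_per_species[sp])
        if k < 0:
            raise ValueError(f"negative sample count for {sp}")
        if k and sp not in model.tip_pop:
            raise ValueError(f"unknown species {sp!r}")
        for j in range(k):
            idx = len(labels)
            labels.append(f"{sp}^{j + 1}")
            species.append(sp)
            lineage_pop[idx] = model.tip_pop[sp]

    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    ages = np.zeros(n_nodes)
    indicators: dict[tuple[int, str], int] = {}
    next_node = n_tips
    t = 0.0
    boundaries = [e.time for e in model.events] + [np.inf]
    events: list = list(model.events) + [None]

    for ev, t_end in zip(events, boundaries):
        # Gillespie within (t, t_end)
        while len(lineage_pop) > 1:
            per_pop: dict[int, list[int]] = {}
            for lin, p in lineage_pop.items():
                per_pop.setdefault(p, []).append(lin)
            coal_rate = {
                p: len(ls) * (len(ls) - 1) / model.theta[p]
                for p, ls in per_pop.items()
                if len(ls) > 1
            }
            mig_terms: list[tuple[int, int, float]] = []  # (pop_from, pop_to, rate)
            for p, ls in per_pop.items():
                for q, r in model.mig_rate.get(p, {}).items():
                    if model.alive(q, t):
                        mig_terms.append((p, q, len(ls) * r))
            total = sum(coal_rate.values()) + sum(m[2] for m in mig_terms)
            if total == 0.0:
                break
            wait = rng.exponential(1.0 / total)
            if t + wait >= t_end:
                break
            t += wait
            u = rng.uniform(0, total)
            acc = 0.0
            done = False
            for p, r in coal_rate.items():
                acc += r
                if u < acc:
                    pair = rng.choice(len(per_pop[p]), size=2, replace=False)
                    a, b = per_pop[p][pair[0]], per_pop[p][pair[1]]
                    node = next_node
                    next_node += 1
                    parent[a] = node
                    parent[b] = node
                    ages[node] = t
                    del lineage_pop[a], lineage_pop[b]
                    lineage_pop[node] = p
                    done = True
                    break
            if not done:
                for p, q, r in mig_terms:
                    acc += r
                    if u < acc:
                        lin = per_pop[p][rng.integers(len(per_pop[p]))]
                        lineage_pop[lin] = q
                        done = True
                        break
            if not done:  # numerical edge: attribute to last term
                raise RuntimeError("event selection failed")
        if ev is None:
            break
        t = ev.time
        if ev.kind == "div":
            for lin, p in list(lineage_pop.items()):
                if p in ev.sources:
                    lineage_pop[lin] = ev.target
        else:  # introgression pulse: both sides exchange simultaneously
            moves: dict[int, int] = {}
            for src, main, donor, label, phi in ev.sides:
                for lin, p in lineage_pop.items():
                    if p == src:
                        take_donor = rng.random() < phi
                        indicators[(lin, label)] = int(take_donor)
                        moves[lin] = donor if take_donor else main
            lineage_pop.update(moves)
    if len(lineage_pop) != 1:
        raise RuntimeError("simulation ended with more than one lineage")
    return GeneTree(labels, species, parent, ages, indicators)


def jc69_evolve(seq_idx: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve integer-coded bases for time t under the equal-rates model."""
    if t < 0:
        raise ValueError("negative branch length")
    p_same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    out = seq_idx.copy()
    change = rng.random(seq_idx.shape) > p_same
    if np.any(change):
        # new base uniform among the three others
        shift = rng.integers(1, 4, size=int(change.sum()))
        out[change] = (out[change] + shift) % 4
    return out


def sim_alignment_jc69(tree: GeneTree, n_sites: int, rng_seed) -> LocusAlignment:
    """Simulate an i.i.d.-sites JC69 alignment on a gene tree."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = _as_rng(rng_seed)
    ch = tree.children()
    seqs_idx: dict[int, np.ndarray] = {}
    root = tree.root
    seqs_idx[root] = rng.integers(0, 4, size=n_sites)
    stack = [root]
    while stack:
        node = stack.pop()
        for c in ch[node]:
            seqs_idx[c] = jc69_evolve(seqs_idx[node], tree.branch_length(c), rng)
            stack.append(c)
    seqs = ["".join(BASES[seqs_idx[i]]) for i in range(tree.n_tips)]
    return LocusAlignment(list(tree.labels), seqs)


def sim_diploid_collapse(hap_a: str, hap_b: str) -> str:
    """Collapse two phased haploid sequences into one unphased diploid
    sequence, coding heterozygous sites with IUPAC ambiguity codes."""
    if len(hap_a) != len(hap_b):
        raise ValueError("haplotypes differ in length")
    out = []
    for x, y in zip(hap_a.upper(), hap_b.upper()):
        if x == y:
            out.append(x)
        elif x in "ACGT" and y in "ACGT":
            out.append(IUPAC_PAIR[frozenset((x, y))])
        else:
            out.append("N")
    return "".join(out)


def _locus_rng(master_seed: int, locus_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(int(master_seed), spawn_key=(int(locus_index),))
    return np.random.default_rng(ss)


def sim_block_dataset(
    net: SpeciesNetwork,
    params: ParamSet,
    n_blocks: int,
    loci_per_block: int,
    sites_per_locus: int | tuple[int, int],
    samples: Mapping[str, int],
    diploid: bool = False,
    rng_seed: int = 0,
    out_dir: str | Path | None = None,
    theta_model: str = "linked",
):
    """Simulate a blockwise multilocus dataset and its truth record.

    ``sites_per_locus`` is either a fixed length or an inclusive
    (low, high) range sampled uniformly per locus.  With ``diploid`` the
    requested per-species counts are unphased diploid individuals: two
    haploid sequences are simulated per individual and collapsed with
    IUPAC codes.  Each locus uses an independent seed stream derived from
    (rng_seed, locus index), so datasets are reproducible regardless of
    generation order.

    Returns (alignments, gene_trees, index DataFrame); when ``out_dir``
    is given also writes one FASTA per locus, ``loci_index.tsv`` and
    ``truth.json``.
    """
    problems = validate(net, params, theta_model)
    if problems:
        raise ValueError("invalid model: " + "; ".join(problems))
    model = compile_model(net, params, theta_model)
    hap_samples = {sp: (2 * k if diploid else k) for sp, k in samples.items()}

    alignments: list[LocusAlignment] = []
    gene_trees: list[GeneTree] = []
    rows = []
    n_loci = n_blocks * loci_per_block
    for i in range(n_loci):
        rng = _locus_rng(rng_seed, i)
        if isinstance(sites_per_locus, int):
            n_sites = sites_per_locus
        else:
            lo, hi = sites_per_locus
            n_sites = int(rng.integers(lo, hi + 1))
        tree = sim_gene_tree(net, params, hap_samples, rng, theta_model, model=model)
        aln = sim_alignment_jc69(tree, n_sites, rng)
        if diploid:
            labels, seqs = [], []
            by_sp: dict[str, list[int]] = {}
            for j, sp in enumerate(tree.species):
                by_sp.setdefault(sp, []).append(j)
            for sp in sorted(by_sp):
                idxs = by_sp[sp]
                for k in range(0, len(idxs), 2):
                    labels.append(f"{sp}-{k // 2 + 1}")
                    seqs.append(
                        sim_diploid_collapse(aln.seqs[idxs[k]], aln.seqs[idxs[k + 1]])
                    )
            aln = LocusAlignment(labels, seqs)
        aln.meta.update(block=i // loci_per_block, locus=i)
        alignments.append(aln)
        gene_trees.append(tree)
        rows.append(
            {
                "locus": i,
                "block": i // loci_per_block,
                "n_seqs": aln.n_seqs,
                "n_sites": aln.n_sites,
                "file": f"locus_{i:05d}.fasta",
            }
        )
    index = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for aln, row in zip(alignments, rows):
            write_fasta(aln, out / row["file"])
        index.to_csv(out / "loci_index.tsv", sep="\t", index=False)
        truth = {
            "network": write_network(net, params.phi),
            "params": json.loads(params.to_json()),
            "theta_model": theta_model,
            "samples": dict(samples),
            "diploid": diploid,
            "seed": int(rng_seed),
            "gene_trees": [t.newick() for t in gene_trees],
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return alignments, gene_trees, index
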