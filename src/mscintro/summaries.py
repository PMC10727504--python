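"""Downstream summaries: MAP-tree tabulation, time calibration,
coding/noncoding slope, heterozygosity.

Topology identity uses a canonical rooted-Newick form (child subtrees
sorted lexicographically) so MAP-tree counting is deterministic.
Optional "lumping" replaces every maximal clade whose tips all belong
to a designated taxon set by a single labelled tip before comparison,
so trees differing only inside that clade become identical (the study
groups besckei/numata/melpomene as 'BNM' this way).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "lump_topology",
    "tabulate_map_trees",
    "calibrate_age",
    "calibrate_age_ma",
    "coding_noncoding_slope",
    "heterozygosity",
]

HET_CODES = set("RYSWKM")
MISSING = {"-", "N", "?"}


# -- topology lumping --------------------------------------------------------

def _parse_topology(text: str):
    text = text.strip().rstrip(";")
    pos = 0

    def parse():
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            children = [parse()]
            while text[pos] == ",":
                pos += 1
                children.append(parse())
            assert text[pos] == ")"
            pos += 1
            # internal labels, if any, are skipped
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            return tuple(children)
        start = pos
        while pos < len(text) and text[pos] not in ",()":
            pos += 1
        return text[start:pos]

    return parse()


def _render(node) -> str:
    if isinstance(node, str):
        return node
    return "(" + ",".join(sorted(_render(c) for c in node)) + ")"


def _tips(node) -> set[str]:
    if isinstance(node, str):
        return {node}
    out = set()
    for c in node:
        out |= _tips(c)
    return out


def lump_topology(newick: str, taxa: set[str], label: str) -> str:
    """Replace maximal clades whose tips are all in ``taxa`` by ``label``.

    Idempotent; if the set is not monophyletic in the tree, each maximal
    all-in-set subtree is collapsed separately (the trees then remain
    distinguishable, as they differ outside the set too).
    """
    tree = _parse_topology(newick)
    all_tips = _tips(tree)
    if not taxa <= all_tips and label not in all_tips:
        # (an already-lumped tree carries the label instead of the taxa)
        raise ValueError("lump set is not a subset of the tree's taxa")

    def walk(node):
        tps = _tips(node)
        if tps <= taxa | {label}:
            return label
        if isinstance(node, str):
            return node
        return tuple(walk(c) for c in node)

    def dedupe(node):
        # adjacent collapsed children merge into one tip
        if isinstance(node, str):
            return node
        kids = [dedupe(c) for c in node]
        out = []
        for k in kids:
            if k == label and label in out:
                continue
            out.append(k)
        return out[0] if len(out) == 1 else tuple(out)

    return _render(dedupe(walk(tree))) + ";"


def tabulate_map_trees(blocks, lump: tuple[set, str] | None = None) -> pd.DataFrame:
    """Tabulate MAP-tree proportions per (region, class).

    ``blocks`` is an iterable of records with keys/attributes
    ``region``, ``cls``, ``map_tree`` and ``map_prob`` (e.g. dicts, or
    BlockPosterior objects via the dict form).  Returns a table with
    one row per (region, class, topology): block count, proportion
    within the (region, class) group, and mean MAP probability.
    """
    rows = []
    for b in blocks:
        get = b.get if isinstance(b, dict) else lambda k, _b=b: getattr(_b, k)
        topo = get("map_tree")
        if lump is not None:
            topo = lump_topology(topo, set(lump[0]), lump[1])
        rows.append(
            {
                "region": get("region"),
                "class": get("cls"),
                "topology": topo,
                "map_prob": float(get("map_prob")),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["region", "class", "topology", "n_blocks", "proportion", "mean_map_prob"]
        )
    g = (
        df.groupby(["region", "class", "topology"])
        .agg(n_blocks=("map_prob", "size"), mean_map_prob=("map_prob", "mean"))
        .reset_index()
    )
    totals = g.groupby(["region", "class"])["n_blocks"].transform("sum")
    g["proportion"] = g["n_blocks"] / totals
    return g[["region", "class", "topology", "n_blocks", "proportion", "mean_map_prob"]]


# -- time calibration --------------------------------------------------------

def calibrate_age(
    tau: float, mu_per_site_per_generation: float, generations_per_year: float
) -> float:
    """Absolute age in years: tau / (mu * generations per year).

    tau is in expected substitutions per site; mu is the neutral
    mutation rate per site per generation.
    """
    if mu_per_site_per_generation <= 0 or generations_per_year <= 0:
        raise ValueError("mutation rate and generation time must be positive")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return tau / (mu_per_site_per_generation * generations_per_year)


def calibrate_age_ma(tau, mu_per_site_per_generation, generations_per_year) -> float:
    """Absolute age in millions of years (Ma)."""
    return calibrate_age(tau, mu_per_site_per_generation, generations_per_year) / 1e6


# -- coding vs noncoding divergence slope ------------------------------------

def coding_noncoding_slope(pairs) -> dict:
    """Through-origin least squares of tau_C on tau_NC.

    ``pairs`` is a sequence of (tau_C, tau_NC); returns the slope b of
    tau_C ~ b * tau_NC and the r-squared of the through-origin fit
    (1 - RSS / sum tau_C^2).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] != 2:
        raise ValueError("need pairs of (tau_C, tau_NC)")
    y, x = arr[:, 0], arr[:, 1]
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("tau_NC values are all zero")
    b = float(np.dot(x, y)) / sxx
    syy = float(np.dot(y, y))
    rss = float(np.sum((y - b * x) ** 2))
    r2 = 1.0 - rss / syy if syy > 0 else float("nan")
    return {"b": b, "r2": r2}


# -- heterozygosity ----------------------------------------------------------

def heterozygosity(sequences_by_individual: dict[str, list[str]]) -> dict[str, float]:
    """Per-individual heterozygous-site fraction of unphased diploid
    sequences, pooled over loci.

    A site counts as heterozygous if it carries a two-base IUPAC
    ambiguity code; '-', 'N' and three/four-base codes are excluded
    from the denominator.
    """
    out = {}
    for ind, seqs in sequences_by_individual.items():
        het = 0
        tot = 0
        for s in seqs:
            for c in s.upper():
                if c in MISSING or c in "BDHV":
                    continue
                tot += 1
                if c in HET_CODES:
                    het += 1
        out[ind] = het / tot if tot else float("nan")
    return out
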