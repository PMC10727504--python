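"""Per-locus coalescent genealogies.

A gene tree is stored as flat arrays over 2*n_tips - 1 nodes: tips are
nodes 0..n_tips-1 (age 0), internal nodes follow in arbitrary order, and
``parent[i]`` is -1 for the root.  ``species[i]`` (tips only) names the
sampled population.  ``indicators`` records, for a lineage (identified by
its child node) crossing a hybridization node, whether it followed the
donor path (1) or its ancestral branch (0).
"""

from __future__ import annotations

import numpy as np

__all__ = ["GeneTree"]


class GeneTree:
    def __init__(
        self,
        labels: list[str],
        species: list[str],
        parent: np.ndarray,
        ages: np.ndarray,
        indicators: dict[tuple[int, str], int] | None = None,
    ):
        self.labels = list(labels)
        self.species = list(species)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.ages = np.asarray(ages, dtype=float)
        self.indicators = dict(indicators or {})
        self.n_tips = len(labels)
        self.n_nodes = 2 * self.n_tips - 1
        if self.parent.shape != (self.n_nodes,) or self.ages.shape != (self.n_nodes,):
            raise ValueError("parent/ages arrays have wrong shape")
        self._check()

    def _check(self) -> None:
        if np.any(self.ages[: self.n_tips] != 0):
            raise ValueError("tip ages must be 0")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError("gene tree must have exactly one root")
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0 and not self.ages[p] > self.ages[i] - 1e-300:
                if self.ages[p] <= self.ages[i] and not (
                    self.ages[p] == self.ages[i] == 0.0
                ):
                    raise ValueError(f"parent {p} not older than child {i}")

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                ch[p].append(i)
        return ch

    def postorder(self) -> list[int]:
        ch = self.children()
        out: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done or not ch[node]:
                out.append(node)
            else:
                stack.append((node, True))
                for c in ch[node]:
                    stack.append((c, False))
        return out

    def branch_length(self, i: int) -> float:
        p = self.parent[i]
        return float(self.ages[p] - self.ages[i]) if p >= 0 else 0.0

    def copy(self) -> "GeneTree":
        return GeneTree(
            self.labels,
            self.species,
            self.parent.copy(),
            self.ages.copy(),
            dict(self.indicators),
        )

    def newick(self, digits: int = 6) -> str:
        ch = self.children()

        def render(i: int) -> str:
            if i < self.n_tips:
                core = self.labels[i]
            else:
                core = "(" + ",".join(render(c) for c in sorted(ch[i])) + ")"
            p = self.parent[i]
            if p < 0:
                return core
            return f"{core}:{self.ages[p] - self.ages[i]:.{digits}g}"

        return render(self.root) + ";"

    def topology_key(self) -> str:
        """Canonical label-based rooted-topology string (ignores ages)."""
        ch = self.children()

        def render(i: int) -> str:
            if i < self.n_tips:
                return self.labels[i]
            parts = sorted(render(c) for c in ch[i])
            return "(" + ",".join(parts) + ")"

        return render(self.root) + ";"
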