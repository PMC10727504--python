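"""Locus alignments: short multi-sequence alignments with IUPAC codes.

Sequences are strings over A,C,G,T plus IUPAC ambiguity codes, '-' and
'N'.  Heterozygous sites of unphased diploid individuals are encoded as
two-base ambiguity codes (R = A/G, etc.), never randomly resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["LocusAlignment", "IUPAC_SETS", "IUPAC_PAIR", "read_fasta", "write_fasta"]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "-": frozenset("ACGT"),
    "?": frozenset("ACGT"),
}

# two-base (unordered) combination -> IUPAC code
IUPAC_PAIR: dict[frozenset[str], str] = {
    v: k for k, v in IUPAC_SETS.items() if len(v) == 2
}
for _b in "ACGT":
    IUPAC_PAIR[frozenset(_b)] = _b

MISSING = {"-", "N", "?"}


@dataclass
class LocusAlignment:
    labels: list[str]
    seqs: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.labels) != len(self.seqs):
            raise ValueError("labels and sequences differ in number")
        if len({len(s) for s in self.seqs}) > 1:
            raise ValueError("sequences have unequal lengths")

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def missing_fraction(self, label_or_index) -> float:
        i = (
            self.labels.index(label_or_index)
            if isinstance(label_or_index, str)
            else label_or_index
        )
        s = self.seqs[i]
        if not s:
            return 0.0
        return sum(c in MISSING for c in s) / len(s)

    def column(self, j: int) -> list[str]:
        return [s[j] for s in self.seqs]

    def drop_columns(self, drop: Iterable[int]) -> "LocusAlignment":
        dropset = set(drop)
        new = [
            "".join(c for j, c in enumerate(s) if j not in dropset) for s in self.seqs
        ]
        return LocusAlignment(list(self.labels), new, dict(self.meta))


def write_fasta(aln: LocusAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=lab, description="")
        for lab, s in zip(aln.labels, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> LocusAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    return LocusAlignment(
        [r.id for r in records], [str(r.seq).upper() for r in records]
    )
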