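"""Ready-made example species networks.

These encode the two Heliconius introgression models analysed in the
melpomene-silvaniform study system: an eight-species model with six
bidirectional introgression pairs (40 free parameters under linked
theta), and an eight-species major-clade backbone with a single
bidirectional pair (25 free parameters).  Tip abbreviations: Bes
(besckei), Num (numata), Par (pardalinus), Ele (elevatus), Hec
(hecale), Tim (timareta), Cyd (cydno), Mel (melpomene), Bur (burneyi),
Dor (doris), Aoe (aoede), Era (erato), Sar (sara).
"""

from __future__ import annotations

from .network import SpeciesNetwork, add_introgression_pair, tree_from_newick

__all__ = ["melpomene_silvaniform_network", "major_clade_backbone_network"]


def melpomene_silvaniform_network() -> SpeciesNetwork:
    """Eight melpomene-silvaniform species with six bidirectional
    introgression pairs.

    Backbone: ((Bes,Num),(((Par,Ele),Hec),((Tim,Cyd),Mel))).  Pairs:
    besckei/numata (b1-n1); numata with the pardalinus-hecale stem
    (n2-eph1) and with the whole silvaniform+melpomene stem
    (n3-tcmeph1), explaining the alternative placements of numata;
    melpomene with cydno (m1-c1) and with timareta (m2-t1); and the
    hybridizing sister pair pardalinus/elevatus (p1-e1).
    """
    net = tree_from_newick(
        "((Bes,Num)bn,(((Par,Ele)pe,Hec)eph,((Tim,Cyd)tc,Mel)tcm)tcmeph)r;"
    )
    net = add_introgression_pair(net, "Bes", "Num", "b1", "n1")
    net = add_introgression_pair(net, "n1", "eph", "n2", "eph1")
    net = add_introgression_pair(net, "n2", "tcmeph", "n3", "tcmeph1")
    net = add_introgression_pair(net, "Mel", "Cyd", "m1", "c1")
    net = add_introgression_pair(net, "m1", "Tim", "m2", "t1")
    net = add_introgression_pair(net, "Par", "Ele", "p1", "e1")
    return net


def major_clade_backbone_network() -> SpeciesNetwork:
    """Eight species spanning the major clades, with one bidirectional
    introgression pair between the aoede lineage and the erato-sara
    clade stem (the event distinguishing the two candidate backbones).
    """
    net = tree_from_newick(
        "(((((Mel,(Bes,Num)bn)ms,Bur)n4,Dor)n3,Aoe)n2,(Era,Sar)es)r;"
    )
    return add_introgression_pair(net, "Aoe", "es", "a1", "es1")
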