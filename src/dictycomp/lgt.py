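"""Lateral-gene-transfer validation.

Implements the two-criterion test for prokaryote-to-Dictyostelia
transfers: the candidate must (i) form a best bidirectional hit with a
prokaryote gene and (ii) have prokaryote genes as its closest sister
group in phylogenies built by two independent methods.  The verdict
logic reproduces the published decision table, including the exception
for genes that look like sequencing contaminants but are present in
all dictyostelid genomes and transcribed.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .io_formats import UNICELLULAR_AMOEBOZOA


@dataclass
class LGTEvidence:
    """Evidence columns for one LGT candidate."""

    gene_id: str
    bbh_prokaryote: bool
    sister_prok_method1: bool
    sister_prok_method2: bool
    present_all_dicty: bool = False
    transcribed: bool = False
    contaminant_suspect: bool = False
    note: str = ""


@dataclass(frozen=True)
class LGTVerdict:
    gene_id: str
    verdict: str  # yes | unlikely | no
    note: str = ""


def _lineage_clade(tree: dendropy.Tree, focal_lineage: set[str]):
    """Maximal clade containing only focal-lineage leaves."""
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    missing = focal_lineage - set(leaves)
    if missing:
        raise ValueError(f"focal leaves {sorted(missing)} absent from tree")
    node = leaves[min(focal_lineage)]
    while node.parent_node is not None:
        parent = node.parent_node
        below = {lf.taxon.label for lf in parent.leaf_iter()}
        if below <= focal_lineage:
            node = parent
        else:
            break
    if node.parent_node is None:
        raise ValueError("focal lineage spans the entire tree; no sister clade")
    return node


def sister_clade(tree: dendropy.Tree, focal_leaf: str, focal_lineage=None) -> set[str]:
    """Leaf set of the sibling subtree of the focal leaf (or lineage).

    With within-lineage duplicates, the focal clade is the maximal
    clade containing only focal-lineage leaves; its sibling subtree is
    returned.  For a two-leaf tree this is simply the other leaf.
    """
    lineage = set(focal_lineage) if focal_lineage else {focal_leaf}
    node = _lineage_clade(tree, lineage)
    sisters: set[str] = set()
    for sib in node.parent_node.child_nodes():
        if sib is node:
            continue
        sisters.update(lf.taxon.label for lf in sib.leaf_iter())
    return sisters


def prokaryote_sister_test(
    tree: dendropy.Tree,
    focal_lineage,
    kingdom_map: dict[str, str],
) -> bool:
    """True iff every leaf of the focal lineage's sister clade is prokaryote.

    The tree must be rooted (midpoint-root it or supply an
    outgroup-rooted tree); every leaf needs a kingdom annotation.
    """
    if not tree.is_rooted:
        raise ValueError("prokaryote sister test requires a rooted tree; "
                         "midpoint-root the tree or supply outgroup rooting")
    lineage = set(focal_lineage)
    sisters = sister_clade(tree, min(lineage), focal_lineage=lineage)
    for leaf in sorted(sisters):
        if leaf not in kingdom_map:
            raise ValueError(f"missing kingdom annotation for leaf '{leaf}'")
    return all(kingdom_map[leaf] == "prokaryote" for leaf in sisters)


def lgt_verdict(evidence: LGTEvidence) -> LGTVerdict:
    """Three-valued verdict from the evidence columns.

    yes: both tree methods agree on a prokaryote sister AND either the
    BBH criterion holds or the contaminant exception applies (gene is
    present in all dictyostelid genomes and transcribed, so it cannot
    be a sequencing contaminant).  no: both tree methods reject the
    prokaryote sister.  Anything else: unlikely (transfer, if any,
    happened more deeply in the eukaryote lineage).
    """
    m1, m2 = evidence.sister_prok_method1, evidence.sister_prok_method2
    exception = (evidence.contaminant_suspect and evidence.present_all_dicty
                 and evidence.transcribed)
    if m1 and m2 and (evidence.bbh_prokaryote or exception):
        verdict = "yes"
    elif not m1 and not m2:
        verdict = "no"
    else:
        verdict = "unlikely"
    return LGTVerdict(evidence.gene_id, verdict, evidence.note)


def screen_candidates(
    presence: dict[str, dict[str, str]],
    outgroup_kingdom: dict[str, str],
) -> list[str]:
    """Screen genes for the LGT candidate list.

    A gene is a candidate iff its best non-amoebozoan hit is prokaryote
    and it is absent from all three unicellular amoebozoan genomes
    (PhyP, AC, EH).  ``presence`` maps gene -> species -> call string.
    """
    out = []
    for gene in sorted(presence):
        if outgroup_kingdom.get(gene) != "prokaryote":
            continue
        calls = presence[gene]
        if all(calls.get(sp, "absent") == "absent" for sp in UNICELLULAR_AMOEBOZOA):
            out.append(gene)
    return out
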