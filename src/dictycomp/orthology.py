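"""Orthology calling by gene-tree / species-tree congruence.

Each homolog of a focal gene is classified as ortholog, paralog or
unresolved homolog from the rooted gene tree: internal nodes are tagged
duplication/speciation by the species-overlap rule, orthologs are
homologs reachable without crossing a duplication, and ortholog calls
must additionally be congruent (zero Robinson–Foulds conflict among
well-supported splits) with the fixed species tree.  Domain
architectures and conservation categories are compared per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .gene_trees import node_support
from .io_formats import DICTYOSTELIDS, UNICELLULAR_AMOEBOZOA

DEFAULT_SUPPORT_MIN = 0.7
DEFAULT_BRANCH_LENGTH_FACTOR = 3.0

CALLS = ("ortholog", "paralog", "homolog_unresolved", "absent")


@dataclass(frozen=True)
class OrthologyCall:
    """Classification of one species' homolog of a focal gene."""

    focal: str
    species: str
    gene: str | None
    call: str
    branch_length_flag: bool = False


@dataclass
class ConservationProfile:
    """Per-species calls and derived conservation category for one gene."""

    focal: str
    calls: dict = field(default_factory=dict)  # species -> OrthologyCall
    category: "ConservationCategory" = None
    domain_conserved: dict = field(default_factory=dict)  # species -> bool
    expression_divergent: dict = field(default_factory=dict)  # species -> bool


def tag_duplications(tree: dendropy.Tree, species_map: dict[str, str]) -> dict:
    """Label every internal node speciation or duplication.

    Species-overlap rule: a node is a duplication iff the species sets
    of (any) two of its children intersect.
    """
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in species_map:
            raise ValueError(f"leaf '{leaf.taxon.label}' has no species mapping")
    labels: dict = {}
    spset: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            spset[node] = {species_map[node.taxon.label]}
            continue
        kids = [spset[c] for c in node.child_nodes()]
        dup = False
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                if kids[i] & kids[j]:
                    dup = True
        labels[node] = "duplication" if dup else "speciation"
        spset[node] = set().union(*kids)
    return labels


def _species_splits(tree, keep: set[str], rename=None, support_min=None):
    """Nontrivial splits of the tree restricted to ``keep`` leaves.

    Leaves are renamed through ``rename`` (id -> species) if given;
    splits whose defining edge has support below ``support_min`` are
    dropped (missing support counts as resolved).  Returns normalized
    frozensets, plus the number of splits dropped for low support.
    """
    names = set()
    for lf in tree.leaf_node_iter():
        nm = lf.taxon.label
        if nm in keep:
            names.add(rename[nm] if rename else nm)
    if len(names) < 4:
        return set(), 0
    ref = min(names)
    splits = set()
    dropped = 0
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        below = set()
        for lf in node.leaf_iter():
            nm = lf.taxon.label
            if nm in keep:
                below.add(rename[nm] if rename else nm)
        if len(below) < 2 or len(below) > len(names) - 2:
            continue
        if support_min is not None:
            sup = node_support(node)
            if sup is not None and sup < support_min:
                dropped += 1
                continue
        side = frozenset(below if ref not in below else names - below)
        splits.add(side)
    return splits, dropped


@dataclass(frozen=True)
class CongruenceResult:
    congruent: bool
    n_informative: int
    unresolved: bool  # no well-supported informative splits at all

    def __bool__(self):
        return self.congruent


def congruent_with_species_tree(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    gene_subset,
    species_map: dict[str, str],
    support_min: float = DEFAULT_SUPPORT_MIN,
) -> CongruenceResult:
    """Does the gene tree, restricted to the subset, mirror the species tree?

    The subset must hold at most one gene per species.  Gene-tree
    splits with bootstrap support below ``support_min`` are ignored;
    congruence holds iff every remaining split also exists in the
    species tree restricted to the same species.  With no informative
    well-supported splits the result is vacuously congruent and flagged
    unresolved.
    """
    subset = set(gene_subset)
    species = [species_map[g] for g in subset]
    if len(set(species)) != len(species):
        raise ValueError("gene subset contains more than one gene for a species")
    gsplits, _ = _species_splits(gene_tree, subset, rename=species_map,
                                 support_min=support_min)
    ssplits, _ = _species_splits(species_tree, set(species))
    congruent = gsplits <= ssplits
    return CongruenceResult(congruent, len(gsplits), unresolved=not gsplits)


def _path_info(leaf_a, leaf_b):
    """LCA, internal path nodes and path length between two leaves."""
    anc_a = []
    node = leaf_a
    while node is not None:
        anc_a.append(node)
        node = node.parent_node
    index = {id(n): i for i, n in enumerate(anc_a)}
    node = leaf_b
    up_b = []
    while id(node) not in index:
        up_b.append(node)
        node = node.parent_node
    lca = node
    path_nodes = anc_a[1 : index[id(lca)] + 1] + [n for n in up_b if not n.is_leaf()]
    length = 0.0
    for n in anc_a[: index[id(lca)]]:
        length += n.edge.length or 0.0
    for n in up_b:
        length += n.edge.length or 0.0
    return lca, path_nodes, length


def classify_homologs(
    focal_gene: str,
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    species_map: dict[str, str],
    support_min: float = DEFAULT_SUPPORT_MIN,
    branch_length_factor: float = DEFAULT_BRANCH_LENGTH_FACTOR,
    species_codes=None,
) -> dict[str, OrthologyCall]:
    """Classify every species' homologs of the focal gene.

    A homolog whose last common ancestor with the focal gene is a
    speciation node is an ortholog candidate (closest path wins; tie
    broken by id); homologs diverging at a duplication node are
    paralogs — so a recent lineage-specific duplicate of the focal
    still has orthologs in other species (co-orthology).  Calls whose
    deciding (LCA) node is poorly supported become
    ``homolog_unresolved``, as do ortholog candidates when the called
    set is incongruent with the species tree.  The branch-length flag
    marks genes whose
    root-to-tip length exceeds ``branch_length_factor`` times the
    family median.
    """
    if species_codes is None:
        species_codes = DICTYOSTELIDS + UNICELLULAR_AMOEBOZOA
    leaves = {lf.taxon.label: lf for lf in gene_tree.leaf_node_iter()}
    if focal_gene not in leaves:
        raise ValueError(f"focal gene '{focal_gene}' absent from gene tree")
    dup_labels = tag_duplications(gene_tree, species_map)
    focal_leaf = leaves[focal_gene]
    focal_sp = species_map[focal_gene]

    root_dist = {}
    for lf in gene_tree.leaf_node_iter():
        d, node = 0.0, lf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        root_dist[lf.taxon.label] = d
    med = sorted(root_dist.values())[len(root_dist) // 2]

    def bl_flag(gid):
        return med > 0 and root_dist[gid] > branch_length_factor * med

    calls: dict[str, OrthologyCall] = {}
    per_leaf = {}
    for gid, lf in leaves.items():
        if gid == focal_gene:
            continue
        lca, path, length = _path_info(focal_leaf, lf)
        is_paralog = dup_labels.get(lca) == "duplication"
        sup = node_support(lca)
        per_leaf[gid] = (is_paralog, 1.0 if sup is None else sup, length)

    for sp in species_codes:
        members = sorted(g for g, s in species_map.items()
                         if s == sp and g in leaves)
        if sp == focal_sp:
            calls[sp] = OrthologyCall(focal_gene, sp, focal_gene, "ortholog",
                                      bl_flag(focal_gene))
            continue
        if not members:
            calls[sp] = OrthologyCall(focal_gene, sp, None, "absent")
            continue
        no_dup = [g for g in members if not per_leaf[g][0]]
        if no_dup:
            best = min(no_dup, key=lambda g: (per_leaf[g][2], g))
            call = "ortholog" if per_leaf[best][1] >= support_min else "homolog_unresolved"
        else:
            best = min(members, key=lambda g: (per_leaf[g][2], g))
            call = "paralog" if per_leaf[best][1] >= support_min else "homolog_unresolved"
        calls[sp] = OrthologyCall(focal_gene, sp, best, call, bl_flag(best))

    called_set = [focal_gene] + [c.gene for c in calls.values() if c.call == "ortholog"
                                 and c.gene != focal_gene]
    if len(called_set) >= 2:
        result = congruent_with_species_tree(
            gene_tree, species_tree, called_set, species_map, support_min)
        if not result.congruent:
            for sp, c in list(calls.items()):
                if c.call == "ortholog" and c.gene != focal_gene:
                    calls[sp] = OrthologyCall(c.focal, sp, c.gene,
                                              "homolog_unresolved", c.branch_length_flag)
    return calls


def compare_architecture(arch_focal, arch_other) -> bool:
    """Are two domain architectures conserved?

    Conserved iff the ordered token sequences are identical after
    collapsing adjacent repeats of the same token (tandem domain-count
    changes do not count as architecture change; order does).
    """

    def collapse(tokens):
        out = []
        for t in tokens:
            if not out or out[-1] != t:
                out.append(t)
        return out

    return collapse(arch_focal) == collapse(arch_other)


@dataclass(frozen=True)
class ConservationCategory:
    """Labeled conservation record across the eight genomes."""

    category: str  # all5_ortholog | DD_only | 4 | II | other
    only: str | None  # DD | 4 | II | None
    all5_ortholog: bool
    multi_only: bool
    uni_plus_multi: bool
    n_dicty_ortholog: int
    n_dicty_present: int


_PRESENT = ("ortholog", "paralog", "homolog_unresolved")


def conservation_category(calls: dict[str, str]) -> ConservationCategory:
    """Derive the conservation category from per-species calls.

    ``calls`` maps each of the eight species codes to a call string.
    ``only`` reproduces the limited-conservation labels: DD only,
    group 4 (DD+DP) or branch II (DD+DP+DL).
    """
    present = {sp for sp, c in calls.items() if c in _PRESENT}
    dicty = present & set(DICTYOSTELIDS)
    uni = present & set(UNICELLULAR_AMOEBOZOA)
    only = None
    if not uni:
        if dicty == {"DD"}:
            only = "DD"
        elif dicty == {"DD", "DP"}:
            only = "4"
        elif dicty == {"DD", "DP", "DL"}:
            only = "II"
    n_orth = sum(1 for sp in DICTYOSTELIDS if calls.get(sp) == "ortholog")
    all5 = n_orth == len(DICTYOSTELIDS)
    if all5:
        cat = "all5_ortholog"
    elif only == "DD":
        cat = "DD_only"
    elif only in ("4", "II"):
        cat = only
    else:
        cat = "other"
    return ConservationCategory(
        category=cat,
        only=only,
        all5_ortholog=all5,
        multi_only=bool(dicty) and not uni,
        uni_plus_multi=bool(dicty) and bool(uni),
        n_dicty_ortholog=n_orth,
        n_dicty_present=len(dicty),
    )
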