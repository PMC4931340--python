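"""Per-family gene trees from sequences.

Distance-based stand-in for the Bayesian trees of the original
workflow: Poisson-corrected p-distances, Saitou–Nei neighbor joining,
midpoint rooting and nonparametric bootstrap supports.  Externally
built trees can always be supplied as Newick instead
(:func:`dictycomp.io_formats.read_newick`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .homology import blosum62_matrix, _make_aligner

#: Saturation handling: p-distances at or above P_CAP are reported as D_MAX.
P_CAP = 0.95
D_MAX = 3.0
#: Alignment columns with more than this gap fraction are ignored.
MAX_GAP_FRAC = 0.5

_GAP = ord("-")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances (substitutions/site) over gene ids."""

    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("nonzero diagonal")
        if not np.allclose(m, m.T):
            raise ValueError("matrix not symmetric")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("distances must be finite and nonnegative")


def poisson_correct(p: float, p_cap: float = P_CAP, d_max: float = D_MAX) -> float:
    """Poisson-corrected distance d = -ln(1-p), capped for saturated pairs."""
    if p >= p_cap:
        return d_max
    return -math.log(1.0 - p)


def pairwise_distance(seq_a: str, seq_b: str, poisson: bool = True) -> float:
    """Distance between two sequences from their global alignment.

    p is the mismatch fraction over columns where both sequences have a
    residue; with ``poisson`` the distance is -ln(1-p) capped at
    ``D_MAX`` for p >= ``P_CAP``, otherwise the raw p-distance.
    """
    aligner = _make_aligner(blosum62_matrix(), 11, 1, "global")
    aln = next(iter(aligner.align(seq_a, seq_b)))
    mism = ncols = 0
    for ca, cb in zip(*aln):
        if ca == "-" or cb == "-":
            continue
        ncols += 1
        if ca != cb:
            mism += 1
    if ncols == 0:
        raise ValueError("zero aligned columns between sequences")
    p = mism / ncols
    return poisson_correct(p) if poisson else p


def implied_alignment(named_seqs) -> tuple[tuple[str, ...], np.ndarray]:
    """Stack sequences into alignment columns.

    Equal-length sequences (no indels, as produced by the bundled
    simulator) align column-for-column.  Unequal lengths fall back to a
    star alignment against the longest sequence; columns inserted
    relative to that reference are dropped.
    """
    items = list(named_seqs)
    ids = tuple(i for i, _ in items)
    seqs = [s for _, s in items]
    lengths = {len(s) for s in seqs}
    if len(lengths) == 1:
        mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
        return ids, mat.reshape(len(seqs), -1).copy()
    ref = max(seqs, key=len)
    aligner = _make_aligner(blosum62_matrix(), 11, 1, "global")
    ncol = len(ref)
    mat = np.full((len(seqs), ncol), _GAP, dtype=np.uint8)
    for row, seq in enumerate(seqs):
        if seq == ref:
            mat[row] = np.frombuffer(seq.encode(), dtype=np.uint8)
            continue
        aln = next(iter(aligner.align(ref, seq)))
        ref_pos = 0
        for cr, cs in zip(*aln):
            if cr == "-":
                continue  # insertion relative to reference: dropped
            if cs != "-":
                mat[row, ref_pos] = ord(cs)
            ref_pos += 1
    return ids, mat


def alignment_distances(
    ids,
    mat: np.ndarray,
    poisson: bool = True,
    max_gap_frac: float = MAX_GAP_FRAC,
) -> DistanceMatrix:
    """Pairwise distances from alignment columns.

    Columns with more than ``max_gap_frac`` gaps are ignored (a crude
    stand-in for trimming poorly aligned blocks); per pair, p is
    computed over columns where both rows hold residues.  Pairs sharing
    no columns are assigned the saturation cap.
    """
    ids = tuple(ids)
    n = len(ids)
    keep = (mat == _GAP).mean(axis=0) <= max_gap_frac
    sub = mat[:, keep]
    resid = sub != _GAP
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = resid[i] & resid[j]
            ncols = int(both.sum())
            if ncols == 0:
                d = D_MAX
            else:
                p = float((sub[i, both] != sub[j, both]).mean())
                d = poisson_correct(p) if poisson else p
            D[i, j] = D[j, i] = d
    return DistanceMatrix(ids, D)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Negative estimated branch lengths are clamped to 0 with the deficit
    transferred to the adjacent (sister) branch, preserving the path
    length between the joined nodes.  Returns an unrooted tree (stored
    with a trifurcating seed node for >= 4 taxa).
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tns = dendropy.TaxonNamespace(ids)
    nodes = []
    for name in ids:
        nd = dendropy.Node(taxon=tns.get_taxon(name))
        nodes.append(nd)
    D = dm.matrix.astype(float).copy()
    active = list(range(n))

    def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        new_idx = len(nodes)
        nodes.append(parent)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i, k] + D[j, k] - dij)
            D[new_idx, k] = D[k, new_idx] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = dendropy.Node()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# midpoint rooting


def _unrooted_adjacency(tree: dendropy.Tree):
    """Undirected edge list with degree-2 seed nodes suppressed.

    Returns (adjacency dict key->[(other, length, support)], names dict
    key->leaf name).  Support is the internal-node label of the child
    end of each original edge.
    """
    adj: dict[int, list] = {}
    names: dict[int, str] = {}

    def _support(node):
        return node.label if (node.label and not node.is_leaf()) else None

    for node in tree.preorder_node_iter():
        key = id(node)
        adj.setdefault(key, [])
        if node.is_leaf():
            names[key] = node.taxon.label if node.taxon else node.label
        for child in node.child_nodes():
            if child.edge.length is None:
                leafname = child.taxon.label if child.taxon else "<internal>"
                raise ValueError(f"missing branch length on edge above '{leafname}'")
            adj.setdefault(id(child), [])
            adj[key].append([id(child), float(child.edge.length), _support(child)])
            adj[id(child)].append([key, float(child.edge.length), _support(child)])
    # suppress degree-2 nodes (the seed node of a rooted input tree)
    for key in list(adj):
        if key not in names and len(adj[key]) == 2:
            (k1, l1, s1), (k2, l2, s2) = adj[key]
            adj[k1] = [e for e in adj[k1] if e[0] != key] + [[k2, l1 + l2, s1 or s2]]
            adj[k2] = [e for e in adj[k2] if e[0] != key] + [[k1, l1 + l2, s1 or s2]]
            del adj[key]
    return adj, names


def _farthest(adj, names, start):
    dist = {start: 0.0}
    parent = {start: None}
    stack = [start]
    while stack:
        cur = stack.pop()
        for other, length, _ in adj[cur]:
            if other not in dist:
                dist[other] = dist[cur] + length
                parent[other] = cur
                stack.append(other)
    leaf_keys = sorted((k for k in dist if k in names), key=lambda k: names[k])
    far = max(leaf_keys, key=lambda k: dist[k])
    return far, dist, parent


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root the tree at the midpoint of the longest leaf-to-leaf path.

    If the midpoint falls exactly on an internal node, the root is
    placed on the path edge leaving that node toward the farther end of
    the path, with a zero-length stub.  Requires every branch length to
    be present.  The unrooted topology (bipartition set) is preserved.
    """
    adj, names = _unrooted_adjacency(tree)
    if len(names) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    some_leaf = min((k for k in names), key=lambda k: names[k])
    u, _, _ = _farthest(adj, names, some_leaf)
    v, dist, parent = _farthest(adj, names, u)
    # path u .. v
    path = [v]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    path.reverse()  # u -> v
    half = dist[v] / 2.0
    cum = 0.0
    for a, b in zip(path, path[1:]):
        length = next(l for o, l, _ in adj[a] if o == b)
        if cum + length >= half - 1e-12:
            x = min(max(half - cum, 0.0), length)
            return _reroot_on_edge(adj, names, a, b, x)
        cum += length
    raise AssertionError("midpoint not located on path")  # pragma: no cover


def _reroot_on_edge(adj, names, a, b, x):
    """Build a rooted dendropy tree with the root x along edge (a, b)."""
    support_ab = next(s for o, _, s in adj[a] if o == b)
    length_ab = next(l for o, l, _ in adj[a] if o == b)
    tns = dendropy.TaxonNamespace(sorted(names.values()))

    def build(key, came_from, edge_len, edge_support):
        node = dendropy.Node()
        if key in names:
            node.taxon = tns.get_taxon(names[key])
        else:
            node.label = edge_support
        node.edge.length = edge_len
        for other, length, support in adj[key]:
            if other == came_from:
                continue
            node.add_child(build(other, key, length, support))
        return node

    root = dendropy.Node()
    left = build(a, b, x, support_ab)
    right = build(b, a, length_ab - x, support_ab)
    root.add_child(left)
    root.add_child(right)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# bootstrap


def node_support(node) -> float | None:
    """Parse the bootstrap/posterior support stored in an internal label."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def tree_splits(tree: dendropy.Tree) -> dict[frozenset, float | None]:
    """Nontrivial unrooted splits of a tree, mapped to their supports.

    Each split is normalized to the side not containing the
    lexicographically smallest leaf name.
    """
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = leaves[0]
    full = frozenset(leaves)
    out: dict[frozenset, float | None] = {}
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if ref not in below else full - below
        if len(side) < 2 or len(side) > len(full) - 2:
            continue
        prev = out.get(side)
        sup = node_support(node)
        if prev is None or (sup is not None and sup > prev):
            out[side] = sup
    return out


def bootstrap_support(
    family_sequences,
    n_reps: int = 100,
    seed: int = 0,
    poisson: bool = True,
) -> dendropy.Tree:
    """Midpoint-rooted NJ tree with bootstrap supports on internal nodes.

    Columns of the implied alignment are resampled with replacement;
    the support of a split is the fraction of replicate NJ trees that
    contain it.  Deterministic given ``seed``.  Internal node labels
    hold the support as text (parse with :func:`node_support`).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    items = [(r.id, r.sequence) if hasattr(r, "id") else tuple(r) for r in family_sequences]
    ids, mat = implied_alignment(items)
    main_dm = alignment_distances(ids, mat, poisson=poisson)
    main = midpoint_root(neighbor_joining(main_dm))

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    ncol = mat.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_dm = alignment_distances(ids, mat[:, cols], poisson=poisson)
        rep = neighbor_joining(rep_dm)
        for split in tree_splits(rep):
            counts[split] = counts.get(split, 0) + 1

    leaves = sorted(ids)
    ref = leaves[0]
    full = frozenset(leaves)
    for node in main.preorder_internal_node_iter(exclude_seed_node=True):
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if ref not in below else full - below
        if len(side) < 2 or len(side) > len(full) - 2:
            node.label = None
            continue
        node.label = f"{counts.get(side, 0) / n_reps:.4f}"
    return main
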