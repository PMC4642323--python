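"""Distance-based phylogenetics: protein distances (p / Poisson), a
deterministic neighbor-joining implementation, bootstrap supports, and the
clade reports used for species-specific duplication counting and the RPW8
monophyly check.

Trees are unrooted (stored with a trifurcating root node); clade counting
roots them at the midpoint of the longest leaf-to-leaf path.  Every
tie-break (NJ join order, bipartition hashing) is deterministic so trees are
reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


class SaturatedDistance(ValueError):
    """p-distance of 1 cannot be Poisson-corrected."""


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (m < 0).any() or not np.isfinite(m).all():
            raise ValueError("distances must be finite and non-negative")
        self.matrix = m

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.matrix[i, j])


def protein_distance(msa: Mapping[str, str], model: str = "poisson",
                     saturation: str = "raise") -> DistanceMatrix:
    """Pairwise protein distances from an MSA with pairwise deletion.

    ``p``: proportion of differing sites among columns where both rows have
    residues.  ``poisson``: d = -ln(1 - p) correction for multiple hits; a
    fully divergent pair (p = 1) raises :class:`SaturatedDistance` unless
    ``saturation="cap"``, which substitutes the largest observable proportion
    (1 - 1/(2*compared)) — used inside bootstrap resampling, where fully
    divergent resamples of unrelated sequences are routine.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    labels = list(msa)
    if len(labels) < 3:
        raise ValueError("need at least 3 sequences")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences differ in length")
    rows = np.array([list(msa[l]) for l in labels])
    gap = rows == "-"
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(f"no comparable sites between {labels[i]} and {labels[j]}")
            p = float((rows[i, both] != rows[j, both]).sum()) / compared
            if model == "poisson":
                if p >= 1.0:
                    if saturation != "cap":
                        raise SaturatedDistance(
                            f"all compared sites differ between {labels[i]} and {labels[j]}")
                    p = 1.0 - 1.0 / (2 * compared)
                p = -math.log1p(-p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=labels, matrix=d)


# --- tree structure ----------------------------------------------------------

@dataclass
class Node:
    """Tree node; ``length`` is the branch to the parent, ``support`` the
    bootstrap percentage of the subtending edge (internal nodes only)."""

    label: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())


@dataclass
class PhyloTree:
    """Unrooted tree stored with a (tri- or multifurcating) root node."""

    root: Node

    @property
    def leaf_labels(self) -> frozenset[str]:
        return self.root.leaf_labels()

    def newick(self, *, with_support: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            sup = ""
            if with_support and node.support is not None:
                sup = f"{node.support:g}"
            return f"({inner}){sup}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> dict[frozenset[str], Node]:
        """Non-trivial leaf bipartitions, canonicalized as the side NOT
        containing the lexicographically smallest leaf."""
        all_leaves = self.leaf_labels
        ref = min(all_leaves)
        out: dict[frozenset[str], Node] = {}

        def walk(node: Node) -> None:
            for child in node.children:
                if not child.is_leaf:
                    side = child.leaf_labels()
                    if ref in side:
                        side = all_leaves - side
                    if 1 < len(side) < len(all_leaves) - 1 or len(side) > 1:
                        out[frozenset(side)] = child
                    walk(child)

        walk(self.root)
        # drop trivial splits (single leaf or all-but-one)
        return {s: n for s, n in out.items()
                if 2 <= len(s) <= len(all_leaves) - 2}


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Ties in Q are broken on the lexicographically smallest label pair.
    Negative branch lengths are clamped to 0 with the deficit transferred to
    the sibling branch.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = dm.matrix.copy()
    nodes: list[Node] = [Node(label=l) for l in dm.labels]
    # smallest leaf label under each working node, for deterministic ties
    min_label: list[str] = list(dm.labels)
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for ai, bi in np.argwhere(q <= qmin + 1e-12):
            if bi <= ai:
                continue
            la = min_label[active[ai]]
            lb = min_label[active[bi]]
            key = (min(la, lb), max(la, lb))
            if best is None or key < best[0]:
                best = (key, int(ai), int(bi))
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        new = Node()
        nodes[i].length = li
        nodes[j].length = lj
        new.children = [nodes[i], nodes[j]]
        # distances from the new node to the others
        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for other in active:
            if other in (i, j):
                continue
            dist = 0.5 * (d[i, other] + d[j, other] - dij)
            d[new_idx, other] = d[other, new_idx] = max(dist, 0.0)
        nodes.append(new)
        min_label.append(min(min_label[i], min_label[j]))
        active = [a for a in active if a not in (i, j)] + [new_idx]
    # final 3-way join
    i, j, k = active
    root = Node()
    nodes[i].length = max(0.5 * (d[i, j] + d[i, k] - d[j, k]), 0.0)
    nodes[j].length = max(0.5 * (d[i, j] + d[j, k] - d[i, k]), 0.0)
    nodes[k].length = max(0.5 * (d[i, k] + d[j, k] - d[i, j]), 0.0)
    order = sorted([i, j, k], key=lambda x: min_label[x])
    root.children = [nodes[x] for x in order]
    return PhyloTree(root=root)


def bootstrap_supports(msa: Mapping[str, str], replicates: int = 1000,
                       seed: int = 0, model: str = "poisson") -> PhyloTree:
    """NJ tree with bootstrap supports.

    Alignment columns are resampled with replacement ``replicates`` times;
    the support of each internal edge of the full-data tree is the
    percentage of replicate trees containing the same leaf bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = neighbor_joining(protein_distance(msa, model=model))
    labels = list(msa)
    rows = np.array([list(msa[l]) for l in labels])
    ncol = rows.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    valid = 0
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        sample = {l: "".join(rows[i, cols]) for i, l in enumerate(labels)}
        try:
            rep = neighbor_joining(protein_distance(sample, model=model,
                                                    saturation="cap"))
        except ValueError:
            continue  # no comparable sites for some pair in this resample
        valid += 1
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1
    if valid == 0:
        raise ValueError("every bootstrap replicate failed (no comparable sites)")
    for bp, node in tree.bipartitions().items():
        node.support = 100.0 * counts[bp] / valid
    return tree


# --- rooting and clade reports ----------------------------------------------

def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Returns a new rooted tree with a binary root placed on the midpoint
    edge; bootstrap supports travel with their edges (the two root-adjacent
    branches share the original midpoint edge's support).
    """
    adj: dict[int, list[tuple[int, float, float | None]]] = {}
    info: dict[int, Node] = {}

    def reg(node: Node) -> int:
        info[id(node)] = node
        adj.setdefault(id(node), [])
        return id(node)

    def walk(node: Node) -> None:
        u = reg(node)
        for child in node.children:
            v = reg(child)
            adj[u].append((v, child.length, child.support))
            adj[v].append((u, child.length, child.support))
            walk(child)

    walk(tree.root)
    leaf_ids = [nid for nid, n in info.items() if n.is_leaf]

    def distances_from(src_id: int) -> tuple[dict[int, float], dict[int, int]]:
        dist = {src_id: 0.0}
        prev = {src_id: src_id}
        stack = [src_id]
        while stack:
            u = stack.pop()
            for v, ln, _ in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + ln
                    prev[v] = u
                    stack.append(v)
        return dist, prev

    # farthest pair by two sweeps would need non-negative metric assumptions
    # beyond clamped NJ output; trees are desk-scale, so scan all leaves
    best = (-1.0, None, None, None)
    sorted_leaves = sorted(leaf_ids, key=lambda i: info[i].label)
    for a in sorted_leaves:
        dist, prev = distances_from(a)
        for b in sorted_leaves:
            if b == a:
                continue
            if dist[b] > best[0] + 1e-15:
                best = (dist[b], a, b, prev)
    total, a, b, prev = best
    if total <= 0:
        return tree
    path = [b]
    while path[-1] != a:
        path.append(prev[path[-1]])
    path.reverse()  # a ... b
    half = total / 2.0
    acc = 0.0
    for k in range(len(path) - 1):
        u, v = path[k], path[k + 1]
        ln, support = next((l, s) for w, l, s in adj[u] if w == v)
        if acc + ln >= half - 1e-12:
            offset_u = half - acc            # root sits offset_u from u
            return _build_rooted(adj, info, u, v, offset_u, ln, support)
        acc += ln
    # numerical fallthrough: root on the last edge's far end
    u, v = path[-2], path[-1]
    ln, support = next((l, s) for w, l, s in adj[u] if w == v)
    return _build_rooted(adj, info, u, v, ln, ln, support)


def _build_rooted(adj, info, u: int, v: int, offset_u: float, edge_len: float,
                  support: float | None) -> PhyloTree:
    """Rebuild a rooted Node tree with the root on edge (u, v)."""

    def build(node_id: int, came_from: int, length: float,
              sup: float | None) -> Node:
        node = info[node_id]
        out = Node(label=node.label, length=length, support=sup)
        for w, ln, s in adj[node_id]:  # adjacency order is deterministic
            if w == came_from:
                continue
            out.children.append(build(w, node_id, ln, s))
        if not out.children and node.label is None:
            raise RuntimeError("internal node became a leaf during rerooting")
        return out

    side_u = build(u, v, max(offset_u, 0.0), support)
    side_v = build(v, u, max(edge_len - offset_u, 0.0), support)
    root = Node(children=[side_u, side_v])
    for child in root.children:
        _suppress_unary(child)
    return PhyloTree(root=root)


def _suppress_unary(node: Node) -> None:
    """Collapse single-child internal nodes created when the old trifurcating
    root lies on the path (its branch lengths merge)."""
    i = 0
    while i < len(node.children):
        c = node.children[i]
        if not c.is_leaf and len(c.children) == 1:
            grand = c.children[0]
            grand.length += c.length
            if grand.support is None:
                grand.support = c.support
            node.children[i] = grand
            continue
        _suppress_unary(c)
        i += 1


@dataclass
class SpeciesClade:
    leaves: frozenset[str]
    support: float | None


@dataclass
class SpeciesCladeReport:
    """Species-specific duplication clades on the midpoint-rooted tree."""

    focal_species: str
    clades: list[SpeciesClade]
    n_clades: int
    n_genes: int
    mean_paralogs: float
    proportion_pct: float        # n_genes / total focal-species genes


def species_specific_clades(tree: PhyloTree, species_map: Mapping[str, str],
                            support_threshold: float = 50.0,
                            focal_species: str | None = None) -> SpeciesCladeReport:
    """Count maximal single-species clades with support strictly above the
    threshold on the midpoint-rooted tree.

    A clade must have >= 2 leaves, all from the focal species, and bootstrap
    support > ``support_threshold``; counted clades are maximal (no counted
    clade is nested inside another).  The proportion is the fraction of the
    focal species' genes that fall in such clades — the species-specific
    duplication share.
    """
    missing = [l for l in tree.leaf_labels if l not in species_map]
    if missing:
        raise KeyError(f"species unknown for leaves: {sorted(missing)}")
    if focal_species is None:
        from collections import Counter
        focal_species = Counter(species_map[l] for l in tree.leaf_labels).most_common(1)[0][0]
    rooted = midpoint_root(tree)
    clades: list[SpeciesClade] = []

    def walk(node: Node) -> None:
        if node.is_leaf:
            return
        leaves = node.leaf_labels()
        same = all(species_map[l] == focal_species for l in leaves)
        supported = node.support is not None and node.support > support_threshold
        if same and len(leaves) >= 2 and supported:
            clades.append(SpeciesClade(leaves=leaves, support=node.support))
            return  # maximality: do not count nested clades
        for c in node.children:
            walk(c)

    # the root itself has no subtending edge; evaluate its children
    for c in rooted.root.children:
        walk(c)
    n_genes = sum(len(c.leaves) for c in clades)
    total_focal = sum(1 for l in tree.leaf_labels if species_map[l] == focal_species)
    from .report import mean_per_group, percentage
    return SpeciesCladeReport(
        focal_species=focal_species,
        clades=sorted(clades, key=lambda c: min(c.leaves)),
        n_clades=len(clades),
        n_genes=n_genes,
        mean_paralogs=mean_per_group(n_genes, len(clades)),
        proportion_pct=percentage(n_genes, total_focal),
    )


def clade_monophyly(tree: PhyloTree, members: Iterable[str]) -> tuple[bool, float | None]:
    """Is ``members`` exactly one side of some edge of the unrooted tree?

    Returns (is_monophyletic, support of that bipartition).  Trivial groups
    (single leaf, all leaves) are monophyletic with support None.
    """
    members = frozenset(members)
    leaves = tree.leaf_labels
    if not members <= leaves:
        raise ValueError(f"unknown members: {sorted(members - leaves)}")
    if len(members) <= 1 or members == leaves:
        return True, None
    bps = tree.bipartitions()
    complement = leaves - members
    for side, node in bps.items():
        if side == members or side == complement:
            return True, node.support
    return False, None
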