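"""Neighbor-joining trees with bootstrap support and clade partitioning.

Distances are uncorrected p-distances with pairwise deletion of columns
containing a gap or an X.  The NJ implementation is the classic
agglomerative algorithm: at each step join the pair minimising
Q(i,j) = (n-2)·d(i,j) - Σ_k d(i,k) - Σ_k d(j,k), with rate-corrected
branch lengths; negative branch lengths are clamped to zero with the
deficit moved to the sister edge; ties are broken by the
lexicographically smallest taxon-id pair, which makes the topology a
pure function of the distance matrix.  Bootstrap support is the
percentage of column-resampled replicate trees containing each internal
bipartition of the full-data tree.  Clades are extracted algorithmically:
root at the midpoint of the longest leaf-to-leaf path, then cut the
longest internal edges greedily until the requested number of
leaf-bearing components exists.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


# ---------------------------------------------------------------------------
# distance matrix

@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (v < 0).any():
            raise ValueError("negative distances")

    def __len__(self) -> int:
        return len(self.ids)


def pdistance_matrix(aligned: Sequence) -> DistanceMatrix:
    """p-distance matrix with pairwise deletion over gap/X columns.

    ``aligned`` is any sequence of records with ``id`` and equal-length
    ``sequence`` attributes; a pair sharing no comparable column is an
    error naming the pair.
    """
    ids = tuple(r.id for r in aligned)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxon ids")
    lengths = {len(r.sequence) for r in aligned}
    if len(lengths) > 1:
        raise ValueError("aligned sequences differ in length")
    seqs = [r.sequence for r in aligned]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            compared = mismatches = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in "-.X" or b in "-.X":
                    continue
                compared += 1
                if a != b:
                    mismatches += 1
            if compared == 0:
                raise ValueError(
                    f"no comparable columns between {ids[i]} and {ids[j]}"
                )
            d[i, j] = d[j, i] = mismatches / compared
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# trees

@dataclass
class TreeNode:
    """A node; ``length`` is the branch above it, ``support`` its label."""

    name: Optional[str] = None
    length: float = 0.0
    support: Optional[int] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class Tree:
    """A (generally unrooted) tree, stored rooted at a basal multifurcation."""

    root: TreeNode

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(leaf.name for leaf in self.root.leaves())

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Non-trivial bipartitions, keyed by the canonical (smaller-id) side.

        Each internal (non-root) node induces the split of its leaf set
        against the rest; the key is the side not containing the
        lexicographically smallest leaf, so splits compare across trees.
        """
        all_leaves = set(self.leaf_names)
        anchor = min(all_leaves)
        out: dict[frozenset[str], TreeNode] = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = {leaf.name for leaf in node.leaves()}
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            key = frozenset(all_leaves - side if anchor in side else side)
            out[key] = node
        return out

    def newick(self, *, decimals: int = 10) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(render(c) for c in node.children)
                label = f"({inner})"
                if node.support is not None:
                    label += str(node.support)
            return f"{label}:{node.length:.{decimals}g}"

        inner = ",".join(render(c) for c in self.root.children)
        return f"({inner});"


def parse_newick(text: str) -> Tree:
    """Parse a newick string (labels, branch lengths, integer supports)."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick must end with ';'")
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(text) and text[pos] not in ":,();":
            pos += 1
        label = text[start:pos]
        if label:
            if node.is_leaf:
                node.name = label
            else:
                node.support = int(label)
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",();":
                pos += 1
            node.length = float(text[start:pos])
        return node

    root = parse_node()
    if text[pos] != ";":
        raise ValueError(f"trailing characters at {pos}")
    return Tree(root)


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(d: DistanceMatrix) -> Tree:
    """Classic neighbor joining; deterministic under the stated tie-break."""
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = {i: TreeNode(name=taxon) for i, taxon in enumerate(d.ids)}
    # tie-break label: lexicographically smallest leaf id in the cluster
    labels = {i: taxon for i, taxon in enumerate(d.ids)}
    dist = {
        (i, j): d.values[i, j]
        for i in range(n) for j in range(i + 1, n)
    }

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    active = set(range(n))
    next_id = n

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            q = (m - 2) * get(i, j) - r[i] - r[j]
            pair_ids = tuple(sorted((labels[i], labels[j])))
            cand = (q, pair_ids, (i, j))
            if best is None or cand[:2] < best[:2]:
                best = cand
        i, j = best[2]
        dij = get(i, j)
        vi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        vj = dij - vi
        # clamp negatives, moving the deficit to the sister edge
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = TreeNode()
        nodes[i].length = vi
        nodes[j].length = vj
        parent.children = [nodes[i], nodes[j]]
        nodes[next_id] = parent
        labels[next_id] = min(labels[i], labels[j])
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, next_id), max(k, next_id))] = (
                get(i, k) + get(j, k) - dij
            ) / 2.0
        active -= {i, j}
        active.add(next_id)
        next_id += 1

    rest = sorted(active)
    root = TreeNode()
    if len(rest) == 2:
        a, b = rest
        dab = get(a, b)
        nodes[a].length = nodes[b].length = dab / 2.0
        root.children = [nodes[a], nodes[b]]
    else:
        a, b, c = rest
        va = max(0.0, (get(a, b) + get(a, c) - get(b, c)) / 2.0)
        vb = max(0.0, (get(a, b) + get(b, c) - get(a, c)) / 2.0)
        vc = max(0.0, (get(a, c) + get(b, c) - get(a, b)) / 2.0)
        for node_id, v in zip(rest, (va, vb, vc)):
            nodes[node_id].length = v
        root.children = [nodes[a], nodes[b], nodes[c]]
    return Tree(root)


def bootstrap_support(
    aligned: Sequence,
    n_reps: int,
    seed: int,
) -> Tree:
    """NJ tree on the full alignment with bootstrap supports attached.

    Each replicate resamples alignment columns with replacement,
    rebuilds the NJ tree, and every internal bipartition of the
    full-data tree is scored by the percentage of replicates containing
    it.  Fully reproducible from the seed; with ``n_reps == 0`` the tree
    carries no supports.
    """
    tree = nj_tree(pdistance_matrix(aligned))
    if n_reps == 0:
        return tree
    splits = tree.bipartitions()
    counts = {key: 0 for key in splits}
    rng = np.random.default_rng(seed)
    length = len(aligned[0].sequence)
    order = sorted(range(len(aligned)), key=lambda i: aligned[i].id)

    @dataclass(frozen=True)
    class _Row:
        id: str
        sequence: str

    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = [
            _Row(aligned[i].id, "".join(aligned[i].sequence[c] for c in cols))
            for i in order
        ]
        rep = nj_tree(pdistance_matrix(resampled))
        rep_splits = rep.bipartitions()
        for key in counts:
            if key in rep_splits:
                counts[key] += 1
    for key, node in splits.items():
        node.support = round(100 * counts[key] / n_reps)
    return tree


# ---------------------------------------------------------------------------
# clade partitioning

@dataclass(frozen=True)
class CladePartition:
    """Assignment of leaves to clades plus per-clade type composition."""

    assignment: dict[str, int]  # leaf name -> clade number (1-based)
    type_counts: dict[int, dict[str, int]]
    majority_type: dict[int, Optional[str]]

    @property
    def n_clades(self) -> int:
        return len(set(self.assignment.values()))

    def clade_members(self, clade: int) -> list[str]:
        return sorted(l for l, c in self.assignment.items() if c == clade)


def _adjacency(tree: Tree) -> dict[int, list[tuple[int, float]]]:
    """Undirected weighted adjacency over node object ids."""
    adj: dict[int, list[tuple[int, float]]] = {}

    def add(u: TreeNode, v: TreeNode, w: float) -> None:
        adj.setdefault(id(u), []).append((id(v), w))
        adj.setdefault(id(v), []).append((id(u), w))

    for node in tree.root.walk():
        for child in node.children:
            add(node, child, child.length)
    return adj


def midpoint_root(tree: Tree) -> tuple[dict, dict, tuple]:
    """Insert a root node at the midpoint of the longest leaf-to-leaf path.

    Returns (adjacency over node keys, node key -> leaf name or None,
    root key).  The structure is a plain graph: sufficient for cutting
    edges into clades.
    """
    adj = _adjacency(tree)
    names = {id(n): n.name for n in tree.root.walk()}

    def farthest(start: int) -> tuple[int, dict[int, float], dict[int, int]]:
        dist = {start: 0.0}
        prev: dict[int, int] = {}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    prev[v] = u
                    stack.append(v)
        leaf_dist = {k: v for k, v in dist.items() if names[k] is not None}
        end = max(leaf_dist, key=lambda k: (leaf_dist[k], names[k]))
        return end, dist, prev

    some_leaf = next(k for k, v in names.items() if v is not None)
    a, _, _ = farthest(some_leaf)
    b, dist, prev = farthest(a)
    # path from b back to a
    path = [b]
    while path[-1] != a:
        path.append(prev[path[-1]])
    half = dist[b] / 2.0
    # walk from b toward a until the midpoint edge
    acc = 0.0
    root_key = ("root",)
    for u, v in zip(path, path[1:]):
        w = next(wt for nbr, wt in adj[u] if nbr == v)
        if acc + w >= half or (u, v) == (path[-2], path[-1]):
            # split edge (u, v): remove it, connect both ends to the root
            adj[u] = [(n, wt) for n, wt in adj[u] if n != v]
            adj[v] = [(n, wt) for n, wt in adj[v] if n != u]
            du = half - acc
            adj[u].append((root_key, du))
            adj[v].append((root_key, w - du))
            adj[root_key] = [(u, du), (v, w - du)]
            names[root_key] = None
            break
        acc += w
    return adj, names, root_key


def clade_partition(
    tree: Tree,
    k: int = 3,
    type_labels: Optional[dict[str, str]] = None,
) -> CladePartition:
    """Cut the midpoint-rooted tree into ``k`` leaf-bearing clades.

    Edges are cut greedily, longest first, internal edges before leaf
    edges, skipping any cut that would strand a component with no
    leaves.  Clades are numbered by their lexicographically smallest
    leaf.  With ``type_labels`` (leaf -> RING type name) the per-clade
    type composition and majority type are reported.
    """
    n_leaves = len(tree.leaf_names)
    if k < 1 or k > n_leaves:
        raise ValueError(f"cannot cut {n_leaves} leaves into {k} clades")
    adj, names, _root = midpoint_root(tree)

    def edge_list():
        seen = set()
        edges = []
        for u in adj:
            for v, w in adj[u]:
                key = frozenset((u, v))
                if key in seen:
                    continue
                seen.add(key)
                is_leaf_edge = names[u] is not None or names[v] is not None
                edges.append((is_leaf_edge, -w, sorted(str(x) for x in key), (u, v, w)))
        edges.sort(key=lambda e: e[:3])
        return [e[3] for e in edges]

    cut: set[frozenset] = set()

    def components() -> list[set]:
        comps = []
        seen: set = set()
        for start in adj:
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, _w in adj[u]:
                    if v in comp or frozenset((u, v)) in cut:
                        continue
                    comp.add(v)
                    stack.append(v)
            seen |= comp
            comps.append(comp)
        return comps

    for u, v, _w in edge_list():
        if len(components()) >= k:
            break
        candidate = frozenset((u, v))
        cut.add(candidate)
        if any(
            all(names[node] is None for node in comp) for comp in components()
        ):
            cut.remove(candidate)  # would strand a leafless component

    comps = components()
    if len(comps) != k:
        raise ValueError(f"could not form {k} leaf-bearing clades")
    leaf_sets = sorted(
        (sorted(names[node] for node in comp if names[node] is not None)
         for comp in comps),
        key=lambda ls: ls[0],
    )
    assignment = {
        leaf: idx for idx, leaves in enumerate(leaf_sets, start=1)
        for leaf in leaves
    }
    type_counts: dict[int, dict[str, int]] = {}
    majority: dict[int, Optional[str]] = {}
    for idx, leaves in enumerate(leaf_sets, start=1):
        counts: dict[str, int] = {}
        if type_labels:
            for leaf in leaves:
                label = type_labels.get(leaf)
                if label is not None:
                    counts[label] = counts.get(label, 0) + 1
        type_counts[idx] = dict(sorted(counts.items()))
        majority[idx] = (
            max(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
            if counts else None
        )
    return CladePartition(assignment, type_counts, majority)
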