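"""Unrooted binary species-tree topologies and rearrangements.

Species trees here are pure topologies (no branch lengths) over a fixed,
ordered taxon set.  Leaves are indexed ``0 .. n-1`` in taxon order; internal
vertices carry arbitrary integer ids ``>= n``.  Two trees are equal iff they
induce the same set of non-trivial bipartitions, with each bipartition named
by the side that does *not* contain leaf 0.

The module provides exhaustive enumeration of all unrooted binary topologies
(by stepwise leaf insertion), uniform random topologies, NNI / SPR / TBR
neighborhoods for hill-climbing searches, and strict / majority-rule
consensus of tree sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Tuple

Split = FrozenSet[int]

#: number of unrooted binary topologies on n labeled leaves: (2n-5)!!
def n_unrooted_topologies(n_taxa: int) -> int:
    if n_taxa < 3:
        return 1
    out = 1
    for k in range(4, n_taxa + 1):
        out *= 2 * k - 5
    return out


class UnrootedTree:
    """An unrooted tree over an ordered taxon set (binary unless built otherwise)."""

    __slots__ = ("taxa", "_adj", "_splits_cache", "_key_cache")

    def __init__(self, taxa: Sequence[str], adj: Dict[int, Tuple[int, ...]]):
        self.taxa = tuple(taxa)
        self._adj = adj
        self._splits_cache: Optional[FrozenSet[Split]] = None
        self._key_cache = None

    # -- construction -----------------------------------------------------

    @classmethod
    def star(
        cls, taxa: Sequence[str], trio: Tuple[int, int, int] = (0, 1, 2)
    ) -> "UnrootedTree":
        """Star tree on three leaves (the seed for stepwise insertion)."""
        n = len(taxa)
        if n < 3:
            raise ValueError("need at least 3 taxa for an unrooted tree")
        hub = n
        a, b, c = trio
        adj = {a: (hub,), b: (hub,), c: (hub,), hub: (a, b, c)}
        return cls(taxa, adj)

    def insert_leaf(self, leaf: int, edge: Tuple[int, int]) -> "UnrootedTree":
        """Return a new tree with ``leaf`` attached in the middle of ``edge``."""
        u, v = edge
        adj = {k: list(vs) for k, vs in self._adj.items()}
        w = max(adj) + 1
        adj[u][adj[u].index(v)] = w
        adj[v][adj[v].index(u)] = w
        adj[w] = [u, v, leaf]
        adj[leaf] = [w]
        return UnrootedTree(self.taxa, {k: tuple(vs) for k, vs in adj.items()})

    @classmethod
    def from_splits(
        cls, taxa: Sequence[str], splits: Iterable[FrozenSet[str]]
    ) -> "UnrootedTree":
        """Build the (possibly non-binary) tree realizing a compatible split set.

        Splits are given as taxon-name sets; each is canonicalized to the side
        not containing ``taxa[0]``.  Incompatible splits raise ``ValueError``.
        """
        taxa = tuple(taxa)
        index = {t: i for i, t in enumerate(taxa)}
        n = len(taxa)
        full = frozenset(range(n))
        clusters = set()
        for s in splits:
            side = frozenset(index[t] for t in s)
            if 0 in side:
                side = full - side
            if not 2 <= len(side) <= n - 2:
                raise ValueError("trivial split supplied")
            clusters.add(side)
        for a in clusters:
            for b in clusters:
                if not (a <= b or b <= a or not (a & b)):
                    raise ValueError("incompatible splits")
        # nest clusters: parent = smallest strict superset (else the root).
        ordered = sorted(clusters, key=len)
        adj: Dict[int, List[int]] = {i: [] for i in range(n)}
        root = n
        adj[root] = []
        node_of: Dict[FrozenSet[int], int] = {}
        nxt = n + 1
        for side in sorted(clusters, key=len, reverse=True):
            parents = [c for c in ordered if side < c]
            parent = node_of[min(parents, key=len)] if parents else root
            node_of[side] = nxt
            adj[nxt] = [parent]
            adj[parent].append(nxt)
            nxt += 1
        for i in range(n):
            containing = [c for c in ordered if i in c]
            parent = node_of[min(containing, key=len)] if containing else root
            adj[i] = [parent]
            adj[parent].append(i)
        return cls(taxa, {k: tuple(vs) for k, vs in adj.items()})

    # -- basic structure ---------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def edges(self) -> List[Tuple[int, int]]:
        out = []
        for u, vs in self._adj.items():
            for v in vs:
                if u < v:
                    out.append((u, v))
        return out

    def internal_edges(self) -> List[Tuple[int, int]]:
        n = self.n_taxa
        return [(u, v) for u, v in self.edges() if u >= n and v >= n]

    def is_binary(self) -> bool:
        n = self.n_taxa
        return all(len(vs) == 3 for u, vs in self._adj.items() if u >= n)

    def _side_leaves(self, u: int, v: int) -> FrozenSet[int]:
        """Leaves reachable from v without crossing edge (u, v)."""
        n = self.n_taxa
        seen = {u, v}
        stack = [v]
        out = []
        while stack:
            x = stack.pop()
            if x < n:
                out.append(x)
            for y in self._adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    def splits(self) -> FrozenSet[Split]:
        """Non-trivial bipartitions, each named by the side not containing leaf 0."""
        if self._splits_cache is None:
            n = self.n_taxa
            full = frozenset(range(n))
            out = set()
            for u, v in self.internal_edges():
                side = self._side_leaves(u, v)
                if 0 in side:
                    side = full - side
                if 2 <= len(side) <= n - 2:
                    out.add(side)
            self._splits_cache = frozenset(out)
        return self._splits_cache

    def taxon_splits(self) -> FrozenSet[FrozenSet[str]]:
        """Splits as taxon-name sets (side not containing the first taxon)."""
        return frozenset(
            frozenset(self.taxa[i] for i in s) for s in self.splits()
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, UnrootedTree)
            and self.taxa == other.taxa
            and self.splits() == other.splits()
        )

    def __hash__(self) -> int:
        if self._key_cache is None:
            self._key_cache = hash((self.taxa, self.splits()))
        return self._key_cache

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"UnrootedTree({self.to_newick()!r})"

    # -- output ------------------------------------------------------------

    def to_newick(self) -> str:
        """Newick string, written with a basal multifurcation (unrooted form)."""

        def sub(x: int, parent: int) -> str:
            if x < self.n_taxa:
                return self.taxa[x]
            kids = [y for y in self._adj[x] if y != parent]
            return "(" + ",".join(sub(y, x) for y in kids) + ")"

        hub = self._adj[0][0]
        parts = [sub(y, hub) for y in self._adj[hub]]
        return "(" + ",".join(parts) + ");"

    # -- rooted traversal for dynamic programming ---------------------------

    def leaves_present(self) -> List[int]:
        """Leaf indices attached to this tree (all of them once fully built)."""
        return sorted(x for x in self._adj if x < self.n_taxa)

    def postorder(self) -> Tuple[int, int, List[Tuple[int, Tuple[int, ...]]]]:
        """Root at the smallest attached leaf; return (root_leaf, hub, postorder).

        ``hub`` is the internal vertex adjacent to the root leaf.  The list
        holds ``(node, children)`` for every internal node in postorder;
        children are node ids (leaves ``< n`` or earlier internal nodes).
        """
        root_leaf = min(x for x in self._adj if x < self.n_taxa)
        hub = self._adj[root_leaf][0]
        order: List[Tuple[int, Tuple[int, ...]]] = []

        def walk(x: int, parent: int) -> None:
            kids = tuple(y for y in self._adj[x] if y != parent)
            for y in kids:
                if y >= self.n_taxa:
                    walk(y, x)
            order.append((x, kids))

        walk(hub, root_leaf)
        return root_leaf, hub, order

    # -- rearrangements ------------------------------------------------------

    def _copy_adj(self) -> Dict[int, List[int]]:
        return {k: list(vs) for k, vs in self._adj.items()}

    def nni_neighbors(self) -> List["UnrootedTree"]:
        """The 2 * (#internal edges) nearest-neighbor-interchange trees."""
        out = []
        for u, v in self.internal_edges():
            a = [x for x in self._adj[u] if x != v]
            b = [x for x in self._adj[v] if x != u]
            for bx in b:
                adj = self._copy_adj()
                # swap subtree a[1] (at u) with subtree bx (at v)
                adj[u][adj[u].index(a[1])] = bx
                adj[v][adj[v].index(bx)] = a[1]
                adj[a[1]][adj[a[1]].index(u)] = v
                adj[bx][adj[bx].index(v)] = u
                out.append(UnrootedTree(self.taxa, {k: tuple(x) for k, x in adj.items()}))
        return out

    def spr_neighbors(self) -> List["UnrootedTree"]:
        """Subtree-prune-regraft neighborhood (deduplicated, self excluded)."""
        seen = {self.splits()}
        out = []
        for u, v in self.edges():
            for a, b in ((u, v), (v, u)):
                # prune the subtree on the b side of edge (a, b)
                if len(self._adj[a]) != 3:
                    continue  # pruning at a leaf's only edge removes the tree
                adj = self._copy_adj()
                x, y = (z for z in adj[a] if z != b)
                # suppress a: connect x - y
                adj[x][adj[x].index(a)] = y
                adj[y][adj[y].index(a)] = x
                adj[a] = []
                # remaining component = everything reachable from x
                comp = set()
                stack = [x]
                while stack:
                    p = stack.pop()
                    if p in comp:
                        continue
                    comp.add(p)
                    stack.extend(adj[p])
                rem_edges = [
                    (p, q) for p in comp for q in adj[p] if p < q and q in comp
                ]
                for p, q in rem_edges:
                    adj2 = {k: list(vs) for k, vs in adj.items()}
                    adj2[a] = [p, q, b]
                    adj2[p][adj2[p].index(q)] = a
                    adj2[q][adj2[q].index(p)] = a
                    t = UnrootedTree(
                        self.taxa, {k: tuple(vs) for k, vs in adj2.items() if vs}
                    )
                    if t.splits() not in seen:
                        seen.add(t.splits())
                        out.append(t)
        return out

    def tbr_neighbors(self) -> List["UnrootedTree"]:
        """Tree-bisection-reconnection neighborhood (deduplicated, self excluded).

        Bisections at external edges reduce to SPR moves of the pruned leaf,
        so the neighborhood is the SPR set plus all internal-edge bisections
        with every re-rooted reattachment of both halves.
        """
        out = self.spr_neighbors()
        seen = {self.splits()} | {t.splits() for t in out}
        for u, v in self.internal_edges():
            adj = self._copy_adj()
            adj[u].remove(v)
            adj[v].remove(u)
            halves = []
            for a in (u, v):
                # suppress the degree-2 cut vertex
                x, y = adj[a]
                adj[x][adj[x].index(a)] = y
                adj[y][adj[y].index(a)] = x
                adj[a] = []
                comp = set()
                stack = [x]
                while stack:
                    p = stack.pop()
                    if p in comp:
                        continue
                    comp.add(p)
                    stack.extend(adj[p])
                comp_edges = [
                    (p, q) for p in comp for q in adj[p] if p < q and q in comp
                ]
                halves.append((a, comp_edges))
            (a, edges_a), (b, edges_b) = halves
            for p, q in edges_a:
                for r, s in edges_b:
                    adj2 = {k: list(vs) for k, vs in adj.items()}
                    adj2[a] = [p, q, b]
                    adj2[p][adj2[p].index(q)] = a
                    adj2[q][adj2[q].index(p)] = a
                    adj2[b] = [r, s, a]
                    adj2[r][adj2[r].index(s)] = b
                    adj2[s][adj2[s].index(r)] = b
                    t = UnrootedTree(
                        self.taxa, {k: tuple(vs) for k, vs in adj2.items() if vs}
                    )
                    if t.splits() not in seen:
                        seen.add(t.splits())
                        out.append(t)
        return out


# -- enumeration and random generation --------------------------------------

def enumerate_topologies(taxa: Sequence[str]) -> Iterator[UnrootedTree]:
    """Yield every unrooted binary topology on ``taxa`` exactly once.

    Stepwise insertion: taxon k goes into each of the 2k-5 edges of every
    (k-1)-taxon tree, which enumerates each topology exactly once.
    """
    taxa = tuple(taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")

    def grow(tree: UnrootedTree, k: int) -> Iterator[UnrootedTree]:
        if k == n:
            yield tree
            return
        for edge in tree.edges():
            yield from grow(tree.insert_leaf(k, edge), k + 1)

    yield from grow(UnrootedTree.star(taxa), 3)


def random_topology(taxa: Sequence[str], rng) -> UnrootedTree:
    """Uniform random unrooted binary topology (uniform edge insertion)."""
    taxa = tuple(taxa)
    tree = UnrootedTree.star(taxa)
    for k in range(3, len(taxa)):
        edges = tree.edges()
        tree = tree.insert_leaf(k, edges[int(rng.integers(len(edges)))])
    return tree


# -- consensus ----------------------------------------------------------------

def consensus(trees: Sequence[UnrootedTree], kind: str = "strict") -> UnrootedTree:
    """Strict (all trees) or majority-rule (>50%) consensus of a tree set."""
    if not trees:
        raise ValueError("consensus of an empty tree list")
    taxa = trees[0].taxa
    for t in trees:
        if t.taxa != taxa:
            raise ValueError("consensus requires a common taxon set")
    counts: Dict[Split, int] = {}
    for t in trees:
        for s in t.splits():
            counts[s] = counts.get(s, 0) + 1
    m = len(trees)
    if kind == "strict":
        keep = [s for s, c in counts.items() if c == m]
    elif kind == "majority":
        keep = [s for s, c in counts.items() if c * 2 > m]
    else:
        raise ValueError(f"unknown consensus kind: {kind!r}")
    named = [frozenset(taxa[i] for i in s) for s in keep]
    return UnrootedTree.from_splits(taxa, named)
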