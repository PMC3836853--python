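"""Seeded synthetic gene-tree sets with known ground truth.

The generator emulates the statistical structure a genes-as-characters
analysis faces: a known species tree; mostly concordant gene trees; a
controlled minority whose topology conflicts with the species tree (modelled
by random NNI perturbation — the method consumes arbitrary gene trees and
assumes no coalescent model, so conflict intensity is dialled directly);
multiplicative lognormal branch-length noise between genes; and a fraction
of artifact genes carrying one enormously long branch, mimicking alignment,
orthology or assembly errors.  Truth labels (concordant / discordant /
artifact) accompany every gene, and a companion generator plants category
enrichments against hypothesis labels for testing the association scan.

All outputs are reproducible bit-for-bit from (config, seed): one root RNG
per run, with per-gene substreams derived from the gene index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .topology import UnrootedTree, random_topology
from .treeio import GeneTree, TaxonSet, parse_newick

CONCORDANT = "concordant"
DISCORDANT = "discordant"
ARTIFACT = "artifact"

#: default taxon names: a 7-letter panel (extended alphabetically if needed)
def default_taxa(n: int) -> Tuple[str, ...]:
    return tuple(f"T{i+1}" for i in range(n))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic gene-tree set.

    Defaults describe a 7-taxon panel of 200 genes with substantial
    gene-tree conflict (30% of genes perturbed by one NNI), moderate
    rate variation between genes, and 18% artifact genes each carrying one
    branch ten times the tree diameter.
    """

    n_taxa: int = 7
    n_genes: int = 200
    discordance: float = 0.30
    topo_moves: int = 1
    length_noise_sd: float = 0.30
    artifact_fraction: float = 0.18
    artifact_scale: float = 10.0
    branch_length_mean: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("discordance", "artifact_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.artifact_fraction > 0 and self.artifact_scale < 10:
            raise ValueError("artifact_scale must be >= 10")


# -- internal mutable tree with branch lengths ---------------------------------


class _LengthTree:
    """Unrooted tree with branch lengths; supports NNI and newick output."""

    def __init__(self, taxa, adj, lengths):
        self.taxa = tuple(taxa)
        self.adj: Dict[int, List[int]] = adj        # node -> neighbor list
        self.lengths: Dict[frozenset, float] = lengths  # {u,v} -> length

    @classmethod
    def from_topology(cls, topo: UnrootedTree, lengths) -> "_LengthTree":
        adj = {k: list(v) for k, v in topo._adj.items()}
        return cls(topo.taxa, adj, dict(lengths))

    def copy(self) -> "_LengthTree":
        return _LengthTree(
            self.taxa, {k: list(v) for k, v in self.adj.items()}, dict(self.lengths)
        )

    def edges(self) -> List[Tuple[int, int]]:
        return [
            (u, v) for u, vs in self.adj.items() for v in vs if u < v
        ]

    def internal_edges(self) -> List[Tuple[int, int]]:
        n = len(self.taxa)
        return [(u, v) for u, v in self.edges() if u >= n and v >= n]

    def nni(self, edge: Tuple[int, int], which: int) -> None:
        """In-place nearest-neighbor interchange across an internal edge."""
        u, v = edge
        a = [x for x in self.adj[u] if x != v][1]
        b = [x for x in self.adj[v] if x != u][which]
        self.adj[u][self.adj[u].index(a)] = b
        self.adj[v][self.adj[v].index(b)] = a
        self.adj[a][self.adj[a].index(u)] = v
        self.adj[b][self.adj[b].index(v)] = u
        la = self.lengths.pop(frozenset((u, a)))
        lb = self.lengths.pop(frozenset((v, b)))
        self.lengths[frozenset((v, a))] = la
        self.lengths[frozenset((u, b))] = lb

    def diameter(self) -> float:
        """Maximum tip-to-tip path length."""
        n = len(self.taxa)
        best = 0.0
        for leaf in range(n):
            if leaf not in self.adj:
                continue
            dist = {leaf: 0.0}
            stack = [leaf]
            while stack:
                x = stack.pop()
                for y in self.adj[x]:
                    if y not in dist:
                        dist[y] = dist[x] + self.lengths[frozenset((x, y))]
                        stack.append(y)
            best = max(best, max(d for k, d in dist.items() if k < n))
        return best

    def to_newick(self) -> str:
        def sub(x: int, parent: int) -> str:
            L = self.lengths[frozenset((x, parent))]
            if x < len(self.taxa):
                return f"{self.taxa[x]}:{L:.10g}"
            kids = [y for y in self.adj[x] if y != parent]
            return "(" + ",".join(sub(y, x) for y in kids) + f"):{L:.10g}"

        hub = self.adj[0][0]
        parts = [sub(y, hub) for y in self.adj[hub]]
        return "(" + ",".join(parts) + ");"


def _lengthtree_from_genetree(gt: GeneTree) -> _LengthTree:
    """Convert a dendropy-backed tree to the internal unrooted form."""
    taxa = tuple(sorted(gt.tip_labels()))
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    adj: Dict[int, List[int]] = {}
    lengths: Dict[frozenset, float] = {}
    ids: Dict[int, int] = {}
    nxt = [n]

    def node_id(node) -> int:
        key = id(node)
        if key not in ids:
            if node.is_leaf():
                ids[key] = index[node.taxon.label]
            else:
                ids[key] = nxt[0]
                nxt[0] += 1
        return ids[key]

    for node in gt.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        u = node_id(node.parent_node)
        v = node_id(node)
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
        lengths[frozenset((u, v))] = node.edge.length or 0.0
    # suppress a degree-2 old root: merge its two incident edges
    for x in list(adj):
        if x >= n and len(adj[x]) == 2:
            p, q = adj[x]
            L = lengths.pop(frozenset((x, p))) + lengths.pop(frozenset((x, q)))
            adj[p][adj[p].index(x)] = q
            adj[q][adj[q].index(x)] = p
            lengths[frozenset((p, q))] = L
            del adj[x]
    return _LengthTree(taxa, adj, lengths)


# -- generators -----------------------------------------------------------------


def simulate_species_tree(
    n_taxa: int, seed: int, branch_length_mean: float = 0.1,
    taxa: Optional[Sequence[str]] = None,
) -> GeneTree:
    """Random species tree: uniform topology, Exp(mean) branch lengths."""
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4")
    rng = np.random.default_rng(seed)
    names = tuple(taxa) if taxa is not None else default_taxa(n_taxa)
    topo = random_topology(names, rng)
    lengths = {
        frozenset(e): float(rng.exponential(branch_length_mean))
        for e in topo.edges()
    }
    lt = _LengthTree.from_topology(topo, lengths)
    return parse_newick(lt.to_newick(), gene_id="species_tree")


def simulate_gene_trees(
    species_tree: GeneTree, cfg: SimulationConfig
) -> Tuple[List[GeneTree], List[str]]:
    """Per-gene trees around a species tree, with truth labels.

    Per gene: with probability ``discordance`` apply ``topo_moves`` random
    NNI moves; multiply every branch by a lognormal(0, length_noise_sd)
    factor; artifact genes (probability ``artifact_fraction``, decided
    independently) then get one uniformly chosen branch inflated to
    ``artifact_scale`` x the tree diameter.
    """
    base = _lengthtree_from_genetree(species_tree)
    root = np.random.default_rng(cfg.seed)
    # per-gene substreams keyed by gene index, independent of generation order
    gene_seeds = root.integers(2**31 - 1, size=cfg.n_genes)
    trees: List[GeneTree] = []
    labels: List[str] = []
    for g in range(cfg.n_genes):
        rng = np.random.default_rng(gene_seeds[g])
        lt = base.copy()
        discordant = rng.random() < cfg.discordance
        artifact = rng.random() < cfg.artifact_fraction
        if discordant:
            for _ in range(cfg.topo_moves):
                ies = lt.internal_edges()
                lt.nni(ies[int(rng.integers(len(ies)))], int(rng.integers(2)))
        if cfg.length_noise_sd > 0:
            for e in list(lt.lengths):
                lt.lengths[e] *= float(
                    rng.lognormal(0.0, cfg.length_noise_sd)
                )
        if artifact:
            edges = lt.edges()
            target = edges[int(rng.integers(len(edges)))]
            lt.lengths[frozenset(target)] = cfg.artifact_scale * lt.diameter()
        trees.append(parse_newick(lt.to_newick(), gene_id=f"g{g+1:06d}"))
        labels.append(
            ARTIFACT if artifact else (DISCORDANT if discordant else CONCORDANT)
        )
    return trees, labels


def plant_enrichment(
    labels: Mapping[str, str],
    n_categories: int,
    enriched: Sequence[Tuple[str, str, float]],
    seed: int,
    baseline: float = 0.1,
) -> Dict[str, Set[str]]:
    """Random category memberships with planted odds ratios.

    Baseline membership probability is ``baseline`` for every
    (gene, category); for an enriched (category, hypothesis, odds_ratio)
    entry, genes carrying that hypothesis label get membership odds
    multiplied by the odds ratio.  Categories are named ``cat0001`` ...;
    enriched entries may name any of them.
    """
    for _, _, odds in enriched:
        if odds <= 0:
            raise ValueError("odds ratios must be positive")
    cats = [f"cat{i+1:04d}" for i in range(n_categories)]
    boost = {(c, h): o for c, h, o in enriched}
    unknown = {c for c, _, _ in enriched} - set(cats)
    if unknown:
        raise ValueError(f"enriched categories not among generated ones: {unknown}")
    rng = np.random.default_rng(seed)
    base_odds = baseline / (1.0 - baseline)
    genes = sorted(labels)
    gene_labels = np.array([labels[g] for g in genes])
    out: Dict[str, Set[str]] = {g: set() for g in genes}
    for cat in cats:
        p = np.full(len(genes), baseline)
        for (c, h), odds_ratio in boost.items():
            if c == cat:
                odds = base_odds * odds_ratio
                p[gene_labels == h] = odds / (1.0 + odds)
        for i in np.flatnonzero(rng.random(len(genes)) < p):
            out[genes[i]].add(cat)
    return out


def write_truth_labels(
    trees: Sequence[GeneTree], labels: Sequence[str], path
) -> None:
    from pathlib import Path

    lines = ["gene_id\tlabel"]
    lines += [f"{t.gene_id}\t{l}" for t, l in zip(trees, labels)]
    Path(path).write_text("\n".join(lines) + "\n")
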