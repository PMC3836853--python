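"""Generalized (Sankoff) parsimony over step-matrix characters.

The length of a species tree under one gene's character is the minimum, over
assignments of the observed haplotype states to internal nodes, of the sum
of step-matrix costs along the tree's edges.  It is computed by the Sankoff
bottom-up dynamic programme on an arbitrary rooting (valid because the cost
matrices are symmetric, so the score is root-invariant); taxa missing from a
gene enter as all-zero leaf cost vectors, i.e. standard missing data.
Internal nodes range only over the character's observed states, matching the
step-matrix (USERTYPE) semantics of classical parsimony software.

On top of the scorer sit an exhaustive search over all unrooted binary
topologies (practical to 9 taxa), a seeded heuristic search (random-order
stepwise addition plus NNI/SPR/TBR hill climbing), and a non-parametric
bootstrap that resamples genes with replacement.

For speed, characters that cover the full taxon set are scored in one
vectorized dynamic programme across all genes simultaneously; characters
with missing taxa fall back to a per-character programme.  A brute-force
enumerator over internal-state assignments serves as an independent oracle
for the dynamic programme on small trees.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .stepmatrix import CharacterMatrix, StepMatrixCharacter
from .topology import (
    UnrootedTree,
    consensus,  # noqa: F401  (re-exported: summarizes ties and replicates)
    enumerate_topologies,
    n_unrooted_topologies,
)
from .treeio import GeneTree, TaxonSet, bipartitions

SCORE_TOL = 1e-9

#: exhaustive search is limited to 9 taxa (135,135 unrooted topologies)
MAX_EXHAUSTIVE_TAXA = 9


@dataclass
class ParsimonyResult:
    """Outcome of a tree search: best score, all tied best trees, #scored."""

    score: float
    best_trees: List[UnrootedTree]
    evaluated: int

    def strict_consensus(self) -> UnrootedTree:
        return consensus(self.best_trees, "strict")


@dataclass
class SearchConfig:
    """How bootstrap replicates search tree space."""

    method: str = "auto"  # auto | exhaustive | heuristic
    n_starts: int = 10
    swap: str = "SPR"


@dataclass
class BootstrapSupport:
    """Per-split support percentages from a gene (character) bootstrap."""

    replicates: int
    clade_support: Dict[FrozenSet[str], float]
    seed: int

    def support(self, taxa: Sequence[str]) -> float:
        return self.clade_support.get(frozenset(taxa), 0.0)


# -- single-character scoring ---------------------------------------------------


def character_length(tree: UnrootedTree, ch: StepMatrixCharacter) -> float:
    """Minimum transformation cost of one character on one species tree."""
    k = ch.n_states
    if k == 0:
        warnings.warn(f"gene {ch.gene_id}: empty state set scored as 0")
        return 0.0
    tindex = {t: i for i, t in enumerate(tree.taxa)}
    try:
        state_of_leaf = {tindex[t]: s for s, t in enumerate(ch.states)}
    except KeyError as exc:
        raise ValueError(
            f"gene {ch.gene_id}: state taxon {exc.args[0]!r} not on species tree"
        ) from None
    present = [l for l in tree.leaves_present() if l in state_of_leaf]
    if len(present) < 2:
        return 0.0
    cost = ch.cost
    root_leaf, hub, order = tree.postorder()
    vec: Dict[int, np.ndarray] = {}
    for node, kids in order:
        v = np.zeros(k)
        for c in kids:
            if c < tree.n_taxa:
                s = state_of_leaf.get(c)
                if s is not None:
                    v = v + cost[:, s]
            else:
                v = v + (cost + vec.pop(c)[None, :]).min(axis=1)
        vec[node] = v
    top = vec[hub]
    s0 = state_of_leaf.get(root_leaf)
    if s0 is None:
        return float(top.min())
    return float((top + cost[:, s0]).min())


def brute_force_length(tree: UnrootedTree, ch: StepMatrixCharacter) -> float:
    """Exact character length by full enumeration of internal-state assignments.

    Independent oracle for :func:`character_length`; refuses more than 7 taxa
    (the assignment space grows as ``k**(n-2)``).
    """
    n = tree.n_taxa
    if n > 7:
        raise ValueError("brute force enumeration is limited to 7 taxa")
    k = ch.n_states
    if k == 0:
        return 0.0
    tindex = {t: i for i, t in enumerate(tree.taxa)}
    state_of_leaf = {tindex[t]: s for s, t in enumerate(ch.states)}
    if len([l for l in tree.leaves_present() if l in state_of_leaf]) < 2:
        return 0.0
    internals = sorted(x for x in tree._adj if x >= n)
    pos = {x: i for i, x in enumerate(internals)}
    assign = np.array(
        list(itertools.product(range(k), repeat=len(internals))), dtype=np.intp
    )
    total = np.zeros(len(assign))
    for u, v in tree.edges():
        if u < n and v < n:  # only possible in degenerate 2-leaf paths
            su, sv = state_of_leaf.get(u), state_of_leaf.get(v)
            if su is not None and sv is not None:
                total += ch.cost[su, sv]
        elif u < n or v < n:
            leaf, internal = (u, v) if u < n else (v, u)
            s = state_of_leaf.get(leaf)
            if s is not None:
                total += ch.cost[assign[:, pos[internal]], s]
        else:
            total += ch.cost[assign[:, pos[u]], assign[:, pos[v]]]
    return float(total.min())


# -- whole-matrix scoring -------------------------------------------------------


class MatrixScorer:
    """Scores topologies against a full character matrix.

    Characters covering every taxon are stacked into one (genes, n, n) cost
    tensor and scored in a single vectorized Sankoff pass per topology.
    """

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        self.taxa = tuple(matrix.taxa.names)
        self.weights = matrix.weights
        self.G = len(matrix.characters)
        full_idx, generic_idx, costs = [], [], []
        for i, ch in enumerate(matrix.characters):
            if ch.states == self.taxa and not ch.missing:
                full_idx.append(i)
                costs.append(ch.cost)
            else:
                generic_idx.append(i)
        self._full_idx = np.array(full_idx, dtype=np.intp)
        self._generic_idx = generic_idx
        self._C = np.stack(costs) if costs else None

    def _check(self, tree: UnrootedTree) -> None:
        if tree.taxa != self.taxa:
            raise ValueError("species tree taxa do not match the character matrix")

    def per_character(self, tree: UnrootedTree) -> np.ndarray:
        """Unweighted character lengths for every gene on one topology."""
        self._check(tree)
        out = np.zeros(self.G)
        if self._C is not None:
            C = self._C
            root_leaf, hub, order = tree.postorder()
            vec: Dict[int, np.ndarray] = {}
            for node, kids in order:
                v: np.ndarray = 0.0
                for c in kids:
                    if c < tree.n_taxa:
                        v = v + C[:, :, c]
                    else:
                        v = v + (C + vec.pop(c)[:, None, :]).min(axis=2)
                vec[node] = v
            out[self._full_idx] = (vec[hub] + C[:, :, root_leaf]).min(axis=1)
        for i in self._generic_idx:
            out[i] = character_length(tree, self.matrix.characters[i])
        return out

    def score(self, tree: UnrootedTree) -> float:
        return float(self.per_character(tree) @ self.weights)


def tree_length(tree: UnrootedTree, matrix: CharacterMatrix) -> float:
    """Weighted sum of character lengths (additive over characters)."""
    return MatrixScorer(matrix).score(tree)


# -- searches -------------------------------------------------------------------


def _tied_min(
    scored: List[Tuple[float, UnrootedTree]]
) -> Tuple[float, List[UnrootedTree]]:
    best = min(s for s, _ in scored)
    seen = set()
    ties = []
    for s, t in scored:
        if s <= best + SCORE_TOL and t.splits() not in seen:
            seen.add(t.splits())
            ties.append(t)
    return best, ties


def exhaustive_search(
    matrix: CharacterMatrix, scorer: Optional[MatrixScorer] = None
) -> ParsimonyResult:
    """Score every unrooted binary topology; return the global optimum set."""
    n = len(matrix.taxa)
    if n > MAX_EXHAUSTIVE_TAXA:
        raise ValueError(
            f"{n} taxa gives {n_unrooted_topologies(n)} topologies; "
            "use heuristic_search instead"
        )
    scorer = scorer or MatrixScorer(matrix)
    best_score = np.inf
    best: List[UnrootedTree] = []
    evaluated = 0
    for tree in enumerate_topologies(matrix.taxa.names):
        s = scorer.score(tree)
        evaluated += 1
        if s < best_score - SCORE_TOL:
            best_score, best = s, [tree]
        elif s <= best_score + SCORE_TOL:
            best.append(tree)
    return ParsimonyResult(float(best_score), best, evaluated)


_NEIGHBORS = {
    "NNI": UnrootedTree.nni_neighbors,
    "SPR": UnrootedTree.spr_neighbors,
    "TBR": UnrootedTree.tbr_neighbors,
}


def heuristic_search(
    matrix: CharacterMatrix,
    n_starts: int = 10,
    swap: str = "SPR",
    seed: int = 0,
    scorer: Optional[MatrixScorer] = None,
) -> ParsimonyResult:
    """Random-addition stepwise build plus steepest-descent branch swapping.

    Each start shuffles the taxon order (seeded), builds a tree by greedy
    stepwise insertion, then repeatedly moves to the best-scoring neighbor
    under the chosen swap (NNI/SPR/TBR) until no neighbor improves.  Results
    are deterministic given the seed.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if swap not in _NEIGHBORS:
        raise ValueError(f"unknown swap {swap!r}; choose from {sorted(_NEIGHBORS)}")
    neighbors = _NEIGHBORS[swap]
    scorer = scorer or MatrixScorer(matrix)
    taxa = matrix.taxa.names
    n = len(taxa)
    rng = np.random.default_rng(seed)
    evaluated = 0
    finals: List[Tuple[float, UnrootedTree]] = []
    for _ in range(n_starts):
        order = [int(x) for x in rng.permutation(n)]
        tree = UnrootedTree.star(taxa, trio=tuple(order[:3]))
        for leaf in order[3:]:
            cands = [tree.insert_leaf(leaf, e) for e in tree.edges()]
            scores = [scorer.score(c) for c in cands]
            evaluated += len(cands)
            tree = cands[int(np.argmin(scores))]
        cur = scorer.score(tree)
        evaluated += 1
        while True:
            nbs = neighbors(tree)
            if not nbs:
                break
            scores = [scorer.score(t) for t in nbs]
            evaluated += len(nbs)
            i = int(np.argmin(scores))
            if scores[i] < cur - SCORE_TOL:
                tree, cur = nbs[i], scores[i]
            else:
                break
        finals.append((cur, tree))
    score, best = _tied_min(finals)
    return ParsimonyResult(score, best, evaluated)


# -- bootstrap ------------------------------------------------------------------


def _splits_of_ties(trees: List[UnrootedTree]) -> Dict[FrozenSet[str], float]:
    """Fractional split weights: each of k tied trees contributes 1/k."""
    out: Dict[FrozenSet[str], float] = {}
    w = 1.0 / len(trees)
    for t in trees:
        for s in t.taxon_splits():
            out[s] = out.get(s, 0.0) + w
    return out


def bootstrap(
    matrix: CharacterMatrix,
    replicates: int = 1000,
    seed: int = 0,
    search: Optional[SearchConfig] = None,
) -> BootstrapSupport:
    """Non-parametric bootstrap over genes (characters).

    Each replicate resamples the genes with replacement to the original
    count, re-runs the tree search, and records the splits of the
    replicate's best tree(s); k tied trees contribute 1/k each.  Support is
    the percentage of replicates containing each split.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    search = search or SearchConfig()
    n = len(matrix.taxa)
    method = search.method
    if method == "auto":
        method = "exhaustive" if n <= MAX_EXHAUSTIVE_TAXA else "heuristic"
    G = len(matrix.characters)
    rng = np.random.default_rng(seed)
    accum: Dict[FrozenSet[str], float] = {}

    if method == "exhaustive":
        # Per-character lengths for every topology are computed once; each
        # replicate is then a weighted sum + argmin over topologies.
        scorer = MatrixScorer(matrix)
        topos = list(enumerate_topologies(matrix.taxa.names))
        L = np.stack([scorer.per_character(t) for t in topos])  # (T, G)
        topo_splits = [t.taxon_splits() for t in topos]
        for _ in range(replicates):
            counts = rng.multinomial(G, np.full(G, 1.0 / G))
            scores = L @ (counts * matrix.weights)
            best = scores.min()
            tied = np.flatnonzero(scores <= best + SCORE_TOL)
            w = 1.0 / len(tied)
            for i in tied:
                for s in topo_splits[i]:
                    accum[s] = accum.get(s, 0.0) + w
    elif method == "heuristic":
        for _ in range(replicates):
            counts = rng.multinomial(G, np.full(G, 1.0 / G))
            keep = np.flatnonzero(counts)
            sub = CharacterMatrix(
                matrix.taxa,
                [matrix.characters[i] for i in keep],
                weights=counts[keep] * matrix.weights[keep],
            )
            rep_seed = int(rng.integers(2**31 - 1))
            res = heuristic_search(
                sub, n_starts=search.n_starts, swap=search.swap, seed=rep_seed
            )
            for s, w in _splits_of_ties(res.best_trees).items():
                accum[s] = accum.get(s, 0.0) + w
    else:
        raise ValueError(f"unknown search method {search.method!r}")

    support = {s: 100.0 * w / replicates for s, w in accum.items()}
    return BootstrapSupport(replicates, support, seed)


# -- interop --------------------------------------------------------------------


def species_tree_from_genetree(gt: GeneTree, taxa: TaxonSet) -> UnrootedTree:
    """Topology-only view of a tree (e.g. a simulated species tree)."""
    if gt.tip_set() != set(taxa.names):
        raise ValueError("tree tips do not match the taxon set")
    ref = taxa.names[0]
    return UnrootedTree.from_splits(taxa.names, bipartitions(gt, reference=ref))
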