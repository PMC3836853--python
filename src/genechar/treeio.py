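"""Gene-tree input, validation, rooting, filtering and patristic distances.

Gene trees arrive as Newick strings (one per gene), typically maximum
likelihood estimates with branch lengths in substitutions per site.  This
module wraps :mod:`dendropy` for parsing, re-rooting and path-length
computation, and adds the quality filter used upstream of the
genes-as-characters pipeline: gene trees whose longest branch exceeds a
threshold (default 1.5) are set aside as likely alignment, orthology or
assembly artifacts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_LONG_BRANCH_THRESHOLD = 1.5


@dataclass(frozen=True)
class TaxonSet:
    """Ordered registry of taxon names with an optional outgroup."""

    names: Tuple[str, ...]
    outgroup: Optional[str] = None

    def __post_init__(self):
        if not self.names:
            raise ValueError("TaxonSet requires at least one taxon")
        if len(set(self.names)) != len(self.names):
            raise ValueError("taxon names must be unique")
        if self.outgroup is not None and self.outgroup not in self.names:
            raise ValueError(f"outgroup {self.outgroup!r} is not in the taxon set")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric patristic (path-length) distance matrix over tree tips."""

    labels: Tuple[str, ...]
    d: np.ndarray

    def __getitem__(self, pair: Tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])

    @property
    def max(self) -> float:
        return float(self.d.max())


class GeneTree:
    """One gene's estimated tree (rooted or unrooted, polytomies allowed)."""

    def __init__(self, gene_id: str, tree: dendropy.Tree):
        self.gene_id = gene_id
        self.tree = tree
        self._validate()

    def _validate(self) -> None:
        labels = self.tip_labels()
        if len(labels) < 2:
            raise ValueError(f"gene {self.gene_id}: tree must have >= 2 tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(
                f"gene {self.gene_id}: duplicate tip label(s): {', '.join(dupes)}"
            )
        defaulted = False
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None:
                edge.length = 0.0
                defaulted = True
            elif edge.length < 0:
                raise ValueError(
                    f"gene {self.gene_id}: negative branch length {edge.length}"
                )
        if defaulted:
            warnings.warn(
                f"gene {self.gene_id}: missing branch length(s) defaulted to 0",
                stacklevel=2,
            )

    # -- basic accessors ----------------------------------------------------

    def tip_labels(self) -> List[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def tip_set(self) -> FrozenSet[str]:
        return frozenset(self.tip_labels())

    def total_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self.tree.preorder_edge_iter()
            if e.tail_node is not None
        )

    def clone(self) -> "GeneTree":
        return GeneTree(self.gene_id, self.tree.clone(depth=1))

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneTree({self.gene_id!r}, {len(self.tip_labels())} tips)"


# -- parsing ------------------------------------------------------------------

def parse_newick(text: str, gene_id: str = "gene") -> GeneTree:
    """Parse one Newick tree; polytomies are preserved, lengths default to 0."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        offset = getattr(exc, "col_num", None)
        where = f" at character {offset}" if offset is not None else ""
        raise ValueError(f"gene {gene_id}: malformed Newick{where}: {exc}") from exc
    return GeneTree(gene_id, tree)


def read_trees(path) -> List[GeneTree]:
    """Read gene trees from a one-tree-per-line file or a directory of .nwk files.

    For a file, gene ids are ``g000001`` ... by line order unless a sidecar
    ``<file>.ids.tsv`` (line_number<TAB>gene_id) exists; for a directory, the
    gene id is the file stem.
    """
    path = Path(path)
    trees: List[GeneTree] = []
    if path.is_dir():
        for f in sorted(path.glob("*.nwk")):
            trees.append(parse_newick(f.read_text(), gene_id=f.stem))
        if not trees:
            raise ValueError(f"no .nwk files found in {path}")
        return trees
    ids: Dict[int, str] = {}
    sidecar = path.with_suffix(path.suffix + ".ids.tsv")
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            if line.strip():
                num, gid = line.split("\t")
                ids[int(num)] = gid
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    for i, line in enumerate(lines, start=1):
        gid = ids.get(i, f"g{i:06d}")
        trees.append(parse_newick(line, gene_id=gid))
    return trees


def write_trees(trees: Iterable[GeneTree], path) -> None:
    Path(path).write_text("".join(t.to_newick() + "\n" for t in trees))


# -- branch-length filter ------------------------------------------------------

def max_branch_length(tree: GeneTree) -> float:
    """Maximum single edge length of the tree as represented."""
    return max(
        (e.length or 0.0)
        for e in tree.tree.preorder_edge_iter()
        if e.tail_node is not None
    )


def filter_long_branch(
    trees: Sequence[GeneTree], threshold: float = DEFAULT_LONG_BRANCH_THRESHOLD
) -> Tuple[List[GeneTree], List[GeneTree]]:
    """Split trees into (kept, removed) by the long-branch rule.

    A tree is removed iff its longest branch is *strictly* greater than the
    threshold; a longest branch exactly at the threshold is kept.  Order is
    preserved on both sides.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    kept, removed = [], []
    for t in trees:
        (removed if max_branch_length(t) > threshold else kept).append(t)
    logger.info(
        "long-branch filter (> %.3g): kept %d, removed %d of %d gene trees",
        threshold, len(kept), len(removed), len(trees),
    )
    return kept, removed


def removal_report(
    trees: Sequence[GeneTree], threshold: float = DEFAULT_LONG_BRANCH_THRESHOLD
) -> str:
    """TSV report (gene_id, max_branch, removed_flag) for the filter run."""
    lines = ["gene_id\tmax_branch\tremoved"]
    for t in trees:
        mb = max_branch_length(t)
        lines.append(f"{t.gene_id}\t{mb:.6g}\t{int(mb > threshold)}")
    return "\n".join(lines) + "\n"


# -- distances, rooting, splits ------------------------------------------------

def patristic_matrix(tree: GeneTree) -> DistanceMatrix:
    """Pairwise path-length (patristic) distances between all tips.

    Independent of root placement: the distance is the sum of branch lengths
    along the unique tip-to-tip path.
    """
    labels = sorted(tree.tip_labels())
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(tuple(labels), d)


def root_on_outgroup(tree: GeneTree, outgroup: str) -> GeneTree:
    """Root a copy of the tree on the edge subtending the outgroup tip.

    The outgroup's branch is split at its midpoint; any degree-2 vertex left
    behind by the old root is suppressed (its two edges merged), so total
    tree length is conserved.
    """
    if outgroup not in tree.tip_set():
        raise ValueError(
            f"gene {tree.gene_id}: outgroup {outgroup!r} is not a tip of the tree"
        )
    t = tree.tree.clone(depth=1)
    leaf = next(
        l for l in t.leaf_node_iter() if l.taxon.label == outgroup
    )
    length = leaf.edge.length or 0.0
    t.reroot_at_edge(leaf.edge, length1=length / 2.0, length2=length / 2.0)
    t.suppress_unifurcations()
    t.is_rooted = True
    return GeneTree(tree.gene_id, t)


def clusters(tree: GeneTree) -> FrozenSet[FrozenSet[str]]:
    """Non-trivial clusters (leaf sets of internal nodes) of a rooted tree."""
    tips = tree.tip_set()
    out = set()
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf() or node is tree.tree.seed_node:
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        if 2 <= len(clade) < len(tips):
            out.add(clade)
    return frozenset(out)


def bipartitions(
    tree: GeneTree, reference: Optional[str] = None
) -> FrozenSet[FrozenSet[str]]:
    """Non-trivial splits of the (unrooted) tree as taxon-name sets.

    Each split is canonicalized to the side *not* containing the reference
    taxon (default: lexicographically first tip).  Polytomies contribute only
    the splits actually present.
    """
    tips = tree.tip_set()
    if reference is None:
        reference = min(tips)
    elif reference not in tips:
        raise ValueError(f"reference taxon {reference!r} is not a tip")
    out = set()
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf() or node is tree.tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if reference in side:
            side = tips - side
        if 2 <= len(side) <= len(tips) - 2:
            out.add(side)
    return frozenset(out)
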