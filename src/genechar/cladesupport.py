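"""Gene-support tallies: which clade hypothesis does each gene tree contain?

The simple count method: define each competing hypothesis by one or more
diagnostic clades (e.g. the archosaur hypothesis for amniotes is the clade
grouping the turtle with birds), classify every gene tree by the first
hypothesis whose clades it contains, and tally.  The hypothesis supported by
the most genes is preferred.  Queries may be evaluated as clusters on the
outgroup-rooted tree or as unrooted splits; an unresolved polytomy never
certifies a resolved sub-clade, because only clades actually present count.

A hypothesis may carry nested sub-queries (progressively larger enclosing
topologies); their counts are tallied alongside and are necessarily monotone
non-increasing as the queries grow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from .treeio import GeneTree, bipartitions, clusters, root_on_outgroup

logger = logging.getLogger(__name__)

OTHER = "other"


@dataclass(frozen=True)
class CladeQuery:
    """A named clade hypothesis: one or more jointly required taxon clusters."""

    name: str
    clades: Tuple[FrozenSet[str], ...]
    rooted: bool = True
    nested: Tuple["CladeQuery", ...] = ()

    def __post_init__(self):
        if not self.clades:
            raise ValueError(f"query {self.name!r}: at least one clade required")
        for clade in self.clades:
            if len(clade) < 2:
                raise ValueError(f"query {self.name!r}: clades need >= 2 taxa")

    def taxa(self) -> FrozenSet[str]:
        out: FrozenSet[str] = frozenset()
        for clade in self.clades:
            out |= clade
        return out


@dataclass
class SupportTally:
    """Gene counts per hypothesis (plus nested sub-queries) and the remainder."""

    total_genes: int
    counts: Dict[str, int]
    nested_counts: Dict[str, int]
    other: int

    @property
    def percentages(self) -> Dict[str, float]:
        if self.total_genes == 0:
            return {k: 0.0 for k in self.counts}
        return {k: 100.0 * v / self.total_genes for k, v in self.counts.items()}

    def display_percentages(self) -> Dict[str, int]:
        """Whole-percent rounding used for published-style tables."""
        return {k: round(v) for k, v in self.percentages.items()}

    def to_tsv(self) -> str:
        lines = ["hypothesis\tcount\tpercent"]
        pct = self.display_percentages()
        for name, c in self.counts.items():
            lines.append(f"{name}\t{c}\t{pct[name]}")
        for name, c in self.nested_counts.items():
            lines.append(f"{name}\t{c}\t")
        lines.append(
            f"{OTHER}\t{self.other}\t"
            f"{round(100.0 * self.other / self.total_genes) if self.total_genes else 0}"
        )
        return "\n".join(lines) + "\n"


def clade_present(
    tree: GeneTree, query: CladeQuery, outgroup: Optional[str] = None
) -> bool:
    """True iff every clade of the query appears on the gene tree.

    Rooted queries test clades as clusters of the outgroup-rooted tree;
    unrooted queries test them as exact splits.  Genes lacking a query taxon
    do not support the query (logged).
    """
    if query.rooted and outgroup is None:
        raise ValueError(f"query {query.name!r} is rooted but no outgroup was given")
    tips = tree.tip_set()
    missing = query.taxa() - tips
    if missing:
        logger.info(
            "gene %s: query %s not testable, missing taxa %s",
            tree.gene_id, query.name, sorted(missing),
        )
        return False
    if query.rooted:
        if outgroup not in tips:
            logger.info(
                "gene %s: outgroup %s absent, query %s counted unsupported",
                tree.gene_id, outgroup, query.name,
            )
            return False
        groups = clusters(root_on_outgroup(tree, outgroup))
    else:
        sides = bipartitions(tree)
        groups = set(sides) | {tips - s for s in sides}
    return all(clade in groups for clade in query.clades)


def classify_gene(
    tree: GeneTree,
    queries: Sequence[CladeQuery],
    outgroup: Optional[str] = None,
) -> str:
    """Name of the first matching top-level query, or ``"other"``.

    Top-level queries must be mutually exclusive on the data: a gene tree
    matching two of them raises an error naming the gene.
    """
    hits = [q.name for q in queries if clade_present(tree, q, outgroup)]
    if len(hits) > 1:
        raise ValueError(
            f"gene {tree.gene_id}: queries are not mutually exclusive; "
            f"matches {hits}"
        )
    return hits[0] if hits else OTHER


def tally(
    trees: Sequence[GeneTree],
    queries: Sequence[CladeQuery],
    outgroup: Optional[str] = None,
) -> SupportTally:
    """Count genes per hypothesis, per nested sub-query, and the remainder."""
    counts = {q.name: 0 for q in queries}
    nested = {sq.name: 0 for q in queries for sq in q.nested}
    other = 0
    for tree in trees:
        label = classify_gene(tree, queries, outgroup)
        if label == OTHER:
            other += 1
        else:
            counts[label] += 1
        for q in queries:
            for sq in q.nested:
                if clade_present(tree, sq, outgroup):
                    nested[sq.name] += 1
    return SupportTally(len(trees), counts, nested, other)


def classification_map(
    trees: Sequence[GeneTree],
    queries: Sequence[CladeQuery],
    outgroup: Optional[str] = None,
) -> Dict[str, str]:
    """gene_id -> hypothesis label (or ``"other"``), for association testing."""
    return {t.gene_id: classify_gene(t, queries, outgroup) for t in trees}


# -- the amniote query set -------------------------------------------------------

def turtle_queries_7sp(
    turtle: str = "PT",
    birds: Tuple[str, str] = ("ZF", "Ch"),
    lizard: str = "An",
) -> List[CladeQuery]:
    """The three competing turtle placements for a 7-species amniote panel.

    Archosaur: turtle sister to the bird clade; lepidosaur: turtle sister to
    the lizard; diapsid: turtle sister to birds+lizard together.  Support
    means the diagnostic clade(s) appear regardless of other relationships.
    """
    zf, ch = birds
    bird_clade = frozenset(birds)
    archosaur = CladeQuery(
        "Archosaur Hypothesis",
        (bird_clade, frozenset({zf, ch, turtle})),
        nested=(
            CladeQuery(
                "Archosaur+An",
                (bird_clade, frozenset({zf, ch, turtle}),
                 frozenset({zf, ch, turtle, lizard})),
            ),
        ),
    )
    lepidosaur = CladeQuery(
        "Lepidosaur Hypothesis",
        (frozenset({turtle, lizard}),),
        nested=(
            CladeQuery(
                "Lepidosaur+birds",
                (frozenset({turtle, lizard}), bird_clade,
                 frozenset({turtle, lizard, zf, ch})),
            ),
        ),
    )
    diapsid = CladeQuery(
        "Diapsid Hypothesis",
        (frozenset({zf, ch, lizard}), frozenset({zf, ch, lizard, turtle})),
    )
    return [archosaur, lepidosaur, diapsid]
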