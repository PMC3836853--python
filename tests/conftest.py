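import numpy as np
import pytest

from genechar import (
    SimulationConfig,
    TaxonSet,
    build_matrix,
    parse_newick,
    simulate_gene_trees,
    simulate_species_tree,
)

WORKED_NEWICK = "((A:1,B:2):1,(C:1,D:1):2);"

#: hand-computed path sums for the worked 4-taxon tree
WORKED_DISTANCES = {
    ("A", "B"): 3.0, ("A", "C"): 5.0, ("A", "D"): 5.0,
    ("B", "C"): 6.0, ("B", "D"): 6.0, ("C", "D"): 2.0,
}

#: the same distances scaled by 10/6 and rounded to 2 dp
WORKED_COSTS = {
    ("A", "B"): 5.00, ("A", "C"): 8.33, ("A", "D"): 8.33,
    ("B", "C"): 10.00, ("B", "D"): 10.00, ("C", "D"): 3.33,
}


@pytest.fixture
def worked_tree():
    return parse_newick(WORKED_NEWICK, "worked")


@pytest.fixture
def worked_character(worked_tree):
    from genechar import build_character

    return build_character(worked_tree)


@pytest.fixture
def abcd_taxa():
    return TaxonSet(("A", "B", "C", "D"))


def balanced_gene_tree(rng, n_taxa=5, lo=0.5, hi=1.0):
    """Random topology with branch lengths uniform in [lo, hi].

    At most a two-fold branch-length imbalance: in this regime a single
    gene's own topology is the strict parsimony optimum of its character.
    (Strongly unbalanced pendants can defeat single-gene identifiability:
    the wrong topology routes its internal states through the short-branch
    haplotypes — single-character long-branch attraction.)
    """
    import re

    from genechar.topology import random_topology

    taxa = tuple(f"X{i+1}" for i in range(n_taxa))
    newick = random_topology(taxa, rng).to_newick()

    def leaf_len(m):
        return m.group(1) + f":{rng.uniform(lo, hi):.6f}"

    newick = re.sub(r"([A-Za-z0-9_]+)", leaf_len, newick)
    newick = re.sub(r"\)(?=[,)])", lambda m: f"):{rng.uniform(lo, hi):.6f}",
                    newick)
    return parse_newick(newick, "balanced")


def random_gene_tree(rng, n_taxa=5, taxa=None):
    """A random clean gene tree via the simulator (one gene, no artifacts)."""
    seed = int(rng.integers(2**31 - 1))
    sp = simulate_species_tree(n_taxa, seed=seed, taxa=taxa)
    cfg = SimulationConfig(
        n_taxa=n_taxa, n_genes=1, discordance=0.0, length_noise_sd=0.5,
        artifact_fraction=0.0, seed=seed,
    )
    trees, _ = simulate_gene_trees(sp, cfg)
    return trees[0]


@pytest.fixture
def small_simulation():
    """7 taxa, 60 genes, moderate discordance, no artifacts; with truth."""
    sp = simulate_species_tree(7, seed=11)
    cfg = SimulationConfig(
        n_taxa=7, n_genes=60, discordance=0.2, length_noise_sd=0.3,
        artifact_fraction=0.0, seed=11,
    )
    trees, labels = simulate_gene_trees(sp, cfg)
    taxa = TaxonSet(tuple(sorted(sp.tip_labels())))
    return sp, trees, labels, taxa
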