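# Methods

## The model: genes as characters

`genechar` infers a species phylogeny by treating each gene — not each
nucleotide or amino-acid site — as one phylogenetic character.  A gene's
character states are the haplotypes observed in the sampled taxa (one state
per taxon), and the transformation cost between two states is the patristic
distance between the corresponding tips on that gene's estimated tree: the
cost, in tree-length units, of evolving one haplotype into the other.  A
gene tree thus becomes an *ordered multi-state character* with a full
step-matrix of pairwise costs, and the species tree is the topology that
minimizes the total transformation cost summed over all genes (generalized,
i.e. Sankoff, parsimony).

The encoding of gene *g* with patristic matrix *d* is

    cost_g(i, j) = round( S * d(i, j) / max_{k,l} d(k, l) ,  2 )

with maximum step *S* = 10.  Every informative gene therefore contributes
the same maximum step regardless of its evolutionary rate; this proportional
rescaling is the operational meaning of *equal gene weighting*.  Rounding to
two decimals forces floating-point tree-length evaluation downstream and
fixes the numerical resolution of the method (see *Resolution limits*).
Rounding is half-away-from-zero; a gene whose distances are all zero yields
an all-zero cost matrix, is flagged uninformative, and is retained (it
cannot affect any score).

Two consequences of the rescaling are deliberate features.  A gene tree
carrying one artifactual, enormously long branch (bad alignment,
non-orthology, mis-assembly) has all its *other* costs crushed toward zero,
so such genes become nearly uninformative instead of dominating the
analysis.  Independently, gene trees whose longest branch exceeds a
threshold (default 1.5 substitutions/site, strict inequality: a branch of
exactly 1.5 is kept) are removed before the analysis, since they are likely
artifacts rather than signal.

## Scoring and search

The length of one character on a candidate species tree is the minimum,
over assignments of *observed* states to internal nodes, of the summed edge
costs.  Internal nodes range only over the gene's observed haplotypes —
the step-matrix (PAUP* USERTYPE) semantics — and hypothetical intermediate
states are not synthesized.  The minimum is computed by the Sankoff
bottom-up dynamic programme on an arbitrary rooting; because cost matrices
are symmetric, the score is provably root-invariant, and the implementation
is checked against a brute-force enumeration of all internal-state
assignments on small trees.  Taxa missing from a gene enter as all-zero
leaf cost vectors (standard missing data; with a zero cost diagonal this is
identical to pruning the leaf).  Characters covering the full taxon set are
scored in a single vectorized pass across all genes; the remainder fall
back to a per-character programme.

Tree space is explored two ways:

* **Exhaustive** — every unrooted binary topology is scored (3, 15, 105,
  945, 10 395, 135 135 trees for 4–9 taxa); the global optimum and all ties
  within 1e-9 are returned.  This is the default at ≤ 9 taxa.
* **Heuristic** — seeded random-addition stepwise insertion followed by
  steepest-descent branch swapping (NNI, SPR, or TBR neighborhoods; SPR by
  default, TBR available) until no neighbor improves, repeated over
  `n_starts` starts.  Deterministic given the seed.

Ties are kept and summarized by strict consensus.  Nodal support comes from
a non-parametric bootstrap over genes: each replicate resamples the
characters with replacement to the original count, re-runs the search, and
records the splits of the replicate's best tree(s); *k* tied trees
contribute 1/*k* each.  With exhaustive search the per-character lengths of
every topology are precomputed once, so a replicate reduces to a weighted
sum and an argmin — 1000 replicates take well under a second at 7 taxa.

## Gene-support tallies and association tests

The simple count method classifies each gene tree by the clade hypothesis
it contains — e.g. for the amniote panel, whether the turtle groups with
the birds (archosaur hypothesis), with the lizard (lepidosaur), or with
birds+lizard jointly (diapsid) — and tallies genes per hypothesis.
"Contains" means the diagnostic clade(s) appear as clusters of the
outgroup-rooted tree (or as exact splits for unrooted queries) regardless
of other relationships; an unresolved polytomy certifies nothing, and a
gene missing a query taxon counts as not supporting (logged).  Hypotheses
may carry nested sub-queries (progressively larger enclosing topologies)
whose counts are necessarily monotone non-increasing.  Top-level queries
must be mutually exclusive on the data; a violation raises an error naming
the offending gene.

Associations between gene categories (positive-selection status, GO/KEGG
membership — opaque labels here; annotation is upstream) and supported
hypotheses use the uncorrected Pearson chi-square statistic on 2×2 tables
with df = 1.  No continuity correction and no multiple-testing adjustment
are applied (a Benjamini–Hochberg column is reported but never used to
filter); categories with ≤ 5 member genes are excluded.  Two layouts:
hypothesis-A-vs-hypothesis-B conditioning on genes supporting either
(selection test), and focal-supporters-vs-all-others (category scan).

## The synthetic-data generator

Real inputs are per-gene ML trees; the generator emulates their statistical
structure so every stage is testable without sequence data:

| parameter | default | meaning |
|---|---|---|
| `n_taxa` | 7 | taxa in the species tree |
| `n_genes` | 200 | gene trees per set |
| `discordance` | 0.30 | probability a gene's topology is perturbed |
| `topo_moves` | 1 | NNI moves applied to a perturbed gene |
| `length_noise_sd` | 0.30 | lognormal sd of per-branch rate factors |
| `artifact_fraction` | 0.18 | share of genes given one artifact branch |
| `artifact_scale` | 10 | artifact branch length, × tree diameter |
| `branch_length_mean` | 0.1 | exponential mean of species-tree branches |

Species trees are uniform over labeled topologies with Exp(0.1) branch
lengths.  Discordance is modeled by NNI perturbation rather than a
multispecies coalescent: the method consumes arbitrary gene trees and makes
no coalescent assumption, and NNI gives direct control of conflict
intensity.  The defaults mirror the analysis regime the method targets:
published tallies show only ~46 % of genes supporting the dominant clade
(hence substantial discordance, 0.30 here), and roughly 18 % of nucleotide
gene trees fail the long-branch filter (hence `artifact_fraction` = 0.18);
recovery experiments in the test-suite use discordance 0.1 with artifacts
off, the stated recovery condition.  All outputs are bit-for-bit
reproducible from (config, seed); per-gene RNG substreams are derived from
the gene index.  A companion generator plants category enrichments with
chosen odds ratios against hypothesis labels, for calibrating the
association scan.

What the generator does **not** emulate: sequence-level estimation error
(gene trees are perturbed copies of the truth, not re-estimated), alignment
and orthology pipelines, coalescent branch-length correlations, and missing
taxa (simulated matrices are complete; missing data are exercised by
dedicated unit fixtures).  Passing tests therefore demonstrate correctness
of the encoding, scoring, search and calibration machinery under controlled
conflict — not robustness to every pathology of real transcriptome data.

## Numerical choices

* Rounding: half-away-from-zero at 2 decimals (the convention is arbitrary
  but fixed and recorded; banker's rounding would differ on exact halves).
* Score ties: absolute tolerance 1e-9; all tied trees retained.
* Branch lengths: missing lengths parse as 0 with a warning; negative
  lengths are rejected.
* `max_branch_length` is the maximum over edges *as represented* in the
  input tree.  Re-rooting conserves total tree length; un-rooting merges
  the two edges left by a suppressed root, so a basally bifurcating input
  re-rooted elsewhere can expose a merged basal edge.  The filter is
  applied to trees as read, before any re-rooting.
* Stepwise addition starts from the first three taxa of the seeded shuffle;
  insertion ties break toward the first-scored edge, making searches
  deterministic given the seed.
* NEXUS output targets PAUP* 4 syntax (DATA block plus per-character
  `USERTYPE ... (STEPMATRIX)` and a `TYPESET`); steps carry exactly two
  decimals, and a JSON sidecar maps state symbols back to taxa.

## Resolution limits and identifiability

Two structural limits of the encoding are worth knowing; both are
properties of the method, not of this implementation, and both are pinned
by tests.

**Star bound.**  On any candidate topology the dynamic programme may assign
one shared ancestral haplotype *X* to every internal node, so no topology
ever scores above `min_X Σ_leaf cost(leaf, X)`.  A single gene identifies
its own topology only when beating that bound.  With branch-length
imbalance up to about two-fold the gene's own topology is the strict
single-gene optimum (verified exhaustively on random 4- and 5-taxon
instances), but when pendant branches dwarf the internal branches the
optimum collapses to the star bound and *all* topologies tie exactly —
identifiability is lost, though no wrong topology is ever strictly
preferred over the truth for a clean gene.

**Rounding resolution.**  Costs live on a 0.01 grid of a 0–10 scale, so
splits whose internal branches contribute less than ~0.1 % of the gene's
maximum distance can vanish in rounding.  A species tree with a near-zero
internal branch then yields an exact multi-tree optimum whose members carry
*identical* per-gene lengths — the characters genuinely contain no
information about that resolution, mirroring how hard polytomies present in
real data.  The package reports all tied trees and their strict consensus
rather than breaking such ties arbitrarily.

## Problem sizes

The test-suite and the acceptance script run at desk scale, chosen so the
full suite completes in well under a minute: 7-taxon species trees with
100–300 genes per simulated set, 20-seed recovery experiments over all 945
seven-taxon topologies, 500-instance oracle comparisons, 1000-tree
normalization sweeps, 1000-replicate bootstraps, and 1000-category null
calibrations.  The pipeline itself handles the published scale
(4 584 genes × 7 taxa) in seconds per search because scoring is vectorized
across genes.

## Known limitations

* Internal states are restricted to observed haplotypes; allowing inferred
  intermediate states (true generalized parsimony over an extended state
  space) could in principle shorten trees but has no natural state set
  here.
* Per-gene reliability weighting (stationarity, internode certainty) is out
  of scope; all genes are weighted equally by construction.
* The chi-square machinery is 2×2-only and refuses tables with zero
  expected cells rather than falling back to an exact test.
* Heuristic search is a hill-climber; with default settings it matched the
  exhaustive optimum in every tested 7-taxon instance, but no global
  guarantee exists beyond ≤ 9 taxa where exhaustive search is available.
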