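"""Association between gene categories and supported phylogenetic hypotheses.

Given per-gene hypothesis labels (from the gene-support tally) and per-gene
category memberships (GO terms, KEGG pathways, positive-selection status —
opaque strings here; annotation itself happens upstream), this module builds
2x2 contingency tables and tests independence with the uncorrected Pearson
chi-square statistic on 1 degree of freedom.  No continuity correction and
no multiple-testing adjustment are applied — that is the procedure whose
printed statistics this reproduces — though a Benjamini–Hochberg column is
reported for reference.

Two table layouts are supported:

* ``two_hypotheses`` — condition on the genes supporting either of two focal
  hypotheses; rows = category present/absent, columns = hypothesis A/B
  (the positive-selection test layout).
* ``focal_vs_other`` — focal-hypothesis supporters versus all other genes;
  the category-scan layout with columns A+/A-/O+/O-.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_GENES = 5


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows category present/absent (or group 1/2)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def observed(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float
    expected: np.ndarray
    df: int = 1


def expected_counts(t: ContingencyTable2x2) -> np.ndarray:
    """Expected cell counts under independence: row sum x col sum / total."""
    obs = t.observed
    return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / t.total


def chisq_2x2(t: ContingencyTable2x2) -> ChiSquareResult:
    """Uncorrected Pearson chi-square test on a 2x2 table (df = 1).

    Raises if any expected count is zero (an exact test would be needed;
    not provided here).
    """
    exp = expected_counts(t)
    if np.any(exp == 0):
        raise ValueError(
            "zero expected cell count; use an exact test instead of chi-square"
        )
    stat = float(((t.observed - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return ChiSquareResult(stat, p, exp)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported, never used to filter)."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj


def association_scan(
    gene_labels: Mapping[str, str],
    categories: Mapping[str, Set[str]],
    focal: str,
    second: Optional[str] = None,
    min_genes: int = DEFAULT_MIN_GENES,
    mode: str = "focal_vs_other",
) -> pd.DataFrame:
    """Chi-square scan of every sufficiently large category.

    ``gene_labels`` maps gene id -> hypothesis label; ``categories`` maps
    gene id -> set of category ids.  In ``focal_vs_other`` mode the table is
    (focal supporters with/without the category) versus (all other genes
    with/without); in ``two_hypotheses`` mode only genes labelled ``focal``
    or ``second`` enter, rows = category present/absent, columns = the two
    hypotheses.  Categories with no more than ``min_genes`` member genes
    (strictly) are excluded.  Rows are sorted by p-value.
    """
    if mode not in ("focal_vs_other", "two_hypotheses"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "two_hypotheses" and second is None:
        raise ValueError("two_hypotheses mode requires a second hypothesis label")
    if mode == "two_hypotheses":
        genes = [g for g, l in gene_labels.items() if l in (focal, second)]
    else:
        genes = list(gene_labels)
    members: Dict[str, Set[str]] = {}
    for g in genes:
        for cat in categories.get(g, ()):
            members.setdefault(cat, set()).add(g)
    rows = []
    for cat, gset in sorted(members.items()):
        if len(gset) <= min_genes:
            continue
        if mode == "two_hypotheses":
            a = sum(1 for g in gset if gene_labels[g] == focal)
            b = len(gset) - a
            n_focal = sum(1 for g in genes if gene_labels[g] == focal)
            table = ContingencyTable2x2(a, b, n_focal - a, len(genes) - n_focal - b)
        else:
            focal_genes = [g for g in genes if gene_labels[g] == focal]
            a = sum(1 for g in focal_genes if g in gset)
            o_plus = len(gset) - a
            table = ContingencyTable2x2(
                a, len(focal_genes) - a, o_plus, len(genes) - len(focal_genes) - o_plus
            )
        try:
            res = chisq_2x2(table)
        except ValueError:
            continue
        exp = res.expected
        rows.append(
            {
                "category": cat,
                "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                "expected_a": exp[0, 0],
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    if not rows:
        import warnings

        warnings.warn("no category passed the minimum-size filter")
        return pd.DataFrame(
            columns=["category", "a", "b", "c", "d", "expected_a",
                     "statistic", "p_value", "p_bh"]
        )
    df = pd.DataFrame(rows)
    df["p_bh"] = _bh_adjust(df["p_value"].to_numpy())
    return df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
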