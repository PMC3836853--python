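"""Gene trees as ordered multi-state characters with step-matrix costs.

Each gene becomes one character: its states are the haplotypes observed for
the taxa present in the gene, and the cost of transforming one state into
another is the patristic distance between the two haplotypes on the gene
tree, rescaled so the largest pairwise distance is exactly ``max_step``
(default 10) and rounded to ``decimals`` digits (default 2, which forces
floating-point tree-length evaluation downstream).  Because of the
rescaling, every gene contributes the same maximum step regardless of its
rate: this is what "equal weighting of genes" means operationally, and it is
also what defuses artifactual long branches — one huge branch shrinks all
other costs of that gene toward zero, leaving the character nearly
uninformative.

The exporter writes a PAUP*-style NEXUS file: a DATA block with one column
per gene and an ASSUMPTIONS block declaring one USERTYPE ... (STEPMATRIX)
per character plus the TYPESET that applies it.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .treeio import GeneTree, TaxonSet, patristic_matrix

#: state symbol alphabet for NEXUS columns (PAUP*-compatible)
SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"

DEFAULT_MAX_STEP = 10.0
DEFAULT_DECIMALS = 2


def round_half_away(x: np.ndarray, decimals: int) -> np.ndarray:
    """Round half away from zero (10**-decimals grid); numpy rounds half to even."""
    scale = 10.0 ** decimals
    return np.sign(x) * np.floor(np.abs(x) * scale + 0.5) / scale


@dataclass(frozen=True, eq=False)
class StepMatrixCharacter:
    """One gene rendered as an ordered multi-state character.

    ``states`` holds the taxa whose haplotypes are the character states, in
    taxon-set order; ``cost[i, j]`` is the scaled, rounded transformation
    cost between states i and j; ``missing`` lists taxa absent from the gene.
    """

    gene_id: str
    states: Tuple[str, ...]
    cost: np.ndarray
    missing: FrozenSet[str] = frozenset()
    uninformative: bool = False

    def __post_init__(self):
        k = len(self.states)
        if self.cost.shape != (k, k):
            raise ValueError(f"gene {self.gene_id}: cost must be {k}x{k}")
        if not np.allclose(self.cost, self.cost.T):
            raise ValueError(f"gene {self.gene_id}: cost matrix must be symmetric")
        if np.any(np.diag(self.cost) != 0):
            raise ValueError(f"gene {self.gene_id}: cost diagonal must be zero")
        if np.any(self.cost < 0):
            raise ValueError(f"gene {self.gene_id}: negative costs")
        self.cost.setflags(write=False)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, taxon: str) -> int:
        return self.states.index(taxon)


@dataclass
class CharacterMatrix:
    """All step-matrix characters over a common taxon set, equally weighted."""

    taxa: TaxonSet
    characters: List[StepMatrixCharacter]
    weights: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.weights is None:
            self.weights = np.ones(len(self.characters))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.characters),):
            raise ValueError("one weight per character required")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        names = set(self.taxa.names)
        for ch in self.characters:
            extra = set(ch.states) - names
            if extra:
                raise ValueError(
                    f"gene {ch.gene_id}: tip(s) not in taxon set: {sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.characters)


# -- construction --------------------------------------------------------------

def build_character(
    tree: GeneTree,
    max_step: float = DEFAULT_MAX_STEP,
    decimals: int = DEFAULT_DECIMALS,
    taxa: Optional[TaxonSet] = None,
) -> StepMatrixCharacter:
    """Convert one gene tree into a step-matrix character.

    Costs are ``round(max_step * d / d_max, decimals)`` with ``d`` the
    patristic distance.  A gene whose distances are all zero yields an
    all-zero cost matrix flagged ``uninformative``.  Rounding is
    half-away-from-zero.
    """
    dm = patristic_matrix(tree)
    if taxa is not None:
        order = [t for t in taxa.names if t in set(dm.labels)]
        missing = frozenset(taxa.names) - set(dm.labels)
    else:
        order = list(dm.labels)
        missing = frozenset()
    idx = [dm.labels.index(t) for t in order]
    d = dm.d[np.ix_(idx, idx)]
    d_max = float(d.max())
    if d_max == 0.0:
        return StepMatrixCharacter(
            tree.gene_id, tuple(order), np.zeros_like(d), missing, uninformative=True
        )
    cost = round_half_away(max_step * d / d_max, decimals)
    return StepMatrixCharacter(tree.gene_id, tuple(order), cost, missing)


def build_matrix(
    trees: Sequence[GeneTree],
    taxa: TaxonSet,
    max_step: float = DEFAULT_MAX_STEP,
    decimals: int = DEFAULT_DECIMALS,
) -> CharacterMatrix:
    """One equally weighted character per gene tree over a common taxon set."""
    names = set(taxa.names)
    chars = []
    for tree in trees:
        extra = tree.tip_set() - names
        if extra:
            raise ValueError(
                f"gene {tree.gene_id}: tip(s) not in taxon set: {sorted(extra)}"
            )
        chars.append(build_character(tree, max_step, decimals, taxa=taxa))
    return CharacterMatrix(taxa, chars)


# -- NEXUS export ---------------------------------------------------------------

def _fmt(x: float, decimals: int = DEFAULT_DECIMALS) -> str:
    return f"{x:.{decimals}f}"


def export_nexus(matrix: CharacterMatrix, decimals: int = DEFAULT_DECIMALS) -> str:
    """Serialize as NEXUS with per-character STEPMATRIX usertypes.

    One DATA-block column per gene (state symbol = index of the taxon among
    the gene's states, ``?`` for missing taxa) and one
    ``USERTYPE <gene> (STEPMATRIX)`` per character in the ASSUMPTIONS block,
    applied to its column by a TYPESET.  Steps carry exactly ``decimals``
    decimal digits.
    """
    n = len(matrix.taxa)
    if n > len(SYMBOLS):
        raise ValueError(
            f"{n} taxa exceed the {len(SYMBOLS)}-symbol state alphabet"
        )
    pad = max(len(t) for t in matrix.taxa.names) + 2
    rows = {t: [] for t in matrix.taxa.names}
    for ch in matrix.characters:
        for t in matrix.taxa.names:
            if t in ch.missing:
                rows[t].append("?")
            else:
                rows[t].append(SYMBOLS[ch.state_index(t)])
    lines = [
        "#NEXUS",
        "",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={n} NCHAR={len(matrix)};",
        f"  FORMAT SYMBOLS=\"{SYMBOLS[:n]}\" MISSING=?;",
        "  MATRIX",
    ]
    for t in matrix.taxa.names:
        lines.append(f"    {t:<{pad}}{''.join(rows[t])}")
    lines += ["  ;", "END;", "", "BEGIN ASSUMPTIONS;"]
    for ch in matrix.characters:
        k = ch.n_states
        syms = [SYMBOLS[i] for i in range(k)]
        lines.append(f"  USERTYPE {ch.gene_id} (STEPMATRIX) = {k}")
        lines.append("    [" + " ".join(syms) + "]")
        for i in range(k):
            row = [
                "." if i == j else _fmt(float(ch.cost[i, j]), decimals)
                for j in range(k)
            ]
            lines.append("    " + " ".join(row))
        lines.append("  ;")
    assignments = ", ".join(
        f"{ch.gene_id}: {i + 1}" for i, ch in enumerate(matrix.characters)
    )
    lines.append(f"  TYPESET * genesteps = {assignments};")
    lines.append("END;")
    return "\n".join(lines) + "\n"


def state_map(matrix: CharacterMatrix) -> str:
    """JSON sidecar: gene_id -> column index; per gene, state symbol -> taxon."""
    payload = {
        "columns": {ch.gene_id: i for i, ch in enumerate(matrix.characters)},
        "states": {
            ch.gene_id: {SYMBOLS[i]: t for i, t in enumerate(ch.states)}
            for ch in matrix.characters
        },
    }
    return json.dumps(payload, indent=2)


# -- native JSON serialization ---------------------------------------------------

def matrix_to_json(matrix: CharacterMatrix) -> str:
    """Loss-free native serialization of a character matrix."""
    payload = {
        "taxa": list(matrix.taxa.names),
        "outgroup": matrix.taxa.outgroup,
        "weights": matrix.weights.tolist(),
        "characters": [
            {
                "gene_id": ch.gene_id,
                "states": list(ch.states),
                "cost": ch.cost.tolist(),
                "missing": sorted(ch.missing),
                "uninformative": ch.uninformative,
            }
            for ch in matrix.characters
        ],
    }
    return json.dumps(payload)


def matrix_from_json(text: str) -> CharacterMatrix:
    payload = json.loads(text)
    taxa = TaxonSet(tuple(payload["taxa"]), payload.get("outgroup"))
    chars = [
        StepMatrixCharacter(
            c["gene_id"],
            tuple(c["states"]),
            np.array(c["cost"], dtype=float),
            frozenset(c["missing"]),
            c["uninformative"],
        )
        for c in payload["characters"]
    ]
    return CharacterMatrix(taxa, chars, weights=np.array(payload["weights"]))


# -- NEXUS re-import (round-trip of our own dialect) ----------------------------

def parse_nexus(text: str) -> CharacterMatrix:
    """Re-parse a NEXUS file written by :func:`export_nexus`."""
    data_m = re.search(r"MATRIX\s*\n(.*?)\n\s*;", text, re.S)
    if not data_m:
        raise ValueError("no DATA MATRIX block found")
    taxa_rows: List[Tuple[str, str]] = []
    for line in data_m.group(1).splitlines():
        parts = line.split()
        if len(parts) == 2:
            taxa_rows.append((parts[0], parts[1]))
    names = tuple(t for t, _ in taxa_rows)
    usertypes: Dict[str, np.ndarray] = {}
    for m in re.finditer(
        r"USERTYPE\s+(\S+)\s+\(STEPMATRIX\)\s*=\s*(\d+)\s*\n(.*?)\n\s*;", text, re.S
    ):
        gid, k = m.group(1), int(m.group(2))
        body = [
            l for l in m.group(3).splitlines() if l.strip() and "[" not in l
        ]
        rows = []
        for l in body[:k]:
            rows.append([0.0 if tok == "." else float(tok) for tok in l.split()])
        usertypes[gid] = np.array(rows)
    order = re.search(r"TYPESET\s*\*\s*\S+\s*=\s*(.*?);", text, re.S)
    if not order:
        raise ValueError("no TYPESET found")
    gene_order = [a.split(":")[0].strip() for a in order.group(1).split(",")]
    chars = []
    for col, gid in enumerate(gene_order):
        cost = usertypes[gid]
        present, missing = [], set()
        for t, row in taxa_rows:
            sym = row[col]
            if sym == "?":
                missing.add(t)
            else:
                present.append((SYMBOLS.index(sym), t))
        states = tuple(t for _, t in sorted(present))
        chars.append(
            StepMatrixCharacter(
                gid, states, cost, frozenset(missing),
                uninformative=bool(np.all(cost == 0)),
            )
        )
    return CharacterMatrix(TaxonSet(names), chars)
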