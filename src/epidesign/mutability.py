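"""Allowed-residue maps (M) and per-substitution penalty tables.

Three independent predicates decide which substitutions are "safe enough" to
offer to the optimizer; each also yields the per-substitution penalty summed
in variant reports:

* **BLOSUM** — relative BLOSUM-62 score: diagonal minus substitution score at
  most ``max_diff`` (default 4).  Penalty is the 0/1 disallowed flag.
* **Conservation** — tree-weighted residue frequency in a family alignment at
  least ``freq_min`` (default 0.05); sequences are weighted bottom-up on the
  phylogeny so redundant close relatives are not over-counted.  Penalty is
  the negative natural log of the weighted frequency.
* **ΔΔG°** — an externally computed per-substitution folding free-energy
  table; allowed when the value is at most ``margin`` kcal/mol (default 0.25)
  above the wild-type self entry.  Penalty is that relative ΔΔG°.

Every builder always admits the wild-type residue at every position.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Mapping

import dendropy
from Bio.Align import substitution_matrices

from .alphabet import AMINO_ACIDS, GAP_CHARS, validate_sequence

FREQ_EPS = 1e-6  # conservation penalty cap: -ln(eps) for unseen residues
CONSERVATION_PENALTY_CAP = -math.log(FREQ_EPS)


class AlignmentWarning(UserWarning):
    pass


@dataclass
class AllowedResidues:
    """The map M: per-position sets of permitted residues (wild type always in)."""

    sequence: str
    allowed: list[frozenset[str]]
    source: str = "explicit"

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence)
        if len(self.allowed) != len(self.sequence):
            raise ValueError("allowed sets must cover every position of the sequence")
        self.allowed = [frozenset(s) for s in self.allowed]
        for i, (wt, s) in enumerate(zip(self.sequence, self.allowed), start=1):
            if not s:
                raise ValueError(f"empty allowed set at position {i}")
            if wt not in s:
                raise ValueError(f"wild-type {wt} missing from allowed set at position {i}")

    def __len__(self) -> int:
        return len(self.sequence)

    def sizes(self) -> list[int]:
        return [len(s) for s in self.allowed]

    def mean_size(self) -> float:
        """Mean |allowed(i)| over positions, wild type included in each count."""
        return sum(self.sizes()) / len(self)

    def intersect(self, other: "AllowedResidues") -> "AllowedResidues":
        if other.sequence != self.sequence:
            raise ValueError("cannot intersect allowed sets for different sequences")
        merged = [
            (a & b) | {wt}
            for a, b, wt in zip(self.allowed, other.allowed, self.sequence)
        ]
        return AllowedResidues(self.sequence, merged, source="intersection")


@dataclass
class PenaltyTables:
    """Per-(position, residue) penalty contributions for the report columns.

    Keys are (1-based position, residue).  A table left as ``None`` was not
    built; a built table must cover every substitution it is asked about.
    Wild-type entries are 0 for the BLOSUM flag and relative ΔΔG°; the
    conservation penalty of the wild type is its own -ln frequency (0 only at
    full conservation) but contributes nothing to reports, which sum over
    substituted positions only.
    """

    blosum_flag: dict[tuple[int, str], int] | None = None
    conservation_penalty: dict[tuple[int, str], float] | None = None
    ddg: dict[tuple[int, str], float] | None = None

    def merge(self, other: "PenaltyTables") -> "PenaltyTables":
        return PenaltyTables(
            blosum_flag=other.blosum_flag or self.blosum_flag,
            conservation_penalty=other.conservation_penalty or self.conservation_penalty,
            ddg=other.ddg or self.ddg,
        )


# ---------------------------------------------------------------------------
# BLOSUM predicate
# ---------------------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum_allowed(seq: str, max_diff: int = 4) -> tuple[AllowedResidues, PenaltyTables]:
    """Relative-BLOSUM-62 allowed sets: B(wt,wt) - B(wt,a) <= max_diff.

    Returns the allowed map and a 0/1 flag table (0 = allowed) over every
    position x residue.
    """
    seq = validate_sequence(seq)
    allowed: list[frozenset[str]] = []
    flags: dict[tuple[int, str], int] = {}
    for i, wt in enumerate(seq, start=1):
        diag = _BLOSUM62[wt, wt]
        ok = {a for a in AMINO_ACIDS if diag - _BLOSUM62[wt, a] <= max_diff} | {wt}
        allowed.append(frozenset(ok))
        for a in AMINO_ACIDS:
            flags[(i, a)] = 0 if a in ok else 1
    return AllowedResidues(seq, allowed, source="blosum"), PenaltyTables(blosum_flag=flags)


# ---------------------------------------------------------------------------
# Tree-weighted conservation predicate
# ---------------------------------------------------------------------------


def gsc_weights(tree: dendropy.Tree) -> dict[str, float]:
    """Bottom-up tree-based sequence weights (Gerstein–Sonnhammer–Chothia style).

    Visiting edges from the leaves toward the root, each edge's length is
    divided among the leaves below it in proportion to their currently
    accumulated weights (equally while all are still zero); a leaf's weight is
    its accumulated total.  If every branch length is zero the weights are
    returned uniform, with a warning.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
    if any(lb is None for lb in labels):
        raise ValueError("every leaf must be labeled")
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate leaf labels: {sorted(labels)}")
    acc: dict[int, float] = {id(lf): 0.0 for lf in leaves}
    leaf_label: dict[int, str] = {id(lf): lb for lf, lb in zip(leaves, labels)}
    for node in tree.postorder_node_iter():
        length = node.edge.length or 0.0
        if length == 0.0:
            continue
        below = [id(lf) for lf in (node.leaf_iter() if not node.is_leaf() else [node])]
        total = sum(acc[k] for k in below)
        if total == 0.0:
            share = length / len(below)
            for k in below:
                acc[k] += share
        else:
            for k in below:
                acc[k] += length * acc[k] / total
    weights = {leaf_label[k]: v for k, v in acc.items()}
    if all(v == 0.0 for v in weights.values()):
        warnings.warn(
            "all branch lengths are zero; using uniform sequence weights",
            AlignmentWarning,
            stacklevel=2,
        )
        weights = {lb: 1.0 for lb in weights}
    return weights


@dataclass
class WeightedAlignment:
    """A gapped family alignment with per-sequence weights and a target row.

    ``column_map`` maps 1-based target positions to 0-based alignment columns;
    if omitted it is derived from the (gapped) target row by skipping gaps.
    """

    rows: dict[str, str]
    weights: dict[str, float]
    target_id: str
    column_map: dict[int, int] | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows must all have equal length")
        if self.target_id not in self.rows:
            raise ValueError(f"target id {self.target_id!r} not in alignment")
        missing = sorted(set(self.rows) - set(self.weights))
        if missing:
            raise ValueError(f"no weight for alignment sequences: {missing}")
        extra = sorted(set(self.weights) - set(self.rows))
        if extra:
            raise ValueError(f"weights given for unknown sequences: {extra}")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("sequence weights must be positive")
        if self.column_map is None:
            cmap: dict[int, int] = {}
            pos = 0
            for col, ch in enumerate(self.rows[self.target_id]):
                if ch not in GAP_CHARS:
                    pos += 1
                    cmap[pos] = col
            self.column_map = cmap

    @property
    def target_sequence(self) -> str:
        return "".join(
            ch for ch in self.rows[self.target_id] if ch not in GAP_CHARS
        ).upper()

    def column_frequencies(self, position: int) -> dict[str, float]:
        """Weighted residue frequencies at a target position, over non-gap rows."""
        col = self.column_map[position]
        num: dict[str, float] = {}
        denom = 0.0
        for sid, row in self.rows.items():
            ch = row[col].upper()
            if ch in GAP_CHARS:
                continue
            w = self.weights[sid]
            denom += w
            num[ch] = num.get(ch, 0.0) + w
        if denom == 0.0:
            return {}
        return {a: v / denom for a, v in num.items()}


def weighted_alignment(
    rows: Mapping[str, str],
    target_id: str,
    tree: dendropy.Tree | None = None,
) -> WeightedAlignment:
    """Assemble a WeightedAlignment, weighting rows on the tree if given.

    Without a tree, uniform weights are used (with a warning): every family
    member then counts equally, including redundant near-duplicates.
    """
    rows = dict(rows)
    if tree is not None:
        weights = gsc_weights(tree)
        missing = sorted(set(rows) - set(weights))
        extra = sorted(set(weights) - set(rows))
        if missing or extra:
            raise ValueError(
                f"tree leaves and alignment ids disagree; in alignment only: "
                f"{missing}; in tree only: {extra}"
            )
    else:
        warnings.warn(
            "no phylogenetic tree supplied; using uniform sequence weights",
            AlignmentWarning,
            stacklevel=2,
        )
        weights = {sid: 1.0 for sid in rows}
    return WeightedAlignment(rows=rows, weights=weights, target_id=target_id)


def conservation_penalty_of(freq: float) -> float:
    """-ln(frequency), capped so zero-frequency residues stay finite."""
    return -math.log(max(freq, FREQ_EPS))


def conservation_allowed(
    walign: WeightedAlignment, freq_min: float = 0.05
) -> tuple[AllowedResidues, PenaltyTables]:
    """Family-frequency allowed sets: weighted frequency >= freq_min.

    Frequencies at each target position are taken over non-gap rows of the
    mapped alignment column.  The penalty table stores -ln f(i, a) for every
    residue (capped for unseen residues); a residue at exactly the default 5%
    boundary carries penalty -ln 0.05 ~ 3.00.
    """
    if not 0 < freq_min < 1:
        raise ValueError("freq_min must be in (0, 1)")
    seq = walign.target_sequence
    seq = validate_sequence(seq, what="alignment target row")
    allowed: list[frozenset[str]] = []
    pen: dict[tuple[int, str], float] = {}
    for i, wt in enumerate(seq, start=1):
        freqs = walign.column_frequencies(i)
        freqs = {a: f for a, f in freqs.items() if a in set(AMINO_ACIDS)}
        if not freqs:
            warnings.warn(
                f"position {i}: all-gap alignment column; only the wild type "
                f"({wt}) is allowed there",
                AlignmentWarning,
                stacklevel=2,
            )
            allowed.append(frozenset({wt}))
            for a in AMINO_ACIDS:
                pen[(i, a)] = 0.0 if a == wt else CONSERVATION_PENALTY_CAP
            continue
        ok = {a for a, f in freqs.items() if f >= freq_min} | {wt}
        allowed.append(frozenset(ok))
        for a in AMINO_ACIDS:
            pen[(i, a)] = conservation_penalty_of(freqs.get(a, 0.0))
    return (
        AllowedResidues(seq, allowed, source="conservation"),
        PenaltyTables(conservation_penalty=pen),
    )


# ---------------------------------------------------------------------------
# ΔΔG° predicate
# ---------------------------------------------------------------------------


def foldx_allowed(
    seq: str,
    ddg_table: Mapping[tuple[int, str], float],
    margin: float = 0.25,
) -> tuple[AllowedResidues, PenaltyTables]:
    """ΔΔG°-based allowed sets from an external per-substitution energy table.

    ``ddg_table`` maps (1-based position, mutant residue) to predicted ΔΔG° in
    kcal/mol and must contain a wild-type self entry at every position; values
    are re-referenced so the wild type is 0, and residues within ``margin``
    kcal/mol of wild type (inclusive) are allowed.
    """
    seq = validate_sequence(seq)
    missing = [i for i, wt in enumerate(seq, start=1) if (i, wt) not in ddg_table]
    if missing:
        raise ValueError(f"ddG table lacks wild-type self entries at positions {missing}")
    allowed: list[frozenset[str]] = []
    rel: dict[tuple[int, str], float] = {}
    for i, wt in enumerate(seq, start=1):
        ref = ddg_table[(i, wt)]
        ok = {wt}
        for a in AMINO_ACIDS:
            if (i, a) not in ddg_table:
                continue
            r = ddg_table[(i, a)] - ref
            rel[(i, a)] = 0.0 if a == wt else r
            if r <= margin:
                ok.add(a)
        allowed.append(frozenset(ok))
    return AllowedResidues(seq, allowed, source="foldx"), PenaltyTables(ddg=rel)


# ---------------------------------------------------------------------------
# Variant-space combinatorics
# ---------------------------------------------------------------------------


def count_variants(M: AllowedResidues, k: int) -> int:
    """Exact number of sequences differing from wild type at exactly k positions."""
    if k < 0:
        raise ValueError("k must be >= 0")
    n = len(M)
    if k > n:
        return 0
    opts = [len(s) - 1 for s in M.allowed]
    total = 0
    for pos in combinations(range(n), k):
        prod = 1
        for p in pos:
            prod *= opts[p]
        total += prod
    return total


def enumerate_variants(M: AllowedResidues, k: int) -> Iterator[str]:
    """Yield every exactly-k-substitution sequence once, in deterministic order.

    Order: ascending substituted-position tuples, then alphabetical residues.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    n = len(M)
    if k > n:
        return
    wt = M.sequence
    alts = [sorted(s - {w}) for s, w in zip(M.allowed, wt)]

    def rec(pos_choice: tuple[int, ...], idx: int, current: list[str]) -> Iterator[str]:
        if idx == len(pos_choice):
            yield "".join(current)
            return
        p = pos_choice[idx]
        for a in alts[p]:
            current[p] = a
            yield from rec(pos_choice, idx + 1, current)
        current[p] = wt[p]

    for pos_choice in combinations(range(n), k):
        if any(not alts[p] for p in pos_choice):
            continue
        yield from rec(pos_choice, 0, list(wt))
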