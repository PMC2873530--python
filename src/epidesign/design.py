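"""Globally optimal epitope-minimizing sequence design by dynamic programming.

The objective is the total predicted epitope count of a variant: the sum,
over every length-w window (w = 9 publicly), of the number of panel alleles
recognizing that window.  Because a window only sees w consecutive residues,
the problem has optimal substructure over the suffix of the last w-1 residues:

    T[i, X]  = best total score of any feasible prefix ending at position i
               whose last w-1 residues form X,
    T[w-1, X] = 0 for every X in M(1) x ... x M(w-1),
    T[i, X]  = min over a in M(i-w+1) of  T[i-1, (a, x1..x_{w-2})] + c(a . X),

where c scores the w-mer ending at i and "." is concatenation.  The answer is
min over X of T[n, X], traced back to a sequence.  A second index s turns T
into R[i, X, s], the best score with exactly s substitutions (or, generally,
integer substitution cost) spent so far; the base row charges the cost of the
N-terminal (w-1)-mer and each step charges the cost of the newly fixed
C-terminal residue.

Only reachable states are materialized (states are componentwise drawn from
the allowed map M, and budget-pruned), so table size scales with the product
of allowed-set sizes over any w-1 consecutive positions, not with 20^(w-1).

Ties are resolved deterministically in favor of the wild type: variants with
equal score are ordered by substitution count, then by a lexicographic key in
which the wild-type residue sorts first at every position.

Near-optimal enumeration follows the classic slack-carrying backtrace: every
completion whose prefix-optimum plus suffix cost stays within optimum +
epsilon is expanded, which yields exactly the set of feasible variants within
the slack, each once (a state path determines the sequence and vice versa).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Iterable

from .alphabet import AMINO_ACIDS, validate_sequence
from .epitope import AllelePanel, scan_sequence
from .mutability import AllowedResidues, count_variants, enumerate_variants


class InfeasibleError(Exception):
    """No variant satisfies the requested budget/slack constraints."""


class EnumerationGuardError(Exception):
    """Brute-force space exceeds the safety guard."""


# ---------------------------------------------------------------------------
# Scorers
# ---------------------------------------------------------------------------


class PanelScorer:
    """Window-count scorer backed by an allele panel at a fixed percent level."""

    def __init__(self, panel: AllelePanel, percent: int | None = None):
        self.panel = panel
        self.percent = panel.percent_level if percent is None else percent
        self.window = panel.window
        self.alphabet = panel.alphabet
        self._cache: dict[str, int] = {}
        # pin thresholds now so scoring is pure lookups
        self._thetas = [
            (m, m.threshold_scaled(self.percent)) for m in panel.matrices
        ]

    def __call__(self, win: str) -> int:
        c = self._cache.get(win)
        if c is None:
            c = sum(
                1 for m, th in self._thetas if m._score_scaled_unchecked(win) >= th
            )
            self._cache[win] = c
        return c


class CallableScorer:
    """Adapter for a plain window -> count function (synthetic fixtures, oracles)."""

    def __init__(self, fn: Callable[[str], int], window: int, alphabet: str):
        self.fn = fn
        self.window = window
        self.alphabet = alphabet
        self._cache: dict[str, int] = {}

    def __call__(self, win: str) -> int:
        c = self._cache.get(win)
        if c is None:
            c = int(self.fn(win))
            self._cache[win] = c
        return c


# ---------------------------------------------------------------------------
# Problem and result containers
# ---------------------------------------------------------------------------


@dataclass
class Variant:
    """A designed sequence with its substitution list and integer total score."""

    sequence: str
    substitutions: list[tuple[int, str, str]]  # (1-based position, wt, mut)
    total_score: int | None = None
    sub_cost_total: int = 0

    @property
    def sub_count(self) -> int:
        return len(self.substitutions)


@dataclass
class DesignProblem:
    """A deimmunization instance: sequence + window scorer + allowed map M.

    ``sub_cost(i, a)`` is an optional non-negative integer substitution score
    (default: 1 per substitution, always 0 for the wild type); ``budget``
    bounds the total cost; ``window_cap`` forbids any window from scoring
    above its wild-type count (no new epitopes, per-window).
    """

    sequence: str
    scorer: Callable[[str], int]
    M: AllowedResidues
    sub_cost: Callable[[int, str], int] | None = None
    budget: int | None = None
    budget_mode: str = "at_most"  # or "exact"
    window_cap: bool = False

    def __post_init__(self) -> None:
        alph = getattr(self.scorer, "alphabet", None) or AMINO_ACIDS
        self.sequence = validate_sequence(self.sequence, alph)
        w = self.window
        if len(self.sequence) < w:
            raise ValueError(
                f"sequence length {len(self.sequence)} is shorter than the window ({w})"
            )
        if self.M.sequence != self.sequence:
            raise ValueError("allowed-residue map was built for a different sequence")
        if self.budget is not None and self.budget < 0:
            raise ValueError("substitution budget must be >= 0")
        if self.budget_mode not in ("at_most", "exact"):
            raise ValueError("budget_mode must be 'at_most' or 'exact'")
        for i, wt in enumerate(self.sequence, start=1):
            if self.cost(i, wt) != 0:
                raise ValueError(f"sub_cost of the wild type at position {i} must be 0")

    @property
    def window(self) -> int:
        return getattr(self.scorer, "window", 9)

    @property
    def n(self) -> int:
        return len(self.sequence)

    def cost(self, position: int, residue: str) -> int:
        """Integer substitution cost of placing ``residue`` at 1-based ``position``."""
        if residue == self.sequence[position - 1]:
            return 0
        if self.sub_cost is None:
            return 1
        c = int(self.sub_cost(position, residue))
        if c < 0:
            raise ValueError("substitution costs must be non-negative")
        return c

    def wildtype_window_counts(self) -> list[int]:
        w = self.window
        return [
            self.scorer(self.sequence[j : j + w]) for j in range(self.n - w + 1)
        ]

    def variant_from_sequence(self, seq: str, total_score: int | None = None) -> Variant:
        subs = [
            (i, wt, mut)
            for i, (wt, mut) in enumerate(zip(self.sequence, seq), start=1)
            if wt != mut
        ]
        return Variant(
            sequence=seq,
            substitutions=subs,
            total_score=self.total_score(seq) if total_score is None else total_score,
            sub_cost_total=sum(self.cost(i, mut) for i, _, mut in subs),
        )

    def total_score(self, seq: str) -> int:
        """Objective value of ``seq``: sum of window counts over all windows."""
        w = self.window
        if len(seq) != self.n:
            raise ValueError("variant length differs from the target")
        return sum(self.scorer(seq[j : j + w]) for j in range(self.n - w + 1))

    def sequence_key(self, seq: str):
        """Deterministic tie-break key: wild-type residue sorts first per position."""
        return tuple(
            (0, "") if ch == wt else (1, ch) for ch, wt in zip(seq, self.sequence)
        )


@dataclass
class DPTables:
    """Forward DP columns plus the effective window costs used to build them.

    ``cols[i]`` (for i = window-2 .. n-1, 0-based last processed position)
    maps a suffix tuple X of length window-1 to ``{s: best score}``; the base
    column charges the substitution cost of the N-terminal (w-1)-mer.
    Budget-infeasible and cap-violating states are simply absent.
    """

    problem: DesignProblem
    cols: dict[int, dict[tuple[str, ...], dict[int, int]]]
    track_s: bool = True  # False: substitution cost not indexed (s pinned to 0)

    def final_states(self) -> Iterable[tuple[tuple[str, ...], int, int]]:
        last = self.problem.n - 1
        for X, smap in self.cols[last].items():
            for s, v in smap.items():
                yield X, s, v


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------


def build_tables(problem: DesignProblem) -> DPTables:
    """Fill the budgeted suffix-state recurrence over all reachable states."""
    seq = problem.sequence
    n, w = problem.n, problem.window
    M = problem.M.allowed
    smax = problem.budget if problem.budget is not None else None

    # cheapest exit for unsatisfiable exact budgets; also lets a slack budget
    # collapse to the unindexed recurrence (s carries no information there)
    cost_bound = sum(
        max(problem.cost(i, a) for a in sset)
        for i, sset in enumerate(M, start=1)
    )
    if smax is not None and problem.budget_mode == "exact" and smax > cost_bound:
        raise InfeasibleError(
            f"exact substitution cost {smax} exceeds the maximum achievable "
            f"({cost_bound})"
        )
    if smax is not None and problem.budget_mode == "at_most" and smax >= cost_bound:
        smax = None
    track_s = smax is not None or problem.budget_mode == "exact"

    caps: list[int] | None = None
    if problem.window_cap:
        caps = problem.wildtype_window_counts()

    def window_cost(offset0: int, win: str) -> int | None:
        """Score of a window starting at 0-based offset; None if cap-forbidden."""
        c = problem.scorer(win)
        if caps is not None and c > caps[offset0]:
            return None
        return c

    # residue ordering: wild type first, then alphabetical (deterministic traces)
    def ordered(i0: int) -> list[str]:
        wt = seq[i0]
        return [wt] + sorted(M[i0] - {wt})

    cols: dict[int, dict[tuple[str, ...], dict[int, int]]] = {}

    # base column: every feasible assignment of positions 0..w-2
    base: dict[tuple[str, ...], dict[int, int]] = {}
    def grow(prefix: tuple[str, ...], cost: int, i0: int) -> None:
        if smax is not None and cost > smax:
            return
        if i0 == w - 1:
            base[prefix] = {cost: 0}
            return
        for a in ordered(i0):
            grow(prefix + (a,), cost + (problem.cost(i0 + 1, a) if track_s else 0), i0 + 1)

    grow((), 0, 0)
    cols[w - 2] = base

    for i in range(w - 1, n):  # 0-based position being fixed
        prev = cols[i - 1]
        cur: dict[tuple[str, ...], dict[int, int]] = {}
        for Xprev, smap in prev.items():
            for x_new in ordered(i):
                step = problem.cost(i + 1, x_new) if track_s else 0
                if smax is not None:
                    entries = [(s + step, v) for s, v in smap.items() if s + step <= smax]
                    if not entries:
                        continue  # budget-dead branch: never score or materialize
                else:
                    entries = [(s + step, v) for s, v in smap.items()]
                win = "".join(Xprev) + x_new
                c = window_cost(i - w + 1, win)
                if c is None:
                    continue
                Xcur = Xprev[1:] + (x_new,)
                slot = cur.setdefault(Xcur, {})
                for s2, v in entries:
                    v2 = v + c
                    if s2 not in slot or v2 < slot[s2]:
                        slot[s2] = v2
        cols[i] = cur
    return DPTables(problem=problem, cols=cols, track_s=track_s)


def _best_final(tables: DPTables, s_filter: Callable[[int], bool]) -> int | None:
    best: int | None = None
    for _, s, v in tables.final_states():
        if s_filter(s) and (best is None or v < best):
            best = v
    return best


# ---------------------------------------------------------------------------
# Backtrace / enumeration
# ---------------------------------------------------------------------------


def _traceback(
    tables: DPTables,
    target: int,
    s_filter: Callable[[int], bool],
    limit: int | None = None,
) -> list[Variant]:
    """All feasible variants with total score <= target and final cost in the filter.

    Deterministic order of discovery; each sequence appears exactly once
    (a suffix-state path and a sequence determine each other).
    """
    problem = tables.problem
    seq, n, w = problem.sequence, problem.n, problem.window
    caps = problem.wildtype_window_counts() if problem.window_cap else None
    out: list[Variant] = []

    def window_cost(offset0: int, win: str) -> int | None:
        c = problem.scorer(win)
        if caps is not None and c > caps[offset0]:
            return None
        return c

    def dfs(i: int, X: tuple[str, ...], s: int, suffix_cost: int, tail: list[str]) -> bool:
        """Extend backward from column i; tail holds residues at i+1..n-1 reversed."""
        if i == w - 2:
            full = "".join(X) + "".join(reversed(tail))
            total = suffix_cost  # all n-w+1 windows accumulated on the way down
            out.append(problem.variant_from_sequence(full, total_score=total))
            return limit is not None and len(out) >= limit
        x_new = X[-1]
        step = problem.cost(i + 1, x_new) if tables.track_s else 0
        s_prev = s - step
        if s_prev < 0:
            return False
        prev = tables.cols[i - 1]
        wt = seq[i - w + 1]
        for a in [wt] + sorted(problem.M.allowed[i - w + 1] - {wt}):
            Xprev = (a,) + X[:-1]
            smap = prev.get(Xprev)
            if smap is None or s_prev not in smap:
                continue
            c = window_cost(i - w + 1, "".join(Xprev) + x_new)
            if c is None:
                continue
            if smap[s_prev] + c + suffix_cost <= target:
                tail.append(x_new)
                stop = dfs(i - 1, Xprev, s_prev, suffix_cost + c, tail)
                tail.pop()
                if stop:
                    return True
        return False

    last = n - 1
    for X in sorted(tables.cols[last]):
        for s, v in sorted(tables.cols[last][X].items()):
            if s_filter(s) and v <= target:
                if dfs(last, X, s, 0, []):
                    return out
    return out


def _s_filter(problem: DesignProblem):
    if problem.budget is None:
        return lambda s: True
    if problem.budget_mode == "exact":
        b = problem.budget
        return lambda s: s == b
    b = problem.budget
    return lambda s: s <= b


def _rank_key(problem: DesignProblem):
    def key(v: Variant):
        return (v.total_score, v.sub_count, problem.sequence_key(v.sequence))

    return key


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


TRACE_GUARD = 100_000
"""Most tied/near-tied variants ever materialized during a traceback.

Exceeding it means the slack (or a degenerate scorer) makes the tied set
astronomically large; callers should constrain the problem (budget, smaller
epsilon) rather than enumerate it.
"""


def _traced(tables: DPTables, target: int, filt, cap: int) -> list[Variant]:
    variants = _traceback(tables, target, filt, limit=cap + 1)
    if len(variants) > cap:
        raise EnumerationGuardError(
            f"more than {cap} variants tie within the requested slack; "
            f"add a substitution budget or reduce epsilon"
        )
    return variants


def optimize(problem: DesignProblem, tables: DPTables | None = None) -> Variant:
    """Globally optimal variant under the problem's constraints.

    Ties are broken toward the wild type: among minimum-score variants the one
    with fewest substitutions is returned, residues matching wild type
    preferred position by position.
    """
    tables = tables or build_tables(problem)
    filt = _s_filter(problem)
    best = _best_final(tables, filt)
    if best is None:
        raise InfeasibleError(
            "no feasible variant satisfies the substitution budget"
            + (" (exact mode)" if problem.budget_mode == "exact" else "")
        )
    co = _traced(tables, best, filt, TRACE_GUARD)
    return min(co, key=_rank_key(problem))


def optimize_budget(
    problem: DesignProblem, s: int, mode: str = "at_most"
) -> Variant:
    """Best variant whose substitution cost is exactly / at most ``s``."""
    if s < 0:
        raise ValueError("substitution budget must be >= 0")
    constrained = DesignProblem(
        sequence=problem.sequence,
        scorer=problem.scorer,
        M=problem.M,
        sub_cost=problem.sub_cost,
        budget=s,
        budget_mode=mode,
        window_cap=problem.window_cap,
    )
    return optimize(constrained)


def enumerate_near_optimal(
    problem: DesignProblem,
    epsilon: int = 0,
    limit: int = 1000,
    tables: DPTables | None = None,
) -> list[Variant]:
    """Every feasible variant scoring within ``epsilon`` of the optimum.

    Integer ``epsilon`` is in window-allele-count units (the objective's own
    grid).  Results are ranked by (score, substitution count, wild-type-first
    lexicographic key) and truncated to ``limit``; epsilon = 0 yields the full
    co-optimal set.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if limit <= 0:
        raise ValueError("limit must be positive")
    tables = tables or build_tables(problem)
    filt = _s_filter(problem)
    best = _best_final(tables, filt)
    if best is None:
        raise InfeasibleError("no feasible variant satisfies the substitution budget")
    variants = _traced(tables, best + epsilon, filt, max(limit, TRACE_GUARD))
    variants.sort(key=_rank_key(problem))
    return variants[:limit]


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------


@dataclass
class BruteForceResult:
    """Score distribution of an exhaustively enumerated variant space."""

    histogram: Counter
    n_sequences: int
    minimum: int
    median: float
    argmin: list[Variant] = field(default_factory=list)


def brute_force(
    problem: DesignProblem,
    k: int | None = None,
    guard: int = 10**6,
) -> BruteForceResult:
    """Score every sequence of the (optionally exactly-k-substitution) space.

    Serves as the independent check on the dynamic program and reproduces the
    exhaustive-search view of the design space (score histogram, median,
    minimum, and the full argmin set).  Refuses spaces larger than ``guard``.
    """
    M = problem.M
    if k is not None:
        size = count_variants(M, k)
        seqs: Iterable[str] = enumerate_variants(M, k)
    else:
        size = 1
        for sset in M.allowed:
            size *= len(sset)
            if size > guard:
                break
        wt = M.sequence
        choices = [[w] + sorted(s - {w}) for s, w in zip(M.allowed, wt)]
        seqs = ("".join(t) for t in product(*choices))
    if size > guard:
        raise EnumerationGuardError(
            f"exhaustive space has {size} sequences, above the guard ({guard})"
        )
    caps = problem.wildtype_window_counts() if problem.window_cap else None
    w = problem.window
    filt = _s_filter(problem)
    hist: Counter = Counter()
    best: int | None = None
    argmin: list[str] = []
    n_seen = 0
    for sq in seqs:
        cost = sum(problem.cost(i, ch) for i, ch in enumerate(sq, start=1))
        if not filt(cost):
            continue
        if caps is not None and any(
            problem.scorer(sq[j : j + w]) > caps[j] for j in range(problem.n - w + 1)
        ):
            continue
        total = problem.total_score(sq)
        hist[total] += 1
        n_seen += 1
        if best is None or total < best:
            best = total
            argmin = [sq]
        elif total == best:
            argmin.append(sq)
    if best is None:
        raise InfeasibleError("no sequence in the enumerated space satisfies the constraints")
    scores = sorted(hist.elements())
    mid = len(scores) // 2
    median = (
        float(scores[mid])
        if len(scores) % 2
        else (scores[mid - 1] + scores[mid]) / 2.0
    )
    argmin_variants = [problem.variant_from_sequence(sq, total_score=best) for sq in argmin]
    argmin_variants.sort(key=_rank_key(problem))
    return BruteForceResult(
        histogram=hist,
        n_sequences=n_seen,
        minimum=best,
        median=median,
        argmin=argmin_variants,
    )
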