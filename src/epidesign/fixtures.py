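"""Deterministic synthetic fixtures: matrices, allowed maps, trees, problems.

Everything here is a pure function of its spec (seed included), so the whole
pipeline is exercisable offline with no external matrix sets, alignments or
structures.  These generators make no attempt to imitate real HLA binding
motif statistics; they exist to give the scoring engine and the optimizer
known ground truth:

* ``random_panel`` draws pocket-profile weights on the one-decimal grid and
  calibrates thresholds exactly, so tail probabilities are known.
* ``planted_problem`` builds a design instance whose optimal score after any
  number of substitutions has a closed form computed by independent
  combinatorial bookkeeping (including the promiscuous-position scenario
  where one substitution clears several overlapping hot windows).
* ``random_problem`` pairs a random panel with a random sparse allowed map,
  sized so a brute-force oracle stays tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .alphabet import AMINO_ACIDS
from .design import CallableScorer, DesignProblem, PanelScorer
from .epitope import AllelePanel, PocketProfileMatrix
from .mutability import AllowedResidues


@dataclass
class FixtureSpec:
    """Parameters of a synthetic fixture; equal specs yield identical fixtures."""

    seed: int = 0
    length: int = 12
    alphabet: str = AMINO_ACIDS
    window: int = 9
    n_alleles: int = 3
    weight_sd: float = 1.0
    weight_sparsity: float = 0.5  # fraction of weight cells forced to zero
    percent: int = 10
    max_allowed: int = 3  # residues per position, wild type included
    n_mutable: int = 4  # positions with more than just the wild type
    planted: list[tuple[int, str, str]] = field(default_factory=list)
    # planted: (1-based position, hot residue, designated fix residue)


def random_matrix(spec: FixtureSpec, allele_id: str, rng: np.random.Generator) -> PocketProfileMatrix:
    w, L = spec.window, len(spec.alphabet)
    weights = np.round(rng.normal(0.0, spec.weight_sd, size=(w, L)), 1)
    mask = rng.random(size=(w, L)) < spec.weight_sparsity
    weights[mask] = 0.0
    return PocketProfileMatrix(
        allele_id, weights, alphabet=spec.alphabet, window=spec.window
    )


def random_panel(spec: FixtureSpec) -> AllelePanel:
    """Seeded panel of random one-decimal matrices with exact thresholds."""
    rng = np.random.default_rng(spec.seed)
    mats = [
        random_matrix(spec, f"SYN*{i:04d}", rng) for i in range(spec.n_alleles)
    ]
    for m in mats:
        m.calibrate_threshold(spec.percent)
    return AllelePanel(mats, percent_level=spec.percent)


def random_sequence(spec: FixtureSpec, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(spec.alphabet), size=spec.length))


def random_allowed(spec: FixtureSpec, sequence: str, rng: np.random.Generator) -> AllowedResidues:
    """Sparse allowed map: ``n_mutable`` positions get up to ``max_allowed`` residues."""
    n = len(sequence)
    sets = [{wt} for wt in sequence]
    mutable = rng.choice(n, size=min(spec.n_mutable, n), replace=False)
    for p in mutable:
        extra = rng.choice(
            [a for a in spec.alphabet if a != sequence[p]],
            size=spec.max_allowed - 1,
            replace=False,
        )
        sets[p] |= set(extra)
    return AllowedResidues(sequence, [frozenset(s) for s in sets], source="explicit")


def random_problem(spec: FixtureSpec) -> DesignProblem:
    """Random panel + random sequence + sparse allowed map, brute-forceable."""
    rng = np.random.default_rng(spec.seed)
    panel = random_panel(spec)
    seq = random_sequence(spec, rng)
    M = random_allowed(spec, seq, rng)
    return DesignProblem(sequence=seq, scorer=PanelScorer(panel, spec.percent), M=M)


# ---------------------------------------------------------------------------
# Planted problems with closed-form optima
# ---------------------------------------------------------------------------


@dataclass
class PlantedProblem:
    """A design instance whose exact optima are known by construction."""

    problem: DesignProblem
    hot_residue: str
    hot_positions: list[int]  # 1-based
    n_alleles: int
    expected_optimum: dict[int, int]  # substitution count k -> optimal total score


def _windows_hit(n: int, w: int, hot_positions: set[int]) -> int:
    """Number of windows (1-based starts) containing at least one hot position."""
    count = 0
    for j in range(1, n - w + 2):
        if any(j <= p <= j + w - 1 for p in hot_positions):
            count += 1
    return count


def planted_problem(spec: FixtureSpec) -> PlantedProblem:
    """Build a problem where windows containing a designated hot residue are
    recognized by every allele and the designated fixes are the only moves.

    The scorer counts ``n_alleles`` for any window containing the hot residue
    letter and 0 otherwise; the hot letter occurs in the wild type exactly at
    the planted positions, and each planted position may only be left alone or
    substituted to its designated fix.  The optimal exactly-k-substitution
    score therefore has a closed form — minimize, over k-subsets of planted
    positions to fix, the number of windows still containing a hot position —
    evaluated here by direct subset enumeration, an accounting wholly
    independent of the scanning and DP machinery it validates.
    """
    if not spec.planted:
        raise ValueError("spec.planted must name at least one (position, hot, fix)")
    rng = np.random.default_rng(spec.seed)
    hot = {h for _, h, _ in spec.planted}
    if len(hot) != 1:
        raise ValueError("all plants must share a single hot residue")
    hot_res = next(iter(hot))
    fixes = {p: f for p, _, f in spec.planted}
    if any(f == hot_res for f in fixes.values()):
        raise ValueError("a designated fix equal to the hot residue is inconsistent")
    positions = sorted(fixes)
    if positions[0] < 1 or positions[-1] > spec.length:
        raise ValueError("planted positions outside the sequence")

    safe = [a for a in spec.alphabet if a != hot_res]
    seq = list(rng.choice(safe, size=spec.length))
    for p in positions:
        seq[p - 1] = hot_res
    sequence = "".join(seq)

    sets = [frozenset({wt}) for wt in sequence]
    for p, f in fixes.items():
        sets[p - 1] = frozenset({hot_res, f})
    M = AllowedResidues(sequence, list(sets), source="explicit")

    def count(win: str) -> int:
        return spec.n_alleles if hot_res in win else 0

    scorer = CallableScorer(count, window=spec.window, alphabet=spec.alphabet)
    problem = DesignProblem(sequence=sequence, scorer=scorer, M=M)

    expected: dict[int, int] = {}
    for k in range(len(positions) + 1):
        best = min(
            _windows_hit(spec.length, spec.window, set(positions) - set(sub))
            for sub in combinations(positions, k)
        )
        expected[k] = best * spec.n_alleles
    return PlantedProblem(
        problem=problem,
        hot_residue=hot_res,
        hot_positions=positions,
        n_alleles=spec.n_alleles,
        expected_optimum=expected,
    )
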