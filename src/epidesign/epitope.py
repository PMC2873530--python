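"""Additive pocket-profile scoring of 9-mer peptides against MHC-II (HLA-DR) alleles.

The model: each allele carries a 9 x 20 table of position-specific binding
weights (a "pocket profile"); a peptide's score is the sum of the nine
per-position weights, and the peptide is called an epitope for the allele when
its score reaches the allele's threshold for a chosen stringency level
(1-10 %, smaller = stricter).

Weights are read at one-decimal precision and held internally as integers
scaled by 10.  All score and threshold comparisons are therefore exact integer
arithmetic: there are no floating-point ties anywhere in calibration or in the
downstream sequence-design dynamic program.

Threshold calibration is exact.  With each window position drawn uniformly
from the alphabet, the score distribution over all 20^9 peptides is the
9-fold convolution of the per-position weight distributions; the threshold for
level p is the smallest attained score whose upper-tail fraction is <= p/100.
Explicitly supplied thresholds (e.g. a published per-allele table) override
the built-in calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, validate_peptide, validate_sequence

DEFAULT_ALLELES = (
    "DRB1*0101",
    "DRB1*0301",
    "DRB1*0401",
    "DRB1*0701",
    "DRB1*0801",
    "DRB1*1101",
    "DRB1*1301",
    "DRB1*1501",
)

SCALE = 10  # one-decimal weight grid -> integer arithmetic


class DegenerateMatrixWarning(UserWarning):
    """Raised when a matrix scores every peptide identically (no peptide recognized)."""


def _as_scaled(weights: np.ndarray) -> np.ndarray:
    """Round a float weight table to one decimal and scale to int64."""
    w = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("matrix weights must be finite")
    return np.rint(np.round(w, 1) * SCALE).astype(np.int64)


class PocketProfileMatrix:
    """One allele's additive position x residue weight table plus threshold map.

    Parameters
    ----------
    allele_id : nonempty allele name, e.g. ``"DRB1*0101"``.
    weights : (window, len(alphabet)) array of per-position, per-residue
        weights, one-decimal precision.  Columns follow ``alphabet`` order.
    thresholds : optional explicit ``{percent: score}`` map (unscaled, same
        units as the weights).  Explicit entries override calibration.
    alphabet, window : the engine is generic so small-alphabet oracle tests
        can enumerate exhaustively; the public panel surface pins the
        20-letter alphabet and 9-mer windows.
    """

    def __init__(
        self,
        allele_id: str,
        weights,
        thresholds: dict[int, float] | None = None,
        alphabet: str = AMINO_ACIDS,
        window: int = 9,
    ):
        if not allele_id:
            raise ValueError("allele_id must be nonempty")
        self.allele_id = allele_id
        self.alphabet = alphabet
        self.window = window
        self._index = {a: i for i, a in enumerate(alphabet)}
        scaled = _as_scaled(weights)
        if scaled.shape != (window, len(alphabet)):
            raise ValueError(
                f"weights for {allele_id} must have shape ({window}, {len(alphabet)}), "
                f"got {scaled.shape}"
            )
        self.weights_scaled = scaled
        self._explicit_thresholds: dict[int, int] = {}
        self._calibrated: dict[int, int] = {}
        if thresholds:
            for pct, theta in thresholds.items():
                self.set_threshold(int(pct), float(theta))

    # -- weights ----------------------------------------------------------
    @property
    def weights(self) -> np.ndarray:
        """Weight table in natural (unscaled) units."""
        return self.weights_scaled / SCALE

    def set_threshold(self, percent: int, value: float) -> None:
        if not 1 <= percent <= 10:
            raise ValueError(f"percent level must be in 1..10, got {percent}")
        self._explicit_thresholds[percent] = int(np.rint(round(value, 1) * SCALE))

    @property
    def thresholds(self) -> dict[int, float]:
        out = dict(self._calibrated)
        out.update(self._explicit_thresholds)
        return {p: v / SCALE for p, v in sorted(out.items())}

    # -- scoring ----------------------------------------------------------
    def score_scaled(self, pep: str) -> int:
        pep = validate_peptide(pep, self.window, self.alphabet)
        return self._score_scaled_unchecked(pep)

    def _score_scaled_unchecked(self, pep: str) -> int:
        # hot path for the design DP: input already validated upstream
        idx = self._index
        W = self.weights_scaled
        total = 0
        for p, c in enumerate(pep):
            total += W[p, idx[c]]
        return int(total)

    def score(self, pep: str) -> float:
        """Sum of position-specific weights over the peptide (natural units)."""
        return self.score_scaled(pep) / SCALE

    # -- exact score distribution and calibration -------------------------
    def score_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact distribution of scaled scores over all |alphabet|^window peptides.

        Returns sorted unique scaled score values and their exact integer
        counts (python ints held in an object array would be overkill: counts
        fit comfortably in int64 up to 20^9 and beyond for float-free sums —
        they are returned as an object ndarray of python ints to stay exact
        for any window/alphabet combination).
        """
        dist: dict[int, int] = {0: 1}
        for p in range(self.window):
            nxt: dict[int, int] = {}
            row = self.weights_scaled[p]
            for v, cnt in dist.items():
                for wgt in row:
                    key = v + int(wgt)
                    nxt[key] = nxt.get(key, 0) + cnt
            dist = nxt
        values = np.array(sorted(dist), dtype=np.int64)
        counts = np.array([dist[int(v)] for v in values], dtype=object)
        return values, counts

    def calibrate_threshold(self, percent: int) -> float:
        """Exact threshold for the top-``percent``-% stringency level.

        The threshold is the smallest attained score whose upper-tail
        fraction over all |alphabet|^window peptides is <= percent/100
        (integer-exact comparison).  If no attained score qualifies — every
        peptide scores the same — the threshold is placed one grid step above
        the constant so that no peptide is recognized, with a warning.
        """
        if not 1 <= percent <= 10:
            raise ValueError(f"percent level must be in 1..10, got {percent}")
        if percent in self._explicit_thresholds:
            return self._explicit_thresholds[percent] / SCALE
        if percent not in self._calibrated:
            self._calibrated[percent] = self._calibrate_scaled(percent)
        return self._calibrated[percent] / SCALE

    def threshold_scaled(self, percent: int) -> int:
        self.calibrate_threshold(percent)
        if percent in self._explicit_thresholds:
            return self._explicit_thresholds[percent]
        return self._calibrated[percent]

    def _calibrate_scaled(self, percent: int) -> int:
        values, counts = self.score_distribution()
        total = len(self.alphabet) ** self.window
        tail = 0
        theta: int | None = None
        # walk from the top score down; stop before the tail fraction exceeds p
        for v, cnt in zip(values[::-1], counts[::-1]):
            tail += int(cnt)
            if tail * 100 > percent * total:
                break
            theta = int(v)
        if theta is None:
            theta = int(values[-1]) + 1
            if len(values) == 1:
                warnings.warn(
                    f"matrix {self.allele_id}: degenerate (constant) score "
                    f"distribution; threshold set above the constant, no peptide "
                    f"is recognized",
                    DegenerateMatrixWarning,
                    stacklevel=2,
                )
        return theta


@dataclass
class AllelePanel:
    """Ordered set of pocket-profile matrices scored together.

    The epitope score of a window is the number of panel alleles whose
    threshold it meets (the fraction-of-panel form divides by the panel size
    and is a pure display transform).
    """

    matrices: list[PocketProfileMatrix]
    percent_level: int = 10

    def __post_init__(self) -> None:
        ids = [m.allele_id for m in self.matrices]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate allele ids in panel: {ids}")
        if not 1 <= self.percent_level <= 10:
            raise ValueError("percent_level must be in 1..10")
        if not self.matrices:
            raise ValueError("panel must contain at least one matrix")
        w = {m.window for m in self.matrices}
        a = {m.alphabet for m in self.matrices}
        if len(w) != 1 or len(a) != 1:
            raise ValueError("all panel matrices must share window and alphabet")

    @property
    def allele_ids(self) -> list[str]:
        return [m.allele_id for m in self.matrices]

    @property
    def window(self) -> int:
        return self.matrices[0].window

    @property
    def alphabet(self) -> str:
        return self.matrices[0].alphabet

    def __len__(self) -> int:
        return len(self.matrices)

    def window_count(self, pep: str, percent: int | None = None) -> int:
        """Number of panel alleles recognizing the peptide at the given level."""
        pct = self.percent_level if percent is None else percent
        return sum(
            1 for m in self.matrices if m.score_scaled(pep) >= m.threshold_scaled(pct)
        )


@dataclass
class EpitopeProfile:
    """Per-window allele hits over a scanned sequence.

    ``windows[i]`` (0-based start offset) maps allele_id -> raw score for the
    window starting there; ``hits[i]`` is the set of allele ids meeting their
    threshold.  ``E`` is the total predicted epitope count: the sum of hit-set
    sizes over all ``n - window + 1`` windows.
    """

    sequence: str
    percent: int
    allele_ids: list[str]
    window: int = 9
    scores: list[dict[str, float]] = field(default_factory=list)
    hits: list[frozenset[str]] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.sequence) - self.window + 1

    @property
    def window_counts(self) -> list[int]:
        return [len(h) for h in self.hits]

    @property
    def total(self) -> int:
        """E: total number of (window, allele) predicted epitopes."""
        return sum(len(h) for h in self.hits)

    def fraction_counts(self) -> list[float]:
        """Per-window epitope score as the fraction of panel alleles hit."""
        k = len(self.allele_ids)
        return [len(h) / k for h in self.hits]


def score_peptide(matrix: PocketProfileMatrix, pep: str) -> float:
    """Additive pocket-profile score: sum of the per-position weights of ``pep``."""
    return matrix.score(pep)


def calibrate_thresholds(matrix: PocketProfileMatrix, percent: int) -> float:
    """Exact-convolution threshold for the given stringency level (see class docs)."""
    return matrix.calibrate_threshold(percent)


def scan_sequence(panel: AllelePanel, seq: str, percent: int | None = None) -> EpitopeProfile:
    """Score every window of ``seq`` against every panel allele.

    A window is a hit for an allele iff its additive score meets the allele's
    threshold at the requested stringency level (inclusive comparison).
    """
    pct = panel.percent_level if percent is None else percent
    w = panel.window
    seq = validate_sequence(seq, panel.alphabet)
    if len(seq) < w:
        raise ValueError(f"sequence length {len(seq)} is shorter than the window ({w})")
    thetas = {m.allele_id: m.threshold_scaled(pct) for m in panel.matrices}
    scores: list[dict[str, float]] = []
    hits: list[frozenset[str]] = []
    for i in range(len(seq) - w + 1):
        win = seq[i : i + w]
        sc = {m.allele_id: m.score_scaled(win) for m in panel.matrices}
        hits.append(
            frozenset(aid for aid, s in sc.items() if s >= thetas[aid])
        )
        scores.append({aid: s / SCALE for aid, s in sc.items()})
    return EpitopeProfile(
        sequence=seq,
        percent=pct,
        allele_ids=panel.allele_ids,
        window=w,
        scores=scores,
        hits=hits,
    )


def recognition_histogram(
    panel: AllelePanel,
    percent: int | None = None,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo histogram of peptides recognized by exactly m panel alleles.

    Samples ``n_samples`` windows uniformly over alphabet^window and returns a
    length ``len(panel)+1`` vector of fractions (summing to 1): entry m is the
    fraction of sampled peptides recognized by exactly m alleles at the given
    stringency level.  Bit-reproducible for a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    pct = panel.percent_level if percent is None else percent
    rng = np.random.default_rng(seed)
    w, L = panel.window, len(panel.alphabet)
    idx = rng.integers(0, L, size=(n_samples, w))
    n_hit = np.zeros(n_samples, dtype=np.int64)
    pos = np.arange(w)
    for m in panel.matrices:
        theta = m.threshold_scaled(pct)
        sc = m.weights_scaled[pos, idx].sum(axis=1)
        n_hit += sc >= theta
    counts = np.bincount(n_hit, minlength=len(panel) + 1)
    return counts / n_samples
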