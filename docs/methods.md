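# Methods

This note records the model, the numerical conventions, the synthetic test
conditions, and the genuinely open design choices in `epidesign`. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scoring model and threshold calibration

A pocket-profile matrix is a 9 × 20 table of additive per-position,
per-residue binding weights for one HLA-DR allele; a 9-mer's score is the
sum of its nine weights, and the peptide is predicted to bind when the score
reaches the allele's threshold at a stringency level of 1–10 % (the top k %
of all peptides). The additive form ignores position coupling inside the
MHC-II groove; that is the standard pocket-profile assumption and everything
downstream inherits it.

**Decimal grid.** Published pocket-profile weights carry one decimal, so
weights are rounded to one decimal on input and held as integers scaled by
10. Every score, threshold, and dynamic-programming comparison is exact
integer arithmetic: there are no floating-point ties anywhere.

**Exact calibration.** With each window position uniform over the 20
residues, the score distribution over all 20⁹ peptides is the 9-fold
convolution of the per-position weight distributions, computed exactly with
integer counts. The threshold for level k is defined as the **smallest
attained score whose upper-tail fraction is ≤ k/100**. Restricting
candidates to attained scores makes the rule well-posed on the grid (the
infimum over all grid points would collapse to one step below the tail
boundary) and gives the natural degenerate behavior: if no attained score
qualifies — e.g. a constant distribution — the threshold is placed one grid
step above the maximum, no peptide is recognized, and a warning is emitted.
The hit rule is inclusive (score ≥ θ). Thresholds are non-increasing as the
level loosens from 1 % to 10 %.

**Published thresholds.** The derivation set behind the published per-allele
1–10 % threshold tables is not documented; exact convolution over the
uniform peptide space is this package's own calibration. Explicitly supplied
`#threshold` lines in a matrix file override calibration and are the
fidelity path for reproducing published epitope counts. The published
HLA-DRB1 matrix set itself is not redistributed with the package; users who
have it can convert it to the matrix TSV dialect and place it at
`tests/data/propred/drb1_matrices.tsv` to activate the fidelity tests.

**Window length** is fixed at 9 on the public surface. The engine is written
against a generic (alphabet, window) pair solely so that small-alphabet
oracle tests (4 letters, window 3, ≤ 4¹⁰ enumeration) can validate
calibration, scanning, and the DP against total enumeration.

**Non-standard residues** (B, J, O, U, X, Z) and gaps are rejected with the
offending character named, never skipped: a silently dropped window would
silently change every total epitope count.

## Allowed-residue predicates

All three builders admit the wild type at every position unconditionally,
and tightening any cutoff can only shrink the sets.

* **Relative BLOSUM-62** (default cutoff 4): residue x is allowed at
  position i iff B(wt, wt) − B(wt, x) ≤ 4, using biopython's packaged
  BLOSUM-62 table. The per-substitution report metric is the 0/1 disallowed
  flag. On the packaged 17-residue fragment this rule yields per-position
  set sizes averaging 4.2 (computed, not assumed, by the acceptance
  machinery) — a position whose wild type is proline allows only proline.
* **Tree-weighted conservation** (default frequency floor 0.05): sequence
  weights follow the bottom-up edge-apportionment scheme
  (Gerstein–Sonnhammer–Chothia): visiting edges leaf-to-root, each edge's
  length is split among the leaves below in proportion to their accumulated
  weights, equally while all are zero. Duplicating a leaf at zero distance
  splits that leaf's weight and leaves all others unchanged, which is
  exactly the redundancy guard the weighting exists for. Column frequencies
  are weighted fractions over non-gap rows (the denominator excludes gap
  rows; the choice is ours — alternatives would distort columns with many
  gaps). The penalty is −ln f, so the admission boundary f = 0.05 carries
  penalty ≈ 3.00 and f = 0.01 carries 4.61; natural log is required for
  those two anchors to hold simultaneously. Unseen residues (f = 0) are
  capped at −ln 10⁻⁶ to keep reports finite and are never allowed. The
  frequency rule is "f ≥ floor": admitting only residues *rarer* than the
  floor would contradict the predicate's purpose. An all-gap column admits
  only the wild type, with a warning. Without a tree, uniform weights are
  used and a warning notes the redundancy risk.
* **ΔΔG° filter** (default margin 0.25 kcal/mol): an external
  per-substitution energy table (TSV, wild-type self rows required) is
  re-referenced so the wild type is 0; residues with relative ΔΔG° ≤ margin
  (inclusive boundary) are allowed. The package parses and filters the
  table; it never computes energies.

Substitutions are treated independently throughout — no pairwise coupling
of stability effects. That is a deliberate scope boundary, not an oversight;
candidate variants should go to a structure-aware tool for post-hoc
assessment of non-additive effects.

## The dynamic program

States are (position i, last-8-mer X), with X drawn componentwise from M;
the base column enumerates the feasible N-terminal 8-mers, each later column
extends by one residue and pays the count of alleles hitting the newly
completed 9-mer. Key implementation commitments:

* **Sparse state materialization.** Only states reachable through M exist;
  there is never a dense n × 20⁸ table. With a substitution budget, base
  states above the budget are never created and budget-dead transitions are
  pruned *before* the window is scored, which is what keeps dense
  (ΔΔG°-style) allowed maps tractable under small budgets.
* **Budget index.** R[i, X, s] tracks exact integer substitution cost
  (default cost: 1 per substitution). "At most s" minimizes over s′ ≤ s.
  When no budget binds (none given, or an at-most bound at or above the
  maximum achievable cost) the s index is dropped entirely; an exact-mode
  budget above the maximum achievable cost is reported infeasible without
  building tables.
* **Tie-breaking** is total and deterministic: (total score, substitution
  count, lexicographic key in which the wild-type residue sorts first at
  each position). Only the wild-type preference is scientifically mandated;
  the rest is this package's convention, chosen so identical inputs always
  produce byte-identical outputs.
* **Near-optimal enumeration** uses the classic slack-carrying backtrace:
  a completion is expanded while best-prefix + step + suffix ≤ optimum + ε.
  Since a state path determines the sequence and vice versa, each variant is
  produced exactly once. ε is in integer window-allele-count units. Results
  are fully materialized, ranked, then truncated to the caller's limit; a
  guard (100 000 traces) turns pathological tie explosions (e.g. a scorer
  that zeroes everything with no budget) into an explicit error suggesting a
  budget, rather than memory exhaustion.
* **No-new-epitope mode** (`window_cap`): transitions whose window would
  score above its wild-type count are simply forbidden. Off by default —
  per-window non-deterioration is normally an observed outcome of global
  optimization, not a constraint — but the DP admits it at no asymptotic
  cost.
* **Problem sizes.** Cost scales with the product of allowed-set sizes over
  any 8 consecutive positions. Peptide-scale problems (n ≈ 17, BLOSUM sets)
  solve in milliseconds under budgets of a few substitutions; unbudgeted
  runs over dense allowed maps grow with that product and are the regime
  where budgets (the normal use) should be set.

A brute-force oracle (`brute_force`) scores every sequence of the allowed
space, or its exactly-k-substitution slice, behind a 10⁶-sequence guard. It
exists to check the DP and to expose the score histogram of a design space
(median, minimum, argmin multiplicity); the test suite holds the DP equal to
it on hundreds of seeded random instances.

## Synthetic fixtures: what they do and do not show

Generators are pure functions of their spec, seed included.

* `random_panel` draws weights i.i.d. normal (σ = 1.0 by default, half the
  cells zeroed, rounded to the decimal grid) and calibrates thresholds
  exactly. Random instances for DP/oracle equivalence use n = 9–14,
  1–3 alleles, and ≤ 3 allowed residues at 3–5 mutable positions, keeping
  exhaustive enumeration comfortably inside the oracle guard while still
  exercising overlapping-window interactions.
* `planted_problem` makes windows containing a designated hot residue score
  the full panel and gives each planted position exactly one fix; the
  exact-k optimum then has a closed form evaluated by independent subset
  accounting. Plants at a shared overlap reproduce the promiscuous-position
  effect (one substitution deleting several overlapping predicted epitopes).

These fixtures validate the *machinery* — calibration tails, scan totals,
DP optimality, enumeration completeness. They are i.i.d. and motif-free, so
passing tests say nothing about real HLA binding specificity; fidelity to
published per-allele predictions additionally needs the published matrix and
threshold set loaded through the matrix dialect, and full-protein case
studies further need the real sequences, family alignments, and energy
tables.

## Coordinates, formats, determinism

1-based inclusive positions everywhere, with a user-supplied numbering
offset so a fragment starting at residue 71 reports "V79T". Variant display
uses dot-strings ("........T.F......") and mutation lists; both parse back
losslessly. Reports carry epitope counts at 10 % and 5 % by default, real
columns render with two decimals, and the external-predictor column S is
input-only (rendered "n/a" when absent). The target FASTA must be
single-record — picking the first of several silently would be a trap. All
randomness flows through explicit seeds; identical configuration and seed
give byte-identical outputs, and the run manifest echoes the configuration,
package version, and seed.

## Known limitations

* The additive 9-mer model ignores flanking-residue effects and peptide
  processing; predicted epitope counts are a design objective, not an
  immunogenicity measurement.
* Stability predicates are independent per position; compensating or
  conflicting substitution pairs are invisible to them.
* Exact-convolution calibration assumes a uniform background over peptide
  space; published threshold tables, where available, supersede it.
* Unbudgeted optimization over dense allowed maps can be memory- and
  time-hungry (state space is the product of allowed-set sizes over 8
  consecutive positions); use substitution budgets, which is also how the
  method is meant to be driven in practice.
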