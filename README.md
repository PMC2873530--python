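# epidesign

Globally optimal T-cell epitope removal for protein deimmunization.

Therapeutic proteins of non-human origin are routinely recognized by the
patient's immune system: peptide fragments of the protein are displayed on
MHC class II (in humans, predominantly HLA-DR) and can trigger an
anti-biotherapeutic T-cell response. One mitigation strategy is *epitope
deletion* — introducing a small number of point substitutions that destroy
predicted MHC-II binding peptides while leaving the protein stable and
active. `epidesign` is a toolkit for protein engineers that makes this a
global optimization rather than a local, epitope-by-epitope patch job.

## The model

**Epitope score.** Each HLA-DR allele *a* carries a pocket-profile matrix
*W<sup>a</sup> ∈ ℝ<sup>9×20</sup>* of additive position-specific binding
weights. A 9-mer peptide *p* scores
*score<sub>a</sub>(p) = Σ<sub>j=1..9</sub> W<sup>a</sup>[j, p<sub>j</sub>]*,
and is called an epitope for *a* when the score reaches the allele's
threshold *θ<sub>a</sub>(k)* for a stringency level *k* ∈ 1..10 % (the top
*k* % best-recognized peptides). For a panel *A* of alleles (canonically the
eight common DRB1 alleles \*0101, \*0301, \*0401, \*0701, \*0801, \*1101,
\*1301, \*1501), the epitope score of a window is the number of panel
alleles hitting it, and the objective for a sequence *S* of length *n* is
the total predicted epitope content

> E(S) = Σ<sub>i=1..n−8</sub> Σ<sub>a∈A</sub> 1{score<sub>a</sub>(S<sub>i..i+8</sub>) ≥ θ<sub>a</sub>(k)}.

Thresholds are calibrated *exactly*: the score distribution over all
20<sup>9</sup> peptides is the 9-fold convolution of the per-position weight
distributions, computed on an integer grid (weights carry one decimal), and
θ is the smallest attained score whose upper tail is ≤ k/100. A published
per-allele threshold table can be supplied instead and takes precedence.

**Allowed residues.** A map *M(i)* ⊆ {A..Y} restricts each position to
substitutions deemed safe for stability/activity, always including the
wild type. Three builders are provided:

* relative BLOSUM-62: allow *x* at position *i* iff
  B(wt<sub>i</sub>, wt<sub>i</sub>) − B(wt<sub>i</sub>, x) ≤ 4;
* family conservation: allow residues whose tree-weighted frequency in a
  family alignment is ≥ 5 % (sequences weighted bottom-up on the phylogeny
  so redundant close homologs are not over-counted);
* ΔΔG°: allow residues predicted ≤ 0.25 kcal/mol less stable than wild type,
  from an externally computed per-substitution energy table.

**Optimization.** Because a window sees only 9 consecutive residues, the
problem has optimal substructure over 8-mer suffix states:

> T[i, X] = min<sub>x ∈ M(i−8)</sub> T[i−1, (x, X<sub>1..7</sub>)] + c(x·X),

with T[8, ·] = 0, where *c* counts the alleles hitting the 9-mer *x·X*. An
extra index R[i, X, s] tracks exact substitution count (or a user-supplied
integer substitution cost), giving optima under "exactly s" / "at most s"
budgets. The DP materializes only states reachable through *M*, finds the
provably global minimum, prefers the wild type on ties, and enumerates all
variants within a slack ε of the optimum by a slack-carrying backtrace.

## Worked example

The packaged fixture is the immunodominant staphylokinase fragment SakSTAR
71–87 (`TAYKEFRVVELDPSAKI`). With a synthetic 8-allele panel (seeded, exact
thresholds) and the BLOSUM-62 allowed sets:

```python
import epidesign as ed
from epidesign.fixtures import FixtureSpec, random_panel
from epidesign.design import DesignProblem, PanelScorer, optimize_budget

panel = random_panel(FixtureSpec(seed=8, n_alleles=8, weight_sparsity=0.3))
wt = ed.SAKSTAR_71_87
M, penalties = ed.blosum_allowed(wt)

print(ed.scan_sequence(panel, wt, 10).window_counts)
v = optimize_budget(DesignProblem(sequence=wt, scorer=PanelScorer(panel, 10), M=M),
                    1, mode="at_most")
r = ed.evaluate_variant(v, panel, penalties, percents=(10,), offset=71, wildtype=wt)
print(ed.dot_string(v, wt), r.mutations, "E10:", r.E[10], "B:", r.B)
```

prints

```
[0, 0, 0, 2, 3, 2, 0, 0, 0]
.......I......... V78I E10: 3 B: 0
```

The wild-type fragment carries 7 predicted epitopes concentrated in three
overlapping windows (starts 74–76). Position 78 lies inside all three — a
*promiscuous* position — so the single conservative substitution V78I
(BLOSUM penalty B = 0) deletes 4 of the 7 predicted epitopes at once; the
optimizer proves that no second allowed substitution removes any of the
remaining 3.

The same pipeline is scriptable from the shell:

```bash
epidesign design --sequence src/epidesign/data/sakstar_71_87.fasta \
    --matrices panel.tsv --offset 71 --budget 2 --out-dir out/
epidesign scan --sequence my.fasta --matrices panel.tsv --percent 5
epidesign exhaust --sequence my.fasta --matrices panel.tsv -k 2
```

`design` writes a ranked variant table (dot-string, mutation list, epitope
counts at 10 %/5 %, BLOSUM/conservation/ΔΔG° penalty sums), per-variant
epitope profiles and per-allele maps, and a run manifest. Exit codes: 0
success, 2 input error, 3 infeasible/empty.

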