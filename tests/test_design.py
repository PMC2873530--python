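"""The design dynamic program against brute-force oracles and planted optima."""

import pytest

import epidesign as ed
from epidesign.design import (
    CallableScorer,
    DesignProblem,
    EnumerationGuardError,
    InfeasibleError,
    brute_force,
    enumerate_near_optimal,
    optimize,
    optimize_budget,
)
from epidesign.fixtures import FixtureSpec, planted_problem, random_problem

AA = ed.AMINO_ACIDS


def naive_total(problem, seq):
    """Independent rescoring: plain double loop over windows."""
    w = problem.window
    return sum(problem.scorer(seq[j : j + w]) for j in range(len(seq) - w + 1))


def specs(n_instances, start_seed=0):
    for seed in range(start_seed, start_seed + n_instances):
        yield FixtureSpec(
            seed=seed,
            length=9 + seed % 6,  # n in 9..14
            window=9,
            n_alleles=1 + seed % 3,
            max_allowed=2 + seed % 2,  # <= 3 residues per position
            n_mutable=3 + seed % 3,
            percent=10,
        )


class TestOptimize:
    def test_singleton_map_returns_wildtype(self):
        spec = FixtureSpec(seed=3, length=11, n_mutable=0)
        prob = random_problem(spec)
        v = optimize(prob)
        assert v.sequence == prob.sequence
        assert v.total_score == naive_total(prob, prob.sequence)
        assert v.substitutions == []

    def test_matches_brute_force(self):
        for spec in specs(40):
            prob = random_problem(spec)
            bf = brute_force(prob)
            v = optimize(prob)
            assert v.total_score == bf.minimum, spec.seed
            assert v.total_score == naive_total(prob, v.sequence)

    def test_never_worse_than_wildtype(self):
        for spec in specs(10, start_seed=100):
            prob = random_problem(spec)
            assert optimize(prob).total_score <= naive_total(prob, prob.sequence)

    def test_wildtype_preferred_on_ties(self):
        # zero scorer: every sequence ties at 0 -> wild type must come back
        for seed in (0, 1):
            spec = FixtureSpec(seed=seed, length=12, n_mutable=4)
            prob = random_problem(spec)
            tied = DesignProblem(
                sequence=prob.sequence,
                scorer=CallableScorer(lambda win: 0, window=9, alphabet=AA),
                M=prob.M,
            )
            assert optimize(tied).sequence == tied.sequence

    def test_feasibility_of_returned_variant(self):
        for spec in specs(10, start_seed=50):
            prob = random_problem(spec)
            v = optimize(prob)
            for i, ch in enumerate(v.sequence):
                assert ch in prob.M.allowed[i]

    def test_determinism(self):
        spec = next(iter(specs(1, start_seed=7)))
        a = optimize(random_problem(spec))
        b = optimize(random_problem(spec))
        assert a == b


class TestBudget:
    def test_zero_budget_is_wildtype(self):
        prob = random_problem(FixtureSpec(seed=5, length=12, n_mutable=4))
        v = optimize_budget(prob, 0, mode="at_most")
        assert v.sequence == prob.sequence
        v = optimize_budget(prob, 0, mode="exact")
        assert v.sequence == prob.sequence

    def test_budget_matches_brute_force_slices(self):
        for spec in specs(15, start_seed=200):
            prob = random_problem(spec)
            unconstrained = brute_force(prob).minimum
            for s in range(4):
                # exact-s slice
                try:
                    exact = optimize_budget(prob, s, mode="exact").total_score
                except InfeasibleError:
                    exact = None
                want = [
                    naive_total(prob, sq)
                    for sq in ed.enumerate_variants(prob.M, s)
                ]
                assert exact == (min(want) if want else None), (spec.seed, s)
                # at-most-s via enumeration over smaller slices
                atmost = optimize_budget(prob, s, mode="at_most").total_score
                pool = [
                    naive_total(prob, sq)
                    for kk in range(s + 1)
                    for sq in ed.enumerate_variants(prob.M, kk)
                ]
                assert atmost == min(pool), (spec.seed, s)
                assert exact is None or atmost <= exact
            n_mut = sum(len(s_) > 1 for s_ in prob.M.allowed)
            assert optimize_budget(prob, n_mut, mode="at_most").total_score == unconstrained

    def test_min_over_exact_equals_unconstrained(self):
        for spec in specs(8, start_seed=300):
            prob = random_problem(spec)
            n_mut = sum(len(s) > 1 for s in prob.M.allowed)
            exacts = []
            for s in range(n_mut + 1):
                try:
                    exacts.append(optimize_budget(prob, s, mode="exact").total_score)
                except InfeasibleError:
                    pass
            assert min(exacts) == optimize(prob).total_score

    def test_monotone_in_budget(self):
        prob = random_problem(FixtureSpec(seed=9, length=13, n_mutable=5))
        best = [optimize_budget(prob, s, mode="at_most").total_score for s in range(5)]
        assert best == sorted(best, reverse=True)

    def test_negative_budget_rejected(self):
        prob = random_problem(FixtureSpec(seed=9, length=13))
        with pytest.raises(ValueError):
            optimize_budget(prob, -1)

    def test_integer_substitution_costs(self):
        """Generalized cost: expensive positions are skipped under a tight bound."""
        spec = FixtureSpec(seed=21, length=12, n_mutable=4)
        base = random_problem(spec)
        costs = {}
        for i, (wt, sset) in enumerate(zip(base.sequence, base.M.allowed), start=1):
            for a in sset - {wt}:
                costs[(i, a)] = 1 + (i % 3)

        prob = DesignProblem(
            sequence=base.sequence,
            scorer=base.scorer,
            M=base.M,
            sub_cost=lambda i, a: costs[(i, a)],
            budget=2,
            budget_mode="at_most",
        )
        v = optimize(prob)
        # brute-force the cost-constrained space
        feas = []
        from itertools import product

        choices = [sorted(s) for s in base.M.allowed]
        for tup in product(*choices):
            sq = "".join(tup)
            cost = sum(
                costs[(i, ch)]
                for i, (ch, wt) in enumerate(zip(sq, base.sequence), start=1)
                if ch != wt
            )
            if cost <= 2:
                feas.append(naive_total(base, sq))
        assert v.total_score == min(feas)
        assert v.sub_cost_total <= 2


class TestNearOptimal:
    def test_trivial_map_yields_only_wildtype(self):
        prob = random_problem(FixtureSpec(seed=2, length=11, n_mutable=0))
        vs = enumerate_near_optimal(prob, epsilon=0, limit=10)
        assert [v.sequence for v in vs] == [prob.sequence]

    @pytest.mark.parametrize("epsilon", [0, 1, 2])
    def test_matches_brute_force_filter(self, epsilon):
        for spec in specs(12, start_seed=400):
            prob = random_problem(spec)
            bf = brute_force(prob)
            vs = enumerate_near_optimal(prob, epsilon=epsilon, limit=100000)
            got = sorted(v.sequence for v in vs)
            from itertools import product

            choices = [sorted(s) for s in prob.M.allowed]
            want = sorted(
                "".join(t)
                for t in product(*choices)
                if naive_total(prob, "".join(t)) <= bf.minimum + epsilon
            )
            assert got == want, (spec.seed, epsilon)
            # ranking: scores non-decreasing; wild type first among score ties
            scores = [v.total_score for v in vs]
            assert scores == sorted(scores)
            if vs[0].total_score == naive_total(prob, prob.sequence):
                assert vs[0].sequence == prob.sequence

    def test_limit_truncates_after_ranking(self):
        prob = random_problem(FixtureSpec(seed=8, length=12, n_mutable=4))
        all_vs = enumerate_near_optimal(prob, epsilon=2, limit=100000)
        head = enumerate_near_optimal(prob, epsilon=2, limit=3)
        assert [v.sequence for v in head] == [v.sequence for v in all_vs[:3]]

    def test_bad_limit_rejected(self):
        prob = random_problem(FixtureSpec(seed=8, length=12))
        with pytest.raises(ValueError):
            enumerate_near_optimal(prob, epsilon=0, limit=0)


class TestWindowCap:
    def test_no_window_exceeds_wildtype(self):
        for spec in specs(10, start_seed=500):
            prob = random_problem(spec)
            capped = DesignProblem(
                sequence=prob.sequence, scorer=prob.scorer, M=prob.M, window_cap=True
            )
            caps = capped.wildtype_window_counts()
            for v in enumerate_near_optimal(capped, epsilon=2, limit=50):
                w = capped.window
                for j in range(capped.n - w + 1):
                    assert prob.scorer(v.sequence[j : j + w]) <= caps[j]

    def test_cap_agrees_with_filtered_brute_force(self):
        spec = FixtureSpec(seed=31, length=12, n_mutable=4)
        prob = random_problem(spec)
        capped = DesignProblem(
            sequence=prob.sequence, scorer=prob.scorer, M=prob.M, window_cap=True
        )
        assert optimize(capped).total_score == brute_force(capped).minimum


class TestPlanted:
    def test_single_plant_cleared_by_one_substitution(self):
        spec = FixtureSpec(seed=4, length=11, n_alleles=2, planted=[(6, "W", "A")])
        pp = planted_problem(spec)
        assert pp.expected_optimum[1] == 0
        v = optimize_budget(pp.problem, 1, mode="exact")
        assert v.total_score == 0

    def test_promiscuous_position_clears_overlapping_windows(self):
        # both hot windows share position 7; fixing it zeroes the whole profile
        spec = FixtureSpec(seed=6, length=12, n_alleles=3, planted=[(7, "W", "G")])
        pp = planted_problem(spec)
        wt_total = naive_total(pp.problem, pp.problem.sequence)
        assert wt_total > 0
        v = optimize_budget(pp.problem, 1, mode="exact")
        assert v.total_score == 0
        assert v.substitutions == [(7, "W", "G")]

    def test_closed_form_recovered_and_brute_force_agrees(self):
        for seed in range(6):
            spec = FixtureSpec(
                seed=seed,
                length=12 + seed % 3,
                n_alleles=1 + seed % 3,
                planted=[(4, "W", "A"), (9 + seed % 3, "W", "G")],
            )
            pp = planted_problem(spec)
            for k, expected in pp.expected_optimum.items():
                v = optimize_budget(pp.problem, k, mode="exact")
                assert v.total_score == expected, (seed, k)
                bf = brute_force(pp.problem, k=k)
                assert bf.minimum == expected, (seed, k)

    def test_inconsistent_plant_rejected(self):
        with pytest.raises(ValueError, match="hot"):
            planted_problem(
                FixtureSpec(seed=0, length=12, planted=[(3, "W", "W")])
            )


class TestBruteForce:
    def test_single_position_histogram(self):
        spec = FixtureSpec(seed=11, length=9, n_mutable=1, max_allowed=3)
        prob = random_problem(spec)
        bf = brute_force(prob)
        assert sum(bf.histogram.values()) == 3

    def test_histogram_total_equals_count_variants(self):
        prob = random_problem(FixtureSpec(seed=13, length=12, n_mutable=4))
        for k in (1, 2):
            bf = brute_force(prob, k=k)
            assert sum(bf.histogram.values()) == ed.count_variants(prob.M, k)

    def test_guard_rejected_with_size(self):
        M = ed.AllowedResidues("A" * 12, [frozenset(AA[:10])] * 12)
        prob = DesignProblem(
            sequence="A" * 12,
            scorer=CallableScorer(lambda w: 0, window=9, alphabet=AA),
            M=M,
        )
        with pytest.raises(EnumerationGuardError, match="10"):
            brute_force(prob, guard=1000)
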