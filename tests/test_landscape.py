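"""Welch/Dunnett-T3 statistics, letters, accessibility, trajectories, epistasis."""

import itertools

import numpy as np
import pytest
from scipy import stats

from evoland.landscape import (
    LandscapeMeasurement,
    accessibility_summary,
    all_genotypes,
    assign_statistical_groups,
    classify_edges,
    compact_letter_display,
    dunnett_t3_adjust,
    enumerate_trajectories,
    forward_edges,
    greedy_best_trajectory,
    multiplicative_epistasis,
    sidak_adjust,
    smm_sf,
    welch_test,
)
from evoland.simulate import simulate_landscape_replicates


def _measurement(truth: dict, n_reps=8, cv=0.05, seed=0, loci=None):
    loci = loci or tuple(f"L{i}" for i in range(len(next(iter(truth)))))
    return simulate_landscape_replicates(truth, n_reps=n_reps, cv=cv, seed=seed, loci=loci)


class TestCombinatorics:
    @pytest.mark.parametrize("L", [1, 2, 3, 4])
    def test_genotype_and_edge_counts_match_closed_forms(self, L):
        assert len(all_genotypes(L)) == 2**L
        assert len(forward_edges(L)) == L * 2 ** (L - 1)


class TestWelch:
    def test_matches_scipy_unequal_variance_t(self, rng):
        a, b = rng.normal(1, 0.2, 9), rng.normal(1.4, 0.5, 6)
        t, df, p = welch_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_equal_variance_equal_n_matches_pooled_t(self, rng):
        a = rng.normal(0, 1, 8)
        b = a + 0.5  # identical spread, equal n
        t, df, p = welch_test(a, b)
        pooled = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(pooled.statistic, abs=1e-12)
        assert df == pytest.approx(2 * a.size - 2, abs=1e-9)

    def test_identical_samples_give_t_zero_p_one(self):
        t, _, p = welch_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (t, p) == (0.0, 1.0)

    def test_clear_separation_is_extreme_under_permutation(self):
        a, b = [1.0, 1.01, 0.99], [2.0, 2.01, 1.99]
        t_obs, _, p = welch_test(a, b)
        assert p < 1e-4
        pooled = np.array(a + b)
        t_perms = []
        for comb in itertools.combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(comb)] = True
            t_perm, _, _ = welch_test(pooled[mask], pooled[~mask])
            t_perms.append(abs(t_perm))
        assert abs(t_obs) == pytest.approx(max(t_perms))


class TestDunnettT3:
    def test_single_comparison_equals_raw_p(self):
        t, df = 2.3, 11.0
        raw = 2 * stats.t.sf(t, df)
        adj = dunnett_t3_adjust([t], [df], m=1)[0]
        assert adj == pytest.approx(raw, rel=1e-5)

    def test_smm_adjustment_at_most_bonferroni(self):
        for m in [3, 10, 120]:
            for t, df in [(3.0, 10.0), (4.5, 14.0), (5.5, 25.0)]:
                raw = 2 * stats.t.sf(t, df)
                adj = dunnett_t3_adjust([t], [df], m=m)[0]
                assert adj <= min(1.0, m * raw) + 1e-12
                assert adj >= raw - 1e-12

    def test_adjusted_p_monotone_in_t(self):
        ts = np.linspace(0.5, 6.0, 12)
        adj = dunnett_t3_adjust(ts, np.full_like(ts, 12.0), m=20)
        assert np.all(np.diff(adj) <= 1e-12)

    def test_sidak_fallback_agrees_within_two_percent_at_large_df(self):
        # the Sidak approximation treats the comparisons as independent, which
        # matches the shared-studentizer SMM once df is large; at small df the
        # SMM is deliberately less conservative
        for t, df in [(3.5, 300.0), (4.0, 120.0), (4.5, 200.0)]:
            raw = 2 * stats.t.sf(t, df)
            smm = dunnett_t3_adjust([t], [df], m=120)[0]
            sidak = sidak_adjust(raw, 120)
            assert smm == pytest.approx(sidak, rel=0.02)
        # and it is strictly less conservative at the study's small df
        small = dunnett_t3_adjust([4.2], [14.0], m=120)[0]
        assert small < sidak_adjust(2 * stats.t.sf(4.2, 14.0), 120)

    def test_smm_with_one_comparison_is_t_distribution(self):
        for q, df in [(1.0, 5.0), (2.5, 14.0), (4.0, 40.0)]:
            assert smm_sf(q, 1, df) == pytest.approx(2 * stats.t.sf(q, df), rel=1e-5)


class TestCompactLetters:
    def test_three_separated_groups_get_three_letters(self):
        sig = {(i, j): True for i, j in itertools.combinations(range(3), 2)}
        assert compact_letter_display(3, sig) == ["a", "b", "c"]

    def test_no_significant_pairs_share_one_letter(self):
        sig = {(i, j): False for i, j in itertools.combinations(range(4), 2)}
        assert compact_letter_display(4, sig) == ["a", "a", "a", "a"]

    def test_random_matrices_satisfy_consistency_and_clique_cover(self, rng):
        # oracle: letters must be cliques of the non-significance graph,
        # contained in some maximal clique, covering every item
        n = 6
        for _ in range(25):
            sig = {
                (i, j): bool(rng.random() < 0.4)
                for i, j in itertools.combinations(range(n), 2)
            }
            letters = compact_letter_display(n, sig)
            assert all(letters)
            for (i, j), is_sig in sig.items():
                shared = set(letters[i]) & set(letters[j])
                assert bool(shared) == (not is_sig)
            # brute-force maximal non-significant cliques
            def compatible(sub):
                return all(
                    not sig[(a, b)]
                    for a, b in itertools.combinations(sorted(sub), 2)
                )
            classes = {}
            for i, ls in enumerate(letters):
                for letter in ls:
                    classes.setdefault(letter, set()).add(i)
            maximal = [
                set(sub)
                for r in range(1, n + 1)
                for sub in itertools.combinations(range(n), r)
                if compatible(sub)
                and not any(
                    compatible(set(sub) | {k}) for k in range(n) if k not in sub
                )
            ]
            for members in classes.values():
                assert compatible(members)
                assert any(members <= mc for mc in maximal)


class TestEdgesAndAccessibility:
    def test_four_locus_landscape_emits_thirty_two_edges(self, reference_measurement):
        edges = classify_edges(reference_measurement)
        assert len(edges) == 32

    def test_single_locus_landscape_has_one_edge(self):
        meas = _measurement({(0,): 0.1, (1,): 0.4})
        edges = classify_edges(meas)
        assert len(edges) == 1
        assert edges[0].klass == "significant_increase"

    def test_two_locus_strongly_additive_landscape_all_increases(self):
        truth = {(0, 0): 0.05, (1, 0): 0.2, (0, 1): 0.25, (1, 1): 0.9}
        edges = classify_edges(_measurement(truth, n_reps=10, cv=0.05))
        assert all(e.klass == "significant_increase" for e in edges)

    def test_missing_genotype_reported_by_name(self):
        meas = LandscapeMeasurement(
            loci=("A", "B"),
            replicates={(0, 0): [0.1, 0.11], (1, 1): [0.4, 0.41]},
        )
        with pytest.raises(ValueError, match="missing genotypes"):
            classify_edges(meas)

    def test_accessibility_counts_match_brute_force(self, rng):
        for L in (2, 3, 4):
            truth = {
                g: float(rng.uniform(0.05, 0.5)) for g in all_genotypes(L)
            }
            meas = _measurement(truth, n_reps=6, cv=0.1, seed=int(rng.integers(1e6)))
            edges = classify_edges(meas)
            n_acc, n_tot, reachable = accessibility_summary(edges)
            # oracle: enumerate edges directly
            acc = [e for e in edges if e.klass != "significant_decrease"]
            assert n_tot == L * 2 ** (L - 1)
            assert n_acc == len(acc)
            expect_reach = {(0,) * L} | {e.to for e in acc}
            assert reachable == expect_reach

    def test_strict_mode_requires_significant_increase(self, reference_measurement):
        edges = classify_edges(reference_measurement)
        n_strict, _, _ = accessibility_summary(edges, mode="increase")
        n_lenient, _, _ = accessibility_summary(edges, mode="not-decrease")
        assert n_strict <= n_lenient


class TestTrajectories:
    def test_all_orderings_enumerated(self, reference_measurement):
        edges = classify_edges(reference_measurement)
        traj = enumerate_trajectories(edges, reference_measurement.loci)
        assert len(traj) == 24

    def test_single_locus_has_one_ordering(self):
        edges = classify_edges(_measurement({(0,): 0.1, (1,): 0.4}))
        assert len(enumerate_trajectories(edges)) == 1

    def test_orderings_through_deleterious_edge_flagged_by_count(self):
        # deterministic classes: construct edges manually around one bad step
        meas = _measurement(
            {
                (0, 0): 0.10,
                (1, 0): 0.50,
                (0, 1): 0.15,
                (1, 1): 0.30,
            },
            n_reps=10,
            cv=0.02,
        )
        edges = classify_edges(meas)
        bad = [e for e in edges if e.klass == "significant_decrease"]
        assert len(bad) == 1  # only the step from (1,0) to (1,1) loses fitness
        traj = enumerate_trajectories(edges)
        # for L=2 each edge is used by exactly one ordering
        assert (traj["n_decrease_steps"] > 0).sum() == 1
        assert (~traj["fully_accessible"]).sum() == 1

    def test_factorial_guard(self, reference_measurement):
        edges = classify_edges(reference_measurement)
        with pytest.raises(ValueError, match="guard"):
            enumerate_trajectories(edges, max_loci=3)


class TestGreedy:
    def test_additive_landscape_orders_by_decreasing_effect(self):
        # independent multiplicative effects 4x, 2x, 1.5x
        effects = [4.0, 2.0, 1.5]
        truth = {
            g: 0.02 * np.prod([effects[i] ** g[i] for i in range(3)])
            for g in all_genotypes(3)
        }
        meas = _measurement(truth, cv=0.0)
        assert greedy_best_trajectory(meas) == [0, 1, 2]

    def test_equal_effects_tie_broken_by_locus_order_with_warning(self):
        truth = {g: 0.1 * (2.0 ** sum(g)) for g in all_genotypes(2)}
        meas = _measurement(truth, cv=0.0)
        with pytest.warns(UserWarning, match="tie"):
            assert greedy_best_trajectory(meas) == [0, 1]

    def test_greedy_choice_is_per_step_maximal_on_random_landscapes(self, rng):
        for _ in range(10):
            L = 4
            truth = {g: float(rng.uniform(0.05, 0.5)) for g in all_genotypes(L)}
            meas = _measurement(truth, cv=0.0, seed=0)
            path = greedy_best_trajectory(meas)
            g = [0] * L
            for step in path:
                options = {
                    i: truth[tuple(g[:i] + [1] + g[i + 1 :])]
                    for i in range(L)
                    if g[i] == 0
                }
                assert truth[
                    tuple(g[:step] + [1] + g[step + 1 :])
                ] == max(options.values())
                g[step] = 1

    def test_greedy_avoids_cheater_intermediate(self, reference_measurement):
        # only the first locus helps alone; the deletion helps only after it;
        # the path must skip the second locus (the cheater) until last
        path = greedy_best_trajectory(reference_measurement)
        loci = reference_measurement.loci
        assert loci[path[0]] == "gapA*"
        assert loci[path[-1]] == "rpoS*"


class TestEpistasis:
    def test_multiplicative_landscape_has_ratio_one(self):
        effects = [1.5, 2.0, 1.2, 1.1]
        truth = {
            g: 0.01 * np.prod([effects[i] ** g[i] for i in range(4)])
            for g in all_genotypes(4)
        }
        meas = _measurement(truth, cv=0.0)
        summary = multiplicative_epistasis(meas, n_boot=100)
        assert summary.ratio == pytest.approx(1.0, abs=1e-9)

    def test_expected_fold_equals_product_oracle(self, rng):
        for _ in range(5):
            truth = {g: float(rng.uniform(0.05, 0.5)) for g in all_genotypes(4)}
            meas = _measurement(truth, cv=0.0)
            summary = multiplicative_epistasis(meas, n_boot=10)
            founder = truth[(0, 0, 0, 0)]
            product = np.prod(
                [
                    truth[tuple(1 if j == i else 0 for j in range(4))] / founder
                    for i in range(4)
                ]
            )
            assert summary.expected_fold == pytest.approx(product, rel=1e-12)

    def test_fourfold_expectation_with_thirtytwofold_observation(self):
        # single-mutant folds {4,1,1,1} and a 32-fold full mutant: ratio 8
        truth = {g: 0.01 for g in all_genotypes(4)}
        truth[(1, 0, 0, 0)] = 0.04
        truth[(1, 1, 1, 1)] = 0.32
        meas = _measurement(truth, cv=0.0)
        summary = multiplicative_epistasis(meas, n_boot=10)
        assert summary.expected_fold == pytest.approx(4.0)
        assert summary.observed_fold == pytest.approx(32.0)
        assert summary.ratio == pytest.approx(8.0)

    def test_groups_share_letters_iff_not_significant(self, reference_measurement):
        letters = assign_statistical_groups(reference_measurement)
        edges = classify_edges(reference_measurement)
        for e in edges:
            shared = set(letters[e.frm]) & set(letters[e.to])
            if e.klass == "not_significant":
                assert shared
            else:
                assert not shared
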