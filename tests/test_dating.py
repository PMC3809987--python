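"""Penalized-likelihood dating: objective and penalty arithmetic, exact-data
recovery, constraint activation, smoothing behavior, a grid-search oracle,
cross-validation, and PROFILE summaries."""

import itertools

import numpy as np
import pytest

from chronopl import (
    Calibration,
    CalibrationSet,
    Chronogram,
    CladeSpec,
    InfeasibleCalibrationError,
    PLConfig,
    PLProblem,
    RateModel,
    assign_rates,
    cross_validate,
    crown_age,
    fit_pl,
    is_ultrametric,
    make_calibration_set,
    mrca,
    penalty,
    pl_objective,
    profile,
    simulate_chronogram,
    to_phylogram,
)
from chronopl.treeio import Tree, parse_newick


def root_window(chron, lo=0.8, hi=1.2):
    taxa = chron.tree.clade_leaves(chron.tree.root)
    return CalibrationSet(
        [
            Calibration(
                CladeSpec("root", taxa),
                min_age=lo * chron.root_age,
                max_age=hi * chron.root_age,
            )
        ]
    )


def grid_oracle_best(problem, n_grid=50):
    """Lower bound on the attainable PL objective: grid the free internal
    ages (root fixed), set each branch rate to its conditional Poisson MLE
    x_k/(L t_k), and evaluate the full penalized objective."""
    tree = problem.phylogram
    L = problem.config.num_sites
    bounds = problem.node_bounds()
    root = tree.root
    root_age = next(
        b[0] for nid, b in bounds.items() if nid == root
    )
    free = [
        n for n in tree.postorder() if not tree.nodes[n].is_leaf and n != root
    ]
    best = -np.inf
    axes = [np.linspace(root_age * 1e-3, root_age * 0.999, n_grid)] * len(free)
    for combo in itertools.product(*axes):
        ages = {n: 0.0 for n in tree.leaves()}
        ages[root] = root_age
        ages.update(dict(zip(free, combo)))
        ok = all(
            ages[tree.nodes[nid].parent] > ages[nid] for nid in tree.branches()
        )
        if not ok:
            continue
        rates = {}
        for nid in tree.branches():
            t = ages[tree.nodes[nid].parent] - ages[nid]
            rates[nid] = max(problem.x[nid] / (L * t), 1e-12)
        val = pl_objective(problem, ages, rates)
        best = max(best, val)
    return best


class TestPenalty:
    def test_equal_rates_zero(self, strict_phylogram):
        rates = {n: 0.01 for n in strict_phylogram.branches()}
        assert penalty(rates, strict_phylogram, "log") == pytest.approx(0.0)
        assert penalty(rates, strict_phylogram, "additive") == pytest.approx(0.0)

    def test_single_parent_child_pair_hand_value(self):
        # ((A,B),C): the cherry's two child branches have the internal
        # branch as parent; root variance uses the root's two children
        tree = parse_newick("((A:1,B:1):1,C:1);")
        internal = next(
            n for n in tree.postorder()
            if not tree.nodes[n].is_leaf and n != tree.root
        )
        e = np.e
        rates = {n: e for n in tree.branches()}
        a_leaf = next(n for n in tree.leaves() if tree.nodes[n].label == "A")
        rates[a_leaf] = e**2  # one (log e^2 - log e)^2 = 1 contribution
        expected_root_var = 0.0  # root children (internal, C) both at rate e
        assert penalty(rates, tree, "log") == pytest.approx(1.0 + expected_root_var)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_recomputation(self, seed):
        chron = simulate_chronogram(10, 50.0, seed)
        tree = chron.to_tree()
        rng = np.random.default_rng(seed)
        rates = {n: float(rng.lognormal(-4.5, 0.8)) for n in tree.branches()}
        for kind, f in (("log", np.log), ("additive", lambda x: x)):
            expected = 0.0
            for nid in tree.branches():
                p = tree.nodes[nid].parent
                if p != tree.root:
                    expected += (f(rates[nid]) - f(rates[p])) ** 2
            vals = [f(rates[c]) for c in tree.nodes[tree.root].children]
            expected += np.var(vals)
            assert penalty(rates, tree, kind) == pytest.approx(expected, rel=1e-12)


class TestPLObjective:
    def _single_branch_problem(self):
        # a 3-leaf tree but we evaluate the Poisson kernel analytically
        tree = parse_newick("((A:0.01,B:0.01):0.01,C:0.02);")
        cals = CalibrationSet(
            [Calibration(CladeSpec("root", {"A", "B", "C"}), fixed_age=10.0)]
        )
        return PLProblem(tree, cals, PLConfig(smoothing=0.9, num_sites=1000))

    def test_poisson_kernel_hand_value(self):
        # x=10 and mean r*L*t=10 contributes 10 log 10 - 10 = 13.0259...
        tree = parse_newick("(A:0.01,B:0.01);")
        cals = CalibrationSet(
            [Calibration(CladeSpec("root", {"A", "B"}), fixed_age=10.0)]
        )
        prob = PLProblem(tree, cals, PLConfig(smoothing=0.9, num_sites=1000))
        ages = {tree.root: 10.0, **{n: 0.0 for n in tree.leaves()}}
        rates = {n: 0.001 for n in tree.branches()}  # r*L*t = 10 per branch
        # two identical branches, equal rates => penalty 0
        expected = 2 * (10 * np.log(10) - 10)
        assert pl_objective(prob, ages, rates) == pytest.approx(expected, abs=1e-9)

    def test_equal_rates_is_pure_likelihood(self, small_chronogram):
        phylo = to_phylogram(
            small_chronogram, {n: 0.01 for n in small_chronogram.tree.branches()}
        )
        cals = root_window(small_chronogram)
        rates = {n: 0.01 for n in phylo.branches()}
        lo = PLProblem(phylo, cals, PLConfig(smoothing=1e-9, num_sites=1000))
        hi = PLProblem(phylo, cals, PLConfig(smoothing=1e6, num_sites=1000))
        a = pl_objective(lo, small_chronogram.ages, rates)
        b = pl_objective(hi, small_chronogram.ages, rates)
        assert a == pytest.approx(b, abs=1e-9)

    def test_larger_smoothing_lowers_objective_for_unequal_rates(
        self, small_chronogram
    ):
        phylo = to_phylogram(
            small_chronogram, {n: 0.01 for n in small_chronogram.tree.branches()}
        )
        cals = root_window(small_chronogram)
        rng = np.random.default_rng(0)
        rates = {n: float(rng.lognormal(-4.6, 0.5)) for n in phylo.branches()}
        vals = [
            pl_objective(
                PLProblem(phylo, cals, PLConfig(smoothing=lam, num_sites=1000)),
                small_chronogram.ages,
                rates,
            )
            for lam in (0.1, 10.0)
        ]
        assert vals[1] < vals[0]

    def test_nonpositive_duration_raises(self):
        prob = self._single_branch_problem()
        tree = prob.phylogram
        ages = {n: 0.0 for n in tree.nodes}
        ages[tree.root] = 0.0  # zero-duration branches
        rates = {n: 0.01 for n in tree.branches()}
        with pytest.raises(ValueError):
            pl_objective(prob, ages, rates)


class TestFitPL:
    def test_exact_strict_clock_recovery(self):
        chron = simulate_chronogram(12, 80.0, 5)
        r = 0.008
        phylo = to_phylogram(chron, {n: r for n in chron.tree.branches()})
        prob = PLProblem(
            phylo, root_window(chron), PLConfig(smoothing=0.9, num_sites=1500)
        )
        sol = fit_pl(prob)
        assert sol.converged
        for nid, true_age in chron.ages.items():
            if true_age > 0:
                assert sol.chronogram.ages[nid] == pytest.approx(true_age, rel=0.01)
        for rate in sol.rates.values():
            assert rate == pytest.approx(r, rel=0.01)

    def test_min_age_constraint_activates(self):
        chron = simulate_chronogram(10, 60.0, 9)
        phylo = to_phylogram(chron, {n: 0.01 for n in chron.tree.branches()})
        # pick a non-root internal node and demand it be older than truth
        tree = chron.tree
        nid = next(
            n for n in tree.postorder()
            if not tree.nodes[n].is_leaf and n != tree.root
            and chron.ages[n] < 0.5 * chron.root_age
        )
        forced = chron.ages[nid] * 1.5
        cals = CalibrationSet(
            list(root_window(chron))
            + [Calibration(CladeSpec("forced", tree.clade_leaves(nid)), min_age=forced)]
        )
        sol = fit_pl(PLProblem(phylo, cals, PLConfig(smoothing=0.9, num_sites=1500)))
        est = sol.chronogram.ages[mrca(sol.chronogram.tree, tree.clade_leaves(nid))]
        assert est == pytest.approx(forced, abs=1e-6)
        assert any(f"min={forced:.8g}" in a for a in sol.active_constraints)

    def test_smoothing_shrinks_rate_spread(self):
        chron = simulate_chronogram(15, 60.0, 2)
        rates = assign_rates(chron, RateModel("iid_lognormal", 0.01, 0.6), 3)
        phylo = to_phylogram(chron, rates)
        spreads = {}
        for lam in (0.1, 1e6):
            sol = fit_pl(
                PLProblem(
                    phylo, root_window(chron), PLConfig(smoothing=lam, num_sites=1500)
                )
            )
            rv = np.array(list(sol.rates.values()))
            spreads[lam] = rv.max() / rv.min()
        assert spreads[1e6] < spreads[0.1]

    def test_solution_is_ultrametric_and_feasible(self):
        chron = simulate_chronogram(15, 90.0, 4)
        rates = assign_rates(chron, RateModel("autocorrelated_lognormal", 0.006, 0.3), 5)
        phylo = to_phylogram(chron, rates)
        cals = make_calibration_set(chron, "full", 6)
        sol = fit_pl(PLProblem(phylo, cals, PLConfig(smoothing=0.9, num_sites=1500)))
        assert is_ultrametric(sol.chronogram.to_tree(), tol=1e-6)
        for cal in cals:
            node = mrca(sol.chronogram.tree, cal.clade.taxa)
            age = sol.chronogram.ages[node]
            if cal.min_age is not None:
                assert age >= cal.min_age - 1e-6
            if cal.max_age is not None:
                assert age <= cal.max_age + 1e-6

    def test_best_of_restarts_reported(self):
        chron = simulate_chronogram(8, 40.0, 1)
        rates = assign_rates(chron, RateModel("iid_lognormal", 0.01, 0.4), 2)
        phylo = to_phylogram(chron, rates)
        sol = fit_pl(
            PLProblem(
                phylo, root_window(chron),
                PLConfig(smoothing=0.9, num_sites=1500, restarts=4),
            )
        )
        assert len(sol.restart_objectives) == 4
        assert sol.objective >= max(sol.restart_objectives) - 1e-6

    def test_lambda_zero_limit_gives_per_branch_mle_rates(self):
        # tiny smoothing: fitted rates approach x_k/(L t_k) at fitted ages
        chron = simulate_chronogram(6, 30.0, 3)
        rates = assign_rates(chron, RateModel("iid_lognormal", 0.01, 0.3), 4)
        phylo = to_phylogram(chron, rates)
        prob = PLProblem(
            phylo, root_window(chron), PLConfig(smoothing=1e-9, num_sites=1500)
        )
        sol = fit_pl(prob)
        tree = sol.chronogram.tree
        for nid in phylo.branches():
            node = phylo.nodes[nid]
            t = sol.chronogram.ages[node.parent] - (
                0.0 if node.is_leaf else sol.chronogram.ages[nid]
            )
            mle = prob.x[nid] / (1500 * t)
            if mle > 1e-10:
                assert sol.rates[nid] == pytest.approx(mle, rel=1e-4)

    def test_infeasible_calibrations_raise_before_fit(self):
        chron = simulate_chronogram(8, 50.0, 0)
        tree = chron.tree
        nid = next(
            n for n in tree.postorder()
            if not tree.nodes[n].is_leaf and n != tree.root
        )
        cals = CalibrationSet(
            [
                Calibration(
                    CladeSpec("root", tree.clade_leaves(tree.root)), max_age=20.0
                ),
                Calibration(
                    CladeSpec("deep", tree.clade_leaves(nid)), min_age=30.0
                ),
            ]
        )
        phylo = to_phylogram(chron, {n: 0.01 for n in tree.branches()})
        with pytest.raises(InfeasibleCalibrationError):
            fit_pl(PLProblem(phylo, cals, PLConfig(num_sites=1500)))

    def test_polytomy_rejected(self):
        tree = parse_newick("(A:1,B:1,C:1);")
        cals = CalibrationSet(
            [Calibration(CladeSpec("root", {"A", "B", "C"}), fixed_age=10.0)]
        )
        with pytest.raises(ValueError):
            fit_pl(PLProblem(tree, cals, PLConfig(num_sites=100)))

    @pytest.mark.parametrize("seed", range(3))
    def test_beats_grid_oracle(self, seed):
        # 4-taxon problems with the root age fixed: the optimizer must meet
        # or beat a dense grid over the free ages with profiled rates
        chron = simulate_chronogram(4, 20.0, seed)
        rates = assign_rates(chron, RateModel("iid_lognormal", 0.02, 0.4), seed + 10)
        phylo = to_phylogram(chron, rates)
        cals = CalibrationSet(
            [
                Calibration(
                    CladeSpec("root", chron.tree.clade_leaves(chron.tree.root)),
                    fixed_age=chron.root_age,
                )
            ]
        )
        prob = PLProblem(phylo, cals, PLConfig(smoothing=0.9, num_sites=1000))
        sol = fit_pl(prob)
        assert sol.objective >= grid_oracle_best(prob, n_grid=50) - 1e-4

    def test_scale_consistency(self):
        # multiplying calibration ages by c scales ages by c, rates by 1/c
        chron = simulate_chronogram(8, 50.0, 6)
        rates = assign_rates(chron, RateModel("iid_lognormal", 0.01, 0.3), 7)
        phylo = to_phylogram(chron, rates)
        c = 3.0
        sols = []
        for scale in (1.0, c):
            cals = CalibrationSet(
                [
                    Calibration(
                        CladeSpec("root", chron.tree.clade_leaves(chron.tree.root)),
                        fixed_age=scale * chron.root_age,
                    )
                ]
            )
            sols.append(
                fit_pl(PLProblem(phylo, cals, PLConfig(smoothing=0.9, num_sites=1500)))
            )
        base, scaled = sols
        # invariance is exact in the objective; agreement is limited by the
        # optimizer's termination tolerance
        for nid, age in base.chronogram.ages.items():
            assert scaled.chronogram.ages[nid] == pytest.approx(c * age, rel=1e-3, abs=1e-4)
        for nid, r in base.rates.items():
            assert scaled.rates[nid] == pytest.approx(r / c, rel=1e-3)


class TestCrossValidate:
    def _clock_problem(self, lam=0.9):
        chron = simulate_chronogram(7, 40.0, 8)
        phylo = to_phylogram(chron, {n: 0.01 for n in chron.tree.branches()})
        return PLProblem(
            phylo,
            root_window(chron),
            PLConfig(smoothing=lam, num_sites=1500, restarts=2),
        )

    def test_clock_limit_prefers_large_lambda(self):
        prob = self._clock_problem()
        grid = [0.1, 1.0, 100.0]
        scores = cross_validate(prob, grid)
        assert scores[100.0] <= min(scores.values()) + 1e-6

    def test_scores_finite_nonnegative(self):
        chron = simulate_chronogram(6, 30.0, 12)
        rates = assign_rates(chron, RateModel("iid_lognormal", 0.01, 0.5), 13)
        phylo = to_phylogram(chron, rates)
        prob = PLProblem(
            phylo, root_window(chron), PLConfig(num_sites=1500, restarts=2)
        )
        scores = cross_validate(prob, [0.5, 2.0])
        for v in scores.values():
            assert np.isfinite(v) and v >= 0


class TestProfile:
    def _cherry_chron(self, age):
        tree = Tree()
        root = tree.add_node()
        tree.add_node(root, label="A")
        tree.add_node(root, label="B")
        return Chronogram(tree, {root: age, **{n: 0.0 for n in tree.leaves()}})

    def test_single_tree(self):
        summary = profile([self._cherry_chron(10.0)], [CladeSpec("ab", {"A", "B"})])
        row = summary["ab"]
        assert row.mean == pytest.approx(10.0)
        assert row.sd == 0.0 and row.n_valid == 1

    def test_two_trees_hand_arithmetic(self):
        chrons = [self._cherry_chron(10.0), self._cherry_chron(20.0)]
        row = profile(chrons, [CladeSpec("ab", {"A", "B"})])["ab"]
        assert row.mean == pytest.approx(15.0)
        assert row.sd == pytest.approx(7.0711, abs=1e-4)

    def test_missing_clades_excluded(self):
        chrons = [self._cherry_chron(10.0), self._cherry_chron(12.0)]
        summary = profile(
            chrons,
            [CladeSpec("ab", {"A", "B"}), CladeSpec("cd", {"C", "D"})],
        )
        assert summary["ab"].n_valid == 2
        assert summary["cd"].n_valid == 0 and summary["cd"].mean is None
        frame = summary.to_frame()
        assert set(frame["clade"]) == {"ab", "cd"}
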